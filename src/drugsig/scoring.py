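"""Ligand-based compound-protein interaction scoring.

A compound is scored against a protein by comparing its substructure
fingerprint to every predicted ligand of the protein's binding sites.  The
strongest match (maximum Tanimoto coefficient over all site ligands) and the
confidence score of the site it came from are combined into a single
interaction score in [0, 1].  Repeating this over a proteome library yields
the compound's proteome-wide interaction signature (one matrix row).

Scoring protocols
-----------------
``product`` (default)
    score = maxTanimoto x site_score; rewards both chemical match and site
    confidence while staying in [0, 1].
``tanimoto_only``
    score = maxTanimoto; ignores site confidence.
``sitescore_weighted``
    score = 0.5 x maxTanimoto + 0.5 x site_score.

Ties in the maximum Tanimoto are broken by higher site score, then by
lexicographically smaller site id, so results are reproducible.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from drugsig.datatypes import (
    CompoundRecord,
    InteractionMatrix,
    ProteinSiteModel,
    as_fingerprint,
)

PROTOCOLS = ("product", "tanimoto_only", "sitescore_weighted")


def tanimoto(fp_a, fp_b) -> float:
    """Tanimoto coefficient |A&B| / |A|B| between two equal-length bit vectors.

    Defined as 0.0 when both fingerprints are empty (empty union), so that
    signatures stay finite.
    """
    a = as_fingerprint(fp_a)
    b = as_fingerprint(fp_b)
    if a.size != b.size:
        raise ValueError(f"fingerprint length mismatch: {a.size} vs {b.size}")
    inter = int(np.count_nonzero(a & b))
    union = int(np.count_nonzero(a | b))
    if union == 0:
        return 0.0
    return inter / union


def _combine(max_tanimoto: float, site_score: float, protocol: str) -> float:
    if protocol == "product":
        return max_tanimoto * site_score
    if protocol == "tanimoto_only":
        return max_tanimoto
    if protocol == "sitescore_weighted":
        return 0.5 * max_tanimoto + 0.5 * site_score
    raise ValueError(f"unknown scoring protocol {protocol!r}; choose from {PROTOCOLS}")


def score_interaction(
    compound: CompoundRecord, protein: ProteinSiteModel, protocol: str = "product"
) -> float:
    """Interaction score for one compound-protein pair.

    Scans every (site, ligand) pair, selects the pair with the maximum
    Tanimoto coefficient (ties: higher site score, then smaller site id) and
    combines that maximum with the selected site's confidence score under
    ``protocol``.
    """
    if protocol not in PROTOCOLS:
        raise ValueError(f"unknown scoring protocol {protocol!r}; choose from {PROTOCOLS}")
    best = None  # (tanimoto, site_score, site_id)
    for site in protein.sites:
        for fp in site.ligand_fingerprints:
            t = tanimoto(compound.fingerprint, fp)
            key = (t, site.site_score, site.site_id)
            if best is None or _better(key, best):
                best = key
    t, s, _ = best
    return _combine(t, s, protocol)


def _better(key, best) -> bool:
    t, s, sid = key
    bt, bs, bsid = best
    if t != bt:
        return t > bt
    if s != bs:
        return s > bs
    return sid < bsid


def build_matrix(
    compounds: Sequence[CompoundRecord],
    proteins: Sequence[ProteinSiteModel],
    protocol: str = "product",
) -> InteractionMatrix:
    """Score every compound against every protein: the interaction matrix.

    Row i is compound i's proteome-wide interaction signature.  Entries equal
    :func:`score_interaction` on the corresponding pair exactly; the
    computation is vectorised per protein (integer popcount matmul) for
    speed.
    """
    if not compounds or not proteins:
        raise ValueError("compounds and proteins must be non-empty")
    if protocol not in PROTOCOLS:
        raise ValueError(f"unknown scoring protocol {protocol!r}; choose from {PROTOCOLS}")
    ids = [c.compound_id for c in compounds]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate compound_ids in library")
    L = compounds[0].fingerprint.size
    for c in compounds:
        if c.fingerprint.size != L:
            raise ValueError(f"fingerprint length mismatch for {c.compound_id}")

    C = np.stack([c.fingerprint for c in compounds]).astype(np.int64)
    c_pop = C.sum(axis=1)

    scores = np.empty((len(compounds), len(proteins)), dtype=float)
    for j, protein in enumerate(proteins):
        # order ligand columns by (site_score desc, site_id asc) so that the
        # first argmax over equal Tanimoto values realises the tie rule
        ordered_sites = sorted(protein.sites, key=lambda s: (-s.site_score, s.site_id))
        lig_fps, lig_scores = [], []
        for site in ordered_sites:
            for fp in site.ligand_fingerprints:
                if fp.size != L:
                    raise ValueError(
                        f"ligand fingerprint length mismatch in {protein.protein_id}"
                    )
                lig_fps.append(fp)
                lig_scores.append(site.site_score)
        Lg = np.stack(lig_fps).astype(np.int64)
        l_pop = Lg.sum(axis=1)
        inter = C @ Lg.T
        union = c_pop[:, None] + l_pop[None, :] - inter
        with np.errstate(invalid="ignore", divide="ignore"):
            T = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
        pick = np.argmax(T, axis=1)
        t_max = T[np.arange(len(compounds)), pick]
        s_pick = np.asarray(lig_scores)[pick]
        if protocol == "product":
            scores[:, j] = t_max * s_pick
        elif protocol == "tanimoto_only":
            scores[:, j] = t_max
        else:
            scores[:, j] = 0.5 * t_max + 0.5 * s_pick
    return InteractionMatrix(ids, [p.protein_id for p in proteins], scores)
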