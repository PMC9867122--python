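"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates the shape of a real screening study: a compound
library with an approved/experimental split, per-protein binding-site models
whose predicted ligands share substructure with designated library compounds,
an indication catalog in which same-indication drugs share an
indication-specific chemical scaffold, four-parameter-logistic dose-response
plates with known GI50, and comparative-Ct qPCR tables with known fold
changes.  Everything is reproducible bit-for-bit from a single integer seed
(NumPy PCG64 streams).

Default library scale is the real study size divided by ten (245 approved +
1077 experimental compounds, 532 proteins) so the full pipeline runs in
seconds while preserving the library-structure proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from drugsig.datatypes import (
    APPROVED,
    BindingSite,
    CompoundRecord,
    EXPERIMENTAL,
    IndicationCatalog,
    Indication,
    ProteinSiteModel,
)

#: column schema for dose-response plate tables
DR_COLUMNS = ["drug_a", "conc_a", "drug_b", "conc_b", "replicate", "absorbance"]
#: column schema for qPCR Ct tables
CT_COLUMNS = ["sample", "condition", "gene", "ct"]

#: default housekeeping gene name used in generated Ct tables
HOUSEKEEPING_GENE = "beta-actin"


@dataclass(frozen=True)
class LibraryConfig:
    """Parameters of the synthetic compound/protein/indication world.

    Counts default to one tenth of the real study libraries; probabilities
    control how strongly same-indication chemistry is planted
    (``scaffold_share_prob``) and how noisy fingerprints are
    (``noise_bit_prob``).
    """

    n_approved: int = 245
    n_experimental: int = 1077
    n_proteins: int = 532
    n_sites_per_protein: tuple = (1, 4)
    n_ligands_per_site: tuple = (1, 5)
    fingerprint_length: int = 256
    n_indications: int = 40
    drugs_per_indication: tuple = (2, 6)
    scaffold_share_prob: float = 0.75
    noise_bit_prob: float = 0.01
    seed: int = 0

    def __post_init__(self):
        for name in ("n_approved", "n_experimental", "n_proteins", "n_indications"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.fingerprint_length < 64:
            raise ValueError("fingerprint_length must be >= 64")
        for name in ("scaffold_share_prob", "noise_bit_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")
        for name in ("n_sites_per_protein", "n_ligands_per_site", "drugs_per_indication"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ValueError(f"{name} must be a (lo, hi) range with 1 <= lo <= hi")
        if self.drugs_per_indication[1] > self.n_approved:
            raise ValueError(
                "drugs_per_indication upper bound exceeds the number of approved compounds"
            )


@dataclass
class SyntheticWorld:
    """A generated study: compounds, site models, catalog and the planted truth."""

    config: LibraryConfig
    compounds: list
    site_models: list
    catalog: IndicationCatalog
    truth: dict = field(default_factory=dict)

    @property
    def approved(self):
        return [c for c in self.compounds if c.status == APPROVED]

    @property
    def experimental(self):
        return [c for c in self.compounds if c.status == EXPERIMENTAL]


def _sample_bits(rng, length: int, k: int) -> np.ndarray:
    fp = np.zeros(length, dtype=bool)
    fp[rng.choice(length, size=min(k, length), replace=False)] = True
    return fp


def generate_world(config: LibraryConfig) -> SyntheticWorld:
    """Generate a full synthetic study world from ``config``.

    Planted structure:

    * each indication owns a scaffold bit-set (about 19% of the fingerprint);
      a member compound inherits it with probability ``scaffold_share_prob``,
      on top of its own private random bits (6-12% of the fingerprint);
    * indication membership is sampled without replacement across indications
      while the approved supply lasts, so planted memberships are disjoint and
      the truth is unambiguous; once exhausted, drugs are reused;
    * every fingerprint bit is then flipped independently with probability
      ``noise_bit_prob`` (and at least one set bit is enforced);
    * each binding-site ligand is, with probability one half, a copy of a
      random library compound's fingerprint ("true binder" ligands that make
      chemically similar compounds score high at that protein), otherwise
      random bits; site confidence scores are Uniform(0, 1).
    """
    rng = np.random.default_rng(config.seed)
    L = config.fingerprint_length
    scaffold_k = max(8, round(0.1875 * L))
    private_lo, private_hi = max(4, round(0.0625 * L)), max(8, round(0.125 * L))

    n_total = config.n_approved + config.n_experimental
    width = len(str(n_total))
    approved_ids = [f"APR-{i:0{width}d}" for i in range(config.n_approved)]
    experimental_ids = [f"EXP-{i:0{width}d}" for i in range(config.n_experimental)]
    all_ids = approved_ids + experimental_ids
    statuses = [APPROVED] * config.n_approved + [EXPERIMENTAL] * config.n_experimental

    # indication scaffolds and memberships
    scaffolds = {}
    memberships = {}
    pool = list(approved_ids)
    rng.shuffle(pool)
    for i in range(config.n_indications):
        ind_id = f"IND-{i:03d}"
        scaffolds[ind_id] = _sample_bits(rng, L, scaffold_k)
        size = int(rng.integers(config.drugs_per_indication[0], config.drugs_per_indication[1] + 1))
        if len(pool) >= size:
            members = [pool.pop() for _ in range(size)]
        else:  # supply exhausted: reuse approved drugs (multi-indication drugs)
            members = list(rng.choice(approved_ids, size=size, replace=False))
        memberships[ind_id] = members

    # which compounds carry which scaffolds
    scaffold_of: dict = {cid: [] for cid in all_ids}
    for ind_id, members in memberships.items():
        for cid in members:
            if rng.random() < config.scaffold_share_prob:
                scaffold_of[cid].append(ind_id)

    compounds = []
    for cid, status in zip(all_ids, statuses):
        fp = _sample_bits(rng, L, int(rng.integers(private_lo, private_hi + 1)))
        for ind_id in scaffold_of[cid]:
            fp |= scaffolds[ind_id]
        if config.noise_bit_prob > 0:
            fp ^= rng.random(L) < config.noise_bit_prob
        if not fp.any():
            fp[rng.integers(L)] = True
        compounds.append(CompoundRecord(cid, cid.lower(), status, fp))
    fp_by_id = {c.compound_id: c.fingerprint for c in compounds}

    site_models = []
    ligand_sources = {}
    for j in range(config.n_proteins):
        pid = f"PROT-{j:04d}"
        n_sites = int(rng.integers(config.n_sites_per_protein[0], config.n_sites_per_protein[1] + 1))
        sites = []
        for s in range(n_sites):
            sid = f"{pid}:S{s}"
            n_lig = int(rng.integers(config.n_ligands_per_site[0], config.n_ligands_per_site[1] + 1))
            ligs = []
            for l in range(n_lig):
                if rng.random() < 0.5:  # true-binder ligand copied from the library
                    src = all_ids[int(rng.integers(n_total))]
                    ligs.append(fp_by_id[src].copy())
                    ligand_sources[(pid, sid, l)] = src
                else:
                    ligs.append(_sample_bits(rng, L, int(rng.integers(private_lo, 2 * private_hi + 1))))
            sites.append(BindingSite(sid, float(rng.random()), tuple(ligs)))
        site_models.append(ProteinSiteModel(pid, tuple(sites)))

    catalog = IndicationCatalog(
        {
            ind_id: Indication(ind_id, f"indication {ind_id}", frozenset(members))
            for ind_id, members in memberships.items()
        }
    )
    truth = {
        "scaffold_bits": {k: np.flatnonzero(v).tolist() for k, v in scaffolds.items()},
        "scaffold_membership": {cid: list(inds) for cid, inds in scaffold_of.items() if inds},
        "ligand_sources": {f"{p}|{s}|{l}": src for (p, s, l), src in ligand_sources.items()},
    }
    world = SyntheticWorld(config, compounds, site_models, catalog, truth)
    catalog.validate_against([c.compound_id for c in compounds])
    return world


def four_pl(dose, gi50: float, hill: float, top: float, bottom: float):
    """Four-parameter logistic response: bottom + (top-bottom)/(1+(gi50/dose)^hill)."""
    dose = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (1.0 + (gi50 / dose) ** hill)


def generate_dose_response(
    gi50: float,
    hill: float = 1.0,
    top: float = 100.0,
    bottom: float = 0.0,
    doses: Sequence[float] = (0.1, 0.3, 1.0, 3.0, 10.0, 30.0, 100.0, 300.0),
    n_reps: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
    drug: str = "drug",
    n_controls: int | None = None,
) -> pd.DataFrame:
    """Simulate a dose-response plate (absorbance units) for one drug.

    The untreated-control wells have mean absorbance 1.0 (100% viability);
    treated absorbance is ``(1 - response/100)`` where the mean response
    follows the 4PL curve, plus Gaussian noise of ``noise_sd`` percentage
    points.  Triplicates by default, as in a standard viability assay.
    """
    doses = np.asarray(doses, dtype=float)
    if gi50 <= 0:
        raise ValueError("gi50 must be positive")
    if np.any(doses <= 0):
        raise ValueError("doses must be positive (conc 0 rows are the generated controls)")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    n_controls = n_reps if n_controls is None else n_controls

    rows = []
    for r in range(n_controls):
        ab = 1.0 + rng.normal(0.0, noise_sd / 100.0)
        rows.append((drug, 0.0, None, np.nan, r, ab))
    response = four_pl(doses, gi50, hill, top, bottom)
    for dose, resp in zip(doses, response):
        for r in range(n_reps):
            ab = (1.0 - resp / 100.0) + rng.normal(0.0, noise_sd / 100.0)
            rows.append((drug, float(dose), None, np.nan, r, ab))
    return pd.DataFrame(rows, columns=DR_COLUMNS)


def generate_combination_table(
    drug_a: str,
    drug_b: str,
    params_a: Mapping[str, float],
    params_b: Mapping[str, float],
    doses_a: Sequence[float],
    doses_b: Sequence[float],
    bliss_excess: float = 0.0,
    n_reps: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a factorial two-drug combination plate.

    The combined mean response follows Bliss independence of the two 4PL
    single-agent curves plus a constant ``bliss_excess`` (percentage points)
    in every interior cell, clipped to 100 — a planted synergy surplus.
    ``params_*`` are dicts with keys gi50/hill/top/bottom.
    """
    doses_a = np.asarray(doses_a, dtype=float)
    doses_b = np.asarray(doses_b, dtype=float)
    if np.any(doses_a < 0) or np.any(doses_b < 0):
        raise ValueError("doses must be non-negative")
    rng = np.random.default_rng(seed)

    def single(dose, p):
        if dose == 0:
            return 0.0
        return float(four_pl(dose, p["gi50"], p.get("hill", 1.0), p.get("top", 100.0), p.get("bottom", 0.0)))

    rows = []
    grid_a = np.concatenate(([0.0], doses_a)) if 0.0 not in doses_a else doses_a
    grid_b = np.concatenate(([0.0], doses_b)) if 0.0 not in doses_b else doses_b
    for ca in grid_a:
        for cb in grid_b:
            fa, fb = single(ca, params_a), single(cb, params_b)
            resp = 100.0 * (1.0 - (1.0 - fa / 100.0) * (1.0 - fb / 100.0))
            if ca > 0 and cb > 0:
                resp = min(100.0, resp + bliss_excess)
            for r in range(n_reps):
                ab = (1.0 - resp / 100.0) + rng.normal(0.0, noise_sd / 100.0)
                rows.append((drug_a, float(ca), drug_b, float(cb), r, ab))
    out = pd.DataFrame(rows, columns=DR_COLUMNS)
    # the (0, 0) cells are the untreated controls; mark them as such
    return out


def generate_ct_table(
    true_fold_changes: Mapping[str, Mapping[str, float]],
    base_ct: float = 24.0,
    housekeeping_ct: float = 16.0,
    noise_sd: float = 0.0,
    n_reps: int = 3,
    seed: int = 0,
    reference_condition: str = "untreated",
) -> pd.DataFrame:
    """Simulate a qPCR Ct table so the comparative-Ct pipeline recovers
    ``true_fold_changes`` exactly at ``noise_sd=0``.

    One extra Ct cycle corresponds to a halving of transcript, so a planted
    fold change ``f`` shifts the treated target Ct by ``-log2(f)`` relative
    to the reference condition.  Every sample also gets a housekeeping-gene
    measurement at ``housekeeping_ct``.
    """
    genes = sorted({g for folds in true_fold_changes.values() for g in folds})
    for cond, folds in true_fold_changes.items():
        for g, f in folds.items():
            if f <= 0:
                raise ValueError(f"fold change must be positive, got {f} for ({cond}, {g})")
    rng = np.random.default_rng(seed)
    conditions = [reference_condition] + [c for c in true_fold_changes if c != reference_condition]

    rows = []
    for cond in conditions:
        for r in range(n_reps):
            sample = f"{cond}_r{r + 1}"
            rows.append((sample, cond, HOUSEKEEPING_GENE, housekeeping_ct + rng.normal(0, noise_sd)))
            for gene in genes:
                fold = 1.0 if cond == reference_condition else true_fold_changes[cond].get(gene, 1.0)
                ct = base_ct - np.log2(fold) + rng.normal(0, noise_sd)
                rows.append((sample, cond, gene, ct))
    return pd.DataFrame(rows, columns=CT_COLUMNS)
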