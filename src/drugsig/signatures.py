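"""Signature comparison: cosine distance, library ranking and aggregation.

Compounds with similar proteome-wide interaction signatures are hypothesised
to behave similarly in cells, so repurposing candidates are generated by
ranking the whole library against query compounds by cosine distance between
signatures, optionally restricted to a proteome panel (e.g. a disease-focused
gene subset).  Multi-query aggregation averages similarities and ranks over
several queries and reports each query's library-wide mean similarity as a
control, mirroring a bar-plot comparison of candidate compounds against
multiple known inhibitors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from drugsig.datatypes import InteractionMatrix, PanelDefinition


class ZeroSignatureError(ValueError):
    """A signature vector is all zeros: cosine similarity is undefined.

    Signals upstream that a compound scored zero against every panel protein.
    """


def cosine_distance(u, v) -> float:
    """Cosine distance 1 - u.v / (|u||v|) between two signature vectors.

    Zero for (positively) proportional vectors; raises
    :class:`ZeroSignatureError` on an all-zero input.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"signature length mismatch: {u.shape} vs {v.shape}")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ZeroSignatureError("all-zero signature: cosine distance undefined")
    return 1.0 - float(np.dot(u, v) / (nu * nv))


def _panel_scores(matrix: InteractionMatrix, panel: PanelDefinition | None) -> np.ndarray:
    if panel is None:
        return matrix.scores
    panel.validate_against(matrix)
    return matrix.scores[:, matrix.column_indices(panel.protein_ids)]


def _distances_to_query(scores: np.ndarray, q_idx: int) -> np.ndarray:
    """Cosine distances from every row to row ``q_idx`` (vectorised)."""
    q = scores[q_idx]
    nq = np.linalg.norm(q)
    norms = np.linalg.norm(scores, axis=1)
    if nq == 0.0:
        raise ZeroSignatureError("query signature is all zeros on this panel")
    if np.any(norms == 0.0):
        bad = int(np.flatnonzero(norms == 0.0)[0])
        raise ZeroSignatureError(f"all-zero signature at row {bad} on this panel")
    return 1.0 - (scores @ q) / (norms * nq)


@dataclass(frozen=True)
class SimilarityRanking:
    """Ranked neighbours of one query compound (query itself excluded)."""

    query_id: str
    panel_id: str
    entries: pd.DataFrame  # columns: compound_id, distance, rank

    def rank_of(self, compound_id: str) -> int:
        row = self.entries.loc[self.entries["compound_id"] == compound_id]
        if row.empty:
            raise KeyError(f"{compound_id!r} not in ranking")
        return int(row["rank"].iloc[0])

    def top(self, k: int) -> pd.DataFrame:
        return self.entries.head(k)


def rank_against_query(
    matrix: InteractionMatrix,
    query_id: str,
    panel: PanelDefinition | None = None,
) -> SimilarityRanking:
    """Rank every other library compound by cosine distance to the query.

    Distances are computed on the panel's columns only (full matrix when
    ``panel`` is None).  The query is excluded from its own ranking; ties in
    distance are broken lexicographically by compound id and ranks run
    1..N-1.
    """
    if query_id not in matrix:
        raise KeyError(f"unknown query_id {query_id!r}")
    scores = _panel_scores(matrix, panel)
    q_idx = matrix.compound_ids.index(query_id)
    dist = _distances_to_query(scores, q_idx)

    others = [i for i in range(len(matrix.compound_ids)) if i != q_idx]
    order = sorted(others, key=lambda i: (dist[i], matrix.compound_ids[i]))
    entries = pd.DataFrame(
        {
            "compound_id": [matrix.compound_ids[i] for i in order],
            "distance": [float(dist[i]) for i in order],
            "rank": np.arange(1, len(order) + 1),
        }
    )
    return SimilarityRanking(query_id, panel.panel_id if panel else "human", entries)


def aggregate_multi_query(
    matrix: InteractionMatrix,
    query_ids: Sequence[str],
    candidate_ids: Sequence[str],
    panel: PanelDefinition | None = None,
) -> pd.DataFrame:
    """Aggregate candidate similarity and rank over several query compounds.

    Similarity is reported as ``1 - cosine_distance`` (higher = more
    similar).  For each candidate the table carries the per-query similarity
    and rank, their means, and for each query the library-mean control: the
    query's mean similarity to all non-query compounds.  Candidates that are
    themselves queries are allowed but flagged in the ``is_query`` column.

    Returns a DataFrame indexed by candidate_id with columns
    ``sim_<q>``/``rank_<q>`` per query, ``mean_similarity``, ``mean_rank``
    and ``is_query``; the per-query controls are stored in
    ``result.attrs["library_mean_control"]`` (with key ``__overall__`` for
    their mean).
    """
    for cid in list(query_ids) + list(candidate_ids):
        if cid not in matrix:
            raise KeyError(f"unknown compound_id {cid!r}")

    sims: dict = {}
    ranks: dict = {}
    controls: dict = {}
    for q in query_ids:
        ranking = rank_against_query(matrix, q, panel)
        by_id = ranking.entries.set_index("compound_id")
        q_sims = {}
        q_ranks = {}
        for c in candidate_ids:
            if c == q:  # identical to the query by definition
                q_sims[c], q_ranks[c] = 1.0, 0
            else:
                q_sims[c] = 1.0 - float(by_id.loc[c, "distance"])
                q_ranks[c] = int(by_id.loc[c, "rank"])
        sims[q], ranks[q] = q_sims, q_ranks
        non_query = by_id.loc[~by_id.index.isin(query_ids), "distance"]
        controls[q] = float((1.0 - non_query).mean())

    out = pd.DataFrame(index=pd.Index(list(candidate_ids), name="candidate_id"))
    for q in query_ids:
        out[f"sim_{q}"] = [sims[q][c] for c in candidate_ids]
        out[f"rank_{q}"] = [ranks[q][c] for c in candidate_ids]
    out["mean_similarity"] = out[[f"sim_{q}" for q in query_ids]].mean(axis=1)
    out["mean_rank"] = out[[f"rank_{q}" for q in query_ids]].mean(axis=1)
    out["is_query"] = [c in set(query_ids) for c in candidate_ids]
    controls["__overall__"] = float(np.mean([controls[q] for q in query_ids]))
    out.attrs["library_mean_control"] = controls
    return out
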