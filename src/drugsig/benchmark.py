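"""Indication-accuracy benchmarking of the signature space.

The benchmark asks: if I rank all approved compounds against one approved
drug by signature similarity, do I recover another drug approved for the
same indication within the top-k?  For an indication with ``d`` approved
drugs, ``c`` of which recover at least one co-approved partner within the
cutoff, the indication accuracy is ``c/d x 100``; the headline statistic is
the unweighted mean over all indications with at least two approved drugs.

A random control replaces the similarity rankings with uniformly random
permutations.  Its exact expectation has a hypergeometric closed form: with
``N`` compounds in the comparison set, a drug with ``d-1`` co-approved
partners among the other ``N-1`` compounds recovers at least one partner in
the top-k with probability ``1 - C(N-d, k) / C(N-1, k)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import comb

from drugsig.datatypes import IndicationCatalog, InteractionMatrix
from drugsig.signatures import ZeroSignatureError

logger = logging.getLogger(__name__)


@dataclass
class BenchmarkResult:
    """Per-indication and average top-k recovery accuracies."""

    cutoffs: list
    per_indication: dict  # indication_id -> {cutoff: accuracy %}
    average: dict  # cutoff -> unweighted mean accuracy %
    weighted_average: dict  # cutoff -> mean weighted by indication size d
    c_counts: dict  # indication_id -> {cutoff: c}
    d_counts: dict  # indication_id -> d
    excluded: list = field(default_factory=list)  # indications with < 2 drugs

    @property
    def n_indications(self) -> int:
        return len(self.per_indication)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ind, accs in self.per_indication.items():
            row = {"indication_id": ind, "d": self.d_counts[ind]}
            for k in self.cutoffs:
                row[f"top{k}_accuracy"] = accs[k]
                row[f"top{k}_c"] = self.c_counts[ind][k]
            rows.append(row)
        return pd.DataFrame(rows)


def _pairwise_cosine_distances(scores: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(scores, axis=1)
    if np.any(norms == 0.0):
        bad = int(np.flatnonzero(norms == 0.0)[0])
        raise ZeroSignatureError(f"all-zero signature at row {bad}")
    z = scores / norms[:, None]
    d = 1.0 - z @ z.T
    return np.clip(d, 0.0, 2.0)


def benchmark(
    matrix: InteractionMatrix,
    catalog: IndicationCatalog,
    cutoffs: Sequence[int] = (10, 25, 50, 100),
    approved_only: bool = True,
    approved_ids: Sequence[str] | None = None,
) -> BenchmarkResult:
    """Run the per-indication top-k recovery benchmark.

    The comparison set is the approved compounds only (the benchmarking
    protocol proper) unless ``approved_only=False``, in which case the full
    library is ranked (candidate-generation parity).  ``approved_ids``
    specifies which matrix compounds are approved; by default every compound
    referenced by the catalog is taken as approved.

    Each drug of each benchmarked indication is used as a query; ties in
    distance are broken lexicographically by compound id (as in
    :func:`drugsig.signatures.rank_against_query`).
    """
    cutoffs = sorted(int(k) for k in cutoffs)
    if approved_ids is None:
        approved_ids = sorted(catalog.all_compound_ids())
    catalog.validate_against(matrix.compound_ids)
    if approved_only:
        comparison_ids = [c for c in matrix.compound_ids if c in set(approved_ids)]
    else:
        comparison_ids = list(matrix.compound_ids)
    n = len(comparison_ids)
    if any(k < 1 for k in cutoffs):
        raise ValueError("cutoffs must be positive")
    if cutoffs and cutoffs[-1] > n - 1:
        raise ValueError(f"cutoff {cutoffs[-1]} exceeds comparison-set size - 1 ({n - 1})")

    sub = matrix.subset_compounds(comparison_ids)
    dist = _pairwise_cosine_distances(sub.scores)
    idx_of = {c: i for i, c in enumerate(comparison_ids)}
    # numeric tie-break key: position in lexicographic id order
    id_rank = np.empty(n, dtype=int)
    id_rank[np.argsort(np.asarray(comparison_ids))] = np.arange(n)

    usable = catalog.with_min_drugs(2)
    excluded = [i.indication_id for i in catalog if i.n_drugs < 2]
    for ind_id in excluded:
        logger.info("excluding indication %s (<2 approved drugs)", ind_id)

    per_indication, c_counts, d_counts = {}, {}, {}
    for ind in sorted(usable, key=lambda x: x.indication_id):
        members = sorted(ind.approved_compound_ids)
        d = len(members)
        member_idx = np.array([idx_of[m] for m in members])
        c_at = {k: 0 for k in cutoffs}
        for qi in member_idx:
            order = np.lexsort((id_rank, dist[qi]))
            order = order[order != qi]  # query excluded from its own ranking
            partner_mask = np.isin(order, member_idx[member_idx != qi])
            pos = np.flatnonzero(partner_mask)
            best_rank = int(pos[0]) + 1 if pos.size else np.inf
            for k in cutoffs:
                if best_rank <= k:
                    c_at[k] += 1
        per_indication[ind.indication_id] = {k: 100.0 * c_at[k] / d for k in cutoffs}
        c_counts[ind.indication_id] = dict(c_at)
        d_counts[ind.indication_id] = d

    average = {
        k: float(np.mean([v[k] for v in per_indication.values()])) if per_indication else np.nan
        for k in cutoffs
    }
    ds = np.array([d_counts[i] for i in per_indication])
    weighted_average = {
        k: float(
            np.sum([per_indication[i][k] * d_counts[i] for i in per_indication]) / ds.sum()
        )
        if per_indication
        else np.nan
        for k in cutoffs
    }
    return BenchmarkResult(cutoffs, per_indication, average, weighted_average, c_counts, d_counts, excluded)


def expected_random_accuracy(n_compounds: int, d: int, k: int) -> float:
    """Closed-form expected accuracy (%) of a random ranking.

    Probability that a drug with ``d - 1`` co-approved partners uniformly
    placed among the other ``n_compounds - 1`` ranks has at least one partner
    within the top ``k``: ``1 - C(N-d, k) / C(N-1, k)``.  Cutoffs spanning
    the whole comparison set give 100.
    """
    n = n_compounds
    if d < 2:
        raise ValueError("closed form requires an indication with >= 2 drugs")
    if k >= n - 1:
        if k > n - 1:
            logger.warning("cutoff %d > comparison-set size - 1 (%d): accuracy forced to 100", k, n - 1)
        return 100.0
    p_miss = comb(n - d, k, exact=True) / comb(n - 1, k, exact=True) if n - d >= k else 0.0
    return 100.0 * (1.0 - p_miss)


@dataclass
class RandomControlResult:
    """Monte-Carlo random-ranking control with its analytic expectation."""

    cutoffs: list
    mc_mean: dict  # cutoff -> mean average accuracy % over replicates
    mc_se: dict  # cutoff -> standard error over replicates
    expected: dict  # cutoff -> closed-form expectation %
    n_reps: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cutoff": self.cutoffs,
                "mc_mean": [self.mc_mean[k] for k in self.cutoffs],
                "mc_se": [self.mc_se[k] for k in self.cutoffs],
                "expected": [self.expected[k] for k in self.cutoffs],
            }
        )


def random_control(
    catalog: IndicationCatalog,
    n_compounds: int,
    cutoffs: Sequence[int] = (10, 25, 50, 100),
    n_reps: int = 1000,
    seed: int = 0,
) -> RandomControlResult:
    """Monte-Carlo random control: benchmark accuracy under random rankings.

    Each replicate assigns every query drug an independent uniformly random
    ranking of the other ``n_compounds - 1`` compounds (simulated by giving
    all compounds i.i.d. uniform sort keys) and recomputes the average
    indication accuracy.  Also reports the hypergeometric closed form via
    :func:`expected_random_accuracy`.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    cutoffs = sorted(int(k) for k in cutoffs)
    usable = catalog.with_min_drugs(2)
    if len(usable) == 0:
        raise ValueError("no indication with >= 2 drugs")
    rng = np.random.default_rng(seed)
    n = n_compounds

    inds = sorted(usable, key=lambda x: x.indication_id)
    # per replicate and indication: fraction of drugs recovering a partner
    acc = {k: np.zeros((n_reps, len(inds))) for k in cutoffs}
    for j, ind in enumerate(inds):
        d = ind.n_drugs
        for _ in range(d):  # each drug queried independently
            if n - 1 <= 0:
                raise ValueError("comparison set must contain at least 2 compounds")
            # rank of the best partner among N-1 under a random permutation:
            # i.i.d. uniform keys; partners are the first d-1 columns
            keys = rng.random((n_reps, n - 1))
            best_partner = keys[:, : d - 1].min(axis=1)
            best_rank = (keys < best_partner[:, None]).sum(axis=1) + 1
            for k in cutoffs:
                hit = best_rank <= min(k, n - 1)
                if k >= n - 1:
                    hit = np.ones(n_reps, dtype=bool)
                acc[k][:, j] += hit / d
    for k in cutoffs:
        acc[k] *= 100.0

    mc_mean, mc_se = {}, {}
    for k in cutoffs:
        if k > n - 1:
            logger.warning("cutoff %d spans the whole comparison set: accuracy is 100", k)
        rep_avg = acc[k].mean(axis=1)  # average over indications, per replicate
        mc_mean[k] = float(rep_avg.mean())
        mc_se[k] = float(rep_avg.std(ddof=1) / np.sqrt(n_reps)) if n_reps > 1 else float("nan")
    expected = {
        k: float(np.mean([expected_random_accuracy(n, ind.n_drugs, k) for ind in inds]))
        for k in cutoffs
    }
    return RandomControlResult(cutoffs, mc_mean, mc_se, expected, n_reps)
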