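"""Comparative-Ct (delta-delta-Ct) relative gene-expression analysis.

Each sample's target-gene threshold cycle is first normalised to the
housekeeping gene measured in the same sample (dCt = Ct_target - Ct_hk);
condition-level regulation is then the difference of mean dCt between the
treated and reference (untreated) conditions:

    ddCt = mean dCt(treated) - mean dCt(reference)
    fold_change = 2^(-ddCt)

so one extra cycle (ddCt = 1) means a halving of transcript.  Conditions are
compared with a two-sided two-sample Student t-test on the per-sample dCt
values (Welch's correction optional), significance read at p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from drugsig.simulate import CT_COLUMNS, HOUSEKEEPING_GENE


class PairingError(ValueError):
    """A sample lacks its housekeeping-gene measurement."""


class DdctModel:
    """Comparative-Ct model over a tidy Ct table.

    Parameters
    ----------
    table : DataFrame with columns sample, condition, gene, ct
    reference_condition : the untreated/control condition name
    housekeeping_gene : the per-sample normaliser (default beta-actin)
    """

    def __init__(
        self,
        table: pd.DataFrame,
        reference_condition: str,
        housekeeping_gene: str = HOUSEKEEPING_GENE,
    ):
        missing = [c for c in CT_COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"Ct table lacks columns {missing}")
        if (table["ct"] <= 0).any():
            raise ValueError("Ct values must be positive")
        if reference_condition not in set(table["condition"]):
            raise ValueError(f"reference condition {reference_condition!r} not in table")
        self.table = table
        self.reference_condition = reference_condition
        self.housekeeping_gene = housekeeping_gene

    def _delta_ct(self) -> pd.DataFrame:
        """Per (sample, target gene) housekeeping-normalised dCt."""
        mean_ct = (
            self.table.groupby(["condition", "sample", "gene"])["ct"].mean().reset_index()
        )
        hk = mean_ct[mean_ct["gene"] == self.housekeeping_gene].set_index("sample")["ct"]
        targets = mean_ct[mean_ct["gene"] != self.housekeeping_gene].copy()
        unpaired = sorted(set(targets["sample"]) - set(hk.index))
        if unpaired:
            raise PairingError(
                f"samples without a {self.housekeeping_gene} measurement: {unpaired[:5]}"
            )
        targets["delta_ct"] = targets["ct"].to_numpy() - hk.loc[targets["sample"]].to_numpy()
        return targets

    def fit(self, equal_var: bool = True) -> "DdctResults":
        dct = self._delta_ct()
        ref = dct[dct["condition"] == self.reference_condition]
        rows = []
        for (cond, gene), grp in dct.groupby(["condition", "gene"]):
            ref_vals = ref.loc[ref["gene"] == gene, "delta_ct"].to_numpy()
            if ref_vals.size == 0:
                raise PairingError(f"gene {gene!r} missing from the reference condition")
            vals = grp["delta_ct"].to_numpy()
            ddct = float(vals.mean() - ref_vals.mean())
            if cond == self.reference_condition:
                p = np.nan
            else:
                with np.errstate(invalid="ignore", divide="ignore"):
                    _, p = stats.ttest_ind(vals, ref_vals, equal_var=equal_var)
                p = float(p)
            rows.append(
                {
                    "condition": cond,
                    "gene": gene,
                    "delta_ct": float(vals.mean()),
                    "delta_ct_sd": float(vals.std(ddof=1)) if vals.size > 1 else np.nan,
                    "ddct": ddct,
                    "fold_change": float(2.0 ** (-ddct)),
                    "p_value": p,
                    "n": int(vals.size),
                }
            )
        out = pd.DataFrame(rows).sort_values(["condition", "gene"]).reset_index(drop=True)
        return DdctResults(self, out)


@dataclass
class DdctResults:
    """Relative-expression estimates per (condition, gene)."""

    model: DdctModel
    table: pd.DataFrame

    def fold_change(self, condition: str, gene: str) -> float:
        row = self.table[(self.table["condition"] == condition) & (self.table["gene"] == gene)]
        if row.empty:
            raise KeyError(f"no estimate for ({condition!r}, {gene!r})")
        return float(row["fold_change"].iloc[0])

    def summary(self) -> str:
        lines = [
            "Comparative-Ct relative expression",
            f"reference: {self.model.reference_condition}   "
            f"housekeeping: {self.model.housekeeping_gene}",
            "=" * 62,
            f"{'condition':<16}{'gene':<12}{'ddCt':>8}{'fold':>8}{'p':>10}",
        ]
        for _, r in self.table.iterrows():
            p = "" if np.isnan(r["p_value"]) else f"{r['p_value']:.3g}"
            lines.append(
                f"{r['condition']:<16}{r['gene']:<12}{r['ddct']:>8.3f}{r['fold_change']:>8.3f}{p:>10}"
            )
        return "\n".join(lines)


def ddct_analysis(
    table: pd.DataFrame,
    reference_condition: str,
    housekeeping_gene: str = HOUSEKEEPING_GENE,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Convenience wrapper: fit :class:`DdctModel` and return the tidy table."""
    return DdctModel(table, reference_condition, housekeeping_gene).fit(equal_var=equal_var).table
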