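"""In-vitro viability analytics: normalisation, GI50 fitting, synergy calls.

Raw plate absorbances are normalised to percentage inhibition against the
untreated controls; dose-response curves are fitted with the
four-parameter-logistic (4PL) model

    y(x) = bottom + (top - bottom) / (1 + (gi50 / x)^hill)

where ``gi50`` is the midpoint concentration, ``hill`` the slope and
``top``/``bottom`` the plateaus (percent inhibition).  GI50 values are
capped at the maximum tested dose when the fit exceeds it or the curve never
reaches 50% inhibition.  Synergy between a drug pair is called when the
combination shifts the titrated drug's potency at least two-fold relative to
the single agent.

The fitting API follows the model/results idiom: build a
:class:`DoseResponseModel` from data, call :meth:`~DoseResponseModel.fit`,
and read estimates, standard errors and diagnostics off the returned
:class:`Gi50Results` (or print ``results.summary()``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from drugsig.simulate import DR_COLUMNS, four_pl


class ControlError(ValueError):
    """The plate has no usable untreated-control wells."""


def _conc(table: pd.DataFrame, col: str) -> pd.Series:
    if col not in table.columns:
        return pd.Series(0.0, index=table.index)
    return pd.to_numeric(table[col], errors="coerce").fillna(0.0)


def _control_mask(table: pd.DataFrame) -> pd.Series:
    return (_conc(table, "conc_a") == 0.0) & (_conc(table, "conc_b") == 0.0)


def normalize_wells(table: pd.DataFrame) -> pd.DataFrame:
    """Per-well inhibition % relative to the untreated-control mean.

    Adds ``inhibition_raw`` (unclamped, kept for diagnostics and fitting)
    and ``inhibition`` (clamped to [0, 100], the heatmap scale).
    """
    missing = [c for c in ("conc_a", "absorbance") if c not in table.columns]
    if missing:
        raise ValueError(f"dose-response table lacks columns {missing}")
    ctrl = table.loc[_control_mask(table), "absorbance"]
    if ctrl.empty:
        raise ControlError("no untreated-control wells (conc 0) in table")
    ctrl_mean = float(ctrl.mean())
    if ctrl_mean <= 0:
        raise ControlError(f"untreated-control mean absorbance must be positive, got {ctrl_mean}")
    out = table.copy()
    out["inhibition_raw"] = 100.0 * (1.0 - out["absorbance"] / ctrl_mean)
    out["inhibition"] = out["inhibition_raw"].clip(0.0, 100.0)
    return out


def normalize_inhibition(table: pd.DataFrame) -> pd.DataFrame:
    """Mean inhibition % and SD per condition, normalised to untreated controls.

    A condition is a unique (drug_a, conc_a, drug_b, conc_b) combination;
    the untreated control appears as the conc-0 condition with 0% mean by
    construction only in expectation — its wells are normalised like any
    others.  Clamped means are in ``inhibition``; unclamped diagnostics in
    ``inhibition_raw``.
    """
    wells = normalize_wells(table)
    keys = ["drug_a", "conc_a"]
    if "drug_b" in wells.columns:
        keys += ["drug_b", "conc_b"]
    grouped = wells.groupby(keys, dropna=False)
    out = grouped.agg(
        n=("inhibition", "size"),
        inhibition=("inhibition", "mean"),
        sd=("inhibition", "std"),
        inhibition_raw=("inhibition_raw", "mean"),
        sd_raw=("inhibition_raw", "std"),
    ).reset_index()
    return out.sort_values(keys).reset_index(drop=True)


def inhibition_ttests(table: pd.DataFrame, equal_var: bool = True) -> pd.DataFrame:
    """Two-sided Student t-test of each treated condition against the controls.

    Welch's correction available via ``equal_var=False``; significance is
    conventionally read at p < 0.05.
    """
    wells = normalize_wells(table)
    ctrl = wells.loc[_control_mask(wells), "inhibition_raw"]
    keys = ["drug_a", "conc_a"]
    if "drug_b" in wells.columns:
        keys += ["drug_b", "conc_b"]
    rows = []
    for cond, grp in wells.loc[~_control_mask(wells)].groupby(keys, dropna=False):
        t, p = stats.ttest_ind(grp["inhibition_raw"], ctrl, equal_var=equal_var)
        rows.append(dict(zip(keys, cond)) | {"t": float(t), "p_value": float(p),
                                             "significant": bool(p < 0.05)})
    return pd.DataFrame(rows)


class DoseResponseModel:
    """4PL dose-response model for one titration.

    Parameters
    ----------
    dose : array of positive concentrations (µM)
    response : array of inhibition percentages (may be unclamped)
    dilution : "log" fits in log10-dose space (log-scale dilution series),
        "linear" fits the concentration directly; the model is the same,
        the parametrisation changes conditioning.
    """

    def __init__(self, dose, response, dilution: str = "log"):
        self.dose = np.asarray(dose, dtype=float)
        self.response = np.asarray(response, dtype=float)
        if dilution not in ("log", "linear"):
            raise ValueError("dilution must be 'log' or 'linear'")
        if self.dose.shape != self.response.shape:
            raise ValueError("dose and response must have the same length")
        if np.any(self.dose <= 0):
            raise ValueError("doses must be positive (drop control wells before fitting)")
        if np.unique(self.dose).size < 4:
            raise ValueError("need >= 4 distinct doses to fit four parameters")
        self.dilution = dilution
        self.max_dose = float(self.dose.max())

    @classmethod
    def from_table(
        cls,
        table: pd.DataFrame,
        drug: str | None = None,
        dilution: str = "log",
        partner_conc: float | None = 0.0,
    ) -> "DoseResponseModel":
        """Build from a raw plate table, normalising against its controls.

        ``partner_conc`` selects the fixed dose of the second drug (0 for the
        single-agent titration, None to ignore the partner column).
        """
        wells = normalize_wells(table)
        sel = wells["conc_a"] > 0
        if drug is not None:
            sel &= wells["drug_a"] == drug
        if partner_conc is not None and "conc_b" in wells.columns:
            sel &= _conc(wells, "conc_b") == partner_conc
        sub = wells.loc[sel]
        return cls(sub["conc_a"].to_numpy(), sub["inhibition_raw"].to_numpy(), dilution)

    def predict(self, params, dose) -> np.ndarray:
        gi50, hill, top, bottom = params
        return four_pl(np.asarray(dose, dtype=float), gi50, hill, top, bottom)

    def _initial_guess(self):
        x, y = self.dose, self.response
        bottom0, top0 = float(np.min(y)), float(np.max(y))
        if top0 - bottom0 < 1e-9:
            top0 = bottom0 + 1.0
        half = 0.5 * (top0 + bottom0)
        gi50_0 = float(x[np.argmin(np.abs(y - half))])
        return gi50_0, 1.0, top0, bottom0

    def fit(self, maxfev: int = 10000) -> "Gi50Results":
        """Nonlinear least squares of the 4PL; GI50 capped at the max dose.

        Non-convergence is reported through ``converged``/``cap_reason`` with
        the GI50 capped — never a silent failure.
        """
        gi50_0, hill0, top0, bottom0 = self._initial_guess()
        x, y = self.dose, self.response

        if self.dilution == "log":
            lx = np.log10(x)

            def model(lx_, lgi50, hill, top, bottom):
                return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (lgi50 - lx_)))

            p0 = (np.log10(gi50_0), hill0, top0, bottom0)
            bounds = ([np.log10(x.min()) - 6, 1e-3, -100.0, -100.0],
                      [np.log10(x.max()) + 6, 50.0, 250.0, 250.0])
            xdata = lx
        else:

            def model(x_, gi50, hill, top, bottom):
                return bottom + (top - bottom) / (1.0 + (gi50 / x_) ** hill)

            p0 = (gi50_0, hill0, top0, bottom0)
            bounds = ([x.min() * 1e-6, 1e-3, -100.0, -100.0],
                      [x.max() * 1e6, 50.0, 250.0, 250.0])
            xdata = x

        converged = True
        message = ""
        try:
            popt, pcov = optimize.curve_fit(
                model, xdata, y, p0=p0, bounds=bounds, maxfev=maxfev
            )
        except RuntimeError as exc:  # no convergence: report, never hide
            converged = False
            message = str(exc)
            popt = np.asarray(p0, dtype=float)
            pcov = np.full((4, 4), np.nan)

        if self.dilution == "log":
            gi50, hill, top, bottom = 10.0 ** popt[0], popt[1], popt[2], popt[3]
            bse_raw = np.sqrt(np.diag(pcov))
            # delta method for gi50 = 10^p: d/dp = ln(10) 10^p
            gi50_se = float(bse_raw[0] * np.log(10.0) * gi50) if np.isfinite(bse_raw[0]) else np.nan
            bse = np.array([gi50_se, bse_raw[1], bse_raw[2], bse_raw[3]])
        else:
            gi50, hill, top, bottom = popt
            bse = np.sqrt(np.diag(pcov))

        fitted = four_pl(x, gi50, hill, top, bottom)
        resid = y - fitted
        capped = False
        cap_reason = None
        if not converged:
            capped, cap_reason = True, f"fit did not converge: {message}"
        elif gi50 > self.max_dose:
            capped, cap_reason = True, "fitted GI50 exceeds the maximum tested dose"
        elif four_pl(self.max_dose, gi50, hill, top, bottom) < 50.0:
            capped, cap_reason = True, "curve does not reach 50% inhibition at the maximum dose"
        reported = self.max_dose if capped else float(gi50)

        return Gi50Results(
            model=self,
            gi50=reported,
            gi50_uncapped=float(gi50),
            hill=float(hill),
            top=float(top),
            bottom=float(bottom),
            bse=bse,
            capped=capped,
            cap_reason=cap_reason,
            converged=converged,
            rss=float(np.sum(resid**2)),
            rmse=float(np.sqrt(np.mean(resid**2))),
            nobs=int(y.size),
        )


@dataclass
class Gi50Results:
    """4PL fit results: estimates, uncertainties and diagnostics."""

    model: DoseResponseModel
    gi50: float  # reported GI50 (µM), capped at the max tested dose if needed
    gi50_uncapped: float
    hill: float
    top: float
    bottom: float
    bse: np.ndarray  # standard errors of (gi50, hill, top, bottom)
    capped: bool
    cap_reason: str | None
    converged: bool
    rss: float
    rmse: float
    nobs: int

    @property
    def params(self) -> dict:
        return {"gi50": self.gi50, "hill": self.hill, "top": self.top, "bottom": self.bottom}

    def predict(self, dose) -> np.ndarray:
        return four_pl(dose, self.gi50_uncapped, self.hill, self.top, self.bottom)

    def dose_at(self, level: float = 50.0) -> tuple:
        """Concentration where the fitted curve crosses ``level`` % inhibition.

        Returns ``(dose, status)`` with status one of ``"in_range"``,
        ``"above_max"`` (curve never reaches the level: dose capped at the
        maximum tested concentration) or ``"below_min"`` (already above the
        level at the lowest tested dose: dose floored there).  Unlike the
        4PL midpoint parameter, this is an absolute potency — the right
        quantity when a combination partner alone shifts the whole curve.
        """
        b, t, h, g = self.bottom, self.top, self.hill, self.gi50_uncapped
        lo, hi = float(self.model.dose.min()), float(self.model.dose.max())
        if level >= t:  # upper plateau below the level: never crosses
            return hi, "above_max"
        if level <= b:  # already above the level everywhere
            return lo, "below_min"
        dose = g * ((level - b) / (t - level)) ** (1.0 / h)
        if dose > hi:
            return hi, "above_max"
        if dose < lo:
            return lo, "below_min"
        return float(dose), "in_range"

    def summary(self) -> str:
        lines = [
            "Four-parameter logistic dose-response fit",
            "=" * 45,
            f"observations: {self.nobs}    dilution: {self.model.dilution}",
            f"RSS: {self.rss:.4g}    RMSE: {self.rmse:.4g}",
            "-" * 45,
            f"{'param':<10}{'estimate':>12}{'std err':>12}",
        ]
        for name, val, se in zip(("gi50", "hill", "top", "bottom"),
                                 (self.gi50_uncapped, self.hill, self.top, self.bottom),
                                 self.bse):
            lines.append(f"{name:<10}{val:>12.4g}{se:>12.4g}")
        lines.append("-" * 45)
        cap = f" (capped: {self.cap_reason})" if self.capped else ""
        lines.append(f"reported GI50: {self.gi50:.4g} uM{cap}")
        if not self.converged:
            lines.append("WARNING: fit did not converge")
        return "\n".join(lines)


def fit_gi50(
    table_or_dose,
    response=None,
    dilution: str = "log",
    drug: str | None = None,
    partner_conc: float | None = 0.0,
) -> Gi50Results:
    """Fit a GI50: convenience wrapper over :class:`DoseResponseModel`.

    Accepts either a raw plate DataFrame (normalised internally) or explicit
    ``dose``/``response`` arrays.
    """
    if isinstance(table_or_dose, pd.DataFrame):
        model = DoseResponseModel.from_table(
            table_or_dose, drug=drug, dilution=dilution, partner_conc=partner_conc
        )
    else:
        model = DoseResponseModel(table_or_dose, response, dilution=dilution)
    return model.fit()


@dataclass(frozen=True)
class SynergyCall:
    """Two-fold potency-shift synergy call for a drug pair."""

    drug_pair: tuple
    potency_shift: float  # single-agent GI50 / combination GI50 (fold)
    synergistic: bool
    shift_is_lower_bound: bool = False  # single-agent GI50 was capped
    shift_is_upper_bound: bool = False  # combination GI50 was capped
    note: str = ""


def _potency(value) -> tuple:
    if isinstance(value, Gi50Results):
        return float(value.gi50), bool(value.capped)
    return float(value), False


def assess_synergy(
    single,
    combination,
    drug_pair: tuple = ("drug_a", "drug_b"),
    threshold: float = 2.0,
) -> SynergyCall:
    """Call synergy from the single-agent vs combination potency shift.

    ``potency_shift = GI50_single / GI50_combination``; synergistic when the
    shift is at least two-fold.  Both inputs may be :class:`Gi50Results` or
    plain effective-dose numbers on the same drug's dose axis.  A capped
    single-agent GI50 makes the shift a lower bound (the true shift can only
    be larger); a capped combination GI50 makes it an upper bound.
    """
    s, s_capped = _potency(single)
    c, c_capped = _potency(combination)
    if c <= 0:
        raise ValueError("combination potency must be positive")
    if s <= 0:
        raise ValueError("single-agent potency must be positive")
    shift = s / c
    note = ""
    if s_capped:
        note = "single-agent GI50 capped at max dose; shift is a lower bound"
    if c_capped:
        note = (note + "; " if note else "") + "combination GI50 capped; shift is an upper bound"
    return SynergyCall(
        drug_pair=tuple(drug_pair),
        potency_shift=float(shift),
        synergistic=bool(shift >= threshold),
        shift_is_lower_bound=s_capped,
        shift_is_upper_bound=c_capped,
        note=note,
    )


def combination_grid(table: pd.DataFrame, drug_a: str, drug_b: str) -> pd.DataFrame:
    """Mean inhibition % grid for a factorial two-drug design.

    Rows are drug-a concentrations, columns drug-b concentrations, both
    including zero (single-agent margins; cell (0, 0) is the untreated
    control, 0% by definition of the normalisation in expectation).  Missing
    cells are NaN, never silently zero.
    """
    sel = table[
        ((table["drug_a"] == drug_a) | (_na_eq(table["conc_a"])))
        & ((table["drug_b"] == drug_b) | (_na_eq(table["conc_b"])))
    ]
    if sel.empty:
        raise ValueError(f"no rows for pair ({drug_a}, {drug_b})")
    summary = normalize_inhibition(sel)
    summary["conc_b"] = summary["conc_b"].fillna(0.0)
    grid = summary.pivot_table(
        index="conc_a", columns="conc_b", values="inhibition", aggfunc="mean", dropna=False
    )
    return grid.sort_index().sort_index(axis=1)


def _na_eq(series: pd.Series) -> pd.Series:
    return series.isna() | (series == 0.0)


def combination_potency_shifts(
    table: pd.DataFrame,
    drug_a: str,
    drug_b: str,
    dilution: str = "log",
    threshold: float = 2.0,
) -> pd.DataFrame:
    """Per-row synergy analysis of a factorial design.

    For each fixed dose of drug B, refit the drug-A titration (the grid row)
    and compare the dose of A reaching 50% absolute inhibition with the
    single-agent (drug B at 0) value via the two-fold shift rule.  The
    absolute crossing is used — not the 4PL midpoint — because a partner
    that is itself active shifts the whole row above the midpoint scale.
    Potencies outside the tested range are capped/floored at its edges, in
    which case the shift is a bound rather than an estimate.
    """
    single = fit_gi50(table, dilution=dilution, drug=drug_a, partner_conc=0.0)
    p_single, s_status = single.dose_at(50.0)
    rows = []
    partner_doses = sorted(c for c in table["conc_b"].dropna().unique() if c > 0)
    for cb in partner_doses:
        combo = fit_gi50(table, dilution=dilution, drug=drug_a, partner_conc=float(cb))
        p_combo, c_status = combo.dose_at(50.0)
        shift = p_single / p_combo
        # shift is a lower bound when the single-agent potency is capped high
        # or the combination potency is floored low
        lower_bound = (s_status == "above_max") or (c_status == "below_min")
        rows.append(
            {
                "conc_b": float(cb),
                "gi50_single": p_single,
                "single_capped": s_status == "above_max",
                "gi50_combination": p_combo,
                "combination_capped": c_status == "above_max",
                "potency_shift": float(shift),
                "synergistic": bool(shift >= threshold),
                "shift_is_lower_bound": lower_bound,
            }
        )
    return pd.DataFrame(rows)
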