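"""Calibration, semi-quantitation, removal statistics and molar mass
balances.

Parents are quantified on the M+2 isotopologue channel (its low
abundance avoids detector saturation at the dosed concentrations);
identified TPs use their own calibration curves when a standard exists,
or otherwise a predicted response factor whose uncertainty is carried
as a documented factor-5 band.  Mass balances express the summed molar
TP formation as a percentage of the molar parent removal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .chem import MolecularFormula, molar_mass
from .model import ExperimentDesign


class CalibrationError(ValueError):
    pass


@dataclass
class CalibrationCurve:
    analyte_id: str
    response_channel: str            # "monoisotopic" | "M+2"
    points: list[tuple[float, float]]  # (conc µg/L, response)
    slope: float = 0.0
    intercept: float = 0.0
    r_squared: float = 0.0
    max_abs_residual_fraction: float = 0.0
    accepted: bool = False
    rejection_reason: str = ""


def fit_calibration(points: Sequence[tuple[float, float]], analyte_id: str,
                    channel: str = "monoisotopic",
                    min_points: int = 5, min_r2: float = 0.99,
                    max_residual_fraction: float = 0.30,
                    weighting: str = "none") -> CalibrationCurve:
    """Least-squares calibration line with hard acceptance invariants:
    >= ``min_points`` points, R² >= ``min_r2`` and every |residual| within
    ``max_residual_fraction`` of the fitted response.  A failing curve is
    returned rejected with a named reason and cannot be used to quantify."""
    curve = CalibrationCurve(analyte_id=analyte_id, response_channel=channel,
                             points=[(float(c), float(r)) for c, r in points])
    if len(points) < min_points:
        curve.rejection_reason = (f"{len(points)} points < required "
                                  f"{min_points}")
        return curve
    x = np.array([c for c, _ in points], dtype=float)
    y = np.array([r for _, r in points], dtype=float)
    if weighting == "1/x":
        w = 1.0 / np.where(x > 0, x, np.min(x[x > 0]))
    elif weighting == "none":
        w = np.ones_like(x)
    else:
        raise CalibrationError(f"unknown weighting {weighting!r}")
    wsum = w.sum()
    xm = (w * x).sum() / wsum
    ym = (w * y).sum() / wsum
    sxx = (w * (x - xm) ** 2).sum()
    sxy = (w * (x - xm) * (y - ym)).sum()
    curve.slope = float(sxy / sxx)
    curve.intercept = float(ym - curve.slope * xm)
    fitted = curve.slope * x + curve.intercept
    ss_res = float(((y - fitted) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    curve.r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        resid_frac = np.abs(y - fitted) / np.abs(fitted)
    curve.max_abs_residual_fraction = float(np.nanmax(resid_frac))
    if curve.r_squared < min_r2:
        curve.rejection_reason = (f"R²={curve.r_squared:.4f} < {min_r2}")
    elif curve.max_abs_residual_fraction > max_residual_fraction:
        curve.rejection_reason = (
            f"max residual {curve.max_abs_residual_fraction:.0%} > "
            f"{max_residual_fraction:.0%}")
    else:
        curve.accepted = True
    return curve


@dataclass
class Quantity:
    value_ugL: float
    extrapolated: bool = False


def quantify(response: float, curve: CalibrationCurve) -> Quantity:
    """Invert an accepted calibration line; extrapolation beyond the
    calibrated range is flagged, a rejected curve is an error."""
    if not curve.accepted:
        raise CalibrationError(
            f"calibration for {curve.analyte_id!r} was rejected "
            f"({curve.rejection_reason}); cannot quantify")
    conc = (response - curve.intercept) / curve.slope
    lo = min(c for c, _ in curve.points)
    hi = max(c for c, _ in curve.points)
    return Quantity(value_ugL=float(conc),
                    extrapolated=not (lo <= conc <= hi))


# ---------------------------------------------------------------------------
# Semi-quantitation

@dataclass
class SemiQuant:
    analyte_id: str
    conc_ugL: float
    conc_uM: float
    provenance: str                 # "standard" | "predicted"
    uncertainty_factor: float       # 1 for standards, ~5 for predictions


def semi_quantify(analyte_id: str, response: float,
                  formula: MolecularFormula,
                  curve: CalibrationCurve | None = None,
                  rf_predictor: Callable[[str], float] | None = None,
                  rf_uncertainty_factor: float = 5.0) -> SemiQuant:
    """Concentration of a TP from its standard curve when available, else
    from a predicted response factor (signal per µg/L).  µg/L converts to
    µM through the molar mass derived from the formula."""
    mw = molar_mass(formula)
    if curve is not None:
        q = quantify(response, curve)
        return SemiQuant(analyte_id=analyte_id, conc_ugL=q.value_ugL,
                         conc_uM=q.value_ugL / mw, provenance="standard",
                         uncertainty_factor=1.0)
    if rf_predictor is None:
        raise CalibrationError(
            f"cannot quantify {analyte_id!r}: no standard curve and no "
            "response-factor predictor")
    rf = rf_predictor(analyte_id)
    if rf <= 0:
        raise CalibrationError(
            f"cannot quantify {analyte_id!r}: non-positive predicted "
            "response factor")
    conc = response / rf
    return SemiQuant(analyte_id=analyte_id, conc_ugL=conc, conc_uM=conc / mw,
                     provenance="predicted",
                     uncertainty_factor=rf_uncertainty_factor)


def parent_rf_predictor(parent_rf: float) -> Callable[[str], float]:
    """Default predictor: assume the TP responds like its parent at equal
    mass concentration."""
    return lambda _analyte: parent_rf


# ---------------------------------------------------------------------------
# Removal statistics

@dataclass
class RemovalStat:
    parent_id: str
    condition: str
    removal_percent: float
    t_statistic: float | None
    df: int | None
    p_value: float | None
    significant: bool | None        # None when untestable (single replicate)


def pooled_t(group_a: Sequence[float], group_b: Sequence[float]
             ) -> tuple[float, int, float]:
    """Two-sample pooled-variance t statistic, degrees of freedom and
    two-sided p."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("pooled t-test needs >= 2 observations per group")
    df = na + nb - 2
    sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / df
    if sp2 == 0:
        t = 0.0 if a.mean() == b.mean() else np.inf
    else:
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2.0 * float(stats.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
    return float(t), int(df), min(p, 1.0)


def removal_stats(conc_0h: Sequence[float], conc_2h: Sequence[float],
                  parent_id: str, condition: str,
                  alpha: float = 0.05) -> RemovalStat:
    """Percent removal normalised to the 0 h exposure controls, with a
    pooled t-test for significance when replicates allow."""
    c0 = np.asarray(conc_0h, dtype=float)
    c2 = np.asarray(conc_2h, dtype=float)
    if len(c0) == 0 or len(c2) == 0 or c0.mean() <= 0:
        raise ValueError("removal needs positive 0 h concentrations")
    removal = 100.0 * (1.0 - c2.mean() / c0.mean())
    if len(c0) >= 2 and len(c2) >= 2:
        t, df, p = pooled_t(c0, c2)
        return RemovalStat(parent_id=parent_id, condition=condition,
                           removal_percent=removal, t_statistic=t, df=df,
                           p_value=p, significant=p <= alpha)
    return RemovalStat(parent_id=parent_id, condition=condition,
                       removal_percent=removal, t_statistic=None, df=None,
                       p_value=None, significant=None)


# ---------------------------------------------------------------------------
# Molar mass balance

@dataclass
class MassBalance:
    parent_id: str
    condition: str
    parent_removed_uM: float
    tp_contributions: list[tuple[str, float, str]]  # (tp, µM, provenance)
    explained_fraction_percent: float | None
    notes: list[str] = field(default_factory=list)

    @property
    def defined(self) -> bool:
        return self.explained_fraction_percent is not None


def mass_balance(parent_id: str, condition: str, parent_removed_uM: float,
                 tp_quants: Sequence[SemiQuant],
                 shared_tps: set[str] | None = None,
                 shared_mode: str = "both",
                 excluded_tps: set[str] | None = None) -> MassBalance:
    """Σ TP µM over parent removal µM, as a percentage.

    TPs linked to several parents cannot be attributed exactly; by
    config they are either counted fully toward each parent with a note
    ("both") or split equally ("split").  Individual TPs can be excluded
    from the sum (e.g. when formed jointly with another TP in the same
    reaction) while remaining itemised.  Non-positive parent removal
    leaves the balance undefined rather than quoting a misleading ratio.
    """
    shared_tps = shared_tps or set()
    excluded_tps = excluded_tps or set()
    notes: list[str] = []
    contributions: list[tuple[str, float, str]] = []
    total = 0.0
    for q in tp_quants:
        amount = q.conc_uM
        if q.analyte_id in shared_tps:
            if shared_mode == "split":
                amount = amount / 2.0
                notes.append(f"{q.analyte_id}: shared between parents, "
                             "split equally")
            else:
                notes.append(f"{q.analyte_id}: shared between parents, "
                             "attributed fully to each (upper bound)")
        contributions.append((q.analyte_id, amount, q.provenance))
        if q.analyte_id in excluded_tps:
            notes.append(f"{q.analyte_id}: excluded from the balance sum")
            continue
        total += amount
    if parent_removed_uM <= 0:
        return MassBalance(parent_id=parent_id, condition=condition,
                           parent_removed_uM=parent_removed_uM,
                           tp_contributions=contributions,
                           explained_fraction_percent=None,
                           notes=notes + ["no significant parent removal; "
                                          "balance undefined"])
    return MassBalance(parent_id=parent_id, condition=condition,
                       parent_removed_uM=parent_removed_uM,
                       tp_contributions=contributions,
                       explained_fraction_percent=100.0 * total
                       / parent_removed_uM,
                       notes=notes)
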