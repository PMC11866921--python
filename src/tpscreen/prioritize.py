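"""Feature prioritization: reduce an aligned feature table to the small
set that plausibly contains transformation products.

Three steps compose: (1) blank subtraction against the 0 h exposure
controls, (2) minimum-intensity / replicate-detection filters, and
(3) ordinary least squares of the replicate-mean 2 h mixture intensity
on the initial parent concentration.  TPs form from the dosed parents,
so their abundance scales (approximately linearly) with the initial
concentration while background chemicals do not; a positive slope with
either a significant one-sided p-value or, tolerantly, a high R²
(accommodating detector/reactant saturation) keeps a feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .model import ExperimentDesign, FeatureGroupTable, Parent

# the concentration-trend arms: photolytic mixture experiments only
# (dark controls are presence/absence controls, not part of the series)
PHOTO_CONDITIONS = ("U", "UH", "UHN")


@dataclass
class RegressionResult:
    group_id: str
    n_points: int
    slope: float
    intercept: float
    r_squared: float
    p_value: float           # one-sided, H1: slope > 0
    kept: bool
    reason: str


@dataclass
class PrioritizationResult:
    features: FeatureGroupTable            # surviving TP-plausible features
    parent_features: FeatureGroupTable     # features matching dosed parents
    regressions: list[RegressionResult]
    step_counts: dict[str, int]            # provenance accounting


def parent_feature_ids(features: FeatureGroupTable, parents: list[Parent],
                       mz_tol_mda: float = 5.0) -> set[str]:
    """Feature groups whose m/z matches a parent [M+H]+ within tolerance.

    Parents are tracked for removal statistics but are not TP candidates,
    so they are exempted from (and removed by) prioritization.
    """
    ids: set[str] = set()
    mz = features.df["mz"].to_numpy()
    for p in parents:
        hit = np.abs(mz - p.mz) <= mz_tol_mda / 1000.0
        ids.update(features.df.loc[hit, "group_id"])
    return ids


def blank_subtract(features: FeatureGroupTable, design: ExperimentDesign,
                   blank_factor: float = 5.0,
                   exempt: set[str] | None = None) -> FeatureGroupTable:
    """Drop feature groups not clearly elevated over the 0 h controls.

    A group survives when its maximum 2 h intensity reaches at least
    ``blank_factor`` times the mean intensity across matching 0 h samples;
    groups absent from every 0 h sample always survive (the rule is
    ordered to avoid division).
    """
    exempt = exempt or set()
    two_h = [s.sample_id for s in design.samples
             if s.exposure_h == 2 and s.sample_type != "blank"
             and s.sample_id in features.sample_columns]
    zero_h = [s.sample_id for s in design.samples
              if s.exposure_h == 0 and s.sample_id in features.sample_columns]
    if not two_h:
        return features
    max2 = features.intensities(two_h).max(axis=1)
    mean0 = (features.intensities(zero_h).mean(axis=1)
             if zero_h else np.zeros(len(features)))
    keep = max2 >= blank_factor * mean0
    keep |= mean0 == 0
    keep &= ~features.df["group_id"].isin(exempt).to_numpy()
    return FeatureGroupTable(features.df.loc[keep].reset_index(drop=True))


def replicate_filter(features: FeatureGroupTable, design: ExperimentDesign,
                     min_intensity: float = 0.0,
                     min_replicate_detections: int = 2) -> FeatureGroupTable:
    """Keep features detected in at least ``min_replicate_detections``
    replicates of some 2 h mixture arm (condition x concentration)."""
    arms: dict[tuple, list[str]] = {}
    for s in design.select(exposure_h=2, sample_type="mixture"):
        if s.condition in PHOTO_CONDITIONS \
                and s.sample_id in features.sample_columns:
            arms.setdefault((s.condition, s.mixture_level), []).append(s.sample_id)
    if not arms:
        return features
    keep = np.zeros(len(features), dtype=bool)
    for cols in arms.values():
        inten = features.intensities(cols)
        detected = (inten > max(min_intensity, 0.0)).sum(axis=1)
        keep |= detected >= min(min_replicate_detections, len(cols))
    return FeatureGroupTable(features.df.loc[keep].reset_index(drop=True))


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Slope, intercept, R² and one-sided p (slope > 0) via normal equations."""
    n = len(x)
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    sxy = float(((x - xm) * (y - ym)).sum())
    syy = float(((y - ym) ** 2).sum())
    slope = sxy / sxx
    intercept = ym - slope * xm
    if syy == 0:
        # flat response: R² undefined, treat as no fit
        return slope, intercept, 0.0, 1.0
    r2 = sxy * sxy / (sxx * syy)
    df = n - 2
    if df <= 0:
        return slope, intercept, r2, 1.0
    resid = syy - slope * sxy
    if resid <= 0:
        p_one = 0.0 if slope > 0 else 1.0
    else:
        se = np.sqrt(resid / df / sxx)
        t = slope / se
        p_one = float(stats.t.sf(t, df))
    return slope, intercept, r2, p_one


def regress_concentration(features: FeatureGroupTable,
                          design: ExperimentDesign,
                          alpha: float = 0.05,
                          r2_relaxed: float = 0.7,
                          min_conc_levels: int = 2,
                          min_intensity: float = 0.0,
                          replicate_mode: str = "mean",
                          ) -> list[RegressionResult]:
    """OLS of 2 h mixture intensity on initial parent concentration.

    Replicates (and conditions) at each concentration level are averaged
    before the fit unless ``replicate_mode='per_replicate'``.  A feature
    detected in fewer than ``min_conc_levels`` concentration arms is
    excluded outright (non-detections would otherwise fabricate two-point
    lines); within an included feature, non-detections count as zero.
    Kept iff slope > 0 and (one-sided p <= alpha or R² >= r2_relaxed).
    """
    arm_cols: dict[float, list[str]] = {}
    for s in design.select(exposure_h=2, sample_type="mixture"):
        if s.condition in PHOTO_CONDITIONS \
                and s.sample_id in features.sample_columns:
            arm_cols.setdefault(s.mixture_level, []).append(s.sample_id)
    levels = sorted(arm_cols)
    if len(levels) < 2:
        raise ValueError("regression needs >= 2 distinct mixture "
                         "concentration levels")
    arm_matrices = {lv: features.intensities(arm_cols[lv]) for lv in levels}
    results: list[RegressionResult] = []
    for i, gid in enumerate(features.df["group_id"]):
        detected_levels = sum(
            1 for lv in levels
            if (arm_matrices[lv][i] > max(min_intensity, 0.0)).any())
        if detected_levels < min_conc_levels:
            results.append(RegressionResult(
                group_id=gid, n_points=0, slope=0.0, intercept=0.0,
                r_squared=0.0, p_value=1.0, kept=False,
                reason=f"detected in {detected_levels} < {min_conc_levels} "
                       "concentration arms"))
            continue
        if replicate_mode == "mean":
            x = np.array(levels, dtype=float)
            y = np.array([arm_matrices[lv][i].mean() for lv in levels])
        elif replicate_mode == "per_replicate":
            x = np.concatenate([[lv] * arm_matrices[lv].shape[1]
                                for lv in levels]).astype(float)
            y = np.concatenate([arm_matrices[lv][i] for lv in levels])
        else:
            raise ValueError(f"unknown replicate_mode {replicate_mode!r}")
        slope, intercept, r2, p_one = _ols_line(x, y)
        if slope <= 0:
            kept, reason = False, "non-positive slope"
        elif p_one <= alpha:
            kept, reason = True, f"significant (p={p_one:.3g})"
        elif r2 >= r2_relaxed:
            kept, reason = True, f"tolerant branch (R²={r2:.3f})"
        else:
            kept, reason = False, f"no trend (p={p_one:.3g}, R²={r2:.3f})"
        results.append(RegressionResult(
            group_id=gid, n_points=len(x), slope=slope, intercept=intercept,
            r_squared=r2, p_value=p_one, kept=kept, reason=reason))
    return results


def prioritize(features: FeatureGroupTable, design: ExperimentDesign,
               parents: list[Parent], config: dict) -> PrioritizationResult:
    """Full prioritization chain with per-step provenance counts."""
    pcfg = config["prioritize"]
    features.validate_against(design)
    counts = {"sample_grouped": len(features)}

    parent_ids = parent_feature_ids(features, parents,
                                    mz_tol_mda=config["mz_tol_mda"])
    parent_tab = features.subset(parent_ids)
    counts["parent_features"] = len(parent_tab)

    after_blank = blank_subtract(features, design,
                                 blank_factor=pcfg["blank_factor"],
                                 exempt=parent_ids)
    counts["after_blank_subtraction"] = len(after_blank)

    after_rep = replicate_filter(
        after_blank, design, min_intensity=pcfg["min_intensity"],
        min_replicate_detections=pcfg["min_replicate_detections"])
    counts["after_replicate_filter"] = len(after_rep)

    regressions = regress_concentration(
        after_rep, design, alpha=pcfg["alpha"],
        r2_relaxed=pcfg["r2_relaxed"],
        min_conc_levels=pcfg["min_conc_levels"],
        min_intensity=pcfg["min_intensity"],
        replicate_mode=pcfg["replicate_mode"])
    kept_ids = [r.group_id for r in regressions if r.kept]
    prioritized = after_rep.subset(kept_ids)
    counts["prioritized"] = len(prioritized)

    return PrioritizationResult(features=prioritized,
                                parent_features=parent_tab,
                                regressions=regressions,
                                step_counts=counts)
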