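"""Filtering and ranking of candidate structures/formulas for unknown
features.

Candidates (offline snapshots of database retrievals, or decoy tables)
pass an element filter and an elution-order filter, are scored on
parent-substructure fit, similarity to structure suspects and in-silico
annotation, combined into a TP score (mean of the components that are
present), thresholded against suspect-derived calibration percentiles,
and cut to the top 25 per feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._elements import KNOWN_ELEMENTS
from .chem import (
    MolecularFormula,
    StructureRecord,
    StructureError,
    parse_formula,
    structure_fit,
    structure_similarity,
)
from .annotate import AnnotationScore, compound_annotation_score
from .model import Parent, Ms2Spectrum, Suspect


@dataclass
class CandidateScore:
    group_id: str
    candidate_id: str
    kind: str                       # "compound" | "formula"
    fit_formula: float
    fit_compound: float | None = None
    sim_suspects: float | None = None
    ann_compound: float | None = None
    ann_formula: float | None = None
    tp_score: float = 0.0
    rank: int = 0
    survived: bool = True
    stage_dropped: str = ""

    def components(self) -> dict[str, float]:
        out = {"fit_formula": self.fit_formula}
        for name in ("fit_compound", "sim_suspects", "ann_compound",
                     "ann_formula"):
            value = getattr(self, name)
            if value is not None:
                out[name] = value
        return out


def combine_score(components: dict[str, float],
                  weights: dict[str, float] | None = None) -> float:
    """TP score: mean of the present components (absent components are
    renormalised away rather than counted as zero), optionally weighted."""
    if not components:
        return 0.0
    if weights:
        num = sum(weights.get(k, 1.0) * v for k, v in components.items())
        den = sum(weights.get(k, 1.0) for k in components)
        return num / den if den else 0.0
    return sum(components.values()) / len(components)


# ---------------------------------------------------------------------------
# Filters

def element_filter(candidates: pd.DataFrame,
                   forbidden: tuple[str, ...] = ("Cl", "Br", "Si", "P"),
                   counts: dict | None = None) -> pd.DataFrame:
    """Drop candidates containing elements implausible for TPs of the
    dosed parents (default Cl/Br/Si/P: absent from the parents and not
    introduced by oxidative photochemistry)."""
    if not forbidden:
        return candidates
    keep = []
    for _, row in candidates.iterrows():
        formula = parse_formula(str(row["formula"]), alphabet=KNOWN_ELEMENTS)
        keep.append(not any(formula.count(e) for e in forbidden))
    out = candidates.loc[keep].reset_index(drop=True)
    if counts is not None:
        counts["element_filter"] = len(out)
    return out


def elution_order_filter(candidates: pd.DataFrame, parent: Parent,
                         feature_rt: float, tol_logp: float = 2.0,
                         counts: dict | None = None) -> pd.DataFrame:
    """Reversed-phase elution-order plausibility: a candidate whose log P
    differs from the parent's by more than ``tol_logp`` in the direction
    contradicting the observed RT order is removed.  Formula candidates
    and failed log P predictions are retained (fail-open)."""
    rt_sign = np.sign(feature_rt - parent.rt)
    keep = []
    flags = []
    for _, row in candidates.iterrows():
        if row["kind"] != "compound" or rt_sign == 0:
            keep.append(True)
            flags.append("")
            continue
        try:
            cand = StructureRecord.from_smiles(str(row["candidate_id"]),
                                               str(row["smiles"]))
            dlogp = cand.logp - parent.structure.logp
        except StructureError:
            keep.append(True)
            flags.append("logp_failed")
            continue
        contradicts = np.sign(dlogp) != 0 and np.sign(dlogp) != rt_sign
        keep.append(not (contradicts and abs(dlogp) > tol_logp))
        flags.append("")
    out = candidates.loc[keep].reset_index(drop=True)
    if counts is not None:
        counts["rt_filter"] = len(out)
    return out


# ---------------------------------------------------------------------------
# Metrics

def formula_fit(candidate_formula: MolecularFormula,
                parent_formula: MolecularFormula) -> float:
    """Fraction of the candidate's atoms (hydrogens included) available in
    the parent: sum of element-wise minima over the candidate's total atom
    count.  1.0 iff the candidate is element-wise contained in the parent."""
    cand = candidate_formula.counts
    par = parent_formula.counts
    total = sum(cand.values())
    shared = sum(min(n, par.get(e, 0)) for e, n in cand.items())
    return shared / total if total else 0.0


def derive_thresholds(suspect_scores: list[CandidateScore],
                      percentile: float = 5.0,
                      min_calibration: int = 5,
                      method: str = "lower",
                      log: list[str] | None = None
                      ) -> dict[str, float] | None:
    """Per-metric lower thresholds from suspect-matched calibration scores.

    The threshold for each metric is the given lower percentile over the
    calibration values.  The default ``lower`` interpolation returns an
    attained value, so by construction at least (100 - percentile)% of
    calibration suspects reach every threshold even for small calibration
    sets; ``linear`` (the numpy default) interpolates between order
    statistics.  Too few suspects disables thresholding with a warning
    rather than thresholding on noise.
    """
    if len(suspect_scores) < min_calibration:
        if log is not None:
            log.append(f"thresholds disabled: only {len(suspect_scores)} "
                       f"calibration suspects (< {min_calibration})")
        return None
    thresholds: dict[str, float] = {}
    metric_names = ("fit_compound", "sim_suspects", "ann_compound",
                    "fit_formula", "ann_formula")
    for name in metric_names:
        values = [getattr(s, name) for s in suspect_scores
                  if getattr(s, name) is not None]
        if len(values) >= min_calibration:
            thresholds[name] = float(np.percentile(values, percentile,
                                                   method=method))
    return thresholds


def _passes_thresholds(score: CandidateScore,
                       thresholds: dict[str, float] | None) -> bool:
    if not thresholds:
        return True
    for name, floor in thresholds.items():
        value = getattr(score, name)
        if value is not None and value < floor:
            return False
    return True


def score_candidate(group_id: str, candidate_id: str, kind: str,
                    formula: MolecularFormula,
                    structure: StructureRecord | None,
                    parent: Parent,
                    structure_suspects: list[Suspect],
                    spectrum: Ms2Spectrum | None,
                    config: dict) -> CandidateScore:
    rcfg = config["ranking"]
    acfg = config["annotation"]
    fit_f = formula_fit(formula, parent.structure.formula)
    fit_c = sim = ann_c = ann_f = None
    if kind == "compound" and structure is not None:
        fit_c = structure_fit(structure, parent.structure,
                              timeout_s=rcfg["mcs_timeout_s"],
                              direction=rcfg["fit_direction"]).value
        sims = [structure_similarity(structure, s.structure)
                for s in structure_suspects]
        sim = max(sims) if sims else None
        ann = compound_annotation_score(
            spectrum, structure, fragment_depth=acfg["fragment_depth"],
            hydrogen_tolerance=acfg["hydrogen_tolerance"],
            tol_mda=acfg["fragment_tol_mda"])
        ann_c = None if ann.absent else ann.value
    score = CandidateScore(group_id=group_id, candidate_id=candidate_id,
                           kind=kind, fit_formula=fit_f, fit_compound=fit_c,
                           sim_suspects=sim, ann_compound=ann_c,
                           ann_formula=ann_f)
    score.tp_score = combine_score(score.components())
    return score


def rank_candidates(group_id: str, candidates: pd.DataFrame, parent: Parent,
                    suspects: list[Suspect], feature_rt: float,
                    spectrum: Ms2Spectrum | None,
                    thresholds: dict[str, float] | None,
                    config: dict,
                    counts: dict | None = None) -> list[CandidateScore]:
    """Filter, score, threshold and top-N rank the candidates offered for
    one unknown feature.  Ties break by formula fit, then candidate id,
    so ranking is deterministic."""
    rcfg = config["ranking"]
    counts = counts if counts is not None else {}
    counts["raw"] = len(candidates)
    structure_suspects = [s for s in suspects
                          if s.parent_id == parent.parent_id
                          and s.kind == "structure"]
    filtered = element_filter(candidates,
                              tuple(rcfg["forbidden_elements"]), counts)
    filtered = elution_order_filter(filtered, parent, feature_rt,
                                    tol_logp=rcfg["logp_tolerance"],
                                    counts=counts)
    scores: list[CandidateScore] = []
    for _, row in filtered.iterrows():
        kind = str(row["kind"])
        formula = parse_formula(str(row["formula"]), alphabet=KNOWN_ELEMENTS)
        structure = None
        if kind == "compound":
            structure = StructureRecord.from_smiles(str(row["candidate_id"]),
                                                    str(row["smiles"]))
        scores.append(score_candidate(
            group_id, str(row["candidate_id"]), kind, formula, structure,
            parent, structure_suspects, spectrum, config))

    surviving = [s for s in scores if _passes_thresholds(s, thresholds)]
    surviving_ids = set(map(id, surviving))
    for s in scores:
        if id(s) not in surviving_ids:
            s.survived = False
            s.stage_dropped = "threshold"
    counts["after_thresholds"] = len(surviving)
    surviving.sort(key=lambda s: (-s.tp_score, -s.fit_formula,
                                  s.candidate_id))
    top_n = rcfg["top_n"]
    for i, s in enumerate(surviving):
        s.rank = i + 1
        if i >= top_n:
            s.survived = False
            s.stage_dropped = "top_n"
    counts["top_n"] = min(len(surviving), top_n)
    return surviving[:top_n]


def suspect_calibration_scores(matched: list[tuple[str, Suspect, float,
                                                   Ms2Spectrum | None]],
                               parents: dict[str, Parent],
                               suspects: list[Suspect],
                               config: dict) -> list[CandidateScore]:
    """Evaluate the ranking metrics on suspect-matched features.

    Each matched structure suspect is scored as if it were an unknown
    candidate; its similarity metric is computed leave-one-out against
    the *other* structure suspects of the parent, so the calibration
    distribution reflects what genuinely novel candidates can attain.
    """
    out: list[CandidateScore] = []
    for group_id, suspect, feature_rt, spectrum in matched:
        if suspect.kind != "structure":
            continue
        parent = parents[suspect.parent_id]
        others = [s for s in suspects
                  if s.parent_id == suspect.parent_id
                  and s.kind == "structure"
                  and s.suspect_id != suspect.suspect_id]
        out.append(score_candidate(
            group_id, suspect.suspect_id, "compound", suspect.formula,
            suspect.structure, parent, others, spectrum, config))
    return out


def score_proposed_structures(group_id: str,
                              assigned_formula: MolecularFormula,
                              proposals: list[StructureRecord],
                              parent: Parent,
                              suspects: list[Suspect],
                              spectrum: Ms2Spectrum | None,
                              config: dict) -> list[CandidateScore]:
    """Score manually proposed structures for a formula-annotated feature.

    Proposals must share the feature's assigned formula; mismatches are
    rejected by name.
    """
    structure_suspects = [s for s in suspects
                          if s.parent_id == parent.parent_id
                          and s.kind == "structure"]
    scores: list[CandidateScore] = []
    for prop in proposals:
        if prop.formula.counts != assigned_formula.counts:
            raise ValueError(
                f"proposal {prop.identifier!r}: formula "
                f"{prop.formula.render()} does not match assigned "
                f"{assigned_formula.render()}")
        scores.append(score_candidate(
            group_id, prop.identifier, "compound", prop.formula, prop,
            parent, structure_suspects, spectrum, config))
    scores.sort(key=lambda s: (-s.tp_score, s.candidate_id))
    for i, s in enumerate(scores):
        s.rank = i + 1
    return scores
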