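"""Identification-confidence assignment.

Levels follow the widely used five-level communication scheme for HRMS
identifications: 1 confirmed by reference standard, 2 probable (library
MS2 match), 3 tentative structure (3a when a standard matches but close
isomers cannot be excluded), 4 unambiguous molecular formula, 5 exact
mass only.  Sub-levels 3b-d are collapsed to a single tentative class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chem import IsotopePattern

LEVEL_ORDER = {"1": 0, "2": 1, "3a": 2, "3b": 3, "4": 4, "5": 5}


@dataclass
class ConfidenceLevel:
    level: str                    # "1" | "2" | "3a" | "3b" | "4" | "5"
    evidence: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.level not in LEVEL_ORDER:
            raise ValueError(f"unknown confidence level {self.level!r}")

    def better_than(self, other: "ConfidenceLevel") -> bool:
        return LEVEL_ORDER[self.level] < LEVEL_ORDER[other.level]

    @property
    def display(self) -> str:
        return "3 (tentative)" if self.level == "3b" else self.level


def isotope_fit_score(measured: IsotopePattern,
                      theoretical: IsotopePattern) -> float:
    """Isotopic-pattern goodness of fit: 1000 x the root-mean-square
    deviation of the abundance fractions over offsets 0..2, after
    normalising each pattern to unit sum.

    0 for identical patterns; the conventional acceptance threshold of
    <100 then corresponds to per-peak fraction deviations below ~10%.
    """
    offsets = (0, 1, 2)
    m = np.array([measured.abundance(o) for o in offsets], dtype=float)
    t = np.array([theoretical.abundance(o) for o in offsets], dtype=float)
    if m.sum() <= 0 or t.sum() <= 0:
        raise ValueError("patterns must cover offsets 0..2")
    m = m / m.sum()
    t = t / t.sum()
    return 1000.0 * float(np.sqrt(np.mean((m - t) ** 2)))


@dataclass
class StandardEvidence:
    confirmed: bool
    evidence: list[str]
    isotope_score: float | None = None


def confirm_with_standard(feature_mz: float, feature_rt: float,
                          standard_mz: float, standard_rt: float,
                          measured_pattern: IsotopePattern | None = None,
                          theoretical_pattern: IsotopePattern | None = None,
                          rt_tol_min: float = 0.1,
                          mz_tol_mda: float = 5.0,
                          msigma_max: float = 100.0) -> StandardEvidence:
    """Reference-standard confirmation: RT within tolerance, accurate m/z
    within tolerance, and (when a measured pattern is available) isotope
    fit below the acceptance score.  Evidence is itemised per criterion."""
    evidence: list[str] = []
    ok = True
    drt = abs(feature_rt - standard_rt)
    if drt <= rt_tol_min:
        evidence.append(f"RT match (|ΔRT|={drt:.3f} min <= {rt_tol_min})")
    else:
        evidence.append(f"RT mismatch (|ΔRT|={drt:.3f} min > {rt_tol_min})")
        ok = False
    dmz = abs(feature_mz - standard_mz) * 1000.0
    if dmz <= mz_tol_mda:
        evidence.append(f"m/z match (|Δm/z|={dmz:.2f} mDa <= {mz_tol_mda:g})")
    else:
        evidence.append(f"m/z mismatch (|Δm/z|={dmz:.2f} mDa > {mz_tol_mda:g})")
        ok = False
    score = None
    if measured_pattern is not None and theoretical_pattern is not None:
        score = isotope_fit_score(measured_pattern, theoretical_pattern)
        if score < msigma_max:
            evidence.append(f"isotope fit {score:.1f} < {msigma_max:g}")
        else:
            evidence.append(f"isotope fit {score:.1f} >= {msigma_max:g}")
            ok = False
    return StandardEvidence(confirmed=ok, evidence=evidence,
                            isotope_score=score)


def assign_level(*,
                 standard_confirmed: bool = False,
                 isomer_ambiguous: bool = False,
                 library_match: bool = False,
                 has_structure_candidate: bool = False,
                 annotation_support: float | None = None,
                 unambiguous_formula: bool = False,
                 annotation_floor: float = 0.2) -> ConfidenceLevel:
    """Map the evidence bundle of one parent/TP link to a confidence level.

    Precedence: standard confirmation (1, or 3a under isomer ambiguity),
    then MS2 library match (2), then a structure candidate with
    sufficient in-silico annotation support (tentative, 3b), then a
    single surviving formula (4), else exact mass only (5).
    """
    if standard_confirmed and not isomer_ambiguous:
        return ConfidenceLevel("1", ["reference standard confirmed, "
                                     "no competing isomer"])
    if standard_confirmed and isomer_ambiguous:
        return ConfidenceLevel("3a", ["reference standard matched but "
                                      "close isomeric suspects remain"])
    if library_match:
        return ConfidenceLevel("2", ["MS2 library spectrum match"])
    if has_structure_candidate and annotation_support is not None \
            and annotation_support >= annotation_floor:
        return ConfidenceLevel("3b", [
            f"structure candidate with annotation support "
            f"{annotation_support:.2f} >= {annotation_floor:g}"])
    if has_structure_candidate and annotation_support is None:
        # structure evidence without MS2 stays tentative
        return ConfidenceLevel("3b", ["structure candidate without MS2 "
                                      "(prioritised on fit/similarity)"])
    if unambiguous_formula:
        return ConfidenceLevel("4", ["single formula passing isotope/"
                                     "enumeration constraints"])
    return ConfidenceLevel("5", ["accurate mass only"])
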