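"""Core data containers for a designed degradation experiment.

An experiment exposes mixtures (and single-parent solutions) of parent
micropollutants to photolytic conditions; LC-HRMS feature detection
upstream yields an aligned feature-group table which, together with the
experiment design, MS2 spectra and suspect lists, is everything the
screening workflow consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .chem import (
    MolecularFormula,
    StructureRecord,
    formula_from_smiles,
    monoisotopic_mass,
)

CONDITIONS = ("U", "UH", "UHN", "D", "DH", "DHN")
SUSPECT_SOURCES = ("CTS", "BTE", "BTH", "LIT", "PC", "LOGIC")


class ValidationError(ValueError):
    """A named, total validation failure: malformed input never yields a
    partially constructed object."""


@dataclass(frozen=True)
class SampleInfo:
    sample_id: str
    sample_type: str          # "mixture" | "single:<parent_id>" | "blank" | "standard"
    condition: str            # U / UH / UHN / D / DH / DHN
    exposure_h: float         # 0 or 2
    initial_conc_ugL: dict[str, float]
    replicate: int

    @property
    def is_single(self) -> bool:
        return self.sample_type.startswith("single:")

    @property
    def single_parent(self) -> str | None:
        return self.sample_type.split(":", 1)[1] if self.is_single else None

    @property
    def mixture_level(self) -> float:
        """The common initial concentration of a mixture/single sample."""
        return max(self.initial_conc_ugL.values(), default=0.0)


@dataclass
class ExperimentDesign:
    samples: list[SampleInfo]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValidationError(f"duplicate sample_id(s): {sorted(dupes)}")
        for s in self.samples:
            if s.condition not in CONDITIONS:
                raise ValidationError(
                    f"sample {s.sample_id!r}: unknown condition {s.condition!r}")
            if s.exposure_h not in (0, 2):
                raise ValidationError(
                    f"sample {s.sample_id!r}: exposure must be 0 or 2 h")
            if s.replicate < 1:
                raise ValidationError(
                    f"sample {s.sample_id!r}: replicate must be >= 1")
        # every 2 h sample needs at least one 0 h partner of the same
        # type/condition/concentration (used for blank subtraction)
        zero_keys = {self._partner_key(s) for s in self.samples
                     if s.exposure_h == 0}
        for s in self.samples:
            if s.exposure_h == 2 and s.sample_type != "blank":
                if self._partner_key(s) not in zero_keys:
                    raise ValidationError(
                        f"sample {s.sample_id!r} (2 h) has no matching 0 h "
                        "control")

    @staticmethod
    def _partner_key(s: SampleInfo) -> tuple:
        conc = tuple(sorted(s.initial_conc_ugL.items()))
        return (s.sample_type, s.condition, conc)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def by_id(self, sample_id: str) -> SampleInfo:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def select(self, *, exposure_h: float | None = None,
               sample_type: str | None = None,
               condition: str | None = None,
               single_parent: str | None = None) -> list[SampleInfo]:
        out = []
        for s in self.samples:
            if exposure_h is not None and s.exposure_h != exposure_h:
                continue
            if sample_type is not None:
                if sample_type == "single":
                    if not s.is_single:
                        continue
                elif s.sample_type != sample_type:
                    continue
            if condition is not None and s.condition != condition:
                continue
            if single_parent is not None and s.single_parent != single_parent:
                continue
            out.append(s)
        return out

    @property
    def parent_ids(self) -> list[str]:
        ids: list[str] = []
        for s in self.samples:
            for p in s.initial_conc_ugL:
                if p not in ids:
                    ids.append(p)
        return sorted(ids)

    def zero_hour_partners(self, s: SampleInfo) -> list[SampleInfo]:
        key = self._partner_key(s)
        return [z for z in self.samples
                if z.exposure_h == 0 and self._partner_key(z) == key]


@dataclass
class FeatureGroupTable:
    """Aligned feature groups: one m/z + retention time per group and a
    per-sample intensity matrix (wide layout)."""

    df: pd.DataFrame  # columns: group_id, mz, rt, <sample_id>...

    def __post_init__(self) -> None:
        required = {"group_id", "mz", "rt"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValidationError(
                f"feature table missing column(s): {sorted(missing)}")
        if self.df["group_id"].duplicated().any():
            dup = self.df.loc[self.df["group_id"].duplicated(), "group_id"]
            raise ValidationError(
                f"duplicate feature group_id(s): {sorted(set(dup))[:5]}")
        if (self.df["mz"] <= 0).any():
            raise ValidationError("feature table contains non-positive m/z")
        if (self.df["rt"] < 0).any():
            raise ValidationError("feature table contains negative RT")
        if (self.df[self.sample_columns] < 0).to_numpy().any():
            raise ValidationError("feature table contains negative intensity")
        self.df = self.df.reset_index(drop=True)

    @property
    def sample_columns(self) -> list[str]:
        return [c for c in self.df.columns
                if c not in ("group_id", "mz", "rt")]

    def validate_against(self, design: ExperimentDesign) -> None:
        unknown = set(self.sample_columns) - set(design.sample_ids)
        if unknown:
            raise ValidationError(
                f"intensity column(s) for unknown sample(s): {sorted(unknown)}")

    def intensities(self, sample_ids: Sequence[str]) -> np.ndarray:
        return self.df[list(sample_ids)].to_numpy(dtype=float)

    def subset(self, group_ids: Iterable[str]) -> "FeatureGroupTable":
        keep = self.df["group_id"].isin(set(group_ids))
        return FeatureGroupTable(self.df.loc[keep].reset_index(drop=True))

    def row(self, group_id: str) -> pd.Series:
        hit = self.df[self.df["group_id"] == group_id]
        if hit.empty:
            raise KeyError(group_id)
        return hit.iloc[0]

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class Ms2Spectrum:
    feature_group_id: str
    precursor_mz: float
    peaks: list[tuple[float, float]]  # (mz, intensity), ascending mz

    def __post_init__(self) -> None:
        mzs = [m for m, _ in self.peaks]
        if mzs != sorted(mzs):
            self.peaks = sorted(self.peaks)
        if any(i <= 0 for _, i in self.peaks):
            raise ValidationError(
                f"spectrum {self.feature_group_id!r}: non-positive peak "
                "intensity")

    @property
    def base_intensity(self) -> float:
        return max((i for _, i in self.peaks), default=0.0)


@dataclass
class Suspect:
    """A hypothesised TP, either with a known structure (SMILES) or with a
    known molecular formula only."""

    suspect_id: str
    parent_id: str
    kind: str                     # "structure" | "formula"
    formula: MolecularFormula
    smiles: str | None = None
    sources: frozenset[str] = frozenset()
    transformation_label: str = ""
    _structure: StructureRecord | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.kind not in ("structure", "formula"):
            raise ValidationError(
                f"suspect {self.suspect_id!r}: kind must be structure|formula")
        if self.kind == "structure":
            if not self.smiles:
                raise ValidationError(
                    f"structure suspect {self.suspect_id!r} lacks SMILES")
            derived = formula_from_smiles(self.smiles, self.suspect_id)
            if derived.counts != self.formula.counts:
                raise ValidationError(
                    f"suspect {self.suspect_id!r}: formula "
                    f"{self.formula.render()} does not match SMILES formula "
                    f"{derived.render()}")
        elif self.smiles:
            raise ValidationError(
                f"formula suspect {self.suspect_id!r} must not carry SMILES")
        unknown = set(self.sources) - set(SUSPECT_SOURCES)
        if unknown:
            raise ValidationError(
                f"suspect {self.suspect_id!r}: unknown source tag(s) "
                f"{sorted(unknown)}")

    @property
    def structure(self) -> StructureRecord:
        if self.kind != "structure":
            raise ValueError(f"suspect {self.suspect_id!r} has no structure")
        if self._structure is None:
            self._structure = StructureRecord.from_smiles(
                self.suspect_id, self.smiles)
        return self._structure

    @property
    def neutral_mass(self) -> float:
        return monoisotopic_mass(self.formula)


@dataclass
class Parent:
    """A parent micropollutant dosed in the experiment."""

    parent_id: str
    structure: StructureRecord
    rt: float                     # minutes
    response_factor: float        # intensity per µg/L at the detector

    @property
    def mz(self) -> float:
        from .chem import adduct_mz
        return adduct_mz(self.structure.monoisotopic_mass)


@dataclass
class TPLink:
    parent_id: str
    group_id: str
    candidate_ref: str            # suspect_id or "unknown"
    status: str = "kept"          # "kept" | "removed:<reason>"

    @property
    def kept(self) -> bool:
        return self.status == "kept"

    def key(self) -> tuple[str, str, str]:
        return (self.parent_id, self.group_id, self.candidate_ref)
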