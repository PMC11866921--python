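"""In-silico photodegradation experiments.

The generator emulates the design of a mixture photodegradation study:
four pharmaceutical parents dosed together at 25/75/150 µg/L (three
replicates, 2 h exposure to UV, UV+H2O2 and UV+H2O2+NOM), single-parent
runs at 150 µg/L (two replicates), dark controls, and 0 h exposure
counterparts of every arm.  Planted transformation products form with
condition-specific molar yields from the removed parent, so their
intensities are linear in the initial parent concentration; background
("noise") features carry concentration-independent intensities, which is
exactly the contrast the prioritization stage exploits.  A fixed seed
makes the output byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .annotate import fragment_structure
from .chem import (
    FormulaError,
    MolecularFormula,
    StructureRecord,
    adduct_mz,
    formula_add,
    formula_subtract,
    molar_mass,
    monoisotopic_mass,
)
from .model import (
    ExperimentDesign,
    FeatureGroupTable,
    Ms2Spectrum,
    Parent,
    SampleInfo,
    Suspect,
)
from .suspects import parse_delta

PHOTO_CONDITIONS = ("U", "UH", "UHN")
DARK_CONDITIONS = ("D", "DH", "DHN")


@dataclass
class ParentSpec:
    parent: Parent
    # removal fraction of the parent after 2 h, per condition
    removal: dict[str, float]

    def __post_init__(self) -> None:
        for cond, r in self.removal.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(
                    f"removal fraction for {self.parent.parent_id}/{cond} "
                    f"out of [0,1]: {r}")


@dataclass
class TPDef:
    tp_id: str
    parent_id: str
    yields: dict[str, float]       # condition -> molar yield from removal
    rt: float                      # minutes
    response_factor: float         # intensity per µg/L
    smiles: str | None = None
    formula_delta: str | None = None   # e.g. "+O", applied to the parent
    feature_id: str | None = None      # share one feature between parents
    has_ms2: bool = True

    def __post_init__(self) -> None:
        if (self.smiles is None) == (self.formula_delta is None):
            raise ValueError(
                f"TP {self.tp_id!r}: exactly one of smiles/formula_delta")
        for cond, y in self.yields.items():
            if not 0.0 <= y <= 1.0:
                raise ValueError(
                    f"yield for {self.tp_id}/{cond} out of [0,1]: {y}")


@dataclass
class SimulationSpec:
    parents: list[ParentSpec]
    tp_defs: list[TPDef]
    concentrations: tuple[float, ...] = (25.0, 75.0, 150.0)
    mixture_replicates: int = 3
    single_replicates: int = 2
    dark_replicates: int = 2
    n_noise_features: int = 300
    noise_sigma: float = 0.1       # lognormal sigma on every intensity
    mz_jitter_mda: float = 0.3     # measurement error on feature m/z
    saturation_cap: float | None = None
    seed: int = 1

    def __post_init__(self) -> None:
        for ps in self.parents:
            for cond in PHOTO_CONDITIONS + DARK_CONDITIONS:
                total = sum(tp.yields.get(cond, 0.0) for tp in self.tp_defs
                            if tp.parent_id == ps.parent.parent_id)
                if total > 1.0 + 1e-12:
                    raise ValueError(
                        f"total TP yield for {ps.parent.parent_id}/{cond} "
                        f"exceeds 1: {total:.3f}")

    def parent_by_id(self, parent_id: str) -> ParentSpec:
        for ps in self.parents:
            if ps.parent.parent_id == parent_id:
                return ps
        raise KeyError(parent_id)


@dataclass
class SimulationResult:
    design: ExperimentDesign
    features: FeatureGroupTable
    spectra: list[Ms2Spectrum]
    truth: pd.DataFrame
    parents: list[Parent]


# ---------------------------------------------------------------------------
# Default study: four pharmaceuticals

_PARENT_DATA = [
    # id, SMILES, RT (min), response factor, removal U/UH/UHN/D/DH/DHN
    ("FLE", "O=C(NCC1CCCCN1)c1cc(OCC(F)(F)F)ccc1OCC(F)(F)F",
     9.6, 210.0, (0.06, 0.24, 0.28, 0.0, 0.22, 0.0)),
    ("MET", "CC(C)NCC(O)COc1ccc(CCOC)cc1",
     5.8, 260.0, (0.16, 0.28, 0.31, 0.0, 0.09, 0.12)),
    ("SMX", "Cc1cc(NS(=O)(=O)c2ccc(N)cc2)no1",
     6.4, 240.0, (0.85, 0.80, 0.77, 0.21, 0.25, 0.32)),
    ("PHE", "CC1=CC(=O)N(c2ccccc2)N1C",
     5.2, 300.0, (0.88, 0.85, 0.80, 0.0, 0.0, 0.0)),
]

# Planted TPs.  "suspected" controls whether the structure also appears in
# the default suspect lists (True -> found by suspect screening;
# False -> exercised through the unknown-screening workflow).
_TP_DATA = [
    # tp_id, parent, smiles/delta, rt, rf, yields U/UH/UHN, feature, ms2, suspected
    ("SMX-aniline", "SMX", "Nc1ccccc1", 3.9, 180.0,
     (0.12, 0.10, 0.08), "F_aniline", True, True),
    ("PHE-aniline", "PHE", "Nc1ccccc1", 3.9, 180.0,
     (0.10, 0.09, 0.07), "F_aniline", True, True),
    ("SMX-sulfanilic", "SMX", "Nc1ccc(cc1)S(=O)(=O)O", 1.8, 90.0,
     (0.15, 0.17, 0.12), None, True, True),
    ("SMX-amino-isox", "SMX", "Cc1cc(N)no1", 2.6, 120.0,
     (0.20, 0.18, 0.15), None, True, True),
    ("SMX-hydroxy", "SMX", "Cc1cc(NS(=O)(=O)c2ccc(N)c(O)c2)no1", 5.9, 150.0,
     (0.10, 0.14, 0.11), None, True, False),
    ("MET-O-desmethyl", "MET", "CC(C)NCC(O)COc1ccc(CCO)cc1", 4.6, 230.0,
     (0.18, 0.20, 0.16), None, True, True),
    ("MET-alpha-OH", "MET", "CC(C)NCC(O)COc1ccc(C(O)CCO)cc1", 4.2, 220.0,
     (0.12, 0.14, 0.12), None, True, True),
    ("MET-deisopropyl", "MET", "NCC(O)COc1ccc(CCOC)cc1", 4.9, 200.0,
     (0.10, 0.12, 0.10), None, True, False),
    ("MET-peroxide", "MET", None, 5.1, 180.0,
     (0.0, 0.10, 0.09), None, False, True),          # formula-only, +H2O2
    ("PHE-4-hydroxy", "PHE", "CC1=C(O)C(=O)N(c2ccccc2)N1C", 4.4, 260.0,
     (0.16, 0.18, 0.15), None, True, True),
    ("PHE-desmethyl", "PHE", "O=C1CC(C)=NN1c1ccccc1", 4.8, 240.0,
     (0.12, 0.11, 0.10), None, True, False),
    ("FLE-des-CF3", "FLE", "O=C(NCC1CCCCN1)c1cc(O)ccc1OCC(F)(F)F",
     8.8, 170.0, (0.05, 0.18, 0.20), None, False, True),
]

# Additional (non-planted) suspects padding the per-parent lists, the way
# aggregated prediction/literature sources offer many more hypotheses than
# the experiment confirms.
_EXTRA_SUSPECTS = {
    "SMX": [
        ("sulfanilamide", "Nc1ccc(cc1)S(N)(=O)=O", ("BTE", "LIT")),
        ("acetyl-smx", "CC(=O)Nc1ccc(cc1)S(=O)(=O)Nc1cc(C)on1", ("BTH",)),
        ("2-aminophenol", "Nc1ccccc1O", ("LIT",)),
        ("phenol", "Oc1ccccc1", ("CTS", "LIT")),
        ("benzoquinone", "O=C1C=CC(=O)C=C1", ("CTS",)),
    ],
    "MET": [
        ("atenolol-amide", "CC(C)NCC(O)COc1ccc(CC(N)=O)cc1", ("BTH",)),
        ("met-aldehyde", "CC(C)NCC(O)COc1ccc(CC=O)cc1", ("BTE", "LIT")),
        ("met-diol", "OCC(O)COc1ccc(CCOC)cc1", ("BTE",)),
        ("met-phenyl", "CC(C)NCC(O)COc1ccccc1", ("LIT",)),
        ("metoprolol-acid", "CC(C)NCC(O)COc1ccc(CC(O)=O)cc1", ("LIT", "PC")),
    ],
    "PHE": [
        ("4-aminoantipyrine", "CC1=C(N)C(=O)N(c2ccccc2)N1C", ("BTH", "LIT")),
        ("n-phenylmaleimide", "O=C1C=CC(=O)N1c1ccccc1", ("CTS",)),
        ("acetanilide", "CC(=O)Nc1ccccc1", ("LIT",)),
        ("phe-epoxide", "CC1=CC(=O)N(C2CCCCC2)N1C", ("BTE",)),
    ],
    "FLE": [
        # positional isomer of the planted des-CF3 TP: both match the same
        # feature by accurate mass (the level-3a ambiguity case)
        ("fle-des-cf3-iso", "O=C(NCC1CCCCN1)c1cc(OCC(F)(F)F)ccc1O",
         ("CTS", "BTE", "BTH")),
        ("fle-acid", "OC(=O)c1cc(OCC(F)(F)F)ccc1OCC(F)(F)F", ("BTE",)),
        ("aminomethylpiperidine", "NCC1CCCCN1", ("BTH",)),
    ],
}

# TPs with reference standards (confirmation + calibration curves).
_STANDARD_TPS = ("SMX-aniline", "SMX-amino-isox", "SMX-sulfanilic",
                 "FLE-des-CF3")


def default_parents() -> list[ParentSpec]:
    out = []
    for pid, smiles, rt, rf, removal in _PARENT_DATA:
        conds = PHOTO_CONDITIONS + DARK_CONDITIONS
        out.append(ParentSpec(
            parent=Parent(parent_id=pid,
                          structure=StructureRecord.from_smiles(pid, smiles),
                          rt=rt, response_factor=rf),
            removal=dict(zip(conds, removal))))
    return out


def default_tp_defs() -> list[TPDef]:
    out = []
    for (tp_id, parent, smiles, rt, rf, yields, feature_id, has_ms2,
         _suspected) in _TP_DATA:
        out.append(TPDef(
            tp_id=tp_id, parent_id=parent, smiles=smiles,
            formula_delta=None if smiles else "+H2O2",
            yields=dict(zip(PHOTO_CONDITIONS, yields)),
            rt=rt, response_factor=rf, feature_id=feature_id,
            has_ms2=has_ms2))
    # one dark-control TP: metoprolol + O forms (slowly) with H2O2 alone
    out.append(TPDef(
        tp_id="MET-oxide", parent_id="MET",
        smiles="CC(C)NCC(O)COc1ccc(CCOC)cc1O", formula_delta=None,
        yields={"U": 0.05, "UH": 0.06, "UHN": 0.05, "DH": 0.02, "DHN": 0.02},
        rt=5.5, response_factor=210.0, has_ms2=True))
    return out


def synthetic_tp_defs(parents: list[ParentSpec], n: int, seed: int,
                      existing: list[TPDef] | None = None) -> list[TPDef]:
    """Extra formula-delta TPs to scale an experiment up (e.g. to plant
    50 TPs): random feasible metabolic-logic deltas, RT/response factors
    drawn once from realistic ranges.  Yields are drawn small and scaled
    to respect the remaining per-parent yield budget."""
    rng = np.random.default_rng(seed)
    budget: dict[str, float] = {}
    for ps in parents:
        used = max((sum(tp.yields.get(c, 0.0) for tp in (existing or [])
                        if tp.parent_id == ps.parent.parent_id)
                    for c in PHOTO_CONDITIONS + DARK_CONDITIONS),
                   default=0.0)
        budget[ps.parent.parent_id] = max(0.0, 0.95 - used)
    deltas = ["+O", "+O2", "-H2+O", "+H2O", "-H2", "+H2", "-CH2",
              "+O3", "-C2H4", "+CH2O", "-CO", "-CH4+O", "+H2O2+O"]
    out: list[TPDef] = []
    i = 0
    while len(out) < n:
        ps = parents[int(rng.integers(len(parents)))]
        delta = deltas[int(rng.integers(len(deltas)))]
        formula = ps.parent.structure.formula
        try:
            for sign, term in parse_delta(delta):
                formula = (formula_add(formula, term) if sign > 0
                           else formula_subtract(formula, term))
        except FormulaError:
            continue
        i += 1
        per_tp = budget[ps.parent.parent_id] / max(1, n)
        yields = {cond: float(rng.uniform(0.3, 1.0)) * per_tp
                  for cond in PHOTO_CONDITIONS}
        out.append(TPDef(
            tp_id=f"XTP-{ps.parent.parent_id}-{i:03d}",
            parent_id=ps.parent.parent_id,
            formula_delta=delta,
            yields=yields,
            rt=float(rng.uniform(1.5, 11.5)),
            response_factor=float(rng.uniform(80.0, 320.0)),
            has_ms2=False))
    return out


def default_simulation_spec(seed: int = 1, n_noise_features: int = 300,
                            noise_sigma: float = 0.1,
                            extra_tps: int = 0,
                            saturation_cap: float | None = None,
                            ) -> SimulationSpec:
    parents = default_parents()
    tps = default_tp_defs()
    if extra_tps:
        tps = tps + synthetic_tp_defs(parents, extra_tps, seed + 101,
                                      existing=tps)
    return SimulationSpec(parents=parents, tp_defs=tps,
                          n_noise_features=n_noise_features,
                          noise_sigma=noise_sigma,
                          saturation_cap=saturation_cap, seed=seed)


# ---------------------------------------------------------------------------
# Design assembly

def build_design(spec: SimulationSpec) -> ExperimentDesign:
    samples: list[SampleInfo] = []
    parent_ids = [ps.parent.parent_id for ps in spec.parents]
    top = max(spec.concentrations)

    def add(sample_type: str, condition: str, conc_map: dict[str, float],
            n_rep: int, tag: str) -> None:
        for exposure in (0.0, 2.0):
            for rep in range(1, n_rep + 1):
                sid = f"{tag}_{condition}_{int(exposure)}h_r{rep}"
                samples.append(SampleInfo(
                    sample_id=sid, sample_type=sample_type,
                    condition=condition, exposure_h=exposure,
                    initial_conc_ugL=dict(conc_map), replicate=rep))

    for cond in PHOTO_CONDITIONS:
        for conc in spec.concentrations:
            add("mixture", cond, {p: conc for p in parent_ids},
                spec.mixture_replicates, f"mix{int(conc)}")
    for pid in parent_ids:
        for cond in PHOTO_CONDITIONS:
            add(f"single:{pid}", cond, {pid: top},
                spec.single_replicates, f"sgl{pid}")
    for cond in DARK_CONDITIONS:
        add("mixture", cond, {p: top for p in parent_ids},
            spec.dark_replicates, "dark")
    return ExperimentDesign(samples)


# ---------------------------------------------------------------------------
# Simulation core

def _tp_formula(spec: SimulationSpec, tp: TPDef) -> MolecularFormula:
    if tp.smiles is not None:
        return StructureRecord.from_smiles(tp.tp_id, tp.smiles).formula
    formula = spec.parent_by_id(tp.parent_id).parent.structure.formula
    for sign, term in parse_delta(tp.formula_delta):
        formula = (formula_add(formula, term) if sign > 0
                   else formula_subtract(formula, term))
    return formula


def simulate(spec: SimulationSpec) -> SimulationResult:
    """Generate (design, feature table, spectra, truth table).

    Deterministic: the same spec (seed included) reproduces the output
    byte-for-byte.  Planted-TP molar formation per sample equals
    parent removal (µM) x yield; intensities are response factor x mass
    concentration x multiplicative lognormal noise, optionally truncated
    at a saturation cap.
    """
    rng = np.random.default_rng(spec.seed)
    design = build_design(spec)
    samples = design.samples
    n_samples = len(samples)
    parent_specs = {ps.parent.parent_id: ps for ps in spec.parents}

    feature_rows: list[dict] = []
    truth_rows: list[dict] = []
    concentrations: list[np.ndarray] = []   # µg/L per sample, pre-noise

    def sample_parent_conc(ps: ParentSpec, s: SampleInfo) -> float:
        initial = s.initial_conc_ugL.get(ps.parent.parent_id, 0.0)
        if initial <= 0:
            return 0.0
        if s.exposure_h == 0:
            return initial
        return initial * (1.0 - ps.removal.get(s.condition, 0.0))

    # parents
    for ps in spec.parents:
        conc = np.array([sample_parent_conc(ps, s) for s in samples])
        concentrations.append(conc * ps.parent.response_factor)
        feature_rows.append({
            "group_id": f"P_{ps.parent.parent_id}",
            "mz": adduct_mz(ps.parent.structure.monoisotopic_mass),
            "rt": ps.parent.rt,
        })
        truth_rows.append({
            "group_id": f"P_{ps.parent.parent_id}", "kind": "parent",
            "parent_id": ps.parent.parent_id, "tp_id": "",
            "smiles": ps.parent.structure.smiles,
            "formula": ps.parent.structure.formula.render(),
            "rt": ps.parent.rt,
            "response_factor": ps.parent.response_factor,
        })

    # planted TPs (shared feature_ids accumulate onto one feature)
    tp_features: dict[str, int] = {}
    tp_structures: dict[str, StructureRecord | None] = {}
    for tp in spec.tp_defs:
        ps = parent_specs[tp.parent_id]
        formula = _tp_formula(spec, tp)
        mw_parent = molar_mass(ps.parent.structure.formula)
        mw_tp = molar_mass(formula)
        conc = np.zeros(n_samples)
        for j, s in enumerate(samples):
            initial = s.initial_conc_ugL.get(tp.parent_id, 0.0)
            if initial <= 0 or s.exposure_h == 0:
                continue
            removed_uM = (initial / mw_parent) * ps.removal.get(s.condition,
                                                                0.0)
            tp_uM = removed_uM * tp.yields.get(s.condition, 0.0)
            conc[j] = tp_uM * mw_tp
        fid = tp.feature_id or f"T_{tp.tp_id}"
        if fid in tp_features:
            concentrations[tp_features[fid]] += conc * tp.response_factor
        else:
            tp_features[fid] = len(feature_rows)
            concentrations.append(conc * tp.response_factor)
            feature_rows.append({
                "group_id": fid,
                "mz": adduct_mz(monoisotopic_mass(formula)),
                "rt": tp.rt,
            })
        if tp.smiles is not None:
            tp_structures.setdefault(
                fid, StructureRecord.from_smiles(tp.tp_id, tp.smiles))
        else:
            tp_structures.setdefault(fid, None)
        truth_rows.append({
            "group_id": fid, "kind": "tp", "parent_id": tp.parent_id,
            "tp_id": tp.tp_id, "smiles": tp.smiles or "",
            "formula": formula.render(), "rt": tp.rt,
            "response_factor": tp.response_factor,
            **{f"yield_{c}": tp.yields.get(c, 0.0)
               for c in PHOTO_CONDITIONS + DARK_CONDITIONS},
        })

    # background features: intensity independent of dosed concentration
    n_noise = spec.n_noise_features
    noise_mz = rng.uniform(80.0, 600.0, size=n_noise)
    noise_rt = rng.uniform(0.5, 12.5, size=n_noise)
    noise_base = rng.lognormal(mean=np.log(8.0e3), sigma=1.0, size=n_noise)
    for k in range(n_noise):
        feature_rows.append({
            "group_id": f"N{k:05d}",
            "mz": float(noise_mz[k]),
            "rt": float(noise_rt[k]),
        })
        concentrations.append(np.full(n_samples, noise_base[k]))
        truth_rows.append({
            "group_id": f"N{k:05d}", "kind": "noise", "parent_id": "",
            "tp_id": "", "smiles": "", "formula": "",
            "rt": float(noise_rt[k]), "response_factor": np.nan,
        })

    signal = np.vstack(concentrations)
    if spec.noise_sigma > 0:
        noise = rng.lognormal(mean=0.0, sigma=spec.noise_sigma,
                              size=signal.shape)
    else:
        noise = np.ones_like(signal)
    intensity = signal * noise
    if spec.saturation_cap is not None:
        intensity = np.minimum(intensity, spec.saturation_cap)

    mz_jitter = rng.normal(0.0, spec.mz_jitter_mda / 1000.0,
                           size=len(feature_rows))
    df = pd.DataFrame(feature_rows)
    df["mz"] = df["mz"].to_numpy() + mz_jitter
    df = pd.concat([df, pd.DataFrame(
        intensity, columns=[s.sample_id for s in samples])], axis=1)
    features = FeatureGroupTable(df)

    spectra = _planted_spectra(spec, features, tp_features, tp_structures,
                               rng)
    truth = pd.DataFrame(truth_rows)
    return SimulationResult(design=design, features=features,
                            spectra=spectra, truth=truth,
                            parents=[ps.parent for ps in spec.parents])


def _planted_spectra(spec: SimulationSpec, features: FeatureGroupTable,
                     tp_features: dict[str, int],
                     tp_structures: dict[str, StructureRecord | None],
                     rng: np.random.Generator) -> list[Ms2Spectrum]:
    """Fragment spectra for planted structure TPs, generated from the true
    structure via the bond-breaking fragmenter plus m/z jitter."""
    has_ms2: dict[str, bool] = {}
    for tp in spec.tp_defs:
        fid = tp.feature_id or f"T_{tp.tp_id}"
        has_ms2[fid] = has_ms2.get(fid, False) or tp.has_ms2
    spectra: list[Ms2Spectrum] = []
    for fid in sorted(tp_features):
        structure = tp_structures.get(fid)
        if structure is None or not has_ms2.get(fid, False):
            continue
        frags = fragment_structure(structure, depth=2)
        precursor_mz = float(features.row(fid)["mz"])
        masses = sorted({round(m, 6) for _, m in frags.fragments},
                        reverse=True)
        peaks = []
        for i, m in enumerate(masses[:8]):
            mz = m + 1.007276 + float(rng.normal(0.0, 0.0008))
            inten = 1000.0 * (0.75 ** i)
            peaks.append((mz, inten))
        # co-isolated background: real MS2 carries peaks the true structure
        # cannot explain; the same peaks appear in the flanking (off-peak)
        # spectrum, which is what the background-removal step subtracts
        background = [(float(rng.uniform(50.0, precursor_mz - 20.0)),
                       float(rng.uniform(60.0, 220.0))) for _ in range(2)]
        peaks.extend(background)
        spectra.append(Ms2Spectrum(feature_group_id=fid,
                                   precursor_mz=precursor_mz,
                                   peaks=sorted(peaks)))
        spectra.append(Ms2Spectrum(
            feature_group_id=f"{fid}::flank1",
            precursor_mz=precursor_mz,
            peaks=sorted((mz, inten * float(rng.uniform(0.8, 1.2)))
                         for mz, inten in background)))
    return spectra


# ---------------------------------------------------------------------------
# Default suspect lists, decoys, standards

def default_suspects(parents: list[Parent]) -> list[Suspect]:
    """Structure-suspect lists emulating aggregated prediction/literature
    sources: the planted TPs marked as suspected, plus per-parent padding
    hypotheses that the experiment does not confirm."""
    out: list[Suspect] = []
    source_cycle = {
        True: (("LIT", "BTE"), ("CTS", "LIT"), ("BTE",), ("BTH", "LIT"),
               ("BTE", "LIT"), ("CTS", "BTE", "BTH"), ("PC",)),
    }
    i = 0
    for (tp_id, parent, smiles, _rt, _rf, _yields, _fid, _ms2,
         suspected) in _TP_DATA:
        if not suspected or smiles is None:
            continue
        rec = StructureRecord.from_smiles(tp_id, smiles)
        sources = source_cycle[True][i % len(source_cycle[True])]
        i += 1
        out.append(Suspect(
            suspect_id=f"SUS-{tp_id}", parent_id=parent, kind="structure",
            smiles=smiles, formula=rec.formula,
            sources=frozenset(sources), transformation_label=tp_id))
    for parent_id, entries in _EXTRA_SUSPECTS.items():
        for name, smiles, sources in entries:
            rec = StructureRecord.from_smiles(name, smiles)
            out.append(Suspect(
                suspect_id=f"SUS-{parent_id}-{name}", parent_id=parent_id,
                kind="structure", smiles=smiles, formula=rec.formula,
                sources=frozenset(sources), transformation_label=name))
    return out


_DECOY_SCAFFOLDS = [
    "c1ccccc1", "c1ccncc1", "c1ccc2ccccc2c1", "C1CCCCC1", "C1CCNCC1",
    "c1ccoc1", "c1ccsc1", "c1cnc[nH]1", "c1ccc2[nH]ccc2c1", "C1CCOC1",
    "c1cncnc1", "C1CCNC1",
]
_DECOY_SUBSTITUENTS = [
    "CC(=O)N", "CCO", "CN(C)", "COC(=O)", "NC(=O)", "OCC(O)C", "CCCC",
    "CC(C)O", "N(CC)CC", "OC(=O)CC", "CCN", "COCC",
]


def decoy_library() -> list[tuple[str, str]]:
    """A deterministic drug-like decoy set (~140 structures) built by
    combining scaffolds and substituents; used as the offline stand-in for
    database candidate retrieval."""
    from rdkit import Chem
    seen: set[str] = set()
    out: list[tuple[str, str]] = []
    for sub in _DECOY_SUBSTITUENTS:
        for scaf in _DECOY_SCAFFOLDS:
            smiles = sub + scaf
            mol = Chem.MolFromSmiles(smiles)
            if mol is None:
                continue
            canonical = Chem.MolToSmiles(mol)
            if canonical in seen:
                continue
            seen.add(canonical)
            out.append((f"DEC{len(out):03d}", canonical))
    return out


def candidate_tables(result: SimulationResult,
                     decoys: list[tuple[str, str]] | None = None
                     ) -> pd.DataFrame:
    """Compound-candidate tables for every planted structure TP feature:
    the true structure hidden among the full decoy library, with neutral
    candidate ids ordered by structure key."""
    decoys = decoys if decoys is not None else decoy_library()
    rows = []
    truth = result.truth
    planted = truth[(truth["kind"] == "tp") & (truth["smiles"] != "")]
    for gid in sorted(set(planted["group_id"])):
        entries = [(s,) for s in planted.loc[planted["group_id"] == gid,
                                             "smiles"]]
        all_smiles = [s for (s,) in entries] + [s for _, s in decoys]
        keyed = sorted({_connectivity_key(s): s
                        for s in all_smiles}.items())
        for i, (_key, smiles) in enumerate(keyed):
            rows.append({
                "group_id": gid,
                "candidate_id": f"C-{gid}-{i:03d}",
                "kind": "compound",
                "smiles": smiles,
                "formula": StructureRecord.from_smiles("c", smiles)
                .formula.render(),
            })
    return pd.DataFrame(rows)


def _connectivity_key(smiles: str) -> str:
    return StructureRecord.from_smiles("k", smiles).canonical_key()


def standards_tables(result: SimulationResult
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reference-standard table and calibration series.

    Parents calibrate on the M+2 isotopologue channel over 12.5-250 µg/L
    (two-fold serial dilution); TP standards on the monoisotopic channel
    over 1.2-150 µg/L.  Responses are exactly linear: the curves encode
    the planted response factors.
    """
    from .chem import isotope_pattern, parse_formula
    from ._elements import KNOWN_ELEMENTS
    std_rows, cal_rows = [], []
    truth = result.truth
    for p in result.parents:
        std_rows.append({
            "analyte_id": f"STD-{p.parent_id}", "rt": p.rt,
            "smiles": p.structure.smiles,
            "formula": p.structure.formula.render(),
            "target_id": p.parent_id,
        })
        m2 = isotope_pattern(p.structure.formula).abundance(2)
        conc = 250.0
        for _ in range(5):
            cal_rows.append({"analyte_id": f"STD-{p.parent_id}",
                             "channel": "M+2", "conc_ugL": conc,
                             "response": p.response_factor * m2 * conc})
            conc /= 2.0
    tp_rows = truth[truth["kind"] == "tp"]
    for tp_id in _STANDARD_TPS:
        row = tp_rows[tp_rows["tp_id"] == tp_id]
        if row.empty:
            continue
        row = row.iloc[0]
        std_rows.append({
            "analyte_id": f"STD-{tp_id}", "rt": float(row["rt"]),
            "smiles": row["smiles"], "formula": row["formula"],
            "target_id": tp_id,
        })
        conc = 150.0
        for _ in range(6):
            cal_rows.append({"analyte_id": f"STD-{tp_id}",
                             "channel": "monoisotopic", "conc_ugL": conc,
                             "response": float(row["response_factor"]) * conc})
            conc /= 2.0
    return pd.DataFrame(std_rows), pd.DataFrame(cal_rows)


# ---------------------------------------------------------------------------
# One-call writer used by the CLI

def write_simulation(result: SimulationResult, out_dir) -> dict[str, str]:
    import os
    from . import io as tio
    os.makedirs(out_dir, exist_ok=True)
    paths = {name: os.path.join(out_dir, fname) for name, fname in [
        ("design", "design.csv"), ("features", "features.csv"),
        ("parents", "parents.csv"), ("suspects", "suspects.csv"),
        ("spectra", "spectra.msp"), ("truth", "truth.csv"),
        ("candidates", "candidates.csv"), ("standards", "standards.csv"),
        ("calibration", "calibration.csv"),
    ]}
    tio.write_design(result.design, paths["design"])
    tio.write_features(result.features, paths["features"])
    tio.write_parents(result.parents, paths["parents"])
    tio.write_suspects(default_suspects(result.parents), paths["suspects"])
    tio.write_msp(result.spectra, paths["spectra"])
    result.truth.to_csv(paths["truth"], index=False)
    candidate_tables(result).to_csv(paths["candidates"], index=False)
    standards, calibration = standards_tables(result)
    standards.to_csv(paths["standards"], index=False)
    calibration.to_csv(paths["calibration"], index=False)
    return paths
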