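"""Molecular formula algebra, monoisotopic masses, isotope patterns,
adduct m/z and structure metrics.

These primitives underpin every downstream screening stage: suspect
matching works on exact [M+H]+ masses, parent quantitation on the low
abundance M+2 isotopologue cluster, and unknown-candidate ranking on
maximum-common-substructure fit and fingerprint similarity.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._elements import (
    ATOMIC_WEIGHT,
    DEFAULT_ALPHABET,
    ISOTOPE_ABUNDANCE,
    KNOWN_ELEMENTS,
    MONOISOTOPIC_MASS,
    PROTON_MASS,
)

__all__ = [
    "FormulaError",
    "StructureError",
    "MolecularFormula",
    "IsotopePattern",
    "StructureRecord",
    "parse_formula",
    "formula_add",
    "formula_subtract",
    "monoisotopic_mass",
    "molar_mass",
    "adduct_mz",
    "isotope_pattern",
    "structure_similarity",
    "structure_fit",
    "StructureFitResult",
    "predict_logp",
    "rdbe",
]


class FormulaError(ValueError):
    """Raised for malformed or chemically infeasible formula input."""


class StructureError(ValueError):
    """Raised when a SMILES string cannot be interpreted as a structure."""


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")

# Positive-mode electrospray adducts.  Only [M+H]+ is used by the default
# workflow; the table is the extension point for other ionisation modes.
ADDUCTS: dict[str, float] = {
    "[M+H]+": PROTON_MASS,
}


@dataclass(frozen=True)
class MolecularFormula:
    """An immutable elemental composition with Hill-order rendering.

    Element counts are strictly positive; an empty formula is not
    representable (subtraction that would empty the formula raises).
    """

    _counts: tuple[tuple[str, int], ...]

    @staticmethod
    def from_counts(counts: Mapping[str, int],
                    alphabet: Sequence[str] | None = None) -> "MolecularFormula":
        alphabet = tuple(alphabet) if alphabet is not None else KNOWN_ELEMENTS
        clean: dict[str, int] = {}
        for elem, n in counts.items():
            if n == 0:
                continue
            if elem not in KNOWN_ELEMENTS:
                raise FormulaError(f"unknown element symbol {elem!r}")
            if elem not in alphabet:
                raise FormulaError(
                    f"element {elem!r} outside the configured alphabet "
                    f"{'/'.join(alphabet)}")
            if n < 0:
                raise FormulaError(f"negative count for element {elem!r}")
            clean[elem] = int(n)
        if not clean:
            raise FormulaError("empty formula is not allowed")
        return MolecularFormula(_hill_sorted(clean))

    @property
    def counts(self) -> dict[str, int]:
        return dict(self._counts)

    def count(self, element: str) -> int:
        return dict(self._counts).get(element, 0)

    @property
    def elements(self) -> tuple[str, ...]:
        return tuple(e for e, _ in self._counts)

    def render(self) -> str:
        return "".join(f"{e}{n if n > 1 else ''}" for e, n in self._counts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        return formula_add(self, other)

    def __sub__(self, other: "MolecularFormula") -> "MolecularFormula":
        return formula_subtract(self, other)

    def contains(self, other: "MolecularFormula") -> bool:
        mine = self.counts
        return all(mine.get(e, 0) >= n for e, n in other.counts.items())

    def heavy_atom_count(self) -> int:
        return sum(n for e, n in self._counts if e != "H")


def _hill_sorted(counts: Mapping[str, int]) -> tuple[tuple[str, int], ...]:
    """Hill order: C first, then H, then other elements alphabetically.
    Without carbon, everything (H included) is alphabetical."""
    elems = sorted(counts)
    if "C" in counts:
        ordered = ["C"] + (["H"] if "H" in counts else []) + [
            e for e in elems if e not in ("C", "H")]
    else:
        ordered = elems
    return tuple((e, counts[e]) for e in ordered)


def parse_formula(text: str,
                  alphabet: Sequence[str] | None = None) -> MolecularFormula:
    """Parse a Hill-order / element-count string like ``C10H11N3O3S``.

    Repeated element symbols accumulate.  Symbols outside the configured
    alphabet (default C/H/N/O/S/F) are rejected by name.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("formula string is empty")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(text):
        if match.start() != pos:
            raise FormulaError(
                f"unparseable formula {text!r} at position {pos}")
        pos = match.end()
        elem, digits = match.groups()
        n = int(digits) if digits else 1
        if n <= 0:
            raise FormulaError(
                f"zero count for element {elem!r} in {text!r}")
        counts[elem] = counts.get(elem, 0) + n
    if pos != len(text):
        raise FormulaError(f"unparseable formula {text!r} at position {pos}")
    return MolecularFormula.from_counts(
        counts, alphabet=alphabet if alphabet is not None else DEFAULT_ALPHABET)


def formula_add(a: MolecularFormula, b: MolecularFormula) -> MolecularFormula:
    counts = a.counts
    for e, n in b.counts.items():
        counts[e] = counts.get(e, 0) + n
    return MolecularFormula(_hill_sorted(counts))


def formula_subtract(a: MolecularFormula, b: MolecularFormula) -> MolecularFormula:
    counts = a.counts
    for e, n in b.counts.items():
        have = counts.get(e, 0)
        if have < n:
            raise FormulaError(
                f"cannot subtract: element {e!r} deficient "
                f"({have} available, {n} required)")
        counts[e] = have - n
        if counts[e] == 0:
            del counts[e]
    if not counts:
        raise FormulaError("subtraction produced an empty formula")
    return MolecularFormula(_hill_sorted(counts))


def monoisotopic_mass(f: MolecularFormula) -> float:
    """Sum of most-abundant-isotope masses, in Da."""
    return sum(MONOISOTOPIC_MASS[e] * n for e, n in f.counts.items())


def molar_mass(f: MolecularFormula) -> float:
    """Average molar mass (g/mol) from standard atomic weights."""
    return sum(ATOMIC_WEIGHT[e] * n for e, n in f.counts.items())


def adduct_mz(mass: float, adduct: str = "[M+H]+") -> float:
    """m/z of an adduct ion of a neutral of the given monoisotopic mass."""
    try:
        shift = ADDUCTS[adduct]
    except KeyError:
        raise FormulaError(
            f"unsupported adduct {adduct!r}; known: {sorted(ADDUCTS)}")
    return mass + shift


def rdbe(f: MolecularFormula) -> float:
    """Ring plus double bond equivalents for CHNOSF-type formulas.

    Monovalent halogens count like hydrogen, divalent O/S contribute
    nothing, trivalent N adds half a degree.
    """
    c = f.count("C") + f.count("Si")
    h = f.count("H") + f.count("F") + f.count("Cl") + f.count("Br")
    n = f.count("N") + f.count("P")
    return c - h / 2.0 + n / 2.0 + 1.0


@dataclass(frozen=True)
class IsotopePattern:
    """Nominal-mass-aggregated isotopologue abundances relative to the
    monoisotopic peak (offset 0 has abundance 1 by construction)."""

    entries: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        offsets = [o for o, _ in self.entries]
        if offsets != sorted(set(offsets)):
            raise ValueError("isotope pattern offsets must strictly increase")
        if not self.entries or self.entries[0] != (0, 1.0):
            raise ValueError("offset 0 must be present with abundance 1")
        if any(a < 0 for _, a in self.entries):
            raise ValueError("negative abundance in isotope pattern")

    def abundance(self, offset: int) -> float:
        for o, a in self.entries:
            if o == offset:
                return a
        return 0.0


def isotope_pattern(f: MolecularFormula, max_offset: int = 2) -> IsotopePattern:
    """Isotopologue abundances by nominal mass offset, via convolution of
    per-element isotope distributions, normalised to the monoisotopic peak.

    Isotopes with equal nominal mass are agglomerated, which matches how
    quadrupole-TOF instruments report the M+1/M+2 clusters.
    """
    if max_offset < 2:
        raise ValueError("max_offset must be >= 2")
    size = max_offset + 1
    dist = np.zeros(size)
    dist[0] = 1.0
    for elem, n in f.counts.items():
        atom = np.asarray(ISOTOPE_ABUNDANCE[elem])
        if atom.size == 1:
            continue
        elem_dist = _poly_power(atom, n, size)
        dist = np.convolve(dist, elem_dist)[:size]
    if dist[0] <= 0:
        raise FormulaError("monoisotopic abundance vanished (bad formula)")
    rel = dist / dist[0]
    rel[0] = 1.0
    return IsotopePattern(tuple((i, float(rel[i])) for i in range(size)))


def _poly_power(coeffs: np.ndarray, n: int, size: int) -> np.ndarray:
    """(Σ c_i x^i)^n truncated to the first `size` coefficients, by
    exponentiation through repeated squaring."""
    result = np.zeros(size)
    result[0] = 1.0
    base = np.zeros(size)
    base[: min(size, coeffs.size)] = coeffs[:size]
    while n:
        if n & 1:
            result = np.convolve(result, base)[:size]
        base = np.convolve(base, base)[:size]
        n >>= 1
    return result


# ---------------------------------------------------------------------------
# Structures

def _rdkit():
    from rdkit import Chem, RDLogger
    RDLogger.DisableLog("rdApp.*")
    return Chem


def _mol_from_smiles(smiles: str, who: str = "structure"):
    Chem = _rdkit()
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureError(f"unparseable SMILES for {who}: {smiles!r}")
    return mol


def formula_from_smiles(smiles: str, who: str = "structure") -> MolecularFormula:
    from rdkit.Chem import rdMolDescriptors
    mol = _mol_from_smiles(smiles, who)
    text = rdMolDescriptors.CalcMolFormula(mol)
    # strip charge suffixes such as "+" on ionic species
    text = text.rstrip("+-0123456789") if text[-1] in "+-" else text
    return parse_formula(text, alphabet=KNOWN_ELEMENTS)


@dataclass
class StructureRecord:
    """A candidate/parent/suspect structure with derived chemistry cached."""

    identifier: str
    smiles: str
    formula: MolecularFormula = field(repr=False)
    monoisotopic_mass: float = field(repr=False)
    _logp: float | None = field(default=None, repr=False)
    _mol: object = field(default=None, repr=False, compare=False)

    @staticmethod
    def from_smiles(identifier: str, smiles: str) -> "StructureRecord":
        mol = _mol_from_smiles(smiles, identifier)
        formula = formula_from_smiles(smiles, identifier)
        rec = StructureRecord(identifier=identifier, smiles=smiles,
                              formula=formula,
                              monoisotopic_mass=monoisotopic_mass(formula))
        rec._mol = mol
        return rec

    @property
    def mol(self):
        if self._mol is None:
            self._mol = _mol_from_smiles(self.smiles, self.identifier)
        return self._mol

    @property
    def logp(self) -> float:
        if self._logp is None:
            self._logp = predict_logp(self)
        return self._logp

    def canonical_key(self) -> str:
        """Connectivity-level InChI key block (first 14 characters), used to
        merge stereoisomers when deduplicating suspects."""
        from rdkit import Chem
        key = Chem.MolToInchiKey(self.mol)
        return key.split("-")[0]


@lru_cache(maxsize=4096)
def _fingerprint_cached(smiles: str, radius: int, n_bits: int):
    from rdkit.Chem import rdFingerprintGenerator
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius,
                                                    fpSize=n_bits)
    return gen.GetFingerprint(_mol_from_smiles(smiles))


def structure_similarity(a: StructureRecord, b: StructureRecord,
                         radius: int = 2, n_bits: int = 2048) -> float:
    """Tanimoto similarity of circular (Morgan) fingerprints.

    Radius 2 / 2048 bits is the field's de-facto standard (ECFP4-like);
    symmetric and 1.0 for identical connectivity.
    """
    from rdkit import DataStructs
    fa = _fingerprint_cached(a.smiles, radius, n_bits)
    fb = _fingerprint_cached(b.smiles, radius, n_bits)
    return float(DataStructs.TanimotoSimilarity(fa, fb))


@dataclass(frozen=True)
class StructureFitResult:
    value: float
    fit_in_candidate: float
    fit_in_parent: float
    mcs_atoms: int
    timed_out: bool


def structure_fit(candidate: StructureRecord, parent: StructureRecord,
                  timeout_s: float = 2.0,
                  direction: str = "max") -> StructureFitResult:
    """Maximum-common-substructure "fit" between a candidate and a parent.

    The MCS is connected and element- and bond-order-matched.  The fit is
    |MCS| divided by the heavy-atom count of each molecule; ``direction``
    selects ``max`` of the two ratios (default), ``candidate`` or
    ``parent``.  A timeout yields a flagged result whose MCS size is the
    best found so far (a conservative lower bound), never a silent value.
    """
    from rdkit.Chem import rdFMCS
    params = rdFMCS.MCSParameters()
    params.AtomTyper = rdFMCS.AtomCompare.CompareElements
    params.BondTyper = rdFMCS.BondCompare.CompareOrder
    params.Timeout = max(1, int(round(timeout_s)))
    res = rdFMCS.FindMCS([candidate.mol, parent.mol], params)
    n = res.numAtoms if res.numAtoms > 0 else 0
    n_cand = candidate.mol.GetNumHeavyAtoms()
    n_par = parent.mol.GetNumHeavyAtoms()
    fit_c = n / n_cand if n_cand else 0.0
    fit_p = n / n_par if n_par else 0.0
    if direction == "max":
        value = max(fit_c, fit_p)
    elif direction == "candidate":
        value = fit_c
    elif direction == "parent":
        value = fit_p
    else:
        raise ValueError(f"unknown fit direction {direction!r}")
    if res.canceled:
        warnings.warn(
            f"MCS timed out for {candidate.identifier} vs {parent.identifier};"
            " reported fit is a lower bound", RuntimeWarning, stacklevel=2)
    return StructureFitResult(value=value, fit_in_candidate=fit_c,
                              fit_in_parent=fit_p, mcs_atoms=n,
                              timed_out=bool(res.canceled))


def predict_logp(s: StructureRecord) -> float:
    """Crippen atom-contribution octanol/water log P estimate.

    Deterministic for a given structure; used only for coarse elution-order
    reasoning (reversed phase: higher log P elutes later), so estimator
    bias is tolerable.
    """
    from rdkit.Chem import Crippen
    return float(Crippen.MolLogP(s.mol))
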