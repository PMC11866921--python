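"""Suspect TP screening: aggregate multi-source suspect lists, generate
formula suspects by metabolic logic, and match both to prioritized
features by accurate [M+H]+ m/z.

Structure suspects (known SMILES) take precedence over formula suspects:
a feature claimed by a structure suspect is not offered to formula
screening, and features matching neither are handed to the
unknown-screening workflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chem import (
    FormulaError,
    MolecularFormula,
    StructureRecord,
    adduct_mz,
    formula_add,
    formula_subtract,
    monoisotopic_mass,
    parse_formula,
)
from .model import FeatureGroupTable, Parent, Suspect


@dataclass
class SuspectMatch:
    group_id: str
    suspect_id: str
    parent_id: str
    kind: str              # "structure" | "formula"
    mz_error_mda: float


@dataclass
class ScreenResult:
    matches: list[SuspectMatch]
    structure_matched: list[str]   # feature group ids (ordered, unique)
    formula_matched: list[str]
    unknown: list[str]
    accounting: dict                # per-parent Table-style counts


def aggregate_suspects(lists: list[Suspect]) -> list[Suspect]:
    """Deduplicate suspects across prediction/literature sources.

    Structure suspects merge on the connectivity block of the InChI key
    (so stereoisomers collapse); formula suspects merge on
    (parent, formula).  Source tags are unioned; the first-seen id and
    label win.  Idempotent.
    """
    merged: dict[tuple, Suspect] = {}
    for s in lists:
        if s.kind == "structure":
            key = ("structure", s.parent_id, s.structure.canonical_key())
        else:
            key = ("formula", s.parent_id, s.formula.render())
        if key in merged:
            prev = merged[key]
            merged[key] = Suspect(
                suspect_id=prev.suspect_id, parent_id=prev.parent_id,
                kind=prev.kind, smiles=prev.smiles, formula=prev.formula,
                sources=frozenset(prev.sources | s.sources),
                transformation_label=prev.transformation_label
                or s.transformation_label)
        else:
            merged[key] = s
    return list(merged.values())


def source_overlap_counts(suspects: list[Suspect]) -> dict[str, dict[str, int]]:
    """Per-source totals and per-source unique counts (overlap summary)."""
    total: dict[str, int] = {}
    unique: dict[str, int] = {}
    for s in suspects:
        for src in s.sources:
            total[src] = total.get(src, 0) + 1
        if len(s.sources) == 1:
            (src,) = s.sources
            unique[src] = unique.get(src, 0) + 1
    return {"total": total, "unique_to_source": unique}


def parse_delta(text: str) -> list[tuple[int, MolecularFormula]]:
    """Parse a transformation delta like ``+O``, ``-H2+O`` or ``-C2HF3``
    into signed formula terms."""
    text = text.strip().replace(" ", "")
    if not text:
        raise FormulaError("empty transformation delta")
    if text[0] not in "+-":
        text = "+" + text
    terms: list[tuple[int, MolecularFormula]] = []
    token = ""
    sign = 1
    for ch in text:
        if ch in "+-":
            if token:
                terms.append((sign, parse_formula(token)))
            sign = 1 if ch == "+" else -1
            token = ""
        else:
            token += ch
    if not token:
        raise FormulaError(f"dangling sign in delta {text!r}")
    terms.append((sign, parse_formula(token)))
    return terms


def logic_formula_suspects(parent: Parent,
                           deltas: list[str],
                           log: list[str] | None = None) -> list[Suspect]:
    """Formula suspects from parent ± simple metabolic-logic deltas
    (oxidation, hydration, dealkylation, ...).  Infeasible deltas (e.g.
    a defluorination applied to a fluorine-free parent) are skipped with
    a logged reason."""
    out: list[Suspect] = []
    seen: set[str] = set()
    for i, delta in enumerate(deltas):
        formula = parent.structure.formula
        try:
            for sign, term in parse_delta(delta):
                formula = (formula_add(formula, term) if sign > 0
                           else formula_subtract(formula, term))
        except FormulaError as err:
            if log is not None:
                log.append(f"logic delta {delta!r} infeasible for "
                           f"{parent.parent_id}: {err}")
            continue
        rendered = formula.render()
        if rendered in seen:
            continue
        seen.add(rendered)
        out.append(Suspect(
            suspect_id=f"LOGIC-{parent.parent_id}-{i + 1}",
            parent_id=parent.parent_id,
            kind="formula",
            formula=formula,
            sources=frozenset({"LOGIC"}),
            transformation_label=f"{parent.parent_id}{delta}"))
    return out


def match_suspects(features: FeatureGroupTable, suspects: list[Suspect],
                   config: dict) -> ScreenResult:
    """Match prioritized features to suspects by accurate m/z.

    Structure suspects claim features first; only unclaimed features are
    screened against formula suspects; the remainder are "unknowns".
    Every feature lands in exactly one class.
    """
    tol = config["mz_tol_mda"] / 1000.0
    adduct = config["adduct"]
    feat_mz = features.df["mz"].to_numpy()
    gids = list(features.df["group_id"])

    matches: list[SuspectMatch] = []
    claimed: dict[str, str] = {}   # group_id -> class

    for kind in ("structure", "formula"):
        for s in suspects:
            if s.kind != kind:
                continue
            target = adduct_mz(s.neutral_mass, adduct)
            err = feat_mz - target
            for idx in np.flatnonzero(np.abs(err) <= tol):
                gid = gids[idx]
                if claimed.get(gid) == "structure" and kind == "formula":
                    continue   # structure matches take the feature
                matches.append(SuspectMatch(
                    group_id=gid, suspect_id=s.suspect_id,
                    parent_id=s.parent_id, kind=kind,
                    mz_error_mda=float(err[idx] * 1000.0)))
                claimed.setdefault(gid, kind)

    structure_matched = [g for g in gids if claimed.get(g) == "structure"]
    formula_matched = [g for g in gids if claimed.get(g) == "formula"]
    unknown = [g for g in gids if g not in claimed]

    parents = sorted({s.parent_id for s in suspects})
    accounting: dict = {"per_parent": {}, "totals": {}}
    for p in parents:
        p_struct = [s for s in suspects if s.parent_id == p
                    and s.kind == "structure"]
        p_form = [s for s in suspects if s.parent_id == p
                  and s.kind == "formula"]
        m_struct = {m.suspect_id for m in matches
                    if m.parent_id == p and m.kind == "structure"}
        m_form = {m.suspect_id for m in matches
                  if m.parent_id == p and m.kind == "formula"}
        feats = {m.group_id for m in matches if m.parent_id == p}
        accounting["per_parent"][p] = {
            "total_structure_suspects": len(p_struct),
            "matched_structure_suspects": len(m_struct),
            "total_formula_suspects": len(p_form),
            "matched_formula_suspects": len(m_form),
            "matched_features": len(feats),
        }
    accounting["totals"] = {
        "structure_matched_features": len(structure_matched),
        "formula_matched_features": len(formula_matched),
        "unknown_features": len(unknown),
        "prioritized_features": len(gids),
    }
    return ScreenResult(matches=matches, structure_matched=structure_matched,
                        formula_matched=formula_matched, unknown=unknown,
                        accounting=accounting)
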