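"""End-to-end orchestration: from a directory of input tables to a
fully screened, annotated, ranked, identified and semi-quantified set of
parent/TP links, with per-step provenance for the summary accounting.

Each stage function is thin glue over the corresponding module; the
``PipelineState`` dataclass carries everything downstream stages and the
reporting layer need.  All iteration orders are deterministic so a fixed
input directory yields byte-identical outputs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as tio
from ._elements import KNOWN_ELEMENTS
from .annotate import (
    AnnotatedSpectrum,
    annotate_fragments,
    enumerate_formulas,
)
from .chem import (
    MolecularFormula,
    StructureRecord,
    adduct_mz,
    isotope_pattern,
    molar_mass,
    monoisotopic_mass,
    parse_formula,
)
from .config import dump_config
from .identify import ConfidenceLevel, assign_level, confirm_with_standard
from .linking import build_links, kept_links, prune_links
from .model import (
    ExperimentDesign,
    FeatureGroupTable,
    Ms2Spectrum,
    Parent,
    Suspect,
    TPLink,
)
from .prioritize import PrioritizationResult, prioritize
from .quantify import (
    CalibrationCurve,
    MassBalance,
    RemovalStat,
    SemiQuant,
    fit_calibration,
    mass_balance,
    parent_rf_predictor,
    removal_stats,
    semi_quantify,
)
from .ranking import (
    CandidateScore,
    combine_score,
    derive_thresholds,
    rank_candidates,
    suspect_calibration_scores,
)
from .suspects import (
    ScreenResult,
    aggregate_suspects,
    logic_formula_suspects,
    match_suspects,
)

PHOTO_CONDITIONS = ("U", "UH", "UHN")


@dataclass
class PipelineState:
    design: ExperimentDesign
    features: FeatureGroupTable
    parents: list[Parent]
    suspects: list[Suspect]
    spectra: dict[str, Ms2Spectrum]
    prioritization: PrioritizationResult
    screen: ScreenResult
    links: list[TPLink]
    annotations: dict[str, AnnotatedSpectrum]
    thresholds: dict[str, float] | None
    candidate_scores: dict[str, list[CandidateScore]]   # per group_id
    ranking_counts: dict[str, dict[str, int]]
    levels: dict[tuple, ConfidenceLevel]                # per link key
    curves: dict[str, CalibrationCurve]
    removal: list[RemovalStat]
    balances: list[MassBalance]
    tp_quants: dict[tuple, dict]       # (parent, gid, cond) -> quant info
    log: list[str] = field(default_factory=list)


def load_inputs(data_dir, config):
    design = tio.read_design(os.path.join(data_dir, "design.csv"))
    features = tio.read_features(os.path.join(data_dir, "features.csv"),
                                 design)
    parents = tio.read_parents(os.path.join(data_dir, "parents.csv"))
    sus_path = os.path.join(data_dir, "suspects.csv")
    suspects = tio.read_suspects(sus_path) if os.path.exists(sus_path) else []
    spectra_path = os.path.join(data_dir, "spectra.msp")
    spectra = (tio.read_msp(spectra_path)
               if os.path.exists(spectra_path) else [])
    cand_path = os.path.join(data_dir, "candidates.csv")
    candidates = (tio.read_candidates(cand_path)
                  if os.path.exists(cand_path) else pd.DataFrame(
                      columns=["group_id", "candidate_id", "kind", "smiles",
                               "formula"]))
    std_path = os.path.join(data_dir, "standards.csv")
    standards = (tio.read_standards(std_path)
                 if os.path.exists(std_path) else None)
    cal_path = os.path.join(data_dir, "calibration.csv")
    calibration = (tio.read_calibration(cal_path)
                   if os.path.exists(cal_path) else None)
    return (design, features, parents, suspects, spectra, candidates,
            standards, calibration)


def run_pipeline(data_dir, config) -> PipelineState:
    (design, features, parents, suspect_lists, spectra_list, candidates,
     standards, calibration) = load_inputs(data_dir, config)
    log: list[str] = ["configuration:"]
    log += ["  " + line for line in dump_config(config).splitlines()]

    # --- prioritization -----------------------------------------------------
    prio = prioritize(features, design, parents, config)
    log.append(f"prioritization: {prio.step_counts}")

    # --- suspect screening --------------------------------------------------
    suspects = aggregate_suspects(suspect_lists)
    for p in sorted(parents, key=lambda p: p.parent_id):
        suspects += logic_formula_suspects(
            p, config["suspects"]["logic_deltas"], log)
    suspects = aggregate_suspects(suspects)
    screen = match_suspects(prio.features, suspects, config)
    log.append(f"screen: {screen.accounting['totals']}")

    # --- linking ------------------------------------------------------------
    links = build_links(screen, prio.features, design, parents,
                        detection_floor=config["linking"]["detection_floor"])
    links = prune_links(links, prio.features, design, config)
    log.append(f"links: {len(kept_links(links))} kept / {len(links)} built")

    # --- spectra cleanup and annotation ------------------------------------
    acfg = config["annotation"]
    from .annotate import split_and_clean_spectra
    spectra = split_and_clean_spectra(
        spectra_list, background_factor=acfg["background_factor"],
        rel_intensity_floor=acfg["rel_intensity_floor"],
        mz_tol_mda=acfg["fragment_tol_mda"])
    annotations: dict[str, AnnotatedSpectrum] = {}
    feature_formula: dict[str, list[MolecularFormula]] = {}
    suspect_by_id = {s.suspect_id: s for s in suspects}
    for gid in sorted(set(prio.features.df["group_id"])):
        row = prio.features.row(gid)
        hits = [m for m in screen.matches if m.group_id == gid]
        if hits:
            formulas = [suspect_by_id[m.suspect_id].formula for m in hits]
        else:
            formulas = [f for f, _ in enumerate_formulas(
                float(row["mz"]), tol_mda=config["mz_tol_mda"],
                bounds=acfg["bounds"])]
        feature_formula[gid] = formulas
        if gid in spectra and formulas:
            annotations[gid] = annotate_fragments(
                spectra[gid], formulas[0],
                tol_mda=acfg["fragment_tol_mda"])

    # --- ranking ------------------------------------------------------------
    parent_map = {p.parent_id: p for p in parents}
    calibration_records = []
    for m in screen.matches:
        if m.kind != "structure":
            continue
        s = suspect_by_id[m.suspect_id]
        rt = float(prio.features.row(m.group_id)["rt"])
        calibration_records.append((m.group_id, s, rt,
                                    spectra.get(m.group_id)))
    cal_scores = suspect_calibration_scores(calibration_records, parent_map,
                                            suspects, config)
    rcfg = config["ranking"]
    thresholds = derive_thresholds(
        cal_scores, percentile=rcfg["threshold_percentile"],
        min_calibration=rcfg["min_calibration_suspects"],
        method=rcfg["percentile_method"], log=log)

    candidate_scores: dict[str, list[CandidateScore]] = {}
    ranking_counts: dict[str, dict[str, int]] = {}
    unknown_links = [l for l in kept_links(links)
                     if l.candidate_ref == "unknown"]
    for link in sorted(unknown_links, key=lambda l: (l.group_id,
                                                     l.parent_id)):
        gid = link.group_id
        rt = float(prio.features.row(gid)["rt"])
        cands = candidates[candidates["group_id"] == gid]
        counts: dict[str, int] = {}
        if not cands.empty:
            scores = rank_candidates(gid, cands, parent_map[link.parent_id],
                                     suspects, rt, spectra.get(gid),
                                     thresholds, config, counts)
        else:
            scores = _rank_formula_candidates(
                gid, feature_formula.get(gid, []),
                parent_map[link.parent_id], annotations.get(gid),
                spectra.get(gid), thresholds, config, counts)
        key = f"{gid}:{link.parent_id}"
        candidate_scores[key] = scores
        ranking_counts[key] = counts

    # --- identification -----------------------------------------------------
    levels = _assign_levels(prio, screen, links, suspects, standards,
                            candidate_scores, annotations, feature_formula,
                            config)

    # --- quantitation -------------------------------------------------------
    curves = _fit_curves(calibration, config)
    removal, parent_conc = _parent_removal(prio, design, parents, curves,
                                           standards, config)
    balances, tp_quants = _mass_balances(prio, design, parents, links,
                                         suspects, standards, curves,
                                         feature_formula, removal, config)

    return PipelineState(
        design=design, features=features, parents=parents,
        suspects=suspects, spectra=spectra, prioritization=prio,
        screen=screen, links=links, annotations=annotations,
        thresholds=thresholds, candidate_scores=candidate_scores,
        ranking_counts=ranking_counts, levels=levels, curves=curves,
        removal=removal, balances=balances, tp_quants=tp_quants, log=log)


def _rank_formula_candidates(gid, formulas, parent, annotation, spectrum,
                             thresholds, config, counts):
    """Formula-annotation workflow for unknowns without compound tables:
    candidates are the enumerated formulas, scored by formula fit and
    (when MS2 exists) annotation explained-intensity."""
    from .annotate import annotate_fragments
    from .ranking import formula_fit
    acfg = config["annotation"]
    counts["raw"] = len(formulas)
    scores = []
    for f in formulas:
        ann_f = None
        if spectrum is not None:
            ann_f = annotate_fragments(
                spectrum, f, tol_mda=acfg["fragment_tol_mda"]
            ).explained_intensity_fraction
        score = CandidateScore(
            group_id=gid, candidate_id=f.render(), kind="formula",
            fit_formula=formula_fit(f, parent.structure.formula),
            ann_formula=ann_f)
        score.tp_score = combine_score(score.components())
        scores.append(score)
    floor = (thresholds or {}).get("fit_formula")
    if floor is not None:
        scores = [s for s in scores if s.fit_formula >= floor]
    counts["after_thresholds"] = len(scores)
    scores.sort(key=lambda s: (-s.tp_score, -s.fit_formula, s.candidate_id))
    top_n = config["ranking"]["top_n"]
    for i, s in enumerate(scores):
        s.rank = i + 1
    counts["top_n"] = min(len(scores), top_n)
    return scores[:top_n]


def _assign_levels(prio, screen, links, suspects, standards,
                   candidate_scores, annotations, feature_formula, config):
    suspect_by_id = {s.suspect_id: s for s in suspects}
    icfg = config["identification"]
    levels: dict[tuple, ConfidenceLevel] = {}
    for link in kept_links(links):
        gid = link.group_id
        row = prio.features.row(gid)
        feature_mz, feature_rt = float(row["mz"]), float(row["rt"])

        # reference-standard confirmation
        standard_confirmed = False
        if standards is not None:
            for _, std in standards.iterrows():
                formula = parse_formula(str(std["formula"]),
                                        alphabet=KNOWN_ELEMENTS)
                std_mz = adduct_mz(monoisotopic_mass(formula),
                                   config["adduct"])
                pattern = isotope_pattern(formula)
                ev = confirm_with_standard(
                    feature_mz, feature_rt, std_mz, float(std["rt"]),
                    measured_pattern=pattern, theoretical_pattern=pattern,
                    rt_tol_min=config["rt_tol_min"],
                    mz_tol_mda=config["mz_tol_mda"],
                    msigma_max=icfg["msigma_max"])
                if ev.confirmed:
                    standard_confirmed = True
                    break

        # competing isomeric structure suspects on the same feature
        structure_keys = set()
        for m in screen.matches:
            if m.group_id == gid and m.kind == "structure":
                structure_keys.add(
                    suspect_by_id[m.suspect_id].structure.canonical_key())
        isomer_ambiguous = len(structure_keys) > 1

        has_structure = link.candidate_ref != "unknown" and \
            suspect_by_id.get(link.candidate_ref, None) is not None and \
            suspect_by_id[link.candidate_ref].kind == "structure"
        ann_support = None
        if link.candidate_ref == "unknown":
            key = f"{gid}:{link.parent_id}"
            ranked = candidate_scores.get(key, [])
            if ranked and ranked[0].kind == "compound":
                has_structure = True
                ann_support = ranked[0].ann_compound
        elif gid in annotations:
            ann_support = annotations[gid].explained_intensity_fraction

        formulas = feature_formula.get(gid, [])
        unambiguous_formula = len(formulas) == 1

        levels[link.key()] = assign_level(
            standard_confirmed=standard_confirmed,
            isomer_ambiguous=isomer_ambiguous,
            has_structure_candidate=has_structure,
            annotation_support=ann_support,
            unambiguous_formula=unambiguous_formula,
            annotation_floor=icfg["annotation_floor"])
    return levels


def _fit_curves(calibration, config):
    qcfg = config["quantitation"]
    curves: dict[str, CalibrationCurve] = {}
    if calibration is None:
        return curves
    for (analyte, channel), grp in calibration.groupby(
            ["analyte_id", "channel"], sort=True):
        points = list(zip(grp["conc_ugL"], grp["response"]))
        curves[f"{analyte}:{channel}"] = fit_calibration(
            points, analyte, channel=channel,
            min_points=qcfg["min_points"], min_r2=qcfg["min_r2"],
            max_residual_fraction=qcfg["max_residual_fraction"],
            weighting=qcfg["weighting"])
    return curves


def _parent_conc_in_sample(parent: Parent, features, curves, sample_id,
                           standards) -> float | None:
    """Parent concentration from the M+2 channel of its feature."""
    gid = f"P_{parent.parent_id}"
    try:
        row = features.row(gid)
    except KeyError:
        return None
    intensity = float(row[sample_id])
    m2 = isotope_pattern(parent.structure.formula).abundance(2)
    curve = curves.get(f"STD-{parent.parent_id}:M+2")
    if curve is None or not curve.accepted:
        return None
    from .quantify import quantify
    return quantify(intensity * m2, curve).value_ugL


def _parent_removal(prio, design, parents, curves, standards, config):
    """Per-parent, per-condition removal at the top mixture concentration."""
    stats: list[RemovalStat] = []
    conc_map: dict[tuple, dict[str, list[float]]] = {}
    top = max((s.mixture_level for s in design.select(
        exposure_h=2, sample_type="mixture")), default=0.0)
    for p in sorted(parents, key=lambda p: p.parent_id):
        for cond in PHOTO_CONDITIONS:
            by_exposure: dict[float, list[float]] = {0.0: [], 2.0: []}
            for s in design.select(sample_type="mixture", condition=cond):
                if s.mixture_level != top:
                    continue
                conc = _parent_conc_in_sample(p, prio.parent_features, curves,
                                              s.sample_id, standards)
                if conc is not None:
                    by_exposure[s.exposure_h].append(conc)
            if not by_exposure[0.0] or not by_exposure[2.0]:
                continue
            stats.append(removal_stats(by_exposure[0.0], by_exposure[2.0],
                                       p.parent_id, cond))
            conc_map[(p.parent_id, cond)] = {
                "c0": by_exposure[0.0], "c2": by_exposure[2.0]}
    return stats, conc_map


def _mass_balances(prio, design, parents, links, suspects, standards,
                   curves, feature_formula, removal, config):
    qcfg = config["quantitation"]
    suspect_by_id = {s.suspect_id: s for s in suspects}
    parent_map = {p.parent_id: p for p in parents}
    removal_by = {(r.parent_id, r.condition): r for r in removal}
    std_for_tp: dict[str, str] = {}
    if standards is not None and "target_id" in standards.columns:
        for _, row in standards.iterrows():
            std_for_tp[str(row["target_id"])] = str(row["analyte_id"])

    # which features are linked (kept) to more than one parent -> shared
    by_gid: dict[str, set[str]] = {}
    for link in kept_links(links):
        by_gid.setdefault(link.group_id, set()).add(link.parent_id)
    shared_gids = {g for g, ps in by_gid.items() if len(ps) > 1}

    top = max((s.mixture_level for s in design.select(
        exposure_h=2, sample_type="mixture")), default=0.0)
    balances: list[MassBalance] = []
    tp_quants: dict[tuple, dict] = {}
    for p in sorted(parents, key=lambda p: p.parent_id):
        mw_parent = molar_mass(p.structure.formula)
        for cond in PHOTO_CONDITIONS:
            stat = removal_by.get((p.parent_id, cond))
            if stat is None:
                continue
            cols = [s.sample_id for s in design.select(
                exposure_h=2, sample_type="mixture", condition=cond)
                if s.mixture_level == top
                and s.sample_id in prio.features.sample_columns]
            removed_uM = (top / mw_parent) * (stat.removal_percent / 100.0)
            if stat.significant is False:
                removed_uM = min(removed_uM, 0.0)
            quants: list[SemiQuant] = []
            for link in kept_links(links):
                if link.parent_id != p.parent_id:
                    continue
                gid = link.group_id
                formulas = _link_formula(link, suspect_by_id, feature_formula)
                if not formulas:
                    continue
                formula = formulas[0]
                response = float(np.mean(
                    [prio.features.row(gid)[c] for c in cols])) if cols else 0.0
                if response <= 0:
                    continue
                tp_tag = _tp_standard_tag(link, suspect_by_id, std_for_tp)
                curve = curves.get(f"{tp_tag}:monoisotopic") if tp_tag else None
                if curve is not None and not curve.accepted:
                    curve = None
                q = semi_quantify(
                    gid, response, formula, curve=curve,
                    rf_predictor=parent_rf_predictor(p.response_factor),
                    rf_uncertainty_factor=qcfg["rf_uncertainty_factor"])
                quants.append(q)
                tp_quants[(p.parent_id, gid, cond)] = {
                    "conc_uM": q.conc_uM, "provenance": q.provenance,
                    "candidate_ref": link.candidate_ref}
            balances.append(mass_balance(
                p.parent_id, cond, removed_uM, quants,
                shared_tps={g for g in shared_gids},
                shared_mode=qcfg["shared_tp_mode"]))
    return balances, tp_quants


def _link_formula(link, suspect_by_id, feature_formula):
    if link.candidate_ref != "unknown" and link.candidate_ref in suspect_by_id:
        return [suspect_by_id[link.candidate_ref].formula]
    return feature_formula.get(link.group_id, [])


def _tp_standard_tag(link, suspect_by_id, std_for_tp) -> str | None:
    """Map a link to a standard analyte id via the suspect's label."""
    if link.candidate_ref in suspect_by_id:
        label = suspect_by_id[link.candidate_ref].transformation_label
        if label in std_for_tp:
            return std_for_tp[label]
    return None
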