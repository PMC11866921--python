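"""Automated reporting: per-TP summary sections, workflow accounting
tables, and a self-contained HTML + JSON report.

Every TP candidate gets an identifier of the form
``<Class>-<PARENT>-M<nominal [M+H]+>-<index>`` where the class encodes
the workflow branch that produced it: SuS (structure suspect), SuF
(formula suspect), UnC (unknown, compound annotation), UnF (unknown,
formula annotation).  The summary tables are cross-checked against the
per-stage provenance counts; an inconsistency is a hard failure, since
it would mean the bookkeeping lost or double-counted a feature.
"""

from __future__ import annotations

import base64
import html
import io as _io
from dataclasses import dataclass

import numpy as np

from .linking import kept_links
from .model import Suspect
from .pipeline import PipelineState

PHOTO_CONDITIONS = ("U", "UH", "UHN")


class AccountingError(RuntimeError):
    """Summary tables disagree with stage provenance."""


def tp_identifier(cls: str, parent_id: str, nominal_mz: int,
                  index: int) -> str:
    return f"{cls}-{parent_id}-M{nominal_mz}-{index}"


def link_class(link, suspect_by_id: dict[str, Suspect],
               candidate_scores) -> str:
    if link.candidate_ref != "unknown":
        s = suspect_by_id.get(link.candidate_ref)
        if s is not None:
            return "SuS" if s.kind == "structure" else "SuF"
        return "SuS"
    ranked = candidate_scores.get(f"{link.group_id}:{link.parent_id}", [])
    if ranked and ranked[0].kind == "compound":
        return "UnC"
    return "UnF"


def condition_presence(state: PipelineState, gid: str) -> dict[str, bool]:
    """Presence flags per photolytic condition plus S for any
    single-parent experiment (the legend used on TP overview figures)."""
    flags = {}
    feats = state.prioritization.features
    row = feats.row(gid)
    for cond in PHOTO_CONDITIONS:
        cols = [s.sample_id for s in state.design.select(
            exposure_h=2, sample_type="mixture", condition=cond)
            if s.sample_id in feats.sample_columns]
        flags[cond] = bool(cols and (row[cols] > 0).any())
    single_cols = [s.sample_id for s in state.design.select(
        exposure_h=2, sample_type="single")
        if s.sample_id in feats.sample_columns]
    flags["S"] = bool(single_cols and (row[single_cols] > 0).any())
    return flags


def abundance_table(state: PipelineState, gid: str) -> list[dict]:
    """Replicate-mean 2 h mixture intensity per initial concentration."""
    feats = state.prioritization.features
    row = feats.row(gid)
    arms: dict[float, list[str]] = {}
    for s in state.design.select(exposure_h=2, sample_type="mixture"):
        if s.sample_id in feats.sample_columns:
            arms.setdefault(s.mixture_level, []).append(s.sample_id)
    return [{"conc_ugL": level,
             "mean_intensity": float(np.mean([row[c] for c in cols]))}
            for level, cols in sorted(arms.items())]


def report_tp(state: PipelineState, link, identifier: str) -> dict:
    """One report section per TP candidate: identity, scores, condition
    presence, abundance trend, annotated spectrum and confidence level."""
    gid = link.group_id
    suspect_by_id = {s.suspect_id: s for s in state.suspects}
    feats = state.prioritization.features
    row = feats.row(gid)
    section = {
        "identifier": identifier,
        "group_id": gid,
        "parent_id": link.parent_id,
        "candidate_ref": link.candidate_ref,
        "mz": float(row["mz"]),
        "rt": float(row["rt"]),
        "condition_presence": condition_presence(state, gid),
        "abundance_vs_concentration": abundance_table(state, gid),
    }
    regression = next((r for r in state.prioritization.regressions
                       if r.group_id == gid), None)
    if regression is not None:
        section["regression"] = {
            "slope": regression.slope, "r_squared": regression.r_squared,
            "p_value": regression.p_value}
    if link.candidate_ref in suspect_by_id:
        s = suspect_by_id[link.candidate_ref]
        section["candidate"] = {
            "kind": s.kind, "formula": s.formula.render(),
            "smiles": s.smiles or "",
            "sources": sorted(s.sources),
            "label": s.transformation_label}
    ranked = state.candidate_scores.get(f"{gid}:{link.parent_id}", [])
    if ranked:
        section["top_candidates"] = [{
            "candidate_id": c.candidate_id, "kind": c.kind,
            "tp_score": round(c.tp_score, 4), "rank": c.rank,
            **{k: round(v, 4) for k, v in c.components().items()},
        } for c in ranked[:5]]
    if gid in state.annotations:
        ann = state.annotations[gid]
        section["annotated_spectrum"] = {
            "precursor_formula": ann.precursor_formula.render(),
            "explained_intensity_fraction":
                round(ann.explained_intensity_fraction, 4),
            "peaks": [{
                "mz": round(a.mz, 5), "intensity": a.intensity,
                "formula": a.formula.render() if a.formula else "",
                "error_mda": (round(a.error_mda, 3)
                              if a.error_mda is not None else None),
            } for a in ann.assignments]}
    level = state.levels.get(link.key())
    if level is not None:
        section["confidence_level"] = {"level": level.display,
                                       "evidence": level.evidence}
    quants = {cond: state.tp_quants.get((link.parent_id, gid, cond))
              for cond in PHOTO_CONDITIONS}
    section["semi_quantitation"] = {
        cond: ({"conc_uM": round(q["conc_uM"], 5),
                "provenance": q["provenance"]} if q else None)
        for cond, q in quants.items()}
    return section


def assign_identifiers(state: PipelineState) -> dict[tuple, str]:
    """Deterministic TP identifiers for every kept link."""
    suspect_by_id = {s.suspect_id: s for s in state.suspects}
    feats = state.prioritization.features
    counters: dict[tuple, int] = {}
    identifiers: dict[tuple, str] = {}
    ordered = sorted(kept_links(state.links),
                     key=lambda l: (l.parent_id, float(
                         feats.row(l.group_id)["mz"]), l.candidate_ref))
    for link in ordered:
        cls = link_class(link, suspect_by_id, state.candidate_scores)
        nominal = int(round(float(feats.row(link.group_id)["mz"])))
        key = (cls, link.parent_id, nominal)
        counters[key] = counters.get(key, 0) + 1
        identifiers[link.key()] = tp_identifier(cls, link.parent_id, nominal,
                                                counters[key])
    return identifiers


def report_summary(state: PipelineState) -> dict:
    """Workflow accounting in the shape of the study's overview tables,
    cross-checked against stage provenance."""
    totals = state.screen.accounting["totals"]
    prio_counts = state.prioritization.step_counts
    n_struct = len(state.screen.structure_matched)
    n_form = len(state.screen.formula_matched)
    n_unknown = len(state.screen.unknown)
    if n_struct != totals["structure_matched_features"] \
            or n_form != totals["formula_matched_features"] \
            or n_unknown != totals["unknown_features"]:
        raise AccountingError("screen accounting disagrees with match lists")
    if n_struct + n_form + n_unknown != prio_counts["prioritized"]:
        raise AccountingError(
            f"feature classes ({n_struct}+{n_form}+{n_unknown}) do not "
            f"partition the prioritized set ({prio_counts['prioritized']})")

    links = kept_links(state.links)
    suspect_links = [l for l in links if l.candidate_ref != "unknown"]
    unknown_links = [l for l in links if l.candidate_ref == "unknown"]
    per_parent: dict[str, dict] = {}
    for p in sorted(state.screen.accounting["per_parent"]):
        entry = dict(state.screen.accounting["per_parent"][p])
        entry["suspect_links"] = sum(1 for l in suspect_links
                                     if l.parent_id == p)
        entry["unknown_links"] = sum(1 for l in unknown_links
                                     if l.parent_id == p)
        per_parent[p] = entry
    if sum(e["suspect_links"] for e in per_parent.values()) \
            != len(suspect_links):
        raise AccountingError("per-parent suspect link counts do not sum")

    multi = {}
    by_gid: dict[str, list] = {}
    for l in links:
        by_gid.setdefault(l.group_id, []).append(l)
    for gid, ls in sorted(by_gid.items()):
        ps = sorted({l.parent_id for l in ls})
        if len(ps) > 1:
            multi[gid] = ps

    level_counts: dict[str, int] = {}
    for link in links:
        lv = state.levels.get(link.key())
        if lv is not None:
            level_counts[lv.display] = level_counts.get(lv.display, 0) + 1

    ranking = {key: dict(counts)
               for key, counts in sorted(state.ranking_counts.items())}

    return {
        "features": {
            "sample_grouped": prio_counts["sample_grouped"],
            "prioritized": prio_counts["prioritized"],
            "per_step": prio_counts,
        },
        "suspect_screening": {
            "totals": totals,
            "per_parent": per_parent,
            "total_matched_features": n_struct + n_form,
        },
        "links": {
            "total_kept": len(links),
            "suspect_links": len(suspect_links),
            "unknown_links": len(unknown_links),
            "multi_parent_features": multi,
        },
        "candidate_prioritization": ranking,
        "identification_levels": dict(sorted(level_counts.items())),
        "mass_balance": [{
            "parent_id": b.parent_id, "condition": b.condition,
            "parent_removed_uM": round(b.parent_removed_uM, 5),
            "explained_percent": (round(b.explained_fraction_percent, 2)
                                  if b.defined else None),
            "notes": b.notes,
        } for b in state.balances],
        "removal": [{
            "parent_id": r.parent_id, "condition": r.condition,
            "removal_percent": round(r.removal_percent, 2),
            "p_value": (round(r.p_value, 5)
                        if r.p_value is not None else None),
            "significant": r.significant,
        } for r in state.removal],
    }


def build_report(state: PipelineState) -> dict:
    identifiers = assign_identifiers(state)
    links = kept_links(state.links)
    seen_keys = set()
    sections = []
    for link in sorted(links, key=lambda l: identifiers[l.key()]):
        if link.key() in seen_keys:
            raise AccountingError(f"duplicate link {link.key()}")
        seen_keys.add(link.key())
        sections.append(report_tp(state, link, identifiers[link.key()]))
    return {"summary": report_summary(state), "tps": sections}


# ---------------------------------------------------------------------------
# HTML rendering

def _abundance_plot_b64(section: dict) -> str:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    rows = section["abundance_vs_concentration"]
    fig, ax = plt.subplots(figsize=(3.2, 2.2), dpi=90)
    ax.bar([str(int(r["conc_ugL"])) for r in rows],
           [r["mean_intensity"] for r in rows], color="#4878a8")
    ax.set_xlabel("initial conc (µg/L)")
    ax.set_ylabel("mean intensity")
    ax.set_title(section["identifier"], fontsize=8)
    fig.tight_layout()
    buf = _io.BytesIO()
    fig.savefig(buf, format="png", metadata={"Software": "tpscreen"})
    plt.close(fig)
    return base64.b64encode(buf.getvalue()).decode("ascii")


def _dict_table(d: dict) -> str:
    rows = "".join(f"<tr><th>{html.escape(str(k))}</th>"
                   f"<td>{html.escape(str(v))}</td></tr>"
                   for k, v in d.items())
    return f"<table>{rows}</table>"


def render_html(report: dict, plots: bool = True) -> str:
    parts = [
        "<!DOCTYPE html><html><head><meta charset='utf-8'>",
        "<title>TP screening report</title>",
        "<style>body{font-family:sans-serif;margin:2em;}"
        "table{border-collapse:collapse;margin:0.5em 0;}"
        "td,th{border:1px solid #999;padding:2px 8px;font-size:12px;"
        "text-align:left;}h2{border-bottom:1px solid #ccc;}</style>",
        "</head><body>",
        "<h1>Transformation-product screening report</h1>",
        "<h2>Workflow summary</h2>",
    ]
    summary = report["summary"]
    parts.append(_dict_table(summary["features"]["per_step"]))
    parts.append("<h3>Suspect screening</h3>")
    parts.append(_dict_table(summary["suspect_screening"]["totals"]))
    parts.append("<h3>Parent removal</h3>")
    for row in summary["removal"]:
        parts.append(_dict_table(row))
    parts.append("<h3>Mass balances</h3>")
    for row in summary["mass_balance"]:
        parts.append(_dict_table(
            {k: v for k, v in row.items() if k != "notes"}))
    parts.append(f"<h2>TP candidates ({len(report['tps'])})</h2>")
    for section in report["tps"]:
        parts.append(f"<h3>{html.escape(section['identifier'])}</h3>")
        head = {"parent": section["parent_id"],
                "feature": section["group_id"],
                "m/z": f"{section['mz']:.4f}",
                "RT (min)": f"{section['rt']:.2f}",
                "candidate": section["candidate_ref"],
                "conditions": ", ".join(
                    k for k, v in section["condition_presence"].items() if v)}
        if "confidence_level" in section:
            head["confidence level"] = section["confidence_level"]["level"]
        parts.append(_dict_table(head))
        if plots:
            b64 = _abundance_plot_b64(section)
            parts.append(f"<img src='data:image/png;base64,{b64}'/>")
        else:
            parts.append(_dict_table({
                f"{r['conc_ugL']:g} µg/L": f"{r['mean_intensity']:.0f}"
                for r in section["abundance_vs_concentration"]}))
        if "annotated_spectrum" in section:
            ann = section["annotated_spectrum"]
            rows = "".join(
                f"<tr><td>{p['mz']}</td><td>{p['intensity']:.0f}</td>"
                f"<td>{html.escape(p['formula'])}</td>"
                f"<td>{p['error_mda'] if p['error_mda'] is not None else ''}"
                "</td></tr>"
                for p in ann["peaks"])
            parts.append(
                "<table><tr><th>m/z</th><th>intensity</th><th>formula</th>"
                f"<th>error (mDa)</th></tr>{rows}</table>")
    parts.append("</body></html>")
    return "".join(parts)
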