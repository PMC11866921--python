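"""Readers and writers for the plain-text formats the workflow exchanges.

Everything is CSV except spectra (MSP text or centroided mzML) and the
configuration (YAML).  All readers are total over their documented
dialect: malformed input raises a named ``ValidationError`` rather than
yielding a partial object, and write->read->write is byte-stable for
canonical files.
"""

from __future__ import annotations

import json
import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .chem import (
    MolecularFormula,
    StructureRecord,
    parse_formula,
    formula_from_smiles,
)
from ._elements import KNOWN_ELEMENTS
from .model import (
    ExperimentDesign,
    FeatureGroupTable,
    Ms2Spectrum,
    Parent,
    SampleInfo,
    Suspect,
    TPLink,
    ValidationError,
)

_CONC_PREFIX = "conc_"


def _read_csv(path, required: Sequence[str], what: str) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"sample_id": str, "group_id": str})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{what} file {path}: missing column(s) {missing}")
    return df


# ---------------------------------------------------------------------------
# Experiment design

def read_design(path) -> ExperimentDesign:
    df = _read_csv(path, ["sample_id", "type", "condition", "exposure_h",
                          "replicate"], "design")
    conc_cols = [c for c in df.columns if c.startswith(_CONC_PREFIX)]
    samples = []
    for _, row in df.iterrows():
        conc = {c[len(_CONC_PREFIX):]: float(row[c]) for c in conc_cols
                if float(row[c]) > 0}
        samples.append(SampleInfo(
            sample_id=str(row["sample_id"]),
            sample_type=str(row["type"]),
            condition=str(row["condition"]),
            exposure_h=float(row["exposure_h"]),
            initial_conc_ugL=conc,
            replicate=int(row["replicate"]),
        ))
    return ExperimentDesign(samples)


def write_design(design: ExperimentDesign, path) -> None:
    parents = design.parent_ids
    rows = []
    for s in design.samples:
        row = {
            "sample_id": s.sample_id,
            "type": s.sample_type,
            "condition": s.condition,
            "exposure_h": s.exposure_h,
            "replicate": s.replicate,
        }
        for p in parents:
            row[_CONC_PREFIX + p] = s.initial_conc_ugL.get(p, 0.0)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Feature tables

def read_features(path, design: ExperimentDesign | None = None) -> FeatureGroupTable:
    df = _read_csv(path, ["group_id", "mz", "rt"], "feature")
    table = FeatureGroupTable(df)
    if design is not None:
        table.validate_against(design)
    return table


def read_features_long(path, design: ExperimentDesign | None = None) -> FeatureGroupTable:
    """Long layout (group_id, mz, rt, sample_id, intensity) for interop."""
    df = _read_csv(path, ["group_id", "mz", "rt", "sample_id", "intensity"],
                   "long feature")
    wide = df.pivot_table(index=["group_id", "mz", "rt"], columns="sample_id",
                          values="intensity", fill_value=0.0,
                          aggfunc="sum").reset_index()
    wide.columns.name = None
    table = FeatureGroupTable(wide)
    if design is not None:
        table.validate_against(design)
    return table


def write_features(features: FeatureGroupTable, path) -> None:
    features.df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Parents

def read_parents(path) -> list[Parent]:
    df = _read_csv(path, ["parent_id", "smiles", "rt", "response_factor"],
                   "parent")
    out = []
    for _, row in df.iterrows():
        out.append(Parent(
            parent_id=str(row["parent_id"]),
            structure=StructureRecord.from_smiles(str(row["parent_id"]),
                                                  str(row["smiles"])),
            rt=float(row["rt"]),
            response_factor=float(row["response_factor"]),
        ))
    ids = [p.parent_id for p in out]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate parent_id in parent table")
    return out


def write_parents(parents: Sequence[Parent], path) -> None:
    pd.DataFrame([{
        "parent_id": p.parent_id,
        "smiles": p.structure.smiles,
        "rt": p.rt,
        "response_factor": p.response_factor,
    } for p in parents]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Suspects

def read_suspects(path) -> list[Suspect]:
    df = _read_csv(path, ["suspect_id", "parent_id", "kind", "smiles",
                          "formula", "sources", "label"], "suspect")
    if df["suspect_id"].duplicated().any():
        dup = sorted(set(df.loc[df["suspect_id"].duplicated(), "suspect_id"]))
        raise ValidationError(f"duplicate suspect_id(s): {dup[:5]}")
    out = []
    for _, row in df.iterrows():
        smiles = None if pd.isna(row["smiles"]) or row["smiles"] == "" \
            else str(row["smiles"])
        sources = frozenset(str(row["sources"]).split(";")) \
            if not pd.isna(row["sources"]) and str(row["sources"]) else frozenset()
        out.append(Suspect(
            suspect_id=str(row["suspect_id"]),
            parent_id=str(row["parent_id"]),
            kind=str(row["kind"]),
            smiles=smiles,
            formula=parse_formula(str(row["formula"]),
                                  alphabet=KNOWN_ELEMENTS),
            sources=sources,
            transformation_label="" if pd.isna(row["label"]) else str(row["label"]),
        ))
    return out


def write_suspects(suspects: Sequence[Suspect], path) -> None:
    pd.DataFrame([{
        "suspect_id": s.suspect_id,
        "parent_id": s.parent_id,
        "kind": s.kind,
        "smiles": s.smiles or "",
        "formula": s.formula.render(),
        "sources": ";".join(sorted(s.sources)),
        "label": s.transformation_label,
    } for s in suspects]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Candidate structure tables (offline stand-ins for database retrieval)

def read_candidates(path) -> pd.DataFrame:
    """Candidate table: group_id, candidate_id, kind, smiles, formula.

    ``kind`` is "compound" (SMILES present) or "formula".  Structure
    formulas are verified against the SMILES.
    """
    df = _read_csv(path, ["group_id", "candidate_id", "kind", "smiles",
                          "formula"], "candidate")
    for _, row in df.iterrows():
        if row["kind"] == "compound":
            if pd.isna(row["smiles"]) or not str(row["smiles"]):
                raise ValidationError(
                    f"compound candidate {row['candidate_id']!r} lacks SMILES")
        elif row["kind"] != "formula":
            raise ValidationError(
                f"candidate {row['candidate_id']!r}: kind must be "
                "compound|formula")
    return df


def write_candidates(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# TP links

def read_links(path) -> list[TPLink]:
    df = _read_csv(path, ["parent_id", "group_id", "candidate_ref", "status"],
                   "link")
    return [TPLink(str(r["parent_id"]), str(r["group_id"]),
                   str(r["candidate_ref"]), str(r["status"]))
            for _, r in df.iterrows()]


def write_links(links: Sequence[TPLink], path) -> None:
    pd.DataFrame([{
        "parent_id": l.parent_id,
        "group_id": l.group_id,
        "candidate_ref": l.candidate_ref,
        "status": l.status,
    } for l in links]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Reference standards and calibration series

def read_standards(path) -> pd.DataFrame:
    """Standards: analyte_id, rt, smiles (optional), formula, optional
    response_factor used for quantitation without a curve."""
    df = _read_csv(path, ["analyte_id", "rt", "smiles", "formula"], "standard")
    for _, row in df.iterrows():
        if not pd.isna(row["smiles"]) and str(row["smiles"]):
            derived = formula_from_smiles(str(row["smiles"]),
                                          str(row["analyte_id"]))
            if derived.counts != parse_formula(
                    str(row["formula"]), alphabet=KNOWN_ELEMENTS).counts:
                raise ValidationError(
                    f"standard {row['analyte_id']!r}: formula/SMILES mismatch")
    return df


def read_calibration(path) -> pd.DataFrame:
    """Calibration points: analyte_id, channel, conc_ugL, response."""
    return _read_csv(path, ["analyte_id", "channel", "conc_ugL", "response"],
                     "calibration")


# ---------------------------------------------------------------------------
# Spectra: MSP text and centroided mzML

def read_msp(path) -> list[Ms2Spectrum]:
    spectra = []
    name = None
    precursor = None
    peaks: list[tuple[float, float]] = []
    n_expected = None

    def flush():
        nonlocal name, precursor, peaks, n_expected
        if name is None:
            return
        if precursor is None:
            raise ValidationError(f"MSP record {name!r}: missing PrecursorMZ")
        if n_expected is not None and len(peaks) != n_expected:
            raise ValidationError(
                f"MSP record {name!r}: expected {n_expected} peaks, "
                f"got {len(peaks)}")
        spectra.append(Ms2Spectrum(feature_group_id=name,
                                   precursor_mz=precursor, peaks=peaks))
        name, precursor, peaks, n_expected = None, None, [], None

    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                flush()
                continue
            if ":" in line and not line[0].isdigit():
                key, _, value = line.partition(":")
                key = key.strip().lower()
                if key == "name":
                    flush()
                    name = value.strip()
                elif key in ("precursormz", "precursor_mz"):
                    precursor = float(value)
                elif key == "num peaks":
                    n_expected = int(value)
            else:
                parts = line.split()
                if len(parts) < 2:
                    raise ValidationError(
                        f"MSP peak line not 'mz intensity': {line!r}")
                peaks.append((float(parts[0]), float(parts[1])))
    flush()
    return spectra


def write_msp(spectra: Sequence[Ms2Spectrum], path,
              comments: dict[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for sp in spectra:
            fh.write(f"Name: {sp.feature_group_id}\n")
            fh.write(f"PrecursorMZ: {sp.precursor_mz:.5f}\n")
            if comments and sp.feature_group_id in comments:
                fh.write(f"Comments: {comments[sp.feature_group_id]}\n")
            fh.write(f"Num Peaks: {len(sp.peaks)}\n")
            for mz, inten in sp.peaks:
                fh.write(f"{mz:.5f} {inten:.1f}\n")
            fh.write("\n")


def read_mzml(path, features: FeatureGroupTable | None = None,
              isolation_window_mz: float = 0.5,
              rt_window_min: float = 0.5) -> list[Ms2Spectrum]:
    """Centroided MS2 spectra from mzML.

    Parsing is deliberately narrow: ms level, scan start time, selected
    precursor m/z, and the two peak arrays (64/32-bit floats, plain or
    zlib-compressed), which is all the workflow consumes.  When a feature
    table is given, each spectrum is mapped to the feature whose m/z lies
    within half the isolation window of the precursor and whose RT
    (minutes) is within the RT window; unmapped spectra keep the mzML
    spectrum id.
    """
    import base64
    import xml.etree.ElementTree as ET
    import zlib

    ns = "{http://psi.hupo.org/ms/mzml}"
    out = []
    tree = ET.parse(str(path))
    for spec in tree.iter(f"{ns}spectrum"):
        params = {cv.get("name"): cv.get("value")
                  for cv in spec.findall(f"{ns}cvParam")}
        if params.get("ms level") != "2":
            continue
        sid = spec.get("id")
        rt = None
        scan = spec.find(f"{ns}scanList/{ns}scan")
        if scan is not None:
            for cv in scan.findall(f"{ns}cvParam"):
                if cv.get("name") == "scan start time":
                    rt = float(cv.get("value"))
                    if cv.get("unitName", "minute").startswith("sec"):
                        rt /= 60.0
        ion = spec.find(f"{ns}precursorList/{ns}precursor/"
                        f"{ns}selectedIonList/{ns}selectedIon")
        precursor = None
        if ion is not None:
            for cv in ion.findall(f"{ns}cvParam"):
                if cv.get("name") == "selected ion m/z":
                    precursor = float(cv.get("value"))
        if precursor is None:
            raise ValidationError(f"mzML spectrum {sid!r}: no precursor m/z")
        arrays: dict[str, np.ndarray] = {}
        for arr in spec.findall(f"{ns}binaryDataArrayList/"
                                f"{ns}binaryDataArray"):
            names = {cv.get("name") for cv in arr.findall(f"{ns}cvParam")}
            binary = arr.find(f"{ns}binary")
            raw = base64.b64decode(binary.text or "")
            if "zlib compression" in names:
                raw = zlib.decompress(raw)
            dtype = "<f4" if "32-bit float" in names else "<f8"
            data = np.frombuffer(raw, dtype=dtype).astype(float)
            if "m/z array" in names:
                arrays["mz"] = data
            elif "intensity array" in names:
                arrays["intensity"] = data
        if "mz" not in arrays or "intensity" not in arrays:
            raise ValidationError(f"mzML spectrum {sid!r}: missing peak "
                                  "arrays")
        peaks = [(float(m), float(i))
                 for m, i in zip(arrays["mz"], arrays["intensity"]) if i > 0]
        gid = str(sid)
        if features is not None:
            gid = _map_to_feature(features, precursor, rt,
                                  isolation_window_mz, rt_window_min) or gid
        out.append(Ms2Spectrum(feature_group_id=gid, precursor_mz=precursor,
                               peaks=peaks))
    return out


def _map_to_feature(features: FeatureGroupTable, precursor: float,
                    rt: float | None, isolation_window_mz: float,
                    rt_window_min: float) -> str | None:
    df = features.df
    ok = (df["mz"] - precursor).abs() <= isolation_window_mz / 2.0
    if rt is not None:
        ok &= (df["rt"] - rt).abs() <= rt_window_min
    hits = df.loc[ok]
    if hits.empty:
        return None
    best = (hits["mz"] - precursor).abs().idxmin()
    return str(df.loc[best, "group_id"])


# ---------------------------------------------------------------------------
# JSON / run-log helpers

def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def append_runlog(out_dir, lines: Iterable[str]) -> None:
    os.makedirs(out_dir, exist_ok=True)
    with open(os.path.join(out_dir, "run.log"), "a") as fh:
        for line in lines:
            fh.write(line.rstrip("\n") + "\n")
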