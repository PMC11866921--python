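"""Parent-TP linking and pruning with single-parent evidence.

Suspect-matched features link to their suspect's parent; unknown
features provisionally link to every parent present in the mixtures.
The single-parent experiments then prune implausible links: a feature
observed in another parent's single-parent run most likely stems from
that other parent, unless the mixture intensity dwarfs it (5x) or the
feature also shows up in the linked parent's own single run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import ExperimentDesign, FeatureGroupTable, Parent, TPLink
from .suspects import ScreenResult


def build_links(screen: ScreenResult, features: FeatureGroupTable,
                design: ExperimentDesign, parents: list[Parent],
                detection_floor: float = 0.0) -> list[TPLink]:
    """Provisional links.  Unknown features attach to every parent whose
    mixture samples contain the feature (all parents are co-dosed in
    mixtures, so presence alone cannot attribute; pruning comes next)."""
    links: list[TPLink] = []
    seen: set[tuple] = set()
    mixture_cols = [s.sample_id for s in design.select(exposure_h=2,
                                                       sample_type="mixture")
                    if s.sample_id in features.sample_columns]
    present_in_mixture: dict[str, bool] = {}
    if mixture_cols:
        inten = features.intensities(mixture_cols)
        present = (inten > detection_floor).any(axis=1)
        present_in_mixture = dict(zip(features.df["group_id"], present))

    for m in screen.matches:
        link = TPLink(parent_id=m.parent_id, group_id=m.group_id,
                      candidate_ref=m.suspect_id)
        if link.key() not in seen:
            seen.add(link.key())
            links.append(link)
    for gid in screen.unknown:
        if not present_in_mixture.get(gid, False):
            continue
        for p in parents:
            link = TPLink(parent_id=p.parent_id, group_id=gid,
                          candidate_ref="unknown")
            if link.key() not in seen:
                seen.add(link.key())
                links.append(link)
    return links


def _arm_max_intensity(features: FeatureGroupTable, design: ExperimentDesign,
                       gid: str, samples) -> float:
    cols = [s.sample_id for s in samples
            if s.sample_id in features.sample_columns]
    if not cols:
        return 0.0
    return float(features.row(gid)[cols].max())


def prune_links(links: list[TPLink], features: FeatureGroupTable,
                design: ExperimentDesign, config: dict) -> list[TPLink]:
    """Apply the single-parent pruning rule to every link.

    For link (P, F): if F is present in the single-parent experiments of
    any other parent Q, the link is removed unless the mixture intensity
    is at least ``single_parent_ratio`` (default 5) times the intensity in
    Q's single run, or F is also present in P's own single run.
    Intensities are maxima across replicates; the mixture side uses the
    highest concentration arm (single-parent runs are dosed only there).
    """
    lcfg = config["linking"]
    ratio = lcfg["single_parent_ratio"]
    floor = lcfg["detection_floor"]

    single_parents = sorted({s.single_parent
                             for s in design.select(exposure_h=2,
                                                    sample_type="single")})
    mixtures = design.select(exposure_h=2, sample_type="mixture")
    top_level = max((s.mixture_level for s in mixtures), default=0.0)
    top_mixtures = [s for s in mixtures if s.mixture_level == top_level]

    out: list[TPLink] = []
    for link in links:
        if not link.kept:
            out.append(link)
            continue
        gid = link.group_id
        mix_int = _arm_max_intensity(features, design, gid, top_mixtures)
        own_runs = design.select(exposure_h=2, sample_type="single",
                                 single_parent=link.parent_id)
        own_present = _arm_max_intensity(features, design, gid,
                                         own_runs) > floor
        removed_reason = None
        for q in single_parents:
            if q == link.parent_id:
                continue
            q_runs = design.select(exposure_h=2, sample_type="single",
                                   single_parent=q)
            q_int = _arm_max_intensity(features, design, gid, q_runs)
            if q_int <= floor:
                continue
            if mix_int >= ratio * q_int:
                continue
            if own_present:
                continue
            removed_reason = (f"present in single-parent run of {q} "
                              f"(mixture/single ratio "
                              f"{mix_int / q_int:.2f} < {ratio:g})")
            break
        if removed_reason is None:
            out.append(link)
        else:
            out.append(TPLink(parent_id=link.parent_id, group_id=gid,
                              candidate_ref=link.candidate_ref,
                              status=f"removed:{removed_reason}"))
    return out


def kept_links(links: list[TPLink]) -> list[TPLink]:
    return [l for l in links if l.kept]
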