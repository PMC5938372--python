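"""Arm-level SCNA calling, driver-SCNA annotation, wGII, and the ITH index.

Copy-number alterations are called relative to the sample-wide ploidy:
a segment is a gain where cn_total > round(ploidy) and a loss where
cn_total < round(ploidy) (half-up rounding).  An arm gain/loss is called
when strictly more than 50% of the arm is gained/lost.  The weighted
genome instability index (wGII) is the mean, over the 22 autosomes, of
the fraction of each chromosome's covered length at aberrant copy
number, which weights every chromosome equally regardless of size.

The ITH index summarizes driver heterogeneity as
(# subclonal drivers) / (# clonal drivers), counting driver mutations
and driver SCNAs together; with zero clonal drivers it is reported as
undefined (NaN) rather than infinite.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict

import pandas as pd

from .model import (
    ArmDefinition,
    DEFAULT_THRESHOLDS,
    DRIVER_SCNAS,
    DriverEvent,
    HeterogeneityReport,
    SegmentCall,
    Thresholds,
    is_autosome,
    round_half_up,
)

logger = logging.getLogger("clonevo")

__all__ = [
    "call_arm_events",
    "annotate_driver_scnas",
    "compute_wgii",
    "compute_ith_index",
]


def _overlap(seg: SegmentCall, arm: ArmDefinition) -> int:
    return max(0, min(seg.end, arm.end) - max(seg.start, arm.start))


def call_arm_events(
    segments: list[SegmentCall],
    arms: list[ArmDefinition],
    ploidy: float,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Call arm-level gains/losses for one region.

    Returns a frame with one row per called event: columns region_id,
    arm, direction (gain|loss), fraction_aberrant.  The denominator is
    the full arm length; the fraction must strictly exceed 0.5.  Sex
    chromosomes are ignored.  Arms with zero covered length are skipped
    with a warning.
    """
    baseline = round_half_up(ploidy)
    rows = []
    region_id = segments[0].region_id if segments else None
    for arm in arms:
        if not is_autosome(arm.chrom):
            continue
        overlapping = [
            s for s in segments if s.chrom == arm.chrom and _overlap(s, arm) > 0
        ]
        if not overlapping:
            logger.warning("arm %s has zero covered length; skipped", arm.label)
            continue
        gain_len = sum(_overlap(s, arm) for s in overlapping if s.cn_total > baseline)
        loss_len = sum(_overlap(s, arm) for s in overlapping if s.cn_total < baseline)
        for direction, aberrant in (("gain", gain_len), ("loss", loss_len)):
            fraction = aberrant / arm.length
            if fraction > thresholds.arm_event_fraction:
                rows.append(
                    {
                        "region_id": region_id,
                        "arm": arm.label,
                        "direction": direction,
                        "fraction_aberrant": fraction,
                    }
                )
    return pd.DataFrame(rows, columns=["region_id", "arm", "direction", "fraction_aberrant"])


def call_arm_events_cohort(
    segments: list[SegmentCall],
    arms: list[ArmDefinition],
    ploidy_by_region: dict[str, float],
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Arm events for every region of a tumor, concatenated."""
    by_region: dict[str, list[SegmentCall]] = defaultdict(list)
    for s in segments:
        by_region[s.region_id].append(s)
    frames = [
        call_arm_events(segs, arms, ploidy_by_region[r], thresholds)
        for r, segs in sorted(by_region.items())
        if r in ploidy_by_region
    ]
    if not frames:
        return pd.DataFrame(columns=["region_id", "arm", "direction", "fraction_aberrant"])
    return pd.concat(frames, ignore_index=True)


def annotate_driver_scnas(
    arm_events: pd.DataFrame,
    qc_regions: list[str],
    driver_scna_set: tuple[str, ...] = DRIVER_SCNAS,
) -> list[DriverEvent]:
    """Promote arm events in the configured driver set to DriverEvents.

    A driver SCNA is clonal when called in every QC-passing region,
    otherwise subclonal.
    """
    out = []
    if arm_events.empty:
        return out
    labels = arm_events["direction"] + "_" + arm_events["arm"]
    df = arm_events.assign(label=labels)
    df = df[df["region_id"].isin(qc_regions)]
    for label, grp in df.groupby("label", sort=True):
        if label not in driver_scna_set:
            continue
        present = frozenset(grp["region_id"])
        clonality = "clonal" if present >= set(qc_regions) else "subclonal"
        direction = "scna_gain" if label.startswith("gain") else "scna_loss"
        out.append(
            DriverEvent(
                event_id=f"scna:{label}",
                event_type=direction,
                label=label,
                regions_present=present,
                tumor_clonality=clonality,
            )
        )
    return out


def compute_wgii(
    segments: list[SegmentCall],
    arms: list[ArmDefinition],
    ploidy: float,
) -> float:
    """Weighted genome instability index for one region.

    Mean over the autosomes of (aberrant covered bp / covered bp);
    aberrant means cn_total != round(ploidy).  Chromosomes with zero
    coverage are excluded from the mean with a warning.
    """
    baseline = round_half_up(ploidy)
    chrom_bounds: dict[str, list[ArmDefinition]] = defaultdict(list)
    for a in arms:
        if is_autosome(a.chrom):
            chrom_bounds[a.chrom].append(a)
    fractions = []
    for chrom, chrom_arms in sorted(chrom_bounds.items(), key=lambda kv: int(kv[0])):
        covered = 0
        aberrant = 0
        for s in segments:
            if s.chrom != chrom:
                continue
            for a in chrom_arms:
                ov = _overlap(s, a)
                covered += ov
                if s.cn_total != baseline:
                    aberrant += ov
        if covered == 0:
            logger.warning("chromosome %s has zero coverage; excluded from wGII", chrom)
            continue
        fractions.append(aberrant / covered)
    if not fractions:
        return float("nan")
    return sum(fractions) / len(fractions)


def compute_wgii_per_region(
    segments: list[SegmentCall],
    arms: list[ArmDefinition],
    ploidy_by_region: dict[str, float],
) -> dict[str, float]:
    by_region: dict[str, list[SegmentCall]] = defaultdict(list)
    for s in segments:
        by_region[s.region_id].append(s)
    return {
        r: compute_wgii(segs, arms, ploidy_by_region[r])
        for r, segs in sorted(by_region.items())
        if r in ploidy_by_region
    }


def compute_ith_index(
    tumor_id: str,
    driver_events: list[DriverEvent],
    wgii_per_region: dict[str, float] | None = None,
) -> HeterogeneityReport:
    """ITH index and wGII summary for one tumor.

    Drivers include driver mutations and driver SCNAs.  The per-tumor
    wGII convention is the maximum observed regional wGII.
    """
    wgii_per_region = wgii_per_region or {}
    n_clonal = sum(1 for e in driver_events if e.tumor_clonality == "clonal")
    n_subclonal = sum(1 for e in driver_events if e.tumor_clonality == "subclonal")
    ith = n_subclonal / n_clonal if n_clonal > 0 else float("nan")
    finite = [v for v in wgii_per_region.values() if not math.isnan(v)]
    return HeterogeneityReport(
        tumor_id=tumor_id,
        n_clonal_drivers=n_clonal,
        n_subclonal_drivers=n_subclonal,
        ith_index=ith,
        wgii_per_region=dict(wgii_per_region),
        wgii_max=max(finite) if finite else float("nan"),
    )
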