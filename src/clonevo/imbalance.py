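"""Copy-neutral allelic imbalance (CNAI) and mirrored subclonal allelic
imbalance (MSAI) detection from heterozygous-SNP B-allele frequencies.

Allelic imbalance on a chromosome arm is quantified by the mean absolute
deviation of heterozygous-SNP BAFs from 0.5 (``mean(|BAF - 0.5|)``),
computed per sample and germline-corrected by subtracting the germline
arm MAD.  CNAI — imbalance on an arm without a total copy-number gain or
loss — is called by three ordered criteria: (1) corrected MAD ≥ 0.1;
(2) corrected MAD ≥ the median MAD of gain/loss-event arms in the same
sample and ≥ 0.05; (3) a rescue pass, run when an arm shows CNAI in two
or more regions, re-examining remaining regions against the lowest
quartile of event MADs in each region (floor 0.05).

MSAI — different regions showing imbalance of *opposite* parental
alleles on the same arm, the signature of parallel SCNA evolution — is
detected by sign concordance of per-SNP BAF deviations: SNP deviations
are oriented so that the most imbalanced region has positive mean
deviation; any region whose oriented mean deviation is below −δ carries
the mirror-image imbalance.  This avoids full haplotype phasing while
using the same shared-heterozygous-SNP evidence.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .model import ArmDefinition, DEFAULT_THRESHOLDS, Thresholds

logger = logging.getLogger("clonevo")

__all__ = [
    "select_het_snps",
    "compute_arm_mads",
    "call_cnai",
    "classify_cnai_clonality",
    "detect_msai",
]


def _arm_of(arms: list[ArmDefinition]):
    """Vectorizable (chrom, pos) -> arm label lookup."""
    table = [(a.chrom, a.start, a.end, a.label) for a in arms]

    def lookup(chrom: str, pos: int) -> str | None:
        for c, s, e, label in table:
            if c == chrom and s <= pos < e:
                return label
        return None

    return lookup


def select_het_snps(
    baf: pd.DataFrame,
    germline_id: str,
    region_ids: list[str],
    window: tuple[float, float] = (0.35, 0.65),
) -> pd.DataFrame:
    """Qualifying heterozygous SNPs: germline BAF inside ``window`` and
    the SNP observed in the germline sample and every region."""
    lo, hi = window
    germ = baf[baf["sample_id"] == germline_id]
    ok = germ[(germ["baf"] >= lo) & (germ["baf"] <= hi)]
    ok_pos = set(zip(ok["chrom"], ok["pos"]))
    required = set(region_ids) | {germline_id}
    counts = (
        baf[baf["sample_id"].isin(required)]
        .groupby(["chrom", "pos"])["sample_id"]
        .nunique()
    )
    complete = {k for k, n in counts.items() if n == len(required)}
    keep = ok_pos & complete
    mask = [
        (c, p) in keep for c, p in zip(baf["chrom"], baf["pos"])
    ]
    return baf[np.array(mask) & baf["sample_id"].isin(required)].copy()


def compute_arm_mads(
    baf: pd.DataFrame,
    arms: list[ArmDefinition],
    germline_id: str,
    region_ids: list[str],
    window: tuple[float, float] = (0.35, 0.65),
    min_snps: int = 10,
) -> pd.DataFrame:
    """Per-(sample, arm) MAD table with germline correction.

    Columns: sample_id, arm, n_snps, mad_raw, mad_corrected (tumor MAD
    minus germline MAD for the same arm; NaN for the germline rows'
    correction baseline itself is 0).  Arms with fewer than ``min_snps``
    qualifying SNPs yield no row (logged).
    """
    snps = select_het_snps(baf, germline_id, region_ids, window)
    if snps.empty:
        return pd.DataFrame(columns=["sample_id", "arm", "n_snps", "mad_raw", "mad_corrected"])
    lookup = _arm_of(arms)
    snps = snps.assign(
        arm=[lookup(c, p) for c, p in zip(snps["chrom"], snps["pos"])]
    )
    snps = snps.dropna(subset=["arm"])
    snps = snps.assign(dev=(snps["baf"] - 0.5).abs())
    grouped = snps.groupby(["sample_id", "arm"])
    rows = []
    for (sample, arm), grp in grouped:
        if len(grp) < min_snps:
            logger.warning(
                "arm %s in sample %s has %d < %d SNPs; no MAD", arm, sample, len(grp), min_snps
            )
            continue
        rows.append(
            {"sample_id": sample, "arm": arm, "n_snps": len(grp),
             "mad_raw": float(grp["dev"].mean())}
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(columns=["sample_id", "arm", "n_snps", "mad_raw", "mad_corrected"])
    germ_mad = (
        df[df["sample_id"] == germline_id].set_index("arm")["mad_raw"].to_dict()
    )
    df["mad_corrected"] = [
        row.mad_raw - germ_mad.get(row.arm, 0.0) for row in df.itertuples()
    ]
    return df.sort_values(["sample_id", "arm"]).reset_index(drop=True)


def call_cnai(
    mads: pd.DataFrame,
    arm_events: pd.DataFrame,
    germline_id: str,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """CNAI calls per (region, arm) with the triggering criterion.

    ``mads`` is the output of :func:`compute_arm_mads`; ``arm_events``
    has columns region_id, arm, direction.  Only regions with at least
    one arm MAD > 0.05 are considered.  Criterion 2 requires at least
    two gain/loss-event arms with MADs in the sample; the rescue pass is
    applied once after criteria 1-2.
    """
    tumor = mads[mads["sample_id"] != germline_id]
    if tumor.empty:
        return pd.DataFrame(columns=["region_id", "arm", "mad_corrected", "criterion"])
    event_arms: dict[str, set[str]] = {}
    for rec in arm_events.itertuples():
        event_arms.setdefault(rec.region_id, set()).add(rec.arm)

    # region screen: at least one arm with MAD > 0.05
    considered = {
        s
        for s, grp in tumor.groupby("sample_id")
        if (grp["mad_corrected"] > thresholds.mad_floor).any()
    }

    calls: list[dict] = []
    called: set[tuple[str, str]] = set()
    event_mads_by_region: dict[str, np.ndarray] = {}
    for sample, grp in tumor.groupby("sample_id"):
        ev = grp[grp["arm"].isin(event_arms.get(sample, set()))]["mad_corrected"]
        event_mads_by_region[sample] = ev.to_numpy()

    for rec in tumor.itertuples():
        sample, arm, mad = rec.sample_id, rec.arm, rec.mad_corrected
        if sample not in considered or arm in event_arms.get(sample, set()):
            continue
        if mad >= thresholds.mad_cnai:
            criterion = "mad_ge_0.1"
        else:
            ev = event_mads_by_region.get(sample, np.array([]))
            if len(ev) >= 2 and mad >= np.median(ev) and mad >= thresholds.mad_floor:
                criterion = "ge_median_event_mad"
            else:
                continue
        calls.append(
            {"region_id": sample, "arm": arm, "mad_corrected": mad, "criterion": criterion}
        )
        called.add((sample, arm))

    # rescue: arms CNAI in >=2 regions re-examined in remaining regions
    arm_counts: dict[str, int] = {}
    for _, a in called:
        arm_counts[a] = arm_counts.get(a, 0) + 1
    rescue_arms = {a for a, n in arm_counts.items() if n >= 2}
    for rec in tumor.itertuples():
        sample, arm, mad = rec.sample_id, rec.arm, rec.mad_corrected
        if (
            arm not in rescue_arms
            or (sample, arm) in called
            or sample not in considered
            or arm in event_arms.get(sample, set())
        ):
            continue
        ev = event_mads_by_region.get(sample, np.array([]))
        if len(ev) == 0:
            continue  # quartile cutoff undefined without event arms
        cutoff = float(np.percentile(ev, 25))
        if mad >= cutoff and mad >= thresholds.mad_floor:
            calls.append(
                {"region_id": sample, "arm": arm, "mad_corrected": mad,
                 "criterion": "rescue_lowest_quartile"}
            )
            called.add((sample, arm))
    return (
        pd.DataFrame(calls, columns=["region_id", "arm", "mad_corrected", "criterion"])
        .sort_values(["arm", "region_id"])
        .reset_index(drop=True)
    )


def classify_cnai_clonality(
    cnai_calls: pd.DataFrame,
    arm_events: pd.DataFrame,
    region_ids: list[str],
) -> pd.DataFrame:
    """Clonality categories for arms exhibiting CNAI.

    clonal_CNAI: every region CNAI, no gains/losses anywhere on the arm;
    clonal_loss_and_CNAI: every region shows a loss or CNAI;
    subclonal: CNAI somewhere but neither clonal pattern holds.
    """
    cnai_by_arm: dict[str, set[str]] = {}
    for rec in cnai_calls.itertuples():
        cnai_by_arm.setdefault(rec.arm, set()).add(rec.region_id)
    loss_by_arm: dict[str, set[str]] = {}
    gainloss_by_arm: dict[str, set[str]] = {}
    for rec in arm_events.itertuples():
        gainloss_by_arm.setdefault(rec.arm, set()).add(rec.region_id)
        if rec.direction == "loss":
            loss_by_arm.setdefault(rec.arm, set()).add(rec.region_id)
    all_regions = set(region_ids)
    rows = []
    for arm in sorted(cnai_by_arm):
        cnai = cnai_by_arm[arm]
        losses = loss_by_arm.get(arm, set())
        gainloss = gainloss_by_arm.get(arm, set())
        if cnai >= all_regions and not gainloss:
            cat = "clonal_CNAI"
        elif (cnai | losses) >= all_regions:
            cat = "clonal_loss_and_CNAI"
        else:
            cat = "subclonal"
        rows.append({"arm": arm, "clonality_category": cat,
                     "n_cnai_regions": len(cnai & all_regions)})
    return pd.DataFrame(rows, columns=["arm", "clonality_category", "n_cnai_regions"])


def detect_msai(
    baf: pd.DataFrame,
    arms: list[ArmDefinition],
    germline_id: str,
    region_ids: list[str],
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Detect mirrored subclonal allelic imbalance per arm.

    For each arm with ≥2 imbalanced regions (germline-corrected MAD ≥
    0.05), per-SNP BAF deviations are oriented by their sign in the most
    imbalanced (reference) region; a region whose oriented mean
    deviation is ≤ −δ while the reference is ≥ +δ is mirrored.  Returns
    one row per (arm, mirrored region pair).
    """
    delta = thresholds.msai_delta
    snps = select_het_snps(baf, germline_id, region_ids, thresholds.msai_baf_window)
    if snps.empty:
        return pd.DataFrame(
            columns=["arm", "region_a", "region_b", "score_a", "score_b", "n_snps"]
        )
    lookup = _arm_of(arms)
    snps = snps.assign(
        arm=[lookup(c, p) for c, p in zip(snps["chrom"], snps["pos"])]
    ).dropna(subset=["arm"])
    rows = []
    for arm, grp in snps.groupby("arm", sort=True):
        wide = grp.pivot_table(index=["chrom", "pos"], columns="sample_id", values="baf")
        if germline_id not in wide.columns:
            continue
        wide = wide.dropna()
        if len(wide) < thresholds.min_snps_per_arm:
            logger.warning("arm %s: %d shared SNPs < minimum; MSAI skipped", arm, len(wide))
            continue
        dev = wide - 0.5
        germ_mad = dev[germline_id].abs().mean()
        mads = {
            r: dev[r].abs().mean() - germ_mad
            for r in region_ids
            if r in dev.columns
        }
        imbalanced = [r for r, m in mads.items() if m >= thresholds.mad_floor]
        if len(imbalanced) < 2:
            continue
        ref = max(imbalanced, key=lambda r: mads[r])
        orient = np.sign(dev[ref].to_numpy())
        orient[orient == 0] = 1.0
        score_ref = float(np.mean(orient * dev[ref].to_numpy()))
        if score_ref < delta:
            continue
        for other in imbalanced:
            if other == ref:
                continue
            score = float(np.mean(orient * dev[other].to_numpy()))
            if score <= -delta:
                rows.append(
                    {"arm": arm, "region_a": ref, "region_b": other,
                     "score_a": score_ref, "score_b": score, "n_snps": len(wide)}
                )
    return pd.DataFrame(
        rows, columns=["arm", "region_a", "region_b", "score_a", "score_b", "n_snps"]
    )
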