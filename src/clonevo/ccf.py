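"""Variant filtering, DNV merging, cancer-cell-fraction estimation, and
clonality classification.

The central model relates the expected variant allele frequency of a
somatic mutation to the fraction of cancer cells carrying it::

    vaf = CNmut * CCF * p / (CNn * (1 - p) + CNt * p)

where ``p`` is tumor purity, ``CNt``/``CNn`` the tumor/normal locus copy
numbers (CNn assumed 2 on autosomes) and ``CNmut`` ∈ {1..CNt} the number
of chromosomal copies carrying the mutation.  CCF is estimated on the
grid {0.01, ..., 1.00} jointly with CNmut by maximizing the binomial
likelihood of the observed alt read count; ties break toward smaller
CNmut, then smaller CCF.

Clonality thresholds: a mutation is clonal in a region when CCF > 0.5,
present when CCF > 0.1, otherwise absent.  A mutation is clonal at tumor
level only when clonal in every QC-passing region, with an exception for
long INDELs (>6 bp affected) which are clonal when present everywhere.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .model import (
    CCFEstimate,
    DEFAULT_THRESHOLDS,
    MutationCall,
    Region,
    Thresholds,
    round_half_up,
)

__all__ = [
    "expected_vaf",
    "estimate_ccf",
    "tumor_clonality",
    "apply_variant_filters",
    "apply_post_ccf_filters",
    "merge_dnvs",
    "two_proportion_test",
]

CCF_GRID = np.round(np.arange(1, 101) / 100.0, 2)


def expected_vaf(ccf, cn_mut, purity: float, cn_total, cn_normal: int = 2):
    """Expected VAF under the copy-number-aware clonality model."""
    ccf = np.asarray(ccf, dtype=float)
    cn_mut = np.asarray(cn_mut, dtype=float)
    return cn_mut * ccf * purity / (cn_normal * (1 - purity) + cn_total * purity)


def estimate_ccf(
    call: MutationCall, region: Region, thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> CCFEstimate:
    """Grid maximum-likelihood (CCF, CNmut) for one call in one region.

    Searches CCF ∈ {0.01..1.00} × CNmut ∈ {1..CNt}; the flattened search
    is ordered CNmut-major ascending so exact likelihood ties resolve to
    the smaller CNmut, then the smaller CCF.
    """
    if call.depth <= 0:
        raise ValueError("estimate_ccf requires depth > 0")
    if region.purity <= 0:
        raise ValueError("estimate_ccf requires purity > 0")
    if call.cn_total < 1:
        # mutated locus reported at zero copies: inconsistent input
        return CCFEstimate(ccf=float("nan"), cn_mut=0, region_clonality="inconsistent")
    cn_mut = np.arange(1, call.cn_total + 1)[:, None]       # (CNt, 1)
    evaf = expected_vaf(CCF_GRID[None, :], cn_mut, region.purity, call.cn_total, call.cn_normal)
    loglik = stats.binom.logpmf(call.alt_reads, call.depth, evaf)
    flat = int(np.argmax(loglik))                           # first max = smallest CNmut/CCF
    best_mut = flat // len(CCF_GRID) + 1
    best_ccf = float(CCF_GRID[flat % len(CCF_GRID)])
    if best_ccf > thresholds.ccf_clonal:
        clonality = "clonal"
    elif best_ccf > thresholds.ccf_present:
        clonality = "subclonal"
    else:
        clonality = "absent"
    return CCFEstimate(ccf=best_ccf, cn_mut=best_mut, region_clonality=clonality)


def tumor_clonality(
    region_clonality: dict[str, str],
    variant_class: str,
    indel_span: int,
    qc_regions: list[str],
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> str:
    """Tumor-level clonality from per-region calls.

    ``region_clonality`` maps region_id -> clonal|subclonal|absent;
    regions not in the map count as absent.  Long INDELs (>6 bp
    affected) are clonal when present in every QC-passing region, to
    compensate for VAF underestimation at long indels.
    """
    states = {r: region_clonality.get(r, "absent") for r in qc_regions}
    long_indel = variant_class == "INDEL" and indel_span > thresholds.long_indel_bp
    if long_indel:
        if all(s in ("clonal", "subclonal") for s in states.values()):
            return "clonal"
        return "subclonal"
    if all(s == "clonal" for s in states.values()):
        return "clonal"
    return "subclonal"


# ---------------------------------------------------------------------------
# Variant filters (pre-CCF)


@dataclass
class FilterResult:
    kept: list[MutationCall]
    rejected: list[tuple[MutationCall, str]]


def apply_variant_filters(
    calls: list[MutationCall],
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    blacklist: set[str] | None = None,
) -> FilterResult:
    """Apply the pre-CCF variant filters per tumor.

    Row level: supporting reads on both strands; per-region depth within
    [50, 3000].  Variant level (across all regions of the tumor):
    germline support ≤5 alt reads AND germline VAF ≤1% (conjunctive);
    >5 alt reads in at least one surviving region; optional gene/region
    blacklist (excluded genomic classes).  A variant left with zero
    regions is dropped entirely.
    """
    blacklist = blacklist or set()
    kept: list[MutationCall] = []
    rejected: list[tuple[MutationCall, str]] = []
    by_variant: dict[tuple, list[MutationCall]] = defaultdict(list)
    for c in calls:
        by_variant[c.variant_key].append(c)

    for key, group in by_variant.items():
        # variant-level: germline support (criterion i, conjunctive)
        g_alt = max(c.germline_alt_reads for c in group)
        g_depth = max(c.germline_depth for c in group)
        g_vaf = g_alt / g_depth if g_depth > 0 else 0.0
        if g_alt > thresholds.germline_max_alt_reads or g_vaf > thresholds.germline_max_vaf:
            rejected.extend((c, "germline_support") for c in group)
            continue
        # variant-level: excluded genomic classes (criterion ii)
        if any((c.gene or "") in blacklist or c.chrom in blacklist for c in group):
            rejected.extend((c, "blacklist") for c in group)
            continue
        survivors = []
        for c in group:
            if not (c.strand_fwd and c.strand_rev) and c.alt_reads > 0:
                rejected.append((c, "strand_bias"))
            elif not (thresholds.depth_min <= c.depth <= thresholds.depth_max):
                rejected.append((c, "depth_range"))
            else:
                survivors.append(c)
        # variant-level: >5 supporting reads in ≥1 region (criterion iv)
        if not any(c.alt_reads > thresholds.min_alt_reads_any_region for c in survivors):
            rejected.extend((c, "min_alt_support") for c in survivors)
            continue
        kept.extend(survivors)
    return FilterResult(kept=kept, rejected=rejected)


def apply_post_ccf_filters(
    estimates: dict[tuple, dict[str, CCFEstimate]],
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> tuple[dict[tuple, dict[str, CCFEstimate]], list[tuple]]:
    """CCF-based filters: a variant must reach CCF > 0.5 in at least one
    region (criterion v); per-region presence requires CCF > 0.1
    (criterion vi, encoded in ``region_clonality``).

    ``estimates`` maps variant_key -> {region_id: CCFEstimate}.  Returns
    the surviving estimates and the rejected variant keys.
    """
    kept: dict[tuple, dict[str, CCFEstimate]] = {}
    dropped: list[tuple] = []
    for key, per_region in estimates.items():
        if any(
            not np.isnan(e.ccf) and e.ccf > thresholds.ccf_clonal
            for e in per_region.values()
        ):
            kept[key] = per_region
        else:
            dropped.append(key)
    return kept, dropped


# ---------------------------------------------------------------------------
# DNV merging


def two_proportion_test(a1: int, d1: int, a2: int, d2: int) -> float:
    """Two-sided two-proportion chi-square test without continuity
    correction; p-value for H0: the two binomial proportions are equal."""
    if d1 == 0 or d2 == 0:
        return 1.0
    p_pool = (a1 + a2) / (d1 + d2)
    if p_pool in (0.0, 1.0):
        return 1.0
    p1, p2 = a1 / d1, a2 / d2
    chi2 = (p1 - p2) ** 2 / (p_pool * (1 - p_pool) * (1 / d1 + 1 / d2))
    return float(stats.chi2.sf(chi2, df=1))


def merge_dnvs(
    calls: list[MutationCall], thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> list[MutationCall]:
    """Merge adjacent SNV pairs into dinucleotide variants (DNVs).

    Two SNVs at consecutive positions are merged when their VAFs are
    consistently balanced: the two-proportion test p ≥ 0.05 in every
    region where both are observed.  The merged record spans both
    positions; alt reads and depth are set to the pair mean (rounded
    half-up) per region.  Runs of >2 adjacent SNVs merge greedily
    left-to-right into non-overlapping pairs.
    """
    by_variant: dict[tuple, list[MutationCall]] = defaultdict(list)
    for c in calls:
        if c.variant_class == "SNV":
            by_variant[c.variant_key].append(c)
    keys = sorted(by_variant, key=lambda k: (k[0], k[1], k[2]))
    merged_keys: set[tuple] = set()
    out: list[MutationCall] = []
    for key in keys:
        if key in merged_keys:
            continue
        tumor, chrom, pos, ref, alt = key
        partner = next(
            (
                k
                for k in by_variant
                if k not in merged_keys
                and k[0] == tumor
                and k[1] == chrom
                and k[2] == pos + 1
            ),
            None,
        )
        if partner is None:
            continue
        g1 = {c.region_id: c for c in by_variant[key]}
        g2 = {c.region_id: c for c in by_variant[partner]}
        shared = sorted(set(g1) & set(g2))
        if not shared:
            continue
        balanced = all(
            two_proportion_test(
                g1[r].alt_reads, g1[r].depth, g2[r].alt_reads, g2[r].depth
            )
            >= thresholds.dnv_proportion_p
            for r in shared
        )
        if not balanced:
            continue
        merged_keys.update({key, partner})
        for r in shared:
            c1, c2 = g1[r], g2[r]
            alt_reads = round_half_up((c1.alt_reads + c2.alt_reads) / 2)
            depth = round_half_up((c1.depth + c2.depth) / 2)
            out.append(
                replace(
                    c1,
                    pos=c1.pos,
                    ref=c1.ref + c2.ref,
                    alt=c1.alt + c2.alt,
                    variant_class="DNV",
                    alt_reads=alt_reads,
                    depth=max(depth, alt_reads),
                )
            )
    untouched = [
        c
        for c in calls
        if not (c.variant_class == "SNV" and c.variant_key in merged_keys)
    ]
    return untouched + out


# ---------------------------------------------------------------------------
# Table-level convenience


def estimate_ccf_table(
    calls: list[MutationCall],
    regions: dict[str, Region],
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Per-(variant, region) CCF estimates as a tidy frame.

    ``regions`` maps region_id -> Region (for purity).  Calls in regions
    missing from the map are skipped.
    """
    rows = []
    for c in calls:
        region = regions.get(c.region_id)
        if region is None or c.depth <= 0:
            continue
        est = estimate_ccf(c, region, thresholds)
        rows.append(
            {
                "tumor_id": c.tumor_id, "region_id": c.region_id,
                "chrom": c.chrom, "pos": c.pos, "ref": c.ref, "alt": c.alt,
                "gene": c.gene, "variant_class": c.variant_class,
                "vaf": c.vaf, "ccf": est.ccf, "cn_mut": est.cn_mut,
                "region_clonality": est.region_clonality,
                "indel_span": c.indel_span,
            }
        )
    return pd.DataFrame(rows)


def tumor_clonality_table(
    ccf_table: pd.DataFrame,
    qc_regions: dict[str, list[str]],
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Tumor-level clonality per variant from a per-region CCF table.

    ``qc_regions`` maps tumor_id -> list of QC-passing region ids.
    """
    rows = []
    keys = ["tumor_id", "chrom", "pos", "ref", "alt"]
    for key, grp in ccf_table.groupby(keys, sort=True):
        tumor_id = key[0]
        per_region = dict(zip(grp["region_id"], grp["region_clonality"]))
        clonality = tumor_clonality(
            per_region,
            grp["variant_class"].iloc[0],
            int(grp["indel_span"].iloc[0]),
            qc_regions.get(tumor_id, sorted(per_region)),
            thresholds,
        )
        present = sorted(
            r for r, s in per_region.items() if s in ("clonal", "subclonal")
        )
        rows.append(
            dict(
                zip(keys, key),
                gene=grp["gene"].iloc[0],
                variant_class=grp["variant_class"].iloc[0],
                tumor_clonality=clonality,
                regions_present=",".join(present),
            )
        )
    return pd.DataFrame(rows)
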