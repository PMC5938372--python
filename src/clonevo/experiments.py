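"""Parameter-recovery and calibration experiments.

Each experiment regenerates synthetic data under the documented study
conditions (≈500x coverage, purities 0.4-0.9, 7 biopsies per tumor),
runs the corresponding pipeline stage from scratch, and measures how
well the truth is recovered.  They are used both by the test suite and
by the reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ccf import estimate_ccf
from .imbalance import detect_msai
from .model import DEFAULT_THRESHOLDS, MutationCall, Region, synthetic_arm_table
from .pipeline import analyze_tumor, _tree_event_meta
from .simulate import (
    SimulationConfig,
    SimTumor,
    simulate_baf_tracks,
    simulate_reads,
    simulate_tumor,
)
from .stats import parallel_evolution_test
from .subtypes import SUBTYPES, classify_tumor
from .trees import same_topology

__all__ = [
    "ccf_recovery",
    "tree_recovery",
    "subtype_recovery",
    "msai_operating_characteristics",
    "parallel_test_calibration",
    "parallel_test_power",
]

CCF_GRID = np.round(np.arange(1, 101) / 100.0, 2)


def ccf_recovery(
    n_mutations: int = 1000,
    depth: float = 500.0,
    purity_range: tuple[float, float] = (0.4, 0.9),
    seed: int = 0,
) -> dict:
    """Simulate mutations at diploid loci (CNt=2, CNmut=1), re-estimate
    CCF from the noisy read counts, and summarize recovery.

    Returns mean absolute CCF error and the clonal/subclonal
    misclassification rate among mutations with true CCF outside
    [0.45, 0.55].  True CCFs are stratified evenly over the estimation
    grid (a uniform design with lower Monte-Carlo variance than iid
    uniform draws).
    """
    rng = np.random.default_rng(seed)
    errors = []
    boundary_total = 0
    boundary_wrong = 0
    for i in range(n_mutations):
        true_ccf = float(CCF_GRID[i % len(CCF_GRID)])
        purity = float(rng.uniform(*purity_range))
        alt, d = simulate_reads(true_ccf, 1, 2, purity, depth, rng, noise=True)
        call = MutationCall(
            tumor_id="T", region_id="R", chrom="1", pos=100, ref="A", alt="T",
            variant_class="SNV", alt_reads=alt, depth=d, cn_total=2,
        )
        region = Region("R", "T", purity=purity, ploidy=2.0, mean_depth=depth)
        est = estimate_ccf(call, region)
        errors.append(abs(est.ccf - true_ccf))
        if abs(true_ccf - 0.5) > 0.05:
            boundary_total += 1
            if (est.ccf > 0.5) != (true_ccf > 0.5):
                boundary_wrong += 1
    return {
        "mean_abs_error": float(np.mean(errors)),
        "misclassification_rate": boundary_wrong / boundary_total,
        "n": n_mutations,
    }


def _manifest_entry(tumor: SimTumor) -> dict:
    return {
        "vhl_status": tumor.vhl_status,
        "case_id": tumor.tumor_id,
        "germline_id": tumor.germline_id,
        "regions": tumor.regions,
    }


def _analyze(tumor: SimTumor, cfg: SimulationConfig):
    arms = synthetic_arm_table(cfg.n_chromosomes, cfg.arm_length)
    return analyze_tumor(
        tumor.tumor_id, tumor.mutation_calls, tumor.segments,
        _manifest_entry(tumor), arms, DEFAULT_THRESHOLDS,
    )


def tree_recovery(
    n_tumors: int = 100,
    read_noise: bool = False,
    depth: float = 500.0,
    seed: int = 0,
) -> dict:
    """Simulate tumors (3-10 clones, 7 regions), reconstruct the clone
    tree from the read-level data, and count exact topology recoveries
    (compared as hierarchies of region-presence patterns)."""
    cfg = SimulationConfig(
        n_tumors=n_tumors, depth=depth, read_noise=read_noise, seed=seed
    )
    streams = np.random.SeedSequence(seed).spawn(n_tumors + 1)
    top = np.random.default_rng(streams[0])
    recovered = 0
    for i in range(n_tumors):
        subtype = SUBTYPES[int(top.integers(0, len(SUBTYPES)))]
        rng = np.random.default_rng(streams[i + 1])
        tumor = simulate_tumor(f"T{i + 1:03d}", subtype, cfg, rng)
        result = _analyze(tumor, cfg)
        if same_topology(result.tree, tumor.tree):
            recovered += 1
    return {"recovered": recovered, "n": n_tumors, "rate": recovered / n_tumors}


def subtype_recovery(
    n_tumors: int = 200,
    read_noise: bool = True,
    depth: float = 500.0,
    seed: int = 0,
) -> dict:
    """End-to-end subtype label recovery: simulate tumors from the seven
    subtype templates, run the full per-tumor pipeline, classify from
    the reconstructed tree, and compare with the generating label."""
    cfg = SimulationConfig(
        n_tumors=n_tumors, depth=depth, read_noise=read_noise, seed=seed
    )
    streams = np.random.SeedSequence(seed).spawn(n_tumors + 1)
    correct = 0
    for i in range(n_tumors):
        subtype = SUBTYPES[i % len(SUBTYPES)]
        rng = np.random.default_rng(streams[i + 1])
        tumor = simulate_tumor(f"T{i + 1:03d}", subtype, cfg, rng)
        result = _analyze(tumor, cfg)
        meta = _tree_event_meta(result)
        call = classify_tumor(result.tree, meta, tumor.vhl_status)
        if call.subtype == subtype:
            correct += 1
    return {"correct": correct, "n": n_tumors, "rate": correct / n_tumors}


def msai_operating_characteristics(
    n_positive: int = 100,
    n_negative: int = 100,
    n_snps: int = 100,
    depth: float = 500.0,
    purity_range: tuple[float, float] = (0.4, 0.9),
    seed: int = 0,
) -> dict:
    """MSAI detection sensitivity and false-positive rate.

    Positive replicates: two regions with copy-neutral LOH of *opposite*
    parental alleles on one arm.  Negative replicates: the same
    imbalance magnitude but of the *same* allele in both regions.
    """
    arms = synthetic_arm_table(1, 50_000_000)
    arm = arms[0]

    def replicate(mirrored: bool, rng: np.random.Generator) -> bool:
        regions = [
            Region(f"R{j}", "T", float(rng.uniform(*purity_range)), 2.0, depth)
            for j in (1, 2)
        ]
        allele_b = "B" if mirrored else "A"
        states = {
            arm.label: {"R1": ("cnloh", "A"), "R2": ("cnloh", allele_b)}
        }
        baf = simulate_baf_tracks(
            "T", "N", regions, states, arms, n_snps, depth, rng
        )
        events = detect_msai(baf, arms, "N", ["R1", "R2"], DEFAULT_THRESHOLDS)
        return len(events) > 0

    rng = np.random.default_rng(seed)
    tp = sum(replicate(True, rng) for _ in range(n_positive))
    fp = sum(replicate(False, rng) for _ in range(n_negative))
    return {
        "sensitivity": tp / n_positive,
        "false_positive_rate": fp / n_negative,
        "n_positive": n_positive,
        "n_negative": n_negative,
    }


def _one_parallel_cohort(
    n_cases: int,
    n_regions: int,
    p_gene: float,
    rng: np.random.Generator,
    n_inject: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-case distinct-mutation counts for one gene under the
    Bernoulli-trials model, optionally with ``n_inject`` cases forced to
    carry two parallel subclonal mutations."""
    k = rng.binomial(n_regions, p_gene, size=n_cases)
    if n_inject:
        idx = rng.choice(n_cases, size=n_inject, replace=False)
        k[idx] = np.maximum(k[idx], 2)
    cases = [f"K{i:03d}" for i in range(n_cases)]
    counts = pd.DataFrame({"GENE": k}, index=cases)
    return counts, pd.Series(n_regions, index=cases)


def parallel_test_calibration(
    n_cohorts: int = 200,
    n_cases: int = 100,
    n_regions: int = 7,
    p_gene: float = 10 / 700,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Type-I error of the parallel-evolution permutation test under its
    own Bernoulli null (no injected parallelism)."""
    rng = np.random.default_rng(seed)
    rejections = 0
    tested = 0
    for _ in range(n_cohorts):
        counts, n_reg = _one_parallel_cohort(n_cases, n_regions, p_gene, rng)
        res = parallel_evolution_test(counts, n_reg, rng, n_perm)
        if len(res):
            tested += 1
            if res["p"].iloc[0] < alpha:
                rejections += 1
    return {
        "rejection_rate": rejections / tested if tested else float("nan"),
        "n_cohorts_tested": tested,
    }


def parallel_test_power(
    n_cohorts: int = 200,
    n_cases: int = 100,
    n_regions: int = 7,
    p_gene: float = 10 / 700,
    n_inject: int = 3,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Power with ``n_inject`` cases per cohort carrying two parallel
    subclonal mutations of the tested gene."""
    rng = np.random.default_rng(seed)
    rejections = 0
    tested = 0
    for _ in range(n_cohorts):
        counts, n_reg = _one_parallel_cohort(
            n_cases, n_regions, p_gene, rng, n_inject
        )
        res = parallel_evolution_test(counts, n_reg, rng, n_perm)
        if len(res):
            tested += 1
            if res["p"].iloc[0] < alpha:
                rejections += 1
    return {"power": rejections / tested if tested else float("nan"), "n_cohorts_tested": tested}
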