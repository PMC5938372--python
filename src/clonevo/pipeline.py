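"""End-to-end orchestration: per-tumor analysis and cohort statistics.

Stage order: variant filters → DNV merge → CCF/clonality → arm events &
driver SCNAs → wGII/ITH → clone tree → allelic imbalance → cohort
statistics (parallel evolution, co-occurrence, ordering) → subtype
classification → saturation/downsampling.
"""

from __future__ import annotations

import hashlib
import json
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .ccf import (
    apply_variant_filters,
    estimate_ccf_table,
    merge_dnvs,
    tumor_clonality_table,
)
from .imbalance import call_cnai, classify_cnai_clonality, compute_arm_mads, detect_msai
from .model import (
    COOCCURRENCE_EVENTS,
    DEFAULT_THRESHOLDS,
    DRIVER_GENES,
    ArmDefinition,
    CloneTree,
    DriverEvent,
    HeterogeneityReport,
    MutationCall,
    Region,
    SegmentCall,
    Thresholds,
    synthetic_arm_table,
)
from .sampling import downsample_pairs, saturation_curve
from .scna import (
    annotate_driver_scnas,
    call_arm_events_cohort,
    compute_ith_index,
    compute_wgii_per_region,
)
from .stats import (
    clone_event_matrix,
    combine_cooccurrence_modes,
    cooccurrence_test,
    core_event_label,
    enumerate_trajectories,
    ordering_test,
    parallel_evolution_test,
)
from .subtypes import classify_cohort
from .trees import build_event_matrix, cluster_events, order_clones

logger = logging.getLogger("clonevo")

__all__ = ["TumorResult", "CohortResult", "analyze_tumor", "analyze_cohort", "run_pipeline"]


@dataclass
class TumorResult:
    tumor_id: str
    qc_regions: list[str]
    ccf_table: pd.DataFrame
    clonality_table: pd.DataFrame
    arm_events: pd.DataFrame
    driver_events: dict[str, DriverEvent]
    tree: CloneTree
    conflicts: list[dict]
    heterogeneity: HeterogeneityReport
    vhl_status: str
    case_id: str


@dataclass
class CohortResult:
    tumors: dict[str, TumorResult]
    parallel: pd.DataFrame = field(default_factory=pd.DataFrame)
    cooccurrence: pd.DataFrame = field(default_factory=pd.DataFrame)
    ordering: pd.DataFrame = field(default_factory=pd.DataFrame)
    subtypes: pd.DataFrame = field(default_factory=pd.DataFrame)
    saturation: pd.DataFrame = field(default_factory=pd.DataFrame)
    downsampling: pd.DataFrame = field(default_factory=pd.DataFrame)


def _mutation_event_id(gene: str | None, chrom: str, pos: int, ref: str, alt: str) -> str:
    g = gene or "NA"
    return f"mut:{g}:{chrom}:{pos}:{ref}:{alt}"


def analyze_tumor(
    tumor_id: str,
    calls: list[MutationCall],
    segments: list[SegmentCall],
    manifest_entry: dict,
    arms: list[ArmDefinition],
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> TumorResult:
    """Run the single-tumor stages: filters, CCF, clonality, SCNA
    metrics and clone-tree reconstruction."""
    qc = cio.qc_passing_regions(manifest_entry, thresholds.region_min_mean_depth)
    qc_ids = [r.region_id for r in qc]
    region_map: dict[str, Region] = {r.region_id: r for r in qc}
    calls = [c for c in calls if c.region_id in region_map]

    filtered = apply_variant_filters(calls, thresholds)
    merged = merge_dnvs(filtered.kept, thresholds)
    ccf_table = estimate_ccf_table(merged, region_map, thresholds)

    # criterion v: CCF > 0.5 somewhere, else the variant is dropped
    if len(ccf_table):
        keys = ["chrom", "pos", "ref", "alt"]
        reach = ccf_table.groupby(keys)["ccf"].transform("max")
        ccf_table = ccf_table[reach > thresholds.ccf_clonal].reset_index(drop=True)

    clonality = tumor_clonality_table(ccf_table, {tumor_id: qc_ids}, thresholds)

    ploidy = {r.region_id: r.ploidy for r in qc}
    arm_events = call_arm_events_cohort(
        [s for s in segments if s.region_id in region_map], arms, ploidy, thresholds
    )
    driver_scnas = annotate_driver_scnas(arm_events, qc_ids)

    driver_events: dict[str, DriverEvent] = {e.event_id: e for e in driver_scnas}
    for rec in clonality.itertuples():
        if rec.gene in DRIVER_GENES:
            present = frozenset(
                r for r in str(rec.regions_present).split(",") if r
            )
            if not present:
                continue
            eid = _mutation_event_id(rec.gene, rec.chrom, rec.pos, rec.ref, rec.alt)
            driver_events[eid] = DriverEvent(
                event_id=eid, event_type="mutation", label=rec.gene,
                regions_present=present, tumor_clonality=rec.tumor_clonality,
                gene=rec.gene, variant_class=rec.variant_class,
            )

    wgii = compute_wgii_per_region(
        [s for s in segments if s.region_id in region_map], arms, ploidy
    )
    het = compute_ith_index(tumor_id, list(driver_events.values()), wgii)

    # clone tree over all kept mutations + arm-level SCNAs
    matrix_events: list[tuple[str, str, frozenset[str]]] = []
    kinds: dict[str, str] = {}
    for rec in clonality.itertuples():
        present = frozenset(r for r in str(rec.regions_present).split(",") if r)
        if not present:
            continue
        eid = _mutation_event_id(rec.gene, rec.chrom, rec.pos, rec.ref, rec.alt)
        matrix_events.append((eid, "mutation_nonsyn", present))
        kinds[eid] = "mutation_nonsyn"
    if len(arm_events):
        labels = arm_events["direction"] + "_" + arm_events["arm"]
        for label, grp in arm_events.assign(label=labels).groupby("label"):
            present = frozenset(grp["region_id"]) & set(qc_ids)
            if not present:
                continue
            eid = f"scna:{label}"
            matrix_events.append((eid, "scna", present))
            kinds[eid] = "scna"
    matrix = build_event_matrix(matrix_events, qc_ids)
    clusters = cluster_events(matrix, kinds)
    tree, conflicts = order_clones(clusters, qc_ids, tumor_id)

    return TumorResult(
        tumor_id=tumor_id,
        qc_regions=qc_ids,
        ccf_table=ccf_table,
        clonality_table=clonality,
        arm_events=arm_events,
        driver_events=driver_events,
        tree=tree,
        conflicts=conflicts,
        heterogeneity=het,
        vhl_status=manifest_entry.get("vhl_status", "mutated"),
        case_id=manifest_entry.get("case_id", tumor_id),
    )


def _tree_event_meta(result: TumorResult) -> dict[str, DriverEvent]:
    """DriverEvents for every event id referenced by the tumor's tree
    (non-driver passenger mutations included, marked by their gene)."""
    meta = dict(result.driver_events)
    clonality_by_id = {}
    for rec in result.clonality_table.itertuples():
        eid = _mutation_event_id(rec.gene, rec.chrom, rec.pos, rec.ref, rec.alt)
        clonality_by_id[eid] = rec
    for clone in result.tree.clones.values():
        for eid in clone.events:
            if eid in meta:
                continue
            rec = clonality_by_id.get(eid)
            if rec is None:
                continue
            present = frozenset(r for r in str(rec.regions_present).split(",") if r)
            if not present:
                continue
            meta[eid] = DriverEvent(
                event_id=eid, event_type="mutation", label=rec.gene or "NA",
                regions_present=present, tumor_clonality=rec.tumor_clonality,
                gene=rec.gene if isinstance(rec.gene, str) else None,
                variant_class=rec.variant_class,
            )
    return meta


def _presence_matrix(result: TumorResult) -> tuple[pd.DataFrame, pd.Series]:
    """Driver-event presence matrix (events × biopsies) and tumor-level
    clonality, for the sampling analyses."""
    rows = {}
    clonality = {}
    for eid, ev in sorted(result.driver_events.items()):
        rows[eid] = [r in ev.regions_present for r in result.qc_regions]
        clonality[eid] = ev.tumor_clonality
    mat = pd.DataFrame.from_dict(rows, orient="index", columns=result.qc_regions).astype(int)
    return mat, pd.Series(clonality)


def analyze_cohort(
    mutations: list[MutationCall],
    segments: list[SegmentCall],
    baf: pd.DataFrame | None,
    manifest: dict,
    arms: list[ArmDefinition],
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    rng: np.random.Generator | None = None,
    run_imbalance: bool = True,
) -> tuple[CohortResult, dict]:
    """Run the full pipeline over a cohort.

    Returns the cohort result and a dict of allelic-imbalance tables
    (arm MADs, CNAI calls and categories, MSAI events).
    """
    rng = rng or np.random.default_rng(0)
    mut_by_tumor: dict[str, list[MutationCall]] = defaultdict(list)
    for m in mutations:
        mut_by_tumor[m.tumor_id].append(m)
    seg_by_tumor: dict[str, list[SegmentCall]] = defaultdict(list)
    for s in segments:
        seg_by_tumor[s.tumor_id].append(s)

    tumors: dict[str, TumorResult] = {}
    for tumor_id in sorted(manifest):
        tumors[tumor_id] = analyze_tumor(
            tumor_id,
            mut_by_tumor.get(tumor_id, []),
            seg_by_tumor.get(tumor_id, []),
            manifest[tumor_id],
            arms,
            thresholds,
        )

    # --- parallel evolution -------------------------------------------------
    clonality_all = pd.concat(
        [t.clonality_table for t in tumors.values() if len(t.clonality_table)],
        ignore_index=True,
    ) if tumors else pd.DataFrame()
    n_regions = pd.Series({t: len(r.qc_regions) for t, r in tumors.items()})
    if len(clonality_all):
        sub = clonality_all[
            (clonality_all["tumor_clonality"] == "subclonal")
            & (clonality_all["gene"].notna())
        ]
        counts = (
            sub.groupby(["tumor_id", "gene"]).size().unstack(fill_value=0)
            .reindex(index=n_regions.index, fill_value=0)
        )
        parallel = parallel_evolution_test(
            counts, n_regions, rng, thresholds.n_permutations, thresholds
        )
    else:
        parallel = pd.DataFrame()

    # --- co-occurrence ------------------------------------------------------
    trees = {t: r.tree for t, r in tumors.items()}
    event_meta = {t: _tree_event_meta(r) for t, r in tumors.items()}
    co_labels = {
        t: {
            eid: (ev.gene if ev.is_mutation else ev.label)
            for eid, ev in meta.items()
            if (ev.gene if ev.is_mutation else ev.label) in COOCCURRENCE_EVENTS
        }
        for t, meta in event_meta.items()
    }
    mrca = clone_event_matrix(trees, co_labels, COOCCURRENCE_EVENTS, "mrca_only")
    both = clone_event_matrix(trees, co_labels, COOCCURRENCE_EVENTS, "mrca_plus_terminal")
    co_m = cooccurrence_test(mrca)
    co_b = cooccurrence_test(both)
    cooccurrence = (
        combine_cooccurrence_modes(co_m, co_b, thresholds.alpha)
        if len(co_m) and len(co_b)
        else pd.DataFrame()
    )

    # --- event ordering -----------------------------------------------------
    traj_labels = {
        t: {
            eid: lab
            for eid, ev in meta.items()
            if (
                lab := core_event_label(
                    "mutation" if ev.is_mutation else "scna", ev.gene, ev.label
                )
            )
            is not None
        }
        for t, meta in event_meta.items()
    }
    _, pair_counts = enumerate_trajectories(trees, traj_labels)
    ordering = ordering_test(pair_counts, thresholds)

    # --- subtype classification --------------------------------------------
    subtype_inputs = {
        t: (r.tree, event_meta[t], r.vhl_status) for t, r in tumors.items()
    }
    case_of = {t: r.case_id for t, r in tumors.items()}
    subtypes = classify_cohort(subtype_inputs, case_of)

    # --- sampling analyses --------------------------------------------------
    sat_rows, down_rows = [], []
    for t, r in tumors.items():
        mat, clon = _presence_matrix(r)
        if not len(mat):
            continue
        curve = saturation_curve(mat, thresholds.max_subsets, rng)
        for rec in curve.itertuples():
            sat_rows.append(
                {"tumor_id": t, "size": rec.size, "mean_detected": rec.mean_detected,
                 "mode": rec.mode}
            )
        if len(r.qc_regions) >= 2:
            missed, illusion = downsample_pairs(mat, clon)
            down_rows.append(
                {"tumor_id": t, "mean_missed": missed, "mean_illusion": illusion}
            )
    saturation = pd.DataFrame(sat_rows)
    downsampling = pd.DataFrame(down_rows)

    # --- allelic imbalance --------------------------------------------------
    ai_tables: dict[str, pd.DataFrame] = {}
    if run_imbalance and baf is not None and len(baf):
        mad_frames, cnai_frames, cat_frames, msai_frames = [], [], [], []
        for tumor_id, r in tumors.items():
            tb = baf[baf["tumor_id"] == tumor_id]
            if not len(tb):
                continue
            germ = manifest[tumor_id].get("germline_id", f"{tumor_id}_N")
            mads = compute_arm_mads(
                tb, arms, germ, r.qc_regions,
                thresholds.het_baf_window, thresholds.min_snps_per_arm,
            )
            if len(mads):
                cnai = call_cnai(mads, r.arm_events, germ, thresholds)
                cats = classify_cnai_clonality(cnai, r.arm_events, r.qc_regions)
                msai = detect_msai(tb, arms, germ, r.qc_regions, thresholds)
                for df, acc in (
                    (mads, mad_frames), (cnai, cnai_frames),
                    (cats, cat_frames), (msai, msai_frames),
                ):
                    if len(df):
                        acc.append(df.assign(tumor_id=tumor_id))
        for name, acc in (
            ("arm_mads", mad_frames), ("cnai", cnai_frames),
            ("cnai_clonality", cat_frames), ("msai", msai_frames),
        ):
            ai_tables[name] = (
                pd.concat(acc, ignore_index=True) if acc else pd.DataFrame()
            )

    result = CohortResult(
        tumors=tumors, parallel=parallel, cooccurrence=cooccurrence,
        ordering=ordering, subtypes=subtypes, saturation=saturation,
        downsampling=downsampling,
    )
    return result, ai_tables


# ---------------------------------------------------------------------------
# Config-driven entry point


_KNOWN_KEYS = {"inputs", "simulate", "seed", "thresholds", "arms"}


def run_pipeline(config: dict | str | Path, out_dir: str | Path) -> dict:
    """Execute the pipeline from a config mapping or YAML file.

    Config keys: ``inputs`` (paths to mutations/segments/baf/manifest)
    or ``simulate`` (SimulationConfig overrides), optional ``seed``,
    ``thresholds`` overrides and ``arms`` ({n_chromosomes, arm_length}).
    Writes stage TSVs, per-tumor tree JSONs and a run manifest; returns
    the manifest dict.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    unknown = set(config) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    seed = int(config.get("seed", 0))
    thresholds = Thresholds(**config.get("thresholds", {}))
    arm_cfg = config.get("arms", {})
    arms = synthetic_arm_table(
        int(arm_cfg.get("n_chromosomes", 22)),
        int(arm_cfg.get("arm_length", 50_000_000)),
    )

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if "simulate" in config:
        from .simulate import SimulationConfig, simulate_cohort, write_cohort

        sim_cfg = SimulationConfig(**{**config["simulate"], "seed": seed})
        cohort = simulate_cohort(sim_cfg)
        write_cohort(cohort, out / "inputs")
        mutations, segments = cohort.mutations, cohort.segments
        baf, manifest = cohort.baf, cohort.manifest
    else:
        inputs = config["inputs"]
        mutations = cio.read_mutation_table(inputs["mutations"])
        segments = cio.read_segments(inputs["segments"])
        baf = cio.read_baf_table(inputs["baf"]) if inputs.get("baf") else None
        manifest = cio.read_manifest(inputs["manifest"])

    rng = np.random.default_rng(seed)
    result, ai_tables = analyze_cohort(
        mutations, segments, baf, manifest, arms, thresholds, rng
    )

    counts: dict[str, int] = {}
    frames = {
        "parallel_evolution.tsv": result.parallel,
        "cooccurrence.tsv": result.cooccurrence,
        "event_ordering.tsv": result.ordering,
        "subtypes.tsv": result.subtypes,
        "saturation.tsv": result.saturation,
        "downsampling.tsv": result.downsampling,
    }
    het_rows = [
        {
            "tumor_id": t, "n_clonal_drivers": r.heterogeneity.n_clonal_drivers,
            "n_subclonal_drivers": r.heterogeneity.n_subclonal_drivers,
            "ith_index": r.heterogeneity.ith_index,
            "wgii_max": r.heterogeneity.wgii_max,
        }
        for t, r in result.tumors.items()
    ]
    frames["heterogeneity.tsv"] = pd.DataFrame(het_rows)
    frames["ccf.tsv"] = pd.concat(
        [r.ccf_table for r in result.tumors.values() if len(r.ccf_table)],
        ignore_index=True,
    ) if result.tumors else pd.DataFrame()
    frames["clonality.tsv"] = pd.concat(
        [r.clonality_table for r in result.tumors.values() if len(r.clonality_table)],
        ignore_index=True,
    ) if result.tumors else pd.DataFrame()
    for name, df in ai_tables.items():
        frames[f"{name}.tsv"] = df
    for name, df in frames.items():
        df.to_csv(out / name, sep="\t", index=False)
        counts[name] = len(df)
    tree_dir = out / "trees"
    tree_dir.mkdir(exist_ok=True)
    for t, r in result.tumors.items():
        cio.write_tree(r.tree, tree_dir / f"{t}.json", "json")
        cio.write_tree(r.tree, tree_dir / f"{t}.nwk", "newick")

    cfg_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()
    manifest_out = {
        "seed": seed,
        "config_sha256": cfg_hash,
        "n_tumors": len(result.tumors),
        "row_counts": counts,
        "thresholds": {k: getattr(thresholds, k) for k in thresholds.__dataclass_fields__},
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest_out, fh, indent=2, sort_keys=True, default=str)
    return manifest_out
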