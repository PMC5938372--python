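"""Synthetic multi-region cohort simulator with ground truth.

Generates cohorts with the statistical structure the analysis stages
assume: each tumor is a rooted clone tree; biopsy regions are mixtures
of clones obeying the nesting constraint (a child clone's cancer cell
fraction never exceeds its parent's in any region); mutations follow the
infinite-sites assumption (one mutation, one clone, no back-mutation);
read counts are binomial at Poisson-distributed depth around the target
coverage; arm-level SCNAs are painted onto a miniature synthetic genome;
SNP BAF tracks reflect clone-weighted allelic copy numbers, with
optional mirrored (MSAI) arms where two regions lose opposite parental
alleles.

Driver events are placed according to evolutionary-subtype templates so
that the rule-based classifier must return the requested subtype,
enabling end-to-end label-recovery tests.  Region-presence patterns are
constructed with disjoint sibling occupancy (strict spatial
segregation), which makes them perfect-phylogeny compatible and the
containment tree reconstruction exactly invertible in the noise-free
setting.

The study this scaffolding emulates is observational; the generative
choices here are test scaffolding, not a fitted model of ccRCC growth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ccf import expected_vaf
from .io import write_manifest, write_mutation_table, write_segments
from .model import (
    Clone,
    CloneTree,
    DRIVER_SCNAS,
    MutationCall,
    Region,
    SegmentCall,
    synthetic_arm_table,
)
from .subtypes import SUBTYPES

__all__ = [
    "SimulationConfig",
    "SimEvent",
    "CohortTruth",
    "Cohort",
    "simulate_clone_tree",
    "simulate_region_composition",
    "assign_drivers_by_subtype",
    "simulate_reads",
    "simulate_baf_tracks",
    "simulate_tumor",
    "simulate_cohort",
    "write_cohort",
]


@dataclass
class SimulationConfig:
    """Cohort-level simulation settings.

    Defaults mirror the multi-region driver-panel study design: a median
    of 7 biopsies per tumor, ~500x target coverage, purities 0.4-0.9,
    3-10 clones per tumor, and the seven evolutionary subtypes in equal
    proportion.
    """

    n_tumors: int = 20
    regions_per_tumor: tuple[int, int] = (7, 7)
    clones_per_tumor: tuple[int, int] = (3, 10)
    depth: float = 500.0
    purity_range: tuple[float, float] = (0.4, 0.9)
    subtype_mix: dict[str, float] = field(
        default_factory=lambda: {s: 1.0 / len(SUBTYPES) for s in SUBTYPES}
    )
    passenger_rate: float = 2.0          # mean passenger mutations per clone
    n_extra_scnas: tuple[int, int] = (1, 3)  # extra driver SCNAs per tumor
    msai_rate: float = 0.3               # tumors given one mirrored CN-LOH arm
    n_snps_per_arm: int = 100
    n_chromosomes: int = 22
    arm_length: int = 50_000_000
    read_noise: bool = True              # False: deterministic expected counts
    min_clone_ccf: float = 0.65          # floor keeps every clone detectable
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.subtype_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"subtype_mix must sum to 1, got {total}")


@dataclass
class SimEvent:
    """Ground-truth description of one simulated event."""

    event_id: str
    kind: str                 # "mutation" | "scna"
    clone_id: str
    gene: str | None = None
    variant_class: str = "SNV"
    chrom: str | None = None
    pos: int | None = None
    ref: str = "A"
    alt: str = "T"
    arm: str | None = None    # for SCNAs
    direction: str | None = None  # gain | loss | cnloh
    allele: str | None = None     # parental allele affected ("A"/"B")
    is_core_driver: bool = False


@dataclass
class SimTumor:
    tumor_id: str
    tree: CloneTree
    events: dict[str, SimEvent]
    clone_ccfs: dict[str, dict[str, float]]   # clone -> region -> CCF
    regions: list[Region]
    germline_id: str
    subtype: str
    vhl_status: str
    msai_arms: list[tuple[str, str, str]]     # (arm, region_a, region_b)
    mutation_calls: list[MutationCall]
    segments: list[SegmentCall]
    baf: pd.DataFrame


@dataclass
class CohortTruth:
    trees: dict[str, CloneTree]
    events: dict[str, dict[str, SimEvent]]
    clone_ccfs: dict[str, dict[str, dict[str, float]]]
    subtypes: dict[str, str]
    vhl_status: dict[str, str]
    msai_arms: dict[str, list[tuple[str, str, str]]]


@dataclass
class Cohort:
    config: SimulationConfig
    mutations: list[MutationCall]
    segments: list[SegmentCall]
    baf: pd.DataFrame
    manifest: dict
    truth: CohortTruth


# ---------------------------------------------------------------------------
# Tree topology and region composition


def simulate_clone_tree(
    k_clones: int, rng: np.random.Generator, tumor_id: str = "T"
) -> CloneTree:
    """Random rooted tree skeleton with ``k_clones`` nodes, grown by
    uniform attachment (each new clone picks its parent uniformly)."""
    if k_clones < 1:
        raise ValueError(f"k_clones must be ≥ 1, got {k_clones}")
    ids = [f"C{i + 1}" for i in range(k_clones)]
    parent: dict[str, str | None] = {ids[0]: None}
    for i in range(1, k_clones):
        parent[ids[i]] = ids[int(rng.integers(0, i))]
    clones = {cid: Clone(cid) for cid in ids}
    return CloneTree(tumor_id=tumor_id, clones=clones, parent=parent)


def _min_regions_needed(tree: CloneTree) -> int:
    """Minimum number of regions so that every clone can receive a
    distinct nested presence pattern under disjoint sibling occupancy."""

    def need(node: str) -> int:
        kids = tree.children(node)
        if not kids:
            return 1
        total = sum(need(k) for k in kids)
        return total + (1 if len(kids) == 1 else 0)

    return need(tree.root)


def simulate_region_composition(
    tree: CloneTree,
    n_regions: int,
    rng: np.random.Generator,
    min_clone_ccf: float = 0.65,
    max_retries: int = 500,
) -> tuple[CloneTree, dict[str, dict[str, float]]]:
    """Assign region-presence patterns and per-region clone CCFs.

    The root occupies every region; each child receives a non-empty
    subset of its parent's regions, siblings disjoint, single children
    leaving the parent at least one private region.  CCFs decrease down
    the tree (child = parent − U(0.05, 0.25), floored at
    ``min_clone_ccf``), so the nesting constraint holds by construction
    and every clone is confidently detectable somewhere.
    """
    if n_regions < 1:
        raise ValueError("n_regions must be ≥ 1")
    if _min_regions_needed(tree) > n_regions:
        raise ValueError(
            f"tree needs ≥{_min_regions_needed(tree)} regions, got {n_regions}"
        )
    region_ids = [f"R{i + 1}" for i in range(n_regions)]

    def need(node: str) -> int:
        kids = tree.children(node)
        if not kids:
            return 1
        return sum(need(k) for k in kids) + (1 if len(kids) == 1 else 0)

    assignment: dict[str, frozenset[str]] = {tree.root: frozenset(region_ids)}

    def assign(node: str, pool: list[str]) -> None:
        kids = tree.children(node)
        if not kids:
            return
        needs = [need(k) for k in kids]
        reserve = 1 if len(kids) == 1 else 0
        extra = len(pool) - sum(needs) - reserve
        shares = list(needs)
        for _ in range(extra):
            # each spare region goes to a random child or stays private
            slot = int(rng.integers(0, len(kids) + 1))
            if slot < len(kids):
                shares[slot] += 1
        pool = list(pool)
        rng.shuffle(pool)
        offset = 0
        for kid, share in zip(kids, shares):
            sub = pool[offset: offset + share]
            offset += share
            assignment[kid] = frozenset(sub)
            assign(kid, sub)

    assign(tree.root, region_ids)

    ccfs: dict[str, dict[str, float]] = {
        tree.root: {r: 1.0 for r in region_ids}
    }

    def fill(node: str) -> None:
        for kid in tree.children(node):
            ccfs[kid] = {}
            for r in assignment[kid]:
                parent_ccf = ccfs[node][r]
                child = max(min_clone_ccf, parent_ccf - rng.uniform(0.05, 0.25))
                ccfs[kid][r] = min(child, parent_ccf)
            fill(kid)

    fill(tree.root)
    for cid in tree.clones:
        tree.clones[cid].regions = assignment[cid]
    return tree, ccfs


def _feasible_tree(
    k_clones: int, n_regions: int, rng: np.random.Generator, tumor_id: str
) -> CloneTree:
    """Sample topologies until one fits the region budget, lowering the
    clone count as a last resort."""
    k = k_clones
    while k >= 1:
        for _ in range(200):
            tree = simulate_clone_tree(k, rng, tumor_id)
            if _min_regions_needed(tree) <= n_regions:
                return tree
        k -= 1
    raise RuntimeError("could not build a feasible clone tree")


# ---------------------------------------------------------------------------
# Driver placement by subtype template


_GENE_ARMS = {
    "VHL": "3p", "PBRM1": "3p", "SETD2": "3p", "BAP1": "3p",
    "PIK3CA": "3q", "MTOR": "1p", "PTEN": "10q", "KDM5C": "2p",
    "CSMD3": "8q", "TP53": "17p", "TSC1": "9q", "TSC2": "16p",
    "ARID1A": "1p", "TCEB1": "8q",
}

# driver SCNAs safe to sprinkle without touching the 3p root loss
_EXTRA_SCNAS = tuple(s for s in DRIVER_SCNAS if s != "loss_3p")


def assign_drivers_by_subtype(
    tree: CloneTree,
    subtype: str,
    rng: np.random.Generator,
    n_extra_scnas: int = 2,
) -> tuple[dict[str, SimEvent], str]:
    """Place driver events so the rule-based classifier must return
    ``subtype``.  Returns (events, vhl_status).

    Templates (root = MRCA clone):

    - multiple_clonal_driver: root VHL + PBRM1 + SETD2 (+3p loss)
    - BAP1_driven: root VHL (+3p loss); BAP1 alone in a subclone
    - PBRM1_SETD2: root VHL + PBRM1 (+3p loss); SETD2 in a subclone
    - PBRM1_PI3K: root VHL + PBRM1 (+3p loss); MTOR/PIK3CA in a subclone
    - PBRM1_SCNA: root VHL + PBRM1 (+3p loss); driver SCNA in a subclone
    - VHL_wildtype: root SETD2 (+3p loss); no VHL, not methylated
    - VHL_monodriver: root VHL + 3p loss; no other core driver
    """
    if subtype not in SUBTYPES:
        raise ValueError(f"unknown subtype {subtype!r}")
    non_root = [c for c in sorted(tree.clones) if c != tree.root]
    if subtype not in ("multiple_clonal_driver", "VHL_monodriver", "VHL_wildtype") and not non_root:
        raise ValueError(f"subtype {subtype} needs ≥2 clones")
    events: dict[str, SimEvent] = {}
    counter = [0]

    def add_mut(gene: str, clone: str) -> None:
        counter[0] += 1
        eid = f"mut:{gene}:{counter[0]}"
        events[eid] = SimEvent(
            event_id=eid, kind="mutation", clone_id=clone, gene=gene,
            is_core_driver=True,
        )

    def add_scna(label: str, clone: str) -> None:
        direction, arm = label.split("_")
        eid = f"scna:{label}"
        if eid in events:
            return
        events[eid] = SimEvent(
            event_id=eid, kind="scna", clone_id=clone, arm=arm,
            direction=direction, allele="A" if rng.random() < 0.5 else "B",
            is_core_driver=True,
        )

    root = tree.root
    pick = lambda: non_root[int(rng.integers(0, len(non_root)))]

    vhl_status = "mutated"
    add_scna("loss_3p", root)
    if subtype == "multiple_clonal_driver":
        add_mut("VHL", root)
        add_mut("PBRM1", root)
        add_mut("SETD2", root)
    elif subtype == "BAP1_driven":
        add_mut("VHL", root)
        add_mut("BAP1", pick())
    elif subtype == "PBRM1_SETD2":
        add_mut("VHL", root)
        add_mut("PBRM1", root)
        add_mut("SETD2", pick())
    elif subtype == "PBRM1_PI3K":
        add_mut("VHL", root)
        add_mut("PBRM1", root)
        add_mut("MTOR" if rng.random() < 0.5 else "PIK3CA", pick())
    elif subtype == "PBRM1_SCNA":
        add_mut("VHL", root)
        add_mut("PBRM1", root)
        label = _EXTRA_SCNAS[int(rng.integers(0, len(_EXTRA_SCNAS)))]
        add_scna(label, pick())
    elif subtype == "VHL_wildtype":
        vhl_status = "wildtype"
        add_mut("SETD2", root)
    elif subtype == "VHL_monodriver":
        add_mut("VHL", root)

    # extra clonal driver SCNAs for copy-number realism; placed in the
    # root so they cannot create an unintended PBRM1->SCNA ordering
    used_arms = {e.arm for e in events.values() if e.kind == "scna"}
    candidates = [s for s in _EXTRA_SCNAS if s.split("_")[1] not in used_arms]
    rng.shuffle(candidates)
    for label in candidates[:n_extra_scnas]:
        add_scna(label, root)
        used_arms.add(label.split("_")[1])
    return events, vhl_status


# ---------------------------------------------------------------------------
# Read counts, segments and BAF tracks


def simulate_reads(
    ccf: float,
    cn_mut: int,
    cn_total: int,
    purity: float,
    depth: float,
    rng: np.random.Generator,
    noise: bool = True,
) -> tuple[int, int]:
    """Draw (alt_reads, depth) for one mutation in one region.

    Depth ~ Poisson(depth) truncated at ≥1; alt ~ Binomial(depth, vaf)
    with vaf from the clonality model.  With ``noise=False`` the
    expected counts are returned deterministically.
    """
    evaf = float(expected_vaf(ccf, cn_mut, purity, cn_total)) if ccf > 0 else 0.0
    if evaf > 1.0 + 1e-9:
        raise ValueError(f"inconsistent truth: expected vaf {evaf:.3f} > 1")
    if not noise:
        d = max(1, int(round(depth)))
        return int(round(evaf * d)), d
    d = 0
    while d < 1:
        d = int(rng.poisson(depth))
    alt = int(rng.binomial(d, min(evaf, 1.0)))
    return alt, d


def _allelic_cn(region_arm_state: str) -> tuple[int, int]:
    """Parental allele copy numbers (cA, cB) for an arm state where the
    affected allele is A; mirror for allele B."""
    return {
        "neutral": (1, 1),
        "loss": (0, 1),     # allele A lost
        "gain": (2, 1),     # allele A gained
        "cnloh": (0, 2),    # copy-neutral LOH of allele A
    }[region_arm_state]


def simulate_baf_tracks(
    tumor_id: str,
    germline_id: str,
    regions: list[Region],
    arm_states: dict[str, dict[str, tuple[str, str]]],
    arms,
    n_snps_per_arm: int,
    depth: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Heterozygous-SNP BAF tracks for germline and all regions.

    ``arm_states`` maps arm label -> {region_id: (state, allele)} with
    state ∈ {neutral, loss, gain, cnloh} and allele the affected
    parental allele; missing regions are neutral.  Germline BAFs are
    binomial around 0.5; tumor BAFs follow the purity-weighted allelic
    copy numbers.  Each SNP's alt base is assigned to a random parental
    haplotype, fixed across samples.
    """
    rows = []
    arm_by_label = {a.label: a for a in arms}
    for label in sorted(arm_states):
        arm = arm_by_label[label]
        span = arm.end - arm.start
        positions = arm.start + 1 + (
            np.arange(n_snps_per_arm) * max(1, span // (n_snps_per_arm + 1))
        )
        alt_hap = rng.random(n_snps_per_arm) < 0.5  # True: alt on allele A
        d_germ = np.maximum(1, rng.poisson(depth, n_snps_per_arm))
        alt_germ = rng.binomial(d_germ, 0.5)
        for pos, d, a in zip(positions, d_germ, alt_germ):
            rows.append(
                {"tumor_id": tumor_id, "sample_id": germline_id,
                 "chrom": arm.chrom, "pos": int(pos), "baf": a / d, "depth": int(d)}
            )
        for region in regions:
            state, allele = arm_states[label].get(region.region_id, ("neutral", "A"))
            c_aff, c_oth = _allelic_cn(state)
            if allele == "A":
                cA, cB = c_aff, c_oth
            else:
                cA, cB = c_oth, c_aff
            p = region.purity
            tot = p * (cA + cB) + (1 - p) * 2
            frac_A = (p * cA + (1 - p) * 1) / tot
            frac = np.where(alt_hap, frac_A, 1 - frac_A)
            d_reg = np.maximum(1, rng.poisson(depth, n_snps_per_arm))
            alt_reads = rng.binomial(d_reg, frac)
            for pos, d, a in zip(positions, d_reg, alt_reads):
                rows.append(
                    {"tumor_id": tumor_id, "sample_id": region.region_id,
                     "chrom": arm.chrom, "pos": int(pos), "baf": a / d,
                     "depth": int(d)}
                )
    return pd.DataFrame(
        rows, columns=["tumor_id", "sample_id", "chrom", "pos", "baf", "depth"]
    )


# ---------------------------------------------------------------------------
# Whole-tumor and whole-cohort assembly


def _gene_positions(arms, extra_genes: list[str]) -> dict[str, tuple[str, int]]:
    arm_by_label = {a.label: a for a in arms}
    pos: dict[str, tuple[str, int]] = {}
    for i, (gene, arm_label) in enumerate(sorted(_GENE_ARMS.items())):
        if arm_label in arm_by_label:
            arm = arm_by_label[arm_label]
        else:  # miniature genomes without the canonical arm
            arm = list(arms)[i % len(list(arms))]
        pos[gene] = (arm.chrom, arm.start + 1_000_000 + 10_000 * i)
    arm_list = list(arms)
    for i, gene in enumerate(extra_genes):
        arm = arm_list[i % len(arm_list)]
        pos[gene] = (arm.chrom, arm.start + 5_000_000 + 10_000 * (i // len(arm_list) + 1) + 137 * i)
    return pos


def simulate_tumor(
    tumor_id: str,
    subtype: str,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> SimTumor:
    """Simulate one tumor end to end: tree, drivers, passengers,
    segments, mutation read counts and BAF tracks."""
    arms = synthetic_arm_table(cfg.n_chromosomes, cfg.arm_length)
    n_regions = int(rng.integers(cfg.regions_per_tumor[0], cfg.regions_per_tumor[1] + 1))
    k = int(rng.integers(cfg.clones_per_tumor[0], cfg.clones_per_tumor[1] + 1))
    tree = _feasible_tree(k, n_regions, rng, tumor_id)
    tree, ccfs = simulate_region_composition(
        tree, n_regions, rng, min_clone_ccf=cfg.min_clone_ccf
    )

    n_extra = int(rng.integers(cfg.n_extra_scnas[0], cfg.n_extra_scnas[1] + 1))
    events, vhl_status = assign_drivers_by_subtype(tree, subtype, rng, n_extra)

    # passenger mutations: every non-root clone carries at least one so
    # each clone is marked by a non-synonymous mutation
    passenger_genes = [f"PSG{i:03d}" for i in range(200)]
    counter = len(events)
    for cid in sorted(tree.clones):
        n_pass = int(rng.poisson(cfg.passenger_rate))
        if cid != tree.root:
            n_pass = max(1, n_pass)
        for _ in range(n_pass):
            counter += 1
            gene = passenger_genes[int(rng.integers(0, len(passenger_genes)))]
            eid = f"mut:{gene}:{counter}"
            events[eid] = SimEvent(
                event_id=eid, kind="mutation", clone_id=cid, gene=gene
            )

    # register events on their clones
    for eid in sorted(events):
        tree.clones[events[eid].clone_id].events.append(eid)

    # regions with purity and depth
    regions = [
        Region(
            region_id=f"{tumor_id}_{r}",
            tumor_id=tumor_id,
            purity=float(rng.uniform(*cfg.purity_range)),
            ploidy=2.0,
            mean_depth=cfg.depth,
        )
        for r in sorted(ccfs[tree.root].keys(), key=lambda x: int(x[1:]))
    ]
    # re-key regions/ccfs to cohort-unique ids
    rename = {r: f"{tumor_id}_{r}" for r in ccfs[tree.root]}
    ccfs = {c: {rename[r]: v for r, v in d.items()} for c, d in ccfs.items()}
    for c in tree.clones.values():
        c.regions = frozenset(rename[r] for r in c.regions)
    region_by_id = {r.region_id: r for r in regions}

    # arm states per region: SCNAs painted where their clone is present
    arm_states: dict[str, dict[str, tuple[str, str]]] = {a.label: {} for a in arms}
    for ev in events.values():
        if ev.kind != "scna":
            continue
        for rid in tree.clones[ev.clone_id].regions:
            arm_states[ev.arm][rid] = (ev.direction, ev.allele or "A")

    # optional mirrored CN-LOH arm: two regions lose opposite alleles
    msai_arms: list[tuple[str, str, str]] = []
    if len(regions) >= 2 and rng.random() < cfg.msai_rate:
        free_arms = [a.label for a in arms if not arm_states[a.label]]
        if free_arms:
            arm = free_arms[int(rng.integers(0, len(free_arms)))]
            idx = rng.choice(len(regions), size=2, replace=False)
            r1, r2 = regions[int(idx[0])].region_id, regions[int(idx[1])].region_id
            arm_states[arm][r1] = ("cnloh", "A")
            arm_states[arm][r2] = ("cnloh", "B")
            msai_arms.append((arm, r1, r2))

    # segments: one per arm per region
    cn_of_state = {"neutral": (2, 1), "loss": (1, 0), "gain": (3, 1), "cnloh": (2, 0)}
    segments = []
    for region in regions:
        for arm in arms:
            state, _allele = arm_states[arm.label].get(
                region.region_id, ("neutral", "A")
            )
            cn_total, cn_minor = cn_of_state[state]
            segments.append(
                SegmentCall(
                    tumor_id=tumor_id, region_id=region.region_id,
                    chrom=arm.chrom, start=arm.start, end=arm.end,
                    cn_total=cn_total, cn_minor=cn_minor,
                )
            )
    arm_cn = {
        (region.region_id, a.label): cn_of_state[
            arm_states[a.label].get(region.region_id, ("neutral", "A"))[0]
        ][0]
        for region in regions
        for a in arms
    }
    # mutation read counts
    gene_pos = _gene_positions(arms, passenger_genes)
    arm_lookup = [(a.chrom, a.start, a.end, a.label) for a in arms]

    def arm_of(chrom: str, pos: int) -> str:
        for c, s, e, label in arm_lookup:
            if c == chrom and s <= pos - 1 < e:
                return label
        raise KeyError((chrom, pos))

    calls: list[MutationCall] = []
    used_pos: dict[str, int] = {}
    for eid, ev in sorted(events.items()):
        if ev.kind != "mutation":
            continue
        chrom, base = gene_pos[ev.gene]
        shift = used_pos.get(ev.gene, 0)
        used_pos[ev.gene] = shift + 3
        pos = base + shift
        ev.chrom, ev.pos = chrom, pos
        arm = arm_of(chrom, pos)
        clone_ccf = ccfs[ev.clone_id]
        for region in regions:
            ccf = clone_ccf.get(region.region_id, 0.0)
            cn_total = arm_cn[(region.region_id, arm)]
            alt, d = simulate_reads(
                ccf, 1, cn_total, region.purity, cfg.depth, rng, cfg.read_noise
            )
            g_depth = max(1, int(rng.poisson(cfg.depth))) if cfg.read_noise else int(cfg.depth)
            calls.append(
                MutationCall(
                    tumor_id=tumor_id, region_id=region.region_id,
                    chrom=chrom, pos=pos, ref="A", alt="T",
                    variant_class=ev.variant_class, gene=ev.gene,
                    alt_reads=alt, depth=d, cn_total=cn_total,
                    germline_alt_reads=0, germline_depth=g_depth,
                    strand_fwd=True, strand_rev=True,
                )
            )

    # BAF tracks only for arms that can show imbalance plus a neutral
    # background sample of arms (keeps tables small)
    germline_id = f"{tumor_id}_N"
    interesting = sorted(
        {label for label, states in arm_states.items() if states}
    )
    neutral_pool = sorted(set(a.label for a in arms) - set(interesting))
    background = neutral_pool[: max(0, 6 - len(interesting))]
    tracked = {label: arm_states[label] for label in interesting + background}
    baf = simulate_baf_tracks(
        tumor_id, germline_id, regions, tracked, arms,
        cfg.n_snps_per_arm, cfg.depth, rng,
    )

    return SimTumor(
        tumor_id=tumor_id, tree=tree, events=events, clone_ccfs=ccfs,
        regions=regions, germline_id=germline_id, subtype=subtype,
        vhl_status=vhl_status, msai_arms=msai_arms,
        mutation_calls=calls, segments=segments, baf=baf,
    )


def simulate_cohort(cfg: SimulationConfig) -> Cohort:
    """Simulate a full cohort from a master seed; per-tumor substreams
    make the output byte-identical for a fixed seed."""
    master = np.random.SeedSequence(cfg.seed)
    streams = master.spawn(cfg.n_tumors + 1)
    top_rng = np.random.default_rng(streams[0])
    subtype_names = sorted(cfg.subtype_mix)
    probs = np.array([cfg.subtype_mix[s] for s in subtype_names])
    assigned = [
        subtype_names[int(i)]
        for i in top_rng.choice(len(subtype_names), size=cfg.n_tumors, p=probs)
    ]
    mutations: list[MutationCall] = []
    segments: list[SegmentCall] = []
    bafs = []
    manifest: dict = {}
    truth = CohortTruth(
        trees={}, events={}, clone_ccfs={}, subtypes={}, vhl_status={}, msai_arms={}
    )
    for i in range(cfg.n_tumors):
        tumor_id = f"T{i + 1:03d}"
        rng = np.random.default_rng(streams[i + 1])
        tumor = simulate_tumor(tumor_id, assigned[i], cfg, rng)
        mutations.extend(tumor.mutation_calls)
        segments.extend(tumor.segments)
        bafs.append(tumor.baf)
        manifest[tumor_id] = {
            "vhl_status": tumor.vhl_status,
            "case_id": tumor_id,
            "regions": tumor.regions,
            "germline_id": tumor.germline_id,
        }
        truth.trees[tumor_id] = tumor.tree
        truth.events[tumor_id] = tumor.events
        truth.clone_ccfs[tumor_id] = tumor.clone_ccfs
        truth.subtypes[tumor_id] = tumor.subtype
        truth.vhl_status[tumor_id] = tumor.vhl_status
        truth.msai_arms[tumor_id] = tumor.msai_arms
    baf = (
        pd.concat(bafs, ignore_index=True)
        if bafs
        else pd.DataFrame(columns=["tumor_id", "sample_id", "chrom", "pos", "baf", "depth"])
    )
    return Cohort(
        config=cfg, mutations=mutations, segments=segments, baf=baf,
        manifest=manifest, truth=truth,
    )


def true_driver_events(tree: CloneTree, events: dict[str, SimEvent]):
    """Ground-truth :class:`DriverEvent` objects for driver mutations
    and driver SCNAs of one simulated tumor.

    Tumor clonality follows from the construction: only the root clone
    occupies (and is clonal in) every region.
    """
    from .model import DRIVER_GENES, DriverEvent

    out: dict[str, DriverEvent] = {}
    for eid, ev in sorted(events.items()):
        regions = tree.clones[ev.clone_id].regions
        clonality = "clonal" if ev.clone_id == tree.root else "subclonal"
        if ev.kind == "mutation" and ev.gene in DRIVER_GENES:
            out[eid] = DriverEvent(
                event_id=eid, event_type="mutation", label=ev.gene,
                regions_present=regions, tumor_clonality=clonality,
                gene=ev.gene, variant_class=ev.variant_class,
            )
        elif ev.kind == "scna" and f"{ev.direction}_{ev.arm}" in DRIVER_SCNAS:
            label = f"{ev.direction}_{ev.arm}"
            out[eid] = DriverEvent(
                event_id=eid, event_type=f"scna_{ev.direction}", label=label,
                regions_present=regions, tumor_clonality=clonality,
            )
    return out


def write_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    """Write the four input tables plus the ground truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_mutation_table(cohort.mutations, out / "mutations.tsv")
    write_segments(cohort.segments, out / "segments.tsv")
    cohort.baf.to_csv(out / "baf.tsv", sep="\t", index=False)
    write_manifest(cohort.manifest, out / "manifest.yaml")
    truth = {
        "subtypes": cohort.truth.subtypes,
        "vhl_status": cohort.truth.vhl_status,
        "msai_arms": cohort.truth.msai_arms,
        "trees": {
            t: {
                "root": tree.root,
                "parent": {c: p for c, p in tree.parent.items()},
                "clones": {
                    c: {"events": sorted(cl.events), "regions": sorted(cl.regions)}
                    for c, cl in tree.clones.items()
                },
            }
            for t, tree in cohort.truth.trees.items()
        },
        "clone_ccfs": cohort.truth.clone_ccfs,
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
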