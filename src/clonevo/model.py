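"""Shared domain types, default gene/arm sets, and analysis thresholds.

The package analyses multi-region tumor sequencing cohorts of the kind
produced by driver-panel studies of clear-cell renal cell carcinoma
(ccRCC): per-region somatic mutation calls with read counts, absolute
copy-number segments with purity/ploidy, and germline-heterozygous SNP
B-allele-frequency tables.  Everything downstream (cancer cell fraction
estimation, clone trees, heterogeneity metrics, evolutionary statistics)
operates on the types defined here.

Coordinate conventions: mutations are 1-based (VCF style); copy-number
segments are 0-based half-open (BED style).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "DRIVER_GENES",
    "PI3K_PATHWAY_GENES",
    "CORE_MUTATION_GENES",
    "DRIVER_SCNA_LOSSES",
    "DRIVER_SCNA_GAINS",
    "DRIVER_SCNAS",
    "COOCCURRENCE_EVENTS",
    "Thresholds",
    "Region",
    "MutationCall",
    "CCFEstimate",
    "SegmentCall",
    "ArmDefinition",
    "DriverEvent",
    "Clone",
    "CloneTree",
    "SNPBAFRecord",
    "HeterogeneityReport",
    "synthetic_arm_table",
    "hg19_arm_table",
    "round_half_up",
]

# High-confidence ccRCC driver genes targeted by the panel.
DRIVER_GENES: tuple[str, ...] = (
    "VHL", "PBRM1", "SETD2", "PIK3CA", "MTOR", "PTEN", "KDM5C",
    "CSMD3", "BAP1", "TP53", "TSC1", "TSC2", "ARID1A", "TCEB1",
)

# PI3K/AKT/mTOR pathway members within the driver list.
PI3K_PATHWAY_GENES: frozenset[str] = frozenset({"PIK3CA", "MTOR", "PTEN", "TSC1", "TSC2"})

# "Core" mutational drivers used for trajectories and subtype rules:
# the four frequently mutated 3p-region genes plus the PI3K pathway.
CORE_MUTATION_GENES: frozenset[str] = (
    frozenset({"VHL", "PBRM1", "BAP1", "SETD2"}) | PI3K_PATHWAY_GENES
)

# Recurrent arm-level driver SCNAs in ccRCC.
DRIVER_SCNA_LOSSES: tuple[str, ...] = ("1p", "3p", "4q", "6q", "8p", "9p", "14q")
DRIVER_SCNA_GAINS: tuple[str, ...] = ("1q", "2q", "5q", "7q", "8q", "12p", "20q")
DRIVER_SCNAS: tuple[str, ...] = tuple(
    [f"loss_{a}" for a in DRIVER_SCNA_LOSSES] + [f"gain_{a}" for a in DRIVER_SCNA_GAINS]
)

# Events tested in the clone-level co-occurrence analysis: the most
# frequent mutational drivers, the most frequent SCNAs, and SCNAs with
# prognostic value.
COOCCURRENCE_EVENTS: tuple[str, ...] = (
    "BAP1", "PBRM1", "SETD2", "VHL",
    "loss_3p", "gain_5q", "loss_4q", "loss_9p", "loss_14q", "gain_8q",
)


def round_half_up(x: float) -> int:
    """Round to nearest integer with .5 going up (not banker's rounding)."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class Thresholds:
    """All tunable cut-offs of the analysis, in one auditable place.

    Defaults follow the published ccRCC multi-region protocol; every
    value can be overridden via the pipeline config.
    """

    # CCF clonality: >0.5 clonal in a region, >0.1 present in a region
    ccf_clonal: float = 0.5
    ccf_present: float = 0.1
    # variant filters
    germline_max_alt_reads: int = 5       # criterion i: ≤5 germline alt reads
    germline_max_vaf: float = 0.01        # criterion i: germline VAF ≤1%
    min_alt_reads_any_region: int = 5     # criterion iv: >5 reads in ≥1 region
    depth_min: int = 50                   # criterion vii
    depth_max: int = 3000                 # criterion vii
    dnv_proportion_p: float = 0.05        # DNV merge when proportion-test p ≥ this
    long_indel_bp: int = 6                # tumor-clonality exception for INDELs >6 bp
    region_min_mean_depth: float = 100.0  # region QC
    # SCNA calling
    arm_event_fraction: float = 0.5       # >50% of arm aberrant
    # allelic imbalance
    het_baf_window: tuple[float, float] = (0.35, 0.65)   # CNAI germline window
    msai_baf_window: tuple[float, float] = (0.30, 0.70)  # MSAI germline window
    mad_cnai: float = 0.10                # CNAI criterion 1
    mad_floor: float = 0.05               # CNAI criteria 2/3 floor and region screen
    min_snps_per_arm: int = 10
    msai_delta: float = 0.05              # signed-deviation threshold
    # evolutionary statistics
    min_subclonal_mutations: int = 10     # parallel-evolution gene qualification
    n_permutations: int = 1000
    min_ordering_cases: int = 10          # binomial ordering test
    alpha: float = 0.05
    # sampling analysis
    max_subsets: int = 18_000_000         # exhaustive iff C(n,s) < this


DEFAULT_THRESHOLDS = Thresholds()


# ---------------------------------------------------------------------------
# Per-region sample metadata


@dataclass
class Region:
    """One sequenced tumor biopsy region."""

    region_id: str
    tumor_id: str
    purity: float
    ploidy: float
    mean_depth: float
    qc_pass: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.purity <= 1.0):
            raise ValueError(f"purity must be in [0,1], got {self.purity}")
        if self.ploidy <= 0:
            raise ValueError(f"ploidy must be positive, got {self.ploidy}")


@dataclass
class MutationCall:
    """One somatic variant observed in one region, with read counts and
    copy-number context."""

    tumor_id: str
    region_id: str
    chrom: str
    pos: int                      # 1-based
    ref: str
    alt: str
    variant_class: str            # SNV | DNV | INDEL
    alt_reads: int
    depth: int
    cn_total: int                 # locus total copy number in the tumor (CNt)
    gene: str | None = None
    cn_normal: int = 2            # CNn, 2 for autosomes
    germline_alt_reads: int = 0
    germline_depth: int = 0
    strand_fwd: bool = True
    strand_rev: bool = True

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be ≥1, got {self.pos}")
        if self.alt_reads < 0 or self.depth < 0:
            raise ValueError("read counts must be non-negative")
        if self.alt_reads > self.depth:
            raise ValueError(
                f"alt_reads ({self.alt_reads}) exceeds depth ({self.depth}) "
                f"at {self.chrom}:{self.pos}"
            )

    @property
    def vaf(self) -> float:
        return self.alt_reads / self.depth if self.depth > 0 else 0.0

    @property
    def variant_key(self) -> tuple[str, str, int, str, str]:
        """Identity of the variant across regions of one tumor."""
        return (self.tumor_id, self.chrom, self.pos, self.ref, self.alt)

    @property
    def indel_span(self) -> int:
        """Number of bases the variant affects (0 for substitutions)."""
        return abs(len(self.ref) - len(self.alt))


@dataclass(frozen=True)
class CCFEstimate:
    """Grid maximum-likelihood cancer cell fraction for one call."""

    ccf: float                # on the grid {0.01, ..., 1.00}
    cn_mut: int               # mutated copies, 1..CNt
    region_clonality: str     # clonal | subclonal | absent


@dataclass
class SegmentCall:
    """Absolute copy-number segment in one region (0-based half-open)."""

    tumor_id: str
    region_id: str
    chrom: str
    start: int
    end: int
    cn_total: int
    cn_minor: int | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"segment start must precede end: {self.chrom}:{self.start}-{self.end}"
            )
        if self.cn_total < 0:
            raise ValueError("cn_total must be non-negative")
        if self.cn_minor is not None and self.cn_minor > self.cn_total:
            raise ValueError("cn_minor cannot exceed cn_total")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ArmDefinition:
    """One chromosome arm interval (0-based half-open)."""

    chrom: str
    arm: str      # "p" or "q"
    start: int
    end: int

    @property
    def label(self) -> str:
        return f"{self.chrom}{self.arm}"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class DriverEvent:
    """A tumor-level driver: a mutation in the driver-gene list or an
    arm-level driver SCNA, with its presence pattern across regions."""

    event_id: str
    event_type: str                # mutation | scna_loss | scna_gain
    label: str                     # gene symbol or arm symbol e.g. "loss_9p"
    regions_present: frozenset[str]
    tumor_clonality: str           # clonal | subclonal
    gene: str | None = None
    variant_class: str | None = None   # for mutations: SNV | DNV | INDEL

    def __post_init__(self) -> None:
        if not self.regions_present:
            raise ValueError(f"event {self.event_id} present in no region")

    @property
    def is_mutation(self) -> bool:
        return self.event_type == "mutation"

    @property
    def is_scna(self) -> bool:
        return self.event_type in ("scna_loss", "scna_gain")


# ---------------------------------------------------------------------------
# Clone trees


@dataclass
class Clone:
    """One node of a clone tree: a cluster of events sharing a
    region-presence pattern."""

    clone_id: str
    events: list[str] = field(default_factory=list)
    regions: frozenset[str] = field(default_factory=frozenset)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Clone):
            return NotImplemented
        return (
            self.clone_id == other.clone_id
            and sorted(self.events) == sorted(other.events)
            and self.regions == other.regions
        )


@dataclass
class CloneTree:
    """Rooted tree of clones; the root is the MRCA clone carrying the
    ubiquitous events."""

    tumor_id: str
    clones: dict[str, Clone]
    parent: dict[str, str | None]   # clone_id -> parent clone_id (root -> None)

    def __post_init__(self) -> None:
        roots = [c for c, p in self.parent.items() if p is None]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {len(roots)}")
        if set(self.parent) != set(self.clones):
            raise ValueError("parent map and clone set disagree")
        # acyclicity: every node must reach the root
        root = roots[0]
        for node in self.clones:
            seen = set()
            cur: str | None = node
            while cur is not None:
                if cur in seen:
                    raise ValueError(f"cycle detected at clone {cur}")
                seen.add(cur)
                cur = self.parent[cur]
            if root not in seen:
                raise ValueError(f"clone {node} does not reach the root")

    @property
    def root(self) -> str:
        return next(c for c, p in self.parent.items() if p is None)

    def children(self, clone_id: str) -> list[str]:
        return sorted(c for c, p in self.parent.items() if p == clone_id)

    def leaves(self) -> list[str]:
        parents = {p for p in self.parent.values() if p is not None}
        return sorted(c for c in self.clones if c not in parents)

    def ancestors(self, clone_id: str) -> list[str]:
        """Strict ancestors, nearest first."""
        out = []
        cur = self.parent[clone_id]
        while cur is not None:
            out.append(cur)
            cur = self.parent[cur]
        return out

    def is_ancestor(self, a: str, b: str) -> bool:
        """True iff a is a strict ancestor of b."""
        return a in self.ancestors(b)

    def root_to_leaf_paths(self) -> list[list[str]]:
        paths = []
        for leaf in self.leaves():
            path = [leaf] + self.ancestors(leaf)
            paths.append(list(reversed(path)))
        return paths

    def n_clones(self) -> int:
        return len(self.clones)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CloneTree):
            return NotImplemented
        return (
            self.tumor_id == other.tumor_id
            and self.parent == other.parent
            and self.clones == other.clones
        )

    def validate_nesting(self) -> None:
        """Check child regions ⊆ parent regions throughout."""
        for c, p in self.parent.items():
            if p is None:
                continue
            if not self.clones[c].regions <= self.clones[p].regions:
                raise ValueError(
                    f"clone {c} regions not nested within parent {p}"
                )


@dataclass
class SNPBAFRecord:
    """B-allele frequency of one heterozygous SNP in one sample.

    ``sample_id`` is a tumor region id or the germline sample id.
    """

    tumor_id: str
    sample_id: str
    chrom: str
    pos: int
    baf: float
    depth: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.baf <= 1.0):
            raise ValueError(f"baf must be in [0,1], got {self.baf}")
        if self.depth <= 0:
            raise ValueError("depth must be positive")


@dataclass
class HeterogeneityReport:
    """Per-tumor heterogeneity and instability summary."""

    tumor_id: str
    n_clonal_drivers: int
    n_subclonal_drivers: int
    ith_index: float            # NaN when n_clonal_drivers == 0 (undefined)
    wgii_per_region: dict[str, float]
    wgii_max: float

    @property
    def ith_defined(self) -> bool:
        return not math.isnan(self.ith_index)


# ---------------------------------------------------------------------------
# Arm tables


def synthetic_arm_table(
    n_chromosomes: int = 22, arm_length: int = 50_000_000
) -> list[ArmDefinition]:
    """Miniature synthetic genome: ``n_chromosomes`` autosomes, each with
    a p and a q arm of ``arm_length`` bp.  Used by the cohort simulator so
    no external reference genome is needed."""
    arms = []
    for i in range(1, n_chromosomes + 1):
        chrom = str(i)
        arms.append(ArmDefinition(chrom, "p", 0, arm_length))
        arms.append(ArmDefinition(chrom, "q", arm_length, 2 * arm_length))
    return arms


# hg19 autosome lengths and centromere midpoints (Mb-rounded, GRCh37).
_HG19 = {
    "1": (249_250_621, 125_000_000),
    "2": (243_199_373, 93_300_000),
    "3": (198_022_430, 91_000_000),
    "4": (191_154_276, 50_400_000),
    "5": (180_915_260, 48_400_000),
    "6": (171_115_067, 61_000_000),
    "7": (159_138_663, 59_900_000),
    "8": (146_364_022, 45_600_000),
    "9": (141_213_431, 49_000_000),
    "10": (135_534_747, 40_200_000),
    "11": (135_006_516, 53_700_000),
    "12": (133_851_895, 35_800_000),
    "13": (115_169_878, 17_900_000),
    "14": (107_349_540, 17_600_000),
    "15": (102_531_392, 19_000_000),
    "16": (90_354_753, 36_600_000),
    "17": (81_195_210, 24_000_000),
    "18": (78_077_248, 17_200_000),
    "19": (59_128_983, 26_500_000),
    "20": (63_025_520, 27_500_000),
    "21": (48_129_895, 13_200_000),
    "22": (51_304_566, 14_700_000),
}


def hg19_arm_table() -> list[ArmDefinition]:
    """Built-in hg19-style autosome arm table (22 autosomes, p/q split at
    the centromere midpoint)."""
    arms = []
    for chrom, (length, cen) in _HG19.items():
        arms.append(ArmDefinition(chrom, "p", 0, cen))
        arms.append(ArmDefinition(chrom, "q", cen, length))
    return arms


AUTOSOMES: frozenset[str] = frozenset(str(i) for i in range(1, 23))


def is_autosome(chrom: str) -> bool:
    return chrom.removeprefix("chr") in AUTOSOMES
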