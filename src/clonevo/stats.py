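"""Cohort-level evolutionary statistics: parallel evolution, clone-level
co-occurrence, and event-ordering tests.

Parallel evolution
    A gene shows parallel evolution when distinct subclonal mutations
    hit it independently within one tumor.  For each qualifying gene
    (≥10 subclonal mutations cohort-wide) the observed number of
    parallel events, Σ_cases max(0, k_case − 1), is compared with a null
    in which each case's mutation count is Binomial(n_regions, p_gene),
    with p_gene the cohort-wide per-biopsy mutation frequency.  This
    Bernoulli-trials null accounts for densely sampled cases having more
    chances of co-arising mutations.  Significance is empirical over
    permutations with the (b+1)/(B+1) correction; Benjamini–Hochberg
    across genes.

Co-occurrence
    Pairwise event co-occurrence across clones is scored against the
    probabilistic (hypergeometric) model: with N clones, event A in N_A
    and B in N_B, the co-occurrence count J is hypergeometric, giving
    exact enrichment and depletion tails.  Enrichment is reported as
    log2(observed/expected).  A pair counts as significant overall only
    when significant in the same direction in both the MRCA-only and
    MRCA-plus-terminal-subclone analyses.

Event ordering
    Root-to-leaf trajectories through each clone tree yield ordered
    core-event pairs (deduplicated per case); pairs observed in ≥10
    cases are tested against a symmetric Binomial(n, 0.5) null,
    two-sided via the doubled smaller tail.
"""

from __future__ import annotations

import itertools
from collections import Counter, defaultdict

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model import (
    CORE_MUTATION_GENES,
    DEFAULT_THRESHOLDS,
    DRIVER_SCNAS,
    PI3K_PATHWAY_GENES,
    CloneTree,
    Thresholds,
)

__all__ = [
    "benjamini_hochberg",
    "simulate_parallel_null",
    "parallel_evolution_test",
    "cooccurrence_test",
    "combine_cooccurrence_modes",
    "enumerate_trajectories",
    "ordering_test",
    "core_event_label",
]


def benjamini_hochberg(pvals) -> np.ndarray:
    """BH-adjusted q-values."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    return sps.false_discovery_control(p, method="bh")


# ---------------------------------------------------------------------------
# Parallel evolution


def _parallel_statistic(statistic: str):
    def stat(k: np.ndarray, axis=None):
        if statistic == "parallel_events":
            return np.maximum(0, k - 1).sum(axis=axis)
        return (k >= 2).sum(axis=axis)

    return stat


def simulate_parallel_null(
    n_regions: np.ndarray,
    p_gene: float,
    n_perm: int,
    rng: np.random.Generator,
    statistic: str = "parallel_events",
) -> np.ndarray:
    """Null replicates of the parallelism statistic: per case,
    k ~ Binomial(n_regions, p_gene); the statistic is summed over cases."""
    n_regions = np.asarray(n_regions, dtype=int)
    sims = rng.binomial(n_regions[None, :].repeat(n_perm, axis=0), p_gene)
    return _parallel_statistic(statistic)(sims, axis=1)


def parallel_evolution_test(
    counts: pd.DataFrame,
    n_regions: pd.Series,
    rng: np.random.Generator,
    n_perm: int = 1000,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    statistic: str = "parallel_events",
) -> pd.DataFrame:
    """Permutation test for parallel evolution per gene.

    Parameters
    ----------
    counts
        cases × genes frame; entry = number of *distinct* subclonal
        mutations of that gene in that case.
    n_regions
        biopsies sequenced per case (index aligned with ``counts``).

    ``statistic`` selects the parallelism summary: ``parallel_events``
    (default), the total count of co-arising mutations Σ max(0, k − 1);
    or ``parallel_cases``, the number of cases with k ≥ 2.

    Returns one row per qualifying gene with the observed parallel-event
    count, the cohort-wide per-biopsy mutation frequency used for the
    null, the empirical p and the BH q.  Genes with fewer than 10
    subclonal mutations cohort-wide are excluded (listed in the frame's
    ``attrs['skipped_genes']``).
    """
    if statistic not in ("parallel_events", "parallel_cases"):
        raise ValueError(f"unknown statistic {statistic!r}")
    stat = _parallel_statistic(statistic)
    counts = counts.sort_index()
    n_regions = n_regions.loc[counts.index].to_numpy()
    total_biopsies = int(n_regions.sum())
    rows = []
    skipped = []
    for gene in sorted(counts.columns):
        k = counts[gene].to_numpy()
        total = int(k.sum())
        if total < thresholds.min_subclonal_mutations:
            skipped.append(gene)
            continue
        p_gene = total / total_biopsies
        observed = int(stat(k))
        null_stats = simulate_parallel_null(
            n_regions, min(p_gene, 1.0), n_perm, rng, statistic
        )
        p_emp = (int((null_stats >= observed).sum()) + 1) / (n_perm + 1)
        rows.append(
            {
                "gene": gene,
                "n_subclonal_mutations": total,
                "per_biopsy_frequency": p_gene,
                "observed_parallel": observed,
                "null_mean": float(null_stats.mean()),
                "p": p_emp,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "gene", "n_subclonal_mutations", "per_biopsy_frequency",
            "observed_parallel", "null_mean", "p",
        ],
    )
    if len(df):
        df["q"] = benjamini_hochberg(df["p"])
    else:
        df["q"] = []
    df.attrs["skipped_genes"] = skipped
    return df


def subclonal_mutation_counts(
    clonality_table: pd.DataFrame, genes: list[str]
) -> pd.DataFrame:
    """Cases × genes counts of distinct subclonal mutations, from a
    tumor-clonality table (columns tumor_id, gene, tumor_clonality)."""
    sub = clonality_table[
        (clonality_table["tumor_clonality"] == "subclonal")
        & (clonality_table["gene"].isin(genes))
    ]
    counts = (
        sub.groupby(["tumor_id", "gene"]).size().unstack(fill_value=0)
    )
    return counts.reindex(columns=genes, fill_value=0)


# ---------------------------------------------------------------------------
# Co-occurrence


def hypergeom_tails(n: int, n_a: int, n_b: int, j: int) -> tuple[float, float]:
    """Exact co-occurrence tails under the hypergeometric model:
    P(J ≥ j) and P(J ≤ j) for J = |A ∩ B| with |A| = n_a, |B| = n_b
    among n clones."""
    rv = sps.hypergeom(n, n_a, n_b)
    return float(rv.sf(j - 1)), float(rv.cdf(j))


def cooccurrence_test(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise hypergeometric co-occurrence over a clones × events
    binary matrix.

    For each unordered event pair: observed co-occurrence count j,
    expected N_A·N_B/N, enrichment log2(obs/exp), exact tails
    p_gt = P(J ≥ j) and p_lt = P(J ≤ j); BH correction within each tail
    across pairs.  Pairs with a zero marginal are skipped; expected = 0
    yields NA enrichment.
    """
    N = len(matrix)
    events = list(matrix.columns)
    rows = []
    for a, b in itertools.combinations(events, 2):
        n_a = int(matrix[a].sum())
        n_b = int(matrix[b].sum())
        if n_a == 0 or n_b == 0:
            continue
        j = int((matrix[a].astype(bool) & matrix[b].astype(bool)).sum())
        expected = n_a * n_b / N
        p_gt, p_lt = hypergeom_tails(N, n_a, n_b, j)
        if expected == 0:
            enrichment = float("nan")
        elif j == 0:
            enrichment = float("-inf")
        else:
            enrichment = float(np.log2(j / expected))
        rows.append(
            {
                "event_a": a, "event_b": b, "n": N, "n_a": n_a, "n_b": n_b,
                "observed": j, "expected": expected, "enrichment": enrichment,
                "p_gt": p_gt, "p_lt": p_lt,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "event_a", "event_b", "n", "n_a", "n_b", "observed",
            "expected", "enrichment", "p_gt", "p_lt",
        ],
    )
    if len(df):
        df["q_gt"] = benjamini_hochberg(df["p_gt"])
        df["q_lt"] = benjamini_hochberg(df["p_lt"])
    else:
        df["q_gt"] = []
        df["q_lt"] = []
    return df


def combine_cooccurrence_modes(
    mrca_only: pd.DataFrame,
    mrca_plus_terminal: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Merge the two analysis modes; a pair is significant overall only
    when significant with the same direction in both."""
    key = ["event_a", "event_b"]
    merged = mrca_only.merge(
        mrca_plus_terminal, on=key, suffixes=("_mrca", "_all")
    )

    def direction(row, suffix):
        if row[f"q_gt{suffix}"] < alpha:
            return "cooccurrence"
        if row[f"q_lt{suffix}"] < alpha:
            return "exclusivity"
        return "none"

    dirs_m = merged.apply(lambda r: direction(r, "_mrca"), axis=1)
    dirs_a = merged.apply(lambda r: direction(r, "_all"), axis=1)
    merged["direction"] = [
        m if (m == a and m != "none") else "none" for m, a in zip(dirs_m, dirs_a)
    ]
    merged["significant"] = merged["direction"] != "none"
    return merged


def clone_event_matrix(
    trees: dict[str, CloneTree],
    event_labels: dict[str, dict[str, str]],
    tested_events: tuple[str, ...],
    mode: str = "mrca_only",
) -> pd.DataFrame:
    """Rows = clones (MRCA per case, optionally plus terminal subclones),
    columns = tested events, cells binary.

    ``event_labels`` maps tumor_id -> {event_id: tested-event label}.
    """
    rows = {}
    for tumor_id, tree in sorted(trees.items()):
        labels = event_labels.get(tumor_id, {})
        clone_ids = [tree.root]
        if mode == "mrca_plus_terminal":
            clone_ids += [c for c in tree.leaves() if c != tree.root]
        for cid in clone_ids:
            present = {
                labels[e] for e in tree.clones[cid].events if e in labels
            }
            rows[f"{tumor_id}:{cid}"] = [int(ev in present) for ev in tested_events]
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(tested_events))


# ---------------------------------------------------------------------------
# Trajectories and event ordering


def core_event_label(kind: str, gene: str | None, label: str) -> str | None:
    """Map an event to its core-trajectory label, or None if non-core.

    Mutational core events are VHL, PBRM1, BAP1, SETD2 and the PI3K
    pathway (collapsed to one 'PI3K' label); SCNA core events are the
    driver SCNAs.
    """
    if kind == "mutation":
        if gene in PI3K_PATHWAY_GENES:
            return "PI3K"
        if gene in CORE_MUTATION_GENES:
            return gene
        return None
    if label in DRIVER_SCNAS:
        return label
    return None


def _is_scna_label(label: str) -> bool:
    return label.startswith(("loss_", "gain_"))


def enumerate_trajectories(
    trees: dict[str, CloneTree],
    event_core_labels: dict[str, dict[str, str]],
) -> tuple[dict[str, set[tuple[str, str]]], Counter]:
    """Collect ordered core-event pairs from root-to-leaf trajectories.

    ``event_core_labels`` maps tumor_id -> {event_id: core label}; events
    absent from the map are ignored.  An ordered pair (A, B) means A lies
    in a strict ancestor clone of B on some trajectory.  Pairs are
    deduplicated per case; events in the same clone produce no pair;
    PI3K↔SCNA pairs are excluded (nonspecific many-to-many relation).

    Returns (per-case pair sets, cohort pair counts).
    """
    per_case: dict[str, set[tuple[str, str]]] = {}
    for tumor_id, tree in sorted(trees.items()):
        labels = event_core_labels.get(tumor_id, {})
        pairs: set[tuple[str, str]] = set()
        for path in tree.root_to_leaf_paths():
            clone_labels = [
                sorted(
                    {labels[e] for e in tree.clones[cid].events if e in labels}
                )
                for cid in path
            ]
            for i, j in itertools.combinations(range(len(path)), 2):
                for a in clone_labels[i]:
                    for b in clone_labels[j]:
                        if a == b:
                            continue
                        if {"PI3K"} & {a, b} and (
                            _is_scna_label(a) or _is_scna_label(b)
                        ):
                            continue
                        pairs.add((a, b))
        per_case[tumor_id] = pairs
    counts: Counter = Counter()
    for pairs in per_case.values():
        counts.update(pairs)
    return per_case, counts


def ordering_test(
    pair_counts: Counter,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Exact binomial directionality test on ordered event pairs.

    For each unordered pair with a + b ≥ 10 cases (a = cases with A
    before B, b = the reverse), p is the two-sided binomial probability
    at null 0.5 (doubled smaller tail, capped at 1), BH-corrected across
    tested pairs.
    """
    unordered: dict[frozenset, dict] = {}
    for (a, b), n in pair_counts.items():
        key = frozenset((a, b))
        rec = unordered.setdefault(key, {})
        rec[(a, b)] = n
    rows = []
    for key, rec in unordered.items():
        (pair1, n1) = max(rec.items(), key=lambda kv: (kv[1], kv[0]))
        n2 = sum(v for k, v in rec.items() if k != pair1)
        n = n1 + n2
        if n < thresholds.min_ordering_cases:
            continue
        p = min(1.0, 2.0 * float(sps.binom.cdf(min(n1, n2), n, 0.5)))
        rows.append(
            {
                "event_first": pair1[0], "event_second": pair1[1],
                "n_forward": n1, "n_reverse": n2, "p": p,
            }
        )
    df = pd.DataFrame(
        rows, columns=["event_first", "event_second", "n_forward", "n_reverse", "p"]
    ).sort_values(["event_first", "event_second"]).reset_index(drop=True)
    if len(df):
        df["q"] = benjamini_hochberg(df["p"])
    else:
        df["q"] = []
    return df
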