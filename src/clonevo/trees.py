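"""Driver clone-tree reconstruction from event presence/absence patterns.

With dense multi-region sampling, the region-presence pattern of each
event cluster constrains its position in the clonal hierarchy by a
pigeonhole argument: a clone's mutations can only be observed in regions
the clone (or its descendants) occupies, so a descendant's presence
pattern is a subset of its ancestor's.  The reconstruction therefore:

1. builds a binary events × regions matrix (mutations present at
   CCF > 0.1; SCNAs called in the region),
2. clusters events with identical patterns into candidate clones
   (a valid cluster needs ≥1 non-synonymous mutation or ≥2 arm SCNAs),
3. orders clusters by strict subset containment of their patterns, with
   the ubiquitous cluster as the root/MRCA.

Crossing patterns (neither nested nor disjoint) cannot arise under a
perfect phylogeny; when noise produces them, the smaller cluster is
attached to the candidate parent with maximal region overlap and the
conflict is flagged with its Jaccard overlap so it can be audited.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .model import Clone, CloneTree

__all__ = [
    "build_event_matrix",
    "cluster_events",
    "order_clones",
    "terminal_subclones",
    "same_topology",
    "EventCluster",
]


def build_event_matrix(
    events: list[tuple[str, str, frozenset[str]]],
    regions: list[str],
) -> pd.DataFrame:
    """Binary events × regions presence matrix.

    ``events`` is a list of (event_id, kind, regions_present) where kind
    is ``mutation_nonsyn``, ``mutation_syn`` or ``scna``.  Columns are
    restricted to the supplied (QC-passing) regions; rows that end up
    all-zero are dropped.
    """
    rows = {}
    for event_id, _kind, present in events:
        rows[event_id] = [r in present for r in regions]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=regions).astype(int)
    return df[df.sum(axis=1) > 0]


@dataclass
class EventCluster:
    pattern: frozenset[str]
    events: list[str] = field(default_factory=list)
    kinds: list[str] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        """A valid cluster has ≥1 non-synonymous mutation or ≥2 arm SCNAs."""
        n_nonsyn = sum(1 for k in self.kinds if k == "mutation_nonsyn")
        n_scna = sum(1 for k in self.kinds if k == "scna")
        return n_nonsyn >= 1 or n_scna >= 2


def cluster_events(
    matrix: pd.DataFrame, kinds: dict[str, str] | None = None
) -> list[EventCluster]:
    """Group events with identical region-presence patterns.

    ``kinds`` maps event_id -> kind (defaults to mutation_nonsyn).
    Clusters are returned sorted by decreasing pattern size then pattern.
    """
    kinds = kinds or {}
    by_pattern: dict[frozenset[str], EventCluster] = {}
    for event_id, row in matrix.iterrows():
        pattern = frozenset(matrix.columns[row.astype(bool)])
        cluster = by_pattern.setdefault(pattern, EventCluster(pattern=pattern))
        cluster.events.append(str(event_id))
        cluster.kinds.append(kinds.get(str(event_id), "mutation_nonsyn"))
    out = sorted(
        by_pattern.values(),
        key=lambda c: (-len(c.pattern), tuple(sorted(c.pattern))),
    )
    for c in out:
        order = sorted(range(len(c.events)), key=lambda i: c.events[i])
        c.events = [c.events[i] for i in order]
        c.kinds = [c.kinds[i] for i in order]
    return out


def _merge_invalid(clusters: list[EventCluster]) -> tuple[list[EventCluster], list[str]]:
    """Merge invalid clusters (lone arm SCNA) into their minimal strict
    superset cluster; clusters with no superset are excluded and flagged."""
    valid = [c for c in clusters if c.valid]
    flagged: list[str] = []
    for c in clusters:
        if c.valid:
            continue
        supersets = [v for v in valid if c.pattern < v.pattern]
        if supersets:
            target = min(
                supersets, key=lambda v: (len(v.pattern), tuple(sorted(v.pattern)))
            )
            target.events.extend(c.events)
            target.kinds.extend(c.kinds)
        else:
            flagged.extend(c.events)
    return valid, flagged


def order_clones(
    clusters: list[EventCluster],
    all_regions: list[str],
    tumor_id: str,
) -> tuple[CloneTree, list[dict]]:
    """Order clusters into a clone tree by subset containment.

    The ubiquitous cluster is the root; every other cluster attaches to
    its minimal strict superset.  Crossing patterns attach to the placed
    cluster with maximal region overlap and are reported as conflicts
    (with Jaccard overlap); their effective clone regions are clipped to
    the parent so the nesting invariant always holds.  Invalid clusters
    are first merged into their minimal strict superset or excluded.

    Returns (tree, conflicts); conflicts also records excluded events.
    """
    clusters, flagged = _merge_invalid(clusters)
    conflicts: list[dict] = [
        {"type": "excluded_invalid_cluster", "events": e} for e in flagged
    ]
    universe = frozenset(all_regions)
    if not clusters:
        # no events: monoclonal placeholder covering all regions
        root = Clone(clone_id="C1", events=[], regions=universe)
        return CloneTree(tumor_id=tumor_id, clones={"C1": root}, parent={"C1": None}), conflicts

    clusters = sorted(
        clusters, key=lambda c: (-len(c.pattern), tuple(sorted(c.pattern)))
    )
    if clusters[0].pattern != universe:
        # no ubiquitous cluster: synthesize an empty root
        clusters.insert(0, EventCluster(pattern=universe))
        conflicts.append({"type": "synthetic_root", "events": ""})

    clones: dict[str, Clone] = {}
    parent: dict[str, str | None] = {}
    placed: list[tuple[str, EventCluster]] = []
    for i, cluster in enumerate(clusters):
        cid = f"C{i + 1}"
        if i == 0:
            clones[cid] = Clone(cid, events=list(cluster.events), regions=cluster.pattern)
            parent[cid] = None
            placed.append((cid, cluster))
            continue
        supersets = [
            (pid, pc) for pid, pc in placed if cluster.pattern < clones[pid].regions
        ]
        if supersets:
            pid = min(
                supersets,
                key=lambda t: (len(clones[t[0]].regions), tuple(sorted(clones[t[0]].regions))),
            )[0]
            regions = cluster.pattern
            # crossing check: overlap with a sibling that neither
            # contains nor is disjoint from this pattern
            for sib in [c for c, p in parent.items() if p == pid]:
                sib_regions = clones[sib].regions
                inter = cluster.pattern & sib_regions
                if inter and not (
                    cluster.pattern <= sib_regions or sib_regions <= cluster.pattern
                ):
                    conflicts.append(
                        {
                            "type": "crossing_pattern",
                            "events": ",".join(cluster.events),
                            "crosses": ",".join(sorted(clones[sib].events)),
                            "attached_to": pid,
                            "jaccard": len(inter)
                            / len(cluster.pattern | sib_regions),
                        }
                    )
        else:
            # crossing pattern: attach by maximal overlap, clip regions
            pid = max(
                placed,
                key=lambda t: (
                    len(cluster.pattern & clones[t[0]].regions),
                    len(clones[t[0]].regions),
                    tuple(sorted(clones[t[0]].regions)),
                ),
            )[0]
            overlap = cluster.pattern & clones[pid].regions
            union = cluster.pattern | clones[pid].regions
            conflicts.append(
                {
                    "type": "crossing_pattern",
                    "events": ",".join(cluster.events),
                    "attached_to": pid,
                    "jaccard": len(overlap) / len(union) if union else 0.0,
                }
            )
            regions = overlap if overlap else clones[pid].regions
        clones[cid] = Clone(cid, events=list(cluster.events), regions=frozenset(regions))
        parent[cid] = pid
        placed.append((cid, cluster))
    tree = CloneTree(tumor_id=tumor_id, clones=clones, parent=parent)
    tree.validate_nesting()
    return tree, conflicts


def terminal_subclones(tree: CloneTree) -> list[str]:
    """Leaf clones; for a monoclonal tree the root is its own terminal."""
    return tree.leaves()


def same_topology(a: CloneTree, b: CloneTree) -> bool:
    """Compare two trees as hierarchies of region-presence patterns
    (invariant to clone labels and event order)."""

    def edges(t: CloneTree) -> tuple[frozenset, set[tuple[frozenset, frozenset]]]:
        root_pat = t.clones[t.root].regions
        edge_set = {
            (t.clones[p].regions, t.clones[c].regions)
            for c, p in t.parent.items()
            if p is not None
        }
        return root_pat, edge_set

    pats_a = sorted(map(sorted, (c.regions for c in a.clones.values())))
    pats_b = sorted(map(sorted, (c.regions for c in b.clones.values())))
    return pats_a == pats_b and edges(a) == edges(b)
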