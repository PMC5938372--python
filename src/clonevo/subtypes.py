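"""Rule-based evolutionary subtype classification.

Tumors are assigned to one of seven evolutionary subtypes by rules
applied hierarchically, first match wins:

i.    ≥2 clonal mutational events in BAP1/PBRM1/SETD2/PTEN
      → multiple_clonal_driver
ii.   a clone carrying a BAP1 mutation with no other core mutational
      driver besides VHL in that same clone → BAP1_driven
iii.  PBRM1 mutation followed by a SETD2 mutation → PBRM1_SETD2
iv.   PBRM1 mutation followed by a PI3K-pathway mutation → PBRM1_PI3K
v.    PBRM1 mutation followed by a driver SCNA → PBRM1_SCNA
vi.   no VHL mutation and no VHL promoter methylation → VHL_wildtype
vii.  VHL is the only core mutational driver → VHL_monodriver

"Followed by" means the second event lies in a strict descendant clone
of the first; co-occurrence within one clone does not satisfy it.  A
tumor matching no rule is reported as unassigned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .model import (
    CORE_MUTATION_GENES,
    DRIVER_SCNAS,
    PI3K_PATHWAY_GENES,
    CloneTree,
    DriverEvent,
)

__all__ = ["SUBTYPES", "SubtypeCall", "classify_tumor", "classify_cohort"]

SUBTYPES: tuple[str, ...] = (
    "multiple_clonal_driver",
    "BAP1_driven",
    "PBRM1_SETD2",
    "PBRM1_PI3K",
    "PBRM1_SCNA",
    "VHL_wildtype",
    "VHL_monodriver",
)

_RULE_OF_SUBTYPE = {s: i + 1 for i, s in enumerate(SUBTYPES)}
_RULE_I_GENES = frozenset({"BAP1", "PBRM1", "SETD2", "PTEN"})


@dataclass
class SubtypeCall:
    tumor_id: str
    subtype: str                       # one of SUBTYPES or "unassigned"
    matched_rule: int | None
    evidence: list[str] = field(default_factory=list)


def _clone_gene_sets(
    tree: CloneTree, events: dict[str, DriverEvent]
) -> dict[str, dict[str, set[str]]]:
    """Per clone: sets of mutated core genes, all mutated genes, and
    driver-SCNA labels."""
    out = {}
    for cid, clone in tree.clones.items():
        core, muts, scnas = set(), set(), set()
        for eid in clone.events:
            ev = events.get(eid)
            if ev is None:
                continue
            if ev.is_mutation and ev.gene:
                muts.add(ev.gene)
                if ev.gene in CORE_MUTATION_GENES:
                    core.add(ev.gene)
            elif ev.is_scna and ev.label in DRIVER_SCNAS:
                scnas.add(ev.label)
        out[cid] = {"core": core, "mutations": muts, "scnas": scnas}
    return out


def _followed_by(
    tree: CloneTree,
    per_clone: dict[str, dict[str, set[str]]],
    first_gene: str,
    second: str,
    kind: str,
) -> tuple[str, str] | None:
    """First clone with ``first_gene`` mutation having a strict
    descendant clone with the second event; ``kind`` selects gene,
    pathway ('pi3k') or SCNA ('scna') semantics for the second event."""
    for anc in sorted(tree.clones):
        if first_gene not in per_clone[anc]["mutations"]:
            continue
        for desc in sorted(tree.clones):
            if not tree.is_ancestor(anc, desc):
                continue
            info = per_clone[desc]
            hit = (
                (kind == "gene" and second in info["mutations"])
                or (kind == "pi3k" and info["mutations"] & PI3K_PATHWAY_GENES)
                or (kind == "scna" and info["scnas"])
            )
            if hit:
                return anc, desc
    return None


def classify_tumor(
    tree: CloneTree,
    events: dict[str, DriverEvent],
    vhl_status: str = "mutated",
) -> SubtypeCall:
    """Apply the seven rules in order to one tumor.

    ``events`` maps event_id -> DriverEvent for every event referenced
    by the tree; ``vhl_status`` ∈ {mutated, methylated, wildtype} carries
    the promoter-methylation assay result (rule vi); VHL mutation itself
    is read from the events.
    """
    per_clone = _clone_gene_sets(tree, events)
    vhl_mutated = any(
        e.is_mutation and e.gene == "VHL" for e in events.values()
    )

    # rule i: ≥2 clonal mutational events in the four early driver genes
    clonal_rule1 = [
        e
        for e in events.values()
        if e.is_mutation
        and e.gene in _RULE_I_GENES
        and e.tumor_clonality == "clonal"
    ]
    if len(clonal_rule1) >= 2:
        return SubtypeCall(
            tree.tumor_id, "multiple_clonal_driver", 1,
            [e.event_id for e in sorted(clonal_rule1, key=lambda e: e.event_id)],
        )

    # rule ii: a clone with BAP1 and no other core driver besides VHL
    for cid in sorted(tree.clones):
        core = per_clone[cid]["core"]
        if "BAP1" in core and core <= {"BAP1", "VHL"}:
            return SubtypeCall(tree.tumor_id, "BAP1_driven", 2, [cid])

    # rules iii-v: PBRM1 followed by SETD2 / PI3K / driver SCNA
    for subtype, second, kind in (
        ("PBRM1_SETD2", "SETD2", "gene"),
        ("PBRM1_PI3K", None, "pi3k"),
        ("PBRM1_SCNA", None, "scna"),
    ):
        hit = _followed_by(tree, per_clone, "PBRM1", second, kind)
        if hit:
            return SubtypeCall(
                tree.tumor_id, subtype, _RULE_OF_SUBTYPE[subtype], list(hit)
            )

    # rule vi: VHL wild-type (no mutation, no methylation)
    if not vhl_mutated and vhl_status != "methylated":
        return SubtypeCall(tree.tumor_id, "VHL_wildtype", 6, [])

    # rule vii: VHL the only core mutational driver
    all_core = set().union(*(pc["core"] for pc in per_clone.values()))
    if vhl_mutated and all_core == {"VHL"}:
        return SubtypeCall(tree.tumor_id, "VHL_monodriver", 7, [])

    return SubtypeCall(tree.tumor_id, "unassigned", None, [])


def classify_cohort(
    tumors: dict[str, tuple[CloneTree, dict[str, DriverEvent], str]],
    case_of_tumor: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Classify every case of a cohort.

    ``tumors`` maps tumor_id -> (tree, events, vhl_status).  For
    bilateral/multifocal cases ``case_of_tumor`` maps tumor ids to case
    ids; only the index tumor (first in sorted order) is classified per
    case.  Tumors with a missing tree are reported as
    unclassifiable_input, distinct from unassigned.
    """
    case_of_tumor = case_of_tumor or {t: t for t in tumors}
    index_tumor: dict[str, str] = {}
    for tumor_id in sorted(tumors):
        case = case_of_tumor.get(tumor_id, tumor_id)
        index_tumor.setdefault(case, tumor_id)
    rows = []
    for case, tumor_id in sorted(index_tumor.items()):
        tree, events, vhl_status = tumors[tumor_id]
        if tree is None:
            rows.append(
                {"case_id": case, "tumor_id": tumor_id,
                 "subtype": "unclassifiable_input", "matched_rule": None,
                 "evidence": ""}
            )
            continue
        call = classify_tumor(tree, events, vhl_status)
        rows.append(
            {"case_id": case, "tumor_id": tumor_id, "subtype": call.subtype,
             "matched_rule": call.matched_rule, "evidence": ",".join(call.evidence)}
        )
    return pd.DataFrame(
        rows, columns=["case_id", "tumor_id", "subtype", "matched_rule", "evidence"]
    )
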