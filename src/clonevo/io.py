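"""Readers and writers for the tabular input formats and tree serializations.

Formats
-------
mutation table : TSV, one row per (variant, region); VCF-like columns,
    1-based positions.
segment table  : SEG-like TSV, 0-based half-open coordinates.
SNP BAF table  : TSV, one row per (SNP, sample); samples are tumor
    regions or the germline sample.
cohort manifest: YAML mapping tumors to regions with purity/ploidy/QC.
clone trees    : JSON (canonical, lossless round-trip) and Newick
    (export; events carried in comments).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml

from .model import (
    Clone,
    CloneTree,
    MutationCall,
    Region,
    SegmentCall,
    SNPBAFRecord,
    is_autosome,
)

logger = logging.getLogger("clonevo")

MUTATION_COLUMNS = [
    "tumor_id", "region_id", "chrom", "pos", "ref", "alt", "variant_class",
    "alt_reads", "depth", "germline_alt_reads", "germline_depth",
    "cn_total", "strand_fwd", "strand_rev",
]
SEGMENT_COLUMNS = ["tumor_id", "region_id", "chrom", "start", "end", "cn_total"]
BAF_COLUMNS = ["tumor_id", "sample_id", "chrom", "pos", "baf", "depth"]


class TableFormatError(ValueError):
    """Malformed input table; message carries row-level context."""


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(f"{what}: missing required column(s) {missing}")


def _as_bool(series: pd.Series) -> pd.Series:
    if series.dtype == bool:
        return series
    return series.astype(str).str.lower().isin(["true", "1", "t", "yes"])


# ---------------------------------------------------------------------------
# Mutations


def read_mutation_table(path: str | Path) -> list[MutationCall]:
    """Read a mutation TSV into :class:`MutationCall` records.

    Raises :class:`TableFormatError` naming the offending column or the
    1-based data row for invariant violations (e.g. alt_reads > depth).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    _require_columns(df, MUTATION_COLUMNS, f"mutation table {path}")
    for col in ("alt_reads", "depth", "germline_alt_reads", "germline_depth", "cn_total"):
        if (df[col] < 0).any():
            row = int(df.index[df[col] < 0][0]) + 1
            raise TableFormatError(f"{path}: negative {col} at data row {row}")
    df["strand_fwd"] = _as_bool(df["strand_fwd"])
    df["strand_rev"] = _as_bool(df["strand_rev"])
    calls = []
    for i, rec in enumerate(df.to_dict("records"), start=1):
        try:
            calls.append(
                MutationCall(
                    tumor_id=str(rec["tumor_id"]),
                    region_id=str(rec["region_id"]),
                    chrom=str(rec["chrom"]),
                    pos=int(rec["pos"]),
                    ref=str(rec["ref"]),
                    alt=str(rec["alt"]),
                    variant_class=str(rec["variant_class"]),
                    alt_reads=int(rec["alt_reads"]),
                    depth=int(rec["depth"]),
                    cn_total=int(rec["cn_total"]),
                    gene=None if pd.isna(rec.get("gene")) else str(rec["gene"]),
                    germline_alt_reads=int(rec["germline_alt_reads"]),
                    germline_depth=int(rec["germline_depth"]),
                    strand_fwd=bool(rec["strand_fwd"]),
                    strand_rev=bool(rec["strand_rev"]),
                )
            )
        except ValueError as exc:
            raise TableFormatError(f"{path}: data row {i}: {exc}") from exc
    return calls


def mutation_calls_to_frame(calls: Iterable[MutationCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append(
            {
                "tumor_id": c.tumor_id, "region_id": c.region_id,
                "chrom": c.chrom, "pos": c.pos, "ref": c.ref, "alt": c.alt,
                "variant_class": c.variant_class, "gene": c.gene,
                "alt_reads": c.alt_reads, "depth": c.depth, "vaf": c.vaf,
                "germline_alt_reads": c.germline_alt_reads,
                "germline_depth": c.germline_depth,
                "cn_total": c.cn_total,
                "strand_fwd": c.strand_fwd, "strand_rev": c.strand_rev,
            }
        )
    return pd.DataFrame(rows)


def write_mutation_table(calls: Iterable[MutationCall], path: str | Path) -> None:
    mutation_calls_to_frame(calls).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Segments


def read_segments(path: str | Path) -> list[SegmentCall]:
    """Read a SEG-like TSV, returning segments sorted by (chrom, start).

    Overlapping segments within one region are an error; non-autosomal
    segments are accepted but logged (they are excluded from wGII and
    arm-driver calling downstream).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    _require_columns(df, SEGMENT_COLUMNS, f"segment table {path}")
    segs = []
    for i, rec in enumerate(df.to_dict("records"), start=1):
        cn_minor = rec.get("cn_minor")
        try:
            segs.append(
                SegmentCall(
                    tumor_id=str(rec["tumor_id"]),
                    region_id=str(rec["region_id"]),
                    chrom=str(rec["chrom"]),
                    start=int(rec["start"]),
                    end=int(rec["end"]),
                    cn_total=int(rec["cn_total"]),
                    cn_minor=None if cn_minor is None or pd.isna(cn_minor) else int(cn_minor),
                )
            )
        except ValueError as exc:
            raise TableFormatError(f"{path}: data row {i}: {exc}") from exc
    segs.sort(key=lambda s: (s.tumor_id, s.region_id, s.chrom, s.start))
    prev: SegmentCall | None = None
    for s in segs:
        if (
            prev is not None
            and (s.tumor_id, s.region_id, s.chrom) == (prev.tumor_id, prev.region_id, prev.chrom)
            and s.start < prev.end
        ):
            raise TableFormatError(
                f"{path}: overlapping segments in region {s.region_id} on "
                f"chrom {s.chrom}: [{prev.start},{prev.end}) and [{s.start},{s.end})"
            )
        prev = s
    n_nonauto = sum(1 for s in segs if not is_autosome(s.chrom))
    if n_nonauto:
        logger.warning("%s: %d non-autosomal segment(s) (excluded from wGII)", path, n_nonauto)
    return segs


def segments_to_frame(segs: Iterable[SegmentCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "tumor_id": s.tumor_id, "region_id": s.region_id, "chrom": s.chrom,
                "start": s.start, "end": s.end, "cn_total": s.cn_total,
                "cn_minor": s.cn_minor,
            }
            for s in segs
        ]
    )


def write_segments(segs: Iterable[SegmentCall], path: str | Path) -> None:
    segments_to_frame(segs).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# SNP BAF tables


def read_baf_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    _require_columns(df, BAF_COLUMNS, f"BAF table {path}")
    bad = df[(df["baf"] < 0) | (df["baf"] > 1)]
    if len(bad):
        raise TableFormatError(
            f"{path}: BAF outside [0,1] at data row {int(bad.index[0]) + 1}"
        )
    return df


def baf_records_to_frame(records: Iterable[SNPBAFRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "tumor_id": r.tumor_id, "sample_id": r.sample_id, "chrom": r.chrom,
                "pos": r.pos, "baf": r.baf, "depth": r.depth,
            }
            for r in records
        ]
    )


# ---------------------------------------------------------------------------
# Cohort manifest


def read_manifest(path: str | Path) -> dict:
    """Read a cohort manifest YAML.

    Returns ``{tumor_id: {"vhl_status": str, "case_id": str,
    "regions": [Region, ...]}}``.  Region QC (purity failure) is an
    explicit ``qc_pass`` flag; regions with mean depth below the QC
    threshold are flagged by the caller.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not raw or "tumors" not in raw:
        raise TableFormatError(f"manifest {path}: missing top-level 'tumors' mapping")
    out: dict = {}
    for tumor_id, entry in raw["tumors"].items():
        regions = [
            Region(
                region_id=str(r["region_id"]),
                tumor_id=str(tumor_id),
                purity=float(r["purity"]),
                ploidy=float(r["ploidy"]),
                mean_depth=float(r["mean_depth"]),
                qc_pass=bool(r.get("qc_pass", True)),
            )
            for r in entry["regions"]
        ]
        out[str(tumor_id)] = {
            "vhl_status": str(entry.get("vhl_status", "mutated")),
            "case_id": str(entry.get("case_id", tumor_id)),
            "germline_id": str(entry.get("germline_id", f"{tumor_id}_N")),
            "regions": regions,
        }
    return out


def write_manifest(manifest: dict, path: str | Path) -> None:
    raw = {"tumors": {}}
    for tumor_id, entry in manifest.items():
        raw["tumors"][tumor_id] = {
            "vhl_status": entry["vhl_status"],
            "case_id": entry.get("case_id", tumor_id),
            "germline_id": entry.get("germline_id", f"{tumor_id}_N"),
            "regions": [
                {
                    "region_id": r.region_id, "purity": round(float(r.purity), 6),
                    "ploidy": float(r.ploidy), "mean_depth": float(r.mean_depth),
                    "qc_pass": bool(r.qc_pass),
                }
                for r in entry["regions"]
            ],
        }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=True)


def qc_passing_regions(manifest_entry: dict, min_depth: float = 100.0) -> list[Region]:
    """Regions surviving QC: explicit flag and mean depth ≥ threshold."""
    return [
        r
        for r in manifest_entry["regions"]
        if r.qc_pass and r.mean_depth >= min_depth
    ]


# ---------------------------------------------------------------------------
# Clone trees


def tree_to_dict(tree: CloneTree) -> dict:
    return {
        "tumor_id": tree.tumor_id,
        "root": tree.root,
        "clones": [
            {
                "clone_id": c.clone_id,
                "events": sorted(c.events),
                "regions": sorted(c.regions),
            }
            for c in sorted(tree.clones.values(), key=lambda c: c.clone_id)
        ],
        "edges": sorted(
            [p, c] for c, p in tree.parent.items() if p is not None
        ),
    }


def tree_from_dict(d: dict) -> CloneTree:
    clones = {
        c["clone_id"]: Clone(
            clone_id=c["clone_id"],
            events=sorted(c["events"]),
            regions=frozenset(c["regions"]),
        )
        for c in d["clones"]
    }
    parent: dict[str, str | None] = {cid: None for cid in clones}
    for p, c in d["edges"]:
        parent[c] = p
    return CloneTree(tumor_id=d["tumor_id"], clones=clones, parent=parent)


def write_tree(tree: CloneTree, path: str | Path, format: str = "json") -> None:
    """Serialize a clone tree.

    JSON is canonical and round-trips losslessly; Newick encodes the
    topology with clone ids as labels and the event list in a comment.
    """
    if format == "json":
        with open(path, "w") as fh:
            json.dump(tree_to_dict(tree), fh, indent=2, sort_keys=True)
            fh.write("\n")
    elif format == "newick":
        with open(path, "w") as fh:
            fh.write(tree_to_newick(tree) + "\n")
    else:
        raise ValueError(f"unknown tree format {format!r}")


def read_tree(path: str | Path) -> CloneTree:
    with open(path) as fh:
        return tree_from_dict(json.load(fh))


def tree_to_newick(tree: CloneTree) -> str:
    def render(node: str) -> str:
        kids = tree.children(node)
        events = "|".join(sorted(tree.clones[node].events))
        comment = f"[&events={events}]" if events else ""
        if kids:
            inner = ",".join(render(k) for k in kids)
            return f"({inner}){node}{comment}"
        return f"{node}{comment}"

    return render(tree.root) + ";"
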