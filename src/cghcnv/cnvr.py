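"""CNV regions: cross-sample aggregation, catalogue summaries, comparisons.

A CNVR is the transitive union of per-sample CNV calls that overlap by at
least 1 bp on the same chromosome.  Its frequency is the percentage of test
samples contributing at least one member call; its type is loss, gain, or
"both" when members of both directions fall in the region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .core import Cnvr, GenomeSpec, chrom_sort_key, normalize_chrom

__all__ = ["merge_cnvrs", "summarize_catalog", "call_count_summary",
           "type_composition", "compare_catalogs", "multi_catalog_union",
           "CatalogComparison", "SIZE_BINS_KB"]

#: size histogram bin edges in kb: <10, 10-20, 20-50, 50-100, 100-500, >=500
SIZE_BINS_KB = (10, 20, 50, 100, 500)


def merge_cnvrs(calls: Sequence, n_test_samples: int,
                exclude_chroms: Sequence[str] = ("Y",)) -> List[Cnvr]:
    """Aggregate all samples' calls into CNVRs by transitive >=1 bp overlap.

    ``exclude_chroms`` drops chromosomes that should not enter the catalogue
    (chrY by default: on a mixed-sex panel its dosage reflects sex, not CNV).
    Output is sorted by genome order and numbered CNVR_1, CNVR_2, ...
    Merging is order-independent: shuffling the calls yields an identical
    catalogue.
    """
    if n_test_samples < 1:
        raise ValueError("n_test_samples must be >= 1")
    excluded = {normalize_chrom(c) for c in exclude_chroms}
    by_chrom: Dict[str, list] = {}
    for c in calls:
        chrom = normalize_chrom(c.chrom)
        if chrom in excluded:
            continue
        by_chrom.setdefault(chrom, []).append(c)

    cnvrs: List[Cnvr] = []
    for chrom in sorted(by_chrom, key=chrom_sort_key):
        members = sorted(by_chrom[chrom], key=lambda c: (c.start, c.end))
        cluster: list = []
        cur_end = None
        for call in members + [None]:
            if call is not None and cluster and call.start < cur_end:
                cluster.append(call)
                cur_end = max(cur_end, call.end)
                continue
            if cluster:
                cnvrs.append(_build_cnvr(chrom, cluster, n_test_samples))
            if call is not None:
                cluster = [call]
                cur_end = call.end
    for i, r in enumerate(cnvrs, start=1):
        r.id = f"CNVR_{i}"
    return cnvrs


def _build_cnvr(chrom: str, members: list, n_test_samples: int) -> Cnvr:
    directions = {m.direction for m in members}
    cnvr_type = "both" if directions == {"gain", "loss"} else directions.pop()
    samples = frozenset(m.sample_id for m in members)
    return Cnvr(
        id="", chrom=chrom,
        start=min(m.start for m in members),
        end=max(m.end for m in members),
        member_calls=list(members),
        samples=samples,
        frequency=100.0 * len(samples) / n_test_samples,
        cnvr_type=cnvr_type,
    )


def call_count_summary(counts: Sequence[int]) -> dict:
    """Total and mean CNV calls per individual (2-decimal mean, as reported
    in per-sample summary tables)."""
    counts = list(counts)
    if not counts:
        raise ValueError("no per-sample counts")
    total = int(sum(counts))
    return {"n_samples": len(counts), "total_cnvs": total,
            "mean_cnvs_per_sample": round(total / len(counts), 2)}


def type_composition(type_counts: Dict[str, int]) -> dict:
    """Percentages of loss/gain/both CNVRs and the loss:gain fold ratio."""
    total = sum(type_counts.values())
    if total == 0:
        raise ValueError("empty catalogue")
    out = {f"{t}_percent": round(100.0 * n / total, 2)
           for t, n in type_counts.items()}
    out["n_cnvrs"] = total
    gains = type_counts.get("gain", 0)
    if gains:
        out["loss_gain_ratio"] = round(type_counts.get("loss", 0) / gains, 2)
    return out


def summarize_catalog(cnvrs: Sequence[Cnvr], genome: GenomeSpec) -> dict:
    """Catalogue-level summary: counts, lengths, per-chromosome coverage,
    size histogram, type composition, frequency spectrum.

    Lengths are reported in kb (mean/median to 2 decimals); per-chromosome
    coverage as percent of the chromosome's length.
    """
    lengths_bp = genome.lengths
    for r in cnvrs:
        if r.chrom not in lengths_bp:
            raise ValueError(f"{r.id}: chromosome {r.chrom} not in genome")
        if r.end > lengths_bp[r.chrom]:
            raise ValueError(f"{r.id}: extends past the end of {r.chrom}")
    n = len(cnvrs)
    sizes_kb = np.array([r.length for r in cnvrs], dtype=float) / 1e3
    total_kb = float(sizes_kb.sum())

    per_chrom = {}
    for chrom in genome.names:
        sub = [r for r in cnvrs if r.chrom == chrom]
        length = sum(r.length for r in sub)
        per_chrom[chrom] = {
            "count": len(sub),
            "length_kb": round(length / 1e3, 2),
            "percent_of_chrom": round(100.0 * length / lengths_bp[chrom], 2),
        }

    edges = [0, *SIZE_BINS_KB, np.inf]
    hist, _ = np.histogram(sizes_kb, bins=edges) if n else (np.zeros(len(edges) - 1, int), None)
    labels = ["<10", "10-20", "20-50", "50-100", "100-500", ">=500"]

    type_counts = {"loss": 0, "gain": 0, "both": 0}
    for r in cnvrs:
        type_counts[r.cnvr_type] += 1

    freqs = np.array([r.frequency for r in cnvrs]) if n else np.array([])
    summary = {
        "n_cnvrs": n,
        "total_length_kb": round(total_kb, 2),
        "mean_length_kb": round(float(sizes_kb.mean()), 2) if n else 0.0,
        "median_length_kb": round(float(np.median(sizes_kb)), 2) if n else 0.0,
        "genome_percent": round(100.0 * total_kb * 1e3 / genome.total_length, 2),
        "per_chromosome": per_chrom,
        "size_histogram_kb": dict(zip(labels, (int(h) for h in hist))),
        "type_counts": type_counts,
        "type_percent": {t: round(100.0 * c / n, 2) if n else 0.0
                         for t, c in type_counts.items()},
        "singleton_percent": round(
            100.0 * sum(1 for r in cnvrs if len(r.samples) == 1) / n, 2) if n else 0.0,
        "freq_ge50_percent": round(
            100.0 * int((freqs >= 50.0).sum()) / n, 2) if n else 0.0,
    }
    return summary


@dataclass
class CatalogComparison:
    """Overlap of a query CNVR catalogue with one reference catalogue.

    ``overlap_length_kb`` is the summed *full* length of the query CNVRs
    that overlap at least one reference CNVR (not the intersected bases),
    and ``length_percent`` its share of the query catalogue's total length.
    """

    n_query: int
    n_overlapping: int
    count_percent: float
    overlap_length_kb: float
    length_percent: float
    overlapping_ids: frozenset = field(default_factory=frozenset)


def _intervals(regions) -> list:
    out = []
    for i, r in enumerate(regions):
        if hasattr(r, "chrom"):
            out.append((normalize_chrom(r.chrom), int(r.start), int(r.end),
                        getattr(r, "id", None) or i))
        else:
            chrom, start, end, *rest = r
            out.append((normalize_chrom(chrom), int(start), int(end),
                        rest[0] if rest else i))
    return out


def compare_catalogs(query, reference) -> CatalogComparison:
    """Count/length overlap of query CNVRs with a reference catalogue
    (>=1 bp overlap counts a query CNVR as shared)."""
    q = _intervals(query)
    if not q:
        raise ValueError("empty query catalogue")
    ref_by_chrom: Dict[str, list] = {}
    for chrom, s, e, _ in _intervals(reference):
        ref_by_chrom.setdefault(chrom, []).append((s, e))
    for chrom in ref_by_chrom:
        ref_by_chrom[chrom].sort()

    hit_ids = set()
    hit_len = 0
    total_len = 0
    for chrom, s, e, qid in q:
        total_len += e - s
        for rs, re_ in ref_by_chrom.get(chrom, []):
            if rs >= e:
                break
            if re_ > s:  # >=1 bp overlap
                hit_ids.add(qid)
                hit_len += e - s
                break
    return CatalogComparison(
        n_query=len(q),
        n_overlapping=len(hit_ids),
        count_percent=round(100.0 * len(hit_ids) / len(q), 2),
        overlap_length_kb=round(hit_len / 1e3, 2),
        length_percent=round(100.0 * hit_len / total_len, 2) if total_len else 0.0,
        overlapping_ids=frozenset(hit_ids),
    )


def multi_catalog_union(comparisons: Sequence[CatalogComparison]) -> int:
    """Number of query CNVRs overlapping >=1 reference across all
    comparisons: the union of the per-reference hit sets, not their sum."""
    if not comparisons:
        raise ValueError("need at least one comparison")
    union: Set = set()
    for c in comparisons:
        union |= set(c.overlapping_ids)
    return len(union)
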