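"""Gene content of CNVRs and selective-constraint comparison.

Overlaps CNVRs with a gene annotation (>=1 bp, half-open convention), tallies
biotypes, flags conserved single-copy genes hit by CNVRs, and compares dN/dS
between CNVR genes and copy-neutral genes with a Wilcoxon rank-sum test
(exact enumeration at small n, tie-corrected normal approximation otherwise).
Elevated dN/dS among CNVR genes indicates relaxed purifying selection, the
expected signature of dosage-redundant regions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import norm, rankdata

from .core import Cnvr, GeneRecord, normalize_chrom

logger = logging.getLogger(__name__)

__all__ = ["GeneOverlapRecord", "annotate_cnvrs", "biotype_counts",
           "rank_sum_test", "flag_conserved_single_copy"]


@dataclass
class GeneOverlapRecord:
    """One gene's overlap with the CNVR catalogue."""

    gene_id: str
    cnvr_ids: List[str]
    overlap_bp: int
    containment: str  # "complete" when the gene lies inside a single CNVR


def annotate_cnvrs(cnvrs: Sequence[Cnvr], genes: Sequence[GeneRecord]
                   ) -> List[GeneOverlapRecord]:
    """Genes completely or partially overlapped by CNVRs.

    A gene is reported iff it shares >= 1 bp with at least one CNVR
    (half-open intervals: abutting regions share nothing).  Containment is
    "complete" when one CNVR covers the whole gene.
    """
    by_chrom: Dict[str, list] = {}
    for r in cnvrs:
        by_chrom.setdefault(normalize_chrom(r.chrom), []).append(r)
    for lst in by_chrom.values():
        lst.sort(key=lambda r: r.start)

    out = []
    for g in genes:
        hits = []
        total = 0
        complete = False
        for r in by_chrom.get(normalize_chrom(g.chrom), []):
            if r.start >= g.end:
                break
            ov = min(g.end, r.end) - max(g.start, r.start)
            if ov > 0:
                hits.append(r.id)
                total += ov
                if r.start <= g.start and g.end <= r.end:
                    complete = True
        if hits:
            out.append(GeneOverlapRecord(g.gene_id, hits, total,
                                         "complete" if complete else "partial"))
    return out


def biotype_counts(records: Sequence[GeneOverlapRecord],
                   genes: Sequence[GeneRecord]) -> Dict[str, int]:
    """Tally biotypes of the CNVR-overlapping genes."""
    types = {g.gene_id: g.biotype for g in genes}
    counts: Dict[str, int] = {b: 0 for b in GeneRecord.BIOTYPES}
    for rec in records:
        counts[types[rec.gene_id]] += 1
    return counts


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Mann-Whitney U of group b (midranks; larger when b tends larger)."""
    combined = np.concatenate([a, b])
    ranks = rankdata(combined)
    r_b = ranks[len(a):].sum()
    return float(r_b - len(b) * (len(b) + 1) / 2.0)


def rank_sum_test(group_a: Sequence[float], group_b: Sequence[float],
                  alternative: str = "two_sided",
                  exact_max_n: int = 8) -> Tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney) test; "greater" tests b > a.

    Exact enumeration of all C(n_a+n_b, n_a) labelings when both groups have
    <= ``exact_max_n`` observations; otherwise midranks with tie-corrected
    variance and a continuity-corrected normal approximation.  Returns
    (U of group b, p value).  If every value is identical, p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if alternative not in ("two_sided", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    u_obs = _u_statistic(a, b)
    n_a, n_b = a.size, b.size
    n = n_a + n_b
    combined = np.concatenate([a, b])
    if np.ptp(combined) == 0:
        return u_obs, 1.0

    if n_a <= exact_max_n and n_b <= exact_max_n:
        # permutation null: every assignment of labels to the observed values
        idx = range(n)
        mean_u = n_a * n_b / 2.0
        ge = two = total = 0
        for b_pos in combinations(idx, n_b):
            b_set = set(b_pos)
            aa = combined[[i for i in idx if i not in b_set]]
            bb = combined[list(b_pos)]
            u = _u_statistic(aa, bb)
            total += 1
            if u >= u_obs - 1e-12:
                ge += 1
            if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12:
                two += 1
        p = ge / total if alternative == "greater" else two / total
        return u_obs, min(1.0, p)

    mean_u = n_a * n_b / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts)).sum())
    var_u = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_u <= 0:
        return u_obs, 1.0
    sd = math.sqrt(var_u)
    if alternative == "greater":
        z = (u_obs - mean_u - 0.5) / sd
        p = float(norm.sf(z))
    else:
        z = (abs(u_obs - mean_u) - 0.5) / sd
        p = float(2.0 * norm.sf(max(z, 0.0)))
    return u_obs, min(1.0, p)


def flag_conserved_single_copy(genes: Sequence[GeneRecord],
                               orthology_table: Mapping[str, Sequence],
                               cnvr_overlaps: Optional[Sequence[GeneOverlapRecord]] = None
                               ) -> List[GeneRecord]:
    """Conserved single-copy genes: high orthology confidence and strictly
    >80% identity in every listed species.

    ``orthology_table`` maps gene_id to (confidence, identity) pairs, one
    per species (a single pair is accepted).  Genes missing from the table
    are treated as non-conserved (logged).  When ``cnvr_overlaps`` is given,
    the result is intersected with the CNVR-overlapping genes.
    """
    if not orthology_table:
        logger.warning("empty orthology table: no conserved single-copy genes")
        return []
    keep = []
    overlapping = ({r.gene_id for r in cnvr_overlaps}
                   if cnvr_overlaps is not None else None)
    for g in genes:
        entry = orthology_table.get(g.gene_id)
        if entry is None:
            logger.info("gene %s absent from orthology table; treated as "
                        "non-conserved", g.gene_id)
            continue
        pairs = [entry] if entry and not isinstance(entry[0], (tuple, list)) else list(entry)
        if all(conf == "high" and identity > 80 for conf, identity in pairs):
            if overlapping is None or g.gene_id in overlapping:
                keep.append(g)
    return keep
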