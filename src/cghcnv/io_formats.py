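"""Readers and writers for every file the pipeline touches.

Dialects:

* ratio tables — tab-delimited, ``#`` comments, columns ``probe_id chrom
  start end intensity_test intensity_ref snr_test snr_ref log2_ratio``;
  an empty log2_ratio marks a flagged probe.
* BED — 0-based half-open on disk; an optional companion table carries
  1-based inclusive coordinates matching the convention of printed CNV
  tables.
* gene annotation — 4/5-column BED or a GFF-like tab format with
  ``gene_id=...;gene_biotype=...`` attributes.
* Ct tables — CSV with ``sample,target_id,well,Ct`` (``Undetermined``
  parsed as missing).
"""

from __future__ import annotations

import csv
import logging
import math
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .core import (CtTable, GeneRecord, ProbeMap, RatioTrack, chrom_sort_key,
                   normalize_chrom)

logger = logging.getLogger(__name__)

__all__ = [
    "RATIO_COLUMNS",
    "read_ratio_table",
    "write_ratio_table",
    "write_bed",
    "read_bed",
    "write_truth_bed",
    "read_gene_annotation",
    "read_ct_table",
    "write_ct_table",
]

RATIO_COLUMNS = ["probe_id", "chrom", "start", "end", "intensity_test",
                 "intensity_ref", "snr_test", "snr_ref", "log2_ratio"]

_BIOTYPE_MAP = {
    "protein_coding": "protein_coding",
    "pseudogene": "pseudo",
    "pseudo": "pseudo",
    "miscrna": "miscRNA",
    "misc_rna": "miscRNA",
}


def write_ratio_table(track: RatioTrack, path) -> None:
    """Write a track and its probe map as one tab-delimited ratio table."""
    pm = track.probe_map.probes
    df = pd.DataFrame({
        "probe_id": pm["probe_id"],
        "chrom": pm["chrom"],
        "start": pm["start"],
        "end": pm["end"],
        "intensity_test": track.data["intensity_test"],
        "intensity_ref": track.data["intensity_ref"],
        "snr_test": track.data["snr_test"],
        "snr_ref": track.data["snr_ref"],
        "log2_ratio": track.data["log2_ratio"],
    })
    with open(path, "w") as fh:
        fh.write(f"# ratio table, sample={track.sample_id}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="", float_format="%.6g")


def read_ratio_table(path, sample_id: Optional[str] = None) -> Tuple[ProbeMap, RatioTrack]:
    """Parse a tab-delimited ratio table into a probe map and a track.

    Probes come back sorted by (chrom, start); malformed rows raise with
    their line number.  An empty ``log2_ratio`` field is carried as NaN
    (flagged probe) and excluded from downstream statistics but kept in
    the row count.
    """
    path = Path(path)
    sample = sample_id or path.stem
    header_line = 0
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.startswith("#"):
                header_line = i
                break
            if "sample=" in line and sample_id is None:
                sample = line.split("sample=", 1)[1].strip()
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"probe_id": str, "chrom": str})
    missing = [c for c in RATIO_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    bad = df.index[~(df["start"] < df["end"])]
    if len(bad):
        lineno = int(bad[0]) + header_line + 1
        raise ValueError(f"{path}: line {lineno}: start >= end")

    df["chrom"] = df["chrom"].map(normalize_chrom)
    order = df.sort_values(["chrom", "start"],
                           key=lambda s: s.map(chrom_sort_key) if s.name == "chrom" else s,
                           kind="stable")
    if not order.index.equals(df.index):
        logger.info("%s: input unsorted; sorted by (chrom, start)", path)
        df = order
    df = df.reset_index(drop=True)

    pmap = ProbeMap(df[["probe_id", "chrom", "start", "end"]])
    data = pd.DataFrame({
        "log2_ratio": pd.to_numeric(df["log2_ratio"], errors="coerce"),
        "intensity_test": df["intensity_test"].astype(float),
        "intensity_ref": df["intensity_ref"].astype(float),
        "snr_test": df["snr_test"].astype(float),
        "snr_ref": df["snr_ref"].astype(float),
        "qc_pass": np.ones(len(df), dtype=bool),
    })
    return pmap, RatioTrack(sample_id=sample, probe_map=pmap, data=data)


def _as_interval(region) -> tuple:
    """Normalise a region-like object to (chrom, start, end, extra...)."""
    if hasattr(region, "chrom"):
        extras = []
        for attr in ("id", "cnvr_type", "frequency", "sample_id", "mean_log2",
                     "score", "n_probes", "copy_state"):
            if hasattr(region, attr):
                extras.append(getattr(region, attr))
        return (region.chrom, int(region.start), int(region.end), *extras)
    chrom, start, end, *extra = region
    return (chrom, int(start), int(end), *extra)


def write_bed(regions: Iterable, path, one_based_report: bool = False,
              header: str = "regions") -> None:
    """Write intervals as BED (0-based half-open).

    With ``one_based_report`` a companion ``<path>.1based.tsv`` is written
    whose start is +1 (1-based inclusive), the convention of printed CNV
    coordinate tables.
    """
    rows = [_as_interval(r) for r in regions]
    for r in rows:
        if r[1] < 0 or r[2] < 0:
            raise ValueError(f"negative coordinate in {r[:3]}")
    rows.sort(key=lambda r: (chrom_sort_key(r[0]), r[1]))
    with open(path, "w") as fh:
        fh.write(f"# {header}\n")
        for chrom, start, end, *extra in rows:
            name = "chr" + normalize_chrom(chrom)
            fields = [name, str(start), str(end)] + [str(x) for x in extra]
            fh.write("\t".join(fields) + "\n")
    if one_based_report:
        with open(str(path) + ".1based.tsv", "w") as fh:
            fh.write(f"# {header} (1-based inclusive)\n")
            for chrom, start, end, *extra in rows:
                fields = [normalize_chrom(chrom), str(start + 1), str(end)] + [str(x) for x in extra]
                fh.write("\t".join(fields) + "\n")


def read_bed(path) -> List[tuple]:
    """Read BED back as (chrom, start, end, extra...) tuples, 0-based half-open."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno}: fewer than 3 BED columns")
            chrom = normalize_chrom(parts[0])
            start, end = int(parts[1]), int(parts[2])
            if start < 0 or start >= end:
                raise ValueError(f"{path}: line {lineno}: bad interval {start}-{end}")
            out.append((chrom, start, end, *parts[3:]))
    return out


def write_truth_bed(truth: Sequence, path) -> None:
    """Truth segments as BED with copy_state in column 5."""
    rows = [(t.chrom, t.start, t.end, t.sample_id, t.copy_state) for t in truth]
    write_bed(rows, path, header="truth segments (name=sample, score=copy_state)")


def read_gene_annotation(path, format: str = "bed") -> List[GeneRecord]:
    """Read gene intervals from BED or a GFF-like file.

    BED columns: chrom start end gene_id [biotype].  GFF-like: 9 columns with
    1-based start and ``gene_id=...;gene_biotype=...`` attributes.  Unknown
    biotypes default to "other"; overlapping genes are allowed.
    """
    genes: List[GeneRecord] = []
    if format == "bed":
        for chrom, start, end, *extra in read_bed(path):
            gene_id = extra[0] if extra else f"gene_{len(genes)}"
            biotype = _BIOTYPE_MAP.get(str(extra[1]).lower(), None) if len(extra) > 1 else "other"
            if biotype is None:
                biotype = extra[1] if len(extra) > 1 and extra[1] in GeneRecord.BIOTYPES else "other"
            genes.append(GeneRecord(gene_id, chrom, start, end, biotype))
    elif format == "gff_like":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 9:
                    raise ValueError(f"{path}: line {lineno}: fewer than 9 GFF columns")
                chrom = normalize_chrom(parts[0])
                start1, end1 = int(parts[3]), int(parts[4])
                attrs = {}
                for item in parts[8].strip().strip(";").split(";"):
                    if "=" in item:
                        k, v = item.split("=", 1)
                        attrs[k.strip()] = v.strip()
                gene_id = attrs.get("gene_id", attrs.get("ID", f"gene_{len(genes)}"))
                biotype = _BIOTYPE_MAP.get(attrs.get("gene_biotype", "").lower(), "other")
                genes.append(GeneRecord(gene_id, chrom, start1 - 1, end1, biotype))
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    return genes


def write_ct_table(ct: CtTable, path) -> None:
    df = ct.records.copy()
    df = df.rename(columns={"sample_id": "sample", "ct": "Ct"})
    with open(path, "w") as fh:
        fh.write(f"# reference_sample={ct.reference_sample},control_target={ct.control_target}\n")
        df.to_csv(fh, index=False, float_format="%.6g")


def read_ct_table(path, reference_sample: Optional[str] = None,
                  control_target: Optional[str] = None) -> CtTable:
    """Read a CSV Ct table (columns sample, target_id, well, Ct).

    ``Undetermined``/empty Ct values are parsed as missing and the well is
    flagged; negative Ct values are rejected.  Every (sample, target) pair
    must have at least one well.
    """
    ref, ctrl = reference_sample, control_target
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        for item in first.lstrip("#").strip().split(","):
            if item.startswith("reference_sample=") and ref is None:
                ref = item.split("=", 1)[1]
            if item.startswith("control_target=") and ctrl is None:
                ctrl = item.split("=", 1)[1]
    df = pd.read_csv(path, comment="#", dtype={"sample": str, "target_id": str})
    df = df.rename(columns={"sample": "sample_id", "Ct": "ct"})
    for col in CtTable.REQUIRED:
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    ct_vals = pd.to_numeric(df["ct"], errors="coerce")
    n_missing = int(ct_vals.isna().sum())
    if n_missing:
        logger.warning("%s: %d well(s) with undetermined Ct flagged as missing", path, n_missing)
    if (ct_vals.dropna() < 0).any():
        raise ValueError(f"{path}: negative Ct value")
    df["ct"] = ct_vals
    counts = df.groupby(["sample_id", "target_id"]).size()
    if (counts < 1).any():
        raise ValueError(f"{path}: (sample, target) pair with no wells")
    return CtTable(records=df, reference_sample=ref or "REF",
                   control_target=ctrl or "GCG")
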