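"""Core data containers shared across the aCGH CNV pipeline.

Coordinates are 0-based half-open everywhere inside the package; conversion
to 1-based inclusive happens only when report tables are written.  Chromosome
names are normalised internally (leading ``chr``/``Chr.`` stripped) and the
``chr`` prefix is re-added on BED export.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "normalize_chrom",
    "chrom_sort_key",
    "GenomeSpec",
    "ProbeMap",
    "RatioTrack",
    "TruthSegment",
    "AberrationSegment",
    "CnvCall",
    "Cnvr",
    "CtTable",
    "GeneRecord",
]

_CHR_PREFIX = re.compile(r"^chr\.?", re.IGNORECASE)


def normalize_chrom(name: str) -> str:
    """Strip a leading ``chr``/``Chr.`` prefix from a chromosome name."""
    return _CHR_PREFIX.sub("", str(name).strip())


def chrom_sort_key(name: str):
    """Sort chromosomes numerically first, then X, Y, then anything else."""
    name = normalize_chrom(name)
    if name.isdigit():
        return (0, int(name), "")
    special = {"X": 0, "Y": 1}
    if name in special:
        return (1, special[name], "")
    return (2, 0, name)


@dataclass(frozen=True)
class GenomeSpec:
    """An ordered set of chromosomes with a diploid baseline copy number."""

    chromosomes: tuple  # of (name, length) pairs
    ploidy_baseline: int = 2

    def __post_init__(self):
        chroms = tuple((normalize_chrom(n), int(l)) for n, l in self.chromosomes)
        names = [n for n, _ in chroms]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        if any(l <= 0 for _, l in chroms):
            raise ValueError("chromosome lengths must be > 0")
        if self.ploidy_baseline < 1:
            raise ValueError("ploidy_baseline must be >= 1")
        object.__setattr__(self, "chromosomes", chroms)

    @property
    def names(self) -> list:
        return [n for n, _ in self.chromosomes]

    @property
    def lengths(self) -> dict:
        return dict(self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)


class ProbeMap:
    """Ordered genomic probe coordinates, shared by every sample of a design.

    Wraps a DataFrame with columns ``probe_id, chrom, start, end`` sorted by
    (chrom, start) in genome order.
    """

    REQUIRED = ("probe_id", "chrom", "start", "end")

    def __init__(self, probes: pd.DataFrame, genome: Optional[GenomeSpec] = None):
        missing = [c for c in self.REQUIRED if c not in probes.columns]
        if missing:
            raise ValueError(f"probe table missing columns: {missing}")
        df = probes.copy()
        df["chrom"] = df["chrom"].map(normalize_chrom)
        order = sorted(range(len(df)), key=lambda i: (chrom_sort_key(df["chrom"].iat[i]), df["start"].iat[i]))
        if order != list(range(len(df))):
            df = df.iloc[order]
        self.probes = df.reset_index(drop=True)
        self.genome = genome

    def __len__(self) -> int:
        return len(self.probes)

    @property
    def chroms(self) -> list:
        seen = []
        for c in self.probes["chrom"]:
            if not seen or seen[-1] != c:
                seen.append(c)
        return seen

    def chrom_slice(self, chrom: str) -> slice:
        """Index range (positional, half-open) of one chromosome's probes."""
        chrom = normalize_chrom(chrom)
        mask = (self.probes["chrom"] == chrom).to_numpy()
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            return slice(0, 0)
        return slice(int(idx[0]), int(idx[-1]) + 1)

    @property
    def starts(self) -> np.ndarray:
        return self.probes["start"].to_numpy()

    @property
    def ends(self) -> np.ndarray:
        return self.probes["end"].to_numpy()


@dataclass
class RatioTrack:
    """One sample's per-probe intensities and log2 ratios on a ProbeMap.

    ``log2_ratio`` may contain NaN for flagged probes; ``qc_pass`` marks
    probes that survived the intensity/SNR filter (all True before QC).
    """

    sample_id: str
    probe_map: ProbeMap
    data: pd.DataFrame  # log2_ratio, intensity_test, intensity_ref, snr_test, snr_ref, qc_pass
    noise_sigma: Optional[float] = None
    centering_shift: float = 0.0

    COLUMNS = ("log2_ratio", "intensity_test", "intensity_ref", "snr_test", "snr_ref", "qc_pass")

    def __post_init__(self):
        if len(self.data) != len(self.probe_map):
            raise ValueError("track length does not match probe map")
        for c in self.COLUMNS:
            if c not in self.data.columns:
                raise ValueError(f"track missing column {c!r}")
        if self.noise_sigma is not None and self.noise_sigma <= 0:
            raise ValueError("noise_sigma must be > 0 once estimated")

    def copy(self) -> "RatioTrack":
        return RatioTrack(self.sample_id, self.probe_map, self.data.copy(),
                          self.noise_sigma, self.centering_shift)

    @property
    def log2(self) -> np.ndarray:
        return self.data["log2_ratio"].to_numpy()

    @property
    def passing(self) -> np.ndarray:
        """Boolean mask: QC pass and finite log2 ratio."""
        return (self.data["qc_pass"].to_numpy(dtype=bool)
                & np.isfinite(self.data["log2_ratio"].to_numpy()))


@dataclass(frozen=True)
class TruthSegment:
    """A planted copy-number segment with its expected log2 shift."""

    sample_id: str
    chrom: str
    start: int
    end: int
    copy_state: int
    expected_log2: float

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad segment coordinates {self.start}..{self.end}")
        if self.copy_state < 0:
            raise ValueError("copy_state must be >= 0")


@dataclass(frozen=True)
class AberrationSegment:
    """A detected aberrant interval (pre-filter), indexed over passing probes."""

    sample_id: str
    chrom: str
    probe_start_index: int  # half-open over the chromosome's passing probes
    probe_end_index: int
    start: int              # genomic: first probe start
    end: int                # genomic: last probe end
    n_probes: int
    mean_log2: float
    score: float

    @property
    def direction(self) -> str:
        return "gain" if self.mean_log2 > 0 else "loss"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CnvCall(AberrationSegment):
    """An aberration that passed the post-analysis filter (>=5 probes, |mean|>0.5)."""

    passes_filter: bool = True


@dataclass
class Cnvr:
    """A cross-sample CNV region: union of transitively overlapping calls."""

    id: str
    chrom: str
    start: int
    end: int
    member_calls: list
    samples: frozenset
    frequency: float     # percent of test samples carrying >=1 member call
    cnvr_type: str       # loss | gain | both

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CtTable:
    """qPCR cycle-threshold records: (sample_id, target_id, well, ct) rows.

    ``control_target`` names the single-copy control amplicon (e.g. a GCG
    segment); ``reference_sample`` is the sample with baseline copy number
    at every target.
    """

    records: pd.DataFrame
    reference_sample: str
    control_target: str

    REQUIRED = ("sample_id", "target_id", "well", "ct")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.records.columns]
        if missing:
            raise ValueError(f"Ct table missing columns: {missing}")

    def mean_ct(self, sample_id: str, target_id: str) -> float:
        """Mean Ct over replicate wells (NaN wells excluded)."""
        df = self.records
        sel = df[(df["sample_id"] == sample_id) & (df["target_id"] == target_id)]
        if sel.empty:
            raise KeyError(f"no wells for sample {sample_id!r}, target {target_id!r}")
        vals = sel["ct"].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError(f"all wells undetermined for sample {sample_id!r}, target {target_id!r}")
        return float(vals.mean())

    @property
    def samples(self) -> list:
        return sorted(self.records["sample_id"].unique())


@dataclass(frozen=True)
class GeneRecord:
    """A gene interval with a coarse biotype tag."""

    gene_id: str
    chrom: str
    start: int
    end: int
    biotype: str = "other"

    BIOTYPES = ("protein_coding", "pseudo", "miscRNA", "other")

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene_id}: start >= end")
        if self.biotype not in self.BIOTYPES:
            raise ValueError(f"gene {self.gene_id}: unknown biotype {self.biotype!r}")
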