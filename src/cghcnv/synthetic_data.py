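"""Synthetic aCGH data with known ground truth.

Every input the pipeline consumes can be generated here: probe maps emulating
a ~1M-feature two-colour array design (mean probe spacing ~2.6 kb), truth CNV
tracks, noisy per-probe log2-ratio tracks, sex-mismatched hybridisations
(male test vs. female reference), and qPCR Ct tables consistent with integer
copy states.  All randomness flows from a single integer seed per call; there
is no global state, so identical seeds give byte-identical outputs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import CtTable, GenomeSpec, ProbeMap, RatioTrack, TruthSegment, normalize_chrom

__all__ = [
    "NoiseSpec",
    "QpcrTarget",
    "default_genome",
    "simulate_probe_map",
    "simulate_truth",
    "simulate_ratio_track",
    "simulate_sex_mismatch",
    "simulate_qpcr",
]

#: log2 shift assigned to a homozygous deletion (copy_state 0); real arrays
#: saturate rather than reaching -inf.
ZERO_COPY_LOG2_FLOOR = -4.0


@dataclass(frozen=True)
class NoiseSpec:
    """Per-probe noise model for a simulated hybridisation.

    probe_sd
        SD (log2 units) of iid Gaussian probe noise.
    wave_amplitude, wave_period
        Amplitude (log2) and period (bp) of a sinusoidal genomic wave,
        emulating the long-range autocorrelated artefact of real arrays.
    dye_bias_slope
        Linear intensity-dependent bias: log2 units added per unit of
        (mean log-intensity - its mean), the artefact LOWESS removes.
    qc_fail_fraction
        Fraction of probes whose intensities/SNR are drawn below the QC
        thresholds so the filter path is exercised.
    """

    probe_sd: float = 0.15
    wave_amplitude: float = 0.0
    wave_period: float = 10e6
    dye_bias_slope: float = 0.0
    qc_fail_fraction: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.probe_sd < 0:
            raise ValueError("probe_sd must be >= 0")
        if self.wave_amplitude < 0:
            raise ValueError("wave_amplitude must be >= 0")
        if not 0 <= self.qc_fail_fraction < 1:
            raise ValueError("qc_fail_fraction in [0, 1)")


@dataclass(frozen=True)
class QpcrTarget:
    """A qPCR amplicon inside (or outside) a putative CNV region."""

    target_id: str
    chrom: str
    start: int
    end: int


def default_genome(n_autosomes: int = 2, autosome_mb: float = 40.0,
                   with_x: bool = True, x_mb: float = 30.0,
                   with_y: bool = False, y_mb: float = 5.0) -> GenomeSpec:
    """A small desk-scale genome: a few autosomes plus optional sex chromosomes."""
    chroms = [(str(i + 1), int(autosome_mb * 1e6)) for i in range(n_autosomes)]
    if with_x:
        chroms.append(("X", int(x_mb * 1e6)))
    if with_y:
        chroms.append(("Y", int(y_mb * 1e6)))
    return GenomeSpec(tuple(chroms))


def expected_log2(copy_state: int, baseline: int = 2) -> float:
    """log2(copy_state / baseline), floored for the zero-copy state."""
    if copy_state == 0:
        return ZERO_COPY_LOG2_FLOOR
    return math.log2(copy_state / baseline)


def simulate_probe_map(genome: GenomeSpec, mean_spacing: float = 2632.0,
                       probe_length: int = 60, seed: int = 0) -> ProbeMap:
    """Place probes along each chromosome with exponential inter-probe gaps.

    Start-to-start spacing has the requested mean; probes are 60-mers by
    default.  Chromosomes shorter than the spacing may receive zero probes
    (warning, not an error).
    """
    if not mean_spacing > probe_length > 0:
        raise ValueError("require mean_spacing > probe_length > 0")
    rng = np.random.default_rng(seed)
    rows = []
    k = 0
    for chrom, length in genome.chromosomes:
        # draw enough gaps in one vectorised shot, then trim to the chromosome
        n_guess = max(8, int(2 * length / mean_spacing) + 8)
        gaps = rng.exponential(mean_spacing - probe_length, size=n_guess)
        starts = np.cumsum(gaps + probe_length) - probe_length
        while starts.size and starts[-1] + probe_length <= length:
            extra = rng.exponential(mean_spacing - probe_length, size=n_guess)
            starts = np.concatenate([starts, starts[-1] + np.cumsum(extra + probe_length)])
        starts = starts[starts + probe_length <= length]
        if starts.size == 0:
            warnings.warn(f"chromosome {chrom}: no probes fit at spacing {mean_spacing}")
            continue
        for s in starts.astype(np.int64):
            rows.append((f"P{k:07d}", chrom, int(s), int(s) + probe_length))
            k += 1
    df = pd.DataFrame(rows, columns=["probe_id", "chrom", "start", "end"])
    return ProbeMap(df, genome=genome)


def simulate_truth(genome: GenomeSpec, n_segments: int,
                   size_range: Tuple[int, int] = (7_000, 500_000),
                   state_weights: Optional[Mapping[int, float]] = None,
                   seed: int = 0, sample_id: str = "S1",
                   max_tries: int = 200) -> list:
    """Plant non-overlapping copy-number segments with known states.

    Sizes are drawn log-uniformly within ``size_range`` (CNVs span orders of
    magnitude; small ones dominate real catalogues).  ``state_weights`` maps
    copy states (!= baseline) to probabilities; the default favours losses
    roughly 2.6:1 over gains, the ratio typical of aCGH surveys.
    """
    if state_weights is None:
        state_weights = {1: 0.725, 3: 0.275}
    baseline = genome.ploidy_baseline
    states = sorted(state_weights)
    if baseline in states:
        raise ValueError("state_weights must not include the baseline state")
    w = np.array([state_weights[s] for s in states], dtype=float)
    if not math.isclose(w.sum(), 1.0, rel_tol=1e-6):
        raise ValueError("state_weights must sum to 1")
    rng = np.random.default_rng(seed)
    lengths = genome.lengths
    names = genome.names
    probs = np.array([lengths[c] for c in names], dtype=float)
    probs /= probs.sum()

    placed = {c: [] for c in names}  # list of (start, end) per chromosome
    segs = []
    lo, hi = size_range
    for _ in range(n_segments):
        state = int(rng.choice(states, p=w))
        for attempt in range(max_tries):
            chrom = str(rng.choice(names, p=probs))
            size = int(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            size = min(size, lengths[chrom])
            start = int(rng.integers(0, lengths[chrom] - size + 1))
            end = start + size
            if all(end <= s or start >= e for s, e in placed[chrom]):
                placed[chrom].append((start, end))
                segs.append(TruthSegment(sample_id, chrom, start, end, state,
                                         expected_log2(state, baseline)))
                break
        else:
            raise RuntimeError(
                f"could not place segment {len(segs) + 1}/{n_segments} on "
                f"chromosome {chrom} after {max_tries} tries")
    segs.sort(key=lambda s: (s.chrom, s.start))
    return segs


def _signal_vector(probe_map: ProbeMap, truth: Sequence[TruthSegment]) -> np.ndarray:
    """Expected log2 per probe: the covering truth segment's shift, else 0.

    A probe is covered when its midpoint falls inside the segment.
    """
    chroms = probe_map.probes["chrom"].to_numpy()
    mid = (probe_map.starts + probe_map.ends) // 2
    signal = np.zeros(len(probe_map))
    for seg in truth:
        chrom = normalize_chrom(seg.chrom)
        mask = (chroms == chrom) & (mid >= seg.start) & (mid < seg.end)
        signal[mask] = seg.expected_log2
    return signal


def _assemble_track(probe_map: ProbeMap, signal: np.ndarray, noise: NoiseSpec,
                    sample_id: str) -> RatioTrack:
    rng = np.random.default_rng(noise.seed)
    n = len(probe_map)
    pos = probe_map.starts.astype(float)

    log2 = signal.copy()
    if noise.probe_sd > 0:
        log2 = log2 + rng.normal(0.0, noise.probe_sd, size=n)
    if noise.wave_amplitude > 0:
        log2 = log2 + noise.wave_amplitude * np.sin(2 * np.pi * pos / noise.wave_period)

    # two-channel intensities consistent with the ratio; reference channel
    # lognormal around ~1000 fluorescence units
    log_ref = rng.normal(np.log(1000.0), 0.4, size=n)
    intensity_ref = np.exp(log_ref)
    if noise.dye_bias_slope != 0.0:
        a = 0.5 * (np.log2(intensity_ref * 2.0 ** log2) + np.log2(intensity_ref))
        log2 = log2 + noise.dye_bias_slope * (a - a.mean())
    intensity_test = intensity_ref * 2.0 ** log2
    snr = np.exp(rng.normal(np.log(100.0), 0.3, size=n))
    snr_test = snr
    snr_ref = np.exp(rng.normal(np.log(100.0), 0.3, size=n))

    data = pd.DataFrame({
        "log2_ratio": log2,
        "intensity_test": intensity_test,
        "intensity_ref": intensity_ref,
        "snr_test": snr_test,
        "snr_ref": snr_ref,
        "qc_pass": np.ones(n, dtype=bool),
    })
    if noise.qc_fail_fraction > 0 and n > 0:
        n_fail = int(round(noise.qc_fail_fraction * n))
        idx = rng.choice(n, size=n_fail, replace=False)
        half = n_fail // 2
        # half fail on intensity, half on SNR
        data.loc[idx[:half], "intensity_test"] = rng.uniform(5, 45, size=half)
        data.loc[idx[half:], "snr_ref"] = rng.uniform(2, 20, size=n_fail - half)
    return RatioTrack(sample_id=sample_id, probe_map=probe_map, data=data)


def simulate_ratio_track(probe_map: ProbeMap, truth: Sequence[TruthSegment],
                         noise: NoiseSpec, sample_id: Optional[str] = None) -> RatioTrack:
    """A noisy log2-ratio track: truth signal + Gaussian noise + wave + dye bias.

    With ``probe_sd == 0`` and no wave/bias, covered probes carry exactly the
    truth segment's expected log2 (the zero-noise limit used by exactness
    tests).  An empty truth list yields a pure-noise track.
    """
    if probe_map.genome is not None:
        lengths = probe_map.genome.lengths
        for seg in truth:
            if seg.chrom not in lengths or seg.end > lengths[seg.chrom]:
                raise ValueError(f"truth segment {seg.chrom}:{seg.start}-{seg.end} "
                                 "outside the probe map's genome")
    if sample_id is None:
        sample_id = truth[0].sample_id if truth else "sim"
    signal = _signal_vector(probe_map, truth)
    return _assemble_track(probe_map, signal, noise, sample_id)


def simulate_sex_mismatch(probe_map: ProbeMap, noise: NoiseSpec,
                          x_name: str = "X", y_name: str = "Y",
                          y_gain_log2: float = 1.0,
                          sample_id: str = "sex_mismatch") -> RatioTrack:
    """Male test vs. female reference hybridisation.

    chrX probes are centred at log2 = -1 (one copy vs. two), chrY probes (if
    the design has them) at a configurable gain level, autosomes at 0.  Such
    arrays act as a genome-wide truth set for false-positive estimation:
    every real chrX event is a loss and every chrY event a gain.
    """
    chroms = probe_map.probes["chrom"].to_numpy()
    x_name = normalize_chrom(x_name)
    if x_name not in set(chroms):
        raise ValueError(f"probe map has no chromosome {x_name!r}")
    signal = np.zeros(len(probe_map))
    signal[chroms == x_name] = -1.0
    signal[chroms == normalize_chrom(y_name)] = y_gain_log2
    return _assemble_track(probe_map, signal, noise, sample_id)


def simulate_qpcr(truth: Sequence[TruthSegment],
                  targets: Sequence[Tuple[QpcrTarget, str]],
                  efficiency: float = 2.0, ct_sd: float = 0.1,
                  seed: int = 0, n_replicates: int = 2,
                  baseline: int = 2,
                  reference_sample: str = "REF",
                  control_target: str = "GCG") -> CtTable:
    """Simulate qPCR cycle thresholds consistent with integer copy states.

    Ct = const - log_efficiency(copy_number) + noise, with replicate wells
    per (sample, target).  The control amplicon sits in a single-copy gene
    (two copies in every diploid sample), and the reference sample carries
    baseline copy number at every target, so for efficiency 2 the
    2^-ddCt estimate of a noiseless 4-copy sample is exactly 2.0.
    """
    if not 1.9 <= efficiency <= 2.1:
        raise ValueError("efficiency must be within [1.9, 2.1]")
    rng = np.random.default_rng(seed)
    log_eff = math.log(efficiency)

    # truth lookup: sample -> list of segments
    by_sample: dict = {}
    for seg in truth:
        by_sample.setdefault(seg.sample_id, []).append(seg)

    def copy_at(sample: str, t: QpcrTarget) -> int:
        if sample == reference_sample:
            return baseline
        mid = (t.start + t.end) // 2
        for seg in by_sample.get(sample, []):
            if seg.chrom == normalize_chrom(t.chrom) and seg.start <= mid < seg.end:
                return seg.copy_state
        return baseline  # region with no truth info is baseline copy

    # per-target baseline Ct constants (arbitrary but fixed within a run)
    consts: dict = {control_target: 22.0}
    rows = []
    pairs = list(targets)
    samples_per_target: dict = {}
    for t, sample in pairs:
        samples_per_target.setdefault(t, set()).add(sample)
    for t in samples_per_target:
        samples_per_target[t].add(reference_sample)
        if t.target_id not in consts:
            consts[t.target_id] = float(rng.uniform(24.0, 30.0))

    control_samples = sorted({s for ss in samples_per_target.values() for s in ss})
    for sample in control_samples:
        # control amplicon: single-copy gene, two copies in every sample
        base_ct = consts[control_target] - math.log(baseline) / log_eff
        for well in range(1, n_replicates + 1):
            ct = base_ct + (rng.normal(0.0, ct_sd) if ct_sd > 0 else 0.0)
            rows.append((sample, control_target, well, ct))
    for t, samples in samples_per_target.items():
        for sample in sorted(samples):
            cn = copy_at(sample, t)
            if cn == 0:
                # no template: amplification stalls far out
                base_ct = consts[t.target_id] + 12.0
            else:
                base_ct = consts[t.target_id] - math.log(cn) / log_eff
            for well in range(1, n_replicates + 1):
                ct = base_ct + (rng.normal(0.0, ct_sd) if ct_sd > 0 else 0.0)
                rows.append((sample, t.target_id, well, ct))

    df = pd.DataFrame(rows, columns=["sample_id", "target_id", "well", "ct"])
    return CtTable(records=df, reference_sample=reference_sample,
                   control_target=control_target)
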