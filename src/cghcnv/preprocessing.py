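"""Probe-level QC, LOWESS normalisation, noise estimation, centralisation.

Order of operations for one hybridisation: ``qc_filter`` (intensity > 50 and
SNR > 25 in both channels, strict), ``lowess_normalize`` (remove the
intensity-dependent dye bias), ``estimate_noise`` (derivative log-ratio
spread, a robust per-array sigma), then ``centralize`` (shift the dominant
copy-neutral mode of the log2 distribution to zero).  All four are
shift/trend removals: they never change probe count or order.
"""

from __future__ import annotations

import logging
import warnings
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter1d
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .core import RatioTrack

logger = logging.getLogger(__name__)

__all__ = ["qc_filter", "lowess_normalize", "estimate_noise", "centralize",
           "preprocess_track", "NOISE_FLOOR"]

#: lower bound on the noise estimate; keeps interval scores finite on
#: degenerate (constant) tracks
NOISE_FLOOR = 1e-3


def qc_filter(track: RatioTrack, min_intensity: float = 50.0,
              min_snr: float = 25.0) -> RatioTrack:
    """Flag probes failing the intensity/SNR criteria (strict inequalities).

    A probe passes iff both channels have intensity > ``min_intensity`` and
    SNR > ``min_snr`` and its log2 ratio is present.  Failing probes are
    excluded from every downstream statistic but retained in the arrays.
    Idempotent.  Raises if no probe passes (uninterpretable array).
    """
    out = track.copy()
    d = out.data
    passing = ((d["intensity_test"].to_numpy() > min_intensity)
               & (d["intensity_ref"].to_numpy() > min_intensity)
               & (d["snr_test"].to_numpy() > min_snr)
               & (d["snr_ref"].to_numpy() > min_snr)
               & np.isfinite(d["log2_ratio"].to_numpy()))
    if not passing.any():
        raise ValueError(f"sample {track.sample_id}: all probes fail QC")
    out.data["qc_pass"] = passing
    n_fail = int((~passing).sum())
    logger.info("sample %s: QC retained %d/%d probes (%d excluded)",
                track.sample_id, len(d) - n_fail, len(d), n_fail)
    return out


def lowess_normalize(track: RatioTrack, span: float = 0.3,
                     min_probes: int = 50) -> RatioTrack:
    """Remove the intensity-dependent trend from the log2 ratios.

    Fits a locally weighted regression of log2 ratio on mean log-intensity
    A = (log2 I_test + log2 I_ref)/2 over passing probes and subtracts the
    fitted trend, the standard two-colour dye-bias correction.
    """
    out = track.copy()
    mask = out.passing
    if int(mask.sum()) < min_probes:
        raise ValueError(f"sample {track.sample_id}: fewer than {min_probes} "
                         "passing probes; cannot normalize")
    d = out.data
    log2 = d["log2_ratio"].to_numpy(dtype=float)
    a = 0.5 * (np.log2(d["intensity_test"].to_numpy())
               + np.log2(d["intensity_ref"].to_numpy()))
    fitted = _sm_lowess(log2[mask], a[mask], frac=span, it=2,
                        return_sorted=False)
    new = log2.copy()
    new[mask] = log2[mask] - fitted
    out.data["log2_ratio"] = new
    return out


def estimate_noise(track: RatioTrack) -> float:
    """Derivative log-ratio spread: a robust, aberration-insensitive sigma.

    Successive probe-to-probe differences within each chromosome are pooled;
    for iid Gaussian probes with sd sigma the differences have sd
    sigma*sqrt(2) and median |diff| = 0.6745 * sigma * sqrt(2), so

        sigma_hat = median(|diff|) / (0.6745 * sqrt(2)).

    Aberration breakpoints contribute only a handful of large differences,
    which the median ignores.  The estimate is stored on the track; a
    constant track falls back to ``NOISE_FLOOR`` with a warning.
    """
    diffs = []
    mask = track.passing
    chroms = track.probe_map.probes["chrom"].to_numpy()
    log2 = track.log2
    for chrom in track.probe_map.chroms:
        sel = (chroms == chrom) & mask
        vals = log2[sel]
        if vals.size >= 2:
            diffs.append(np.diff(vals))
    if not diffs:
        raise ValueError(f"sample {track.sample_id}: not enough passing probes "
                         "to estimate noise")
    pooled = np.abs(np.concatenate(diffs))
    sigma = float(np.median(pooled)) / (0.6745 * np.sqrt(2.0))
    if sigma < NOISE_FLOOR:
        warnings.warn(f"sample {track.sample_id}: noise estimate {sigma:.2g} "
                      f"below floor; using {NOISE_FLOOR}")
        sigma = NOISE_FLOOR
    track.noise_sigma = sigma
    return sigma


def _mode_shift(values: np.ndarray, bin_width: float) -> tuple:
    """Mode of a sample via a smoothed histogram with parabolic refinement.

    Returns (shift, ambiguous): the location of the highest-density bin
    refined by fitting a parabola through it and its neighbours, and a flag
    raised when a second, well-separated peak rivals the chosen one.
    """
    lo, hi = values.min(), values.max()
    if hi - lo < bin_width:
        return float(values.mean()), False
    edges = np.arange(lo - bin_width, hi + 2 * bin_width, bin_width)
    counts, edges = np.histogram(values, bins=edges)
    # smooth at ~1/4 of the robust spread so probe noise does not pick the bin
    mad = np.median(np.abs(values - np.median(values)))
    sigma_bins = max(1.0, 0.35 * (mad / 0.6745) / bin_width)
    smooth = gaussian_filter1d(counts.astype(float), sigma_bins, mode="nearest")
    centers = 0.5 * (edges[:-1] + edges[1:])

    peak = int(np.argmax(smooth))
    # near-ties: prefer the shift of smaller magnitude
    near = np.flatnonzero(smooth >= smooth[peak] * (1 - 1e-9))
    if near.size > 1:
        peak = int(near[np.argmin(np.abs(centers[near]))])
        if np.ptp(centers[near]) > 5 * bin_width:
            warnings.warn("centralization: tied modes; choosing the smaller shift")
    # rival peak detection: another local maximum of comparable height far away
    ambiguous = False
    interior = smooth[1:-1]
    local_max = np.flatnonzero((interior >= smooth[:-2]) & (interior >= smooth[2:])) + 1
    for j in local_max:
        if abs(centers[j] - centers[peak]) > 0.3 and smooth[j] >= 0.5 * smooth[peak]:
            ambiguous = True
            break
    # parabolic refinement through the peak bin and neighbours
    shift = centers[peak]
    if 0 < peak < len(smooth) - 1:
        y0, y1, y2 = smooth[peak - 1], smooth[peak], smooth[peak + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            shift = centers[peak] + 0.5 * bin_width * (y0 - y2) / denom
    return float(shift), ambiguous


def centralize(track: RatioTrack, bin_width: float = 0.01, max_iter: int = 10,
               tol: float = 1e-3, mask: Optional[np.ndarray] = None) -> RatioTrack:
    """Shift the dominant (copy-neutral) mode of the log2 distribution to 0.

    The mode is the highest-density histogram bin (width ``bin_width`` log2
    units) of the passing probes, refined parabolically; iterates until the
    incremental shift drops below ``tol``.  ``mask`` can exclude probes in
    known/suspected aberrant intervals so they do not drag the baseline —
    segmentation-driven masking (intervals scoring beyond the detection
    threshold) is applied by the pipeline's second centralisation pass.

    The cumulative shift is recorded in ``centering_shift``.  If a rival mode
    of comparable density exists (e.g. an aberration covering most of the
    genome), a warning is emitted since the neutral state may not be the
    taller peak.
    """
    out = track.copy()
    sel = out.passing
    if mask is not None:
        sel = sel & ~np.asarray(mask, dtype=bool)
    values = out.data["log2_ratio"].to_numpy(dtype=float)[sel]
    if values.size == 0:
        raise ValueError(f"sample {track.sample_id}: no probes available for "
                         "centralization")
    total = 0.0
    for _ in range(max_iter):
        shift, ambiguous = _mode_shift(values - total, bin_width)
        if ambiguous:
            warnings.warn(f"sample {track.sample_id}: centralization mode is "
                          "ambiguous (rival density peak); baseline may not be "
                          "copy-neutral")
        total += shift
        if abs(shift) < tol:
            break
    out.data["log2_ratio"] = out.data["log2_ratio"] - total
    out.centering_shift = out.centering_shift + total
    return out


def preprocess_track(track: RatioTrack, min_intensity: float = 50.0,
                     min_snr: float = 25.0, span: float = 0.3,
                     bin_width: float = 0.01,
                     centralization_threshold: Optional[float] = 6.0,
                     sigma_g_frac: float = 0.2) -> RatioTrack:
    """Full preprocessing chain: QC -> LOWESS -> noise -> centralize.

    When ``centralization_threshold`` is set, a second centralisation pass
    masks intervals whose interval score exceeds it (in absolute value), so
    clear aberrations do not pull the baseline — the role of the
    "centralization threshold" in aberration-detection suites.
    """
    t = qc_filter(track, min_intensity=min_intensity, min_snr=min_snr)
    t = lowess_normalize(t, span=span)
    estimate_noise(t)
    t = centralize(t, bin_width=bin_width)
    if centralization_threshold is not None:
        from .segmentation import detect_aberrations
        # seeded mode is plenty for masking: only clear aberrations matter
        segs = detect_aberrations(t, threshold=centralization_threshold,
                                  sigma_g_frac=sigma_g_frac, mode="seeded")
        if segs:
            mask = np.zeros(len(t.probe_map), dtype=bool)
            chroms = t.probe_map.probes["chrom"].to_numpy()
            starts, ends = t.probe_map.starts, t.probe_map.ends
            for s in segs:
                mask |= (chroms == s.chrom) & (starts < s.end) & (ends > s.start)
            t = centralize(t, bin_width=bin_width, mask=mask)
    return t
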