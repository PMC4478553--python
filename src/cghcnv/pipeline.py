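"""End-to-end orchestration: simulate -> preprocess -> call -> merge ->
validate -> cluster -> report.

``run_pipeline`` is exactly the composition of the module operations — no
hidden computation — and is deterministic for a given config: the same seed
reproduces every output byte-for-byte.  Each run directory receives the
resolved config, per-sample call BEDs, the CNVR catalogue and summary, a
sex-mismatch validation report, a qPCR validation report, the dendrogram as
Newick, and one machine-readable ``summary.json`` with every headline
statistic.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional

import numpy as np
import yaml

from . import clustering, cnvr, io_formats, preprocessing, segmentation, validation
from .core import GenomeSpec
from .synthetic_data import (NoiseSpec, QpcrTarget, simulate_probe_map,
                             simulate_qpcr, simulate_ratio_track,
                             simulate_sex_mismatch, simulate_truth)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """All pipeline parameters; defaults are the survey's printed settings
    (detection threshold 6, post-filter 5 probes / 0.5 log ratio, QC
    intensity > 50 and SNR > 25)."""

    # simulated cohort
    n_samples: int = 12
    n_segments_per_sample: int = 8
    chromosomes: list = field(default_factory=lambda: [["1", 20_000_000],
                                                       ["X", 12_000_000]])
    mean_spacing: float = 2632.0
    probe_length: int = 60
    probe_sd: float = 0.15
    seed: int = 1

    # preprocessing
    min_intensity: float = 50.0
    min_snr: float = 25.0
    lowess_span: float = 0.3
    centralization_bin: float = 0.01
    centralization_threshold: float = 6.0

    # segmentation
    threshold: float = 6.0
    sigma_g_frac: float = 0.2
    min_probes: int = 5
    min_abs_log2: float = 0.5
    mode: str = "exact"

    # validation / clustering
    n_sex_mismatch_arrays: int = 2
    n_qpcr_targets: int = 8
    ct_sd: float = 0.1
    n_boot: int = 200
    cluster_metric: str = "jaccard"

    def validate(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.min_probes < 1:
            raise ValueError("min_probes must be >= 1")
        if not 0 < self.lowess_span <= 1:
            raise ValueError("lowess_span must be in (0, 1]")
        if self.probe_sd < 0 or self.ct_sd < 0:
            raise ValueError("noise SDs must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run the full pipeline into ``outdir``; returns the summary dict."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")

    rng = np.random.default_rng(config.seed)

    genome = GenomeSpec(tuple((c, l) for c, l in config.chromosomes))
    probe_map = simulate_probe_map(genome, config.mean_spacing,
                                   config.probe_length,
                                   seed=int(rng.integers(2 ** 31)))

    # --- simulate and call each test sample -------------------------------
    all_calls = []
    truth_all = []
    sample_ids = [f"S{i + 1:02d}" for i in range(config.n_samples)]
    for sid in sample_ids:
        truth = simulate_truth(genome, config.n_segments_per_sample,
                               seed=int(rng.integers(2 ** 31)), sample_id=sid)
        truth_all.extend(truth)
        noise = NoiseSpec(probe_sd=config.probe_sd,
                          seed=int(rng.integers(2 ** 31)))
        track = simulate_ratio_track(probe_map, truth, noise, sample_id=sid)
        track = preprocessing.preprocess_track(
            track, min_intensity=config.min_intensity, min_snr=config.min_snr,
            span=config.lowess_span, bin_width=config.centralization_bin,
            centralization_threshold=config.centralization_threshold,
            sigma_g_frac=config.sigma_g_frac)
        segs = segmentation.detect_aberrations(
            track, threshold=config.threshold,
            sigma_g_frac=config.sigma_g_frac, mode=config.mode)
        calls = segmentation.filter_calls(segs, config.min_probes,
                                          config.min_abs_log2)
        all_calls.extend(calls)
        io_formats.write_bed(calls, outdir / f"calls_{sid}.bed",
                             header=f"CNV calls {sid}")
    io_formats.write_truth_bed(truth_all, outdir / "truth.bed")

    # --- CNVR catalogue ---------------------------------------------------
    cnvrs = cnvr.merge_cnvrs(all_calls, n_test_samples=config.n_samples)
    io_formats.write_bed(cnvrs, outdir / "cnvrs.bed", one_based_report=True,
                         header="CNVR catalogue")
    catalog_summary = cnvr.summarize_catalog(cnvrs, genome)

    # --- sex-mismatch validation -----------------------------------------
    fpr = None
    if "X" in genome.names:
        sm_calls = []
        for k in range(config.n_sex_mismatch_arrays):
            noise = NoiseSpec(probe_sd=config.probe_sd,
                              seed=int(rng.integers(2 ** 31)))
            tr = simulate_sex_mismatch(probe_map, noise,
                                       sample_id=f"sexmm{k + 1}")
            tr = preprocessing.preprocess_track(
                tr, min_intensity=config.min_intensity,
                min_snr=config.min_snr, span=config.lowess_span,
                centralization_threshold=config.centralization_threshold,
                sigma_g_frac=config.sigma_g_frac)
            segs = segmentation.detect_aberrations(
                tr, threshold=config.threshold,
                sigma_g_frac=config.sigma_g_frac, mode=config.mode)
            sm_calls.extend(segmentation.filter_calls(
                segs, config.min_probes, config.min_abs_log2))
        fpr = validation.sex_mismatch_fpr(
            sm_calls, chrx_length=genome.lengths["X"],
            n_arrays=config.n_sex_mismatch_arrays)

    # --- qPCR validation of a few called CNVRs ----------------------------
    qpcr_report = []
    assayable = [r for r in cnvrs if r.cnvr_type != "both"][:config.n_qpcr_targets]
    if assayable:
        targets = []
        for r in assayable:
            mid = (r.start + r.end) // 2
            t = QpcrTarget(r.id, r.chrom, max(r.start, mid - 100), min(r.end, mid + 100))
            for sid in sample_ids:
                targets.append((t, sid))
        ct = simulate_qpcr(truth_all, targets, ct_sd=config.ct_sd,
                           seed=int(rng.integers(2 ** 31)))
        for r in assayable:
            preds = {}
            for sid in sample_ids:
                if sid in r.samples:
                    direction = next(m.direction for m in r.member_calls
                                     if m.sample_id == sid)
                    preds[sid] = direction
                else:
                    preds[sid] = None
            ratios = {sid: validation.ddct_copy_ratio(ct, r.id, sid)
                      for sid in sample_ids}
            calls_q = {sid: validation.classify_qpcr(v) for sid, v in ratios.items()}
            res = validation.predictive_rates(preds, calls_q, target_id=r.id,
                                              per_sample_ratio=ratios)
            qpcr_report.append({
                "cnvr": r.id, "type": r.cnvr_type,
                "n_positive": res.n_positive,
                "positive_predictive_rate": res.positive_predictive_rate,
                "n_negative": res.n_negative,
                "negative_predictive_rate": res.negative_predictive_rate,
            })

    # --- clustering -------------------------------------------------------
    newick = None
    if len(cnvrs) >= 2 and config.n_samples >= 2:
        mat = clustering.presence_matrix(cnvrs, sample_ids)
        if mat.to_numpy().std() > 0:
            tree = clustering.bootstrap_support(mat, metric=config.cluster_metric,
                                                n_boot=config.n_boot,
                                                seed=int(rng.integers(2 ** 31)))
            newick = tree.to_newick()
            (outdir / "dendrogram.nwk").write_text(newick + "\n")

    summary = {
        "n_samples": config.n_samples,
        "per_sample_calls": {sid: sum(1 for c in all_calls if c.sample_id == sid)
                             for sid in sample_ids},
        "total_calls": len(all_calls),
        "catalog": catalog_summary,
        "sex_mismatch_fpr_percent": fpr,
        "qpcr": qpcr_report,
        "dendrogram_newick": newick,
        "seed": config.seed,
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
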