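"""Simulate one noisy aCGH track with planted CNVs and call them back.

Plants copy-number segments on a small genome, adds Gaussian probe noise,
runs the full preprocessing chain (QC, LOWESS, noise estimate, centring) and
the interval-score detector, and prints the calls next to the truth.
"""

from cghcnv import preprocessing, segmentation
from cghcnv.synthetic_data import (NoiseSpec, default_genome,
                                   simulate_probe_map, simulate_ratio_track,
                                   simulate_truth)

genome = default_genome(n_autosomes=1, autosome_mb=20, with_x=False)
probe_map = simulate_probe_map(genome, mean_spacing=2632, seed=1)
truth = simulate_truth(genome, n_segments=5, seed=2, sample_id="demo")
track = simulate_ratio_track(probe_map, truth, NoiseSpec(probe_sd=0.15, seed=3))

track = preprocessing.preprocess_track(track)
segments = segmentation.detect_aberrations(track, threshold=6)
calls = segmentation.filter_calls(segments, min_probes=5, min_abs_mean=0.5)

print(f"probes: {len(probe_map)}, noise sigma: {track.noise_sigma:.3f}")
print("\ntruth segments (copy state, expected log2):")
for t in truth:
    print(f"  {t.chrom}:{t.start}-{t.end}  cn={t.copy_state} "
          f"log2={t.expected_log2:+.2f}")
print("\ncalls passing the 5-probe / 0.5-log-ratio filter:")
for c in calls:
    print(f"  {c.chrom}:{c.start}-{c.end}  {c.direction:4s} "
          f"mean={c.mean_log2:+.2f} score={c.score:+.1f} probes={c.n_probes}")
print("\nEach call should line up with a truth segment: the mean log2 "
      "estimates log2(copy/2), the score is the interval statistic that "
      "cleared the detection threshold of 6.")
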