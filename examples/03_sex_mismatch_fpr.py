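"""False-positive rate from sex-mismatched hybridisations.

A male test sample against a female reference makes chrX a built-in
deletion control: every chrX probe sits at one copy versus two, so any chrX
segment called as a gain is a false positive.  The FPR is the gain-called
fraction of chrX length, summed over arrays.
"""

from cghcnv import segmentation, validation
from cghcnv.preprocessing import estimate_noise
from cghcnv.synthetic_data import (NoiseSpec, default_genome,
                                   simulate_probe_map, simulate_sex_mismatch)

genome = default_genome(n_autosomes=1, autosome_mb=15, with_x=True, x_mb=15)
probe_map = simulate_probe_map(genome, seed=5)

calls = []
for k in range(2):  # two mismatched arrays, as in a 12-sample mixed-sex panel
    track = simulate_sex_mismatch(probe_map, NoiseSpec(probe_sd=0.15,
                                                       seed=60 + k))
    estimate_noise(track)
    segs = segmentation.detect_aberrations(track, threshold=6)
    calls.extend(segmentation.filter_calls(segs))

x_calls = [c for c in calls if c.chrom == "X"]
fpr = validation.sex_mismatch_fpr(calls, chrx_length=genome.lengths["X"],
                                  n_arrays=2)
print(f"chrX calls: {len(x_calls)} "
      f"({sum(c.direction == 'loss' for c in x_calls)} losses)")
print(f"measured FPR: {fpr}%  (gain-called chrX length / chrX length / arrays)")

# the same arithmetic on a published survey's printed lengths:
from cghcnv.datasets import SEX_MISMATCH as SM
published = validation.sex_mismatch_fpr_from_length(
    SM["false_length_bp"], SM["chrx_length_bp"], SM["n_arrays"])
print(f"reference survey: {SM['false_length_bp']:,} bp of false gains on a "
      f"{SM['chrx_length_bp'] / 1e6:.0f} Mb chrX over {SM['n_arrays']} arrays "
      f"-> {published}%")
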