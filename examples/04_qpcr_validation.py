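"""qPCR confirmation by the 2^-ddCt method.

Simulates cycle thresholds for samples with known copy states, converts
them to copy-number ratios against a single-copy control gene and a
two-copy reference sample, classifies each sample, and computes the
positive/negative predictive rates against the array predictions.
"""

from cghcnv import validation
from cghcnv.core import TruthSegment
from cghcnv.synthetic_data import QpcrTarget, simulate_qpcr

# truth: three carriers (two losses, one gain) among six samples
truth = [TruthSegment("S1", "1", 100_000, 150_000, 1, -1.0),
         TruthSegment("S2", "1", 100_000, 150_000, 1, -1.0),
         TruthSegment("S3", "1", 100_000, 150_000, 4, 1.0)]
samples = [f"S{i}" for i in range(1, 7)]
target = QpcrTarget("CNVR_demo", "1", 120_000, 120_200)

ct = simulate_qpcr(truth, [(target, s) for s in samples], ct_sd=0.1, seed=8)

ratios = {s: validation.ddct_copy_ratio(ct, "CNVR_demo", s) for s in samples}
calls = {s: validation.classify_qpcr(r) for s, r in ratios.items()}
print("sample  2^-ddCt  call")
for s in samples:
    print(f"{s:6s}  {ratios[s]:7.3f}  {calls[s]}")

predictions = {"S1": "loss", "S2": "loss", "S3": "gain",
               "S4": None, "S5": None, "S6": None}
res = validation.predictive_rates(predictions, calls, target_id="CNVR_demo")
print(f"\npositive predictive rate: {res.positive_predictive_rate} "
      f"({res.n_positive_confirmed}/{res.n_positive} carriers confirmed)")
print(f"negative predictive rate: {res.negative_predictive_rate} "
      f"({res.n_negative_confirmed}/{res.n_negative} non-carriers where qPCR "
      "found variation anyway)")
print("\nA ratio near 0.5 means one copy, near 1 two copies, near 2 four; "
      "cutoffs 0.7/1.4 turn ratios into loss/normal/gain calls.")
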