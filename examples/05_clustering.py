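"""Cluster samples by their CNVR carrier profiles.

Encodes two groups of samples with group-exclusive CNVR blocks as a binary
matrix, clusters them with UPGMA on Jaccard distances, and attaches
bootstrap branch support.  The planted two-group structure should come back
with ~100% support.
"""

import pandas as pd

from cghcnv import clustering

rows = {}
for s in ["eu1", "eu2", "eu3"]:          # group 1 shares CNVRs 0-9
    rows[s] = [1] * 10 + [0] * 10
for s in ["asia1", "asia2", "asia3"]:    # group 2 shares CNVRs 10-19
    rows[s] = [0] * 10 + [1] * 10
matrix = pd.DataFrame.from_dict(rows, orient="index",
                                columns=[f"CNVR_{i}" for i in range(20)])
# a little within-group variation
matrix.iloc[0, 3] = 0
matrix.iloc[4, 15] = 0

tree = clustering.bootstrap_support(matrix, metric="jaccard", n_boot=1000,
                                    seed=13)
print("newick (internal labels = bootstrap %):")
print(tree.to_newick())
print("\ncluster support:")
for leaves, bp in sorted(tree.bp_support.items(), key=lambda kv: -kv[1]):
    print(f"  {sorted(leaves)}: {bp:.0f}%")
print("\nThe two groups separate at the root with full support; branches "
      "inside a group reflect only the injected variation.")
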