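# Methods

This note describes the models and procedures the package implements, the
parameters that matter, what the synthetic data does and does not emulate,
and the numerical choices made where the design was open.

## Signal model

A two-colour aCGH probe measures the log2 ratio of test to reference
fluorescence. For a test sample with `c` copies of a locus against a
diploid reference, the expected probe value is `log2(c/2)`: 0 for
copy-neutral, −1 for a hemizygous loss, +0.585 for a single-copy gain,
+1 for a two-copy gain. A homozygous deletion would be −∞; real arrays
saturate, so the generator floors it at −4. Around this mean the probe
carries approximately Gaussian noise plus slowly varying artefacts
(genomic waves, intensity-dependent dye bias) that preprocessing removes.

## Preprocessing

**QC filter.** A probe is usable when both channels exceed intensity 50
and signal-to-noise 25, both strict inequalities. Failing probes are
excluded from every statistic but kept in the arrays so row counts and
probe order never change; the filter is idempotent.

**LOWESS normalisation.** The dye bias is a smooth function of mean
log-intensity `A = (log2 I_t + log2 I_r)/2`. A locally weighted regression
of log2 ratio on `A` (span 0.3, two robustifying iterations — the
conventional two-colour default at desk scale) is fitted over passing
probes and subtracted. Normalisation is applied on intensity only, not on
genomic position.

**Noise estimate (DLRS).** The per-array sigma is estimated from
successive probe-to-probe differences within chromosomes:
`σ̂ = median|Δ| / (0.6745·√2)`. Differences straddle an aberration
breakpoint only a handful of times per segment, so the median is
essentially insensitive to real CNVs (tests bound the effect of a 50-probe
aberration at < 2%). A floor of 1e-3 keeps interval scores finite on
degenerate (constant) tracks.

**Centralisation.** The dominant copy-neutral state is moved to zero by
subtracting the mode of the log2 distribution: a 0.01-log2-unit histogram,
smoothed with a Gaussian kernel of ~0.35·σ̂ so probe noise does not pick
the peak bin, with parabolic refinement through the peak and its
neighbours; iterated until the incremental shift is < 1e-3. When a rival
density peak of comparable height exists (an aberration covering much of
the genome), a warning is emitted because the taller peak may not be the
neutral state. The pipeline performs a second pass in which intervals
scoring beyond the detection threshold are masked before the mode is
recomputed — the role of a "centralisation threshold" in aberration
detection suites — using the seeded detector, since only clear aberrations
matter for masking.

## Segmentation

The detector implements the open interval-score family. An interval of
`n` passing probes with mean `m` on an array with noise `σ` scores

    S = m / sqrt(σ²/n + σ_g²)

With `σ_g = 0` this is the classical interval score `Σx/(σ√n)`. The
**fuzzy zero** term `σ_g` models a global, array-wide uncertainty in the
zero level: as `n → ∞` the score of a fixed mean saturates at `m/σ_g`, so
long, low-amplitude runs (residual waves, centring error) cannot reach the
threshold no matter how many probes they span. Default `σ_g = 0.2·σ̂`
(configurable, 0 disables): at σ = 0.15 this blocks any interval of mean
below 6·σ_g = 0.18 regardless of length while leaving the score of
filter-relevant aberrations (|mean| > 0.5) effectively untouched. This is
an ADM2-*like* method — the proprietary implementation's exact boundaries
are not reproduced, and its undocumented "bin" parameter is interpreted
here as the seeding window size of the coarse-to-fine mode.

Detection scans every interval of a chromosome (exact O(n²) mode, the
reference at desk scale), emits the top-|score| interval when it clears
the threshold (default 6), and recurses on both flanks. Ties break to the
leftmost start, then the shortest interval, so results are reproducible.
The seeded mode scores 10-probe windows at half-window stride, expands
windows reaching half the threshold by a two-window margin, merges them,
and runs the exact scan only inside those regions; it agrees with the
exact mode whenever all signal lies within the seeded regions. Abutting
same-direction segments are merged afterwards (the greedy recursion can
split one aberration when the fuzzy zero lets a high-amplitude core
outscore the full interval); oracle-equivalence tests disable this merge.

At threshold 6 the per-track family-wise false-call probability on pure
noise is tiny: with the fuzzy zero the effective per-interval requirement
exceeds 6.1σ even at n = 1, and the acceptance suite measures ≤ 1 spurious
call over 100 pure-noise 5,000-probe tracks.

**Post-filter.** Calls require ≥ 5 probes and |mean log2| strictly > 0.5
— the stringent criteria that trade sensitivity for a low false-positive
rate. Only passing calls enter CNVR construction.

## CNVRs

Calls from all samples merge into CNV regions by transitive ≥ 1 bp overlap
on the same chromosome (the common aggregation convention; no reciprocal
fraction is required). Frequency is the percentage of test samples
contributing a member call — the reference is not in the denominator — and
a region is typed "both" when it contains members of both directions.
chrY is excluded from catalogues by default: on a mixed-sex panel its
dosage reflects sex, not CNV. Catalogue comparison counts a query region
as shared when it overlaps any reference region by ≥ 1 bp; the length
share is the summed *full* length of shared query regions over the query
total, and multi-catalogue totals take the union of hit sets, never the
sum. Reported percentages round to 2 decimals.

Coordinates are 0-based half-open everywhere internally; printed reports
add 1 to starts (1-based inclusive), the convention of published CNV
coordinate tables.

## Validation

**Sex-mismatch FPR.** On a male-test/female-reference array every chrX
locus is one copy against two, so chrX segments with positive mean log2
are false calls. FPR = 100 · (summed false length) / (chrX length ·
number of arrays). It is linear in false length and inversely linear in
array count.

**2^−ΔΔCt.** Replicate wells are averaged on the Ct scale; ΔCt = mean
Ct(target) − mean Ct(control gene) per sample; ΔΔCt subtracts the
reference sample's ΔCt; the copy-number ratio is 2^−ΔΔCt (exactly 1 for
the reference itself). Classification cutoffs default to 1.4 (gain,
inclusive) and 0.7 (loss, inclusive): each sits midway between 1 and the
expected 3-copy (1.5) or 1-copy (0.5) ratio. **Limitation:** with
duplicate wells and per-well Ct noise of 0.1 cycles, sd(ΔΔCt) ≈ 0.14 log2,
so a true 3-copy sample falls below the 1.4 cutoff roughly a quarter of
the time — single-copy gains are intrinsically marginal for qPCR
confirmation at this noise level, while 1- and 4-copy states separate
cleanly (> 95% concordance, measured by the acceptance script). This
asymmetry is one reason array surveys confirm losses more reliably than
gains.

**Predictive rates.** Per assay, a predicted carrier is confirmed when
its qPCR call matches the predicted direction (for "both"-type regions,
the sample's own call direction); a predicted non-carrier is "confirmed"
when qPCR finds any variation — deliberately counting array false
negatives, which stringent calling criteria inflate. Rates with zero
denominators are reported as missing, and table averages are means over
the defined per-assay rates.

## Gene analysis

Gene-CNVR overlap uses the same ≥ 1 bp half-open convention (abutting
intervals share nothing); containment is "complete" when a single CNVR
covers the gene. dN/dS values are consumed as a prepared table — elevated
ratios among CNVR genes indicate relaxed purifying selection — and
compared by a Wilcoxon rank-sum test: exact enumeration of all
`C(n_a+n_b, n_a)` labelings when both groups have ≤ 8 observations
(exactness where it is cheap), otherwise midranks with tie-corrected
variance and a continuity-corrected normal approximation. The test is
invariant under common monotone transforms, and its two-sided type-I
error at α = 0.05 is measured at 0.048 over 10,000 null datasets.
Conserved single-copy genes require high orthology confidence and
strictly > 80% identity in every listed species. GO/KEGG enrichment is
out of scope (external services with versioned databases).

## Clustering

Samples become binary vectors over the CNVR catalogue (1 = contributes a
member call). Default distance is Jaccard — shared *absence* of a CNVR is
weak evidence of relatedness, so it is ignored; simple matching is
available. UPGMA merges the closest pair at half its distance and updates
by size-weighted means, with a deterministic lexicographic tie-break;
heights are ultrametric by construction. Branch support is the ordinary
bootstrap proportion: CNVR columns resampled with replacement, the tree
rebuilt, and each original cluster scored by the share of replicates
containing the same leaf set. Multiscale (AU) corrections are out of
scope; BP is sufficient for the structural claim that well-separated
sample groups re-form under resampling. Default 1,000 replicates at desk
scale; 10,000 matches the published setting for the porcine panel.

## Synthetic data: what it emulates, and not

The generator reproduces the features the pipeline's statistics depend
on: exponential-like inter-probe spacing around a requested mean (default
2,632 bp, a 1M-probe design's average on a ~2.8 Gb genome), 60-mer
probes, iid Gaussian probe noise (default sd 0.15, chosen so the 5-probe
/ 0.5-log-ratio filter is meaningful rather than trivial), optional
sinusoidal waves and intensity-dependent dye bias to exercise LOWESS, a
configurable fraction (default 1%) of QC-failing probes, loss-biased
truth segments (weights 0.725/0.275 on copy states 1/3, matching the
~2.6:1 loss:gain excess aCGH surveys report), sex-mismatch tracks, and Ct
values satisfying Ct = const − log_eff(copies) + noise with duplicate
wells and efficiencies constrained to [1.9, 2.1]. One probe map is drawn
per design and shared by all samples, as with a physical array. All
randomness flows from a single integer seed per call; no global state.

It does **not** model probe sequence composition or GC waves fitted from
real genomes, spatial/scanner artefacts, mosaic (fractional) copy states,
or correlated noise beyond the sinusoid — so passing tests demonstrate
correctness of the statistics under the stated noise model, not
performance on any particular real hybridisation.

## Problem sizes and defaults

The bundled pipeline config simulates 12 samples on a 32 Mb two-chromosome
genome (~12,000 probes) — large enough that every stage (QC, LOWESS,
centring, exact-scan segmentation, CNVR merging, qPCR validation,
bootstrap clustering) runs with non-trivial inputs while a full run
completes in well under a minute. The acceptance script measures segment
recovery on 10 tracks × 5 planted segments, spurious calls on 20
pure-noise 5,000-probe tracks, and qPCR concordance on 500 assays.

## Known limitations

* Segment boundaries are maximum-score estimates; at amplitude 0.5 and
  sd 0.15 the boundary of a short segment can be off by a few probes.
* The fuzzy-zero variance form and the seeding-window reading of the
  "bin" parameter are open interpretations of an undocumented method.
* CNVR frequency treats any member call as carriage; no genotype (copy
  count) is assigned to regions, which also limits what the clustering
  can resolve.
* The LOWESS span and centralisation bandwidth are conventional defaults,
  not fitted to any specific platform.
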