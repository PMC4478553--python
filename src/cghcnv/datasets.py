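"""Bundled summary tables from a 12-sample porcine 1M-feature aCGH survey.

A diverse pig panel (one Asian wild boar, nine Chinese indigenous animals
from six breeds, two European commercial animals) hybridised against a
single Duroc reference.  The raw arrays are not shipped; these are the
survey's published summary statistics, used as worked inputs for the
accounting functions (per-sample call counts, sex-mismatch false-call
lengths, CNVR type composition, catalogue totals, and the qPCR
confirmation table).
"""

from __future__ import annotations

__all__ = [
    "PER_SAMPLE_CNV_COUNTS", "SEX_MISMATCH", "CNVR_TYPE_COUNTS",
    "CATALOG_TOTALS", "QPCR_ASSAY_COUNTS", "QPCR_OVERALL",
]

#: CNV calls per test individual (sample id -> count).  DN1 and R2 are the
#: two males; the reference is female, giving two sex-mismatched arrays.
PER_SAMPLE_CNV_COUNTS = {
    "A1": 180, "DN1": 144, "DN5": 229, "M2": 153, "MS7": 211, "MS8": 224,
    "R2": 262, "W1": 118, "Z2": 291, "Z5": 260, "C3": 139, "Y2": 65,
}

#: Sex-mismatch control: 17 chrX segments with positive mean log2 summing to
#: 1,045,770 bp across the two male-vs-female arrays; chrX length per the
#: porcine 10.2 assembly.
SEX_MISMATCH = {
    "n_false_segments": 17,
    "false_length_bp": 1_045_770,
    "chrx_length_bp": 144_288_218,
    "n_arrays": 2,
}

#: CNVR catalogue type composition.
CNVR_TYPE_COUNTS = {"loss": 529, "gain": 200, "both": 29}

#: Catalogue totals: 758 CNVRs covering 47.43 Mb.
CATALOG_TOTALS = {"n_cnvrs": 758, "total_length_mb": 47.43,
                  "genome_percent": 1.69}

#: qPCR confirmation assays for the 17 confirmed CNVRs: one row per primer
#: pair, (cnvr_id, primer, n_positive, n_positive_confirmed, n_negative,
#: n_negative_confirmed).  Positives are array-predicted carriers; a
#: negative is "confirmed" when qPCR finds variation the array missed.
QPCR_ASSAY_COUNTS = [
    (43,  "CGH1-1",  11, 11,  1, 1),
    (43,  "Gene2-2", 11, 11,  1, 1),
    (47,  "E1-2",     9,  3,  2, 0),
    (72,  "LD1-2",    7,  7,  5, 3),
    (72,  "LD1-3",    7,  7,  5, 3),
    (105, "F1-2",    12, 12,  0, 0),
    (105, "F1-3",    12, 12,  0, 0),
    (108, "RD2B-4",   2,  2, 10, 2),
    (114, "J1-3",     8,  8,  4, 1),
    (152, "CGH3-1",  11, 11,  1, 1),
    (152, "Gene9-4", 11, 11,  1, 1),
    (339, "R1-3",     2,  2, 10, 7),
    (418, "CGH7-1",  12, 12,  0, 0),
    (418, "CGH7-3",  12, 12,  0, 0),
    (441, "D1",       2,  2, 10, 6),
    (441, "D5",       2,  1, 10, 0),
    (464, "F2",       7,  6,  5, 2),
    (464, "F4",       7,  6,  5, 1),
    (579, "RD14A-2",  7,  7,  5, 3),
    (579, "RD14B-2",  7,  4,  5, 0),
    (588, "D1-1",     2,  1, 11, 0),
    (588, "D2-1",     2,  1, 11, 0),
    (620, "CGH2-1",   2,  2, 10, 0),
    (620, "kit6",     2,  2, 10, 0),
    (659, "K5",       1,  1, 10, 0),
    (734, "CGH6A-2",  8,  8,  4, 2),
    (734, "CGH5B-1",  8,  8,  4, 2),
    (736, "R2-2",     3,  3,  8, 6),
]

#: Assay-level agreement: 31 assays over 19 tested CNVRs, 28 concordant
#: with the array prediction, 17 CNVRs confirmed by >=1 assay.
QPCR_OVERALL = {
    "n_assays": 31,
    "n_assays_concordant": 28,
    "n_cnvrs_tested": 19,
    "n_cnvrs_confirmed": 17,
}
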