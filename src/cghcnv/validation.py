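"""Call-reliability accounting: sex-mismatch FPR, 2^-ddCt, predictive rates.

Three independent lines of evidence on call quality:

* **Sex-mismatched arrays** (male test vs. female reference) make chrX a
  genome-wide deletion control: any chrX segment called as a gain is a
  false positive, and the FPR is the gain-called fraction of chrX length.
* **qPCR relative quantification**: the 2^-ddCt method converts cycle
  thresholds into a copy-number ratio against a single-copy control gene
  and a baseline reference sample (ratio 1 = two copies, 2 = four, 0.5 = one).
* **Predictive rates**: per assay, the fraction of array-predicted carriers
  confirmed by qPCR (positive rate) and the fraction of predicted
  non-carriers in which qPCR nevertheless finds variation (negative rate —
  an accounting of array false negatives).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence

import numpy as np

from .core import CtTable

__all__ = [
    "sex_mismatch_fpr", "sex_mismatch_fpr_from_length",
    "ddct_copy_ratio", "classify_qpcr", "predictive_rates",
    "rates_from_counts", "average_rates", "confirmation_summary",
    "QpcrAssayResult",
]


def sex_mismatch_fpr_from_length(false_length_bp: float, chrx_length: float,
                                 n_arrays: int) -> float:
    """FPR percent from a total false-call length:
    100 * false_length / (chrX length * number of arrays)."""
    if n_arrays <= 0:
        raise ValueError("n_arrays must be >= 1")
    if chrx_length <= 0:
        raise ValueError("chrx_length must be > 0")
    return round(100.0 * false_length_bp / (chrx_length * n_arrays), 2)


def sex_mismatch_fpr(calls: Sequence, chrx_length: float, n_arrays: int,
                     x_name: str = "X") -> float:
    """FPR percent from chrX segments of male-vs-female arrays.

    On such arrays every chrX probe sits at one copy versus two, so chrX
    segments with positive mean log2 are false calls; their summed length
    over all arrays, relative to chrX length times the number of arrays,
    is the false-positive rate.
    """
    from .core import normalize_chrom
    x = normalize_chrom(x_name)
    false_len = sum(c.end - c.start for c in calls
                    if normalize_chrom(c.chrom) == x and c.mean_log2 > 0)
    return sex_mismatch_fpr_from_length(false_len, chrx_length, n_arrays)


def ddct_copy_ratio(ct: CtTable, target_id: str, sample_id: str) -> float:
    """Relative copy number of one sample at one target by 2^-ddCt.

    dCt = mean Ct(target) - mean Ct(control gene) per sample;
    ddCt = dCt(sample) - dCt(reference sample); ratio = 2^-ddCt.
    Replicate wells are averaged on the Ct scale.  The reference sample's
    own ratio is exactly 1.
    """
    try:
        ctrl_s = ct.mean_ct(sample_id, ct.control_target)
    except KeyError:
        raise ValueError(f"sample {sample_id!r}: no control-gene wells") from None
    try:
        ctrl_r = ct.mean_ct(ct.reference_sample, ct.control_target)
    except KeyError:
        raise ValueError(f"reference sample {ct.reference_sample!r}: "
                         "no control-gene wells") from None
    dct_sample = ct.mean_ct(sample_id, target_id) - ctrl_s
    dct_ref = ct.mean_ct(ct.reference_sample, target_id) - ctrl_r
    return float(2.0 ** -(dct_sample - dct_ref))


def classify_qpcr(cn_ratio: float, gain_cutoff: float = 1.4,
                  loss_cutoff: float = 0.7) -> str:
    """Call gain/loss/normal from a 2^-ddCt ratio.

    Defaults sit midway between the expected 3-vs-2-copy ratio (1.5) and 1,
    and the 1-vs-2-copy ratio (0.5) and 1.  Boundaries are inclusive:
    ratio == gain_cutoff is a gain, ratio == loss_cutoff a loss.
    """
    if loss_cutoff >= gain_cutoff:
        raise ValueError("loss_cutoff must be < gain_cutoff")
    if cn_ratio <= 0:
        raise ValueError("cn_ratio must be > 0")
    if cn_ratio >= gain_cutoff:
        return "gain"
    if cn_ratio <= loss_cutoff:
        return "loss"
    return "normal"


@dataclass
class QpcrAssayResult:
    """Per-assay confirmation accounting against array predictions."""

    target_id: str
    n_positive: int
    n_positive_confirmed: int
    n_negative: int
    n_negative_confirmed: int
    positive_predictive_rate: Optional[float]
    negative_predictive_rate: Optional[float]
    per_sample_ratio: Dict[str, float] = field(default_factory=dict)
    per_sample_call: Dict[str, str] = field(default_factory=dict)


def predictive_rates(predictions: Mapping[str, Optional[str]],
                     qpcr_calls: Mapping[str, str],
                     target_id: str = "",
                     per_sample_ratio: Optional[Mapping[str, float]] = None
                     ) -> QpcrAssayResult:
    """Confirmation rates for one assay.

    ``predictions`` maps each sample to its array-predicted direction
    ("gain"/"loss") or None for predicted non-carriers; for a "both"-type
    region each carrier's own direction is used.  A positive sample is
    confirmed when its qPCR call matches the predicted direction; a
    negative sample is "confirmed" when qPCR finds any variation (a
    non-normal call) — the false-negative accounting convention.  A rate
    with a zero denominator is reported as None (printed as em-dash).
    """
    if set(predictions) != set(qpcr_calls):
        raise ValueError("predictions and qPCR calls cover different samples")
    n_pos = n_pos_conf = n_neg = n_neg_conf = 0
    for sample, direction in predictions.items():
        call = qpcr_calls[sample]
        if direction is None:
            n_neg += 1
            if call != "normal":
                n_neg_conf += 1
        else:
            n_pos += 1
            if call == direction:
                n_pos_conf += 1
    return QpcrAssayResult(
        target_id=target_id,
        n_positive=n_pos, n_positive_confirmed=n_pos_conf,
        n_negative=n_neg, n_negative_confirmed=n_neg_conf,
        positive_predictive_rate=round(n_pos_conf / n_pos, 4) if n_pos else None,
        negative_predictive_rate=round(n_neg_conf / n_neg, 4) if n_neg else None,
        per_sample_ratio=dict(per_sample_ratio or {}),
        per_sample_call=dict(qpcr_calls),
    )


def rates_from_counts(rows: Sequence) -> list:
    """Recompute per-assay predictive rates from printed sample counts.

    ``rows`` are (cnvr_id, primer, n_pos, n_pos_confirmed, n_neg,
    n_neg_confirmed); each rate is confirmed/denominator to 4 decimals,
    None when the denominator is zero.
    """
    out = []
    for cnvr_id, primer, np_, npc, nn, nnc in rows:
        out.append({
            "cnvr_id": cnvr_id, "primer": primer,
            "positive_predictive_rate": round(npc / np_, 4) if np_ else None,
            "negative_predictive_rate": round(nnc / nn, 4) if nn else None,
        })
    return out


def average_rates(rates: Sequence[Optional[float]]) -> float:
    """Mean of the defined rates (undefined entries excluded), 4 decimals —
    the row-average convention of printed confirmation tables."""
    vals = [r for r in rates if r is not None]
    if not vals:
        raise ValueError("no defined rates to average")
    return round(sum(vals) / len(vals), 4)


def confirmation_summary(n_assays: int, n_assays_concordant: int,
                         n_cnvrs_tested: int, n_cnvrs_confirmed: int) -> dict:
    """Assay-level agreement and per-CNVR confirmation (>=1 agreeing assay),
    as percentages to 2 decimals."""
    if n_assays <= 0 or n_cnvrs_tested <= 0:
        raise ValueError("counts must be positive")
    return {
        "assay_agreement_percent": round(100.0 * n_assays_concordant / n_assays, 2),
        "cnvr_confirmation_percent": round(100.0 * n_cnvrs_confirmed / n_cnvrs_tested, 2),
    }
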