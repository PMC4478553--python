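import numpy as np
import pandas as pd
import pytest

from cghcnv.core import GenomeSpec, ProbeMap, RatioTrack
from cghcnv.synthetic_data import (NoiseSpec, default_genome,
                                   simulate_probe_map, simulate_ratio_track,
                                   simulate_truth)


@pytest.fixture(scope="session")
def small_genome():
    return default_genome(n_autosomes=1, autosome_mb=10, with_x=True, x_mb=5)


@pytest.fixture(scope="session")
def probe_map(small_genome):
    return simulate_probe_map(small_genome, mean_spacing=2632, seed=11)


def make_track(log2, sample_id="T", chrom="1", spacing=1000, probe_len=60,
               noise_sigma=None):
    """Build a RatioTrack directly from a log2 vector (QC all-pass)."""
    log2 = np.asarray(log2, dtype=float)
    n = log2.size
    starts = np.arange(n) * spacing
    pm = ProbeMap(pd.DataFrame({
        "probe_id": [f"p{i}" for i in range(n)],
        "chrom": chrom, "start": starts, "end": starts + probe_len,
    }))
    data = pd.DataFrame({
        "log2_ratio": log2,
        "intensity_test": np.full(n, 1000.0),
        "intensity_ref": np.full(n, 1000.0),
        "snr_test": np.full(n, 100.0),
        "snr_ref": np.full(n, 100.0),
        "qc_pass": np.ones(n, dtype=bool),
    })
    return RatioTrack(sample_id=sample_id, probe_map=pm, data=data,
                      noise_sigma=noise_sigma)
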