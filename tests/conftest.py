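import numpy as np
import pytest

from pepagg import synthdata
from pepagg.curation import PeptideRecord


@pytest.fixture(scope="session")
def small_benchmark():
    """A 120-peptide labelled benchmark with noise-free traces."""
    cfg = synthdata.SyntheticConfig(n_peptides=120, seed=42)
    tc = synthdata.TraceModelConfig(noise_sd=0.0, seed=42)
    return synthdata.make_benchmark(cfg, tc)


@pytest.fixture(scope="session")
def labelled_records():
    """600 planted-label records under the default generator settings."""
    cfg = synthdata.SyntheticConfig(n_peptides=600, seed=7)
    return synthdata.planted_labels(synthdata.sample_peptides(cfg), cfg)


def gaussian_peak(sigma=1.0, height=1.0, center=0.0, half_span=8.0, n=4001, baseline=0.0):
    t = np.linspace(center - half_span, center + half_span, n)
    return t, baseline + height * np.exp(-0.5 * ((t - center) / sigma) ** 2)


@pytest.fixture
def make_record():
    def _make(sequence, **kw):
        kw.setdefault("id", f"rec-{sequence[:6]}")
        return PeptideRecord(sequence=sequence, **kw)

    return _make
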