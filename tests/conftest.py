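import numpy as np
import pytest

from terseq import synthetic


@pytest.fixture
def flat_design():
    """Study time grid, 3 replicates, equal library sizes (8M reads).

    Equal depths make zero-dispersion data exactly reproducible across
    timepoints and replicates, which the exact-recovery tests rely on.
    """
    ls = np.full((len(synthetic.SAMPLE_TIMES_S), 3), 8_000_000)
    return synthetic.TimeSeriesDesign(library_sizes=ls)


@pytest.fixture
def drawn_design():
    """Study design with library sizes drawn from the observed range."""
    return synthetic.default_design(seed=7)


def make_truth(**kw):
    """A well-expressed upregulated operon; override fields per test."""
    k = np.log(2) / 240.0  # 4-minute mRNA half-life
    defaults = dict(name="op", ter_true=40.0, delay_true=20.0,
                    s_b=20 * k, s_a=140 * k, gamma=k, mu=0.0,
                    direction="increase", operon_length=2700, dispersion=0.0)
    defaults.update(kw)
    return synthetic.OperonTruth(**defaults)


@pytest.fixture
def truth_factory():
    return make_truth
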