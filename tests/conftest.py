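import numpy as np
import pytest

from phasegan.spectra import SpectralDataset, Spectrum


@pytest.fixture
def random_dataset():
    """Factory for random labeled datasets (optionally with metadata)."""

    def make(n=10, length=12, classes=("solution", "gel"), seed=0, with_meta=False):
        rng = np.random.default_rng(seed)
        spectra = []
        for i in range(n):
            label = classes[i % len(classes)]
            meta = {"well": int(i), "experiment": f"e{i % 3}"} if with_meta else {}
            spectra.append(Spectrum(rng.normal(size=length), label, meta))
        return SpectralDataset(spectra, list(classes))

    return make
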