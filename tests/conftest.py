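import numpy as np
import pytest

from exonmsbf import (
    SpectralConfig,
    SynthConfig,
    build_filter_bank,
    generate,
)
from exonmsbf.evaluate import exon_mask
from exonmsbf.transform import predict_full


@pytest.fixture(scope="session")
def default_bank():
    return build_filter_bank(SpectralConfig())


@pytest.fixture(scope="session")
def small_bank():
    """Reduced bank (4 scales, supports 10..100) for brute-force oracles."""
    return build_filter_bank(SpectralConfig(L=600, J=4))


def _predict_set(records, bank):
    out = []
    for sr in records:
        track, stack, mp = predict_full(sr.record, bank=bank)
        mask = exon_mask(track.length, sr.truth)
        out.append((sr, track, stack, mp, mask))
    return out


@pytest.fixture(scope="session")
def suite_predictions(default_bank):
    """Full pipeline on the canonical 50-sequence biased suite (seed 1)."""
    return _predict_set(generate(SynthConfig(seed=1)), default_bank)


@pytest.fixture(scope="session")
def null_predictions(default_bank):
    """Bias-0 control: planted interval layout with no codon signal (seed 2)."""
    return _predict_set(
        generate(SynthConfig(seed=2, bias_strength=0.0)), default_bank
    )
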