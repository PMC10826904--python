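import numpy as np
import pytest

from metanorm import (
    NCounterDataset,
    NormSimConfig,
    ProbeAnnotation,
    ProbeClass,
    simulate_ncounter,
)

POS_FM = (128.0, 32.0, 8.0, 2.0, 0.5, 0.125)


def toy_annotation(P=6, N=2, H=2, R=3):
    ann = [ProbeAnnotation(f"POS_{chr(65 + p)}", ProbeClass.POSITIVE, POS_FM[p])
           for p in range(P)]
    ann += [ProbeAnnotation(f"NEG_{n + 1}", ProbeClass.NEGATIVE) for n in range(N)]
    ann += [ProbeAnnotation(f"HK_{h + 1}", ProbeClass.HOUSEKEEPING) for h in range(H)]
    ann += [ProbeAnnotation(f"GENE_{r + 1}", ProbeClass.REGULAR) for r in range(R)]
    return ann


@pytest.fixture
def toy_dataset():
    """2 samples x (6+2+2+3) probes with deterministic small counts."""
    rng = np.random.default_rng(99)
    counts = rng.integers(0, 5000, size=(2, 13))
    return NCounterDataset(counts=counts, sample_ids=["S1", "S2"],
                           annotation=toy_annotation())


@pytest.fixture
def small_sim():
    """Moderate synthetic dataset with its ground truth."""
    cfg = NormSimConfig()
    return simulate_ncounter(cfg, (8, 6, 4, 3, 10), seed=123)
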