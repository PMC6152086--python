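"""Shared fixtures: seeded separable blob task and small synthetic datasets."""

import numpy as np
import pytest

import ppilm as P


def make_blobs(n, rng, center=2.0, spread=0.5):
    """Two well-separated Gaussian classes in 2-D with +/-1 labels."""
    n2 = n // 2
    X = np.vstack([
        rng.normal(-center, spread, size=(n2, 2)),
        rng.normal(center, spread, size=(n - n2, 2)),
    ])
    y = np.concatenate([np.full(n2, -1), np.full(n - n2, 1)])
    return X, y


#: Kernel width matched to the blob construction: the within-class
#: pairwise distance scale is spread * 2 = 1.
BLOB_THETA = 1.0


@pytest.fixture(scope="session")
def blob_task():
    rng = np.random.default_rng(42)
    X_train, y_train = make_blobs(60, rng)
    X_test, y_test = make_blobs(200, rng)
    return X_train, y_train, X_test, y_test


@pytest.fixture(scope="session")
def blob_fit(blob_task):
    X_train, y_train, _, _ = blob_task
    return P.PCVM(y_train, X_train).fit(theta=BLOB_THETA)


@pytest.fixture(scope="session")
def medium_synthetic():
    """A synthetic dataset large enough for the pair-similarity signal
    to be learnable (the concatenated-descriptor task is sample-hungry:
    positives lie near the diagonal of the latent space)."""
    cfg = P.SynthConfig(
        n_proteins=800, n_pairs=1000, delta=1.0, sigma=0.1,
        length_range=(30, 60), seed=7,
    )
    pssms, pairs, meta = P.simulate_dataset(cfg)
    return cfg, pssms, pairs, meta


@pytest.fixture(scope="session")
def small_synthetic():
    """A small separable synthetic dataset: profiles, pairs, metadata."""
    cfg = P.SynthConfig(
        n_proteins=120, n_pairs=150, delta=1.0, sigma=0.1,
        length_range=(30, 60), seed=7,
    )
    pssms, pairs, meta = P.simulate_dataset(cfg)
    return cfg, pssms, pairs, meta
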