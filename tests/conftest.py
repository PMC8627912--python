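"""Shared fixtures: small peak lists and seeded synthetic datasets."""

import numpy as np
import pandas as pd
import pytest

import rnclink as rl


def make_peak_list(residues, shifts_h=None, shifts_n=None, intensity=1000.0,
                   noise=10.0, **metadata):
    """Construct a small PeakList with sensible defaults."""
    residues = list(residues)
    n = len(residues)
    df = pd.DataFrame(
        {
            "residue_index": residues,
            "residue_name": ["X"] * n,
            "shift_H": shifts_h if shifts_h is not None else np.full(n, 8.2),
            "shift_N": shifts_n if shifts_n is not None else np.full(n, 118.0),
            "intensity": np.broadcast_to(np.asarray(intensity, float), (n,)).copy(),
            "noise": np.broadcast_to(np.asarray(noise, float), (n,)).copy(),
        }
    )
    return rl.PeakList(df=df, **metadata)


@pytest.fixture(scope="session")
def binding_truth():
    """Two-variant binding ground truth at the default study conditions."""
    return rl.BindingGroundTruth.from_populations(ddg=1.9)


@pytest.fixture(scope="session")
def csp_dataset_clean(binding_truth):
    """Noise-free CSP dataset for exact round-trip checks."""
    return rl.simulate_csp_dataset(binding_truth, noise_sd=(0.0, 0.0), seed=0)


@pytest.fixture(scope="session")
def csp_tables_clean(binding_truth, csp_dataset_clean):
    data = csp_dataset_clean
    return {
        v: {
            L: rl.compute_csp(rl.match_peaks(data[(v, L)], data[(v, None)]))
            for L in binding_truth.lengths
        }
        for v in binding_truth.variants
    }


@pytest.fixture(scope="session")
def csp_fit_noisy(binding_truth):
    """Global exchange fit on one noisy synthetic dataset (seed fixed)."""
    data = rl.simulate_csp_dataset(binding_truth, noise_sd=(0.003, 0.02), seed=1)
    tables = {
        v: {
            L: rl.compute_csp(rl.match_peaks(data[(v, L)], data[(v, None)]))
            for L in binding_truth.lengths
        }
        for v in binding_truth.variants
    }
    sigma = (np.sqrt(2) * 0.003, np.sqrt(2) * 0.02)
    return rl.global_exchange_fit(
        tables, sigma=sigma, n_starts=12, n_boot=100, seed=1
    )
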