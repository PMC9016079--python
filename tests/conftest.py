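import numpy as np
import pandas as pd
import pytest

from aseqtl.simulate import SimConfig, simulate_ase_dataset


def make_balanced_pairs(n_pairs=25, count=40, lib=1e5, n_hom=0, hom_count=80):
    """Observation table whose heterozygote pairs have identical counts.

    By symmetry the HPMM profile likelihood is even in beta, so the MLE of
    beta is exactly zero.
    """
    rows = []
    for i in range(n_pairs):
        sid = f"H{i:03d}"
        rows.append((sid, float(count), 1.0, lib / 2.0))
        rows.append((sid, float(count), 0.0, lib / 2.0))
    for i in range(n_hom):
        x = float(i % 2)
        rows.append((f"M{i:03d}", float(hom_count), x, lib))
    return pd.DataFrame(rows, columns=["subject_id", "y", "X", "K"])


@pytest.fixture(scope="session")
def small_dataset():
    """One seeded simulated dataset (n=80, beta=0.3, MAF 0.4)."""
    cfg = SimConfig(n_subjects=80, maf=0.4, beta=0.3, seed=11)
    return simulate_ase_dataset(cfg, np.random.default_rng(cfg.seed))


@pytest.fixture(scope="session")
def null_dataset():
    cfg = SimConfig(n_subjects=80, maf=0.4, beta=0.0, seed=12)
    return simulate_ase_dataset(cfg, np.random.default_rng(cfg.seed))
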