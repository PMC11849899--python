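import numpy as np
import pandas as pd
import pytest

from heterogroup.genotype_io import GenotypeMatrix
from heterogroup.popsim import SimConfig, simulate_panel


def make_matrix(dosage, chroms=None, pedigree=None, prefix="S"):
    """Build a small GenotypeMatrix from a raw dosage array."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    markers = pd.DataFrame(
        {
            "marker_id": [f"m{j}" for j in range(m)],
            "chrom": [str(c) for c in (chroms if chroms is not None else [1] * m)],
            "pos": [(j + 1) * 100 for j in range(m)],
            "ref": ["A"] * m,
            "alt": ["T"] * m,
            "multiallelic": False,
            "is_indel": False,
        }
    )
    samples = [f"{prefix}{i}" for i in range(n)]
    return GenotypeMatrix(samples=samples, markers=markers, dosage=dosage,
                          pedigree=pedigree)


@pytest.fixture(scope="session")
def small_panel():
    """Mid-size structured panel shared across module tests (fixed seed)."""
    cfg = SimConfig(
        n_subpops=3,
        n_per_subpop=[60, 50, 40],
        n_markers=400,
        fst=0.10,
        residual_het=0.02,
        admix_fraction=0.10,
        seed=7,
    )
    g, truth = simulate_panel(cfg)
    return g, truth


@pytest.fixture(scope="session")
def study_scale_panels():
    """Panels at the study's simulation conditions (300 samples, 1000 SNPs),
    generated once and shared by the recovery tests."""
    panels = []
    for seed in range(20):
        cfg = SimConfig(
            n_subpops=3,
            n_per_subpop=[100, 100, 100],
            n_markers=1000,
            fst=0.10,
            residual_het=0.02,
            seed=seed,
        )
        panels.append(simulate_panel(cfg))
    return panels
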