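import numpy as np
import pandas as pd
import pytest

from regeqtl import GenotypeDataset, PlantedEffect, SimConfig


def make_dataset(dosage, phenotype=None, positions=None, contig="chr1",
                 dp=None, gq=None, **sample_cols):
    """Small GenotypeDataset straight from a dosage matrix."""
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    pos = positions if positions is not None else np.arange(1, m + 1) * 1000
    variants = pd.DataFrame(
        {
            "contig": contig,
            "pos": pos,
            "ref": "A",
            "alt": "G",
            "biallelic": True,
        }
    )
    variants["variant_id"] = [
        f"{contig}:{p}:A:G" for p in variants["pos"]
    ]
    samples = pd.DataFrame(
        index=pd.Index([f"S{i:03d}" for i in range(n)], name="sample")
    )
    if phenotype is not None:
        samples["phenotype"] = np.asarray(phenotype, dtype=int)
    for k, v in sample_cols.items():
        samples[k] = v
    return GenotypeDataset(
        samples=samples, variants=variants, dosage=dosage,
        dp=None if dp is None else np.asarray(dp),
        gq=None if gq is None else np.asarray(gq),
    )


@pytest.fixture
def small_config():
    return SimConfig(
        n_cases=120,
        n_controls=80,
        n_variants=60,
        n_genes=10,
        planted_risk=[
            PlantedEffect(3, 1.8, "G0001", 0.6),
            PlantedEffect(17, 1.0, "G0002", -0.5),
        ],
        seed=11,
        contig_lengths={"chr1": 1_000_000, "chr2": 1_000_000},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
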