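from datetime import date

import numpy as np
import pandas as pd
import pytest

from ssgeval import GenotypeMatrix, Pedigree, SimConfig


@pytest.fixture
def trio_pedigree():
    """Two founders and one offspring."""
    return Pedigree.from_records(
        [
            ("A", "0", "0", date(2000, 1, 1), "M", "X"),
            ("B", "0", "0", date(2000, 1, 1), "F", "X"),
            ("C", "A", "B", date(2005, 1, 1), "F", "X"),
        ]
    )


@pytest.fixture
def fullsib_pedigree():
    """Founders A, B; full sibs C, D; inbred offspring E of C x D."""
    return Pedigree.from_records(
        [
            ("A", "0", "0", None, "M", "X"),
            ("B", "0", "0", None, "F", "X"),
            ("C", "A", "B", None, "M", "X"),
            ("D", "A", "B", None, "F", "X"),
            ("E", "C", "D", None, "F", "X"),
        ]
    )


def random_pedigree(rng, n, n_founders=None, breed="X"):
    """A random valid pedigree: parents always earlier-born animals."""
    n_founders = n_founders or max(4, n // 4)
    records = []
    sexes = []
    for i in range(n):
        sex = "M" if rng.random() < 0.5 else "F"
        sexes.append(sex)
        if i < n_founders:
            s = d = "0"
        else:
            males = [j for j in range(i) if sexes[j] == "M"]
            females = [j for j in range(i) if sexes[j] == "F"]
            s = f"I{rng.choice(males)}" if males and rng.random() < 0.9 else "0"
            d = f"I{rng.choice(females)}" if females and rng.random() < 0.9 else "0"
        records.append((f"I{i}", s, d, date(2000 + i // 50, 1, 1), sex, breed))
    return Pedigree.from_records(records)


def random_genotypes(rng, n_animals=10, n_markers=50, missing_rate=0.0):
    markers = pd.DataFrame(
        {
            "snp_id": [f"S{j}" for j in range(n_markers)],
            "chrom": np.sort(rng.integers(1, 32, size=n_markers)),
            "bp": np.arange(1, n_markers + 1) * 1000,
            "alleleA": ["A"] * n_markers,
            "alleleB": ["G"] * n_markers,
        }
    )
    calls = rng.integers(0, 3, size=(n_animals, n_markers)).astype(np.int8)
    if missing_rate > 0:
        calls = np.where(
            rng.random(calls.shape) < missing_rate, np.int8(-1), calls
        )
    ids = [f"A{i}" for i in range(n_animals)]
    return GenotypeMatrix(ids, markers, calls)


@pytest.fixture
def tiny_sim_config():
    return SimConfig(
        seed=11,
        n_breeds=2,
        breed_sizes=(40, 25),
        breed_names=("B1", "B2"),
        n_generations=2,
        markers_per_chrom=20,
        n_chromosomes=5,
        qtl_spec=((3, 60_000_000, 0.2),),
        h2_polygenic=0.25,
        missing_rate=0.02,
    )
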