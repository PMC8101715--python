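import numpy as np
import pytest

from herdgen import MapSpec, Pedigree, SimConfig, simulate_cohort


def random_pedigree(seed: int, n_max: int = 40):
    """Random acyclic pedigree as (Pedigree, parents-dict) for oracle checks."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, n_max + 1))
    rows = []
    parents = {}
    males, females = [], []
    for i in range(n):
        iid = f"I{i}"
        sex = "male" if rng.random() < 0.5 else "female"
        sire = dam = None
        if males and rng.random() < 0.7:
            sire = males[int(rng.integers(len(males)))]
        if females and rng.random() < 0.7:
            dam = females[int(rng.integers(len(females)))]
        rows.append((iid, sire, dam, sex, 2000 + i // 5))
        parents[iid] = (sire, dam)
        (males if sex == "male" else females).append(iid)
    return Pedigree.from_tuples(rows), parents


@pytest.fixture
def full_sib_pedigree():
    """Offspring of two full sibs whose parents are unrelated founders."""
    return Pedigree.from_tuples(
        [
            ("A", None, None, "male", 2000),
            ("B", None, None, "female", 2000),
            ("C", "A", "B", "male", 2002),
            ("D", "A", "B", "female", 2002),
            ("E", "C", "D", "male", 2005),
        ]
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Gene-dropped cohort on a small dense map (session-cached)."""
    cfg = SimConfig(
        n_founders=12,
        n_generations=3,
        offspring_per_generation=30,
        map=MapSpec(n_chromosomes=4, total_snps=4000, spacing_kb=20.0),
        seed=11,
    )
    return simulate_cohort(cfg)
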