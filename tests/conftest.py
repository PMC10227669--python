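"""Shared fixtures: small random genotype pools and hand-built coverage sets."""

from __future__ import annotations

import numpy as np
import pytest

from hlacover.matching import CoverageSets
from hlacover.model import (
    LOCUS_ORDER,
    Allele,
    Genotype,
    GenotypePool,
    PoolRole,
    merge_genotypes,
)

# small per-locus panels so random genotypes collide often (mismatch counts
# of 0..2 per locus all arise, homozygosity is common)
PANEL_SIZES = {"A": 4, "B": 4, "C": 3, "DQB1": 3, "DRB1": 3}


def make_allele(locus, index: int) -> Allele:
    return Allele(locus, f"{locus.value}*{index:02d}:01")


def random_genotype(rng: np.random.Generator) -> Genotype:
    pairs = []
    for locus in LOCUS_ORDER:
        size = PANEL_SIZES[locus.value]
        i, j = rng.integers(1, size + 1, size=2)
        pairs.append(tuple(sorted((make_allele(locus, i), make_allele(locus, j)))))
    return Genotype(tuple(pairs))


def random_pool(rng: np.random.Generator, n: int, role: PoolRole) -> GenotypePool:
    return merge_genotypes([random_genotype(rng) for _ in range(n)], role)


def distinct_genotypes(n: int) -> list[Genotype]:
    """n pairwise distinct genotypes (differing at HLA-A only)."""
    out = []
    for k in range(n):
        pairs = []
        for locus in LOCUS_ORDER:
            if locus.value == "A":
                a = make_allele(locus, k + 1)
                pairs.append((a, a))
            else:
                a = make_allele(locus, 1)
                pairs.append((a, a))
        out.append(Genotype(tuple(pairs)))
    return out


def toy_patients(weights: list[int]) -> GenotypePool:
    gs = distinct_genotypes(len(weights))
    return GenotypePool(tuple(zip(gs, weights)), PoolRole.PATIENT)


def make_cov(
    sets: list[set[int]],
    costs: list[float] | None = None,
    knockout: list[bool] | None = None,
    match_counts: list[dict[int, int]] | None = None,
) -> CoverageSets:
    ids = tuple(f"D{j}" for j in range(len(sets)))
    return CoverageSets(
        ids=ids,
        sets={k: frozenset(s) for k, s in zip(ids, sets)},
        donor_of={k: j for j, k in enumerate(ids)},
        costs={k: (costs[j] if costs else 1.0) for j, k in enumerate(ids)},
        is_knockout={k: (knockout[j] if knockout else False) for j, k in enumerate(ids)},
        match_counts=(
            {k: match_counts[j] for j, k in enumerate(ids)} if match_counts else None
        ),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
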