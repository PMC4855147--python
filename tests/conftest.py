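"""Shared fixtures: a small allele catalog, a genotype matrix reproducing
the published per-locus heterozygote and allele counts, and helpers for
synthetic read runs.  Everything is generated programmatically and seeded.
"""

from __future__ import annotations

import numpy as np
import pytest

from mhcdrift.records import (
    Allele,
    AlleleCatalog,
    GenotypeMatrix,
    SampleRecord,
)
from mhcdrift.simulate import TagScheme

LOCI = {"exon2": 99, "intron2a": 89, "exon4": 92}


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join("ACGT"[b] for b in rng.integers(0, 4, size=length))


@pytest.fixture(scope="session")
def catalog() -> AlleleCatalog:
    """Seven alleles at exon2/intron2a, five at exon4, well separated."""
    rng = np.random.default_rng(42)
    cat = AlleleCatalog(LOCI)
    for locus, length in LOCI.items():
        n = 5 if locus == "exon4" else 7
        base = random_sequence(length, rng)
        for i in range(n):
            arr = list(base)
            # i substitutions at distinct sites keeps alleles >=1 apart and
            # never a pure C/T-G/A pair of the base (transversions used)
            for pos in range(0, 3 * i, 3):
                arr[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[arr[pos]]
            cat.add(Allele(f"{locus[0]}{i + 1}", locus, "".join(arr)))
    return cat


def _het_pairs(prefix: str, pairs: list[tuple[int, int]]):
    return [(f"{prefix}{a}", f"{prefix}{b}") for a, b in pairs]


@pytest.fixture(scope="session")
def table2_matrix() -> GenotypeMatrix:
    """Genotypes reproducing the published temporal diversity counts.

    Mainland (12 diploids): heterozygote counts 10/11/12 and allele counts
    7/7/5 at exon2/intron2a/exon4; island (12 diploids): 7/7/4 heterozygotes
    and 5/5/2 alleles, all island alleles also present on the mainland.
    """
    genos = {
        ("exon2", "mainland"): _het_pairs("e", [(1, 2), (1, 3), (2, 3), (4, 5),
                                                (6, 7), (1, 4), (2, 5), (3, 6),
                                                (4, 7), (5, 6), (1, 1), (2, 2)]),
        ("exon2", "island"): _het_pairs("e", [(1, 2), (2, 3), (3, 4), (4, 5),
                                              (1, 3), (2, 4), (1, 5), (1, 1),
                                              (2, 2), (3, 3), (4, 4), (5, 5)]),
        ("intron2a", "mainland"): _het_pairs("i", [(1, 2), (2, 3), (3, 4), (4, 5),
                                                   (5, 6), (6, 7), (1, 3), (2, 4),
                                                   (3, 5), (4, 6), (5, 7), (1, 1)]),
        ("intron2a", "island"): _het_pairs("i", [(1, 2), (2, 3), (3, 4), (4, 5),
                                                 (1, 3), (2, 4), (1, 5), (1, 1),
                                                 (2, 2), (3, 3), (4, 4), (5, 5)]),
        ("exon4", "mainland"): _het_pairs("x", [(1, 2), (2, 3), (3, 4), (4, 5),
                                                (1, 3), (2, 4), (3, 5), (1, 4),
                                                (2, 5), (1, 5), (1, 2), (2, 3)]),
        ("exon4", "island"): _het_pairs("x", [(1, 2), (1, 2), (1, 2), (1, 2),
                                              (1, 1), (1, 1), (1, 1), (1, 1),
                                              (2, 2), (2, 2), (2, 2), (2, 2)]),
    }
    matrix = GenotypeMatrix()
    for period, age, tag in (("mainland", 20_000.0, "M"), ("island", 5_000.0, "W")):
        for i in range(12):
            matrix.samples.append(
                SampleRecord(sample_id=f"{tag}{i:02d}", age_cal_bp=age)
            )
    for (locus, period), pairs in genos.items():
        tag = "M" if period == "mainland" else "W"
        for i, (a1, a2) in enumerate(pairs):
            matrix.set_genotype(f"{tag}{i:02d}", locus, a1, a2)
    return matrix


@pytest.fixture()
def tag_scheme() -> TagScheme:
    return TagScheme.default(8)


@pytest.fixture(scope="session")
def primer_pairs() -> dict[str, tuple[str, str]]:
    rng = np.random.default_rng(7)
    return {loc: (random_sequence(12, rng), random_sequence(12, rng)) for loc in LOCI}
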