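"""Core domain types for temporal MHC amplicon genotyping.

The objects here are deliberately thin: an allele is a named nucleotide
sequence at a locus, a genotype is an unordered pair of allele ids, and a
sample carries a calibrated radiocarbon age used to assign it to a temporal
period (pre-isolation mainland vs. post-isolation island).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

VALID_BASES = frozenset("ACGT")

MAINLAND = "mainland"
ISLAND = "island"
EXCLUDED = "excluded"

#: Default locus set: fragment lengths of the three analysed DQA fragments.
DEFAULT_LOCI = {"exon2": 99, "intron2a": 89, "exon4": 92}


@dataclass(frozen=True)
class SampleRecord:
    """One dated specimen.

    ``age_cal_bp`` is the calibrated age in years before present; ages
    printed as bounds (e.g. ">=49 000") are stored at their bound value with
    ``age_is_bound`` set.
    """

    sample_id: str
    age_cal_bp: float
    age_is_bound: bool = False
    region: str = ""
    material: str = ""

    def __post_init__(self) -> None:
        if self.age_cal_bp < 0:
            raise ValueError(f"negative age for sample {self.sample_id!r}")


@dataclass(frozen=True)
class TemporalAssignment:
    """Two-threshold rule splitting samples into temporal periods.

    A sample is *mainland* iff strictly older than ``mainland_min_age``
    (default 13 cal ka, the pre-isolation continental population), *island*
    iff strictly younger than ``island_max_age`` (default 10 cal ka, after
    sea-level rise isolated the island), otherwise *excluded*.
    """

    mainland_min_age: float = 13_000.0
    island_max_age: float = 10_000.0

    def __post_init__(self) -> None:
        if not self.mainland_min_age > self.island_max_age:
            raise ValueError("mainland_min_age must exceed island_max_age")

    def period(self, age_cal_bp: float) -> str:
        if age_cal_bp > self.mainland_min_age:
            return MAINLAND
        if age_cal_bp < self.island_max_age:
            return ISLAND
        return EXCLUDED


def assign_periods(
    samples: Iterable[SampleRecord],
    rule: TemporalAssignment | None = None,
) -> dict[str, str]:
    """Label each sample mainland/island/excluded by its calibrated age.

    Returns a mapping sample_id -> period; input order and ids are never
    altered (labels only).
    """
    rule = rule or TemporalAssignment()
    return {s.sample_id: rule.period(s.age_cal_bp) for s in samples}


@dataclass(frozen=True)
class Allele:
    allele_id: str
    locus_id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        bad = set(seq) - VALID_BASES
        if bad:
            raise ValueError(
                f"allele {self.locus_id}|{self.allele_id}: non-ACGT "
                f"characters {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", seq)


class AlleleCatalog:
    """Named nucleotide alleles per locus.

    The catalog is the unit counted by N_A, rarefaction, and the coalescent
    retention statistic.  Loci carry expected fragment lengths; an allele
    whose sequence length disagrees with its locus is rejected.
    """

    def __init__(self, loci: Mapping[str, int] | None = None) -> None:
        self.loci: dict[str, int] = dict(loci) if loci else {}
        self._alleles: dict[tuple[str, str], Allele] = {}

    def add_locus(self, locus_id: str, length: int) -> None:
        self.loci[locus_id] = int(length)

    def add(self, allele: Allele) -> None:
        if allele.locus_id not in self.loci:
            raise KeyError(f"unknown locus {allele.locus_id!r}")
        expected = self.loci[allele.locus_id]
        if expected and len(allele.sequence) != expected:
            raise ValueError(
                f"allele {allele.locus_id}|{allele.allele_id}: length "
                f"{len(allele.sequence)} != expected {expected}"
            )
        key = (allele.locus_id, allele.allele_id)
        if key in self._alleles:
            raise ValueError(f"duplicate allele id {allele.locus_id}|{allele.allele_id}")
        self._alleles[key] = allele

    def get(self, locus_id: str, allele_id: str) -> Allele:
        return self._alleles[(locus_id, allele_id)]

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self._alleles

    def alleles(self, locus_id: str | None = None) -> list[Allele]:
        if locus_id is None:
            return list(self._alleles.values())
        return [a for a in self._alleles.values() if a.locus_id == locus_id]

    def __len__(self) -> int:
        return len(self._alleles)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AlleleCatalog):
            return NotImplemented
        return self.loci == other.loci and self._alleles == other._alleles


@dataclass
class GenotypeMatrix:
    """Per-sample, per-locus unordered diploid allele calls.

    ``entries`` maps (sample_id, locus_id) to a frozenset of 1 or 2 allele
    ids (homozygotes hold a single id).  A failed locus is simply absent.
    No entry ever holds more than two alleles: that is the single-locus
    sanity check of the original scoring.
    """

    entries: dict[tuple[str, str], frozenset[str]] = field(default_factory=dict)
    samples: list[SampleRecord] = field(default_factory=list)

    def set_genotype(
        self, sample_id: str, locus_id: str, allele1: str, allele2: str | None = None
    ) -> None:
        pair = frozenset([allele1, allele2 or allele1])
        if len(pair) > 2:  # unreachable with two args; guards future edits
            raise ValueError("more than two alleles per locus")
        self.entries[(sample_id, locus_id)] = pair

    def genotype(self, sample_id: str, locus_id: str) -> frozenset[str] | None:
        return self.entries.get((sample_id, locus_id))

    def is_heterozygote(self, sample_id: str, locus_id: str) -> bool | None:
        g = self.genotype(sample_id, locus_id)
        return None if g is None else len(g) == 2

    def loci(self) -> list[str]:
        return sorted({loc for _, loc in self.entries})

    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def periods(self, rule: TemporalAssignment | None = None) -> dict[str, str]:
        return assign_periods(self.samples, rule)

    def allele_counts(self, locus_id: str, sample_ids: Iterable[str]) -> dict[str, int]:
        """Gene-copy counts per allele at a locus, over the given samples."""
        counts: dict[str, int] = {}
        for sid in sample_ids:
            g = self.entries.get((sid, locus_id))
            if g is None:
                continue
            pair = sorted(g)
            if len(pair) == 1:
                pair = pair * 2
            for a in pair:
                counts[a] = counts.get(a, 0) + 1
        return counts

    def validate_against(self, catalog: AlleleCatalog) -> None:
        for (sid, loc), pair in self.entries.items():
            for aid in pair:
                if (loc, aid) not in catalog:
                    raise ValueError(
                        f"sample {sid}, locus {loc}: allele {aid!r} not in catalog"
                    )
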