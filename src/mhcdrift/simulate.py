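"""Synthetic-data generation with known ground truth.

Every downstream stage (demultiplexing, allele calling, diversity,
selection, drift scan) is testable against data built here: diploid
genotypes drawn from given allele frequencies, Wright–Fisher drift between
two temporal strata, and tagged amplicon reads carrying the artefacts an
ancient-DNA pipeline must filter — allelic dropout in single PCR
replicates, per-base sequencing error, and post-mortem deamination
(C→T / G→A) damage.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import AlleleCatalog, GenotypeMatrix, SampleRecord

_BASES = "ACGT"


@dataclass
class ReadErrorModel:
    """Error process for one PCR replicate of one sample/locus.

    per_base_error    substitution probability per sequenced base
    deamination_rate  probability a read carries exactly one C→T (or G→A)
                      damage artefact at a uniformly chosen eligible site
    ado_prob          probability each allele independently drops out of a
                      replicate (allelic dropout)
    depth_mean        expected read count per replicate (Poisson)
    """

    per_base_error: float = 0.0
    deamination_rate: float = 0.0
    ado_prob: float = 0.0
    depth_mean: float = 100.0

    def __post_init__(self) -> None:
        for name in ("per_base_error", "deamination_rate", "ado_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


@dataclass
class TagScheme:
    """Dual 6-nt tags identifying (sample, replicate) amplicon pools.

    Every pair of tags differs at >= 2 positions so that a single
    sequencing error cannot turn one valid tag into another.
    """

    tags: list[str]
    pairing: dict[tuple[str, str], tuple[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for t in self.tags:
            if len(t) != 6 or set(t) - set(_BASES):
                raise ValueError(f"tag {t!r} is not a 6-nt ACGT sequence")
        for a, b in itertools.combinations(self.tags, 2):
            if _hamming(a, b) < 2:
                raise ValueError(f"tags {a} and {b} differ at fewer than 2 positions")

    @classmethod
    def default(cls, n_tags: int = 8) -> "TagScheme":
        """Greedy lexicographic tag design with pairwise distance >= 2."""
        chosen: list[str] = []
        for combo in itertools.product(_BASES, repeat=6):
            cand = "".join(combo)
            if all(_hamming(cand, t) >= 2 for t in chosen):
                chosen.append(cand)
                if len(chosen) == n_tags:
                    break
        if len(chosen) < n_tags:
            raise ValueError(f"cannot design {n_tags} tags at distance >= 2")
        return cls(tags=chosen)

    def assign(self, sample_ids: list[str], n_replicates: int) -> None:
        """Assign one (forward, reverse) tag pair per sample replicate."""
        pairs = list(itertools.product(self.tags, self.tags))
        needed = len(sample_ids) * n_replicates
        if needed > len(pairs):
            raise ValueError(
                f"{needed} sample-replicates exceed {len(pairs)} tag pairs"
            )
        self.pairing = {}
        it = iter(pairs)
        for sid in sample_ids:
            for rep in range(1, n_replicates + 1):
                self.pairing[next(it)] = (sid, rep)


def generate_genotypes(
    freqs_per_locus: dict[str, dict[str, float]],
    n_samples: int,
    seed: int,
    ages: list[float] | None = None,
    sample_prefix: str = "S",
) -> GenotypeMatrix:
    """Draw diploid genotypes under Hardy–Weinberg from given frequencies.

    Each gene copy is drawn independently, so the expected observed
    heterozygosity approaches 1 - sum(p^2) as samples accumulate.
    """
    rng = np.random.default_rng(seed)
    matrix = GenotypeMatrix()
    for locus, freqs in freqs_per_locus.items():
        total = sum(freqs.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"locus {locus}: frequencies sum to {total}, not 1")
    ids = [f"{sample_prefix}{i:04d}" for i in range(n_samples)]
    for i, sid in enumerate(ids):
        age = ages[i] if ages is not None else 0.0
        matrix.samples.append(SampleRecord(sample_id=sid, age_cal_bp=age))
    for locus, freqs in freqs_per_locus.items():
        names = sorted(freqs)
        p = np.array([freqs[n] for n in names])
        p = p / p.sum()
        draws = rng.choice(len(names), size=(n_samples, 2), p=p)
        for i, sid in enumerate(ids):
            matrix.set_genotype(sid, locus, names[draws[i, 0]], names[draws[i, 1]])
    return matrix


def wright_fisher_drift(
    freqs: dict[str, float], generations: int, n_e: int, rng: np.random.Generator
) -> dict[str, float]:
    """Propagate allele frequencies through multinomial drift.

    One generation resamples 2*n_e gene copies from the current
    frequencies; with zero generations the input is returned unchanged.
    """
    if generations < 0 or n_e < 1:
        raise ValueError("need generations >= 0 and n_e >= 1")
    names = sorted(freqs)
    p = np.array([freqs[n] for n in names], dtype=float)
    p = p / p.sum()
    copies = 2 * n_e
    for _ in range(generations):
        counts = rng.multinomial(copies, p)
        p = counts / copies
    return dict(zip(names, p))


def generate_temporal_dataset(
    founder_freqs: dict[str, dict[str, float]],
    n_mainland: int,
    n_island: int,
    drift_generations: int,
    n_e: int,
    seed: int,
    mainland_age: float = 20_000.0,
    island_age: float = 5_000.0,
) -> GenotypeMatrix:
    """Two temporal strata: founders, and founders after Wright–Fisher drift.

    Mainland samples are drawn from the founder frequencies; island samples
    from a drifted trajectory of the same frequencies, emulating isolation
    at reduced effective size.
    """
    rng = np.random.default_rng(seed)
    drifted = {
        locus: wright_fisher_drift(freqs, drift_generations, n_e, rng)
        for locus, freqs in founder_freqs.items()
    }
    main = generate_genotypes(
        founder_freqs, n_mainland, seed=int(rng.integers(2**31)),
        ages=[mainland_age] * n_mainland, sample_prefix="M",
    )
    # drifted frequencies may have lost alleles; drop zero-frequency entries
    drifted = {
        loc: {a: f for a, f in fr.items() if f > 0} for loc, fr in drifted.items()
    }
    isl = generate_genotypes(
        {loc: {a: f / sum(fr.values()) for a, f in fr.items()}
         for loc, fr in ((loc, fr) for loc, fr in drifted.items())},
        n_island, seed=int(rng.integers(2**31)),
        ages=[island_age] * n_island, sample_prefix="W",
    )
    merged = GenotypeMatrix()
    merged.samples = main.samples + isl.samples
    merged.entries = {**main.entries, **isl.entries}
    return merged


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _mutate_read(seq: str, model: ReadErrorModel, rng: np.random.Generator) -> str:
    out = list(seq)
    if model.per_base_error > 0:
        hits = np.nonzero(rng.random(len(out)) < model.per_base_error)[0]
        for i in hits:
            alts = [b for b in _BASES if b != out[i]]
            out[i] = alts[rng.integers(3)]
    if model.deamination_rate > 0 and rng.random() < model.deamination_rate:
        eligible = [i for i, b in enumerate(out) if b in "CG"]
        if eligible:
            i = eligible[rng.integers(len(eligible))]
            out[i] = "T" if out[i] == "C" else "A"
    return "".join(out)


def generate_reads(
    genotypes: GenotypeMatrix,
    catalog: AlleleCatalog,
    tag_scheme: TagScheme,
    primer_pairs: dict[str, tuple[str, str]],
    error_model: ReadErrorModel,
    n_replicates: int,
    seed: int,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Emit tagged amplicon reads plus a truth table.

    Read layout (sequencing orientation):
    ``forward_tag + forward_primer + fragment + revcomp(reverse_primer) +
    revcomp(reverse_tag)``.  Dropout is drawn independently per allele per
    replicate; errors per read.  The truth table records, per
    (sample, locus, replicate), the intended genotype and which alleles
    dropped out.
    """
    rng = np.random.default_rng(seed)
    sample_ids = genotypes.sample_ids()
    if not tag_scheme.pairing:
        tag_scheme.assign(sample_ids, n_replicates)
    pair_for = {v: k for k, v in tag_scheme.pairing.items()}
    for sid in sample_ids:
        for rep in range(1, n_replicates + 1):
            if (sid, rep) not in pair_for:
                raise ValueError(f"no tag pair assigned for {sid} replicate {rep}")

    reads: list[tuple[str, str]] = []
    truth_rows = []
    serial = 0
    for sid in sample_ids:
        for locus, (fwd, rev) in primer_pairs.items():
            geno = genotypes.genotype(sid, locus)
            if geno is None:
                continue
            allele_ids = sorted(geno)
            seqs = {aid: catalog.get(locus, aid).sequence for aid in allele_ids}
            for rep in range(1, n_replicates + 1):
                ftag, rtag = pair_for[(sid, rep)]
                # each physical allele copy drops out independently
                present = [
                    aid for aid in allele_ids if rng.random() >= error_model.ado_prob
                ]
                dropped = [aid for aid in allele_ids if aid not in present]
                depth = int(rng.poisson(error_model.depth_mean))
                if present:
                    which = rng.integers(len(present), size=depth)
                    for j in range(depth):
                        aid = present[which[j]]
                        frag = _mutate_read(seqs[aid], error_model, rng)
                        read = ftag + fwd + frag + _revcomp(rev) + _revcomp(rtag)
                        reads.append((f"read{serial:07d}", read))
                        serial += 1
                truth_rows.append(
                    {
                        "sample_id": sid,
                        "locus_id": locus,
                        "replicate": rep,
                        "allele1": allele_ids[0],
                        "allele2": allele_ids[-1],
                        "dropped_alleles": ";".join(dropped),
                        "n_reads": depth if present else 0,
                    }
                )
    truth = pd.DataFrame(truth_rows)
    return reads, truth
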