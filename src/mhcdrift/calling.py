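"""Replicated-amplicon genotype scoring for ancient DNA.

The scoring procedure works per sample and locus, on two independent PCR
replicates (plus an optional third for homozygote confirmation):

1. within each replicate, cluster identical reads and keep every cluster
   holding at least 5% of the replicate's reads as a candidate allele;
2. accept candidates seen in both replicates;
3. discard a candidate seen in only one replicate ("singleton") when it
   differs from an accepted candidate solely by C/T and/or G/A changes —
   the signature of post-mortem cytosine deamination — unless the same
   sequence was accepted in another sample or appears in an external
   (e.g. extant-relative) allele list, in which case it is retained;
4. samples accepted as homozygous stay provisional until a concordant
   third replicate confirms them, guarding against allelic dropout.

The dropout rate itself is estimated from replicate amplifications of
consensus heterozygotes, giving the false-negative probability
``ado_rate**k`` for ``k`` concordant homozygous replicates.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .records import GenotypeMatrix, SampleRecord
from .simulate import TagScheme, _hamming, _revcomp

HETEROZYGOTE = "heterozygote"
HOMOZYGOTE_CONFIRMED = "homozygote_confirmed"
HOMOZYGOTE_PENDING = "homozygote_pending_third_replicate"
FAILED = "failed"


@dataclass
class ClusterSet:
    """Identical-read clusters for one replicate of one sample/locus."""

    locus_id: str
    replicate_id: str
    clusters: list[tuple[str, int, float]]  # (sequence, count, frequency)
    min_frequency: float = 0.05

    def candidates(self) -> list[str]:
        return [seq for seq, _, f in self.clusters if f >= self.min_frequency - 1e-12]


@dataclass
class ConsensusGenotype:
    sample_id: str
    locus_id: str
    alleles: list[str]
    status: str
    discarded: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class AdoEstimate:
    ado_rate: float
    n_informative: int
    n_dropout_events: int
    false_negative_prob: float


def demultiplex(
    reads: Iterable[tuple[str, str]],
    tag_scheme: TagScheme,
    max_mismatch: int = 1,
    tag_len: int = 6,
) -> tuple[dict[tuple[str, int], list[str]], dict[str, int]]:
    """Sort reads by their 5' and 3' tags, tolerating ``max_mismatch``.

    A read is assigned iff each observed tag matches exactly one scheme tag
    within the mismatch tolerance and the (forward, reverse) pair is a
    registered sample/replicate.  Everything else lands in the unassigned
    counts (``no_match``, ``ambiguous``, ``unknown_pair``).  Assigned reads
    are returned with both tags stripped.
    """

    def match(observed: str) -> str | None:
        hits = [t for t in tag_scheme.tags if _hamming(observed, t) <= max_mismatch]
        return hits[0] if len(hits) == 1 else ("AMBIG" if len(hits) > 1 else None)

    groups: dict[tuple[str, int], list[str]] = {}
    unassigned = {"no_match": 0, "ambiguous": 0, "unknown_pair": 0, "too_short": 0}
    for _, seq in reads:
        if len(seq) < 2 * tag_len:
            unassigned["too_short"] += 1
            continue
        f = match(seq[:tag_len])
        r = match(_revcomp(seq[-tag_len:]))
        if f is None or r is None:
            unassigned["no_match"] += 1
            continue
        if f == "AMBIG" or r == "AMBIG":
            unassigned["ambiguous"] += 1
            continue
        key = tag_scheme.pairing.get((f, r))
        if key is None:
            unassigned["unknown_pair"] += 1
            continue
        groups.setdefault(key, []).append(seq[tag_len:-tag_len])
    return groups, unassigned


def _matches(observed: str, expected: str, max_mismatch: int) -> bool:
    return len(observed) == len(expected) and _hamming(observed, expected) <= max_mismatch


def trim_primers(
    reads: Iterable[str],
    primer_pairs: dict[str, tuple[str, str]],
    max_mismatch: int = 1,
) -> tuple[dict[str, list[str]], int]:
    """Assign reads to loci by their primers and strip the primers.

    A read belongs to a locus when it starts with the forward primer and
    ends with the reverse complement of the reverse primer, each within the
    mismatch tolerance; reads matching no locus are dropped (counted).
    """
    by_locus: dict[str, list[str]] = {loc: [] for loc in primer_pairs}
    dropped = 0
    for seq in reads:
        for locus, (fwd, rev) in primer_pairs.items():
            rc = _revcomp(rev)
            if len(seq) <= len(fwd) + len(rc):
                continue
            if _matches(seq[: len(fwd)], fwd, max_mismatch) and _matches(
                seq[-len(rc):], rc, max_mismatch
            ):
                by_locus[locus].append(seq[len(fwd): -len(rc)])
                break
        else:
            dropped += 1
    return by_locus, dropped


def cluster_replicate(
    reads: Sequence[str],
    locus_id: str = "",
    replicate_id: str = "",
    min_frequency: float = 0.05,
) -> ClusterSet:
    """Group identical reads; candidates are clusters at >= ``min_frequency``.

    The threshold is inclusive (a cluster at exactly 5% qualifies).
    Clusters are ordered by count, ties broken lexicographically, so the
    output is deterministic.
    """
    if not reads:
        raise ValueError("empty replicate: no reads to cluster")
    counts = Counter(reads)
    total = sum(counts.values())
    clusters = sorted(
        ((seq, c, c / total) for seq, c in counts.items()),
        key=lambda x: (-x[1], x[0]),
    )
    return ClusterSet(locus_id, replicate_id, clusters, min_frequency)


def differs_only_by_damage(seq: str, reference: str) -> bool:
    """True when seq differs from reference only at C/T or G/A positions.

    This is the deamination signature: every mismatch pairs C with T or G
    with A (either direction).  Identical or unequal-length sequences
    return False.
    """
    if len(seq) != len(reference) or seq == reference:
        return False
    for a, b in zip(seq, reference):
        if a != b and {a, b} not in ({"C", "T"}, {"G", "A"}):
            return False
    return True


def reconcile_replicates(
    cluster_sets: Sequence[ClusterSet],
    dataset_allele_pool: Iterable[str] = (),
    external_alleles: Iterable[str] = (),
    sample_id: str = "",
    locus_id: str = "",
) -> ConsensusGenotype:
    """Merge replicate candidate sets into a consensus genotype.

    With two replicates: shared candidates are accepted; a singleton
    (present in one replicate) that looks like deamination damage relative
    to an accepted candidate is discarded unless rescued by an identical
    accepted allele elsewhere in the run or in the external catalog (then
    retained); any other singleton is unresolved and fails the call.  With
    three replicates a simple majority (>= 2 of 3) arbitrates every
    candidate, and single-accepted-allele calls become confirmed
    homozygotes.
    """
    if len(cluster_sets) not in (2, 3):
        raise ValueError("need 2 primary replicates (plus optional third)")
    pool = set(dataset_allele_pool)
    external = set(external_alleles)
    reps = [set(cs.candidates()) for cs in cluster_sets]
    discarded: list[tuple[str, str]] = []

    if len(reps) == 3:
        tally = Counter()
        for r in reps:
            tally.update(r)
        accepted = {c for c, n in tally.items() if n >= 2}
        for c in sorted(set(tally) - accepted):
            discarded.append((c, "minority_in_three_replicates"))
        unresolved: list[str] = []
    else:
        accepted = reps[0] & reps[1]
        unresolved = []
        for s in sorted(reps[0] ^ reps[1]):
            if any(differs_only_by_damage(s, a) for a in accepted):
                if s in pool or s in external:
                    accepted = accepted | {s}  # rescued: seen elsewhere
                else:
                    discarded.append((s, "deamination_singleton"))
            else:
                unresolved.append(s)

    if unresolved:
        return ConsensusGenotype(
            sample_id, locus_id, sorted(accepted), FAILED,
            discarded + [(s, "unresolved_singleton") for s in unresolved],
        )
    if len(accepted) > 2:
        return ConsensusGenotype(
            sample_id, locus_id, sorted(accepted), FAILED,
            discarded + [("", "more_than_two_concordant_alleles")],
        )
    if len(accepted) == 2:
        return ConsensusGenotype(sample_id, locus_id, sorted(accepted), HETEROZYGOTE, discarded)
    if len(accepted) == 1:
        status = HOMOZYGOTE_CONFIRMED if len(reps) == 3 else HOMOZYGOTE_PENDING
        return ConsensusGenotype(sample_id, locus_id, sorted(accepted), status, discarded)
    return ConsensusGenotype(
        sample_id, locus_id, [], FAILED, discarded + [("", "no_concordant_candidate")]
    )


def estimate_ado(
    consensus: Iterable[ConsensusGenotype],
    per_replicate_calls: dict[tuple[str, str], list[set[str]]],
    k_concordant: int = 2,
) -> AdoEstimate:
    """Estimate the allelic-dropout rate from consensus heterozygotes.

    Each primary replicate amplification of a consensus heterozygote is
    informative; it counts as a dropout event when it shows exactly one of
    the two consensus alleles.  The false-negative probability — scoring a
    true heterozygote as homozygous in ``k_concordant`` independent
    replicates — is ``ado_rate ** k_concordant``.
    """
    informative = 0
    dropouts = 0
    for cg in consensus:
        if cg.status != HETEROZYGOTE:
            continue
        pair = set(cg.alleles)
        for rep_candidates in per_replicate_calls.get((cg.sample_id, cg.locus_id), []):
            observed = rep_candidates & pair
            if not observed:
                continue  # total amplification failure, not dropout of one allele
            informative += 1
            if len(observed) == 1:
                dropouts += 1
    if informative == 0:
        raise ValueError("no informative heterozygous amplifications")
    rate = dropouts / informative
    return AdoEstimate(
        ado_rate=rate,
        n_informative=informative,
        n_dropout_events=dropouts,
        false_negative_prob=rate**k_concordant,
    )


def call_genotypes(
    reads: Iterable[tuple[str, str]],
    tag_scheme: TagScheme,
    primer_pairs: dict[str, tuple[str, str]],
    samples: dict[str, SampleRecord] | None = None,
    external_alleles: Iterable[str] = (),
    min_frequency: float = 0.05,
    max_tag_mismatch: int = 1,
    max_primer_mismatch: int = 1,
    catalog=None,
) -> tuple[GenotypeMatrix, list[ConsensusGenotype], AdoEstimate | None]:
    """Run the full scoring pipeline: demux -> trim -> cluster -> reconcile.

    The cross-sample rescue pool for the damage filter is built from
    candidates concordant across a sample's own replicates, excluding the
    sample under evaluation.  Returns the called matrix (heterozygotes and
    confirmed or pending homozygotes; failures omitted), all consensus
    records, and the dropout estimate (None when no heterozygote was
    called).
    """
    groups, _ = demultiplex(reads, tag_scheme, max_tag_mismatch)
    # (sample, locus) -> {replicate: candidate set}
    per_rep: dict[tuple[str, str], dict[int, set[str]]] = {}
    for (sid, rep), grp in groups.items():
        by_locus, _ = trim_primers(grp, primer_pairs, max_primer_mismatch)
        for locus, frags in by_locus.items():
            if not frags:
                continue
            cs = cluster_replicate(frags, locus, f"{sid}.{rep}", min_frequency)
            per_rep.setdefault((sid, locus), {})[rep] = set(cs.candidates())

    # first pass: concordant candidates per sample feed the rescue pool
    concordant: dict[tuple[str, str], set[str]] = {}
    for key, reps in per_rep.items():
        primary = [reps[r] for r in sorted(reps)][:2]
        if len(primary) == 2:
            concordant[key] = primary[0] & primary[1]

    consensus: list[ConsensusGenotype] = []
    matrix = GenotypeMatrix()
    per_rep_lists: dict[tuple[str, str], list[set[str]]] = {}
    for (sid, locus), reps in sorted(per_rep.items()):
        ordered = [reps[r] for r in sorted(reps)]
        per_rep_lists[(sid, locus)] = ordered[:2]
        if len(ordered) < 2:
            consensus.append(ConsensusGenotype(sid, locus, [], FAILED,
                                               [("", "single_replicate")]))
            continue
        pool = set()
        for (osid, oloc), acc in concordant.items():
            if osid != sid and oloc == locus:
                pool |= acc
        sets = [
            ClusterSet(locus, str(i), [(s, 1, 1.0) for s in cands], 0.0)
            for i, cands in enumerate(ordered[:3])
        ]
        cg = reconcile_replicates(sets, pool, external_alleles, sid, locus)
        consensus.append(cg)
        if cg.status != FAILED and cg.alleles:
            a = cg.alleles
            if catalog is not None:
                by_seq = {al.sequence: al.allele_id for al in catalog.alleles(locus)}
                a = [by_seq.get(s, s) for s in a]
            matrix.set_genotype(sid, locus, a[0], a[-1])
    if samples:
        seen = {sid for sid, _ in matrix.entries}
        matrix.samples = [samples[sid] for sid in sorted(seen) if sid in samples]
    ado = None
    try:
        ado = estimate_ado(consensus, per_rep_lists)
    except ValueError:
        pass
    return matrix, consensus, ado
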