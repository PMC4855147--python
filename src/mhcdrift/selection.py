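"""Synonymous/non-synonymous selection scans on codon alignments.

Implements the Nei–Gojobori (1986) counting method with Jukes–Cantor
multiple-hit correction and codon-based Z-tests of positive selection,
neutrality, and purifying selection.  Antigen-binding-region (ABR) codons
can be masked in or out, so a fragment can be scanned whole, ABR-only, or
non-ABR-only.

Counting conventions (all exposed to tests):

* every single-base change at a codon position carries weight 1/3 of a
  site; changes producing stop codons are excluded from both the
  synonymous and non-synonymous site totals, so S + N can fall below
  3 x codon_count;
* codons differing at k positions are scored by averaging over all k!
  substitution orderings, dropping pathways that pass through a stop;
* per-pair proportions pS = Sd / S and pN = Nd / N use site counts
  averaged over the two sequences;
* standard errors come from a seeded codon-column bootstrap, and the
  Z-test variance uses the bootstrap of the difference d_N - d_S jointly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from Bio.Data.CodonTable import unambiguous_dna_by_id

_TABLE = unambiguous_dna_by_id[1]
_AA = dict(_TABLE.forward_table)
_STOPS = set(_TABLE.stop_codons)
_BASES = "ACGT"

POSITIVE = "positive"
NEUTRAL = "neutral"
PURIFYING = "purifying"


class SaturationError(ValueError):
    """Raised when a proportion of differences is beyond the JC domain."""


@dataclass
class CodonAlignment:
    """In-frame nucleotide alignment with an optional ABR codon mask.

    ``abr_mask`` holds 1-based codon indices designated antigen-binding.
    """

    names: list[str]
    sequences: list[str]
    abr_mask: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError("sequences have unequal lengths")
        (length,) = lengths or {0}
        if length % 3:
            raise ValueError(f"alignment length {length} is not a multiple of 3")
        for name, seq in zip(self.names, self.sequences):
            for i in range(0, len(seq), 3):
                if seq[i : i + 3] in _STOPS:
                    raise ValueError(
                        f"internal stop codon at codon {i // 3 + 1} in {name}"
                    )
        bad = set(self.abr_mask) - set(range(1, self.codon_count + 1))
        if bad:
            raise ValueError(f"ABR mask indices outside alignment: {sorted(bad)}")

    @property
    def codon_count(self) -> int:
        return len(self.sequences[0]) // 3 if self.sequences else 0

    @property
    def non_abr_mask(self) -> frozenset[int]:
        return frozenset(range(1, self.codon_count + 1)) - self.abr_mask

    @classmethod
    def from_catalog(cls, catalog, locus_id: str, abr_mask: Iterable[int] = ()) -> "CodonAlignment":
        alleles = sorted(catalog.alleles(locus_id), key=lambda a: a.allele_id)
        return cls(
            names=[a.allele_id for a in alleles],
            sequences=[a.sequence for a in alleles],
            abr_mask=frozenset(abr_mask),
        )


def _codon_site_counts(codon: str) -> tuple[float, float]:
    """(synonymous, non-synonymous) site weights of one codon.

    Each of the 9 single-base changes weighs 1/3 site; changes to stop
    codons are excluded entirely.
    """
    if codon in _STOPS:
        raise ValueError(f"stop codon {codon} has no site counts")
    aa = _AA[codon]
    s = n = 0.0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if alt in _STOPS:
                continue
            if _AA[alt] == aa:
                s += 1 / 3
            else:
                n += 1 / 3
    return s, n


def ng_site_counts(sequence: str, mask: Iterable[int] | None = None) -> tuple[float, float]:
    """Total synonymous and non-synonymous sites of an in-frame sequence."""
    seq = sequence.upper()
    if len(seq) % 3:
        raise ValueError("sequence length is not a multiple of 3")
    indices = set(mask) if mask is not None else None
    s_total = n_total = 0.0
    for c in range(len(seq) // 3):
        if indices is not None and c + 1 not in indices:
            continue
        codon = seq[3 * c : 3 * c + 3]
        if codon in _STOPS:
            raise ValueError(f"internal stop codon at codon {c + 1}")
        s, n = _codon_site_counts(codon)
        s_total += s
        n_total += n
    return s_total, n_total


def _codon_pair_differences(a: str, b: str) -> tuple[float, float] | None:
    """Average (synonymous, non-synonymous) differences between two codons.

    Averages over all orderings of the differing positions, excluding
    pathways through stop codons.  Returns None when every pathway is
    blocked by a stop.
    """
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return 0.0, 0.0
    syn_sum = nsyn_sum = 0.0
    n_paths = 0
    for order in itertools.permutations(diff):
        cur = a
        syn = nsyn = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if nxt in _STOPS:
                ok = False
                break
            if _AA[cur] == _AA[nxt]:
                syn += 1
            else:
                nsyn += 1
            cur = nxt
        if ok:
            syn_sum += syn
            nsyn_sum += nsyn
            n_paths += 1
    if n_paths == 0:
        return None
    return syn_sum / n_paths, nsyn_sum / n_paths


@dataclass
class PairwiseNG:
    sd: float  # synonymous differences
    nd: float  # non-synonymous differences
    s_sites: float  # synonymous sites, averaged over the pair
    n_sites: float
    p_s: float
    p_n: float
    skipped_codons: int


def _pair_codon_arrays(a: str, b: str) -> tuple[np.ndarray, ...]:
    """Per-codon (sd, nd, s_sites, n_sites, included) arrays for a pair."""
    n_codons = len(a) // 3
    sd = np.zeros(n_codons)
    nd = np.zeros(n_codons)
    ss = np.zeros(n_codons)
    nn = np.zeros(n_codons)
    included = np.ones(n_codons, dtype=bool)
    for c in range(n_codons):
        ca, cb = a[3 * c : 3 * c + 3], b[3 * c : 3 * c + 3]
        d = _codon_pair_differences(ca, cb)
        if d is None:
            included[c] = False
            continue
        sd[c], nd[c] = d
        sa, na = _codon_site_counts(ca)
        sb, nb = _codon_site_counts(cb)
        ss[c] = (sa + sb) / 2
        nn[c] = (na + nb) / 2
    return sd, nd, ss, nn, included


def ng_pairwise(seq_a: str, seq_b: str, mask: Iterable[int] | None = None) -> PairwiseNG:
    """Nei–Gojobori proportions of synonymous/non-synonymous differences."""
    a, b = seq_a.upper(), seq_b.upper()
    if len(a) != len(b) or len(a) % 3:
        raise ValueError("sequences must be equal-length and in frame")
    sd, nd, ss, nn, inc = _pair_codon_arrays(a, b)
    keep = np.ones(len(sd), dtype=bool)
    if mask is not None:
        keep[:] = False
        keep[[i - 1 for i in mask]] = True
    skipped = int((keep & ~inc).sum())
    inc = inc & keep
    s_sites = float(ss[inc].sum())
    n_sites = float(nn[inc].sum())
    s_d = float(sd[inc].sum())
    n_d = float(nd[inc].sum())
    return PairwiseNG(
        sd=s_d, nd=n_d, s_sites=s_sites, n_sites=n_sites,
        p_s=s_d / s_sites if s_sites else 0.0,
        p_n=n_d / n_sites if n_sites else 0.0,
        skipped_codons=skipped,
    )


def jukes_cantor(p: float) -> float:
    """JC69 distance d = -(3/4) ln(1 - 4p/3); undefined at p >= 3/4."""
    if p < 0:
        raise ValueError("proportion of differences cannot be negative")
    if p >= 0.75:
        raise SaturationError(f"p = {p} is saturated (>= 3/4)")
    return -0.75 * np.log1p(-4.0 * p / 3.0)


def _jc_array(p: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        d = -0.75 * np.log1p(-4.0 * p / 3.0)
    d[p >= 0.75] = np.nan
    return d


@dataclass
class DnDsResult:
    d_n: float
    d_s: float
    se_d_n: float
    se_d_s: float
    se_diff: float
    ratio: float
    n_pairs: int
    n_codons: int

    @property
    def z(self) -> float:
        if self.se_diff == 0:
            return 0.0
        return (self.d_n - self.d_s) / self.se_diff


def mean_dnds(
    sequences: Sequence[str],
    mask: Iterable[int] | None = None,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> DnDsResult:
    """Mean pairwise JC-corrected d_N and d_S with codon-bootstrap SEs.

    Distances are averaged over all unordered sequence pairs, restricted to
    the masked codons.  SEs resample codon columns with replacement; the
    variance of d_N - d_S is taken from the joint bootstrap, not from the
    marginal SEs in quadrature.
    """
    seqs = [s.upper() for s in sequences]
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    n_codons_total = len(seqs[0]) // 3
    cols = sorted(mask) if mask is not None else list(range(1, n_codons_total + 1))
    if not cols:
        raise ValueError("mask selects no codons")
    col_idx = np.array([c - 1 for c in cols])

    pairs = list(itertools.combinations(range(len(seqs)), 2))
    n_p, n_c = len(pairs), len(cols)
    SD = np.zeros((n_p, n_c))
    ND = np.zeros((n_p, n_c))
    SS = np.zeros((n_p, n_c))
    NN = np.zeros((n_p, n_c))
    for k, (i, j) in enumerate(pairs):
        sd, nd, ss, nn, inc = _pair_codon_arrays(seqs[i], seqs[j])
        use = inc[col_idx]
        SD[k] = np.where(use, sd[col_idx], 0.0)
        ND[k] = np.where(use, nd[col_idx], 0.0)
        SS[k] = np.where(use, ss[col_idx], 0.0)
        NN[k] = np.where(use, nn[col_idx], 0.0)

    def point(weights: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        # weights: (n_c,) or (n_c, B) codon multiplicities
        s_d = SD @ weights
        n_d = ND @ weights
        s_s = SS @ weights
        n_s = NN @ weights
        with np.errstate(invalid="ignore", divide="ignore"):
            p_s = np.where(s_s > 0, s_d / np.maximum(s_s, 1e-300), 0.0)
            p_n = np.where(n_s > 0, n_d / np.maximum(n_s, 1e-300), 0.0)
        return _jc_array(p_n).mean(axis=0), _jc_array(p_s).mean(axis=0)

    d_n, d_s = point(np.ones(n_c))
    d_n, d_s = float(d_n), float(d_s)

    rng = np.random.default_rng(seed)
    draws = rng.integers(0, n_c, size=(n_bootstrap, n_c))
    weights = np.zeros((n_c, n_bootstrap))
    for b in range(n_bootstrap):
        weights[:, b] = np.bincount(draws[b], minlength=n_c)
    dn_b, ds_b = point(weights)
    se_dn = float(np.nanstd(dn_b, ddof=1))
    se_ds = float(np.nanstd(ds_b, ddof=1))
    se_diff = float(np.nanstd(dn_b - ds_b, ddof=1))

    if d_n == 0:
        ratio = 0.0
    elif d_s == 0:
        ratio = float("nan")  # undefined: non-synonymous change with no synonymous
    else:
        ratio = d_n / d_s
    return DnDsResult(d_n, d_s, se_dn, se_ds, se_diff, ratio, n_p, n_c)


@dataclass
class ZTestResult:
    hypothesis: str
    z: float
    p: float


def z_test(d_n: float, d_s: float, se_diff: float, hypothesis: str) -> ZTestResult:
    """Codon-based Z-test of selection against the normal reference.

    positive:  H1 d_N > d_S, one-tailed; p reported as 1 when Z <= 0
    purifying: H1 d_N < d_S, one-tailed, statistic reported as -Z;
               p reported as 1 when Z >= 0
    neutral:   H1 d_N != d_S, two-tailed
    The p = 1 convention for a statistic contradicting the one-sided
    alternative matches how such tables are conventionally printed.
    """
    if hypothesis not in (POSITIVE, NEUTRAL, PURIFYING):
        raise ValueError(f"unknown hypothesis {hypothesis!r}")
    if se_diff < 0:
        raise ValueError("se_diff must be non-negative")
    if se_diff == 0:
        z = 0.0
    else:
        z = (d_n - d_s) / se_diff
    if hypothesis == POSITIVE:
        p = 1.0 if z <= 0 else float(stats.norm.sf(z))
        return ZTestResult(POSITIVE, z, p)
    if hypothesis == PURIFYING:
        p = 1.0 if z >= 0 else float(stats.norm.cdf(z))
        return ZTestResult(PURIFYING, -z, p)
    p = 1.0 if z == 0 else float(2 * stats.norm.sf(abs(z)))
    return ZTestResult(NEUTRAL, z, min(p, 1.0))


def selection_scan(
    alignment: CodonAlignment,
    regions: dict[str, Iterable[int] | None] | None = None,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Tabulate d_N, d_S, d_N/d_S and the three Z-tests per region.

    Default regions: the whole fragment plus, when an ABR mask is present,
    the ABR and non-ABR partitions.
    """
    if regions is None:
        regions = {"all": None}
        if alignment.abr_mask:
            regions["ABR"] = alignment.abr_mask
            regions["non-ABR"] = alignment.non_abr_mask
    rows = []
    for name, mask in regions.items():
        r = mean_dnds(alignment.sequences, mask, n_bootstrap, seed)
        tests = {
            h: z_test(r.d_n, r.d_s, r.se_diff, h)
            for h in (POSITIVE, NEUTRAL, PURIFYING)
        }
        rows.append(
            {
                "region": name,
                "n_codons": r.n_codons,
                "d_n": r.d_n, "se_d_n": r.se_d_n,
                "d_s": r.d_s, "se_d_s": r.se_d_s,
                "dn_ds": r.ratio,
                "z_positive": tests[POSITIVE].z, "p_positive": tests[POSITIVE].p,
                "z_neutral": tests[NEUTRAL].z, "p_neutral": tests[NEUTRAL].p,
                "z_purifying": tests[PURIFYING].z, "p_purifying": tests[PURIFYING].p,
            }
        )
    return pd.DataFrame(rows)
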