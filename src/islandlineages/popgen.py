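"""Frequency tables, diversity, Tajima's D, Fst matrices, AMOVA, NJ trees.

The fixation index is computed throughout as the one-level AMOVA ratio
``Fst = Va / (Va + Vw)``, where ``Va`` and ``Vw`` are the among-group and
within-group variance components of the squared inter-haplotype distance
decomposition (Excoffier, Smouse & Quattro 1992).  Permutation P-values
use the ``(b + 1)/(m + 1)`` estimator so that a finite number of
permutations never yields P = 0.  Negative variance-component estimates
are reported as computed, not truncated.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .core_io import (
    HVS1_SEQUENCED,
    IslandLineagesError,
    MtSample,
    RegionSpec,
    StrProfile,
    YFILER_SINGLE_COPY_LOCI,
)

__all__ = [
    "FreqTable",
    "DiversityResult",
    "NeutralityResult",
    "DistanceMatrix",
    "AmovaResult",
    "SampleSizeError",
    "UndefinedStatisticError",
    "frequency_table",
    "gene_diversity",
    "tajimas_d",
    "tajimas_d_from_summaries",
    "label_distance_matrix",
    "str_profile_distance_matrix",
    "mt_hvs1_distance_matrix",
    "amova_one_level",
    "fst_from_components",
    "pairwise_fst",
    "differentiation_test",
    "nj_tree",
]


class SampleSizeError(IslandLineagesError, ValueError):
    """Too few samples/groups for the requested statistic."""


class UndefinedStatisticError(IslandLineagesError, ValueError):
    """The statistic is undefined on this input (e.g. S = 0)."""


# --------------------------------------------------------------------------
# Frequency table and diversity
# --------------------------------------------------------------------------

@dataclass
class FreqTable:
    """Haplogroup-by-population counts with percentages (2 decimals)."""

    counts: pd.DataFrame
    percent: pd.DataFrame
    n: pd.Series


def frequency_table(
    assignments: Mapping[str, str],
    group_map: Mapping[str, str],
) -> FreqTable:
    """Direct-counting frequency table.

    ``assignments`` maps sample_id -> haplogroup, ``group_map`` maps
    sample_id -> population.  Every sample must have a group; empty groups
    are excluded with a warning.
    """
    missing = set(assignments) - set(group_map)
    if missing:
        raise SampleSizeError(f"samples without a group: {sorted(missing)[:5]}")
    df = pd.DataFrame(
        {
            "haplogroup": [assignments[s] for s in assignments],
            "population": [group_map[s] for s in assignments],
        }
    )
    empty = set(group_map.values()) - set(df["population"])
    if empty:
        warnings.warn(f"empty populations excluded: {sorted(empty)}")
    counts = (
        df.groupby(["haplogroup", "population"]).size().unstack(fill_value=0).sort_index()
    )
    counts = counts[sorted(counts.columns)]
    n = counts.sum(axis=0)
    percent = (100.0 * counts / n).round(2)
    return FreqTable(counts, percent, n)


@dataclass(frozen=True)
class DiversityResult:
    H: float
    sd: float
    n: int


def gene_diversity(counts: Sequence[int]) -> DiversityResult:
    """Nei's unbiased gene diversity with its standard deviation.

    ``H = n/(n-1) * (1 - sum p_i^2)``; the variance follows Nei (1987,
    eq. 8.12).
    """
    counts = [int(c) for c in counts if c > 0]
    n = sum(counts)
    if n < 2:
        raise SampleSizeError(f"gene diversity needs n >= 2, got n = {n}")
    p = np.asarray(counts, dtype=float) / n
    sum2 = float(np.sum(p**2))
    sum3 = float(np.sum(p**3))
    h = n / (n - 1) * (1.0 - sum2)
    var = (2.0 / (n * (n - 1))) * (2.0 * (n - 2) * (sum3 - sum2**2) + sum2 - sum2**2)
    return DiversityResult(h, math.sqrt(max(var, 0.0)), n)


# --------------------------------------------------------------------------
# Tajima's D
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NeutralityResult:
    D: float
    S: int
    pi: float
    p_band: str


def _tajima_constants(n: int) -> tuple[float, float]:
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return e1, e2


def _tajima_p_band(D: float, n: int) -> str:
    """Significance band from Tajima's (1989) beta approximation."""
    a1 = sum(1.0 / i for i in range(1, n))
    _, e2 = _tajima_constants(n)
    dmin = (2.0 / n - 1.0 / a1) / math.sqrt(e2)
    dmax = ((n + 1) / (2.0 * n) - 1.0 / a1) / math.sqrt(e2)
    # Generalised beta on (dmin, dmax) with mean 0 and variance 1.
    alpha = -(1.0 + dmin * dmax) * dmax / (dmax - dmin)
    beta = (1.0 + dmin * dmax) * dmin / (dmax - dmin)
    if not (alpha > 0 and beta > 0):
        return "n/a"
    x = (D - dmin) / (dmax - dmin)
    cdf = sp_stats.beta.cdf(min(max(x, 0.0), 1.0), alpha, beta)
    p = 2.0 * min(cdf, 1.0 - cdf)
    if p < 0.01:
        return "P < 0.01"
    if p < 0.05:
        return "P < 0.05"
    if p < 0.10:
        return "0.05 < P < 0.10"
    return "P > 0.10"


def tajimas_d(sequences: Sequence[str]) -> NeutralityResult:
    """Tajima's D over equal-length aligned sequences.

    ``D = (pi - S/a1) / sqrt(e1*S + e2*S*(S-1))`` with the 1989 constants;
    raises when there are no segregating sites.
    """
    n = len(sequences)
    if n < 4:
        raise SampleSizeError(f"Tajima's D needs >= 4 sequences, got {n}")
    length = len(sequences[0])
    if any(len(s) != length for s in sequences):
        raise SampleSizeError("sequences must cover the same region (equal lengths)")
    arr = np.frombuffer("".join(sequences).encode(), dtype="S1").reshape(n, length)
    segregating = [j for j in range(length) if len(set(arr[:, j].tobytes())) > 1]
    S = len(segregating)
    pairs = n * (n - 1) // 2
    diffs = 0
    for i, j in itertools.combinations(range(n), 2):
        diffs += int(np.count_nonzero(arr[i] != arr[j]))
    pi = diffs / pairs
    return tajimas_d_from_summaries(S, pi, n)


def tajimas_d_from_summaries(S: int, pi: float, n: int) -> NeutralityResult:
    """Tajima's D from the segregating-site count and mean pairwise diversity."""
    if n < 4:
        raise SampleSizeError(f"Tajima's D needs n >= 4, got {n}")
    if S == 0:
        raise UndefinedStatisticError("Tajima's D is undefined when S = 0")
    a1 = sum(1.0 / i for i in range(1, n))
    e1, e2 = _tajima_constants(n)
    D = (pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))
    return NeutralityResult(D, S, pi, _tajima_p_band(D, n))


# --------------------------------------------------------------------------
# Distances
# --------------------------------------------------------------------------

def label_distance_matrix(labels: Sequence) -> np.ndarray:
    """Identity (0/1) distance between categorical lineage labels."""
    arr = np.asarray(labels, dtype=object)
    return (arr[:, None] != arr[None, :]).astype(float)


def str_profile_distance_matrix(
    profiles: Sequence[StrProfile],
    mode: str = "differing_loci",
) -> np.ndarray:
    """Pairwise Y-STR distances over the single-copy loci.

    ``differing_loci`` counts loci with unequal repeat numbers (an Fst-like
    haplotypic distance); ``squared_steps`` sums squared repeat differences
    (Rst-like).
    """
    vecs = np.asarray([p.vector(YFILER_SINGLE_COPY_LOCI) for p in profiles], dtype=float)
    diff = vecs[:, None, :] - vecs[None, :, :]
    if mode == "differing_loci":
        return np.count_nonzero(diff, axis=2).astype(float)
    if mode == "squared_steps":
        return np.sum(diff**2, axis=2)
    raise ValueError(f"unknown Y-STR distance mode {mode!r}")


def mt_hvs1_distance_matrix(
    samples: Sequence[MtSample],
    region: RegionSpec = HVS1_SEQUENCED,
) -> np.ndarray:
    """Pairwise nucleotide differences between HVS-1 haplotypes
    (symmetric difference of the variant sets restricted to the region)."""
    restricted = [frozenset(v for v in s.variants if v.position in region) for s in samples]
    n = len(restricted)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = len(restricted[i] ^ restricted[j])
    return d


# --------------------------------------------------------------------------
# AMOVA
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AmovaResult:
    """One-level AMOVA variance decomposition with permutation P."""

    va: float
    vw: float
    fst: float
    p: float
    n_perm: int

    @property
    def total(self) -> float:
        return self.va + self.vw


def fst_from_components(va: float, vw: float) -> float:
    """Fixation index from among/within variance components: ``Va/(Va+Vw)``."""
    total = va + vw
    if total <= 0:
        raise UndefinedStatisticError(f"non-positive total variance {total}")
    return va / total


def _amova_components(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    """Variance components from a squared-distance matrix and group codes."""
    N = len(codes)
    ssd_total = d2.sum() / (2.0 * N)
    ssd_within = 0.0
    sizes = np.zeros(n_groups)
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        sizes[g] = len(idx)
        if len(idx) > 1:
            ssd_within += d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    ssd_among = ssd_total - ssd_within
    df_among = n_groups - 1
    df_within = N - n_groups
    if df_within <= 0:
        raise SampleSizeError("AMOVA needs more samples than groups")
    ms_within = ssd_within / df_within
    n_bar = (N - np.sum(sizes**2) / N) / df_among
    va = (ssd_among / df_among - ms_within) / n_bar
    return va, ms_within


def amova_one_level(
    distances: np.ndarray,
    groups: Sequence,
    n_perm: int = 1000,
    seed: int | None = None,
    squared: bool = False,
) -> AmovaResult:
    """One-level AMOVA of a distance matrix against group labels.

    ``distances`` is an N x N matrix of inter-individual distances (squared
    internally unless ``squared=True``); ``groups`` gives each individual's
    group.  The permutation P-value is the fraction of group-label
    shuffles with Fst >= observed, with the ``(b+1)/(m+1)`` correction.
    """
    d = np.asarray(distances, dtype=float)
    d2 = d if squared else d**2
    labels = list(groups)
    uniq = sorted(set(labels), key=str)
    if len(uniq) < 2:
        raise SampleSizeError("AMOVA needs at least two groups")
    codes = np.asarray([uniq.index(g) for g in labels])
    counts = np.bincount(codes, minlength=len(uniq))
    if np.any(counts < 2):
        small = [uniq[i] for i in np.flatnonzero(counts < 2)]
        raise SampleSizeError(f"groups with fewer than 2 members: {small}")

    va, vw = _amova_components(d2, codes, len(uniq))
    total = va + vw
    fst = va / total if total != 0 else 0.0

    if n_perm <= 0:
        return AmovaResult(va, vw, fst, float("nan"), 0)
    rng = np.random.default_rng(seed)
    hits = 0
    perm = codes.copy()
    for _ in range(n_perm):
        rng.shuffle(perm)
        pva, pvw = _amova_components(d2, perm, len(uniq))
        ptotal = pva + pvw
        pfst = pva / ptotal if ptotal != 0 else 0.0
        if pfst >= fst - 1e-12:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return AmovaResult(va, vw, fst, p, n_perm)


# --------------------------------------------------------------------------
# Pairwise Fst matrix
# --------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Symmetric pairwise Fst matrix with permutation P-values."""

    labels: list[str]
    values: np.ndarray
    pvalues: np.ndarray | None = None

    def to_phylip(self) -> str:
        lines = [f"{len(self.labels)}"]
        for i, label in enumerate(self.labels):
            row = " ".join(f"{x:.6f}" for x in self.values[i])
            lines.append(f"{label:<10s} {row}")
        return "\n".join(lines) + "\n"


def _expand_population(data, mode: str) -> tuple[np.ndarray | list, Callable]:
    """Return (items, distance_matrix_builder) for one population."""
    if mode == "haplogroup_counts":
        labels = [h for h, c in sorted(data.items(), key=lambda kv: str(kv[0])) for _ in range(c)]
        return labels, label_distance_matrix
    if mode == "str_haplotypes":
        return list(data), str_profile_distance_matrix
    if mode == "hvs1_sequences":
        return list(data), mt_hvs1_distance_matrix
    raise ValueError(f"unknown pairwise_fst mode {mode!r}")


def pairwise_fst(
    populations: Mapping[str, object],
    mode: str = "haplogroup_counts",
    n_perm: int = 10000,
    seed: int | None = None,
) -> DistanceMatrix:
    """Matrix of pairwise AMOVA fixation indices between populations.

    ``populations`` maps name -> haplogroup count dict, list of
    ``StrProfile`` or list of ``MtSample`` depending on ``mode``.
    """
    names = sorted(populations)
    if len(names) < 2:
        raise SampleSizeError("pairwise Fst needs >= 2 populations")
    expanded = {}
    for name in names:
        items, builder = _expand_population(populations[name], mode)
        if len(items) < 2:
            raise SampleSizeError(f"population {name!r} has fewer than 2 members")
        expanded[name] = items
    k = len(names)
    fst = np.zeros((k, k))
    pvals = np.ones((k, k))
    ss = np.random.SeedSequence(seed)
    pair_seeds = iter(ss.generate_state(k * (k - 1) // 2))
    for i, j in itertools.combinations(range(k), 2):
        items = list(expanded[names[i]]) + list(expanded[names[j]])
        groups = [names[i]] * len(expanded[names[i]]) + [names[j]] * len(expanded[names[j]])
        dmat = builder(items)
        res = amova_one_level(dmat, groups, n_perm=n_perm, seed=int(next(pair_seeds)))
        fst[i, j] = fst[j, i] = res.fst
        pvals[i, j] = pvals[j, i] = res.p
    return DistanceMatrix(names, fst, pvals)


# --------------------------------------------------------------------------
# Exact population differentiation (Monte-Carlo)
# --------------------------------------------------------------------------

def differentiation_test(
    counts_a: Mapping[str, int],
    counts_b: Mapping[str, int],
    mc_steps: int = 10000,
    seed: int | None = None,
) -> float:
    """Raymond–Rousset-style exact differentiation test, Monte-Carlo version.

    Estimates the probability, under the hypergeometric null with fixed
    margins, of 2 x K haplotype tables no more probable than the observed
    one.  Matches the two-sided Fisher exact test on 2 x 2 tables.
    """
    haplotypes = sorted(set(counts_a) | set(counts_b))
    a = np.asarray([counts_a.get(h, 0) for h in haplotypes], dtype=int)
    b = np.asarray([counts_b.get(h, 0) for h in haplotypes], dtype=int)
    col_totals = a + b
    n_a = int(a.sum())
    n_total = int(col_totals.sum())
    if n_a == 0 or n_total - n_a == 0:
        raise SampleSizeError("both populations must be non-empty")

    log_fact = np.concatenate([[0.0], np.cumsum(np.log(np.arange(1, n_total + 1)))])

    def log_prob(top: np.ndarray) -> float:
        # product over columns of C(c_k, a_k), divided by C(N, nA)
        lp = -(log_fact[n_total] - log_fact[n_a] - log_fact[n_total - n_a])
        bottom = col_totals - top
        lp += float(
            np.sum(log_fact[col_totals] - log_fact[top] - log_fact[bottom])
        )
        return lp

    observed_lp = log_prob(a)
    pool = np.repeat(np.arange(len(haplotypes)), col_totals)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(mc_steps):
        rng.shuffle(pool)
        top = np.bincount(pool[:n_a], minlength=len(haplotypes))
        if log_prob(top) <= observed_lp + 1e-9:
            hits += 1
    return (hits + 1) / (mc_steps + 1)


# --------------------------------------------------------------------------
# Neighbor joining
# --------------------------------------------------------------------------

def nj_tree(matrix: DistanceMatrix | None = None, labels: Sequence[str] | None = None,
            distances: np.ndarray | None = None) -> str:
    """Saitou–Nei neighbor joining; returns an unrooted Newick string.

    Ties in the Q criterion are broken deterministically by label order.
    """
    if matrix is not None:
        labels = matrix.labels
        distances = matrix.values
    if labels is None or distances is None:
        raise ValueError("provide a DistanceMatrix or labels + distances")
    n = len(labels)
    if n < 3:
        raise SampleSizeError(f"neighbor joining needs >= 3 taxa, got {n}")
    d = np.asarray(distances, dtype=float).copy()
    nodes = [str(l) for l in labels]  # Newick fragments, in label-sorted tie order

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best = None
        for i, j in itertools.combinations(range(m), 2):
            q = (m - 2) * d[i, j] - r[i] - r[j]
            key = (q, nodes[i], nodes[j])
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        vi = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        vj = d[i, j] - vi
        new = f"({nodes[i]}:{vi:.6f},{nodes[j]}:{vj:.6f})"
        dk = 0.5 * (d[i] + d[j] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d = np.vstack([d[np.ix_(keep, keep)], dk[keep]])
        d = np.hstack([d, np.append(dk[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [new]

    # Resolve the last three nodes around the central vertex.
    (d01, d02, d12) = (d[0, 1], d[0, 2], d[1, 2])
    b0 = 0.5 * (d01 + d02 - d12)
    b1 = 0.5 * (d01 + d12 - d02)
    b2 = 0.5 * (d02 + d12 - d01)
    return f"({nodes[0]}:{b0:.6f},{nodes[1]}:{b1:.6f},{nodes[2]}:{b2:.6f});"
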