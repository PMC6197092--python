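"""Interpopulation differentiation and genetic distance matrices.

Population pairs are compared per locus by a permutation G-test on the
2 × k allele-count table (allele labels shuffled across the two samples,
holding totals fixed).  Across populations two matrices are built from
shared-panel frequency tables: Nei's allele-sharing distance

    D_A = 1 − (1/L) Σ_loci Σ_alleles sqrt(x_a · y_a)

and the Weir–Cockerham fixation index θ in its frequency-and-sample-size
form (alleles as sampling units, no genotypic heterozygosity term —
the form available when only published frequency tables exist for the
reference populations).  θ is a variance-components ratio accumulated
over loci and alleles; slightly negative pairwise estimates are
legitimate and are reported raw, then clamped to 0 in the distance-matrix
view that feeds ordination and tree building.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .equilibrium import g_statistic
from .str_data import AlleleLabel, DistanceMatrix, FrequencyTable, StrDataError


@dataclass(frozen=True)
class DifferentiationResult:
    locus: str
    pop_a: str
    pop_b: str
    p_value: float
    statistic: float
    n_permutations: int


def differentiation_test(
    counts_a: Mapping[AlleleLabel, int],
    counts_b: Mapping[AlleleLabel, int],
    n_permutations: int = 10_000,
    seed: int | np.random.Generator | None = None,
    locus: str = "",
    pop_a: str = "A",
    pop_b: str = "B",
) -> DifferentiationResult:
    """Permutation G-test of allele-frequency homogeneity at one locus."""
    na, nb = sum(counts_a.values()), sum(counts_b.values())
    if na == 0 or nb == 0:
        raise StrDataError("differentiation_test: zero allele observations in a population")
    alleles = sorted(set(counts_a) | set(counts_b))
    k = len(alleles)
    oa = np.array([counts_a.get(a, 0) for a in alleles], dtype=np.int64)
    ob = np.array([counts_b.get(a, 0) for a in alleles], dtype=np.int64)
    g_obs = g_statistic(np.vstack([oa, ob]))
    if k == 1:
        return DifferentiationResult(locus, pop_a, pop_b, 1.0, 0.0, 0)
    if seed is None:
        raise StrDataError("differentiation_test requires a seed")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pool = np.repeat(np.arange(k), oa + ob)
    n = na + nb
    hits = 0
    batch = max(1, min(n_permutations, 2_000_000 // max(n, 1)))
    done = 0
    while done < n_permutations:
        b = min(batch, n_permutations - done)
        order = np.argsort(rng.random((b, n)), axis=1)
        perm = pool[order]
        ca = np.zeros((b, k), dtype=np.int64)
        np.add.at(ca, (np.repeat(np.arange(b), na), perm[:, :na].ravel()), 1)
        cb = (oa + ob)[None, :] - ca
        g = _g_rows(ca, cb, na, nb)
        hits += int((g >= g_obs - 1e-12).sum())
        done += b
    p = (1 + hits) / (1 + n_permutations)
    return DifferentiationResult(locus, pop_a, pop_b, p, g_obs, n_permutations)


def _g_rows(ca: np.ndarray, cb: np.ndarray, na: int, nb: int) -> np.ndarray:
    """Row-wise G for batches of 2×k tables with fixed row totals."""
    tot = (ca + cb).astype(float)  # column margins, constant across rows
    n = na + nb
    ea = tot * (na / n)
    eb = tot * (nb / n)
    out = np.zeros(ca.shape[0])
    for obs, exp in ((ca, ea), (cb, eb)):
        nz = obs > 0
        o = obs.astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(nz & (exp > 0), o * np.log(np.where(nz, o, 1.0) / np.where(exp > 0, exp, 1.0)), 0.0)
        out += t.sum(axis=1)
    return 2.0 * out


def differentiation_all(
    counts: Mapping[str, Mapping[str, Mapping[AlleleLabel, int]]],
    loci: Sequence[str],
    n_permutations: int = 10_000,
    seed: int | None = None,
) -> list[DifferentiationResult]:
    """Pairwise per-locus differentiation tests from allele-count maps
    (``counts[pop][locus][allele]``)."""
    rng = np.random.default_rng(seed)
    out = []
    for pa, pb in itertools.combinations(sorted(counts), 2):
        for locus in loci:
            out.append(
                differentiation_test(
                    counts[pa][locus], counts[pb][locus],
                    n_permutations=n_permutations, seed=rng,
                    locus=locus, pop_a=pa, pop_b=pb,
                )
            )
    return out


# ---------------------------------------------------------------------------
# distances

def nei_da(
    fs_a: FrequencyTable, fs_b: FrequencyTable, loci: Sequence[str] | None = None
) -> float:
    """Nei's D_A allele-sharing distance over a shared locus panel.

    Alleles absent from one population contribute 0 to the square-root
    product sum, so disjoint allele sets at every locus give D_A = 1 and
    identical tables give 0.
    """
    panel = list(loci) if loci is not None else [l for l in fs_a.loci if l in fs_b.freqs]
    if not panel:
        raise StrDataError("nei_da: empty shared locus panel")
    acc = 0.0
    for locus in panel:
        fa = fs_a.freqs.get(locus, {})
        fb = fs_b.freqs.get(locus, {})
        if not fa or not fb:
            raise StrDataError(f"nei_da: locus {locus} missing from one table")
        acc += sum(math.sqrt(fa[a] * fb[a]) for a in fa.keys() & fb.keys())
    return 1.0 - acc / len(panel)


def weir_cockerham_theta(
    tables: Sequence[FrequencyTable], loci: Sequence[str] | None = None
) -> float:
    """Multi-allelic multi-locus Weir–Cockerham θ from allele frequencies
    and diploid sample sizes.

    Treats the 2n_i allele copies of each population as the sampling
    units: per locus and allele, with c_i = 2n_i, p̄ the weighted mean
    frequency and r populations,

        MSP = Σ c_i (p_i − p̄)² / (r − 1)
        MSG = Σ c_i p_i (1 − p_i) / (C − r)
        n_c = (C − Σc_i²/C) / (r − 1)

    and θ = Σ (MSP − MSG) / Σ (MSP + (n_c − 1)·MSG), both sums running
    over all alleles of all loci.  May be slightly negative when the
    populations are effectively identical.
    """
    if len(tables) < 2:
        raise StrDataError("theta needs at least 2 populations")
    panel = list(loci) if loci is not None else [
        l for l in tables[0].loci if all(l in t.freqs for t in tables)
    ]
    if not panel:
        raise StrDataError("theta: empty shared locus panel")
    r = len(tables)
    num = 0.0
    den = 0.0
    for locus in panel:
        c = np.array([2.0 * t.sample_sizes.get(locus, 0) for t in tables])
        if np.any(c <= 0):
            raise StrDataError(f"theta: missing sample size at locus {locus}")
        C = c.sum()
        n_c = (C - (c ** 2).sum() / C) / (r - 1)
        alleles = sorted({a for t in tables for a in t.freqs[locus]})
        for a in alleles:
            p = np.array([t.freqs[locus].get(a, 0.0) for t in tables])
            pbar = (c * p).sum() / C
            msp = (c * (p - pbar) ** 2).sum() / (r - 1)
            msg = (c * p * (1.0 - p)).sum() / (C - r)
            num += msp - msg
            den += msp + (n_c - 1.0) * msg
    if den == 0.0:
        return 0.0
    return num / den


def pairwise_fst(
    tables: Mapping[str, FrequencyTable], loci: Sequence[str] | None = None
) -> DistanceMatrix:
    """Pairwise Weir–Cockerham θ matrix (raw values; may dip below 0)."""
    pops = list(tables)
    if len(pops) < 2:
        raise StrDataError("pairwise_fst needs at least 2 populations")
    n = len(pops)
    out = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        th = weir_cockerham_theta([tables[pops[i]], tables[pops[j]]], loci)
        out[i, j] = out[j, i] = th
    return DistanceMatrix(pops, out, allow_negative=True)


def nei_da_matrix(
    tables: Mapping[str, FrequencyTable], loci: Sequence[str] | None = None
) -> DistanceMatrix:
    pops = list(tables)
    if len(pops) < 2:
        raise StrDataError("nei_da_matrix needs at least 2 populations")
    n = len(pops)
    out = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        out[i, j] = out[j, i] = nei_da(tables[pops[i]], tables[pops[j]], loci)
    # exact-rational zero for identical tables can round to -1e-17
    return DistanceMatrix(pops, np.maximum(out, 0.0))


def distance_matrices(
    tables: Mapping[str, FrequencyTable], loci: Sequence[str] | None = None
) -> tuple[DistanceMatrix, DistanceMatrix]:
    """(D_A, raw FST) matrices with identical label order."""
    return nei_da_matrix(tables, loci), pairwise_fst(tables, loci)
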