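"""Exact tests of Hardy–Weinberg equilibrium and linkage disequilibrium.

The HWE test conditions on the observed allele counts: under random
mating every genotype table consistent with those counts has the Levene
probability

    P(table) = n! · 2^h · Π_a m_a! / (Π_g n_g! · (2n)!)

with n individuals, m_a allele counts, n_g genotype counts and h
heterozygotes.  The exact P-value sums P(table) over all tables no more
probable than the observed one.  Small conditionings are enumerated
completely; larger ones are sampled by random pairing of the allele
vector (each shuffle of the 2n alleles into n pairs is one draw from the
Levene distribution), which is unbiased and embarrassingly simple.

Linkage disequilibrium between two STR loci is tested genotypically —
phase is unknown for autosomal data — with a log-likelihood-ratio G
statistic on the genotype × genotype contingency table and a permutation
null obtained by shuffling one locus' genotype column.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np

from .str_data import AlleleLabel, GenotypeDataset, StrDataError

logger = logging.getLogger(__name__)

#: above this many candidate genotype tables, fall back to Monte-Carlo
DEFAULT_ENUMERATION_CAP = 100_000
DEFAULT_MC_DRAWS = 100_000

#: tables whose log-probability is within this of the observed one count as ties
_LOG_TIE_TOL = 1e-9


@dataclass(frozen=True)
class HweResult:
    locus: str
    p_value: float
    method: str  # "enumeration" | "monte_carlo"
    mc_error: float | None = None
    n_tables: int | None = None
    n_draws: int | None = None


@dataclass(frozen=True)
class LdResult:
    locus_a: str
    locus_b: str
    p_value: float
    statistic: float
    n_permutations: int
    degenerate: bool = False
    significant_after_correction: bool | None = None


def bonferroni(alpha: float, m: int) -> float:
    """Family-wise level alpha split over m tests."""
    if m < 1:
        raise StrDataError("bonferroni: m must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise StrDataError("bonferroni: alpha must be in (0, 1)")
    return alpha / m


# ---------------------------------------------------------------------------
# HWE exact test

def _counts_to_arrays(genotype_counts: dict) -> tuple[list, np.ndarray, np.ndarray]:
    """Map {(allele, allele): count} to allele list, allele count vector and
    a dense genotype count matrix (upper triangle)."""
    if not genotype_counts:
        raise StrDataError("no genotypes at locus")
    alleles = sorted({a for pair in genotype_counts for a in pair})
    idx = {a: i for i, a in enumerate(alleles)}
    k = len(alleles)
    table = np.zeros((k, k), dtype=np.int64)
    for (a1, a2), c in genotype_counts.items():
        if c < 0:
            raise StrDataError("negative genotype count")
        i, j = sorted((idx[a1], idx[a2]))
        table[i, j] += c
    m = np.zeros(k, dtype=np.int64)
    for i in range(k):
        for j in range(i, k):
            m[i] += table[i, j]
            m[j] += table[i, j]
    return alleles, m, table


def _log_levene_const(m: np.ndarray, n: int) -> float:
    return math.lgamma(n + 1) + sum(math.lgamma(int(x) + 1) for x in m) - math.lgamma(2 * n + 1)


def _log_table_weight(table: np.ndarray) -> float:
    """h·log2 − Σ_g log n_g!, the table-dependent part of log P."""
    k = table.shape[0]
    h = int(table.sum() - np.trace(table))
    s = sum(math.lgamma(int(table[i, j]) + 1) for i in range(k) for j in range(i, k))
    return h * math.log(2.0) - s


#: enumeration is only attempted below these sizes (beyond them the table
#: count always dwarfs any practical cap and the attempt would waste time)
_ENUM_MAX_N = 60
_ENUM_MAX_K = 8


def _enumerate_tables(m: np.ndarray, cap: int):
    """Yield every symmetric genotype table with allele margins ``m``,
    aborting (yield None) once more than ``cap`` tables have been produced.

    Yields the live work table for speed — copy before storing."""
    k = len(m)
    table = np.zeros((k, k), dtype=np.int64)
    produced = 0

    def rec(i: int, rem: np.ndarray):
        nonlocal produced
        if i == k:
            produced += 1
            yield None if produced > cap else table
            return
        r = int(rem[i])
        if r == 0:
            yield from rec(i + 1, rem)
            return
        js = [j for j in range(i + 1, k) if rem[j] > 0]

        def fill_het(pos: int, left: int):
            if pos == len(js):
                if left == 0:
                    yield from rec(i + 1, rem)
                return
            j = js[pos]
            hi = min(left, int(rem[j]))
            for x in range(hi + 1):
                table[i, j] = x
                rem[j] -= x
                yield from fill_het(pos + 1, left - x)
                rem[j] += x
                table[i, j] = 0

        for n_ii in range(r // 2 + 1):
            table[i, i] = n_ii
            yield from fill_het(0, r - 2 * n_ii)
            table[i, i] = 0

    yield from rec(0, m.copy())


def _mc_pvalue(
    alleles: list, m: np.ndarray, obs_weight: float, draws: int, rng: np.random.Generator
) -> tuple[float, float]:
    """Monte-Carlo p by random pairing of the allele vector (vectorized)."""
    from scipy.special import gammaln

    k = len(m)
    n = int(m.sum()) // 2
    vec = np.repeat(np.arange(k), m)
    hits = 0
    batch = max(1, min(draws, 4_000_000 // max(1, 2 * n)))
    done = 0
    log2 = math.log(2.0)
    while done < draws:
        b = min(batch, draws - done)
        order = np.argsort(rng.random((b, 2 * n)), axis=1)
        perm = vec[order]
        a1 = np.minimum(perm[:, ::2], perm[:, 1::2])
        a2 = np.maximum(perm[:, ::2], perm[:, 1::2])
        h = (a1 != a2).sum(axis=1)
        codes = a1 * k + a2
        counts = np.zeros((b, k * k), dtype=np.int64)
        rows = np.repeat(np.arange(b), n)
        np.add.at(counts, (rows, codes.ravel()), 1)
        slg = gammaln(counts + 1.0).sum(axis=1)
        weights = h * log2 - slg
        hits += int((weights <= obs_weight + _LOG_TIE_TOL).sum())
        done += b
    p = (1 + hits) / (1 + draws)
    se = math.sqrt(max(p * (1 - p), 1e-300) / draws)
    return p, se


def hwe_exact(
    genotype_counts: dict,
    locus: str = "",
    enumeration_cap: int = DEFAULT_ENUMERATION_CAP,
) -> HweResult:
    """Complete-enumeration HWE exact test.

    ``genotype_counts`` maps unordered allele pairs to counts, e.g.
    ``{("A","A"): 1, ("A","B"): 2}``.  Raises if the conditioning exceeds
    ``enumeration_cap`` tables; use :func:`hwe_test` for automatic
    Monte-Carlo fallback.
    """
    alleles, m, obs = _counts_to_arrays(genotype_counts)
    n = int(obs.sum())
    if n == 0:
        raise StrDataError("zero individuals")
    if len(alleles) == 1:
        return HweResult(locus, 1.0, "enumeration", n_tables=1)
    obs_w = _log_table_weight(obs)
    total = 0.0
    p_sum = 0.0
    n_tables = 0
    for t in _enumerate_tables(m, enumeration_cap):
        if t is None:
            raise StrDataError(
                f"locus {locus or '?'}: more than {enumeration_cap} tables; use hwe_test"
            )
        n_tables += 1
        w = _log_table_weight(t)
        pw = math.exp(w)
        total += pw
        if w <= obs_w + _LOG_TIE_TOL:
            p_sum += pw
    # normalizing over enumerated tables avoids any constant-term rounding
    return HweResult(locus, min(p_sum / total, 1.0), "enumeration", n_tables=n_tables)


def levene_probabilities(
    genotype_counts: dict, enumeration_cap: int = DEFAULT_ENUMERATION_CAP
) -> np.ndarray:
    """Levene probability of every genotype table consistent with the
    allele counts of ``genotype_counts``.  The probabilities sum to 1."""
    alleles, m, obs = _counts_to_arrays(genotype_counts)
    n = int(obs.sum())
    const = _log_levene_const(m, n)
    probs = []
    for t in _enumerate_tables(m, enumeration_cap):
        if t is None:
            raise StrDataError(f"more than {enumeration_cap} tables")
        probs.append(math.exp(const + _log_table_weight(t)))
    return np.array(probs)


def hwe_test(
    genotype_counts: dict,
    locus: str = "",
    enumeration_cap: int = DEFAULT_ENUMERATION_CAP,
    draws: int = DEFAULT_MC_DRAWS,
    seed: int | np.random.Generator | None = None,
) -> HweResult:
    """HWE exact test with automatic method choice.

    Enumerates completely when the conditioning has at most
    ``enumeration_cap`` tables, otherwise draws ``draws`` Monte-Carlo
    tables (seed required for the Monte-Carlo path).
    """
    alleles, m, obs = _counts_to_arrays(genotype_counts)
    if int(obs.sum()) == 0:
        raise StrDataError("zero individuals")
    n = int(obs.sum())
    if n <= _ENUM_MAX_N and len(alleles) <= _ENUM_MAX_K:
        try:
            return hwe_exact(genotype_counts, locus, enumeration_cap)
        except StrDataError as e:
            if "tables" not in str(e):
                raise
    if seed is None:
        raise StrDataError(f"locus {locus or '?'}: Monte-Carlo HWE test requires a seed")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    obs_w = _log_table_weight(obs)
    p, se = _mc_pvalue(alleles, m, obs_w, draws, rng)
    return HweResult(locus, p, "monte_carlo", mc_error=se, n_draws=draws)


def genotype_counts_at(ds: GenotypeDataset, locus: str) -> dict:
    counts: dict = {}
    for g in ds.genotypes_at(locus):
        key = (g.a1, g.a2)
        counts[key] = counts.get(key, 0) + 1
    return counts


def hwe_all(
    ds: GenotypeDataset,
    seed: int | None = None,
    draws: int = DEFAULT_MC_DRAWS,
    enumeration_cap: int = DEFAULT_ENUMERATION_CAP,
    alpha: float = 0.05,
) -> list[HweResult]:
    """HWE exact test at every locus of a dataset."""
    rng = np.random.default_rng(seed) if seed is not None else None
    out = []
    for locus in ds.loci:
        out.append(
            hwe_test(genotype_counts_at(ds, locus), locus=locus,
                     enumeration_cap=enumeration_cap, draws=draws, seed=rng)
        )
    below = sum(r.p_value < alpha for r in out)
    below_bonf = sum(r.p_value < bonferroni(alpha, len(out)) for r in out)
    logger.info(
        "HWE: %d/%d loci below alpha=%g, %d below Bonferroni level %g",
        below, len(out), alpha, below_bonf, bonferroni(alpha, len(out)),
    )
    return out


# ---------------------------------------------------------------------------
# linkage disequilibrium

def g_statistic(table: np.ndarray) -> float:
    """Log-likelihood-ratio G of a contingency table, 2 Σ O ln(O/E)."""
    obs = np.asarray(table, dtype=float)
    total = obs.sum()
    if total == 0:
        return 0.0
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    mask = obs > 0
    return float(2.0 * (obs[mask] * np.log(obs[mask] / expected[mask])).sum())


def _paired_codes(ds: GenotypeDataset, locus_a: str, locus_b: str) -> tuple[np.ndarray, np.ndarray]:
    ia, ib = ds.locus_index(locus_a), ds.locus_index(locus_b)
    ga, gb = [], []
    for row in ds.calls:
        if not row[ia].is_missing and not row[ib].is_missing:
            ga.append((row[ia].a1.tenths, row[ia].a2.tenths))
            gb.append((row[ib].a1.tenths, row[ib].a2.tenths))
    if len(ga) < 2:
        raise StrDataError(f"fewer than 2 individuals typed at both {locus_a} and {locus_b}")
    ua = {g: i for i, g in enumerate(sorted(set(ga)))}
    ub = {g: i for i, g in enumerate(sorted(set(gb)))}
    return (np.array([ua[g] for g in ga]), np.array([ub[g] for g in gb]))


def ld_exact(
    ds: GenotypeDataset,
    locus_a: str,
    locus_b: str,
    n_permutations: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> LdResult:
    """Genotypic LD permutation test for one locus pair.

    Permuting one locus' genotype column is exact in distribution under
    independence; the +1 correction keeps p in (0, 1].  A monomorphic
    locus makes the test degenerate (p = 1).
    """
    ca, cb = _paired_codes(ds, locus_a, locus_b)
    ka, kb = int(ca.max()) + 1, int(cb.max()) + 1
    if ka == 1 or kb == 1:
        return LdResult(locus_a, locus_b, 1.0, 0.0, 0, degenerate=True)
    if seed is None:
        raise StrDataError("ld_exact requires a seed")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(ca)
    joint = np.zeros((ka, kb), dtype=np.int64)
    np.add.at(joint, (ca, cb), 1)
    g_obs = g_statistic(joint)

    # margins are invariant under permutation, so E is fixed
    row = joint.sum(axis=1).astype(float)
    col = joint.sum(axis=0).astype(float)
    logE = np.log(np.outer(row, col) / n)
    hits = 0
    batch = max(1, min(n_permutations, 2_000_000 // max(n, 1)))
    done = 0
    codes_base = ca * kb
    while done < n_permutations:
        b = min(batch, n_permutations - done)
        order = np.argsort(rng.random((b, n)), axis=1)
        perm_cb = cb[order]
        codes = codes_base[None, :] + perm_cb
        counts = np.zeros((b, ka * kb), dtype=np.int64)
        np.add.at(counts, (np.repeat(np.arange(b), n), codes.ravel()), 1)
        nz = counts > 0
        cf = counts.astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(nz, cf * (np.log(np.where(nz, cf, 1.0)) - logE.ravel()[None, :]), 0.0)
        g_perm = 2.0 * terms.sum(axis=1)
        hits += int((g_perm >= g_obs - 1e-12).sum())
        done += b
    p = (1 + hits) / (1 + n_permutations)
    return LdResult(locus_a, locus_b, p, g_obs, n_permutations)


def ld_all_pairs(
    ds: GenotypeDataset,
    n_permutations: int = 10_000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> list[LdResult]:
    """LD test for all L(L−1)/2 locus pairs with Bonferroni flagging."""
    loci = ds.loci
    if len(loci) < 2:
        raise StrDataError("need at least 2 loci for LD analysis")
    pairs = list(itertools.combinations(loci, 2))
    level = bonferroni(alpha, len(pairs))
    rng = np.random.default_rng(seed)
    out = []
    for a, b in pairs:
        r = ld_exact(ds, a, b, n_permutations=n_permutations, seed=rng)
        out.append(
            LdResult(r.locus_a, r.locus_b, r.p_value, r.statistic,
                     r.n_permutations, r.degenerate, r.p_value < level)
        )
    sig = sum(bool(r.significant_after_correction) for r in out)
    logger.info("LD: %d/%d pairs below Bonferroni level %g", sig, len(pairs), level)
    return out


def ld_matrix(results: list[LdResult], loci: list[str]):
    """Lower-triangle p-value DataFrame in the layout of a published
    pairwise LD table (rows/columns in reversed locus order)."""
    import pandas as pd

    rev = list(reversed(loci))
    df = pd.DataFrame(np.nan, index=rev[1:], columns=rev[:-1])
    lut = {frozenset((r.locus_a, r.locus_b)): r.p_value for r in results}
    for i, a in enumerate(rev[1:], start=1):
        for b in rev[:i]:
            df.loc[a, b] = lut[frozenset((a, b))]
    return df
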