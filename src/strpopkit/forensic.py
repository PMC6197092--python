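"""Forensic identification and paternity parameters for STR loci.

Per locus: observed heterozygosity (Ho), expected heterozygosity
(He = 1 − Σp²), matching probability (MP, sum of squared genotype
proportions), power of discrimination (DP = 1 − MP), polymorphism
information content (PIC, Botstein form), and probabilities of exclusion
in motherless duo and full trio paternity cases.  Across loci the
parameters combine multiplicatively: CDP = 1 − Π MP and
CPE = 1 − Π (1 − PE).  The combined discrimination power of a 20-locus
panel carries ~24 leading nines, so combined values are also reported as
extended-precision digit strings.

Conventions (each one reproduces published spreadsheet output for STR
panels): He is the plain 1 − Σp² without the 2n/(2n−1) correction; PIC is
1 − Σp² − (Σp²)² + Σp⁴; PE_trio is the Brenner form h²(1 − 2hH²) on
observed heterozygosity h (H = 1 − h); PE_duo is the single-parent form
1 − 4Σp² + 2(Σp²)² + 4Σp³ − 3Σp⁴; MP uses observed genotype proportions,
not the Hardy–Weinberg expectation, so it needs genotype-level data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, getcontext
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .str_data import (
    AlleleLabel,
    FrequencyTable,
    GenotypeDataset,
    StrDataError,
    frequencies_from_genotypes,
)

PROFILE_COLUMNS = ["Ho", "He", "MP", "DP", "PIC", "PE_duo", "PE_trio", "P_hwe"]


def _check_freqs(freqs: Mapping) -> list[float]:
    if not freqs:
        raise StrDataError("empty allele-frequency map")
    p = [float(v) for v in freqs.values()]
    if any(x <= 0 for x in p):
        raise StrDataError("allele frequencies must be positive")
    return p


def observed_heterozygosity(ds: GenotypeDataset, locus: str) -> float:
    """Fraction of typed individuals heterozygous at ``locus``."""
    gts = ds.genotypes_at(locus)
    if not gts:
        raise StrDataError(f"no data at locus {locus!r}")
    return sum(g.is_heterozygous for g in gts) / len(gts)


def expected_heterozygosity(freqs: Mapping[AlleleLabel, float]) -> float:
    """He = 1 − Σ pᵢ² (no small-sample correction)."""
    p = _check_freqs(freqs)
    return 1.0 - sum(x * x for x in p)


def pic(freqs: Mapping[AlleleLabel, float]) -> float:
    """Polymorphism information content, 1 − Σp² − (Σp²)² + Σp⁴."""
    p = _check_freqs(freqs)
    s2 = sum(x * x for x in p)
    s4 = sum(x ** 4 for x in p)
    return 1.0 - s2 - s2 * s2 + s4


def match_probability(ds: GenotypeDataset, locus: str) -> float:
    """MP = Σ_G f_G² over observed genotype proportions at ``locus``."""
    gts = ds.genotypes_at(locus)
    if not gts:
        raise StrDataError(f"no data at locus {locus!r}")
    counts: dict = {}
    for g in gts:
        counts[g] = counts.get(g, 0) + 1
    n = len(gts)
    return sum((c / n) ** 2 for c in counts.values())


def power_of_discrimination(ds: GenotypeDataset, locus: str) -> float:
    return 1.0 - match_probability(ds, locus)


def expected_match_probability(freqs: Mapping[AlleleLabel, float]) -> float:
    """MP expected under Hardy–Weinberg proportions: Σp⁴ + 2[(Σp²)² − Σp⁴]."""
    p = _check_freqs(freqs)
    s2 = sum(x * x for x in p)
    s4 = sum(x ** 4 for x in p)
    return s4 + 2.0 * (s2 * s2 - s4)


def pe_trio(ho: float) -> float:
    """Probability of exclusion with both parents typed, h²(1 − 2hH²)."""
    if not 0.0 <= ho <= 1.0:
        raise StrDataError(f"Ho must be in [0, 1], got {ho}")
    h = ho
    H = 1.0 - h
    return h * h * (1.0 - 2.0 * h * H * H)


def pe_duo(freqs: Mapping[AlleleLabel, float]) -> float:
    """Probability of exclusion in motherless (duo) cases,
    1 − 4Σp² + 2(Σp²)² + 4Σp³ − 3Σp⁴."""
    p = _check_freqs(freqs)
    s2 = sum(x * x for x in p)
    s3 = sum(x ** 3 for x in p)
    s4 = sum(x ** 4 for x in p)
    return 1.0 - 4.0 * s2 + 2.0 * s2 * s2 + 4.0 * s3 - 3.0 * s4


@dataclass(frozen=True)
class CombinedParams:
    """Multi-locus combined parameters, as floats and as digit strings.

    CDP for a full forensic panel differs from 1 by ~1e-25, far below
    float precision, so the digit strings (computed in 50-digit decimal
    arithmetic) are the faithful representation.
    """

    cdp: float
    cpe_duo: float
    cpe_trio: float
    cdp_digits: str
    cpe_duo_digits: str
    cpe_trio_digits: str


def _one_minus_product(values: Iterable[float], digits: int = 40) -> tuple[float, str]:
    """1 − Π vᵢ in extended precision; returns (float, digit string)."""
    getcontext().prec = digits + 10
    prod = Decimal(1)
    for v in values:
        v = float(v)
        if not 0.0 <= v <= 1.0:
            raise StrDataError(f"per-locus value {v} outside [0, 1]")
        prod *= Decimal(str(v))
    result = Decimal(1) - prod
    q = result.quantize(Decimal(1).scaleb(-digits))
    return float(result), format(q, "f")


def combine(
    mp: Sequence[float] | None = None,
    pe_duo: Sequence[float] | None = None,
    pe_trio: Sequence[float] | None = None,
    digits: int = 40,
) -> CombinedParams:
    """Combine per-locus parameters across a panel.

    CDP = 1 − Π MP_l; CPE_x = 1 − Π (1 − PE_x,l).  Any of the three inputs
    may be omitted (NaN in the result).  ``digits`` controls the length of
    the reported digit strings.
    """
    cdp, cdp_s = (math.nan, "")
    cduo, cduo_s = (math.nan, "")
    ctrio, ctrio_s = (math.nan, "")
    if mp is not None:
        if len(mp) == 0:
            raise StrDataError("combine: need at least one locus")
        cdp, cdp_s = _one_minus_product(mp, digits)
    if pe_duo is not None:
        cduo, cduo_s = _one_minus_product([1.0 - float(x) for x in pe_duo], digits)
    if pe_trio is not None:
        ctrio, ctrio_s = _one_minus_product([1.0 - float(x) for x in pe_trio], digits)
    return CombinedParams(cdp, cduo, ctrio, cdp_s, cduo_s, ctrio_s)


def profile_from_genotypes(
    ds: GenotypeDataset,
    loci: Sequence[str] | None = None,
    hwe_seed: int | None = None,
    hwe_draws: int = 100_000,
) -> tuple[pd.DataFrame, CombinedParams]:
    """Full forensic profile from genotype data: one row per locus with
    Ho, He, MP, DP, PIC, PE_duo, PE_trio and the HWE exact-test P-value,
    plus the combined panel parameters."""
    from .equilibrium import hwe_test  # local import to avoid a cycle

    loci = list(loci) if loci is not None else list(ds.loci)
    if not loci:
        raise StrDataError("empty locus list")
    rows = {}
    for locus in loci:
        freqs, _ = frequencies_from_genotypes(ds, locus)
        ho = observed_heterozygosity(ds, locus)
        mp_ = match_probability(ds, locus)
        res = hwe_test(_genotype_counts(ds, locus), locus=locus, seed=hwe_seed, draws=hwe_draws)
        rows[locus] = [ho, expected_heterozygosity(freqs), mp_, 1.0 - mp_,
                       pic(freqs), pe_duo(freqs), pe_trio(ho), res.p_value]
    table = pd.DataFrame.from_dict(rows, orient="index", columns=PROFILE_COLUMNS)
    combined = combine(mp=table["MP"].tolist(),
                       pe_duo=table["PE_duo"].tolist(),
                       pe_trio=table["PE_trio"].tolist())
    return table, combined


def _genotype_counts(ds: GenotypeDataset, locus: str) -> dict:
    counts: dict = {}
    for g in ds.genotypes_at(locus):
        key = (g.a1, g.a2)
        counts[key] = counts.get(key, 0) + 1
    return counts


def profile_from_frequencies(
    table: FrequencyTable,
    ho: Mapping[str, float] | None = None,
    loci: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, CombinedParams]:
    """Forensic profile from a published frequency table.

    MP, DP and the HWE P-value require genotype-level data and are reported
    as NaN; Ho (and hence PE_trio) is populated only when an Ho vector is
    supplied alongside the frequencies.
    """
    loci = list(loci) if loci is not None else table.loci
    if not loci:
        raise StrDataError("empty locus list")
    rows = {}
    for locus in loci:
        freqs = table.freqs[locus]
        h = float(ho[locus]) if ho is not None and locus in ho else math.nan
        rows[locus] = [
            h,
            expected_heterozygosity(freqs),
            math.nan,
            math.nan,
            pic(freqs),
            pe_duo(freqs),
            pe_trio(h) if not math.isnan(h) else math.nan,
            math.nan,
        ]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=PROFILE_COLUMNS)
    combined = combine(
        mp=None,
        pe_duo=df["PE_duo"].tolist(),
        pe_trio=df["PE_trio"].dropna().tolist() if df["PE_trio"].notna().all() else None,
    )
    return df, combined
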