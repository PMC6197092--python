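"""Synthetic STR data with known ground truth.

Three generators cover every stage of the pipeline: HWE (optionally
inbred) genotype sampling from a frequency table, Balding–Nichols
Dirichlet sampling of structured subpopulation frequencies with a
controlled fixation index, and a two-locus generator with tunable
inter-locus dependence for calibrating the LD test.  Every generator is
a pure function of its config and seed: identical inputs give identical
output across runs and platforms.

The packaged reference table — allele frequencies, observed
heterozygosities and forensic parameters of 20 autosomal STR loci typed
in 2 000 Qinghai Han individuals — ships as CSV with checksums and is
exposed by :func:`reference_panel`; it anchors the simulators to a
realistic forensic panel (9–24 alleles per locus, microvariants
included) and is the golden oracle for the forensic-parameter tests.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .str_data import (
    AlleleLabel,
    FrequencyTable,
    GenotypeDataset,
    LocusGenotype,
    StrDataError,
)

_FIXTURE_SHA256 = {
    "qinghai_han_freqs.csv": "6d3f00c7183dd7bd49a6dacf3ee3cdc217dc5a876e7b0e97bebc8823899be2c8",
    "qinghai_han_params.csv": "41c1e37644385857b98353604c12998656ba18c4c2b37c63b0906f9d2fe2741b",
}


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    if seed is None:
        raise StrDataError("a seed is mandatory for every simulator")
    return np.random.default_rng(seed)


def sample_genotypes(
    freqs: FrequencyTable,
    n: int,
    f_is: float = 0.0,
    seed: int | np.random.Generator | None = None,
    population: str | None = None,
    sample_prefix: str = "S",
) -> GenotypeDataset:
    """Draw ``n`` diploid individuals from a frequency table.

    Loci are independent.  Per individual and locus, with probability
    ``f_is`` one allele is drawn and duplicated (autozygous); otherwise
    two alleles are drawn independently — so realized heterozygosity has
    expectation (1 − f_is)·He and f_is = 0 is exact HWE sampling.
    """
    if n < 1:
        raise StrDataError("n must be >= 1")
    if not 0.0 <= f_is <= 1.0:
        raise StrDataError(f"F_is must be in [0, 1], got {f_is}")
    rng = _rng(seed)
    ft = freqs.renormalized()
    pop = population or ft.population
    loci = ft.loci
    calls_cols: list[list[LocusGenotype]] = []
    for locus in loci:
        alleles = sorted(ft.freqs[locus])
        p = np.array([ft.freqs[locus][a] for a in alleles])
        draws = rng.choice(len(alleles), size=(n, 2), p=p)
        if f_is > 0:
            auto = rng.random(n) < f_is
            draws[auto, 1] = draws[auto, 0]
        calls_cols.append([LocusGenotype(alleles[i], alleles[j]) for i, j in draws])
    calls = [[calls_cols[j][i] for j in range(len(loci))] for i in range(n)]
    ids = [f"{sample_prefix}{i+1}" for i in range(n)]
    return GenotypeDataset(ids, [pop] * n, list(loci), calls)


def balding_nichols_freqs(
    ancestral: FrequencyTable,
    k: int,
    f_st: float,
    seed: int | np.random.Generator | None = None,
    name_prefix: str = "pop",
) -> dict[str, FrequencyTable]:
    """K subpopulation frequency tables under the Balding–Nichols model.

    Per locus and population the frequency vector is drawn from
    Dirichlet(p·(1−F)/F) around the ancestral vector p, which has
    E[x_a] = p_a and Var[x_a] = F·p_a(1−p_a) — i.e. a fixation index of
    F between the subpopulations.  Populations and loci are independent.
    """
    if not 0.0 < f_st < 1.0:
        raise StrDataError(f"F_st must be in (0, 1), got {f_st}")
    if k < 2:
        raise StrDataError("need at least K=2 subpopulations")
    rng = _rng(seed)
    ft = ancestral.renormalized()
    scale = (1.0 - f_st) / f_st
    out: dict[str, FrequencyTable] = {}
    for i in range(k):
        freqs: dict[str, dict[AlleleLabel, float]] = {}
        for locus in ft.loci:
            alleles = sorted(ft.freqs[locus])
            p = np.array([ft.freqs[locus][a] for a in alleles])
            x = rng.dirichlet(p * scale)
            # Dirichlet can return exact zeros for tiny alphas; keep the
            # support positive so the table remains a valid frequency map
            x = np.maximum(x, 1e-12)
            x = x / x.sum()
            freqs[locus] = {a: float(v) for a, v in zip(alleles, x)}
        out[f"{name_prefix}{i+1}"] = FrequencyTable(f"{name_prefix}{i+1}", freqs)
    return out


def linked_pair(
    freqs: FrequencyTable,
    n: int,
    coupling: float,
    seed: int | np.random.Generator | None = None,
    locus: str | None = None,
) -> GenotypeDataset:
    """Two-locus dataset with controlled inter-locus dependence.

    Locus ``A`` is drawn under HWE from the given table's first (or
    named) locus; locus ``B`` copies A's genotype with probability
    ``coupling`` and is otherwise drawn independently from the same
    frequencies.  coupling = 0 gives exact independence, coupling = 1
    a perfect duplicate.
    """
    if not 0.0 <= coupling <= 1.0:
        raise StrDataError(f"coupling must be in [0, 1], got {coupling}")
    rng = _rng(seed)
    ft = freqs.renormalized()
    locus = locus or ft.loci[0]
    alleles = sorted(ft.freqs[locus])
    p = np.array([ft.freqs[locus][a] for a in alleles])
    a_draws = rng.choice(len(alleles), size=(n, 2), p=p)
    b_draws = rng.choice(len(alleles), size=(n, 2), p=p)
    copy = rng.random(n) < coupling
    b_draws[copy] = a_draws[copy]
    calls = [
        [LocusGenotype(alleles[i1], alleles[j1]), LocusGenotype(alleles[i2], alleles[j2])]
        for (i1, j1), (i2, j2) in zip(a_draws, b_draws)
    ]
    ids = [f"S{i+1}" for i in range(n)]
    return GenotypeDataset(ids, ["sim"] * n, ["A", "B"], calls)


# ---------------------------------------------------------------------------
# packaged reference table

@dataclass(frozen=True)
class ReferencePanel:
    """The packaged 20-locus Qinghai Han reference table."""

    frequencies: FrequencyTable
    ho: dict[str, float]
    parameters: pd.DataFrame  # rows Ho..P, columns = loci


def _fixture_text(name: str) -> str:
    path = resources.files("strpopkit.data").joinpath(name)
    data = path.read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != _FIXTURE_SHA256[name]:
        raise StrDataError(
            f"packaged fixture {name} fails its checksum (got {digest}); "
            "the installation is corrupted"
        )
    return data.decode()


def reference_panel() -> ReferencePanel:
    """Load the packaged reference frequency table and parameter rows.

    Returns the 20-locus frequency table (n = 2 000 diploid individuals
    per locus), the observed-heterozygosity vector and the full printed
    parameter block (Ho, He, MP, DP, PIC, PE(D), PE(T), HWE P).
    """
    import csv as _csv
    import io

    freq_rows = list(_csv.reader(io.StringIO(_fixture_text("qinghai_han_freqs.csv"))))
    loci = freq_rows[0][1:]
    freqs: dict[str, dict[AlleleLabel, float]] = {l: {} for l in loci}
    for row in freq_rows[1:]:
        allele = AlleleLabel.parse(row[0])
        for locus, cell in zip(loci, row[1:]):
            if cell.strip():
                freqs[locus][allele] = float(cell)
    table = FrequencyTable("QinghaiHan", freqs, {l: 2000 for l in loci})

    param_rows = list(_csv.reader(io.StringIO(_fixture_text("qinghai_han_params.csv"))))
    params = pd.DataFrame(
        [[float(x) for x in r[1:]] for r in param_rows[1:]],
        index=[r[0] for r in param_rows[1:]],
        columns=param_rows[0][1:],
    )
    ho = params.loc["Ho"].to_dict()
    return ReferencePanel(table, ho, params)
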