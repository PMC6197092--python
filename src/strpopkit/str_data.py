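"""Domain types and file formats for autosomal STR population data.

STR alleles are named by repeat count and may carry one partial-repeat
digit (microvariants such as 9.3 or 29.2).  Everything downstream — the
forensic parameters, the equilibrium tests, the distance matrices — works
on the two containers defined here: :class:`GenotypeDataset` (individuals
× loci diploid calls) and :class:`FrequencyTable` (per-locus allele →
frequency maps, the shape of a published population table).

Supported external formats: genotype CSV (long and wide dialects),
wide allele-frequency CSV (allele rows × locus columns), GenePop 4 text,
PHYLIP square distance matrices and Newick trees.
"""

from __future__ import annotations

import csv
import logging
import os
import re
import tempfile
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

MISSING_TOKENS = {"", "-", "NA", "na", "."}

#: printed frequency tables are rounded to 4 decimals, so a column may
#: legitimately sum to 1 +/- 0.005
FREQ_SUM_TOL = 0.005


class StrDataError(ValueError):
    """Malformed STR data (bad allele label, duplicate sample, ...)."""


_ALLELE_RE = re.compile(r"^(\d+)(?:\.(\d))?$")


@dataclass(frozen=True, order=True)
class AlleleLabel:
    """An STR allele named by its repeat count, e.g. 8, 9.3, 29.2.

    Stored as integer tenths of a repeat so that equality and ordering are
    exact and the string form round-trips (``"9.3" -> 9.3 -> "9.3"``;
    integer alleles never print a decimal point).
    """

    tenths: int

    @classmethod
    def parse(cls, text: str) -> "AlleleLabel":
        m = _ALLELE_RE.match(text.strip())
        if m is None:
            raise StrDataError(
                f"malformed allele label {text!r}: expected a repeat count "
                "with at most one fractional digit (e.g. 8, 9.3)"
            )
        whole, frac = m.groups()
        return cls(int(whole) * 10 + (int(frac) if frac else 0))

    @classmethod
    def from_number(cls, value: float) -> "AlleleLabel":
        tenths = round(value * 10)
        if abs(value * 10 - tenths) > 1e-9:
            raise StrDataError(f"allele value {value} has more than one fractional digit")
        return cls(tenths)

    @property
    def value(self) -> float:
        return self.tenths / 10.0

    def __str__(self) -> str:
        whole, frac = divmod(self.tenths, 10)
        return str(whole) if frac == 0 else f"{whole}.{frac}"

    def __repr__(self) -> str:
        return f"AlleleLabel({self})"


@dataclass(frozen=True)
class LocusGenotype:
    """An unordered diploid call; the canonical form has a1 <= a2.

    A missing genotype carries no allele labels and is excluded from every
    count downstream.
    """

    a1: AlleleLabel | None = None
    a2: AlleleLabel | None = None

    def __post_init__(self) -> None:
        if (self.a1 is None) != (self.a2 is None):
            raise StrDataError("half-missing genotype: both alleles or neither")
        if self.a1 is not None and self.a2 is not None and self.a2 < self.a1:
            lo, hi = self.a2, self.a1
            object.__setattr__(self, "a1", lo)
            object.__setattr__(self, "a2", hi)

    @classmethod
    def missing(cls) -> "LocusGenotype":
        return cls(None, None)

    @property
    def is_missing(self) -> bool:
        return self.a1 is None

    @property
    def is_heterozygous(self) -> bool:
        if self.is_missing:
            raise StrDataError("missing genotype has no zygosity")
        return self.a1 != self.a2

    def __str__(self) -> str:
        return "-/-" if self.is_missing else f"{self.a1}/{self.a2}"


def genotype(a1: str | float, a2: str | float) -> LocusGenotype:
    """Convenience constructor: ``genotype("9.3", 8)``."""

    def lab(a) -> AlleleLabel:
        return AlleleLabel.parse(a) if isinstance(a, str) else AlleleLabel.from_number(a)

    return LocusGenotype(lab(a1), lab(a2))


@dataclass
class GenotypeDataset:
    """Diploid STR calls for a sample of individuals at a panel of loci."""

    sample_ids: list[str]
    populations: list[str]
    loci: list[str]
    calls: list[list[LocusGenotype]]  # row i aligns with sample_ids[i]

    def __post_init__(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = sorted({s for s in self.sample_ids if self.sample_ids.count(s) > 1})
            raise StrDataError(f"duplicate sample_id(s): {', '.join(dupes)}")
        if len(self.populations) != len(self.sample_ids):
            raise StrDataError("populations and sample_ids length mismatch")
        for sid, row in zip(self.sample_ids, self.calls):
            if len(row) != len(self.loci):
                raise StrDataError(f"sample {sid}: expected {len(self.loci)} loci, got {len(row)}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def locus_index(self, locus: str) -> int:
        try:
            return self.loci.index(locus)
        except ValueError:
            raise StrDataError(f"locus {locus!r} not in dataset") from None

    def genotypes_at(self, locus: str) -> list[LocusGenotype]:
        """Non-missing genotypes at a locus (per-locus deletion)."""
        j = self.locus_index(locus)
        return [row[j] for row in self.calls if not row[j].is_missing]

    def typed_count(self, locus: str) -> int:
        return len(self.genotypes_at(locus))

    def allele_counts(self, locus: str) -> dict[AlleleLabel, int]:
        counts: dict[AlleleLabel, int] = {}
        for g in self.genotypes_at(locus):
            counts[g.a1] = counts.get(g.a1, 0) + 1
            counts[g.a2] = counts.get(g.a2, 0) + 1
        return dict(sorted(counts.items()))


@dataclass
class FrequencyTable:
    """Per-locus allele frequency maps with diploid sample sizes.

    The in-memory form of a published population frequency table: for each
    locus a map ``allele -> frequency`` plus the number of typed diploid
    individuals behind it (0 when unknown, e.g. model-derived tables).
    """

    population: str
    freqs: dict[str, dict[AlleleLabel, float]]
    sample_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for locus, fmap in self.freqs.items():
            if not fmap:
                raise StrDataError(f"locus {locus!r}: empty allele set")
            for a, f in fmap.items():
                if not (0.0 < f <= 1.0):
                    raise StrDataError(f"locus {locus}: frequency of allele {a} is {f}, outside (0, 1]")
            s = sum(fmap.values())
            if abs(s - 1.0) > FREQ_SUM_TOL:
                logger.warning(
                    "frequency table %s, locus %s: column sums to %.4f (expected 1 +/- %.3f)",
                    self.population, locus, s, FREQ_SUM_TOL,
                )
        self.sample_sizes = {l: int(self.sample_sizes.get(l, 0)) for l in self.freqs}

    @property
    def loci(self) -> list[str]:
        return list(self.freqs)

    def n_allele_entries(self) -> int:
        """Total number of distinct (locus, allele) pairs."""
        return sum(len(m) for m in self.freqs.values())

    def max_frequency(self) -> float:
        return max(max(m.values()) for m in self.freqs.values())

    def renormalized(self) -> "FrequencyTable":
        """Divide every column by its sum so frequencies sum exactly to 1."""
        out = {
            locus: {a: f / s for a, f in fmap.items()}
            for locus, fmap in self.freqs.items()
            for s in (sum(fmap.values()),)
        }
        return FrequencyTable(self.population, out, dict(self.sample_sizes))

    def restricted(self, loci: Sequence[str]) -> "FrequencyTable":
        missing = [l for l in loci if l not in self.freqs]
        if missing:
            raise StrDataError(f"{self.population}: loci absent from table: {missing}")
        return FrequencyTable(
            self.population,
            {l: dict(self.freqs[l]) for l in loci},
            {l: self.sample_sizes.get(l, 0) for l in loci},
        )


@dataclass
class DistanceMatrix:
    """Symmetric labelled distance matrix with a zero diagonal.

    ``allow_negative`` flags raw FST output, where slightly negative
    pairwise estimates are legitimate; the clamped view is what feeds
    MDS and neighbor-joining.
    """

    labels: list[str]
    values: np.ndarray
    allow_negative: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise StrDataError(f"matrix shape {self.values.shape} does not match {n} labels")
        if n and np.max(np.abs(self.values - self.values.T)) > 1e-12:
            raise StrDataError("distance matrix is not symmetric within 1e-12")
        np.fill_diagonal(self.values, 0.0)
        if not self.allow_negative and n and self.values.min() < 0:
            raise StrDataError("negative off-diagonal distance in a non-FST matrix")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = self.labels.index(pair[0]), self.labels.index(pair[1])
        return float(self.values[i, j])

    def clamped(self) -> "DistanceMatrix":
        return DistanceMatrix(list(self.labels), np.maximum(self.values, 0.0))

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


# ---------------------------------------------------------------------------
# atomic writes

def atomic_write_text(path: str | os.PathLike, text: str) -> None:
    """Write via a temp file in the same directory, then rename."""
    d = os.path.dirname(os.fspath(path)) or "."
    fd, tmp = tempfile.mkstemp(dir=d, suffix=".tmp")
    try:
        with os.fdopen(fd, "w", newline="") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# ---------------------------------------------------------------------------
# genotype CSV

def _parse_cell(text: str, where: str) -> AlleleLabel | None:
    t = text.strip()
    if t in MISSING_TOKENS:
        return None
    try:
        return AlleleLabel.parse(t)
    except StrDataError as e:
        raise StrDataError(f"{where}: {e}") from None


def read_genotypes(path: str | os.PathLike, dialect: str = "long") -> GenotypeDataset:
    """Read a genotype CSV.

    long dialect — columns ``sample_id,population,locus,allele1,allele2``,
    one row per (sample, locus).  wide dialect — one row per sample with
    columns ``sample_id,population`` then two columns per locus named
    ``<locus>_1`` and ``<locus>_2``.  Blank or ``-`` allele cells mean the
    genotype is missing at that locus.
    """
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh) if r and any(c.strip() for c in r)]
    rows = [r for r in rows if not r[0].lstrip().startswith("#")]
    if not rows:
        raise StrDataError(f"{path}: empty file")
    header, body = rows[0], rows[1:]

    if dialect == "long":
        expected = ["sample_id", "population", "locus", "allele1", "allele2"]
        if [h.strip() for h in header[:5]] != expected:
            raise StrDataError(f"{path}: long dialect requires header {','.join(expected)}")
        order: list[str] = []
        pops: dict[str, str] = {}
        loci: list[str] = []
        cells: dict[tuple[str, str], LocusGenotype] = {}
        for i, r in enumerate(body, start=2):
            if len(r) < 5:
                raise StrDataError(f"{path} row {i}: expected 5 columns")
            sid, pop, locus = r[0].strip(), r[1].strip(), r[2].strip()
            if sid not in pops:
                order.append(sid)
                pops[sid] = pop
            if locus not in loci:
                loci.append(locus)
            a1 = _parse_cell(r[3], f"{path} row {i} column allele1")
            a2 = _parse_cell(r[4], f"{path} row {i} column allele2")
            if (a1 is None) != (a2 is None):
                raise StrDataError(f"{path} row {i}: half-missing genotype")
            cells[(sid, locus)] = LocusGenotype(a1, a2)
        calls = [[cells.get((sid, l), LocusGenotype.missing()) for l in loci] for sid in order]
        return GenotypeDataset(order, [pops[s] for s in order], loci, calls)

    if dialect == "wide":
        if [h.strip() for h in header[:2]] != ["sample_id", "population"]:
            raise StrDataError(f"{path}: wide dialect requires leading columns sample_id,population")
        pairs = header[2:]
        if len(pairs) % 2:
            raise StrDataError(f"{path}: odd number of allele columns")
        loci = []
        for k in range(0, len(pairs), 2):
            c1, c2 = pairs[k].strip(), pairs[k + 1].strip()
            if not (c1.endswith("_1") and c2.endswith("_2") and c1[:-2] == c2[:-2]):
                raise StrDataError(f"{path}: allele columns must be <locus>_1,<locus>_2 (got {c1},{c2})")
            loci.append(c1[:-2])
        sids, pops_l, calls = [], [], []
        for i, r in enumerate(body, start=2):
            if len(r) != 2 + 2 * len(loci):
                raise StrDataError(f"{path} row {i}: expected {2 + 2 * len(loci)} columns")
            sids.append(r[0].strip())
            pops_l.append(r[1].strip())
            row = []
            for k, locus in enumerate(loci):
                a1 = _parse_cell(r[2 + 2 * k], f"{path} row {i} column {locus}_1")
                a2 = _parse_cell(r[3 + 2 * k], f"{path} row {i} column {locus}_2")
                if (a1 is None) != (a2 is None):
                    raise StrDataError(f"{path} row {i}: half-missing genotype at {locus}")
                row.append(LocusGenotype(a1, a2))
            calls.append(row)
        return GenotypeDataset(sids, pops_l, loci, calls)

    raise StrDataError(f"unknown genotype CSV dialect {dialect!r}")


def write_genotypes(ds: GenotypeDataset, path: str | os.PathLike, dialect: str = "long") -> None:
    lines: list[str] = []
    if dialect == "long":
        lines.append("sample_id,population,locus,allele1,allele2")
        for sid, pop, row in zip(ds.sample_ids, ds.populations, ds.calls):
            for locus, g in zip(ds.loci, row):
                a1 = "" if g.is_missing else str(g.a1)
                a2 = "" if g.is_missing else str(g.a2)
                lines.append(f"{sid},{pop},{locus},{a1},{a2}")
    elif dialect == "wide":
        cols = ["sample_id", "population"]
        for l in ds.loci:
            cols += [f"{l}_1", f"{l}_2"]
        lines.append(",".join(cols))
        for sid, pop, row in zip(ds.sample_ids, ds.populations, ds.calls):
            cells = [sid, pop]
            for g in row:
                cells += ["", ""] if g.is_missing else [str(g.a1), str(g.a2)]
            lines.append(",".join(cells))
    else:
        raise StrDataError(f"unknown genotype CSV dialect {dialect!r}")
    atomic_write_text(path, "\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# frequency tables

def read_frequency_table(
    path: str | os.PathLike,
    population: str | None = None,
    n: int | Mapping[str, int] = 0,
    renormalize: bool = False,
) -> FrequencyTable:
    """Read a wide allele-frequency CSV (allele rows × locus columns).

    The first column holds allele labels; blank cells mean the allele is
    absent at that locus.  Column sums outside 1 ± 0.005 trigger a warning
    (printed tables are rounded); pass ``renormalize=True`` to divide each
    column by its sum instead.
    """
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh) if r and any(c.strip() for c in r)]
    rows = [r for r in rows if not r[0].lstrip().startswith("#")]
    if not rows:
        raise StrDataError(f"{path}: empty file")
    loci = [c.strip() for c in rows[0][1:]]
    freqs: dict[str, dict[AlleleLabel, float]] = {l: {} for l in loci}
    for i, r in enumerate(rows[1:], start=2):
        allele = AlleleLabel.parse(r[0])
        for locus, cell in zip(loci, r[1:]):
            cell = cell.strip()
            if not cell:
                continue
            f = float(cell)
            if f < 0:
                raise StrDataError(f"{path} row {i}, locus {locus}: negative frequency {f}")
            if f > 0:
                freqs[locus][allele] = f
    freqs = {l: m for l, m in freqs.items() if m}
    pop = population or os.path.splitext(os.path.basename(os.fspath(path)))[0]
    sizes = dict(n) if isinstance(n, Mapping) else {l: n for l in freqs}
    table = FrequencyTable(pop, freqs, sizes)
    return table.renormalized() if renormalize else table


def write_frequency_table(table: FrequencyTable, path: str | os.PathLike) -> None:
    loci = table.loci
    alleles = sorted({a for m in table.freqs.values() for a in m})
    lines = ["allele," + ",".join(loci)]
    for a in alleles:
        cells = [repr(table.freqs[l][a]) if a in table.freqs[l] else "" for l in loci]
        lines.append(f"{a}," + ",".join(cells))
    atomic_write_text(path, "\n".join(lines) + "\n")


def exact_frequencies_from_genotypes(
    ds: GenotypeDataset, locus: str
) -> tuple[dict[AlleleLabel, Fraction], int]:
    """Rational allele frequencies (they sum to exactly 1) with n_l."""
    counts = ds.allele_counts(locus)
    if not counts:
        raise StrDataError(f"no data at locus {locus!r}")
    n_l = ds.typed_count(locus)
    denom = 2 * n_l
    return {a: Fraction(c, denom) for a, c in counts.items()}, n_l


def frequencies_from_genotypes(
    ds: GenotypeDataset, locus: str
) -> tuple[dict[AlleleLabel, float], int]:
    """Sample allele frequencies at one locus, with the typed count n_l.

    Counts are formed over non-missing genotypes only; the division is done
    in rational arithmetic before conversion to float.
    """
    exact, n_l = exact_frequencies_from_genotypes(ds, locus)
    return {a: float(f) for a, f in exact.items()}, n_l


def frequency_table_from_genotypes(ds: GenotypeDataset, population: str | None = None) -> FrequencyTable:
    freqs, sizes = {}, {}
    for locus in ds.loci:
        f, n_l = frequencies_from_genotypes(ds, locus)
        freqs[locus], sizes[locus] = f, n_l
    pop = population or (ds.populations[0] if ds.populations else "pop")
    return FrequencyTable(pop, freqs, sizes)


# ---------------------------------------------------------------------------
# GenePop 4

_GENEPOP_MICRO_BASE = 900


def _genepop_code_table(ds: GenotypeDataset) -> dict[str, dict[AlleleLabel, int]]:
    """Integer codes per locus: integer alleles code as their repeat count,
    microvariants get successive codes from 900 up (bijective, recorded in
    the file's title line)."""
    table: dict[str, dict[AlleleLabel, int]] = {}
    for locus in ds.loci:
        alleles = sorted({a for g in ds.genotypes_at(locus) for a in (g.a1, g.a2)})
        if len(alleles) > 999:
            raise StrDataError(f"locus {locus}: more than 999 distinct alleles")
        codes: dict[AlleleLabel, int] = {}
        nxt = _GENEPOP_MICRO_BASE
        for a in alleles:
            if a.tenths % 10 == 0 and a.tenths // 10 <= 999:
                codes[a] = a.tenths // 10
            else:
                codes[a] = nxt
                nxt += 1
        if len(set(codes.values())) != len(codes) or any(c > 999 for c in codes.values()):
            raise StrDataError(f"locus {locus}: cannot assign unique 3-digit GenePop codes")
        table[locus] = codes
    return table


def write_genepop(ds: GenotypeDataset, path: str | os.PathLike, title: str = "strpopkit export") -> None:
    """Write GenePop 4 text, one ``Pop`` block per population label.

    Microvariant alleles cannot be coded as their repeat count (GenePop
    codes are integers), so each gets an unused code >= 900; the mapping is
    embedded in the title line as ``locus:allele=code`` entries and is
    parsed back by :func:`read_genepop`.
    """
    codes = _genepop_code_table(ds)
    micro = [
        f"{locus}:{a}={c}"
        for locus, cmap in codes.items()
        for a, c in sorted(cmap.items())
        if c >= _GENEPOP_MICRO_BASE
    ]
    head = title + (" | microvariant codes " + " ".join(micro) if micro else "")
    lines = [head]
    lines += ds.loci
    by_pop: dict[str, list[int]] = {}
    for i, pop in enumerate(ds.populations):
        by_pop.setdefault(pop, []).append(i)
    for pop, idxs in by_pop.items():
        lines.append("Pop")
        for i in idxs:
            cells = []
            for locus, g in zip(ds.loci, ds.calls[i]):
                if g.is_missing:
                    cells.append("000000")
                else:
                    cells.append(f"{codes[locus][g.a1]:03d}{codes[locus][g.a2]:03d}")
            lines.append(f"{ds.sample_ids[i]} , " + " ".join(cells))
    atomic_write_text(path, "\n".join(lines) + "\n")


def read_genepop(path: str | os.PathLike) -> GenotypeDataset:
    """Read GenePop 4 text written by :func:`write_genepop`."""
    with open(path) as fh:
        lines = [l.rstrip("\n") for l in fh if l.strip()]
    title = lines[0]
    micro: dict[str, dict[int, AlleleLabel]] = {}
    if "microvariant codes" in title:
        for entry in title.split("microvariant codes", 1)[1].split():
            loc_part, code = entry.rsplit("=", 1)
            locus, allele = loc_part.split(":", 1)
            micro.setdefault(locus, {})[int(code)] = AlleleLabel.parse(allele)
    loci: list[str] = []
    k = 1
    while k < len(lines) and lines[k].strip().lower() != "pop":
        loci.extend(x.strip() for x in lines[k].split(",") if x.strip())
        k += 1
    sids, pops, calls = [], [], []
    pop_no = 0
    for line in lines[k:]:
        if line.strip().lower() == "pop":
            pop_no += 1
            continue
        sid, geno = line.split(",", 1)
        sids.append(sid.strip())
        pops.append(f"pop{pop_no}")
        row = []
        for locus, cell in zip(loci, geno.split()):
            c1, c2 = int(cell[:3]), int(cell[3:6])
            if c1 == 0 or c2 == 0:
                row.append(LocusGenotype.missing())
            else:
                def decode(c: int) -> AlleleLabel:
                    if c in micro.get(locus, {}):
                        return micro[locus][c]
                    return AlleleLabel(c * 10)
                row.append(LocusGenotype(decode(c1), decode(c2)))
        calls.append(row)
    return GenotypeDataset(sids, pops, loci, calls)


# ---------------------------------------------------------------------------
# PHYLIP distances and Newick

def write_phylip_distances(dm: DistanceMatrix, path: str | os.PathLike) -> None:
    """Square PHYLIP distance matrix; labels are truncated to 10 characters
    and a truncation collision is an error."""
    if not dm.labels:
        raise StrDataError("empty distance matrix")
    short = [l[:10] for l in dm.labels]
    if len(set(short)) != len(short):
        colliding = sorted({s for s in short if short.count(s) > 1})
        raise StrDataError(f"PHYLIP label truncation collision: {', '.join(colliding)}")
    lines = [f"{len(dm.labels):5d}"]
    for name, row in zip(short, dm.values):
        lines.append(f"{name:<10s}" + "".join(f" {v:12.8f}" for v in row))
    atomic_write_text(path, "\n".join(lines) + "\n")


def read_phylip_distances(path: str | os.PathLike) -> DistanceMatrix:
    with open(path) as fh:
        lines = [l.rstrip("\n") for l in fh if l.strip()]
    n = int(lines[0])
    labels, rows = [], []
    for line in lines[1 : n + 1]:
        labels.append(line[:10].strip())
        rows.append([float(x) for x in line[10:].split()])
    return DistanceMatrix(labels, np.array(rows), allow_negative=True)


def write_newick(newick: str, path: str | os.PathLike) -> None:
    if not newick.rstrip().endswith(";"):
        newick = newick.rstrip() + ";"
    atomic_write_text(path, newick + "\n")
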