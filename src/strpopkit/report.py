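"""Assembled analysis reports: CSV tables plus a human-readable summary.

Every output file starts with a comment header carrying the package
version and a hash of the run configuration, so two runs with the same
config hash produce identical payloads.  Printed tables are rounded
half-even to a configurable number of decimals; the combined panel
parameters are additionally written as extended-precision digit strings
(the combined discrimination power of a 20-locus panel has ~24 leading
nines, which a float cannot represent).
"""

from __future__ import annotations

import hashlib
import io
import json
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .equilibrium import HweResult, LdResult, ld_matrix
from .forensic import CombinedParams
from .str_data import DistanceMatrix, atomic_write_text


def config_hash(config: Mapping) -> str:
    """Stable short hash of a run configuration mapping."""
    blob = json.dumps({k: repr(v) for k, v in sorted(config.items())}, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def output_header(config: Mapping) -> str:
    return f"# strpopkit v{__version__} config={config_hash(config)}\n"


def write_csv(df: pd.DataFrame, path: str, config: Mapping, digits: int = 4) -> None:
    """Write a table with the standard comment header, rounding half-even."""
    buf = io.StringIO()
    buf.write(output_header(config))
    rounded = df.copy()
    for c in rounded.columns:
        if pd.api.types.is_float_dtype(rounded[c]):
            rounded[c] = rounded[c].map(
                lambda x: float(np.format_float_positional(x, precision=digits,
                                                           unique=False, fractional=True))
                if pd.notna(x) else x
            )
    rounded.to_csv(buf)
    atomic_write_text(path, buf.getvalue())


@dataclass
class ReportBundle:
    files: list[str]
    summary: str


def make_report(
    profile: pd.DataFrame,
    combined: CombinedParams,
    hwe: list[HweResult] | None = None,
    ld: list[LdResult] | None = None,
    distances: tuple[DistanceMatrix, DistanceMatrix] | None = None,
    out_prefix: str = "report",
    config: Mapping | None = None,
    digits: int = 4,
) -> ReportBundle:
    """Assemble the analysis outputs into CSVs plus one summary text."""
    config = dict(config or {})
    files: list[str] = []
    lines: list[str] = [output_header(config).rstrip("\n"), ""]

    path = f"{out_prefix}_params.csv"
    write_csv(profile, path, config, digits)
    files.append(path)
    lines.append(f"Forensic parameters for {len(profile)} loci -> {path}")
    if combined.cdp_digits:
        lines.append(f"  combined power of discrimination  CDP = {combined.cdp_digits}")
    if combined.cpe_duo_digits:
        lines.append(f"  combined exclusion (duo cases)    CPE_duo = {combined.cpe_duo_digits}")
    if combined.cpe_trio_digits:
        lines.append(f"  combined exclusion (trio cases)   CPE_trio = {combined.cpe_trio_digits}")

    if hwe:
        df = pd.DataFrame(
            {
                "locus": [r.locus for r in hwe],
                "p_value": [r.p_value for r in hwe],
                "method": [r.method for r in hwe],
                "mc_error": [r.mc_error for r in hwe],
            }
        ).set_index("locus")
        path = f"{out_prefix}_hwe.csv"
        write_csv(df, path, config, digits)
        files.append(path)
        below = int((df["p_value"] < 0.05).sum())
        lines.append(f"HWE exact tests: {below}/{len(df)} loci with P < 0.05 -> {path}")

    if ld:
        loci = list(dict.fromkeys([r.locus_a for r in ld] + [r.locus_b for r in ld]))
        df = ld_matrix(ld, loci)
        path = f"{out_prefix}_ld.csv"
        write_csv(df, path, config, digits)
        files.append(path)
        sig = sum(bool(r.significant_after_correction) for r in ld)
        lines.append(f"LD permutation tests: {sig}/{len(ld)} pairs significant after "
                     f"Bonferroni correction -> {path}")

    if distances is not None:
        da, fst = distances
        for dm, tag in ((da, "da"), (fst, "fst")):
            path = f"{out_prefix}_{tag}.csv"
            write_csv(dm.to_dataframe(), path, config, digits)
            files.append(path)
        lines.append(f"Distance matrices ({len(da.labels)} populations) -> "
                     f"{out_prefix}_da.csv, {out_prefix}_fst.csv")

    summary = "\n".join(lines) + "\n"
    path = f"{out_prefix}_summary.txt"
    atomic_write_text(path, summary)
    files.append(path)
    return ReportBundle(files, summary)
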