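"""Packaged experimental/predicted pKa benchmark tables and their scoring.

Two literature benchmark sets ship with the package: the hyperstable
staphylococcal nuclease variant Delta+PHS (19 acidic/His residues;
methods pHtMD, conventional CpHMD, PROPKA) and the E. coli acid-stress
chaperone HdeA (13 Asp/Glu residues; methods pHtMD, pH-REMD on dimer and
monomer, PROPKA).  Rows enter the deviation summaries only when a point
experimental pKa exists and every compared method made a prediction;
experimental bounds (e.g. "<2.2") are stored as bounds and excluded.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

_DATA_FILES = {
    "snase": "snase_table1.tsv",
    "hdea": "hdea_table2.tsv",
}

# sha256 of the packaged tables, guarding against silent edits
_EXPECTED_SHA256 = {
    "snase_table1.tsv": "ac604695ac3ebda2d9df7adb75627c6c4a83f6f43320b975b0a767b2aa7953ae",
    "hdea_table2.tsv": "950612ac2e562153c798c94ed31795146f5f7791b666858b002eb2450567b5da",
}


@dataclass
class PkaTable:
    """A residue-by-method pKa comparison table.

    ``data`` columns: ``residue``, ``exp_pka`` (float, NaN when missing or
    a bound), ``exp_bound`` (original bound string or None), one column
    per method plus ``<method>_dev`` holding the printed two-decimal
    deviation, and ``include`` flags for summary rows.
    """

    name: str
    data: pd.DataFrame
    methods: tuple[str, ...]

    def included(self) -> pd.DataFrame:
        return self.data[self.data["include"]]

    def validate(self) -> None:
        inc = self.included()
        if inc["exp_pka"].isna().any():
            raise ValueError("included rows must have point experimental values")
        for m in self.methods:
            if inc[m].isna().any():
                raise ValueError(f"included rows must have a {m} prediction")


@dataclass
class DeviationSummary:
    method: str
    sum_abs_dev: float
    mean_abs_dev: float
    n: int


def _parse_cell(v: str) -> float:
    v = v.strip()
    if v in ("-", ""):
        return math.nan
    if v.startswith(("<", ">")):
        return math.nan
    return float(v)


def _load_table(name: str) -> PkaTable:
    fname = _DATA_FILES[name]
    raw = resources.files("phtmd.data").joinpath(fname).read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _EXPECTED_SHA256[fname]:
        raise ValueError(f"packaged table {fname} is corrupted (sha256 mismatch)")
    df = pd.read_csv(pd.io.common.BytesIO(raw), sep="\t", dtype=str)
    methods = tuple(
        c for c in df.columns if c not in ("residue", "exp_pka", "include", "notes") and not c.endswith("_dev")
    )
    out = pd.DataFrame({"residue": df["residue"]})
    out["exp_bound"] = [
        v.strip() if isinstance(v, str) and v.strip().startswith(("<", ">")) else None
        for v in df["exp_pka"]
    ]
    out["exp_pka"] = [_parse_cell(v) for v in df["exp_pka"]]
    for m in methods:
        out[m] = [_parse_cell(v) for v in df[m]]
        out[f"{m}_dev"] = [_parse_cell(v) for v in df[f"{m}_dev"]]
    out["include"] = df["include"].str.strip().str.lower() == "true"
    out["notes"] = df["notes"]
    table = PkaTable(name=name, data=out, methods=methods)
    table.validate()
    return table


def load_builtin_tables() -> dict[str, PkaTable]:
    """Load the packaged benchmark tables (keys ``snase`` and ``hdea``)."""
    return {name: _load_table(name) for name in _DATA_FILES}


def deviation_summary(
    table: PkaTable, method: str, mode: str = "printed", allow_empty: bool = False
) -> DeviationSummary:
    """Sum and mean of |predicted - experimental| over included rows.

    ``mode='printed'`` (default) sums the two-decimal per-row deviations
    as printed alongside the predictions, reproducing the published
    summary rows exactly; ``mode='recomputed'`` recomputes deviations from
    the pKa columns before rounding the summary.
    """
    if method not in table.methods:
        raise KeyError(
            f"method {method!r} not in table {table.name!r}; available: {list(table.methods)}"
        )
    if mode not in ("printed", "recomputed"):
        raise ValueError("mode must be 'printed' or 'recomputed'")
    inc = table.included()
    n = len(inc)
    if n == 0:
        if allow_empty:
            return DeviationSummary(method=method, sum_abs_dev=math.nan, mean_abs_dev=math.nan, n=0)
        raise ValueError(f"table {table.name!r} has no rows included in the summary")
    if mode == "printed":
        devs = inc[f"{method}_dev"].to_numpy(dtype=float)
    else:
        devs = np.abs(inc[method].to_numpy(dtype=float) - inc["exp_pka"].to_numpy(dtype=float))
    total = float(devs.sum())
    return DeviationSummary(
        method=method,
        sum_abs_dev=round(total, 2),
        mean_abs_dev=round(total / n, 2),
        n=n,
    )


def render_report(table: PkaTable) -> str:
    """Plain-text comparison report of a benchmark table."""
    lines = [f"Benchmark table: {table.name} ({len(table.data)} residues)"]
    header = ["residue", "exp"] + [m for m in table.methods]
    lines.append("  ".join(f"{h:>14s}" for h in header))
    for row in table.data.itertuples(index=False):
        exp = row.exp_bound if row.exp_bound else (f"{row.exp_pka:.2f}" if not math.isnan(row.exp_pka) else "-")
        cells = [f"{row.residue:>14s}", f"{exp:>14s}"]
        for m in table.methods:
            v = getattr(row, m)
            cells.append(f"{v:>14.2f}" if not math.isnan(v) else f"{'-':>14s}")
        lines.append("  ".join(cells))
    for m in table.methods:
        s = deviation_summary(table, m)
        lines.append(
            f"{m}: sum of |dev| = {s.sum_abs_dev:.2f}, mean = {s.mean_abs_dev:.2f} over {s.n} residues"
        )
    return "\n".join(lines)
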