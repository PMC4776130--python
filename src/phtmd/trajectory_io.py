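"""Readers and writers bridging constant-pH MD output and window summaries.

Two text dialects are handled:

* AMBER-style constant-pH output ("cpout"): blocks separated by blank
  lines.  A *full* record starts with a ``Solvent pH:`` line and lists the
  state of every titrating residue; a *delta* record lists only residues
  whose state changed since the previous frame.  Both variants (full
  record every frame, or full + delta) are accepted; a block is a full
  record iff it carries a ``Solvent pH:`` line.
* Whitespace-delimited per-frame SASA tables (cpptraj-style) with a header
  row of site labels.

Raw cpout state indices are mapped to deprotonation indicators via a
per-residue-type state table; for histidine the "deprotonated" indicator
means *singly protonated* (the two neutral tautomers are aggregated).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: residue-type -> set of raw state indices that count as "deprotonated"
#: (for HIP: singly protonated).  AMBER-style defaults: carboxylates AS4 and
#: GL4 have one deprotonated (state 0) and four syn/anti protonated forms;
#: HIP state 0 is doubly protonated, 1-2 the neutral tautomers; LYS/CYS/TYR
#: state 0 protonated, 1 deprotonated.
DEFAULT_STATE_MAP: dict[str, frozenset[int]] = {
    "AS4": frozenset({0}),
    "GL4": frozenset({0}),
    "HIP": frozenset({1, 2}),
    "LYS": frozenset({1}),
    "CYS": frozenset({1}),
    "TYR": frozenset({1}),
}


@dataclass
class WindowSummary:
    """One titration data point: a constant-pH window reduced to numbers."""

    ph: float
    site_id: str
    f_deprot: float
    n_transitions: int
    sasa_frac: float | None = None
    n_samples: int = 0
    valid: bool = True

    def __post_init__(self) -> None:
        if self.n_samples == 0:
            self.valid = False
        if self.n_samples > 0 and not 0.0 <= self.f_deprot <= 1.0:
            raise ValueError(f"f_deprot must be in [0, 1], got {self.f_deprot}")
        if self.n_samples > 0 and self.n_transitions > self.n_samples - 1:
            raise ValueError("n_transitions cannot exceed n_samples - 1")


@dataclass
class CpoutFrames:
    """Per-frame reconstruction of a constant-pH output stream."""

    ph: np.ndarray  # (n_frames,)
    states: np.ndarray  # (n_frames, n_residues) raw state indices
    indicators: np.ndarray  # (n_frames, n_residues) 0/1 deprotonation
    residue_types: list[str]


def read_cpout(
    stream,
    residue_types: Sequence[str],
    state_map: Mapping[str, Iterable[int]] | None = None,
) -> CpoutFrames:
    """Parse constant-pH MD output into per-frame states and indicators.

    Parameters
    ----------
    stream
        Text stream or string of cpout records.
    residue_types
        Residue type label per titrating residue, in residue-index order;
        used to map raw state indices through ``state_map``.
    state_map
        Overrides/extends :data:`DEFAULT_STATE_MAP`.
    """
    if isinstance(stream, str):
        lines = stream.splitlines()
    else:
        lines = stream.read().splitlines()
    smap = dict(DEFAULT_STATE_MAP)
    if state_map:
        smap.update({k: frozenset(v) for k, v in state_map.items()})
    for rt in residue_types:
        if rt not in smap:
            raise ValueError(
                f"no protonation-state mapping for residue type {rt!r}; "
                "supply one via state_map"
            )

    nres = len(residue_types)
    # split into blank-line-separated blocks
    blocks: list[list[str]] = []
    cur: list[str] = []
    for ln in lines:
        if ln.strip():
            cur.append(ln)
        elif cur:
            blocks.append(cur)
            cur = []
    if cur:
        blocks.append(cur)

    phs: list[float] = []
    states: list[np.ndarray] = []
    current: np.ndarray | None = None
    current_ph: float | None = None
    for bi, block in enumerate(blocks):
        try:
            is_full = any(ln.lstrip().startswith("Solvent pH:") for ln in block)
            updates: dict[int, int] = {}
            ph_here = current_ph
            for ln in block:
                s = ln.strip()
                if s.startswith("Solvent pH:"):
                    ph_here = float(s.split(":", 1)[1])
                elif s.startswith("Residue"):
                    parts = s.replace(":", " ").split()
                    # "Residue <k> State <m>"
                    k = int(parts[1])
                    m = int(parts[parts.index("State") + 1])
                    if not 0 <= k < nres:
                        raise ValueError(f"residue index {k} out of range")
                    updates[k] = m
            if is_full:
                if len(updates) != nres:
                    raise ValueError(
                        f"full record lists {len(updates)} of {nres} residues"
                    )
                current = np.zeros(nres, dtype=np.int64)
                for k, m in updates.items():
                    current[k] = m
                current_ph = ph_here
            else:
                if current is None:
                    raise ValueError(
                        "constant-pH output starts with a delta record; a full "
                        "record with 'Solvent pH:' must come first"
                    )
                current = current.copy()
                for k, m in updates.items():
                    current[k] = m
        except ValueError:
            if current is None or bi < len(blocks) - 1:
                raise
            warnings.warn("dropping trailing partial cpout record", stacklevel=2)
            break
        phs.append(float(current_ph))
        states.append(current)

    if not states:
        raise ValueError("no frames found in constant-pH output")
    state_mat = np.stack(states)
    ind = np.zeros_like(state_mat, dtype=np.uint8)
    for j, rt in enumerate(residue_types):
        ind[:, j] = np.isin(state_mat[:, j], list(smap[rt])).astype(np.uint8)
    return CpoutFrames(
        ph=np.asarray(phs), states=state_mat, indicators=ind, residue_types=list(residue_types)
    )


def windows_from_cpout(
    frames: CpoutFrames,
    site_ids: Sequence[str],
    sasa: pd.DataFrame | None = None,
) -> list[WindowSummary]:
    """Bin cpout frames into windows by contiguous runs of constant pH.

    The ramped protocol changes solvent pH between runs, so a window is a
    maximal run of frames with identical recorded pH.  ``f_deprot`` is the
    exact mean deprotonation indicator over the frames of each window.
    """
    if len(site_ids) != frames.indicators.shape[1]:
        raise ValueError("site_ids length must match the number of residues")
    # run-length encode the pH series
    ph = frames.ph
    boundaries = np.flatnonzero(np.diff(ph) != 0.0) + 1
    starts = np.concatenate([[0], boundaries])
    stops = np.concatenate([boundaries, [len(ph)]])
    out: list[WindowSummary] = []
    for a, b in zip(starts, stops):
        ind = frames.indicators[a:b]
        nsamp = b - a
        for j, sid in enumerate(site_ids):
            col = ind[:, j]
            sasa_frac = None
            if sasa is not None and sid in sasa.columns:
                v = sasa[sid].to_numpy()[a:b]
                v = v[~np.isnan(v)]
                sasa_frac = float(v.mean()) if v.size else None
            out.append(
                WindowSummary(
                    ph=float(ph[a]),
                    site_id=sid,
                    f_deprot=float(col.mean()),
                    n_transitions=int((col[1:] != col[:-1]).sum()),
                    sasa_frac=sasa_frac,
                    n_samples=int(nsamp),
                )
            )
    return out


def read_sasa_table(stream, reference_max: Mapping[str, float]) -> pd.DataFrame:
    """Parse a per-frame SASA table and normalize by reference maxima.

    The table is whitespace-delimited with a header row of site labels
    (an optional leading ``#Frame``/``Frame`` column is treated as frame
    index).  Every site column must have a reference maximum SASA (in the
    same units, typically A^2); output values are fractions of it.
    """
    if isinstance(stream, str):
        import io

        stream = io.StringIO(stream)
    header = stream.readline().split()
    if not header:
        raise ValueError("empty SASA table")
    if header[0].lstrip("#").lower() == "frame":
        cols = header[1:]
        has_frame = True
    else:
        cols = header
        has_frame = False
    for c in cols:
        if c not in reference_max:
            raise ValueError(f"no reference maximum SASA for site {c!r}")
    rows = []
    for lineno, ln in enumerate(stream, start=2):
        if not ln.strip():
            continue
        parts = ln.split()
        if has_frame:
            parts = parts[1:]
        if len(parts) != len(cols):
            raise ValueError(f"line {lineno}: expected {len(cols)} values, got {len(parts)}")
        vals = []
        for c, p in zip(cols, parts):
            if p in ("nan", "NA", "NaN", "-"):
                vals.append(math.nan)
            else:
                try:
                    vals.append(float(p))
                except ValueError:
                    raise ValueError(f"line {lineno}: non-numeric SASA value {p!r}") from None
        rows.append(vals)
    df = pd.DataFrame(rows, columns=cols, dtype=float)
    for c in cols:
        df[c] = df[c] / float(reference_max[c])
    return df


_SUMMARY_COLUMNS = ["ph", "site_id", "f_deprot", "n_transitions", "sasa_frac", "n_samples", "valid"]


def summaries_to_frame(summaries: Sequence[WindowSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "ph": s.ph,
                "site_id": s.site_id,
                "f_deprot": s.f_deprot,
                "n_transitions": s.n_transitions,
                "sasa_frac": math.nan if s.sasa_frac is None else s.sasa_frac,
                "n_samples": s.n_samples,
                "valid": bool(s.valid),
            }
            for s in summaries
        ],
        columns=_SUMMARY_COLUMNS,
    )


def write_window_summaries(summaries: Sequence[WindowSummary], path_or_stream) -> None:
    """Write window summaries as a comma-separated table (>=12 sig. digits)."""
    df = summaries_to_frame(summaries)
    df.to_csv(path_or_stream, index=False, float_format="%.12g")


def read_window_summaries(path_or_stream) -> list[WindowSummary]:
    df = pd.read_csv(path_or_stream)
    missing = set(_SUMMARY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"window-summary table missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        s = WindowSummary(
            ph=float(row.ph),
            site_id=str(row.site_id),
            f_deprot=float(row.f_deprot),
            n_transitions=int(row.n_transitions),
            sasa_frac=None if pd.isna(row.sasa_frac) else float(row.sasa_frac),
            n_samples=int(row.n_samples),
        )
        s.valid = bool(row.valid)
        out.append(s)
    return out
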