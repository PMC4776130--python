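"""From protonation traces to pKa values.

Pipeline: windowed deprotonated fractions and transition counts ->
solvent-exposure filtering (points with side-chain SASA below 30% of the
model-compound maximum are excluded) -> weighted Hill fit

    f_deprot(pH) = 1 / (1 + 10^{n (pKa - pH)})

-> replicate averaging, ramp combination, hysteresis and net-charge
profiles.  A fit is refused (no pKa reported) when the valid fractions
never bracket the titration midpoint, the situation of residues buried
over the whole scanned range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .samplers import ProtonationTrace
from .titration_model import SiteSystem, analytic_hill_curve
from .trajectory_io import WindowSummary

SASA_THRESHOLD = 0.30
HILL_N_MAX = 5.0


@dataclass
class TitrationFit:
    """Result of fitting one site's titration curve."""

    site_id: str
    pka: float | None
    hill_n: float | None
    n_points_used: int
    n_points_excluded_sasa: int = 0
    n_points_excluded_invalid: int = 0
    converged: bool = False
    residual_norm: float = math.nan
    reason: str = ""

    def __post_init__(self) -> None:
        if not self.converged:
            self.pka = None
            self.hill_n = None
        elif self.hill_n is not None and self.hill_n <= 0:
            raise ValueError("converged fit must have positive Hill coefficient")


def summarize_windows(
    traces: Sequence[ProtonationTrace],
    site_ids: Sequence[str],
    sasa: Mapping[str, Sequence[float]] | None = None,
    equilibration_fraction: float = 0.0,
) -> list[WindowSummary]:
    """Reduce each window's samples to one data point per site.

    ``f_deprot`` is the mean deprotonation indicator over the recorded
    samples (after discarding the leading ``equilibration_fraction``);
    ``n_transitions`` counts state changes between consecutive recorded
    samples.  ``sasa`` maps site_id to either one SASA fraction per window
    or one per recorded frame (then window-averaged).
    """
    if not 0.0 <= equilibration_fraction < 1.0:
        raise ValueError("equilibration_fraction must be in [0, 1)")
    nw = len(traces)
    total_frames = sum(t.samples.shape[0] for t in traces)
    out: list[WindowSummary] = []
    frame_offset = 0
    for w, trace in enumerate(traces):
        samp = trace.samples
        skip = int(samp.shape[0] * equilibration_fraction)
        kept = samp[skip:]
        for j, sid in enumerate(site_ids):
            col = kept[:, j]
            sasa_frac = None
            if sasa is not None and sid in sasa:
                series = np.asarray(sasa[sid], dtype=float)
                if series.shape[0] == nw:
                    sasa_frac = float(series[w])
                elif series.shape[0] == total_frames:
                    seg = series[frame_offset : frame_offset + samp.shape[0]]
                    seg = seg[~np.isnan(seg)]
                    sasa_frac = float(seg.mean()) if seg.size else None
                else:
                    raise ValueError(
                        f"sasa series for {sid!r} has length {series.shape[0]}; expected "
                        f"{nw} (per window) or {total_frames} (per frame)"
                    )
            out.append(
                WindowSummary(
                    ph=trace.ph,
                    site_id=sid,
                    f_deprot=float(col.mean()) if col.size else 0.0,
                    n_transitions=int((col[1:] != col[:-1]).sum()),
                    sasa_frac=sasa_frac,
                    n_samples=int(col.size),
                )
            )
        frame_offset += samp.shape[0]
    return out


def sasa_filter(
    summaries: Sequence[WindowSummary], threshold: float = SASA_THRESHOLD
) -> list[WindowSummary]:
    """Invalidate points whose side chain is buried (SASA fraction < threshold).

    Strictly-less comparison: a point exactly at the threshold is retained.
    Points without SASA information are untouched.  Fractions are never
    modified, only the validity flags.
    """
    out = []
    for s in summaries:
        t = WindowSummary(
            ph=s.ph,
            site_id=s.site_id,
            f_deprot=s.f_deprot,
            n_transitions=s.n_transitions,
            sasa_frac=s.sasa_frac,
            n_samples=s.n_samples,
        )
        t.valid = s.valid and not (s.sasa_frac is not None and s.sasa_frac < threshold)
        out.append(t)
    return out


def _initial_pka(ph: np.ndarray, f: np.ndarray) -> float:
    """pH at which f crosses 0.5, by linear interpolation on sorted data."""
    order = np.argsort(ph)
    ph, f = ph[order], f[order]
    above = f >= 0.5
    for k in range(len(f) - 1):
        if above[k] != above[k + 1]:
            f0, f1 = f[k], f[k + 1]
            if f1 == f0:
                return float(0.5 * (ph[k] + ph[k + 1]))
            return float(ph[k] + (0.5 - f0) * (ph[k + 1] - ph[k]) / (f1 - f0))
    return float(np.median(ph))


def fit_hill(
    summaries: Sequence[WindowSummary],
    site_id: str | None = None,
    midpoint_margin: float = 0.05,
    min_points: int = 4,
) -> TitrationFit:
    """Weighted nonlinear least-squares Hill fit for one site.

    Points are weighted by their sample counts.  The fit is refused
    (``converged=False``, no pKa) when fewer than ``min_points`` valid
    points remain or when the valid fractions never bracket the midpoint
    (all below 0.5 + margin or all above 0.5 - margin), which is the
    signature of a residue that does not titrate in the scanned range.
    """
    rows = list(summaries)
    if site_id is None:
        ids = {s.site_id for s in rows}
        if len(ids) != 1:
            raise ValueError(f"summaries contain multiple sites {sorted(ids)}; pass site_id")
        site_id = ids.pop()
    else:
        rows = [s for s in rows if s.site_id == site_id]
        if not rows:
            raise ValueError(f"no summaries for site {site_id!r}")

    n_sasa = sum(1 for s in rows if s.n_samples > 0 and s.sasa_frac is not None and not s.valid)
    n_invalid = sum(1 for s in rows if not s.valid) - n_sasa
    valid = [s for s in rows if s.valid]

    def refused(reason: str) -> TitrationFit:
        return TitrationFit(
            site_id=site_id,
            pka=None,
            hill_n=None,
            n_points_used=len(valid),
            n_points_excluded_sasa=n_sasa,
            n_points_excluded_invalid=n_invalid,
            converged=False,
            reason=reason,
        )

    if len(valid) < min_points:
        return refused(f"only {len(valid)} valid points (< {min_points})")
    ph = np.array([s.ph for s in valid])
    f = np.array([s.f_deprot for s in valid])
    w = np.array([s.n_samples for s in valid], dtype=float)
    if f.min() > 0.5 - midpoint_margin or f.max() < 0.5 + midpoint_margin:
        return refused(
            "deprotonated fractions never bracket the titration midpoint; "
            "site does not titrate in the scanned pH range"
        )

    p0 = np.array([_initial_pka(ph, f), 1.0])
    lo = np.array([ph.min() - 2.0, 1e-3])
    hi = np.array([ph.max() + 2.0, HILL_N_MAX])
    p0 = np.clip(p0, lo + 1e-9, hi - 1e-9)
    sigma = 1.0 / np.sqrt(w / w.max())

    def model(x, pka, n):
        return analytic_hill_curve(pka, n, x)

    try:
        popt, _ = curve_fit(model, ph, f, p0=p0, bounds=(lo, hi), sigma=sigma, maxfev=10000)
    except RuntimeError as exc:  # pragma: no cover - pathological data
        return refused(f"least-squares did not converge: {exc}")
    resid = f - model(ph, *popt)
    return TitrationFit(
        site_id=site_id,
        pka=float(popt[0]),
        hill_n=float(popt[1]),
        n_points_used=len(valid),
        n_points_excluded_sasa=n_sasa,
        n_points_excluded_invalid=n_invalid,
        converged=True,
        residual_norm=float(np.sqrt(np.mean(resid**2))),
    )


def combine_ramps(
    summaries_a: Sequence[WindowSummary], summaries_b: Sequence[WindowSummary]
) -> list[WindowSummary]:
    """Merge two runs (e.g. 7->2 and 7->12) into one pH-sorted dataset.

    Windows at identical pH are all kept; the fit treats them as
    replicate points.
    """
    merged = list(summaries_a) + list(summaries_b)
    merged.sort(key=lambda s: (s.ph, s.site_id))
    return merged


@dataclass
class ReplicateSummary:
    """Unweighted mean/SD of fitted pKa values over converged replicates."""

    mean_pka: float | None
    sd_pka: float | None
    values: list[float | None]
    n_converged: int

    def rounded(self, ndigits: int = 2) -> float | None:
        return None if self.mean_pka is None else round(self.mean_pka, ndigits)


def average_replicates(fits: Sequence[TitrationFit]) -> ReplicateSummary:
    """Arithmetic mean and sample SD over converged replicate fits."""
    values = [f.pka if f.converged else None for f in fits]
    ok = [v for v in values if v is not None]
    if not ok:
        return ReplicateSummary(mean_pka=None, sd_pka=None, values=values, n_converged=0)
    mean = float(np.mean(ok))
    sd = float(np.std(ok, ddof=1)) if len(ok) > 1 else None
    return ReplicateSummary(mean_pka=mean, sd_pka=sd, values=values, n_converged=len(ok))


def hysteresis(fit_forward: TitrationFit, fit_backward: TitrationFit) -> float | None:
    """|pKa_forward - pKa_backward|; None if either fit was refused."""
    if not (fit_forward.converged and fit_backward.converged):
        return None
    return abs(fit_forward.pka - fit_backward.pka)


def net_charge_curve(
    traces: Sequence[ProtonationTrace], system: SiteSystem
) -> np.ndarray:
    """Mean total charge per window: one (pH, charge) point per window.

    Charge = sum of state-dependent site charges plus static perturber
    charges, averaged over the window's recorded samples.
    """
    cp = system.charge_prot
    static = system.static_charge_total()
    out = np.empty((len(traces), 2))
    for k, tr in enumerate(traces):
        mean_d = tr.samples.mean(axis=0)
        out[k, 0] = tr.ph
        out[k, 1] = float((cp - mean_d).sum() + static)
    return out
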