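"""Synthetic systems and data generators.

Everything the test suite titrates is generated here: single-site
model-compound systems (Ace-X-Nme analogues), a two-cysteine pentapeptide
analogue with charged termini (calibrated so its exact titration midpoints
match the literature-reported shifted cysteine pKa values 8.14 and 9.41),
a buried-residue scenario for exercising the solvent-exposure filter, and
synthetic constant-pH-output / SASA text files for the readers.

All generators are deterministic for a given seed and every writer
round-trips through its reader.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import numpy as np
import yaml
from scipy.optimize import brentq, fsolve

from .samplers import ProtonationTrace, Schedule, run_phtmd
from .titration_model import SiteSystem, StaticCharge, TitratableSite, exact_titration_curve

ACFCA_TARGET_PKAS = (8.14, 9.41)  # shifted Cys2 / Cys4 midpoints to reproduce
CYS_PKA_REF = 8.5


@lru_cache(maxsize=1)
def model_pka_table() -> dict[str, dict]:
    """Reference pKa / kind per model-compound side chain (packaged config)."""
    text = resources.files("phtmd.data").joinpath("model_pkas.yaml").read_text()
    return yaml.safe_load(text)


def model_compound(kind: str, pka_ref: float | None = None) -> SiteSystem:
    """Single uncoupled titratable site emulating an Ace-X-Nme model peptide.

    ``kind`` is one of asp, glu, his, cys, tyr, lys (case-insensitive).
    """
    table = model_pka_table()
    key = kind.lower()
    if key not in table:
        raise ValueError(f"unknown model compound {kind!r}; expected one of {sorted(table)}")
    entry = table[key]
    pka = float(entry["pka_ref"]) if pka_ref is None else float(pka_ref)
    if entry["kind"] == "base":
        cp, cd = 1, 0
    else:
        cp, cd = 0, -1
    site = TitratableSite(
        site_id=key, pka_ref=pka, charge_prot=cp, charge_deprot=cd, kind=entry["kind"]
    )
    return SiteSystem([site])


def _exact_midpoint(system: SiteSystem, site: int, lo: float = 2.0, hi: float = 14.0) -> float:
    def g(ph: float) -> float:
        return float(exact_titration_curve(system, [ph])[0, site] - 0.5)

    return brentq(g, lo, hi, xtol=1e-10)


def _acfca_system(u1: float, u2: float, w12: float) -> SiteSystem:
    cys2 = TitratableSite("Cys2", CYS_PKA_REF, 0, -1, "acid")
    cys4 = TitratableSite("Cys4", CYS_PKA_REF, 0, -1, "acid")
    coupling = np.array([[0.0, w12], [w12, 0.0]])
    statics = [
        StaticCharge(charge=+1.0, coupling=(u1, 0.0), label="N-terminus"),
        StaticCharge(charge=-1.0, coupling=(0.0, u2), label="C-terminus"),
    ]
    return SiteSystem([cys2, cys4], coupling, statics)


@lru_cache(maxsize=4)
def _calibrate_acfca(w12: float) -> tuple[float, float]:
    t1, t2 = ACFCA_TARGET_PKAS

    def residual(u):
        sys_ = _acfca_system(u[0], u[1], w12)
        return [_exact_midpoint(sys_, 0) - t1, _exact_midpoint(sys_, 1) - t2]

    u0 = np.array([CYS_PKA_REF - t1, t2 - CYS_PKA_REF])
    sol = fsolve(residual, u0, xtol=1e-12)
    return float(sol[0]), float(sol[1])


def acfca_like(w12: float = 0.1, coupled: bool = True) -> SiteSystem:
    """Two-cysteine system with charged-termini perturbers.

    The N-terminal +1 charge couples to Cys2 and the C-terminal -1 charge
    to Cys4; coupling magnitudes are solved numerically at build time so
    the *exact* titration midpoints equal 8.14 (Cys2, pulled down by the
    positive terminus) and 9.41 (Cys4, pushed up by the negative
    terminus).  ``coupled=False`` drops terminus and inter-site couplings,
    reverting both midpoints to the 8.5 reference.
    """
    if not coupled:
        return _acfca_system(0.0, 0.0, 0.0)
    u1, u2 = _calibrate_acfca(w12)
    return _acfca_system(u1, u2, w12)


def buried_site_scenario(
    burial_ph_below: float = 4.0,
    seed: int = 0,
    pka_ref: float = 4.2,
    ph_start: float = 8.0,
    ph_end: float = 2.0,
    rate: float = 0.05,
    sweeps_per_window: int = 2000,
) -> tuple[SiteSystem, list[ProtonationTrace], dict[str, np.ndarray]]:
    """Glu-like site that becomes buried (and stops titrating) at low pH.

    Below ``burial_ph_below`` the recorded samples are frozen in the
    protonated state (no transitions: the proton is trapped in the buried
    conformation) and the SASA fraction drops well below the 0.30
    exclusion threshold.  The frozen low-pH points drag the unfiltered
    Hill fit to an overestimated pKa; excluding them moves the fit back
    toward the reference value.  Returns (system, traces, sasa-series
    dict) feeding straight into summarize_windows and sasa_filter.
    """
    system = model_compound("glu", pka_ref=pka_ref)
    sched = Schedule(
        ph_start=ph_start, ph_end=ph_end, rate=rate, steps_per_window=sweeps_per_window, seed=seed
    )
    traces = run_phtmd(system, sched)
    rng = np.random.default_rng(seed)
    sasa = np.empty(len(traces))
    for k, tr in enumerate(traces):
        if tr.ph < burial_ph_below:
            tr.samples = np.zeros_like(tr.samples)  # frozen protonated, zero transitions
            tr.final_state = tr.samples[-1].copy()
            sasa[k] = 0.15 + 0.05 * rng.random()
        else:
            sasa[k] = 0.75 + 0.15 * rng.random()
    return system, traces, {"glu": sasa}


def write_synthetic_cpout(
    states: np.ndarray,
    phs: np.ndarray,
    residue_types: list[str] | None = None,
    full_every: int | None = None,
) -> str:
    """Emit constant-pH-output text that read_cpout parses back exactly.

    ``states`` is (n_frames, n_residues) of raw state indices; ``phs`` the
    recorded solvent pH per frame.  A full record is written at frame 0,
    whenever the pH changes, and every ``full_every`` frames if given;
    other frames are delta records listing only changed residues.
    """
    states = np.asarray(states, dtype=int)
    phs = np.asarray(phs, dtype=float)
    if states.ndim != 2 or states.shape[0] != phs.shape[0]:
        raise ValueError("states must be (n_frames, n_residues) aligned with phs")
    nf, nr = states.shape
    out: list[str] = []
    for t in range(nf):
        full = t == 0 or phs[t] != phs[t - 1]
        if full_every is not None and t % full_every == 0:
            full = True
        if full:
            out.append(f"Solvent pH: {phs[t]:12.5f}")
            out.append(f"Time step: {t:10d}")
            for k in range(nr):
                out.append(f"Residue {k:4d} State: {states[t, k]:2d}")
        else:
            out.append(f"Time step: {t:10d}")
            for k in range(nr):
                if states[t, k] != states[t - 1, k]:
                    out.append(f"Residue {k:4d} State: {states[t, k]:2d}")
        out.append("")
    return "\n".join(out)


def write_synthetic_sasa_table(
    sasa: np.ndarray, site_labels: list[str], reference_max: dict[str, float]
) -> str:
    """Emit a whitespace-delimited frame x site SASA table (absolute units).

    ``sasa`` holds *fractions*; values are multiplied by each site's
    reference maximum so that read_sasa_table recovers the fractions.
    """
    sasa = np.atleast_2d(np.asarray(sasa, dtype=float))
    if sasa.shape[1] != len(site_labels):
        raise ValueError("sasa must have one column per site label")
    lines = ["#Frame " + " ".join(f"{c:>12s}" for c in site_labels)]
    for t in range(sasa.shape[0]):
        cells = []
        for j, c in enumerate(site_labels):
            v = sasa[t, j]
            cells.append(f"{'nan':>12s}" if np.isnan(v) else f"{v * reference_max[c]:12.6f}")
        lines.append(f"{t + 1:6d} " + " ".join(cells))
    return "\n".join(lines) + "\n"


def random_system(
    rng: np.random.Generator,
    n_sites: int | None = None,
    max_sites: int = 4,
    coupling_scale: float = 0.8,
) -> SiteSystem:
    """Random small coupled system for property tests."""
    if n_sites is None:
        n_sites = int(rng.integers(1, max_sites + 1))
    sites = []
    for i in range(n_sites):
        base = bool(rng.random() < 0.4)
        sites.append(
            TitratableSite(
                site_id=f"s{i}",
                pka_ref=float(rng.uniform(3.0, 11.0)),
                charge_prot=1 if base else 0,
                charge_deprot=0 if base else -1,
                kind="base" if base else "acid",
            )
        )
    W = rng.uniform(-coupling_scale, coupling_scale, size=(n_sites, n_sites))
    W = np.triu(W, 1)
    W = W + W.T
    statics = []
    if rng.random() < 0.5:
        statics.append(
            StaticCharge(
                charge=float(rng.choice([-1.0, 1.0])),
                coupling=tuple(rng.uniform(-0.5, 0.5, size=n_sites)),
                label="perturber",
            )
        )
    return SiteSystem(sites, W, statics)
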