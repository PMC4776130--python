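"""Canned validation protocols.

Self-contained workflows used to validate the sampler/fit chain against
known ground truth: model-compound pKa recovery, hysteresis of the coupled
two-cysteine fixture, and agreement between the ramped-pH protocol and
pH replica exchange on the same system.  Each returns plain dictionaries
so callers (tests, scripts, notebooks) can aggregate as they like.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from . import fixtures
from .analysis import fit_hill, hysteresis, summarize_windows
from .samplers import (
    DEFAULT_RATE,
    DEFAULT_SWEEPS_PER_WINDOW,
    ReplicaLadder,
    Schedule,
    run_phremd,
    run_phtmd,
    run_updown,
)
from .titration_model import SiteSystem

MODEL_COMPOUND_KINDS = ("asp", "glu", "his", "cys", "tyr", "lys")
#: replica pH values used for the two-cysteine comparison ladder
ACFCA_LADDER = (7.1, 8.1, 8.3, 8.7, 8.9, 9.9)


def titrate_and_fit(
    system: SiteSystem, schedule: Schedule
) -> dict[str, "object"]:
    """Run one ramped titration and Hill-fit every site."""
    traces = run_phtmd(system, schedule)
    summaries = summarize_windows(traces, system.site_ids)
    return {sid: fit_hill(summaries, sid) for sid in system.site_ids}


def model_compound_recovery(
    seeds: Iterable[int],
    kinds: Sequence[str] = MODEL_COMPOUND_KINDS,
    rate: float = DEFAULT_RATE,
    sweeps_per_window: int = DEFAULT_SWEEPS_PER_WINDOW,
    span: float = 3.0,
) -> dict[str, dict[str, float]]:
    """Titrate each model compound over pKa_ref +/- span, averaging seeds.

    The ramp descends from high to low pH (each side chain starts
    deprotonated and becomes protonated), mirroring the classic titration
    direction.  Returns per kind: reference pKa, seed-mean fitted pKa and
    Hill coefficient, and the absolute pKa error of the seed mean.
    """
    out: dict[str, dict[str, float]] = {}
    for ki, kind in enumerate(kinds):
        system = fixtures.model_compound(kind)
        pka_ref = system.sites[0].pka_ref
        pkas, ns = [], []
        for seed in seeds:
            # salt the stream per compound: the Hamiltonian is translation
            # invariant in pH, so unsalted runs would be exact replicas
            sched = Schedule(
                ph_start=pka_ref + span,
                ph_end=pka_ref - span,
                rate=rate,
                steps_per_window=sweeps_per_window,
                seed=int(seed) + 100_003 * ki,
            )
            fit = titrate_and_fit(system, sched)[kind]
            if not fit.converged:  # pragma: no cover - full-span ramps always converge
                raise RuntimeError(f"model-compound fit failed for {kind}: {fit.reason}")
            pkas.append(fit.pka)
            ns.append(fit.hill_n)
        out[kind] = {
            "pka_ref": float(pka_ref),
            "pka_mean": float(np.mean(pkas)),
            "hill_n_mean": float(np.mean(ns)),
            "abs_error": float(abs(np.mean(pkas) - pka_ref)),
        }
    return out


def acfca_hysteresis(
    seeds: Iterable[int],
    ph_start: float = 7.0,
    ph_end: float = 11.0,
    rate: float = DEFAULT_RATE,
    sweeps_per_window: int = DEFAULT_SWEEPS_PER_WINDOW,
) -> dict[str, float]:
    """Up/down titration of the coupled two-cysteine fixture.

    Fits the ascending and descending ramps separately per site and
    returns the seed-averaged absolute pKa difference per site.
    """
    system = fixtures.acfca_like()
    diffs: dict[str, list[float]] = {sid: [] for sid in system.site_ids}
    for seed in seeds:
        sched = Schedule(
            ph_start=ph_start,
            ph_end=ph_end,
            rate=rate,
            steps_per_window=sweeps_per_window,
            seed=int(seed),
        )
        fwd, bwd = run_updown(system, sched)
        sum_f = summarize_windows(fwd, system.site_ids)
        sum_b = summarize_windows(bwd, system.site_ids)
        for sid in system.site_ids:
            h = hysteresis(fit_hill(sum_f, sid), fit_hill(sum_b, sid))
            if h is None:  # pragma: no cover
                raise RuntimeError(f"hysteresis fit failed for {sid}")
            diffs[sid].append(h)
    return {sid: float(np.mean(v)) for sid, v in diffs.items()}


def phtmd_vs_remd(
    seeds: Iterable[int],
    ph_start: float = 7.0,
    ph_end: float = 11.0,
    rate: float = DEFAULT_RATE,
    sweeps_per_window: int = DEFAULT_SWEEPS_PER_WINDOW,
    ladder_phs: Sequence[float] = ACFCA_LADDER,
    exchange_interval: int = 100,
) -> dict[str, float]:
    """Compare ramped-pH and replica-exchange pKa estimates per site.

    The replica-exchange run gets the same aggregate sweep budget as the
    ramp (total sweeps split evenly across replicas).  Returns the
    seed-averaged absolute pKa difference per site.
    """
    system = fixtures.acfca_like()
    diffs: dict[str, list[float]] = {sid: [] for sid in system.site_ids}
    for seed in seeds:
        sched = Schedule(
            ph_start=ph_start,
            ph_end=ph_end,
            rate=rate,
            steps_per_window=sweeps_per_window,
            seed=int(seed),
        )
        fits_ramp = titrate_and_fit(system, sched)
        budget = sched.n_windows * sweeps_per_window
        ladder = ReplicaLadder(
            ph_values=tuple(ladder_phs),
            exchange_interval=exchange_interval,
            sweeps_total=budget // len(ladder_phs),
            seed=int(seed),
        )
        result = run_phremd(system, ladder)
        sum_remd = summarize_windows(result.traces, system.site_ids)
        for sid in system.site_ids:
            fit_r = fit_hill(sum_remd, sid)
            if not (fits_ramp[sid].converged and fit_r.converged):  # pragma: no cover
                raise RuntimeError(f"fit failed for {sid}")
            diffs[sid].append(abs(fits_ramp[sid].pka - fit_r.pka))
    return {sid: float(np.mean(v)) for sid, v in diffs.items()}
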