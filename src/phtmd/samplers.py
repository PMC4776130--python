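"""Protonation-state samplers: Metropolis sweeps, the ramped-pH titration
protocol (pHtMD), its up/down hysteresis variant, and pH replica exchange.

The titration protocol mimics a wet-lab titration: a long series of
constant-pH Monte Carlo windows whose solvent pH is ramped in small steps
(default 0.02 pH units per window), each window starting from the previous
window's final protonation state.  A fitted titration curve over the
windowed deprotonated fractions then yields pKa and Hill coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .titration_model import LN10, SiteSystem, validate_state

DEFAULT_RATE = 0.02
DEFAULT_SWEEPS_PER_WINDOW = 10_000


@dataclass(frozen=True)
class Schedule:
    """pH ramp schedule for a titration run.

    ``rate`` is the pH change per window; the ramp is the arithmetic
    sequence from ``ph_start`` to ``ph_end`` inclusive with
    ``round(|ph_end - ph_start| / rate) + 1`` windows.  One window plays
    the role of one engine time unit of the original protocol.
    """

    ph_start: float
    ph_end: float
    rate: float = DEFAULT_RATE
    steps_per_window: int = DEFAULT_SWEEPS_PER_WINDOW
    record_every: int = 1
    equilibration_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.steps_per_window < 1:
            raise ValueError("steps_per_window must be >= 1")
        if self.record_every < 1 or self.record_every > self.steps_per_window:
            raise ValueError("record_every must be in [1, steps_per_window]")
        if not 0.0 <= self.equilibration_fraction < 1.0:
            raise ValueError("equilibration_fraction must be in [0, 1)")

    @property
    def n_windows(self) -> int:
        return int(round(abs(self.ph_end - self.ph_start) / self.rate)) + 1

    @property
    def ph_values(self) -> np.ndarray:
        return np.linspace(self.ph_start, self.ph_end, self.n_windows)

    def reversed(self, seed: int | None = None) -> "Schedule":
        return Schedule(
            ph_start=self.ph_end,
            ph_end=self.ph_start,
            rate=self.rate,
            steps_per_window=self.steps_per_window,
            record_every=self.record_every,
            equilibration_fraction=self.equilibration_fraction,
            seed=self.seed + 1 if seed is None else seed,
        )


@dataclass
class ProtonationTrace:
    """Recorded protonation samples of one constant-pH window."""

    window_index: int
    ph: float
    samples: np.ndarray  # (n_recorded, n_sites) uint8 deprotonation indicators
    final_state: np.ndarray  # (n_sites,) uint8

    def __post_init__(self) -> None:
        if self.samples.ndim != 2 or self.samples.shape[0] == 0:
            raise ValueError("samples must be a non-empty (n_recorded, n_sites) array")


@dataclass(frozen=True)
class ReplicaLadder:
    """Fixed-pH replica ladder for pH replica exchange."""

    ph_values: tuple[float, ...]
    exchange_interval: int = 100
    sweeps_total: int = 100_000
    record_every: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        phs = tuple(float(p) for p in self.ph_values)
        if len(phs) < 2:
            raise ValueError("a replica ladder needs at least 2 replicas")
        if any(b <= a for a, b in zip(phs, phs[1:])):
            raise ValueError("ph_values must be sorted strictly increasing")
        object.__setattr__(self, "ph_values", phs)
        if self.exchange_interval < 1:
            raise ValueError("exchange_interval must be >= 1")

    @property
    def n_replicas(self) -> int:
        return len(self.ph_values)

    @property
    def n_swap_attempts(self) -> int:
        """Total neighbour-pair swap attempts over the run.

        Even rounds try pairs (0,1),(2,3),... and odd rounds (1,2),(3,4),...
        """
        n_events = self.sweeps_total // self.exchange_interval
        nrep = self.n_replicas
        even_pairs = nrep // 2
        odd_pairs = (nrep - 1) // 2
        n_even = (n_events + 1) // 2
        return n_even * even_pairs + (n_events - n_even) * odd_pairs


@dataclass
class RemdResult:
    """Per-replica traces plus exchange bookkeeping."""

    traces: list[ProtonationTrace]
    swap_attempts: int
    swap_accepts: int

    @property
    def acceptance_rate(self) -> float:
        return self.swap_accepts / self.swap_attempts if self.swap_attempts else float("nan")


def _flat_arrays(system: SiteSystem):
    b = system.pka_ref - system.static_field()
    W = np.ascontiguousarray(system.coupling, dtype=np.float64)
    cp = np.ascontiguousarray(system.charge_prot, dtype=np.float64)
    return np.ascontiguousarray(b), W, cp


def flip_delta_energy(system: SiteSystem, state: np.ndarray, i: int, ph: float) -> float:
    """Energy change (kT) of flipping site i's protonation in ``state``."""
    d = validate_state(system, state)
    b, W, cp = _flat_arrays(system)
    delta = 1.0 - 2.0 * d[i]
    return LN10 * delta * (b[i] - ph - float(W[i] @ (cp - d)))


def mc_sweep(
    system: SiteSystem, state: np.ndarray, ph: float, rng: np.random.Generator
) -> np.ndarray:
    """One Metropolis sweep: attempt one flip per site in random order.

    Each flip is accepted with probability min(1, exp(-dE)); the sweep
    satisfies detailed balance with respect to the Boltzmann distribution
    exp(-E(s, pH)).  Returns the updated state (the input is not modified).
    """
    d = validate_state(system, state).astype(np.uint8)
    b, W, cp = _flat_arrays(system)
    for i in rng.permutation(system.n_sites):
        delta = 1.0 - 2.0 * d[i]
        de = LN10 * delta * (b[i] - ph - float(W[i] @ (cp - d)))
        if de <= 0.0 or rng.random() < np.exp(-de):
            d[i] = 1 - d[i]
    return d


def default_initial_state(system: SiteSystem, ph: float) -> np.ndarray:
    """Heuristic start state: each site deprotonated iff pH > its pKa_ref."""
    return (ph > system.pka_ref).astype(np.uint8)


def _mix_seed(seed: int, salt: int = 0) -> int:
    return int(np.random.SeedSequence([seed, salt]).generate_state(1)[0] % (2**31 - 1))


def run_phtmd(
    system: SiteSystem,
    schedule: Schedule,
    initial_state: np.ndarray | None = None,
) -> list[ProtonationTrace]:
    """Run the ramped-pH titration protocol.

    Window k runs ``steps_per_window`` Monte Carlo sweeps at the k-th ramp
    pH, starting from the previous window's final state ("final coordinates
    in, final coordinates out").  Deterministic for a given schedule seed.
    """
    if initial_state is None:
        d0 = default_initial_state(system, schedule.ph_start)
    else:
        d0 = validate_state(system, initial_state).astype(np.uint8)
    b, W, cp = _flat_arrays(system)
    phs = schedule.ph_values
    samples, finals = _kernels.phtmd_ramp(
        d0,
        b,
        W,
        cp,
        np.ascontiguousarray(phs),
        schedule.steps_per_window,
        schedule.record_every,
        _mix_seed(schedule.seed),
    )
    return [
        ProtonationTrace(window_index=k, ph=float(phs[k]), samples=samples[k], final_state=finals[k])
        for k in range(len(phs))
    ]


def run_updown(
    system: SiteSystem,
    schedule: Schedule,
    initial_state: np.ndarray | None = None,
) -> tuple[list[ProtonationTrace], list[ProtonationTrace]]:
    """Forward ramp followed by the mirrored return ramp (hysteresis check).

    The backward ramp starts from the forward run's final state, mirroring
    the handoff used within a single ramp.
    """
    forward = run_phtmd(system, schedule, initial_state)
    backward = run_phtmd(system, schedule.reversed(), forward[-1].final_state)
    return forward, backward


def swap_log10_acceptance(ph_a: float, ph_b: float, d_count_a: float, d_count_b: float) -> float:
    """log10 of the replica-swap acceptance ratio (capped at 0 by min(1, .))."""
    return (ph_a - ph_b) * (d_count_b - d_count_a)


def run_phremd(
    system: SiteSystem,
    ladder: ReplicaLadder,
    initial_states: np.ndarray | None = None,
) -> RemdResult:
    """pH replica exchange: fixed-pH replicas with neighbour state swaps.

    Swap acceptance min(1, 10^{(pH_a - pH_b)(D(s_b) - D(s_a))}) with D the
    deprotonation count preserves detailed balance, so each replica's
    marginal equals the fixed-pH Boltzmann ensemble at its pH.
    """
    nrep = ladder.n_replicas
    if initial_states is None:
        d0s = np.stack([default_initial_state(system, p) for p in ladder.ph_values])
    else:
        d0s = np.asarray(initial_states, dtype=np.uint8)
        if d0s.shape != (nrep, system.n_sites):
            raise ValueError(f"initial_states must have shape ({nrep}, {system.n_sites})")
    b, W, cp = _flat_arrays(system)
    samples, attempts, accepts = _kernels.phremd(
        np.ascontiguousarray(d0s),
        b,
        W,
        cp,
        np.ascontiguousarray(np.asarray(ladder.ph_values, dtype=np.float64)),
        ladder.sweeps_total,
        ladder.exchange_interval,
        ladder.record_every,
        _mix_seed(ladder.seed, salt=1),
    )
    traces = [
        ProtonationTrace(
            window_index=r,
            ph=float(ladder.ph_values[r]),
            samples=samples[r],
            final_state=samples[r, -1].copy(),
        )
        for r in range(nrep)
    ]
    return RemdResult(traces=traces, swap_attempts=int(attempts), swap_accepts=int(accepts))
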