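# Methods

## The titration Hamiltonian

The package replaces the all-atom force field of a constant-pH MD engine
with a minimal multi-site titration Hamiltonian over protonation
microstates `d ∈ {0,1}^N` (1 = deprotonated):

    E(d, pH) / ln10 = Σᵢ dᵢ (pKa_ref,i − pH)
                      + Σ_{i<j} w_ij qᵢ(d) q_j(d)
                      + Σ_{i,k} u_ik qᵢ(d) Q_k

* `pKa_ref,i` — intrinsic (model-compound) pKa of site *i*.
* `qᵢ(d) = q_prot,i − dᵢ` — site charge; acids titrate 0 → −1, bases
  +1 → 0.  Acids and bases therefore share the identical
  deprotonated-fraction curve `f(pH) = 1/(1+10^{pKa−pH})` for an isolated
  site and differ only in charge bookkeeping.  (Histidine is treated as a
  two-state base; its two neutral tautomers are distinguished only in the
  constant-pH-output mapping layer, where both count as "singly
  protonated".)
* `w_ij` — symmetric pairwise couplings, `u_ik`/`Q_k` — couplings to
  non-titrating perturber charges such as peptide termini.  All couplings
  are in pKa (log₁₀) units: energies are expressed per `kT·ln10`, so
  temperature is folded into the couplings and the observable is the pKa
  shift itself rather than an absolute energy.  The all-protonated state
  of a coupling-free system has energy zero by construction.

For `N ≤ 20` sites the partition function is enumerated exactly
(`exact_titration_curve`, log-sum-exp accumulation), which serves as the
oracle every sampler is validated against.  The mean total deprotonation
from this enumeration is provably non-decreasing in pH (its derivative is
`ln10 · Var(Σdᵢ) ≥ 0`), which the property tests assert on random
systems.

## Samplers

**Metropolis sweeps.** One sweep attempts one flip per site in a fresh
random permutation; a flip is accepted with probability
`min(1, e^{−ΔE})`.  Single-site flips are ergodic on this state space;
optional pair moves were considered and dropped as unnecessary.

**Ramped-pH protocol.** A run is a series of constant-pH windows on an
arithmetic pH ramp (default rate 0.02 pH units/window, i.e. 50 windows
per pH unit; `round(|ΔpH|/rate)+1` windows inclusive of both ends).  Each
window runs `steps_per_window` sweeps (default 10 000) and hands its
final state to the next window.  One window plays the role of one
nanosecond of the MD protocol this emulates; the default sweep count was
chosen so that single-site runs sit deep in the quasi-equilibrium regime
(window-to-window equilibration is fast relative to the 0.02-unit pH
step), which the rate-halving property test verifies.  The
`equilibration_fraction` knob (default 0: whole windows are analysed)
discards the leading fraction of each window, useful for sharper
couplings where windows start mildly out of equilibrium.

**Up/down titration.** The hysteresis check runs the forward ramp, then a
mirrored ramp seeded with the forward run's final state (continuity, as
within a single ramp).  The two ramps are fitted separately; pooling both
into one fit is available via `combine_ramps`.

**pH replica exchange.** Replicas sample at fixed pH values; every
`exchange_interval` sweeps, neighbouring pairs (alternating even/odd
pairing) attempt a state swap accepted with probability
`min(1, 10^{(pH_a−pH_b)(D(s_b)−D(s_a))})`, `D` being the total
deprotonation count — the pH-coupled part of the energy — so the swap
move preserves detailed balance and each replica's marginal is the
fixed-pH Boltzmann ensemble.  In the ramp-vs-REMD comparison the ladder
receives the same aggregate sweep budget as the ramp, split evenly across
replicas.

All kernels are numba-compiled and seeded explicitly; identical seeds
give bit-identical traces.

## Analysis

* **Window summaries.** `f_deprot` = mean deprotonation indicator over a
  window's recorded samples; `n_transitions` = state changes between
  consecutive *recorded* samples (the recording stride is the unit —
  relevant when `record_every > 1`).
* **Solvent-exposure filter.** Points with side-chain SASA below 30 % of
  the model-compound maximum are marked invalid (strictly-less
  comparison: exactly 30 % is retained).  The filter touches only
  validity flags, never the fractions.
* **Hill fit.** Weighted nonlinear least squares of
  `f = 1/(1+10^{n(pKa−pH)})` over valid points, weights = sample counts
  (a no-op for equal-length windows, correct for truncated ones).
  Initialisation: pKa₀ from linear interpolation of the 0.5 crossing
  (fallback: median pH), n₀ = 1; bounds `n ∈ (0, 5]`,
  `pKa ∈ [min pH − 2, max pH + 2]`.  The fit is *refused* — no pKa
  reported — when fewer than 4 valid points remain or when the valid
  fractions never bracket the midpoint (all stay on one side of
  0.5 ± 0.05).  This operationalises the refusal to report pKa values for
  residues that do not titrate in the scanned range; the margin is
  deliberately permissive so that sparse replica-ladder datasets whose
  highest point reaches only ~0.75 still fit, while a buried residue
  pinned near 0 or 1 is refused.  A stricter well-determined band (e.g.
  requiring coverage beyond 0.2–0.8) can be imposed by the caller.
* **Replicate averaging.** Unweighted arithmetic mean and sample SD over
  converged replicate fits; non-converged replicates are listed but
  excluded.
* **Net charge.** Mean total charge (titrating + static) per window, one
  point per window — a pKa-free readout of the pH range over which a
  system's charge state changes.

## Fixtures (what the generators emulate — and what they do not)

* `model_compound` — single uncoupled sites with reference pKa values
  Asp 4.0, Glu 4.4, His 6.5, Cys 8.5, Tyr 9.6, Lys 10.4 (the constant-pH
  reference parametrisation; configurable in `data/model_pkas.yaml`).
* `acfca_like` — two cysteines (pKa_ref 8.5) with a +1 N-terminal and a
  −1 C-terminal perturber plus a weak direct Cys–Cys coupling
  (w = 0.1).  The terminus couplings are solved numerically at build time
  (midpoint root-finding on the enumeration oracle inside a 2-D solve) so
  the exact titration midpoints equal 8.14 and 9.41.  The calibration
  targets the protocol chain — sampler → schedule → fit — not molecular
  electrostatics: the couplings are effective parameters, not computed
  from structure.
* `buried_site_scenario` — a Glu-like site whose windows below a burial
  pH are frozen in the protonated state (zero transitions) with SASA
  dropped below the 30 % threshold.  The frozen points drag the
  unfiltered fit to an overestimated pKa; filtering recovers a value near
  the reference, reproducing the direction of the buried-residue
  correction.
* `write_synthetic_cpout` / `write_synthetic_sasa_table` — text writers
  that round-trip exactly through the readers (full records at pH changes
  and optionally every *k* frames, delta records between).

Passing tests on these fixtures validate the *protocol arithmetic*:
schedule bookkeeping, Boltzmann-correct sampling, unbiased curve fitting,
filtering and averaging.  They say nothing about conformational sampling
of real proteins — the Hamiltonian has no coordinates, so phenomena such
as pH-driven unfolding, dimer dissociation or conformation-dependent
couplings are outside what these tests can show.  Real constant-pH MD
output can be analysed through `read_cpout`/`windows_from_cpout`, where
windows are defined by contiguous runs of constant recorded solvent pH
(the ramp driver changes pH between runs), not by frame count.

## Numerical choices

* Exact curves via log-sum-exp; enumeration refused above 20 sites.
* Metropolis acceptance short-circuits `ΔE ≤ 0`; at an isolated site's
  midpoint `ΔE = 0`, so flips always accept and the chain alternates —
  harmless (the marginal is still exactly ½) but a reminder that
  consecutive samples are anti-correlated, which is why goodness-of-fit
  tests thin the chain.
* Problem sizes in the validation protocols: six model compounds ×
  6 seeds × 301 windows × 10⁴ sweeps; hysteresis and REMD comparisons use
  5 seeds on the 201-window pH 7→11 ramp.  These sizes put Monte Carlo
  error well below the quantities being bounded (fitted-pKa errors of
  order 10⁻³).
* Sum/mean deviations of the packaged benchmark tables are computed by
  default from the printed two-decimal per-row deviations (summing then
  rounding reproduces the published summary rows exactly); recomputing
  from the pKa columns first is available as a mode and agrees to within
  rounding.
* Seeds are mixed through `numpy.random.SeedSequence` before reaching the
  compiled kernels; per-compound streams are salted because the
  Hamiltonian is translation-invariant in pH and unsalted runs of
  different compounds would be exact replicas of each other.

## Known limitations

* Two-state sites only; the three-state histidine exists solely in the
  output-mapping layer (tautomers aggregated), and polyprotic residues
  are out of scope.
* Couplings are inputs, not derived from structure; no continuum
  electrostatics.
* No bootstrap confidence intervals on fitted pKa values; replicate SD is
  the provided uncertainty measure.
* The Hill equation is used in its standard
  `f = 1/(1+10^{n(pKa−pH)})` form, the conventional
  midpoint-plus-cooperativity parameterisation of titration curves;
  no multi-proton generalisation is fitted.
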