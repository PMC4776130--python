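"""Multi-site titration Hamiltonian and exact reference thermodynamics.

The model describes N two-state titratable sites (plus optional fixed
"static" perturber charges such as peptide termini).  A microstate is a
vector ``d`` of deprotonation indicators (0 = protonated, 1 = deprotonated).
Its dimensionless energy, in units of kT, is

    E(d, pH) = ln(10) * [ sum_i d_i (pKa_ref_i - pH)
                          + sum_{i<j} w_ij q_i(d) q_j(d)
                          + sum_{i,k} u_ik q_i(d) Q_k ]

where ``q_i(d) = charge_prot_i - d_i`` is the state-dependent site charge
(every deprotonation removes one elementary charge), ``w`` the symmetric
pairwise site-site coupling matrix in pKa (log10) units, and ``Q_k`` the
static perturber charges with per-site couplings ``u_ik``.  An isolated,
uncoupled site therefore titrates with Henderson-Hasselbalch midpoint at
its reference pKa; acids (0 -> -1) and bases (+1 -> 0) share the same
deprotonated-fraction curve and differ only in charge bookkeeping.

Energies carry no explicit temperature: couplings are expressed directly
as pKa shifts, the observable the protocol is built to measure.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.special import logsumexp

LN10 = float(np.log(10.0))

#: kinds of titratable site; ``his3`` marks the three-state histidine used
#: only by the constant-pH-MD output mapping layer (thermodynamically it is
#: treated as a two-state base with the tautomers aggregated).
SITE_KINDS = ("acid", "base", "his3")

ENUMERATION_LIMIT = 20


@dataclass(frozen=True)
class TitratableSite:
    """One titratable group: reference pKa plus protonation charges."""

    site_id: str
    pka_ref: float
    charge_prot: int
    charge_deprot: int
    kind: str = "acid"

    def __post_init__(self) -> None:
        if self.kind not in SITE_KINDS:
            raise ValueError(f"unknown site kind {self.kind!r}; expected one of {SITE_KINDS}")
        if not np.isfinite(self.pka_ref):
            raise ValueError(f"site {self.site_id!r}: pka_ref must be finite")
        if self.charge_deprot != self.charge_prot - 1:
            raise ValueError(
                f"site {self.site_id!r}: deprotonation must remove one proton "
                f"(charge_deprot = charge_prot - 1), got {self.charge_prot} -> {self.charge_deprot}"
            )


@dataclass(frozen=True)
class StaticCharge:
    """Non-titrating perturber (e.g. a charged terminus).

    ``coupling[i]`` is the pKa-unit interaction applied to the product of
    this charge with site i's state-dependent charge.
    """

    charge: float
    coupling: tuple[float, ...]
    label: str = ""


class SiteSystem:
    """Ordered collection of titratable sites with pairwise couplings.

    Parameters
    ----------
    sites
        Ordered list of :class:`TitratableSite`.
    coupling
        Symmetric (n, n) matrix of pairwise couplings in pKa units,
        zero on the diagonal.  ``None`` means uncoupled.
    static_charges
        Optional list of :class:`StaticCharge` perturbers.
    """

    def __init__(
        self,
        sites: list[TitratableSite],
        coupling: np.ndarray | None = None,
        static_charges: list[StaticCharge] | None = None,
    ):
        if not sites:
            raise ValueError("a SiteSystem needs at least one site")
        self.sites = list(sites)
        n = len(self.sites)
        ids = [s.site_id for s in self.sites]
        if len(set(ids)) != n:
            raise ValueError("site_id labels must be unique")
        if coupling is None:
            coupling = np.zeros((n, n))
        coupling = np.asarray(coupling, dtype=float)
        if coupling.shape != (n, n):
            raise ValueError(f"coupling must be ({n}, {n}), got {coupling.shape}")
        if not np.allclose(coupling, coupling.T, atol=1e-12):
            raise ValueError("coupling matrix must be symmetric")
        if not np.allclose(np.diag(coupling), 0.0, atol=1e-12):
            raise ValueError("coupling matrix must have zero diagonal")
        self.coupling = coupling
        self.static_charges = list(static_charges or [])
        for sc in self.static_charges:
            if len(sc.coupling) != n:
                raise ValueError(
                    f"static charge {sc.label!r}: coupling vector length "
                    f"{len(sc.coupling)} != number of sites {n}"
                )

    # -- derived arrays ---------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def site_ids(self) -> list[str]:
        return [s.site_id for s in self.sites]

    @property
    def pka_ref(self) -> np.ndarray:
        return np.array([s.pka_ref for s in self.sites], dtype=float)

    @property
    def charge_prot(self) -> np.ndarray:
        return np.array([s.charge_prot for s in self.sites], dtype=float)

    def static_field(self) -> np.ndarray:
        """g_i = sum_k u_ik Q_k, the static perturber field on each site."""
        g = np.zeros(self.n_sites)
        for sc in self.static_charges:
            g += sc.charge * np.asarray(sc.coupling, dtype=float)
        return g

    def static_charge_total(self) -> float:
        return float(sum(sc.charge for sc in self.static_charges))

    def site_index(self, site_id: str) -> int:
        try:
            return self.site_ids.index(site_id)
        except ValueError:
            raise KeyError(f"no site with id {site_id!r}") from None

    def site_charges(self, state: np.ndarray) -> np.ndarray:
        """State-dependent charge q_i = charge_prot_i - d_i per site."""
        d = validate_state(self, state)
        return self.charge_prot - d

    def total_charge(self, state: np.ndarray) -> float:
        return float(self.site_charges(state).sum() + self.static_charge_total())

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        triplets = []
        n = self.n_sites
        for i in range(n):
            for j in range(i + 1, n):
                if self.coupling[i, j] != 0.0:
                    triplets.append([self.site_ids[i], self.site_ids[j], float(self.coupling[i, j])])
        return {
            "sites": [
                {
                    "id": s.site_id,
                    "pka_ref": float(s.pka_ref),
                    "kind": s.kind,
                    "charge_prot": int(s.charge_prot),
                    "charge_deprot": int(s.charge_deprot),
                }
                for s in self.sites
            ],
            "coupling": triplets,
            "static_charges": [
                {
                    "label": sc.label,
                    "charge": float(sc.charge),
                    "coupling": [float(u) for u in sc.coupling],
                }
                for sc in self.static_charges
            ],
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "SiteSystem":
        sites = [
            TitratableSite(
                site_id=str(s["id"]),
                pka_ref=float(s["pka_ref"]),
                charge_prot=int(s["charge_prot"]),
                charge_deprot=int(s["charge_deprot"]),
                kind=s.get("kind", "acid"),
            )
            for s in doc["sites"]
        ]
        ids = [s.site_id for s in sites]
        n = len(sites)
        coupling = np.zeros((n, n))
        for a, b, w in doc.get("coupling") or []:
            i, j = ids.index(str(a)), ids.index(str(b))
            coupling[i, j] = coupling[j, i] = float(w)
        statics = [
            StaticCharge(
                charge=float(sc["charge"]),
                coupling=tuple(float(u) for u in sc["coupling"]),
                label=str(sc.get("label", "")),
            )
            for sc in doc.get("static_charges") or []
        ]
        return cls(sites, coupling, statics)

    def to_yaml(self, stream=None) -> str | None:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if stream is None:
            return text
        stream.write(text)
        return None

    @classmethod
    def from_yaml(cls, source) -> "SiteSystem":
        if isinstance(source, str) and "\n" not in source and not source.lstrip().startswith("sites"):
            with open(source) as fh:
                doc = yaml.safe_load(fh)
        elif isinstance(source, str):
            doc = yaml.safe_load(io.StringIO(source))
        else:
            doc = yaml.safe_load(source)
        return cls.from_dict(doc)

    def __repr__(self) -> str:  # pragma: no cover
        return f"SiteSystem({self.site_ids}, {len(self.static_charges)} static charges)"


def validate_state(system: SiteSystem, state: np.ndarray) -> np.ndarray:
    d = np.asarray(state)
    if d.shape != (system.n_sites,):
        raise ValueError(f"state must have shape ({system.n_sites},), got {d.shape}")
    if not np.isin(d, (0, 1)).all():
        raise ValueError("state entries must be 0 (protonated) or 1 (deprotonated)")
    return d.astype(float)


def microstate_energy(system: SiteSystem, state: np.ndarray, ph: float) -> float:
    """Energy of a protonation microstate at the given solvent pH, in kT.

    The all-protonated state of a coupling-free system has energy zero.
    """
    if not np.isfinite(ph):
        raise ValueError("ph must be finite")
    d = validate_state(system, state)
    q = system.charge_prot - d
    e = float(d @ (system.pka_ref - ph))
    e += float(q @ system.coupling @ q) / 2.0
    e += float(system.static_field() @ q)
    return LN10 * e


def _enumerate_states(n: int) -> np.ndarray:
    """(2^n, n) matrix of deprotonation indicators."""
    idx = np.arange(2**n, dtype=np.int64)
    return ((idx[:, None] >> np.arange(n)) & 1).astype(float)


def state_log_weights(system: SiteSystem, ph: float) -> tuple[np.ndarray, np.ndarray]:
    """All microstates and their (unnormalized) log Boltzmann weights at pH."""
    n = system.n_sites
    if n > ENUMERATION_LIMIT:
        raise ValueError(
            f"exact enumeration is limited to {ENUMERATION_LIMIT} sites "
            f"(got {n}); use the Monte Carlo samplers instead"
        )
    D = _enumerate_states(n)
    q = system.charge_prot[None, :] - D
    const = D @ system.pka_ref
    const += 0.5 * np.einsum("si,ij,sj->s", q, system.coupling, q)
    const += q @ system.static_field()
    nde = D.sum(axis=1)
    logw = -LN10 * (const - ph * nde)
    return D, logw


def exact_titration_curve(system: SiteSystem, ph_grid) -> np.ndarray:
    """Exact per-site deprotonated fraction by full microstate enumeration.

    Returns an array of shape ``(len(ph_grid), n_sites)``; computation is
    overflow-safe via log-sum-exp.
    """
    ph_grid = np.atleast_1d(np.asarray(ph_grid, dtype=float))
    n = system.n_sites
    out = np.empty((ph_grid.size, n))
    for k, ph in enumerate(ph_grid):
        D, logw = state_log_weights(system, ph)
        logz = logsumexp(logw)
        for i in range(n):
            mask = D[:, i] > 0.5
            if not mask.any():  # pragma: no cover - d always attainable
                out[k, i] = 0.0
            else:
                out[k, i] = np.exp(logsumexp(logw[mask]) - logz)
    return out


def exact_mean_charge(system: SiteSystem, ph_grid) -> np.ndarray:
    """Exact ensemble-mean total charge on a pH grid (enumeration oracle)."""
    f = exact_titration_curve(system, ph_grid)
    return (system.charge_prot[None, :] - f).sum(axis=1) + system.static_charge_total()


def analytic_hill_curve(pka: float, n: float, ph) -> np.ndarray | float:
    """Hill titration curve f(pH) = 1 / (1 + 10^{n (pKa - pH)}).

    ``f(pKa) = 0.5`` exactly; strictly increasing in pH for ``n > 0``.
    """
    if n <= 0:
        raise ValueError("Hill coefficient n must be positive")
    ph_arr = np.asarray(ph, dtype=float)
    # expit-style overflow-safe evaluation
    x = LN10 * n * (ph_arr - pka)
    with np.errstate(over="ignore"):
        out = np.where(x >= 0, 1.0 / (1.0 + np.exp(-x)), np.exp(x) / (1.0 + np.exp(x)))
    if np.isscalar(ph) or out.ndim == 0:
        return float(out)
    return out
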