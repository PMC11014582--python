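"""Self-consistent mean-field theory for clustered LIF networks.

The theory replaces every presynaptic population by Gaussian current noise
with mean ``mu`` and variance ``sigma^2`` determined by the population
firing rates and the connectivity, and closes the loop through the LIF
transfer function for exponential synapses,

    Phi = [tau_ref + tau_m*sqrt(pi) * int_{q_r}^{q_t} e^{x^2} erfc(-x) dx]^-1

with integration bounds ``q = (V - tau_m*mu)/(sqrt(tau_m)*sigma) +
a*sqrt(tau_syn/tau_m)``; the boundary shift is the colored-noise
(synaptic-filtering) correction with ``a = |zeta(1/2)|/sqrt(2)``.

With quenched input disorder (heterogeneous background rates across cells)
each population acquires a Gaussian spread ``Delta`` of mean inputs, and
the self-consistent unknowns become the population mean rate and the
across-cell rate variance, evaluated by Gauss-Hermite quadrature over the
quenched variable.

The module exposes a generic :class:`PopulationSystem` (also used by the
reduced two-cluster theory in :mod:`metastable.effective`) and the
clustered-network front-end :class:`ClusteredMFT` with branch scans over
the number of active clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss
from numpy.polynomial.legendre import leggauss
from scipy.optimize import root
from scipy.special import erfcx, erfi

from .network import depressed_weight
from .params import TRANSFER_BOUNDARY_SHIFT, NetworkSpec

_GL_X, _GL_W = leggauss(80)
_GH_X, _GH_W = hermegauss(41)  # weight exp(-z^2/2); sum w = sqrt(2*pi)
_GH_W = _GH_W / np.sqrt(2.0 * np.pi)


def _int_erfcx_neg(lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Vectorized integral of erfcx(-x) over [lo, hi] (elementwise)."""
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    out = np.zeros(np.broadcast(lo, hi).shape)
    # split at +-8 so the Gauss-Legendre rule sees smooth, well-scaled pieces
    for a, b in ((-np.inf, -8.0), (-8.0, 8.0), (8.0, np.inf)):
        seg_lo = np.clip(lo, a, b)
        seg_hi = np.clip(hi, a, b)
        length = seg_hi - seg_lo
        mask = length > 0
        if not np.any(mask):
            continue
        mid = 0.5 * (seg_lo + seg_hi)
        half = 0.5 * length
        x = mid[..., None] + half[..., None] * _GL_X
        vals = erfcx(-x) @ _GL_W
        out += np.where(mask, half * vals, 0.0)
    return out


def _siegert_integral(qr: np.ndarray, qt: np.ndarray) -> np.ndarray:
    """int_{qr}^{qt} e^{x^2} erfc(-x) dx, numerically stable.

    For x > 0 the integrand is split as 2*e^{x^2} - erfcx(x); the first
    term integrates exactly to sqrt(pi)*erfi and the remainder is smooth.
    """
    qr = np.asarray(qr, dtype=float)
    qt = np.asarray(qt, dtype=float)
    out = _int_erfcx_neg(np.minimum(qr, 0.0), np.minimum(qt, 0.0))
    pos_lo = np.maximum(qr, 0.0)
    pos_hi = np.maximum(qt, 0.0)
    mask = pos_hi > pos_lo
    if np.any(mask):
        lo = np.where(mask, pos_lo, 0.0)
        hi = np.where(mask, pos_hi, 0.0)
        with np.errstate(over="ignore"):
            grow = np.sqrt(np.pi) * (erfi(hi) - erfi(lo))
        # int erfcx(x) dx over [lo,hi] equals int erfcx(-u) du over [-hi,-lo]
        out += np.where(mask, grow - _int_erfcx_neg(-hi, -lo), 0.0)
    return out


def lif_transfer_rate(mu, sigma, tau_m, tau_ref, tau_syn, V_th, V_r,
                      a: float = TRANSFER_BOUNDARY_SHIFT) -> np.ndarray:
    """Firing rate of an LIF neuron with white-noise input (mu, sigma).

    ``mu`` is the mean input current in mV/s, ``sigma^2`` its variance in
    mV^2/s; voltages in mV, times in s.  Returns spikes/s, bounded by
    1/tau_ref.  Raises if sigma <= 0.
    """
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("transfer function requires sigma > 0")
    shift = a * np.sqrt(np.asarray(tau_syn) / np.asarray(tau_m))
    denom = np.sqrt(tau_m) * sigma
    qt = (V_th - tau_m * mu) / denom + shift
    qr = (V_r - tau_m * mu) / denom + shift
    rate = np.zeros(np.broadcast(qt, mu).shape)
    ok = qt < 26.0  # beyond this the mean first-passage time overflows
    integral = _siegert_integral(np.where(ok, qr, 0.0), np.where(ok, qt, 1.0))
    denom_t = tau_ref + tau_m * np.sqrt(np.pi) * integral
    rate = np.where(ok, 1.0 / denom_t, 0.0)
    return rate if rate.shape else float(rate)


@dataclass
class PopulationMoments:
    mu: np.ndarray          # mean input, mV/s
    sigma2: np.ndarray      # input variance, mV^2/s
    delta2: Optional[np.ndarray] = None  # across-cell variance of mean inputs


@dataclass
class MFTSolution:
    """Self-consistent population rates (and across-cell variances)."""

    nu: np.ndarray                      # population-mean rates, spikes/s
    s2: Optional[np.ndarray]            # across-cell rate variances
    nA: int
    residual: float
    converged: bool
    labels: Sequence[str] = field(default_factory=list)

    def as_series(self) -> pd.Series:
        return pd.Series(self.nu, index=list(self.labels))


class PopulationSystem:
    """Generic multi-population LIF rate system.

    Defined by per-population intrinsic constants, an in-degree matrix
    ``K`` (post x pre), a signed weight matrix ``Wmat`` in mV, external
    mean/variance drives, and optionally a quenched external spread
    ``ext_delta`` (mV/s) per population.
    """

    def __init__(self, labels, tau_m, tau_ref, tau_syn, V_th, V_r,
                 K, Wmat, ext_mean, ext_var, ext_delta=None):
        self.labels = list(labels)
        n = len(self.labels)
        self.tau_m = np.asarray(tau_m, dtype=float)
        self.tau_ref = np.asarray(tau_ref, dtype=float)
        self.tau_syn = np.asarray(tau_syn, dtype=float)
        self.V_th = np.asarray(V_th, dtype=float)
        self.V_r = np.asarray(V_r, dtype=float)
        self.KW = np.asarray(K, dtype=float) * np.asarray(Wmat, dtype=float)
        self.KW2 = np.asarray(K, dtype=float) * np.asarray(Wmat, dtype=float) ** 2
        self.ext_mean = np.asarray(ext_mean, dtype=float)
        self.ext_var = np.asarray(ext_var, dtype=float)
        self.ext_delta = (np.zeros(n) if ext_delta is None
                          else np.asarray(ext_delta, dtype=float))
        self.n = n

    # -- plain (no quenched disorder) -----------------------------------
    def moments(self, nu: np.ndarray) -> PopulationMoments:
        nu = np.asarray(nu, dtype=float)
        return PopulationMoments(mu=self.KW @ nu + self.ext_mean,
                                 sigma2=self.KW2 @ nu + self.ext_var)

    def rates(self, nu: np.ndarray) -> np.ndarray:
        m = self.moments(nu)
        return lif_transfer_rate(m.mu, np.sqrt(m.sigma2), self.tau_m,
                                 self.tau_ref, self.tau_syn, self.V_th, self.V_r)

    def solve(self, init: np.ndarray, tol: float = 1e-10, max_iter: int = 400,
              damping: float = 0.3, frozen: Optional[np.ndarray] = None):
        """Damped fixed-point iteration with a root-finder fallback.

        ``frozen`` is a boolean mask of populations whose rates are held
        fixed at their init values (used by the effective theory).
        """
        frozen = (np.zeros(self.n, dtype=bool) if frozen is None
                  else np.asarray(frozen, dtype=bool))
        free = ~frozen
        nu = np.array(init, dtype=float)

        def step(x):
            full = nu.copy()
            full[free] = x
            out = self.rates(full)
            return out[free]

        x = nu[free].copy()
        for _ in range(max_iter):
            fx = step(x)
            if np.max(np.abs(fx - x)) < tol:
                nu[free] = fx
                return nu, float(np.max(np.abs(fx - x))), True
            x = (1.0 - damping) * x + damping * fx
        sol = root(lambda y: step(np.clip(y, 0.0, None)) - np.clip(y, 0.0, None),
                   x, method="hybr", tol=1e-12)
        y = np.clip(sol.x, 0.0, None)
        res = float(np.max(np.abs(step(y) - y)))
        nu[free] = y
        return nu, res, res < max(tol, 1e-8)

    # -- quenched disorder ----------------------------------------------
    def quenched_moments(self, nu_bar: np.ndarray, s2: np.ndarray) -> PopulationMoments:
        m = self.moments(nu_bar)
        delta2 = self.KW2 @ np.asarray(s2, dtype=float) + self.ext_delta ** 2
        return PopulationMoments(mu=m.mu, sigma2=m.sigma2, delta2=delta2)

    def quenched_rates(self, nu_bar: np.ndarray, s2: np.ndarray):
        """One application of the quenched self-consistency map.

        Returns the updated (nu_bar, s2) obtained by integrating the
        transfer function over the Gaussian quenched variable.
        """
        m = self.quenched_moments(nu_bar, s2)
        delta = np.sqrt(np.clip(m.delta2, 0.0, None))
        # mu(z) = mu_bar + delta*z over standardized Gauss-Hermite nodes
        mu_z = m.mu[:, None] + delta[:, None] * _GH_X[None, :]
        nz = lif_transfer_rate(mu_z, np.sqrt(m.sigma2)[:, None],
                               self.tau_m[:, None], self.tau_ref[:, None],
                               self.tau_syn[:, None], self.V_th[:, None],
                               self.V_r[:, None])
        nu_new = nz @ _GH_W
        s2_new = np.clip((nz ** 2) @ _GH_W - nu_new ** 2, 0.0, None)
        return nu_new, s2_new

    def solve_quenched(self, nu_init: np.ndarray, s2_init: Optional[np.ndarray] = None,
                       tol: float = 1e-10, max_iter: int = 4000,
                       damping: float = 0.3, frozen: Optional[np.ndarray] = None):
        frozen = (np.zeros(self.n, dtype=bool) if frozen is None
                  else np.asarray(frozen, dtype=bool))
        free = ~frozen
        nu = np.array(nu_init, dtype=float)
        s2 = np.zeros(self.n) if s2_init is None else np.array(s2_init, dtype=float)
        for _ in range(max_iter):
            nu_new, s2_new = self.quenched_rates(nu, s2)
            nu_new[frozen] = nu[frozen]
            s2_new[frozen] = s2[frozen]
            err = max(np.max(np.abs(nu_new - nu)), np.max(np.abs(s2_new - s2)))
            if err < tol:
                return nu_new, s2_new, float(err), True
            nu = (1.0 - damping) * nu + damping * nu_new
            s2 = (1.0 - damping) * s2 + damping * s2_new
        return nu, s2, float(err), False


# ---------------------------------------------------------------------------
# Clustered-network front end
# ---------------------------------------------------------------------------

def _counts(spec: NetworkSpec, a: str, b: str) -> dict:
    """Rounded per-group in-degrees, matching the network builder exactly."""
    C, fb, p = spec.C(a, b), spec.f_pop(b), spec.p
    return {
        "same": int(round(fb * C)),
        "other_total": int(round((p - 1) * fb * C)) if p > 1 else 0,
        "bg": int(round((1 - p * fb) * C)),
        "clu_total": int(round(p * fb * C)),
    }


class ClusteredMFT:
    """Mean-field theory of the full clustered network (2(p+1) populations).

    ``Jplus_override`` substitutes intracluster couplings for the theory
    only (the simulation/theory couplings can differ; the offset procedure
    matching simulated and theoretical active-cluster rates lives in the
    calling analysis).  Population order: E clusters 1..p, E background,
    I clusters 1..p, I background.
    """

    def __init__(self, spec: NetworkSpec, Jplus_override: Optional[dict] = None):
        spec.validate()
        self.spec = spec
        p = spec.p
        Jp = {a: dict(spec.Jplus[a]) for a in ("E", "I")}
        if Jplus_override:
            for a, row in Jplus_override.items():
                Jp[a].update(row)
        scale = spec.weight_scale
        labels, tau_m, tau_ref, tau_syn, V_th, V_r = [], [], [], [], [], []
        ext_mean, ext_var = [], []
        for a in ("E", "I"):
            for g in range(1, p + 2):
                labels.append(f"{a}{g}" if g <= p else f"{a}bg")
                tau_m.append(spec.tau_m[a])
                tau_ref.append(spec.tau_ref[a])
                tau_syn.append(spec.tau_syn["E"])  # single tau_s in the theory
                V_th.append(spec.V_thresh[a])
                V_r.append(spec.V_reset[a])
                Jx = spec.J_ext[a] * scale
                ext_mean.append(spec.C_ext[a] * Jx * spec.nu0[a])
                ext_var.append(spec.C_ext[a] * Jx ** 2 * spec.nu0[a])
        n = 2 * (p + 1)
        K = np.zeros((n, n))
        W = np.zeros((n, n))

        def idx(a, g):
            return (0 if a == "E" else p + 1) + g - 1

        for a in ("E", "I"):
            for b in ("E", "I"):
                cc = _counts(spec, a, b)
                sgn = 1.0 if b == "E" else -1.0
                jp = Jp[a][b] * scale * sgn
                jm = depressed_weight(spec.J[a][b], Jp[a][b], spec.f_pop(a),
                                      spec.f_pop(b), p) * scale * sgn
                j0 = spec.J[a][b] * scale * sgn
                for g in range(1, p + 1):  # clustered rows
                    K[idx(a, g), idx(b, g)] = cc["same"]
                    for l in range(1, p + 1):
                        if l != g:
                            K[idx(a, g), idx(b, l)] = cc["other_total"] / (p - 1)
                            W[idx(a, g), idx(b, l)] = jm
                    K[idx(a, g), idx(b, p + 1)] = cc["bg"]
                    W[idx(a, g), idx(b, g)] = jp
                    W[idx(a, g), idx(b, p + 1)] = jm
                # background row
                for l in range(1, p + 1):
                    K[idx(a, p + 1), idx(b, l)] = cc["clu_total"] / p
                    W[idx(a, p + 1), idx(b, l)] = jm
                K[idx(a, p + 1), idx(b, p + 1)] = cc["bg"]
                W[idx(a, p + 1), idx(b, p + 1)] = j0

        self.system = PopulationSystem(labels, tau_m, tau_ref, tau_syn, V_th,
                                       V_r, K, W, ext_mean, ext_var)
        self._idx = idx
        self.p = p

    # ------------------------------------------------------------------
    def input_moments(self, nu: np.ndarray) -> PopulationMoments:
        return self.system.moments(nu)

    def init_vector(self, nA: int, nu_high_E=50.0, nu_low_E=2.0,
                    nu_high_I=20.0, nu_low_I=8.0) -> np.ndarray:
        p = self.p
        nu = np.empty(2 * (p + 1))
        nu[:p] = nu_low_E
        nu[:nA] = nu_high_E
        nu[p] = nu_low_E
        nu[p + 1:2 * p + 1] = nu_low_I
        nu[p + 1:p + 1 + nA] = nu_high_I
        nu[2 * p + 1] = nu_low_I
        return nu

    def _classify(self, nu: np.ndarray, nA: int, min_gap: float = 0.5) -> bool:
        """Does the solution have the sought active/inactive structure?"""
        p = self.p
        e = nu[:p]
        if nA == 0:
            return float(np.ptp(e)) < 1e-3
        hi, lo = e[:nA], e[nA:]
        if lo.size == 0:
            return float(np.ptp(hi)) < 1e-3
        return (np.ptp(hi) < 1e-3 and np.ptp(lo) < 1e-3
                and hi.min() - lo.max() > min_gap)

    def solve_plain(self, nA: int, init: Optional[np.ndarray] = None,
                    tol: float = 1e-10, **init_kw) -> MFTSolution:
        """Search for a self-consistent state with nA active clusters.

        Returns ``converged=False`` (not an error) when the branch does not
        exist at these parameters, i.e. the solver either fails or lands on
        a state without the requested structure.
        """
        if not (0 <= nA <= self.p):
            raise ValueError("nA must be in 0..p")
        if init is None:
            init = self.init_vector(nA, **init_kw)
        nu, res, ok = self.system.solve(init, tol=tol)
        ok = ok and self._classify(nu, nA)
        return MFTSolution(nu=nu, s2=None, nA=nA, residual=res, converged=ok,
                           labels=self.system.labels)

    def solve_quenched(self, delta_H: dict | float, nA: int,
                       init: Optional[np.ndarray] = None,
                       s2_init: Optional[np.ndarray] = None,
                       tol: float = 1e-10, **init_kw) -> MFTSolution:
        if np.isscalar(delta_H):
            delta_H = {"E": float(delta_H), "I": 0.0}
        spec = self.spec
        ext_delta = np.zeros(self.system.n)
        for a in ("E", "I"):
            dH = delta_H.get(a, 0.0)
            val = spec.C_ext[a] * spec.J_ext[a] * spec.weight_scale * dH * spec.nu0[a]
            sl = slice(0, self.p + 1) if a == "E" else slice(self.p + 1, None)
            ext_delta[sl] = val
        self.system.ext_delta = ext_delta
        if init is None:
            init = self.init_vector(nA, **init_kw)
        nu, s2, res, ok = self.system.solve_quenched(init, s2_init, tol=tol)
        ok = ok and self._classify(nu, nA)
        return MFTSolution(nu=nu, s2=s2, nA=nA, residual=res, converged=ok,
                           labels=self.system.labels)

    def scan_states(self, delta_H_grid: Sequence[float],
                    nA_set: Sequence[int], tol: float = 1e-10) -> pd.DataFrame:
        """Branch table over (delta_H, nA): existence flag and key rates."""
        rows = []
        for dH in delta_H_grid:
            for nA in nA_set:
                sol = self.solve_quenched(dH, nA, tol=tol)
                e = sol.nu[:self.p]
                nu_up = float(e[:nA].mean()) if nA >= 1 else float(e.mean())
                nu_dn = float(e[nA:].mean()) if 0 < nA < self.p else float(e.mean())
                rows.append(dict(delta_H=dH, nA=nA, exists=bool(sol.converged),
                                 nu_up_E=nu_up, nu_down_E=nu_dn,
                                 nu_bg_E=float(sol.nu[self.p]),
                                 residual=sol.residual))
        return pd.DataFrame(rows)


def uniform_mft(spec: NetworkSpec) -> PopulationSystem:
    """Two-population mean-field system for the uniform architecture."""
    scale = spec.weight_scale
    labels = ["E", "I"]
    K = np.array([[spec.C("E", "E"), spec.C("E", "I")],
                  [spec.C("I", "E"), spec.C("I", "I")]], dtype=float)
    W = np.array([[spec.J["E"]["E"], -spec.J["E"]["I"]],
                  [spec.J["I"]["E"], -spec.J["I"]["I"]]]) * scale
    ext_mean = [spec.C_ext[a] * spec.J_ext[a] * scale * spec.nu0[a] for a in labels]
    ext_var = [spec.C_ext[a] * (spec.J_ext[a] * scale) ** 2 * spec.nu0[a]
               for a in labels]
    return PopulationSystem(labels,
                            [spec.tau_m[a] for a in labels],
                            [spec.tau_ref[a] for a in labels],
                            [spec.tau_syn["E"]] * 2,
                            [spec.V_thresh[a] for a in labels],
                            [spec.V_reset[a] for a in labels],
                            K, W, ext_mean, ext_var)
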