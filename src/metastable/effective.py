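"""Effective mean-field reduction of a two-cluster network.

A reduced network of two excitatory clusters (E1, E2), a background E
population and a background I population is analyzed by freezing the
"in-focus" cluster rates, letting the ambient populations adapt
self-consistently, and reading out the induced cluster rates.  The
resulting 2D flow map ``nu_out - nu_in`` exposes the attractor structure:
in the bistable phase, two stable cluster states linked by an unstable
(uniform) saddle on the diagonal.  Integrating the flow along a trajectory
through the three fixed points yields a 1D effective potential whose
barrier height h measures the stability of the cluster states; h shrinks
with the input-heterogeneity arousal modulation and vanishes when the two
wells merge.

With arousal (quenched input spread), each population is described only by
its mean rate: the across-cell rate variance is set to zero and the
transfer function is averaged over the Gaussian quenched variable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq, root

from .meanfield import _GH_W, _GH_X, PopulationSystem, lif_transfer_rate
from .network import depressed_weight
from .params import NetworkSpec

POP_LABELS = ("E1", "E2", "Eb", "Ib")


@dataclass
class ReducedNetworkSpec:
    """Two-cluster reduction: E1, E2, Eb, Ib.

    Built with the clustered construction except that weights between the
    two clusters are NOT depressed (they stay at the baseline ``J_EE``);
    cluster-background weights are depressed per the weight-conservation
    rule with p=2.  ``f`` is the fraction of the E population per cluster;
    it is larger than in the full network so that two clusters carry a
    comparable share of the excitatory mass.
    """

    base: NetworkSpec = field(default_factory=NetworkSpec)
    f: float = 0.08
    Jplus_EE: float = 10.0
    # E->I coupling is strengthened relative to the full network: the
    # reduced model has no inhibitory clustering, so stability of the
    # moderate-rate wells relies on stronger global inhibitory feedback
    J_IE: float = 2.4

    def build(self, delta_H_E: float = 0.0) -> PopulationSystem:
        spec = self.base
        scale = spec.weight_scale
        f = self.f
        jp = self.Jplus_EE if self.Jplus_EE is not None else spec.Jplus["E"]["E"]
        jEE = spec.J["E"]["E"]
        jm = depressed_weight(jEE, jp, f, f, 2)
        CEE, CEI = spec.C("E", "E"), spec.C("E", "I")
        CIE, CII = spec.C("I", "E"), spec.C("I", "I")
        jEI, jII = spec.J["E"]["I"], spec.J["I"]["I"]
        jIE = self.J_IE if self.J_IE is not None else spec.J["I"]["E"]
        # in-degree counts (post x pre) over (E1, E2, Eb, Ib)
        nc = int(round(f * CEE))
        nb = int(round((1 - 2 * f) * CEE))
        K = np.array([
            [nc, nc, nb, CEI],
            [nc, nc, nb, CEI],
            [int(round(f * CEE)), int(round(f * CEE)), nb, CEI],
            [int(round(f * CIE)), int(round(f * CIE)),
             int(round((1 - 2 * f) * CIE)), CII],
        ], dtype=float)
        W = np.array([
            [jp, jEE, jm, -jEI],
            [jEE, jp, jm, -jEI],
            [jm, jm, jEE, -jEI],
            [jIE, jIE, jIE, -jII],
        ]) * scale
        tau_m = [spec.tau_m["E"]] * 3 + [spec.tau_m["I"]]
        tau_ref = [spec.tau_ref["E"]] * 3 + [spec.tau_ref["I"]]
        tau_syn = [spec.tau_syn["E"]] * 4
        V_th = [spec.V_thresh["E"]] * 3 + [spec.V_thresh["I"]]
        V_r = [spec.V_reset["E"]] * 3 + [spec.V_reset["I"]]
        ext_mean, ext_var, ext_delta = [], [], []
        for a in ("E", "E", "E", "I"):
            Jx = spec.J_ext[a] * scale
            ext_mean.append(spec.C_ext[a] * Jx * spec.nu0[a])
            ext_var.append(spec.C_ext[a] * Jx ** 2 * spec.nu0[a])
            dH = delta_H_E if a == "E" else 0.0
            ext_delta.append(spec.C_ext[a] * Jx * dH * spec.nu0[a])
        return PopulationSystem(POP_LABELS, tau_m, tau_ref, tau_syn, V_th, V_r,
                                K, W, ext_mean, ext_var, ext_delta)


@dataclass
class FlowField:
    nu1: np.ndarray          # grid axis for cluster 1 input rate
    nu2: np.ndarray
    F1: np.ndarray           # nu_out - nu_in component along cluster 1
    F2: np.ndarray
    ambient: np.ndarray      # (n1, n2, 2): adapted (Eb, Ib) rates
    delta_H: float = 0.0


@dataclass
class FixedPoint:
    nu: np.ndarray
    stable: bool


@dataclass
class EffectivePotential:
    path: np.ndarray         # (n, 2) trajectory through the fixed points
    arc: np.ndarray          # path coordinate (arc length)
    U: np.ndarray            # potential values (relative)
    wells: np.ndarray        # indices of the two minima
    saddle: int              # index of the interior maximum
    h: float                 # barrier height


class EffectiveMFT:
    """Mascaro-Amit in-focus/ambient reduction of the 2-cluster network."""

    def __init__(self, rspec: Optional[ReducedNetworkSpec] = None,
                 delta_H: float = 0.0):
        self.rspec = rspec or ReducedNetworkSpec()
        self.delta_H = float(delta_H)
        self.system = self.rspec.build(self.delta_H)
        self._frozen = np.array([True, True, False, False])

    # -- population-level transfer with quenched averaging (s^2 = 0) ----
    def _rates_quenched(self, nu: np.ndarray) -> np.ndarray:
        sysm = self.system
        m = sysm.moments(nu)
        delta = sysm.ext_delta
        if self.delta_H == 0.0:
            return lif_transfer_rate(m.mu, np.sqrt(m.sigma2), sysm.tau_m,
                                     sysm.tau_ref, sysm.tau_syn, sysm.V_th,
                                     sysm.V_r)
        mu_z = m.mu[:, None] + delta[:, None] * _GH_X[None, :]
        nz = lif_transfer_rate(mu_z, np.sqrt(m.sigma2)[:, None],
                               sysm.tau_m[:, None], sysm.tau_ref[:, None],
                               sysm.tau_syn[:, None], sysm.V_th[:, None],
                               sysm.V_r[:, None])
        return nz @ _GH_W

    def ambient_adapt(self, nu_in: np.ndarray, init=(5.0, 10.0),
                      tol: float = 1e-10, max_iter: int = 2000) -> np.ndarray:
        """Self-consistent (Eb, Ib) rates for frozen in-focus rates."""
        def resid(y):
            yc = np.clip(y, 0.0, None)
            nu = np.array([nu_in[0], nu_in[1], yc[0], yc[1]])
            return self._rates_quenched(nu)[2:] - yc

        sol = root(resid, np.asarray(init, dtype=float), method="hybr", tol=1e-12)
        y = np.clip(sol.x, 0.0, None)
        if np.max(np.abs(resid(y))) < 1e-8:
            return y
        # fallback: damped iteration from a neutral guess
        x = np.array([5.0, 10.0])
        damping = 0.3
        for _ in range(max_iter):
            fx = x + resid(x)
            if np.max(np.abs(fx - x)) < tol:
                return np.clip(fx, 0.0, None)
            x = np.clip((1 - damping) * x + damping * fx, 0.0, None)
        raise RuntimeError(
            f"ambient adaptation failed at nu_in={tuple(nu_in)}")

    def induced_rates(self, nu_in: np.ndarray,
                      ambient: Optional[np.ndarray] = None) -> np.ndarray:
        """Output rates of E1, E2 given frozen inputs and adapted ambient."""
        if ambient is None:
            ambient = self.ambient_adapt(nu_in)
        nu = np.array([nu_in[0], nu_in[1], ambient[0], ambient[1]])
        return self._rates_quenched(nu)[:2]

    def flow(self, nu_in: np.ndarray, ambient: Optional[np.ndarray] = None) -> np.ndarray:
        return self.induced_rates(nu_in, ambient) - np.asarray(nu_in, dtype=float)

    def compute_flow_map(self, grid: Optional[np.ndarray] = None) -> FlowField:
        if grid is None:
            grid = np.linspace(0.0, 80.0, 60)
        n = grid.size
        F1 = np.zeros((n, n))
        F2 = np.zeros((n, n))
        amb = np.zeros((n, n, 2))
        guess = (5.0, 10.0)
        for i, a in enumerate(grid):
            g = guess
            for j, b in enumerate(grid):
                am = self.ambient_adapt((a, b), init=g)
                g = tuple(am)   # warm start along the row
                out = self.induced_rates((a, b), am)
                F1[i, j] = out[0] - a
                F2[i, j] = out[1] - b
                amb[i, j] = am
            if j == n - 1:
                guess = tuple(amb[i, 0])
        return FlowField(nu1=grid, nu2=grid, F1=F1, F2=F2, ambient=amb,
                         delta_H=self.delta_H)

    def find_fixed_points(self, field: Optional[FlowField] = None,
                          seeds: Optional[list] = None, tol: float = 1e-8) -> list:
        """Zeros of the flow, deduplicated, with linear-stability labels."""
        cand = []
        if seeds is not None:
            cand.extend(seeds)
        if field is not None:
            s1 = np.sign(field.F1)
            s2 = np.sign(field.F2)
            flip = ((np.diff(s1, axis=0)[:, :-1] != 0) | (np.diff(s1, axis=1)[:-1] != 0)) & \
                   ((np.diff(s2, axis=0)[:, :-1] != 0) | (np.diff(s2, axis=1)[:-1] != 0))
            for i, j in zip(*np.nonzero(flip)):
                cand.append((field.nu1[i], field.nu2[j]))
        if not cand:
            cand = [(2.0, 2.0), (40.0, 2.0), (2.0, 40.0), (20.0, 20.0)]
        out = []
        for c in cand:
            sol = root(lambda x: self.flow(np.clip(x, 0.0, None)), np.asarray(c, float),
                       method="hybr", tol=1e-12)
            x = np.clip(sol.x, 0.0, None)
            if np.max(np.abs(self.flow(x))) > tol:
                continue
            if any(np.hypot(*(x - fp.nu)) < 0.5 for fp in out):
                continue
            eps = 1e-3
            Jm = np.zeros((2, 2))
            f0 = self.flow(x)
            for k in range(2):
                dx = np.zeros(2)
                dx[k] = eps
                Jm[:, k] = (self.flow(x + dx) - f0) / eps
            stable = bool(np.all(np.real(np.linalg.eigvals(Jm)) < 0))
            out.append(FixedPoint(nu=x, stable=stable))
        return out

    # -- potential ------------------------------------------------------
    def _refine_path(self, pts: np.ndarray, n_iter: int = 0) -> np.ndarray:
        return pts

    def integrate_potential(self, fixed_points: list,
                            n_seg: int = 120) -> EffectivePotential:
        """Potential along well -> saddle -> well, U = -int F . dl."""
        stable = [fp for fp in fixed_points if fp.stable]
        unstable = [fp for fp in fixed_points if not fp.stable]
        if len(stable) < 2 or not unstable:
            raise ValueError("path requires two wells and a saddle")
        w1, w2 = stable[0].nu, stable[1].nu
        sd = min(unstable, key=lambda fp: np.hypot(*(fp.nu - 0.5 * (w1 + w2)))).nu
        seg1 = np.linspace(w1, sd, n_seg // 2, endpoint=False)
        seg2 = np.linspace(sd, w2, n_seg // 2 + 1)
        path = np.vstack([seg1, seg2])
        U = np.zeros(len(path))
        for k in range(1, len(path)):
            mid = 0.5 * (path[k] + path[k - 1])
            dl = path[k] - path[k - 1]
            U[k] = U[k - 1] - float(np.dot(self.flow(mid), dl))
        arc = np.concatenate([[0.0], np.cumsum(
            np.hypot(*np.diff(path, axis=0).T))])
        saddle_idx = len(seg1)
        wells = np.array([0, len(path) - 1])
        h = float(U[saddle_idx] - max(U[wells[0]], U[wells[1]]))
        return EffectivePotential(path=path, arc=arc, U=U, wells=wells,
                                  saddle=saddle_idx, h=max(h, 0.0))

    def barrier_height(self) -> float:
        fps = self.find_fixed_points(seeds=[(2.0, 2.0), (50.0, 2.0), (2.0, 50.0),
                                            (15.0, 15.0), (30.0, 30.0)])
        stable = [fp for fp in fps if fp.stable]
        unstable = [fp for fp in fps if not fp.stable]
        off_diag = [fp for fp in stable if abs(fp.nu[0] - fp.nu[1]) > 1.0]
        if len(off_diag) < 2 or not unstable:
            return 0.0
        return self.integrate_potential(fps).h


def barrier_height_curve(rspec: Optional[ReducedNetworkSpec] = None,
                         delta_H_grid=np.linspace(0.0, 0.15, 7)) -> pd.DataFrame:
    """Barrier height h versus the arousal modulation for the reduced net."""
    rows = []
    for dH in np.atleast_1d(delta_H_grid):
        emft = EffectiveMFT(rspec, delta_H=float(dH))
        fps = emft.find_fixed_points(seeds=[(2.0, 2.0), (50.0, 2.0), (2.0, 50.0),
                                            (15.0, 15.0), (30.0, 30.0)])
        stable = [fp for fp in fps if fp.stable]
        off = [fp for fp in stable if abs(fp.nu[0] - fp.nu[1]) > 1.0]
        h = 0.0
        if len(off) >= 2 and any(not fp.stable for fp in fps):
            h = emft.integrate_potential(fps).h
        rows.append(dict(delta_H=float(dH), h=h, n_fixed_points=len(fps),
                         bistable=len(off) >= 2))
    return pd.DataFrame(rows)
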