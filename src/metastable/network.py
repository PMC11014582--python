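"""Construction of uniform and clustered network realizations.

Connectivity uses fixed in-degrees: every neuron receives exactly the
prescribed number of connections from each presynaptic group, drawn at
random without replacement and without self-connections.  The clustered
architecture arranges a fraction ``p*f`` of each population into ``p``
non-overlapping assemblies with potentiated within-assembly weights
``J+``, depressed between-assembly and assembly/background weights ``J-``
(:func:`depressed_weight`), and unchanged background-background weights,
so that the summed synaptic weight equals that of the uniform network.

Inhibitory weights are stored with negative sign in the realized matrix so
the voltage equation needs no case logic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .params import POPS, ArousalSpec, NetworkSpec, StimulusSet

BACKGROUND = "background"


def depressed_weight(J: float, Jplus: float, fa: float, fb: float, p: int) -> float:
    """Intercluster weight J- that conserves the total summed weight.

    Solves ``J- = ((fa+fb-p*fa*fb)*J - fa*fb*J+)/(fa+fb-p*fa*fb-fa*fb)``,
    the unique value for which the clustered network with intracluster
    weight ``J+`` has the same summed synaptic weight as the uniform
    network with homogeneous weight ``J``.
    """
    denom = fa + fb - p * fa * fb - fa * fb
    if abs(denom) < 1e-12:
        raise ValueError(
            f"degenerate weight normalization: fa={fa}, fb={fb}, p={p} "
            "make fa+fb-p*fa*fb-fa*fb vanish")
    return ((fa + fb - p * fa * fb) * J - fa * fb * Jplus) / denom


@dataclass
class ConnectivityRealization:
    """A realized weighted network.

    ``W`` is a CSC sparse matrix (post x pre) holding signed physical
    weights in mV.  ``membership[a]`` assigns each neuron of population
    ``a`` a cluster index in 1..p, or p+1 for the background group.
    """

    W: sp.csc_matrix
    membership: dict
    spec: NetworkSpec
    seed: Optional[int] = None

    def neurons(self, a: str) -> np.ndarray:
        """Global indices of population a (E first, then I)."""
        if a == "E":
            return np.arange(self.spec.NE)
        return np.arange(self.spec.NE, self.spec.N)

    def cluster_members(self, a: str, c: int) -> np.ndarray:
        """Global indices of the cells of population a in cluster c (1-based)."""
        local = np.flatnonzero(self.membership[a] == c)
        return local if a == "E" else local + self.spec.NE


def _membership(spec: NetworkSpec, a: str) -> np.ndarray:
    """Cluster labels 1..p in blocks of floor(f*N); remainder -> p+1."""
    n, size = spec.N_pop(a), spec.cluster_size(a)
    m = np.full(n, spec.p + 1, dtype=np.int64)
    for c in range(spec.p):
        m[c * size:(c + 1) * size] = c + 1
    return m


def _draw(rng, pool: np.ndarray, k: int, exclude: int) -> np.ndarray:
    """k distinct draws from pool, never equal to `exclude`."""
    if exclude in pool:
        pool = pool[pool != exclude]
    if k > pool.size:
        raise ValueError(f"cannot draw {k} in-connections from pool of {pool.size}")
    return rng.choice(pool, size=k, replace=False)


def build_uniform(spec: NetworkSpec, seed) -> ConnectivityRealization:
    """Fixed in-degree Erdos-Renyi-like network; all weights J[a][b]."""
    spec.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    scale = spec.weight_scale
    rows, cols, vals = [], [], []
    offset = {"E": 0, "I": spec.NE}
    for a in POPS:
        for b in POPS:
            C = spec.C(a, b)
            w = spec.J[a][b] * scale * (1.0 if b == "E" else -1.0)
            pool = np.arange(spec.N_pop(b)) + offset[b]
            for i in range(spec.N_pop(a)):
                pre = _draw(rng, pool, C, i + offset[a])
                rows.append(np.full(C, i + offset[a]))
                cols.append(pre)
                vals.append(np.full(C, w))
    W = sp.csc_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(spec.N, spec.N))
    membership = {a: np.full(spec.N_pop(a), spec.p + 1, dtype=np.int64) for a in POPS}
    return ConnectivityRealization(W=W, membership=membership, spec=spec, seed=None)


def build_clustered(spec: NetworkSpec, seed) -> ConnectivityRealization:
    """Clustered architecture with exact per-group in-degrees.

    A clustered neuron receives ``f_b*C_ab`` same-cluster, ``(p-1)*f_b*C_ab``
    other-cluster and ``(1-p*f_b)*C_ab`` background connections from
    population b; a background neuron receives ``p*f_b*C_ab`` from clusters
    and ``(1-p*f_b)*C_ab`` from the background.  Fractional counts are
    rounded to the nearest integer, identically for every neuron of a
    population, preserving the homogeneity the mean-field analysis assumes.
    """
    spec.validate()
    if spec.p < 1:
        raise ValueError("clustered architecture requires p >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    scale = spec.weight_scale
    membership = {a: _membership(spec, a) for a in POPS}
    offset = {"E": 0, "I": spec.NE}
    member_global = {}
    for b in POPS:
        for c in range(1, spec.p + 2):
            member_global[b, c] = np.flatnonzero(membership[b] == c) + offset[b]
        member_global[b, "clustered"] = np.flatnonzero(membership[b] <= spec.p) + offset[b]

    rows, cols, vals = [], [], []

    def add(post: int, pre: np.ndarray, w: float):
        rows.append(np.full(pre.size, post))
        cols.append(pre)
        vals.append(np.full(pre.size, w))

    for a in POPS:
        for b in POPS:
            C, fb = spec.C(a, b), spec.f_pop(b)
            n_same = int(round(fb * C))
            n_other = int(round((p_other := (spec.p - 1) * fb) * C)) if spec.p > 1 else 0
            n_bg = int(round((1 - spec.p * fb) * C))
            sgn = 1.0 if b == "E" else -1.0
            Jp = spec.Jplus[a][b] * scale * sgn
            Jm = depressed_weight(spec.J[a][b], spec.Jplus[a][b],
                                  spec.f_pop(a), fb, spec.p) * scale * sgn
            J0 = spec.J[a][b] * scale * sgn
            bg_pool = member_global[b, spec.p + 1]
            clustered_pool = member_global[b, "clustered"]
            for i_local in range(spec.N_pop(a)):
                i = i_local + offset[a]
                c = membership[a][i_local]
                if c <= spec.p:  # clustered postsynaptic cell
                    same_pool = member_global[b, c]
                    other_pool = clustered_pool[
                        (clustered_pool < same_pool[0]) | (clustered_pool > same_pool[-1])]
                    add(i, _draw(rng, same_pool, n_same, i), Jp)
                    if n_other:
                        add(i, _draw(rng, other_pool, n_other, i), Jm)
                    if n_bg:
                        add(i, _draw(rng, bg_pool, n_bg, i), Jm)
                else:  # background postsynaptic cell
                    n_clu = int(round(spec.p * fb * C))
                    if n_clu:
                        add(i, _draw(rng, clustered_pool, n_clu, i), Jm)
                    if n_bg:
                        add(i, _draw(rng, bg_pool, n_bg, i), J0)
    W = sp.csc_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(spec.N, spec.N))
    return ConnectivityRealization(W=W, membership=membership, spec=spec, seed=None)


def build_network(spec: NetworkSpec, seed) -> ConnectivityRealization:
    return build_uniform(spec, seed) if spec.p == 0 else build_clustered(spec, seed)


def draw_arousal_inputs(spec: NetworkSpec, arousal: ArousalSpec, seed) -> ArousalSpec:
    """Populate per-cell external rates for the requested arousal mode.

    Input-mean modulation scales every cell's rate by ``1 + delta_M``.
    Input-heterogeneity modulation adds quenched Gaussian spread,
    ``nu = nu0 + z*delta_H*nu0`` clipped at zero; in clustered networks all
    assemblies share one realization of the within-cluster draw so every
    cluster receives the same spatially-averaged input, while background
    cells get independent draws.
    """
    arousal.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z, nu_ext = {}, {}
    for a in POPS:
        n, nu0 = spec.N_pop(a), spec.nu0[a]
        if arousal.mode == "input_mean":
            z[a] = np.zeros(n)
            nu_ext[a] = np.full(n, nu0 * (1.0 + arousal.delta_M[a]))
        elif arousal.mode == "input_heterogeneity":
            dH = arousal.delta_H[a]
            if arousal.z is not None and a in arousal.z:
                # reuse a quenched realization (shared across a delta_H grid)
                z[a] = arousal.z[a]
            elif spec.p >= 1:
                size = spec.cluster_size(a)
                z_clu = rng.standard_normal(size)
                z_bg = rng.standard_normal(n - spec.p * size)
                z[a] = np.concatenate([np.tile(z_clu, spec.p), z_bg])
            else:
                z[a] = rng.standard_normal(n)
            nu_ext[a] = np.clip(nu0 + z[a] * dH * nu0, 0.0, None)
        else:
            z[a] = np.zeros(n)
            nu_ext[a] = np.full(n, nu0)
    import dataclasses
    return dataclasses.replace(arousal, z=z, nu_ext=nu_ext)


def stimulus_timecourse(t: np.ndarray, stim: StimulusSet) -> np.ndarray:
    """Difference-of-exponentials stimulus envelope, unit peak.

    ``s(t) = gamma*(exp(-(t-t0)/tau_d) - exp(-(t-t0)/tau_r))`` for
    ``t >= t0`` and 0 before onset; ``gamma`` normalizes the analytic peak
    (at ``t0 + tau_r*tau_d/(tau_d-tau_r)*log(tau_d/tau_r)``) to 1.
    """
    if stim.tau_d <= stim.tau_r or stim.tau_r <= 0:
        raise ValueError("stimulus requires tau_d > tau_r > 0")
    t = np.asarray(t, dtype=float)
    dt_peak = (stim.tau_r * stim.tau_d / (stim.tau_d - stim.tau_r)
               * np.log(stim.tau_d / stim.tau_r))
    peak = np.exp(-dt_peak / stim.tau_d) - np.exp(-dt_peak / stim.tau_r)
    u = t - stim.t_stim
    s = np.where(u >= 0,
                 np.exp(-np.clip(u, 0, None) / stim.tau_d)
                 - np.exp(-np.clip(u, 0, None) / stim.tau_r), 0.0)
    return s / peak


def build_stimulus_targets(conn: ConnectivityRealization, stim: StimulusSet,
                           seed, match_p: Optional[int] = None) -> StimulusSet:
    """Assign targeted clusters/cells to each stimulus.

    Clustered: each stimulus targets floor(p/2) clusters chosen at random
    and 50% of the E cells within each targeted cluster.  Uniform: the same
    total number of E cells, drawn from the whole E population.  Different
    stimuli may overlap.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    spec = conn.spec
    import dataclasses
    targeted_clusters, targeted_cells = [], []
    half_cluster = int(round(0.5 * spec.cluster_size("E")))
    if spec.p >= 1:
        n_clu = spec.p // 2
        for _ in range(stim.n_stimuli):
            cl = np.sort(rng.choice(np.arange(1, spec.p + 1), size=n_clu, replace=False))
            cells = []
            for c in cl:
                members = conn.cluster_members("E", c)
                cells.append(np.sort(rng.choice(members, size=half_cluster, replace=False)))
            targeted_clusters.append(cl)
            targeted_cells.append(np.sort(np.concatenate(cells)))
    else:
        # match the total targeted-cell count of the clustered counterpart
        p_ref = match_p if match_p is not None else NetworkSpec().p
        n_cells = (p_ref // 2) * half_cluster
        all_e = np.arange(spec.NE)
        for _ in range(stim.n_stimuli):
            targeted_clusters.append(np.array([], dtype=np.int64))
            targeted_cells.append(np.sort(rng.choice(all_e, size=n_cells, replace=False)))
    return dataclasses.replace(stim, targeted_clusters=targeted_clusters,
                               targeted_cells=targeted_cells)


def export_connectivity(conn: ConnectivityRealization, prefix: str) -> None:
    """Write coordinate-format sparse matrix and a membership table."""
    coo = conn.W.tocoo()
    pd.DataFrame({"post": coo.row, "pre": coo.col, "weight_mV": coo.data}
                 ).to_csv(f"{prefix}_edges.csv", index=False)
    rows = []
    for a in POPS:
        off = 0 if a == "E" else conn.spec.NE
        for i, c in enumerate(conn.membership[a]):
            rows.append((i + off, a, int(c)))
    pd.DataFrame(rows, columns=["neuron_id", "population", "cluster_id"]
                 ).to_csv(f"{prefix}_membership.csv", index=False)
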