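"""Event-on-grid integration of the LIF network with exponential synapses.

The membrane and synaptic equations are linear between spikes, so the
integrator uses the exact (exponential) propagator over each time step;
spike times are forced to the simulation grid.  Background drive is, for
each cell, the superposition of ``C_ext`` independent Poisson synapses of
equal weight, implemented as a single Poisson process of the summed rate
(statistically identical); arrivals are generated by inter-event sampling.
Stimulus input is a deterministic current entering the voltage equation of
targeted cells only.

Voltage is clamped at reset for the refractory period; synaptic currents
keep evolving during refractoriness (only the voltage is stated to be
clamped; treating currents as unclamped is the package's assumption).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from numba import njit

from .network import (ConnectivityRealization, build_network,
                      build_stimulus_targets, draw_arousal_inputs,
                      stimulus_timecourse)
from .params import (ArousalSpec, NetworkSpec, SimulationConfig, StimulusSet,
                     rng_streams)


@dataclass
class SpikeData:
    """Spike times for one simulated trial.

    ``times`` are in seconds from trial start; ``t_stim`` marks stimulus
    onset (``align()`` returns onset-origin times).  ``ids`` are global
    neuron indices (E cells first).
    """

    times: np.ndarray
    ids: np.ndarray
    n_neurons: int
    T: float
    t_stim: Optional[float] = None
    trial_id: int = 0
    stimulus_id: Optional[int] = None
    arousal_value: float = 0.0
    meta: dict = field(default_factory=dict)

    def align(self) -> np.ndarray:
        return self.times - (self.t_stim or 0.0)

    def spike_trains(self, subset: Optional[np.ndarray] = None) -> list:
        idx = np.arange(self.n_neurons) if subset is None else np.asarray(subset)
        order = np.argsort(self.ids, kind="stable")
        ids, times = self.ids[order], self.times[order]
        bounds = np.searchsorted(ids, np.concatenate([idx, idx + 1]))
        k = idx.size
        return [np.sort(times[bounds[j]:bounds[k + j]]) for j in range(k)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "neuron_id": self.ids, "spike_time_s": self.times,
            "trial_id": self.trial_id,
            "stimulus_id": -1 if self.stimulus_id is None else self.stimulus_id,
        })


@njit(cache=True)
def _integrate(n_steps, dt, V, alpha, cE, cI, cS, betaE, betaI,
               ref_steps, V_th, V_r, indptr, targets, weights,
               tau_sE, tau_sI, ext_rate, ext_jump, stim_amp, s_t,
               seed, spike_t, spike_i):
    np.random.seed(seed)
    N = V.size
    IE = np.zeros(N)
    II = np.zeros(N)
    refr = np.zeros(N, dtype=np.int64)
    next_ext = np.empty(N)
    for i in range(N):
        if ext_rate[i] > 0.0:
            next_ext[i] = np.random.exponential(1.0 / ext_rate[i])
        else:
            next_ext[i] = 1e30
    n_sp = 0
    cap = spike_t.size
    spiked = np.empty(N, dtype=np.int64)
    for step in range(n_steps):
        t_next = (step + 1) * dt
        s_now = s_t[step]
        n_fired = 0
        for i in range(N):
            if refr[i] > 0:
                refr[i] -= 1
                V[i] = V_r[i]
            else:
                v = (alpha[i] * V[i] + cE[i] * IE[i] + cI[i] * II[i]
                     + cS[i] * stim_amp[i] * s_now)
                if v >= V_th[i]:
                    V[i] = V_r[i]
                    refr[i] = ref_steps[i]
                    if n_sp < cap:
                        spike_t[n_sp] = t_next
                        spike_i[n_sp] = i
                    n_sp += 1
                    spiked[n_fired] = i
                    n_fired += 1
                else:
                    V[i] = v
            # decay synaptic currents and add external arrivals
            IE[i] *= betaE
            II[i] *= betaI
            while next_ext[i] <= t_next:
                IE[i] += ext_jump[i]
                next_ext[i] += np.random.exponential(1.0 / ext_rate[i])
        for k in range(n_fired):
            j = spiked[k]
            for m in range(indptr[j], indptr[j + 1]):
                w = weights[m]
                if w > 0.0:
                    IE[targets[m]] += w / tau_sE
                else:
                    II[targets[m]] += w / tau_sI
        if not np.isfinite(V[0]):
            return -step  # diagnostic: abort step index
    return n_sp


@njit(cache=True)
def _ou_voltage_counts(n_neurons, n_steps, dt, tau_m, muV, sigV,
                       V_th, V_r, ref_steps, seed, burn_steps):
    """Spike counts of LIF neurons under white-noise drive, sampling the
    membrane potential as an exact OU process between grid points."""
    np.random.seed(seed)
    a = np.exp(-dt / tau_m)
    kick = sigV * np.sqrt(1.0 - a * a)
    # continuity correction for discretely observed first passage:
    # excursions between samples are missed, equivalent to a barrier
    # raised by 0.5826*(per-step SD) (|zeta(1/2)|/sqrt(2*pi))
    th_eff = V_th - 0.5826 * kick
    counts = np.zeros(n_neurons, dtype=np.int64)
    for i in range(n_neurons):
        V = V_r
        refr = 0
        for step in range(burn_steps + n_steps):
            if refr > 0:
                refr -= 1
                V = V_r
            else:
                V = muV + (V - muV) * a + kick * np.random.standard_normal()
                if V >= th_eff:
                    V = V_r
                    refr = ref_steps
                    if step >= burn_steps:
                        counts[i] += 1
    return counts


def white_noise_rate(mu, sigma, tau_m=0.02, V_th=4.0, V_r=0.0,
                     tau_ref=0.005, T=4.0, n_neurons=25, dt=2e-6, seed=0,
                     burn_in=0.5):
    """Empirical rates of LIF neurons with Gaussian white-noise input.

    ``mu`` is the mean input (mV/s) and ``sigma^2`` the white-noise
    intensity (mV^2/s), the same convention as the transfer function; the
    membrane potential is an OU process with mean ``tau_m*mu`` and
    variance ``tau_m*sigma^2/2``, sampled exactly at the grid.
    """
    muV = tau_m * mu
    sigV = np.sqrt(tau_m / 2.0) * sigma
    counts = _ou_voltage_counts(n_neurons, int(round(T / dt)), dt, tau_m,
                                float(muV), float(sigV), V_th, V_r,
                                int(np.ceil(tau_ref / dt)), seed,
                                int(round(burn_in / dt)))
    return counts / T


@njit(cache=True)
def _diffusion_counts(n_neurons, n_steps, dt, tau_m, tau_s, mu, sigma,
                      V_th, V_r, ref_steps, seed, burn_steps):
    """Spike counts of LIF neurons driven by an OU (filtered white noise)
    current with mean mu and white-noise intensity sigma; retained as a
    finite-filter variant of the transfer-function oracle."""
    np.random.seed(seed)
    alpha = np.exp(-dt / tau_m)
    beta = np.exp(-dt / tau_s)
    sd_I = sigma / np.sqrt(2.0 * tau_s)
    kick = sd_I * np.sqrt(1.0 - beta * beta)
    # exact deterministic propagation of the (V, I) pair over one step
    k_vi = (tau_m * tau_s / (tau_m - tau_s)) * (alpha - beta)
    counts = np.zeros(n_neurons, dtype=np.int64)
    for i in range(n_neurons):
        V = V_r
        I = mu + sd_I * np.random.standard_normal()
        refr = 0
        for step in range(burn_steps + n_steps):
            if refr > 0:
                refr -= 1
                V = V_r
            else:
                V = alpha * V + tau_m * mu * (1.0 - alpha) + k_vi * (I - mu)
                if V >= V_th:
                    V = V_r
                    refr = ref_steps
                    if step >= burn_steps:
                        counts[i] += 1
            I = mu + (I - mu) * beta + kick * np.random.standard_normal()
    return counts


def diffusion_rate(mu, sigma, tau_m=0.02, tau_s=0.001, V_th=4.0, V_r=0.0,
                   tau_ref=0.005, T=20.0, n_neurons=25, dt=1e-5, seed=0,
                   burn_in=0.5):
    """Empirical rates of n independent diffusion-driven LIF neurons."""
    n_steps = int(round(T / dt))
    counts = _diffusion_counts(n_neurons, n_steps, dt, tau_m, tau_s,
                               float(mu), float(sigma), V_th, V_r,
                               int(np.ceil(tau_ref / dt)), seed,
                               int(round(burn_in / dt)))
    return counts / T


class Simulator:
    """Reusable integrator bound to one connectivity realization."""

    def __init__(self, conn: ConnectivityRealization, config: SimulationConfig):
        config.validate()
        self.conn = conn
        self.config = config
        spec = conn.spec
        N = spec.N
        dt = config.dt
        pop = np.array(["E"] * spec.NE + ["I"] * spec.NI)
        self.tau_m = np.array([spec.tau_m[a] for a in pop])
        tau_sE, tau_sI = spec.tau_syn["E"], spec.tau_syn["I"]
        self.alpha = np.exp(-dt / self.tau_m)
        betaE, betaI = np.exp(-dt / tau_sE), np.exp(-dt / tau_sI)
        kE = self.tau_m * tau_sE / (self.tau_m - tau_sE)
        kI = self.tau_m * tau_sI / (self.tau_m - tau_sI)
        self.cE = kE * (self.alpha - betaE)
        self.cI = kI * (self.alpha - betaI)
        self.cS = self.tau_m * (1.0 - self.alpha)
        self.betaE, self.betaI = betaE, betaI
        self.tau_sE, self.tau_sI = tau_sE, tau_sI
        self.V_th = np.array([spec.V_thresh[a] for a in pop])
        self.V_r = np.array([spec.V_reset[a] for a in pop])
        self.ref_steps = np.array(
            [int(np.ceil(spec.tau_ref[a] / dt)) for a in pop], dtype=np.int64)
        W = conn.W.tocsc()
        self.indptr = W.indptr.astype(np.int64)
        self.targets = W.indices.astype(np.int64)
        self.weights = W.data.astype(np.float64)
        self.C_ext = np.array([spec.C_ext[a] for a in pop], dtype=float)
        self.J_ext_mV = np.array(
            [spec.J_ext[a] * spec.weight_scale for a in pop])

    def run_trial(self, arousal: ArousalSpec, stim: Optional[StimulusSet],
                  stimulus_id: Optional[int], seed: int,
                  T: Optional[float] = None) -> SpikeData:
        spec = self.conn.spec
        cfg = self.config
        T = cfg.T_trial if T is None else T
        dt = cfg.dt
        n_steps = int(round(T / dt))
        streams = rng_streams(seed, "init", "poisson")
        V = streams["init"].uniform(self.V_r, self.V_th)
        if arousal.nu_ext is None:
            raise ValueError("arousal inputs not drawn; call draw_arousal_inputs")
        nu_ext = np.concatenate([arousal.nu_ext["E"], arousal.nu_ext["I"]])
        ext_rate = self.C_ext * nu_ext
        ext_jump = self.J_ext_mV / self.tau_sE
        stim_amp = np.zeros(spec.N)
        s_t = np.zeros(n_steps)
        if stim is not None and stimulus_id is not None:
            cells = stim.targeted_cells[stimulus_id]
            stim_amp[cells] = (stim.A_stim["E"] * spec.nu0["E"]
                               * spec.C_ext["E"] * spec.J_ext["E"]
                               * spec.weight_scale)
            tgrid = np.arange(n_steps) * dt
            s_t = stimulus_timecourse(tgrid, stim)
        cap = int(spec.N * T * 120) + 1000  # generous mean-rate headroom
        spike_t = np.empty(cap)
        spike_i = np.empty(cap, dtype=np.int64)
        kernel_seed = int(streams["poisson"].integers(0, 2**31 - 1))
        n_sp = _integrate(
            n_steps, dt, V, self.alpha, self.cE, self.cI, self.cS,
            self.betaE, self.betaI, self.ref_steps, self.V_th, self.V_r,
            self.indptr, self.targets, self.weights, self.tau_sE, self.tau_sI,
            ext_rate, ext_jump, stim_amp, s_t, kernel_seed, spike_t, spike_i)
        if n_sp < 0:
            raise FloatingPointError(
                f"non-finite membrane potential at step {-n_sp}")
        if n_sp > cap:
            raise RuntimeError("spike buffer overflow; raise the headroom")
        return SpikeData(
            times=spike_t[:n_sp].copy(), ids=spike_i[:n_sp].copy(),
            n_neurons=spec.N, T=T,
            t_stim=None if stim is None or stimulus_id is None else stim.t_stim,
            stimulus_id=stimulus_id,
            arousal_value=float(arousal.delta_H["E"] if arousal.mode ==
                                "input_heterogeneity" else arousal.delta_M["E"]))


def simulate_trial(conn: ConnectivityRealization, arousal: ArousalSpec,
                   stim: Optional[StimulusSet], config: SimulationConfig,
                   seed: int, stimulus_id: Optional[int] = None) -> SpikeData:
    """One trial of network activity (convenience wrapper)."""
    return Simulator(conn, config).run_trial(arousal, stim, stimulus_id, seed)


def run_experiment(spec: NetworkSpec, arousal_mode: str, delta_grid,
                   config: SimulationConfig, n_realizations: int,
                   n_trials_per_stimulus: Optional[int] = None,
                   n_stimuli: Optional[int] = 5, master_seed: int = 0,
                   spontaneous: bool = False, stim_template: Optional[StimulusSet] = None,
                   match_p: Optional[int] = None):
    """Simulate realizations x arousal values x stimuli x trials.

    Yields ``(realization, delta, conn, stim, trials)`` where ``trials`` is
    a list of :class:`SpikeData`.  Each trial uses fresh random membrane
    initial conditions; everything is deterministic given ``master_seed``.
    For ``spontaneous=True`` no stimulus is presented and the per-arousal
    trial count is ``n_trials_per_stimulus``.
    """
    n_trials = n_trials_per_stimulus or config.n_trials_per_stimulus
    for r in range(n_realizations):
        streams = rng_streams(master_seed + 7919 * r,
                              "connectivity", "arousal", "targets", "trials")
        conn = build_network(spec, streams["connectivity"])
        stim = None
        if not spontaneous:
            template = stim_template or StimulusSet(t_stim=config.t_stim)
            stim = build_stimulus_targets(conn, template, streams["targets"],
                                          match_p=match_p)
        sim = Simulator(conn, config)
        # one quenched realization per network realization, shared across
        # the arousal grid (inputs vary monotonically in delta per cell)
        z_shared = draw_arousal_inputs(
            spec, ArousalSpec(mode="input_heterogeneity",
                              delta_H={"E": 1.0, "I": 0.0}),
            streams["arousal"]).z
        for delta in np.atleast_1d(delta_grid):
            if arousal_mode == "input_mean":
                ar = ArousalSpec(mode="input_mean",
                                 delta_M={"E": float(delta), "I": 0.0})
            elif arousal_mode == "input_heterogeneity":
                ar = ArousalSpec(mode="input_heterogeneity",
                                 delta_H={"E": float(delta), "I": 0.0},
                                 z=z_shared)
            else:
                ar = ArousalSpec(mode="none")
            ar = draw_arousal_inputs(spec, ar, streams["arousal"])
            trials = []
            if spontaneous:
                for k in range(n_trials):
                    seed = int(streams["trials"].integers(0, 2**31 - 1))
                    sd = sim.run_trial(ar, None, None, seed)
                    sd.trial_id = k
                    trials.append(sd)
            else:
                for s in range(n_stimuli):
                    for k in range(n_trials):
                        seed = int(streams["trials"].integers(0, 2**31 - 1))
                        sd = sim.run_trial(ar, stim, s, seed)
                        sd.trial_id = k
                        trials.append(sd)
            yield r, float(delta), conn, stim, trials
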