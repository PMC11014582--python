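"""Study-scale drivers: simulate, then measure everything per arousal level.

These functions wire the simulator to the analysis stack in the way the
model study is organized: several network realizations per arousal value,
5 stimuli x n trials per realization for evoked campaigns, spontaneous-only
trials for spectra and cluster-state statistics.  They return tidy
DataFrames keyed by (realization, delta) and are what the acceptance
script and the heavier tests run.

Problem sizes default to a scaled-down version of the full study (3
realizations, 10 trials/stimulus, 1.7 s evoked trials at dt = 1e-4 s); the
integrator is exact between grid points, so the coarser grid only
quantizes spike times.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import clusters as cl
from . import decoding as dec
from . import variability as vb
from .network import build_network, draw_arousal_inputs
from .params import ArousalSpec, NetworkSpec, SimulationConfig
from .simulate import run_experiment


def evoked_campaign(spec: NetworkSpec, delta_grid, arch: str = "clustered",
                    n_realizations: int = 3, n_trials_per_stimulus: int = 10,
                    master_seed: int = 0, dt: float = 1e-4,
                    T_trial: float = 1.7, t_stim: float = 1.0,
                    n_feature_runs: int = 5, decode_step: float = 0.02,
                    collect_cluster_metrics: bool = True) -> pd.DataFrame:
    """Stimulus-evoked simulations with decoding and variability readouts.

    Returns one row per (realization, delta) with peak decoding accuracy
    (feature-sampled: one cell per cluster plus one background cell, or
    p+1 random cells for uniform networks), the population discriminability
    index, Fano factors, and - for clustered networks - evoked cluster
    signal/reliability in the peak decoding window.
    """
    sim_spec = spec if arch == "clustered" else spec.replace(p=0)
    config = SimulationConfig(dt=dt, T_trial=T_trial, t_stim=t_stim)
    rows = []
    for r, delta, conn, stim, trials in run_experiment(
            sim_spec, "input_heterogeneity", delta_grid, config,
            n_realizations, n_trials_per_stimulus, master_seed=master_seed,
            match_p=spec.p):
        rng = np.random.default_rng(master_seed + 104729 * r + 13)
        # analysis cell subset: several candidates per cluster for feature
        # sampling plus a random fill (400 cells) for discriminability
        if arch == "clustered":
            mem_full = conn.membership["E"]
            chosen = [rng.choice(np.flatnonzero(mem_full == c),
                                 size=min(5, (mem_full == c).sum()),
                                 replace=False)
                      for c in range(1, spec.p + 2)]
            e_units = np.unique(np.concatenate(chosen))
        else:
            e_units = np.array([], dtype=np.int64)
        fill = rng.choice(np.setdiff1d(np.arange(sim_spec.NE), e_units),
                          size=max(0, 400 - e_units.size), replace=False)
        e_units = np.sort(np.concatenate([e_units, fill]))
        tensor = dec.sliding_counts(trials, e_units, window=0.1,
                                    step=decode_step, t_range=(-0.1, 0.6))
        if arch == "clustered":
            membership = conn.membership["E"]
        else:
            # membership only conveys p (= max - 1) in the uniform case
            membership = np.full(e_units.size, spec.p + 1)
        res = dec.model_feature_sample(tensor, e_units, membership,
                                       seed=int(rng.integers(2**31 - 1)),
                                       n_runs=n_feature_runs,
                                       uniform=(arch != "clustered"))
        dsc = vb.dsc_pipeline(tensor)
        row = dict(realization=r, delta=delta, arch=arch,
                   peak_accuracy=res.peak_accuracy,
                   peak_window=res.peak_window, D_sc=dsc.D_sc)
        if arch == "clustered":
            # Fano factors per stimulus on (sampled) targeted-cluster cells
            ff_spont, ff_evoked, ff_delta = [], [], []
            for s in range(5):
                sel = [tr for tr in trials if tr.stimulus_id == s]
                cells = np.flatnonzero(np.isin(e_units,
                                               stim.targeted_cells[s]))
                tens_s = dec.sliding_counts(sel, e_units[cells], window=0.1,
                                            step=0.02, t_range=(-0.2, 0.3))
                rates = tens_s.counts.mean(axis=(1, 2)) / 0.1
                fr = vb.fano_timecourse(tens_s,
                                        cells=np.flatnonzero(rates >= 1.0))
                ff_spont.append(np.nanmean(fr.ff_spont))
                if fr.ff_evoked is not None:
                    ff_evoked.append(np.nanmean(fr.ff_evoked))
                    ff_delta.append(np.nanmean(fr.delta_ff))
            row["ff_spont"] = float(np.nanmean(ff_spont))
            row["ff_evoked"] = float(np.nanmean(ff_evoked))
            row["delta_ff"] = float(np.nanmean(ff_delta))
        if arch == "clustered" and collect_cluster_metrics:
            rate_mats = [cl.cluster_rates(tr, conn.membership["E"], spec.p)
                         for tr in trials]
            base = cl.baseline_subtract(rate_mats)
            sids = [tr.stimulus_id for tr in trials]
            row["cluster_signal"] = cl.cluster_signal(
                rate_mats, stim.targeted_clusters, sids, res.peak_window)
            row["cluster_reliability"] = cl.cluster_reliability(
                base, stim.targeted_clusters, sids, res.peak_window)
            summ = cl.state_summary(rate_mats)
            row["nA_mode"] = summ.nA_star
            row["tau_activation"] = summ.tau_activation
            row["P_nA"] = summ.P_nA
            row["r_up"] = summ.r_up
            row["r_down"] = summ.r_down
        rows.append(row)
    return pd.DataFrame(rows)


def spontaneous_campaign(spec: NetworkSpec, delta_grid,
                         n_realizations: int = 3, n_trials: int = 10,
                         master_seed: int = 1000, dt: float = 1e-4,
                         T_trial: float = 2.6,
                         spectra: bool = True) -> pd.DataFrame:
    """Spontaneous-only simulations: cluster states, timescales, spectra.

    Trials are spontaneous (no stimulus); spectra use the final 2.5 s of
    each trial.  One row per (realization, delta) with the pooled P(nA),
    modal active-cluster count, activation timescale, conditional rates
    and the population-averaged low-frequency power of E cells with rate
    >= 1 spike/s.
    """
    config = SimulationConfig(dt=dt, T_trial=T_trial, t_stim=T_trial)
    rows = []
    for r, delta, conn, _, trials in run_experiment(
            spec, "input_heterogeneity", delta_grid, config,
            n_realizations, n_trials, master_seed=master_seed,
            spontaneous=True):
        rate_mats = [cl.cluster_rates(tr, conn.membership["E"], spec.p)
                     for tr in trials]
        for rm in rate_mats:
            rm.t_stim = T_trial        # windows are relative to trial end
        summ = cl.state_summary(rate_mats, window=(-T_trial + 0.1, -0.1))
        cell_rates = np.zeros(spec.NE)
        for tr in trials:
            cell_rates += np.bincount(tr.ids[tr.ids < spec.NE],
                                      minlength=spec.NE) / tr.T
        row = dict(realization=r, delta=delta, nA_mode=summ.nA_star,
                   P_nA=summ.P_nA, tau_activation=summ.tau_activation,
                   r_up=summ.r_up, r_down=summ.r_down,
                   cell_rates_E=cell_rates / len(trials))
        if spectra:
            T_spec = 2.5
            offset = T_trial - T_spec
            p_low = []
            for unit in range(0, spec.NE, 4):   # subsample cells for speed
                trains = []
                for tr in trials:
                    st = tr.times[tr.ids == unit] - offset
                    trains.append(st[st >= 0.0])
                total_T = len(trains) * T_spec
                n_spikes = sum(t.size for t in trains)
                if n_spikes / total_T < 1.0:
                    continue
                p_low.append(vb.multitaper_spectrum(trains, T=T_spec).P_low)
            row["P_low"] = float(np.mean(p_low)) if p_low else np.nan
            row["n_cells_P_low"] = len(p_low)
        rows.append(row)
    return pd.DataFrame(rows)


def transfer_vs_simulation(seed: int = 0, mu_V_grid=(3.0, 3.5, 4.0, 4.5, 5.0),
                           sigma_V_grid=(1.0, 1.5, 2.0, 2.5, 3.0),
                           n_neurons: int = 25, T: float = 4.0,
                           dt: float = 1e-6) -> pd.DataFrame:
    """White-noise single-neuron simulation versus the transfer function.

    Each grid point drives ``n_neurons`` independent LIF neurons with
    Gaussian white noise of mean ``mu = mu_V/tau_m`` and intensity
    ``sigma`` chosen so the integration-variable scale
    ``sqrt(tau_m)*sigma`` equals ``sigma_V`` (mV); the membrane potential
    is sampled as an exact OU process.  The theory is evaluated in the
    same (zero synaptic filtering) limit; the SEM is the across-neuron
    spread of empirical rates over >= 100 s of total simulated time.
    """
    from .meanfield import lif_transfer_rate
    from .simulate import white_noise_rate
    rows = []
    tau_m, tau_ref, V_th, V_r = 0.02, 0.005, 4.0, 0.0
    for i, muV in enumerate(mu_V_grid):
        for j, sigV in enumerate(sigma_V_grid):
            mu = muV / tau_m
            sigma = sigV / np.sqrt(tau_m)
            rates = white_noise_rate(mu, sigma, tau_m=tau_m, V_th=V_th,
                                     V_r=V_r, tau_ref=tau_ref, T=T,
                                     n_neurons=n_neurons, dt=dt,
                                     seed=seed + 101 * i + j)
            theory = float(lif_transfer_rate(mu, sigma, tau_m, tau_ref,
                                             0.0, V_th, V_r))
            rows.append(dict(mu_V=muV, sigma_V=sigV,
                             rate_sim=float(rates.mean()),
                             rate_theory=theory,
                             sem_sim=float(rates.std(ddof=1)
                                           / np.sqrt(n_neurons))))
    return pd.DataFrame(rows)


def decode_session_by_pupil(session, seed: int, window: float = 0.1,
                            step: float = 0.02, t_range=(-0.1, 0.6),
                            pre_stim: float = 0.7) -> tuple:
    """Arousal-conditioned decoding of a recording session.

    Cleans the pupil trace, builds the units x trials x windows tensor
    around tone onsets, partitions trials by pre-stimulus pupil deciles
    (tone-balanced), and returns the per-decile peak accuracy and decile
    centers (fraction of maximum dilation).
    """
    from .empirical import _sliding_counts_1ms, clean_pupil_trace
    cl = clean_pupil_trace(session.pupil_t, session.pupil)
    events = session.tone_times
    labels = session.tone_freqs
    counts = []
    for st in session.spike_times:
        starts, c = _sliding_counts_1ms(st, events, t_range, window=window,
                                        step=step)
        counts.append(c)
    tensor = dec.TrialTensor(counts=np.stack(counts),
                             labels=np.searchsorted(
                                 np.unique(labels), labels),
                             window_starts=starts, window=window)
    grid_t, grid_d = cl["t"], cl["diameter"]
    pupil_trial = np.array([
        np.nanmean(grid_d[np.searchsorted(grid_t, ev - pre_stim):
                          np.searchsorted(grid_t, ev)])
        for ev in events])
    ok = np.isfinite(pupil_trial)
    tensor = tensor.select_trials(np.flatnonzero(ok))
    pupil_trial = pupil_trial[ok]
    part = dec.pupil_partition(pupil_trial, tensor.labels, seed=seed)
    accs = []
    rng = np.random.default_rng(seed)
    for b in range(10):
        sub = tensor.select_trials(part.balanced_trials[b])
        res = dec.decode_timecourse(sub, seed=int(rng.integers(2**31 - 1)))
        accs.append(res.peak_accuracy)
    return np.array(accs), part.centers


def zscore_across_delta(df: pd.DataFrame, column: str) -> pd.DataFrame:
    """Within-realization z-score of a column across the arousal grid."""
    out = df.copy()
    def z(g):
        v = g[column].to_numpy(dtype=float)
        s = v.std(ddof=0)
        g = g.copy()
        g[column + "_z"] = (v - v.mean()) / s if s > 0 else 0.0 * v
        return g
    return out.groupby("realization", group_keys=False)[out.columns].apply(z)
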