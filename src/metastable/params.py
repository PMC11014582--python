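"""Model parameterization.

All quantities use SI-like units: seconds for times, spikes/s for rates,
millivolts for voltages.  Synaptic efficacies (``J``-type fields) are stored
as scaled weights ``j``; the physical voltage jump of a synapse is
``j / sqrt(N)`` mV, the standard convention for networks whose weights are
defined relative to network size.

The default parameter set below places the clustered network in the
metastable regime: at the default intracluster coupling ``jee_plus = 15.75``
the network switches stochastically among cluster states with a modal number
of three active clusters, while the uniform (unclustered) network shows
asynchronous-irregular activity.  The defaults were calibrated with the
package's own mean-field theory (see ``metastable.meanfield`` and
docs/methods.md) and are all overridable, either directly or through a YAML
config file (:func:`load_config`).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml

POPS = ("E", "I")


@dataclass
class NetworkSpec:
    """Full parameterization of a uniform or clustered E/I LIF network.

    ``p = 0`` denotes the uniform architecture.  Connection probabilities
    ``p_conn[a][b]`` and weights ``J[a][b]`` are indexed postsynaptic-first
    (``J["E"]["I"]`` is the weight of an I->E synapse).  Weights are stored
    as positive magnitudes; inhibitory synapses enter the voltage equation
    with negative sign (applied when the connectivity matrix is realized).
    """

    NE: int = 1600
    NI: int = 400
    p: int = 18
    fE: float = 0.05
    fI: float = 0.05
    p_conn: dict = field(default_factory=lambda: {
        "E": {"E": 0.27, "I": 0.5},
        "I": {"E": 0.5, "I": 0.5},
    })
    # baseline scaled weights j (voltage jump = j/sqrt(N) mV)
    J: dict = field(default_factory=lambda: {
        "E": {"E": 1.0, "I": 8.0},
        "I": {"E": 1.2, "I": 5.5},
    })
    # intracluster (potentiated) weights; potentiated inhibitory pathways
    # give each active assembly self-limiting local inhibition
    Jplus: dict = field(default_factory=lambda: {
        "E": {"E": 15.75, "I": 16.0},
        "I": {"E": 2.4, "I": 6.6},
    })
    tau_m: dict = field(default_factory=lambda: {"E": 0.02, "I": 0.02})
    tau_syn: dict = field(default_factory=lambda: {"E": 0.005, "I": 0.005})
    V_thresh: dict = field(default_factory=lambda: {"E": 4.0, "I": 4.0})
    V_reset: dict = field(default_factory=lambda: {"E": 0.0, "I": 0.0})
    tau_ref: dict = field(default_factory=lambda: {"E": 0.005, "I": 0.005})
    C_ext: dict = field(default_factory=lambda: {"E": 320, "I": 320})
    J_ext: dict = field(default_factory=lambda: {"E": 17.0, "I": 11.0})
    nu0: dict = field(default_factory=lambda: {"E": 5.0, "I": 4.4})

    @property
    def N(self) -> int:
        return self.NE + self.NI

    @property
    def weight_scale(self) -> float:
        """Physical weight (mV) per unit of scaled weight j."""
        return 1.0 / np.sqrt(self.N)

    def N_pop(self, a: str) -> int:
        return self.NE if a == "E" else self.NI

    def f_pop(self, a: str) -> float:
        return self.fE if a == "E" else self.fI

    def C(self, a: str, b: str) -> int:
        """Total in-degree of an (a)-cell from population b."""
        return int(round(self.p_conn[a][b] * self.N_pop(b)))

    def cluster_size(self, a: str) -> int:
        return int(np.floor(self.f_pop(a) * self.N_pop(a)))

    def validate(self) -> None:
        if self.p < 0:
            raise ValueError("p must be >= 0")
        for a in POPS:
            if self.p * self.f_pop(a) > 1.0 + 1e-12:
                raise ValueError(f"p*f{a} = {self.p * self.f_pop(a):.3f} > 1")
            for b in POPS:
                if self.C(a, b) > self.N_pop(b):
                    raise ValueError(f"in-degree C[{a}][{b}] exceeds N{b}")

    def replace(self, **kw) -> "NetworkSpec":
        return dataclasses.replace(self, **kw)


@dataclass
class ArousalSpec:
    """Arousal as a modification of the background-input rates.

    ``mode``
        ``"none"``, ``"input_mean"`` (uniform increase of the mean rate) or
        ``"input_heterogeneity"`` (quenched Gaussian across-cell spread).
    ``delta_M`` / ``delta_H``
        per-population modulation strengths (dimensionless, >= 0).
    ``z`` / ``nu_ext``
        populated by :func:`metastable.network.draw_arousal_inputs`: the
        per-cell standard-normal draws and resulting external rates.
    """

    mode: str = "none"
    delta_M: dict = field(default_factory=lambda: {"E": 0.0, "I": 0.0})
    delta_H: dict = field(default_factory=lambda: {"E": 0.0, "I": 0.0})
    z: Optional[dict] = None
    nu_ext: Optional[dict] = None

    def validate(self) -> None:
        if self.mode not in ("none", "input_mean", "input_heterogeneity"):
            raise ValueError(f"unknown arousal mode {self.mode!r}")
        for d in (self.delta_M, self.delta_H):
            for a in POPS:
                if d[a] < 0:
                    raise ValueError("arousal modulations must be >= 0")


@dataclass
class StimulusSet:
    """Targets and timecourse of the sensory stimuli.

    Each stimulus targets 50% of the clusters (chosen at random) and, within
    each targeted cluster, 50% of the E cells; in uniform networks the same
    total number of E cells is targeted.  The timecourse is a difference of
    exponentials normalized to unit peak.
    """

    n_stimuli: int = 5
    A_stim: dict = field(default_factory=lambda: {"E": 0.075, "I": 0.0})
    tau_r: float = 0.075
    tau_d: float = 0.2
    t_stim: float = 1.0
    targeted_clusters: Optional[list] = None
    targeted_cells: Optional[list] = None


@dataclass
class SimulationConfig:
    dt: float = 0.5e-4
    T_trial: float = 3.5
    t_stim: float = 1.0
    n_trials_per_stimulus: int = 30
    record_Vm: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if not (0 <= self.t_stim <= self.T_trial):
            raise ValueError("t_stim must lie within the trial")


# Boundary-shift constant of the LIF transfer function for exponential
# synapses: a*sqrt(tau_syn/tau_m) shifts the integration bounds.  This is
# the Fourcaud-Brunel colored-noise correction; with the integration
# variable scaled by sqrt(2 Var V) the constant is |zeta(1/2)|/sqrt(2).
TRANSFER_BOUNDARY_SHIFT = 1.0327357254

# Threshold (spikes/s) above which a cluster counts as "active".
CLUSTER_ACTIVE_THRESHOLD = 15.0


def load_config(path) -> dict:
    """Read a YAML config into {network, arousal, stimulus, simulation}.

    Missing sections/keys keep their defaults; nested dicts are merged
    shallowly per field.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out = {}
    for key, cls in (("network", NetworkSpec), ("arousal", ArousalSpec),
                     ("stimulus", StimulusSet), ("simulation", SimulationConfig)):
        obj = cls()
        for k, v in (raw.get(key) or {}).items():
            if not hasattr(obj, k):
                raise KeyError(f"unknown {key} field {k!r}")
            cur = getattr(obj, k)
            if isinstance(cur, dict) and isinstance(v, dict):
                merged = dict(cur)
                for kk, vv in v.items():
                    if isinstance(merged.get(kk), dict) and isinstance(vv, dict):
                        merged[kk] = {**merged[kk], **vv}
                    else:
                        merged[kk] = vv
                setattr(obj, k, merged)
            else:
                setattr(obj, k, v)
        out[key] = obj
    return out


def rng_streams(master_seed: int, *names: str) -> dict:
    """Independent named RNG streams derived from one master seed.

    Separate streams for connectivity, quenched arousal draws, stimulus
    targets, initial conditions and Poisson drive keep every source of
    randomness independently reproducible.
    """
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(len(names))
    return {name: np.random.default_rng(c) for name, c in zip(names, children)}
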