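"""Synthetic greenhouse-trial datasets with a known causal structure.

The generator emulates the shape and statistical structure of a 73-sample
cucumber seedling trial: 13 environmental treatments (8 climate parameters,
held stable per trial), four physiological sampling days (0/3/6/9, 10 leaf
parameters) and three growth stages (per-day height and leaf-area
increments for days 0-3/4-6/7-9, plus fresh and dry weight determined once
at day 9).

The causal model is linear-Gaussian on latent scales:

* each trial's environmental set-point vector is observed with a small
  within-trial jitter (growth chambers hold conditions only approximately);
* each seedling carries an individual physiological deviation eta (10-dim),
  constant across sampling days — seedlings differ beyond what their
  environment explains;
* physiological latents at stage t are ``s_t * (A z_env) + eta + noise``
  where z_env is the standardised environment, A is the env->physio
  coefficient map and the stage scale s_t grows over the treatment
  (environmental influence needs time to express);
* growth latents at stage k are ``w_k * (D z_env) + B eta + noise``: growth
  responds both to environment and to the seedling's physiological
  individuality.  The B-channel is what makes physiological measurements
  informative about growth beyond the environment alone;
* observed physiology maps latents onto realistic scales; the chlorophyll
  fluorescence parameters PhiPS2, Fv'/Fm' and qP are derived from simulated
  raw fluorescence levels (F'm, F_s, F'0) through their defining identities
  and are therefore bounded in [0, 1] by construction, as is PhiCO2 by
  clipping; ETR follows PhiPS2 x PAR x 0.84 x 0.5.

Declared null parameters (all-zero coefficient columns) provide ground
truth for screening-recovery experiments.  Everything is deterministic
given the effect-model seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import reference
from .blocks import ENV_PARAMS, PHYSIO_PARAMS, SCHEMA_COLUMNS, SeedlingDataset

__all__ = [
    "TrialDesign",
    "EffectModel",
    "FluorescenceRaw",
    "derive_fluorescence_params",
    "default_effect_model",
    "generate_dataset",
]

#: Realistic sampling ranges for randomized designs (same units as e1..e8).
ENV_RANGES = {
    "e1": (18.0, 35.0), "e2": (18.0, 25.0), "e3": (350.0, 900.0),
    "e4": (14.0, 30.0), "e5": (30.0, 75.0), "e6": (30.0, 700.0),
    "e7": (0.01, 2.5), "e8": (0.01, 1.3),
}

#: Replicates per trial reaching the reference total of 73 samples
#: (8 trials x 6 + 5 trials x 5).
DEFAULT_REPLICATES = (6, 6, 6, 6, 6, 6, 6, 6, 5, 5, 5, 5, 5)


@dataclass
class TrialDesign:
    """Environmental set-points per trial and replicate counts."""

    environments: np.ndarray            # (n_trials, 8)
    replicates: tuple[int, ...]         # per-trial seedling counts

    def __post_init__(self) -> None:
        self.environments = np.asarray(self.environments, dtype=float)
        self.replicates = tuple(int(r) for r in self.replicates)
        if self.environments.ndim != 2 or self.environments.shape[1] != 8:
            raise ValueError("environments must be (n_trials, 8)")
        if len(self.replicates) != len(self.environments):
            raise ValueError("one replicate count per trial required")
        if self.environments.shape[0] < 1 or any(r < 1 for r in self.replicates):
            raise ValueError("need at least one trial and one replicate each")
        if np.any(self.environments <= 0):
            raise ValueError("environmental set-points must be positive")

    @property
    def n_samples(self) -> int:
        return sum(self.replicates)

    @classmethod
    def default(cls) -> "TrialDesign":
        """The packaged 13-treatment reference design, 73 samples."""
        return cls(reference.TRIAL_ENVIRONMENTS.copy(), DEFAULT_REPLICATES)

    @classmethod
    def randomized(
        cls, n_trials: int, replicates_per_trial: int, seed: int = 0
    ) -> "TrialDesign":
        """Independently sampled treatments spanning ``ENV_RANGES``.

        Unlike the packaged design, whose parameters are mutually
        correlated across its 13 rows, a randomized design decorrelates the
        environmental columns — required when screening must attribute
        effects to individual parameters.
        """
        rng = np.random.default_rng(seed)
        env = np.column_stack([
            rng.uniform(*ENV_RANGES[e], size=n_trials) for e in ENV_PARAMS
        ])
        return cls(env, (replicates_per_trial,) * n_trials)


@dataclass
class FluorescenceRaw:
    """Light-adapted raw fluorescence levels (arbitrary units)."""

    fm_prime: np.ndarray    # maximal fluorescence F'm
    fs: np.ndarray          # steady-state fluorescence F_s
    f0_prime: np.ndarray    # minimal fluorescence F'0

    def __post_init__(self) -> None:
        self.fm_prime = np.atleast_1d(np.asarray(self.fm_prime, dtype=float))
        self.fs = np.atleast_1d(np.asarray(self.fs, dtype=float))
        self.f0_prime = np.atleast_1d(np.asarray(self.f0_prime, dtype=float))
        if np.any(self.fs < 0) or np.any(self.f0_prime < 0):
            raise ValueError("fluorescence levels must be non-negative")
        if np.any(self.fm_prime <= self.fs):
            raise ValueError("F'm must exceed F_s")
        if np.any(self.fm_prime <= self.f0_prime):
            raise ValueError("F'm must exceed F'0")


def derive_fluorescence_params(
    raw: FluorescenceRaw,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PhiPS2, Fv'/Fm' and qP from raw light-adapted fluorescence.

    PhiPS2 = (F'm - F_s)/F'm, Fv'/Fm' = (F'm - F'0)/F'm and
    qP = (F'm - F_s)/(F'm - F'0); all lie in [0, 1] whenever F_s >= F'0.
    """
    phi_ps2 = (raw.fm_prime - raw.fs) / raw.fm_prime
    fvfm = (raw.fm_prime - raw.f0_prime) / raw.fm_prime
    qp = (raw.fm_prime - raw.fs) / (raw.fm_prime - raw.f0_prime)
    return phi_ps2, fvfm, qp


@dataclass
class EffectModel:
    """Linear-Gaussian effect structure with declared null parameters."""

    env_to_physio: np.ndarray           # (10, 8) latent coefficients
    env_to_growth: np.ndarray           # (4, 8)
    physio_to_growth: np.ndarray        # (4, 10), acts on eta
    stage_scale: tuple[float, ...] = (0.15, 0.55, 0.85, 1.0)   # days 0/3/6/9
    growth_stage_scale: tuple[float, ...] = (0.5, 0.8, 1.0)    # G1/G2/G3
    individual_sd: float = 0.6
    noise_sd: float = 0.3
    env_jitter: float = 0.02            # relative within-trial deviation
    null_parameters: frozenset[str] = frozenset()
    seed: int = 0

    def __post_init__(self) -> None:
        self.env_to_physio = np.asarray(self.env_to_physio, dtype=float)
        self.env_to_growth = np.asarray(self.env_to_growth, dtype=float)
        self.physio_to_growth = np.asarray(self.physio_to_growth, dtype=float)
        if self.env_to_physio.shape != (10, 8):
            raise ValueError("env_to_physio must be (10, 8)")
        if self.env_to_growth.shape != (4, 8):
            raise ValueError("env_to_growth must be (4, 8)")
        if self.physio_to_growth.shape != (4, 10):
            raise ValueError("physio_to_growth must be (4, 10)")
        if self.noise_sd < 0 or self.individual_sd < 0:
            raise ValueError("noise scales must be non-negative")
        self.null_parameters = frozenset(self.null_parameters)
        for pid in self.null_parameters:
            if pid in ENV_PARAMS:
                j = ENV_PARAMS.index(pid)
                if np.any(self.env_to_physio[:, j]) or np.any(self.env_to_growth[:, j]):
                    raise ValueError(f"null parameter {pid} has nonzero coefficients")
            elif pid in PHYSIO_PARAMS:
                j = PHYSIO_PARAMS.index(pid)
                if np.any(self.physio_to_growth[:, j]):
                    raise ValueError(f"null parameter {pid} has nonzero coefficients")
            else:
                raise ValueError(f"unknown null parameter {pid}")

    def to_dict(self) -> dict:
        return {
            "env_to_physio": self.env_to_physio.tolist(),
            "env_to_growth": self.env_to_growth.tolist(),
            "physio_to_growth": self.physio_to_growth.tolist(),
            "stage_scale": list(self.stage_scale),
            "growth_stage_scale": list(self.growth_stage_scale),
            "individual_sd": self.individual_sd,
            "noise_sd": self.noise_sd,
            "env_jitter": self.env_jitter,
            "null_parameters": sorted(self.null_parameters),
            "seed": self.seed,
        }


#: Fixed seed for the *structural* coefficient draw; independent of the
#: data seed so two datasets from the same effect model share one causal map.
_STRUCTURE_SEED = 402017


def default_effect_model(
    null_parameters: tuple[str, ...] | frozenset[str] = (),
    seed: int = 0,
    noise_sd: float = 0.3,
    individual_sd: float = 0.6,
) -> EffectModel:
    """The default study-scale effect model.

    Coefficients are moderate-to-strong (magnitudes 0.35-0.9 for
    environmental effects, 0.25-0.6 for physiological ones) with random
    signs, drawn once from a fixed structural seed; columns of any declared
    null parameter are zeroed.
    """
    rng = np.random.default_rng(_STRUCTURE_SEED)

    def draw(shape, lo, hi):
        mag = rng.uniform(lo, hi, size=shape)
        sign = rng.choice([-1.0, 1.0], size=shape)
        return mag * sign

    env_to_physio = draw((10, 8), 0.35, 0.9)
    env_to_growth = draw((4, 8), 0.35, 0.9)
    physio_to_growth = draw((4, 10), 0.25, 0.6)
    for pid in null_parameters:
        if pid in ENV_PARAMS:
            j = ENV_PARAMS.index(pid)
            env_to_physio[:, j] = 0.0
            env_to_growth[:, j] = 0.0
        elif pid in PHYSIO_PARAMS:
            physio_to_growth[:, PHYSIO_PARAMS.index(pid)] = 0.0
    return EffectModel(
        env_to_physio=env_to_physio,
        env_to_growth=env_to_growth,
        physio_to_growth=physio_to_growth,
        individual_sd=individual_sd,
        noise_sd=noise_sd,
        null_parameters=frozenset(null_parameters),
        seed=seed,
    )


def _observed_physio(latents: np.ndarray, par: np.ndarray) -> np.ndarray:
    """Map 10 latent responses onto observed physiological scales."""
    n = len(latents)
    obs = np.empty((n, 10))
    obs[:, 0] = np.clip(6.0 + 2.0 * latents[:, 0], 0.05, None)        # Pn
    obs[:, 1] = np.clip(0.30 + 0.08 * latents[:, 1], 0.005, None)     # Cond
    obs[:, 2] = np.clip(300.0 + 35.0 * latents[:, 2], 50.0, None)     # Ci

    # Fluorescence block: raw levels from latents, derived via identities.
    fvfm_target = 0.65 + 0.10 * np.tanh(latents[:, 3])
    qp_target = 0.70 + 0.20 * np.tanh(0.5 * (latents[:, 4] + latents[:, 6]))
    fm = np.full(n, 1.2)
    f0 = fm * (1.0 - fvfm_target)
    fs = fm - qp_target * (fm - f0)
    phi_ps2, fvfm, qp = derive_fluorescence_params(FluorescenceRaw(fm, fs, f0))
    obs[:, 3] = np.clip(fvfm, 0.0, 1.0)                               # Fv'/Fm'
    obs[:, 4] = np.clip(phi_ps2, 0.0, 1.0)                            # PhiPS2
    obs[:, 5] = np.clip(0.06 + 0.02 * latents[:, 5], 0.0, 1.0)        # PhiCO2
    obs[:, 6] = np.clip(qp, 0.0, 1.0)                                 # qP
    obs[:, 7] = obs[:, 4] * par * 0.84 * 0.5                          # ETR
    obs[:, 8] = np.clip(3.0 + 0.8 * latents[:, 8], 0.05, None)        # Tr
    obs[:, 9] = np.clip(1.6 + 0.4 * latents[:, 9], 0.05, None)        # VpdL
    return obs


def generate_dataset(
    design: TrialDesign | None = None,
    effects: EffectModel | None = None,
) -> SeedlingDataset:
    """Generate one full trial dataset (deterministic given effects.seed)."""
    design = design or TrialDesign.default()
    effects = effects or default_effect_model()
    n = design.n_samples
    if n < 2:
        raise ValueError("design yields fewer than 2 samples")
    rng = np.random.default_rng(effects.seed)

    trial_id = np.concatenate([
        np.full(r, t + 1, dtype=int) for t, r in enumerate(design.replicates)
    ])
    env_setpoints = np.repeat(design.environments, design.replicates, axis=0)
    env_obs = env_setpoints * (
        1.0 + effects.env_jitter * rng.standard_normal((n, 8))
    )
    env_obs = np.clip(env_obs, 1e-6, None)

    sd = env_obs.std(axis=0, ddof=1)
    sd[sd == 0.0] = 1.0
    env_z = (env_obs - env_obs.mean(axis=0)) / sd

    eta = effects.individual_sd * rng.standard_normal((n, 10))
    par = env_obs[:, ENV_PARAMS.index("e6")]

    physio = {}
    for k, day in enumerate((0, 3, 6, 9)):
        latents = (
            effects.stage_scale[k] * (env_z @ effects.env_to_physio.T)
            + eta
            + effects.noise_sd * rng.standard_normal((n, 10))
        )
        physio[day] = _observed_physio(latents, par)

    growth = {}
    for k in range(3):
        glat = (
            effects.growth_stage_scale[k] * (env_z @ effects.env_to_growth.T)
            + eta @ effects.physio_to_growth.T
            + effects.noise_sd * rng.standard_normal((n, 4))
        )
        growth[k] = glat
    g3 = np.clip(2.0 + 0.7 * growth[2][:, 2], 0.01, None)     # fresh wt, day 9
    g4 = np.clip(0.22 + 0.07 * growth[2][:, 3], 0.001, None)  # dry wt, day 9

    data: dict[str, np.ndarray] = {
        "sample_id": np.arange(1, n + 1),
        "trial_id": trial_id,
    }
    for j, e in enumerate(ENV_PARAMS):
        data[e] = env_obs[:, j]
    for day in (0, 3, 6, 9):
        for j, p in enumerate(PHYSIO_PARAMS):
            data[f"{p}_d{day}"] = physio[day][:, j]
    for k, day in enumerate((3, 6, 9)):
        data[f"g1_d{day}"] = np.clip(1.2 + 0.45 * growth[k][:, 0], 0.01, None)
        data[f"g2_d{day}"] = np.clip(28.0 + 9.0 * growth[k][:, 1], 0.1, None)
    data["g3"] = g3
    data["g4"] = g4

    frame = pd.DataFrame(data, columns=list(SCHEMA_COLUMNS))
    return SeedlingDataset(
        frame=frame,
        ground_truth={
            "effect_model": effects.to_dict(),
            "null_parameters": sorted(effects.null_parameters),
            "seed": effects.seed,
            "design": {
                "environments": design.environments.tolist(),
                "replicates": list(design.replicates),
            },
        },
    )
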