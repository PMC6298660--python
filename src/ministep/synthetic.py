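"""Synthetic residence-hall study generator.

Produces panels that emulate the observed study conditions: ~276 actors
followed over four waves of one academic year, a sparse directed
friendship network with floor clustering and reciprocation (mean
within-hall out-degree ~3.3 at wave 1), an ordinal BMI distribution
matching the observed wave-1 marginals, covariate marginals (71% female,
~52% non-White, 93% first-year), forward co-evolution under a true
parameter vector, and wave-specific missingness hitting the observed
participation counts (239/241/218/192) while every retained actor stays
observed at two or more waves.

Wave 1 is drawn from a deliberately simple inhomogeneous Bernoulli model
with a reciprocation pass — the co-evolution process is conditioned on
the first wave, so only its moments matter for testing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .data_model import (
    BehaviorScale,
    CovariateTable,
    N_CATEGORIES,
    Wave,
    WavePanel,
    write_panel,
)
from .effects import EffectSpec, standard_spec
from .engine import ParameterVector, SaomModel

__all__ = ["SyntheticStudyConfig", "gen_covariates", "gen_initial_state",
           "apply_missingness", "gen_study"]

#: Observed wave-1 BMI category proportions (11 categories).
WAVE1_BMI_PROPORTIONS = np.array(
    [5.0, 6.3, 13.0, 14.2, 9.2, 10.0, 6.7, 7.5, 11.7, 8.8, 7.5]) / 100.0

#: Observed race/ethnicity proportions (White, Black, Hispanic, Other).
RACE_PROPORTIONS = {"White": 0.490, "Black": 0.105, "Hispanic": 0.272, "Other": 0.134}


def _default_theta() -> ParameterVector:
    """True parameters: the fitted no-demographics model (rates and
    coefficients) for the default effect specification."""
    return ParameterVector(
        network_rates=[4.250, 2.221, 3.310],
        behavior_rates=[1.059, 0.738, 0.892],
        network_coefs=[-2.341, 4.248, 1.002, -0.666, -0.149, -0.221,
                       0.021, -0.021, 0.003, 0.002, 0.005],
        behavior_coefs=[0.310, 0.041, 5.205],
    )


@dataclass
class SyntheticStudyConfig:
    """Study-condition defaults for the generator."""

    n_actors: int = 276
    n_waves: int = 4
    female_fraction: float = 0.710
    race_fractions: dict = field(default_factory=lambda: dict(RACE_PROPORTIONS))
    first_year_fraction: float = 0.931
    n_floors: int = 10
    mean_outdegree: float = 3.3
    same_floor_multiplier: float = 1.5
    reciprocation_boost: float = 0.4
    bmi_proportions: np.ndarray = field(
        default_factory=lambda: WAVE1_BMI_PROPORTIONS.copy())
    participation: tuple = (239, 241, 218, 192)
    theta: ParameterVector = field(default_factory=_default_theta)
    seed: int = 0

    def __post_init__(self):
        for frac in (self.female_fraction, self.first_year_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        total = sum(self.race_fractions.values())
        if abs(total - 1.0) > 0.02:
            raise ValueError("race fractions must sum to ~1")
        self.race_fractions = {k: v / total for k, v in self.race_fractions.items()}
        self.bmi_proportions = np.asarray(self.bmi_proportions, dtype=float)
        self.bmi_proportions = self.bmi_proportions / self.bmi_proportions.sum()
        if len(self.participation) != self.n_waves:
            raise ValueError("one participation count per wave is required")
        if any(c > self.n_actors for c in self.participation):
            raise ValueError("participation counts cannot exceed n_actors")
        if self.mean_outdegree > self.n_actors - 1:
            raise ValueError("mean out-degree cannot exceed n - 1")

    def spec(self) -> EffectSpec:
        return standard_spec(demographics=False)


def _actor_ids(n: int) -> list[str]:
    return [f"s{k + 1:03d}" for k in range(n)]


def gen_covariates(config: SyntheticStudyConfig, seed: int | None = None) -> CovariateTable:
    """Independent covariate draws matching the configured marginals;
    floors are assigned uniformly."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_actors
    races = list(config.race_fractions)
    frame = pd.DataFrame(
        {
            "male": (rng.random(n) >= config.female_fraction).astype(int),
            "race": rng.choice(races, size=n, p=[config.race_fractions[r] for r in races]),
            "first_year": (rng.random(n) < config.first_year_fraction).astype(int),
            "floor": [f"floor_{f + 1}" for f in rng.integers(config.n_floors, size=n)],
        },
        index=_actor_ids(n),
    )
    return CovariateTable(frame)


def _tie_probabilities(base: float, same_floor: np.ndarray, multiplier: float) -> np.ndarray:
    q = np.where(same_floor, base * multiplier, base)
    return np.clip(q, 0.0, 1.0)


def _expected_mean_outdegree(base, same_floor, multiplier, r) -> float:
    q = _tie_probabilities(base, same_floor, multiplier)
    p = q + (1.0 - q) * q.T * r
    np.fill_diagonal(p, 0.0)
    return float(p.sum() / p.shape[0])


def gen_initial_state(covariates: CovariateTable, config: SyntheticStudyConfig,
                      seed: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Draw the wave-1 network and behavior codes.

    Directed ties are Bernoulli with a base rate calibrated (by root
    finding on the closed-form expectation) so the realized mean
    out-degree matches the target, a same-floor multiplier, and a
    reciprocation pass that adds the mutual tie with the configured
    probability. Behavior codes are drawn from the observed wave-1
    category frequencies.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_actors
    floors = covariates.values("floor")
    same_floor = floors[:, None] == floors[None, :]
    np.fill_diagonal(same_floor, False)

    def gap(base):
        return _expected_mean_outdegree(base, same_floor, config.same_floor_multiplier,
                                        config.reciprocation_boost) - config.mean_outdegree

    hi = min(1.0, 1.0 / config.same_floor_multiplier)
    base = brentq(gap, 1e-9, hi)
    q = _tie_probabilities(base, same_floor, config.same_floor_multiplier)
    np.fill_diagonal(q, 0.0)
    x = (rng.random((n, n)) < q).astype(np.int8)
    np.fill_diagonal(x, 0)
    # reciprocation pass: close asymmetric dyads with probability r
    asym = (x.T == 1) & (x == 0)
    x[asym & (rng.random((n, n)) < config.reciprocation_boost)] = 1
    np.fill_diagonal(x, 0)

    z = rng.choice(np.arange(1, N_CATEGORIES + 1), size=n,
                   p=config.bmi_proportions).astype(float)
    return x, z


def apply_missingness(panel: WavePanel, participation, seed: int = 0) -> WavePanel:
    """Mark actors non-participating to hit per-wave counts exactly.

    Missingness is completely at random subject to every actor remaining
    observed at two or more waves; a non-participant loses behavior and
    outgoing ties at the wave but keeps incoming nominations.
    """
    n, w = panel.n_actors, panel.n_waves
    if len(participation) != w:
        raise ValueError("one participation count per wave is required")
    drops = [n - int(c) for c in participation]
    if any(d < 0 for d in drops):
        raise ValueError("participation counts cannot exceed n_actors")
    if sum(drops) > n * (w - 2):
        raise ValueError("participation counts incompatible with the >=2-waves constraint")
    rng = np.random.default_rng(seed)
    observed = np.ones((n, w), dtype=bool)
    for m in sorted(range(w), key=lambda m: -drops[m]):
        eligible = np.nonzero(observed.sum(axis=1) >= 3)[0]
        if eligible.size < drops[m]:
            raise ValueError("participation counts incompatible with the >=2-waves constraint")
        out = rng.choice(eligible, size=drops[m], replace=False)
        observed[out, m] = False

    waves = []
    for m in range(w):
        src = panel.waves[m]
        adj = src.adjacency.copy()
        adj[~observed[:, m], :] = 0
        beh = src.behavior.copy()
        beh[~observed[:, m]] = np.nan
        waves.append(Wave(adj, beh, observed[:, m].copy(),
                          None if src.bmi_raw is None else src.bmi_raw.copy()))
    return WavePanel(list(panel.actor_ids), waves, list(panel.wave_labels))


def gen_study(config: SyntheticStudyConfig | None = None, out_dir=None):
    """Generate a full synthetic study: covariates, wave-1 state, forward
    co-evolution under the true parameters, and missingness.

    Returns ``(panel, covariates, manifest)``; when ``out_dir`` is given,
    also writes Links_all/BMI/covariates CSVs plus a manifest JSON there.
    """
    config = config or SyntheticStudyConfig()
    rng = np.random.default_rng(config.seed)
    cov_seed, init_seed, sim_seed, miss_seed = rng.integers(2 ** 31, size=4)

    covariates = gen_covariates(config, seed=int(cov_seed))
    x0, z0 = gen_initial_state(covariates, config, seed=int(init_seed))

    # full-scale range; centering from the generated wave-1 distribution
    scale = BehaviorScale(N_CATEGORIES, float(z0.mean()), float(N_CATEGORIES - 1))
    model = SaomModel(config.spec(), scale, covariates={}, sim_c=0.0)
    sim_rng = np.random.default_rng(int(sim_seed))
    panel = model.simulate_panel(x0, z0, config.theta, config.n_waves - 1, sim_rng)
    panel.actor_ids = list(covariates.actor_ids)
    panel = apply_missingness(panel, config.participation, seed=int(miss_seed))

    manifest = {
        "config": {
            **{k: v for k, v in asdict(config).items() if k not in ("theta", "bmi_proportions")},
            "bmi_proportions": config.bmi_proportions.tolist(),
            "theta": config.theta.to_dict(),
        },
        "seeds": {"covariates": int(cov_seed), "initial_state": int(init_seed),
                  "simulation": int(sim_seed), "missingness": int(miss_seed)},
        "scale": {"centering_constant": scale.centering_constant, "range": scale.range},
    }
    if out_dir is not None:
        import os
        os.makedirs(out_dir, exist_ok=True)
        write_panel(panel, f"{out_dir}/Links_all.csv", f"{out_dir}/BMI.csv",
                    covariates, f"{out_dir}/covariates.csv")
        with open(f"{out_dir}/manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    return panel, covariates, manifest
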