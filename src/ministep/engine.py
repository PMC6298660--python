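"""Continuous-time ministep simulator for network-behavior co-evolution.

Between two observation waves, actors receive change opportunities from
exponential clocks: with per-actor rates lambda_net and lambda_beh, the
pooled process has total intensity n_active * (lambda_net + lambda_beh)
over a period of unit length. At each event one active actor is drawn
uniformly, the function (network vs. behavior) proportional to the rates,
and the actor makes a multinomial-logit choice among single-change
alternatives: toggling one outgoing tie (or keeping the current state),
or moving the ordinal behavior one category up or down (or staying),
with infeasible moves outside 1..11 excluded.

Choice probabilities are computed from change statistics, so only the
delta of each effect under each alternative is ever evaluated; these
deltas are validated against full recomputation in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import BehaviorScale, N_CATEGORIES, Wave, WavePanel
from .effects import (
    EffectSpec,
    behavior_change_statistic,
    network_change_statistics,
)

__all__ = ["ParameterVector", "MinistepTrace", "SaomModel", "SimulationResult"]


@dataclass
class ParameterVector:
    """Rates per period plus one coefficient per effect (the model's theta)."""

    network_rates: np.ndarray
    behavior_rates: np.ndarray
    network_coefs: np.ndarray
    behavior_coefs: np.ndarray

    def __post_init__(self):
        self.network_rates = np.asarray(self.network_rates, dtype=float)
        self.behavior_rates = np.asarray(self.behavior_rates, dtype=float)
        self.network_coefs = np.asarray(self.network_coefs, dtype=float)
        self.behavior_coefs = np.asarray(self.behavior_coefs, dtype=float)
        if np.any(self.network_rates < 0) or np.any(self.behavior_rates < 0):
            raise ValueError("rates must be nonnegative")
        if len(self.network_rates) != len(self.behavior_rates):
            raise ValueError("network and behavior rate vectors must cover the same periods")

    @property
    def n_periods(self) -> int:
        return len(self.network_rates)

    def as_array(self) -> np.ndarray:
        return np.concatenate([
            self.network_rates, self.behavior_rates,
            self.network_coefs, self.behavior_coefs,
        ])

    @classmethod
    def from_array(cls, arr, n_periods: int, n_net: int, n_beh: int) -> "ParameterVector":
        arr = np.asarray(arr, dtype=float)
        m = n_periods
        return cls(arr[:m], arr[m:2 * m], arr[2 * m:2 * m + n_net], arr[2 * m + n_net:2 * m + n_net + n_beh])

    def labels(self, spec: EffectSpec) -> list[str]:
        out = [f"rate_network_period_{m + 1}" for m in range(self.n_periods)]
        out += [f"rate_behavior_period_{m + 1}" for m in range(self.n_periods)]
        out += [f"network_{lab}" for lab in spec.labels("network")]
        out += [f"behavior_{lab}" for lab in spec.labels("behavior")]
        return out

    def to_dict(self) -> dict:
        return {
            "network_rates": self.network_rates.tolist(),
            "behavior_rates": self.behavior_rates.tolist(),
            "network_coefs": self.network_coefs.tolist(),
            "behavior_coefs": self.behavior_coefs.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterVector":
        return cls(d["network_rates"], d["behavior_rates"],
                   d["network_coefs"], d["behavior_coefs"])


@dataclass
class MinistepTrace:
    """Record of the ministeps taken within one simulated period."""

    steps: list[tuple] = field(default_factory=list)  # (time, actor, function, detail)
    n_network: int = 0
    n_behavior: int = 0

    def record(self, time: float, actor: int, function: str, detail) -> None:
        self.steps.append((time, actor, function, detail))
        if function == "network":
            self.n_network += 1
        else:
            self.n_behavior += 1


@dataclass
class SimulationResult:
    adjacency: np.ndarray
    behavior: np.ndarray  # category codes (float)
    trace: MinistepTrace
    score: np.ndarray | None = None


class SaomModel:
    """An effect specification bound to covariates and a behavior scale.

    Parameters
    ----------
    spec : EffectSpec
    scale : BehaviorScale
        Centering constant and range for the ordinal behavior variable.
    covariates : dict, optional
        Constant covariate arrays keyed by name. Numeric covariates used
        in alter/ego effects should be centered; categorical covariates
        (for ``same`` effects) are raw labels.
    sim_c : float
        Centering constant of the dyadic similarity score.
    behavior_name : str
        Covariate name under which the (centered) behavior variable is
        available to network effects.
    """

    def __init__(self, spec: EffectSpec, scale: BehaviorScale,
                 covariates: dict | None = None, sim_c: float = 0.0,
                 behavior_name: str = "bmi"):
        self.spec = spec
        self.scale = scale
        self.covariates = dict(covariates or {})
        self.sim_c = float(sim_c)
        self.behavior_name = behavior_name
        for name in spec.covariate_names():
            if name != behavior_name and name not in self.covariates:
                raise KeyError(f"effect spec references unknown covariate {name!r}")

    # -- resolved covariate for one network effect ---------------------------
    def _covariate(self, name, zc):
        if name is None:
            return None
        if name == self.behavior_name:
            return zc
        return self.covariates[name]

    # -- choice distributions -------------------------------------------------
    def network_change_matrix(self, x: np.ndarray, zc: np.ndarray, i: int) -> np.ndarray:
        """Per-effect change statistics for all toggles of actor i: (p, n)."""
        effs = self.spec.network_effects
        out = np.empty((len(effs), x.shape[0]))
        for k, eff in enumerate(effs):
            out[k] = network_change_statistics(eff.name, x, i, self._covariate(eff.covariate, zc))
        return out

    def behavior_change_matrix(self, x: np.ndarray, zc: np.ndarray, i: int) -> np.ndarray:
        """Per-effect change statistics for steps (-1, 0, +1): (p, 3)."""
        effs = self.spec.behavior_effects
        out = np.zeros((len(effs), 3))
        for k, eff in enumerate(effs):
            for c, step in enumerate((-1, 0, 1)):
                out[k, c] = behavior_change_statistic(
                    eff.name, zc, x, i, step, self.scale.range, self.sim_c)
        return out

    def network_choice_distribution(self, i: int, x: np.ndarray, zc: np.ndarray,
                                    coefs) -> tuple[np.ndarray, np.ndarray]:
        """Multinomial-logit probabilities over the n single-toggle
        alternatives (index i = keep the current state).

        Returns ``(probs, dstats)`` where ``dstats`` is the (p, n) change
        statistic matrix used to form the objective differences.
        """
        dstats = self.network_change_matrix(x, zc, i)
        df = np.asarray(coefs, dtype=float) @ dstats
        if not np.all(np.isfinite(df)):
            raise FloatingPointError("non-finite network objective difference")
        w = np.exp(df - df.max())
        probs = w / w.sum()
        return probs, dstats

    def behavior_choice_distribution(self, i: int, x: np.ndarray, z: np.ndarray,
                                     coefs) -> tuple[np.ndarray, np.ndarray]:
        """Probabilities over behavior steps (-1, 0, +1); infeasible steps
        (leaving 1..11) receive probability 0. ``z`` holds category codes.
        """
        if np.isnan(z[i]):
            raise ValueError(f"actor {i} has missing behavior")
        zc = self.scale.center(z)
        dstats = self.behavior_change_matrix(x, zc, i)
        df = np.asarray(coefs, dtype=float) @ dstats
        feasible = np.array([z[i] - 1 >= 1, True, z[i] + 1 <= N_CATEGORIES])
        df = np.where(feasible, df, -np.inf)
        w = np.exp(df - df[feasible].max())
        probs = w / w.sum()
        return probs, dstats

    # -- simulation -----------------------------------------------------------
    def simulate_period(self, x0: np.ndarray, z0: np.ndarray, active: np.ndarray,
                        theta: ParameterVector, period: int,
                        rng: np.random.Generator,
                        collect_scores: bool = False) -> SimulationResult:
        """Simulate one unit-length period of ministeps.

        ``z0`` holds category codes (no missing values among any actor used
        by the effects; impute by carry-forward beforehand). Inactive
        actors receive no change opportunities but remain visible as
        alters. When ``collect_scores`` is set, the result carries the
        gradient of the simulation log-probability with respect to the
        full parameter vector (rates for this period and all coefficients),
        laid out as ParameterVector.as_array().
        """
        x = x0.astype(np.int8).copy()
        z = z0.astype(float).copy()
        if np.any(np.isnan(z)):
            raise ValueError("behavior must be imputed before simulation")
        idx_active = np.nonzero(active)[0]
        n_active = idx_active.size
        if n_active == 0:
            raise ValueError("no active actors in period")
        lam_net = float(theta.network_rates[period])
        lam_beh = float(theta.behavior_rates[period])
        n_net_coef = len(theta.network_coefs)
        n_beh_coef = len(theta.behavior_coefs)
        score = np.zeros(theta.as_array().size) if collect_scores else None
        trace = MinistepTrace()

        total_rate = n_active * (lam_net + lam_beh)
        if total_rate <= 0:
            return SimulationResult(x, z, trace, score)
        p_net = lam_net / (lam_net + lam_beh)

        t = 0.0
        while True:
            t += rng.exponential(1.0 / total_rate)
            if t >= 1.0:
                break
            i = int(idx_active[int(rng.integers(n_active))])
            if rng.random() < p_net:
                zc = self.scale.center(z)
                probs, dstats = self.network_choice_distribution(i, x, zc, theta.network_coefs)
                a = int(np.searchsorted(np.cumsum(probs), rng.random()))
                a = min(a, probs.size - 1)
                if collect_scores and n_net_coef:
                    sl = slice(2 * theta.n_periods, 2 * theta.n_periods + n_net_coef)
                    score[sl] += dstats[:, a] - dstats @ probs
                if a != i:
                    x[i, a] = 1 - x[i, a]
                trace.record(t, i, "network", a if a != i else None)
            else:
                probs, dstats = self.behavior_choice_distribution(i, x, z, theta.behavior_coefs)
                c = int(np.searchsorted(np.cumsum(probs), rng.random()))
                c = min(c, 2)
                step = c - 1
                if collect_scores and n_beh_coef:
                    sl = slice(2 * theta.n_periods + n_net_coef,
                               2 * theta.n_periods + n_net_coef + n_beh_coef)
                    score[sl] += dstats[:, c] - dstats @ probs
                z[i] += step
                trace.record(t, i, "behavior", step)

        if collect_scores:
            if lam_net > 0:
                score[period] = trace.n_network / lam_net - n_active
            if lam_beh > 0:
                score[theta.n_periods + period] = trace.n_behavior / lam_beh - n_active
        return SimulationResult(x, z, trace, score)

    def simulate_panel(self, x0: np.ndarray, z0: np.ndarray, theta: ParameterVector,
                       n_periods: int, rng: np.random.Generator,
                       active: np.ndarray | None = None) -> WavePanel:
        """Chain ministep periods into an (n_periods + 1)-wave panel.

        Wave m+1 is simulated conditional on the simulated wave m; all
        actors are active unless a mask is given.
        """
        n = x0.shape[0]
        if active is None:
            active = np.ones(n, dtype=bool)
        waves = [Wave(x0.astype(np.int8).copy(), z0.astype(float).copy(),
                      np.ones(n, dtype=bool))]
        x, z = x0, z0
        for m in range(n_periods):
            res = self.simulate_period(x, z, active, theta, m, rng)
            x, z = res.adjacency, res.behavior
            waves.append(Wave(x.copy(), z.copy(), np.ones(n, dtype=bool)))
        ids = [f"a{k:03d}" for k in range(n)]
        return WavePanel(ids, waves)
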