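"""Effect statistics for the network and behavior objective functions.

Each actor i evaluates candidate states through a linear objective
f_i(state) = sum_k beta_k s_ik(state). Network effects are functions of
the directed adjacency matrix and (constant or behavior) covariates;
behavior effects are functions of the actor's centered ordinal value and
the values of the actors they nominate.

Change statistics (the delta in s_ik under a single tie toggle or a
single +/-1 behavior step) are implemented in vectorized form and are
required to agree exactly with full recomputation; the test suite
enforces this by brute force on small graphs.

Conventions
-----------
* transitive triplets counts ordered pairs (j, h) with i->j, i->h, h->j:
  the tie i->j closes the two-path i->h->j.
* outdegree-activity is the square of the out-degree; indegree-activity
  is out-degree times in-degree (plain, non-square-root variants).
* average similarity is (1/d_i) * sum_j x_ij (sim_ij - sim_c) with
  sim_ij = 1 - |z_i - z_j| / range; it is 0 for actors with no outgoing
  ties. sim_c is a fixed centering constant (0 in toy settings, the
  observed-dyad mean in data analyses).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "Effect",
    "EffectSpec",
    "NETWORK_EFFECTS",
    "BEHAVIOR_EFFECTS",
    "network_statistic",
    "behavior_statistic",
    "network_change_statistics",
    "behavior_change_statistic",
    "objective",
]

#: Network effect names -> whether a covariate reference is required.
NETWORK_EFFECTS = {
    "outdegree": False,
    "reciprocity": False,
    "transitive_triplets": False,
    "transitive_reciprocated_triplets": False,
    "outdegree_activity": False,
    "indegree_activity": False,
    "alter": True,
    "alter_squared": True,
    "ego": True,
    "ego_squared": True,
    "ego_x_alter": True,
    "same": True,
}

BEHAVIOR_EFFECTS = {
    "linear_shape": False,
    "quadratic_shape": False,
    "average_similarity": False,
}

#: Effects whose covariate must be categorical rather than centered numeric.
_CATEGORICAL_ONLY = {"same"}


@dataclass(frozen=True)
class Effect:
    """One named effect in either objective function."""

    function: str  # "network" | "behavior"
    name: str
    covariate: str | None = None

    def __post_init__(self):
        if self.function == "network":
            if self.name not in NETWORK_EFFECTS:
                raise ValueError(f"unknown network effect {self.name!r}")
            if NETWORK_EFFECTS[self.name] and self.covariate is None:
                raise ValueError(f"network effect {self.name!r} requires a covariate")
            if not NETWORK_EFFECTS[self.name] and self.covariate is not None:
                raise ValueError(f"network effect {self.name!r} takes no covariate")
        elif self.function == "behavior":
            if self.name not in BEHAVIOR_EFFECTS:
                raise ValueError(f"unknown behavior effect {self.name!r}")
            if self.covariate is not None:
                raise ValueError(f"behavior effect {self.name!r} takes no covariate")
        else:
            raise ValueError(f"function must be 'network' or 'behavior', got {self.function!r}")

    @property
    def label(self) -> str:
        if self.covariate:
            return f"{self.covariate}_{self.name}"
        return self.name


@dataclass
class EffectSpec:
    """Ordered list of effects; the order fixes coefficient order."""

    effects: list[Effect] = field(default_factory=list)

    def __post_init__(self):
        self.effects = [e if isinstance(e, Effect) else Effect(**e) for e in self.effects]

    def subset(self, function: str) -> list[Effect]:
        return [e for e in self.effects if e.function == function]

    @property
    def network_effects(self) -> list[Effect]:
        return self.subset("network")

    @property
    def behavior_effects(self) -> list[Effect]:
        return self.subset("behavior")

    def labels(self, function: str) -> list[str]:
        return [e.label for e in self.subset(function)]

    def covariate_names(self) -> set[str]:
        return {e.covariate for e in self.effects if e.covariate is not None}

    # -- config round trip ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "network_effects": [
                {"name": e.name, **({"covariate": e.covariate} if e.covariate else {})}
                for e in self.network_effects
            ],
            "behavior_effects": [{"name": e.name} for e in self.behavior_effects],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EffectSpec":
        effects = [Effect("network", e["name"], e.get("covariate")) for e in d.get("network_effects", [])]
        effects += [Effect("behavior", e["name"]) for e in d.get("behavior_effects", [])]
        return cls(effects)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "EffectSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def standard_spec(demographics: bool = False, behavior: str = "bmi") -> EffectSpec:
    """The default model specification for friendship/BMI co-evolution.

    Without demographics: the six structural network effects, the five
    behavior-covariate selection effects (alter, alter squared, ego, ego
    squared, ego x alter on the centered ordinal variable) and the three
    behavior effects (linear and quadratic shape, average similarity).
    With demographics, adds the attribute effects retained in the full
    model: male alter, White alter, first-year alter, Hispanic ego, same
    floor, same White, same year in college.
    """
    net = [Effect("network", n) for n in (
        "outdegree", "reciprocity", "transitive_triplets",
        "transitive_reciprocated_triplets", "outdegree_activity", "indegree_activity",
    )]
    if demographics:
        net += [
            Effect("network", "alter", "male"),
            Effect("network", "alter", "white"),
            Effect("network", "alter", "first_year"),
            Effect("network", "ego", "hispanic"),
            Effect("network", "same", "floor"),
            Effect("network", "same", "white"),
            Effect("network", "same", "first_year"),
        ]
    net += [
        Effect("network", "alter", behavior),
        Effect("network", "alter_squared", behavior),
        Effect("network", "ego", behavior),
        Effect("network", "ego_squared", behavior),
        Effect("network", "ego_x_alter", behavior),
    ]
    beh = [
        Effect("behavior", "linear_shape"),
        Effect("behavior", "quadratic_shape"),
        Effect("behavior", "average_similarity"),
    ]
    return EffectSpec(net + beh)


def _check_covariate(name: str, v) -> None:
    if v is None:
        raise ValueError(f"effect {name!r} requires a covariate array")
    v = np.asarray(v)
    if name in _CATEGORICAL_ONLY:
        return
    if v.dtype.kind not in "fiu":
        raise TypeError(f"effect {name!r} requires a numeric (centered) covariate")


# ---------------------------------------------------------------------------
# Full statistics
# ---------------------------------------------------------------------------

def network_statistic(name: str, x: np.ndarray, i: int, v=None) -> float:
    """Actor i's statistic s_ik for one network effect.

    ``x`` is the binary adjacency matrix; ``v`` the covariate array
    (centered when numeric), required for covariate effects.
    """
    row = x[i].astype(float)
    col = x[:, i].astype(float)
    if name == "outdegree":
        return float(row.sum())
    if name == "reciprocity":
        return float(row @ col)
    if name == "transitive_triplets":
        # ordered (j, h): i->j, i->h, h->j
        return float(row @ (x.astype(float) @ row))
    if name == "transitive_reciprocated_triplets":
        mutual = row * col
        return float(mutual @ (row @ x.astype(float)))
    if name == "outdegree_activity":
        return float(row.sum() ** 2)
    if name == "indegree_activity":
        return float(row.sum() * col.sum())
    if name in NETWORK_EFFECTS and NETWORK_EFFECTS[name]:
        _check_covariate(name, v)
        v = np.asarray(v)
        if name == "alter":
            return float(row @ v)
        if name == "alter_squared":
            return float(row @ (v.astype(float) ** 2))
        if name == "ego":
            return float(v[i] * row.sum())
        if name == "ego_squared":
            return float(v[i] ** 2 * row.sum())
        if name == "ego_x_alter":
            return float(v[i] * (row @ v))
        if name == "same":
            return float(row @ (v == v[i]).astype(float))
    raise ValueError(f"unknown network effect {name!r}")


def behavior_statistic(name: str, z: np.ndarray, x: np.ndarray, i: int,
                       behavior_range: float, sim_c: float = 0.0) -> float:
    """Actor i's statistic for one behavior effect; ``z`` is centered."""
    if np.isnan(z[i]):
        raise ValueError(f"actor {i} has missing behavior")
    if name == "linear_shape":
        return float(z[i])
    if name == "quadratic_shape":
        return float(z[i] ** 2)
    if name == "average_similarity":
        if behavior_range <= 0:
            raise ValueError("behavior range must be positive")
        friends = np.nonzero(x[i])[0]
        if friends.size == 0:
            return 0.0
        sims = 1.0 - np.abs(z[i] - z[friends]) / behavior_range
        return float(np.mean(sims - sim_c))
    raise ValueError(f"unknown behavior effect {name!r}")


def objective(function: str, spec: EffectSpec, coefs, i: int, x: np.ndarray,
              z: np.ndarray | None = None, covariates: dict | None = None,
              behavior_range: float = float("nan"), sim_c: float = 0.0,
              behavior_name: str = "bmi") -> float:
    """Evaluate f_i = sum_k beta_k s_ik for one actor and one function."""
    effects = spec.subset(function)
    coefs = np.asarray(coefs, dtype=float)
    if coefs.shape != (len(effects),):
        raise ValueError(f"expected {len(effects)} coefficients, got {coefs.shape}")
    total = 0.0
    for beta, eff in zip(coefs, effects):
        if function == "network":
            v = _resolve_covariate(eff.covariate, covariates, z, behavior_name)
            total += beta * network_statistic(eff.name, x, i, v)
        else:
            total += beta * behavior_statistic(eff.name, z, x, i, behavior_range, sim_c)
    return float(total)


def _resolve_covariate(name, covariates, z, behavior_name):
    if name is None:
        return None
    if name == behavior_name:
        if z is None:
            raise ValueError("behavior covariate requested but no behavior supplied")
        return z
    if covariates is None or name not in covariates:
        raise KeyError(f"covariate {name!r} not available")
    return covariates[name]


# ---------------------------------------------------------------------------
# Change statistics
# ---------------------------------------------------------------------------

def network_change_statistics(name: str, x: np.ndarray, i: int, v=None) -> np.ndarray:
    """Delta in actor i's statistic for toggling the tie i->a, for every a.

    Returns an n-vector; entry a is s_ik(after toggling i->a) - s_ik(now),
    and entry i (no admissible toggle) is 0.
    """
    n = x.shape[0]
    xi = x[i].astype(float)
    sign = 1.0 - 2.0 * xi  # +1 where the toggle adds the tie, -1 where it removes
    xf = x.astype(float)
    if name == "outdegree":
        delta = sign.copy()
    elif name == "reciprocity":
        delta = sign * xf[:, i]
    elif name == "transitive_triplets":
        # toggled tie acts as the closing tie i->a and as the i->h leg of
        # two-paths through a; neither sum involves the toggled entry itself.
        closing = xi @ xf          # sum_h x_ih x_ha
        leg = xf @ xi              # sum_j x_ij x_aj
        delta = sign * (closing + leg)
    elif name == "transitive_reciprocated_triplets":
        mutual = xi * xf[:, i]
        delta = sign * (xf[:, i] * (xi @ xf) + xf @ mutual)
    elif name == "outdegree_activity":
        d0 = xi.sum() - xi  # out-degree excluding the toggled tie
        delta = sign * (2.0 * d0 + 1.0)
    elif name == "indegree_activity":
        delta = sign * xf[:, i].sum()
    elif name in NETWORK_EFFECTS and NETWORK_EFFECTS[name]:
        _check_covariate(name, v)
        v = np.asarray(v)
        if name == "alter":
            delta = sign * v.astype(float)
        elif name == "alter_squared":
            delta = sign * v.astype(float) ** 2
        elif name == "ego":
            delta = sign * float(v[i])
        elif name == "ego_squared":
            delta = sign * float(v[i]) ** 2
        elif name == "ego_x_alter":
            delta = sign * float(v[i]) * v.astype(float)
        elif name == "same":
            delta = sign * (v == v[i]).astype(float)
    else:
        raise ValueError(f"unknown network effect {name!r}")
    delta[i] = 0.0
    return delta


def behavior_change_statistic(name: str, z: np.ndarray, x: np.ndarray, i: int,
                              step: int, behavior_range: float,
                              sim_c: float = 0.0) -> float:
    """Delta in actor i's behavior statistic for a +/-1 (or 0) step."""
    if step not in (-1, 0, 1):
        raise ValueError("behavior step must be -1, 0 or +1")
    if step == 0:
        return 0.0
    before = behavior_statistic(name, z, x, i, behavior_range, sim_c)
    z_new = z.copy()
    z_new[i] = z[i] + step
    after = behavior_statistic(name, z_new, x, i, behavior_range, sim_c)
    return after - before
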