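"""Interpretation layer: odds ratios, selection curves, contrast tables,
and Monte Carlo bootstrap confidence intervals.

Network coefficients convert directly to odds ratios for a single tie,
exp(beta). Behavior-function results are interpreted through ministep
contrasts: the odds of moving one category (vs. staying) are compared
between two hypothetical friend configurations, which isolates the peer
influence (average similarity) term because the shape terms cancel.
Uncertainty is propagated by drawing parameter vectors from the
estimated sampling distribution N(theta_hat, covariance) and reporting
percentile intervals of the derived quantity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import BehaviorScale, CATEGORY_LABELS, N_CATEGORIES

__all__ = [
    "ScenarioContrast",
    "BehaviorCoefficients",
    "canonical_contrast",
    "or_from_coefficient",
    "alter_selection_curve",
    "ego_alter_table",
    "behavior_change_or",
    "own_category_or",
    "mc_bootstrap_ci",
]


@dataclass(frozen=True)
class BehaviorCoefficients:
    """Coefficients of the behavior objective: linear and quadratic shape
    plus average similarity (peer influence)."""

    linear: float
    quadratic: float
    average_similarity: float


@dataclass(frozen=True)
class ScenarioContrast:
    """Two friend configurations whose one-step odds are compared.

    ``ego_category`` is the ego's centered category value; the offsets give
    the friends' mean category minus the ego's in scenarios A and B; the
    contrasted move is one category up (+1) or down (-1).
    """

    ego_category: float = 0.0
    friends_offset_a: float = 1.0
    friends_offset_b: float = 0.0
    step: int = 1

    def __post_init__(self):
        if self.step not in (1, -1):
            raise ValueError("step must be +1 or -1")
        lim = N_CATEGORIES - 1
        if abs(self.friends_offset_a) > lim or abs(self.friends_offset_b) > lim:
            raise ValueError(f"friend offsets must lie within +/-{lim}")


def canonical_contrast(step: int = 1) -> ScenarioContrast:
    """The friends-higher vs. friends-same-or-lower contrast.

    Scenario A puts all friends one category above the ego. For an
    increase the baseline puts friends at the ego's category; friends one
    category below would give the identical baseline odds (either way the
    step moves the ego away from the friends' mean), which is why "same
    or lower" forms a single reference class for the increase. For a
    decrease the baseline uses friends one category below, so that the
    step moves toward them; with this pairing the increase and decrease
    odds ratios are exact inverses, exp(+/- 2 beta_avsim / range).
    """
    return ScenarioContrast(ego_category=0.0, friends_offset_a=1.0,
                            friends_offset_b=0.0 if step == 1 else -1.0,
                            step=step)


def or_from_coefficient(beta: float, decimals: int | None = None) -> float:
    """Odds ratio exp(beta); optionally rounded for display."""
    if not np.isfinite(beta):
        raise ValueError("coefficient must be finite")
    value = float(np.exp(beta))
    return round(value, decimals) if decimals is not None else value


def alter_selection_curve(beta_alter: float, beta_alter_sq: float,
                          scale: BehaviorScale) -> dict:
    """Quadratic contribution of an alter's category to being nominated.

    Evaluates g(v) = beta_alter * v + beta_alter_sq * v^2 at the centered
    value of every category and locates the continuous vertex
    v* = -beta_alter / (2 beta_alter_sq) when the parabola opens downward.
    Each grid point carries the kg/m^2 band label of its category.
    """
    codes = np.arange(1, scale.n_categories + 1)
    v = scale.center(codes)
    g = beta_alter * v + beta_alter_sq * v ** 2
    out = {
        "categories": codes.tolist(),
        "labels": list(CATEGORY_LABELS[: scale.n_categories]),
        "centered_values": v.tolist(),
        "contributions": g.tolist(),
        "peak_category": int(codes[int(np.argmax(g))]),
    }
    if beta_alter_sq < 0:
        vertex = -beta_alter / (2.0 * beta_alter_sq)
        out["vertex_centered"] = float(vertex)
        out["vertex_category"] = float(scale.uncenter(vertex))
    else:
        out["vertex_centered"] = None
        out["vertex_category"] = None
        out["monotone"] = "increasing" if beta_alter > 0 else (
            "decreasing" if beta_alter < 0 else "flat")
    return out


def ego_alter_table(theta: dict, ego_grid, alter_grid,
                    scale: BehaviorScale | None = None) -> np.ndarray:
    """Selection-contribution matrix over ego x alter centered values.

    ``theta`` maps coefficient names among {"ego", "ego_squared", "alter",
    "alter_squared", "ego_x_alter"} to values; absent names contribute 0.
    Cell (e, a) = b_ego*v_e + b_egoSq*v_e^2 + b_alt*v_a + b_altSq*v_a^2
    + b_exa*v_e*v_a.
    """
    ego = np.asarray(ego_grid, dtype=float)
    alt = np.asarray(alter_grid, dtype=float)
    if scale is not None:
        lo, hi = 1 - scale.centering_constant, scale.n_categories - scale.centering_constant
        if (ego.min() < lo or ego.max() > hi or alt.min() < lo or alt.max() > hi):
            import warnings
            warnings.warn("grid extends outside the behavior scale range")
    b = {k: float(theta.get(k, 0.0)) for k in
         ("ego", "ego_squared", "alter", "alter_squared", "ego_x_alter")}
    e = ego[:, None]
    a = alt[None, :]
    return (b["ego"] * e + b["ego_squared"] * e ** 2
            + b["alter"] * a + b["alter_squared"] * a ** 2
            + b["ego_x_alter"] * e * a)


def _step_objective_change(coefs: BehaviorCoefficients, ego: float,
                           friends_mean_offset: float, step: int,
                           behavior_range: float) -> float:
    """Change in the behavior objective for a one-category step, with all
    friends at ego + offset. The similarity centering constant cancels."""
    z_new = ego + step
    d_shape = coefs.linear * step + coefs.quadratic * (z_new ** 2 - ego ** 2)
    friend = ego + friends_mean_offset
    sim_before = 1.0 - abs(ego - friend) / behavior_range
    sim_after = 1.0 - abs(z_new - friend) / behavior_range
    return d_shape + coefs.average_similarity * (sim_after - sim_before)


def behavior_change_or(coefs: BehaviorCoefficients, contrast: ScenarioContrast,
                       scale: BehaviorScale) -> float:
    """Odds ratio of a one-category move (vs. staying) between the two
    friend configurations of ``contrast``.

    For the canonical contrast (friends one category above vs. at the
    ego's category, step +1) the shape terms cancel and the value reduces
    to exp(2 * beta_avsim / range).
    """
    lo = 1 - scale.centering_constant
    hi = scale.n_categories - scale.centering_constant
    if not (lo <= contrast.ego_category + contrast.step <= hi):
        raise ValueError("step leaves the category scale for this ego value")
    dfa = _step_objective_change(coefs, contrast.ego_category,
                                 contrast.friends_offset_a, contrast.step, scale.range)
    dfb = _step_objective_change(coefs, contrast.ego_category,
                                 contrast.friends_offset_b, contrast.step, scale.range)
    return float(np.exp(dfa - dfb))


def own_category_or(beta_quadratic: float) -> float:
    """Multiplicative change, per unit of own centered category, in the
    increase-vs-stay odds contributed by the shape terms: exp(2 beta_quad).

    The +1-step shape contribution is beta_lin + beta_quad*(2 z + 1); one
    unit of z multiplies the odds by exp(2 beta_quad).
    """
    return float(np.exp(2.0 * beta_quadratic))


def mc_bootstrap_ci(theta_hat, covariance, functional, n_draws: int = 100_000,
                    seed: int = 0, level: float = 0.95) -> tuple[float, float]:
    """Percentile interval of ``functional(theta)`` under the estimated
    sampling distribution N(theta_hat, covariance).

    ``functional`` maps a parameter vector to a scalar and is applied to
    each multivariate-normal draw; deterministic given ``seed``.
    """
    if n_draws < 100:
        raise ValueError("n_draws must be at least 100")
    theta_hat = np.atleast_1d(np.asarray(theta_hat, dtype=float))
    covariance = np.atleast_2d(np.asarray(covariance, dtype=float))
    if covariance.shape != (theta_hat.size, theta_hat.size):
        raise ValueError("covariance shape does not match theta")
    if not np.allclose(covariance, covariance.T, atol=1e-8):
        raise ValueError("covariance must be symmetric")
    eigs = np.linalg.eigvalsh(covariance)
    if eigs.min() < -1e-8 * max(eigs.max(), 1.0):
        raise ValueError("covariance must be positive semidefinite")
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(theta_hat, covariance, size=n_draws,
                                    method="eigh")
    values = np.apply_along_axis(functional, 1, draws)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(values, [alpha, 1.0 - alpha])
    return float(lo), float(hi)
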