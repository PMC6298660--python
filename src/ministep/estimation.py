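"""Method-of-moments estimation via Robbins-Monro stochastic approximation.

The estimator matches, in expectation, simulated statistics to their
observed targets: for every effect, the statistic summed over actors and
periods at observed end waves; for every rate parameter, the observed
amount of change in its period (tie-flip count for the network, total
absolute category change for behavior). Parameters are found in three
phases:

1. estimate the derivative matrix D of expected statistics with respect
   to theta from simulations at the starting value, using the
   likelihood-ratio (score-function) identity dE[S]/dtheta = cov(S, g)
   where g is the gradient of the simulation log-probability;
2. Robbins-Monro iterations theta <- theta - a * D^-1 (S_sim - target),
   with the gain a halved over subphases and the subphase average carried
   forward;
3. a batch of simulations at the final theta to compute convergence
   t-ratios, the parameter covariance D^-1 Sigma D^-T, and standard
   errors.

Each period is simulated conditional on the *observed* start wave, with
missing behavior imputed by last-observation carry-forward; imputed
actor-wave observations are excluded from the targets so that imputation
cannot masquerade as observed change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data_model import CovariateTable, WavePanel, center_behavior
from .effects import EffectSpec, behavior_statistic, network_statistic
from .engine import ParameterVector, SaomModel

__all__ = [
    "EstimationOptions",
    "EstimationResult",
    "EstimationError",
    "build_model",
    "impute_behavior",
    "similarity_centering",
    "target_statistics",
    "simulate_statistics",
    "initial_parameters",
    "estimate",
    "wald_tests",
]


class EstimationError(RuntimeError):
    pass


@dataclass
class EstimationOptions:
    """Algorithm constants; defaults follow standard practice for this
    estimator family and are freely configurable."""

    n_subphases: int = 4
    n2start: int = 40
    subphase_growth: float = 2.0
    n3: int = 500
    gain0: float = 0.2
    phase1_base: int = 7
    phase1_per_param: int = 3
    max_step: float = 2.0          # elementwise cap on one Robbins-Monro step
    dev_truncation: float = 4.0    # cap on standardized moment deviations
    rate_floor: float = 0.05
    t_conv_threshold: float = 0.1
    overall_threshold: float = 0.25
    max_condition: float = 1e10
    n_restarts: int = 0            # rerun phases 1-3 from theta_hat if unconverged


@dataclass
class EstimationResult:
    theta_hat: ParameterVector
    labels: list[str]
    se: np.ndarray
    covariance: np.ndarray
    t_conv: np.ndarray
    overall_conv: float
    p_values: np.ndarray
    targets: np.ndarray
    sim_mean: np.ndarray
    n_phase3: int
    seed: int
    converged: bool
    options: EstimationOptions = field(repr=False, default_factory=EstimationOptions)

    def summary(self) -> str:
        lines = [f"{'parameter':<38}{'estimate':>10}{'se':>9}{'p':>8}{'t_conv':>8}"]
        est = self.theta_hat.as_array()
        for k, lab in enumerate(self.labels):
            lines.append(
                f"{lab:<38}{est[k]:>10.3f}{self.se[k]:>9.3f}"
                f"{self.p_values[k]:>8.3f}{self.t_conv[k]:>8.3f}")
        lines.append(f"overall convergence ratio: {self.overall_conv:.3f} "
                     f"({'converged' if self.converged else 'NOT converged'})")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "theta_hat": self.theta_hat.to_dict(),
            "labels": self.labels,
            "estimate": self.theta_hat.as_array().tolist(),
            "se": self.se.tolist(),
            "covariance": self.covariance.tolist(),
            "t_conv": self.t_conv.tolist(),
            "overall_conv": self.overall_conv,
            "p_values": self.p_values.tolist(),
            "targets": self.targets.tolist(),
            "sim_mean": self.sim_mean.tolist(),
            "n_phase3": self.n_phase3,
            "seed": self.seed,
            "converged": self.converged,
        }


# ---------------------------------------------------------------------------
# Model assembly from observed data
# ---------------------------------------------------------------------------

def impute_behavior(panel: WavePanel) -> tuple[np.ndarray, np.ndarray]:
    """Carry-forward (then backward) imputation of behavior codes.

    Returns ``(codes, imputed)`` where ``codes`` is a fully observed
    (n, waves) array and ``imputed`` flags entries that were filled in.
    """
    codes = panel.behavior_matrix().copy()
    imputed = np.isnan(codes)
    n, w = codes.shape
    for i in range(n):
        row = codes[i]
        if np.all(np.isnan(row)):
            raise EstimationError(f"actor {panel.actor_ids[i]} has no observed behavior")
        last = np.nan
        for m in range(w):
            if np.isnan(row[m]):
                row[m] = last
            else:
                last = row[m]
        first = row[~np.isnan(row)][0]
        row[np.isnan(row)] = first
    return codes, imputed


def similarity_centering(panel: WavePanel, behavior_range: float) -> float:
    """Mean dyadic similarity 1 - |z_i - z_j| / range over all ordered
    pairs with both behaviors observed, pooled across waves."""
    total, count = 0.0, 0
    for wave in panel.waves:
        z = wave.behavior
        obs = np.nonzero(~np.isnan(z))[0]
        if obs.size < 2:
            continue
        zz = z[obs]
        diff = np.abs(zz[:, None] - zz[None, :])
        sims = 1.0 - diff / behavior_range
        total += sims.sum() - len(obs)  # drop the diagonal (sim = 1)
        count += len(obs) * (len(obs) - 1)
    if count == 0:
        raise EstimationError("no dyads with observed behavior at any wave")
    return total / count


def build_model(panel: WavePanel, spec: EffectSpec,
                covariates: CovariateTable | None = None,
                sim_c: float | None = None,
                behavior_name: str = "bmi") -> SaomModel:
    """Bind an effect specification to a panel's scale and covariates.

    Numeric covariates are centered over all actors; categorical ones
    (floor, race) are passed through for ``same`` effects. ``sim_c``
    defaults to the observed-dyad mean similarity.
    """
    scale = panel.behavior_scale()
    cov_arrays: dict[str, np.ndarray] = {}
    for name in spec.covariate_names():
        if name == behavior_name:
            continue
        if covariates is None:
            raise EstimationError(f"effect spec needs covariate {name!r} but none supplied")
        vals = covariates.reindex(panel.actor_ids).values(name)
        if vals.dtype.kind in "fiu":
            cov_arrays[name] = vals - vals.mean()
        else:
            cov_arrays[name] = vals
    if sim_c is None:
        sim_c = similarity_centering(panel, scale.range)
    return SaomModel(spec, scale, cov_arrays, sim_c=sim_c, behavior_name=behavior_name)


# ---------------------------------------------------------------------------
# Moment statistics
# ---------------------------------------------------------------------------

def _period_masks(panel: WavePanel, m: int):
    """Observation masks for period m: actors active at the start wave,
    egos observable at both ends (network change), actors observed at both
    ends (behavior change), and actors observed at the end wave."""
    start, end = panel.waves[m], panel.waves[m + 1]
    return {
        "active": start.participating,
        "net_rows": start.participating & end.participating,
        "beh_both": start.participating & end.participating,
        "end_obs": end.participating,
    }


def _statistic_sums(model: SaomModel, x: np.ndarray, zc: np.ndarray,
                    mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sum each effect statistic over actors in ``mask`` at one state."""
    net = np.zeros(len(model.spec.network_effects))
    beh = np.zeros(len(model.spec.behavior_effects))
    actors = np.nonzero(mask)[0]
    for k, eff in enumerate(model.spec.network_effects):
        v = model._covariate(eff.covariate, zc)
        net[k] = sum(network_statistic(eff.name, x, int(i), v) for i in actors)
    for k, eff in enumerate(model.spec.behavior_effects):
        beh[k] = sum(
            behavior_statistic(eff.name, zc, x, int(i), model.scale.range, model.sim_c)
            for i in actors)
    return net, beh


def _assemble(panel, model, end_states):
    """Compute the full statistic vector from per-period end states.

    ``end_states[m]`` is (x_end, z_end_codes); masks always come from the
    observed panel so simulated and observed statistics are comparable.
    """
    m_periods = panel.n_periods
    net_rate = np.zeros(m_periods)
    beh_rate = np.zeros(m_periods)
    net_eff = np.zeros(len(model.spec.network_effects))
    beh_eff = np.zeros(len(model.spec.behavior_effects))
    for m in range(m_periods):
        masks = _period_masks(panel, m)
        x_start = panel.waves[m].adjacency
        z_start = panel.waves[m].behavior
        x_end, z_end = end_states[m]
        rows = masks["net_rows"]
        net_rate[m] = np.abs(x_end[rows].astype(int) - x_start[rows].astype(int)).sum()
        both = masks["beh_both"]
        beh_rate[m] = np.abs(z_end[both] - z_start[both]).sum()
        zc_end = model.scale.center(z_end)
        net_m, beh_m = _statistic_sums(model, x_end, zc_end, masks["end_obs"])
        net_eff += net_m
        beh_eff += beh_m
    return np.concatenate([net_rate, beh_rate, net_eff, beh_eff])


def target_statistics(panel: WavePanel, model: SaomModel) -> np.ndarray:
    """Observed moment targets, ordered as ParameterVector.as_array().

    Rate targets are raw change amounts per period; effect targets sum the
    statistic over observed end-wave actors and periods. Imputed behavior
    values fill covariate roles only; imputed actors are excluded from the
    behavior-rate and behavior-statistic sums via the observation masks.
    """
    imputed_codes, _ = impute_behavior(panel)
    end_states = []
    for m in range(panel.n_periods):
        z_end = imputed_codes[:, m + 1]
        end_states.append((panel.waves[m + 1].adjacency, z_end))
    # For behavior-rate targets the observed codes are used directly; the
    # mask already restricts to actors observed at both ends, for whom the
    # imputed codes equal the observed ones.
    return _assemble(panel, model, end_states)


def simulate_statistics(panel: WavePanel, model: SaomModel, theta: ParameterVector,
                        rng: np.random.Generator,
                        collect_scores: bool = False) -> tuple[np.ndarray, np.ndarray | None]:
    """One Monte Carlo draw of the statistic vector (and its score).

    Every period starts from the observed wave (behavior imputed by
    carry-forward) and runs the ministep process for unit time.
    """
    imputed_codes, _ = impute_behavior(panel)
    end_states = []
    score = np.zeros(theta.as_array().size) if collect_scores else None
    for m in range(panel.n_periods):
        masks = _period_masks(panel, m)
        x0 = panel.waves[m].adjacency
        z0 = imputed_codes[:, m]
        res = model.simulate_period(x0, z0, masks["active"], theta, m, rng,
                                    collect_scores=collect_scores)
        end_states.append((res.adjacency, res.behavior))
        if collect_scores:
            score += res.score
    return _assemble(panel, model, end_states), score


# ---------------------------------------------------------------------------
# Estimation
# ---------------------------------------------------------------------------

def initial_parameters(panel: WavePanel, model: SaomModel) -> ParameterVector:
    """Data-driven starting values: rates from observed per-actor change,
    the outdegree coefficient from the observed density logit, all other
    coefficients zero."""
    m_periods = panel.n_periods
    net_rates = np.empty(m_periods)
    beh_rates = np.empty(m_periods)
    for m in range(m_periods):
        masks = _period_masks(panel, m)
        x0 = panel.waves[m].adjacency
        x1 = panel.waves[m + 1].adjacency
        rows = masks["net_rows"]
        n_rows = max(int(rows.sum()), 1)
        net_rates[m] = max(np.abs(x1[rows].astype(int) - x0[rows].astype(int)).sum() / n_rows, 0.5)
        z0, z1 = panel.waves[m].behavior, panel.waves[m + 1].behavior
        both = masks["beh_both"]
        n_both = max(int(both.sum()), 1)
        beh_rates[m] = max(np.abs(z1[both] - z0[both]).sum() / n_both, 0.25)

    n = panel.n_actors
    dens = np.mean([w.adjacency.sum() / (n * (n - 1)) for w in panel.waves])
    dens = min(max(dens, 1e-4), 1 - 1e-4)
    net_coefs = np.zeros(len(model.spec.network_effects))
    for k, eff in enumerate(model.spec.network_effects):
        if eff.name == "outdegree":
            net_coefs[k] = np.log(dens / (1 - dens))
    beh_coefs = np.zeros(len(model.spec.behavior_effects))
    return ParameterVector(net_rates, beh_rates, net_coefs, beh_coefs)


def _derivative_matrix(sims: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Likelihood-ratio derivative estimate dE[S]/dtheta = cov(S, g)."""
    s_c = sims - sims.mean(axis=0)
    g_c = scores - scores.mean(axis=0)
    return s_c.T @ g_c / (sims.shape[0] - 1)


def estimate(panel: WavePanel, spec_or_model, options: EstimationOptions | None = None,
             seed: int = 0, covariates: CovariateTable | None = None,
             theta0: ParameterVector | None = None) -> EstimationResult:
    """Fit the co-evolution model to a panel by the method of moments.

    Parameters
    ----------
    panel : WavePanel
    spec_or_model : EffectSpec or SaomModel
        An effect specification (a model is built with default centering)
        or a ready-made model.
    options : EstimationOptions
    seed : int
        Seeds all simulation randomness; runs are bit-for-bit reproducible
        given identical inputs.
    covariates : CovariateTable, optional
    theta0 : ParameterVector, optional
        Starting value; defaults to :func:`initial_parameters`.

    When ``options.n_restarts`` is positive and the convergence check
    fails, the three phases are rerun from the obtained theta_hat (the
    standard remedy for a fit that has drifted but not yet settled); each
    restart derives a fresh seed from ``seed``.
    """
    options = options or EstimationOptions()
    result = _estimate_once(panel, spec_or_model, options, seed, covariates, theta0)
    for attempt in range(options.n_restarts):
        if result.converged:
            break
        result = _estimate_once(panel, spec_or_model, options,
                                seed + 100_003 * (attempt + 1), covariates,
                                result.theta_hat)
    return result


def _estimate_once(panel, spec_or_model, options, seed, covariates, theta0):
    if isinstance(spec_or_model, SaomModel):
        model = spec_or_model
    else:
        model = build_model(panel, spec_or_model, covariates)
    rng = np.random.default_rng(seed)

    targets = target_statistics(panel, model)
    theta = theta0 or initial_parameters(panel, model)
    n_periods, n_net = theta.n_periods, len(theta.network_coefs)
    n_beh = len(theta.behavior_coefs)
    p = theta.as_array().size

    def run(th, collect=True):
        return simulate_statistics(panel, model, th, rng, collect_scores=collect)

    # -- phase 1: derivative matrix at the start ---------------------------
    n1 = options.phase1_base + options.phase1_per_param * p
    sims = np.empty((n1, p))
    scores = np.empty((n1, p))
    for r in range(n1):
        sims[r], scores[r] = run(theta)
    d_mat = _derivative_matrix(sims, scores)
    stat_sd = np.maximum(sims.std(axis=0, ddof=1), 1e-8)

    # -- phase 2: Robbins-Monro subphases ----------------------------------
    # The first subphase uses only the diagonal of D; later subphases use
    # the full matrix, refreshed from the previous subphase's simulations
    # so the derivative tracks theta (refreshes with an implausible, i.e.
    # non-positive, diagonal are rejected — they arise from the
    # nonstationarity of theta within a subphase). Weakly identified
    # parameters, whose estimated derivative is small or of the wrong
    # sign, are decoupled and updated with a conservative positive
    # diagonal so that noise cannot drive a runaway; deviations are
    # truncated at `dev_truncation` standard deviations for the same
    # reason. Any positive-definite preconditioner leaves the Robbins-
    # Monro fixed point unchanged, so these safeguards affect speed, not
    # the estimand.
    theta_arr = theta.as_array()
    for sub in range(options.n_subphases):
        gain = options.gain0 / (2.0 ** sub)
        n_iter = int(round(options.n2start * options.subphase_growth ** sub))
        d_use = _stabilized(d_mat, stat_sd, diagonal_only=(sub == 0))
        d_inv = _checked_inverse(d_use, options.max_condition, f"phase 2 subphase {sub + 1}")
        trail = np.empty((n_iter, p))
        sub_sims = np.empty((n_iter, p))
        sub_scores = np.empty((n_iter, p))
        for it in range(n_iter):
            th = ParameterVector.from_array(theta_arr, n_periods, n_net, n_beh)
            s, g = simulate_statistics(panel, model, th, rng, collect_scores=True)
            sub_sims[it], sub_scores[it] = s, g
            dev = np.clip((s - targets) / stat_sd, -options.dev_truncation,
                          options.dev_truncation) * stat_sd
            step = gain * (d_inv @ dev)
            big = np.abs(step).max()
            if big > options.max_step:
                step *= options.max_step / big
            theta_arr = theta_arr - step
            theta_arr[: 2 * n_periods] = np.maximum(theta_arr[: 2 * n_periods],
                                                    options.rate_floor)
            trail[it] = theta_arr
        theta_arr = trail.mean(axis=0)  # Polyak average carried into next subphase
        d_new = _derivative_matrix(sub_sims, sub_scores)
        # refresh only when backed by enough draws to be full rank and the
        # diagonal is plausible (positive)
        if n_iter >= 2 * p and np.all(np.isfinite(d_new)) and np.all(np.diag(d_new) > 0):
            d_mat = d_new
        stat_sd = np.maximum(sub_sims.std(axis=0, ddof=1), 1e-8)
    theta_hat = ParameterVector.from_array(theta_arr, n_periods, n_net, n_beh)

    # -- phase 3: diagnostics at theta_hat ---------------------------------
    sims3 = np.empty((options.n3, p))
    scores3 = np.empty((options.n3, p))
    for r in range(options.n3):
        sims3[r], scores3[r] = run(theta_hat)
    dev = sims3 - targets
    sd = dev.std(axis=0, ddof=1)
    mean_dev = dev.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_conv = np.where(sd > 0, mean_dev / sd, np.where(mean_dev == 0, 0.0, np.inf))
    sigma = np.cov(sims3, rowvar=False)
    d3 = _derivative_matrix(sims3, scores3)
    d3_inv = _checked_inverse(d3, options.max_condition, "phase 3")
    covariance = d3_inv @ sigma @ d3_inv.T
    covariance = 0.5 * (covariance + covariance.T)
    se = np.sqrt(np.clip(np.diag(covariance), 0.0, None))
    overall = float(np.sqrt(max(mean_dev @ np.linalg.pinv(sigma) @ mean_dev, 0.0)))

    converged = bool(np.all(np.abs(t_conv) < options.t_conv_threshold)
                     and overall < options.overall_threshold)
    if not converged:
        warnings.warn(
            f"estimation has not converged: max |t_conv| = {np.abs(t_conv).max():.3f}, "
            f"overall ratio = {overall:.3f}; rerun from theta_hat or enlarge phase 2")

    est = theta_hat.as_array()
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, est / se, np.nan)
    p_values = 2.0 * (1.0 - stats.norm.cdf(np.abs(z)))

    return EstimationResult(
        theta_hat=theta_hat,
        labels=theta_hat.labels(model.spec),
        se=se,
        covariance=covariance,
        t_conv=t_conv,
        overall_conv=overall,
        p_values=p_values,
        targets=targets,
        sim_mean=sims3.mean(axis=0),
        n_phase3=options.n3,
        seed=seed,
        converged=converged,
        options=options,
    )


def _stabilized(d_mat: np.ndarray, stat_sd: np.ndarray, diagonal_only: bool,
                floor_frac: float = 0.25) -> np.ndarray:
    """Safeguarded copy of the derivative matrix for phase-2 updates.

    Diagonal entries below ``floor_frac * stat_sd`` (in particular,
    negative ones, which can only be estimation noise since every
    statistic is increasing in its own parameter) are raised to that
    floor and the parameter is decoupled from the others.
    """
    floor = floor_frac * stat_sd
    if diagonal_only:
        return np.diag(np.maximum(np.diag(d_mat), floor))
    out = d_mat.copy()
    weak = np.diag(out) < floor
    for k in np.nonzero(weak)[0]:
        out[k, :] = 0.0
        out[:, k] = 0.0
        out[k, k] = floor[k]
    return out


def _checked_inverse(mat: np.ndarray, max_condition: float, where: str) -> np.ndarray:
    cond = np.linalg.cond(mat)
    if not np.isfinite(cond) or cond > max_condition:
        raise EstimationError(
            f"derivative matrix in {where} is numerically singular "
            f"(condition number {cond:.2e}); the model may be unidentified "
            f"or the simulation count too small")
    return np.linalg.inv(mat)


def wald_tests(result: EstimationResult) -> dict[str, np.ndarray]:
    """Two-sided Wald z-tests theta_hat / se for every parameter."""
    est = result.theta_hat.as_array()
    se = result.se
    z = np.full_like(est, np.nan)
    ok = se > 0
    z[ok] = est[ok] / se[ok]
    if np.any(~ok):
        warnings.warn("zero standard error: Wald test undefined for some parameters")
    p = 2.0 * (1.0 - stats.norm.cdf(np.abs(z)))
    return {"labels": result.labels, "z": z, "p": p}
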