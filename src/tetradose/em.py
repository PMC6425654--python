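"""Five-component normal mixture EM for one marker.

Component means and the common variance are shared across all
subpopulations; mixing proportions are estimated per population under
one of four regimes:

* ``p_free``  — only constrained to sum to 1,
* ``p_HW``    — Binomial(4, p) with the allele frequency p estimated,
* ``p_fixed`` — held at supplied values (known parental dosage),
* ``p_F1``    — tetrasomic segregation ratio implied by the current
  modal dosages of the two linked parent populations.

Means may be free or constrained through a dose-response curve with
channel backgrounds ``c_a``, ``c_b`` and curvature ``k``:
``mu_j = arcsin(sqrt(f_B(j) / (f_A(j) + f_B(j))))`` with
``f_B(j) = c_b + j (1 + k j)`` and ``f_A(j) = c_a + (4-j)(1 + k (4-j))``.
Equal-background variants force ``c_a == c_b``; linear variants force
``k == 0``.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.special import logsumexp

from .datamodel import (MAX_DOSAGE, N_DOSAGES, MarkerSignals,
                        PopulationStructure, ValidationError)
from .segregation import f1_segregation, hw_proportions

logger = logging.getLogger(__name__)

# mixing-proportion regimes
P_FREE = "p_free"
P_HW = "p_HW"
P_FIXED = "p_fixed"
P_F1 = "p_F1"
PI_CONSTRAINTS = (P_FREE, P_HW, P_FIXED, P_F1)

# mean parameterisations
MU_FREE = "free"
MU_EQ_LIN = "background_equal_linear"
MU_UNEQ_LIN = "background_unequal_linear"
MU_EQ_QUAD = "background_equal_quadratic"
MU_UNEQ_QUAD = "background_unequal_quadratic"
MU_CONSTRAINTS = (MU_FREE, MU_EQ_LIN, MU_UNEQ_LIN, MU_EQ_QUAD, MU_UNEQ_QUAD)

# parameter counts used in the BIC penalty
MU_N_PARAMS = {MU_FREE: 5, MU_EQ_LIN: 2, MU_UNEQ_LIN: 3,
               MU_EQ_QUAD: 3, MU_UNEQ_QUAD: 4}
PI_N_PARAMS = {P_FREE: 4, P_HW: 1, P_FIXED: 0, P_F1: 0}

#: component means with zero background and a linear dose response
IDEAL_MU = np.arcsin(np.sqrt(np.arange(N_DOSAGES) / MAX_DOSAGE))

#: mass left on each non-target class when a parental dosage is "fixed";
#: a strict 0/1 vector would make outlying parent replicates degenerate
FIXED_EPSILON = 0.02


class EMError(RuntimeError):
    """EM could not be run or did not produce a usable model."""


def spiked_proportions(dosage: int,
                       epsilon: float = FIXED_EPSILON) -> np.ndarray:
    """Near-degenerate mixing vector for a known parental dosage."""
    pi = np.full(N_DOSAGES, epsilon)
    pi[dosage] = 1.0 - (N_DOSAGES - 1) * epsilon
    return pi


@dataclass
class MeanParameterization:
    """Dose-response parameters implying the five component means."""

    c_a: float = 0.0
    c_b: float = 0.0
    k: float = 0.0

    def mu(self) -> np.ndarray:
        j = np.arange(N_DOSAGES, dtype=float)
        f_b = self.c_b + j * (1.0 + self.k * j)
        f_a = self.c_a + (MAX_DOSAGE - j) * (1.0 + self.k * (MAX_DOSAGE - j))
        return np.arcsin(np.sqrt(f_b / (f_a + f_b)))


@dataclass
class EMConfig:
    tol: float = 1e-6
    max_iter: int = 500
    var_floor: float = 1e-6
    min_samples: int = 10


@dataclass
class MixtureModel:
    """Fitted (or starting) mixture model for one marker."""

    mu: np.ndarray
    sigma2: float
    pi: dict[str, np.ndarray]
    mu_constraint: str = MU_FREE
    pi_constraint: dict[str, str] = field(default_factory=dict)
    mean_param: MeanParameterization | None = None
    loglik: float = float("nan")
    n_params: int = 0
    bic: float = float("nan")
    n_iter: int = 0
    converged: bool = False
    loglik_trace: list[float] = field(default_factory=list)

    def copy(self) -> "MixtureModel":
        return copy.deepcopy(self)


@dataclass
class PosteriorMatrix:
    """Per-sample component membership probabilities (rows sum to 1)."""

    values: np.ndarray        # (n_samples, 5); NaN rows where y missing
    observed: np.ndarray      # boolean mask of usable samples


def count_parameters(mu_constraint: str, pi_constraint: dict[str, str],
                     component_mask: np.ndarray | None = None) -> int:
    """Free-parameter count for the BIC penalty.

    A component mask (used by the extreme-component re-evaluation)
    removes one free mean under the free parameterisation and one free
    proportion per ``p_free`` population.
    """
    n_active = N_DOSAGES if component_mask is None else int(component_mask.sum())
    dropped = N_DOSAGES - n_active
    n = 1  # sigma^2
    n += MU_N_PARAMS[mu_constraint]
    if mu_constraint == MU_FREE:
        n -= dropped
    for constraint in pi_constraint.values():
        k = PI_N_PARAMS[constraint]
        if constraint == P_FREE:
            k = max(k - dropped, 0)
        n += k
    return n


def _component_logpdf(y: np.ndarray, mu: np.ndarray, sigma2: float) -> np.ndarray:
    """(n, 5) matrix of log N(y_i; mu_j, sigma2)."""
    return (-0.5 * np.log(2.0 * np.pi * sigma2)
            - (y[:, None] - mu[None, :]) ** 2 / (2.0 * sigma2))


def mixture_density(y, model: MixtureModel, population_id: str):
    """Mixture density sum_j pi_j N(y; mu_j, sigma^2) for one population."""
    if population_id not in model.pi:
        raise ValidationError(f"unknown population {population_id!r}")
    yv = np.atleast_1d(np.asarray(y, dtype=float))
    logpdf = _component_logpdf(yv, model.mu, model.sigma2)
    dens = np.exp(logpdf) @ model.pi[population_id]
    return float(dens[0]) if np.isscalar(y) else dens


def _log_pi_rows(signals: MarkerSignals, structure: PopulationStructure,
                 pi: dict[str, np.ndarray]) -> np.ndarray:
    pops = [structure.population_of(s) for s in signals.sample_ids]
    stacked = np.stack([pi[p] for p in pops])
    with np.errstate(divide="ignore"):
        return np.log(stacked)


def observed_loglik(signals: MarkerSignals, structure: PopulationStructure,
                    model: MixtureModel) -> float:
    obs = signals.observed
    if not obs.any():
        raise EMError(f"no observations for marker {signals.marker_id}")
    logpi = _log_pi_rows(signals, structure, model.pi)[obs]
    logpdf = _component_logpdf(signals.y[obs], model.mu, model.sigma2)
    return float(logsumexp(logpi + logpdf, axis=1).sum())


def e_step(signals: MarkerSignals, structure: PopulationStructure,
           model: MixtureModel) -> PosteriorMatrix:
    """Posterior membership probabilities under the current model."""
    obs = signals.observed
    if not obs.any():
        raise EMError(f"no observations for marker {signals.marker_id}")
    values = np.full((signals.n_samples, N_DOSAGES), np.nan)
    logpi = _log_pi_rows(signals, structure, model.pi)[obs]
    logw = logpi + _component_logpdf(signals.y[obs], model.mu, model.sigma2)
    values[obs] = np.exp(logw - logsumexp(logw, axis=1, keepdims=True))
    return PosteriorMatrix(values=values, observed=obs)


def modal_dosage(weights: np.ndarray) -> int:
    """Argmax dosage; ties go to the class nearest the mean dosage, then low."""
    w = np.asarray(weights, dtype=float)
    top = w.max()
    candidates = np.flatnonzero(w >= top - 1e-12)
    if len(candidates) == 1:
        return int(candidates[0])
    mean_d = float(w @ np.arange(N_DOSAGES)) / float(w.sum())
    return int(min(candidates, key=lambda d: (abs(d - mean_d), d)))


def _population_rows(signals: MarkerSignals, structure: PopulationStructure
                     ) -> dict[str, np.ndarray]:
    pops = np.array([structure.population_of(s) for s in signals.sample_ids],
                    dtype=object)
    return {pid: np.flatnonzero((pops == pid) & signals.observed)
            for pid in structure.populations}


def m_step_pi(posteriors: PosteriorMatrix, signals: MarkerSignals,
              structure: PopulationStructure, pi_constraints: dict[str, str],
              current_pi: dict[str, np.ndarray],
              parent_mode_overrides: dict[str, int] | None = None,
              component_mask: np.ndarray | None = None
              ) -> dict[str, np.ndarray]:
    """Update mixing proportions per population under their constraints."""
    overrides = parent_mode_overrides or {}
    rows = _population_rows(signals, structure)
    mean_post = {pid: (posteriors.values[idx].mean(axis=0) if len(idx)
                       else None)
                 for pid, idx in rows.items()}

    def parent_mode(pid: str) -> int | None:
        if pid in overrides:
            return overrides[pid]
        mp = mean_post.get(pid)
        return None if mp is None else modal_dosage(mp)

    new_pi: dict[str, np.ndarray] = {}
    for pid, constraint in pi_constraints.items():
        if constraint == P_FIXED:
            pi = current_pi[pid].copy()
        elif mean_post[pid] is None and constraint != P_F1:
            pi = current_pi[pid].copy()  # population without observations
        elif constraint == P_FREE:
            pi = mean_post[pid].copy()
        elif constraint == P_HW:
            p = float(mean_post[pid] @ np.arange(N_DOSAGES)) / MAX_DOSAGE
            pi = hw_proportions(min(max(p, 0.0), 1.0))
        elif constraint == P_F1:
            par1, par2 = structure.parents_of(pid)
            d1, d2 = parent_mode(par1), parent_mode(par2)
            if d1 is None or d2 is None:
                pi = current_pi[pid].copy()
            else:
                pi = np.asarray(f1_segregation(d1, d2).proportions)
        else:  # pragma: no cover
            raise ValidationError(f"unknown pi constraint {constraint!r}")
        if component_mask is not None:
            pi = np.where(component_mask, pi, 0.0)
            total = pi.sum()
            if total <= 0:
                pi = np.where(component_mask, 1.0, 0.0)
                total = pi.sum()
            pi = pi / total
        new_pi[pid] = pi
    return new_pi


# ---------------------------------------------------------------------------
# constrained mean fitting


def _theta_to_param(theta: np.ndarray, constraint: str) -> MeanParameterization:
    if constraint == MU_EQ_LIN:
        return MeanParameterization(c_a=theta[0], c_b=theta[0], k=0.0)
    if constraint == MU_UNEQ_LIN:
        return MeanParameterization(c_a=theta[0], c_b=theta[1], k=0.0)
    if constraint == MU_EQ_QUAD:
        return MeanParameterization(c_a=theta[0], c_b=theta[0], k=theta[1])
    if constraint == MU_UNEQ_QUAD:
        return MeanParameterization(c_a=theta[0], c_b=theta[1], k=theta[2])
    raise ValidationError(f"not a constrained mean variant: {constraint!r}")


def _param_to_theta(param: MeanParameterization, constraint: str) -> np.ndarray:
    if constraint == MU_EQ_LIN:
        return np.array([param.c_a])
    if constraint == MU_UNEQ_LIN:
        return np.array([param.c_a, param.c_b])
    if constraint == MU_EQ_QUAD:
        return np.array([param.c_a, param.k])
    if constraint == MU_UNEQ_QUAD:
        return np.array([param.c_a, param.c_b, param.k])
    raise ValidationError(f"not a constrained mean variant: {constraint!r}")


_DEFAULT_THETA_SEEDS = {
    MU_EQ_LIN: [np.array([0.0]), np.array([0.3]), np.array([1.0])],
    MU_UNEQ_LIN: [np.zeros(2), np.array([0.5, 0.1]), np.array([0.1, 0.5])],
    MU_EQ_QUAD: [np.zeros(2), np.array([0.3, 0.1]), np.array([0.0, 0.3])],
    MU_UNEQ_QUAD: [np.zeros(3), np.array([0.5, 0.1, 0.1]),
                   np.array([0.1, 0.5, 0.1])],
}


def fit_mean_parameterization(weights: np.ndarray, targets: np.ndarray,
                              constraint: str,
                              current: MeanParameterization | None = None,
                              multi_start: bool = True
                              ) -> MeanParameterization:
    """Weighted least-squares fit of (c_a, c_b, k) to target means.

    Minimises ``sum_j W_j (target_j - mu_j(theta))^2`` over nonnegative
    parameters; the current parameterisation is always among the starts
    so the objective can never regress between EM iterations.
    """
    active = weights > 1e-12
    sw = np.sqrt(np.where(active, weights, 0.0))

    def residuals(theta):
        return sw * (targets - _theta_to_param(theta, constraint).mu())

    starts = []
    if current is not None:
        starts.append(_param_to_theta(current, constraint))
    if multi_start or current is None:
        starts.extend(_DEFAULT_THETA_SEEDS[constraint])

    best_param, best_obj = None, np.inf
    if current is not None:
        best_param = current
        best_obj = float(np.sum(residuals(_param_to_theta(current, constraint)) ** 2))
    for theta0 in starts:
        try:
            sol = least_squares(residuals, theta0, bounds=(0.0, np.inf),
                                method="trf", xtol=1e-12, ftol=1e-12)
        except Exception:  # pragma: no cover - optimizer failure
            continue
        obj = float(np.sum(sol.fun ** 2))
        if obj < best_obj - 1e-15:
            best_obj = obj
            best_param = _theta_to_param(sol.x, constraint)
    if best_param is None:
        raise EMError(f"mean parameterisation fit failed ({constraint})")
    return best_param


def m_step_mu_sigma(signals: MarkerSignals, posteriors: PosteriorMatrix,
                    mu_constraint: str,
                    current_param: MeanParameterization | None,
                    current_mu: np.ndarray,
                    var_floor: float = 1e-6,
                    multi_start: bool = True
                    ) -> tuple[np.ndarray, float, MeanParameterization | None]:
    """Update component means and the common variance."""
    obs = posteriors.observed
    post = posteriors.values[obs]
    y = signals.y[obs]
    weights = post.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ybar = (post * y[:, None]).sum(axis=0) / weights
    empty = weights <= 1e-12
    ybar = np.where(empty, current_mu, ybar)

    if mu_constraint == MU_FREE:
        mu = ybar.copy()
        param = None
    else:
        param = fit_mean_parameterization(weights, ybar, mu_constraint,
                                          current=current_param,
                                          multi_start=multi_start)
        mu = param.mu()

    sigma2 = float((post * (y[:, None] - mu[None, :]) ** 2).sum() / post.sum())
    return mu, max(sigma2, var_floor), param


# ---------------------------------------------------------------------------
# starting values


def naive_start_assignment(y: np.ndarray) -> np.ndarray:
    """Hard-assign each value to the nearest zero-background ideal mean."""
    return np.argmin(np.abs(y[:, None] - IDEAL_MU[None, :]), axis=1)


def default_start(signals: MarkerSignals, structure: PopulationStructure,
                  mu_constraint: str, pi_constraints: dict[str, str],
                  prior_dosages: dict[str, int] | None = None,
                  start_mu: np.ndarray | None = None) -> MixtureModel:
    """Starting model from naive clustering (or supplied means).

    Values are cut at the midpoints between the ideal means
    ``arcsin(sqrt(j/4))``; group means seed mu, the pooled within-group
    variance seeds sigma^2.  HW panels start at the plug-in allele
    frequency; F1 and fixed-parent populations start from the supplied
    parental dosages when available, otherwise uniform.
    """
    priors = prior_dosages or {}
    obs = signals.observed
    y = signals.y[obs]
    if y.size == 0:
        raise EMError(f"no observations for marker {signals.marker_id}")

    if start_mu is None:
        groups = naive_start_assignment(y)
        mu = IDEAL_MU.copy()
        for j in range(N_DOSAGES):
            sel = groups == j
            if sel.sum() >= 2:
                mu[j] = y[sel].mean()
        mu = np.sort(mu)
        resid = y - mu[groups]
        sigma2 = max(float(np.mean(resid ** 2)), 1e-4)
    else:
        mu = np.sort(np.asarray(start_mu, dtype=float))
        groups = np.argmin(np.abs(y[:, None] - mu[None, :]), axis=1)
        resid = y - mu[groups]
        sigma2 = max(float(np.mean(resid ** 2)), 1e-4)

    mean_param = None
    if mu_constraint != MU_FREE:
        counts = np.bincount(groups, minlength=N_DOSAGES).astype(float)
        mean_param = fit_mean_parameterization(np.maximum(counts, 1.0), mu,
                                               mu_constraint, current=None)
        mu = mean_param.mu()

    rows = _population_rows(signals, structure)
    pi: dict[str, np.ndarray] = {}
    for pid, constraint in pi_constraints.items():
        pop = structure.populations[pid]
        if constraint == P_FIXED and pid in priors:
            pi[pid] = spiked_proportions(priors[pid])
        elif constraint == P_HW:
            idx = rows[pid]
            ratios = signals.ratio[idx] if len(idx) else signals.ratio[obs]
            p = float(np.nanmean(ratios)) if len(ratios) else 0.5
            pi[pid] = hw_proportions(min(max(p, 0.0), 1.0))
        elif constraint == P_F1:
            par1, par2 = structure.parents_of(pid)
            if par1 in priors and par2 in priors:
                pi[pid] = np.asarray(
                    f1_segregation(priors[par1], priors[par2]).proportions)
            else:
                pi[pid] = np.full(N_DOSAGES, 1.0 / N_DOSAGES)
        else:
            pi[pid] = np.full(N_DOSAGES, 1.0 / N_DOSAGES)

    return MixtureModel(mu=mu, sigma2=sigma2, pi=pi,
                        mu_constraint=mu_constraint,
                        pi_constraint=dict(pi_constraints),
                        mean_param=mean_param)


# ---------------------------------------------------------------------------
# the EM loop


def run_em(signals: MarkerSignals, structure: PopulationStructure,
           mu_constraint: str, pi_constraints: dict[str, str],
           start: MixtureModel | None = None,
           config: EMConfig | None = None,
           component_mask: np.ndarray | None = None,
           parent_mode_overrides: dict[str, int] | None = None,
           prior_dosages: dict[str, int] | None = None
           ) -> tuple[MixtureModel, PosteriorMatrix]:
    """Alternate E and M steps until the log-likelihood converges.

    The observed-data log-likelihood is non-decreasing across iterations
    except through the discrete parental-mode plug-in of ``p_F1``; if a
    mode flip ever lowers it, the previous model is restored and the fit
    is declared converged.
    """
    config = config or EMConfig()
    if signals.n_observed < config.min_samples:
        raise EMError(
            f"marker {signals.marker_id}: {signals.n_observed} observations "
            f"< min_samples={config.min_samples}"
        )
    if start is None:
        start = default_start(signals, structure, mu_constraint,
                              pi_constraints, prior_dosages=prior_dosages)
    model = start.copy()
    model.mu_constraint = mu_constraint
    model.pi_constraint = dict(pi_constraints)
    if component_mask is not None:
        for pid in model.pi:
            masked = np.where(component_mask, model.pi[pid], 0.0)
            total = masked.sum()
            model.pi[pid] = (masked / total if total > 0
                             else np.where(component_mask, 1.0, 0.0)
                             / component_mask.sum())

    ll = observed_loglik(signals, structure, model)
    trace = [ll]
    converged = False
    n_iter = 0
    for n_iter in range(1, config.max_iter + 1):
        posteriors = e_step(signals, structure, model)
        new_pi = m_step_pi(posteriors, signals, structure, pi_constraints,
                           model.pi, parent_mode_overrides=parent_mode_overrides,
                           component_mask=component_mask)
        new_mu, new_sigma2, new_param = m_step_mu_sigma(
            signals, posteriors, mu_constraint, model.mean_param, model.mu,
            var_floor=config.var_floor,
            multi_start=(n_iter == 1))

        # keep labels ordered by mean; permute proportions to match
        order = np.argsort(new_mu, kind="stable")
        if not np.array_equal(order, np.arange(N_DOSAGES)):
            new_mu = new_mu[order]
            new_pi = {pid: pi[order] for pid, pi in new_pi.items()}

        candidate = model.copy()
        candidate.mu, candidate.sigma2 = new_mu, new_sigma2
        candidate.pi, candidate.mean_param = new_pi, new_param
        new_ll = observed_loglik(signals, structure, candidate)

        if new_ll < ll - 1e-9:
            # discrete p_F1 parental-mode flip lowered the likelihood
            logger.debug("marker %s: likelihood drop %.3g at iter %d; "
                         "keeping previous model", signals.marker_id,
                         ll - new_ll, n_iter)
            converged = True
            break
        model = candidate
        trace.append(new_ll)
        if abs(new_ll - ll) < config.tol:
            ll = new_ll
            converged = True
            break
        ll = new_ll

    model.loglik = ll
    model.loglik_trace = trace
    model.n_iter = n_iter
    model.converged = converged
    model.n_params = count_parameters(mu_constraint, pi_constraints,
                                      component_mask)
    model.bic = -2.0 * ll + model.n_params * np.log(signals.n_observed)
    return model, e_step(signals, structure, model)
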