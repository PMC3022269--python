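"""Maximum-likelihood estimation of double reduction, linkage and QTL effects.

The observed data are the marker gamete genotype and phenotype of each
pseudotest-backcross individual; the QTL gamete genotype is latent.  The
model is a 10-component normal mixture whose component weights are the
conditional QTL-genotype probabilities given the observed marker, derived
from the gamete-mode model.

Estimation (default, ``mode='profile'``) is a two-level scheme that
mirrors the hierarchy of the segregation model:

1. the marker double-reduction frequency has a closed-form MLE — the
   observed fraction of double-reduction marker genotypes;
2. the recombination fraction is profiled on a grid: at each candidate r
   the genotypic values and residual variance are fitted by an inner EM
   with the mixture weights held fixed, and the r maximising the profiled
   likelihood is refined locally.

The profile is used because the alternative — a single joint EM over the
nine free mode frequencies, ten means and the variance (``mode='em'``,
also implemented, with the posterior mode-count M-step and the implicit
r update) — maximises an extremely flat, overparameterised likelihood:
on simulated data it drifts along a ridge to label-scrambled optima even
when started at the truth, inflating the recombination estimate.  The
structured profile keeps the mixture weights on the two-parameter
mechanism surface at all times, which is what makes the recombination
fraction recoverable at realistic sample sizes.

E-step responsibilities, the mode-count M-step, the rate maps and the
mean/variance updates are exposed as standalone operations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.special import logsumexp

from .gametes import (
    MODE_INDEX,
    N_GAMETES,
    N_MODES,
    build_joint_table,
    chromatid_modes,
    implied_r,
    phi,
    psi,
    validate_modes,
)
from .quantgen import NullConstraint, QTLEffects, means_to_effects
from .simulate import BackcrossDataset

__all__ = [
    "EMOptions",
    "FitResult",
    "log_likelihood",
    "log_likelihood_joint",
    "e_step",
    "m_step_g",
    "m_step_rates",
    "m_step_means",
    "m_step_variance",
    "recombination_count_rows",
    "fit",
    "fit_constrained",
]

_LOG_2PI = float(np.log(2.0 * np.pi))
_TINY = 1e-300


# ---------------------------------------------------------------------------
# options and results


@dataclass(frozen=True)
class EMOptions:
    """Tuning knobs for the fit.

    ``tol`` is the inner-EM convergence threshold on the maximum absolute
    parameter change; ``max_iter`` bounds each inner EM.  ``r_grid_step``
    sets the profile grid spacing on [0, 1/2] and ``refine_points`` the
    resolution of the local refinement pass around the best grid point.
    ``n_starts`` adds randomly jittered mean initializations (the grid
    itself is already a systematic multi-start in r).  ``fix_r`` skips
    profiling and fits at the given recombination fraction.
    ``force_no_double_reduction`` fits the traditional model that ignores
    double reduction (heterozygote gametes only).  ``mode='em'`` selects
    the classic joint EM over free mode frequencies; ``r_update`` chooses
    its r step ('solve': inner fixed point; 'one_step': single
    substitution at the previous iterate).
    """

    max_iter: int = 500
    tol: float = 1e-7
    n_starts: int = 1
    variance_floor: float = 1e-8
    r_grid_step: float = 0.02
    refine_points: int = 7
    force_no_double_reduction: bool = False
    fix_r: float | None = None
    mode: str = "profile"
    r_update: str = "solve"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tol <= 0 or self.max_iter < 1 or self.n_starts < 1:
            raise ValueError("tol > 0, max_iter >= 1, n_starts >= 1 required")
        if self.variance_floor <= 0:
            raise ValueError("variance_floor must be positive")
        if not 0.005 <= self.r_grid_step <= 0.25:
            raise ValueError("r_grid_step must lie in [0.005, 0.25]")
        if self.mode not in ("profile", "em"):
            raise ValueError("mode must be 'profile' or 'em'")
        if self.r_update not in ("solve", "one_step"):
            raise ValueError("r_update must be 'solve' or 'one_step'")


@dataclass
class FitResult:
    """Maximum-likelihood estimates and convergence diagnostics."""

    g_hat: np.ndarray              # posterior-expected mode frequencies
    alpha_hat: float
    beta_hat: float
    r_hat: float
    means_hat: np.ndarray | None
    effects_hat: QTLEffects | None
    sigma2_hat: float
    loglik: float                  # joint marker + phenotype log-likelihood
    loglik_conditional: float      # phenotype mixture log-likelihood given markers
    n_iter: int
    converged: bool
    start_used: int = 0
    floor_activated: bool = False
    n_dropped: int = 0             # individuals excluded (no-DR model only)
    constraint: str | None = None

    def to_dict(self) -> dict:
        eff = None
        if self.effects_hat is not None:
            from .quantgen import EFFECT_NAMES
            eff = dict(zip(EFFECT_NAMES, map(float, self.effects_hat.to_array())))
        means = None
        if self.means_hat is not None:
            means = [None if not np.isfinite(x) else float(x)
                     for x in self.means_hat]
        return {
            "g_hat": [float(x) for x in self.g_hat],
            "alpha_hat": float(self.alpha_hat),
            "beta_hat": float(self.beta_hat),
            "r_hat": float(self.r_hat),
            "means_hat": means,
            "effects_hat": eff,
            "sigma2_hat": float(self.sigma2_hat),
            "loglik": float(self.loglik),
            "loglik_conditional": float(self.loglik_conditional),
            "n_iter": int(self.n_iter),
            "converged": bool(self.converged),
            "start_used": int(self.start_used),
            "floor_activated": bool(self.floor_activated),
            "n_dropped": int(self.n_dropped),
            "constraint": self.constraint,
        }


# ---------------------------------------------------------------------------
# elementary operations (exposed for testing and for the classic EM)


def _log_normal(y: np.ndarray, means: np.ndarray, sigma2: float) -> np.ndarray:
    """n x k matrix of log N(y_i; mu_j, sigma^2)."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive; raise the variance floor")
    z = (y[:, None] - means[None, :]) ** 2 / sigma2
    return -0.5 * (z + np.log(sigma2) + _LOG_2PI)


def _conditional_rows(g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    joint = build_joint_table(g)
    marg = joint.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        cond = np.where(marg > 0, joint / marg, 0.0)
    return cond, marg[:, 0]


def _check_markers_supported(data: BackcrossDataset, marg: np.ndarray) -> None:
    if np.any(marg[np.unique(data.marker)] == 0.0):
        raise ValueError("observed marker genotype has zero frequency under g")


def log_likelihood(data: BackcrossDataset, g, means, sigma2: float) -> float:
    """Conditional mixture log-likelihood of the phenotypes given the markers.

    Sum over individuals of ``log sum_j pi[j | marker_i] N(y_i; mu_j,
    sigma^2)``.
    """
    g = validate_modes(g)
    means = np.asarray(means, dtype=float)
    cond, marg = _conditional_rows(g)
    _check_markers_supported(data, marg)
    log_prior = np.log(cond[data.marker] + _TINY)
    return float(logsumexp(log_prior + _log_normal(data.phenotype, means, sigma2),
                           axis=1).sum())


def log_likelihood_joint(data: BackcrossDataset, g, means, sigma2: float) -> float:
    """Joint log-likelihood of markers and phenotypes.

    Adds the marker-marginal term (which depends on g only through the
    marker DR frequency) to the conditional mixture log-likelihood; this
    is the quantity the EM variants increase monotonically.
    """
    g = validate_modes(g)
    joint = build_joint_table(g)
    marg = joint.sum(axis=1)
    _check_markers_supported(data, marg)
    marker_term = float(np.log(marg[data.marker]).sum())
    return marker_term + log_likelihood(data, g, means, sigma2)


def e_step(data: BackcrossDataset, g, means, sigma2: float) -> np.ndarray:
    """Posterior responsibilities Theta (n x 10), computed in log space.

    Row i applies Bayes' rule over QTL genotypes with individual i's
    marker-conditional prior row; entries with zero prior stay exactly 0.
    """
    g = validate_modes(g)
    means = np.asarray(means, dtype=float)
    cond, marg = _conditional_rows(g)
    _check_markers_supported(data, marg)
    prior = cond[data.marker]
    log_w = np.log(prior + _TINY) + _log_normal(data.phenotype, means, sigma2)
    log_w -= logsumexp(log_w, axis=1, keepdims=True)
    theta = np.exp(log_w)
    theta[prior == 0.0] = 0.0
    return theta / theta.sum(axis=1, keepdims=True)


def m_step_g(data: BackcrossDataset, posteriors: np.ndarray) -> np.ndarray:
    """Mode-frequency update: posterior-expected mode counts divided by n.

    Each joint-table cell (marker l, QTL j) carries exactly one mode
    label, so summing responsibilities cell-wise partitions the total
    mass n and the estimate sums to 1.
    """
    modes_by_marker = MODE_INDEX[data.marker]  # n x 10 mode label per cell
    g = np.zeros(N_MODES)
    np.add.at(g, modes_by_marker.ravel(), posteriors.ravel())
    return g / data.n


def m_step_rates(g_hat, r_prev: float | None = None,
                 r_update: str = "solve") -> tuple[float, float, float]:
    """(alpha, beta, r) from an updated mode vector.

    alpha and beta are the double-reduction sums of the mode vector.
    ``'solve'`` finds the exact root of the implicit r equation;
    ``'one_step'`` substitutes phi, psi at ``r_prev``.  An inadmissible
    mode vector clamps r to [0, 1/2] with a warning.
    """
    g = validate_modes(g_hat)
    alpha = float(g[0] + g[1] + g[4] + g[5])
    beta = float(g[0] + g[1] + g[2] + g[3])
    if r_update == "one_step" and r_prev is not None:
        r = 0.5 * (g[2] + g[4] + 2.0 * (g[1] + g[3] + g[5] + g[8])
                   + 2.0 * phi(r_prev) * g[6] + (1.0 + psi(r_prev)) * g[7])
        if not 0.0 <= r <= 0.5:
            warnings.warn("one-step r update left [0, 0.5]; clamping", stacklevel=2)
            r = min(max(r, 0.0), 0.5)
        return alpha, beta, float(r)
    try:
        r = implied_r(g, strict=True)
    except Exception:
        warnings.warn("mode vector inadmissible; clamping r to [0, 0.5]",
                      stacklevel=2)
        r = implied_r(g, strict=False)
    return alpha, beta, float(r)


def m_step_means(data: BackcrossDataset, posteriors: np.ndarray,
                 previous: np.ndarray | None = None) -> np.ndarray:
    """Responsibility-weighted phenotype means per QTL genotype.

    A genotype with zero total responsibility keeps its previous value
    (or the grand mean when no previous value exists).
    """
    w = posteriors.sum(axis=0)
    t = posteriors.T @ data.phenotype
    means = np.divide(t, w, out=np.zeros_like(t), where=w > 0)
    empty = w == 0
    if np.any(empty):
        fallback = previous if previous is not None \
            else np.full(w.size, data.phenotype.mean())
        means[empty] = np.asarray(fallback, dtype=float)[empty]
    return means


def m_step_variance(data: BackcrossDataset, posteriors: np.ndarray, means,
                    floor: float = 0.0) -> float:
    """Responsibility-weighted mean squared residual, floored at ``floor``."""
    means = np.asarray(means, dtype=float)
    resid2 = (data.phenotype[:, None] - means[None, :]) ** 2
    sigma2 = float((posteriors * resid2).sum() / data.n)
    return max(sigma2, floor)


def recombination_count_rows(r: float) -> np.ndarray:
    """10x10 expected recombination counts per joint cell at the given r.

    The posterior-weighted average of these counts divided by 2 is the
    EM update for r under the chromatid mechanism (recombination events
    and mixed-configuration labels are the latent variables), and equals
    the mode-frequency form of the r estimator.
    """
    per_mode = np.array([0.0, 2.0, 1.0, 2.0, 1.0, 2.0,
                         2.0 * phi(r), 1.0 + psi(r), 2.0])
    return per_mode[MODE_INDEX]


# ---------------------------------------------------------------------------
# shared pieces


def _clamped_alpha(data: BackcrossDataset) -> tuple[float, float]:
    """Observed marker-DR fraction and a version clamped away from {0, 1}."""
    alpha0 = float(np.mean(data.marker < 4))
    return alpha0, min(max(alpha0, 1e-4), 1.0 - 1e-4)


def _initial_means(data: BackcrossDataset, prior_rows: np.ndarray) -> np.ndarray:
    """Hard-assign each individual to its modal prior genotype and take
    group means; empty genotypes start at the grand mean."""
    assign = prior_rows.argmax(axis=1)
    k = prior_rows.shape[1]
    means = np.full(k, data.phenotype.mean())
    for j in range(k):
        sel = assign == j
        if sel.any():
            means[j] = data.phenotype[sel].mean()
    return means


def _wls_means(posteriors: np.ndarray, y: np.ndarray,
               design: np.ndarray) -> np.ndarray:
    """Weighted least-squares mean update onto a null-constraint design."""
    w = posteriors.sum(axis=0)
    t = posteriors.T @ y
    A = design.T @ (w[:, None] * design)
    b = design.T @ t
    if np.linalg.matrix_rank(A) < design.shape[1]:
        raise np.linalg.LinAlgError(
            "weighted constraint design is rank deficient "
            "(a free mean parameter has no responsibility mass)")
    return design @ np.linalg.solve(A, b)


def _means_em_fixed_prior(y: np.ndarray, log_prior: np.ndarray,
                          means0: np.ndarray, sigma20: float, floor: float,
                          options: EMOptions,
                          design: np.ndarray | None = None,
                          ) -> tuple[float, np.ndarray, float, int, bool]:
    """Inner EM for (means, sigma^2) with the mixture weights held fixed.

    Returns (conditional log-likelihood, means, sigma2, iterations,
    converged).  With ``design`` the mean update is the weighted
    least-squares projection onto the constraint.
    """
    means = means0.copy()
    sigma2 = max(sigma20, floor)
    prev = None
    converged = False
    it = 0
    for it in range(1, options.max_iter + 1):
        log_w = log_prior + _log_normal(y, means, sigma2)
        log_w -= logsumexp(log_w, axis=1, keepdims=True)
        theta = np.exp(log_w)
        w = theta.sum(axis=0)
        if design is None:
            t = theta.T @ y
            means = np.where(w > 0,
                             np.divide(t, w, out=np.zeros_like(t), where=w > 0),
                             means)
        else:
            means = _wls_means(theta, y, design)
        sigma2 = max(float((theta * (y[:, None] - means[None, :]) ** 2).sum()
                           / y.size), floor)
        cur = np.concatenate([[sigma2], means])
        if prev is not None and np.abs(cur - prev).max() < options.tol:
            converged = True
            break
        prev = cur
    ll = float(logsumexp(log_prior + _log_normal(y, means, sigma2), axis=1).sum())
    return ll, means, sigma2, it, converged


# ---------------------------------------------------------------------------
# default fit: profile likelihood over r on the chromatid-model surface


def _profile_grid(options: EMOptions) -> np.ndarray:
    n_pts = int(round(0.5 / options.r_grid_step)) + 1
    return np.linspace(0.0, 0.5, n_pts)


def _log_prior_for(data: BackcrossDataset, alpha: float, r: float) -> np.ndarray:
    cond, marg = _conditional_rows(chromatid_modes(alpha, r))
    _check_markers_supported(data, marg)
    return np.log(cond[data.marker] + _TINY)


def _fit_profile(data: BackcrossDataset, options: EMOptions,
                 constraint: NullConstraint | None) -> FitResult:
    y = data.phenotype
    var_y = float(np.var(y))
    floor = options.variance_floor * var_y if var_y > 0 else options.variance_floor
    alpha0, alpha = _clamped_alpha(data)
    rng = np.random.default_rng(options.seed)
    sd_y = np.sqrt(var_y) if var_y > 0 else 1.0

    design = None if constraint is None else constraint.design
    cond_mid, _ = _conditional_rows(chromatid_modes(alpha, 0.25))
    base_means = _initial_means(data, cond_mid[data.marker])
    if design is not None:
        # start inside the constrained space
        proj = design @ np.linalg.lstsq(design, base_means, rcond=None)[0]
        base_means = proj

    best = None
    for start in range(options.n_starts):
        means0 = base_means.copy()
        if start > 0:
            means0 = means0 + rng.normal(0.0, 0.5 * sd_y, size=means0.size)
            if design is not None:
                means0 = design @ np.linalg.lstsq(design, means0, rcond=None)[0]
        res = _profile_scan(data, options, alpha, means0, var_y, floor, design)
        if best is None or res[0] > best[0]:
            best = (*res, start)
    ll_cond, r_hat, means, sigma2, n_iter, converged, start_used = best

    theta = e_step(data, chromatid_modes(alpha, r_hat), means, sigma2)
    g_hat = m_step_g(data, theta)
    beta_hat = float(g_hat[0] + g_hat[1] + g_hat[2] + g_hat[3])
    marker_term = float(np.log(
        build_joint_table(chromatid_modes(alpha, r_hat)).sum(axis=1)[data.marker]
    ).sum())
    return FitResult(
        g_hat=g_hat, alpha_hat=alpha0, beta_hat=beta_hat, r_hat=r_hat,
        means_hat=means, effects_hat=means_to_effects(means),
        sigma2_hat=sigma2, loglik=marker_term + ll_cond,
        loglik_conditional=ll_cond, n_iter=n_iter, converged=converged,
        start_used=start_used, floor_activated=sigma2 == floor,
        constraint=None if constraint is None else constraint.kind)


def _profile_scan(data: BackcrossDataset, options: EMOptions, alpha: float,
                  means0: np.ndarray, var_y: float, floor: float,
                  design: np.ndarray | None):
    y = data.phenotype
    sigma20 = var_y / 2.0 if var_y > 0 else 1.0

    if options.fix_r is not None:
        lp = _log_prior_for(data, alpha, options.fix_r)
        ll, m, s2, it, conv = _means_em_fixed_prior(
            y, lp, means0, sigma20, floor, options, design)
        return ll, float(options.fix_r), m, s2, it, conv

    # flat-profile shortcut: under the all-means-equal constraint the
    # phenotype likelihood does not depend on r at all
    if design is not None and design.shape[1] == 1 \
            and np.allclose(design, design[0, 0]):
        lp = _log_prior_for(data, alpha, 0.25)
        ll, m, s2, it, conv = _means_em_fixed_prior(
            y, lp, means0, sigma20, floor, options, design)
        return ll, 0.25, m, s2, it, conv

    grid = _profile_grid(options)
    # Every grid point is fitted from the same data-driven start: warm
    # starting along the grid is faster but makes the profile path
    # dependent and biases the argmax.  The sweep tolerance is mildly
    # relaxed; the incumbent is re-converged tightly during refinement.
    sweep_options = replace(options, tol=max(options.tol, 1e-6))
    best = None
    total_iter = 0
    for r in grid:
        lp = _log_prior_for(data, alpha, r)
        ll, means, sigma2, it, _ = _means_em_fixed_prior(
            y, lp, means0, sigma20, floor, sweep_options, design)
        total_iter += it
        if best is None or ll > best[0]:
            best = (ll, float(r), means.copy(), sigma2)
    ll_b, r_b, means_b, s2_b = best
    all_conv = True
    if options.refine_points >= 2:
        ll_b = -np.inf  # re-evaluate the incumbent at the tight tolerance
        lo = max(r_b - options.r_grid_step, 0.0)
        hi = min(r_b + options.r_grid_step, 0.5)
        for r in np.linspace(lo, hi, options.refine_points):
            lp = _log_prior_for(data, alpha, r)
            ll, m, s2, it, conv = _means_em_fixed_prior(
                y, lp, means_b, s2_b, floor, options, design)
            total_iter += it
            all_conv &= conv
            if ll > ll_b + 1e-12:
                ll_b, r_b, means_b, s2_b = ll, float(r), m, s2
    return ll_b, r_b, means_b, s2_b, total_iter, all_conv


# ---------------------------------------------------------------------------
# classic joint EM over free mode frequencies (mode='em')


def _fit_free_g(data: BackcrossDataset, options: EMOptions,
                constraint: NullConstraint | None) -> FitResult:
    y = data.phenotype
    var_y = float(np.var(y))
    floor = options.variance_floor * var_y if var_y > 0 else options.variance_floor
    alpha0, alpha = _clamped_alpha(data)
    rng = np.random.default_rng(options.seed)
    sd_y = np.sqrt(var_y) if var_y > 0 else 1.0

    g0 = chromatid_modes(alpha, 0.25)
    g0 = 0.98 * g0 + 0.02 / N_MODES  # zero modes are absorbing in EM
    cond0, _ = _conditional_rows(g0)
    base_means = _initial_means(data, cond0[data.marker])
    design = None if constraint is None else constraint.design
    if design is not None:
        base_means = design @ np.linalg.lstsq(design, base_means, rcond=None)[0]

    best: FitResult | None = None
    for start in range(options.n_starts):
        means = base_means.copy()
        if start > 0:
            means = means + rng.normal(0.0, 0.5 * sd_y, size=N_GAMETES)
            if design is not None:
                means = design @ np.linalg.lstsq(design, means, rcond=None)[0]
        result = _em_loop_free(data, options, design, g0.copy(), means,
                               var_y / 2.0 if var_y > 0 else 1.0, floor, start)
        if best is None or result.loglik > best.loglik:
            best = result
    assert best is not None
    if constraint is not None:
        best.constraint = constraint.kind
    return best


def _em_loop_free(data: BackcrossDataset, options: EMOptions,
                  design: np.ndarray | None, g: np.ndarray,
                  means: np.ndarray, sigma2: float, floor: float,
                  start: int) -> FitResult:
    sigma2 = max(sigma2, floor)
    floor_hit = False
    r_hat = 0.25
    alpha_hat = beta_hat = 0.0
    loglik = -np.inf
    converged = False
    it = 0
    for it in range(1, options.max_iter + 1):
        theta = e_step(data, g, means, sigma2)
        g = m_step_g(data, theta)
        alpha_hat, beta_hat, r_hat = m_step_rates(g, r_hat, options.r_update)
        if design is None:
            means = m_step_means(data, theta, previous=means)
        else:
            means = _wls_means(theta, data.phenotype, design)
        new_sigma2 = m_step_variance(data, theta, means, floor=floor)
        floor_hit = floor_hit or new_sigma2 == floor
        sigma2 = new_sigma2
        new_loglik = log_likelihood_joint(data, g, means, sigma2)
        if np.isfinite(loglik) and abs(new_loglik - loglik) < options.tol:
            loglik = new_loglik
            converged = True
            break
        loglik = new_loglik
    return FitResult(
        g_hat=g, alpha_hat=alpha_hat, beta_hat=beta_hat, r_hat=r_hat,
        means_hat=means, effects_hat=means_to_effects(means),
        sigma2_hat=sigma2, loglik=loglik,
        loglik_conditional=log_likelihood(data, g, means, sigma2),
        n_iter=it, converged=converged, start_used=start,
        floor_activated=floor_hit)


# ---------------------------------------------------------------------------
# traditional model ignoring double reduction


def _fit_no_dr(data: BackcrossDataset, options: EMOptions) -> FitResult:
    """Traditional model: no double reduction, heterozygote gametes only.

    Individuals with double-reduction marker genotypes have zero
    probability under this model and are dropped with a warning — this is
    precisely the misspecification the mode is meant to expose.
    """
    keep = data.marker >= 4
    dropped = int((~keep).sum())
    if dropped:
        warnings.warn(
            f"no-double-reduction model: dropping {dropped} individuals with "
            "double-reduction marker genotypes (zero prior mass)", stacklevel=3)
    sub = BackcrossDataset(marker=data.marker[keep], phenotype=data.phenotype[keep],
                           qtl=None if data.qtl is None else data.qtl[keep])
    if sub.n < 10:
        raise ValueError("too few non-DR individuals for the no-DR model")
    y = sub.phenotype
    var_y = float(np.var(y))
    floor = options.variance_floor * var_y if var_y > 0 else options.variance_floor
    markers6 = sub.marker - 4

    def log_prior_at(r: float) -> np.ndarray:
        cond, _ = _conditional_rows(chromatid_modes(0.0, r))
        return np.log(cond[4:, 4:][markers6] + _TINY)

    means0 = _initial_means(sub, np.exp(log_prior_at(0.25)))
    grid = _profile_grid(options)
    best = None
    means, sigma2 = means0, var_y / 2.0 if var_y > 0 else 1.0
    total_iter = 0
    all_conv = True
    for r in grid:
        ll, means, sigma2, it, conv = _means_em_fixed_prior(
            y, log_prior_at(r), means, sigma2, floor, options)
        total_iter += it
        all_conv &= conv
        if best is None or ll > best[0]:
            best = (ll, float(r), means.copy(), sigma2)
    ll_b, r_b, means6, s2_b = best

    means_full = np.full(N_GAMETES, np.nan)
    means_full[4:] = means6
    g79 = chromatid_modes(0.0, r_b)
    return FitResult(
        g_hat=g79, alpha_hat=0.0, beta_hat=float(g79[:4].sum()), r_hat=r_b,
        means_hat=means_full, effects_hat=None, sigma2_hat=s2_b,
        loglik=ll_b + sub.n * np.log(1.0 / 6.0), loglik_conditional=ll_b,
        n_iter=total_iter, converged=all_conv, n_dropped=dropped)


# ---------------------------------------------------------------------------
# public entry points


def fit(data: BackcrossDataset, options: EMOptions | None = None) -> FitResult:
    """Maximum-likelihood fit of double reduction, linkage and QTL effects.

    Default: marker DR frequency analytically, recombination fraction by
    grid-plus-refinement profile likelihood with an inner EM for the
    genotypic values at each candidate r.  See :class:`EMOptions` for the
    classic free-mode joint EM and the no-double-reduction model.
    """
    options = options or EMOptions()
    if options.force_no_double_reduction:
        return _fit_no_dr(data, options)
    if options.mode == "em":
        return _fit_free_g(data, options, None)
    return _fit_profile(data, options, None)


def fit_constrained(data: BackcrossDataset, constraint: NullConstraint,
                    options: EMOptions | None = None) -> FitResult:
    """Fit with the genotype means confined to a null-constraint subspace.

    Identical to :func:`fit` except the inner mean update is a
    responsibility-weighted least-squares projection onto
    ``constraint.design``.
    """
    options = options or EMOptions()
    if options.force_no_double_reduction:
        raise ValueError("constrained fits are not defined for the no-DR model")
    if options.mode == "em":
        return _fit_free_g(data, options, constraint)
    return _fit_profile(data, options, constraint)
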