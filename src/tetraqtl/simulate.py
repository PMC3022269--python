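"""Pseudotest-backcross simulator for a multivalent tetraploid marker-QTL pair.

A heterozygous quadrivalent tetraploid crossed to a homozygous tester
yields progeny whose genotypes are the parental gametes, so one row per
individual carries a fully informative marker gamete genotype, the latent
QTL gamete genotype and a quantitative phenotype.  Joint (marker, QTL)
genotypes are drawn from the 100-cell joint table of the gamete-mode
model; phenotypes add normal noise scaled to a target heritability.

By default gametes follow the chromatid-transmission mechanism
(:func:`tetraqtl.gametes.chromatid_modes`), under which the QTL
double-reduction frequency is a derived function of (alpha, r).  For
explicitly unequal double reduction, :func:`construct_g` provides a
documented three-parameter mode family that reproduces exactly the
quantities the estimator is defined through (alpha, beta and r as
functions of g, and the joint-table cell structure), subject to the
admissibility bound r >= |beta - alpha| / 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import gametes
from .gametes import (
    GAMETE_PAIRS,
    N_GAMETES,
    build_joint_table,
    chromatid_modes,
    gamete_labels,
    implied_r,
    phi,
    psi,
)
from .quantgen import EFFECT_NAMES, QTLEffects, effects_to_means

__all__ = [
    "FeasibilityError",
    "SimulationConfig",
    "BackcrossDataset",
    "ReplicationSummary",
    "construct_g",
    "min_feasible_r",
    "genetic_variance",
    "error_variance",
    "simulate_dataset",
    "replicate_study",
]


class FeasibilityError(ValueError):
    """Raised when no admissible mode vector exists for (alpha, beta, r)."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated pseudotest-backcross experiment.

    Defaults follow the reference Monte-Carlo design: overall mean 1,
    additive effects 0.6, dominance effects 0.5, and matched double
    reduction at marker and QTL.  With ``beta=None`` (default) gametes
    follow the chromatid-transmission mechanism, under which the QTL
    double-reduction frequency is the derived quantity beta(alpha, r)
    (equal to alpha at r = 0); an explicit ``beta`` switches to the
    general three-parameter mode family.
    """

    n: int = 400
    alpha: float = 0.3
    beta: float | None = None  # defaults to alpha (same DR at marker and QTL)
    r: float = 0.05
    effects: QTLEffects = field(default_factory=lambda: QTLEffects(
        mu=1.0, a1=0.6, a2=0.6, a3=0.6,
        d12=0.5, d13=0.5, d14=0.5, d23=0.5, d24=0.5, d34=0.5))
    h2: float = 0.4
    seed: int = 0
    reps: int = 1000

    def __post_init__(self) -> None:
        if self.n < 10:
            raise ValueError("need at least 10 individuals")
        for name in ("alpha", "beta"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 <= self.r <= 0.5:
            raise ValueError(f"r must lie in [0, 0.5], got {self.r}")
        if not 0.0 < self.h2 < 1.0:
            raise ValueError(f"heritability must lie strictly in (0, 1), got {self.h2}")

    @property
    def beta_effective(self) -> float:
        """QTL double-reduction frequency actually realized by the gametes."""
        if self.beta is None:
            g = chromatid_modes(self.alpha, self.r)
            return float(g[:4].sum())
        return self.beta

    def mode_vector(self) -> np.ndarray:
        """The gamete-mode frequencies these conditions simulate from."""
        if self.beta is None:
            return chromatid_modes(self.alpha, self.r)
        return construct_g(self.alpha, self.beta, self.r)


@dataclass
class BackcrossDataset:
    """Per-individual marker gamete genotype, phenotype and latent QTL genotype.

    ``marker`` and ``qtl`` hold canonical gamete indices (0..9);
    ``qtl`` is only available for simulated data and is never used by the
    estimator (it exists for oracle checks).
    """

    marker: np.ndarray
    phenotype: np.ndarray
    qtl: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.marker = np.asarray(self.marker, dtype=np.int64)
        self.phenotype = np.asarray(self.phenotype, dtype=float)
        if self.marker.shape != self.phenotype.shape or self.marker.ndim != 1:
            raise ValueError("marker and phenotype must be equal-length 1-d arrays")
        if self.marker.min(initial=0) < 0 or self.marker.max(initial=0) >= N_GAMETES:
            raise ValueError("marker codes must lie in 0..9")
        if not np.all(np.isfinite(self.phenotype)):
            raise ValueError("phenotypes must be finite")
        if self.qtl is not None:
            self.qtl = np.asarray(self.qtl, dtype=np.int64)
            if self.qtl.shape != self.marker.shape:
                raise ValueError("qtl must match marker length")

    @property
    def n(self) -> int:
        return self.marker.size

    def to_frame(self) -> pd.DataFrame:
        mlab = gamete_labels("M")
        out = pd.DataFrame({
            "id": np.arange(1, self.n + 1),
            "marker": [mlab[m] for m in self.marker],
            "phenotype": self.phenotype,
        })
        if self.qtl is not None:
            qlab = gamete_labels("Q")
            out.insert(2, "qtl_true", [qlab[q] for q in self.qtl])
        return out


def _modes_from_rho(alpha: float, beta: float, rho: float) -> np.ndarray:
    """Mode vector for DR frequencies (alpha, beta) and recombination intensity rho.

    The double-reduction overlap interpolates between full coincidence
    min(alpha, beta) at rho = 0 (tight linkage: a double reduction spans
    both loci) and independence alpha*beta as recombination decouples the
    loci (lam = 1 - (1-rho)^2, the chance of at least one recombinant
    chromatid).  Within each DR class the mass splits over the available
    recombinant counts with binomial(2, rho) weights.
    """
    lam = 1.0 - (1.0 - rho) ** 2
    m11 = (1.0 - lam) * min(alpha, beta) + lam * alpha * beta
    m_qtl = beta - m11      # DR at QTL only -> modes g3 (1 rec), g4 (2 rec)
    m_marker = alpha - m11  # DR at marker only -> g5, g6
    m_none = 1.0 - alpha - beta + m11
    w0, w1, w2 = (1.0 - rho) ** 2, 2.0 * rho * (1.0 - rho), rho * rho
    g = np.zeros(9)
    both = w0 + w2
    g[0] = m11 * (w0 / both if both > 0 else 1.0)
    g[1] = m11 - g[0]
    # classes restricted to counts {1, 2}: weights 2(1-rho) : rho
    denom = 2.0 - rho
    g[2] = m_qtl * (2.0 * (1.0 - rho) / denom)
    g[3] = m_qtl - g[2]
    g[4] = m_marker * (2.0 * (1.0 - rho) / denom)
    g[5] = m_marker - g[4]
    g[6] = m_none * w0
    g[7] = m_none * w1
    g[8] = m_none * w2
    return g


def _r_residual(alpha: float, beta: float, rho: float, r: float) -> float:
    """r minus the fixed-point right-hand side evaluated at the target r."""
    g = _modes_from_rho(alpha, beta, rho)
    rhs = 0.5 * (g[2] + g[4] + 2.0 * (g[1] + g[3] + g[5] + g[8])
                 + 2.0 * phi(r) * g[6] + (1.0 + psi(r)) * g[7])
    return r - rhs


def min_feasible_r(alpha: float, beta: float, tol: float = 1e-12) -> float:
    """Smallest recombination fraction admissible for the given DR pair.

    Unequal double reduction at two linked loci forces recombination:
    any admissible mode vector satisfies 2r >= |beta - alpha|, and the
    constructor attains that bound as rho -> 0.
    """
    lo, hi = 0.0, 0.5
    if _r_residual(alpha, beta, 0.0, 0.0) >= 0.0:
        return 0.0
    if _r_residual(alpha, beta, 0.0, 0.5) < 0.0:
        raise FeasibilityError(
            f"no admissible recombination fraction for alpha={alpha}, beta={beta}")
    return float(brentq(lambda r: _r_residual(alpha, beta, 0.0, r), lo, hi, xtol=tol))


def construct_g(alpha: float, beta: float, r: float) -> np.ndarray:
    """Mode vector with marker DR alpha, QTL DR beta and recombination r.

    Solves the latent recombination intensity rho so that the implied
    recombination fraction of the resulting mode vector equals ``r``
    exactly (to root-finder precision).  Raises :class:`FeasibilityError`
    when the target r is below the admissibility bound
    ``min_feasible_r(alpha, beta)`` (in particular r < |beta - alpha| / 2
    is inadmissible for *any* mode vector) or beyond the family's upper
    reach near r = 1/2.
    """
    for name, v in (("alpha", alpha), ("beta", beta)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    if not 0.0 <= r <= 0.5:
        raise ValueError(f"r must lie in [0, 0.5], got {r}")

    f0 = _r_residual(alpha, beta, 0.0, r)
    if f0 < 0.0:
        raise FeasibilityError(
            f"r={r} is not attainable with alpha={alpha}, beta={beta}; "
            f"feasible range starts at r={min_feasible_r(alpha, beta):.6f}")
    if f0 == 0.0:
        rho = 0.0
    else:
        f1 = _r_residual(alpha, beta, 1.0, r)
        if f1 > 0.0:
            raise FeasibilityError(
                f"r={r} exceeds the constructor's reach for alpha={alpha}, "
                f"beta={beta}")
        rho = float(brentq(lambda x: _r_residual(alpha, beta, x, r),
                           0.0, 1.0, xtol=1e-14))
    g = _modes_from_rho(alpha, beta, rho)
    g = np.clip(g, 0.0, None)
    return g / g.sum()


def genetic_variance(effects: QTLEffects, beta: float) -> float:
    """Variance of the QTL genotypic values over the gamete-genotype distribution.

    QTL gamete frequencies are beta/4 for each DR homozygote and
    (1 - beta)/6 for each heterozygote.
    """
    means = effects_to_means(effects)
    w = gametes.marker_marginals(beta)  # same DR/non-DR split applies to QTL gametes
    mean = w @ means
    return float(w @ (means - mean) ** 2)


def error_variance(sigma_g2: float, h2: float) -> float:
    """Residual variance giving heritability h2: sigma^2 = sigma_g^2 (1-h2)/h2."""
    if not 0.0 < h2 < 1.0:
        raise ValueError(f"heritability must lie strictly in (0, 1), got {h2}")
    if sigma_g2 < 0.0:
        raise ValueError("genetic variance must be nonnegative")
    if sigma_g2 == 0.0:
        warnings.warn("zero genetic variance: trait is pure noise-free constant",
                      stacklevel=2)
        return 0.0
    return sigma_g2 * (1.0 - h2) / h2


def simulate_dataset(config: SimulationConfig,
                     rng: np.random.Generator | None = None) -> BackcrossDataset:
    """Draw one pseudotest-backcross dataset under ``config``.

    (marker, QTL) gamete pairs are multinomial draws from the 100-cell
    joint table; phenotype = genotypic value + N(0, sigma^2) with sigma^2
    set by the heritability.  Deterministic given ``config.seed`` (or an
    explicitly supplied generator).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    beta = config.beta_effective
    g = config.mode_vector()
    joint = build_joint_table(g).ravel()
    cells = rng.choice(joint.size, size=config.n, p=joint / joint.sum())
    marker, qtl = np.divmod(cells, N_GAMETES)
    means = effects_to_means(config.effects)
    sigma2 = error_variance(genetic_variance(config.effects, beta), config.h2)
    y = means[qtl] + rng.normal(0.0, np.sqrt(sigma2), size=config.n)
    return BackcrossDataset(marker=marker, phenotype=y, qtl=qtl)


@dataclass
class ReplicationSummary:
    """Monte-Carlo means and SDs of the MLEs over simulation replicates."""

    config: SimulationConfig
    estimates: pd.DataFrame        # one row per replicate, one column per parameter
    converged: np.ndarray          # bool per replicate
    aligned_changed: int = 0       # replicates where label alignment mattered

    _PARAMS = ("alpha", "beta", "r", *EFFECT_NAMES, "sigma2")

    @property
    def n_converged(self) -> int:
        return int(self.converged.sum())

    def mean(self) -> pd.Series:
        return self.estimates[self.converged].mean()

    def sd(self) -> pd.Series:
        return self.estimates[self.converged].std(ddof=1)

    def to_frame(self) -> pd.DataFrame:
        """Three-row table: true values, replicate means, replicate SDs."""
        cfg = self.config
        truth = {"alpha": cfg.alpha, "beta": cfg.beta_effective, "r": cfg.r,
                 **dict(zip(EFFECT_NAMES, cfg.effects.to_array())),
                 "sigma2": error_variance(
                     genetic_variance(cfg.effects, cfg.beta_effective), cfg.h2)}
        return pd.DataFrame(
            [truth, self.mean().to_dict(), self.sd().to_dict()],
            index=["true", "mean", "sd"])[list(self._PARAMS)]


def replicate_study(config: SimulationConfig, fit_options=None,
                    align_labels: bool = False,
                    progress: bool = False) -> ReplicationSummary:
    """Simulate-and-fit ``config.reps`` replicates and summarize the MLEs.

    Replicate seeds are spawned from the master seed via
    ``numpy.random.SeedSequence`` so the study is reproducible and each
    replicate independent.  Fit failures are recorded per replicate and
    never abort the study.  With ``align_labels`` the fitted QTL allele
    labels are permuted to best match the truth before summarizing effect
    estimates (the count of replicates where this changes anything is
    reported).
    """
    from .em import EMOptions, fit  # deferred: em imports this module's types

    if config.reps < 2:
        raise ValueError("need at least 2 replicates")
    options = fit_options if fit_options is not None else EMOptions()
    children = np.random.SeedSequence(config.seed).spawn(config.reps)
    rows = []
    converged = np.zeros(config.reps, dtype=bool)
    aligned_changed = 0
    iterator = range(config.reps)
    if progress:  # pragma: no cover - cosmetic
        try:
            from tqdm import tqdm
            iterator = tqdm(iterator, desc="replicates")
        except ImportError:
            pass
    for k in iterator:
        rng = np.random.default_rng(children[k])
        data = simulate_dataset(config, rng=rng)
        try:
            res = fit(data, options)
        except Exception:
            rows.append({p: np.nan for p in ReplicationSummary._PARAMS})
            continue
        converged[k] = res.converged
        effects = res.effects_hat
        if align_labels and effects is not None and res.means_hat is not None:
            aligned, changed = _align_to_truth(res.means_hat, config.effects)
            aligned_changed += int(changed)
            effects = aligned
        row = {"alpha": res.alpha_hat, "beta": res.beta_hat, "r": res.r_hat,
               "sigma2": res.sigma2_hat}
        eff_values = effects.to_array() if effects is not None \
            else np.full(len(EFFECT_NAMES), np.nan)
        row.update(zip(EFFECT_NAMES, eff_values))
        rows.append(row)
    estimates = pd.DataFrame(rows, columns=list(ReplicationSummary._PARAMS))
    return ReplicationSummary(config=config, estimates=estimates,
                              converged=converged, aligned_changed=aligned_changed)


def _align_to_truth(means_hat: np.ndarray,
                    true_effects: QTLEffects) -> tuple[QTLEffects, bool]:
    """Permute QTL allele labels to minimize squared error against truth."""
    from itertools import permutations

    from .quantgen import means_to_effects

    true_means = effects_to_means(true_effects)
    pair_index = {frozenset(p): i for i, p in enumerate(GAMETE_PAIRS)}
    best, best_perm = np.inf, None
    for perm in permutations(range(4)):
        order = [pair_index[frozenset((perm[a], perm[b]))] for a, b in GAMETE_PAIRS]
        sse = float(np.sum((means_hat[order] - true_means) ** 2))
        if sse < best:
            best, best_perm = sse, order
    changed = best_perm != list(range(10))
    return means_to_effects(means_hat[best_perm]), changed
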