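"""Likelihood-ratio tests for QTL presence and for individual genetic effects.

The presence test compares the full 10-component mixture fit against the
single-normal null (all genotypic values equal).  The mixture LR does not
follow a standard chi-square under the null, so the critical threshold is
taken from the empirical distribution of the statistic over datasets with
phenotypes permuted against markers.  Effect tests (additive, dominance,
single effect) compare the full fit against a constrained EM fit; their
default reference is a chi-square with one degree of freedom per
constraint — a pragmatic convention, with a permutation option.

All statistics use the joint marker + phenotype log-likelihoods; the
marker terms cancel exactly because the marker double-reduction estimate
equals the observed DR fraction under every model compared.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .em import EMOptions, FitResult, fit, fit_constrained
from .quantgen import EFFECT_NAMES, constraint_design
from .simulate import BackcrossDataset

__all__ = [
    "TestResult",
    "lr_presence",
    "lr_additive",
    "lr_dominance",
    "lr_single_effect",
]

_NEG_TOL = 1e-6


@dataclass
class TestResult:
    """Outcome of one likelihood-ratio test."""

    name: str
    statistic: float
    level: float
    reject: bool
    p_value: float | None = None
    threshold: float | None = None
    df: int | None = None
    n_perm: int | None = None
    perm_statistics: np.ndarray | None = None
    fit_alt: FitResult | None = None
    fit_null: FitResult | None = None

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "statistic": float(self.statistic),
            "level": float(self.level),
            "reject": bool(self.reject),
            "p_value": None if self.p_value is None else float(self.p_value),
            "threshold": None if self.threshold is None else float(self.threshold),
            "df": self.df,
            "n_perm": self.n_perm,
        }


def _lr(loglik_alt: float, loglik_null: float) -> float:
    stat = 2.0 * (loglik_alt - loglik_null)
    if stat < -_NEG_TOL:
        import warnings
        warnings.warn(f"negative LR statistic {stat:.3g} clamped to 0 "
                      "(optimization noise in nested fits)", stacklevel=3)
    return max(stat, 0.0)


def _perm_cutoff_rank(level: float, n_perm: int) -> int:
    """Number of permuted statistics allowed at or above the observed one.

    With k = floor(level * (n_perm + 1)) and rejection when fewer than k
    permuted statistics reach the observed value, the test is exactly
    level-``level`` under exchangeability (rank argument).
    """
    k = int(np.floor(level * (n_perm + 1)))
    if k < 1:
        raise ValueError(
            f"n_perm={n_perm} too small for level {level}; need at least "
            f"{int(np.ceil(1.0 / level)) - 1} permutations")
    return k


def _presence_statistic(data: BackcrossDataset, options: EMOptions):
    alt = fit(data, options)
    null = fit_constrained(data, constraint_design("presence_null"), options)
    return _lr(alt.loglik, null.loglik), alt, null


def lr_presence(data: BackcrossDataset, options: EMOptions | None = None,
                n_perm: int = 1000, level: float = 0.05,
                seed: int = 0, keep_perm: bool = False) -> TestResult:
    """Permutation LR test for the presence of a segregating QTL.

    H0: all genotypic values equal (single normal; its constrained EM fit
    coincides with the closed-form normal MLE).  The threshold is the
    k-th largest of ``n_perm`` statistics recomputed on phenotype
    reshufflings, k = floor(level * (n_perm + 1)); rejection by rank is
    exactly level-``level`` under the null.
    """
    if n_perm < 20:
        raise ValueError("n_perm < 20 gives a meaningless empirical quantile")
    options = options or EMOptions()
    k = _perm_cutoff_rank(level, n_perm)
    stat, alt, null = _presence_statistic(data, options)

    # Observed and permuted statistics use the identical fit procedure, so
    # the rank comparison is exchangeable under the null.  The null fit is
    # permutation-invariant (the phenotype multiset and the markers are
    # unchanged), so it is computed once and reused.
    rng = np.random.default_rng(seed)
    perm_stats = np.empty(n_perm)
    for b in range(n_perm):
        shuffled = BackcrossDataset(marker=data.marker,
                                    phenotype=rng.permutation(data.phenotype))
        perm_stats[b] = _lr(fit(shuffled, options).loglik, null.loglik)
    order = np.sort(perm_stats)[::-1]
    threshold = float(order[k - 1])  # k-th largest permuted statistic
    n_ge = int(np.sum(perm_stats >= stat))
    return TestResult(
        name="qtl_presence", statistic=stat, level=level,
        reject=n_ge < k, p_value=(1 + n_ge) / (n_perm + 1),
        threshold=threshold, n_perm=n_perm,
        perm_statistics=perm_stats if keep_perm else None,
        fit_alt=alt, fit_null=null)


def _constrained_test(data: BackcrossDataset, kind: str, which: str | None,
                      df: int, name: str, options: EMOptions | None,
                      level: float, method: str, n_perm: int,
                      seed: int) -> TestResult:
    options = options or EMOptions()
    constraint = constraint_design(kind, which)
    alt = fit(data, options)
    null = fit_constrained(data, constraint, options)
    stat = _lr(alt.loglik, null.loglik)
    if method == "chi2":
        p = float(chi2.sf(stat, df))
        return TestResult(name=name, statistic=stat, level=level,
                          reject=p < level, p_value=p, df=df,
                          fit_alt=alt, fit_null=null)
    if method != "permutation":
        raise ValueError("method must be 'chi2' or 'permutation'")
    if n_perm < 20:
        raise ValueError("n_perm < 20 gives a meaningless empirical quantile")
    k = _perm_cutoff_rank(level, n_perm)
    rng = np.random.default_rng(seed)
    perm_stats = np.empty(n_perm)
    for b in range(n_perm):
        shuffled = BackcrossDataset(marker=data.marker,
                                    phenotype=rng.permutation(data.phenotype))
        a = fit(shuffled, options)
        n0 = fit_constrained(shuffled, constraint, options)
        perm_stats[b] = _lr(a.loglik, n0.loglik)
    order = np.sort(perm_stats)[::-1]
    n_ge = int(np.sum(perm_stats >= stat))
    return TestResult(name=name, statistic=stat, level=level,
                      reject=n_ge < k, p_value=(1 + n_ge) / (n_perm + 1),
                      threshold=float(order[k - 1]), df=df, n_perm=n_perm,
                      fit_alt=alt, fit_null=null)


def lr_additive(data: BackcrossDataset, options: EMOptions | None = None,
                level: float = 0.05, method: str = "chi2",
                n_perm: int = 1000, seed: int = 0) -> TestResult:
    """LR test of H0: a1 = a2 = a3 = 0 (homozygote means coincide); 3 df."""
    return _constrained_test(data, "additive_null", None, 3, "additive_effects",
                             options, level, method, n_perm, seed)


def lr_dominance(data: BackcrossDataset, options: EMOptions | None = None,
                 level: float = 0.05, method: str = "chi2",
                 n_perm: int = 1000, seed: int = 0) -> TestResult:
    """LR test of H0: all six dominance effects are 0; 6 df."""
    return _constrained_test(data, "dominance_null", None, 6, "dominance_effects",
                             options, level, method, n_perm, seed)


def lr_single_effect(data: BackcrossDataset, which: str,
                     options: EMOptions | None = None, level: float = 0.05,
                     method: str = "chi2", n_perm: int = 1000,
                     seed: int = 0) -> TestResult:
    """LR test pinning one named effect (e.g. ``'a1'``, ``'d12'``) to 0; 1 df."""
    if which not in EFFECT_NAMES[1:]:
        raise ValueError(f"unknown effect {which!r}; choose from {EFFECT_NAMES[1:]}")
    return _constrained_test(data, "single_effect", which, 1, f"effect_{which}",
                             options, level, method, n_perm, seed)
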