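"""Quantitative-genetic parameterization of the 10 QTL genotypic values.

The 10 unordered QTL gamete genotypes Q_j1 Q_j2 (j1 <= j2) have genotypic
values mu_{j1 j2} decomposed into an overall mean ``mu``, additive allele
effects ``a1, a2, a3`` of Q1..Q3 relative to Q4 (a4 = -a1-a2-a3 implicitly)
and six dominance interactions ``d12 .. d34``:

    mu_11 = mu + a1                 mu_12 = mu + a1 + a2 + d12
    mu_22 = mu + a2                 mu_13 = mu + a1 + a3 + d13
    mu_33 = mu + a3                 mu_14 = mu - a2 - a3 + d14
    mu_44 = mu - a1 - a2 - a3       mu_23 = mu + a2 + a3 + d23
                                    mu_24 = mu - a1 - a3 + d24
                                    mu_34 = mu - a1 - a2 + d34

This is a bijection between the 10 means and the 10 effect parameters;
its inverse is computed algebraically (mu is the average of the four
homozygote values, a_k contrasts among homozygotes, each d the deviation
of a heterozygote from its additive prediction), so the round trip is
exact.  Note that the dominance inverse is *not* the frequently printed
variant d12 = mu12 - (3 mu33 + 3 mu44 - mu11 - mu22)/4, which fails to
invert the decomposition above (tested).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gametes import GAMETE_PAIRS, N_GAMETES

__all__ = [
    "EFFECT_NAMES",
    "QTLEffects",
    "effect_design",
    "effects_to_means",
    "means_to_effects",
    "NullConstraint",
    "constraint_design",
]

EFFECT_NAMES: tuple[str, ...] = (
    "mu", "a1", "a2", "a3", "d12", "d13", "d14", "d23", "d24", "d34",
)

_HOM = slice(0, 4)
_HET = slice(4, 10)


@dataclass(frozen=True)
class QTLEffects:
    """Effect parameterization of the 10 QTL genotypic values (trait units)."""

    mu: float = 0.0
    a1: float = 0.0
    a2: float = 0.0
    a3: float = 0.0
    d12: float = 0.0
    d13: float = 0.0
    d14: float = 0.0
    d23: float = 0.0
    d24: float = 0.0
    d34: float = 0.0

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in EFFECT_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values) -> "QTLEffects":
        values = np.asarray(values, dtype=float)
        if values.shape != (10,):
            raise ValueError("expected 10 effect values")
        return cls(**dict(zip(EFFECT_NAMES, map(float, values))))


def effect_design() -> np.ndarray:
    """10x10 design mapping (mu, a1..a3, d12..d34) to the genotype means."""
    X = np.zeros((N_GAMETES, N_GAMETES))
    X[:, 0] = 1.0  # mu
    for row, (j1, j2) in enumerate(GAMETE_PAIRS):
        for allele in (j1, j2) if j1 != j2 else (j1,):
            if allele < 3:
                X[row, 1 + allele] += 1.0
            else:  # Q4 carries -a1 - a2 - a3
                X[row, 1:4] -= 1.0
    for col, (j1, j2) in enumerate(GAMETE_PAIRS[_HET], start=4):
        X[4 + col - 4, col] = 1.0
    return X


_DESIGN = effect_design()


def effects_to_means(effects: QTLEffects) -> np.ndarray:
    """Genotypic values of the 10 QTL genotypes, in canonical gamete order."""
    return _DESIGN @ effects.to_array()


def means_to_effects(means) -> QTLEffects:
    """Exact inverse of :func:`effects_to_means`.

    mu = mean of the four homozygote values; a_k = (3 mu_kk - sum of the
    other homozygotes)/4; each dominance term is the heterozygote value
    minus its additive (d = 0) prediction.
    """
    m = np.asarray(means, dtype=float)
    if m.shape != (N_GAMETES,):
        raise ValueError("expected 10 genotype means")
    mu = 0.25 * m[_HOM].sum()
    a = np.array([(4.0 * m[k] - m[_HOM].sum()) / 4.0 for k in range(3)])
    additive = QTLEffects(mu, *a)
    d = m[_HET] - effects_to_means(additive)[_HET]
    return QTLEffects(mu, *a, *d)


@dataclass(frozen=True)
class NullConstraint:
    """A linear subspace of genotype-mean space used as a null hypothesis.

    ``design`` maps ``k`` free parameters to the 10 genotype means; the
    EM mean update under the null is weighted least squares onto it.
    """

    kind: str
    design: np.ndarray
    parameter_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        D = np.asarray(self.design, dtype=float)
        if D.ndim != 2 or D.shape[0] != N_GAMETES:
            raise ValueError("constraint design must be 10 x k")
        if np.linalg.matrix_rank(D) != D.shape[1]:
            raise ValueError("constraint design must have full column rank")
        object.__setattr__(self, "design", D)

    @property
    def n_free(self) -> int:
        return self.design.shape[1]


def constraint_design(kind: str, which: str | None = None) -> NullConstraint:
    """Standard null-hypothesis constraint systems.

    - ``'presence_null'``: all 10 means equal (no QTL effect at all); 1 df.
    - ``'additive_null'``: a1 = a2 = a3 = 0, i.e. the four homozygote means
      coincide while the six heterozygote means stay free; 7 df.
    - ``'dominance_null'``: all six d = 0; means are the additive
      predictions from (mu, a1, a2, a3); 4 df.
    - ``'single_effect'``: the named effect (``which``) pinned to 0; 9 df.
    - ``'full'``: unconstrained (10 df), for auditing.
    """
    if kind == "presence_null":
        return NullConstraint(kind, np.ones((N_GAMETES, 1)), ("mu",))
    if kind == "additive_null":
        D = np.zeros((N_GAMETES, 7))
        D[_HOM, 0] = 1.0
        D[_HET, 1:] = np.eye(6)
        names = ("mu_hom",) + tuple(
            f"mu{j1 + 1}{j2 + 1}" for j1, j2 in GAMETE_PAIRS[_HET])
        return NullConstraint(kind, D, names)
    if kind == "dominance_null":
        return NullConstraint(kind, _DESIGN[:, :4], EFFECT_NAMES[:4])
    if kind == "single_effect":
        if which not in EFFECT_NAMES:
            raise ValueError(f"unknown effect {which!r}; choose from {EFFECT_NAMES}")
        keep = [i for i, n in enumerate(EFFECT_NAMES) if n != which]
        names = tuple(EFFECT_NAMES[i] for i in keep)
        return NullConstraint(kind, _DESIGN[:, keep], names)
    if kind == "full":
        return NullConstraint(kind, _DESIGN.copy(), EFFECT_NAMES)
    raise ValueError(f"unknown constraint kind {kind!r}")
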