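"""Fisher's observable gamete-mode model for a quadrivalent tetraploid.

A multivalent (quadrivalent) tetraploid heterozygote produces 10 distinct
diploid gametes per locus: the 4 double-reduction (DR) homozygotes and the
6 ordinary heterozygotes.  For a marker M (alleles M1..M4) linked to a QTL
Q (alleles Q1..Q4) with recombination fraction ``r``, the 100 observable
joint (marker gamete, QTL gamete) genotypes fall into 9 observable gamete
*modes*, with frequencies ``g1..g9``:

======  =======================  ==================  =================
mode    double reduction         recombinants        cells (coef)
======  =======================  ==================  =================
g1      both loci                0                   4  (1/4)
g2      both loci                2                   12 (1/12)
g3      QTL only                 1                   12 (1/12)
g4      QTL only                 2                   12 (1/12)
g5      marker only              1                   12 (1/12)
g6      marker only              2                   12 (1/12)
g7      neither                  0 or 2 (mix, 2phi)  6  (1/6)
g8      neither                  1 or 3 (mix, 1+psi) 24 (1/24)
g9      neither                  2                   6  (1/6)
======  =======================  ==================  =================

Modes g7 and g8 mix two underlying formation configurations, so their
expected recombination counts carry the corrections ``2*phi(r)`` and
``1 + psi(r)``.  The marker DR frequency alpha, the QTL DR frequency beta
and the recombination fraction r are linear (alpha, beta) resp. implicit
(r) functions of the mode vector g.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "GAMETE_PAIRS",
    "N_GAMETES",
    "N_MODES",
    "gamete_labels",
    "is_double_reduction",
    "mode_layout",
    "MODE_INDEX",
    "MODE_COEF",
    "phi",
    "psi",
    "chromatid_modes",
    "validate_modes",
    "build_joint_table",
    "recomb_count_table",
    "marker_marginals",
    "conditional_qtl_given_marker",
    "implied_r",
    "modes_to_params",
    "InadmissibleModesError",
]

#: Canonical gamete order: 4 double-reduction homozygotes, then the 6
#: heterozygotes in lexicographic allele order (0-based allele indices).
GAMETE_PAIRS: tuple[tuple[int, int], ...] = (
    (0, 0), (1, 1), (2, 2), (3, 3),
    (0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3),
)

N_GAMETES = 10
N_MODES = 9

#: Index of the first non-DR gamete; gametes 0..3 are double reductions.
_N_DR = 4


class InadmissibleModesError(ValueError):
    """Raised when a mode vector implies no recombination fraction in [0, 1/2]."""


def gamete_labels(prefix: str = "M") -> list[str]:
    """Labels for the 10 gametes in canonical order, e.g. ``'M1M3'``."""
    return [f"{prefix}{a + 1}{prefix}{b + 1}" for a, b in GAMETE_PAIRS]


def is_double_reduction(index: int) -> bool:
    """True for the four double-reduction gametes (canonical indices 0-3)."""
    return 0 <= index < _N_DR


def _cell_mode(marker: tuple[int, int], qtl: tuple[int, int]) -> tuple[int, Fraction]:
    """Mode index (0-based) and cell coefficient for one joint-genotype cell."""
    m_dr = marker[0] == marker[1]
    q_dr = qtl[0] == qtl[1]
    if m_dr and q_dr:
        if marker[0] == qtl[0]:
            return 0, Fraction(1, 4)          # g1: same allele, 0 recombinants
        return 1, Fraction(1, 12)             # g2: different alleles
    if m_dr and not q_dr:
        if marker[0] in qtl:
            return 4, Fraction(1, 12)         # g5: marker allele in QTL pair
        return 5, Fraction(1, 12)             # g6
    if not m_dr and q_dr:
        if qtl[0] in marker:
            return 2, Fraction(1, 12)         # g3
        return 3, Fraction(1, 12)             # g4
    shared = len(set(marker) & set(qtl))
    if shared == 2:
        return 6, Fraction(1, 6)              # g7: identical pairs
    if shared == 1:
        return 7, Fraction(1, 24)             # g8
    return 8, Fraction(1, 6)                  # g9: disjoint pairs


def mode_layout() -> tuple[np.ndarray, list[list[Fraction]]]:
    """The static 10x10 layout: per cell, mode index and exact coefficient.

    Coefficients are exact rationals; per mode they sum to exactly 1, so a
    mode vector summing to 1 yields a joint table summing to 1.
    """
    modes = np.empty((N_GAMETES, N_GAMETES), dtype=np.int64)
    coefs: list[list[Fraction]] = []
    for i, m in enumerate(GAMETE_PAIRS):
        row: list[Fraction] = []
        for j, q in enumerate(GAMETE_PAIRS):
            h, c = _cell_mode(m, q)
            modes[i, j] = h
            row.append(c)
        coefs.append(row)
    return modes, coefs


MODE_INDEX, _COEF_FRACTIONS = mode_layout()
#: Cell coefficients as floats (values are 1/4, 1/12, 1/6, 1/24).
MODE_COEF = np.array([[float(c) for c in row] for row in _COEF_FRACTIONS])


def _check_r(r: float) -> None:
    if not 0.0 <= r <= 0.5:
        raise ValueError(f"recombination fraction must lie in [0, 0.5], got {r}")


def phi(r: float) -> float:
    """Correction phi(r) = r^2 / (10 r^2 - 18 r + 9) for the g7 mode.

    The denominator is positive on [0, 1/2]; phi increases from 0 to 0.1.
    """
    _check_r(r)
    return r * r / (10.0 * r * r - 18.0 * r + 9.0)


def psi(r: float) -> float:
    """Correction psi(r) = r / (3 - 2 r) for the g8 mode; in [0, 1/4]."""
    _check_r(r)
    return r / (3.0 - 2.0 * r)


def validate_modes(g, atol: float = 1e-9) -> np.ndarray:
    """Validate and return a mode-frequency vector as a float array of length 9."""
    g = np.asarray(g, dtype=float)
    if g.shape != (N_MODES,):
        raise ValueError(f"mode vector must have length {N_MODES}, got shape {g.shape}")
    if np.any(g < -atol):
        raise ValueError(f"mode frequencies must be nonnegative, got {g}")
    total = g.sum()
    if abs(total - 1.0) > atol:
        raise ValueError(f"mode frequencies must sum to 1, got {total}")
    return np.clip(g, 0.0, None)


def build_joint_table(g) -> np.ndarray:
    """The 10x10 joint (marker gamete, QTL gamete) frequency table.

    Rows index marker gametes, columns QTL gametes, both in canonical
    order; entry (l, j) is ``coef(l, j) * g[mode(l, j)]``.  Sums to 1.
    """
    g = validate_modes(g)
    return MODE_COEF * g[MODE_INDEX]


def recomb_count_table(r: float) -> np.ndarray:
    """Expected recombination-event count for each of the 100 joint cells.

    Entries depend only on the cell's mode: 0 (g1), 1 (g3, g5),
    2 (g2, g4, g6, g9), ``2*phi(r)`` (g7) and ``1 + psi(r)`` (g8).
    """
    _check_r(r)
    per_mode = np.array([0.0, 2.0, 1.0, 2.0, 1.0, 2.0,
                         2.0 * phi(r), 1.0 + psi(r), 2.0])
    return per_mode[MODE_INDEX]


def chromatid_modes(alpha: float, r: float) -> np.ndarray:
    """Mode frequencies under the chromatid-transmission mechanism.

    The gamete's two chromatids carry the marker alleles of the sampled
    gamete (identical alleles for a double reduction); each chromatid
    transmits its parental QTL allele with probability ``1 - r`` or, after
    a recombination event, one of the other three alleles uniformly.  This
    mechanism reproduces the mode corrections exactly —
    ``phi = r^2 / (9(1-r)^2 + r^2)`` is the probability that a same-pair
    heterozygote cell arose from two recombinant chromatids, and
    ``psi = r / (3(1-r) + r)`` the analogous mix for shared-allele cells —
    and yields the QTL double-reduction frequency as a derived quantity
    ``beta(alpha, r) = g1+g2+g3+g4`` (equal to alpha at r = 0).
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    _check_r(r)
    q = 1.0 - r
    g = np.empty(N_MODES)
    g[0] = alpha * q * q
    g[1] = alpha * r * r / 3.0
    g[2] = 2.0 * (1.0 - alpha) * r * q / 3.0
    g[3] = 2.0 * (1.0 - alpha) * r * r / 9.0
    g[4] = 2.0 * alpha * r * q
    g[5] = 2.0 * alpha * r * r / 3.0
    g[6] = (1.0 - alpha) * (q * q + r * r / 9.0)
    g[7] = 4.0 * (1.0 - alpha) * (r * q / 3.0 + r * r / 9.0)
    g[8] = 2.0 * (1.0 - alpha) * r * r / 9.0
    return g


def marker_marginals(alpha: float) -> np.ndarray:
    """Marker gamete frequencies: alpha/4 per DR gamete, (1-alpha)/6 otherwise."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    out = np.empty(N_GAMETES)
    out[:_N_DR] = alpha / 4.0
    out[_N_DR:] = (1.0 - alpha) / 6.0
    return out


def conditional_qtl_given_marker(g) -> np.ndarray:
    """Conditional QTL-gamete probabilities given each marker gamete.

    Row l is the joint-table row divided by its marginal; rows whose
    marker marginal is zero are returned as NaN (that marker genotype
    cannot occur and has no defined conditional).
    """
    joint = build_joint_table(g)
    marg = joint.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        cond = joint / marg
    cond[marg[:, 0] == 0.0] = np.nan
    return cond


def _r_linear_part(g: np.ndarray) -> float:
    # g3 + g5 + 2(g2 + g4 + g6 + g9)
    return g[2] + g[4] + 2.0 * (g[1] + g[3] + g[5] + g[8])


def implied_r(g, tol: float = 1e-10, strict: bool = True) -> float:
    """Recombination fraction implied by a mode vector.

    Solves the fixed point ``r = (1/2)[g3 + g5 + 2(g2+g4+g6+g9)
    + 2 phi(r) g7 + (1 + psi(r)) g8]`` on [0, 1/2].  The right-hand side
    has slope < 1, so the root is unique when it exists.

    With ``strict=True`` an absent root raises
    :class:`InadmissibleModesError`; otherwise the endpoint minimising the
    fixed-point residual is returned.
    """
    g = validate_modes(g)

    def resid(r: float) -> float:
        return r - 0.5 * (_r_linear_part(g)
                          + 2.0 * phi(r) * g[6]
                          + (1.0 + psi(r)) * g[7])

    if g[6] == 0.0 and g[7] == 0.0:
        r = 0.5 * _r_linear_part(g)
        if r > 0.5 + tol:
            if strict:
                raise InadmissibleModesError(
                    f"mode vector implies r = {r:.6f} > 0.5")
            return 0.5
        return min(r, 0.5)

    f0 = resid(0.0)
    f1 = resid(0.5)
    if f0 == 0.0:
        return 0.0
    # resid(0) <= 0 always; a root exists iff resid(0.5) >= 0.
    if f1 < 0.0:
        if strict:
            raise InadmissibleModesError(
                "mode vector admits no recombination fraction in [0, 0.5] "
                f"(fixed-point residual at 0.5 is {f1:.6f})")
        return 0.5
    if f1 == 0.0:
        return 0.5
    return float(brentq(resid, 0.0, 0.5, xtol=tol))


def modes_to_params(g, convention: str = "matrix",
                    strict: bool = True) -> tuple[float, float, float]:
    """Map a mode vector to (alpha, beta, r).

    ``convention='matrix'`` (default) reads the DR sums off the joint
    table: alpha (marker) = g1+g2+g5+g6 sits in the marker-DR rows, beta
    (QTL) = g1+g2+g3+g4 in the QTL-DR columns.  ``convention='printed'``
    swaps the two sums (the widely reproduced printed form); the swap is
    exposed only for auditing, since the matrix form is the one under
    which alpha equals the observable marker-DR fraction.
    """
    g = validate_modes(g)
    alpha = float(g[0] + g[1] + g[4] + g[5])
    beta = float(g[0] + g[1] + g[2] + g[3])
    if convention == "printed":
        alpha, beta = beta, alpha
    elif convention != "matrix":
        raise ValueError(f"unknown convention {convention!r}")
    return alpha, beta, implied_r(g, strict=strict)
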