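"""Kabirian-based isomorphic optinalysis.

Two equal-length real structures ``A`` and ``B`` are compared as mirror
reflections of one another about a centre ``delta``.  The concatenated
sequence of ``2n + 1`` values (n from one structure, the centre, n from
the other) is re-mapped onto a uniform grid of ``2n + 1`` points — the
*optiscale* ``r_i = i * k`` — and similarity is summarised by the
Kabirian coefficient

    Kc = r_{n+1} * (sum(A) + delta + sum(B)) / S,

where ``S`` is the sum of *scalements*, i.e. the sum over all slots of
value times its optiscale point.  ``Kc`` translates bijectively to a
probability of similarity in ``[-1, 1]`` through the four-phase
translation models; the forward and backward translations close on each
other (the Y-rule), every ``Kc`` having two backward images (the
bi-coefficients), one per branch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateConstructionError, DomainError, InvalidArgumentError

__all__ = [
    "Optiscale",
    "OptinalyticConstruction",
    "BiCoefficients",
    "make_optiscale",
    "lay_out_pair",
    "sum_of_scalements",
    "kabirian_coefficient",
    "kc_to_psim",
    "psim_to_pdev",
    "pdev_to_psim",
    "psim_to_kc_alternates",
]

HEAD_TO_HEAD = "head_to_head"
TAIL_TO_TAIL = "tail_to_tail"


@dataclass(frozen=True)
class Optiscale:
    """Uniform grid of ``2n + 1`` points ``r_i = i * k`` (negated for the
    negative variant).  ``r_{n+1}`` is the median optiscale point."""

    n: int
    k: float = 1.0
    negative: bool = False

    @property
    def values(self) -> np.ndarray:
        grid = self.k * np.arange(1, 2 * self.n + 2, dtype=float)
        return -grid if self.negative else grid

    @property
    def r1(self) -> float:
        return -self.k if self.negative else self.k

    @property
    def median(self) -> float:
        sign = -1.0 if self.negative else 1.0
        return sign * (self.n + 1) * self.k


def make_optiscale(n: int, k: float = 1.0, negative: bool = False) -> Optiscale:
    """Build the optiscale for structures of length ``n``.

    Parameters
    ----------
    n
        Item length of each structure; the grid has ``2n + 1`` points.
    k
        Uniform interval between grid points, ``k > 0``.
    negative
        Use the negative-real variant ``r_i = -i * k``.
    """
    if not isinstance(n, (int, np.integer)) or n < 1:
        raise InvalidArgumentError(f"n must be a positive integer, got {n!r}")
    if not k > 0:
        raise InvalidArgumentError(f"k must be positive, got {k!r}")
    return Optiscale(int(n), float(k), bool(negative))


@dataclass(frozen=True)
class OptinalyticConstruction:
    """An isoreflective pair ``A``, ``B`` about a centre ``delta``,
    re-mapped with an optiscale of the same item length.

    ``pairing`` selects which ends of the two structures sit furthest
    from the centre: head-to-head lays out ``a_1..a_n, delta, b_n..b_1``,
    tail-to-tail ``a_n..a_1, delta, b_1..b_n``.
    """

    a: np.ndarray
    b: np.ndarray
    delta: float = 0.0
    pairing: str = HEAD_TO_HEAD
    scale: Optiscale = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=float)
        b = np.asarray(self.b, dtype=float)
        if a.ndim != 1 or b.ndim != 1 or a.size == 0:
            raise InvalidArgumentError("A and B must be nonempty 1-D sequences")
        if a.size != b.size:
            raise InvalidArgumentError(
                f"A and B must have equal length, got {a.size} and {b.size}"
            )
        if self.pairing not in (HEAD_TO_HEAD, TAIL_TO_TAIL):
            raise InvalidArgumentError(f"unknown pairing {self.pairing!r}")
        scale = self.scale if self.scale is not None else make_optiscale(a.size)
        if scale.n != a.size:
            raise InvalidArgumentError(
                f"optiscale built for n={scale.n}, structures have n={a.size}"
            )
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "scale", scale)

    @property
    def n(self) -> int:
        return int(self.a.size)

    def layout_values(self) -> np.ndarray:
        """The 2n+1 values in slot order, pairing applied."""
        if self.pairing == HEAD_TO_HEAD:
            return np.concatenate([self.a, [self.delta], self.b[::-1]])
        return np.concatenate([self.a[::-1], [self.delta], self.b])


def lay_out_pair(c: OptinalyticConstruction) -> list[tuple[float, float]]:
    """Return the ``2n + 1`` (value, optiscale point) pairs in slot order."""
    return list(zip(c.layout_values().tolist(), c.scale.values.tolist()))


def sum_of_scalements(c: OptinalyticConstruction) -> float:
    """Sum over the 2n+1 slots of value times its optiscale point."""
    return float(np.dot(c.layout_values(), c.scale.values))


def kabirian_coefficient(c: OptinalyticConstruction) -> float:
    """Kabirian coefficient of similarity of the isoreflective pair.

    ``Kc = r_{n+1} * (sum(A) + delta + sum(B)) / sum_of_scalements``.
    Both terms vanishing (all-zero structures about a zero centre) is
    taken as the identical-structures limit, ``Kc = 1``.
    """
    numerator = c.scale.median * (float(c.a.sum()) + c.delta + float(c.b.sum()))
    denominator = sum_of_scalements(c)
    if denominator == 0.0:
        if numerator == 0.0:
            warnings.warn(
                "all-zero construction: Kabirian coefficient defined as 1 "
                "(identical-structures limit)",
                RuntimeWarning,
                stacklevel=2,
            )
            return 1.0
        raise DegenerateConstructionError(
            "sum of scalements is zero with nonzero numerator"
        )
    return numerator / denominator


def kc_to_psim(kc: float, n: int, r1: float = 1.0) -> float:
    """Forward translation of a Kabirian coefficient to the probability
    of similarity in ``[-1, 1]``.

    The branch for ``0 <= kc <= 1`` maps ``[(n+1)/(2n+1), 1] -> [0, 1]``
    and ``[0, (n+1)/(2n+1)] -> [-1, 0]``; every other ``kc`` goes through
    the inverse branch, which maps ``[1, n+1] -> [0, 1]``.
    """
    if n < 1:
        raise InvalidArgumentError("n must be >= 1")
    if r1 == 0:
        raise DomainError("r1 must be nonzero")
    hi = n * r1 + r1          # (n+1) r1
    full = 2 * n * r1 + r1    # (2n+1) r1
    if 0.0 <= kc <= 1.0:
        return (hi - kc * full) / (r1 * kc - hi)
    denominator = full * kc - hi
    if denominator == 0.0:
        raise DomainError(
            f"kc={kc} hits the excluded point (n+1)/(2n+1) on the inverse branch"
        )
    return (hi - r1 * kc) / denominator


def psim_to_pdev(psim: float) -> float:
    """Probability of dissimilarity: ``1 - psim`` for ``psim >= 0``,
    ``-1 - psim`` otherwise."""
    if not -1.0 <= psim <= 1.0:
        raise DomainError(f"psim must lie in [-1, 1], got {psim}")
    return 1.0 - psim if psim >= 0.0 else -1.0 - psim


def pdev_to_psim(pdev: float) -> float:
    """Backward translation, the branchwise inverse of :func:`psim_to_pdev`."""
    if not -1.0 <= pdev <= 1.0:
        raise DomainError(f"pdev must lie in [-1, 1], got {pdev}")
    return 1.0 - pdev if pdev >= 0.0 else -1.0 - pdev


@dataclass(frozen=True)
class BiCoefficients:
    """The two backward images of a probability of similarity: branch-1
    (``kc`` in ``[0, 1]``) and branch-2 (``kc`` outside ``[0, 1)``).
    Both translate forward to the same ``psim``."""

    kc_alt1: float
    kc_alt2: float


def psim_to_kc_alternates(psim: float, n: int, r1: float = 1.0) -> BiCoefficients:
    """Backward translation of a probability of similarity to its two
    possible Kabirian bi-coefficients."""
    if not -1.0 <= psim <= 1.0:
        raise DomainError(f"psim must lie in [-1, 1], got {psim}")
    if n < 1:
        raise InvalidArgumentError("n must be >= 1")
    if r1 == 0:
        raise DomainError("r1 must be nonzero")
    hi = n * r1 + r1
    full = 2 * n * r1 + r1
    kc_alt1 = hi * (psim + 1.0) / (r1 * psim + full)
    denom2 = r1 + psim * full
    if denom2 == 0.0:
        warnings.warn(
            "branch-2 bi-coefficient undefined at psim = -r1/((2n+1) r1)",
            RuntimeWarning,
            stacklevel=2,
        )
        kc_alt2 = float("nan")
    else:
        kc_alt2 = hi * (1.0 + psim) / denom2
    return BiCoefficients(kc_alt1, kc_alt2)
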