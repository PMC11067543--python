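"""Classical reference estimators: standard deviation and coefficient
of variation, in population (divisor N) and sample (divisor N-1) forms.
The coefficient of variation is reported on the percent scale and keeps
the sign of the mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidArgumentError, UndefinedCVError

__all__ = [
    "ClassicalResult",
    "population_std",
    "sample_std",
    "coefficient_of_variation",
    "classical_summary",
]


def _as_vector(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise InvalidArgumentError("data must be a nonempty 1-D sequence")
    return arr


def population_std(x) -> float:
    """Root mean squared deviation from the mean (divisor N)."""
    return float(np.std(_as_vector(x), ddof=0))


def sample_std(x) -> float:
    """Square root of the unbiased variance estimate (divisor N-1)."""
    arr = _as_vector(x)
    if arr.size < 2:
        raise InvalidArgumentError("sample_std requires n >= 2")
    return float(np.std(arr, ddof=1))


def coefficient_of_variation(x, population: bool = True) -> float:
    """CV = 100 * std / mean (percent); sign follows the mean."""
    arr = _as_vector(x)
    mean = float(arr.mean())
    if mean == 0.0:
        raise UndefinedCVError("coefficient of variation undefined for zero mean")
    std = population_std(arr) if population else sample_std(arr)
    return 100.0 * std / mean


@dataclass(frozen=True)
class ClassicalResult:
    std_population: float
    std_sample: float
    cv_population: float
    cv_sample: float
    mean: float
    n: int


def classical_summary(x) -> ClassicalResult:
    """All four classical dispersion figures plus the mean, in one pass."""
    arr = _as_vector(x)
    return ClassicalResult(
        std_population=population_std(arr),
        std_sample=sample_std(arr),
        cv_population=coefficient_of_variation(arr, population=True),
        cv_sample=coefficient_of_variation(arr, population=False),
        mean=float(arr.mean()),
        n=arr.size,
    )
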