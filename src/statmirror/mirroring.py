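"""The statistical-mirroring dispersion pipeline.

A univariate sample is (optionally) centred, compulsorily ordered, and
paired isoreflectively with its *statistical mirror* — a constant vector
of ``n`` copies of a principal value (mean, median, mode, max, min, or
an external reference) of the transformed data.  Fitting the isomorphic
optinalysis model to that pair yields five dispersion estimates: the
Kabirian coefficient of statistical proximity ``kc``, the probability of
proximity ``pprox``, the probability of deviation ``pdev``, and the two
backward bi-coefficients ``kc_alt1``/``kc_alt2``.

Presets follow the raw / integral / absolute naming: *raw* skips
centring (scale-invariant estimators), *integral* centres keeping signs,
*absolute* centres and keeps absolute distances (scaloc-invariant
estimators).  "Meanic" presets use the mean as both centring statistic
and principal value, "medianic" the median, and so on.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, replace

import numpy as np

from .errors import InvalidArgumentError, ModalUndefinedError
from .optinalysis import (
    HEAD_TO_HEAD,
    OptinalyticConstruction,
    kabirian_coefficient,
    kc_to_psim,
    make_optiscale,
    psim_to_kc_alternates,
    psim_to_pdev,
)

__all__ = [
    "MirroringConfig",
    "MirroringResult",
    "MirrorSet",
    "MirroringClassification",
    "center_data",
    "order_data",
    "design_mirror",
    "build_construction",
    "run_mirroring",
    "named_preset",
    "preset_names",
    "classify_mirroring",
]

_LOCATIONS = ("mean", "median", "mode", "max", "min", "reference")
_CENTERINGS = ("none",) + _LOCATIONS
_ABSOLUTE_MODES = ("signed", "absolute_positive", "absolute_negative")
_ORDERINGS = ("ascending", "descending")
_PAIRINGS = ("head_to_head", "tail_to_tail")


@dataclass(frozen=True)
class MirroringConfig:
    """All preprocessing and mirror-design choices for one estimator."""

    centering: str = "none"
    absolute_mode: str = "signed"
    ordering: str = "ascending"
    principal: str = "mean"
    pairing: str = HEAD_TO_HEAD
    reference_value: float | None = None
    optiscale_k: float = 1.0

    def __post_init__(self) -> None:
        if self.centering not in _CENTERINGS:
            raise InvalidArgumentError(f"unknown centering {self.centering!r}")
        if self.absolute_mode not in _ABSOLUTE_MODES:
            raise InvalidArgumentError(f"unknown absolute_mode {self.absolute_mode!r}")
        if self.ordering not in _ORDERINGS:
            raise InvalidArgumentError(f"unknown ordering {self.ordering!r}")
        if self.principal not in _LOCATIONS:
            raise InvalidArgumentError(f"unknown principal {self.principal!r}")
        if self.pairing not in _PAIRINGS:
            raise InvalidArgumentError(f"unknown pairing {self.pairing!r}")
        needs_ref = self.centering == "reference" or self.principal == "reference"
        if needs_ref and self.reference_value is None:
            raise InvalidArgumentError(
                "reference_value required when centering or principal is 'reference'"
            )
        if not self.optiscale_k > 0:
            raise InvalidArgumentError("optiscale_k must be positive")


@dataclass(frozen=True)
class MirrorSet:
    """A statistical mirror: ``n`` copies of the principal value ``p``."""

    principal_value: float
    n: int

    @property
    def values(self) -> np.ndarray:
        return np.full(self.n, self.principal_value, dtype=float)


@dataclass(frozen=True)
class MirroringResult:
    """The five outputs of one statistical-mirroring run.

    ``pprox`` and ``pdev`` are fractions in ``[-1, 1]``; render as
    percentages only at the presentation layer.
    """

    kc: float
    pprox: float
    pdev: float
    kc_alt1: float
    kc_alt2: float
    n: int
    config: MirroringConfig

    def as_record(self) -> dict:
        rec = {
            "kc": self.kc,
            "pprox": self.pprox,
            "pdev": self.pdev,
            "kc_alt1": self.kc_alt1,
            "kc_alt2": self.kc_alt2,
            "n": self.n,
        }
        rec.update(
            {
                "centering": self.config.centering,
                "absolute_mode": self.config.absolute_mode,
                "ordering": self.config.ordering,
                "principal": self.config.principal,
                "pairing": self.config.pairing,
                "reference_value": self.config.reference_value,
                "optiscale_k": self.config.optiscale_k,
            }
        )
        return rec


def _as_vector(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise InvalidArgumentError("data must be a nonempty 1-D sequence")
    return arr


def _mode(values: np.ndarray) -> float:
    counts = Counter(values.tolist())
    top = max(counts.values())
    if top == 1:
        raise ModalUndefinedError("mode undefined: no repeated value in the data")
    return min(v for v, c in counts.items() if c == top)


def _location(values: np.ndarray, statistic: str, ref: float | None) -> float:
    if statistic == "mean":
        return float(values.mean())
    if statistic == "median":
        return float(np.median(values))
    if statistic == "mode":
        return _mode(values)
    if statistic == "max":
        return float(values.max())
    if statistic == "min":
        return float(values.min())
    if statistic == "reference":
        if ref is None:
            raise InvalidArgumentError("reference value missing")
        return float(ref)
    raise InvalidArgumentError(f"unknown location statistic {statistic!r}")


def center_data(
    x,
    mode: str = "none",
    absolute_mode: str = "signed",
    ref: float | None = None,
) -> np.ndarray:
    """Optional location removal, elementwise, with optional absolute
    positive/negative distances."""
    arr = _as_vector(x)
    if mode != "none":
        arr = arr - _location(arr, mode, ref)
    if absolute_mode == "absolute_positive":
        arr = np.abs(arr)
    elif absolute_mode == "absolute_negative":
        arr = -np.abs(arr)
    elif absolute_mode != "signed":
        raise InvalidArgumentError(f"unknown absolute_mode {absolute_mode!r}")
    return arr


def order_data(x, ordering: str = "ascending") -> np.ndarray:
    """Compulsory theoretical ordering (stable mergesort); this is what
    makes the estimators permutation-invariant."""
    arr = _as_vector(x)
    out = np.sort(arr, kind="stable")
    if ordering == "descending":
        out = out[::-1]
    elif ordering != "ascending":
        raise InvalidArgumentError(f"unknown ordering {ordering!r}")
    return out


def design_mirror(x_transformed, principal: str = "mean", ref: float | None = None) -> MirrorSet:
    """Amplify a location estimate of the transformed data into the
    constant mirror vector."""
    arr = _as_vector(x_transformed)
    return MirrorSet(_location(arr, principal, ref), arr.size)


def build_construction(x, cfg: MirroringConfig) -> OptinalyticConstruction:
    """Run the preprocessing phase and return the optinalytic
    construction (A = transformed data, B = mirror, delta = 0) that the
    model-calculation phase consumes."""
    transformed = order_data(
        center_data(x, cfg.centering, cfg.absolute_mode, cfg.reference_value),
        cfg.ordering,
    )
    mirror = design_mirror(transformed, cfg.principal, cfg.reference_value)
    return OptinalyticConstruction(
        a=transformed,
        b=mirror.values,
        delta=0.0,
        pairing=cfg.pairing,
        scale=make_optiscale(transformed.size, cfg.optiscale_k),
    )


def run_mirroring(x, cfg: MirroringConfig) -> MirroringResult:
    """Full statistical-mirroring estimate: preprocessing, mirror
    design, optinalytic construction, and the coefficient/probability
    chain."""
    c = build_construction(x, cfg)
    total = float(c.a.sum()) + c.delta + float(c.b.sum())
    if total == 0.0 and sum(np.any(v != 0) for v in (c.a, c.b)) > 0:
        warnings.warn(
            "degenerate estimate: structures sum to zero (signed centring "
            "about the principal value forces kc = 0)",
            RuntimeWarning,
            stacklevel=2,
        )
    kc = kabirian_coefficient(c)
    pprox = kc_to_psim(kc, c.n, c.scale.r1)
    pdev = psim_to_pdev(pprox)
    alts = psim_to_kc_alternates(pprox, c.n, c.scale.r1)
    return MirroringResult(kc, pprox, pdev, alts.kc_alt1, alts.kc_alt2, c.n, cfg)


_PREFIXES = {"raw": ("none", "signed"), "integral": (None, "signed"), "absolute": (None, "absolute_positive")}
_SUFFIXES = {
    "meanic": "mean",
    "medianic": "median",
    "modalic": "mode",
    "maximalic": "max",
    "minimalic": "min",
    "reference": "reference",
}


def preset_names() -> list[str]:
    """All recognised preset identifiers."""
    return [f"{p}_{s}" for p in _PREFIXES for s in _SUFFIXES]


def named_preset(name: str, reference_value: float | None = None) -> MirroringConfig:
    """Resolve a preset id like ``absolute_meanic`` into a full config.

    ``raw`` skips centring; ``integral`` centres (by the same statistic
    as the principal value) keeping signs; ``absolute`` centres and
    returns absolute positive distances.  Ordering is ascending and
    pairing head-to-head throughout.
    """
    try:
        prefix, suffix = name.split("_", 1)
        centering, absolute_mode = _PREFIXES[prefix]
        principal = _SUFFIXES[suffix]
    except (ValueError, KeyError):
        raise InvalidArgumentError(
            f"unknown preset {name!r}; expected one of {', '.join(preset_names())}"
        ) from None
    if centering is None:
        centering = principal
    return MirroringConfig(
        centering=centering,
        absolute_mode=absolute_mode,
        ordering="ascending",
        principal=principal,
        pairing=HEAD_TO_HEAD,
        reference_value=reference_value,
    )


@dataclass(frozen=True)
class MirroringClassification:
    """Endo/exo label and the invariance class a config belongs to."""

    statistical: str  # "endo" | "exo"
    invariance: str   # "scale" | "scaloc"


def classify_mirroring(cfg: MirroringConfig) -> MirroringClassification:
    """Classify a config: endo-statistical when the principal value is a
    location estimate of the data itself, exo-statistical when it is an
    external reference; scale-invariant when the location parameter is
    retained (no centring), scaloc-invariant when it is removed."""
    statistical = "exo" if cfg.principal == "reference" else "endo"
    invariance = "scale" if cfg.centering == "none" else "scaloc"
    return MirroringClassification(statistical, invariance)


def with_pairing(cfg: MirroringConfig, pairing: str) -> MirroringConfig:
    """Convenience copy of a config with the alternate reflection."""
    return replace(cfg, pairing=pairing)
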