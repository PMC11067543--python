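"""Monte-Carlo dataset generation.

Two designs are supported: a grid of pure normal populations
``N(mu, sigma)`` over sample sizes, and a Gaussian-mixture contamination
grid in which each observation is drawn from a contaminant component
with probability ``p`` (Bernoulli mixing) and from the base component
otherwise.  Contamination is either a location shift (``mu2`` moved,
``sigma2 = sigma1``) or a scaling inflation (``sigma2`` inflated,
``mu2 = mu1``).

Every (combination, iteration) cell owns a child seed derived from the
master seed by counter, so the clean (``p = 0``) partner of a
contaminated dataset reuses exactly the same base-component draws and
the pair differs only where the contamination mask fires.

The default grids are the study conditions: 5 sample sizes x 5 means x
5 sigmas (125 normal combinations) and 11 contamination levels x 5
parameter pairs x 5 shape pairs at one sample size (275 mixture
combinations), 1000 iterations per cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError

__all__ = [
    "NormalDesign",
    "MixtureDesign",
    "SimRecord",
    "SimulatedBatch",
    "generate_normal",
    "generate_mixture",
]

LOCATION_SHIFT = "location_shift"
SCALING = "scaling"

# Default study grids (the exact published grids are configuration, not code).
DEFAULT_SAMPLE_SIZES = (10, 20, 50, 100, 200)
DEFAULT_MUS = (0.0, 2.0, 5.0, 10.0, 20.0)
DEFAULT_SIGMAS = (0.5, 1.0, 2.0, 5.0, 10.0)
DEFAULT_LEVELS = (0.0, 0.05, 0.10, 0.15, 0.20, 0.25, 0.30, 0.35, 0.40, 0.45, 0.50)
DEFAULT_MIXTURE_N = 100
DEFAULT_SHIFT = 10.0      # contaminant mean offset (absolute units)
DEFAULT_INFLATION = 5.0   # contaminant sigma multiplier


@dataclass(frozen=True)
class NormalDesign:
    """Grid of normal populations: one cell per (N, mu, sigma) triple,
    ``iterations`` datasets per cell."""

    sample_sizes: tuple = DEFAULT_SAMPLE_SIZES
    mus: tuple = DEFAULT_MUS
    sigmas: tuple = DEFAULT_SIGMAS
    iterations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise InvalidArgumentError("iterations must be >= 1")
        if any(n < 1 for n in self.sample_sizes):
            raise InvalidArgumentError("sample sizes must be >= 1")
        if any(s <= 0 for s in self.sigmas):
            raise InvalidArgumentError("sigmas must be positive")

    @property
    def combos(self) -> list[dict]:
        return [
            {"N": int(n), "mu": float(m), "sigma": float(s)}
            for n, m, s in product(self.sample_sizes, self.mus, self.sigmas)
        ]


def _default_pairs(scenario: str) -> tuple[tuple, tuple]:
    if scenario == LOCATION_SHIFT:
        mu_pairs = tuple((m, m + DEFAULT_SHIFT) for m in DEFAULT_MUS)
        sigma_pairs = tuple((s, s) for s in DEFAULT_SIGMAS)
    else:
        mu_pairs = tuple((m, m) for m in DEFAULT_MUS)
        sigma_pairs = tuple((s, DEFAULT_INFLATION * s) for s in DEFAULT_SIGMAS)
    return mu_pairs, sigma_pairs


@dataclass(frozen=True)
class MixtureDesign:
    """Gaussian-mixture contamination grid: one cell per (level, mu
    pair, sigma pair, N) tuple.  ``p = 0`` reduces to the pure base
    component."""

    scenario: str = LOCATION_SHIFT
    contamination_levels: tuple = DEFAULT_LEVELS
    mu_pairs: tuple = None  # type: ignore[assignment]
    sigma_pairs: tuple = None  # type: ignore[assignment]
    sample_sizes: tuple = (DEFAULT_MIXTURE_N,)
    iterations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in (LOCATION_SHIFT, SCALING):
            raise InvalidArgumentError(f"unknown scenario {self.scenario!r}")
        if any(not 0.0 <= p <= 1.0 for p in self.contamination_levels):
            raise InvalidArgumentError("contamination levels must lie in [0, 1]")
        if self.iterations < 1:
            raise InvalidArgumentError("iterations must be >= 1")
        mu_pairs, sigma_pairs = _default_pairs(self.scenario)
        if self.mu_pairs is None:
            object.__setattr__(self, "mu_pairs", mu_pairs)
        if self.sigma_pairs is None:
            object.__setattr__(self, "sigma_pairs", sigma_pairs)
        if any(s1 <= 0 or s2 <= 0 for s1, s2 in self.sigma_pairs):
            raise InvalidArgumentError("sigmas must be positive")

    @property
    def combos(self) -> list[dict]:
        return [
            {
                "level": float(p),
                "mu1": float(mp[0]),
                "mu2": float(mp[1]),
                "sigma1": float(sp[0]),
                "sigma2": float(sp[1]),
                "N": int(n),
            }
            for p, mp, sp, n in product(
                self.contamination_levels, self.mu_pairs, self.sigma_pairs, self.sample_sizes
            )
        ]


@dataclass(frozen=True)
class SimRecord:
    combo_id: int
    params: dict
    iteration: int
    data: np.ndarray
    contaminated: bool = False


@dataclass
class SimulatedBatch:
    """Flat list of simulated datasets plus the design that produced
    them.  Clean/contaminated partners share (combo_id, iteration)."""

    design: object
    records: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def combo_count(self) -> int:
        return len({r.combo_id for r in self.records})

    def to_frame(self) -> pd.DataFrame:
        """Long-format view; data serialized as ';'-joined full-precision text."""
        rows = []
        for r in self.records:
            row = {"combo_id": r.combo_id, "iteration": r.iteration, "contaminated": r.contaminated}
            row.update(r.params)
            row["data"] = ";".join(repr(v) for v in r.data.tolist())
            rows.append(row)
        return pd.DataFrame(rows)


def _cell_rng(seed: int, combo_id: int, iteration: int) -> np.random.Generator:
    # counter-style child seeds: every cell is independent and replayable
    return np.random.default_rng(np.random.SeedSequence([int(seed), combo_id, iteration]))


def generate_normal(design: NormalDesign) -> SimulatedBatch:
    """Draw ``iterations`` datasets from N(mu, sigma) for every grid cell."""
    batch = SimulatedBatch(design)
    for combo_id, params in enumerate(design.combos):
        for it in range(design.iterations):
            rng = _cell_rng(design.seed, combo_id, it)
            data = rng.normal(params["mu"], params["sigma"], params["N"])
            batch.records.append(SimRecord(combo_id, params, it, data))
    return batch


def generate_mixture(design: MixtureDesign) -> SimulatedBatch:
    """Draw paired clean/contaminated datasets for every grid cell.

    Per cell: base draws from component 1, contaminant draws from
    component 2, and a Bernoulli(p) mask.  The clean record is the base
    draw; the contaminated record replaces masked entries with the
    contaminant draw, so at ``p = 0`` the pair is bit-identical.
    """
    batch = SimulatedBatch(design)
    for combo_id, params in enumerate(design.combos):
        for it in range(design.iterations):
            rng = _cell_rng(design.seed, combo_id, it)
            base = rng.normal(params["mu1"], params["sigma1"], params["N"])
            contaminant = rng.normal(params["mu2"], params["sigma2"], params["N"])
            mask = rng.random(params["N"]) < params["level"]
            contaminated = np.where(mask, contaminant, base)
            batch.records.append(SimRecord(combo_id, params, it, base, contaminated=False))
            batch.records.append(SimRecord(combo_id, params, it, contaminated, contaminated=True))
    return batch
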