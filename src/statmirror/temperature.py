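"""Temperature-scale invariance demonstration.

Each temperature scale is an affine transform ``a * x + b`` of degree
Celsius.  Running the estimator battery on the same series expressed in
every scale exposes each estimator's invariance class: the standard
deviation survives pure shifts (Kelvin), the CV and raw meanic
mirroring survive pure rescalings (Newton, Reaumur), and absolute
meanic mirroring survives every affine transform with ``a != 0``.

Note: the Delisle conversion here follows the source's printed formula,
which coincides with the Fahrenheit one; the historical Delisle scale
(a negative-slope transform) is deliberately not substituted.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classical import coefficient_of_variation, population_std
from .errors import InvalidArgumentError
from .mirroring import named_preset, run_mirroring

__all__ = ["SCALES", "convert_temperature", "scale_invariance_table"]

# scale id -> (a, b) with T_scale = a * T_celsius + b
SCALES: dict[str, tuple[float, float]] = {
    "celsius": (1.0, 0.0),
    "kelvin": (1.0, 273.15),
    "rankine": (9 / 5, 273.15 * 9 / 5),
    "fahrenheit": (9 / 5, 32.0),
    "romer": (21 / 40, 7.5),
    "newton": (33 / 100, 0.0),
    "reaumur": (4 / 5, 0.0),
    "delisle": (9 / 5, 32.0),  # as printed in the source; see module docstring
}


def convert_temperature(x_celsius, scale: str) -> np.ndarray:
    """Convert a Celsius series to another temperature scale."""
    try:
        a, b = SCALES[scale]
    except KeyError:
        raise InvalidArgumentError(
            f"unknown scale {scale!r}; expected one of {', '.join(SCALES)}"
        ) from None
    return a * np.asarray(x_celsius, dtype=float) + b


def _battery() -> dict:
    amm = named_preset("absolute_meanic")
    rmm = named_preset("raw_meanic")
    rows = {}
    for tag, cfg in (("AMM", amm),):
        for out, label in (("kc", "Kc"), ("pprox", "Pprox"), ("pdev", "Pdev"),
                           ("kc_alt1", "Kcalt1"), ("kc_alt2", "Kcalt2")):
            rows[f"{tag}: {label}"] = lambda x, cfg=cfg, out=out: getattr(run_mirroring(x, cfg), out)
    rows["STD"] = population_std
    for out, label in (("kc", "Kc"), ("pprox", "Pprox"), ("pdev", "Pdev"),
                       ("kc_alt1", "Kcalt1"), ("kc_alt2", "Kcalt2")):
        rows[f"RMM: {label}"] = lambda x, cfg=rmm, out=out: getattr(run_mirroring(x, cfg), out)
    rows["CV"] = lambda x: coefficient_of_variation(x, population=True)
    return rows


def scale_invariance_table(x_celsius, scales: tuple = tuple(SCALES)) -> pd.DataFrame:
    """Run the battery on the series converted to every scale.

    Rows are estimators (AMM outputs, STD, RMM outputs, CV), columns the
    temperature scales.
    """
    battery = _battery()
    table = {
        scale: {name: fn(convert_temperature(x_celsius, scale)) for name, fn in battery.items()}
        for scale in scales
    }
    return pd.DataFrame(table, index=list(battery))
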