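"""Packaged worked-example datasets.

Three small printed datasets back the worked examples and the
invariance demonstrations: a six-value random sample used for the
manual calculation, a 12-month mean-temperature series (deg C, Katsina
State, Nigeria, 30-year averages), and a family of duplicated four-value
score sets used to show set-duplication invariance.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .errors import InvalidArgumentError

__all__ = ["TemperatureSeries", "load_fixture", "fixture_names"]

_TABLE2_SAMPLE = (-0.02, 6.31, 6.20, -4.36, 1.22, 2.87)

_MONTHS = ("Jan", "Feb", "Mar", "Apr", "May", "Jun",
           "Jul", "Aug", "Sep", "Oct", "Nov", "Dec")
_TEMPERATURES_C = (21.6, 24.7, 28.3, 31.2, 31.5, 29.7,
                   26.9, 25.4, 26.7, 27.7, 25.7, 22.2)

_GROUP_BASE = (2, 9, 23, 25)
# group number -> duplication count c (sample size is 4c)
_GROUP_DUPLICATES = {1: 1, 2: 2, 3: 3, 4: 4, 5: 7, 6: 50, 7: 1000}


@dataclass(frozen=True)
class TemperatureSeries:
    """Monthly mean temperatures in degree Celsius."""

    values: np.ndarray
    labels: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))


def fixture_names() -> list[str]:
    return (["table2_sample", "table4_temperatures"]
            + [f"table6_group{k}" for k in sorted(_GROUP_DUPLICATES)])


def load_fixture(name: str):
    """Return a packaged dataset by name.

    ``table2_sample`` -> 6-value ndarray; ``table4_temperatures`` ->
    :class:`TemperatureSeries`; ``table6_group{1..7}`` -> the duplicated
    score sets (ndarray).
    """
    if name == "table2_sample":
        return np.array(_TABLE2_SAMPLE, dtype=float)
    if name == "table4_temperatures":
        return TemperatureSeries(np.array(_TEMPERATURES_C), _MONTHS)
    m = re.fullmatch(r"table6_group(\d+)", name)
    if m:
        group = int(m.group(1))
        if group not in _GROUP_DUPLICATES:
            raise InvalidArgumentError(f"no such group: {name!r}")
        c = _GROUP_DUPLICATES[group]
        return np.array(sorted(_GROUP_BASE * c), dtype=float)
    raise InvalidArgumentError(
        f"unknown fixture {name!r}; expected one of {', '.join(fixture_names())}"
    )
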