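"""File and inline I/O helpers for the command-line tool.

Series come in as single-column CSV (optional header) or inline
comma-separated literals; estimate matrices and reports go out as
RFC-4180 CSV with full double precision, so a write/read round trip is
bit-exact.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import InvalidArgumentError

__all__ = ["read_series", "parse_inline", "write_matrix", "read_matrix", "load_config"]

# unicode minus sometimes appears in copy-pasted numeric text
_MINUS = "−"


def parse_inline(text: str) -> np.ndarray:
    """Parse a comma-separated numeric literal into a vector."""
    cleaned = text.replace(_MINUS, "-").strip()
    if not cleaned:
        raise InvalidArgumentError("empty inline series")
    try:
        return np.array([float(tok) for tok in cleaned.split(",") if tok.strip()])
    except ValueError as exc:
        raise InvalidArgumentError(f"non-numeric value in inline series: {exc}") from None


def read_series(source: str | Path) -> np.ndarray:
    """Read a univariate series from a one-column CSV file (header
    optional) or, if ``source`` is not an existing path, from an inline
    comma-separated literal.  Order is preserved."""
    path = Path(str(source))
    if not path.exists():
        return parse_inline(str(source))
    lines = [ln.strip() for ln in path.read_text(encoding="utf-8").splitlines() if ln.strip()]
    if not lines:
        raise InvalidArgumentError(f"empty file: {path}")
    start = 0
    try:
        float(lines[0].replace(_MINUS, "-"))
    except ValueError:
        start = 1  # header row
    values = []
    for ln in lines[start:]:
        try:
            values.append(float(ln.replace(_MINUS, "-")))
        except ValueError:
            raise InvalidArgumentError(f"non-numeric cell in {path}: {ln!r}") from None
    if not values:
        raise InvalidArgumentError(f"no numeric rows in {path}")
    return np.array(values)


def write_matrix(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a matrix/report CSV with 17 significant digits."""
    frame.to_csv(path, index=False, float_format="%.17g")


def read_matrix(path: str | Path) -> pd.DataFrame:
    # round_trip parser: 17-significant-digit text reloads bit-exactly
    return pd.read_csv(path, float_precision="round_trip")


def load_config(path: str | Path) -> dict:
    """Load a YAML (or plain key: value) run configuration."""
    text = Path(path).read_text(encoding="utf-8")
    cfg = yaml.safe_load(_io.StringIO(text))
    if not isinstance(cfg, dict):
        raise InvalidArgumentError(f"config {path} must be a mapping")
    return cfg
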