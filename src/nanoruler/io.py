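"""Localization-table I/O and histogram rendering.

The canonical on-disk format is a comma-separated table with header
``frame,x_nm,y_nm,z_nm,photons,background,channel`` (coordinates in nm),
the common denominator of SMLM localization-table conventions.  Importers
accept a handful of header aliases (``x [nm]``, ``x``, ...).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "COLUMNS",
    "read_localizations",
    "write_localizations",
    "RenderSpec",
    "render_histogram",
    "save_image",
]

COLUMNS = ["frame", "x_nm", "y_nm", "z_nm", "photons", "background", "channel"]

MANDATORY = ["frame", "x_nm", "y_nm"]

_ALIASES = {
    "x": "x_nm", "y": "y_nm", "z": "z_nm",
    "x [nm]": "x_nm", "y [nm]": "y_nm", "z [nm]": "z_nm",
    "x_nm": "x_nm", "y_nm": "y_nm", "z_nm": "z_nm",
    "frame": "frame", "t": "frame",
    "photons": "photons", "intensity": "photons",
    "background": "background", "bg": "background",
    "channel": "channel", "ch": "channel",
}

_DEFAULTS = {"z_nm": 0.0, "photons": np.nan, "background": np.nan, "channel": 0}


def read_localizations(path, dialect: Optional[dict] = None) -> pd.DataFrame:
    """Read a delimited localization table.

    Missing optional columns are filled with defaults and logged via a
    warning; missing mandatory columns (frame, x, y) raise.  Malformed rows
    are dropped and counted in ``table.attrs["n_skipped"]``.  A table
    without a z column is flagged 2D via ``table.attrs["mode"]``.
    """
    dialect = dialect or {}
    sep = dialect.get("sep", ",")
    df = pd.read_csv(path, sep=sep, skipinitialspace=True)
    rename = {}
    for col in df.columns:
        key = str(col).strip().lower()
        if key in _ALIASES:
            rename[col] = _ALIASES[key]
    df = df.rename(columns=rename)

    missing = [c for c in MANDATORY if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")

    mode = "3d" if "z_nm" in df.columns else "2d"
    for col, default in _DEFAULTS.items():
        if col not in df.columns:
            warnings.warn(f"{path}: column {col!r} absent, filled with {default}")
            df[col] = default

    n_before = len(df)
    for col in COLUMNS:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df = df.dropna(subset=MANDATORY).reset_index(drop=True)
    n_skipped = n_before - len(df)
    if n_skipped:
        warnings.warn(f"{path}: skipped {n_skipped} malformed row(s)")
    if len(df) == 0:
        warnings.warn(f"{path}: table is empty")

    df = df[COLUMNS]
    df.attrs["mode"] = mode
    df.attrs["n_skipped"] = n_skipped
    return df


def write_localizations(table: pd.DataFrame, path) -> None:
    """Write a localization table with deterministic column order/format."""
    df = table.copy()
    for col, default in _DEFAULTS.items():
        if col not in df.columns:
            df[col] = default
    df = df[COLUMNS]
    df.to_csv(path, index=False, float_format="%.4f")


@dataclass
class RenderSpec:
    """2D localization-histogram rendering parameters."""

    plane: str = "xy"          # xy | xz | yz
    bin_nm: float = 6.0        # histogram bin size (6 nm is the default render bin)
    slab: Optional[tuple] = None   # (lo, hi) bounds along the remaining axis, nm
    cmap: str = "hot"

    def __post_init__(self):
        if self.bin_nm <= 0:
            raise ValueError("bin_nm must be positive")
        if self.plane not in ("xy", "xz", "yz"):
            raise ValueError(f"unknown plane {self.plane!r}")


_PLANE_AXES = {"xy": ("x_nm", "y_nm", "z_nm"),
               "xz": ("x_nm", "z_nm", "y_nm"),
               "yz": ("y_nm", "z_nm", "x_nm")}


def render_histogram(table: pd.DataFrame, spec: RenderSpec) -> np.ndarray:
    """Render a 2D count histogram of the selected slab.

    Total counts equal the number of localizations inside the slab; an
    empty slab yields a blank image with a warning.
    """
    ax0, ax1, ax_slab = _PLANE_AXES[spec.plane]
    df = table
    if spec.slab is not None:
        lo, hi = spec.slab
        df = df[(df[ax_slab] >= lo) & (df[ax_slab] < hi)]
    if len(df) == 0:
        warnings.warn("render_histogram: empty slab, returning blank image")
        return np.zeros((1, 1))
    u, v = df[ax0].to_numpy(), df[ax1].to_numpy()
    b = spec.bin_nm
    e0 = np.arange(np.floor(u.min() / b) * b, u.max() + b, b)
    e1 = np.arange(np.floor(v.min() / b) * b, v.max() + b, b)
    hist, _, _ = np.histogram2d(u, v, bins=(e0, e1))
    return hist


def save_image(hist: np.ndarray, path, cmap: str = "hot") -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plt.imsave(path, np.asarray(hist).T[::-1], cmap=cmap)
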