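"""Species-level trait construction.

Covers three measurement pipelines feeding the comparative analyses:

* geometric cell biovolumes from linear dimensions (cylinder, sphere,
  prolate spheroid), with the standard fallback rules when cell height is
  unreported (``height = diameter / 2``, or ``height = diameter`` for
  chain-forming centric genera such as *Skeletonema*);
* maximum specific growth rate ``mu`` (h^-1) from relative chlorophyll-a
  fluorescence time series, by the linear method: the steepest OLS slope of
  ln(RF) versus time over sliding windows that fit well enough (R^2 cutoff),
  and doubling time ``T_d = ln(2) / mu``;
* the variable transformations applied before statistics: log10 for genome
  size, doubling time and cell volumes; arcsin(sqrt(x)) for repeat
  proportions; GC percent and temperature untransformed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CellShapeSpec",
    "GrowthCurve",
    "cell_volume",
    "max_growth_rate",
    "doubling_time",
    "transform_traits",
    "LOG10_COLUMNS",
]

SHAPES = ("cylinder", "sphere", "prolate_spheroid")
HEIGHT_RULES = ("measured", "half_diameter", "equal_diameter")


@dataclass
class CellShapeSpec:
    shape: str
    diameter_um: float
    height_um: float | None = None
    height_rule: str = "measured"

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}; use one of {SHAPES}")
        if self.height_rule not in HEIGHT_RULES:
            raise ValueError(f"unknown height rule {self.height_rule!r}")
        if self.diameter_um <= 0:
            raise ValueError("diameter must be positive")
        if self.height_um is not None and self.height_um <= 0:
            raise ValueError("height must be positive when given")


def cell_volume(spec: CellShapeSpec) -> float:
    """Biovolume (um^3) from the assigned geometric solid.

    cylinder: V = pi (d/2)^2 h; sphere: V = pi/6 d^3;
    prolate spheroid: V = pi/6 d^2 h. Missing heights are filled by the
    spec's rule (half_diameter: h = d/2; equal_diameter: h = d).
    """
    d = spec.diameter_um
    if spec.shape == "sphere":  # no height needed
        return math.pi / 6.0 * d**3
    h = spec.height_um
    if h is None:
        if spec.height_rule == "half_diameter":
            h = d / 2.0
        elif spec.height_rule == "equal_diameter":
            h = d
        else:
            raise ValueError("height absent but height_rule is 'measured'")
    if spec.shape == "cylinder":
        return math.pi * (d / 2.0) ** 2 * h
    return math.pi / 6.0 * d**2 * h  # prolate spheroid


@dataclass
class GrowthCurve:
    """Relative-fluorescence growth time series for one culture replicate."""

    time_h: np.ndarray
    rf: np.ndarray
    replicate_id: str = "rep1"
    temperature_c: float | None = None

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.rf = np.asarray(self.rf, dtype=float)
        if self.time_h.shape != self.rf.shape or self.time_h.ndim != 1:
            raise ValueError("time and RF must be 1-D arrays of equal length")
        if len(self.time_h) < 4:
            raise ValueError("growth curve needs at least 4 points")
        if np.any(np.diff(self.time_h) <= 0):
            raise ValueError("times must be strictly increasing")

    @classmethod
    def from_tsv(cls, path):
        """Read one or more replicate curves from a TSV (time_h, rf, replicate_id)."""
        df = pd.read_csv(path, sep="\t", comment="#")
        return [
            cls(g["time_h"].to_numpy(), g["rf"].to_numpy(), replicate_id=str(rid))
            for rid, g in df.groupby("replicate_id", sort=True)
        ]


class NoExponentialPhaseError(RuntimeError):
    """No sliding window met the R^2 requirement for a log-linear fit."""


def _window_slope_r2(t: np.ndarray, ln_rf: np.ndarray) -> tuple[float, float]:
    tc = t - t.mean()
    yc = ln_rf - ln_rf.mean()
    sxx = float(tc @ tc)
    syy = float(yc @ yc)
    if syy == 0.0:
        # zero-variance response: define R^2 = 0 (and slope 0)
        return 0.0, 0.0
    sxy = float(tc @ yc)
    slope = sxy / sxx
    return slope, sxy * sxy / (sxx * syy)


def max_growth_rate(curve: GrowthCurve, window: int = 5, r2_min: float = 0.95) -> float:
    """Maximum specific growth rate by the linear (sliding-window) method.

    Fits ln(RF) ~ time by OLS over every contiguous window of ``window``
    points; returns the steepest slope among windows with R^2 >= r2_min
    (earliest window on ties).
    """
    if np.any(curve.rf <= 0):
        raise ValueError("RF values must be strictly positive")
    if window < 3:
        raise ValueError("window must be >= 3 points")
    n = len(curve.time_h)
    if window > n:
        raise ValueError(f"window {window} exceeds curve length {n}")
    ln_rf = np.log(curve.rf)
    best: float | None = None
    for start in range(n - window + 1):
        sl = slice(start, start + window)
        slope, r2 = _window_slope_r2(curve.time_h[sl], ln_rf[sl])
        if r2 >= r2_min and (best is None or slope > best):
            best = slope
    if best is None:
        raise NoExponentialPhaseError(
            f"no window of {window} points reached R^2 >= {r2_min}"
        )
    return float(best)


def doubling_time(mu_per_h: float) -> float:
    """Doubling time in hours, T_d = ln(2) / mu."""
    if mu_per_h <= 0:
        raise ValueError("growth rate must be positive")
    return math.log(2) / mu_per_h


def strain_doubling_time(mus: "list[float] | np.ndarray") -> float:
    """Mean of the replicate doubling times of a strain."""
    mus = np.asarray(mus, dtype=float)
    if len(mus) == 0:
        raise ValueError("no replicates")
    return float(np.mean([doubling_time(m) for m in mus]))


#: raw column -> transformed column for the log10-transformed variables
LOG10_COLUMNS = {
    "genome_size_bp": "genome_size_log10",
    "doubling_time_h": "doubling_time_log10",
    "min_cell_vol_um3": "min_cell_vol_log10",
    "max_cell_vol_um3": "max_cell_vol_log10",
}


def transform_traits(table: pd.DataFrame) -> pd.DataFrame:
    """Append the transformed analysis columns to a raw trait table.

    Genome size, doubling time and cell volumes are log10-transformed;
    repeat fraction is mapped by arcsin(sqrt(x)); GC percent and growth
    temperature pass through untouched.
    """
    out = table.copy()
    for raw, new in LOG10_COLUMNS.items():
        if raw in out.columns:
            vals = out[raw].to_numpy(dtype=float)
            if np.any(vals[~np.isnan(vals)] <= 0):
                raise ValueError(f"column {raw!r} has nonpositive values; cannot log10")
            out[new] = np.log10(vals)
    if "repeat_fraction" in out.columns:
        rf = out["repeat_fraction"].to_numpy(dtype=float)
        ok = ~np.isnan(rf)
        if np.any((rf[ok] < 0) | (rf[ok] > 1)):
            raise ValueError("repeat_fraction must lie in [0, 1]")
        out["repeat_asin"] = np.arcsin(np.sqrt(rf))
    return out
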