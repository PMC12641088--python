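"""Patlak graphical analysis of tracer kinetics and ROI aggregation.

For an irreversibly trapped tracer the two-compartment model is linear
in transformed coordinates:

    CT(t)/CP(t) = K1 * (integral_0^t CP dtau) / CP(t) + V0

where CT is tissue and CP plasma radioactivity concentration, K1 the
influx rate constant (proportional to regional cerebral blood flow) and
V0 the initial distribution volume.  Plotting CT/CP against the
normalized integral and fitting the linear portion by ordinary least
squares yields (K1, V0).

The module also aggregates per-ROI CBF values into the 24 arterial
territories (12 per hemisphere) as the area-weighted mean of the
constituent ROIs of each territory.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .data import HEMISPHERES, TERRITORIES


@dataclass(frozen=True)
class TimeActivityCurve:
    """Frame-wise plasma (cp) and tissue (ct) concentration curves.

    ``times`` are frame midpoints in seconds, strictly increasing.
    """

    times: np.ndarray
    cp: np.ndarray
    ct: np.ndarray

    def __post_init__(self) -> None:
        t, cp, ct = map(np.asarray, (self.times, self.cp, self.ct))
        if not (t.shape == cp.shape == ct.shape) or t.ndim != 1:
            raise ValueError("times, cp, ct must be 1-D arrays of equal length")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(cp < 0):
            raise ValueError("cp must be non-negative")


@dataclass(frozen=True)
class PatlakFit:
    """Estimated influx rate constant and distribution volume."""

    k1: float          # 1/min
    v0: float          # dimensionless
    fit_window: tuple[int, int]  # [start, stop) frame indices
    r2: float


def _cumulative_input(times: np.ndarray, cp: np.ndarray) -> np.ndarray:
    """Trapezoidal integral of cp from time 0 (units: cp * seconds).

    Below the first frame midpoint the input is taken constant at the
    first frame's value, so a constant input integrates to exactly
    cp * t.
    """
    inner = cumulative_trapezoid(cp, times, initial=0.0)
    return inner + cp[0] * times[0]


def patlak_transform(curve: TimeActivityCurve) -> tuple[np.ndarray, np.ndarray]:
    """Patlak coordinates: normalized integral (minutes) and CT/CP ratio.

    xs(t) = integral_0^t cp / cp(t), converted from seconds to minutes;
    ys(t) = ct(t) / cp(t).  Frames with cp == 0 are an error because
    both coordinates are undefined there.
    """
    t = np.asarray(curve.times, dtype=float)
    cp = np.asarray(curve.cp, dtype=float)
    ct = np.asarray(curve.ct, dtype=float)
    zero = np.flatnonzero(cp == 0.0)
    if zero.size:
        raise ValueError(f"cp is zero at frame(s) {zero.tolist()[:10]}")
    cum = _cumulative_input(t, cp)
    xs = cum / cp / 60.0
    ys = ct / cp
    return xs, ys


def patlak_fit(
    curve: TimeActivityCurve, window: tuple[int, int] | None = None
) -> PatlakFit:
    """OLS fit of the Patlak plot over the linear portion.

    ``window`` is a [start, stop) frame-index range; by default the fit
    uses the frames where the normalized integral exceeds 40% of its
    final value, a simple proxy for the late linear portion.
    """
    xs, ys = patlak_transform(curve)
    n = xs.size
    if window is None:
        start = int(np.argmax(xs >= 0.4 * xs[-1]))
        window = (start, n)
    lo, hi = window
    if not (0 <= lo < hi <= n):
        raise ValueError(f"fit window {window} outside curve of length {n}")
    if hi - lo < 3:
        raise ValueError("fit window must contain at least 3 frames")
    xw, yw = xs[lo:hi], ys[lo:hi]
    if np.ptp(xw) == 0.0:
        raise ValueError("degenerate fit window: no spread in the abscissa")
    slope, intercept = np.polyfit(xw, yw, 1)
    resid = yw - (slope * xw + intercept)
    ss_tot = float(((yw - yw.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - float(resid @ resid) / ss_tot
    return PatlakFit(k1=float(slope), v0=float(intercept),
                     fit_window=(lo, hi), r2=r2)


@dataclass
class ROITemplate:
    """Mapping of template ROIs to territories with area weights.

    ``table`` columns: roi_id, hemisphere, territory, area.  Every ROI
    belongs to exactly one of the 12 territories of one hemisphere and
    carries a positive area weight.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"roi_id", "hemisphere", "territory", "area"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"template missing column(s) {sorted(missing)}")
        bad_terr = set(self.table["territory"]) - set(TERRITORIES)
        if bad_terr:
            raise ValueError(f"unknown territory name(s) {sorted(bad_terr)}")
        bad_hemi = set(self.table["hemisphere"]) - set(HEMISPHERES)
        if bad_hemi:
            raise ValueError(f"unknown hemisphere(s) {sorted(bad_hemi)}")
        if self.table["roi_id"].duplicated().any():
            raise ValueError("duplicate roi_id in template")
        if (self.table["area"] <= 0).any():
            raise ValueError("ROI areas must be positive")
        self.table = self.table.reset_index(drop=True)


def toy_roi_template(rois_per_territory: int = 4) -> ROITemplate:
    """A small synthetic stand-in for the proprietary 636-ROI template.

    Each of the 24 hemisphere-territories gets ``rois_per_territory``
    ROIs with unequal areas (1, 2, 3, ...), exercising the weighted
    aggregation without reproducing the real template geometry.
    """
    rows = []
    roi = 0
    for territory in TERRITORIES:
        for hemi in HEMISPHERES:
            for j in range(rois_per_territory):
                roi += 1
                rows.append((f"roi{roi:03d}", hemi, territory, float(j + 1)))
    return ROITemplate(
        pd.DataFrame(rows, columns=["roi_id", "hemisphere", "territory", "area"])
    )


def aggregate_territories(
    roi_values: Mapping[str, float], template: ROITemplate
) -> dict[str, float]:
    """Area-weighted mean of constituent ROIs for each of the 24 regions.

    Returns a mapping region identifier ("{territory}_{hemisphere}") ->
    aggregated value.  Every template ROI must have a value.
    """
    missing = [r for r in template.table["roi_id"] if r not in roi_values]
    if missing:
        raise ValueError(f"missing ROI value(s): {missing}")
    out: dict[str, float] = {}
    for (territory, hemi), sub in template.table.groupby(
        ["territory", "hemisphere"], sort=False
    ):
        w = sub["area"].to_numpy(float)
        v = np.array([roi_values[r] for r in sub["roi_id"]], dtype=float)
        out[f"{territory}_{hemi}"] = float((w * v).sum() / w.sum())
    return out


def global_normalize(
    roi_values: Mapping[str, float], template: ROITemplate
) -> dict[str, float]:
    """Divide every ROI value by the all-ROI area-weighted mean.

    Optional post-step mirroring global count normalization of regional
    CBF maps.
    """
    w = template.table.set_index("roi_id")["area"]
    total = sum(w[r] * v for r, v in roi_values.items() if r in w.index)
    wsum = float(w[[r for r in roi_values if r in w.index]].sum())
    gmean = total / wsum
    if gmean <= 0:
        raise ValueError("global mean must be positive")
    return {r: v / gmean for r, v in roi_values.items()}
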