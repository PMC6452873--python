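"""Adaptive-laboratory-evolution growth analytics.

Per-flask growth rates from OD600 time series (slope of a least-squares fit
to ln OD vs time, in h^-1), with the three QC rejection rules used on
automated ALE platforms: fewer than three OD measurements, OD range outside
[0.2, 0.4], or regression R^2 below 0.98.  Generations per flask are
log2(final/initial OD); cumulative cell divisions (CCD) accumulate the net
cell-count increase across serial flasks and serve as the x-axis of fitness
trajectories, which are fitted with a monotone piecewise-cubic curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import PchipInterpolator
from sklearn.isotonic import IsotonicRegression

MIN_POINTS = 3
RANGE_LOW = 0.2
RANGE_HIGH = 0.4
MIN_R_SQUARED = 0.98

#: Default flask working volume (ml) and OD-to-cell-density conversion
#: (cells per ml per OD600 unit) used for cumulative cell divisions.
DEFAULT_VOLUME_ML = 15.0
DEFAULT_CELLS_PER_OD_ML = 1e9


@dataclass
class ODMeasurement:
    time: float  # hours
    od600: float

    def __post_init__(self):
        if self.od600 <= 0:
            raise ValueError(f"OD600 must be positive for log transform "
                             f"(got {self.od600} at t={self.time} h)")


@dataclass
class FlaskSeries:
    flask_id: str
    measurements: list[ODMeasurement]
    initial_od: float | None = None
    final_od: float | None = None

    def __post_init__(self):
        times = [m.time for m in self.measurements]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError(f"flask {self.flask_id}: times must be strictly increasing")
        if self.initial_od is None and self.measurements:
            self.initial_od = self.measurements[0].od600
        if self.final_od is None and self.measurements:
            self.final_od = self.measurements[-1].od600


@dataclass
class GrowthRateEstimate:
    flask_id: str
    mu: float  # h^-1
    r_squared: float | None
    n_points: int
    od_range: float
    accepted: bool
    rejection_reasons: list[str] = field(default_factory=list)


@dataclass
class PassageRecord:
    flask_id: str
    generations: float
    cell_divisions: float
    cumulative_cell_divisions: float


def estimate_growth_rate(series: FlaskSeries) -> GrowthRateEstimate:
    """OLS slope of ln OD600 vs time, with the three QC rejection rules.

    A series is rejected (``accepted=False``) if it has fewer than three
    measurements (``too_few_points``), its OD range falls below 0.2
    (``range_low``) or above 0.4 (``range_high``), or the regression's
    squared Pearson correlation is below 0.98 (``poor_fit``).  The flags are
    independent; a series can carry several.  Exactly three points is
    allowed.
    """
    t = np.array([m.time for m in series.measurements], dtype=float)
    od = np.array([m.od600 for m in series.measurements], dtype=float)
    n = len(t)
    reasons: list[str] = []
    od_range = float(od.max() - od.min()) if n else 0.0

    mu, r2 = float("nan"), None
    if n >= 2:
        fit = stats.linregress(t, np.log(od))
        mu = float(fit.slope)
    if n >= MIN_POINTS:
        r2 = float(fit.rvalue**2)

    if n < MIN_POINTS:
        reasons.append("too_few_points")
    if od_range < RANGE_LOW:
        reasons.append("range_low")
    elif od_range > RANGE_HIGH:
        reasons.append("range_high")
    if r2 is not None and r2 < MIN_R_SQUARED:
        reasons.append("poor_fit")

    return GrowthRateEstimate(
        flask_id=series.flask_id,
        mu=mu,
        r_squared=r2,
        n_points=n,
        od_range=od_range,
        accepted=not reasons,
        rejection_reasons=reasons,
    )


def generations(od_initial: float, od_final: float) -> float:
    """Doublings across one flask: log2(final OD / initial OD)."""
    if od_initial <= 0 or od_final <= 0:
        raise ValueError("ODs must be positive for generations")
    return math.log2(od_final / od_initial)


def cumulative_cell_divisions(
    passages: list[tuple[str, float, float]] | list[tuple[str, float, float, float]],
    cells_per_od_ml: float = DEFAULT_CELLS_PER_OD_ML,
    volume_ml: float = DEFAULT_VOLUME_ML,
) -> list[PassageRecord]:
    """Cumulative cell divisions across ordered serial flasks.

    Each passage is ``(flask_id, od_initial, od_final)`` with an optional
    fourth element overriding the flask volume in ml.  Divisions per flask
    are the net cell-count increase N_final − N_initial with
    N = OD × volume × cells_per_od_ml — a parameterized convention (see the
    methods note); the running sum is the CCD.
    """
    if cells_per_od_ml <= 0 or volume_ml <= 0:
        raise ValueError("conversion factor and volume must be positive")
    out: list[PassageRecord] = []
    ccd = 0.0
    for rec in passages:
        flask_id, od_i, od_f = rec[0], float(rec[1]), float(rec[2])
        vol = float(rec[3]) if len(rec) > 3 else volume_ml
        if od_i <= 0 or od_f <= 0 or vol <= 0:
            raise ValueError(f"flask {flask_id}: ODs and volume must be positive")
        divisions = (od_f - od_i) * vol * cells_per_od_ml
        ccd += divisions
        out.append(
            PassageRecord(
                flask_id=flask_id,
                generations=generations(od_i, od_f),
                cell_divisions=divisions,
                cumulative_cell_divisions=ccd,
            )
        )
    return out


class MonotoneTrajectory:
    """Non-decreasing growth-rate-vs-CCD curve.

    Isotonic regression projects the observed rates onto the nearest
    non-decreasing sequence; a shape-preserving piecewise-cubic Hermite
    interpolant (PCHIP) through the isotonic values then gives a smooth
    curve that is non-decreasing everywhere.  Evaluation outside the data
    range clamps to the end values.
    """

    def __init__(self, ccd: np.ndarray, rate: np.ndarray):
        order = np.argsort(ccd)
        ccd, rate = np.asarray(ccd, float)[order], np.asarray(rate, float)[order]
        # aggregate duplicate x by mean before the isotonic fit
        df = pd.DataFrame({"x": ccd, "y": rate}).groupby("x", as_index=False).mean()
        x, y = df["x"].to_numpy(), df["y"].to_numpy()
        if len(x) < 2:
            raise ValueError("trajectory fit needs >= 2 distinct CCD values")
        iso = IsotonicRegression(increasing=True).fit(x, y)
        self.x = x
        self.y = iso.predict(x)
        self._interp = PchipInterpolator(self.x, self.y, extrapolate=False)

    def __call__(self, ccd) -> np.ndarray:
        ccd = np.asarray(ccd, dtype=float)
        out = self._interp(np.clip(ccd, self.x[0], self.x[-1]))
        return out if out.shape else float(out)


def fit_trajectory(points: list[tuple[float, float]]) -> MonotoneTrajectory:
    """Fit the monotone piecewise-cubic growth-rate trajectory to (CCD, rate) points."""
    if len(points) < 2:
        raise ValueError("trajectory fit needs >= 2 points")
    arr = np.asarray(points, dtype=float)
    return MonotoneTrajectory(arr[:, 0], arr[:, 1])


# ---------------------------------------------------------------------------
# CSV layer
# ---------------------------------------------------------------------------

def read_od_csv(path) -> list[FlaskSeries]:
    """Read long-format OD series: columns flask_id, time_h, od600."""
    df = pd.read_csv(path)
    required = {"flask_id", "time_h", "od600"}
    if not required <= set(df.columns):
        raise ValueError(f"OD CSV must have columns {sorted(required)}")
    out = []
    for fid, grp in df.groupby("flask_id", sort=False):
        grp = grp.sort_values("time_h")
        out.append(
            FlaskSeries(
                flask_id=str(fid),
                measurements=[
                    ODMeasurement(float(t), float(od))
                    for t, od in zip(grp["time_h"], grp["od600"])
                ],
            )
        )
    return out


def estimates_to_frame(estimates: list[GrowthRateEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "flask_id": [e.flask_id for e in estimates],
            "mu_per_h": [e.mu for e in estimates],
            "r_squared": [e.r_squared for e in estimates],
            "n_points": [e.n_points for e in estimates],
            "od_range": [e.od_range for e in estimates],
            "accepted": [e.accepted for e in estimates],
            "rejection_reasons": [";".join(e.rejection_reasons) for e in estimates],
        }
    )
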