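"""Linear calibration of enzymatic activity against a conformational distance.

The activity a positive allosteric modulator (PAM) induces in LCAT, expressed
as percent of the no-PAM control (100% = control), is regressed on the mean
CYS50–ASN65 α-carbon distance its bound complex adopts in MD.  A fitted line
then predicts the activity of new screening candidates from their simulated
distances alone, before any wet-lab work.

The model follows the statsmodels idiom: :class:`ActivityCalibration` is
built from data and its :meth:`~ActivityCalibration.fit` returns a
:class:`CalibrationResults` carrying the estimates, their uncertainties and a
``summary()`` table; prediction with t-based intervals hangs off the results
object.

The regression is unweighted ordinary least squares by default.  Both axes
carry SEMs in practice, but an errors-in-variables treatment is not part of
the calibration contract; inverse-variance weighting by the activity SEMs is
available behind ``weighted=True``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .distance import ReplicateSummary

__all__ = [
    "CalibrationPoint",
    "ActivityCalibration",
    "CalibrationResults",
    "ActivityPrediction",
    "pearson_r",
    "rank_candidates",
]


@dataclass
class CalibrationPoint:
    """One reference compound: its MD distance summary and measured activity."""

    compound_id: str
    distance: ReplicateSummary
    activity_pct: float
    activity_sem: float = 0.0

    def __post_init__(self) -> None:
        if self.activity_pct <= 0:
            raise ValueError(f"{self.compound_id}: activity_pct must be > 0")
        if self.distance.mean <= 0:
            raise ValueError(f"{self.compound_id}: distance mean must be > 0")


@dataclass
class ActivityPrediction:
    """Predicted activity of one candidate with a prediction interval."""

    compound_id: str
    predicted_activity_pct: float
    interval_low: float
    interval_high: float
    reference_margin: float
    level: float = 0.95

    def __post_init__(self) -> None:
        if not self.interval_low <= self.predicted_activity_pct <= self.interval_high:
            raise ValueError("prediction must lie inside its interval")


def _as_mean(distance) -> float:
    if isinstance(distance, ReplicateSummary):
        return float(distance.mean)
    return float(distance)


def _unit_of(distance) -> str | None:
    if isinstance(distance, ReplicateSummary):
        return distance.unit
    return None


class ActivityCalibration:
    """OLS model of activity (% of control) on mean residue-pair distance.

    Parameters
    ----------
    distances : array-like or list of ReplicateSummary
        Mean distances, one per reference compound.
    activities : array-like
        Activities as percent of the no-PAM control.
    compound_ids : list of str, optional
    activity_sems : array-like, optional
        Used only when ``weighted=True`` (weights 1/sem²).
    distance_unit : str
        Unit tag ("nm" or "angstrom"); predictions refuse mismatched units.
    weighted : bool
        Inverse-variance weighting by activity SEMs (off by default).
    """

    def __init__(
        self,
        distances,
        activities,
        compound_ids=None,
        activity_sems=None,
        distance_unit: str = "nm",
        weighted: bool = False,
    ):
        units = {u for u in (_unit_of(d) for d in distances) if u is not None}
        if len(units) > 1:
            raise ValueError(f"calibration distances mix units: {sorted(units)}")
        if units and distance_unit not in units:
            distance_unit = units.pop()
        self.x = np.asarray([_as_mean(d) for d in distances], dtype=float)
        self.y = np.asarray(activities, dtype=float)
        if self.x.shape != self.y.shape:
            raise ValueError("distances and activities differ in length")
        n = len(self.x)
        if n < 3:
            raise ValueError(f"need at least 3 calibration points, got {n}")
        if np.ptp(self.x) == 0:
            raise ValueError("degenerate calibration: all distances equal")
        self.compound_ids = (
            list(compound_ids) if compound_ids is not None else [f"c{i}" for i in range(n)]
        )
        self.activity_sems = (
            np.asarray(activity_sems, dtype=float) if activity_sems is not None else None
        )
        self.distance_unit = distance_unit
        self.weighted = weighted

    @classmethod
    def from_points(cls, points: list[CalibrationPoint], **kwargs) -> "ActivityCalibration":
        return cls(
            distances=[p.distance for p in points],
            activities=[p.activity_pct for p in points],
            compound_ids=[p.compound_id for p in points],
            activity_sems=[p.activity_sem for p in points],
            **kwargs,
        )

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        distance_col: str = "distance",
        activity_col: str = "activity_pct",
        id_col: str = "compound_id",
        **kwargs,
    ) -> "ActivityCalibration":
        return cls(
            distances=df[distance_col].to_numpy(),
            activities=df[activity_col].to_numpy(),
            compound_ids=df[id_col].tolist() if id_col in df else None,
            **kwargs,
        )

    def fit(self) -> "CalibrationResults":
        exog = sm.add_constant(self.x)
        if self.weighted:
            if self.activity_sems is None or np.any(self.activity_sems <= 0):
                raise ValueError("weighted fit requires positive activity SEMs")
            res = sm.WLS(self.y, exog, weights=1.0 / self.activity_sems**2).fit()
        else:
            res = sm.OLS(self.y, exog).fit()
        r = pearson_r(self.x, self.y)
        return CalibrationResults(model=self, _sm_results=res, r=r)


@dataclass
class CalibrationResults:
    """Fitted calibration line with prediction support."""

    model: ActivityCalibration
    _sm_results: object
    r: float

    @property
    def intercept(self) -> float:
        return float(self._sm_results.params[0])

    @property
    def slope(self) -> float:
        return float(self._sm_results.params[1])

    @property
    def slope_se(self) -> float:
        return float(self._sm_results.bse[1])

    @property
    def intercept_se(self) -> float:
        return float(self._sm_results.bse[0])

    @property
    def r_squared(self) -> float:
        return float(self.r**2)

    @property
    def residual_se(self) -> float:
        # sqrt of residual mean square on n-2 dof
        return float(np.sqrt(self._sm_results.mse_resid))

    @property
    def n(self) -> int:
        return len(self.model.x)

    @property
    def distance_unit(self) -> str:
        return self.model.distance_unit

    @property
    def fittedvalues(self) -> np.ndarray:
        return np.asarray(self._sm_results.fittedvalues)

    @property
    def residuals(self) -> np.ndarray:
        return np.asarray(self._sm_results.resid)

    def predict(
        self,
        distance,
        compound_id: str = "",
        reference_activity_pct: float = 100.0,
        level: float = 0.95,
    ) -> ActivityPrediction:
        """Point prediction with a t-based prediction interval.

        ``reference_activity_pct`` sets the benchmark against which the
        margin is reported, e.g. 100 for the no-PAM control or 230 for the
        strongest reference activator.
        """
        unit = _unit_of(distance)
        if unit is not None and unit != self.distance_unit:
            raise ValueError(
                f"distance unit {unit!r} does not match model unit "
                f"{self.distance_unit!r}"
            )
        x = _as_mean(distance)
        frame = self._sm_results.get_prediction(
            np.array([[1.0, x]])
        ).summary_frame(alpha=1.0 - level)
        yhat = float(frame["mean"].iloc[0])
        lo = float(frame["obs_ci_lower"].iloc[0])
        hi = float(frame["obs_ci_upper"].iloc[0])
        if self.residual_se < 1e-12:  # perfect line: no residual scatter
            lo = hi = yhat
        return ActivityPrediction(
            compound_id=compound_id,
            predicted_activity_pct=yhat,
            interval_low=lo,
            interval_high=hi,
            reference_margin=yhat - reference_activity_pct,
            level=level,
        )

    def predict_many(
        self,
        summaries: dict,
        reference_activity_pct: float = 100.0,
        level: float = 0.95,
    ) -> list[ActivityPrediction]:
        return [
            self.predict(d, compound_id=cid, reference_activity_pct=reference_activity_pct, level=level)
            for cid, d in summaries.items()
        ]

    def summary(self) -> str:
        lines = [
            "Activity-vs-distance calibration (OLS)",
            f"  n points        : {self.n}",
            f"  slope           : {self.slope:.4f} %/{self.distance_unit} (SE {self.slope_se:.4f})",
            f"  intercept       : {self.intercept:.4f} % (SE {self.intercept_se:.4f})",
            f"  Pearson r       : {self.r:.4f}",
            f"  R-squared       : {self.r_squared:.4f}",
            f"  residual SE     : {self.residual_se:.4f} % (df={self.n - 2})",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r": self.r,
            "r_squared": self.r_squared,
            "residual_se": self.residual_se,
            "n": self.n,
            "distance_unit": self.distance_unit,
        }

    def plot(self, ax=None):
        """Scatter of calibration points with the fitted line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self.model.x, self.model.y, label="calibration points")
        xs = np.linspace(self.model.x.min(), self.model.x.max(), 50)
        ax.plot(xs, self.intercept + self.slope * xs, label="OLS fit")
        ax.set_xlabel(f"distance ({self.distance_unit})")
        ax.set_ylabel("activity (% of control)")
        ax.legend()
        return ax


def pearson_r(x, y) -> float:
    """Product-moment correlation; errors on zero variance or length < 3."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance input")
    return float(scipy.stats.pearsonr(x, y).statistic)


def rank_candidates(
    predictions: list[ActivityPrediction], threshold_pct: float = 100.0
) -> pd.DataFrame:
    """Rank predictions by activity, flagging predicted activators.

    Returns a DataFrame sorted descending by predicted activity with an
    ``is_activator`` flag (predicted ≥ threshold; 100% = no-PAM control).
    """
    if not predictions:
        raise ValueError("no predictions to rank")
    df = pd.DataFrame(
        {
            "compound_id": [p.compound_id for p in predictions],
            "predicted_activity_pct": [p.predicted_activity_pct for p in predictions],
            "interval_low": [p.interval_low for p in predictions],
            "interval_high": [p.interval_high for p in predictions],
            "reference_margin": [p.reference_margin for p in predictions],
        }
    )
    df["is_activator"] = df["predicted_activity_pct"] >= threshold_pct
    df = df.sort_values(
        ["predicted_activity_pct", "compound_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    df.index = df.index + 1
    df.index.name = "rank"
    return df
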