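"""Per-subject individualized QT interval (QTi) from the QT-RR scatter.

The subject's template-level (QT, RR) points are fitted by ordinary
least squares, ``QT = alpha * RR + beta``, where alpha is the QT-RR
slope quantifying QT rate dependence. QTi is the fitted QT at an RR
interval of 1,000 ms (60 beats/min): ``QTi = alpha * 1000 + beta``.
Evaluations on the alternative RR grid 600-1400 ms use the same line;
extrapolation outside the observed RR range is permitted but flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RR_GRID",
    "FitError",
    "QTRRModel",
    "QTRRResults",
    "fit_qt_rr",
    "qti_at",
    "subject_qti",
]

RR_GRID = (600, 700, 800, 900, 1000, 1100, 1200, 1300, 1400)
MIN_POINTS_DEFAULT = 480  # 4 h of valid 30-s windows


class FitError(ValueError):
    """Raised when a QT-RR regression cannot be fitted."""


class QTRRModel:
    """Linear QT-RR model for one subject.

    Parameters
    ----------
    qt_ms, rr_ms : array-like
        Template-level QT and the mean RR of the same 30-s window (ms).
    min_points : int
        Minimum number of points for a valid fit. The default, 480,
        matches 4 h of valid 30-s windows; pass a smaller value for
        deliberately short recordings.
    """

    def __init__(self, qt_ms, rr_ms, min_points: int = MIN_POINTS_DEFAULT):
        self.qt_ms = np.asarray(qt_ms, dtype=float)
        self.rr_ms = np.asarray(rr_ms, dtype=float)
        if self.qt_ms.shape != self.rr_ms.shape:
            raise ValueError("qt_ms and rr_ms must have equal length")
        self.min_points = int(min_points)

    @classmethod
    def from_measurements(cls, measurements,
                          min_points: int = MIN_POINTS_DEFAULT):
        """Build from :class:`~qtiholter.processing.QTMeasurement`
        records, keeping only ok-quality points (this drops everything
        flagged no-T-wave, onset failure or QT > 700 ms)."""
        ok = [m for m in measurements if m.quality == "ok"]
        return cls([m.qt_ms for m in ok], [m.rr_ms for m in ok],
                   min_points=min_points)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, qt_col: str = "qt_ms",
                       rr_col: str = "rr_ms",
                       min_points: int = MIN_POINTS_DEFAULT):
        d = df.dropna(subset=[qt_col, rr_col])
        return cls(d[qt_col].to_numpy(), d[rr_col].to_numpy(),
                   min_points=min_points)

    def fit(self) -> "QTRRResults":
        """Ordinary least squares; raises :class:`FitError` on fewer
        than ``min_points`` points or zero RR spread."""
        n = self.qt_ms.size
        if n < max(self.min_points, 2):
            raise FitError(
                f"only {n} valid points (minimum {self.min_points})")
        if np.ptp(self.rr_ms) == 0.0:
            raise FitError("zero RR variance: slope is unidentifiable")
        if np.ptp(self.qt_ms) == 0.0:
            # degenerate flat response: slope 0, r defined as 0
            alpha, beta, r = 0.0, float(self.qt_ms[0]), 0.0
            alpha_se = beta_se = 0.0
        else:
            res = stats.linregress(self.rr_ms, self.qt_ms)
            alpha, beta, r = float(res.slope), float(res.intercept), float(
                res.rvalue)
            alpha_se, beta_se = float(res.stderr), float(res.intercept_stderr)
        return QTRRResults(
            alpha=alpha, beta=beta, pearson_r=r,
            alpha_se=alpha_se, beta_se=beta_se, n_points=n,
            rr_range_ms=(float(self.rr_ms.min()), float(self.rr_ms.max())),
        )


@dataclass
class QTRRResults:
    """Fitted QT-RR line, its uncertainty and QTi evaluations."""

    alpha: float
    beta: float
    pearson_r: float
    alpha_se: float
    beta_se: float
    n_points: int
    rr_range_ms: tuple

    @property
    def qti_1000(self) -> float:
        """Individualized QT interval: fitted QT at RR = 1,000 ms."""
        return self.alpha * 1000.0 + self.beta

    def qti_at(self, rr_ms: float) -> float:
        """Fitted QT (ms) at an arbitrary RR interval."""
        return self.alpha * rr_ms + self.beta

    def predict(self, rr_ms) -> np.ndarray:
        return self.alpha * np.asarray(rr_ms, dtype=float) + self.beta

    def is_extrapolated(self, rr_ms: float) -> bool:
        """True when ``rr_ms`` lies outside the observed RR range (the
        line may still be evaluated there; flag it)."""
        lo, hi = self.rr_range_ms
        return not (lo <= rr_ms <= hi)

    def qti_grid(self, grid=RR_GRID) -> dict:
        """QTi evaluations over the alternative RR grid, with
        extrapolation flags."""
        return {
            int(rr): {"qti_ms": self.qti_at(rr),
                      "extrapolated": self.is_extrapolated(rr)}
            for rr in grid
        }

    def to_row(self) -> dict:
        row = {
            "alpha": self.alpha,
            "beta": self.beta,
            "pearson_r": self.pearson_r,
            "n_points": self.n_points,
            "rr_min": self.rr_range_ms[0],
            "rr_max": self.rr_range_ms[1],
        }
        for rr in RR_GRID:
            row[f"qti_{rr}"] = self.qti_at(rr)
        return row

    def summary(self) -> str:
        lines = [
            "QT-RR linear regression (QT = alpha * RR + beta)",
            "-" * 48,
            f"n points            {self.n_points:>10d}",
            f"alpha (QT-RR slope) {self.alpha:>10.4f}  (SE {self.alpha_se:.4f})",
            f"beta (ms)           {self.beta:>10.1f}  (SE {self.beta_se:.1f})",
            f"Pearson r           {self.pearson_r:>10.3f}",
            f"RR range (ms)       {self.rr_range_ms[0]:>6.0f} - "
            f"{self.rr_range_ms[1]:.0f}",
            f"QTi at 1,000 ms     {self.qti_1000:>10.1f} ms"
            + ("  [extrapolated]" if self.is_extrapolated(1000.0) else ""),
        ]
        return "\n".join(lines)


def fit_qt_rr(measurements, min_points: int = MIN_POINTS_DEFAULT) -> QTRRResults:
    """Fit the per-subject QT-RR line from measurement records."""
    return QTRRModel.from_measurements(measurements,
                                       min_points=min_points).fit()


def qti_at(results: QTRRResults, rr_ms: float) -> float:
    """Functional alias for :meth:`QTRRResults.qti_at`."""
    return results.qti_at(rr_ms)


def subject_qti(
    recording,
    min_points: int = MIN_POINTS_DEFAULT,
    **measure_kwargs,
):
    """Full per-subject pipeline: measure the recording, fit the line.

    Returns ``(results, report)``; ``results`` is None when the
    recording is invalid (insufficient useful registration) or the fit
    fails, with the reason recorded on the report.
    """
    from .processing import measure_recording

    measurements, report = measure_recording(recording, **measure_kwargs)
    if report.status != "ok":
        return None, report
    try:
        results = fit_qt_rr(measurements, min_points=min_points)
    except FitError as exc:
        report.status = "invalid"
        report.reason = f"regression failure: {exc}"
        return None, report
    return results, report
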