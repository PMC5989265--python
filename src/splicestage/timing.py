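"""Sigmoidal switch-timing model for developmental Ψ trajectories.

Each exon's inclusion time course is parameterized as

    Ψ(t) = a + (k − a) / (1 + exp(−b (t − m)))

with ``a``/``k`` the low/high inclusion levels, ``b`` the slope (its
sign carries the switch direction) and ``m`` the switch time — the
point of maximal inclusion change — on a log10 post-conception-day
axis. Fit quality is the normalized residual

    ε = sqrt( Σ_i (Ψ_i − Ψ̂_i)² / (N (k − a)) )

over the N non-missing time points, and a fit is reliable when
ε < 0.15, k − a > 0.2 and m > 0.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import expit
from sklearn.base import BaseEstimator

from .datamodel import PsiMatrix

__all__ = [
    "MOUSE_GESTATION_DAYS",
    "DAYS_PER_MONTH",
    "TimeAxis",
    "to_log10_pcdays",
    "sigmoid",
    "normalized_residual",
    "SigmoidFit",
    "SigmoidSwitchModel",
    "fit_sigmoid",
    "rank_by_switch_time",
]

MOUSE_GESTATION_DAYS = 19.5
DAYS_PER_MONTH = 30.44

_LABEL_RE = re.compile(
    r"^(?:E(?P<e>\d+(?:\.\d+)?)|P(?P<p>\d+(?:\.\d+)?)|"
    r"(?P<mo>\d+(?:\.\d+)?)\s*(?:mo|months?))$"
)


def to_log10_pcdays(age_label: str, gestation_days: float = MOUSE_GESTATION_DAYS) -> float:
    """Convert an age label (E14.5, P4, 21mo, ...) to log10 post-conception days.

    Embryonic ages are post-conception days directly; postnatal days add
    the gestation length; months convert at 30.44 days/month.
    """
    m = _LABEL_RE.match(age_label.strip())
    if not m:
        raise ValueError(f"unparseable age label: {age_label!r}")
    if m.group("e") is not None:
        pcdays = float(m.group("e"))
    elif m.group("p") is not None:
        pcdays = gestation_days + float(m.group("p"))
    else:
        pcdays = gestation_days + DAYS_PER_MONTH * float(m.group("mo"))
    if pcdays <= 0:
        raise ValueError(f"non-positive post-conception age for {age_label!r}")
    return float(np.log10(pcdays))


@dataclass
class TimeAxis:
    """Ordered stage labels with their log10 post-conception-day values."""

    labels: list[str]
    t: np.ndarray

    @classmethod
    def from_labels(cls, labels, gestation_days: float = MOUSE_GESTATION_DAYS):
        t = np.array([to_log10_pcdays(lb, gestation_days) for lb in labels])
        if not np.all(np.diff(t) > 0):
            raise ValueError("age labels must be strictly increasing in time")
        return cls(labels=list(labels), t=t)

    def __len__(self) -> int:
        return len(self.labels)


def sigmoid(t, a, k, b, m):
    """Four-parameter logistic: a + (k − a)/(1 + e^{−b(t−m)})."""
    t = np.asarray(t, dtype=float)
    return a + (k - a) * expit(b * (t - m))


def normalized_residual(traj, fitted, k, a) -> float:
    """Residual normalized by trajectory span: sqrt(SSE / (N (k−a)))."""
    traj = np.asarray(traj, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    keep = np.isfinite(traj)
    if k - a <= 0:
        return np.inf
    n = keep.sum()
    if n == 0:
        return np.inf
    sse = float(np.sum((traj[keep] - fitted[keep]) ** 2))
    return float(np.sqrt(sse / (n * (k - a))))


@dataclass
class SigmoidFit:
    """Fitted switch parameters for one exon."""

    a: float
    k: float
    b: float
    m: float
    epsilon: float
    reliable: bool
    n_points: int

    def predict(self, t):
        return sigmoid(t, self.a, self.k, self.b, self.m)


def _fit_one(
    t: np.ndarray,
    y: np.ndarray,
    m_bounds: tuple[float, float],
    eps_max: float,
    span_min: float,
) -> SigmoidFit:
    """Multi-start bounded least squares for one trajectory."""
    lo = np.array([0.0, 0.0, -50.0, m_bounds[0]])
    hi = np.array([1.0, 1.0, 50.0, m_bounds[1]])

    # m starts: observed half-range crossing plus time-axis quantiles
    ylo, yhi = y.min(), y.max()
    half = (ylo + yhi) / 2.0
    crossing = t[np.argmin(np.abs(y - half))]
    m_starts = [crossing] + list(np.quantile(t, [0.25, 0.5, 0.75]))

    best = None
    best_sse = np.inf
    for m0 in m_starts:
        for b0 in (4.0, -4.0):
            x0 = np.clip(
                np.array([ylo, yhi, b0, m0]),
                lo + 1e-9,
                hi - 1e-9,
            )
            try:
                res = least_squares(
                    lambda p: sigmoid(t, *p) - y,
                    x0,
                    bounds=(lo, hi),
                    method="trf",
                )
            except Exception:
                continue
            sse = float(np.sum(res.fun**2))
            if sse < best_sse - 1e-12:
                best_sse = sse
                best = res.x
    a, k, b, m = best
    if a > k:  # canonical orientation: a = low level, direction in sign(b)
        a, k, b = k, a, -b
    eps = normalized_residual(y, sigmoid(t, a, k, b, m), k, a)
    reliable = bool(eps < eps_max and (k - a) > span_min and m > 0)
    return SigmoidFit(
        a=float(a), k=float(k), b=float(b), m=float(m),
        epsilon=float(eps), reliable=reliable, n_points=len(y),
    )


class SigmoidSwitchModel(BaseEstimator):
    """Per-exon sigmoidal switch-time estimator.

    Fits the four-parameter logistic independently to each row of an
    exon × time-point Ψ matrix by bounded multi-start nonlinear least
    squares, scores each fit with the normalized residual ε, and flags
    fits as reliable when ``ε < eps_max``, ``k − a > span_min`` and
    ``m > 0``.

    Parameters
    ----------
    eps_max, span_min : float
        Reliability thresholds on fit quality and trajectory span.
    min_points : int
        Minimum non-missing time points required to attempt a fit.
    m_margin : float
        Switch time is constrained to [min(t) − m_margin, max(t) + m_margin].

    Attributes
    ----------
    fits_ : pandas.DataFrame
        One row per exon: a, k, b, m, epsilon, reliable, n_points.
    time_axis_ : TimeAxis
    """

    def __init__(
        self,
        eps_max: float = 0.15,
        span_min: float = 0.2,
        min_points: int = 5,
        m_margin: float = 0.5,
        gestation_days: float = MOUSE_GESTATION_DAYS,
    ):
        self.eps_max = eps_max
        self.span_min = span_min
        self.min_points = min_points
        self.m_margin = m_margin
        self.gestation_days = gestation_days

    def fit(self, X, y=None, *, stage_labels=None, times=None):
        """Fit per-row sigmoids.

        ``X`` is an exon × time-point array/DataFrame of Ψ values (NaN =
        missing); supply either ``stage_labels`` (age labels, parsed to
        log10 pc-days) or explicit ``times``.
        """
        if isinstance(X, PsiMatrix):
            X = X.psi
        if isinstance(X, pd.DataFrame):
            index = X.index
            if stage_labels is None and times is None:
                stage_labels = list(X.columns)
            values = X.to_numpy(dtype=float)
        else:
            values = np.asarray(X, dtype=float)
            index = pd.RangeIndex(len(values))
        if times is not None:
            axis = TimeAxis(labels=[str(x) for x in times], t=np.asarray(times, float))
        else:
            axis = TimeAxis.from_labels(stage_labels, self.gestation_days)
        if values.shape[1] != len(axis):
            raise ValueError("time axis length must match number of columns")

        m_bounds = (axis.t.min() - self.m_margin, axis.t.max() + self.m_margin)
        records = []
        for row in values:
            keep = np.isfinite(row)
            if keep.sum() < self.min_points:
                records.append(
                    dict(a=np.nan, k=np.nan, b=np.nan, m=np.nan,
                         epsilon=np.inf, reliable=False, n_points=int(keep.sum()))
                )
                continue
            f = _fit_one(axis.t[keep], row[keep], m_bounds,
                         self.eps_max, self.span_min)
            records.append(vars(f))
        self.fits_ = pd.DataFrame(records, index=index)
        self.time_axis_ = axis
        return self

    def rank_by_switch_time(self) -> pd.Index:
        """Reliable exons in ascending switch-time order (ties by exon_id)."""
        return rank_by_switch_time(self.fits_)


def fit_sigmoid(
    traj,
    stage_labels=None,
    times=None,
    min_points: int = 5,
    **kwargs,
) -> SigmoidFit:
    """Fit the sigmoid to a single trajectory (thin estimator wrapper)."""
    traj = np.asarray(traj, dtype=float)
    model = SigmoidSwitchModel(min_points=min_points, **kwargs)
    model.fit(traj[None, :], stage_labels=stage_labels, times=times)
    row = model.fits_.iloc[0]
    return SigmoidFit(
        a=row["a"], k=row["k"], b=row["b"], m=row["m"],
        epsilon=row["epsilon"], reliable=bool(row["reliable"]),
        n_points=int(row["n_points"]),
    )


def rank_by_switch_time(fits: pd.DataFrame) -> pd.Index:
    """Order reliable fits by ascending switch time m; ties by exon_id."""
    reliable = fits[fits["reliable"].astype(bool)].copy()
    reliable["_id"] = reliable.index.astype(str)
    return reliable.sort_values(["m", "_id"], kind="mergesort").index
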