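"""Agreement metrics between predicted and reference quality scores.

Nine metrics: MSE, R², MAE, RMSE, explained variance, median absolute
error, and the three correlation coefficients standard in image quality
assessment — Pearson (PLCC), Spearman (SROCC) and Kendall tau-b (KLCC).

Degenerate inputs (constant vectors, where a correlation or R² is
mathematically undefined) raise :class:`UndefinedMetricError` instead of
returning NaN; :func:`evaluate_all` converts such failures into missing
fields with a warning so batch pipelines fail soft but loud.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, fields

import numpy as np
from scipy import stats

from ._errors import UndefinedMetricError, ValidationError

__all__ = [
    "ScorePair",
    "EvalReport",
    "plcc",
    "srocc",
    "klcc",
    "mse",
    "mae",
    "rmse",
    "medae",
    "r_squared",
    "explained_variance",
    "evaluate_all",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScorePair:
    """Aligned predicted / actual score vectors."""

    predicted: np.ndarray
    actual: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.predicted, dtype=np.float64)
        a = np.asarray(self.actual, dtype=np.float64)
        if p.ndim != 1 or a.ndim != 1:
            raise ValidationError("score vectors must be 1-D")
        if p.shape != a.shape:
            raise ValidationError(f"length mismatch: {p.shape} vs {a.shape}")
        if p.size < 2:
            raise ValidationError("need at least 2 paired scores")
        if not (np.all(np.isfinite(p)) and np.all(np.isfinite(a))):
            raise ValidationError("scores must be finite")
        object.__setattr__(self, "predicted", p)
        object.__setattr__(self, "actual", a)

    @property
    def n(self) -> int:
        return self.predicted.size


# Field order mirrors the conventional error-metric table layout.
@dataclass(frozen=True)
class EvalReport:
    """All nine metrics; a field is None when undefined for the input."""

    mse: float | None
    r_squared: float | None
    mae: float | None
    rmse: float | None
    explained_variance: float | None
    median_absolute_error: float | None
    plcc: float | None
    srocc: float | None
    klcc: float | None

    #: Human-readable column names, in report order.
    COLUMNS = (
        "Mean squared error", "R Squared", "Mean absolute error", "RMSE",
        "Explained variance score", "Median absolute error",
        "PLCC", "SROCC", "KLCC",
    )

    def as_dict(self) -> dict[str, float | None]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def to_json(self) -> str:
        return json.dumps(self.as_dict(), indent=2)

    def to_csv_row(self) -> str:
        header = ",".join(self.COLUMNS)
        vals = ",".join(
            "" if v is None else f"{v:.6g}" for v in self.as_dict().values()
        )
        return header + "\n" + vals + "\n"


def _check_nonconstant(x: np.ndarray, name: str) -> None:
    if np.all(x == x[0]):
        raise UndefinedMetricError(f"{name} vector is constant; metric undefined")


def plcc(pair: ScorePair) -> float:
    """Pearson linear correlation coefficient."""
    _check_nonconstant(pair.predicted, "predicted")
    _check_nonconstant(pair.actual, "actual")
    p, a = pair.predicted, pair.actual
    dp, da = p - p.mean(), a - a.mean()
    return float(np.sum(dp * da) / np.sqrt(np.sum(dp**2) * np.sum(da**2)))


def _mean_ranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def srocc(pair: ScorePair) -> float:
    """Spearman rank-order correlation (tie-aware mean-rank form).

    Equals the classic 1 − 6ΣRᵢ²/(S(S²−1)) closed form exactly when
    there are no ties.
    """
    _check_nonconstant(pair.predicted, "predicted")
    _check_nonconstant(pair.actual, "actual")
    rp = _mean_ranks(pair.predicted)
    ra = _mean_ranks(pair.actual)
    return plcc(ScorePair(predicted=rp, actual=ra))


def klcc(pair: ScorePair) -> float:
    """Kendall's tau-b: (Sc − Sd)/√((Sc+Sd+Tp)(Sc+Sd+Ta)).

    Pairs tied in both variables count toward neither tie term.
    """
    _check_nonconstant(pair.predicted, "predicted")
    _check_nonconstant(pair.actual, "actual")
    tau = stats.kendalltau(pair.predicted, pair.actual, variant="b").statistic
    if not np.isfinite(tau):
        raise UndefinedMetricError("tau-b denominator is zero")
    return float(tau)


def mse(pair: ScorePair) -> float:
    """Mean squared error."""
    return float(np.mean((pair.predicted - pair.actual) ** 2))


def mae(pair: ScorePair) -> float:
    """Mean absolute error."""
    return float(np.mean(np.abs(pair.predicted - pair.actual)))


def rmse(pair: ScorePair) -> float:
    """Root mean squared error (√MSE)."""
    return float(np.sqrt(mse(pair)))


def medae(pair: ScorePair) -> float:
    """Median absolute error (standard median: midpoint for even n)."""
    return float(np.median(np.abs(pair.predicted - pair.actual)))


def r_squared(pair: ScorePair) -> float:
    """Coefficient of determination R² = 1 − Σ(a−p)²/Σ(a−ā)²."""
    _check_nonconstant(pair.actual, "actual")
    a, p = pair.actual, pair.predicted
    return float(1.0 - np.sum((a - p) ** 2) / np.sum((a - a.mean()) ** 2))


def explained_variance(pair: ScorePair) -> float:
    """Explained variance 1 − Var(a−p)/Var(a) (population variance).

    Unlike R², a constant prediction offset does not lower this score.
    """
    _check_nonconstant(pair.actual, "actual")
    a, p = pair.actual, pair.predicted
    return float(1.0 - np.var(a - p) / np.var(a))


_METRIC_FUNCS = {
    "mse": mse,
    "r_squared": r_squared,
    "mae": mae,
    "rmse": rmse,
    "explained_variance": explained_variance,
    "median_absolute_error": medae,
    "plcc": plcc,
    "srocc": srocc,
    "klcc": klcc,
}


def evaluate_all(pair: ScorePair) -> EvalReport:
    """Compute every metric; undefined ones become None with a warning."""
    out: dict[str, float | None] = {}
    for name, fn in _METRIC_FUNCS.items():
        try:
            out[name] = fn(pair)
        except UndefinedMetricError as exc:
            logger.warning("metric %s undefined: %s", name, exc)
            out[name] = None
    return EvalReport(**out)
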