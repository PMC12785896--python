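"""Model evaluation: correlation R, RMSE, MAE, RPD, and the paired t-test.

RPD (ratio of performance to deviation) is the standard deviation of the
measured reference values divided by the RMSE of prediction; RPD > 2.5 is the
conventional bar for a quantitatively reliable NIR calibration. The SD uses
the sample convention (n-1 denominator) on the evaluated set by default; a
global SD may be supplied instead via :func:`rpd_from` when comparing against
population-level statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "EvaluationReport",
    "PairedTestResult",
    "pearson_r",
    "rmse",
    "mae",
    "rpd",
    "rpd_from",
    "paired_t_test",
    "evaluate",
]

#: Conventional adequacy bound for a quantitative NIR calibration.
RPD_ADEQUATE = 2.5


@dataclass
class EvaluationReport:
    r: float
    rmse: float
    mae: float
    rpd: float
    n: int
    sd_v: float
    set_label: str = ""


@dataclass
class PairedTestResult:
    t_statistic: float
    p_value: float
    mean_diff: float
    sd_diff: float
    n: int

    @property
    def no_systematic_bias(self) -> bool:
        """True when the two-tailed p exceeds 0.05."""
        return self.p_value > 0.05


def _pair(measured, predicted, min_n=1):
    y = np.asarray(measured, dtype=float).ravel()
    Y = np.asarray(predicted, dtype=float).ravel()
    if y.shape != Y.shape:
        raise ValueError("measured and predicted must have equal length")
    if y.size < min_n:
        raise ValueError(f"need at least {min_n} samples")
    return y, Y


def pearson_r(measured, predicted) -> float:
    """Pearson correlation between measured and predicted values."""
    y, Y = _pair(measured, predicted, min_n=2)
    yc, Yc = y - y.mean(), Y - Y.mean()
    denom = np.sqrt((yc**2).sum() * (Yc**2).sum())
    if denom == 0:
        raise ValueError("degenerate: zero variance in measured or predicted")
    return float(np.clip((yc * Yc).sum() / denom, -1.0, 1.0))


def rmse(measured, predicted) -> float:
    y, Y = _pair(measured, predicted)
    return float(np.sqrt(np.mean((y - Y) ** 2)))


def mae(measured, predicted) -> float:
    y, Y = _pair(measured, predicted)
    return float(np.mean(np.abs(y - Y)))


def rpd_from(sd: float, rmse_value: float) -> float:
    """RPD = SD / RMSE evaluated on supplied scalars."""
    if rmse_value <= 0:
        raise ZeroDivisionError("RPD is unbounded when RMSE is zero")
    return sd / rmse_value


def rpd(measured, predicted, sd: float | None = None) -> float:
    """RPD of a prediction: SD of the measured values over the RMSE.

    ``sd`` overrides the per-set sample SD with a global value when given.
    """
    y, Y = _pair(measured, predicted, min_n=2)
    sd_v = float(np.std(y, ddof=1)) if sd is None else float(sd)
    return rpd_from(sd_v, rmse(y, Y))


def paired_t_test(measured, predicted) -> PairedTestResult:
    """Paired t-test of predicted vs. measured (H0: mean difference is 0).

    t = dbar / (s_d / sqrt(n)) with d_i = predicted_i - measured_i; two-tailed
    p from Student's t with n-1 degrees of freedom. p > 0.05 means no
    detected systematic bias.
    """
    y, Y = _pair(measured, predicted, min_n=2)
    d = Y - y
    dbar = float(d.mean())
    s_d = float(d.std(ddof=1))
    if s_d == 0:
        raise ValueError("degenerate: all paired differences identical")
    n = d.size
    t = dbar / (s_d / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return PairedTestResult(float(t), float(p), dbar, s_d, n)


def evaluate(measured, predicted, set_label: str = "", sd: float | None = None) -> EvaluationReport:
    """Full metric panel for one evaluated set."""
    y, Y = _pair(measured, predicted, min_n=2)
    sd_v = float(np.std(y, ddof=1)) if sd is None else float(sd)
    e = rmse(y, Y)
    return EvaluationReport(
        r=pearson_r(y, Y),
        rmse=e,
        mae=mae(y, Y),
        rpd=rpd_from(sd_v, e),
        n=y.size,
        sd_v=sd_v,
        set_label=set_label,
    )
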