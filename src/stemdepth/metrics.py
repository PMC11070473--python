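"""Agreement statistics between method and caliper stem diameters.

Given paired vectors w (method, mm) and k (manual reference, mm) over n
plants, the suite reports

* MAPE  = 100/n * sum |w_i - k_i| / k_i            (percent)
* MAE   = 1/n * sum |w_i - k_i|                    (mm)
* RMSE  = sqrt(1/n * sum (w_i - k_i)^2)            (mm)
* R^2   = 1 - sum (k_i - w_i)^2 / sum (k_i - kbar)^2

R^2 here scores the method's values directly against the identity line —
it is not the R^2 of a fitted regression, and can be negative for a poor
method.  Agreement beyond correlation is measured by Lin's concordance
correlation coefficient

    rho_c = 2 rho sigma_w sigma_k / (sigma_w^2 + sigma_k^2 + (mu_w - mu_k)^2)

with population (1/n) moments, which penalizes location and scale shifts
that Pearson's rho ignores.  Paired differences are additionally tested
with the two-sided Wilcoxon signed-rank test.

The two 60-plant field tables used throughout ship as packaged CSVs, see
:func:`load_table`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ParameterError

__all__ = [
    "PairedMeasurements",
    "MetricsReport",
    "load_table",
    "mape",
    "mae",
    "rmse",
    "r2",
    "ccc",
    "wilcoxon_signed_rank",
    "summary_stats",
    "evaluate",
]


@dataclass(frozen=True)
class PairedMeasurements:
    """Paired method (w) and manual reference (k) diameters in mm."""

    w: np.ndarray
    k: np.ndarray
    labels: tuple | None = None

    def __post_init__(self):
        w = np.asarray(self.w, dtype=float)
        k = np.asarray(self.k, dtype=float)
        if w.shape != k.shape or w.ndim != 1 or w.size < 2:
            raise ParameterError("w and k must be equal-length 1-D, n >= 2")
        if (w <= 0).any() or (k <= 0).any():
            raise ParameterError("diameters must be positive")
        object.__setattr__(self, "w", w)
        object.__setattr__(self, "k", k)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PairedMeasurements":
        """Build from a DataFrame with measured_mm / true_mm [/ id] columns."""
        labels = tuple(df["id"]) if "id" in df.columns else None
        return cls(df["measured_mm"].to_numpy(), df["true_mm"].to_numpy(),
                   labels=labels)


def load_table(name: str) -> PairedMeasurements:
    """Load a packaged field table: ``"table1"`` (depth-based method) or
    ``"table2"`` (pinhole-imaging baseline), 60 plants each."""
    if name not in ("table1", "table2"):
        raise ParameterError("table name must be 'table1' or 'table2'")
    with resources.files("stemdepth.data").joinpath(f"{name}.csv").open() as fh:
        return PairedMeasurements.from_frame(pd.read_csv(fh))


def _wk(pm) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(pm, PairedMeasurements):
        return pm.w, pm.k
    w, k = pm
    return np.asarray(w, dtype=float), np.asarray(k, dtype=float)


def mape(pm) -> float:
    """Mean absolute percentage error, in percent."""
    w, k = _wk(pm)
    if (k == 0).any():
        raise ZeroDivisionError("reference values must be nonzero for MAPE")
    return float(np.mean(np.abs(w - k) / k) * 100.0)


def mae(pm) -> float:
    """Mean absolute error, mm."""
    w, k = _wk(pm)
    return float(np.mean(np.abs(w - k)))


def rmse(pm) -> float:
    """Root mean square error, mm; always >= MAE."""
    w, k = _wk(pm)
    return float(np.sqrt(np.mean((w - k) ** 2)))


def r2(pm) -> float:
    """Coefficient of determination against the identity line."""
    w, k = _wk(pm)
    ss_tot = np.sum((k - k.mean()) ** 2)
    if ss_tot == 0:
        raise ParameterError("reference values are constant; R^2 undefined")
    return float(1.0 - np.sum((k - w) ** 2) / ss_tot)


def ccc(pm) -> float:
    """Lin's concordance correlation coefficient (population moments)."""
    w, k = _wk(pm)
    sw, sk = w.std(), k.std()          # population (1/n) standard deviations
    if sw == 0 or sk == 0:
        raise ParameterError("a constant vector has no concordance")
    rho = float(np.corrcoef(w, k)[0, 1])
    return float(2 * rho * sw * sk
                 / (sw ** 2 + sk ** 2 + (w.mean() - k.mean()) ** 2))


def wilcoxon_signed_rank(pm, mode: str = "approx",
                         continuity_correction: bool = False) -> float:
    """Two-sided Wilcoxon signed-rank p-value on the paired differences.

    Zero differences are dropped (Wilcoxon's rule).  The default mode is
    the normal approximation with tie-corrected variance and no continuity
    correction; ``mode="exact"`` enumerates the null distribution (valid
    for moderate n without ties).  All differences zero is degenerate and
    returns p = 1.
    """
    w, k = _wk(pm)
    d = w - k
    d = d[d != 0]
    if d.size == 0:
        return 1.0
    if d.size < 6:
        raise ParameterError("need >= 6 nonzero differences")
    if mode not in ("approx", "exact"):
        raise ParameterError(f"unknown mode {mode!r}")
    res = stats.wilcoxon(d, zero_method="wilcox", alternative="two-sided",
                         correction=continuity_correction, method=mode)
    return float(res.pvalue)


def summary_stats(values, method: str = "linear") -> dict:
    """Box-plot style summary: median, quartiles, IQR and max-min width.

    Quartiles use linear interpolation by default; ``method`` accepts any
    numpy quantile method name because box-plot conventions vary.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ParameterError("empty sample")
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75], method=method)
    return {"median": float(med), "q1": float(q1), "q3": float(q3),
            "iqr": float(q3 - q1), "width": float(v.max() - v.min())}


@dataclass(frozen=True)
class MetricsReport:
    """Full evaluation of one method against the manual reference."""

    n: int
    mape: float
    mae: float
    rmse: float
    r2: float
    ccc: float
    wilcoxon_p: float
    measured_summary: dict
    true_summary: dict

    def to_dict(self) -> dict:
        return {
            "n": self.n, "mape_percent": self.mape, "mae_mm": self.mae,
            "rmse_mm": self.rmse, "r2": self.r2, "ccc": self.ccc,
            "wilcoxon_p": self.wilcoxon_p,
            "measured_summary_mm": self.measured_summary,
            "true_summary_mm": self.true_summary,
        }


def evaluate(pm) -> MetricsReport:
    """Compute the full metrics suite over paired measurements."""
    w, k = _wk(pm)
    try:
        p = wilcoxon_signed_rank((w, k))
    except ParameterError:           # too few nonzero differences to test
        p = float("nan")
    return MetricsReport(
        n=int(w.size),
        mape=mape((w, k)), mae=mae((w, k)), rmse=rmse((w, k)),
        r2=r2((w, k)), ccc=ccc((w, k)),
        wilcoxon_p=p,
        measured_summary=summary_stats(w),
        true_summary=summary_stats(k),
    )
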