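"""Method-comparison statistics: Pearson, Passing-Bablok, Bland-Altman.

Validates a test method (optical-flow movement, ``y``) against a reference
method (manual-delineation movement, ``x``) the way clinical method-comparison
studies do:

* Pearson correlation with its two-sided *t*-test p-value;
* Passing-Bablok regression — slope is the shifted median of all pairwise
  slopes :math:`S_{ij} = (y_j - y_i)/(x_j - x_i)`, with slopes equal to −1
  excluded and the median offset by :math:`K = \\#\\{S_{ij} < -1\\}`, so that
  the estimate is invariant under exchange of the two methods (Passing &
  Bablok, 1983).  Confidence bounds come from the rank-based normal
  approximation of the same paper; intercept is
  :math:`\\mathrm{median}(y - b x)`.
* Bland-Altman agreement — bias is the mean of the differences
  :math:`d = y - x` and the limits of agreement are
  :math:`\\mathrm{bias} \\pm k\\,\\mathrm{SD}(d)` (sample SD, ``k`` = 1.96 by
  default).

The module is organised statsmodels-style: build a :class:`MethodComparison`
model from paired data, call :meth:`~MethodComparison.fit`, and read the
estimates off the returned :class:`AgreementResults` (which also owns the
diagnostic plots and the ``summary()`` table).  Thin functional wrappers
(:func:`pearson`, :func:`passing_bablok`, :func:`bland_altman`) are provided
for one-off use.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PairedSeries",
    "MethodComparison",
    "AgreementResults",
    "DegenerateDataError",
    "pearson",
    "passing_bablok",
    "bland_altman",
    "agreement_report",
]


class DegenerateDataError(ValueError):
    """The paired data cannot support the requested statistic."""


@dataclass(frozen=True)
class PairedSeries:
    """Paired measurements of one quantity by two methods.

    ``x`` is the reference method, ``y`` the test method.
    """

    x: np.ndarray
    y: np.ndarray
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if x.size < 3:
            raise ValueError(f"need at least 3 pairs, got {x.size}")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValueError("paired values must be finite")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if self.labels is not None and len(self.labels) != x.size:
            raise ValueError("labels must match the number of pairs")

    def __len__(self) -> int:
        return self.x.size


# ---------------------------------------------------------------------------
# elementary statistics


def pearson(data: PairedSeries) -> tuple[float, float]:
    """Sample Pearson correlation and its two-sided p-value."""
    if np.ptp(data.x) == 0 or np.ptp(data.y) == 0:
        raise DegenerateDataError("correlation undefined: a series has zero variance")
    r, p = stats.pearsonr(data.x, data.y)
    return float(r), float(p)


def _pairwise_slopes(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """All valid pairwise slopes for Passing-Bablok, sorted ascending.

    Pairs with identical x and identical y (0/0) are skipped; identical x
    with differing y yields an infinite slope, signed by the y difference so
    +inf sorts to the top and -inf below every finite slope; slopes exactly
    equal to -1 are excluded (they carry no information about the direction
    of the method difference under the procedure's symmetry requirement).
    """
    n = x.size
    i, j = np.triu_indices(n, k=1)
    dx = x[j] - x[i]
    dy = y[j] - y[i]
    both_zero = (dx == 0) & (dy == 0)
    dx, dy = dx[~both_zero], dy[~both_zero]
    slopes = np.empty(dx.shape)
    finite = dx != 0
    slopes[finite] = dy[finite] / dx[finite]
    slopes[~finite] = np.sign(dy[~finite]) * np.inf
    slopes = slopes[slopes != -1.0]
    return np.sort(slopes)


def _shifted_median(sorted_vals: np.ndarray, offset: int) -> float:
    """Median of a sorted array shifted upward by ``offset`` ranks.

    Even counts average the two central order statistics.
    """
    n = sorted_vals.size
    if n == 0:
        raise DegenerateDataError("no valid pairwise slopes")
    if n % 2:
        idx = (n + 1) // 2 + offset - 1  # 1-based -> 0-based
        return float(sorted_vals[idx])
    lo = n // 2 + offset - 1
    return float(0.5 * (sorted_vals[lo] + sorted_vals[lo + 1]))


def passing_bablok(
    data: PairedSeries, conf_level: float = 0.95
) -> tuple[float, float, tuple[float, float], tuple[float, float]]:
    """Passing-Bablok regression slope and intercept with rank-based CIs.

    Returns ``(slope, intercept, (slope_lo, slope_hi), (int_lo, int_hi))``.
    """
    x, y = data.x, data.y
    if np.ptp(x) == 0:
        raise DegenerateDataError("Passing-Bablok undefined: all x identical")
    slopes = _pairwise_slopes(x, y)
    n_slopes = slopes.size
    k_offset = int(np.count_nonzero(slopes < -1.0))
    slope = _shifted_median(slopes, k_offset)
    if not np.isfinite(slope):
        raise DegenerateDataError("Passing-Bablok slope is not finite")

    # rank-based normal-approximation confidence bounds
    n = x.size
    z = stats.norm.ppf(0.5 + conf_level / 2.0)
    w = z * np.sqrt(n * (n - 1) * (2 * n + 5) / 18.0)
    m1 = int(np.round((n_slopes - w) / 2.0))
    m2 = n_slopes - m1 + 1
    lo_idx = np.clip(m1 + k_offset - 1, 0, n_slopes - 1)
    hi_idx = np.clip(m2 + k_offset - 1, 0, n_slopes - 1)
    slope_lo = float(slopes[lo_idx])
    slope_hi = float(slopes[hi_idx])

    intercept = float(np.median(y - slope * x))
    int_lo = float(np.median(y - slope_hi * x)) if np.isfinite(slope_hi) else -np.inf
    int_hi = float(np.median(y - slope_lo * x)) if np.isfinite(slope_lo) else np.inf
    return slope, intercept, (slope_lo, slope_hi), (int_lo, int_hi)


def bland_altman(
    data: PairedSeries, k: float = 1.96
) -> tuple[float, float, float]:
    """Bias and limits of agreement: ``mean(d) -/+ k * SD(d)``, d = y - x."""
    d = data.y - data.x
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1)) if d.size > 1 else 0.0
    return bias, bias - k * sd, bias + k * sd


# ---------------------------------------------------------------------------
# model / results


class MethodComparison:
    """Method-comparison model over paired measurements.

    Parameters
    ----------
    x, y
        Reference-method and test-method values (equal length, n >= 3).
    labels
        Optional case identifiers.

    Examples
    --------
    >>> model = MethodComparison([1, 2, 3, 4], [1.1, 2.0, 3.2, 3.9])
    >>> results = model.fit()
    >>> round(results.pb_slope, 3)
    0.95
    """

    def __init__(self, x: Sequence[float], y: Sequence[float], labels=None) -> None:
        self.data = PairedSeries(np.asarray(x, float), np.asarray(y, float), labels)

    @classmethod
    def from_dataframe(cls, frame, x: str = "x", y: str = "y", labels: str | None = None):
        """Build the model from DataFrame columns."""
        lab = tuple(map(str, frame[labels])) if labels else None
        return cls(frame[x].to_numpy(), frame[y].to_numpy(), labels=lab)

    def fit(self, ba_k: float = 1.96, conf_level: float = 0.95) -> "AgreementResults":
        """Compute all three statistics and return them as a results object."""
        r, p = pearson(self.data)
        slope, intercept, slope_ci, int_ci = passing_bablok(self.data, conf_level)
        bias, loa_low, loa_high = bland_altman(self.data, ba_k)
        return AgreementResults(
            data=self.data,
            pearson_r=r,
            p_value=p,
            pb_slope=slope,
            pb_intercept=intercept,
            pb_slope_ci=slope_ci,
            pb_intercept_ci=int_ci,
            ba_bias=bias,
            ba_loa_low=loa_low,
            ba_loa_high=loa_high,
            ba_k=ba_k,
            conf_level=conf_level,
        )


@dataclass(frozen=True)
class AgreementResults:
    """Fitted method-comparison statistics with plotting and summary."""

    data: PairedSeries
    pearson_r: float
    p_value: float
    pb_slope: float
    pb_intercept: float
    pb_slope_ci: tuple[float, float]
    pb_intercept_ci: tuple[float, float]
    ba_bias: float
    ba_loa_low: float
    ba_loa_high: float
    ba_k: float = 1.96
    conf_level: float = 0.95

    @property
    def nobs(self) -> int:
        return len(self.data)

    def summary(self) -> str:
        """Plain-text summary table of all fitted quantities."""
        lines = [
            "Method comparison (x = reference, y = test)",
            "=" * 52,
            f"{'n pairs':<32}{self.nobs:>20d}",
            f"{'Pearson r':<32}{self.pearson_r:>20.4f}",
            f"{'p-value':<32}{self.p_value:>20.3g}",
            f"{'Passing-Bablok slope':<32}{self.pb_slope:>20.4f}",
            f"{'  slope {:.0f}% CI'.format(self.conf_level * 100):<32}"
            f"{'[{:.4f}, {:.4f}]'.format(*self.pb_slope_ci):>20}",
            f"{'Passing-Bablok intercept':<32}{self.pb_intercept:>20.4f}",
            f"{'  intercept {:.0f}% CI'.format(self.conf_level * 100):<32}"
            f"{'[{:.4f}, {:.4f}]'.format(*self.pb_intercept_ci):>20}",
            f"{'Bland-Altman bias':<32}{self.ba_bias:>20.4f}",
            f"{'  limits of agreement':<32}"
            f"{'[{:.4f}, {:.4f}]'.format(self.ba_loa_low, self.ba_loa_high):>20}",
            "=" * 52,
        ]
        return "\n".join(lines)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "statistic": [
                    "n",
                    "pearson_r",
                    "p_value",
                    "pb_slope",
                    "pb_slope_ci_low",
                    "pb_slope_ci_high",
                    "pb_intercept",
                    "pb_intercept_ci_low",
                    "pb_intercept_ci_high",
                    "ba_bias",
                    "ba_loa_low",
                    "ba_loa_high",
                ],
                "value": [
                    self.nobs,
                    self.pearson_r,
                    self.p_value,
                    self.pb_slope,
                    self.pb_slope_ci[0],
                    self.pb_slope_ci[1],
                    self.pb_intercept,
                    self.pb_intercept_ci[0],
                    self.pb_intercept_ci[1],
                    self.ba_bias,
                    self.ba_loa_low,
                    self.ba_loa_high,
                ],
            }
        )

    def plot_regression(self, ax=None):
        """Scatter of y vs x with the Passing-Bablok fit and identity line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        ax.scatter(self.data.x, self.data.y, s=18, alpha=0.7, edgecolor="none")
        span = np.array([min(self.data.x.min(), 0), self.data.x.max() * 1.05])
        ax.plot(span, span, "k--", lw=0.8, label="identity")
        ax.plot(
            span,
            self.pb_intercept + self.pb_slope * span,
            "r-",
            lw=1.2,
            label=f"y = {self.pb_slope:.2f}x + {self.pb_intercept:.2f}",
        )
        ax.set_xlabel("reference method")
        ax.set_ylabel("test method")
        ax.set_title(f"Passing-Bablok (r = {self.pearson_r:.2f})")
        ax.legend(frameon=False)
        return ax

    def plot_bland_altman(self, ax=None):
        """Difference-vs-mean plot with bias and limits of agreement."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5.5, 4))
        mean = 0.5 * (self.data.x + self.data.y)
        diff = self.data.y - self.data.x
        ax.scatter(mean, diff, s=18, alpha=0.7, edgecolor="none")
        for val, style, label in (
            (self.ba_bias, "-", f"bias {self.ba_bias:.2f}"),
            (self.ba_loa_low, "--", f"-{self.ba_k} SD"),
            (self.ba_loa_high, "--", f"+{self.ba_k} SD"),
        ):
            ax.axhline(val, color="r", ls=style, lw=1.0)
        ax.set_xlabel("mean of methods")
        ax.set_ylabel("difference (test - reference)")
        ax.set_title("Bland-Altman")
        return ax

    def save_plots(self, out_dir: str | Path, prefix: str = "agreement") -> list[Path]:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for name, plot in (
            ("passing_bablok", self.plot_regression),
            ("bland_altman", self.plot_bland_altman),
        ):
            fig, ax = plt.subplots(figsize=(5.5, 4.5))
            plot(ax=ax)
            p = out_dir / f"{prefix}_{name}.png"
            fig.tight_layout()
            fig.savefig(p, dpi=110)
            plt.close(fig)
            paths.append(p)
        return paths


def agreement_report(
    data: PairedSeries, out_dir: str | Path | None = None
) -> AgreementResults:
    """Fit all three statistics; optionally write plots and a report CSV."""
    results = MethodComparison(data.x, data.y, data.labels).fit()
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        results.to_frame().to_csv(out_dir / "agreement_report.csv", index=False)
        results.save_plots(out_dir)
    return results
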