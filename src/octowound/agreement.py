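"""Agreement statistics between paired measurement series.

Implements the validation statistics used to compare automated against
manual (or ground-truth) wound measurements:

* **ICC** — intraclass correlation, two-way random effects, absolute
  agreement, single measures (ICC(2,1)), computed from the two-way ANOVA
  mean squares:

  .. math::

     ICC = \\frac{MS_R - MS_E}
                {MS_R + (k-1) MS_E + \\tfrac{k}{n}(MS_C - MS_E)}

  with :math:`MS_R` the between-subject, :math:`MS_C` the between-rater
  and :math:`MS_E` the residual mean square, :math:`n` subjects and
  :math:`k = 2` raters.

* **Bland-Altman** — bias = mean(a - b); limits of agreement are
  bias +/- 2 x SD of the differences (exactly 2, the study's convention,
  not 1.96).

* **Pearson / Spearman** correlation with two-sided p-values (midranks
  for ties).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PairedSeries",
    "AgreementReport",
    "icc",
    "bland_altman",
    "correlations",
    "agreement_report",
    "validate_pipeline",
]

#: Returned where a statistic is undefined (zero variance input).
UNDEFINED = float("nan")


@dataclass(frozen=True)
class PairedSeries:
    """Two same-length, same-unit measurement series to be compared."""

    a: np.ndarray
    b: np.ndarray
    label_a: str = "ML"
    label_b: str = "Investigator"

    def __post_init__(self) -> None:
        object.__setattr__(self, "a", np.asarray(self.a, dtype=float))
        object.__setattr__(self, "b", np.asarray(self.b, dtype=float))
        if self.a.shape != self.b.shape or self.a.ndim != 1:
            raise ValueError("paired series must be 1D and of equal length")
        if not (np.all(np.isfinite(self.a)) and np.all(np.isfinite(self.b))):
            raise ValueError("paired series must be finite")

    @property
    def n(self) -> int:
        return self.a.size


@dataclass
class AgreementReport:
    icc: float
    bias: float
    loa_low: float
    loa_high: float
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    n: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "icc", "bias", "loa_low", "loa_high",
            "pearson_r", "pearson_p", "spearman_rho", "spearman_p", "n",
        )}


def icc(series: PairedSeries) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    Returns NaN (flagged sentinel) when the total variance is zero.
    """
    if series.n < 3:
        raise ValueError("ICC needs at least 3 pairs")
    x = np.stack([series.a, series.b], axis=1)  # (n subjects, k=2 raters)
    n, k = x.shape
    grand = x.mean()
    if np.allclose(x, grand):
        return UNDEFINED
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    denom = ms_rows + (k - 1) * ms_err + k / n * (ms_cols - ms_err)
    if denom == 0:
        return UNDEFINED
    return float((ms_rows - ms_err) / denom)


def bland_altman(series: PairedSeries) -> tuple[float, float, float]:
    """(bias, loa_low, loa_high) with limits at bias -/+ 2 x sample SD."""
    if series.n < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs")
    d = series.a - series.b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, bias - 2.0 * sd, bias + 2.0 * sd


def correlations(series: PairedSeries) -> tuple[float, float, float, float]:
    """(pearson_r, pearson_p, spearman_rho, spearman_p), two-sided."""
    if series.n < 3:
        raise ValueError("correlation needs at least 3 pairs")
    if np.ptp(series.a) == 0 or np.ptp(series.b) == 0:
        return UNDEFINED, UNDEFINED, UNDEFINED, UNDEFINED
    pr = stats.pearsonr(series.a, series.b)
    sr = stats.spearmanr(series.a, series.b)
    return (
        float(pr.statistic),
        float(pr.pvalue),
        float(sr.statistic),
        float(sr.pvalue),
    )


def agreement_report(series: PairedSeries) -> AgreementReport:
    bias, lo, hi = bland_altman(series)
    r, rp, rho, rhop = correlations(series)
    return AgreementReport(
        icc=icc(series),
        bias=bias,
        loa_low=lo,
        loa_high=hi,
        pearson_r=r,
        pearson_p=rp,
        spearman_rho=rho,
        spearman_p=rhop,
        n=series.n,
    )


def validate_pipeline(estimated, reference) -> dict[str, AgreementReport]:
    """One agreement report per measurement, matched by scan id.

    ``estimated`` and ``reference`` are lists of
    :class:`~octowound.volumetry.ScanQuantification`; the reference side is
    typically phantom ground truth or manual measurements.
    """
    est = {q.scan_id: q for q in estimated}
    ref = {q.scan_id: q for q in reference}
    if set(est) != set(ref):
        offenders = sorted(set(est) ^ set(ref))
        raise ValueError(f"scan id mismatch between series: {offenders}")
    ids = sorted(est)
    reports: dict[str, AgreementReport] = {}
    from .core import WOUND_CLASSES  # local import avoids a cycle

    for cls in WOUND_CLASSES:
        series = PairedSeries(
            a=np.array([est[i].volumes[cls] for i in ids]),
            b=np.array([ref[i].volumes[cls] for i in ids]),
        )
        reports[f"{cls.name.lower()}_volume"] = agreement_report(series)
    reports["wound_width"] = agreement_report(
        PairedSeries(
            a=np.array([est[i].wound_width for i in ids]),
            b=np.array([ref[i].wound_width for i in ids]),
        )
    )
    reports["clot_depth"] = agreement_report(
        PairedSeries(
            a=np.array([est[i].clot_depth for i in ids]),
            b=np.array([ref[i].clot_depth for i in ids]),
        )
    )
    return reports


def bland_altman_plot(series: PairedSeries, ax=None, title: str = ""):
    """Difference-vs-mean plot with bias and +/-2 SD limit lines."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    mean = (series.a + series.b) / 2
    diff = series.a - series.b
    bias, lo, hi = bland_altman(series)
    ax.scatter(mean, diff, s=12)
    ax.axhline(bias, color="k")
    for y in (lo, hi):
        ax.axhline(y, color="k", linestyle=":")
    ax.set_xlabel(f"mean of {series.label_a} and {series.label_b}")
    ax.set_ylabel(f"{series.label_a} - {series.label_b}")
    if title:
        ax.set_title(title)
    return ax
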