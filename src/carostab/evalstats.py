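"""Evaluation statistics: normalized RMSE, linear regression/correlation, Bland-Altman."""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from .core import ArgumentError, DegenerateInputError


@dataclass
class AgreementReport:
    """Agreement between an estimate and a reference series."""

    mean_diff: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    r: float | None = None
    slope: float | None = None
    intercept: float | None = None
    nrmse: float | None = None

    def as_dict(self) -> dict:
        return asdict(self)


def _pair(estimate, reference, min_n: int = 2):
    est = np.asarray(estimate, dtype=float).ravel()
    ref = np.asarray(reference, dtype=float).ravel()
    if est.shape != ref.shape:
        raise ArgumentError("series must have equal lengths")
    if len(est) < min_n:
        raise ArgumentError(f"need at least {min_n} samples")
    return est, ref


def rmse(estimate, reference) -> float:
    """Plain root-mean-square error between two series."""
    est, ref = _pair(estimate, reference)
    return float(np.sqrt(np.mean((est - ref) ** 2)))


def nrmse(estimate, reference, normalizer: str = "range") -> float:
    """RMSE of (estimate - reference), normalized by the reference scale.

    ``normalizer``: ``"range"`` (peak-to-peak, default), ``"rms"`` or
    ``"mean"`` of the reference.  A constant reference (zero range) is
    degenerate.
    """
    est, ref = _pair(estimate, reference)
    if normalizer == "range":
        scale = np.ptp(ref)
    elif normalizer == "rms":
        scale = np.sqrt(np.mean(ref**2))
    elif normalizer == "mean":
        scale = abs(ref.mean())
    else:
        raise ArgumentError(f"unknown normalizer {normalizer!r}")
    if scale == 0:
        raise DegenerateInputError("reference scale is zero")
    return float(np.sqrt(np.mean((est - ref) ** 2)) / scale)


def regression_corr(x, y) -> tuple:
    """Ordinary least-squares line and Pearson correlation: (slope, intercept, R)."""
    x, y = _pair(x, y, min_n=3)
    if np.ptp(x) == 0:
        raise DegenerateInputError("x has zero variance")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue)


def bland_altman(a, b) -> AgreementReport:
    """Bland-Altman agreement: mean difference and 95% limits (mean +/- 1.96 SD).

    Differences are a - b; the SD uses the n-1 (sample) denominator.
    """
    a, b = _pair(a, b)
    d = a - b
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementReport(mean_diff=mean, sd_diff=sd,
                           loa_lower=mean - 1.96 * sd,
                           loa_upper=mean + 1.96 * sd)


def agreement_report(estimate, reference) -> AgreementReport:
    """Full agreement summary of an estimate against a reference series."""
    est, ref = _pair(estimate, reference, min_n=3)
    report = bland_altman(est, ref)
    slope, intercept, r = regression_corr(ref, est)
    report.slope, report.intercept, report.r = slope, intercept, r
    report.nrmse = nrmse(est, ref)
    return report
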