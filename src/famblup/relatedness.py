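"""Relatedness summaries: second-degree-relative counts and their effect on accuracy.

An individual's approximate number of second-degree-or-closer relatives (SDR)
is the count of pairwise relationship coefficients above a threshold (default
0.25, the expected value for exact second-degree pairs on the unit-diagonal
scale).  Regressing per-individual EGV accuracy on the SDR count quantifies
how much the information available about an individual's relatives drives the
reliability of their prediction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .kinship import RelationshipMatrix

__all__ = ["SdrSummary", "AccuracyRegression", "count_sdr",
           "regress_accuracy_on_sdr", "lowess_curve"]


@dataclass
class SdrSummary:
    individual_ids: list[str]
    sdr_count: np.ndarray
    threshold: float
    matrix_method: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"individual_id": self.individual_ids,
                             "sdr_count": self.sdr_count})


@dataclass
class AccuracyRegression:
    slope: float
    intercept: float
    r_squared: float
    slope_se: float
    p_value: float       # two-sided for slope = 0
    n: int


def count_sdr(K: RelationshipMatrix, threshold: float = 0.25) -> SdrSummary:
    """Count, per individual, relationship coefficients strictly above threshold.

    Requires a unit-diagonal (normalized) matrix so that the threshold sits on
    the additive-relationship scale.
    """
    if not K.normalized:
        raise ValueError("count_sdr requires a normalized (unit-diagonal) "
                         "matrix; apply normalize_diagonal first")
    v = K.values.copy()
    np.fill_diagonal(v, -np.inf)
    counts = (v > threshold).sum(axis=1)
    return SdrSummary(list(K.individual_ids), counts.astype(int),
                      float(threshold), K.method)


def regress_accuracy_on_sdr(accuracy: np.ndarray, sdr: SdrSummary,
                            phenotyped: np.ndarray | None = None,
                            exclude_unphenotyped: bool = False
                            ) -> AccuracyRegression:
    """OLS of per-individual accuracy on SDR count.

    R² is the squared Pearson correlation; when the accuracy vector is
    constant the regression is degenerate and (slope 0, R² 0) is returned
    with a warning.  Zero variance in the SDR counts is an error.
    """
    ea = np.asarray(accuracy, dtype=float)
    x = sdr.sdr_count.astype(float)
    if ea.shape != x.shape:
        raise ValueError("accuracy and SDR vectors are not aligned")
    if exclude_unphenotyped:
        if phenotyped is None:
            raise ValueError("exclude_unphenotyped requires a phenotyped mask")
        keep = np.asarray(phenotyped, dtype=bool)
        ea, x = ea[keep], x[keep]
    if ea.size < 3:
        raise ValueError("regression needs at least 3 individuals")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in SDR counts; regression undefined")
    if np.ptp(ea) == 0:
        warnings.warn("accuracy is constant; returning slope 0, R^2 0",
                      stacklevel=2)
        return AccuracyRegression(0.0, float(ea[0]), 0.0, 0.0, 1.0, ea.size)
    res = stats.linregress(x, ea)
    return AccuracyRegression(float(res.slope), float(res.intercept),
                              float(res.rvalue ** 2), float(res.stderr),
                              float(res.pvalue), ea.size)


def lowess_curve(accuracy: np.ndarray, sdr: SdrSummary,
                 span: float = 0.75) -> pd.DataFrame:
    """Local-regression curve of accuracy against SDR count (for plotting).

    The linear fit from :func:`regress_accuracy_on_sdr` remains the reported
    statistic; this smooth is presentation only (fixed span 0.75).
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess
    sm = lowess(np.asarray(accuracy, float), sdr.sdr_count.astype(float),
                frac=span, return_sorted=True)
    return pd.DataFrame({"sdr_count": sm[:, 0], "accuracy_smooth": sm[:, 1]})
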