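"""Group-wise parameter summaries and significance testing.

Compares each of the seven image parameters between the normal and cancer
groups with a two-sample, two-tailed Student t-test (Welch's unequal-variance
form by default; the pooled-variance form is available for comparability with
spreadsheet defaults).  No multiple-testing correction is applied: each
parameter is tested at its own alpha, matching the conventional per-parameter
reporting for this kind of table.

Images are treated as independent samples even though several images come
from each subject in a real acquisition; with clustered data the p-values
here are anti-conservative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ParameterError
from .io import FEATURE_COLUMNS


@dataclass
class ParameterComparison:
    parameter: str
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    t_statistic: float
    p_value: float
    significant: bool


@dataclass
class GroupComparison:
    group_a: str
    group_b: str
    alpha: float
    rows: list[ParameterComparison]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "parameter": r.parameter,
                    f"mean_{self.group_a}": r.mean_a,
                    f"sd_{self.group_a}": r.sd_a,
                    f"mean_{self.group_b}": r.mean_b,
                    f"sd_{self.group_b}": r.sd_b,
                    "t": r.t_statistic,
                    "p": r.p_value,
                    "significant": r.significant,
                }
                for r in self.rows
            ]
        )


def _ttest(a: np.ndarray, b: np.ndarray, pooled: bool) -> tuple[float, float]:
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        warnings.warn("both groups have zero variance with unequal means; p set to 0")
        return float("inf") if a.mean() > b.mean() else float("-inf"), 0.0
    t, p = sps.ttest_ind(a, b, equal_var=pooled)
    return float(t), float(p)


def compare_groups(
    features_a,
    features_b,
    alpha: float = 0.05,
    group_names: tuple[str, str] = ("normal", "cancer"),
    pooled: bool = False,
    parameters=FEATURE_COLUMNS,
) -> GroupComparison:
    """Per-parameter mean +/- sd and two-sample t-test between two groups.

    ``features_a``/``features_b`` are (n, 7) arrays, DataFrames with the
    canonical columns, or lists of FeatureVector.
    """

    def as_matrix(f):
        if isinstance(f, pd.DataFrame):
            return f[list(parameters)].to_numpy(dtype=np.float64)
        f = list(f)
        if f and hasattr(f[0], "to_array"):
            return np.stack([fv.to_array() for fv in f])
        return np.asarray(f, dtype=np.float64)

    A, B = as_matrix(features_a), as_matrix(features_b)
    if len(A) < 2 or len(B) < 2:
        raise ParameterError("each group needs at least 2 samples")
    if not 0.0 < alpha < 1.0:
        raise ParameterError("alpha must be in (0, 1)")
    rows = []
    for k, name in enumerate(parameters):
        a, b = A[:, k], B[:, k]
        t, p = _ttest(a, b, pooled)
        rows.append(
            ParameterComparison(
                parameter=name,
                mean_a=float(a.mean()),
                sd_a=float(a.std(ddof=1)),
                mean_b=float(b.mean()),
                sd_b=float(b.std(ddof=1)),
                t_statistic=t,
                p_value=p,
                significant=bool(p < alpha),
            )
        )
    return GroupComparison(group_names[0], group_names[1], alpha, rows)
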