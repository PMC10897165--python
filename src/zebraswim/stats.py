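"""Two-group comparison statistics in the reporting style of the assays.

Groups are compared with an unpaired Student's (pooled-variance) t test
and summarised as mean ± SEM with significance stars.  Welch's unequal-
variance test is available by flag.  No multiple-testing correction is
applied across behavioural panels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = ["GroupComparison", "compare_groups", "significance_stars"]


def significance_stars(p: float) -> str:
    """The conventional star code: * <0.05, ** <0.01, *** <0.001, **** <0.0001."""
    if p < 0.0001:
        return "****"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class GroupComparison:
    label_a: str
    label_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    t: float
    p: float
    stars: str

    def summary(self) -> str:
        return (
            f"{self.label_a}: {self.mean_a:.4g} ± {self.sem_a:.4g} (n={self.n_a}); "
            f"{self.label_b}: {self.mean_b:.4g} ± {self.sem_b:.4g} (n={self.n_b}); "
            f"t = {self.t:.4g}, p = {self.p:.4g} [{self.stars}]"
        )


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    label_a: str = "group_a",
    label_b: str = "group_b",
    equal_var: bool = True,
) -> GroupComparison:
    """Unpaired two-sided t test with means, SEMs and stars.

    ``equal_var=True`` gives the Student's pooled-variance test;
    ``False`` gives Welch's.  Two identical constant groups yield
    t = 0, p = 1 rather than an indeterminate value.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two values")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("group values must be finite")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
        t, p = 0.0, 1.0
    else:
        t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return GroupComparison(
        label_a=label_a,
        label_b=label_b,
        n_a=len(a),
        n_b=len(b),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sem_a=float(a.std(ddof=1) / np.sqrt(len(a))),
        sem_b=float(b.std(ddof=1) / np.sqrt(len(b))),
        t=float(t),
        p=float(p),
        stars=significance_stars(float(p)),
    )
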