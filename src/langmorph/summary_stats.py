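"""Effect sizes and tests recomputable from printed group summaries.

Works entirely from per-group (n, mean, SD) triples — the form in which
behavioral comparisons are usually published — so printed tables can be
checked and extended without raw data:

* pooled SD and Cohen's d (pooled denominator, no small-sample correction),
* the pooled two-sample t statistic with n₁ + n₂ − 2 df,
* an "equivalent" Cohen's d for Mann–Whitney U rows via the normal
  approximation z, r = |z|/√N and d = 2r/√(1 − r²).
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO
from pathlib import Path

import math
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupSummary",
    "pooled_sd",
    "cohens_d_from_summary",
    "t_from_summary",
    "u_to_equivalent_d",
    "reference_cohort_summaries",
    "effect_size_table",
    "load_group_summaries",
]


@dataclass(frozen=True)
class GroupSummary:
    """One group's sample size, mean, and standard deviation."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group size must be >= 2")
        if self.sd < 0:
            raise ValueError("SD must be >= 0")


def pooled_sd(a: GroupSummary, b: GroupSummary) -> float:
    """√(((n₁−1)s₁² + (n₂−1)s₂²) / (n₁+n₂−2))."""
    num = (a.n - 1) * a.sd ** 2 + (b.n - 1) * b.sd ** 2
    return math.sqrt(num / (a.n + b.n - 2))


def cohens_d_from_summary(a: GroupSummary, b: GroupSummary) -> float:
    """|mean difference| / pooled SD (magnitude; group order irrelevant)."""
    sp = pooled_sd(a, b)
    if sp == 0:
        if a.mean == b.mean:
            return 0.0
        raise ValueError("zero pooled SD with unequal means: d undefined")
    return abs(a.mean - b.mean) / sp


def t_from_summary(a: GroupSummary, b: GroupSummary) -> tuple[float, int]:
    """Pooled two-sample t and its df; antisymmetric in group order."""
    sp = pooled_sd(a, b)
    if sp == 0:
        raise ValueError("zero pooled SD: t undefined")
    t = (a.mean - b.mean) / (sp * math.sqrt(1.0 / a.n + 1.0 / b.n))
    return t, a.n + b.n - 2


def u_to_equivalent_d(U: float, n1: int, n2: int,
                      tie_sizes: list[int] | None = None) -> float:
    """Equivalent Cohen's d from a Mann–Whitney U statistic.

    Normal approximation: z = (U − n₁n₂/2)/σ_U with σ_U² = n₁n₂(N+1)/12
    (or the tie-corrected variance when ``tie_sizes``, the sizes of tied
    rank groups, are supplied); then r = |z|/√N and d = 2r/√(1 − r²).
    """
    if n1 * n2 == 0:
        raise ValueError("both group sizes must be positive")
    if not (0 <= U <= n1 * n2):
        raise ValueError("U must lie in [0, n1*n2]")
    N = n1 + n2
    if tie_sizes:
        tie_term = sum(t ** 3 - t for t in tie_sizes) / (N * (N - 1))
        var_u = n1 * n2 / 12.0 * ((N + 1) - tie_term)
    else:
        var_u = n1 * n2 * (N + 1) / 12.0
    if var_u <= 0:
        raise ValueError("non-positive U variance (all observations tied?)")
    z = (U - n1 * n2 / 2.0) / math.sqrt(var_u)
    r = abs(z) / math.sqrt(N)
    if r >= 1:
        raise ValueError("|r| >= 1: normal approximation breaks down")
    return 2.0 * r / math.sqrt(1.0 - r ** 2)


# --------------------------------------------------------------- reference

# Published behavioral and total-volume summaries for the reference cohort
# of 80 autistic adult males: 38 with a history of language delay, 42
# without.  Mann–Whitney rows (test == "U") carry medians/IQRs, not
# means/SDs, and report the U statistic instead of t.
_REFERENCE_CSV = """\
measure,n_delay,mean_delay,sd_delay,n_nodelay,mean_nodelay,sd_nodelay,test,stat
Age,38,23.2,5.6,42,25.2,5.6,t,
FIQ,38,106.7,13.1,42,111.1,15.7,t,
PIQ,38,106.1,14.2,42,108.0,16.5,t,
VIQ,38,105.6,12.6,42,111.6,15.7,t,
FAS,38,33.8,11.8,42,41.3,10.3,t,
NWR,38,21.1,4.5,42,21.8,3.9,t,
ADIR-S,38,20.7,5.1,42,17.0,4.9,t,
ADIR-C,38,15.0,4.2,42,13.5,3.7,t,
ADIR-RRB,38,5.0,4.0,42,5.0,3.0,U,786
ADOS-SC,38,10.5,5.2,42,8.6,4.0,t,
ADOS-RRB,38,1.0,2.0,42,1.0,2.0,U,665
AQ,38,30.1,8.0,42,28.8,9.3,t,
EQ,38,23.5,13.1,42,25.4,11.7,t,
EyesTest,38,21.3,5.6,42,22.8,5.6,t,
VIQ-PIQ,38,-0.5,12.9,42,3.6,14.8,t,
TotalGM,38,980,111,42,934,96,t,
TotalWM,38,492,72,42,498,54,t,
TotalCSF,38,282,83,42,259,69,t,
"""


def reference_cohort_summaries() -> pd.DataFrame:
    """The reference cohort's printed per-group summary statistics."""
    return pd.read_csv(StringIO(_REFERENCE_CSV))


def load_group_summaries(path: str | Path) -> pd.DataFrame:
    """Read a group-summary CSV in the same layout as the reference table."""
    return pd.read_csv(path)


def effect_size_table(summaries: pd.DataFrame) -> pd.DataFrame:
    """Recompute t (or use U), two-sided p, and Cohen's d for each measure.

    ``t`` rows get the pooled two-sample t from the summaries; ``U`` rows
    get the equivalent d from the normal approximation (no t/p, since exact
    rank p-values need the raw data).
    """
    rows = []
    for _, r in summaries.iterrows():
        a = GroupSummary(int(r["n_delay"]), float(r["mean_delay"]), float(r["sd_delay"]))
        b = GroupSummary(int(r["n_nodelay"]), float(r["mean_nodelay"]), float(r["sd_nodelay"]))
        if r["test"] == "U":
            d = u_to_equivalent_d(float(r["stat"]), a.n, b.n)
            rows.append({"measure": r["measure"], "statistic": float(r["stat"]),
                         "df": np.nan, "p": np.nan, "cohens_d": round(d, 2)})
        else:
            t, df = t_from_summary(a, b)
            p = 2 * stats.t.sf(abs(t), df)
            rows.append({"measure": r["measure"], "statistic": round(t, 2),
                         "df": df, "p": p, "cohens_d": round(cohens_d_from_summary(a, b), 2)})
    return pd.DataFrame(rows)
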