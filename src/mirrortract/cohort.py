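"""Cohort-level statistics on per-case tract-count outcomes.

The per-case measurement is the percentage decrease in tract count on the
lesioned side relative to the healthy hemisphere.  Aggressiveness is
quantified by regressing the tumor-volume-weighted decrease against the
MIB-1 (Ki-67) proliferation index, and tumor types are compared with a
pooled two-sample t-test on the raw percentage decrease.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

GROUPS = ("meningioma", "LGG", "HGG")

# exact published column names
COL_CASE = "Case no."
COL_AGE = "Age(yrs)"
COL_SEX = "Sex"
COL_LOCATION = "Tumor location"
COL_VOLUME = "Tumor size(cm^3)"
COL_MIB1 = "MIB-1%"
COL_PCT = "Percentage decrease in tract count"


@dataclass
class CohortRow:
    case_id: str
    group: str  # {"meningioma", "LGG", "HGG"}
    age: float
    tumor_volume: float  # cm^3
    mib1: float          # %
    pct_decrease: float  # %

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.tumor_volume <= 0:
            raise ValueError("tumor volume must be > 0")
        if self.mib1 < 0:
            raise ValueError("MIB-1 index must be >= 0")
        if self.pct_decrease > 100:
            raise ValueError("percentage decrease cannot exceed 100")


@dataclass
class RegressionResult:
    r: float
    slope: float
    intercept: float
    p: float
    n: int


def _group_of(case_id: str) -> str:
    cid = case_id.strip().upper()
    if cid.startswith("HGG"):
        return "HGG"
    if cid.startswith("LGG"):
        return "LGG"
    if cid.startswith("M"):
        return "meningioma"
    raise ValueError(f"cannot infer tumor group from case id {case_id!r}")


def read_cohort_csv(path) -> list[CohortRow]:
    """Read a cohort table CSV with the published column names; the
    percentage column may carry a trailing '%'."""
    df = pd.read_csv(path)
    rows = []
    for _, r in df.iterrows():
        pct = str(r[COL_PCT]).rstrip("%")
        rows.append(CohortRow(
            case_id=str(r[COL_CASE]),
            group=_group_of(str(r[COL_CASE])),
            age=float(r[COL_AGE]),
            tumor_volume=float(r[COL_VOLUME]),
            mib1=float(r[COL_MIB1]),
            pct_decrease=float(pct)))
    return rows


def write_cohort_csv(rows: list[CohortRow], path) -> None:
    df = pd.DataFrame({
        COL_CASE: [r.case_id for r in rows],
        COL_AGE: [r.age for r in rows],
        COL_VOLUME: [r.tumor_volume for r in rows],
        COL_MIB1: [r.mib1 for r in rows],
        COL_PCT: [f"{r.pct_decrease:.2f}%" for r in rows],
    })
    df.to_csv(path, index=False)


def published_cohort() -> list[CohortRow]:
    """The packaged 16-case cohort table."""
    with resources.files("mirrortract.data").joinpath(
            "cohort16.csv").open("r") as fh:
        return read_cohort_csv(fh)


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def percent_decrease(n_healthy: int, n_lesioned: int) -> float:
    """100 x (n_healthy - n_lesioned) / n_healthy; negative when the
    lesioned side exceeds the healthy reference."""
    if n_healthy <= 0:
        raise ValueError("healthy-hemisphere tract count must be > 0")
    return 100.0 * (n_healthy - n_lesioned) / n_healthy


def ponder_by_volume(pct: float, volume_cm3: float) -> float:
    """Weight a percentage decrease by tumor size: %/cm^3."""
    if volume_cm3 <= 0:
        raise ValueError("tumor volume must be > 0")
    return pct / volume_cm3


def regress_mib1(table: list[CohortRow]) -> RegressionResult:
    """Simple linear regression of the volume-weighted percentage decrease
    on the MIB-1 index; p is two-sided from the exact t distribution with
    n-2 degrees of freedom."""
    if len(table) < 3:
        raise ValueError("need at least 3 rows for the MIB-1 regression")
    x = np.array([r.mib1 for r in table], dtype=float)
    y = np.array([ponder_by_volume(r.pct_decrease, r.tumor_volume)
                  for r in table])
    if np.allclose(x, x[0]):
        raise ValueError("MIB-1 values are all equal: correlation undefined")
    res = stats.linregress(x, y)
    return RegressionResult(r=float(res.rvalue), slope=float(res.slope),
                            intercept=float(res.intercept),
                            p=float(res.pvalue), n=len(table))


def group_summary(table: list[CohortRow], group: str):
    """(mean, sample SD with n-1 denominator) of the percentage decrease
    within one tumor group."""
    vals = np.array([r.pct_decrease for r in table if r.group == group])
    if len(vals) < 2:
        raise ValueError(f"need >= 2 rows in group {group!r}")
    return float(vals.mean()), float(vals.std(ddof=1))


def group_difference_test(table: list[CohortRow], groups_a, groups_b,
                          equal_var: bool = True):
    """Two-sample t-test of percentage decrease between two sets of tumor
    groups (pooled variance by default; Welch via equal_var=False).
    Returns (t, p)."""
    a = np.array([r.pct_decrease for r in table if r.group in groups_a])
    b = np.array([r.pct_decrease for r in table if r.group in groups_b])
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 rows on each side of the comparison")
    if np.allclose(a, a[0]) and np.allclose(b, b[0]) \
            and np.isclose(a[0], b[0]):
        return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)
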