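"""Exact 2x2 statistics for CIN confirmation assays.

Micronucleus (MNi), nucleoplasmic-bridge (NPB), gamma-H2AX-focus and
abnormal-mitosis scoring all reduce to 2x2 contingency tables: cells
with/without the event in a treated condition versus a control.
Fisher's exact test is computed by full hypergeometric enumeration over
all tables with the observed margins; the two-sided p-value follows the
minimum-likelihood convention (sum the probabilities of every table no
more probable than the observed one), the convention used by the major
statistics packages.  Families of comparisons are Bonferroni-adjusted
with the family size m always taken from the number of comparisons
supplied, and effect sizes are reported as fold elevations of the event
rate over the control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "ContingencyTable",
    "TestResult",
    "fisher_exact",
    "bonferroni_family",
    "fold_elevation",
    "compare_foci_fractions",
    "mn_test_report",
]

# relative tolerance when comparing hypergeometric probabilities, so that
# floating-point ties (symmetric tables) are counted as ties
_REL_TIE_TOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable:
    """Counts for one condition-vs-control comparison.

    a: treated cells with the event;    b: treated cells without;
    c: control cells with the event;    d: control cells without.
    """

    a: int
    b: int
    c: int
    d: int
    condition: str = ""

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b < 1 or self.c + self.d < 1:
            raise ValueError("each row of the table needs at least one cell")

    @property
    def treated_rate(self) -> float:
        return self.a / (self.a + self.b)

    @property
    def control_rate(self) -> float:
        return self.c / (self.c + self.d)


@dataclass
class TestResult:
    """Outcome of one exact test within a Bonferroni family."""

    p_value: float
    adjusted_alpha: float
    m: int
    significant: bool
    fold_elevation: float | None = None
    condition: str = ""


def fisher_exact(table: ContingencyTable, sidedness: str = "two_sided") -> float:
    """Exact p-value for independence in a 2x2 table.

    Enumerates the hypergeometric distribution of the top-left cell over
    every table with the observed margins.  ``two_sided`` sums the
    probabilities of all tables no more probable than the observed one;
    ``one_sided`` is the upper tail P[X >= a] (treated rate at least as
    elevated as observed).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    # support of the top-left cell given the margins
    k_min = max(0, col1 - (c + d))
    k_max = min(row1, col1)
    support = np.arange(k_min, k_max + 1)
    pmf = hypergeom.pmf(support, n, row1, col1)
    p_obs = hypergeom.pmf(a, n, row1, col1)

    if sidedness == "two_sided":
        p = float(pmf[pmf <= p_obs * (1.0 + _REL_TIE_TOL)].sum())
    elif sidedness == "one_sided":
        p = float(pmf[support >= a].sum())
    else:
        raise ValueError(f"unknown sidedness {sidedness!r}")
    return min(p, 1.0)


def bonferroni_family(
    p_values: list[float],
    alpha: float = 0.05,
    folds: list[float] | None = None,
    conditions: list[str] | None = None,
) -> list[TestResult]:
    """Apply a Bonferroni correction across one family of m comparisons.

    The adjusted level alpha/m is applied uniformly; m is the length of
    the supplied list.  With alpha = 0.05 and a family of 45 comparisons
    the adjusted level is ~0.0011.
    """
    m = len(p_values)
    if m < 1:
        raise ValueError("p-value family must be non-empty")
    adjusted = alpha / m
    folds = folds if folds is not None else [None] * m
    conditions = conditions if conditions is not None else [""] * m
    return [
        TestResult(
            p_value=float(p),
            adjusted_alpha=adjusted,
            m=m,
            significant=p < adjusted,
            fold_elevation=f,
            condition=cond,
        )
        for p, f, cond in zip(p_values, folds, conditions)
    ]


def fold_elevation(
    treated: ContingencyTable | float, control_rate: float | None = None
) -> float:
    """Fold elevation of the treated event rate over the control rate.

    Accepts either a :class:`ContingencyTable` (both rates taken from
    it) or a treated rate plus an explicit control rate.  A zero control
    rate leaves the fold undefined; report absolute rates instead.
    """
    if isinstance(treated, ContingencyTable):
        treated_rate = treated.treated_rate
        control = treated.control_rate if control_rate is None else control_rate
    else:
        treated_rate = float(treated)
        control = control_rate
    if control is None:
        raise ValueError("control rate is required")
    if control <= 0:
        raise ValueError(
            "control event rate is 0: fold elevation undefined; "
            "report absolute rates instead"
        )
    return treated_rate / control


def compare_foci_fractions(
    treated: tuple[int, int],
    control: tuple[int, int],
    alpha: float = 0.05,
    condition: str = "",
) -> TestResult:
    """Two-sided exact comparison of with/without-event counts, e.g.
    gamma-H2AX-focus-positive cells in treated vs control.

    Returns the p-value at family size 1 together with the fold
    elevation (None when the control rate is zero).
    """
    table = ContingencyTable(*treated, *control, condition=condition)
    p = fisher_exact(table, "two_sided")
    fold = (
        fold_elevation(table) if table.control_rate > 0 else None
    )
    return TestResult(
        p_value=p,
        adjusted_alpha=alpha,
        m=1,
        significant=p < alpha,
        fold_elevation=fold,
        condition=condition,
    )


def mn_test_report(
    counts: pd.DataFrame,
    control_condition: str,
    alpha: float = 0.05,
    endpoints: tuple[str, ...] = ("n_mni_cells", "n_npb_cells"),
) -> pd.DataFrame:
    """Micronucleus/NPB family report: each non-control condition is
    compared to the control by two-sided Fisher tests for every endpoint,
    Bonferroni-adjusted across the whole family (conditions x endpoints).

    ``counts`` has one row per condition with columns ``condition``,
    ``n_scored`` and one count column per endpoint (cells with >= 1
    event; multiplicities collapse to a binary per-cell call).
    """
    counts = counts.set_index("condition")
    if control_condition not in counts.index:
        raise ValueError(f"control condition {control_condition!r} not in table")
    ctrl = counts.loc[control_condition]
    rows = []
    for condition, row in counts.drop(index=control_condition).iterrows():
        for endpoint in endpoints:
            a = int(row[endpoint])
            b = int(row["n_scored"]) - a
            c = int(ctrl[endpoint])
            d = int(ctrl["n_scored"]) - c
            table = ContingencyTable(a, b, c, d, condition=str(condition))
            rows.append(
                {
                    "condition": condition,
                    "endpoint": endpoint,
                    "n_scored": int(row["n_scored"]),
                    "pct_with_event": 100.0 * table.treated_rate,
                    "pct_control": 100.0 * table.control_rate,
                    "fold_elevation": (
                        fold_elevation(table) if table.control_rate > 0 else np.nan
                    ),
                    "p_value": fisher_exact(table, "two_sided"),
                }
            )
    report = pd.DataFrame(rows)
    results = bonferroni_family(report["p_value"].tolist(), alpha=alpha)
    report["m"] = len(results)
    report["adjusted_alpha"] = results[0].adjusted_alpha if results else np.nan
    report["significant"] = [r.significant for r in results]
    return report
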