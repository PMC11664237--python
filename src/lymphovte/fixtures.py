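"""Embedded summary counts from the source study, with a verification report.

The study this package operationalises published no patient-level data, only
summary tables: 2x2 confusion counts for each risk model, univariate
risk-factor contingency tables, and cohort tallies.  Those printed counts
are embedded here so that every printed diagnostic metric and odds ratio can
be recomputed exactly from first principles and checked against the printed
value — the deterministic core of the package's validation.

Cell conventions: confusion fixtures are (TP, FP, FN, TN); factor fixtures
are (a, b, c, d) = (exposed events, unexposed events, exposed non-events,
unexposed non-events), so OR = (a*d)/(b*c).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import pandas as pd

from .cohort import ConfusionTable
from .diagnostics import chi_square_test, metrics, odds_ratio


@dataclass(frozen=True)
class ConfusionFixture:
    """A published confusion table plus the metric values printed with it."""

    name: str
    source: str
    table: ConfusionTable
    #: printed display-scale values: percentages (1 dp), Youden x100
    expected: Dict[str, float]
    derived: bool = False  # True if counts were reconstructed, not printed


@dataclass(frozen=True)
class FactorFixture:
    """A published exposure-by-outcome table plus its printed OR (and CI)."""

    name: str
    source: str
    a: int
    b: int
    c: int
    d: int
    expected_or: float
    expected_ci: Optional[Tuple[float, float]] = None


# -- retrospective cohort: n=325, 21 VTE ------------------------------------

CONFUSION_FIXTURES: Dict[str, ConfusionFixture] = {
    "khorana": ConfusionFixture(
        name="Khorana high risk",
        source="retrospective cohort risk-score evaluation",
        table=ConfusionTable(tp=3, fp=25, fn=18, tn=279),
        expected={
            "sensitivity": 14.3,
            "ppv": 10.7,
            "specificity": 91.8,
            "npv": 93.9,
            "youden_index": 6.1,
        },
    ),
    "throly": ConfusionFixture(
        name="ThroLy high risk",
        source="retrospective cohort risk-score evaluation",
        table=ConfusionTable(tp=8, fp=31, fn=13, tn=273),
        expected={
            "sensitivity": 38.1,
            "ppv": 20.5,
            "specificity": 89.8,
            "npv": 95.5,
            "youden_index": 27.9,
        },
    ),
    "retro_simul": ConfusionFixture(
        name="simul-mThroLy&D-D (derivation cohort)",
        source="retrospective cohort combined-testing evaluation; counts "
        "reconstructed from the printed sensitivity/specificity",
        table=ConfusionTable(tp=16, fp=87, fn=5, tn=217),
        expected={
            "sensitivity": 76.2,
            "specificity": 71.4,
            "youden_index": 47.6,
        },
        derived=True,
    ),
    "validation_simul": ConfusionFixture(
        name="simul-mThroLy&D-D (validation cohort)",
        source="validation cohort combined-testing evaluation",
        table=ConfusionTable(tp=6, fp=15, fn=3, tn=74),
        expected={
            "sensitivity": 66.7,
            "ppv": 28.6,
            "specificity": 83.1,
            "npv": 96.1,
            "youden_index": 49.8,
        },
    ),
    "cascade": ConfusionFixture(
        name="simul-mThroLy&D-D + TM&TAT (validation cohort)",
        source="validation cohort staged-cascade evaluation",
        table=ConfusionTable(tp=6, fp=0, fn=3, tn=89),
        expected={
            "sensitivity": 66.7,
            "ppv": 100.0,
            "specificity": 100.0,
            "npv": 96.7,
            "youden_index": 66.7,
        },
    ),
}

FACTOR_FIXTURES: Dict[str, FactorFixture] = {
    "history_vte": FactorFixture(
        name="history of VTE",
        source="retrospective cohort univariate risk-factor table",
        a=6, b=15, c=4, d=300,
        expected_or=30.0, expected_ci=(7.644, 117.742),
    ),
    "mediastinal": FactorFixture(
        name="mediastinal involvement",
        source="retrospective cohort univariate risk-factor table",
        a=10, b=11, c=41, d=263,
        expected_or=5.831, expected_ci=(2.330, 14.595),
    ),
    "stage": FactorFixture(
        name="clinical stage III/IV",
        source="retrospective cohort univariate risk-factor table",
        a=17, b=4, c=136, d=168,
        expected_or=5.25, expected_ci=(1.726, 15.969),
    ),
    "ecog": FactorFixture(
        name="ECOG score >= 3",
        source="retrospective cohort univariate risk-factor table",
        a=9, b=12, c=45, d=259,
        expected_or=4.317, expected_ci=(1.720, 10.836),
    ),
    "infection": FactorFixture(
        name="infection",
        source="retrospective cohort univariate risk-factor table",
        a=7, b=14, c=42, d=262,
        expected_or=3.119, expected_ci=(1.189, 8.179),
    ),
    "picc": FactorFixture(
        name="PICC placement",
        source="retrospective cohort univariate risk-factor table",
        a=9, b=12, c=72, d=232,
        expected_or=2.417, expected_ci=(0.979, 5.967),
    ),
}

#: (events, n) tallies per cohort.
INCIDENCE_TALLIES: Dict[str, Tuple[int, int]] = {
    "retrospective": (21, 325),
    "validation": (9, 98),
}

#: High- vs low-risk VTE counts in the validation cohort, [[6,15],[3,74]]
#: (rows: risk group; columns: VTE yes/no) — printed p = 0.002.
VALIDATION_RISK_TABLE = ((6, 15), (3, 74))
VALIDATION_RISK_P = 0.002

RETROSPECTIVE_N = 325
VALIDATION_N = 98


def _check_fixture_sums() -> None:
    for key, fx in CONFUSION_FIXTURES.items():
        n = VALIDATION_N if "validation" in fx.source else RETROSPECTIVE_N
        assert fx.table.n == n, f"fixture {key} cells do not sum to {n}"
    for key, fx in FACTOR_FIXTURES.items():
        assert fx.a + fx.b + fx.c + fx.d == RETROSPECTIVE_N, key


_check_fixture_sums()


def reference_report() -> pd.DataFrame:
    """Recompute every embedded published quantity and compare to its print.

    One row per quantity: the computed value (rounded to printed precision),
    the expected printed value, and whether they match.  Deterministic,
    sub-second, no external input.
    """
    rows = []

    for key, fx in CONFUSION_FIXTURES.items():
        computed = metrics(fx.table).as_percentages()
        for metric, expected in fx.expected.items():
            rows.append(
                {
                    "fixture": key,
                    "quantity": metric,
                    "source": fx.source,
                    "computed": computed[metric],
                    "expected": expected,
                    "match": computed[metric] == expected,
                }
            )

    for key, fx in FACTOR_FIXTURES.items():
        res = odds_ratio(fx.a, fx.b, fx.c, fx.d)
        # ORs printed to three decimals except round values (30, 5.25)
        computed_or = round(res.or_value, 3)
        rows.append(
            {
                "fixture": key,
                "quantity": "odds_ratio",
                "source": fx.source,
                "computed": computed_or,
                "expected": fx.expected_or,
                "match": abs(computed_or - fx.expected_or) < 5e-4,
            }
        )
        if fx.expected_ci is not None:
            ci = (round(res.ci_low, 3), round(res.ci_high, 3))
            rows.append(
                {
                    "fixture": key,
                    "quantity": "or_95ci",
                    "source": fx.source,
                    "computed": ci,
                    "expected": fx.expected_ci,
                    "match": all(
                        abs(x - y) < 5e-4 for x, y in zip(ci, fx.expected_ci)
                    ),
                }
            )

    # incidences, rounded to the precision each was printed at
    printed = {"retrospective": (6.46, 2), "validation": (9.2, 1)}
    for key, (events, n) in INCIDENCE_TALLIES.items():
        expected, ndigits = printed[key]
        computed = round(100.0 * events / n, ndigits)
        rows.append(
            {
                "fixture": key,
                "quantity": "incidence_pct",
                "source": f"{key} cohort tally",
                "computed": computed,
                "expected": expected,
                "match": computed == expected,
            }
        )
    ev = sum(e for e, _ in INCIDENCE_TALLIES.values())
    tot = sum(n for _, n in INCIDENCE_TALLIES.values())
    pooled = round(100.0 * ev / tot, 2)
    rows.append(
        {
            "fixture": "pooled",
            "quantity": "incidence_pct",
            "source": "both cohorts pooled",
            "computed": pooled,
            "expected": 7.09,
            "match": pooled == 7.09,
        }
    )

    _, p = chi_square_test(VALIDATION_RISK_TABLE, correction="yates")
    rows.append(
        {
            "fixture": "validation_risk_groups",
            "quantity": "chi_square_p_yates",
            "source": "validation cohort high- vs low-risk VTE incidence",
            "computed": round(p, 3),
            "expected": VALIDATION_RISK_P,
            "match": round(p, 3) == VALIDATION_RISK_P,
        }
    )

    return pd.DataFrame(rows)
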