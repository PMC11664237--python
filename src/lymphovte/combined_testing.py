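"""Combination algebra for binary diagnostic tests.

Clinically, a single risk score rarely has both the sensitivity and the
specificity one wants.  Two standard remedies are combined testing:

* **simultaneous (parallel)** — run several tests at once; a patient is
  positive if *any* component is positive.  Sensitivity can only go up,
  specificity can only go down.
* **sequential (serial)** — run tests one after another, each only on the
  previous test's positives; a patient is positive only if *all* components
  are positive.  Specificity and PPV go up, sensitivity goes down.

Tests are small declarative objects: a risk-band test over a scoring table,
a threshold test on a lab value, a linear biomarker composite against a
cutoff, or a combination of other tests.  The shipped constants encode the
staged NHL-VTE rule this package implements: mThroLy high risk OR
D-dimer > 1345 ug/dL as a parallel screen, followed (serially) by the
thrombomodulin / thrombin-antithrombin composite 0.125*TM + 0.194*TAT > 3.26.

A test whose deciding field is missing raises :class:`UnevaluableError`
naming the field — a risk cascade must not silently default on the very
marker it is about.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence, Union

from .cohort import BiomarkerPanel, PatientRecord
from .risk_scores import _COMPARE, ScoringTable, classify, score

#: Default cutoffs of the staged rule.
DD_CUTOFF_UG_DL = 1345.0
TM_WEIGHT = 0.125
TAT_WEIGHT = 0.194
COMPOSITE_CUTOFF = 3.26


class UnevaluableError(ValueError):
    """A test could not be evaluated because a required field is missing."""

    def __init__(self, field_name: str, patient_id: str = ""):
        self.field_name = field_name
        who = f" for patient {patient_id!r}" if patient_id else ""
        super().__init__(f"required field {field_name!r} is missing{who}")


@dataclass(frozen=True)
class BandTest:
    """Positive iff the record's score band equals ``band`` (default high)."""

    table: ScoringTable
    band: str = "high"

    @property
    def name(self) -> str:
        return f"{self.table.name} {self.band} risk"

    def __call__(self, record: PatientRecord) -> bool:
        return classify(score(record, self.table), self.table) == self.band


@dataclass(frozen=True)
class ThresholdTest:
    """Positive iff ``field op cutoff`` holds; errors if the field is absent."""

    field: str
    op: Literal["lt", "le", "gt", "ge", "eq"]
    cutoff: float

    @property
    def name(self) -> str:
        sym = {"lt": "<", "le": "<=", "gt": ">", "ge": ">=", "eq": "="}[self.op]
        return f"{self.field} {sym} {self.cutoff:g}"

    def __call__(self, record: PatientRecord) -> bool:
        value = record.get_field(self.field)
        if value is None:
            raise UnevaluableError(self.field, record.id)
        return _COMPARE[self.op](value, self.cutoff)


@dataclass(frozen=True)
class CompositeCoefficients:
    """Linear TM/TAT weights and the cutoff on the composite scale."""

    tm_weight: float = TM_WEIGHT
    tat_weight: float = TAT_WEIGHT
    cutoff: float = COMPOSITE_CUTOFF

    def __post_init__(self) -> None:
        if self.tm_weight == 0 and self.tat_weight == 0:
            raise ValueError("at least one composite weight must be nonzero")


def composite_tm_tat(
    biomarkers: BiomarkerPanel, coeffs: CompositeCoefficients | None = None
) -> float:
    """Linear TM+TAT composite ``w_tm*TM + w_tat*TAT`` (default 0.125/0.194)."""
    coeffs = coeffs or CompositeCoefficients()
    if biomarkers is None or biomarkers.tm is None:
        raise UnevaluableError("tm")
    if biomarkers.tat is None:
        raise UnevaluableError("tat")
    return coeffs.tm_weight * biomarkers.tm + coeffs.tat_weight * biomarkers.tat


@dataclass(frozen=True)
class CompositeTest:
    """Positive iff the TM+TAT composite strictly exceeds its cutoff."""

    coeffs: CompositeCoefficients = field(default_factory=CompositeCoefficients)

    @property
    def name(self) -> str:
        c = self.coeffs
        return f"{c.tm_weight:g}*TM + {c.tat_weight:g}*TAT > {c.cutoff:g}"

    def __call__(self, record: PatientRecord) -> bool:
        if record.biomarkers is None:
            raise UnevaluableError("tm", record.id)
        return composite_tm_tat(record.biomarkers, self.coeffs) > self.coeffs.cutoff


@dataclass(frozen=True)
class CombinationTest:
    """Parallel (OR) or serial (AND, short-circuit, in order) combination."""

    mode: Literal["simultaneous", "sequential"]
    children: tuple["BinaryTest", ...]
    label: str = ""

    def __post_init__(self) -> None:
        if self.mode not in ("simultaneous", "sequential"):
            raise ValueError(f"unknown combination mode {self.mode!r}")
        if len(self.children) < 2:
            raise ValueError("a combination needs at least two child tests")

    @property
    def name(self) -> str:
        if self.label:
            return self.label
        joiner = " OR " if self.mode == "simultaneous" else " THEN "
        return "(" + joiner.join(c.name for c in self.children) + ")"

    def __call__(self, record: PatientRecord) -> bool:
        if self.mode == "simultaneous":
            return any(child(record) for child in self.children)
        # serial: children after a negative are never evaluated, mirroring
        # staged lab ordering (cheap screens gate expensive assays)
        for child in self.children:
            if not child(record):
                return False
        return True


BinaryTest = Union[BandTest, ThresholdTest, CompositeTest, CombinationTest]


def apply_test(test: BinaryTest, record: PatientRecord) -> bool:
    """Evaluate *test* on *record*; True = positive (high risk)."""
    return test(record)


def apply_to_cohort(test: BinaryTest, cohort: Iterable[PatientRecord]) -> list[bool]:
    return [apply_test(test, r) for r in cohort]


def simul_screen(
    mthroly: ScoringTable, dd_cutoff: float = DD_CUTOFF_UG_DL
) -> CombinationTest:
    """Stage-1 parallel screen: mThroLy high risk OR D-dimer > cutoff."""
    return CombinationTest(
        mode="simultaneous",
        children=(BandTest(mthroly, "high"), ThresholdTest("d_dimer", "gt", dd_cutoff)),
        label=f"simul-{mthroly.name}&D-D",
    )


def build_staged_cascade(
    mthroly: ScoringTable,
    dd_cutoff: float = DD_CUTOFF_UG_DL,
    coeffs: CompositeCoefficients | None = None,
) -> CombinationTest:
    """Full staged rule: the parallel screen, then the TM+TAT composite.

    Positive iff (mThroLy high OR D-dimer > dd_cutoff) AND composite > cutoff.
    The composite is only evaluated on stage-1 positives.
    """
    coeffs = coeffs or CompositeCoefficients()
    screen = simul_screen(mthroly, dd_cutoff)
    return CombinationTest(
        mode="sequential",
        children=(screen, CompositeTest(coeffs)),
        label=f"{screen.label} + TM&TAT",
    )
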