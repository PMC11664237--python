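"""Clinical data model for NHL cohorts with venous-thromboembolism outcomes.

One :class:`PatientRecord` holds everything the pipeline consumes for a single
newly diagnosed non-Hodgkin lymphoma patient: demographics and clinical risk
factors, the baseline hematology panel drawn before chemotherapy, the optional
coagulation-biomarker panel (TM, TAT, PIC, t-PAIC), the VTE outcome, and
follow-up information for survival analysis.

Optional fields left as ``None`` mean "unknown": downstream scoring treats an
unknown field as contributing no points (with a warning), while binary
diagnostic tests refuse to evaluate on a missing deciding field.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Optional

ANN_ARBOR_STAGES = ("I", "II", "III", "IV")
SEXES = ("male", "female")
RISK_BANDS = ("low", "intermediate", "high")


@dataclass
class LabPanel:
    """Baseline hematology/coagulation panel.

    Units follow routine laboratory convention: cell counts in 10^9/L
    (RBC 10^12/L), hemoglobin in g/L, MPV/PDW/RDW-SD in fL, LDH in U/L,
    clotting times in seconds, fibrinogen in mg/L, D-dimer in ug/dL and
    FDP in mg/L.  All fields optional; present values must be positive.
    """

    wbc: Optional[float] = None
    ne: Optional[float] = None
    nlr: Optional[float] = None
    rbc: Optional[float] = None
    hb: Optional[float] = None
    plt: Optional[float] = None
    mpv: Optional[float] = None
    pdw: Optional[float] = None
    rdw_sd: Optional[float] = None
    ldh: Optional[float] = None
    pt: Optional[float] = None
    inr: Optional[float] = None
    aptt: Optional[float] = None
    fib: Optional[float] = None
    tt: Optional[float] = None
    d_dimer: Optional[float] = None
    fdp: Optional[float] = None


@dataclass
class BiomarkerPanel:
    """Novel coagulation-activation markers (arbitrary assay units, >= 0).

    tm: thrombomodulin (endothelial damage); tat: thrombin-antithrombin
    complex (coagulation activation); pic: plasmin-antiplasmin complex and
    t_paic: tPA/PAI-1 complex (fibrinolysis activation).
    """

    tm: Optional[float] = None
    tat: Optional[float] = None
    pic: Optional[float] = None
    t_paic: Optional[float] = None


@dataclass
class PatientRecord:
    id: str = ""
    age_years: Optional[float] = None
    sex: Optional[str] = None
    bmi: Optional[float] = None
    stage: Optional[str] = None
    ecog: Optional[int] = None
    b_symptoms: Optional[bool] = None
    picc: Optional[bool] = None
    mediastinal_involvement: Optional[bool] = None
    prior_vte: Optional[bool] = None
    infection: Optional[bool] = None
    reduced_mobility: Optional[bool] = None
    extranodal: Optional[bool] = None
    esa_use: Optional[bool] = None
    labs: LabPanel = field(default_factory=LabPanel)
    biomarkers: Optional[BiomarkerPanel] = None
    vte: Optional[bool] = None
    vte_time_months: Optional[float] = None
    followup_months: Optional[float] = None
    event_death: Optional[bool] = None

    def get_field(self, name: str):
        """Resolve a (possibly lab- or biomarker-level) field by name.

        Lookup order: record attribute, then labs, then biomarkers.
        Returns None for declared-but-absent values; raises KeyError for
        undeclared names so that misconfigured scoring tables fail loudly.
        """
        if name in _RECORD_FIELDS:
            return getattr(self, name)
        if name in _LAB_FIELDS:
            return getattr(self.labs, name)
        if name in _BIOMARKER_FIELDS:
            return getattr(self.biomarkers, name) if self.biomarkers else None
        raise KeyError(f"unknown patient field: {name!r}")


_RECORD_FIELDS = {f.name for f in fields(PatientRecord)} - {"labs", "biomarkers"}
_LAB_FIELDS = {f.name for f in fields(LabPanel)}
_BIOMARKER_FIELDS = {f.name for f in fields(BiomarkerPanel)}

#: Positive lab values only; zero is a measurement artifact, not a result.
_POSITIVE_LABS = tuple(sorted(_LAB_FIELDS))


@dataclass
class ConfusionTable:
    """2x2 prediction-by-outcome counts (test positive = predicted event)."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
            setattr(self, name, int(v))


def validate_record(record: PatientRecord) -> list[str]:
    """Check a record against the data-model invariants.

    Returns a list of human-readable violation strings (empty iff valid);
    never raises and never mutates the record.
    """
    v: list[str] = []
    if record.age_years is not None and record.age_years < 0:
        v.append("age_years negative")
    if record.sex is not None and record.sex not in SEXES:
        v.append(f"sex not in {SEXES}")
    if record.bmi is not None and record.bmi <= 0:
        v.append("bmi non-positive")
    if record.stage is not None and record.stage not in ANN_ARBOR_STAGES:
        v.append("stage not an Ann Arbor label (I, II, III, IV)")
    if record.ecog is not None and not (0 <= record.ecog <= 5):
        v.append("ecog out of range")
    for name in _POSITIVE_LABS:
        val = getattr(record.labs, name)
        if val is not None and val <= 0:
            v.append(f"{name} non-positive")
    if record.biomarkers is not None:
        for name in sorted(_BIOMARKER_FIELDS):
            val = getattr(record.biomarkers, name)
            if val is not None and val < 0:
                v.append(f"{name} negative")
    for name in ("vte_time_months", "followup_months"):
        val = getattr(record, name)
        if val is not None and val < 0:
            v.append(f"{name} negative")
    if (
        record.vte_time_months is not None
        and record.followup_months is not None
        and record.vte_time_months > record.followup_months
    ):
        v.append("vte_time_months exceeds followup_months")
    return v
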