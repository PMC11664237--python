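import pytest

from lymphovte import (
    CohortConfig,
    LabPanel,
    PatientRecord,
    generate,
    khorana_table,
    mthroly_table,
    throly_table,
)


def make_record(**kwargs) -> PatientRecord:
    """A fully valid baseline patient; override any field via kwargs."""
    labs = kwargs.pop("labs", None)
    lab_kwargs = {
        k: kwargs.pop(k)
        for k in list(kwargs)
        if k in LabPanel.__dataclass_fields__
    }
    defaults = dict(
        id="P001",
        age_years=55.0,
        sex="female",
        stage="II",
        ecog=1,
        b_symptoms=False,
        picc=False,
        mediastinal_involvement=False,
        prior_vte=False,
        infection=False,
        reduced_mobility=False,
        extranodal=False,
        esa_use=False,
        vte=False,
    )
    defaults.update(kwargs)
    if labs is None:
        lab_defaults = dict(
            wbc=7.0, ne=4.0, nlr=2.5, rbc=4.2, hb=130.0, plt=220.0, d_dimer=500.0
        )
        lab_defaults.update(lab_kwargs)
        labs = LabPanel(**lab_defaults)
    defaults["labs"] = labs
    return PatientRecord(**defaults)


@pytest.fixture(scope="session")
def khorana():
    return khorana_table()


@pytest.fixture(scope="session")
def throly():
    return throly_table()


@pytest.fixture(scope="session")
def mthroly():
    return mthroly_table()


@pytest.fixture(scope="session")
def small_cohort():
    """500-patient synthetic cohort shared by pipeline-level tests."""
    return generate(CohortConfig(n=500, seed=42))
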