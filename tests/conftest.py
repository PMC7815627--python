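import pytest

from ildtraj import Cohort, PatientRecord, Visit


def make_patient(pid="P1", visits=None, **overrides):
    """Minimal valid patient; `visits` is a list of (t, fvc) or (t, fvc, dlco)."""
    defaults = dict(
        patient_id=pid,
        age_years=55.0,
        sex="female",
        disease_duration_years=8.0,
        subtype="limited",
        ata=False,
        aca=False,
        ara=False,
        mrss=10,
        reflux_dysphagia=False,
        esr=25.0,
        crp_elevated=False,
        nyha_class=1,
        immunosuppressant_use=None,
        died=False,
    )
    defaults.update(overrides)
    visit_objs = []
    for spec in visits or []:
        t, fvc = spec[0], spec[1]
        dlco = spec[2] if len(spec) > 2 else None
        visit_objs.append(Visit(pid, float(t), fvc, dlco))
    return PatientRecord(visits=visit_objs, **defaults)


@pytest.fixture
def simple_patient():
    """Annual schedule, baseline DLCO present, steadily declining FVC."""
    return make_patient("P1", [(0, 90.0, 60.0), (12, 80.0, 55.0), (24, 70.0, 50.0)])


@pytest.fixture
def simple_cohort(simple_patient):
    return Cohort(patients=[simple_patient], provenance="test")
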