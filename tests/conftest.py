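import pytest
from hypothesis import HealthCheck, settings

from strokecourse.cohort_model import (
    NDS_ITEMS,
    NIHSS_ITEMS,
    NDSAssessment,
    NIHSSAssessment,
    PatientRecord,
)
from strokecourse.synthetic_cohort import GeneratorConfig, generate_cohort

settings.register_profile(
    "suite", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


def fill_items(total, template):
    """Deterministic greedy fill of an item dict to a given total."""
    items = {}
    remaining = total
    for name, mx in template.items():
        take = min(mx, remaining)
        items[name] = take
        remaining -= take
    assert remaining == 0, f"total {total} exceeds instrument range"
    return items


def make_patient(nihss_totals, times=None, nds_totals=None, nds_times=None,
                 mrs=0, anamnesis=None, pid="T1", unknown_gp_items=()):
    """A patient whose serial NIHSS (sources gp, admission, h8, h16, h24)
    carries the given totals; optional NDS-0/NDS-1 totals; GP items can be
    masked unknown by name."""
    sources = ("gp", "admission", "h8", "h16", "h24")[:len(nihss_totals)]
    if times is None:
        times = [60, 240, 720, 1200, 1440][:len(nihss_totals)]
    nihss_series = []
    for src, t, tot in zip(sources, times, nihss_totals):
        items = fill_items(tot, NIHSS_ITEMS)
        if src == "gp":
            for name in unknown_gp_items:
                items[name] = None
        nihss_series.append(NIHSSAssessment(timestamp=t, items=items, source=src))
    nds_series = []
    if nds_totals is not None:
        if nds_times is None:
            nds_times = [max(1, times[0] - 10), times[1] if len(times) > 1 else times[0] + 60]
        for t, tot in zip(nds_times, nds_totals):
            nds_series.append(NDSAssessment(timestamp=t, items=fill_items(tot, NDS_ITEMS)))
    return PatientRecord(
        id=pid, onset_type="sudden", onset_time=0,
        admission_time=times[1] if len(times) > 1 else times[0],
        nds_series=nds_series, nihss_series=nihss_series,
        plateau_anamnesis_min=anamnesis, category="infarction",
        mrs_discharge=mrs)


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig()


@pytest.fixture(scope="session")
def small_cohort():
    """A 400-patient default-parameter cohort shared across tests."""
    return generate_cohort(GeneratorConfig(n_patients=400, seed=7))


@pytest.fixture(scope="session")
def big_cohort():
    """A 5000-patient default-parameter cohort shared across tests."""
    return generate_cohort(GeneratorConfig(n_patients=5000, seed=11))
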