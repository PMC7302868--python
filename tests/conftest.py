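import datetime as dt
import textwrap

import pytest

import clockshift as cs


@pytest.fixture(scope="session")
def default_tax():
    return cs.default_taxonomy()


@pytest.fixture
def toy_taxonomy_file(tmp_path):
    """Minimal exhaustive ICD-10 cover: circulatory / respiratory / everything else."""
    p = tmp_path / "toy_map.csv"
    p.write_text(textwrap.dedent("""\
        code_start,code_end,icd_version,dialect,class_id,class_name,system_id,system_name,ambiguous
        A00,H99,10,*,other1,Everything before I,misc,Miscellaneous,0
        I00,I99,10,*,circ,Circulatory,circulatory,Circulatory system,0
        J00,J99,10,*,resp,Respiratory,respiratory,Respiratory system,0
        K00,Z99,10,*,other2,Everything after J,misc,Miscellaneous,0
        """))
    return p


@pytest.fixture
def toy_taxonomy(toy_taxonomy_file):
    return cs.load_taxonomy(toy_taxonomy_file)


@pytest.fixture
def plain_calendar():
    """US-rule calendar without holidays (keeps comparator logic trivial)."""
    return cs.ShiftCalendar(rule="us", holidays=frozenset())


def make_flat_config(n_patients=2000, classes=("c1",), hazard=0.01,
                     window=(dt.date(2010, 2, 1), dt.date(2010, 4, 30)),
                     seed=0, **kw):
    """Structureless generator config: constant hazard, no weekday/seasonal/
    holiday variation, full-window enrollment."""
    defaults = dict(
        n_patients=n_patients, study_window=window, churn=False,
        birth_year_range=(1950, 1989),
        baseline_hazards=cs.flat_hazards(list(classes), hazard),
        weekday_multipliers=(1.0,) * 7, seasonal_amplitude=0.0,
        miscoding_rate=0.0,
        calendar=cs.ShiftCalendar(rule="us", holidays=frozenset()),
        seed=seed)
    defaults.update(kw)
    return cs.SimulationConfig(**defaults)


@pytest.fixture
def flat_config():
    return make_flat_config()
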