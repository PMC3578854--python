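import pytest

from rnaptraffic import (
    EnergyModel,
    KineticParams,
    MotifSpec,
    RunConfig,
    make_template,
    simulate_mra,
    simulate_sra,
)

#: NTP concentration (uM) used for the synthetic study conditions.
NTP_UM = 25.0

#: Motif layout of the 500-nt study template (positions on the template).
STUDY_MOTIFS = [
    MotifSpec("strong_pause", 120),
    MotifSpec("backtrack_trap", 190, 8),
    MotifSpec("backtrack_trap", 260, 8),
    MotifSpec("strong_pause", 330),
    MotifSpec("backtrack_trap", 400, 8),
]


@pytest.fixture(scope="session")
def model():
    return EnergyModel()


@pytest.fixture(scope="session")
def params():
    return KineticParams(ntp_conc={b: NTP_UM for b in "ACGU"})


@pytest.fixture(scope="session")
def pause_template(model):
    """300-nt template with one planted strong pause near position 150."""
    return make_template(300, [MotifSpec("strong_pause", 150)], seed=1, model=model)


@pytest.fixture(scope="session")
def study_template(model):
    """500-nt template with planted pauses and backtracking traps."""
    return make_template(500, STUDY_MOTIFS, seed=11, model=model)


@pytest.fixture(scope="session")
def study_rate_table(study_template, params):
    return RunConfig(template=study_template, params=params).rate_table()


@pytest.fixture(scope="session")
def pause_rate_table(pause_template, params):
    return RunConfig(template=pause_template, params=params).rate_table()


@pytest.fixture(scope="session")
def study_sra_ensemble(study_template, params, study_rate_table):
    """200 single-polymerase replicates on the study template."""
    cfg = RunConfig(template=study_template, params=params, n_rnap_max=1, seed=3)
    return [
        simulate_sra(cfg, replicate=r, rate_table=study_rate_table) for r in range(200)
    ]


@pytest.fixture(scope="session")
def study_mra_ensemble(study_template, params, study_rate_table):
    """200 ten-polymerase replicates on the study template."""
    cfg = RunConfig(template=study_template, params=params, n_rnap_max=10, seed=3)
    return [
        simulate_mra(cfg, replicate=r, rate_table=study_rate_table) for r in range(200)
    ]
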