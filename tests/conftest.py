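import pytest

from moha.harmonization import HarmonizedProfile, TreeConfig
from moha.io_model import MedicalRecord, Participant, WaveRecord
from moha.synthetic_cohort import SyntheticConfig, generate_cohort


@pytest.fixture
def profile_factory():
    """Factory for HarmonizedProfile objects with all factors off by default."""

    def make(participant_id="P1", **overrides):
        return HarmonizedProfile(participant_id=participant_id, **overrides)

    return make


@pytest.fixture
def wave_factory():
    def make(participant_id="P1", wave=1, **overrides):
        return WaveRecord(participant_id=participant_id, wave=wave, **overrides)

    return make


@pytest.fixture
def participant_factory():
    def make(participant_id="P1", **overrides):
        defaults = dict(sex="female", birth_year=2000, waves_present=frozenset({1, 2, 3}))
        defaults.update(overrides)
        return Participant(participant_id=participant_id, **defaults)

    return make


@pytest.fixture
def tiny_cohort(participant_factory, wave_factory):
    """Three hand-built participants: one clear sexual, one clear vertical,
    one with no informative factors (unclassifiable)."""
    participants = [
        participant_factory("S", sex="female", birth_year=1999),
        participant_factory("V", sex="male", birth_year=2001),
        participant_factory("U", sex="male", birth_year=2000, waves_present=frozenset({1})),
    ]
    waves = [
        wave_factory("S", 1, sexual_debut_age=14, art_init_age_selfreport=16,
                     first_hiv_test_age=16, hiv_status_aware=True, art_naive=False),
        wave_factory("S", 2, sexual_debut_age=14, consistent_unprotected_sex=True),
        wave_factory("S", 3),
        wave_factory("V", 1, mother_vital="dead", mother_death_cause="hiv_aids",
                     age_at_mother_death=3, art_init_age_selfreport=4, art_naive=False),
        wave_factory("V", 2, mother_vital="dead", mother_death_cause="hiv_aids"),
        wave_factory("V", 3),
        wave_factory("U", 1),
    ]
    medical = [MedicalRecord("S", art_init_age_record=16), MedicalRecord("V", art_init_age_record=4)]
    return participants, waves, medical


@pytest.fixture(scope="session")
def default_synthetic():
    """A moderately sized zero-noise cohort shared across tests (read-only)."""
    config = SyntheticConfig(n=400, single_wave_mothers_n=60, seed=11)
    return config, generate_cohort(config)


@pytest.fixture
def default_tree_config():
    return TreeConfig()
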