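from __future__ import annotations

import pytest

from leisurenoise import (
    Cohort,
    ExposureRecord,
    Participant,
    default_catalog,
)


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


def make_participant(
    pid: str = "P1",
    *,
    age: int = 21,
    sex: str = "female",
    exposures: tuple[ExposureRecord, ...] = (),
    prior_diagnosis: bool = False,
    consent: bool = True,
    noisy_residence: bool = False,
    tinnitus: bool = False,
    earache: bool = False,
    temporary_loss: bool = False,
    n_yes_items: int = 0,
) -> Participant:
    """Handbuilt survey respondent with ``n_yes_items`` affirmative answers."""
    items = tuple(i < n_yes_items for i in range(11))
    return Participant(
        participant_id=pid,
        age=age,
        sex=sex,
        program="medicine",
        noisy_residence=noisy_residence,
        prior_hearing_diagnosis=prior_diagnosis,
        consent_given=consent,
        exposures=exposures,
        neq_tinnitus=tinnitus,
        neq_earache=earache,
        neq_temporary_loss=temporary_loss,
        hearing_items=items,
    )


#: Exposure profiles that put a participant decisively above / below 85 dBA
#: at the default 40-hour reference week (through the real exposure model).
def loud_exposure() -> tuple[ExposureRecord, ...]:
    # discos at rating 5 -> 105 dBA for 14 h/week: far above the limit
    return (ExposureRecord("disco", 2.0, 7, 5),)


def quiet_exposure() -> tuple[ExposureRecord, ...]:
    # personal audio at rating 1 -> 60 dBA for 1 h/week: far below
    return (ExposureRecord("personal_stereo", 1.0, 1, 1),)


@pytest.fixture()
def small_cohort(catalog) -> Cohort:
    """Five well-formed respondents exercising every field."""
    participants = (
        make_participant("P1", exposures=loud_exposure(), tinnitus=True, n_yes_items=5),
        make_participant("P2", sex="male", exposures=quiet_exposure(), n_yes_items=2),
        make_participant("P3", age=25, exposures=(), earache=True, n_yes_items=0),
        make_participant(
            "P4",
            exposures=(
                ExposureRecord("tv", 1.5, 7, 2),
                ExposureRecord("disco", 3.0, 1, 4),
            ),
            temporary_loss=True,
            n_yes_items=11,
        ),
        make_participant("P5", sex="male", noisy_residence=True, n_yes_items=4),
    )
    return Cohort(participants, catalog)
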