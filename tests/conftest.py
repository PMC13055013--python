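import numpy as np
import pandas as pd
import pytest

from hemimorph import vocab
from hemimorph.synth import CohortConfig, generate_cohort, generate_table1_roster
from hemimorph.types import MorphometricTable, Participant


@pytest.fixture(scope="session")
def small_cohort():
    cfg = CohortConfig(
        n_patients_LH=12, n_patients_RH=10, n_controls=20, seed=7
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def roster():
    return generate_table1_roster()


def random_table(rng: np.random.Generator, n_participants: int = 4) -> tuple:
    """A random valid table + participants for round-trip tests."""
    participants, records = [], []
    for i in range(n_participants):
        is_ctrl = rng.random() < 0.5
        hemi = "LH" if rng.random() < 0.5 else "RH"
        p = Participant(
            id=f"s{i:02d}",
            group="control" if is_ctrl else "patient",
            preserved_hemisphere=None if is_ctrl else hemi,
            age_at_test=float(rng.uniform(7, 22)),
            gender="female" if rng.random() < 0.5 else "male",
            scanner=rng.choice(["a", "b"]),
            surgery_kind="none" if is_ctrl else rng.choice(["resection", "ablation"]),
            ilae_binned="none" if is_ctrl else rng.choice(["low", "high"]),
        )
        participants.append(p)
        for h in p.hemispheres():
            for measure in vocab.MEASURES:
                for region in vocab.vocabulary_for(measure):
                    if rng.random() < 0.5:
                        continue  # sparse tables are valid
                    records.append((p.id, h, measure, region, float(rng.uniform(0.5, 100))))
    df = pd.DataFrame(
        records, columns=["participant_id", "hemisphere", "measure", "region", "value"]
    )
    table = MorphometricTable(df).validate().sorted()
    return table, participants
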