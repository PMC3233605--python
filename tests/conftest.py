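from __future__ import annotations

import pytest

from rxtrends.cohort import build_cohort, in_window_prescriptions
from rxtrends.drugs import DrugDictionary
from rxtrends.sessions import sessions_for_all_units
from rxtrends.simulate import uk_prescribing_preset, generate
from rxtrends import io as rio


@pytest.fixture(scope="session")
def sim_small():
    """One small seeded replicate of the shipped preset, shared across tests."""
    config = uk_prescribing_preset(n_patients=150, seed=11)
    return config, generate(config)


@pytest.fixture(scope="session")
def sim_small_dataset(sim_small, tmp_path_factory):
    """The same replicate written to CSV files."""
    from rxtrends.simulate import write_dataset
    config, result = sim_small
    out = tmp_path_factory.mktemp("simdata")
    write_dataset(result, out)
    return config, result, out


@pytest.fixture(scope="session")
def sim_small_pipeline(sim_small_dataset):
    """Cohort + window-restricted scripts + sessions for the small replicate."""
    config, result, data_dir = sim_small_dataset
    patients = rio.read_patients(data_dir / "patients.csv").frame
    diagnoses = rio.read_diagnoses(data_dir / "diagnoses.csv").frame
    prescriptions = rio.read_prescriptions(data_dir / "prescriptions.csv").frame
    dictionary = DrugDictionary.from_csv(data_dir / "drug_dictionary.csv")
    codelists = rio.read_codelists(data_dir / "codelists.csv")
    cohort = build_cohort(patients, diagnoses, prescriptions, dictionary,
                          codelists, config.study)
    rx = in_window_prescriptions(prescriptions, dictionary, cohort.members)
    sessions = sessions_for_all_units(rx, dictionary, cohort.members, config.study)
    return config, result, cohort, rx, sessions, dictionary
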