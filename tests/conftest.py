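import numpy as np
import pandas as pd
import pytest

from episig import (
    Config,
    apply_probe_filters,
    build_reference_profiles,
    derive_signature,
    generate_discovery_study,
    generate_validation_cohort,
)
from episig.synthetic_data import SimulationParams


@pytest.fixture(scope="session")
def default_params():
    return SimulationParams(seed=1)


@pytest.fixture(scope="session")
def discovery(default_params):
    """Study-scale simulated discovery cohort (10,000 CpGs, 19 vs 53)."""
    return generate_discovery_study(default_params)


@pytest.fixture(scope="session")
def config():
    return Config()


@pytest.fixture(scope="session")
def filtered(discovery, config):
    matrix, sheet, annotation, truth = discovery
    out, report = apply_probe_filters(matrix, annotation, config)
    return out, report


@pytest.fixture(scope="session")
def signature(filtered, discovery, config):
    matrix, _ = filtered
    _, sheet, _, _ = discovery
    return derive_signature(matrix, sheet, config)


@pytest.fixture(scope="session")
def profiles(filtered, discovery, signature):
    matrix, _ = filtered
    _, sheet, _, _ = discovery
    return build_reference_profiles(matrix, sheet, signature)


@pytest.fixture(scope="session")
def validation_cohorts(default_params, discovery):
    _, _, _, truth = discovery
    controls, ctrl_sheet = generate_validation_cohort(
        default_params, truth, "control", 200, seed=20001
    )
    cases, case_sheet = generate_validation_cohort(
        default_params, truth, "case", 19, seed=20002
    )
    return (controls, ctrl_sheet), (cases, case_sheet)


def tiny_beta_matrix(values, probe_prefix="cg", sample_prefix="s"):
    """Helper: BetaMatrix from a nested list/array."""
    from episig import BetaMatrix

    arr = np.asarray(values, dtype=float)
    return BetaMatrix(
        pd.DataFrame(
            arr,
            index=pd.Index(
                [f"{probe_prefix}{i}" for i in range(arr.shape[0])], name="probe_id"
            ),
            columns=[f"{sample_prefix}{j}" for j in range(arr.shape[1])],
        )
    )


def simple_sheet(groups, **extra_cols):
    """Helper: SampleSheet from a list of group labels."""
    from episig import SampleSheet

    ids = [f"s{j}" for j in range(len(groups))]
    data = {"group": groups}
    data.update(extra_cols)
    return SampleSheet(pd.DataFrame(data, index=pd.Index(ids, name="sample_id")))
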