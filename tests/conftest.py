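import numpy as np
import pandas as pd
import pytest

from wakemark import PreprocessConfig, prepare_views
from wakemark.synthetic import ProfileDefaults, generate_study
from wakemark.table import FeatureTable


@pytest.fixture(scope="session")
def small_study():
    """A compact three-experiment study: 6/5/4 participants, 46 features."""
    return generate_study(
        {"linear": 5, "circadian": 8, "mixed": 3, "null": 30},
        seed=101,
        n_participants=(6, 5, 4),
        missing=(4, 3, 0),
    )


@pytest.fixture(scope="session")
def small_views(small_study):
    exp1, exp2, _ = small_study
    return (
        prepare_views(exp1, PreprocessConfig(imputation_seed=7)),
        prepare_views(exp2, PreprocessConfig(imputation_seed=8)),
    )


@pytest.fixture(scope="session")
def candidate_study():
    """Strong-signal study without heavy censoring: 5 linear + 15 null
    features, full participant counts; used by selection/modeling tests."""
    defaults = ProfileDefaults(censor_high_fraction=0.0)
    return generate_study(
        {"linear": 5, "null": 15},
        profile_defaults=defaults,
        seed=21,
        n_participants=(12, 11, 5),
        missing=(10, 11, 0),
    )


def make_table(values, participants=None, tsw=None, feature_ids=None,
               protocol="sleep_deprivation", day=1):
    """Hand-rolled FeatureTable from a 2-D array for unit tests."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    participants = participants if participants is not None else ["P1"] * n
    tsw = tsw if tsw is not None else list(range(n))
    feature_ids = feature_ids if feature_ids is not None else [f"F{j}" for j in range(p)]
    idx = pd.Index([f"s{i}" for i in range(n)], name="sample_id")
    inten = pd.DataFrame(values, index=idx, columns=feature_ids)
    meta = pd.DataFrame(
        {
            "participant_id": participants,
            "experiment_id": "expT",
            "tsw_hours": tsw,
            "day_index": day,
            "protocol_kind": protocol,
            "clock_offset_h": 0.0,
        },
        index=idx,
    )
    return FeatureTable(inten, meta)
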