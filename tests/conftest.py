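import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# hand-tallied six-trial fixture:
#   a/anodal/baseline lag 3: 2 trials, 2 T1-correct, 1 T2-correct -> T2|T1 0.5
#   a/anodal/baseline lag 8: 2 trials, 1 T1-correct, 1 T2-correct -> T2|T1 1.0
#   b/cathodal/baseline lag 3: 1 trial, 0 T1-correct -> T2|T1 undefined
#   b/cathodal/baseline lag 8: 1 trial, 1 T1-correct, 1 T2-correct -> T2|T1 1.0
SIX_TRIALS = pd.DataFrame(
    [
        ("a", 1, "anodal", "baseline", 3, 1, 0),
        ("a", 1, "anodal", "baseline", 3, 1, 1),
        ("a", 1, "anodal", "baseline", 8, 1, 1),
        ("a", 1, "anodal", "baseline", 8, 0, 1),
        ("b", 1, "cathodal", "baseline", 3, 0, 0),
        ("b", 1, "cathodal", "baseline", 8, 1, 1),
    ],
    columns=[
        "participant", "session", "polarity", "block", "lag",
        "t1_correct", "t2_correct",
    ],
)


@pytest.fixture
def six_trials():
    return SIX_TRIALS.copy()


@pytest.fixture
def six_trials_csv(tmp_path):
    path = tmp_path / "six.csv"
    SIX_TRIALS.to_csv(path, index=False)
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def random_trials(rng, n_participants=4, n_per_cell=12, dialect="study2"):
    """Small random but structurally valid trial table."""
    lags = {"study2": [3, 8], "study1": [2, 4, 10]}[dialect]
    rows = []
    for i in range(n_participants):
        first_anodal = i % 2 == 0
        for session in (1, 2):
            pol = (
                "anodal" if (session == 1) == first_anodal else "cathodal"
            )
            for block in ("baseline", "tdcs", "post"):
                for lag in lags:
                    t1 = rng.random(n_per_cell) < 0.8
                    t2 = rng.random(n_per_cell) < 0.6
                    for a, b in zip(t1, t2):
                        rows.append(
                            (f"p{i}", session, pol, block, lag, int(a), int(b))
                        )
    return pd.DataFrame(
        rows,
        columns=[
            "participant", "session", "polarity", "block", "lag",
            "t1_correct", "t2_correct",
        ],
    )
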