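import numpy as np
import pytest

from ecgnoise import generate_clean_ecg
from ecgnoise.stats import ConfusionMatrix

# Published inter-observer confusion matrix (minutes; observer 1 rows,
# observer 2 columns; classes Free/Low/Moderate/Hard/Others).
TABLE2_UPPER = np.array(
    [
        [3.67, 1.86, 0.00, 0.00, 0.00],
        [0.30, 20.46, 0.29, 0.00, 0.00],
        [0.05, 6.92, 6.88, 0.01, 0.00],
        [0.00, 0.03, 0.06, 2.14, 0.01],
        [0.00, 0.00, 0.00, 0.00, 5.08],
    ]
)
CLASS_NAMES = ["noise-free", "low", "moderate", "hard", "other"]


@pytest.fixture
def observer_matrix() -> ConfusionMatrix:
    return ConfusionMatrix(class_names=list(CLASS_NAMES), durations=TABLE2_UPPER.copy())


@pytest.fixture(scope="session")
def clean_record():
    """10 s, 200 Hz, 60 bpm template ECG shared across tests."""
    return generate_clean_ecg(fs=200, duration_s=10, hr_bpm=60, seed=7)
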