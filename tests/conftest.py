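import numpy as np
import pytest

from mmdmarker import ExpressionMatrix, GroupLabels


@pytest.fixture
def small_matrix():
    """3 genes x 6 samples; g1 separates the groups cleanly, g2 is flat-ish."""
    values = np.array(
        [
            [1.0, 2.0, 5.0, 6.0, 10.0, 11.0],
            [3.0, 3.5, 3.1, 3.4, 3.2, 3.3],
            [0.0, 1.0, 0.5, 1.5, 0.2, 1.2],
        ]
    )
    return ExpressionMatrix(
        ("g1", "g2", "g3"),
        ("s1", "s2", "s3", "s4", "s5", "s6"),
        values,
    )


@pytest.fixture
def small_labels():
    return GroupLabels(
        {
            "s1": "tumor", "s2": "tumor",
            "s3": "nat", "s4": "nat",
            "s5": "normal", "s6": "normal",
        }
    )
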