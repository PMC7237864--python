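import numpy as np
import pytest

import embryostrat as es


@pytest.fixture(scope="session")
def default_series():
    """One default synthetic 16-cell series (4 embryos), seed 0."""
    return es.generate_series(es.SeriesConfig(), seed=0)


@pytest.fixture(scope="session")
def default_rpm(default_series):
    rpm, report = es.normalize_pipeline(default_series.expression)
    return rpm, report


@pytest.fixture()
def tiny_matrix():
    """3 genes x 4 cells of easy round numbers (RPM)."""
    values = np.array(
        [
            [10.0, 0.0, 160.0],
            [20.0, 1.0, 80.0],
            [40.0, 0.5, 40.0],
            [80.0, 2.0, 20.0],
        ]
    )
    return es.ExpressionMatrix(values, ["c1", "c2", "c3", "c4"], ["g1", "g2", "g3"], "rpm")
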