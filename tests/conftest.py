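import numpy as np
import pytest

from mirnorm.data import CensoredExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_data(values, condition, censored=None, detection_limit=None,
              replicate=None, **kw):
    """Build a validated container from plain arrays with sane defaults."""
    values = np.asarray(values, dtype=float)
    g, a = values.shape
    condition = np.asarray(condition, dtype=int)
    if censored is None:
        censored = np.zeros((g, a), dtype=bool)
    if detection_limit is None:
        detection_limit = np.full(a, -np.inf)
        if np.asarray(censored).any():
            detection_limit = np.nanmin(np.where(censored, np.inf, values), axis=0)
    if replicate is None:
        replicate = np.empty(a, dtype=int)
        for c in (1, 2):
            idx = np.flatnonzero(condition == c)
            replicate[idx] = np.arange(len(idx))
    vals = values.copy()
    vals[np.asarray(censored, dtype=bool)] = np.nan
    return CensoredExpressionMatrix(values=vals, censored=np.asarray(censored, dtype=bool),
                                    condition=condition, replicate=replicate,
                                    detection_limit=np.asarray(detection_limit, dtype=float),
                                    **kw)


@pytest.fixture
def toy_data(rng):
    """2 genes x 4 arrays, no censoring."""
    values = rng.normal(5.0, 1.0, size=(2, 4))
    return make_data(values, condition=[1, 1, 2, 2])
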