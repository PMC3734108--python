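"""Numerically stable one-sided truncated-normal sampling.

Inverse-CDF sampling computed in log space so that truncation points far
in the lower tail (e.g. a detection limit ten standard deviations below
the mean) still produce finite, correctly bounded draws.
"""

from __future__ import annotations

import numpy as np
from scipy import special

_TINY = np.finfo(float).tiny


def sample_upper_truncated(rng, mean, sd, upper):
    """Draw from Normal(mean, sd^2) truncated to (-inf, upper].

    All arguments broadcast.  Uses x = Phi^{-1}(exp(log u + log Phi(b)))
    via :func:`scipy.special.ndtri_exp`, stable for arbitrarily negative
    standardized bounds b.
    """
    mean, sd, upper = np.broadcast_arrays(
        np.asarray(mean, dtype=float), np.asarray(sd, dtype=float), np.asarray(upper, dtype=float)
    )
    if not np.all(np.isfinite(mean)) or not np.all(np.isfinite(sd)) or np.any(sd <= 0):
        raise ValueError("truncated-normal sampling needs finite mean and positive sd")
    b = (upper - mean) / sd
    u = rng.random(size=b.shape)
    u = np.maximum(u, _TINY)  # keep log(u) finite
    log_p = np.log(u) + special.log_ndtr(b)
    x = special.ndtri_exp(log_p)
    out = mean + sd * x
    # exact bound even under rounding at the boundary
    return np.minimum(out, upper)


def sample_lower_truncated(rng, mean, sd, lower):
    """Draw from Normal(mean, sd^2) truncated to [lower, inf)."""
    return -sample_upper_truncated(rng, -np.asarray(mean, dtype=float), sd, -np.asarray(lower, dtype=float))
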