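"""Onisawa's possibility-to-probability transform for human error.

A crisp failure *possibility* ``P`` in [0, 1] (here, an AHP integrated
weight) is mapped to a failure *probability*

    FP = 10 ** (-K),   K = 2.301 * ((1 - P) / P) ** (1/3)   for P > 0,
    FP = 0                                                   for P = 0.

The transform is strictly increasing, maps 0 to 0 and 1 to 1, and compresses
mid-range possibilities into the small probabilities typical of human-error
rates (P = 0.5 gives FP ≈ 5e-3).
"""

from __future__ import annotations

import numpy as np

ONISAWA_COEFF = 2.301


def failure_probability(possibility):
    """Failure probability for a possibility score (scalar or array) in [0, 1]."""
    p = np.asarray(possibility, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("possibility values must lie in [0, 1]")
    with np.errstate(divide="ignore"):
        k = ONISAWA_COEFF * np.cbrt((1.0 - p) / np.where(p > 0, p, 1.0))
    fp = np.where(p > 0, 10.0 ** (-k), 0.0)
    if np.isscalar(possibility) or fp.ndim == 0:
        return float(fp)
    return fp


# Alias matching the common name of the operation in the risk literature.
onisawa_fp = failure_probability
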