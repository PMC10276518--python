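"""Sample-size estimation for a target sensitivity or specificity.

For a diagnostic-accuracy study, the number of diseased (or non-diseased)
subjects needed to estimate a sensitivity (or specificity) ``P`` with a
``confidence``-level confidence interval of half-width ``d`` is

    n = z^2 * P * (1 - P) / d^2,

with ``z`` the standard-normal quantile at ``1 - alpha/2``.  The result is
rounded up: ``n`` is a minimum count.
"""

from __future__ import annotations

import math

from scipy.stats import norm

__all__ = ["required_sample_size"]


def required_sample_size(p: float, d: float, confidence: float = 0.95) -> int:
    """Minimum subjects to pin down a proportion ``p`` within ``+/- d``.

    Parameters
    ----------
    p:
        Anticipated sensitivity or specificity, in (0, 1).
    d:
        Half-width of the desired confidence interval, in (0, 1).
    confidence:
        Confidence level ``1 - alpha``, in (0, 1); default 0.95.

    Returns
    -------
    int
        ``ceil(z^2 p (1-p) / d^2)``, at least 1.  Uses the exact normal
        quantile (1.959964 at 95%), not the 1.96 shorthand.

    Examples
    --------
    >>> required_sample_size(0.90, 0.10)
    35
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must lie in (0, 1), got {p!r}")
    if not 0.0 < d < 1.0:
        raise ValueError(f"d must lie in (0, 1), got {d!r}")
    if not 0.0 < confidence < 1.0:
        raise ValueError(f"confidence must lie in (0, 1), got {confidence!r}")
    alpha = 1.0 - confidence
    z = norm.ppf(1.0 - alpha / 2.0)
    n = math.ceil(z * z * p * (1.0 - p) / (d * d))
    return max(1, int(n))
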