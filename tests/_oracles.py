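"""Independent numerical oracles used by the tests.

Everything here is written from the model definitions alone (no imports from
the package's fitting/derivation code) so that closed forms and fitters can
be checked against genuinely independent computations.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar


def sigmoid5(x, b, t, e, h, s):
    """The asymmetric five-parameter sigmoid, written out directly."""
    x = np.asarray(x, dtype=float)
    with np.errstate(over="ignore"):
        return b + (t - b) / (1.0 + (e / x) ** h) ** s


def numeric_max_rate(b, t, e, h, s) -> tuple[float, float]:
    """Maximal slope of the sigmoid by brute-force numerical maximization.

    Central-difference derivative evaluated on a wide log-spaced grid, then
    refined with bounded scalar optimization. Independent of any closed-form
    inflection expression.
    """

    def g(x):
        # transition term y(x) - B: same derivative, immune to the
        # catastrophic cancellation of differencing y about the large offset B
        with np.errstate(over="ignore"):
            return (t - b) / (1.0 + (e / np.asarray(x, dtype=float)) ** h) ** s

    def deriv(x: float) -> float:
        dx = x * 1e-6
        return (g(x + dx) - g(x - dx)) / (2.0 * dx)

    xs = e * np.logspace(-15.0, 6.0, 12001)
    dx = xs * 1e-6
    d = (g(xs + dx) - g(xs - dx)) / (2 * dx)
    i = int(np.argmax(d))
    lo, hi = xs[max(i - 1, 0)], xs[min(i + 1, xs.size - 1)]
    res = minimize_scalar(
        lambda x: -deriv(x), bounds=(lo, hi), method="bounded",
        options={"xatol": xs[i] * 1e-12},
    )
    x_star = float(res.x)
    return deriv(x_star), x_star


def random_valid_5pl(rng: np.random.Generator) -> tuple[float, float, float, float, float]:
    """Draw one parameter set with an inflection (H*S > 1, margin 0.1)."""
    while True:
        b = rng.uniform(-10.0, 50.0)
        t = b + rng.uniform(10.0, 200.0)
        e = 10.0 ** rng.uniform(0.5, 3.5)
        h = rng.uniform(0.3, 8.0)
        s = rng.uniform(0.1, 10.0)
        if h * s > 1.1:
            return b, t, e, h, s


def bliss_expected(a, b):
    """Bliss independence reference, written out directly."""
    return a + b - a * b


def csp_direct(dh, dn):
    """Weighted CSP combination, written out directly."""
    return np.sqrt((np.asarray(dh) ** 2 + 0.2 * np.asarray(dn) ** 2) / 2.0)
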