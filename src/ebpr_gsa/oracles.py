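"""Closed-form variance decompositions for the analytic test models.

Independent oracles used to validate the Sobol/SRC estimators: everything
here is derived analytically (or by exact quadrature), never by running the
estimators themselves.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "linear_additive_truth",
    "ishigami_truth",
]


def linear_additive_truth(coefficients, input_stds=None) -> dict:
    """Exact β, S1 and ST for ``y = sum c_i x_i`` with independent inputs.

    For a linear additive model the variance decomposes exactly:
    ``V_i = c_i^2 sigma_i^2``, there are no interactions, and
    ``beta_i^2 = S_i = ST_i``.
    """
    c = np.asarray(coefficients, dtype=float)
    s = np.ones_like(c) if input_stds is None else np.asarray(input_stds, float)
    v_i = (c * s) ** 2
    var_y = v_i.sum()
    s1 = v_i / var_y
    return {
        "beta": np.sign(c) * np.sqrt(s1),
        "s1": s1,
        "st": s1.copy(),
        "var_y": var_y,
    }


def ishigami_truth(a: float = 7.0, b: float = 0.1) -> dict:
    """Analytic Sobol decomposition of the Ishigami function.

    ``y = sin(x1) + a sin^2(x2) + b x3^4 sin(x1)`` with inputs uniform on
    ``[-pi, pi]``:

        V1   = 1/2 (1 + b pi^4 / 5)^2
        V2   = a^2 / 8
        V13  = 8 b^2 pi^8 / 225
        Var  = V1 + V2 + V13
    """
    pi = np.pi
    v1 = 0.5 * (1.0 + b * pi**4 / 5.0) ** 2
    v2 = a**2 / 8.0
    v13 = 8.0 * b**2 * pi**8 / 225.0
    var = v1 + v2 + v13
    s1 = np.array([v1 / var, v2 / var, 0.0])
    st = np.array([(v1 + v13) / var, v2 / var, v13 / var])
    return {"s1": s1, "st": st, "var_y": var, "v_interaction": v13}
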