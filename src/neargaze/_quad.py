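"""Shared second-order (quadratic) 2-D -> 2-D map utilities.

Both the ground-truth display->pupil map of the simulator and the fitted
pupil->display gaze map are full bivariate quadratics

    u = a*x^2 + b*y^2 + c*x + d*y + e*x*y + f
    v = g*x^2 + h*y^2 + i*x + j*y + k*x*y + l

parameterised by 12 coefficients (a..f for the first output, g..l for the
second).  The design-matrix column order [x^2, y^2, x, y, x*y, 1] is fixed
here and used everywhere.
"""

from __future__ import annotations

import numpy as np

N_COEFFS = 12  # 6 per output axis


def quad_design(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Design matrix with columns [x^2, y^2, x, y, x*y, 1], shape (n, 6)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return np.column_stack([x * x, y * y, x, y, x * y, np.ones_like(x)])


def apply_quad_map(coeffs: np.ndarray, x, y) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate the 12-coefficient quadratic map at points (x, y)."""
    c = np.asarray(coeffs, dtype=float)
    if c.shape != (N_COEFFS,):
        raise ValueError(f"expected {N_COEFFS} coefficients, got shape {c.shape}")
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    A = quad_design(x, y)
    return A @ c[:6], A @ c[6:]
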