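"""Field-calibrated reference VAR coefficient sets.

Three bivariate VAR parameter sets estimated from hourly deseasonalized
soil moisture (%) and temperature (°C) at a loam winter-wheat site, one
per representative horizon: topsoil (10 cm, p = 5), subsoil (30 cm,
p = 8) and substratum (90 cm, p = 7).  Variable order is (moisture,
temperature).  All three are stable but close to the unit circle —
realistic, strongly persistent soil dynamics — which makes them good
ground-truth generators for the synthetic-data module and stress cases
for the estimation code.

Innovation covariances are not part of the calibrated sets; the synthetic
generator supplies its own (see :mod:`soilvar.synthetic`).
"""

from __future__ import annotations

import numpy as np

from .process import VARProcess

__all__ = ["REFERENCE_PROCESSES", "reference_process"]


_COEFS_10CM = np.array([
    [[1.593, -0.026], [0.167, 1.754]],
    [[-0.631, 0.019], [-0.205, -0.816]],
    [[0.274, 0.012], [-0.061, 0.026]],
    [[-0.526, 0.024], [-0.094, -0.060]],
    [[0.257, -0.031], [0.008, 0.068]],
])
_INTERCEPT_10CM = np.array([-0.002, 0.005])

_COEFS_30CM = np.array([
    [[1.182, 0.117], [-0.006, 0.559]],
    [[-0.173, -0.090], [-0.022, 0.344]],
    [[-0.016, 0.020], [0.042, 0.228]],
    [[-0.002, -0.054], [-0.003, 0.149]],
    [[0.000, 0.013], [-0.022, 0.012]],
    [[-0.006, -0.014], [0.019, -0.074]],
    [[0.012, 0.040], [-0.010, -0.082]],
    [[-0.027, -0.029], [-0.002, -0.148]],
])
_INTERCEPT_30CM = np.array([-0.002, 0.001])

# The 90 cm calibration is reported without an intercept (deep-soil
# deviations are mean-zero to the printed precision); stored as zero.
_COEFS_90CM = np.array([
    [[0.690, 0.058], [0.133, 0.345]],
    [[0.336, 0.025], [0.026, 0.200]],
    [[0.130, -0.001], [0.045, 0.191]],
    [[-0.024, -0.010], [0.079, 0.103]],
    [[-0.061, -0.031], [-0.166, 0.039]],
    [[-0.004, -0.008], [-0.132, 0.056]],
    [[-0.071, -0.032], [0.011, 0.058]],
])
_INTERCEPT_90CM = np.zeros(2)


def reference_process(depth: int, sigma: np.ndarray | None = None) -> VARProcess:
    """Reference :class:`VARProcess` for a depth in {10, 30, 90} cm.

    ``sigma`` overrides the innovation covariance (identity by default).
    """
    try:
        coefs, intercept = {
            10: (_COEFS_10CM, _INTERCEPT_10CM),
            30: (_COEFS_30CM, _INTERCEPT_30CM),
            90: (_COEFS_90CM, _INTERCEPT_90CM),
        }[depth]
    except KeyError:
        raise ValueError(f"no reference calibration at {depth} cm (have 10, 30, 90)") from None
    return VARProcess(
        coefs=coefs,
        intercept=intercept,
        sigma=sigma,
        labels=(f"MCSD{depth}", f"STSD{depth}"),
    )


REFERENCE_PROCESSES: dict[int, VARProcess] = {d: reference_process(d) for d in (10, 30, 90)}
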