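import numpy as np
import pytest

from ringmotor.energetics import BP_RISE_NM, DEFAULT_SCALE
from ringmotor.fv_models import default_linear_params
from ringmotor.model_fitting import CANONICAL_FORCE_BIN_EDGES, VelocityPoint
from ringmotor.synthetic_data import TetherTrapConfig, Trace, render_trace, wlc_extension
import pandas as pd


@pytest.fixture(scope="session")
def linear_defaults():
    return default_linear_params()


@pytest.fixture(scope="session")
def force_bin_centers():
    e = CANONICAL_FORCE_BIN_EDGES
    return 0.5 * (e[:-1] + e[1:])


def noisy_fv_points(model_velocity, forces, atp, frac_noise, rng, adp=0.0):
    """VelocityPoint list with multiplicative Gaussian noise and true-SEM weights."""
    v_true = np.asarray(model_velocity, dtype=float)
    v = v_true * (1.0 + frac_noise * rng.standard_normal(len(v_true)))
    return [
        VelocityPoint(float(F), float(atp), float(vi), sem=float(frac_noise * vt),
                      adp=float(adp))
        for F, vi, vt in zip(forces, v, v_true)
    ]


def piecewise_trace(
    segments,
    contour0=20000.0,
    setpoint=5.0,
    sample_rate=2500.0,
    noise_sd=0.0,
    seed=0,
    atp=250.0,
):
    """Constant-force trace built from (duration_s, velocity_bp_s) segments.

    Returns (Trace, list of (start, duration) of zero-velocity segments).
    The contour decreases piecewise-linearly; extension follows the WLC at
    the setpoint force. Ground truth pauses are the zero-velocity segments.
    """
    tether = TetherTrapConfig(
        mode="constant_force", setpoint_force=setpoint,
        sample_rate=sample_rate, noise_sd=noise_sd, contour_length0=contour0,
    )
    rng = np.random.default_rng(seed)
    total = sum(d for d, _ in segments)
    n = int(round(total * sample_rate))
    t = np.arange(n) / sample_rate
    contour = np.empty(n)
    pauses = []
    t0, L = 0.0, contour0
    for dur, vel in segments:
        sel = (t >= t0) & (t < t0 + dur)
        contour[sel] = L - vel * (t[sel] - t0)
        if vel == 0.0:
            pauses.append((t0, dur))
        L -= vel * dur
        t0 += dur
    z = wlc_extension(setpoint, 1.0, tether.persistence_length)
    extension = contour * BP_RISE_NM * z
    if noise_sd > 0:
        extension = extension + rng.normal(0.0, noise_sd, n)
    trace = Trace(
        time=t,
        extension=extension,
        force=np.full(n, setpoint),
        contour_length=contour,
        metadata={"cycle": {"atp": atp}},
    )
    return trace, pauses
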