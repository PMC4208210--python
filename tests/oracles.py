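"""Independent brute-force oracles used by the tests.

These deliberately avoid the code paths they check: the rigid-fit oracle
evaluates the registration objective on an exhaustive rotation grid with the
closed-form optimal translation, and the platform-COP oracle minimizes the
moment-balance residual over a position grid.
"""

import numpy as np


def rigid_objective_grid(p, q, step_deg=0.01):
    """Minimum sum-of-squares objective over an exhaustive planar rotation grid.

    For each angle the optimal translation is the difference of centroids
    after rotation, so the objective reduces to the centered clouds.
    Returns (best_objective, best_theta_rad).
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    p0 = p - p.mean(axis=0)
    q0 = q - q.mean(axis=0)
    thetas = np.deg2rad(np.arange(-180.0, 180.0, step_deg))
    cos, sin = np.cos(thetas), np.sin(thetas)
    # rotate the centered source cloud for every candidate angle
    rx = cos[:, None] * p0[None, :, 0] - sin[:, None] * p0[None, :, 1]
    ry = sin[:, None] * p0[None, :, 0] + cos[:, None] * p0[None, :, 1]
    obj = ((rx - q0[None, :, 0]) ** 2 + (ry - q0[None, :, 1]) ** 2).sum(axis=1)
    best = int(np.argmin(obj))
    return float(obj[best]), float(thetas[best])


def cop_moment_residual_grid(force, moment, span=100.0, step=0.5):
    """COP position minimizing the planar moment-balance residual.

    Searches candidate surface positions r = (x, y, 0) on a grid and returns
    the one minimizing || M_xy - (r x F)_xy ||.
    """
    force = np.asarray(force, dtype=float)
    moment = np.asarray(moment, dtype=float)
    xs = np.arange(-span, span + step, step)
    gx, gy = np.meshgrid(xs, xs, indexing="ij")
    # (r x F) with r_z = 0: Mx = y Fz, My = -x Fz
    res = ((moment[0] - gy * force[2]) ** 2 + (moment[1] + gx * force[2]) ** 2)
    i, j = np.unravel_index(np.argmin(res), res.shape)
    return np.array([xs[i], xs[j]])
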