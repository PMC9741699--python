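"""Numba kernel for 1-D Langevin metadynamics.

The integrator is BAOAB (kick / drift / Ornstein-Uhlenbeck / drift / kick),
which stays stable and samples the configurational Boltzmann distribution
accurately at time steps where plain Euler-Maruyama already distorts the
variance.  Forces (physical and bias) are kept on a shared uniform grid and
evaluated by linear interpolation; each deposited Gaussian is accumulated
onto the grid once, so the per-step cost is independent of the number of
hills.  The CV domain has reflective walls at the grid edges.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def _reflect(x, v, lo, hi):
    # a few bounces suffice for any physically sensible step size
    for _ in range(10):
        if x < lo:
            x = 2.0 * lo - x
            v = -v
        elif x > hi:
            x = 2.0 * hi - x
            v = -v
        else:
            break
    if x < lo:
        x = lo
    elif x > hi:
        x = hi
    return x, v


@njit(cache=True)
def _interp(x, lo, dx, arr):
    u = (x - lo) / dx
    i = int(u)
    if i < 0:
        i = 0
    n = arr.shape[0]
    if i > n - 2:
        i = n - 2
    w = u - i
    return arr[i] * (1.0 - w) + arr[i + 1] * w


@njit(cache=True)
def run_baoab_metad(
    x0,
    n_steps,
    dt,
    mass,
    gamma,
    kT,
    grid,
    f_pot,
    hill_height,
    hill_sigma,
    deposit_stride,
    save_stride,
    seed,
):
    np.random.seed(seed)
    lo = grid[0]
    hi = grid[-1]
    dx = grid[1] - grid[0]
    n_grid = grid.shape[0]

    f_bias = np.zeros(n_grid)

    deposit = hill_height > 0.0 and deposit_stride > 0
    n_hills = n_steps // deposit_stride if deposit else 0
    hill_t = np.empty(n_hills)
    hill_c = np.empty(n_hills)

    n_save = n_steps // save_stride
    save_t = np.empty(n_save)
    save_x = np.empty(n_save)

    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(kT * (1.0 - c1 * c1) / mass)

    x = x0
    v = np.sqrt(kT / mass) * np.random.normal()
    f = _interp(x, lo, dx, f_pot) + _interp(x, lo, dx, f_bias)

    ih = 0
    isv = 0
    for step in range(1, n_steps + 1):
        v += 0.5 * dt * f / mass
        x += 0.5 * dt * v
        x, v = _reflect(x, v, lo, hi)
        v = c1 * v + c2 * np.random.normal()
        x += 0.5 * dt * v
        x, v = _reflect(x, v, lo, hi)
        f = _interp(x, lo, dx, f_pot) + _interp(x, lo, dx, f_bias)
        v += 0.5 * dt * f / mass

        if deposit and step % deposit_stride == 0:
            inv2s2 = 1.0 / (2.0 * hill_sigma * hill_sigma)
            for i in range(n_grid):
                d = grid[i] - x
                g = hill_height * np.exp(-d * d * inv2s2)
                # force = -dV/ds of the new Gaussian
                f_bias[i] += g * d / (hill_sigma * hill_sigma)
            hill_t[ih] = step * dt
            hill_c[ih] = x
            ih += 1
            f = _interp(x, lo, dx, f_pot) + _interp(x, lo, dx, f_bias)

        if step % save_stride == 0:
            save_t[isv] = step * dt
            save_x[isv] = x
            isv += 1

    return save_t, save_x, hill_t, hill_c
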