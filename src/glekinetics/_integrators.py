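"""Compiled single-trajectory step loops.

All loops advance the state by ``n`` steps with a symmetric splitting:
half velocity kick (potential force + instantaneous friction/noise force),
half position drift, exact Ornstein--Uhlenbeck update of each auxiliary
exponential component over dt with the velocity held fixed, second half
drift and half kick.  With vanishing friction and noise the scheme reduces
to velocity Verlet, so energy is conserved to O(dt^2) per step.

Gaussian increments ``xi`` are pre-generated by the caller; the loops are
fully deterministic given their inputs.  Every ``stride``-th end-of-step
position (and optionally velocity) is written to the output buffers; the
stride phase counter ``c`` is threaded through calls so chunked runs
decimate exactly like a single long run.
"""

import numpy as np
from numba import njit

# force modes
DOUBLE_WELL = 0
HARMONIC = 1
FLAT = 2


@njit(cache=True, fastmath=True, inline="always")
def _force(mode, p0, p1, p2, p3, x):
    if mode == 0:  # double well: p0=4UL/LL^2, p1=1/LL^2, p2=4UR/LR^2, p3=1/LR^2
        if x <= 0.0:
            return -p0 * x * (x * x * p1 - 1.0)
        else:
            return -p2 * x * (x * x * p3 - 1.0)
    elif mode == 1:  # harmonic: p0=k, p1=x0
        return -p0 * (x - p1)
    else:
        return 0.0


@njit(cache=True, fastmath=True)
def gle_chunk(st, z, n, dt, inv_m, mode, p0, p1, p2, p3,
              th, cgam, sig, xi, out_x, out_v, stride, c, store_v):
    """Equilibrium GLE with N auxiliary exponential components.

    st = [x, v] mutated in place; z (length N) are the combined
    friction+noise auxiliary forces, updated exactly over dt:
    z <- th z - cgam v + sig xi  with th = exp(-dt/tau),
    cgam = gamma (1 - th), sig = sqrt(gamma/(beta tau) (1 - th^2)).
    Returns (number of stored samples, new stride phase).
    """
    x = st[0]
    v = st[1]
    half = 0.5 * dt
    ncomp = z.shape[0]
    k = 0
    for i in range(n):
        zs = 0.0
        for j in range(ncomp):
            zs += z[j]
        v += half * (_force(mode, p0, p1, p2, p3, x) + zs) * inv_m
        x += half * v
        for j in range(ncomp):
            z[j] = th[j] * z[j] - cgam[j] * v + sig[j] * xi[i, j]
        x += half * v
        zs = 0.0
        for j in range(ncomp):
            zs += z[j]
        v += half * (_force(mode, p0, p1, p2, p3, x) + zs) * inv_m
        c += 1
        if c == stride:
            out_x[k] = x
            if store_v:
                out_v[k] = v
            k += 1
            c = 0
    st[0] = x
    st[1] = v
    return k, c


@njit(cache=True, fastmath=True)
def neq_chunk(st, aux, n, dt, inv_m, mode, p0, p1, p2, p3,
              th_v, cgam_v, th_r, sig_r, xi, out_x, out_v, stride, c, store_v):
    """Non-equilibrium GLE: deterministic friction aux + independent OU noise.

    aux = [w, r]: w is the exponential convolution of the velocity with
    decay tau_V (no noise), r is a stationary Ornstein--Uhlenbeck force of
    variance gamma/(beta tau_R) and correlation time tau_R.
    """
    x = st[0]
    v = st[1]
    w = aux[0]
    r = aux[1]
    half = 0.5 * dt
    k = 0
    for i in range(n):
        v += half * (_force(mode, p0, p1, p2, p3, x) + w + r) * inv_m
        x += half * v
        w = th_v * w - cgam_v * v
        r = th_r * r + sig_r * xi[i, 0]
        x += half * v
        v += half * (_force(mode, p0, p1, p2, p3, x) + w + r) * inv_m
        c += 1
        if c == stride:
            out_x[k] = x
            if store_v:
                out_v[k] = v
            k += 1
            c = 0
    st[0] = x
    st[1] = v
    aux[0] = w
    aux[1] = r
    return k, c


@njit(cache=True, fastmath=True)
def langevin_chunk(st, n, dt, inv_m, mode, p0, p1, p2, p3,
                   c1, c2, xi, out_x, out_v, stride, c, store_v):
    """Markovian (white-noise) underdamped Langevin reference, BAOAB scheme.

    c1 = exp(-gamma dt / m), c2 = sqrt((1 - c1^2)/(beta m)).  Serves as an
    independent cross-check for the memoryless limit of the GLE loops.
    """
    x = st[0]
    v = st[1]
    half = 0.5 * dt
    k = 0
    for i in range(n):
        v += half * _force(mode, p0, p1, p2, p3, x) * inv_m
        x += half * v
        v = c1 * v + c2 * xi[i, 0]
        x += half * v
        v += half * _force(mode, p0, p1, p2, p3, x) * inv_m
        c += 1
        if c == stride:
            out_x[k] = x
            if store_v:
                out_v[k] = v
            k += 1
            c = 0
    st[0] = x
    st[1] = v
    return k, c
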