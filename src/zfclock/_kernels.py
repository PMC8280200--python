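"""Jit-compiled integrators for the three-variable clock model.

The deterministic system is advanced with classical fixed-step RK4 (the
light input is piecewise constant, held over each step), the stochastic
system with Euler--Maruyama: each state variable receives an independent
increment ``sigma*sqrt(dt)*N(0,1)`` per step on top of ``drift*dt``.

All kernels take the light input pre-sampled on the integration grid
(``light[k]`` is the level during step ``k``) and record the state every
``stride`` steps.  They return a status integer: -1 on success, otherwise
the index of the first step at which the state became non-finite.

Per-cell reproducibility: each cell in a population kernel reseeds numba's
Mersenne-Twister with its own 32-bit seed, so cell ``j``'s noise draws do
not depend on the total cell count or on which cells are recorded.
"""

import numpy as np
from numba import njit

__all__ = [
    "activation",
    "integrate_deterministic",
    "integrate_cell",
    "integrate_population",
]


@njit(cache=True)
def activation(R, A, K, use_K):
    """Transcriptional activation fraction f(R, A).

    With ``use_K`` the full protein-sequestration form
    ``(A - R - K + sqrt((A - R - K)^2 + 4AK)) / (2A)`` is used; otherwise its
    K -> 0 piecewise limit ``max(0, 1 - R/A)``.
    """
    if use_K:
        b = A - R - K
        return (b + np.sqrt(b * b + 4.0 * A * K)) / (2.0 * A)
    x = 1.0 - R / A
    return x if x > 0.0 else 0.0


@njit(cache=True)
def integrate_deterministic(M0, P0, R0, A, dM, dP, dR, isens, K, use_K, light, dt, stride):
    n_steps = light.shape[0]
    n_rec = n_steps // stride + 1
    states = np.empty((n_rec, 3))
    lum = np.empty(n_rec)
    M, P, R = M0, P0, R0
    states[0, 0] = M
    states[0, 1] = P
    states[0, 2] = R
    lum[0] = activation(R, A, K, use_K)
    r = 1
    for k in range(n_steps):
        iI = isens * light[k]
        k1m = activation(R, A, K, use_K) - dM * M + iI
        k1p = M - dP * P
        k1r = P - dR * R
        M1 = M + 0.5 * dt * k1m
        P1 = P + 0.5 * dt * k1p
        R1 = R + 0.5 * dt * k1r
        k2m = activation(R1, A, K, use_K) - dM * M1 + iI
        k2p = M1 - dP * P1
        k2r = P1 - dR * R1
        M2 = M + 0.5 * dt * k2m
        P2 = P + 0.5 * dt * k2p
        R2 = R + 0.5 * dt * k2r
        k3m = activation(R2, A, K, use_K) - dM * M2 + iI
        k3p = M2 - dP * P2
        k3r = P2 - dR * R2
        M3 = M + dt * k3m
        P3 = P + dt * k3p
        R3 = R + dt * k3r
        k4m = activation(R3, A, K, use_K) - dM * M3 + iI
        k4p = M3 - dP * P3
        k4r = P3 - dR * R3
        M += dt / 6.0 * (k1m + 2.0 * k2m + 2.0 * k3m + k4m)
        P += dt / 6.0 * (k1p + 2.0 * k2p + 2.0 * k3p + k4p)
        R += dt / 6.0 * (k1r + 2.0 * k2r + 2.0 * k3r + k4r)
        if not (np.isfinite(M) and np.isfinite(P) and np.isfinite(R)):
            return states, lum, k
        if (k + 1) % stride == 0 and r < n_rec:
            states[r, 0] = M
            states[r, 1] = P
            states[r, 2] = R
            lum[r] = activation(R, A, K, use_K)
            r += 1
    return states, lum, -1


@njit(cache=True)
def integrate_cell(
    M0, P0, R0, A, dM, dP, dR, isens, sigma, K, use_K, light, dt, stride, seed, n_preroll
):
    """Euler--Maruyama for one cell; ``n_preroll`` unrecorded dark steps first."""
    np.random.seed(seed)
    n_steps = light.shape[0]
    n_rec = n_steps // stride + 1
    states = np.empty((n_rec, 3))
    lum = np.empty(n_rec)
    M, P, R = M0, P0, R0
    s = sigma * np.sqrt(dt)
    for k in range(n_preroll):
        f = activation(R, A, K, use_K)
        dMv = (f - dM * M) * dt + s * np.random.normal()
        dPv = (M - dP * P) * dt + s * np.random.normal()
        dRv = (P - dR * R) * dt + s * np.random.normal()
        M += dMv
        P += dPv
        R += dRv
    states[0, 0] = M
    states[0, 1] = P
    states[0, 2] = R
    lum[0] = activation(R, A, K, use_K)
    r = 1
    for k in range(n_steps):
        f = activation(R, A, K, use_K)
        dMv = (f - dM * M + isens * light[k]) * dt + s * np.random.normal()
        dPv = (M - dP * P) * dt + s * np.random.normal()
        dRv = (P - dR * R) * dt + s * np.random.normal()
        M += dMv
        P += dPv
        R += dRv
        if not (np.isfinite(M) and np.isfinite(P) and np.isfinite(R)):
            return states, lum, k
        if (k + 1) % stride == 0 and r < n_rec:
            states[r, 0] = M
            states[r, 1] = P
            states[r, 2] = R
            lum[r] = activation(R, A, K, use_K)
            r += 1
    return states, lum, -1


@njit(cache=True)
def integrate_population(
    M0,
    P0,
    R0,
    A,
    dM,
    dP,
    dR,
    isens,
    sigma,
    K,
    use_K,
    light,
    dt,
    stride,
    seeds,
    n_record,
    n_preroll,
):
    """Average luminescence over ``len(seeds)`` independent cells.

    Returns (mean luminescence on the record grid, luminescence of the first
    ``n_record`` cells, status).  All cells start from the same state; with
    ``n_preroll > 0`` each cell first runs that many unrecorded dark steps so
    that noise can disperse the phases before t = 0.
    """
    n = seeds.shape[0]
    n_steps = light.shape[0]
    n_rec = n_steps // stride + 1
    acc = np.zeros(n_rec)
    rec = np.zeros((n_record, n_rec))
    s = sigma * np.sqrt(dt)
    for j in range(n):
        np.random.seed(seeds[j])
        M, P, R = M0, P0, R0
        for k in range(n_preroll):
            f = activation(R, A, K, use_K)
            dMv = (f - dM * M) * dt + s * np.random.normal()
            dPv = (M - dP * P) * dt + s * np.random.normal()
            dRv = (P - dR * R) * dt + s * np.random.normal()
            M += dMv
            P += dPv
            R += dRv
        f = activation(R, A, K, use_K)
        acc[0] += f
        if j < n_record:
            rec[j, 0] = f
        r = 1
        for k in range(n_steps):
            f = activation(R, A, K, use_K)
            dMv = (f - dM * M + isens * light[k]) * dt + s * np.random.normal()
            dPv = (M - dP * P) * dt + s * np.random.normal()
            dRv = (P - dR * R) * dt + s * np.random.normal()
            M += dMv
            P += dPv
            R += dRv
            if not (np.isfinite(M) and np.isfinite(P) and np.isfinite(R)):
                return acc, rec, k
            if (k + 1) % stride == 0 and r < n_rec:
                f = activation(R, A, K, use_K)
                acc[r] += f
                if j < n_record:
                    rec[j, r] = f
                r += 1
    return acc / n, rec, -1
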