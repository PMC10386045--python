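"""Bloch-McConnell dynamics under continuous-wave saturation.

Under a CW pulse the coupled magnetization equations of an N-pool system
are linear and time-invariant, dM/dt = A M + b, so both the finite-duration
response and the steady state have exact solutions: a matrix exponential of
the augmented homogeneous system, and the linear solve A M = −b.  The two
routes are independent and cross-check each other.

Frame convention: the rotating frame of the saturation pulse.  A pool with
chemical shift δ ppm irradiated at offset ω ppm precesses at
Δ = 2π·(δ − ω)·field_mhz rad/s; the B1 field lies along x with amplitude
ω1 = 2π·γ·B1(μT), γ = 42.5764 Hz/μT.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import expm

from .pools import GAMMA_HZ_PER_UT, Pool, PoolSystem, exchange_rate

__all__ = ["bm_matrix", "bm_steady_state", "bm_evolve", "zspectrum", "single_pool_steady_state"]


def _rates(system: PoolSystem, ph: float | None) -> list[float]:
    if ph is None:
        return [p.base_rate for p in system.solutes]
    return [exchange_rate(p, ph) for p in system.solutes]


def bm_matrix(
    system: PoolSystem, offset_ppm: float, b1_ut: float, ph: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble (A, b) of dM/dt = A M + b for CW saturation at *offset_ppm*.

    Magnetization ordering is (x, y, z) per pool, water first.  Exchange
    conserves magnetization: solute→water at rate k, water→solute at f·k.
    """
    pools = system.pools
    n = len(pools)
    ks = _rates(system, ph)
    omega1 = 2.0 * np.pi * GAMMA_HZ_PER_UT * b1_ut
    A = np.zeros((3 * n, 3 * n))
    b = np.zeros(3 * n)
    for i, p in enumerate(pools):
        delta = 2.0 * np.pi * (p.shift_ppm - offset_ppm) * system.field_mhz
        r1, r2 = 1.0 / p.t1, 1.0 / p.t2
        j = 3 * i
        A[j, j] += -r2
        A[j, j + 1] += delta
        A[j + 1, j] += -delta
        A[j + 1, j + 1] += -r2
        A[j + 1, j + 2] += omega1
        A[j + 2, j + 1] += -omega1
        A[j + 2, j + 2] += -r1
        m0 = 1.0 if i == 0 else p.fraction
        b[j + 2] = r1 * m0
    # exchange terms couple each solute with water, per component
    for s, (p, k) in enumerate(zip(system.solutes, ks), start=1):
        kw = p.fraction * k  # water -> solute
        for c in range(3):
            w, u = c, 3 * s + c
            A[w, w] += -kw
            A[w, u] += k
            A[u, w] += kw
            A[u, u] += -k
    return A, b


def equilibrium(system: PoolSystem) -> np.ndarray:
    """Thermal-equilibrium magnetization (z = M0 per pool, transverse 0)."""
    m = np.zeros(3 * len(system.pools))
    m[2] = 1.0
    for i, p in enumerate(system.solutes, start=1):
        m[3 * i + 2] = p.fraction
    return m


def bm_steady_state(
    system: PoolSystem, offset_ppm: float, b1_ut: float, ph: float | None = None
) -> float:
    """Normalized water z-magnetization in the CW steady state.

    With b1 = 0 the steady state is thermal equilibrium, z = 1.
    """
    if b1_ut < 0:
        raise ValueError("b1 must be >= 0")
    if b1_ut == 0.0:
        return 1.0
    A, b = bm_matrix(system, offset_ppm, b1_ut, ph)
    m = np.linalg.solve(A, -b)
    return float(m[2])


def bm_evolve(
    system: PoolSystem,
    offset_ppm: float,
    b1_ut: float,
    t_sat: float,
    ph: float | None = None,
    m_init: np.ndarray | None = None,
) -> float:
    """Water z-magnetization after a CW pulse of duration *t_sat* seconds.

    Solves the augmented homogeneous system exactly with a matrix
    exponential; raises if the result is non-finite rather than clamping.
    """
    if t_sat <= 0:
        raise ValueError("t_sat must be > 0")
    if b1_ut < 0:
        raise ValueError("b1 must be >= 0")
    A, b = bm_matrix(system, offset_ppm, b1_ut, ph)
    n = A.shape[0]
    m0 = equilibrium(system) if m_init is None else np.asarray(m_init, dtype=float)
    aug = np.zeros((n + 1, n + 1))
    aug[:n, :n] = A
    aug[:n, n] = b
    m = expm(aug * t_sat) @ np.append(m0, 1.0)
    z = float(m[2])
    if not np.isfinite(z):
        raise ArithmeticError("Bloch-McConnell integration produced a non-finite value")
    return z


def zspectrum(
    system: PoolSystem,
    offsets_ppm: np.ndarray,
    b1_ut: float,
    t_sat: float,
    ph: float | None = None,
    steady_state: bool = False,
) -> np.ndarray:
    """Z-spectrum over *offsets_ppm* (finite pulse by default)."""
    offsets_ppm = np.asarray(offsets_ppm, dtype=float)
    if steady_state:
        return np.array([bm_steady_state(system, w, b1_ut, ph) for w in offsets_ppm])
    return np.array([bm_evolve(system, w, b1_ut, t_sat, ph) for w in offsets_ppm])


def single_pool_steady_state(t1: float, t2: float, offset_hz: float, b1_ut: float) -> float:
    """Closed-form CW steady state of an isolated water pool.

    z = R1(Δ² + R2²) / (R1(Δ² + R2²) + ω1² R2), Δ in rad/s.  Serves as the
    analytic oracle for the matrix machinery in the single-pool limit.
    """
    r1, r2 = 1.0 / t1, 1.0 / t2
    delta = 2.0 * np.pi * offset_hz
    omega1 = 2.0 * np.pi * GAMMA_HZ_PER_UT * b1_ut
    num = r1 * (delta**2 + r2**2)
    return num / (num + omega1**2 * r2)
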