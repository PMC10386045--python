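"""Exchange-pool definitions driving the Bloch-McConnell simulator.

CEST contrast arises from dilute solute pools (amide, amine, optionally a
broad MT pool) whose labile protons exchange with bulk water at a
pH-dependent rate.  Base-catalyzed exchange is modelled as

    k(pH) = base_rate * 10 ** (ph_slope * (pH - 7.0))

i.e. ``base_rate`` is the solute→water exchange rate at pH 7.0 and
``ph_slope`` the decadic sensitivity (1.0 for purely base-catalyzed
exchange, 0 for pH-independent pools such as MT).
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["Pool", "PoolSystem", "exchange_rate", "default_pool_system", "GAMMA_HZ_PER_UT"]

#: Proton gyromagnetic ratio, Hz per μT.
GAMMA_HZ_PER_UT = 42.5764


@dataclass(frozen=True)
class Pool:
    """One proton pool.

    fraction is the proton fraction relative to water (dimensionless,
    0 for the water pool itself); base_rate the exchange rate toward water
    at pH 7.0 in s⁻¹.
    """

    shift_ppm: float
    t1: float
    t2: float
    fraction: float = 0.0
    base_rate: float = 0.0
    ph_slope: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        if self.t1 <= 0 or self.t2 <= 0:
            raise ValueError("relaxation times must be positive")
        if self.t2 > self.t1:
            raise ValueError("t2 must not exceed t1")
        if not 0 <= self.fraction < 1:
            raise ValueError("fraction must be in [0, 1)")
        if self.base_rate < 0:
            raise ValueError("base_rate must be >= 0")


def exchange_rate(pool: Pool, ph: float) -> float:
    """Solute→water exchange rate (s⁻¹) of *pool* at intracellular pH *ph*."""
    if not 0.0 <= ph <= 14.0:
        raise ValueError("pH must lie in [0, 14]")
    return pool.base_rate * 10.0 ** (pool.ph_slope * (ph - 7.0))


@dataclass(frozen=True)
class PoolSystem:
    """Water plus solute pools at a stated field strength.

    field_mhz is the water resonance frequency in MHz (400.22 at 9.4 T);
    it carries the ppm↔Hz conversion used throughout.
    """

    water: Pool
    solutes: tuple[Pool, ...] = field(default_factory=tuple)
    field_mhz: float = 400.22

    def __post_init__(self) -> None:
        object.__setattr__(self, "solutes", tuple(self.solutes))
        if self.water.shift_ppm != 0.0:
            raise ValueError("water pool must resonate at 0 ppm")
        if self.field_mhz <= 0:
            raise ValueError("field_mhz must be positive")
        shifts = [p.shift_ppm for p in self.solutes]
        if len(set(shifts)) != len(shifts):
            raise ValueError("solute chemical shifts must be distinct")

    @property
    def pools(self) -> tuple[Pool, ...]:
        return (self.water, *self.solutes)


def default_pool_system(field_mhz: float = 400.22, include_mt: bool = False) -> PoolSystem:
    """Brain-like 9.4 T three-pool system.

    Water T1 = 2.0 s / T2 = 60 ms; a slow-exchanging amide pool at +3.5 ppm
    (30 s⁻¹ at pH 7) and a fast/intermediate amine pool at +2.75 ppm
    (1500 s⁻¹ at pH 7), both base-catalyzed (decadic slope 1).  These are
    literature-plausible stand-ins, not fitted tissue values; they place the
    AACID statistic on its inverse pH relationship.  An optional broad,
    pH-independent MT pool at −2.4 ppm can be enabled.
    """
    water = Pool(shift_ppm=0.0, t1=2.0, t2=0.060, name="water")
    amide = Pool(
        shift_ppm=3.5, t1=1.0, t2=0.010, fraction=7e-4, base_rate=30.0, ph_slope=1.0, name="amide"
    )
    amine = Pool(
        shift_ppm=2.75, t1=1.0, t2=0.005, fraction=5e-4, base_rate=1500.0, ph_slope=1.0, name="amine"
    )
    solutes: tuple[Pool, ...] = (amide, amine)
    if include_mt:
        mt = Pool(
            shift_ppm=-2.4, t1=1.0, t2=1e-5, fraction=0.05, base_rate=25.0, ph_slope=0.0, name="mt"
        )
        solutes = (*solutes, mt)
    return PoolSystem(water=water, solutes=solutes, field_mhz=field_mhz)


def with_ph(system: PoolSystem, ph: float) -> tuple[PoolSystem, tuple[float, ...]]:
    """Resolve the pH-dependent exchange rates of *system* at *ph*.

    Returns the system unchanged together with the per-solute rates; kept as
    a helper so callers never re-derive the rate law.
    """
    return system, tuple(exchange_rate(p, ph) for p in system.solutes)
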