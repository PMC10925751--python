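"""Synthetic blunt-impact acceleration signals from a lumped-parameter model.

This module stands in for a finite-element impact simulation campaign: it
generates skull acceleration traces over a full factorial design of impact
position, impactor material, impact velocity and impactor size, using a
three-mass surrogate of the block / skull / brain system:

* a rigid cylindrical block of mass ``m_b`` (from its dimensions and
  material density) approaches with the impact velocity;
* a unilateral (compression-only) contact element couples block and skull:
  a linear spring — the series combination of the block's axial stiffness
  E*A/t and an area-scaled scalp stiffness — plus a viscous scalp term
  active only during contact.  Soft impactors are contact-overdamped (long,
  gentle push), stiff ones underdamped (short, sharp pulse);
* the skull shell mass is coupled to an interior (brain) mass by a
  spring-damper tuned to an under-damped skull-brain mode inside the
  14-35 Hz head fundamental-frequency range, and weakly grounded to
  represent the occipital fixation.

The system is integrated with a fixed-step classical Runge-Kutta (RK4)
scheme whose step is at least 50 steps per period of the fastest mode, and
the skull acceleration is sampled at the output rate (5000 Hz by default).
All model constants are calibration choices of this package, documented in
``docs/methods.md``; they are not measurements of any particular head.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product

import numpy as np

from .signal_io import AccelSignal


@dataclass(frozen=True)
class MaterialSpec:
    """Impactor material: density in kg/mm^3, Young's modulus in MPa."""

    name: str
    density: float
    youngs_modulus: float
    poisson: float

    def __post_init__(self) -> None:
        if self.density <= 0 or self.youngs_modulus <= 0:
            raise ValueError("density and Young's modulus must be positive")
        if not 0 <= self.poisson < 0.5:
            raise ValueError("Poisson ratio must lie in [0, 0.5)")


#: The three impactor materials of the factorial design.
MATERIALS = {
    "rubber": MaterialSpec("rubber", density=1.829e-6, youngs_modulus=4.0, poisson=0.45),
    "glass": MaterialSpec("glass", density=2.5e-6, youngs_modulus=70000.0, poisson=0.23),
    "steel": MaterialSpec("steel", density=7.8e-6, youngs_modulus=210000.0, poisson=0.3),
}

#: Cylindrical block sizes as (diameter, thickness) in mm; "d x t" is read
#: as diameter x thickness.
SIZES = {
    "min": (12.5, 12.0),
    "mid": (25.0, 12.0),
    "max": (37.5, 12.0),
}

#: Deliberately weak contact-stiffness multipliers for the impact position
#: (skull curvature/thickness proxy); position is a near-null factor.
POSITION_FACTORS = {"right": 0.9, "front": 1.0, "top": 1.1}

#: Default factor levels of the full factorial design.
DEFAULT_VELOCITIES = (2.0, 6.0, 10.0)


@dataclass(frozen=True)
class ImpactScenario:
    """One cell of the factorial design."""

    position: str
    material: MaterialSpec
    velocity: float
    size: str
    seed: int = 0
    fs: float = 5000.0
    duration: float = 0.2
    snr_db: float | None = None

    def __post_init__(self) -> None:
        if self.position not in POSITION_FACTORS:
            raise ValueError(f"unknown position {self.position!r}")
        if self.size not in SIZES:
            raise ValueError(f"unknown size {self.size!r}")
        if self.velocity < 0:
            raise ValueError("velocity must be non-negative")
        if self.fs <= 0 or self.duration <= 0:
            raise ValueError("fs and duration must be positive")

    @property
    def scenario_id(self) -> str:
        return f"{self.position}_{self.material.name}_{self.size}_{self.velocity:g}"


@dataclass(frozen=True)
class LumpedHeadModel:
    """Parameters of the skull/brain surrogate (SI units).

    Defaults: 4.5 kg total head mass split 1.2 kg shell / 3.3 kg interior,
    skull-brain mode at 25 Hz with 4% damping, 3 Hz grounding mode, and a
    scalp layer of 20 MPa modulus, 6 mm thickness, 2000 Pa*s viscosity.
    """

    m_skull: float = 1.2
    m_brain: float = 3.3
    k_sb: float = 21713.13       # (2*pi*25)^2 * reduced mass -> 25 Hz mode
    c_sb: float = 11.0585        # 4% of critical for that mode
    k_ground: float = 1598.88    # (2*pi*3)^2 * 4.5 kg -> 3 Hz grounding mode
    c_ground: float = 17.0
    scalp_modulus: float = 20.0      # MPa
    scalp_thickness: float = 6.0     # mm
    scalp_viscosity: float = 2000.0  # Pa*s

    def __post_init__(self) -> None:
        if min(self.m_skull, self.m_brain, self.k_sb, self.k_ground,
               self.scalp_modulus, self.scalp_thickness) <= 0:
            raise ValueError("masses, stiffnesses and scalp geometry must be positive")
        if self.c_sb < 0 or self.c_ground < 0 or self.scalp_viscosity < 0:
            raise ValueError("damping coefficients must be non-negative")
        mu = self.m_skull * self.m_brain / (self.m_skull + self.m_brain)
        if self.c_sb >= 2.0 * math.sqrt(self.k_sb * mu):
            raise ValueError("skull-brain coupling must be under-damped")

    @property
    def skull_brain_frequency(self) -> float:
        """Natural frequency (Hz) of the free skull-brain mode."""
        mu = self.m_skull * self.m_brain / (self.m_skull + self.m_brain)
        return math.sqrt(self.k_sb / mu) / (2.0 * math.pi)


DEFAULT_HEAD = LumpedHeadModel()


def block_face_area(size: str) -> float:
    """Contact face area of a block in m^2."""
    d, _ = SIZES[size]
    return math.pi * (d / 2.0) ** 2 * 1e-6


def block_mass(size: str, material: MaterialSpec) -> float:
    """Mass in kg of a cylindrical block, mass = pi (d/2)^2 t rho."""
    d, t = SIZES[size]
    return math.pi * (d / 2.0) ** 2 * t * material.density


def contact_stiffness(size: str, material: MaterialSpec,
                      position_factor: float = 1.0) -> float:
    """Axial stiffness k = E*A/t of the block in N/m, scaled by position."""
    _, t = SIZES[size]
    area = block_face_area(size)
    return material.youngs_modulus * 1e6 * area / (t * 1e-3) * position_factor


def effective_contact(scenario: ImpactScenario, head: LumpedHeadModel) -> tuple[float, float]:
    """Series block+scalp contact stiffness and viscous coefficient (SI)."""
    k_block = contact_stiffness(scenario.size, scenario.material,
                                POSITION_FACTORS[scenario.position])
    area = block_face_area(scenario.size)
    t_scalp = head.scalp_thickness * 1e-3
    k_scalp = head.scalp_modulus * 1e6 * area / t_scalp
    k_c = 1.0 / (1.0 / k_block + 1.0 / k_scalp)
    c_c = head.scalp_viscosity * area / t_scalp
    return k_c, c_c


def simulate_impact(scenario: ImpactScenario,
                    head: LumpedHeadModel = DEFAULT_HEAD,
                    steps_per_period: int = 50,
                    return_states: bool = False):
    """Integrate the three-mass impact and return the skull acceleration.

    The block starts just touching the skull with the impact velocity; the
    contact force is k_c * penetration + c_c * closing speed while the
    block penetrates, clamped to be non-negative (contact cannot pull).
    Integration uses fixed-step RK4 with at least ``steps_per_period``
    steps per period of the fastest mode; a total-mechanical-energy gain
    above 1% aborts with an error (unstable step).  Optional additive white
    Gaussian measurement noise at ``scenario.snr_db`` is drawn from the
    scenario seed.
    """
    m_b = block_mass(scenario.size, scenario.material)
    k_c, c_c = effective_contact(scenario, head)
    m_s, m_br = head.m_skull, head.m_brain
    k_sb, c_sb = head.k_sb, head.c_sb
    k_g, c_g = head.k_ground, head.c_ground

    f_contact = math.sqrt(k_c * (1.0 / m_b + 1.0 / m_s)) / (2.0 * math.pi)
    f_max = max(f_contact, head.skull_brain_frequency)
    dt_out = 1.0 / scenario.fs
    nsub = max(1, math.ceil(dt_out * steps_per_period * f_max))
    h = dt_out / nsub
    n = int(round(scenario.duration * scenario.fs))

    def deriv(y):
        xb, vb, xs, vs, xbr, vbr = y
        pen = xb - xs
        if pen > 0.0:
            fc = k_c * pen + c_c * (vb - vs)
            if fc < 0.0:
                fc = 0.0
        else:
            fc = 0.0
        fsb = k_sb * (xs - xbr) + c_sb * (vs - vbr)
        return (vb, -fc / m_b,
                vs, (fc - fsb - k_g * xs - c_g * vs) / m_s,
                vbr, fsb / m_br)

    def energy(y):
        xb, vb, xs, vs, xbr, vbr = y
        pen = xb - xs
        pot = 0.5 * k_sb * (xs - xbr) ** 2 + 0.5 * k_g * xs ** 2
        if pen > 0.0:
            pot += 0.5 * k_c * pen ** 2
        return 0.5 * (m_b * vb ** 2 + m_s * vs ** 2 + m_br * vbr ** 2) + pot

    y = (0.0, scenario.velocity, 0.0, 0.0, 0.0, 0.0)
    e0 = energy(y)
    acc = np.empty(n)
    states = np.empty((n, 6)) if return_states else None
    for i in range(n):
        if return_states:
            states[i] = y
        acc[i] = deriv(y)[3]
        for _ in range(nsub):
            k1 = deriv(y)
            y2 = tuple(y[j] + 0.5 * h * k1[j] for j in range(6))
            k2 = deriv(y2)
            y3 = tuple(y[j] + 0.5 * h * k2[j] for j in range(6))
            k3 = deriv(y3)
            y4 = tuple(y[j] + h * k3[j] for j in range(6))
            k4 = deriv(y4)
            y = tuple(y[j] + (h / 6.0) * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])
                      for j in range(6))
        if e0 > 0 and energy(y) > 1.01 * e0:
            raise RuntimeError("energy drift above 1%: integration unstable, "
                               "reduce the step (increase steps_per_period)")

    if scenario.snr_db is not None:
        rng = np.random.default_rng(scenario.seed)
        rms = math.sqrt(float(np.mean(acc ** 2)))
        acc = acc + rng.normal(0.0, rms * 10.0 ** (-scenario.snr_db / 20.0), size=n)

    signal = AccelSignal(values=acc, dt=dt_out, unit="m_per_s2",
                         label=scenario.scenario_id)
    return (signal, states) if return_states else signal


def generate_matrix(master_seed: int = 0,
                    positions=tuple(POSITION_FACTORS),
                    materials=tuple(MATERIALS),
                    velocities=DEFAULT_VELOCITIES,
                    sizes=tuple(SIZES),
                    fs: float = 5000.0,
                    duration: float = 0.2,
                    snr_db: float | None = None) -> list[ImpactScenario]:
    """Full factorial Cartesian product of the four factors (3^4 = 81 by default).

    Ordering is deterministic (position, material, velocity, size, each in
    the given level order); each scenario receives a seed derived from the
    master seed so that identical master seeds reproduce identical signals.
    """
    for name, levels in (("positions", positions), ("materials", materials),
                         ("velocities", velocities), ("sizes", sizes)):
        if len(tuple(levels)) == 0:
            raise ValueError(f"empty factor level list: {name}")
    scenarios = []
    for i, (pos, mat, vel, size) in enumerate(product(positions, materials, velocities, sizes)):
        seed = int(np.random.SeedSequence((master_seed, i)).generate_state(1)[0] % (2 ** 31))
        scenarios.append(ImpactScenario(
            position=pos, material=MATERIALS[mat] if isinstance(mat, str) else mat,
            velocity=float(vel), size=size, seed=seed, fs=fs, duration=duration,
            snr_db=snr_db))
    return scenarios
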