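"""Model and run parameters for the binary-colloid BCD simulator.

The physical model is a binary (A-B) mixture of hard spheres of unit
diameter sigma.  Particles of the same species attract through a
short-range square well of width ``epsilon * sigma`` and bond
irreversibly once their centre-of-mass distance falls below
``(1 + epsilon) * sigma``; unlike-species pairs interact through
hard-core repulsion only.  Bonded monomers of species A move only a
fraction ``p_flex_A`` of the time (bond flexibility); B bonds are fully
flexible (``p_flex_B = 1``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict


class InvalidGeometryError(ValueError):
    """Raised for non-positive box dimensions or infeasible packings."""


@dataclass
class ModelParams:
    """Physical parameters of the binary square-well model.

    Parameters
    ----------
    sigma
        Particle diameter; the length unit (fixed at 1).
    epsilon
        Square-well width in units of sigma.  A same-species pair bonds
        irreversibly when its separation is at most ``(1+epsilon)*sigma``.
    p_flex_A, p_flex_B
        Bond flexibility per species: the probability that a *bonded*
        monomer of that species is granted a trial move.  ``0`` freezes
        clusters into rigid bodies, ``1`` lets monomers rattle freely
        within the bond range.  B bonds are fully flexible by default.
    c_A
        Number fraction of species A, ``N_A / N_tot``.
    step_size
        Trial displacement magnitude ``s`` of a monomer move, in sigma.
        Must be smaller than ``epsilon`` so a move cannot jump across
        the attractive well undetected.
    seed
        Seed for the simulation RNG stream.
    """

    sigma: float = 1.0
    epsilon: float = 0.1
    p_flex_A: float = 1.0
    p_flex_B: float = 1.0
    c_A: float = 0.5
    step_size: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_flex_A <= 1.0):
            raise ValueError(f"p_flex_A must lie in [0, 1], got {self.p_flex_A}")
        if not (0.0 <= self.p_flex_B <= 1.0):
            raise ValueError(f"p_flex_B must lie in [0, 1], got {self.p_flex_B}")
        if not (0.0 <= self.c_A <= 1.0):
            raise ValueError(f"c_A must lie in [0, 1], got {self.c_A}")
        if not (0.0 < self.step_size < self.epsilon):
            raise ValueError(
                "step_size must satisfy 0 < s < epsilon "
                f"(got s={self.step_size}, epsilon={self.epsilon})"
            )
        if self.sigma <= 0 or self.epsilon <= 0:
            raise ValueError("sigma and epsilon must be positive")

    @property
    def bond_range(self) -> float:
        """Maximum bonded separation ``(1 + epsilon) * sigma``."""
        return (1.0 + self.epsilon) * self.sigma

    def to_dict(self) -> dict:
        return asdict(self)


def volume_fraction(n_tot: int, sigma: float, L: float) -> float:
    """Total volume fraction ``phi = pi * N * sigma^3 / (6 L^3)``."""
    if L <= 0:
        raise InvalidGeometryError(f"box edge must be positive, got L={L}")
    if n_tot < 0:
        raise ValueError("particle count cannot be negative")
    return math.pi * n_tot * sigma**3 / (6.0 * L**3)


def n_particles_for_phi(phi: float, L: float, sigma: float = 1.0) -> int:
    """Particle count whose volume fraction is closest to ``phi`` in a box of edge L."""
    if L <= 0:
        raise InvalidGeometryError(f"box edge must be positive, got L={L}")
    return round(phi * 6.0 * L**3 / (math.pi * sigma**3))


@dataclass
class BoxSpec:
    """Cubic, fully periodic simulation box.

    ``phi_tot`` is derived from ``L`` and ``N_tot``; use
    :func:`BoxSpec.from_phi` to size the box from a target volume fraction.
    """

    L: float
    N_tot: int
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.L <= 0:
            raise InvalidGeometryError(f"box edge must be positive, got L={self.L}")
        if self.N_tot < 0:
            raise ValueError("N_tot cannot be negative")

    @property
    def phi_tot(self) -> float:
        return volume_fraction(self.N_tot, self.sigma, self.L)

    @classmethod
    def from_phi(cls, phi: float, L: float, sigma: float = 1.0) -> "BoxSpec":
        return cls(L=L, N_tot=n_particles_for_phi(phi, L, sigma), sigma=sigma)

    def to_dict(self) -> dict:
        return {"L": self.L, "N_tot": self.N_tot, "sigma": self.sigma,
                "phi_tot": self.phi_tot}


@dataclass
class EngineParams:
    """Run controls for the propagator.

    ``max_sweeps`` / ``max_reduced_time`` bound the run; the run also ends
    early when ``stop_on_percolation`` is set and every species present has
    formed a spanning cluster, or when ``stop_when_stationary`` is set and
    the mass-average aggregation number of every species changes by less
    than ``stationary_rtol`` per decade of reduced time.

    ``deterministic_gate`` switches the flexibility gate from a Bernoulli
    draw per attempt to a deterministic one-move-in-every-``1/p_flex``
    cycle per particle.
    """

    max_sweeps: int = 1_000_000
    max_reduced_time: float = 100.0
    stop_on_percolation: bool = False
    stop_when_stationary: bool = False
    stationary_rtol: float = 0.01
    zimm_enabled: bool = True
    deterministic_gate: bool = False
    checkpoint_factor: float = 1.3
    snapshot_every: int = 1  # keep a snapshot every k-th checkpoint
    keep_snapshots: bool = True

    def __post_init__(self) -> None:
        if self.max_sweeps < 0:
            raise ValueError("max_sweeps cannot be negative")
        if self.checkpoint_factor <= 1.0:
            raise ValueError("checkpoint_factor must exceed 1")
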