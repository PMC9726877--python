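"""Constrained proton-transfer scan driver over a pluggable energy surface.

The transferring hydrogen is stepped from the donor toward the acceptor by
reducing the H-acceptor distance in fixed increments (0.05 A by default).
At each step the constraint is held exactly — H is reparameterized on the
sphere of the target radius around the acceptor — while the remaining
degrees of freedom are relaxed from the previous point's geometry (warm
start), and the energy is recorded.  The resulting profile is reported
relative to the first point.

The electronic-structure engine behind the real study is deliberately
abstracted away: any object with an ``energy({'D','H','A'})`` method works.
``TwoStateSurface`` supplies the empirical-valence-bond-style surrogate
(two harmonic diabats, constant coupling, lower eigenvalue) used for
validation, and ``HarmonicSurface`` a single-well control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Protocol

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "ScanSpec",
    "EnergySurface",
    "ScanProfile",
    "HarmonicSurface",
    "TwoStateSurface",
    "scan",
    "profile_stats",
]


class EnergySurface(Protocol):
    """Energy (kcal/mol) as a function of donor/hydrogen/acceptor positions."""

    def energy(self, positions: dict[str, np.ndarray]) -> float: ...


@dataclass(frozen=True)
class ScanSpec:
    """Geometry and step plan of one scan."""

    donor: np.ndarray
    hydrogen: np.ndarray
    acceptor: np.ndarray
    step: float = 0.05
    terminal_distance: float = 1.0  # covalent H-A bond length

    def __post_init__(self) -> None:
        for name in ("donor", "hydrogen", "acceptor"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))
        if self.step <= 0:
            raise ValueError("scan step must be positive")
        if self.initial_distance <= self.terminal_distance:
            raise ValueError(
                f"initial d(H-A) = {self.initial_distance:.3f} A must exceed the "
                f"terminal distance {self.terminal_distance:.3f} A"
            )

    @property
    def initial_distance(self) -> float:
        return float(np.linalg.norm(self.hydrogen - self.acceptor))


@dataclass
class ScanProfile:
    """(d(H-A), relative energy) pairs; energies zeroed at the first point."""

    distances: np.ndarray  # A, strictly decreasing by one step
    energies: np.ndarray  # kcal/mol relative to the first point
    hydrogen_positions: np.ndarray  # (n_points, 3) relaxed H per point

    def __len__(self) -> int:
        return len(self.distances)


def _spherical_to_cart(center: np.ndarray, d: float, theta: float, phi: float) -> np.ndarray:
    return center + d * np.array(
        [math.sin(theta) * math.cos(phi),
         math.sin(theta) * math.sin(phi),
         math.cos(theta)]
    )


def _angles_of(center: np.ndarray, point: np.ndarray) -> tuple[float, float]:
    v = point - center
    r = np.linalg.norm(v)
    theta = math.acos(np.clip(v[2] / r, -1.0, 1.0))
    phi = math.atan2(v[1], v[0])
    return theta, phi


def scan(spec: ScanSpec, surface: EnergySurface, xtol: float = 1e-10) -> ScanProfile:
    """Run the constrained scan until d(H-A) reaches the terminal distance.

    At each target distance d the hydrogen lives on the sphere |H - A| = d
    (the constraint is satisfied exactly by construction); its angular
    position is minimized by Nelder-Mead starting from the previous relaxed
    point.  Donor and acceptor stay fixed.
    """
    d0 = spec.initial_distance
    n_points = int(math.floor((d0 - spec.terminal_distance) / spec.step + 1e-9)) + 1
    targets = d0 - spec.step * np.arange(n_points)

    theta, phi = _angles_of(spec.acceptor, spec.hydrogen)
    distances, energies, h_positions = [], [], []
    for step_index, d in enumerate(targets):
        def objective(x: np.ndarray, _d=float(d)) -> float:
            h = _spherical_to_cart(spec.acceptor, _d, x[0], x[1])
            e = surface.energy({"D": spec.donor, "H": h, "A": spec.acceptor})
            if not np.isfinite(e):
                raise FloatingPointError(
                    f"non-finite energy at scan step {step_index} (d = {_d:.3f} A)"
                )
            return e

        res = minimize(
            objective, x0=np.array([theta, phi]), method="Nelder-Mead",
            options={"xatol": xtol, "fatol": 1e-14, "maxiter": 4000},
        )
        if not res.success and not np.isfinite(res.fun):
            raise RuntimeError(f"minimization failed at scan step {step_index}: {res.message}")
        theta, phi = float(res.x[0]), float(res.x[1])
        h = _spherical_to_cart(spec.acceptor, float(d), theta, phi)
        distances.append(float(d))
        energies.append(float(res.fun))
        h_positions.append(h)

    e = np.array(energies)
    return ScanProfile(
        distances=np.array(distances),
        energies=e - e[0],
        hydrogen_positions=np.array(h_positions),
    )


@dataclass(frozen=True)
class ProfileStats:
    barrier: float  # max relative energy, kcal/mol
    endpoint_delta: float  # last - first, kcal/mol
    is_downhill: bool  # True when the product side lies below the start


def profile_stats(p: ScanProfile) -> ProfileStats:
    """Barrier height, endpoint energy difference, and downhill flag."""
    if len(p) < 2:
        raise ValueError("profile statistics need at least 2 points")
    barrier = float(p.energies.max())
    delta = float(p.energies[-1] - p.energies[0])
    return ProfileStats(barrier=barrier, endpoint_delta=delta, is_downhill=delta < 0)


@dataclass(frozen=True)
class HarmonicSurface:
    """Single isotropic harmonic well on the hydrogen position."""

    center: np.ndarray
    k: float = 100.0  # kcal/mol/A^2

    def energy(self, positions: dict[str, np.ndarray]) -> float:
        d2 = float(np.sum((positions["H"] - np.asarray(self.center, float)) ** 2))
        return 0.5 * self.k * d2


@dataclass(frozen=True)
class TwoStateSurface:
    """Empirical-valence-bond-style surrogate: two harmonic diabats.

    Diabat 1 (proton bonded to the donor): 0.5*k_d*(d_DH - r0_donor)^2.
    Diabat 2 (proton on the acceptor):     0.5*k_a*(d_HA - r0_acceptor)^2
    + ``offset`` (the product-side asymmetry; negative = downhill transfer).
    The adiabatic ground state is the lower eigenvalue of the 2x2 matrix
    with constant off-diagonal ``coupling``.  With equal force constants,
    equal bond lengths and zero offset the profile is symmetric: equal
    endpoint energies and the barrier at the midpoint.
    """

    k_donor: float = 300.0  # kcal/mol/A^2, typical X-H stretch stiffness
    k_acceptor: float = 300.0
    r0_donor: float = 1.0  # A, covalent bond length in each diabat
    r0_acceptor: float = 1.0
    coupling: float = 10.0  # kcal/mol
    offset: float = 0.0  # kcal/mol, diabat-2 minus diabat-1 minimum

    def diabats(self, positions: dict[str, np.ndarray]) -> tuple[float, float]:
        d_dh = float(np.linalg.norm(positions["H"] - positions["D"]))
        d_ha = float(np.linalg.norm(positions["H"] - positions["A"]))
        v1 = 0.5 * self.k_donor * (d_dh - self.r0_donor) ** 2
        v2 = 0.5 * self.k_acceptor * (d_ha - self.r0_acceptor) ** 2 + self.offset
        return v1, v2

    def energy(self, positions: dict[str, np.ndarray]) -> float:
        v1, v2 = self.diabats(positions)
        mean, half_gap = 0.5 * (v1 + v2), 0.5 * (v1 - v2)
        return mean - math.sqrt(half_gap**2 + self.coupling**2)
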