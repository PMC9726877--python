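"""Finite-difference linearized Poisson-Boltzmann electrostatics with focusing.

Solves  div(eps grad phi) - eps kappa^2 phi = -4 pi C rho  on nested regular
grids (the three-step focusing schedule 2.5 -> 1.0 -> 0.3 A by default), with
a two-dielectric solute/solvent boundary (eps 4 inside the van der Waals
union of atom spheres, 80 outside), Debye-Hueckel salt screening outside a
2 A ion-exclusion layer, trilinear charge spreading, and Gauss-Seidel/SOR
relaxation.  phi is in kcal/(mol e); C = 332.06 kcal A/(mol e^2).

On top of the solver sit the titration energetics: reaction-field (solvation)
energies, the thermodynamic-cycle intrinsic pKa shift against the isolated
model compound, and the site-site interaction matrix W consumed by the
microstate model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .constants import (
    COULOMB_KCAL,
    EPS_PROTEIN,
    EPS_WATER,
    IONIC_STRENGTH_M,
    T_DEFAULT,
    debye_kappa2,
    kT_ln10,
)

__all__ = [
    "GridSpec",
    "PBGrid",
    "DielectricMap",
    "IonMap",
    "PointChargeSet",
    "SolverSettings",
    "SiteDefinition",
    "SiteEnergetics",
    "DEFAULT_RADII",
    "build_maps",
    "make_focusing_grids",
    "solve_lpbe",
    "solve_focused",
    "reaction_field_energy",
    "site_energetics",
]

#: Default van der Waals radii (A) defining the dielectric boundary.
DEFAULT_RADII: dict[str, float] = {
    "C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8, "H": 1.0, "P": 1.8,
}

#: Thickness of the ion-exclusion (Stern) layer around the solute, A.
STERN_LAYER_A = 2.0


@dataclass(frozen=True)
class GridSpec:
    """A cubic-cell regular grid: origin, spacing (A) and node counts."""

    origin: tuple[float, float, float]
    spacing: float
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if min(self.shape) < 5:
            raise ValueError("grids need at least 5 nodes per axis")

    @property
    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        o, h = self.origin, self.spacing
        return tuple(o[d] + h * np.arange(self.shape[d]) for d in range(3))  # type: ignore[return-value]

    @property
    def extent(self) -> np.ndarray:
        return (np.array(self.shape) - 1) * self.spacing

    def contains(self, pts: np.ndarray, margin_nodes: int = 1) -> bool:
        pts = np.atleast_2d(pts)
        lo = np.array(self.origin) + margin_nodes * self.spacing
        hi = np.array(self.origin) + self.extent - margin_nodes * self.spacing
        return bool(np.all(pts >= lo) and np.all(pts <= hi))


@dataclass
class PBGrid:
    """Electrostatic potential phi (kcal/(mol e)) on a grid."""

    spec: GridSpec
    phi: np.ndarray
    iterations: int = 0
    residual: float = 0.0

    def interpolate(self, pts: np.ndarray) -> np.ndarray:
        """Trilinear phi at arbitrary points (must lie inside the grid)."""
        itp = RegularGridInterpolator(self.spec.axes, self.phi, method="linear")
        return itp(np.atleast_2d(pts))


@dataclass
class DielectricMap:
    """Relative permittivity: per node, and on the three edge families.

    Edge values are assigned from edge-midpoint membership in the solute,
    which resolves the boundary half a cell finer than the node map.
    """

    spec: GridSpec
    node: np.ndarray  # (nx, ny, nz)
    edge_x: np.ndarray  # (nx-1, ny, nz)
    edge_y: np.ndarray  # (nx, ny-1, nz)
    edge_z: np.ndarray  # (nx, ny, nz-1)


@dataclass
class IonMap:
    """Modified screening factor kappa^2 (A^-2) per node; 0 inside the solute
    and its ion-exclusion layer, the bulk Debye value outside."""

    spec: GridSpec
    kappa2: np.ndarray


@dataclass
class PointChargeSet:
    """Point charges: positions (n, 3) in A, charges (n,) in e."""

    positions: np.ndarray
    charges: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, float))
        self.charges = np.atleast_1d(np.asarray(self.charges, float))
        if self.positions.shape != (len(self.charges), 3):
            raise ValueError("positions/charges shape mismatch")

    def __add__(self, other: "PointChargeSet") -> "PointChargeSet":
        return PointChargeSet(
            np.vstack([self.positions, other.positions]),
            np.concatenate([self.charges, other.charges]),
        )


@dataclass(frozen=True)
class SolverSettings:
    eps_protein: float = EPS_PROTEIN
    eps_water: float = EPS_WATER
    ionic_strength: float = IONIC_STRENGTH_M
    temperature: float = T_DEFAULT
    stern_layer: float = STERN_LAYER_A
    omega: float = 1.6  # SOR over-relaxation
    tolerance: float = 1e-6  # max |update| per sweep, kcal/(mol e)
    max_iterations: int = 10_000

    @property
    def kappa2_bulk(self) -> float:
        return debye_kappa2(self.ionic_strength, self.eps_water, self.temperature)


class ConvergenceError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# map construction


def _membership(points: np.ndarray, centers: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """Boolean: is each point inside the union of spheres?  points (..., 3)."""
    flat = points.reshape(-1, 3)
    inside = np.zeros(flat.shape[0], dtype=bool)
    for c, r in zip(centers, radii):
        d2 = np.sum((flat - c) ** 2, axis=1)
        inside |= d2 <= r * r
    return inside.reshape(points.shape[:-1])


def _node_points(spec: GridSpec) -> np.ndarray:
    ax, ay, az = spec.axes
    X, Y, Z = np.meshgrid(ax, ay, az, indexing="ij")
    return np.stack([X, Y, Z], axis=-1)


def build_maps(
    centers: np.ndarray,
    radii: np.ndarray,
    spec: GridSpec,
    settings: SolverSettings = SolverSettings(),
) -> tuple[DielectricMap, IonMap]:
    """Dielectric and screening maps for a union-of-spheres solute.

    eps = eps_protein inside the van der Waals union, eps_water outside
    (edges by midpoint membership); kappa^2 = bulk Debye value outside the
    solute expanded by the Stern layer, 0 inside.  With no atoms, both maps
    are uniform solvent.
    """
    centers = np.atleast_2d(np.asarray(centers, float)) if np.size(centers) else np.empty((0, 3))
    radii = np.atleast_1d(np.asarray(radii, float)) if np.size(radii) else np.empty((0,))
    if len(centers) != len(radii):
        raise ValueError("one radius per atom required")
    if len(centers) and not spec.contains(centers, margin_nodes=0):
        raise ValueError("atoms fall outside the grid; enlarge the grid box")

    pts = _node_points(spec)
    ei, ew = settings.eps_protein, settings.eps_water

    def eps_of(points: np.ndarray) -> np.ndarray:
        if len(centers) == 0:
            return np.full(points.shape[:-1], ew)
        return np.where(_membership(points, centers, radii), ei, ew)

    node = eps_of(pts)
    edge_x = eps_of(0.5 * (pts[:-1] + pts[1:]))
    edge_y = eps_of(0.5 * (pts[:, :-1] + pts[:, 1:]))
    edge_z = eps_of(0.5 * (pts[:, :, :-1] + pts[:, :, 1:]))

    if len(centers):
        excluded = _membership(pts, centers, radii + settings.stern_layer)
        kappa2 = np.where(excluded, 0.0, settings.kappa2_bulk)
    else:
        kappa2 = np.full(spec.shape, settings.kappa2_bulk)
    return DielectricMap(spec, node, edge_x, edge_y, edge_z), IonMap(spec, kappa2)


def make_focusing_grids(
    positions: np.ndarray,
    radii: np.ndarray | None = None,
    spacings: tuple[float, ...] = (2.5, 1.0, 0.3),
    coarse_fill: float = 0.6,
    fine_padding: float = 3.0,
    min_coarse_extent: float = 30.0,
) -> list[GridSpec]:
    """Nested grid schedule centered on the solute.

    The coarse box is sized so the solute (atom spheres when ``radii`` are
    given) spans at most ``coarse_fill`` of it (and at least
    ``min_coarse_extent`` A); the finest box wraps the solute plus
    ``fine_padding`` A; intermediate extents interpolate geometrically.
    """
    positions = np.atleast_2d(np.asarray(positions, float))
    r = np.zeros(len(positions)) if radii is None else np.atleast_1d(np.asarray(radii, float))
    lo = (positions - r[:, None]).min(axis=0)
    hi = (positions + r[:, None]).max(axis=0)
    center = 0.5 * (lo + hi)
    span = float(np.max(hi - lo))
    coarse_extent = max(span / coarse_fill, min_coarse_extent)
    fine_extent = span + 2.0 * fine_padding
    fine_extent = min(fine_extent, coarse_extent)
    n_levels = len(spacings)
    specs: list[GridSpec] = []
    for lvl, h in enumerate(spacings):
        if n_levels == 1:
            extent = coarse_extent
        else:
            f = lvl / (n_levels - 1)
            extent = coarse_extent * (fine_extent / coarse_extent) ** f
        n = int(math.ceil(extent / h)) + 1
        n += (n + 1) % 2  # odd node count keeps the center on a node
        origin = tuple(center - 0.5 * h * (n - 1))
        specs.append(GridSpec(origin=origin, spacing=h, shape=(n, n, n)))
    return specs


# ---------------------------------------------------------------------------
# solver


def _spread_charges(charges: PointChargeSet, spec: GridSpec) -> np.ndarray:
    """Trilinear charge-to-node spreading; conserves total charge exactly."""
    q_grid = np.zeros(spec.shape)
    o = np.array(spec.origin)
    h = spec.spacing
    frac = (charges.positions - o) / h
    base = np.floor(frac).astype(int)
    t = frac - base
    nx, ny, nz = spec.shape
    if np.any(base < 0) or np.any(base + 1 >= np.array([nx, ny, nz])):
        raise ValueError("point charge outside the grid interior")
    for (i, j, k), (tx, ty, tz), q in zip(base, t, charges.charges):
        for dx, wx in ((0, 1 - tx), (1, tx)):
            for dy, wy in ((0, 1 - ty), (1, ty)):
                for dz, wz in ((0, 1 - tz), (1, tz)):
                    q_grid[i + dx, j + dy, k + dz] += q * wx * wy * wz
    return q_grid


def _coulomb_boundary(
    charges: PointChargeSet, spec: GridSpec, settings: SolverSettings
) -> np.ndarray:
    """Screened-Coulomb Dirichlet values on the 6 faces (solvent dielectric)."""
    phi = np.zeros(spec.shape)
    pts = _node_points(spec)
    kappa = math.sqrt(settings.kappa2_bulk)
    face_slices = [
        np.s_[0, :, :], np.s_[-1, :, :],
        np.s_[:, 0, :], np.s_[:, -1, :],
        np.s_[:, :, 0], np.s_[:, :, -1],
    ]
    for fs in face_slices:
        fpts = pts[fs].reshape(-1, 3)
        vals = np.zeros(len(fpts))
        for p, q in zip(charges.positions, charges.charges):
            r = np.linalg.norm(fpts - p, axis=1)
            r = np.maximum(r, 1e-6)
            vals += COULOMB_KCAL * q * np.exp(-kappa * r) / (settings.eps_water * r)
        phi[fs] = vals.reshape(phi[fs].shape)
    return phi


def solve_lpbe(
    eps: DielectricMap,
    ions: IonMap,
    charges: PointChargeSet,
    settings: SolverSettings = SolverSettings(),
    boundary: np.ndarray | None = None,
) -> PBGrid:
    """Relax the 7-point finite-difference LPBE to ``settings.tolerance``.

    ``boundary`` supplies Dirichlet face values (defaults to the analytic
    screened-Coulomb sum in bulk solvent).  Checkerboard (red/black) SOR;
    raises ConvergenceError if max_iterations is hit.
    """
    spec = eps.spec
    h = spec.spacing
    phi = np.array(
        boundary if boundary is not None else _coulomb_boundary(charges, spec, settings),
        dtype=float,
    )
    if phi.shape != spec.shape:
        raise ValueError("boundary array does not match grid shape")

    src = 4.0 * math.pi * COULOMB_KCAL * _spread_charges(charges, spec) / h

    wxm = eps.edge_x[:-1, 1:-1, 1:-1]
    wxp = eps.edge_x[1:, 1:-1, 1:-1]
    wym = eps.edge_y[1:-1, :-1, 1:-1]
    wyp = eps.edge_y[1:-1, 1:, 1:-1]
    wzm = eps.edge_z[1:-1, 1:-1, :-1]
    wzp = eps.edge_z[1:-1, 1:-1, 1:]
    screen = h * h * eps.node[1:-1, 1:-1, 1:-1] * ions.kappa2[1:-1, 1:-1, 1:-1]
    den = wxm + wxp + wym + wyp + wzm + wzp + screen
    src_int = src[1:-1, 1:-1, 1:-1]

    ii, jj, kk = np.indices(den.shape)
    red = (ii + jj + kk) % 2 == 0
    black = ~red
    omega = settings.omega

    interior = phi[1:-1, 1:-1, 1:-1]
    for it in range(1, settings.max_iterations + 1):
        delta = 0.0
        for mask in (red, black):
            num = (
                wxm * phi[:-2, 1:-1, 1:-1]
                + wxp * phi[2:, 1:-1, 1:-1]
                + wym * phi[1:-1, :-2, 1:-1]
                + wyp * phi[1:-1, 2:, 1:-1]
                + wzm * phi[1:-1, 1:-1, :-2]
                + wzp * phi[1:-1, 1:-1, 2:]
                + src_int
            )
            gs = num / den
            upd = omega * (gs[mask] - interior[mask])
            interior[mask] += upd
            if upd.size:
                delta = max(delta, float(np.abs(upd).max()))
        if delta < settings.tolerance:
            return PBGrid(spec, phi, iterations=it, residual=delta)
    raise ConvergenceError(
        f"LPBE solve did not reach {settings.tolerance} in "
        f"{settings.max_iterations} iterations (last update {delta:.3e})"
    )


def _interp_boundary(parent: PBGrid, spec: GridSpec) -> np.ndarray:
    """Child-grid array with faces filled from the parent solution."""
    itp = RegularGridInterpolator(parent.spec.axes, parent.phi, method="linear")
    phi = np.zeros(spec.shape)
    pts = _node_points(spec)
    for fs in (
        np.s_[0, :, :], np.s_[-1, :, :],
        np.s_[:, 0, :], np.s_[:, -1, :],
        np.s_[:, :, 0], np.s_[:, :, -1],
    ):
        fpts = pts[fs].reshape(-1, 3)
        phi[fs] = itp(fpts).reshape(phi[fs].shape)
    return phi


def solve_focused(
    centers: np.ndarray,
    radii: np.ndarray,
    charges: PointChargeSet,
    schedule: list[GridSpec],
    settings: SolverSettings = SolverSettings(),
    uniform_eps: float | None = None,
) -> list[PBGrid]:
    """Run the focusing schedule coarse-to-fine; returns one PBGrid per level.

    The coarsest level takes the analytic screened-Coulomb boundary; each
    finer level takes its Dirichlet boundary from the previous solution by
    trilinear interpolation.  ``uniform_eps`` bypasses the maps and solves in
    a homogeneous salt-free dielectric (the reference leg of energy cycles).
    """
    if not schedule:
        raise ValueError("empty focusing schedule")
    if not schedule[-1].contains(charges.positions):
        raise ValueError("charges must lie inside the finest grid interior")
    solutions: list[PBGrid] = []
    for lvl, spec in enumerate(schedule):
        if uniform_eps is not None:
            uni = replace(settings, eps_water=uniform_eps, eps_protein=uniform_eps,
                          ionic_strength=0.0)
            eps, ions = build_maps(np.empty((0, 3)), np.empty(0), spec, uni)
            lvl_settings = uni
        else:
            eps, ions = build_maps(centers, radii, spec, settings)
            lvl_settings = settings
        boundary = None if lvl == 0 else _interp_boundary(solutions[-1], spec)
        solutions.append(solve_lpbe(eps, ions, charges, lvl_settings, boundary))
    return solutions


# ---------------------------------------------------------------------------
# energies


def reaction_field_energy(
    centers: np.ndarray,
    radii: np.ndarray,
    charges: PointChargeSet,
    schedule: list[GridSpec],
    settings: SolverSettings = SolverSettings(),
    reference_eps: float | None = None,
    return_levels: bool = False,
):
    """Solvation (reaction-field) energy in kcal/mol.

    1/2 sum_i q_i [phi_env(r_i) - phi_uniform(r_i)] with phi_uniform the
    salt-free homogeneous solve (eps = ``reference_eps``, default the protein
    interior value) on the identical grids, so the grid self-energy cancels
    in the difference.  ``return_levels`` also reports the energy from each
    focusing level for convergence studies.
    """
    ref_eps = settings.eps_protein if reference_eps is None else reference_eps
    env = solve_focused(centers, radii, charges, schedule, settings)
    hom = solve_focused(centers, radii, charges, schedule, settings, uniform_eps=ref_eps)
    energies = []
    for g_env, g_hom in zip(env, hom):
        if not g_env.spec.contains(charges.positions):
            energies.append(np.nan)
            continue
        dphi = g_env.interpolate(charges.positions) - g_hom.interpolate(charges.positions)
        energies.append(float(0.5 * np.dot(charges.charges, dphi)))
    if return_levels:
        return energies[-1], energies
    return energies[-1]


@dataclass(frozen=True)
class SiteDefinition:
    """Geometry and charge model of one titratable site.

    The same atom positions carry the protonated and deprotonated partial
    charges; the model compound is the site's atoms excised with unchanged
    geometry.
    """

    id: str
    kind: str  # 'acid' | 'base'
    reference_pKa: float
    positions: np.ndarray  # (m, 3)
    radii: np.ndarray  # (m,)
    q_protonated: np.ndarray  # (m,)
    q_deprotonated: np.ndarray  # (m,)

    def charge_set(self, protonated: bool) -> PointChargeSet:
        q = self.q_protonated if protonated else self.q_deprotonated
        return PointChargeSet(self.positions, q)


@dataclass
class SiteEnergetics:
    """Intrinsic pKa values and the interaction matrix for the microstate model."""

    site_ids: list[str]
    reference_pKa: np.ndarray
    pKa_int: np.ndarray
    dd_solvation: np.ndarray  # protein-minus-model solvation term, kcal/mol
    dd_background: np.ndarray  # fixed-charge (background) term, kcal/mol
    W: np.ndarray  # kcal/mol, symmetrized

    @property
    def shifts(self) -> np.ndarray:
        return self.pKa_int - self.reference_pKa


def site_energetics(
    centers: np.ndarray,
    radii: np.ndarray,
    sites: list[SiteDefinition],
    background: PointChargeSet | None = None,
    schedule: list[GridSpec] | None = None,
    settings: SolverSettings = SolverSettings(),
    max_asymmetry: float = 0.05,
) -> SiteEnergetics:
    """Thermodynamic-cycle intrinsic pKa values and interaction matrix W.

    For each site the protonation energy difference is evaluated in the full
    solute geometry (``centers``/``radii``, i.e. the 'protein') and in the
    isolated model compound (the site's own atoms), both legs as solvation
    (reaction-field) energies against the homogeneous reference plus the
    interaction with ``background`` fixed charges (protein leg only):

        ddG = [G_prot - G_deprot]_protein - [G_prot - G_deprot]_model
        pKa_int = pKa_ref - ddG / (kB T ln 10)

    A protonation made more favorable by the environment (ddG < 0) raises
    pKa_int for acids and bases alike; site kind enters only through the
    charge sets.  W_mu_nu is the (protonated - deprotonated) charge
    difference of site mu interacting, through the protein-environment
    potential, with the charge difference of site nu; the discrete Green's
    function makes it symmetric up to interpolation error, checked against
    ``max_asymmetry`` and then symmetrized.
    """
    if schedule is None:
        schedule = make_focusing_grids(centers, radii)
    n = len(sites)
    ktln10 = kT_ln10(settings.temperature)
    dd_solv = np.zeros(n)
    dd_back = np.zeros(n)
    pka_int = np.zeros(n)
    refs = np.array([s.reference_pKa for s in sites])
    # phi difference fields (protonated - deprotonated) per site, finest grid
    dphi_env: list[PBGrid] = []

    for i, s in enumerate(sites):
        parts: dict[tuple[str, bool], float] = {}
        sols: dict[bool, list[PBGrid]] = {}
        for protonated in (True, False):
            q = s.charge_set(protonated)
            env = solve_focused(centers, radii, q, schedule, settings)
            hom = solve_focused(centers, radii, q, schedule, settings,
                                uniform_eps=settings.eps_protein)
            sols[protonated] = env
            rf = float(
                0.5 * np.dot(
                    q.charges,
                    env[-1].interpolate(q.positions) - hom[-1].interpolate(q.positions),
                )
            )
            # model-compound leg: site atoms alone, same grids
            env_m = solve_focused(s.positions, s.radii, q, schedule, settings)
            hom_m = solve_focused(s.positions, s.radii, q, schedule, settings,
                                  uniform_eps=settings.eps_protein)
            rf_m = float(
                0.5 * np.dot(
                    q.charges,
                    env_m[-1].interpolate(q.positions) - hom_m[-1].interpolate(q.positions),
                )
            )
            back = 0.0
            if background is not None and len(background.charges):
                back = float(
                    np.dot(background.charges, env[-1].interpolate(background.positions))
                )
            parts[("solv", protonated)] = rf - rf_m
            parts[("back", protonated)] = back
        dd_solv[i] = parts[("solv", True)] - parts[("solv", False)]
        dd_back[i] = parts[("back", True)] - parts[("back", False)]
        pka_int[i] = refs[i] - (dd_solv[i] + dd_back[i]) / ktln10
        # linearity: phi of the charge difference = difference of phis
        fine = sols[True][-1]
        dphi_env.append(PBGrid(fine.spec, sols[True][-1].phi - sols[False][-1].phi))

    W = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            dq_j = sites[j].q_protonated - sites[j].q_deprotonated
            W[i, j] = float(np.dot(dq_j, dphi_env[i].interpolate(sites[j].positions)))
    asym = float(np.abs(W - W.T).max()) if n > 1 else 0.0
    if asym > max_asymmetry:
        raise RuntimeError(
            f"W asymmetry {asym:.3f} kcal/mol exceeds tolerance {max_asymmetry}"
        )
    W = 0.5 * (W + W.T)
    return SiteEnergetics(
        site_ids=[s.id for s in sites],
        reference_pKa=refs,
        pKa_int=pka_int,
        dd_solvation=dd_solv,
        dd_background=dd_back,
        W=W,
    )


def born_energy(charge: float, radius: float, eps_in: float, eps_out: float) -> float:
    """Analytic Born solvation energy (kcal/mol) of a centered ion."""
    return -0.5 * COULOMB_KCAL * charge**2 * (1.0 / eps_in - 1.0 / eps_out) / radius
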