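"""Protonation-microstate statistics for interacting titratable sites.

A protein with N titratable sites has 2^N protonation microstates.  Each
microstate x (x_i = 1 protonated, 0 deprotonated) has energy

    E(x; pH) = sum_mu x_mu * dG_int,mu(pH)
             + 1/2 * sum_{mu != nu} q_mu q_nu W_mu_nu,

with dG_int,mu = k_B T ln10 * (pH - pKa_int,mu) for acids and bases alike
(the site kind enters only through the charge pair: acids carry 0/-1 when
protonated/deprotonated, bases +1/0), and W the pairwise electrostatic
interaction between unit charges at the two sites (kcal/mol).  Protonation
probabilities <x_i> are Boltzmann averages over the microstates, evaluated
either by exact enumeration (2^N terms) or by Metropolis Monte Carlo.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import REFERENCE_PKA, SITE_KIND, T_DEFAULT, kT, kT_ln10

__all__ = [
    "TitratableSite",
    "MicrostateSystem",
    "TitrationResult",
    "TitrationCurve",
    "microstate_energy",
    "enumerate_titration",
    "mc_titration",
    "titration_curve",
    "reference_site",
    "histidine_pair",
]

#: |W| above which a site pair is treated as strongly coupled and gets
#: dedicated paired Monte-Carlo moves (kcal/mol).
STRONG_COUPLING_KCAL = 2.5


@dataclass(frozen=True)
class TitratableSite:
    """One two-state protonation site."""

    id: str
    kind: str  # 'acid' or 'base'
    reference_pKa: float
    pKa_int: float

    def __post_init__(self) -> None:
        if self.kind not in ("acid", "base"):
            raise ValueError(f"site kind must be 'acid' or 'base', got {self.kind!r}")
        if not math.isfinite(self.reference_pKa):
            raise ValueError("reference pKa must be finite")

    @property
    def charge_protonated(self) -> int:
        return 0 if self.kind == "acid" else 1

    @property
    def charge_deprotonated(self) -> int:
        return -1 if self.kind == "acid" else 0


def reference_site(resname: str, id: str | None = None, shift: float = 0.0) -> TitratableSite:
    """A site carrying a model-compound reference pKa plus an environment shift.

    ``resname`` is one of ARG, ASP, CYS, GLU, LYS, TYR, HIS_NE, HIS_ND.
    """
    key = resname.upper()
    if key not in REFERENCE_PKA:
        raise KeyError(f"no reference pKa for {resname!r}")
    ref = REFERENCE_PKA[key]
    return TitratableSite(
        id=id or key, kind=SITE_KIND[key], reference_pKa=ref, pKa_int=ref + shift
    )


def histidine_pair(
    id_prefix: str = "His",
    shift_ne: float = 0.0,
    shift_nd: float = 0.0,
    coupling: float = 12.0,
    temperature: float = T_DEFAULT,
) -> tuple[TitratableSite, TitratableSite, float]:
    """Histidine as two coupled basic proton sites (N_eps, N_delta).

    Returns the two sites and the W entry to install between them.  The
    doubly-deprotonated imidazolate is suppressed by an energy penalty c on
    the (0, 0) configuration; within the q-q interaction form this is realized
    exactly by W_eps,delta = c together with a +c/(kT ln10) shift of both
    intrinsic pKa values (the three physical states keep their relative
    energies, and the fully protonated cation stays reachable at low pH).
    Default c = 12 kcal/mol keeps the imidazolate negligible below pH 12.
    """
    bump = coupling / kT_ln10(temperature)
    ne = TitratableSite(
        id=f"{id_prefix}_NE", kind="base",
        reference_pKa=REFERENCE_PKA["HIS_NE"],
        pKa_int=REFERENCE_PKA["HIS_NE"] + shift_ne + bump,
    )
    nd = TitratableSite(
        id=f"{id_prefix}_ND", kind="base",
        reference_pKa=REFERENCE_PKA["HIS_ND"],
        pKa_int=REFERENCE_PKA["HIS_ND"] + shift_nd + bump,
    )
    return ne, nd, coupling


@dataclass
class MicrostateSystem:
    """Titratable sites plus their symmetric interaction matrix W (kcal/mol)."""

    sites: list[TitratableSite]
    W: np.ndarray
    temperature: float = T_DEFAULT

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        n = len(self.sites)
        if self.W.shape != (n, n):
            raise ValueError(f"W shape {self.W.shape} does not match {n} sites")
        if not np.allclose(self.W, self.W.T, atol=1e-9):
            raise ValueError("W must be symmetric")
        if not np.allclose(np.diag(self.W), 0.0):
            raise ValueError("W must have zero diagonal")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def charge_offsets(self) -> np.ndarray:
        """q_i = x_i + offset_i: offset -1 for acids, 0 for bases."""
        return np.array([-1 if s.kind == "acid" else 0 for s in self.sites], dtype=float)

    def dG_int(self, pH: float) -> np.ndarray:
        """Protonation energies dG_int,i(pH) in kcal/mol."""
        pka = np.array([s.pKa_int for s in self.sites])
        return kT_ln10(self.temperature) * (pH - pka)

    def reorder(self, perm: np.ndarray) -> "MicrostateSystem":
        perm = np.asarray(perm)
        return MicrostateSystem(
            [self.sites[i] for i in perm],
            self.W[np.ix_(perm, perm)],
            self.temperature,
        )


def microstate_energy(sys: MicrostateSystem, x: np.ndarray, pH: float) -> float:
    """Energy (kcal/mol) of one microstate; x is the 0/1 protonation vector."""
    x = np.asarray(x, dtype=float)
    if x.shape != (sys.n_sites,):
        raise ValueError(f"microstate length {x.shape} does not match {sys.n_sites} sites")
    q = x + sys.charge_offsets
    return float(x @ sys.dG_int(pH) + 0.5 * q @ sys.W @ q)


@dataclass(frozen=True)
class TitrationResult:
    """Per-site protonation probabilities at one pH."""

    pH: float
    probabilities: np.ndarray  # <x_i> in [0, 1]
    method: str  # 'enumeration' | 'mc'
    mc_standard_error: np.ndarray | None = None
    seed: int | None = None

    @property
    def total_protonation(self) -> float:
        return float(self.probabilities.sum())


def _all_microstates(n: int) -> np.ndarray:
    """(2^n, n) matrix of all 0/1 protonation vectors."""
    idx = np.arange(2**n, dtype=np.uint64)
    return ((idx[:, None] >> np.arange(n, dtype=np.uint64)) & 1).astype(float)


def enumerate_titration(sys: MicrostateSystem, pH: float) -> TitrationResult:
    """Exact Boltzmann average of x_i over all 2^N microstates."""
    n = sys.n_sites
    if n > 25:
        raise ValueError(
            f"{n} sites means 2^{n} microstates; use mc_titration for systems this large"
        )
    X = _all_microstates(n)
    Q = X + sys.charge_offsets
    E = X @ sys.dG_int(pH) + 0.5 * np.einsum("si,ij,sj->s", Q, sys.W, Q)
    E -= E.min()  # stabilize the exponentials
    w = np.exp(-E / kT(sys.temperature))
    probs = (w @ X) / w.sum()
    return TitrationResult(pH=pH, probabilities=probs, method="enumeration")


def mc_titration(
    sys: MicrostateSystem,
    pH: float,
    n_sweeps: int = 10_000,
    seed: int | None = None,
    equilibration_fraction: float = 0.1,
    n_batches: int = 20,
) -> TitrationResult:
    """Metropolis Monte-Carlo estimate of the protonation probabilities.

    One sweep attempts N single-site flips in random order plus one paired
    flip for every strongly coupled pair (|W| > 2.5 kcal/mol).  The first
    10% of sweeps are discarded; standard errors come from 20 batch means.
    The same (seed, inputs) always returns bit-identical output.
    """
    if n_sweeps < 1:
        raise ValueError("n_sweeps must be >= 1")
    if seed is None:
        raise ValueError("mc_titration requires an explicit seed for reproducibility")
    rng = np.random.default_rng(seed)
    n = sys.n_sites
    beta = 1.0 / kT(sys.temperature)
    dG = sys.dG_int(pH)
    W = sys.W
    offs = sys.charge_offsets
    strong = [
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if abs(W[i, j]) > STRONG_COUPLING_KCAL
    ]

    x = rng.integers(0, 2, size=n).astype(float)
    q = x + offs
    # field[i] = sum_nu W[i, nu] * q[nu]  (diag W is zero)
    field = W @ q

    n_equil = int(round(equilibration_fraction * n_sweeps))
    n_prod = n_sweeps - n_equil
    if n_prod < 1:
        n_equil, n_prod = n_sweeps - 1, 1
    samples = np.zeros((n_prod, n))

    for sweep in range(n_sweeps):
        order = rng.permutation(n)
        u = rng.random(n + len(strong))
        for k, i in enumerate(order):
            dx = 1.0 - 2.0 * x[i]
            dE = dx * (dG[i] + field[i])
            if dE <= 0.0 or u[k] < math.exp(-beta * dE):
                x[i] += dx
                q[i] += dx
                field += W[:, i] * dx
        for k, (i, j) in enumerate(strong):
            dxi = 1.0 - 2.0 * x[i]
            dxj = 1.0 - 2.0 * x[j]
            dE = (
                dxi * (dG[i] + field[i])
                + dxj * (dG[j] + field[j])
                + dxi * dxj * W[i, j]
            )
            if dE <= 0.0 or u[n + k] < math.exp(-beta * dE):
                x[i] += dxi
                x[j] += dxj
                q[i] += dxi
                q[j] += dxj
                field += W[:, i] * dxi + W[:, j] * dxj
        if sweep >= n_equil:
            samples[sweep - n_equil] = x

    probs = samples.mean(axis=0)
    n_b = min(n_batches, n_prod)
    usable = (n_prod // n_b) * n_b
    batches = samples[:usable].reshape(n_b, -1, n).mean(axis=1)
    se = batches.std(axis=0, ddof=1) / math.sqrt(n_b) if n_b > 1 else np.full(n, np.inf)
    return TitrationResult(
        pH=pH, probabilities=probs, method="mc", mc_standard_error=se, seed=seed
    )


@dataclass
class TitrationCurve:
    """Protonation probabilities on an ascending pH grid, with pKa_half."""

    pH_grid: np.ndarray  # (n_pH,)
    probabilities: np.ndarray  # (n_pH, n_sites)
    site_ids: list[str]
    method: str
    pKa_half: np.ndarray = field(init=False)  # NaN where <x> never crosses 0.5

    def __post_init__(self) -> None:
        self.pKa_half = np.array(
            [
                _half_titration_pH(self.pH_grid, self.probabilities[:, i])
                for i in range(self.probabilities.shape[1])
            ]
        )

    @property
    def total_protonation(self) -> np.ndarray:
        return self.probabilities.sum(axis=1)


def _half_titration_pH(ph: np.ndarray, p: np.ndarray) -> float:
    """pH where the (descending) protonation curve crosses 0.5.

    Linear interpolation between bracketing grid points; a grid value of
    exactly 0.5 returns the lowest such pH; NaN when there is no crossing.
    """
    for k in range(len(ph)):
        if p[k] == 0.5:
            return float(ph[k])
        if k + 1 < len(ph) and p[k] > 0.5 > p[k + 1]:
            f = (p[k] - 0.5) / (p[k] - p[k + 1])
            return float(ph[k] + f * (ph[k + 1] - ph[k]))
    return float("nan")


def titration_curve(
    sys: MicrostateSystem,
    pH_lo: float,
    pH_hi: float,
    step: float,
    method: str = "enumeration",
    n_sweeps: int = 10_000,
    seed: int | None = None,
) -> TitrationCurve:
    """Titrate the system over an ascending pH grid and locate pKa_half."""
    if not pH_lo < pH_hi:
        raise ValueError("need pH_lo < pH_hi")
    if step <= 0:
        raise ValueError("step must be positive")
    n_pts = int(round((pH_hi - pH_lo) / step)) + 1
    grid = pH_lo + step * np.arange(n_pts)
    if len(grid) < 2:
        raise ValueError("pH grid has fewer than 2 points")
    rows = []
    for k, ph in enumerate(grid):
        if method == "enumeration":
            res = enumerate_titration(sys, float(ph))
        elif method == "mc":
            if seed is None:
                raise ValueError("mc curve requires a seed")
            res = mc_titration(sys, float(ph), n_sweeps=n_sweeps, seed=seed + k)
        else:
            raise ValueError(f"unknown method {method!r}")
        rows.append(res.probabilities)
    return TitrationCurve(
        pH_grid=grid,
        probabilities=np.array(rows),
        site_ids=[s.id for s in sys.sites],
        method=method,
    )
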