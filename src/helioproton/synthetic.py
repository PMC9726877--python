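"""Synthetic inputs with known ground truth for every pipeline stage.

Every generator is a pure function of its spec — the seed is mandatory and
identical specs give bit-identical output.  Ground-truth values bundled with
a fixture (exact enumeration answers, Markov stationary distributions) are
computed by deliberately separate brute-force code paths, never by the
modules the fixtures are meant to test.

The trajectory generator emulates the statistical structure of the MD
analysis: five replicate runs of 1000 frames at 0.15 ns, a hidden two-state
(or k-state) Markov chain switching the monitored H-bond distances, and
isotropic Gaussian positional noise on all atoms.  It makes no attempt at
force-field realism — only the distance/label statistics are meaningful.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .microstates import MicrostateSystem, TitratableSite
from .structure import AtomRecord, Structure
from .trajectory import FRAME_INTERVAL_NS, Trajectory

__all__ = [
    "MicrostateSpec",
    "TrajectorySpec",
    "TrajectoryGroundTruth",
    "gen_microstate_system",
    "gen_trajectory_set",
    "gen_toy_structure",
    "born_ion_structure",
    "two_atom_structure",
    "random_structure",
    "brute_force_titration",
    "markov_stationary",
]

_REFERENCE_CHOICES = [
    ("ARG", "base", 12.0),
    ("ASP", "acid", 4.0),
    ("CYS", "acid", 9.5),
    ("GLU", "acid", 4.4),
    ("LYS", "base", 10.4),
    ("TYR", "acid", 9.6),
]


def brute_force_titration(
    kinds: list[str],
    pka_int: list[float],
    W: np.ndarray,
    pH: float,
    temperature: float = 300.0,
) -> np.ndarray:
    """Independent 2^N Boltzmann-sum oracle for protonation probabilities.

    Plain nested loops over microstates and site pairs; shares no code with
    the microstate module.
    """
    n = len(kinds)
    kt = 1.987204258640832e-3 * temperature
    ktln10 = kt * math.log(10.0)
    z = 0.0
    num = [0.0] * n
    energies = []
    for x in itertools.product((0, 1), repeat=n):
        e = 0.0
        for i in range(n):
            e += x[i] * ktln10 * (pH - pka_int[i])
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                qi = x[i] - 1 if kinds[i] == "acid" else x[i]
                qj = x[j] - 1 if kinds[j] == "acid" else x[j]
                e += 0.5 * qi * qj * float(W[i, j])
        energies.append((x, e))
    e_min = min(e for _, e in energies)
    for x, e in energies:
        w = math.exp(-(e - e_min) / kt)
        z += w
        for i in range(n):
            num[i] += w * x[i]
    return np.array([v / z for v in num])


@dataclass(frozen=True)
class MicrostateSpec:
    """Random titratable system: reference compounds with Gaussian
    environmental shifts and a Gaussian symmetric interaction matrix."""

    seed: int
    n_sites: int = 3
    shift_sd: float = 1.5  # pK units
    w_sd: float = 1.0  # kcal/mol
    pH: float = 7.0
    temperature: float = 300.0

    def __post_init__(self) -> None:
        if not 1 <= self.n_sites <= 25:
            raise ValueError("n_sites must be in [1, 25] for the bundled enumeration")


def gen_microstate_system(spec: MicrostateSpec) -> tuple[MicrostateSystem, np.ndarray]:
    """A random system plus its exact protonation probabilities at spec.pH.

    The expected values come from :func:`brute_force_titration`; the random
    stream generating the system is spawned separately from any stream a
    consumer might use, so fixtures cannot couple accidentally.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(1)[0])
    sites = []
    kinds, pkas = [], []
    for i in range(spec.n_sites):
        resname, kind, ref = _REFERENCE_CHOICES[rng.integers(len(_REFERENCE_CHOICES))]
        shift = float(rng.normal(0.0, spec.shift_sd)) if spec.shift_sd > 0 else 0.0
        sites.append(
            TitratableSite(
                id=f"{resname}{i + 1}", kind=kind,
                reference_pKa=ref, pKa_int=ref + shift,
            )
        )
        kinds.append(kind)
        pkas.append(ref + shift)
    if spec.w_sd > 0 and spec.n_sites > 1:
        raw = rng.normal(0.0, spec.w_sd, (spec.n_sites, spec.n_sites))
        W = 0.5 * (raw + raw.T)
        np.fill_diagonal(W, 0.0)
    else:
        W = np.zeros((spec.n_sites, spec.n_sites))
    system = MicrostateSystem(sites, W, temperature=spec.temperature)
    expected = brute_force_titration(kinds, pkas, W, spec.pH, spec.temperature)
    return system, expected


# ---------------------------------------------------------------------------
# trajectories


def markov_stationary(P: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (eigen route)."""
    P = np.asarray(P, float)
    vals, vecs = np.linalg.eig(P.T)
    k = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, k])
    pi = np.abs(pi)
    return pi / pi.sum()


@dataclass(frozen=True)
class TrajectorySpec:
    """Replicate switching-trajectory generator settings.

    ``scheme`` picks the monitored geometry: 'trp246' builds the Gln26
    OE1 / Trp246 NE1 pair (one distance per frame), 'gate' builds the
    Tyr92 OH hub with Glu230 OE1 and Asn16 ND2 mobiles (two distances).
    ``distance_means``/``distance_sds`` have one row per hidden state and
    one column per monitored distance.
    """

    seed: int
    scheme: str = "trp246"
    n_replicates: int = 5
    n_frames: int = 1000
    frame_interval: float = FRAME_INTERVAL_NS
    state_names: tuple[str, ...] = ("in_hb", "out")
    transition: tuple[tuple[float, ...], ...] = ((0.95, 0.05), (0.05, 0.95))
    distance_means: tuple[tuple[float, ...], ...] = ((3.0,), (7.5,))
    distance_sds: tuple[tuple[float, ...], ...] = ((0.15,), (0.4,))
    noise_sigma: float = 0.0  # A, per coordinate, all atoms
    start: str = "stationary"  # or 'state:<index>'

    def __post_init__(self) -> None:
        if self.scheme not in ("trp246", "gate"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.n_replicates < 1 or self.n_frames < 2:
            raise ValueError("need >= 1 replicate and >= 2 frames")
        P = np.array(self.transition, float)
        k = len(self.state_names)
        if P.shape != (k, k) or np.any(P < 0) or not np.allclose(P.sum(axis=1), 1.0):
            raise ValueError("transition matrix must be row-stochastic over the states")
        m = np.array(self.distance_means, float)
        s = np.array(self.distance_sds, float)
        want = 1 if self.scheme == "trp246" else 2
        if m.shape != (k, want) or s.shape != m.shape:
            raise ValueError(
                f"distance parameters must have shape ({k}, {want}) for {self.scheme}"
            )


@dataclass
class TrajectoryGroundTruth:
    """Hidden-state bookkeeping returned with generated trajectories."""

    spec: TrajectorySpec
    hidden_states: np.ndarray  # (R, F) int state indices
    drawn_distances: np.ndarray  # (R, F, n_dists), pre-noise
    stationary: np.ndarray  # (k,)

    @property
    def state_fractions(self) -> np.ndarray:
        """Observed hidden-state occupancies pooled over replicates."""
        k = len(self.spec.state_names)
        flat = self.hidden_states.ravel()
        return np.array([(flat == i).mean() for i in range(k)])


#: Roster layouts: (chain, resid, resname, name, element, base position).
_TRP_ROSTER = [
    ("A", 26, "GLN", "CA", "C", (0.0, 5.0, 0.0)),
    ("A", 26, "GLN", "OE1", "O", (0.0, 0.0, 0.0)),
    ("A", 246, "TRP", "CA", "C", (5.0, 5.0, 0.0)),
    ("A", 246, "TRP", "NE1", "N", (1.0, 0.0, 0.0)),  # x scaled by d
    ("A", 300, "ALA", "CA", "C", (-6.0, 0.0, 3.0)),
    ("A", 301, "ALA", "CA", "C", (-6.0, 4.0, -3.0)),
]
_GATE_ROSTER = [
    ("A", 92, "TYR", "CA", "C", (0.0, 0.0, 5.0)),
    ("A", 92, "TYR", "OH", "O", (0.0, 0.0, 0.0)),
    ("A", 230, "GLU", "CA", "C", (8.0, 0.0, 5.0)),
    ("A", 230, "GLU", "OE1", "O", (1.0, 0.0, 0.0)),  # x scaled by d1
    ("A", 16, "ASN", "CA", "C", (0.0, 8.0, 5.0)),
    ("A", 16, "ASN", "ND2", "N", (0.0, 1.0, 0.0)),  # y scaled by d2
    ("A", 300, "ALA", "CA", "C", (-6.0, -6.0, 0.0)),
    ("A", 301, "ALA", "CA", "C", (6.0, -6.0, 2.0)),
]


def _roster_structure(layout) -> Structure:
    atoms = [
        AtomRecord(serial=i + 1, name=name, altloc="", resname=resname, chain=chain,
                   resid=resid, x=p[0], y=p[1], z=p[2], element=el)
        for i, (chain, resid, resname, name, el, p) in enumerate(layout)
    ]
    return Structure(atoms)


def gen_trajectory_set(
    spec: TrajectorySpec,
) -> tuple[list[Trajectory], TrajectoryGroundTruth]:
    """Replicate trajectories driven by a hidden Markov chain.

    Per frame, the chain state draws each monitored distance from its
    Gaussian; the mobile atom is placed at exactly that distance from its
    anchor along a fixed axis, then isotropic Gaussian noise (sigma per
    coordinate) perturbs every atom.  With sigma = 0 the measured distances
    recover the drawn ones exactly.
    """
    root = np.random.SeedSequence(spec.seed)
    chain_seed, noise_seed = root.spawn(2)
    rng_chain = np.random.default_rng(chain_seed)
    rng_noise = np.random.default_rng(noise_seed)

    layout = _TRP_ROSTER if spec.scheme == "trp246" else _GATE_ROSTER
    template = _roster_structure(layout)
    base = template.coords
    # indices of mobile atoms and their displacement axes
    if spec.scheme == "trp246":
        mobiles = [(3, np.array([1.0, 0.0, 0.0]), np.zeros(3))]
    else:
        mobiles = [
            (3, np.array([1.0, 0.0, 0.0]), np.zeros(3)),
            (5, np.array([0.0, 1.0, 0.0]), np.zeros(3)),
        ]

    P = np.array(spec.transition, float)
    k = len(spec.state_names)
    pi = markov_stationary(P)
    if spec.start == "stationary":
        start_p = pi
    elif spec.start.startswith("state:"):
        start_p = np.zeros(k)
        start_p[int(spec.start.split(":")[1])] = 1.0
    else:
        raise ValueError(f"unknown start policy {spec.start!r}")

    means = np.array(spec.distance_means, float)
    sds = np.array(spec.distance_sds, float)
    n_d = means.shape[1]
    R, F = spec.n_replicates, spec.n_frames

    hidden = np.zeros((R, F), dtype=int)
    drawn = np.zeros((R, F, n_d))
    trajectories: list[Trajectory] = []
    for r in range(R):
        s = rng_chain.choice(k, p=start_p)
        frames = np.empty((F, len(template), 3))
        for f in range(F):
            hidden[r, f] = s
            d = rng_chain.normal(means[s], sds[s])
            d = np.maximum(d, 0.5)  # distances stay physical
            drawn[r, f] = d
            xyz = base.copy()
            for (idx, axis, anchor), dist in zip(mobiles, d):
                xyz[idx] = anchor + axis * dist
            frames[f] = xyz
            s = rng_chain.choice(k, p=P[s])
        if spec.noise_sigma > 0:
            frames = frames + rng_noise.normal(0.0, spec.noise_sigma, frames.shape)
        trajectories.append(
            Trajectory(template, frames, replicate=f"run{r + 1}",
                       frame_interval=spec.frame_interval)
        )
    truth = TrajectoryGroundTruth(
        spec=spec, hidden_states=hidden, drawn_distances=drawn, stationary=pi
    )
    return trajectories, truth


# ---------------------------------------------------------------------------
# toy structures


def two_atom_structure(distance: float = 5.0) -> Structure:
    """Two single-atom residues ``distance`` A apart (distance-mode tests)."""
    atoms = [
        AtomRecord(1, "OE1", "", "GLU", "A", 1, 0.0, 0.0, 0.0, element="O"),
        AtomRecord(2, "NE1", "", "TRP", "A", 2, distance, 0.0, 0.0, element="N"),
    ]
    return Structure(atoms, title="two-atom toy")


def born_ion_structure(radius: float = 2.0) -> tuple[Structure, float]:
    """A single centered ion; returns the structure and its cavity radius."""
    s = Structure(
        [AtomRecord(1, "NA", "", "ION", "A", 1, 0.0, 0.0, 0.0, element="NA", hetatm=True)],
        title="born ion",
    )
    return s, radius


def random_structure(seed: int, n_atoms: int = 10, box: float = 10.0) -> Structure:
    """Random coordinates in a box, one CA atom per residue (RMSD tests)."""
    rng = np.random.default_rng(seed)
    xyz = rng.uniform(-box / 2, box / 2, (n_atoms, 3))
    atoms = [
        AtomRecord(i + 1, "CA", "", "GLY", "A", i + 1,
                   float(p[0]), float(p[1]), float(p[2]), element="C")
        for i, p in enumerate(xyz)
    ]
    return Structure(atoms, title=f"random-{seed}")


def gen_toy_structure(kind: str, **kwargs) -> Structure:
    """Dispatcher over the toy-structure builders by kind name."""
    if kind == "pair":
        return two_atom_structure(**kwargs)
    if kind == "born":
        return born_ion_structure(**kwargs)[0]
    if kind == "random":
        return random_structure(**kwargs)
    raise ValueError(f"unknown toy-structure kind {kind!r}")
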