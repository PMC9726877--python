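"""Replicate MD-trajectory statistics: distances, conformer classes, RMSF.

The analyses mirror the five-replicate design of the heliorhodopsin MD study
(5 runs x 1000 frames at 0.15 ns): per-frame H-bond distances, the three-way
tryptophan in/out classification on the extracellular surface, the
closed/open classification of the intracellular [Glu230...Tyr92...Asn16]
gate, population tables pooled over replicates, and side-chain RMSF with
replicate means, standard deviations and dRMSF against a reference state.

Frames must be pre-imaged; all classification rules are distance-only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .structure import Selection, Structure, read_pdb_models, superpose_rmsd

__all__ = [
    "Trajectory",
    "DistanceSeries",
    "ConformerLabels",
    "PopulationTable",
    "RMSFTable",
    "TRP246_LABELS",
    "GATE_LABELS",
    "trajectory_from_pdb",
    "trajectory_from_xyz",
    "distance_series",
    "classify_trp246",
    "classify_gate",
    "populations",
    "rmsf",
    "rmsf_table",
]

#: Trp246 classification thresholds (A) on d(O_Gln26 - N_Trp246).
TRP_HBOND_CUT = 3.5
TRP_IN_OUT_CUT = 6.0
TRP246_LABELS = ("in_hb", "in_nohb", "out")

#: Gate classification threshold (A) applied to both H-bond distances.
GATE_CUT = 3.5
GATE_LABELS = ("closed", "open", "mixed")

#: Default sampling interval between stored frames, ns.
FRAME_INTERVAL_NS = 0.15


@dataclass
class Trajectory:
    """Coordinate frames sharing one atom roster (the template structure)."""

    template: Structure
    frames: np.ndarray  # (n_frames, n_atoms, 3)
    replicate: str = "run1"
    frame_interval: float = FRAME_INTERVAL_NS

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1:] != (len(self.template), 3):
            raise ValueError(
                f"frames shape {self.frames.shape} does not match "
                f"{len(self.template)} roster atoms"
            )
        if self.frames.shape[0] < 1:
            raise ValueError("a trajectory needs at least one frame")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    def atom_index(self, address: tuple[str, int, str]) -> int:
        chain, resid, name = address
        for i, a in enumerate(self.template.atoms):
            if a.chain == chain and a.resid == resid and a.name == name:
                return i
        raise ValueError(f"atom {chain}/{resid}/{name} not in the trajectory roster")

    def indices(self, sel: Selection) -> np.ndarray:
        idx = [i for i, a in enumerate(self.template.atoms) if sel._match(a)]
        if not idx:
            raise ValueError(f"selection {sel} matches no roster atoms")
        return np.array(idx, dtype=int)


def trajectory_from_pdb(text: str, replicate: str = "run1",
                        frame_interval: float = FRAME_INTERVAL_NS) -> Trajectory:
    """Build a trajectory from multi-model PDB text (all models one roster)."""
    models = read_pdb_models(text)
    template = models[0]
    roster = [(a.chain, a.resid, a.name) for a in template.atoms]
    for m in models[1:]:
        if [(a.chain, a.resid, a.name) for a in m.atoms] != roster:
            raise ValueError("MODEL blocks do not share one atom roster")
    frames = np.stack([m.coords for m in models])
    return Trajectory(template, frames, replicate, frame_interval)


def trajectory_from_xyz(xyz_text: str, roster: Structure, replicate: str = "run1",
                        frame_interval: float = FRAME_INTERVAL_NS) -> Trajectory:
    """Plain multi-frame XYZ plus a roster structure naming the atoms.

    Each XYZ frame: count line, comment line, then `element x y z` rows in
    roster order.
    """
    lines = xyz_text.splitlines()
    frames = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].split()[0])
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise ValueError(f"truncated XYZ frame at line {i + 1}")
        coords = np.array([[float(v) for v in ln.split()[1:4]] for ln in block])
        frames.append(coords)
        i += 2 + n
    if not frames:
        raise ValueError("no XYZ frames found")
    return Trajectory(roster, np.stack(frames), replicate, frame_interval)


@dataclass
class DistanceSeries:
    """Per-frame distance (A) for one named atom pair."""

    values: np.ndarray
    pair: str
    replicate: str = "run1"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values <= 0):
            raise ValueError("distances must be positive")

    def __len__(self) -> int:
        return len(self.values)


def distance_series(
    t: Trajectory, a: tuple[str, int, str], b: tuple[str, int, str]
) -> DistanceSeries:
    """Euclidean distance between two roster atoms in every frame."""
    ia, ib = t.atom_index(a), t.atom_index(b)
    d = np.linalg.norm(t.frames[:, ia, :] - t.frames[:, ib, :], axis=1)
    return DistanceSeries(d, pair=f"{a[0]}/{a[1]}/{a[2]}-{b[0]}/{b[1]}/{b[2]}",
                          replicate=t.replicate)


@dataclass
class ConformerLabels:
    """One categorical conformer label per frame."""

    labels: np.ndarray  # array of str
    scheme: str  # 'trp246' | 'gate'
    replicate: str = "run1"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        allowed = TRP246_LABELS if self.scheme == "trp246" else GATE_LABELS
        bad = set(np.unique(self.labels)) - set(allowed)
        if bad:
            raise ValueError(f"labels {bad} not in scheme {self.scheme!r}")

    def __len__(self) -> int:
        return len(self.labels)


def classify_trp246(d: DistanceSeries) -> ConformerLabels:
    """Three-way tryptophan conformer classification.

    d < 3.5 A: 'in_hb' (Trp-in, H-bonded to the glutamine carbonyl);
    3.5 <= d <= 6.0 A: 'in_nohb' (Trp-in without the H-bond);
    d > 6.0 A: 'out' (side chain flipped toward the bulk).  The 3.5 A
    boundary itself belongs to 'in_nohb', 6.0 A to 'in_nohb'.
    """
    v = d.values
    labels = np.where(v < TRP_HBOND_CUT, "in_hb",
                      np.where(v <= TRP_IN_OUT_CUT, "in_nohb", "out"))
    return ConformerLabels(labels, scheme="trp246", replicate=d.replicate)


def classify_gate(d1: DistanceSeries, d2: DistanceSeries) -> ConformerLabels:
    """Intracellular-gate classification from the two H-bond distances.

    'closed' when both distances < 3.5 A, 'open' when both >= 3.5 A, and
    'mixed' otherwise (one H-bond kept, one lost — outside both pure
    classes, reported separately so they stay directly comparable).
    """
    if len(d1) != len(d2):
        raise ValueError("distance series lengths differ")
    if d1.replicate != d2.replicate:
        raise ValueError("distance series come from different replicates")
    both_closed = (d1.values < GATE_CUT) & (d2.values < GATE_CUT)
    both_open = (d1.values >= GATE_CUT) & (d2.values >= GATE_CUT)
    labels = np.where(both_closed, "closed", np.where(both_open, "open", "mixed"))
    return ConformerLabels(labels, scheme="gate", replicate=d1.replicate)


@dataclass
class PopulationTable:
    """Per-replicate and pooled conformer fractions (pooling weights every
    frame equally across replicates)."""

    fractions: pd.DataFrame  # index: replicate ids + 'pooled'; columns: labels
    counts: pd.DataFrame


def populations(label_sets: list[ConformerLabels]) -> PopulationTable:
    """Population fractions per replicate plus the frame-pooled row."""
    if not label_sets:
        raise ValueError("need at least one replicate of labels")
    scheme = label_sets[0].scheme
    if any(ls.scheme != scheme for ls in label_sets):
        raise ValueError("all label sets must share one scheme")
    cats = list(TRP246_LABELS if scheme == "trp246" else GATE_LABELS)
    rows = {}
    for ls in label_sets:
        rows[ls.replicate] = [int(np.sum(ls.labels == c)) for c in cats]
    counts = pd.DataFrame.from_dict(rows, orient="index", columns=cats)
    counts.loc["pooled"] = counts.sum(axis=0)
    fractions = counts.div(counts.sum(axis=1), axis=0)
    return PopulationTable(fractions=fractions, counts=counts)


# ---------------------------------------------------------------------------
# RMSF


def _align_frames(frames: np.ndarray, align_idx: np.ndarray,
                  reference: str = "mean", max_iter: int = 5) -> np.ndarray:
    """Superpose every frame onto a common reference over ``align_idx``.

    reference='mean': iterate fit-to-mean until the mean structure is stable;
    reference='first': single pass onto frame 0.
    """
    out = frames.copy()
    ref = out[0, align_idx]
    for it in range(max_iter if reference == "mean" else 1):
        for f in range(out.shape[0]):
            sup = superpose_rmsd(out[f, align_idx], ref)
            out[f] = sup.transform(out[f])
        if reference == "first":
            break
        new_ref = out[:, align_idx].mean(axis=0)
        if np.max(np.abs(new_ref - ref)) < 1e-10:
            break
        ref = new_ref
    return out


def rmsf(
    t: Trajectory,
    residues: list[tuple[str, int]] | None = None,
    align: Selection | None = Selection(names=frozenset({"CA"})),
    reference: str = "mean",
) -> pd.Series:
    """Per-residue side-chain RMSF (A) for one trajectory.

    Frames are first rigidly superposed over the ``align`` selection
    (backbone C-alpha by default; pass ``align=None`` to analyze raw
    coordinates).  Per-atom RMSF is the root-mean-square deviation from the
    time-mean position; a residue's value is the unweighted mean over its
    heavy side-chain atoms.  Residues with no side-chain heavy atoms are
    omitted from the result.
    """
    if t.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    frames = t.frames
    if align is not None:
        frames = _align_frames(frames, t.indices(align), reference=reference)
    mean = frames.mean(axis=0)
    per_atom = np.sqrt(np.mean(np.sum((frames - mean) ** 2, axis=2), axis=0))

    if residues is None:
        seen: dict[tuple[str, int], None] = {}
        for a in t.template.atoms:
            seen.setdefault((a.chain, a.resid))
        residues = list(seen)
    values, index = [], []
    for chain, resid in residues:
        idx = [
            i for i, a in enumerate(t.template.atoms)
            if a.chain == chain and a.resid == resid and a.is_sidechain
        ]
        if not idx:
            continue
        values.append(float(per_atom[idx].mean()))
        index.append(f"{chain}/{resid}")
    return pd.Series(values, index=index, name=t.replicate)


@dataclass
class RMSFTable:
    """Side-chain RMSF per residue and replicate, with across-run statistics."""

    per_replicate: pd.DataFrame  # index residue, one column per replicate
    mean: pd.Series
    sd: pd.Series

    def delta(self, reference: "RMSFTable") -> pd.Series:
        """dRMSF = mean(this state) - mean(reference state), per residue."""
        return (self.mean - reference.mean).rename("dRMSF")


def rmsf_table(
    trajectories: list[Trajectory],
    residues: list[tuple[str, int]] | None = None,
    align: Selection | None = Selection(names=frozenset({"CA"})),
    reference: str = "mean",
) -> RMSFTable:
    """RMSF across replicate trajectories: per-run values, mean and SD."""
    if not trajectories:
        raise ValueError("need at least one trajectory")
    cols = [rmsf(t, residues=residues, align=align, reference=reference)
            for t in trajectories]
    per_rep = pd.concat(cols, axis=1)
    return RMSFTable(
        per_replicate=per_rep,
        mean=per_rep.mean(axis=1).rename("rmsf_mean"),
        sd=per_rep.std(axis=1, ddof=1).fillna(0.0).rename("rmsf_sd"),
    )
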