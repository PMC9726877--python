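"""Minimal PDB structure handling: parsing, selections, superposition, distances.

Covers exactly the dialect the pipeline touches (ATOM/HETATM/MODEL/ENDMDL/TER
records with alternate-location indicators), atom selections, Kabsch rigid
superposition and the distance measures used in the conformer analyses.
Columns 31-54 (coordinates) are parsed strictly; other fields tolerate the
short lines some generators emit.  Residue numbering is 1-based as in PDB.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "AtomRecord",
    "Structure",
    "Selection",
    "PDBParseError",
    "read_pdb",
    "read_pdb_models",
    "write_pdb",
    "resolve_altlocs",
    "superpose_rmsd",
    "pair_distance",
]

#: Backbone atom names; everything else heavy is "side-chain" here.
BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "OXT"})


class PDBParseError(ValueError):
    """Raised for malformed fixed-width PDB records; names the line number."""


@dataclass(frozen=True)
class AtomRecord:
    """One ATOM/HETATM record."""

    serial: int
    name: str
    altloc: str  # '' when blank
    resname: str
    chain: str
    resid: int
    x: float
    y: float
    z: float
    occupancy: float = 1.0
    element: str = ""
    hetatm: bool = False

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @property
    def is_hydrogen(self) -> bool:
        el = self.element or self.name.lstrip("0123456789")[:1]
        return el.upper() == "H"

    @property
    def is_sidechain(self) -> bool:
        return self.name not in BACKBONE_NAMES and not self.is_hydrogen


@dataclass
class Structure:
    """An ordered collection of atoms (one model)."""

    atoms: list[AtomRecord]
    title: str = ""

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("a Structure needs at least one atom")
        keys = [(a.chain, a.resid, a.name, a.altloc) for a in self.atoms]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ValueError(f"duplicate atom addresses: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in A."""
        return np.array([[a.x, a.y, a.z] for a in self.atoms], dtype=float)

    def with_coords(self, xyz: np.ndarray) -> "Structure":
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (len(self.atoms), 3):
            raise ValueError(f"coordinate shape {xyz.shape} does not match atom count")
        atoms = [
            replace(a, x=float(p[0]), y=float(p[1]), z=float(p[2]))
            for a, p in zip(self.atoms, xyz)
        ]
        return Structure(atoms, title=self.title)

    def select(self, sel: "Selection") -> "Structure":
        picked = sel.apply(self.atoms)
        if not picked:
            raise ValueError(f"selection {sel} matches no atoms")
        return Structure(picked, title=self.title)


@dataclass(frozen=True)
class Selection:
    """Predicate over atoms; applying it preserves the input order.

    ``altloc`` policy: 'collapse' keeps blank-altloc atoms plus, per
    (chain, resid, name), the preferred conformer — ``prefer`` if present,
    otherwise highest occupancy with the lowest serial breaking ties.
    'all' keeps every conformer.
    """

    chain: str | None = None
    resids: frozenset[int] | None = None
    names: frozenset[str] | None = None
    sidechain_only: bool = False
    heavy_only: bool = False
    altloc: str = "collapse"
    prefer: str = "A"

    def _match(self, a: AtomRecord) -> bool:
        if self.chain is not None and a.chain != self.chain:
            return False
        if self.resids is not None and a.resid not in self.resids:
            return False
        if self.names is not None and a.name not in self.names:
            return False
        if self.sidechain_only and not a.is_sidechain:
            return False
        if self.heavy_only and a.is_hydrogen:
            return False
        return True

    def apply(self, atoms: Sequence[AtomRecord]) -> list[AtomRecord]:
        picked = [a for a in atoms if self._match(a)]
        if self.altloc == "collapse":
            picked = resolve_altlocs(picked, prefer=self.prefer)
        elif self.altloc != "all":
            picked = [a for a in picked if a.altloc in ("", self.altloc)]
        return picked


def resolve_altlocs(atoms: Sequence[AtomRecord], prefer: str = "A") -> list[AtomRecord]:
    """Collapse alternate conformers to one atom per (chain, resid, name).

    Blank-altloc atoms pass through.  Within an altloc group the ``prefer``
    letter wins when present (the crystal-structure 'A'/'B' serine conformers
    are the use case); otherwise the highest occupancy, ties broken by the
    lower serial.
    """
    groups: dict[tuple[str, int, str], list[AtomRecord]] = {}
    order: list[tuple[str, int, str] | int] = []
    for a in atoms:
        if a.altloc == "":
            order.append(len(order))
            groups[len(order) - 1] = [a]  # type: ignore[index]
        else:
            key = (a.chain, a.resid, a.name)
            if key not in groups:
                order.append(key)
            groups.setdefault(key, []).append(a)  # type: ignore[arg-type]
    out: list[AtomRecord] = []
    for key in order:
        members = groups[key]  # type: ignore[index]
        preferred = [a for a in members if a.altloc == prefer]
        if preferred:
            out.append(preferred[0])
        else:
            out.append(max(members, key=lambda a: (a.occupancy, -a.serial)))
    return out


def _parse_atom_line(line: str, lineno: int) -> AtomRecord:
    def strict_float(lo: int, hi: int, what: str) -> float:
        fieldtxt = line[lo:hi]
        try:
            return float(fieldtxt)
        except ValueError:
            raise PDBParseError(
                f"line {lineno}: bad {what} field {fieldtxt!r} (columns {lo + 1}-{hi})"
            ) from None

    if len(line) < 54:
        raise PDBParseError(f"line {lineno}: record too short for coordinates")
    x = strict_float(30, 38, "x")
    y = strict_float(38, 46, "y")
    z = strict_float(46, 54, "z")
    try:
        serial = int(line[6:11])
    except ValueError:
        serial = 0
    name = line[12:16].strip()
    altloc = line[16:17].strip()
    resname = line[17:20].strip()
    chain = line[21:22].strip() or "A"
    try:
        resid = int(line[22:26])
    except ValueError:
        raise PDBParseError(f"line {lineno}: bad residue number {line[22:26]!r}") from None
    occ_txt = line[54:60].strip() if len(line) >= 60 else ""
    occupancy = float(occ_txt) if occ_txt else 1.0
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        element = name.lstrip("0123456789")[:1]
    return AtomRecord(
        serial=serial,
        name=name,
        altloc=altloc,
        resname=resname,
        chain=chain,
        resid=resid,
        x=x,
        y=y,
        z=z,
        occupancy=occupancy,
        element=element,
        hetatm=line.startswith("HETATM"),
    )


def read_pdb_models(text: str) -> list[Structure]:
    """Parse all MODEL blocks (or the single implicit model) from PDB text."""
    models: list[list[AtomRecord]] = []
    current: list[AtomRecord] = []
    title = ""
    in_model = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6]
        if rec in ("ATOM  ", "HETATM"):
            current.append(_parse_atom_line(line, lineno))
        elif rec == "MODEL ":
            if in_model and current:
                models.append(current)
                current = []
            in_model = True
        elif rec == "ENDMDL":
            models.append(current)
            current = []
            in_model = False
        elif line.startswith("TITLE"):
            title = (title + " " + line[10:].strip()).strip()
    if current:
        models.append(current)
    models = [m for m in models if m]
    if not models:
        raise PDBParseError("no ATOM/HETATM records found")
    return [Structure(m, title=title) for m in models]


def read_pdb(text: str) -> Structure:
    """Parse PDB text, returning the first model."""
    return read_pdb_models(text)[0]


def write_pdb(structures: Structure | Iterable[Structure]) -> str:
    """Serialize one or more models as PDB text (coordinates to 3 decimals)."""
    if isinstance(structures, Structure):
        models = [structures]
        multi = False
    else:
        models = list(structures)
        multi = len(models) > 1
    lines: list[str] = []
    if models and models[0].title:
        lines.append(f"TITLE     {models[0].title}")
    for i, s in enumerate(models, start=1):
        if multi:
            lines.append(f"MODEL     {i:4d}")
        for a in s.atoms:
            record = "HETATM" if a.hetatm else "ATOM  "
            name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
            lines.append(
                f"{record}{a.serial:5d} {name}{a.altloc or ' '}{a.resname:>3s} "
                f"{a.chain}{a.resid:4d}    {a.x:8.3f}{a.y:8.3f}{a.z:8.3f}"
                f"{a.occupancy:6.2f}{0.0:6.2f}          {a.element:>2s}"
            )
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray  # (3, 3) proper rotation, det = +1
    translation: np.ndarray  # (3,)
    rmsd: float  # A, after the fit

    def transform(self, xyz: np.ndarray) -> np.ndarray:
        return np.asarray(xyz, float) @ self.rotation.T + self.translation


def superpose_rmsd(
    mobile: Structure | np.ndarray,
    reference: Structure | np.ndarray,
    sel: Selection | None = None,
) -> SuperpositionResult:
    """Least-squares (Kabsch) rigid superposition of paired atoms.

    Atoms are paired in selection order; counts must match and be >= 3.
    The returned transform maps mobile coordinates onto the reference frame:
    x' = R x + t.  Reflections are never returned (proper rotation enforced).
    """
    if isinstance(mobile, Structure):
        mob = (mobile.select(sel) if sel else mobile).coords
    else:
        mob = np.asarray(mobile, dtype=float)
    if isinstance(reference, Structure):
        ref = (reference.select(sel) if sel else reference).coords
    else:
        ref = np.asarray(reference, dtype=float)
    if mob.shape != ref.shape:
        raise ValueError(
            f"selection counts differ: mobile has {mob.shape[0]}, reference {ref.shape[0]}"
        )
    n = mob.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 paired atoms, got {n}")
    cm, cr = mob.mean(axis=0), ref.mean(axis=0)
    rot, rssd = Rotation.align_vectors(ref - cr, mob - cm)
    rmat = rot.as_matrix()
    rmsd = float(rssd) / np.sqrt(n)
    translation = cr - rmat @ cm
    return SuperpositionResult(rotation=rmat, translation=translation, rmsd=rmsd)


def _resolve(s: Structure, address: tuple[str, int, str | None]) -> list[AtomRecord]:
    chain, resid, name = address
    sel = Selection(
        chain=chain,
        resids=frozenset({resid}),
        names=None if name is None else frozenset({name}),
    )
    atoms = sel.apply(s.atoms)
    if not atoms:
        raise ValueError(f"address {chain}/{resid}" + (f"/{name}" if name else "") + " resolves to no atom")
    return atoms


def pair_distance(
    s: Structure,
    a: tuple[str, int, str | None],
    b: tuple[str, int, str | None],
    mode: str = "min-heavy-sidechain",
) -> float:
    """Distance (A) between two addressed residues/atoms.

    Addresses are (chain, resid, atom_name-or-None).  Modes:

    - ``atom-atom``: distance between the two named atoms (first match each);
    - ``min-heavy-sidechain``: minimum over all heavy side-chain atom pairs;
    - ``centroid``: distance between the unweighted centroids of the matches.

    Symmetric in a and b for every mode.
    """
    atoms_a, atoms_b = _resolve(s, a), _resolve(s, b)
    if mode == "atom-atom":
        pa, pb = atoms_a[0].position, atoms_b[0].position
        return float(np.linalg.norm(pa - pb))
    if mode == "min-heavy-sidechain":
        ha = [x for x in atoms_a if x.is_sidechain]
        hb = [x for x in atoms_b if x.is_sidechain]
        if not ha or not hb:
            raise ValueError("no heavy side-chain atoms under one of the addresses")
        pa = np.array([x.position for x in ha])
        pb = np.array([x.position for x in hb])
        d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=-1)
        return float(d.min())
    if mode == "centroid":
        ca = np.mean([x.position for x in atoms_a], axis=0)
        cb = np.mean([x.position for x in atoms_b], axis=0)
        return float(np.linalg.norm(ca - cb))
    raise ValueError(f"unknown distance mode {mode!r}")
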