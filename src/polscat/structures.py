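"""Atomic structures: file I/O, preprocessing, fixtures and polarizability tables.

Structures are plain collections of atoms at fixed Cartesian coordinates in
Angstrom.  A molecule prepared for the interacting-dipole model is a
:class:`PolarizableSystem`: a structure plus one isotropic polarizability
volume (A^3) per atom, taken from a :class:`PolarizabilityTable`, and an
optional interaction threshold radius.

PDB files are read with gemmi; XYZ files with a small built-in reader.
Multi-model PDB files (MODEL/ENDMDL) yield one frame per model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .errors import ParseError, ValidationError

#: Minimum physically meaningful interatomic separation (A).  Anything closer
#: signals corrupt input and risks the polarization catastrophe even with
#: damping, so it is rejected outright.
MIN_SEPARATION = 0.1

# Two-letter elements recognised by the atom-name fallback.  'Ca' is
# deliberately absent: in protein atom names "CA" is the alpha carbon.
_TWO_LETTER_ELEMENTS = {
    "Cl", "Br", "Na", "Mg", "Zn", "Fe", "Mn", "Cu", "Se", "Si", "Al", "Ni",
}


def element_from_atom_name(name: str) -> str:
    """Infer a chemical element from a PDB atom name.

    Uses the conventional heuristic: strip leading digits, recognise a small
    set of unambiguous two-letter elements, otherwise take the first letter.
    """
    s = name.strip().lstrip("0123456789'*")
    if not s:
        raise ParseError(f"cannot infer element from atom name {name!r}")
    two = s[:2].capitalize()
    if two in _TWO_LETTER_ELEMENTS:
        return two
    return s[0].upper()


@dataclass(frozen=True)
class Atom:
    """A single atom: element symbol plus Cartesian position in Angstrom."""

    element: str
    position: tuple[float, float, float]
    record_kind: str = "generated"  # ATOM | HETATM | generated
    occupancy: float = 1.0
    alt_loc: str = ""
    name: str = ""
    residue: str = ""
    chain: str = ""
    res_seq: int = 0

    def __post_init__(self):
        if not self.element:
            raise ValidationError("atom element must be non-empty")
        if not all(math.isfinite(c) for c in self.position):
            raise ValidationError("atom position must be finite")


class AtomicStructure:
    """An ordered collection of atoms (one conformation / frame)."""

    def __init__(self, atoms: Sequence[Atom], frame_index: int = 0,
                 source: str = ""):
        atoms = list(atoms)
        if not atoms:
            raise ValidationError("no atoms")
        self.atoms = atoms
        self.frame_index = frame_index
        self.source = source
        self._positions: np.ndarray | None = None

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        """(N, 3) array of coordinates in Angstrom."""
        if self._positions is None:
            self._positions = np.array([a.position for a in self.atoms],
                                       dtype=float)
        return self._positions

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def with_positions(self, positions: np.ndarray,
                       frame_index: int | None = None,
                       source: str | None = None) -> "AtomicStructure":
        """Copy of this structure with new coordinates (same atoms/order)."""
        positions = np.asarray(positions, dtype=float)
        if positions.shape != (len(self.atoms), 3):
            raise ValidationError(
                f"positions shape {positions.shape} != ({len(self.atoms)}, 3)")
        atoms = [replace(a, position=tuple(p))
                 for a, p in zip(self.atoms, positions)]
        return AtomicStructure(
            atoms,
            frame_index=self.frame_index if frame_index is None else frame_index,
            source=self.source if source is None else source)

    def min_pair_distance(self) -> float:
        if len(self.atoms) < 2:
            return math.inf
        d, _ = cKDTree(self.positions).query(self.positions, k=2)
        return float(d[:, 1].min())

    def check_separations(self, min_dist: float = MIN_SEPARATION) -> None:
        """Raise if any two atoms are closer than ``min_dist`` (corrupt input)."""
        if len(self.atoms) >= 2:
            pairs = cKDTree(self.positions).query_pairs(min_dist)
            if pairs:
                i, j = sorted(next(iter(pairs)))
                raise ValidationError(
                    f"atoms {i} and {j} are closer than {min_dist} A: "
                    "corrupt structure (polarization catastrophe risk)")


# ---------------------------------------------------------------------------
# Polarizability table
# ---------------------------------------------------------------------------

#: Default isotropic atomic polarizability volumes (A^3) at 589.3 nm.
DEFAULT_ATOMIC_POLARIZABILITIES = {
    "H": 0.514,
    "C": 1.405,
    "N": 1.105,
    "O": 0.862,
    "S": 2.900,
    "P": 3.630,
}


@dataclass(frozen=True)
class PolarizabilityTable:
    """Mapping element -> polarizability volume (A^3)."""

    values: dict = field(
        default_factory=lambda: dict(DEFAULT_ATOMIC_POLARIZABILITIES))
    reference_wavelength_nm: float = 589.3

    def __post_init__(self):
        for el, a in self.values.items():
            if not a > 0:
                raise ValidationError(
                    f"polarizability for {el} must be positive, got {a}")

    def __getitem__(self, element: str) -> float:
        return self.values[element]

    def __contains__(self, element: str) -> bool:
        return element in self.values

    @classmethod
    def default(cls) -> "PolarizabilityTable":
        return cls()

    @classmethod
    def from_file(cls, path: str | Path) -> "PolarizabilityTable":
        """Two-column config (element  value_A3); overrides the defaults.

        Lines starting with '#' are comments; a line ``wavelength <nm>``
        sets the reference wavelength.
        """
        values = dict(DEFAULT_ATOMIC_POLARIZABILITIES)
        wavelength = 589.3
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip().replace(",", " ")
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ParseError(
                    f"{path}:{lineno}: expected 'element value', got {raw!r}")
            key, val = parts
            try:
                fval = float(val)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad number {val!r}") from exc
            if key.lower() in ("wavelength", "wavelength_nm", "lambda"):
                wavelength = fval
            else:
                values[key.capitalize() if len(key) > 1 else key.upper()] = fval
        return cls(values=values, reference_wavelength_nm=wavelength)


@dataclass
class PolarizableSystem:
    """Structure plus per-atom polarizability volumes and threshold radius.

    ``threshold_radius`` (A) sparsifies the dipole-dipole coupling: pairs
    farther apart than the threshold do not interact.  ``None`` means all
    pairs interact.
    """

    structure: AtomicStructure
    alpha: np.ndarray
    threshold_radius: float | None = None

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=float)
        if len(self.alpha) != self.structure.n_atoms:
            raise ValidationError("alpha length != number of atoms")
        if not np.all(self.alpha > 0):
            raise ValidationError("all polarizabilities must be positive")
        if self.threshold_radius is not None and not self.threshold_radius > 0:
            raise ValidationError("threshold radius must be positive")

    @property
    def n_atoms(self) -> int:
        return self.structure.n_atoms


def assign_polarizabilities(structure: AtomicStructure,
                            table: PolarizabilityTable | None = None,
                            strict: bool = True,
                            fallback: float | None = None,
                            threshold_radius: float | None = None,
                            ) -> PolarizableSystem:
    """Attach one polarizability volume per atom from an element table."""
    table = table or PolarizabilityTable.default()
    alpha = np.empty(structure.n_atoms)
    for i, el in enumerate(structure.elements):
        if el in table:
            alpha[i] = table[el]
        elif not strict and fallback is not None:
            alpha[i] = fallback
        else:
            raise ValidationError(
                f"no polarizability for {el} (atom {i})")
    return PolarizableSystem(structure, alpha, threshold_radius)


# ---------------------------------------------------------------------------
# File parsing
# ---------------------------------------------------------------------------

def _frames_from_pdb(path: Path) -> list[AtomicStructure]:
    import gemmi

    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse PDB file {path}: {exc}") from exc

    frames = []
    for imodel, model in enumerate(st):
        raw: list[Atom] = []
        for chain in model:
            for residue in chain:
                het = residue.het_flag == "H"
                for atom in residue:
                    el = atom.element.name
                    if not el or el == "X":
                        el = element_from_atom_name(atom.name)
                    raw.append(Atom(
                        element=el,
                        position=(atom.pos.x, atom.pos.y, atom.pos.z),
                        record_kind="HETATM" if het else "ATOM",
                        occupancy=atom.occ,
                        alt_loc=(atom.altloc or "").strip("\x00"),
                        name=atom.name,
                        residue=residue.name,
                        chain=chain.name,
                        res_seq=residue.seqid.num,
                    ))
        atoms = _collapse_alt_locs(raw)
        if atoms:
            frames.append(AtomicStructure(atoms, frame_index=imodel,
                                          source=str(path)))
    if not frames:
        raise ParseError(f"no atoms in {path}")
    return frames


def _collapse_alt_locs(atoms: list[Atom]) -> list[Atom]:
    """Keep one atom per alternate-location group.

    Highest occupancy wins; occupancy ties are broken by the alphabetically
    first alt-loc identifier (PDB convention).  File order is preserved.
    """
    best: dict[tuple, tuple[int, Atom]] = {}
    order: list[tuple] = []
    for idx, atom in enumerate(atoms):
        if not atom.alt_loc:
            key = ("", idx)  # unique: never collapses
        else:
            key = (atom.chain, atom.res_seq, atom.residue, atom.name)
        if key not in best:
            best[key] = (idx, atom)
            order.append(key)
        else:
            _, held = best[key]
            if (atom.occupancy, _altloc_rank(atom.alt_loc)) > \
                    (held.occupancy, _altloc_rank(held.alt_loc)):
                best[key] = (best[key][0], atom)
    return [best[key][1] for key in order]


def _altloc_rank(alt: str) -> float:
    # Higher rank wins; alphabetically earlier alt-loc must win ties.
    return -ord(alt) if alt else 0.0


def _frames_from_xyz(path: Path) -> list[AtomicStructure]:
    lines = Path(path).read_text().splitlines()
    frames = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].split()[0])
        except (ValueError, IndexError) as exc:
            raise ParseError(
                f"{path}:{i + 1}: expected atom count, got {lines[i]!r}"
            ) from exc
        if i + 1 + n >= len(lines) + 1 and n > 0:
            pass
        atoms = []
        for j in range(n):
            lineno = i + 2 + j
            if lineno >= len(lines):
                raise ParseError(f"{path}: truncated XYZ frame at line {lineno + 1}")
            parts = lines[lineno].split()
            if len(parts) < 4:
                raise ParseError(
                    f"{path}:{lineno + 1}: expected 'element x y z'")
            try:
                pos = tuple(float(v) for v in parts[1:4])
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno + 1}: bad coordinate") from exc
            atoms.append(Atom(element=parts[0].capitalize(), position=pos,
                              record_kind="generated"))
        if not atoms:
            raise ParseError(f"no atoms in {path}")
        frames.append(AtomicStructure(atoms, frame_index=len(frames),
                                      source=str(path)))
        i += 2 + n
    if not frames:
        raise ParseError(f"no atoms in {path}")
    return frames


def read_frames(path: str | Path, fmt: str = "auto") -> list[AtomicStructure]:
    """Read all frames from a PDB or XYZ file (always a list)."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"file not found: {path}")
    if fmt == "auto":
        suffix = path.suffix.lower()
        if suffix in (".pdb", ".ent"):
            fmt = "pdb"
        elif suffix == ".xyz":
            fmt = "xyz"
        else:
            head = path.read_text()[:4000]
            fmt = "pdb" if ("ATOM" in head or "HETATM" in head) else "xyz"
    if fmt == "pdb":
        return _frames_from_pdb(path)
    if fmt == "xyz":
        return _frames_from_xyz(path)
    raise ValidationError(f"unknown format {fmt!r}")


def parse_structure(path: str | Path, fmt: str = "auto"):
    """Read a structure file.

    Returns a single :class:`AtomicStructure` for single-frame input, or an
    ordered list of frames when the file holds several MODEL blocks / frames.
    """
    frames = read_frames(path, fmt)
    return frames[0] if len(frames) == 1 else frames


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def to_xyz(structure: AtomicStructure, comment: str = "") -> str:
    lines = [str(structure.n_atoms), comment or structure.source or "polscat"]
    for a in structure.atoms:
        x, y, z = a.position
        lines.append(f"{a.element:<2s} {x:14.6f} {y:14.6f} {z:14.6f}")
    return "\n".join(lines) + "\n"


def to_pdb(structure: AtomicStructure) -> str:
    lines = []
    for i, a in enumerate(structure.atoms, 1):
        record = "HETATM" if a.record_kind == "HETATM" else "ATOM  "
        name = a.name or a.element
        name_field = f" {name:<3s}" if len(name) < 4 else name[:4]
        x, y, z = a.position
        lines.append(
            f"{record}{i % 100000:5d} {name_field}{(a.alt_loc or ' ')[:1]}"
            f"{(a.residue or 'UNK')[:3]:>3s} {(a.chain or 'A')[:1]}"
            f"{a.res_seq % 10000:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}"
            f"          {a.element[:2]:>2s}")
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_structure(structure: AtomicStructure, path: str | Path,
                    fmt: str = "auto") -> None:
    path = Path(path)
    if fmt == "auto":
        fmt = "pdb" if path.suffix.lower() in (".pdb", ".ent") else "xyz"
    text = to_pdb(structure) if fmt == "pdb" else to_xyz(structure)
    path.write_text(text)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

#: Maximum C-H bond length (A) used by the united-atom hydrogen rule.
UNITED_ATOM_CH_CUTOFF = 1.2


def preprocess_structure(structure: AtomicStructure,
                         remove_hetero: bool = True,
                         united_atom: bool = True) -> AtomicStructure:
    """Strip hetero atoms and/or absorb aliphatic hydrogens.

    ``remove_hetero`` drops all HETATM records (waters, ions, ligands,
    crystallization agents).  ``united_atom`` deletes every hydrogen whose
    nearest heavy atom is a carbon within 1.2 A, emulating a united-atom
    representation in which aliphatic hydrogens are grouped with their parent
    carbon; hydrogens bound to N/O/S are retained.  Atom order is preserved
    and retained polarizabilities are unchanged.  Idempotent.
    """
    atoms = list(structure.atoms)
    if remove_hetero:
        atoms = [a for a in atoms if a.record_kind != "HETATM"]
        if not atoms:
            raise ValidationError("no atoms left after hetero-atom removal")
    if united_atom:
        heavy_idx = [i for i, a in enumerate(atoms) if a.element != "H"]
        h_idx = [i for i, a in enumerate(atoms) if a.element == "H"]
        if h_idx and heavy_idx:
            heavy_pos = np.array([atoms[i].position for i in heavy_idx])
            h_pos = np.array([atoms[i].position for i in h_idx])
            dist, nearest = cKDTree(heavy_pos).query(h_pos, k=1)
            drop = {
                h_idx[m] for m in range(len(h_idx))
                if dist[m] <= UNITED_ATOM_CH_CUTOFF
                and atoms[heavy_idx[int(nearest[m])]].element == "C"
            }
            atoms = [a for i, a in enumerate(atoms) if i not in drop]
    if not atoms:
        raise ValidationError("no atoms left after preprocessing")
    out = AtomicStructure(atoms, frame_index=structure.frame_index,
                          source=structure.source)
    out.check_separations()
    return out


# ---------------------------------------------------------------------------
# Fixture generators
# ---------------------------------------------------------------------------

def _carbons(positions: Iterable[Sequence[float]], source: str) -> AtomicStructure:
    return AtomicStructure(
        [Atom("C", tuple(map(float, p))) for p in positions], source=source)


def _check_spacing(value: float, name: str = "spacing") -> None:
    if not value > MIN_SEPARATION:
        raise ValidationError(f"{name} must exceed {MIN_SEPARATION} A, got {value}")


def carbon_cube(spacing: float = 2.0) -> AtomicStructure:
    """8 carbon atoms at the vertices of a cube of edge ``spacing`` (A)."""
    _check_spacing(spacing)
    verts = [(i * spacing, j * spacing, k * spacing)
             for i in (0, 1) for j in (0, 1) for k in (0, 1)]
    return _carbons(verts, f"carbon_cube(spacing={spacing})")


def carbon_line(n: int = 8, spacing: float = 2.0) -> AtomicStructure:
    """``n`` collinear carbon atoms along z at the given spacing (A)."""
    _check_spacing(spacing)
    if n < 1:
        raise ValidationError("n must be >= 1")
    return _carbons([(0.0, 0.0, i * spacing) for i in range(n)],
                    f"carbon_line(n={n}, spacing={spacing})")


def carbon_dimer(spacing: float = 2.0) -> AtomicStructure:
    """Two carbon atoms along z, ``spacing`` A apart."""
    _check_spacing(spacing)
    return _carbons([(0.0, 0.0, 0.0), (0.0, 0.0, spacing)],
                    f"carbon_dimer(spacing={spacing})")


def diamond(a: float = 3.567, n_cells: int = 2) -> AtomicStructure:
    """Cubic diamond-lattice carbon cluster.

    ``n_cells`` conventional cubic cells per edge, 8 atoms per cell, lattice
    constant ``a`` (A); minimum interatomic distance is a*sqrt(3)/4.
    """
    _check_spacing(a, "lattice constant")
    if n_cells < 1:
        raise ValidationError("n_cells must be >= 1")
    fcc = np.array([(0, 0, 0), (0, .5, .5), (.5, 0, .5), (.5, .5, 0)])
    basis = np.vstack([fcc, fcc + 0.25])
    cells = np.array([(i, j, k)
                      for i in range(n_cells)
                      for j in range(n_cells)
                      for k in range(n_cells)], dtype=float)
    pos = (cells[:, None, :] + basis[None, :, :]).reshape(-1, 3) * a
    return _carbons(pos, f"diamond(a={a}, n_cells={n_cells})")


def diamond_sphere(a: float = 3.567, radius: float = 18.6) -> AtomicStructure:
    """Spherical cubic-diamond carbon cluster of the given radius (A).

    Carved from a diamond lattice around its centre.  A sphere is the shape
    whose average polarizability inverts the Lorentz-Lorenz relation without
    a shape (depolarization) correction, so it is the natural cluster for
    estimating bulk refractive indices.
    """
    _check_spacing(a, "lattice constant")
    if not radius > 0:
        raise ValidationError("radius must be positive")
    n_cells = max(2, int(math.ceil(2.0 * radius / a)) + 1)
    lattice = diamond(a, n_cells)
    pos = lattice.positions
    center = pos.mean(axis=0)
    keep = np.linalg.norm(pos - center, axis=1) <= radius
    if not keep.any():
        raise ValidationError("radius too small: empty cluster")
    return _carbons(pos[keep], f"diamond_sphere(a={a}, radius={radius})")


def methane() -> AtomicStructure:
    """CH4, tetrahedral, r(C-H) = 1.091 A (standard gas-phase geometry)."""
    r = 1.091
    dirs = np.array([(1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)],
                    dtype=float) / math.sqrt(3)
    atoms = [Atom("C", (0.0, 0.0, 0.0))]
    atoms += [Atom("H", tuple(r * d)) for d in dirs]
    return AtomicStructure(atoms, source="methane")


def water() -> AtomicStructure:
    """H2O, r(O-H) = 0.9572 A, H-O-H angle 104.52 deg."""
    r, half = 0.9572, math.radians(104.52 / 2)
    atoms = [
        Atom("O", (0.0, 0.0, 0.0)),
        Atom("H", (r * math.sin(half), 0.0, r * math.cos(half))),
        Atom("H", (-r * math.sin(half), 0.0, r * math.cos(half))),
    ]
    return AtomicStructure(atoms, source="water")


def ethane() -> AtomicStructure:
    """C2H6, staggered D3d: r(C-C)=1.534 A, r(C-H)=1.091 A, H-C-H 109.5 deg."""
    rcc, rch = 1.534, 1.091
    # C-H polar angle from the outward C-C axis for tetrahedral H-C-H:
    cos_t = 1.0 / 3.0
    sin_t = math.sqrt(1 - cos_t ** 2)
    atoms = [Atom("C", (0.0, 0.0, rcc / 2)), Atom("C", (0.0, 0.0, -rcc / 2))]
    for phi_deg in (0, 120, 240):
        phi = math.radians(phi_deg)
        atoms.append(Atom("H", (rch * sin_t * math.cos(phi),
                                rch * sin_t * math.sin(phi),
                                rcc / 2 + rch * cos_t)))
    for phi_deg in (60, 180, 300):
        phi = math.radians(phi_deg)
        atoms.append(Atom("H", (rch * sin_t * math.cos(phi),
                                rch * sin_t * math.sin(phi),
                                -rcc / 2 - rch * cos_t)))
    return AtomicStructure(atoms, source="ethane")


def random_cluster(n: int = 100, box: float = 20.0, min_dist: float = 1.5,
                   seed: int | None = None) -> AtomicStructure:
    """``n`` carbon atoms uniformly placed in a cubic box with a minimum
    separation, via greedy rejection sampling.  Reproducible given ``seed``."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    _check_spacing(min_dist, "min_dist")
    if box <= 0:
        raise ValidationError("box must be positive")
    rng = np.random.default_rng(seed)
    accepted = np.empty((n, 3))
    count = 0
    attempts = 0
    max_attempts = 2000 * n
    while count < n:
        if attempts > max_attempts:
            raise ValidationError(
                f"cannot place {n} atoms with min_dist={min_dist} in box={box}")
        cand = rng.uniform(0.0, box, size=3)
        if count:
            d2 = np.sum((accepted[:count] - cand) ** 2, axis=1)
            if d2.min() < min_dist ** 2:
                attempts += 1
                continue
        accepted[count] = cand
        count += 1
        attempts += 1
    return _carbons(accepted, f"random_cluster(n={n}, box={box}, seed={seed})")


def thermal_frames(base: AtomicStructure, n_frames: int = 10,
                   noise_sigma: float = 0.1, rotate: bool = False,
                   seed: int | None = None) -> list[AtomicStructure]:
    """Synthetic thermally perturbed frames of a base structure.

    Each frame adds isotropic Gaussian displacement noise of standard
    deviation ``noise_sigma`` (A) per coordinate, optionally preceded by a
    uniformly random rigid rotation about the centroid (emulating free
    tumbling in solution).  Reproducible given ``seed``.
    """
    if n_frames < 1:
        raise ValidationError("n_frames must be >= 1")
    if noise_sigma < 0:
        raise ValidationError("noise_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    frames = []
    base_pos = base.positions
    centroid = base_pos.mean(axis=0)
    for i in range(n_frames):
        pos = base_pos.copy()
        if rotate:
            rot = Rotation.random(rng=rng).as_matrix()
            pos = (pos - centroid) @ rot.T + centroid
        if noise_sigma > 0:
            pos = pos + rng.normal(0.0, noise_sigma, size=pos.shape)
        frames.append(base.with_positions(
            pos, frame_index=i, source=f"{base.source}[thermal {i}]"))
    return frames


_FIXTURES = {
    "carbon_cube": carbon_cube,
    "carbon_line": carbon_line,
    "carbon_dimer": carbon_dimer,
    "diamond": diamond,
    "diamond_sphere": diamond_sphere,
    "methane": methane,
    "water": water,
    "ethane": ethane,
    "random_cluster": random_cluster,
}


def generate_fixture(kind: str, seed: int | None = None, **params):
    """Dispatch to a named fixture generator.

    ``thermal_frames`` requires a ``base`` structure in ``params`` and
    returns a list of frames; all other kinds return one structure.
    """
    if kind == "thermal_frames":
        return thermal_frames(seed=seed, **params)
    try:
        fn = _FIXTURES[kind]
    except KeyError:
        raise ValidationError(
            f"unknown fixture kind {kind!r}; choose from "
            f"{sorted(_FIXTURES) + ['thermal_frames']}") from None
    if kind == "random_cluster":
        return fn(seed=seed, **params)
    return fn(**params)
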