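"""Reading, validating and constructing 3D chemical structures.

Structures arrive as PDB files (one molecule per file, explicit hydrogens
preferred); an explicit adapter converts SDF via Open Babel. Each atom is
annotated with its periodic-table (period, group) position, the identity
encoding used by the views representation downstream.

A domain-of-applicability filter rejects structure classes the models are
not trusted on: perfluorinated chains longer than nine carbons,
chloroperfluoro compounds, and betaine-motif compounds.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
from scipy.spatial.distance import pdist, squareform

from .geometry import TETRAHEDRAL, backbone_substituent_dirs, _any_perp, methyl_positions, zigzag_backbone
from .periodic import bond_length, covalent_radius, periodic_position

log = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Molecule",
    "ParseError",
    "ConnectivityError",
    "read_pdb",
    "write_pdb",
    "sdf_to_pdb",
    "periodic_position",
    "domain_filter",
    "fixture_molecule",
    "FIXTURE_NAMES",
]

COORD_TOL = 1e-6  # two atoms closer than this are considered coincident


class ParseError(ValueError):
    """A structure file could not be parsed into a valid molecule."""


class ConnectivityError(ValueError):
    """Bond inference failed; the domain filter refuses to guess."""


@dataclass(frozen=True)
class Atom:
    """One atom: element identity plus 3D position in Angstrom."""

    element: str
    period: int
    group: int
    position: tuple[float, float, float]

    @classmethod
    def make(cls, element: str, position) -> "Atom":
        period, group = periodic_position(element)
        x, y, z = (float(v) for v in position)
        if not all(np.isfinite([x, y, z])):
            raise ParseError(f"non-finite coordinates for atom {element!r}")
        return cls(element=element, period=period, group=group, position=(x, y, z))


@dataclass
class Molecule:
    id: str
    atoms: list[Atom]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ParseError(f"molecule {self.id!r} has no atoms")
        coords = self.coords()
        if len(self.atoms) > 1 and pdist(coords).min() < COORD_TOL:
            raise ParseError(f"molecule {self.id!r} has coincident atoms")

    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def __len__(self) -> int:
        return len(self.atoms)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Molecule":
        """A copy with coordinates mapped through x -> R x + t."""
        new = self.coords() @ np.asarray(rotation).T + np.asarray(translation)
        atoms = [Atom.make(a.element, p) for a, p in zip(self.atoms, new)]
        return Molecule(id=self.id, atoms=atoms, provenance=self.provenance)


# ---------------------------------------------------------------------------
# PDB I/O


def _element_from_record(line: str) -> str:
    """Element from PDB columns 77-78, falling back to atom-name parsing."""
    elem = line[76:78].strip() if len(line) >= 78 else ""
    if elem:
        return elem[0].upper() + elem[1:].lower()
    name = line[12:16].strip()
    alpha = "".join(c for c in name if c.isalpha())
    if not alpha:
        raise ParseError(f"cannot resolve element from record: {line.rstrip()!r}")
    # two-letter symbols start in column 13 when the name is left-packed
    two = alpha[:2].capitalize()
    if len(alpha) >= 2 and not line[12].isspace() and two in {"Cl", "Br", "Si", "Se", "Na", "Mg", "Al", "Ca", "Zn", "Fe", "Cu", "Mn"}:
        return two
    return alpha[0].upper()


def read_pdb(path: str | Path, mol_id: str | None = None) -> Molecule:
    """Read one molecule from a PDB file, preserving atom order.

    Elements come from the element column (77-78); when that is blank the
    atom name is parsed instead. A file whose atoms all lack hydrogens is
    accepted with a warning.
    """
    path = Path(path)
    atoms: list[Atom] = []
    for line in path.read_text().splitlines():
        if not line.startswith(("ATOM", "HETATM")):
            continue
        try:
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
        except (ValueError, IndexError) as exc:
            raise ParseError(f"bad coordinates in record: {line.rstrip()!r}") from exc
        elem = _element_from_record(line)
        atoms.append(Atom.make(elem, (x, y, z)))
    if not atoms:
        raise ParseError(f"no ATOM/HETATM records in {path}")
    if not any(a.element == "H" for a in atoms):
        log.warning("%s contains no hydrogens; accepting heavy-atom-only structure", path.name)
    return Molecule(id=mol_id or path.stem, atoms=atoms, provenance=f"{path}:pdb")


def write_pdb(mol: Molecule, path: str | Path) -> None:
    """Write a minimal single-molecule PDB (HETATM records, element column)."""
    path = Path(path)
    lines = []
    counts: dict[str, int] = {}
    for i, a in enumerate(mol.atoms, start=1):
        counts[a.element] = counts.get(a.element, 0) + 1
        name = f"{a.element}{counts[a.element]}"[:4]
        x, y, z = a.position
        lines.append(
            f"HETATM{i:5d} {name:<4s} LIG A   1    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {a.element:>2s}"
        )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def sdf_to_pdb(sdf_path: str | Path, pdb_path: str | Path) -> Path:
    """Convert an SDF file to PDB via the Open Babel command-line tool.

    This adapter is always invoked explicitly; nothing in the package
    converts formats silently.
    """
    if shutil.which("obabel") is None:
        raise RuntimeError("Open Babel ('obabel') not found on PATH")
    sdf_path, pdb_path = Path(sdf_path), Path(pdb_path)
    proc = subprocess.run(
        ["obabel", str(sdf_path), "-O", str(pdb_path)],
        capture_output=True,
        text=True,
    )
    if proc.returncode != 0 or not pdb_path.exists():
        raise ParseError(f"obabel conversion failed: {proc.stderr.strip()}")
    return pdb_path


# ---------------------------------------------------------------------------
# Bond inference and the domain-of-applicability filter

BOND_SCALE = 1.2  # bonded iff distance < BOND_SCALE * (r_cov_i + r_cov_j)


def infer_bonds(mol: Molecule) -> nx.Graph:
    """Bond graph by the covalent-radius distance rule.

    Raises ConnectivityError when the graph is disconnected: a silent
    acceptance on garbled geometry would defeat the domain filter.
    """
    g = nx.Graph()
    g.add_nodes_from(range(len(mol)))
    if len(mol) == 1:
        return g
    coords = mol.coords()
    radii = np.array([covalent_radius(e) for e in mol.elements()])
    dmat = squareform(pdist(coords))
    cutoff = BOND_SCALE * (radii[:, None] + radii[None, :])
    ii, jj = np.nonzero((dmat < cutoff) & (dmat > 0))
    for i, j in zip(ii, jj):
        if i < j:
            g.add_edge(int(i), int(j))
    if not nx.is_connected(g):
        raise ConnectivityError(
            f"bond inference left molecule {mol.id!r} disconnected "
            f"({nx.number_connected_components(g)} fragments)"
        )
    return g


def _carbon_chain_diameter(g: nx.Graph, carbons: set[int]) -> int:
    """Longest path length (in atoms) through a set of carbons.

    Exact on acyclic carbon skeletons (double-BFS tree diameter per
    component); a lower bound otherwise, which is conservative for the
    long-chain rejection rule.
    """
    sub = g.subgraph(carbons)
    best = 0
    for comp in nx.connected_components(sub):
        cg = sub.subgraph(comp)
        start = next(iter(comp))
        far1 = max(nx.single_source_shortest_path_length(cg, start).items(), key=lambda kv: kv[1])[0]
        far2len = max(nx.single_source_shortest_path_length(cg, far1).values())
        best = max(best, far2len + 1)
    return best


def domain_filter(mol: Molecule) -> tuple[bool, str]:
    """Apply the domain-of-applicability rules.

    Returns (accepted, reason); the reason names the triggered rule for a
    rejection and is empty on acceptance.
    """
    g = infer_bonds(mol)
    elems = mol.elements()
    neighbors = {i: [elems[j] for j in g.neighbors(i)] for i in g.nodes}

    # perfluorinated carbons: bear fluorine, bear no hydrogen
    pf_carbons = {
        i
        for i, e in enumerate(elems)
        if e == "C" and "F" in neighbors[i] and "H" not in neighbors[i]
    }
    if pf_carbons:
        chain = _carbon_chain_diameter(g, pf_carbons)
        if chain > 9:
            return False, "perfluorinated chain length > 9"
        has_ccl = any(
            elems[i] == "Cl" and any(elems[j] == "C" for j in g.neighbors(i))
            for i in g.nodes
        )
        if has_ccl:
            return False, "chloroperfluoro compound"

    # betaine motif: quaternary nitrogen + carboxylate carbon in one molecule
    quat_n = any(
        e == "N" and sum(1 for n in neighbors[i] if n != "H") >= 4
        for i, e in enumerate(elems)
    )
    carboxylate = any(
        e == "C"
        and sum(1 for j in g.neighbors(i) if elems[j] == "O" and g.degree[j] == 1) >= 2
        for i, e in enumerate(elems)
    )
    if quat_n and carboxylate:
        return False, "betaine functional group"

    return True, ""


# ---------------------------------------------------------------------------
# Fixture catalogue (idealized geometry, exact symmetry ties)


def _methane() -> list[Atom]:
    atoms = [Atom.make("C", (0.0, 0.0, 0.0))]
    for d in TETRAHEDRAL:
        atoms.append(Atom.make("H", 1.09 * d))
    return atoms


def _methanol(heavy_only: bool = False) -> list[Atom]:
    c = np.zeros(3)
    o = 1.43 * TETRAHEDRAL[0]
    atoms = [Atom.make("C", c), Atom.make("O", o)]
    if heavy_only:
        return atoms
    for d in TETRAHEDRAL[1:]:
        atoms.append(Atom.make("H", 1.09 * d))
    h_o = methyl_positions(o, c - o, 0.96)[0]
    atoms.append(Atom.make("H", h_o))
    return atoms


def _co2() -> list[Atom]:
    return [
        Atom.make("C", (0.0, 0.0, 0.0)),
        Atom.make("O", (1.16, 0.0, 0.0)),
        Atom.make("O", (-1.16, 0.0, 0.0)),
    ]


def _methyl_isothiocyanate(heavy_only: bool = False) -> list[Atom]:
    c1 = np.zeros(3)
    n = 1.47 * TETRAHEDRAL[0]
    u = TETRAHEDRAL[0]
    p = _any_perp(u)
    bend = np.deg2rad(38.0)  # C-N=C angle of ~142 degrees
    d_nc = np.cos(bend) * u + np.sin(bend) * p
    c2 = n + 1.22 * d_nc
    s = c2 + 1.56 * d_nc  # N=C=S linear
    atoms = [Atom.make("C", c1)]
    if not heavy_only:
        for d in TETRAHEDRAL[1:]:
            atoms.append(Atom.make("H", 1.09 * d))
    atoms += [Atom.make("N", n), Atom.make("C", c2), Atom.make("S", s)]
    return atoms


def _perfluorodecane() -> list[Atom]:
    n = 10
    elems = ["C"] * n
    backbone = zigzag_backbone(elems)
    atoms = [Atom.make("C", backbone[i]) for i in range(n)]
    for i in range(n):
        for d in backbone_substituent_dirs(i, n):
            atoms.append(Atom.make("F", backbone[i] + 1.35 * d))
    return atoms


def _glycine_betaine() -> list[Atom]:
    n_pos = np.zeros(3)
    atoms = [Atom.make("N", n_pos)]
    # three N-methyls
    for d in TETRAHEDRAL[1:]:
        c = 1.47 * d
        atoms.append(Atom.make("C", c))
        for h in methyl_positions(c, n_pos - c, 1.09):
            atoms.append(Atom.make("H", h))
    # CH2-COO(-) arm
    c4 = 1.47 * TETRAHEDRAL[0]
    atoms.append(Atom.make("C", c4))
    tripod = methyl_positions(c4, n_pos - c4, 1.0) - c4  # unit-ish dirs
    d5 = tripod[0] / np.linalg.norm(tripod[0])
    c5 = c4 + 1.54 * d5
    for hdir in tripod[1:]:
        atoms.append(Atom.make("H", c4 + 1.09 * hdir / np.linalg.norm(hdir)))
    atoms.append(Atom.make("C", c5))
    u5 = d5
    p5 = _any_perp(u5)
    for sign in (+1.0, -1.0):
        od = np.cos(np.deg2rad(120.0)) * (-u5) + sign * np.sin(np.deg2rad(120.0)) * p5
        atoms.append(Atom.make("O", c5 + 1.25 * od))
    return atoms


def _chain(element: str, n: int) -> list[Atom]:
    coords = zigzag_backbone([element] * n)
    return [Atom.make(element, c) for c in coords]


_FIXED = {
    "methane": _methane,
    "methanol": _methanol,
    "methanol_heavy": lambda: _methanol(heavy_only=True),
    "co2": _co2,
    "methyl_isothiocyanate": _methyl_isothiocyanate,
    "methyl_isothiocyanate_heavy": lambda: _methyl_isothiocyanate(heavy_only=True),
    "perfluorodecane": _perfluorodecane,
    "glycine_betaine": _glycine_betaine,
}

FIXTURE_NAMES = tuple(_FIXED) + ("chain_C<n> (e.g. chain_C5)",)


def fixture_molecule(name: str) -> Molecule:
    """A bundled idealized-geometry molecule by name.

    Linear carbon chains are available as ``chain_C<n>``. Unknown names
    raise with the catalogue listed.
    """
    if name in _FIXED:
        return Molecule(id=name, atoms=_FIXED[name](), provenance="fixture")
    if name.startswith("chain_C"):
        try:
            n = int(name.removeprefix("chain_C"))
        except ValueError:
            n = 0
        if n >= 1:
            return Molecule(id=name, atoms=_chain("C", n), provenance="fixture")
    raise KeyError(f"unknown fixture {name!r}; catalogue: {', '.join(FIXTURE_NAMES)}")
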