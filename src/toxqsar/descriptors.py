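"""Geometric descriptor formulas and descriptor-matrix pre-selection.

Two bond-based descriptors are computed from 3-D structures:

* gravitation index over bonded atom pairs, G² = Σ_(i>j over bonds)
  m_i·m_j / r_ij² (atomic masses in amu, distances in Å);
* maximum nucleus–nucleus repulsion for a bond type, e.g.
  Enn(C–H) = max over C–H bonds of Z_C·Z_H / R_CH (bare nuclear charges,
  distance in Å; no physical constants applied).

Pre-selection reproduces the screening applied before stepwise model
building: constant columns are removed, optionally columns with negligible
response correlation, and of any descriptor pair correlated at or above the
intercorrelation bound (default 0.8) only the member better correlated with
the response is retained (greedy, descending |corr with y|).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DegenerateGeometryError, NotApplicableError

__all__ = [
    "Atom",
    "Molecule3D",
    "gravitation_index",
    "max_nn_repulsion",
    "preselect",
    "molecule_from_xyz_bonds",
    "molecule_from_molblock",
]

# average atomic masses (amu) and nuclear charges for elements common in
# substituted aromatics; other elements can be supplied explicitly on Atom
_ELEMENTS: dict[str, tuple[float, int]] = {
    "H": (1.008, 1),
    "B": (10.81, 5),
    "C": (12.011, 6),
    "N": (14.007, 7),
    "O": (15.999, 8),
    "F": (18.998, 9),
    "P": (30.974, 15),
    "S": (32.06, 16),
    "Cl": (35.45, 17),
    "Br": (79.904, 35),
    "I": (126.904, 53),
}


@dataclass
class Atom:
    """One atom: element symbol, mass (amu), nuclear charge, coordinates (Å)."""

    element: str
    xyz: tuple[float, float, float]
    mass: float | None = None
    charge: int | None = None

    def __post_init__(self) -> None:
        if self.mass is None or self.charge is None:
            try:
                mass, charge = _ELEMENTS[self.element]
            except KeyError:
                raise ValueError(
                    f"no built-in mass/charge for element {self.element!r}; "
                    "supply them explicitly"
                ) from None
            self.mass = self.mass if self.mass is not None else mass
            self.charge = self.charge if self.charge is not None else charge
        self.xyz = tuple(float(v) for v in self.xyz)


@dataclass
class Molecule3D:
    """Atoms plus a bond list (pairs of 0-based atom indices)."""

    atoms: list[Atom]
    bonds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise ValueError(f"invalid bond ({i}, {j}) for {n} atoms")

    def bond_length(self, i: int, j: int) -> float:
        a = np.asarray(self.atoms[i].xyz)
        b = np.asarray(self.atoms[j].xyz)
        return float(np.linalg.norm(a - b))


def gravitation_index(mol: Molecule3D) -> float:
    """Gravitation index over bonded pairs: Σ m_i·m_j / r_ij² (amu²/Å²)."""
    total = 0.0
    for i, j in mol.bonds:
        r = mol.bond_length(i, j)
        if r == 0.0:
            raise DegenerateGeometryError(
                f"bonded atoms {i} and {j} coincide (zero distance)"
            )
        total += mol.atoms[i].mass * mol.atoms[j].mass / r**2
    return total


def max_nn_repulsion(mol: Molecule3D, pair: tuple[str, str]) -> float:
    """Maximum nucleus–nucleus repulsion Z_a·Z_b / R_ab over bonds of a type.

    ``pair`` is an element pair such as ("C", "H"); matching is orderless.
    Raises :class:`NotApplicableError` when the molecule has no such bond —
    the caller decides the fill policy for the descriptor column.
    """
    wanted = frozenset(pair)
    if len(pair) != 2:
        raise ValueError("pair must name exactly two elements")
    best = None
    for i, j in mol.bonds:
        if frozenset((mol.atoms[i].element, mol.atoms[j].element)) != wanted:
            continue
        r = mol.bond_length(i, j)
        if r == 0.0:
            raise DegenerateGeometryError(
                f"bonded atoms {i} and {j} coincide (zero distance)"
            )
        value = mol.atoms[i].charge * mol.atoms[j].charge / r
        if best is None or value > best:
            best = value
    if best is None:
        raise NotApplicableError(f"molecule has no {pair[0]}–{pair[1]} bond")
    return float(best)


def preselect(
    matrix: pd.DataFrame,
    y,
    r_max: float = 0.8,
    *,
    min_abs_corr_y: float = 0.0,
) -> pd.DataFrame:
    """Screen a descriptor matrix before stepwise model building.

    Removes constant columns and columns with |corr(column, y)| below
    ``min_abs_corr_y`` (disabled by default), then greedily keeps
    descriptors in order of descending |corr with y|, dropping any later
    column whose absolute correlation with an already-accepted column is
    ``>= r_max``. The result is idempotent and its maximum pairwise |r| is
    strictly below ``r_max``.
    """
    if not 0.0 < r_max <= 1.0:
        raise ValueError(f"r_max must be in (0, 1], got {r_max}")
    if not isinstance(matrix, pd.DataFrame):
        matrix = pd.DataFrame(np.asarray(matrix, dtype=float))
    if len(matrix) == 0:
        raise ValueError("descriptor matrix has no rows")
    y = np.asarray(y, dtype=float)
    if len(matrix) != len(y):
        raise ValueError("matrix rows must align with y")
    if len(set(matrix.columns)) != len(matrix.columns):
        raise ValueError("descriptor names must be unique")

    values = matrix.to_numpy(dtype=float)
    variable = values.std(axis=0) > 0
    names = [c for c, keep in zip(matrix.columns, variable) if keep]
    values = values[:, variable]
    if values.shape[1] == 0:
        return matrix[names]

    if y.std() == 0:
        corr_y = np.zeros(values.shape[1])
    else:
        yc = (y - y.mean()) / y.std()
        vc = (values - values.mean(axis=0)) / values.std(axis=0)
        corr_y = np.abs(vc.T @ yc) / len(y)

    keep_floor = corr_y >= min_abs_corr_y
    names = [c for c, keep in zip(names, keep_floor) if keep]
    values = values[:, keep_floor]
    corr_y = corr_y[keep_floor]
    if values.shape[1] == 0:
        return matrix[names]

    inter = np.abs(np.corrcoef(values, rowvar=False))
    if inter.ndim == 0:
        inter = np.array([[1.0]])

    # stable order: descending |corr with y|, original column order on ties
    order = sorted(range(len(names)), key=lambda j: (-corr_y[j], j))
    accepted: list[int] = []
    for j in order:
        if all(inter[j, a] < r_max for a in accepted):
            accepted.append(j)
    kept = [names[j] for j in sorted(accepted)]
    return matrix[kept]


# --- structure input -------------------------------------------------------

def molecule_from_xyz_bonds(text: str) -> Molecule3D:
    """Parse a plain-text atom/bond table.

    Format: one atom per line as ``element x y z``; after a line reading
    ``bonds``, one bond per line as two 1-based atom indices. Blank lines
    and ``#`` comments are ignored.
    """
    atoms: list[Atom] = []
    bonds: list[tuple[int, int]] = []
    in_bonds = False
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.lower() == "bonds":
            in_bonds = True
            continue
        parts = line.split()
        if in_bonds:
            if len(parts) < 2:
                raise ValueError(f"bond line needs two indices: {raw!r}")
            bonds.append((int(parts[0]) - 1, int(parts[1]) - 1))
        else:
            if len(parts) < 4:
                raise ValueError(f"atom line needs element and 3 coordinates: {raw!r}")
            atoms.append(Atom(parts[0], (float(parts[1]), float(parts[2]), float(parts[3]))))
    return Molecule3D(atoms, bonds)


def molecule_from_molblock(text: str) -> Molecule3D:
    """Build a molecule from a MOL/SDF V2000 block (requires rdkit)."""
    try:
        from rdkit import Chem
    except ImportError as exc:  # pragma: no cover - rdkit is an extra
        raise ImportError("rdkit is required to read MOL/SDF input") from exc
    mol = Chem.MolFromMolBlock(text, removeHs=False, sanitize=False)
    if mol is None:
        raise ValueError("could not parse MOL block")
    conf = mol.GetConformer()
    table = Chem.GetPeriodicTable()
    atoms = []
    for atom in mol.GetAtoms():
        pos = conf.GetAtomPosition(atom.GetIdx())
        atoms.append(
            Atom(
                element=atom.GetSymbol(),
                xyz=(pos.x, pos.y, pos.z),
                mass=table.GetAtomicWeight(atom.GetAtomicNum()),
                charge=atom.GetAtomicNum(),
            )
        )
    bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()]
    return Molecule3D(atoms, bonds)
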