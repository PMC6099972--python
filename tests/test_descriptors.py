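"""Bond-descriptor formulas and descriptor pre-selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from toxqsar import Atom, Molecule3D, gravitation_index, max_nn_repulsion, preselect
from toxqsar.descriptors import molecule_from_xyz_bonds
from toxqsar.exceptions import DegenerateGeometryError, NotApplicableError
from toxqsar.synthetic_data import SyntheticSpec, make_linear_dataset


def ch_bond(r=1.09, offset=0.0):
    return [
        Atom("C", (offset, 0.0, 0.0)),
        Atom("H", (offset + r, 0.0, 0.0)),
    ]


def test_gravitation_index_no_bonds_is_zero():
    mol = Molecule3D(ch_bond(), bonds=[])
    assert gravitation_index(mol) == 0.0


def test_gravitation_index_single_ch_bond():
    # 12.011 * 1.008 / 1.09² = 10.190...
    mol = Molecule3D(ch_bond(1.09), bonds=[(0, 1)])
    assert gravitation_index(mol) == pytest.approx(12.011 * 1.008 / 1.09**2)
    assert gravitation_index(mol) == pytest.approx(10.190, abs=1e-3)


def test_gravitation_index_additive_over_disjoint_bonds():
    atoms = ch_bond(1.09) + ch_bond(1.09, offset=10.0)
    mol = Molecule3D(atoms, bonds=[(0, 1), (2, 3)])
    single = gravitation_index(Molecule3D(ch_bond(1.09), bonds=[(0, 1)]))
    assert gravitation_index(mol) == pytest.approx(2 * single)


def test_gravitation_index_coincident_atoms_rejected():
    atoms = [Atom("C", (0, 0, 0)), Atom("H", (0, 0, 0))]
    with pytest.raises(DegenerateGeometryError):
        gravitation_index(Molecule3D(atoms, bonds=[(0, 1)]))


@settings(max_examples=25, deadline=None)
@given(scale=st.floats(min_value=0.1, max_value=10.0))
def test_gravitation_index_scales_inverse_square(scale):
    """Uniform coordinate scaling by s divides the index by s²."""
    atoms = [
        Atom("C", (0.0, 0.0, 0.0)),
        Atom("C", (1.4, 0.0, 0.0)),
        Atom("H", (1.9, 0.9, 0.0)),
    ]
    bonds = [(0, 1), (1, 2)]
    base = gravitation_index(Molecule3D(atoms, bonds))
    scaled_atoms = [
        Atom(a.element, tuple(scale * v for v in a.xyz)) for a in atoms
    ]
    scaled = gravitation_index(Molecule3D(scaled_atoms, bonds))
    assert scaled == pytest.approx(base / scale**2, rel=1e-9)


def test_max_nn_repulsion_ch_examples():
    mol = Molecule3D(ch_bond(1.0), bonds=[(0, 1)])
    assert max_nn_repulsion(mol, ("C", "H")) == pytest.approx(6.0)
    mol2 = Molecule3D(ch_bond(1.09), bonds=[(0, 1)])
    assert max_nn_repulsion(mol2, ("C", "H")) == pytest.approx(6 / 1.09)
    assert max_nn_repulsion(mol2, ("H", "C")) == pytest.approx(6 / 1.09)  # orderless


def test_max_nn_repulsion_picks_shorter_cc_bond():
    atoms = [
        Atom("C", (0.0, 0.0, 0.0)),
        Atom("C", (1.40, 0.0, 0.0)),
        Atom("C", (1.40 + 1.54, 0.0, 0.0)),
    ]
    mol = Molecule3D(atoms, bonds=[(0, 1), (1, 2)])
    assert max_nn_repulsion(mol, ("C", "C")) == pytest.approx(36 / 1.40)


def test_max_nn_repulsion_no_matching_bond():
    mol = Molecule3D(ch_bond(), bonds=[(0, 1)])
    with pytest.raises(NotApplicableError):
        max_nn_repulsion(mol, ("C", "C"))


def test_xyz_bond_parser_roundtrip():
    text = """
    # toluene fragment
    C 0.0 0.0 0.0
    H 1.09 0.0 0.0
    bonds
    1 2
    """
    mol = molecule_from_xyz_bonds(text)
    assert [a.element for a in mol.atoms] == ["C", "H"]
    assert mol.bonds == [(0, 1)]
    assert gravitation_index(mol) == pytest.approx(12.011 * 1.008 / 1.09**2)


# --- preselect -------------------------------------------------------------

def test_preselect_drops_constant_column(rng):
    y = rng.normal(size=30)
    m = pd.DataFrame({"const": np.ones(30), "x": rng.normal(size=30)})
    kept = preselect(m, y)
    assert list(kept.columns) == ["x"]


def test_preselect_keeps_one_of_identical_pair(rng):
    x = rng.normal(size=40)
    y = x + rng.normal(scale=0.5, size=40)
    m = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=40)})
    kept = preselect(m, y)
    assert sorted(kept.columns) in (["a", "c"], ["b", "c"])
    assert kept.shape[1] == 2


def test_preselect_prefers_response_correlated_member():
    """Of a highly collinear pair, the member better correlated with y wins."""
    rng = np.random.default_rng(42)
    n = 200
    y = rng.normal(size=n)
    good = y + rng.normal(scale=0.2, size=n)          # |corr with y| ≈ 0.9
    bad = 0.95 * good + rng.normal(scale=0.28, size=n)  # collinear with good
    noise = rng.normal(size=(n, 47))
    m = pd.DataFrame(noise, columns=[f"n{j}" for j in range(47)])
    m["good"], m["bad"] = good, bad
    # verify construction: the pair really is above the bound and asymmetric
    assert abs(np.corrcoef(good, bad)[0, 1]) > 0.8
    assert abs(np.corrcoef(good, y)[0, 1]) > abs(np.corrcoef(bad, y)[0, 1])
    kept = preselect(m, y, 0.8)
    assert "good" in kept.columns
    assert "bad" not in kept.columns


def test_preselect_output_has_bounded_intercorrelation(rng):
    spec = SyntheticSpec(n=50, p_noise=30, collinearity=0.85, seed=11)
    ds, _ = make_linear_dataset(spec)
    kept = preselect(ds.descriptors, ds.y, 0.8)
    corr = np.abs(np.corrcoef(kept.to_numpy(), rowvar=False))
    np.fill_diagonal(corr, 0.0)
    assert corr.max() < 0.8  # exhaustive pairwise scan


def test_preselect_is_idempotent(rng):
    spec = SyntheticSpec(n=50, p_noise=30, collinearity=0.85, seed=11)
    ds, _ = make_linear_dataset(spec)
    once = preselect(ds.descriptors, ds.y, 0.8)
    twice = preselect(once, ds.y, 0.8)
    assert list(once.columns) == list(twice.columns)


def test_preselect_empty_matrix_rejected():
    with pytest.raises(ValueError, match="no rows"):
        preselect(pd.DataFrame({"a": []}), np.array([]))
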