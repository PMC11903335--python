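"""Structural data model, transforms, and PDB/mmCIF ingestion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from multimeralign import (
    apply_transform,
    make_chain,
    make_complex_pair,
    random_fixture_spec,
    read_structure,
    write_pdb,
)
from multimeralign.structures import (
    ChainStructure,
    ComplexStructure,
    EmptyStructureError,
    RigidTransform,
)

# --- rigid transforms -------------------------------------------------------


def test_identity_transform_is_noop(rng):
    coords = rng.normal(size=(7, 3))
    out = apply_transform(RigidTransform.identity(), coords)
    np.testing.assert_allclose(out, coords, atol=1e-15)


def test_quarter_turn_about_z():
    rz90 = RigidTransform(
        np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]]), np.zeros(3)
    )
    out = apply_transform(rz90, np.array([[1.0, 0.0, 0.0]]))
    np.testing.assert_allclose(out, [[0.0, 1.0, 0.0]], atol=1e-12)


def test_compose_with_inverse_recovers_input(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    t = RigidTransform(rot, rng.uniform(-10, 10, 3))
    coords = rng.normal(scale=10, size=(25, 3))
    round_trip = t.compose(t.inverse()).apply(coords)
    np.testing.assert_allclose(round_trip, coords, atol=1e-9)


def test_reflection_rejected():
    with pytest.raises(ValueError):
        RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))
    with pytest.raises(ValueError):
        RigidTransform(np.eye(3) * 2.0, np.zeros(3))


@settings(derandomize=True, max_examples=25)
@given(st.integers(0, 2**31 - 1))
def test_transforms_preserve_pairwise_distances(seed):
    rng = np.random.default_rng(seed)
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    t = RigidTransform(rot, rng.uniform(-50, 50, 3))
    coords = rng.normal(scale=20, size=(12, 3))
    moved = t.apply(coords)
    d_before = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
    d_after = np.linalg.norm(moved[:, None] - moved[None, :], axis=2)
    np.testing.assert_allclose(d_after, d_before, atol=1e-9)


def test_as_vector12_layout():
    vec = RigidTransform.identity().as_vector12()
    np.testing.assert_array_equal(vec, [1, 0, 0, 0, 1, 0, 0, 0, 1, 0, 0, 0])


# --- data-model invariants --------------------------------------------------


def test_chain_rejects_mismatched_annotations():
    with pytest.raises(ValueError):
        ChainStructure("A", np.zeros((3, 3)), ["ALA"] * 2, [(1, ""), (2, ""), (3, "")])
    with pytest.raises(ValueError):
        ChainStructure("A", np.zeros((2, 3)), ["ALA"] * 2, [(1, ""), (1, "")])


def test_complex_rejects_duplicate_chain_ids():
    chain = ChainStructure("A", np.zeros((3, 3)), ["ALA"] * 3, [(i, "") for i in range(3)])
    with pytest.raises(ValueError):
        ComplexStructure("x", [chain, chain])


# --- file ingestion ---------------------------------------------------------


def test_pdb_roundtrip_preserves_geometry(tmp_path):
    spec = random_fixture_spec(5, n_chains=3, noise_sigma=0.0)
    complex_q, _, _, _ = make_complex_pair(spec)
    path = tmp_path / "q.pdb"
    write_pdb(complex_q, path)
    back = read_structure(path, format_hint="pdb")
    assert back.chain_ids == complex_q.chain_ids
    for orig, rt in zip(complex_q.chains, back.chains):
        assert len(orig) == len(rt)
        np.testing.assert_allclose(rt.ca_coords, orig.ca_coords, atol=1e-3)


def test_hetatm_only_chain_dropped(tmp_path):
    chain = make_chain(12, seed=3, chain_id="A")
    lines = []
    for i, ((x, y, z), name) in enumerate(zip(chain.ca_coords, chain.residue_names), 1):
        lines.append(
            f"ATOM  {i:5d}  CA  {name:>3s} A{i:4d}    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
    for j in range(3):  # chain B: only waters
        lines.append(
            f"HETATM{100+j:5d}  O   HOH B{j+1:4d}    {j*4.0:8.3f}{0.0:8.3f}{0.0:8.3f}  1.00  0.00           O"
        )
    lines.append("END")
    path = tmp_path / "mixed.pdb"
    path.write_text("\n".join(lines) + "\n")
    cx = read_structure(path)
    assert cx.chain_ids == ["A"]
    assert len(cx.chains[0]) == 12


def test_altloc_b_atoms_ignored(tmp_path):
    lines = [
        "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.50  0.00           C",
        "ATOM      2  CA BALA A   1       9.000   9.000   9.000  0.50  0.00           C",
        "ATOM      3  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C",
        "ATOM      4  CA  SER A   3       7.600   0.000   0.000  1.00  0.00           C",
        "END",
    ]
    path = tmp_path / "altloc.pdb"
    path.write_text("\n".join(lines) + "\n")
    cx = read_structure(path)
    assert len(cx.chains[0]) == 3
    np.testing.assert_allclose(cx.chains[0].ca_coords[0], [0.0, 0.0, 0.0], atol=1e-3)


def test_multimodel_uses_first_model_only(tmp_path):
    def model(num, shift):
        out = [f"MODEL     {num:4d}"]
        for i in range(4):
            x = i * 3.8 + shift
            out.append(
                f"ATOM  {i+1:5d}  CA  ALA A{i+1:4d}    {x:8.3f}{0.0:8.3f}{0.0:8.3f}  1.00  0.00           C"
            )
        out.append("ENDMDL")
        return out

    path = tmp_path / "nmr.pdb"
    path.write_text("\n".join(model(1, 0.0) + model(2, 50.0) + ["END"]) + "\n")
    cx = read_structure(path)
    assert len(cx.chains) == 1
    assert cx.chains[0].ca_coords[0][0] == pytest.approx(0.0, abs=1e-3)


def test_mmcif_reading(tmp_path):
    rows = []
    for i in range(5):
        rows.append(
            f"ATOM {i+1} C CA . ALA X 1 {i+1} ? {i*3.8:.3f} 0.000 0.000 1.00 0.00 A {i+1} 1"
        )
    cif = (
        "data_test\n"
        "loop_\n"
        "_atom_site.group_PDB\n_atom_site.id\n_atom_site.type_symbol\n"
        "_atom_site.label_atom_id\n_atom_site.label_alt_id\n_atom_site.label_comp_id\n"
        "_atom_site.label_asym_id\n_atom_site.label_entity_id\n_atom_site.label_seq_id\n"
        "_atom_site.pdbx_PDB_ins_code\n"
        "_atom_site.Cartn_x\n_atom_site.Cartn_y\n_atom_site.Cartn_z\n"
        "_atom_site.occupancy\n_atom_site.B_iso_or_equiv\n"
        "_atom_site.auth_asym_id\n_atom_site.auth_seq_id\n_atom_site.pdbx_PDB_model_num\n"
        + "\n".join(rows)
        + "\n"
    )
    path = tmp_path / "mini.cif"
    path.write_text(cif)
    cx = read_structure(path, format_hint="mmcif")
    assert cx.chain_ids == ["A"]
    assert len(cx.chains[0]) == 5


def test_short_chain_dropped_with_warning(tmp_path):
    lines = []
    chain = make_chain(10, seed=4, chain_id="A")
    for i, ((x, y, z), name) in enumerate(zip(chain.ca_coords, chain.residue_names), 1):
        lines.append(
            f"ATOM  {i:5d}  CA  {name:>3s} A{i:4d}    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
    lines.append(
        "ATOM     90  CA  ALA B   1       0.000   0.000   0.000  1.00  0.00           C"
    )
    lines.append("END")
    path = tmp_path / "short.pdb"
    path.write_text("\n".join(lines) + "\n")
    with pytest.warns(UserWarning, match="dropping chain"):
        cx = read_structure(path)
    assert cx.chain_ids == ["A"]


def test_no_protein_chain_raises(tmp_path):
    path = tmp_path / "waters.pdb"
    path.write_text(
        "HETATM    1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O\nEND\n"
    )
    with pytest.raises(EmptyStructureError):
        read_structure(path)
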