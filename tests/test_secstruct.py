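import numpy as np
import pytest

from structcd.secstruct import assign_ss, extract_elements
from structcd.synth import make_helix, make_sheet, write_pdb
from tests.conftest import (rigid_transform, rotation_matrix,
                            structure_from_fragments)


def _labels(structure, ss):
    return "".join(ss.labels[k] for k in structure.residue_keys())


def _mdtraj_labels(path):
    """Reference assignment, collapsed onto the H/E/G/other alphabet."""
    mdtraj = pytest.importorskip("mdtraj")
    traj = mdtraj.load(str(path))
    raw = mdtraj.compute_dssp(traj, simplified=False)[0]
    return "".join(c if c in "HEG" else "O" for c in raw)


def test_ideal_helix_interior_assigned_h(helix18):
    ss = assign_ss(helix18)
    labels = _labels(helix18, ss)
    assert labels[2:16].count("H") >= 12
    assert len(ss) == 18


def test_helix_agrees_with_reference_assigner(tmp_path, helix18):
    path = tmp_path / "helix.pdb"
    write_pdb(helix18, path)
    ref = _mdtraj_labels(path)
    mine = _labels(helix18, assign_ss(helix18))
    agreement = sum(a == b for a, b in zip(ref, mine)) / len(mine)
    assert agreement >= 0.9


def test_antiparallel_sheet_assigns_e(sheet_2x8):
    ss = assign_ss(sheet_2x8)
    assert ss.count("E") >= 8


def test_sheet_agrees_with_reference_assigner(tmp_path):
    # three 10-residue strands: large enough that strand interiors, not
    # edge conventions, dominate the comparison
    sheet = structure_from_fragments(make_sheet(3, 10), ["strand"] * 3)
    path = tmp_path / "sheet.pdb"
    write_pdb(sheet, path)
    ref = _mdtraj_labels(path)
    mine = _labels(sheet, assign_ss(sheet))
    agreement = sum(a == b for a, b in zip(ref, mine)) / len(mine)
    assert agreement >= 0.9


def test_header_method_maps_ranges(tmp_path, helix18):
    path = tmp_path / "h.pdb"
    write_pdb(helix18, path, ss_ranges=[("A", 2, 12, "helix")])
    ss = assign_ss(helix18, method="header", header_path=path)
    labels = _labels(helix18, ss)
    assert labels == "O" + "H" * 11 + "O" * 6


def test_header_method_310_becomes_g(tmp_path, helix18):
    path = tmp_path / "g.pdb"
    write_pdb(helix18, path, ss_ranges=[("A", 2, 5, "helix310")])
    ss = assign_ss(helix18, method="header", header_path=path)
    assert _labels(helix18, ss)[1:5] == "GGGG"


def test_header_and_geometry_agree_on_ideal_fixture(tmp_path, helix18):
    path = tmp_path / "h.pdb"
    write_pdb(helix18, path, ss_ranges=[("A", 1, 18, "helix")])
    header = assign_ss(helix18, method="header", header_path=path)
    geom = assign_ss(helix18)
    agree = sum(header.labels[k] == geom.labels[k]
                for k in helix18.residue_keys())
    assert agree / 18 >= 0.75   # geometric ends lose their labels


def test_provided_labels_pass_through(helix18):
    provided = {k: "E" for k in helix18.residue_keys()}
    ss = assign_ss(helix18, method="provided", provided=provided)
    assert ss.count("E") == 18


def test_label_conservation(basis6):
    for entry in basis6:
        st = entry.structure
        assert len(assign_ss(st)) == st.n_residues


def test_extract_elements_thresholds(helix18):
    keys = helix18.residue_keys()
    all_o = assign_ss(helix18, method="provided",
                      provided={k: "O" for k in keys})
    assert extract_elements(helix18, all_o) == []

    labels = {k: "O" for k in keys}
    for k in keys[1:3]:
        labels[k] = "H"          # run of 2: below threshold
    for k in keys[5:12]:
        labels[k] = "H"          # run of 7: one element
    ss = assign_ss(helix18, method="provided", provided=labels)
    elements = extract_elements(helix18, ss)
    assert len(elements) == 1
    assert elements[0].n_res == 7


def test_g_runs_never_become_elements(helix18):
    labels = {k: "G" for k in helix18.residue_keys()}
    ss = assign_ss(helix18, method="provided", provided=labels)
    assert extract_elements(helix18, ss) == []


def test_helix_axis_recovered_within_5_degrees():
    axis = np.array([1.0, 2.0, 2.0]) / 3.0
    st = structure_from_fragments([make_helix(12, axis=axis)])
    elements = extract_elements(st, assign_ss(st))
    assert len(elements) == 1
    angle = np.degrees(np.arccos(abs(np.dot(elements[0].axis_dir, axis))))
    assert angle <= 5.0


def test_elements_rotate_with_the_structure(sheet_2x8):
    rot = rotation_matrix([1.0, 1.0, 0.0], 1.1)
    shift = np.array([5.0, -3.0, 8.0])
    moved = rigid_transform(sheet_2x8, rot, shift)
    e0 = extract_elements(sheet_2x8, assign_ss(sheet_2x8))
    e1 = extract_elements(moved, assign_ss(moved))
    assert len(e0) == len(e1) == 2
    for a, b in zip(e0, e1):
        np.testing.assert_allclose(rot @ a.axis_dir, b.axis_dir, atol=1e-6)
        np.testing.assert_allclose(rot @ a.axis_point + shift, b.axis_point,
                                   atol=1e-6)


def test_element_axis_oriented_n_to_c(helix18):
    elements = extract_elements(helix18, assign_ss(helix18))
    assert len(elements) == 1
    chain = helix18.chains[0]
    first = next(r for r in chain.residues
                 if r.seq_pos == elements[0].start_seq)
    last = next(r for r in chain.residues if r.seq_pos == elements[0].end_seq)
    assert np.dot(elements[0].axis_dir, last.ca - first.ca) > 0
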