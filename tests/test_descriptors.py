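import numpy as np
import pytest

from structcd.descriptors import (AboDescriptor, compute_abo, compute_top,
                                  pair_angle, pair_qualifies, segment_distance)
from structcd.secstruct import SSAssignment, SSElement, assign_ss, extract_elements
from tests.conftest import rigid_transform, rotation_matrix


def _assignment(labels):
    return SSAssignment({("A", i + 1): lab for i, lab in enumerate(labels)})


def _element(ss_type, start, direction, point, length=10.0, chain="A",
             start_seq=1):
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    point = np.asarray(point, dtype=float)
    half = 0.5 * length * direction
    return SSElement(ss_type=ss_type, chain_id=chain, start_seq=start_seq,
                     end_seq=start_seq + 9, axis_point=point,
                     axis_dir=direction, endpoints=(point - half, point + half))


@pytest.mark.parametrize("labels, expected", [
    ("H" * 10, (100.0, 0.0, 0.0)),
    ("HHHHEEEEOO", (40.0, 40.0, 20.0)),
    ("HHHHHGGGGG", (50.0, 0.0, 50.0)),     # 3-10 helix counts as other
])
def test_compute_abo(labels, expected):
    abo = compute_abo(_assignment(labels))
    assert (abo.alpha, abo.beta, abo.other) == pytest.approx(expected)


def test_abo_sums_to_100_and_rejects_empty():
    abo = compute_abo(_assignment("HEOGHEOGHE"))
    assert abo.alpha + abo.beta + abo.other == pytest.approx(100.0, abs=1e-6)
    with pytest.raises(ValueError):
        compute_abo(SSAssignment({}))


def test_abo_descriptor_validates_sum():
    with pytest.raises(ValueError):
        AboDescriptor(alpha=50.0, beta=30.0, other=30.0)


@pytest.mark.parametrize("offset, expected", [(10.0, True), (20.0, False),
                                              (13.0, True)])
def test_pair_qualifies_cutoff_inclusive(offset, expected):
    e1 = _element("helix", 1, (0, 0, 1), (0, 0, 0))
    e2 = _element("helix", 1, (0, 0, 1), (offset, 0, 0), start_seq=20)
    assert pair_qualifies(e1, e2) is expected


def test_segment_distance_matches_point_formula_for_parallel_segments():
    d = segment_distance(np.zeros(3), np.array([0.0, 0.0, 10.0]),
                         np.array([3.0, 4.0, 0.0]), np.array([3.0, 4.0, 10.0]))
    assert d == pytest.approx(5.0)


def test_segment_distance_skew_segments():
    # closest approach of the z-axis segment and a shifted x-axis segment
    d = segment_distance(np.array([0.0, 0.0, -5.0]), np.array([0.0, 0.0, 5.0]),
                         np.array([-5.0, 2.0, 7.0]), np.array([5.0, 2.0, 7.0]))
    assert d == pytest.approx(np.hypot(2.0, 2.0))


def test_pair_angle_parallel_and_antiparallel():
    e1 = _element("helix", 1, (0, 0, 1), (0, 0, 0))
    e2 = _element("helix", 1, (0, 0, 1), (8, 0, 0), start_seq=20)
    assert pair_angle(e1, e2) == pytest.approx(0.0)
    e3 = _element("helix", 1, (0, 0, -1), (8, 0, 0), start_seq=20)
    assert pair_angle(e1, e3) == pytest.approx(180.0)


def test_pair_angle_chirality_sign():
    # hand evaluation: d1=x, d2=y, theta=90; chirality = dot(z, m2-m1)
    e1 = _element("helix", 1, (1, 0, 0), (0, 0, 0))
    e2 = _element("helix", 1, (0, 1, 0), (0, 0, 1), start_seq=20)
    assert pair_angle(e1, e2) == pytest.approx(90.0)
    e3 = _element("helix", 1, (0, 1, 0), (0, 0, -1), start_seq=20)
    assert pair_angle(e1, e3) == pytest.approx(270.0)


def test_pair_angle_is_order_independent():
    rng = np.random.default_rng(5)
    for _ in range(50):
        d1, d2 = rng.normal(size=3), rng.normal(size=3)
        p1, p2 = rng.normal(size=3) * 5, rng.normal(size=3) * 5
        e1 = _element("helix", 1, d1, p1, start_seq=1)
        e2 = _element("strand", 1, d2, p2, start_seq=30)
        assert pair_angle(e1, e2) == pytest.approx(pair_angle(e2, e1))


def test_top_single_element_all_zero():
    e = _element("helix", 1, (0, 0, 1), (0, 0, 0))
    assert compute_top([e]).total == 0


def test_top_two_parallel_helices_single_count_in_aa_bin0():
    e1 = _element("helix", 1, (0, 0, 1), (0, 0, 0))
    e2 = _element("helix", 1, (0, 0, 1), (8, 0, 0), start_seq=20)
    top = compute_top([e1, e2])
    assert top.total == 1
    assert top.bins[0] == 1


def test_top_matches_brute_force_on_bundle(bundle4):
    elements = extract_elements(bundle4, assign_ss(bundle4))
    assert len(elements) == 4
    top = compute_top(elements)
    # independent double loop
    expected = np.zeros(36)
    for i in range(len(elements)):
        for j in range(i + 1, len(elements)):
            if pair_qualifies(elements[i], elements[j]):
                group = {("helix", "helix"): 0, ("strand", "strand"): 1}.get(
                    (elements[i].ss_type, elements[j].ss_type), 2)
                expected[group * 12
                         + int(pair_angle(elements[i], elements[j]) // 30) % 12] += 1
    np.testing.assert_array_equal(top.bins, expected)
    assert top.total == sum(
        pair_qualifies(elements[i], elements[j])
        for i in range(len(elements)) for j in range(i + 1, len(elements)))


def test_top_invariant_under_rigid_transform(bundle4):
    rot = rotation_matrix([0.3, -1.0, 0.5], 2.0)
    moved = rigid_transform(bundle4, rot, np.array([12.0, -7.0, 3.0]))
    top0 = compute_top(extract_elements(bundle4, assign_ss(bundle4)))
    top1 = compute_top(extract_elements(moved, assign_ss(moved)))
    np.testing.assert_array_equal(top0.bins, top1.bins)
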