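import numpy as np
import pytest

from structcd.descriptors import compute_abo, compute_top
from structcd.secstruct import assign_ss, extract_elements
from structcd.spectra import WavelengthGrid
from structcd.structure import parse_pdb
from structcd.synth import (SpectrumLaw, SynthSpec, build_architecture,
                            default_mixes, make_basis, make_coil, make_entry,
                            make_helix, make_sheet)
from tests.conftest import structure_from_fragments


def test_helix_geometry_ca_spacing():
    frag = make_helix(18)
    ca = np.array([r["CA"] for r in frag])
    d = np.linalg.norm(np.diff(ca, axis=0), axis=1)
    assert np.all(np.abs(d - 3.8) < 0.15)


def test_helix_assigns_h_and_recovers_axis():
    axis = np.array([0.0, 1.0, 1.0]) / np.sqrt(2.0)
    st = structure_from_fragments([make_helix(18, axis=axis)])
    ss = assign_ss(st)
    assert ss.count("H") >= 12
    elements = extract_elements(st, ss)
    assert len(elements) == 1
    angle = np.degrees(np.arccos(abs(np.dot(elements[0].axis_dir, axis))))
    assert angle <= 5.0


def test_helix_minimum_size():
    with pytest.raises(ValueError):
        make_helix(3)


def test_sheet_assigns_e_and_strand_axes_antiparallel(sheet_2x8):
    ss = assign_ss(sheet_2x8)
    assert ss.count("E") >= 8
    elements = extract_elements(sheet_2x8, ss)
    assert len(elements) == 2
    angle = np.degrees(np.arccos(np.clip(
        np.dot(elements[0].axis_dir, elements[1].axis_dir), -1, 1)))
    assert angle > 165.0                     # antiparallel within 15 degrees
    top = compute_top(elements)
    assert top.bins[12:24].sum() == 1        # one beta-beta pair within 13 A


def test_sheet_minimum_strands():
    with pytest.raises(ValueError):
        make_sheet(1, 8)


def test_coil_assigns_other():
    rng = np.random.default_rng(0)
    st = structure_from_fragments([make_coil(20, rng)])
    ss = assign_ss(st)
    assert ss.count("H", "E") <= 2


def test_build_architecture_hits_target_within_tolerance():
    rng = np.random.default_rng(1)
    for mix, arch in [((60, 0, 40), "helix_bundle"),
                      ((10, 45, 45), "beta_sandwich"),
                      ((35, 25, 40), "alpha_beta")]:
        st, ranges, achieved = build_architecture(*mix, arch, 140, rng)
        abo = compute_abo(assign_ss(st))
        assert abs(abo.alpha - mix[0]) <= 5.0
        assert abs(abo.beta - mix[1]) <= 5.0
        assert achieved[0] == pytest.approx(abo.alpha)


def test_build_architecture_rejects_impossible_mix():
    rng = np.random.default_rng(2)
    with pytest.raises(ValueError):
        build_architecture(0, 100, 0, "helix_bundle", 140, rng)


def test_make_entry_round_trips_and_is_deterministic(tmp_path):
    law = SpectrumLaw()
    pdb1, spec1 = make_entry((60.0, 0.0, 40.0), "helix_bundle",
                             tmp_path / "e1", law,
                             np.random.default_rng(5))
    st = parse_pdb(pdb1)
    abo = compute_abo(assign_ss(st))
    assert abs(abo.alpha - 60.0) <= 5.0
    pdb2, spec2 = make_entry((60.0, 0.0, 40.0), "helix_bundle",
                             tmp_path / "e2", law,
                             np.random.default_rng(5))
    assert pdb1.read_bytes() == pdb2.read_bytes()
    assert spec1.read_bytes() == spec2.read_bytes()


def test_spectrum_law_mixing_and_noise_determinism():
    law = SpectrumLaw()
    comp = law.components()
    s = law.spectrum(50.0, 30.0, 20.0)
    np.testing.assert_allclose(
        s.values, 0.5 * comp["H"] + 0.3 * comp["E"] + 0.2 * comp["O"])
    n1 = law.spectrum(50.0, 30.0, 20.0, noise_sd=0.5,
                      rng=np.random.default_rng(9))
    n2 = law.spectrum(50.0, 30.0, 20.0, noise_sd=0.5,
                      rng=np.random.default_rng(9))
    np.testing.assert_array_equal(n1.values, n2.values)
    with pytest.raises(ValueError):
        law.spectrum(50.0, 30.0, 30.0)


def test_spectrum_law_helix_signature():
    comp = SpectrumLaw().components()
    wl = WavelengthGrid().wavelengths()
    assert comp["H"][np.argmin(np.abs(wl - 193))] > 0
    assert comp["H"][np.argmin(np.abs(wl - 222))] < 0


def test_make_basis_is_byte_reproducible(tmp_path):
    lattice = default_mixes(5)
    spec = SynthSpec(n_entries=len(lattice), mixes=[m for m, _ in lattice],
                     architectures=[a for _, a in lattice], seed=3, n_res=90)
    m1 = make_basis(spec, tmp_path / "b1")
    m2 = make_basis(spec, tmp_path / "b2")
    assert m1.read_bytes() == m2.read_bytes()
    for f1 in sorted((tmp_path / "b1").iterdir()):
        f2 = tmp_path / "b2" / f1.name
        assert f1.read_bytes() == f2.read_bytes(), f1.name


def test_default_mixes_span_content_space():
    mixes = default_mixes(20)
    assert len(mixes) == 20
    alphas = [m[0][0] for m in mixes]
    betas = [m[0][1] for m in mixes]
    assert max(alphas) - min(alphas) >= 50
    assert max(betas) - min(betas) >= 30
    for (a, b, o), _ in mixes:
        assert a + b + o == pytest.approx(100.0)


def test_make_basis_requires_four_entries(tmp_path):
    lattice = default_mixes(3)
    with pytest.raises(ValueError):
        make_basis(SynthSpec(n_entries=len(lattice),
                             mixes=[m for m, _ in lattice],
                             architectures=[a for _, a in lattice]),
                   tmp_path)
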