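import numpy as np
import pytest

from structcd.basis import build_basis
from structcd.structure import Chain, ProteinStructure, Residue
from structcd.synth import (SynthSpec, default_mixes, fragments_to_structure,
                            make_basis, make_helix, make_sheet)

#: Seed of the reference synthetic basis used by the slower integration tests.
BASIS_SEED = 42


def structure_from_fragments(fragments, kinds=None, struct_id="fixture"):
    """One-chain structure with numbering gaps between fragments."""
    st, _ = fragments_to_structure(fragments, kinds, struct_id=struct_id)
    return st


@pytest.fixture(scope="session")
def helix18():
    """Ideal 18-residue alpha helix along +z."""
    return structure_from_fragments([make_helix(18)], ["helix"])


@pytest.fixture(scope="session")
def sheet_2x8():
    """Two-stranded antiparallel sheet, 8 residues per strand."""
    return structure_from_fragments(make_sheet(2, 8), ["strand", "strand"])


@pytest.fixture(scope="session")
def bundle4():
    """Four-helix bundle, 12 residues per helix, axes within contact range."""
    frags = []
    for i in range(4):
        theta = np.pi * i / 2
        origin = (5.5 * np.cos(theta), 5.5 * np.sin(theta), 0.0)
        axis = (0.15 * np.cos(theta), 0.15 * np.sin(theta),
                1.0 if i % 2 == 0 else -1.0)
        axis = np.asarray(axis) / np.linalg.norm(axis)
        frags.append(make_helix(12, origin=origin, axis=axis))
    return structure_from_fragments(frags, ["helix"] * 4)


@pytest.fixture(scope="session")
def basis20_manifest(tmp_path_factory):
    """Reference 20-entry synthetic basis on disk (noise-free, fixed seed)."""
    outdir = tmp_path_factory.mktemp("basis20")
    lattice = default_mixes(20)
    spec = SynthSpec(n_entries=len(lattice),
                     mixes=[m for m, _ in lattice],
                     architectures=[a for _, a in lattice],
                     noise_sd=0.0, seed=BASIS_SEED)
    return make_basis(spec, outdir)


@pytest.fixture(scope="session")
def basis20(basis20_manifest):
    return build_basis(basis20_manifest)


@pytest.fixture(scope="session")
def loo_report20(basis20):
    """Leave-one-out report for the reference basis (computed once)."""
    from structcd.evaluate import loo_cv
    return loo_cv(basis20)


@pytest.fixture(scope="session")
def basis6_manifest(tmp_path_factory):
    """Small 6-entry basis for fast pipeline tests."""
    outdir = tmp_path_factory.mktemp("basis6")
    lattice = default_mixes(6)
    spec = SynthSpec(n_entries=len(lattice),
                     mixes=[m for m, _ in lattice],
                     architectures=[a for _, a in lattice],
                     noise_sd=0.0, seed=BASIS_SEED, n_res=90)
    return make_basis(spec, outdir)


@pytest.fixture(scope="session")
def basis6(basis6_manifest):
    return build_basis(basis6_manifest)


def rigid_transform(structure: ProteinStructure, rotation: np.ndarray,
                    translation: np.ndarray, new_id="moved") -> ProteinStructure:
    chains = []
    for chain in structure.chains:
        residues = [Residue(name=r.name, seq_pos=r.seq_pos,
                            atoms={k: rotation @ v + translation
                                   for k, v in r.atoms.items()})
                    for r in chain.residues]
        chains.append(Chain(chain_id=chain.chain_id, residues=residues))
    return ProteinStructure(id=new_id, chains=chains)


def rotation_matrix(axis, angle_rad):
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle_rad) * k + (1 - np.cos(angle_rad)) * k @ k
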