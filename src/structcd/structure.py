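"""Protein structure model and PDB coordinate input.

The internal model keeps only what the downstream geometry needs: chains of
residues carrying backbone atom coordinates in Angstroms. Reading goes
through gemmi; for multi-model (NMR) files only the first model is kept,
HETATM records and waters are dropped, and alternate locations are resolved
to the highest-occupancy conformer (ties broken by file order).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

__all__ = [
    "Residue",
    "Chain",
    "ProteinStructure",
    "ParseError",
    "parse_pdb",
    "read_header_ss",
    "chain_segments",
]

#: CA-CA distance above which consecutive residues are treated as a chain break.
CHAIN_BREAK_CA_DIST = 4.5


class ParseError(ValueError):
    """Raised when a coordinate file cannot be read into the model."""


@dataclass
class Residue:
    name: str                       # 3-letter code
    seq_pos: int                    # sequence position after insertion-code resolution
    atoms: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def ca(self) -> np.ndarray | None:
        return self.atoms.get("CA")

    def has_backbone(self) -> bool:
        return all(a in self.atoms for a in ("N", "CA", "C", "O"))


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    def ca_coords(self) -> np.ndarray:
        """(n, 3) array of CA coordinates for residues that have a CA."""
        return np.array([r.ca for r in self.residues if r.ca is not None])


@dataclass
class ProteinStructure:
    id: str
    chains: list[Chain] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [c.chain_id for c in self.chains]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate chain ids in structure {self.id!r}")

    @property
    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains)

    def residue_keys(self) -> list[tuple[str, int]]:
        return [(c.chain_id, r.seq_pos) for c in self.chains for r in c.residues]


_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


def _pick_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    best = atoms[0]
    for a in atoms[1:]:
        if a.occ > best.occ:
            best = a
    return best


def parse_pdb(path: str | Path, model_policy: str = "first_model") -> ProteinStructure:
    """Read a PDB coordinate file into a :class:`ProteinStructure`.

    Only MODEL 1 of a multi-model (NMR ensemble) file is retained. HETATM
    records and waters are excluded. Alternate locations resolve to the
    highest-occupancy atom, ties to the first encountered. Residues with
    insertion codes are kept in (resSeq, icode) order; if that ordering has
    duplicate numbers the positions are renumbered to stay strictly
    increasing.
    """
    if model_policy != "first_model":
        raise ValueError(f"unknown model policy {model_policy!r}")
    path = Path(path)
    if not path.exists():
        raise ParseError(f"file not found: {path}")
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise ParseError(f"no coordinate models in {path}")
    model = st[0]

    chains: list[Chain] = []
    for gchain in model:
        residues: list[Residue] = []
        last_pos: int | None = None
        for gres in gchain:
            if gres.het_flag == "H" or gres.name in _WATER_NAMES:
                continue
            by_name: dict[str, list[gemmi.Atom]] = {}
            for atom in gres:
                by_name.setdefault(atom.name, []).append(atom)
            atoms = {
                name: np.array(_pick_altloc(cands).pos.tolist(), dtype=float)
                for name, cands in by_name.items()
            }
            pos = gres.seqid.num
            if last_pos is not None and pos <= last_pos:
                # insertion codes collapse onto one number: renumber minimally
                pos = last_pos + 1
            last_pos = pos
            residues.append(Residue(name=gres.name, seq_pos=pos, atoms=atoms))
        if residues:
            chains.append(Chain(chain_id=gchain.name, residues=residues))

    if not chains:
        raise ParseError(f"no ATOM records in {path}")
    return ProteinStructure(id=path.stem, chains=chains)


def read_header_ss(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Read HELIX/SHEET header annotations.

    Returns ``(chain_id, start_seq, end_seq, ss_type)`` tuples in file order
    with ``ss_type`` in {"helix", "strand", "helix310"}; HELIX class 5 (3-10
    helix) is reported as the distinct "helix310" subtype so callers can map
    it to 'other'. Files without such records yield an empty list.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    out: list[tuple[str, int, int, str]] = []
    for h in st.helices:
        kind = ("helix310" if h.pdb_helix_class == gemmi.Helix.HelixClass.R310
                else "helix")
        out.append((h.start.chain_name, h.start.res_id.seqid.num,
                    h.end.res_id.seqid.num, kind))
    for sheet in st.sheets:
        for strand in sheet.strands:
            out.append((strand.start.chain_name, strand.start.res_id.seqid.num,
                        strand.end.res_id.seqid.num, "strand"))
    return out


def chain_segments(chain: Chain) -> list[list[int]]:
    """Split a chain into contiguous segments (indices into chain.residues).

    A segment break occurs at a gap in residue numbering or where the CA-CA
    distance of consecutive residues exceeds 4.5 A, so that secondary
    structure never spans an unobserved or disordered region.
    """
    segments: list[list[int]] = []
    current: list[int] = []
    prev: Residue | None = None
    for i, res in enumerate(chain.residues):
        broken = False
        if prev is not None:
            if res.seq_pos != prev.seq_pos + 1:
                broken = True
            elif res.ca is not None and prev.ca is not None:
                if np.linalg.norm(res.ca - prev.ca) > CHAIN_BREAK_CA_DIST:
                    broken = True
        if broken and current:
            segments.append(current)
            current = []
        current.append(i)
        prev = res
    if current:
        segments.append(current)
    return segments
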