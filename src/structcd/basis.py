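"""Basis set: structures paired with spectra and precomputed descriptors.

A basis is built from a three-column tab-separated manifest (id,
structure path, spectrum path). Descriptors (ABO and TOP) are computed once
per entry and cached next to the manifest keyed on file content hashes, so
repeated builds and cross-validation runs skip the geometry.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .descriptors import AboDescriptor, TopDescriptor, compute_abo, compute_top
from .secstruct import assign_ss, extract_elements
from .spectra import Spectrum, WavelengthGrid, basis_normalizer, read_spectrum
from .structure import ProteinStructure, parse_pdb

__all__ = ["BasisEntry", "BasisSet", "build_basis", "leave_one_out"]

log = logging.getLogger(__name__)

MIN_BASIS = 4


@dataclass
class BasisEntry:
    id: str
    abo: AboDescriptor
    top: TopDescriptor
    structure_path: Path
    spectrum: Spectrum
    _structure: ProteinStructure | None = field(default=None, repr=False)

    @property
    def structure(self) -> ProteinStructure:
        if self._structure is None:
            self._structure = parse_pdb(self.structure_path)
        return self._structure


@dataclass
class BasisSet:
    entries: list[BasisEntry]
    grid: WavelengthGrid

    def __post_init__(self) -> None:
        ids = [e.id for e in self.entries]
        if len(set(ids)) != len(ids):
            dupes = {i for i in ids if ids.count(i) > 1}
            raise ValueError(f"duplicate basis ids: {sorted(dupes)}")
        for e in self.entries:
            if e.spectrum.grid != self.grid:
                raise ValueError(f"entry {e.id!r} spectrum is on a different grid")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def ids(self) -> list[str]:
        return [e.id for e in self.entries]

    def get(self, entry_id: str) -> BasisEntry:
        for e in self.entries:
            if e.id == entry_id:
                return e
        raise KeyError(f"no basis entry {entry_id!r}")

    def spectra(self) -> list[Spectrum]:
        return [e.spectrum for e in self.entries]

    def normalizer(self) -> float:
        """NRMSD normalizer M: the largest per-wavelength basis spread."""
        return basis_normalizer(self.spectra())


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _cache_path(manifest: Path) -> Path:
    return manifest.with_suffix(".descriptors.tsv")


def _load_cache(path: Path) -> dict[str, tuple[str, AboDescriptor, TopDescriptor]]:
    cache: dict[str, tuple[str, AboDescriptor, TopDescriptor]] = {}
    if not path.exists():
        return cache
    for line in path.read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2 + 3 + 36:
            continue
        entry_id, digest = parts[0], parts[1]
        abo = AboDescriptor(*(float(x) for x in parts[2:5]))
        top = TopDescriptor(np.array([float(x) for x in parts[5:]]))
        cache[entry_id] = (digest, abo, top)
    return cache


def _write_cache(path: Path,
                 cache: dict[str, tuple[str, AboDescriptor, TopDescriptor]]) -> None:
    with path.open("w") as fh:
        fh.write("# id\thash\talpha\tbeta\tother\ttop bins (aa x12, bb x12, ab x12)\n")
        for entry_id, (digest, abo, top) in sorted(cache.items()):
            bins = "\t".join(f"{int(b)}" if float(b).is_integer() else f"{b}"
                             for b in top.bins)
            fh.write(f"{entry_id}\t{digest}\t{abo.alpha!r}\t{abo.beta!r}"
                     f"\t{abo.other!r}\t{bins}\n")


def descriptors_for(structure: ProteinStructure) -> tuple[AboDescriptor, TopDescriptor]:
    """ABO and TOP for a parsed structure using the hydrogen-bond assigner."""
    ss = assign_ss(structure)
    abo = compute_abo(ss)
    top = compute_top(extract_elements(structure, ss))
    return abo, top


def build_basis(manifest: str | Path, grid: WavelengthGrid | None = None,
                use_cache: bool = True) -> BasisSet:
    """Build a basis set from a manifest of (id, structure, spectrum) rows.

    Paths in the manifest are resolved relative to the manifest itself.
    Any row that fails to parse raises an error naming the entry id.
    """
    grid = grid or WavelengthGrid()
    manifest = Path(manifest)
    rows: list[tuple[str, Path, Path]] = []
    for lineno, line in enumerate(manifest.read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 3:
            raise ValueError(f"{manifest}:{lineno}: expected 3 tab-separated columns")
        entry_id, struct_rel, spec_rel = parts
        rows.append((entry_id, manifest.parent / struct_rel,
                     manifest.parent / spec_rel))

    cache = _load_cache(_cache_path(manifest)) if use_cache else {}
    entries: list[BasisEntry] = []
    cache_dirty = False
    for entry_id, struct_path, spec_path in rows:
        try:
            digest = _file_hash(struct_path)
            cached = cache.get(entry_id)
            if cached is not None and cached[0] == digest:
                _, abo, top = cached
                structure = None
                log.debug("descriptor cache hit for %s", entry_id)
            else:
                structure = parse_pdb(struct_path)
                abo, top = descriptors_for(structure)
                cache[entry_id] = (digest, abo, top)
                cache_dirty = True
            spectrum = read_spectrum(spec_path, grid)
            spectrum.id = entry_id
        except (OSError, ValueError) as exc:
            raise ValueError(f"basis entry {entry_id!r}: {exc}") from exc
        entries.append(BasisEntry(id=entry_id, abo=abo, top=top,
                                  structure_path=struct_path, spectrum=spectrum,
                                  _structure=structure))
    if use_cache and cache_dirty:
        try:
            _write_cache(_cache_path(manifest), cache)
        except OSError as exc:      # read-only manifest directory is fine
            log.debug("cannot write descriptor cache: %s", exc)
    return BasisSet(entries=entries, grid=grid)


def leave_one_out(basis: BasisSet, entry_id: str) -> BasisSet:
    """A view of the basis excluding one entry; the original is unchanged."""
    if entry_id not in basis.ids():
        raise KeyError(f"no basis entry {entry_id!r}")
    return BasisSet(entries=[e for e in basis.entries if e.id != entry_id],
                    grid=basis.grid)
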