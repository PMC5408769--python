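"""Outlier refinement of the pooled spectra and final spectrum generation.

The nine pooled neighbor spectra (three per method, with multiplicity when
methods agree) are iteratively pruned: the multiplicity-weighted mean and
per-wavelength standard deviation are computed, each distinct protein is
scored by how many wavelengths deviate from the mean by more than two
standard deviations, and the worst protein is removed whenever that count
exceeds one sixth of the grid. The survivors are combined into the final
spectrum as a score-weighted average normalized by the total number of
retained method slots.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .basis import BasisSet, descriptors_for
from .matching import MatchSet, match
from .spectra import Spectrum, WavelengthGrid
from .structure import ProteinStructure, parse_pdb

__all__ = ["RefinementState", "GenerationResult", "refine", "generate", "predict"]

log = logging.getLogger(__name__)

#: Guard against division by exact-zero ABO/TOP distances in the weighting.
_DIST_EPS = 1e-9


@dataclass
class RefinementState:
    retained: list[str]                       # pooled ids, multiplicity preserved
    removed: list[tuple[str, int, int]]       # (id, iteration, P at removal)
    mean: Spectrum
    sigma: np.ndarray

    @property
    def retained_distinct(self) -> list[str]:
        seen: list[str] = []
        for entry_id in self.retained:
            if entry_id not in seen:
                seen.append(entry_id)
        return seen


@dataclass
class GenerationResult:
    spectrum: Spectrum
    contributions: list[tuple[str, str, float, float]]  # method, id, native, weight
    n_a: int
    n_t: int
    n_z: int
    match_set: MatchSet | None = field(default=None, repr=False)
    refinement: RefinementState | None = field(default=None, repr=False)


def _pool_stats(pooled_ids: list[str], spectra: dict[str, np.ndarray]):
    mat = np.array([spectra[i] for i in pooled_ids])
    mean = mat.mean(axis=0)
    sigma = mat.std(axis=0) if len(pooled_ids) > 1 else np.zeros(mat.shape[1])
    return mean, sigma


def refine(pooled_ids: list[str], spectra: dict[str, np.ndarray],
           grid: WavelengthGrid) -> RefinementState:
    """Iteratively remove outlier proteins from the pooled spectra.

    Each iteration computes the multiplicity-weighted mean and per-
    wavelength standard deviation over the pool, then counts for each
    distinct protein the wavelengths where its spectrum deviates from the
    mean by more than two standard deviations. If the worst count exceeds
    one sixth of the grid points, every pooled occurrence of that protein
    is removed and the loop repeats; it stops when nothing is removed or a
    single distinct protein remains. Ties pick the protein with the larger
    total squared deviation, then the first by id.
    """
    if not pooled_ids:
        raise ValueError("empty pool")
    threshold = grid.n_points // 6       # "more than one sixth", strict
    retained = list(pooled_ids)
    removed: list[tuple[str, int, int]] = []
    iteration = 0
    while True:
        distinct = sorted(set(retained))
        mean, sigma = _pool_stats(retained, spectra)
        if len(distinct) <= 1:
            break
        iteration += 1
        stats = []
        for entry_id in distinct:
            dev = np.abs(spectra[entry_id] - mean)
            p = int(np.sum(dev > 2.0 * sigma))
            stats.append((p, float(np.sum(dev ** 2)), entry_id))
        max_p = max(s[0] for s in stats)
        if max_p <= threshold:
            break
        worst = sorted((s for s in stats if s[0] == max_p),
                       key=lambda s: (-s[1], s[2]))[0]
        retained = [i for i in retained if i != worst[2]]
        removed.append((worst[2], iteration, max_p))
        log.debug("refinement removed %s (P=%d) in iteration %d",
                  worst[2], max_p, iteration)
    mean, sigma = _pool_stats(retained, spectra)
    return RefinementState(retained=retained, removed=removed,
                           mean=Spectrum(grid=grid, values=mean, id="pool-mean"),
                           sigma=sigma)


def _method_weights(method: str, retained: list[tuple[str, float]]) -> list[float]:
    """Convert native scores to weights with per-method mean 1.

    ABO/TOP scores are distances, mapped through 1/(d + eps); ZSC scores are
    similarities used directly. Either way the weights are normalized so a
    method's weights average one, keeping the final 1/(n_A + n_T + n_Z)
    prefactor a plain average when all matches are equally good.
    """
    if method in ("ABO", "TOP"):
        raw = np.array([1.0 / (score + _DIST_EPS) for _, score in retained])
    else:
        raw = np.array([score for _, score in retained], dtype=float)
    if raw.sum() <= 0:
        raw = np.ones(len(retained))
    return list(raw * len(raw) / raw.sum())


def generate(match_set: MatchSet, refinement: RefinementState,
             basis: BasisSet) -> GenerationResult:
    """Score-weighted average of the retained neighbor spectra.

    Per method, the neighbors that survived refinement keep their native
    scores, converted to non-negative weights averaging one within the
    method; the final spectrum is the sum of all weighted spectra divided
    by the total number of retained slots (a convex combination).
    """
    keep = set(refinement.retained_distinct)
    per_method: dict[str, list[tuple[str, float]]] = {}
    for mm in match_set.methods():
        per_method[mm.method] = [(i, s) for i, s in mm.neighbors if i in keep]
    counts = {m: len(v) for m, v in per_method.items()}
    n_total = sum(counts.values())
    if n_total == 0:
        raise ValueError("refinement retained no matched spectra")

    grid = basis.grid
    acc = np.zeros(grid.n_points)
    contributions: list[tuple[str, str, float, float]] = []
    for method, retained in per_method.items():
        if not retained:
            continue
        weights = _method_weights(method, retained)
        for (entry_id, native), w in zip(retained, weights):
            acc += w * basis.get(entry_id).spectrum.values
            contributions.append((method, entry_id, native, w))
    spectrum = Spectrum(grid=grid, values=acc / n_total, id="generated")
    return GenerationResult(spectrum=spectrum, contributions=contributions,
                            n_a=counts["ABO"], n_t=counts["TOP"], n_z=counts["ZSC"],
                            match_set=match_set, refinement=refinement)


def predict(query: str | Path | ProteinStructure, basis: BasisSet) -> GenerationResult:
    """End-to-end spectrum generation for a query structure.

    Parse -> assign secondary structure -> descriptors -> neighbor matching
    -> outlier refinement -> weighted generation. Deterministic for fixed
    inputs.
    """
    try:
        structure = query if isinstance(query, ProteinStructure) else parse_pdb(query)
    except ValueError as exc:
        raise ValueError(f"query parsing failed: {exc}") from exc
    try:
        abo, top = descriptors_for(structure)
    except ValueError as exc:
        raise ValueError(f"descriptor computation failed: {exc}") from exc
    try:
        match_set = match(structure, abo, top, basis)
    except ValueError as exc:
        raise ValueError(f"neighbor matching failed: {exc}") from exc
    spectra = {e.id: e.spectrum.values for e in basis}
    try:
        refinement = refine(match_set.pooled, spectra, basis.grid)
        return generate(match_set, refinement, basis)
    except ValueError as exc:
        raise ValueError(f"spectrum generation failed: {exc}") from exc
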