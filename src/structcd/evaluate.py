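"""Leave-one-out cross-validation and summary statistics.

Each basis entry is removed in turn, its structure is used as the query
against the remaining entries, and the generated spectrum is compared to
the held-out experimental spectrum by NRMSD. The normalizer is computed
from the full basis so all folds share one scale. Predictions at or below
0.1 count as 'good'; at or above 0.2 as 'poor'.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .basis import BasisSet, leave_one_out
from .descriptors import AboDescriptor
from .pipeline import predict
from .spectra import nrmsd

__all__ = ["CvReport", "loo_cv", "ss_map", "GOOD_THRESHOLD", "POOR_THRESHOLD"]

log = logging.getLogger(__name__)

GOOD_THRESHOLD = 0.1
POOR_THRESHOLD = 0.2


@dataclass
class CvReport:
    per_entry: list[tuple[str, float]]
    failed: list[tuple[str, str]] = field(default_factory=list)

    @property
    def overall_mean(self) -> float:
        vals = [v for _, v in self.per_entry]
        return sum(vals) / len(vals) if vals else float("nan")

    @property
    def worst(self) -> float:
        return max((v for _, v in self.per_entry), default=float("nan"))

    @property
    def best(self) -> float:
        return min((v for _, v in self.per_entry), default=float("nan"))

    @property
    def n_good(self) -> int:
        return sum(1 for _, v in self.per_entry if v <= GOOD_THRESHOLD)

    @property
    def n_poor(self) -> int:
        return sum(1 for _, v in self.per_entry if v >= POOR_THRESHOLD)

    def sorted_entries(self) -> list[tuple[str, float]]:
        return sorted(self.per_entry, key=lambda t: t[1])

    def write_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("id\tnrmsd\trank\tflag\n")
            for rank, (entry_id, v) in enumerate(self.sorted_entries(), 1):
                flag = ("good" if v <= GOOD_THRESHOLD
                        else "poor" if v >= POOR_THRESHOLD else "")
                fh.write(f"{entry_id}\t{v:.6f}\t{rank}\t{flag}\n")
            for entry_id, msg in self.failed:
                fh.write(f"{entry_id}\tNA\tNA\tfailed: {msg}\n")


def loo_cv(basis: BasisSet, spectra_dir: str | Path | None = None) -> CvReport:
    """Leave-one-out cross-validation over the basis.

    Folds that fail to produce a spectrum are reported separately and
    excluded from the aggregates. When ``spectra_dir`` is given the per-fold
    generated spectra are written there.
    """
    if len(basis) < 4:
        raise ValueError("cross-validation needs at least 4 basis entries")
    m = basis.normalizer()
    if m <= 0:
        raise ValueError("degenerate basis: all spectra identical (M = 0)")
    per_entry: list[tuple[str, float]] = []
    failed: list[tuple[str, str]] = []
    for entry in basis:
        reduced = leave_one_out(basis, entry.id)
        assert entry.id not in reduced.ids()
        try:
            result = predict(entry.structure, reduced)
        except ValueError as exc:
            log.warning("fold %s failed: %s", entry.id, exc)
            failed.append((entry.id, str(exc)))
            continue
        value = nrmsd(result.spectrum, entry.spectrum, m)
        per_entry.append((entry.id, value))
        if spectra_dir is not None:
            from .spectra import write_spectrum
            out = Path(spectra_dir)
            out.mkdir(parents=True, exist_ok=True)
            write_spectrum(result.spectrum, out / f"{entry.id}.txt",
                           header_lines=[f"leave-one-out fold {entry.id}",
                                         f"nrmsd {value:.6f}"])
    return CvReport(per_entry=per_entry, failed=failed)


def ss_map(basis: BasisSet,
           extra: list[tuple[str, AboDescriptor]] = ()) -> list[tuple[str, float, float]]:
    """(id, alpha, beta) rows for content-space coverage inspection."""
    rows = [(e.id, e.abo.alpha, e.abo.beta) for e in basis]
    rows.extend((name, abo.alpha, abo.beta) for name, abo in extra)
    return rows
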