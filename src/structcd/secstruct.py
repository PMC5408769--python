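"""Secondary-structure assignment and vectorized helix/strand elements.

The geometric assigner implements the Kabsch-Sander electrostatic
hydrogen-bond criterion with the minimal turn/bridge rules needed to label
alpha-helix (H), 3-10 helix (G) and beta-strand (E) residues; everything
else is 'other' (O). Elements are maximal H or E runs of three or more
residues, each carrying a fitted axis used by the topology descriptor.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .structure import Chain, ProteinStructure, chain_segments

__all__ = ["SSAssignment", "SSElement", "assign_ss", "extract_elements",
           "write_assignment"]

log = logging.getLogger(__name__)

#: Kabsch-Sander hydrogen-bond energy threshold (kcal/mol).
HBOND_ENERGY_CUTOFF = -0.5
#: Coupling constant q1*q2*332 of the Kabsch-Sander energy (kcal*A/mol).
_KS_COUPLING = 0.084 * 332.0
#: Minimum element length in residues.
MIN_ELEMENT_LEN = 3


@dataclass
class SSAssignment:
    """Per-residue labels keyed on (chain_id, seq_pos); labels in {H,E,G,O}."""

    labels: dict[tuple[str, int], str]

    def count(self, *which: str) -> int:
        return sum(1 for v in self.labels.values() if v in which)

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class SSElement:
    ss_type: str                 # "helix" | "strand"
    chain_id: str
    start_seq: int
    end_seq: int
    axis_point: np.ndarray       # centroid of the CA atoms
    axis_dir: np.ndarray         # unit vector oriented N -> C
    endpoints: tuple[np.ndarray, np.ndarray]   # axis projections of first/last CA

    @property
    def n_res(self) -> int:
        return self.end_seq - self.start_seq + 1


def assign_ss(structure: ProteinStructure, method: str = "kabsch_sander",
              header_path: str | Path | None = None,
              provided: dict[tuple[str, int], str] | None = None) -> SSAssignment:
    """Assign one label per residue.

    method="kabsch_sander" runs the geometric assigner (backbone N/CA/C/O
    required; residues missing atoms fall back to O with a warning).
    method="header" maps HELIX records to H (class 5 to G) and SHEET records
    to E using the annotations read from ``header_path``.
    method="provided" passes ``provided`` labels through, filling gaps with O.
    """
    if structure.n_residues == 0:
        raise ValueError("empty structure")
    if method == "kabsch_sander":
        return _assign_kabsch_sander(structure)
    if method == "header":
        from .structure import read_header_ss
        if header_path is None:
            raise ValueError("header method needs the source file path")
        ranges = read_header_ss(header_path)
        labels = {key: "O" for key in structure.residue_keys()}
        type_map = {"helix": "H", "helix310": "G", "strand": "E"}
        for chain_id, start, end, kind in ranges:
            lab = type_map[kind]
            for pos in range(start, end + 1):
                if (chain_id, pos) in labels:
                    labels[(chain_id, pos)] = lab
        return SSAssignment(labels)
    if method == "provided":
        if provided is None:
            raise ValueError("provided method needs labels")
        labels = {key: provided.get(key, "O") for key in structure.residue_keys()}
        bad = set(labels.values()) - {"H", "E", "G", "O"}
        if bad:
            raise ValueError(f"invalid labels {bad}")
        return SSAssignment(labels)
    raise ValueError(f"unknown assignment method {method!r}")


# ---------------------------------------------------------------------------
# Kabsch-Sander machinery


def _collect_backbone(structure: ProteinStructure):
    """Flatten residues into parallel arrays; returns per-residue metadata.

    Each entry: (chain_id, seq_pos, segment index, N, CA, C, O or Nones).
    The segment index is global so inter-chain H-bonds stay possible while
    hydrogen placement never crosses a break.
    """
    keys, seg_ids, coords = [], [], {"N": [], "CA": [], "C": [], "O": []}
    seg_counter = 0
    for chain in structure.chains:
        for seg in chain_segments(chain):
            for i in seg:
                res = chain.residues[i]
                keys.append((chain.chain_id, res.seq_pos))
                seg_ids.append(seg_counter)
                for name in coords:
                    v = res.atoms.get(name)
                    coords[name].append(v if v is not None else np.full(3, np.nan))
            seg_counter += 1
    arrays = {k: np.array(v, dtype=float) for k, v in coords.items()}
    return keys, np.array(seg_ids), arrays


def _hbond_matrix(keys, seg_ids, bb) -> np.ndarray:
    """Boolean matrix hb[donor, acceptor]: N-H of donor bonds C=O of acceptor."""
    n = len(keys)
    N, C, O = bb["N"], bb["C"], bb["O"]
    # amide H placed 1.0 A from N along the previous residue's C->O... i.e.
    # opposite the carbonyl: H = N + (C_prev - O_prev)/|C_prev - O_prev|
    H = np.full((n, 3), np.nan)
    for i in range(1, n):
        if seg_ids[i] != seg_ids[i - 1]:
            continue
        co = C[i - 1] - O[i - 1]
        norm = np.linalg.norm(co)
        if norm > 0 and np.all(np.isfinite(co)) and np.all(np.isfinite(N[i])):
            H[i] = N[i] + co / norm

    hb = np.zeros((n, n), dtype=bool)
    valid_donor = np.all(np.isfinite(H), axis=1) & np.all(np.isfinite(N), axis=1)
    valid_acc = np.all(np.isfinite(C), axis=1) & np.all(np.isfinite(O), axis=1)
    don_idx = np.where(valid_donor)[0]
    acc_idx = np.where(valid_acc)[0]
    if don_idx.size == 0 or acc_idx.size == 0:
        return hb

    def dist(a, b):  # (i,3),(j,3) -> (i,j)
        return np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r_on = dist(N[don_idx], O[acc_idx])
        r_ch = dist(H[don_idx], C[acc_idx])
        r_oh = dist(H[don_idx], O[acc_idx])
        r_cn = dist(N[don_idx], C[acc_idx])
        energy = _KS_COUPLING * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
    bonded = energy < HBOND_ENERGY_CUTOFF
    # exclude self and sequence neighbours within the same segment
    di = don_idx[:, None]
    aj = acc_idx[None, :]
    same_seg = seg_ids[don_idx][:, None] == seg_ids[acc_idx][None, :]
    too_close = same_seg & (np.abs(di - aj) <= 1)
    bonded &= ~too_close
    hb[np.ix_(don_idx, acc_idx)] = bonded
    return hb


def _assign_kabsch_sander(structure: ProteinStructure) -> SSAssignment:
    keys, seg_ids, bb = _collect_backbone(structure)
    n = len(keys)
    missing = ~np.all(
        np.concatenate([np.isfinite(bb[k]) for k in ("N", "CA", "C", "O")], axis=1),
        axis=1)
    if missing.any():
        log.warning("%d residues missing backbone atoms fall back to 'O'",
                    int(missing.sum()))
    hb = _hbond_matrix(keys, seg_ids, bb)

    def consec(i: int, j: int) -> bool:
        """True if residues i..j are sequence-consecutive in one segment."""
        return j < n and i >= 0 and seg_ids[i] == seg_ids[j]

    # n-turns: turn_k[i] True when C=O of i accepts the N-H of i+k
    turns = {}
    for k in (3, 4):
        t = np.zeros(n, dtype=bool)
        for i in range(n - k):
            if consec(i, i + k):
                t[i] = hb[i + k, i]
        turns[k] = t

    labels = np.full(n, "O", dtype="<U1")

    # alpha helix: two consecutive 4-turns at i-1 and i label i..i+3
    helix4 = np.zeros(n, dtype=bool)
    for i in range(1, n - 4):
        if turns[4][i - 1] and turns[4][i]:
            helix4[i:i + 4] = True
    labels[helix4] = "H"

    # beta bridges (parallel and antiparallel), ladders of length >= 2 -> E
    def hbond(a: int, b: int) -> bool:
        """DSSP Hbond(a, b): C=O of a accepts the N-H of b."""
        return 0 <= a < n and 0 <= b < n and hb[b, a]

    bridge = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            if seg_ids[i] == seg_ids[j] and j - i < 3:
                continue
            para = (hbond(i - 1, j) and hbond(j, i + 1) and consec(i - 1, i + 1)
                    ) or (hbond(j - 1, i) and hbond(i, j + 1) and consec(j - 1, j + 1))
            anti = (hbond(i, j) and hbond(j, i)) or (
                hbond(i - 1, j + 1) and hbond(j - 1, i + 1)
                and consec(i - 1, i + 1) and consec(j - 1, j + 1))
            if para or anti:
                bridge[i, j] = bridge[j, i] = True
    has_bridge = bridge.any(axis=1)
    sheet = np.zeros(n, dtype=bool)
    for i in range(n):
        if has_bridge[i] and (
                (i > 0 and has_bridge[i - 1] and consec(i - 1, i))
                or (i + 1 < n and has_bridge[i + 1] and consec(i, i + 1))):
            sheet[i] = True
    labels[sheet & (labels == "O")] = "E"

    # 3-10 helix: two consecutive 3-turns, lower priority than H and E
    helix3 = np.zeros(n, dtype=bool)
    for i in range(1, n - 3):
        if turns[3][i - 1] and turns[3][i]:
            helix3[i:i + 3] = True
    labels[helix3 & (labels == "O")] = "G"

    labels[missing] = "O"
    return SSAssignment(dict(zip(keys, labels)))


# ---------------------------------------------------------------------------
# Element extraction


def _fit_axis(ca: np.ndarray):
    """Least-squares line through CA coordinates (first principal component).

    Returns (centroid, unit direction oriented first->last CA, endpoints as
    the projections of the first and last CA onto the axis line).
    """
    centroid = ca.mean(axis=0)
    centered = ca - centroid
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    direction = vt[0]
    if np.dot(direction, ca[-1] - ca[0]) < 0:
        direction = -direction
    t0 = float(np.dot(ca[0] - centroid, direction))
    t1 = float(np.dot(ca[-1] - centroid, direction))
    return centroid, direction, (centroid + t0 * direction, centroid + t1 * direction)


def extract_elements(structure: ProteinStructure, ss: SSAssignment) -> list[SSElement]:
    """Maximal H runs (helix) and E runs (strand) of >= 3 residues, per segment."""
    elements: list[SSElement] = []
    for chain in structure.chains:
        for seg in chain_segments(chain):
            run_label, run_idx = None, []

            def flush():
                if run_label in ("H", "E") and len(run_idx) >= MIN_ELEMENT_LEN:
                    residues = [chain.residues[i] for i in run_idx]
                    ca = np.array([r.ca for r in residues if r.ca is not None])
                    if len(ca) >= MIN_ELEMENT_LEN:
                        point, direction, ends = _fit_axis(ca)
                        elements.append(SSElement(
                            ss_type="helix" if run_label == "H" else "strand",
                            chain_id=chain.chain_id,
                            start_seq=residues[0].seq_pos,
                            end_seq=residues[-1].seq_pos,
                            axis_point=point, axis_dir=direction, endpoints=ends))

            for i in seg:
                lab = ss.labels[(chain.chain_id, chain.residues[i].seq_pos)]
                if lab == run_label:
                    run_idx.append(i)
                else:
                    flush()
                    run_label, run_idx = lab, [i]
            flush()
    return elements


def write_assignment(ss: SSAssignment, path: str | Path) -> None:
    """Dump per-residue labels as tab-separated (chain, seq, label) text."""
    with Path(path).open("w") as fh:
        fh.write("chain\tseq\tlabel\n")
        for (chain_id, seq), lab in ss.labels.items():
            fh.write(f"{chain_id}\t{seq}\t{lab}\n")
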