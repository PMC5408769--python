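"""Structure descriptors: secondary-structure content (ABO) and the
inter-element packing-angle histogram (TOP).

ABO is the (alpha %, beta %, other %) triple from the per-residue
assignment, with 3-10 helix counted as 'other'. TOP bins the chirality-
signed angle between element axis vectors into 12 x 30 degree bins for each
of the alpha-alpha, beta-beta and alpha-beta pair groups (36 bins total);
only element pairs whose axis segments come within 13 A of each other
qualify.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .secstruct import SSAssignment, SSElement

__all__ = ["AboDescriptor", "TopDescriptor", "compute_abo", "pair_qualifies",
           "pair_angle", "compute_top", "segment_distance", "TOP_CUTOFF"]

#: Maximum axis-segment separation (A) for a pair to enter the TOP histogram.
TOP_CUTOFF = 13.0

_GROUPS = {("helix", "helix"): 0, ("strand", "strand"): 1, ("helix", "strand"): 2}


@dataclass(frozen=True)
class AboDescriptor:
    alpha: float
    beta: float
    other: float

    def __post_init__(self) -> None:
        total = self.alpha + self.beta + self.other
        if abs(total - 100.0) > 1e-6:
            raise ValueError(f"ABO percentages sum to {total}, not 100")
        if min(self.alpha, self.beta, self.other) < -1e-9:
            raise ValueError("negative ABO percentage")

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha, self.beta, self.other])


@dataclass
class TopDescriptor:
    """36 non-negative counts: 3 groups (aa, bb, ab) x 12 bins of 30 degrees."""

    bins: np.ndarray

    def __post_init__(self) -> None:
        self.bins = np.asarray(self.bins, dtype=float)
        if self.bins.shape != (36,):
            raise ValueError("TOP descriptor needs exactly 36 bins")
        if (self.bins < 0).any():
            raise ValueError("negative TOP count")

    @property
    def total(self) -> float:
        return float(self.bins.sum())


def compute_abo(ss: SSAssignment) -> AboDescriptor:
    """Percent alpha helix (H), beta strand (E) and other (G + O) content."""
    n = len(ss)
    if n == 0:
        raise ValueError("empty assignment")
    return AboDescriptor(
        alpha=100.0 * ss.count("H") / n,
        beta=100.0 * ss.count("E") / n,
        other=100.0 * ss.count("G", "O") / n,
    )


def segment_distance(p1: np.ndarray, q1: np.ndarray,
                     p2: np.ndarray, q2: np.ndarray) -> float:
    """Minimum Euclidean distance between finite segments p1-q1 and p2-q2."""
    d1 = q1 - p1
    d2 = q2 - p2
    r = p1 - p2
    a = float(np.dot(d1, d1))
    e = float(np.dot(d2, d2))
    f = float(np.dot(d2, r))
    if a <= 1e-12 and e <= 1e-12:
        return float(np.linalg.norm(r))
    if a <= 1e-12:
        s, t = 0.0, np.clip(f / e, 0.0, 1.0)
    else:
        c = float(np.dot(d1, r))
        if e <= 1e-12:
            t, s = 0.0, np.clip(-c / a, 0.0, 1.0)
        else:
            b = float(np.dot(d1, d2))
            denom = a * e - b * b
            s = np.clip((b * f - c * e) / denom, 0.0, 1.0) if denom > 1e-12 else 0.0
            t = (b * s + f) / e
            if t < 0.0:
                t, s = 0.0, np.clip(-c / a, 0.0, 1.0)
            elif t > 1.0:
                t, s = 1.0, np.clip((b - c) / a, 0.0, 1.0)
    closest1 = p1 + s * d1
    closest2 = p2 + t * d2
    return float(np.linalg.norm(closest1 - closest2))


def _canonical_order(e1: SSElement, e2: SSElement) -> tuple[SSElement, SSElement]:
    """Fixed pair ordering: alpha before beta, else chain/sequence order."""
    if e1.ss_type != e2.ss_type:
        return (e1, e2) if e1.ss_type == "helix" else (e2, e1)
    if (e1.chain_id, e1.start_seq) <= (e2.chain_id, e2.start_seq):
        return e1, e2
    return e2, e1


def pair_qualifies(e1: SSElement, e2: SSElement, cutoff: float = TOP_CUTOFF) -> bool:
    """True iff the minimum distance between the axis segments is <= cutoff."""
    return segment_distance(e1.endpoints[0], e1.endpoints[1],
                            e2.endpoints[0], e2.endpoints[1]) <= cutoff


def pair_angle(e1: SSElement, e2: SSElement) -> float:
    """Chirality-signed angle between element axes, in [0, 360).

    The unsigned angle theta = arccos(d1.d2) covers [0, 180]; the sign of
    dot(cross(d1, d2), m2 - m1) on the canonically ordered pair decides
    between theta and 360 - theta, so that all 12 bins per group are
    reachable. Evaluating on the canonical order makes the value
    order-independent.
    """
    a, b = _canonical_order(e1, e2)
    d1, d2 = a.axis_dir, b.axis_dir
    if np.linalg.norm(d1) < 1e-12 or np.linalg.norm(d2) < 1e-12:
        raise ValueError("zero-length element axis")
    theta = float(np.degrees(np.arccos(np.clip(np.dot(d1, d2), -1.0, 1.0))))
    chirality = float(np.dot(np.cross(d1, d2), b.axis_point - a.axis_point))
    angle = theta if chirality >= 0 else 360.0 - theta
    return angle % 360.0


def compute_top(elements: list[SSElement], cutoff: float = TOP_CUTOFF) -> TopDescriptor:
    """Histogram of qualifying pair angles: 3 groups x 12 bins of 30 degrees."""
    bins = np.zeros(36)
    for i in range(len(elements)):
        for j in range(i + 1, len(elements)):
            e1, e2 = elements[i], elements[j]
            if not pair_qualifies(e1, e2, cutoff):
                continue
            a, b = _canonical_order(e1, e2)
            group = _GROUPS[(a.ss_type, b.ss_type)]
            bin_idx = int(pair_angle(a, b) // 30.0) % 12
            bins[group * 12 + bin_idx] += 1
    return TopDescriptor(bins=bins)
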