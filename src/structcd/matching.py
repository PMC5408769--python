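"""Neighbor selection: the top three basis matches per descriptor method.

ABO matching uses the Euclidean distance over (alpha, beta, other)
percentages with a bracketing rule: two of the three selected entries must
straddle the query on its primary content axis (alpha for mainly helical
queries, beta otherwise) so the query is encompassed by the basis rather
than extrapolated; when no strictly-below or strictly-above entry exists
the plain distance top three is returned. TOP matching is the Euclidean
distance over the 36 histogram counts; ZSC matching ranks the normalized
structural-similarity scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .align import compute_zsc
from .basis import BasisSet
from .descriptors import AboDescriptor, TopDescriptor
from .structure import ProteinStructure

__all__ = ["MethodMatch", "MatchSet", "abo_distance", "top_distance",
           "select_abo", "select_top", "select_zsc", "match", "N_NEIGHBORS"]

log = logging.getLogger(__name__)

#: Matches retained per method.
N_NEIGHBORS = 3


@dataclass
class MethodMatch:
    """Ranked neighbors for one method, best first.

    Native scores are Euclidean distances for ABO/TOP (smaller is better)
    and similarities for ZSC (larger is better).
    """

    method: str                              # "ABO" | "TOP" | "ZSC"
    neighbors: list[tuple[str, float]]

    def ids(self) -> list[str]:
        return [entry_id for entry_id, _ in self.neighbors]


@dataclass
class MatchSet:
    abo: MethodMatch
    top: MethodMatch
    zsc: MethodMatch

    @property
    def pooled(self) -> list[str]:
        """Entry ids with multiplicity: an id picked by k methods appears k times."""
        return self.abo.ids() + self.top.ids() + self.zsc.ids()

    def methods(self) -> list[MethodMatch]:
        return [self.abo, self.top, self.zsc]


def abo_distance(q: AboDescriptor, t: AboDescriptor) -> float:
    """Euclidean distance over (alpha, beta, other) percentages."""
    return float(np.linalg.norm(q.as_array() - t.as_array()))


def top_distance(q: TopDescriptor, t: TopDescriptor) -> float:
    """Euclidean distance over the 36 raw histogram counts."""
    return float(np.linalg.norm(q.bins - t.bins))


def _check_size(basis: BasisSet) -> None:
    if len(basis) < N_NEIGHBORS:
        raise ValueError(f"basis has {len(basis)} entries; need >= {N_NEIGHBORS}")


def select_abo(q: AboDescriptor, basis: BasisSet) -> MethodMatch:
    """Top three ABO matches under the bracketing rule.

    The primary axis is alpha when alpha_q >= beta_q (mainly helical),
    otherwise beta. The triple is: the globally nearest entry, the nearest
    entry strictly below the query on the primary axis and the nearest
    strictly above, with duplicates resolved by the next-nearest entry
    satisfying the unmet condition. If either side cannot be filled, the
    plain distance top three is returned. Reported scores are always the
    content-space distances.
    """
    _check_size(basis)
    dists = [(abo_distance(q, e.abo), i, e) for i, e in enumerate(basis)]
    by_dist = sorted(dists, key=lambda t: (t[0], t[1]))
    primary = (lambda e: e.abo.alpha) if q.alpha >= q.beta else (lambda e: e.abo.beta)
    q_val = q.alpha if q.alpha >= q.beta else q.beta

    below = [t for t in by_dist if primary(t[2]) < q_val]
    above = [t for t in by_dist if primary(t[2]) > q_val]

    def plain_top3() -> MethodMatch:
        return MethodMatch(method="ABO",
                           neighbors=[(e.id, d) for d, _, e in by_dist[:N_NEIGHBORS]])

    if not below or not above:
        return plain_top3()
    chosen = [by_dist[0]]
    chosen_ids = {by_dist[0][2].id}
    for side in (below, above):
        pick = next((t for t in side if t[2].id not in chosen_ids), None)
        if pick is None:
            return plain_top3()
        chosen.append(pick)
        chosen_ids.add(pick[2].id)
    chosen.sort(key=lambda t: (t[0], t[1]))
    return MethodMatch(method="ABO", neighbors=[(e.id, d) for d, _, e in chosen])


def select_top(q: TopDescriptor, basis: BasisSet) -> MethodMatch:
    """The three smallest TOP distances, ties broken by basis order."""
    _check_size(basis)
    ranked = sorted(((top_distance(q, e.top), i, e) for i, e in enumerate(basis)),
                    key=lambda t: (t[0], t[1]))
    return MethodMatch(method="TOP",
                       neighbors=[(e.id, d) for d, _, e in ranked[:N_NEIGHBORS]])


def select_zsc(q: ProteinStructure, basis: BasisSet) -> MethodMatch:
    """The three largest normalized similarity scores, ties by basis order."""
    _check_size(basis)
    scored = []
    for i, e in enumerate(basis):
        try:
            z = compute_zsc(q, e.structure).value
        except ValueError as exc:
            log.warning("ZSC against %s failed (%s); scored 0", e.id, exc)
            z = 0.0
        scored.append((-z, i, e, z))
    scored.sort(key=lambda t: (t[0], t[1]))
    return MethodMatch(method="ZSC",
                       neighbors=[(e.id, z) for _, _, e, z in scored[:N_NEIGHBORS]])


def match(query: ProteinStructure, q_abo: AboDescriptor, q_top: TopDescriptor,
          basis: BasisSet) -> MatchSet:
    """Run all three selectors and pool their picks with multiplicity."""
    return MatchSet(abo=select_abo(q_abo, basis),
                    top=select_top(q_top, basis),
                    zsc=select_zsc(query, basis))
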