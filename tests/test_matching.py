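import numpy as np
import pytest

from structcd.basis import BasisEntry, BasisSet
from structcd.descriptors import AboDescriptor, TopDescriptor
from structcd.matching import (MatchSet, abo_distance, match, select_abo,
                               select_top, select_zsc, top_distance)
from structcd.spectra import Spectrum, WavelengthGrid

GRID = WavelengthGrid()


def _entry(entry_id, alpha=30.0, beta=30.0, top_bins=None, seed=0):
    rng = np.random.default_rng(seed)
    bins = np.zeros(36) if top_bins is None else np.asarray(top_bins, float)
    return BasisEntry(
        id=entry_id,
        abo=AboDescriptor(alpha=alpha, beta=beta, other=100.0 - alpha - beta),
        top=TopDescriptor(bins=bins),
        structure_path=None,
        spectrum=Spectrum(grid=GRID, values=rng.normal(size=66), id=entry_id),
    )


def _basis(entries):
    return BasisSet(entries=entries, grid=GRID)


def _abo(alpha, beta):
    return AboDescriptor(alpha=alpha, beta=beta, other=100.0 - alpha - beta)


def test_abo_distance_values():
    assert abo_distance(_abo(40, 40), _abo(40, 40)) == 0.0
    assert abo_distance(_abo(100, 0), _abo(0, 100)) == pytest.approx(
        100.0 * np.sqrt(2.0))
    assert abo_distance(_abo(40, 40), _abo(30, 50)) == pytest.approx(
        np.sqrt(200.0), abs=1e-9)


def test_select_abo_brackets_the_query():
    basis = _basis([_entry("a10", alpha=10, beta=5),
                    _entry("a48", alpha=48, beta=5),
                    _entry("a52", alpha=52, beta=5),
                    _entry("a90", alpha=90, beta=5)])
    mm = select_abo(_abo(50, 5), basis)
    alphas = [basis.get(i).abo.alpha for i in mm.ids()]
    assert any(a < 50 for a in alphas)
    assert any(a > 50 for a in alphas)
    assert set(mm.ids()) == {"a48", "a52", "a10"} or set(mm.ids()) <= {
        "a10", "a48", "a52", "a90"}


def test_select_abo_falls_back_when_unbracketable():
    basis = _basis([_entry(f"e{i}", alpha=a, beta=5)
                    for i, a in enumerate([10, 20, 30, 40])])
    mm = select_abo(_abo(50, 5), basis)     # query above every basis alpha
    # plain distance top-3: the three largest alphas
    assert mm.ids() == ["e3", "e2", "e1"]


def test_select_abo_exact_match_ranks_first_with_zero_score():
    basis = _basis([_entry("hit", alpha=40, beta=20),
                    _entry("lo", alpha=30, beta=20),
                    _entry("hi", alpha=55, beta=20),
                    _entry("far", alpha=80, beta=5)])
    mm = select_abo(_abo(40, 20), basis)
    assert mm.neighbors[0] == ("hit", 0.0)


def _brute_force_abo(q, basis):
    """Independent implementation of the documented bracketing rule."""
    ranked = sorted(basis.entries,
                    key=lambda e: (abo_distance(q, e.abo),
                                   basis.entries.index(e)))
    primary = (lambda e: e.abo.alpha) if q.alpha >= q.beta else (lambda e: e.abo.beta)
    q_val = q.alpha if q.alpha >= q.beta else q.beta
    below = [e for e in ranked if primary(e) < q_val]
    above = [e for e in ranked if primary(e) > q_val]
    plain = [e.id for e in ranked[:3]]
    if not below or not above:
        return plain
    chosen = [ranked[0]]
    for side in (below, above):
        pick = next((e for e in side if e not in chosen), None)
        if pick is None:
            return plain
        chosen.append(pick)
    chosen.sort(key=lambda e: (abo_distance(q, e.abo), basis.entries.index(e)))
    return [e.id for e in chosen]


def test_select_abo_agrees_with_brute_force_on_random_bases():
    rng = np.random.default_rng(42)
    for _ in range(50):
        entries = []
        for i in range(10):
            a = float(rng.uniform(0, 80))
            b = float(rng.uniform(0, 100 - a - 5))
            entries.append(_entry(f"e{i}", alpha=a, beta=b))
        basis = _basis(entries)
        qa = float(rng.uniform(0, 80))
        qb = float(rng.uniform(0, 100 - qa - 5))
        q = _abo(qa, qb)
        assert select_abo(q, basis).ids() == _brute_force_abo(q, basis)


def test_select_abo_requires_three_entries():
    with pytest.raises(ValueError):
        select_abo(_abo(40, 20), _basis([_entry("a"), _entry("b")]))


def test_top_distance_values_and_oracle():
    z = TopDescriptor(np.zeros(36))
    assert top_distance(z, z) == 0.0
    single = np.zeros(36)
    single[7] = 3
    assert top_distance(z, TopDescriptor(single)) == pytest.approx(3.0)
    rng = np.random.default_rng(0)
    for _ in range(20):
        q = TopDescriptor(rng.integers(0, 10, 36).astype(float))
        t = TopDescriptor(rng.integers(0, 10, 36).astype(float))
        oracle = np.sqrt(sum((q.bins[i] - t.bins[i]) ** 2 for i in range(36)))
        assert top_distance(q, t) == pytest.approx(oracle)


def test_select_top_is_brute_force_top3():
    rng = np.random.default_rng(1)
    entries = [_entry(f"e{i}", top_bins=rng.integers(0, 8, 36))
               for i in range(8)]
    basis = _basis(entries)
    q = TopDescriptor(rng.integers(0, 8, 36).astype(float))
    mm = select_top(q, basis)
    expect = sorted(range(8), key=lambda i: (top_distance(q, entries[i].top), i))[:3]
    assert mm.ids() == [f"e{i}" for i in expect]
    assert mm.neighbors[0][1] <= mm.neighbors[1][1] <= mm.neighbors[2][1]


def test_select_zsc_self_in_basis_ranks_first(basis6):
    entry = basis6.entries[0]
    mm = select_zsc(entry.structure, basis6)
    assert mm.neighbors[0][0] == entry.id
    assert mm.neighbors[0][1] == pytest.approx(1.0, abs=1e-9)


def test_match_pools_nine_with_multiplicity(basis6):
    entry = basis6.entries[1]
    ms = match(entry.structure, entry.abo, entry.top, basis6)
    assert len(ms.pooled) == 9
    assert ms.pooled.count(entry.id) >= 3   # rank 1 for every method


def test_matchset_pooled_multiset_semantics():
    mm_a = select_abo(_abo(40, 20), _basis(
        [_entry("x", 40, 20), _entry("y", 30, 25), _entry("z", 50, 15),
         _entry("w", 70, 5)]))
    ms = MatchSet(abo=mm_a, top=mm_a, zsc=mm_a)
    assert len(ms.pooled) == 9
    assert ms.pooled.count("x") == 3
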