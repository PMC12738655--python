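"""Damage scorer: probability ramp, thinning, clustering vs brute force."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from alphacell import (
    DamageParams,
    StrandBreak,
    cluster_breaks,
    damage_probability,
    score_damage,
    select_breaks,
)
from alphacell.damage_clustering import read_event_file, write_event_file
from alphacell.synthetic_fixtures import EVENT_DTYPE


# ---------------------------------------------------------------------------
# independent oracle: union-find over all pairs strictly closer than eps
# (a core threshold of 2 makes density clustering the connected components
# of the "< eps" graph, with singletons as noise)
# ---------------------------------------------------------------------------
def brute_force_summary(positions, strands, params):
    n = len(positions)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(positions[i] - positions[j]) < params.eps_nm:
                parent[find(i)] = find(j)

    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    n_ssb = n_sdsb = n_cdsb = 0
    sizes = {}
    for members in groups.values():
        if len(members) == 1:
            n_ssb += 1
            continue
        sizes[len(members)] = sizes.get(len(members), 0) + 1
        if len({strands[i] for i in members}) == 2:
            if len(members) == 2:
                n_sdsb += 1
            else:
                n_cdsb += 1
        else:
            n_ssb += len(members)
    return n_ssb, n_sdsb, n_cdsb, sizes


def make_breaks(positions, strands):
    return [
        StrandBreak(position=np.asarray(p, float), strand=int(s))
        for p, s in zip(positions, strands)
    ]


class TestDamageProbability:
    def test_ramp_endpoints_exact(self):
        assert damage_probability(5.0) == 0.0
        assert damage_probability(4.0) == 0.0
        assert damage_probability(37.5) == 1.0
        assert damage_probability(100.0) == 1.0

    def test_linear_midpoint(self):
        assert damage_probability(21.25) == pytest.approx(0.5)

    def test_vectorised_and_monotone(self):
        e = np.linspace(0.0, 60.0, 500)
        p = damage_probability(e)
        assert np.all(np.diff(p) >= 0)
        assert np.all((p >= 0) & (p <= 1))


class TestSelectBreaks:
    def _events(self, n, edep):
        ev = np.zeros(n, dtype=EVENT_DTYPE)
        ev["x"] = np.arange(n, dtype=float) * 100.0
        ev["edep"] = edep
        return ev

    def test_empty_input(self, rng):
        assert select_breaks(np.empty(0, dtype=EVENT_DTYPE),
                             DamageParams(), rng) == []

    def test_dna_fraction_sampling_is_binomial(self, rng):
        # all events above the plateau: acceptance probability = 0.16
        n = 10_000
        breaks = select_breaks(self._events(n, 50.0), DamageParams(), rng)
        p = 0.16
        sigma = np.sqrt(n * p * (1 - p))
        assert abs(len(breaks) - n * p) < 3 * sigma

    def test_subthreshold_events_never_break(self, rng):
        assert select_breaks(self._events(5000, 4.9), DamageParams(), rng) == []

    def test_strand_labels_are_balanced(self, rng):
        breaks = select_breaks(self._events(20_000, 50.0),
                               DamageParams(dna_fraction=1.0), rng)
        ones = sum(1 for b in breaks if b.strand == 1)
        n = len(breaks)
        assert abs(ones - n / 2) < 3 * np.sqrt(n / 4)


class TestClusterBreaks:
    def test_opposite_strand_pair_within_eps_is_sdsb(self):
        s = cluster_breaks(make_breaks([[0, 0, 0], [3.0, 0, 0]], [1, 2]))
        assert (s.n_ssb, s.n_sdsb, s.n_cdsb) == (0, 1, 0)

    def test_pair_beyond_eps_is_two_ssb(self):
        s = cluster_breaks(make_breaks([[0, 0, 0], [3.3, 0, 0]], [1, 2]))
        assert (s.n_ssb, s.n_sdsb, s.n_cdsb) == (2, 0, 0)

    def test_pair_at_exactly_eps_is_not_clustered(self):
        s = cluster_breaks(make_breaks([[0, 0, 0], [3.2, 0, 0]], [1, 2]))
        assert (s.n_ssb, s.n_sdsb, s.n_cdsb) == (2, 0, 0)

    def test_density_reachable_chain_is_cdsb(self):
        s = cluster_breaks(
            make_breaks([[0, 0, 0], [2.5, 0, 0], [5.0, 0, 0]], [1, 2, 1])
        )
        assert (s.n_ssb, s.n_sdsb, s.n_cdsb) == (0, 0, 1)
        assert s.cluster_sizes == {3: 1}

    def test_same_strand_cluster_counts_as_tandem_ssb(self):
        s = cluster_breaks(make_breaks([[0, 0, 0], [2.0, 0, 0]], [1, 1]))
        assert (s.n_ssb, s.n_sdsb, s.n_cdsb) == (2, 0, 0)
        assert s.cluster_sizes == {2: 1}  # histogram still records the cluster

    def test_strandless_mode_scores_any_pair_as_dsb(self):
        s = cluster_breaks(
            make_breaks([[0, 0, 0], [2.0, 0, 0]], [1, 1]),
            DamageParams(strandless=True),
        )
        assert (s.n_ssb, s.n_sdsb, s.n_cdsb) == (0, 1, 0)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_matches_brute_force_union_find(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(0, 200))
        # dense enough that clusters of several sizes actually occur
        positions = rng.uniform(0, 40.0, size=(n, 3))
        strands = rng.integers(1, 3, size=n)
        params = DamageParams()
        got = cluster_breaks(make_breaks(positions, strands), params)
        exp_ssb, exp_sdsb, exp_cdsb, exp_sizes = brute_force_summary(
            positions, strands, params
        )
        assert got.n_ssb == exp_ssb
        assert got.n_sdsb == exp_sdsb
        assert got.n_cdsb == exp_cdsb
        assert dict(got.cluster_sizes) == exp_sizes

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_break_conservation_and_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 150))
        positions = rng.uniform(0, 30.0, size=(n, 3))
        strands = rng.integers(1, 3, size=n)
        breaks = make_breaks(positions, strands)
        s = cluster_breaks(breaks)
        clustered = sum(size * cnt for size, cnt in s.dsb_sizes.items())
        assert s.n_ssb + clustered == n
        perm = rng.permutation(n)
        s2 = cluster_breaks([breaks[i] for i in perm])
        assert (s.n_ssb, s.n_sdsb, s.n_cdsb) == (s2.n_ssb, s2.n_sdsb, s2.n_cdsb)

    def test_larger_eps_never_declusters(self, rng):
        positions = rng.uniform(0, 25.0, size=(80, 3))
        strands = rng.integers(1, 3, size=80)
        clustered = []
        for eps in (1.0, 2.0, 3.2, 5.0, 8.0):
            s = cluster_breaks(make_breaks(positions, strands),
                               DamageParams(eps_nm=eps))
            clustered.append(
                sum(size * cnt for size, cnt in s.cluster_sizes.items())
            )
        assert all(a <= b for a, b in zip(clustered, clustered[1:]))


class TestScoreDamage:
    def _cloud(self, offsets, base):
        ev = np.zeros(len(offsets), dtype=EVENT_DTYPE)
        ev["x"] = base + np.asarray(offsets, float)
        ev["edep"] = 100.0
        return ev

    def test_no_cross_decay_clustering(self, rng):
        # one accepted break per decay, 1 nm apart across decays
        params = DamageParams(dna_fraction=1.0)
        events = {0: self._cloud([0.0], 0.0), 1: self._cloud([0.0], 1.0)}
        _, agg = score_damage(events, params, rng)
        assert agg.n_ssb == 2
        assert agg.n_sdsb == agg.n_cdsb == 0

    def test_zero_decays_zero_summary(self, rng):
        _, agg = score_damage({}, DamageParams(), rng)
        assert (agg.n_ssb, agg.n_sdsb, agg.n_cdsb, agg.n_decays) == (0, 0, 0, 0)

    def test_ssb_scales_linearly_with_event_count(self, rng):
        # Poisson thinning: doubling isolated events doubles expected SSBs
        def run(n_events, seed):
            r = np.random.default_rng(seed)
            ev = np.zeros(n_events, dtype=EVENT_DTYPE)
            ev["x"] = np.arange(n_events) * 50.0  # all isolated
            ev["edep"] = 50.0
            _, agg = score_damage({0: ev}, DamageParams(), r)
            return agg.n_ssb

        a = np.mean([run(2000, s) for s in range(10)])
        b = np.mean([run(4000, s) for s in range(10, 20)])
        assert b / a == pytest.approx(2.0, rel=0.15)


class TestEventFileRoundTrip:
    def test_round_trip(self, tmp_path, rng):
        events = {
            0: self._rand_events(rng, 17),
            3: self._rand_events(rng, 5),
        }
        path = tmp_path / "events.tsv"
        write_event_file(path, events)
        back = read_event_file(path)
        assert set(back) == {0, 3}
        for k in back:
            np.testing.assert_allclose(back[k]["x"], events[k]["x"])
            np.testing.assert_allclose(back[k]["edep"], events[k]["edep"])

    @staticmethod
    def _rand_events(rng, n):
        ev = np.zeros(n, dtype=EVENT_DTYPE)
        for f in ("x", "y", "z"):
            ev[f] = rng.uniform(-100, 100, n)
        ev["edep"] = rng.exponential(37.5, n)
        return ev
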