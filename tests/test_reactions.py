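"""Propensity formulas and firing semantics of the six reaction classes."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import polysim as ps
from polysim.reactions import falling_factorial


def brute_force_ordered_tuples(n, k):
    """Oracle: number of ordered k-tuples of distinct molecules among n."""
    return sum(1 for _ in itertools.permutations(range(n), k))


class TestChemicalPropensity:
    def test_two_reactant_mass_action(self):
        system = ps.ReactionSystem()
        system.add_free_chemical("A", 3)
        system.add_free_chemical("B", 4)
        system.add_free_chemical("C", 0)
        rxn = system.add_chemical_reaction([("A", 1), ("B", 1)], [("C", 1)],
                                           k_forward=2.0)
        assert ps.propensity_chemical(rxn) == pytest.approx(24.0)

    def test_dimerization_uses_falling_factorial(self):
        system = ps.ReactionSystem()
        system.add_free_chemical("A", 5)
        system.add_free_chemical("B", 0)
        rxn = system.add_chemical_reaction([("A", 2)], [("B", 1)],
                                           k_forward=1.0)
        assert ps.propensity_chemical(rxn) == pytest.approx(20.0)
        assert ps.propensity_chemical(rxn) == brute_force_ordered_tuples(5, 2)

    def test_exhausted_reactant_gives_zero(self):
        system = ps.ReactionSystem()
        system.add_free_chemical("A", 3)
        system.add_free_chemical("B", 0)
        system.add_free_chemical("C", 0)
        rxn = system.add_chemical_reaction([("A", 1), ("B", 1)], [("C", 1)],
                                           k_forward=2.0)
        assert ps.propensity_chemical(rxn) == 0.0

    @given(n=st.integers(0, 8), k=st.integers(1, 4))
    def test_falling_factorial_matches_enumeration(self, n, k):
        assert falling_factorial(n, k) == brute_force_ordered_tuples(n, k)

    def test_threshold_law_gates_on_stack(self):
        system = ps.ReactionSystem()
        system.add_free_chemical("spent", 99)
        system.add_free_chemical("fresh", 0)
        rxn = system.add_chemical_reaction([("spent", 100)], [("fresh", 100)],
                                           k_forward=3.0, rate_law="threshold")
        assert rxn.propensity() == 0.0
        system.free_chemicals["spent"].count = 100
        assert rxn.propensity() == 3.0
        rxn.fire("forward", np.random.default_rng(0))
        assert system.free_chemicals["fresh"].count == 100
        assert system.free_chemicals["spent"].count == 0

    def test_bound_product_without_bound_reactant_rejected(self):
        system = ps.ReactionSystem()
        system.add_free_chemical("A", 1)
        system.add_bound_chemical("bc")
        with pytest.raises(ps.ValidationError):
            system.add_chemical_reaction([("A", 1)], [("bc", 1)], 1.0)


class TestBindingPropensity:
    def _system(self, copies=1, k_on=0.1, k_off=0.5, free=10):
        system = ps.ReactionSystem()
        system.add_free_chemical("pol", free)
        system.add_sequence("seq", "A" * 50, copies=copies)
        system.register_binding_site("fam", "seq", 0, 10, k_on, k_off, 0)
        system.add_bound_chemical("bound")
        binding = system.add_sequence_binding("pol", "bound", "fam")
        return system, binding

    def test_forward_counts_free_and_available(self):
        _, binding = self._system()
        fwd, rev = ps.propensity_binding(binding)
        assert fwd == pytest.approx(1.0)  # 10 * 0.1 * 1
        assert rev == 0.0

    def test_occupied_site_gives_zero_forward(self, rng):
        system, binding = self._system()
        binding.fire_forward(rng)
        fwd, _ = ps.propensity_binding(binding)
        assert fwd == 0.0

    def test_reverse_sums_over_on_origin_units(self, rng):
        system, binding = self._system(copies=3)
        binding.fire_forward(rng)
        binding.fire_forward(rng)
        _, rev = ps.propensity_binding(binding)
        assert rev == pytest.approx(1.0)  # 2 units * k_off 0.5

    def test_fire_binding_bookkeeping(self, rng):
        system, binding = self._system(copies=3)
        unit_count = len(system.bound_chemicals["bound"])
        binding.fire_forward(rng)
        assert system.free_chemicals["pol"].count == 9
        assert len(system.bound_chemicals["bound"]) == unit_count + 1
        assert system.available_site_count("fam") == 2

    def test_buffered_free_form_not_consumed(self, rng):
        system = ps.ReactionSystem()
        system.add_free_chemical("pol", 10, buffered=True)
        system.add_sequence("seq", "A" * 50, copies=5)
        system.register_binding_site("fam", "seq", 0, 10, 0.1, 0.0, 0)
        system.add_bound_chemical("bound")
        binding = system.add_sequence_binding("pol", "bound", "fam")
        binding.fire_forward(rng)
        assert system.free_chemicals["pol"].count == 10
        assert len(system.bound_chemicals["bound"]) == 1

    def test_site_choice_proportional_to_kon(self, rng):
        system = ps.ReactionSystem()
        # copy number large enough that occupancy feedback on the site
        # weights stays negligible over the draws
        system.add_free_chemical("pol", 100_000, buffered=True)
        system.add_sequence("seq", "A" * 100, copies=20_000_000)
        s1 = system.register_binding_site("fam", "seq", 0, 10, 0.1, 0.0, 0)
        s2 = system.register_binding_site("fam", "seq", 50, 60, 0.3, 0.0, 50)
        system.add_bound_chemical("bound")
        binding = system.add_sequence_binding("pol", "bound", "fam")
        n = 20_000
        for _ in range(n):
            binding.fire_forward(rng)
        f1 = s1.occupied / n
        assert abs(f1 - 0.25) < 0.01


class TestTranslocationAndSwitch:
    def _system(self):
        system = ps.ReactionSystem()
        system.add_sequence("seq", "A" * 40, copies=1)
        mobile = system.add_bound_chemical("mobile")
        post = system.add_bound_chemical("post")
        term = system.add_bound_chemical("terminated")
        system.add_switch("term", "post", "terminated")
        return system, mobile, post, term

    def _place(self, system, bc, position):
        u = system.new_unit()
        u.sequence = system.sequences["seq"]
        u.position = position
        bc.add(u)
        return u

    def test_single_step(self, rng):
        system, mobile, post, _ = self._system()
        tr = system.add_translocation("mobile", "post", 1, 50.0)
        u = self._place(system, mobile, 10)
        tr.fire(rng)
        assert u.position == 11
        assert u in post

    def test_codon_step(self, rng):
        system, mobile, post, _ = self._system()
        tr = system.add_translocation("mobile", "post", 3, 150.0)
        u = self._place(system, mobile, 0)
        tr.fire(rng)
        assert u.position == 3

    def test_switch_on_landing(self, rng):
        system, mobile, post, term = self._system()
        system.add_switch_site("seq", 20, "term")
        tr = system.add_translocation("mobile", "post", 1, 50.0)
        u = self._place(system, mobile, 19)
        tr.fire(rng)
        assert u.position == 20
        assert u in term and u not in post

    def test_propensity_scales_with_members(self, rng):
        system, mobile, post, _ = self._system()
        tr = system.add_translocation("mobile", "post", 1, 50.0)
        for pos in (0, 5, 9):
            self._place(system, mobile, pos)
        assert tr.propensity() == pytest.approx(150.0)

    def test_first_step_clears_origin(self, rng):
        system = ps.ReactionSystem()
        system.add_free_chemical("pol", 5)
        system.add_sequence("seq", "A" * 40, copies=1)
        system.register_binding_site("fam", "seq", 0, 5, 1.0, 0.0, 0)
        system.add_bound_chemical("bound")
        system.add_bound_chemical("post")
        binding = system.add_sequence_binding("pol", "bound", "fam")
        tr = system.add_translocation("bound", "post", 1, 1.0)
        binding.fire_forward(rng)
        assert system.available_site_count("fam") == 0
        tr.fire(rng)
        assert system.available_site_count("fam") == 1


class TestLoading:
    def _system(self, pool=100, buffered=False):
        system = ps.ReactionSystem()
        atp = system.add_free_chemical("ATP", pool, buffered=buffered)
        system.add_free_chemical("PPi", 0)
        system.add_sequence("seq", "TTTTTAAAAA", copies=1)
        loader = system.add_bound_chemical("loader")
        loaded = system.add_bound_chemical("loaded")
        loading = system.add_loading("loader", 1,
                                     {"T": (atp, ["PPi"], 0.1, loaded)})
        return system, loader, loaded, loading

    def _place(self, system, bc, position):
        u = system.new_unit()
        u.sequence = system.sequences["seq"]
        u.position = position
        bc.add(u)
        return u

    def test_total_propensity_and_decomposition(self):
        system, loader, _, loading = self._system()
        self._place(system, loader, 0)
        self._place(system, loader, 1)
        total, decomp = ps.propensity_loading(loading)
        assert total == pytest.approx(20.0)  # 0.1 * 100 * 2
        assert decomp == {"T": pytest.approx(20.0)}

    def test_exhausted_pool_gives_zero(self):
        system, loader, _, loading = self._system(pool=0)
        self._place(system, loader, 0)
        total, decomp = ps.propensity_loading(loading)
        assert total == 0.0

    def test_overrunning_unit_contributes_zero(self):
        system, loader, _, loading = self._system()
        self._place(system, loader, 10)  # window [10, 11) overruns
        total, _ = ps.propensity_loading(loading)
        assert total == 0.0

    def test_unknown_motif_contributes_zero(self):
        system, loader, _, loading = self._system()
        self._place(system, loader, 7)  # reading "A", not in the table
        assert loading.propensity() == 0.0

    def test_fire_consumes_and_reassigns(self, rng):
        system, loader, loaded, loading = self._system()
        u = self._place(system, loader, 0)
        loading.fire(rng)
        assert system.free_chemicals["ATP"].count == 99
        assert system.free_chemicals["PPi"].count == 1
        assert u in loaded

    def test_buffered_pool_unchanged(self, rng):
        system, loader, loaded, loading = self._system(buffered=True)
        self._place(system, loader, 0)
        loading.fire(rng)
        assert system.free_chemicals["ATP"].count == 100


class TestRelease:
    def _system(self, on_unmatched="error"):
        system = ps.ReactionSystem()
        pol = system.add_free_chemical("pol", 0)
        system.add_sequence("seq", "A" * 100, copies=1)
        system.add_sequence("mRNA1", "A" * 40, copies=0)
        system.register_binding_site("P1", "seq", 0, 10, 0.1, 0.0, 10)
        releasing = system.add_bound_chemical("terminating")
        release = system.add_release("terminating", 1.0, [pol],
                                     [("P1", 50, 60, "mRNA1")],
                                     on_unmatched=on_unmatched)
        return system, releasing, release

    def _place(self, system, bc, position):
        u = system.new_unit()
        u.sequence = system.sequences["seq"]
        u.position = position
        u.origin_site = system.families["P1"].sites[0]
        bc.add(u)
        return u

    def test_product_lookup_by_family_and_position(self, rng):
        system, releasing, release = self._system()
        self._place(system, releasing, 55)
        release.fire(rng)
        assert system.sequences["mRNA1"].copies == 1
        assert system.free_chemicals["pol"].count == 1
        assert len(releasing) == 0

    def test_unmatched_position_raises(self, rng):
        system, releasing, release = self._system()
        self._place(system, releasing, 5)
        with pytest.raises(ps.UnmatchedReleaseError):
            release.fire(rng)

    def test_unmatched_can_warn_instead(self, rng):
        system, releasing, release = self._system(on_unmatched="warn")
        self._place(system, releasing, 5)
        with pytest.warns(UserWarning):
            release.fire(rng)
        assert system.sequences["mRNA1"].copies == 0
        assert system.free_chemicals["pol"].count == 1

    def test_overlapping_intervals_rejected(self):
        system = ps.ReactionSystem()
        system.add_sequence("seq", "A" * 100, copies=1)
        system.add_sequence("m1", "A" * 10, copies=0)
        system.add_sequence("m2", "A" * 10, copies=0)
        system.register_binding_site("P1", "seq", 0, 10, 0.1, 0.0, 0)
        system.add_bound_chemical("rel")
        with pytest.raises(ps.ValidationError):
            system.add_release("rel", 1.0, [],
                               [("P1", 50, 60, "m1"), ("P1", 55, 65, "m2")])


class TestTimedEvents:
    def test_add_set_remove(self):
        system = ps.ReactionSystem()
        tet = system.add_free_chemical("tet", 0)
        system.add_event(200.0, "ADD", "tet", 20_000).apply()
        assert tet.count == 20_000
        system.add_event(300.0, "SET", "tet", 7).apply()
        assert tet.count == 7
        system.add_event(400.0, "REMOVE_FREE", "tet", 10).apply()
        assert tet.count == 0  # clamped at zero

    def test_remove_free_leaves_bound_form(self, rng):
        """Washing the free pool must not touch sequestered complexes."""
        system = ps.ReactionSystem()
        tet = system.add_free_chemical("tet", 5)
        system.add_sequence("seq", "A" * 10, copies=1)
        stalled = system.add_bound_chemical("stalled")
        u = system.new_unit()
        u.sequence = system.sequences["seq"]
        stalled.add(u)
        system.add_event(400.0, "REMOVE_FREE", "tet", 10).apply()
        assert tet.count == 0
        assert len(stalled) == 1

    def test_unknown_target_rejected(self):
        system = ps.ReactionSystem()
        with pytest.raises(ps.UnknownComponentError):
            system.add_event(1.0, "ADD", "ghost", 5)

    def test_bad_kind_rejected(self):
        system = ps.ReactionSystem()
        system.add_free_chemical("x", 0)
        with pytest.raises(ps.ValidationError):
            system.add_event(1.0, "DROP", "x", 5)


class TestEngineInvariants:
    def test_mass_conservation_in_cascade(self):
        system = ps.build_n_cascade(10, 1000)
        system.observe(*[f"A_{i}" for i in range(11)])
        traj = ps.run(system, t_end=math.inf, seed=4, solver="direct",
                      log_period=2.0)
        totals = np.zeros(len(traj.times), dtype=int)
        for i in range(11):
            totals += np.array(traj.series(f"A_{i}"))
        assert np.all(totals == 100)

    def test_reversible_reaction_reaches_equilibrium_ratio(self):
        """Two-species isomerization: the stationary split follows
        k_forward/k_backward (binomial mean), checked within 3 SE."""
        kf, kb, n, reps = 0.1, 0.05, 100, 300
        p_b = kf / (kf + kb)
        finals = []
        for rep in range(reps):
            system = ps.ReactionSystem()
            system.add_free_chemical("A", n)
            system.add_free_chemical("B", 0)
            system.add_chemical_reaction([("A", 1)], [("B", 1)], kf, kb)
            system.observe("B")
            traj = ps.run(system, t_end=60.0, seed=1000 + rep, solver="cr",
                          log_period=60.0)
            finals.append(traj.final("B"))
        mean = np.mean(finals)
        se = math.sqrt(n * p_b * (1 - p_b) / reps)
        assert abs(mean - n * p_b) < 3 * se

    def test_dependency_refresh_matches_full_recomputation(self, rng):
        """Firing channels and refreshing only the dependents listed in
        the read map reproduces a from-scratch propensity recomputation at
        every step (superset correctness of the dependency graph)."""
        genome = ps.synthesize_genome(2, rng_seed=5)
        system = ps.build_gene_expression(genome, granularity="detailed")
        system.finalize()
        store = {ch.index: ch.compute() for ch in system.channels}
        for _ in range(3000):
            live = [i for i, a in store.items() if a > 0.0]
            if not live:
                break
            j = live[int(rng.integers(0, len(live)))]
            touched = system.channels[j].fire(rng)
            for key in touched:
                for ci in system.read_map.get(key, ()):
                    store[ci] = system.channels[ci].compute()
            fresh = {ch.index: ch.compute() for ch in system.channels}
            assert store == fresh
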