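"""Synthetic genomes and the benchmark/case-study model builders."""

import numpy as np
import pytest

import polysim as ps


class TestSyntheticGenome:
    def test_deterministic_given_seed(self):
        a = ps.synthesize_genome(5, rng_seed=42)
        b = ps.synthesize_genome(5, rng_seed=42)
        assert a.letters == b.letters
        assert a.genes == b.genes

    def test_invariants_hold(self):
        genome = ps.synthesize_genome(10, (300, 600), rng_seed=7)
        genome.validate()
        for g in genome.genes:
            assert g.promoter[0] < g.tss < g.terminator <= genome.length
            assert g.coding_length % 3 == 0
            assert (g.transcript(genome.letters)[g.start_codon:
                                                 g.start_codon + 3] == "ATG")

    def test_degenerate_length_range_rejected(self):
        with pytest.raises(ps.ValidationError):
            ps.synthesize_genome(3, (600, 300))
        with pytest.raises(ps.ValidationError):
            ps.synthesize_genome(0, (300, 600))

    def test_protein_translation(self):
        genome = ps.synthesize_genome(2, rng_seed=1)
        for g in genome.genes:
            protein = g.protein(genome.letters)
            assert protein.startswith("M")
            assert len(protein) == g.coding_length // 3

    @pytest.mark.parametrize("granularity",
                             ["detailed", "aggregated", "hybrid"])
    def test_runs_under_all_granularities(self, granularity):
        genome = ps.synthesize_genome(10, (300, 600), rng_seed=3)
        system = ps.build_gene_expression(
            genome, granularity=granularity, rng=np.random.default_rng(1))
        traj = ps.run(system, t_end=20.0, seed=2, solver="cr",
                      log_period=10.0)
        assert traj.event_count > 0


class TestCascadeBuilder:
    def test_initial_molecules_n10(self):
        system = ps.build_n_cascade(10)
        assert system.free_chemicals["A_0"].count == 100_000
        assert len(system.reactions) == 10

    def test_initial_molecules_n1000(self):
        system = ps.build_n_cascade(1000)
        assert system.free_chemicals["A_0"].count == 1000
        assert len(system.free_chemicals) == 1001

    def test_non_divisor_rejected(self):
        with pytest.raises(ps.ValidationError):
            ps.build_n_cascade(7)


class TestUnitConversion:
    @pytest.mark.parametrize("mm,expected", [
        (1.0, 600_000),
        (0.0, 0),
        (10.0, 6_000_000),
    ])
    def test_examples(self, mm, expected):
        assert ps.concentration_to_molecules(mm) == expected

    def test_negative_rejected(self):
        with pytest.raises(ps.ValidationError):
            ps.concentration_to_molecules(-1.0)


class TestGeneExpressionBuilder:
    def test_aggregated_adds_two_reactions_per_gene(self):
        genome = ps.synthesize_genome(20, rng_seed=11)
        system = ps.build_gene_expression(genome, granularity="aggregated")
        agg = [r for r in system.reactions if r.tag == "aggregate"]
        # transcription and translation are both aggregated
        assert len(agg) == 2 * 2 * 20
        transcription_agg = [r for r in agg
                             if getattr(r, "mobile_class", None) is not None
                             and r.mobile_class.name.startswith("RNAP")]
        assert len(transcription_agg) == 20

    def test_aggregated_offset_is_fifty_bases(self):
        genome = ps.synthesize_genome(5, rng_seed=11)
        system = ps.build_gene_expression(genome, granularity="aggregated")
        hops = [r for r in system.reactions
                if r.kind == "translocation" and r.tag == "aggregate"]
        assert hops and all(r.step == 50 for r in hops)
        releases = [r for r in system.reactions
                    if r.kind == "release" and r.tag == "aggregate"]
        by_family = {rule.family: rule for r in releases for rule in r.rules}
        for gene in genome.genes:
            rule = by_family[f"promoter_{gene.name}"]
            assert rule.first == gene.tss + 50

    def test_hybrid_five_percent_split(self):
        genome = ps.synthesize_genome(20, rng_seed=11)
        system = ps.build_gene_expression(
            genome, granularity="hybrid", hybrid_detailed_fraction=0.05,
            rng=np.random.default_rng(5))
        assert len(system.metadata["detailed_genes"]) == 1
        assert len(system.metadata["aggregated_genes"]) == 19

    def test_detailed_genes_forced_into_detailed_set(self):
        genome = ps.synthesize_genome(10, rng_seed=11)
        system = ps.build_gene_expression(
            genome, granularity="hybrid", rng=np.random.default_rng(5),
            detailed_genes=["gene07"])
        assert "gene07" in system.metadata["detailed_genes"]

    def test_bad_fraction_rejected(self):
        genome = ps.synthesize_genome(2, rng_seed=0)
        with pytest.raises(ps.ValidationError):
            ps.build_gene_expression(genome, granularity="hybrid",
                                     hybrid_detailed_fraction=1.5)

    def test_promoter_strengths_scale_k_on(self):
        genome = ps.synthesize_genome(3, rng_seed=0)
        strengths = [1.0, 2.0, 4.0]
        system = ps.build_gene_expression(genome, granularity="detailed",
                                          promoter_strengths=strengths)
        params = system.metadata["params"]
        for gene, s in zip(genome.genes, strengths):
            site = system.families[f"promoter_{gene.name}"].sites[0]
            assert site.k_on == pytest.approx(params.promoter_k_on * s)

    def test_metabolism_modes(self):
        genome = ps.synthesize_genome(2, rng_seed=0)
        constant = ps.build_gene_expression(genome, metabolism="constant")
        assert constant.free_chemicals["ATP"].buffered
        stacked = ps.build_gene_expression(genome, metabolism="stacked")
        assert not stacked.free_chemicals["ATP"].buffered
        stacks = [r for r in stacked.reactions
                  if getattr(r, "rate_law", "") == "threshold"]
        assert stacks and all(
            st == 100 for r in stacks for _, st in
            [(fc.name, s) for fc, s in r.reactants.free])


class TestReplicationBuilder:
    def test_balance_relation_asserted(self):
        genome = ps.synthesize_genome(1, (150, 200), rng_seed=0)
        system = ps.build_replication(genome)
        params = ps.ExpressionParams()
        assert ps.recruitment_balance(
            params.dnap_free, params.recruitment_rate) == pytest.approx(0.75)

    def test_off_balance_parameters_rejected(self):
        genome = ps.synthesize_genome(1, (150, 200), rng_seed=0)
        params = ps.ExpressionParams(recruitment_rate=0.2)
        with pytest.raises(ps.ValidationError):
            ps.build_replication(genome, params)

    def test_replication_completes_a_strand(self):
        genome = ps.synthesize_genome(1, (150, 200), rng_seed=0)
        system = ps.build_replication(genome)
        traj = ps.run(system, t_end=30.0, seed=1, solver="cr",
                      log_period=10.0)
        assert traj.final("replicated_strand") >= 1


class TestTetracyclineBuilder:
    def test_schedule_and_records(self):
        genome = ps.synthesize_genome(3, rng_seed=0)
        system = ps.build_gene_expression(genome, granularity="detailed")
        n_reactions = len(system.reactions)
        ps.build_tetracycline_extension(system, 20_000)
        assert "tetracycline" in system.free_chemicals
        assert len(system.reactions) == n_reactions + 1
        kinds = [(e.time, e.kind) for e in sorted(system.events,
                                                  key=lambda e: e.time)]
        assert kinds[0] == (200.0, "ADD")
        assert all(k == "REMOVE_FREE" and t >= 400.0 for t, k in kinds[1:])

    def test_missing_ribosome_class_rejected(self):
        system = ps.build_n_cascade(10, 1000)
        with pytest.raises(ps.UnknownComponentError):
            ps.build_tetracycline_extension(system, 20_000)

    def test_sequestration_is_reversible(self):
        genome = ps.synthesize_genome(2, rng_seed=0)
        system = ps.build_gene_expression(genome, granularity="detailed")
        ps.build_tetracycline_extension(system, 20_000)
        rxn = next(r for r in system.reactions if r.tag == "tetracycline")
        assert rxn.k_backward > 0
        assert rxn.reactants.bound.name == "70S_loading"
        assert rxn.products.bound.name == "70S_tet_stalled"


class TestTboxBuilder:
    def _system(self):
        genome = ps.synthesize_genome(5, rng_seed=4)
        system = ps.build_gene_expression(
            genome, granularity="hybrid", rng=np.random.default_rng(1),
            detailed_genes=["gene02"])
        return genome, system

    def test_requires_detailed_gene(self):
        genome, system = self._system()
        with pytest.raises(ps.ValidationError):
            ps.build_tbox_extension(system, "gene04")  # aggregated gene

    def test_schedule(self):
        _, system = self._system()
        ps.build_tbox_extension(system, "gene02")
        events = {(e.time, e.kind, e.target.name) for e in system.events}
        assert (200.0, "SET", "tyrosine") in events
        assert (600.0, "ADD", "tyrosine") in events

    def test_abort_release_maps_to_aborted_transcript(self):
        genome, system = self._system()
        ps.build_tbox_extension(system, "gene02")
        release = next(r for r in system.reactions
                       if r.kind == "release" and r.tag == "tbox")
        assert release.releasing_class.name == "RNAP_aborting"
        rule = release.rules[0]
        assert rule.product.name == "aborted_gene02"
        gene = next(g for g in genome.genes if g.name == "gene02")
        assert rule.first == gene.tss + 25
        assert len(rule.product.letters) == 25

    def test_switch_site_annotated_in_leader(self):
        genome, system = self._system()
        ps.build_tbox_extension(system, "gene02")
        gene = next(g for g in genome.genes if g.name == "gene02")
        positions = [ss.position for ss in
                     system.sequences["genome"].switch_sites
                     if ss.switch.name == "tbox_gene02"]
        assert positions == [gene.tss + 25]


class TestExpressionParams:
    def test_defaults_validate(self):
        ps.ExpressionParams().validate()

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ps.ValidationError):
            ps.ExpressionParams(transcription_translocation=0).validate()
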