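"""Programmatic builders for the benchmark and case-study models.

All models are desk-scale: linear conversion cascades for solver
benchmarking, gene expression (transcription + translation) on synthetic
genomes at three granularities, a single-origin replication template, and
the two regulatory extensions (tetracycline inhibition of translation,
T-box attenuation of one gene's transcription).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import UnknownComponentError, ValidationError
from .genomes import SyntheticGenome, synthesize_genome  # noqa: F401
from .system import ReactionSystem

GRANULARITIES = ("detailed", "aggregated", "hybrid")
METABOLISMS = ("constant", "detailed", "stacked")

#: monomer carrier loaded per template letter (transcription reads the
#: coding strand and loads the corresponding ribonucleotide)
NTP_FOR_BASE = {"A": "ATP", "C": "CTP", "G": "GTP", "T": "UTP"}
DNTP_FOR_BASE = {"A": "dATP", "C": "dCTP", "G": "dGTP", "T": "dTTP"}

STOP_CODONS = ("TAA", "TAG", "TGA")
SENSE_CODONS = tuple(a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
                     if a + b + c not in STOP_CODONS)


@dataclass
class ExpressionParams:
    """Kinetic and desk-scale population parameters for gene expression.

    Rates are per second.  The elongation cycles set translocation
    (transcription, replication) or loading (translation) as the limiting
    step, with the other steps 10-100x faster; effective loading rates are
    achieved as rate-constant x carrier-pool-size, mirroring how loading
    scales with monomer abundance.
    """
    # transcription: ~50 nt/s limited by translocation
    transcription_translocation: float = 50.0
    transcription_polymerization: float = 500.0
    transcription_loading: float = 1000.0       # effective, within 600-2100
    # translation: ~20 aa/s limited by loading
    translation_loading: float = 20.0           # effective
    translation_transpeptidation: float = 150.0
    translation_translocation: float = 150.0
    # replication: ~750 bp/s limited by translocation
    replication_translocation: float = 750.0
    replication_polymerization: float = 10000.0
    replication_loading: float = 3000.0         # effective, within 1000-10000
    # initiation / termination last about 1 s
    initiation_rate: float = 1.0
    termination_rate: float = 1.0
    # promoter / RBS strength: recruitment rate per free polymerase/ribosome
    promoter_k_on: float = 0.02
    promoter_k_off: float = 0.0
    rbs_k_on: float = 0.02
    rbs_k_off: float = 0.0
    # replication fork arithmetic
    okazaki_length: int = 1000                  # bp per lagging-strand fragment
    dnap_copies: int = 10
    dnap_free: float = 7.5                      # engaged polymerases deduced
    recruitment_rate: float = 0.1
    # cell geometry / cycle
    cell_volume_l: float = 1e-15
    cell_cycle_s: float = 2700.0                # tau ~ 40-50 min
    # desk-scale machine and pool sizes
    rnap_copies: int = 5
    ribosome_copies: int = 8
    ntp_pool: int = 1_000_000
    dntp_pool: int = 100_000_000
    trna_pool: int = 100_000

    def validate(self) -> None:
        for name, value in self.__dict__.items():
            if isinstance(value, (int, float)) and value <= 0 \
                    and name not in ("promoter_k_off", "rbs_k_off"):
                raise ValidationError(f"parameter {name} must be positive")


def concentration_to_molecules(conc_mm: float, volume_l: float = 1e-15,
                               avogadro: float = 6e23) -> int:
    """Molecule count of a concentration given in mM: 1 mM in a 1e-15 L
    cell is 1e-3 * 6e23 * 1e-15 = 6e5 molecules."""
    if conc_mm < 0:
        raise ValidationError("concentration must be >= 0")
    return round(conc_mm * 1e-3 * avogadro * volume_l)


# ----------------------------------------------------------------------
# n-cascades
# ----------------------------------------------------------------------

def build_n_cascade(n: int, total_events: int = 1_000_000) -> ReactionSystem:
    """Linear pathway A_0 -> A_1 -> ... -> A_n with unit rate constants and
    total_events/n initial molecules of A_0, so a complete run fires
    exactly ``total_events`` reactions regardless of seed and solver."""
    if n < 1:
        raise ValidationError("cascade length must be >= 1")
    if total_events % n != 0:
        raise ValidationError(
            f"total_events={total_events} is not divisible by n={n}")
    system = ReactionSystem()
    chems = [system.add_free_chemical(f"A_{i}") for i in range(n + 1)]
    chems[0].count = total_events // n
    for i in range(n):
        system.add_chemical_reaction([(chems[i], 1)], [(chems[i + 1], 1)],
                                     k_forward=1.0)
    system.observe("A_0", f"A_{n}")
    return system


# ----------------------------------------------------------------------
# gene expression
# ----------------------------------------------------------------------

def _ensure_metabolite(system, name, count, metabolism, stack,
                       spent_name=None):
    """Create a monomer-carrier pool under one of the renewal modes:
    buffered (constant), per-molecule regeneration (detailed) or
    stack-wise regeneration (stacked)."""
    spent_name = spent_name or name + "_spent"
    if metabolism == "constant":
        system.add_free_chemical(name, count, buffered=True)
        system.add_free_chemical(spent_name, 0)
        return
    system.add_free_chemical(name, count)
    system.add_free_chemical(spent_name, 0)
    if metabolism == "detailed":
        system.add_chemical_reaction([(spent_name, 1)], [(name, 1)],
                                     k_forward=10.0, tag="metabolism")
    else:  # stacked
        system.add_chemical_reaction([(spent_name, stack)], [(name, stack)],
                                     k_forward=20.0, rate_law="threshold",
                                     tag="metabolism")


def build_gene_expression(genome: SyntheticGenome,
                          params: Optional[ExpressionParams] = None,
                          granularity: str = "detailed",
                          hybrid_detailed_fraction: float = 0.05,
                          rng: Optional[np.random.Generator] = None,
                          metabolism: str = "constant",
                          metabolite_stack: int = 100,
                          promoter_strengths: Optional[Sequence[float]] = None,
                          detailed_genes: Optional[Iterable[str]] = None,
                          ) -> ReactionSystem:
    """Transcription + translation for a synthetic genome.

    Granularities (elongation description):

    * ``detailed``  — nucleotide per nucleotide and codon per codon, one
      generic reaction set shared by all genes plus per-gene annotations;
    * ``aggregated`` — binding stays sequence-based, then the polymerase is
      translocated +50 bases past its binding site (freeing the site), the
      product is created in one step and the polymerase released: exactly
      two additional reactions per gene (tagged ``aggregate``);
    * ``hybrid``    — detailed for a seeded random fraction of genes
      (default 5%), aggregated for the rest; ``detailed_genes`` forces
      specific genes into the detailed set.

    Initiation and termination are identical in all granularities and last
    about one second.  Messengers and proteins are not degraded and
    accumulate.
    """
    if granularity not in GRANULARITIES:
        raise ValidationError(f"unknown granularity {granularity!r}")
    if metabolism not in METABOLISMS:
        raise ValidationError(f"unknown metabolism mode {metabolism!r}")
    if not (0.0 <= hybrid_detailed_fraction <= 1.0):
        raise ValidationError("hybrid detailed fraction must be in [0, 1]")
    params = params or ExpressionParams()
    params.validate()
    genome.validate()
    genes = list(genome.genes)
    if promoter_strengths is None:
        strengths = [1.0] * len(genes)  # promoters all share one strength
    else:
        strengths = list(promoter_strengths)
        if len(strengths) != len(genes):
            raise ValidationError("one promoter strength per gene required")

    forced = set(detailed_genes or ())
    unknown = forced - {g.name for g in genes}
    if unknown:
        raise UnknownComponentError(f"unknown genes {sorted(unknown)}")
    if granularity == "detailed":
        detailed = {g.name for g in genes}
    elif granularity == "aggregated":
        detailed = set(forced)
    else:
        rng = rng or np.random.default_rng(0)
        k = int(round(hybrid_detailed_fraction * len(genes)))
        order = list(rng.permutation(len(genes)))
        detailed = {genes[i].name for i in order[:k]} | forced

    system = ReactionSystem()
    system.metadata["genome"] = genome
    system.metadata["params"] = params
    system.metadata["detailed_genes"] = sorted(detailed)
    system.metadata["aggregated_genes"] = sorted(
        g.name for g in genes if g.name not in detailed)

    rnap = system.add_free_chemical("RNAP", params.rnap_copies)
    ribosome = system.add_free_chemical("ribosome", params.ribosome_copies)
    genome_seq = system.add_sequence("genome", genome.letters, copies=1)

    for ntp in ("ATP", "CTP", "GTP", "UTP"):
        _ensure_metabolite(system, ntp, params.ntp_pool, metabolism,
                           metabolite_stack)
    _ensure_metabolite(system, "tRNA_c", params.trna_pool, metabolism,
                       metabolite_stack, spent_name="tRNA_u")

    # ---- generic transcription machinery (shared by every gene) -------
    rnap_elong = system.add_bound_chemical("RNAP_elongating")
    rnap_loaded = system.add_bound_chemical("RNAP_loaded")
    rnap_ready = system.add_bound_chemical("RNAP_translocating")
    rnap_term = system.add_bound_chemical("RNAP_terminating")
    ntp_const = params.transcription_loading / params.ntp_pool
    system.add_loading(
        rnap_elong, 1,
        {base: (ntp, [ntp + "_spent"], ntp_const, rnap_loaded)
         for base, ntp in NTP_FOR_BASE.items()},
        tag="transcription")
    system.add_chemical_reaction([(rnap_loaded, 1)], [(rnap_ready, 1)],
                                 k_forward=params.transcription_polymerization,
                                 tag="transcription")
    system.add_translocation(rnap_ready, rnap_elong, step=1,
                             rate=params.transcription_translocation,
                             tag="transcription")
    system.add_switch("transcription_termination", rnap_elong, rnap_term)

    # ---- generic translation machinery --------------------------------
    rib_load = system.add_bound_chemical("70S_loading")
    rib_loaded = system.add_bound_chemical("70S_loaded")
    rib_ready = system.add_bound_chemical("70S_translocating")
    rib_term = system.add_bound_chemical("70S_terminating")
    trna = system.free_chemicals["tRNA_c"]
    trna_const = params.translation_loading / params.trna_pool
    system.add_loading(
        rib_load, 3,
        {codon: (trna, ["tRNA_u"], trna_const, rib_loaded)
         for codon in SENSE_CODONS},
        tag="translation")
    system.add_chemical_reaction([(rib_loaded, 1)], [(rib_ready, 1)],
                                 k_forward=params.translation_transpeptidation,
                                 tag="translation")
    system.add_translocation(rib_ready, rib_load, step=3,
                             rate=params.translation_translocation,
                             tag="translation")
    system.add_switch("translation_termination", rib_load, rib_term)

    mrna_release_rows = []
    protein_release_rows = []

    for gene, strength in zip(genes, strengths):
        transcript = gene.transcript(genome.letters)
        mrna = system.add_sequence(f"mRNA_{gene.name}", transcript, copies=0)
        protein = system.add_sequence(f"protein_{gene.name}",
                                      gene.protein(genome.letters) or "M",
                                      copies=0)
        # promoter annotation + sequence-based binding (all granularities)
        prom_family = f"promoter_{gene.name}"
        system.register_binding_site(prom_family, genome_seq,
                                     gene.promoter[0], gene.promoter[1],
                                     k_on=params.promoter_k_on * strength,
                                     k_off=params.promoter_k_off,
                                     reading_offset=gene.tss)
        rnap_bound = system.add_bound_chemical(f"RNAP_bound_{gene.name}")
        system.add_sequence_binding(rnap, rnap_bound, prom_family,
                                    tag="initiation")
        # RBS annotation + ribosome binding on the transcript
        rbs_family = f"rbs_{gene.name}"
        system.register_binding_site(rbs_family, mrna,
                                     gene.rbs[0], gene.rbs[1],
                                     k_on=params.rbs_k_on,
                                     k_off=params.rbs_k_off,
                                     reading_offset=gene.start_codon)
        rib_bound = system.add_bound_chemical(f"70S_bound_{gene.name}")
        system.add_sequence_binding(ribosome, rib_bound, rbs_family,
                                    tag="initiation")

        if gene.name in detailed:
            # initiation hands the particle to the shared elongation classes
            system.add_chemical_reaction([(rnap_bound, 1)], [(rnap_elong, 1)],
                                         k_forward=params.initiation_rate,
                                         tag="initiation")
            system.add_switch_site(genome_seq, gene.terminator,
                                   "transcription_termination")
            mrna_release_rows.append((prom_family, gene.terminator,
                                      gene.terminator + 1, mrna))
            system.add_chemical_reaction([(rib_bound, 1)], [(rib_load, 1)],
                                         k_forward=params.initiation_rate,
                                         tag="initiation")
            system.add_switch_site(mrna, gene.stop_codon,
                                   "translation_termination")
            protein_release_rows.append((rbs_family, gene.stop_codon,
                                         gene.stop_codon + 3, protein))
        else:
            # aggregated shortcut: +50-base hop frees the site, then the
            # product appears in one step and the polymerase is released
            rnap_agg = system.add_bound_chemical(f"RNAP_agg_{gene.name}")
            system.add_translocation(rnap_bound, rnap_agg, step=50,
                                     rate=params.initiation_rate,
                                     tag="aggregate")
            synth_rate = (params.transcription_translocation /
                          gene.transcript_length)
            system.add_release(rnap_agg, synth_rate, [rnap],
                               [(prom_family, gene.tss + 50, gene.tss + 51,
                                 mrna)],
                               tag="aggregate")
            rib_agg = system.add_bound_chemical(f"70S_agg_{gene.name}")
            system.add_translocation(rib_bound, rib_agg, step=50,
                                     rate=params.initiation_rate,
                                     tag="aggregate")
            n_codons = max(1, gene.coding_length // 3)
            system.add_release(rib_agg, params.translation_loading / n_codons,
                               [ribosome],
                               [(rbs_family, gene.start_codon + 50,
                                 gene.start_codon + 51, protein)],
                               tag="aggregate")
        system.observe(mrna.name, protein.name)

    if mrna_release_rows:
        system.add_release(rnap_term, params.termination_rate, [rnap],
                           mrna_release_rows, tag="transcription")
    if protein_release_rows:
        system.add_release(rib_term, params.termination_rate, [ribosome],
                           protein_release_rows, tag="translation")
    system.observe("RNAP", "ribosome")
    return system


# ----------------------------------------------------------------------
# replication (single origin, single fork)
# ----------------------------------------------------------------------

def build_replication(genome: SyntheticGenome,
                      params: Optional[ExpressionParams] = None
                      ) -> ReactionSystem:
    """Base-per-base leading-strand replication from a single origin at the
    left end of the genome.  Polymerase recruitment uses the fork
    arithmetic: with ~1000 bp Okazaki fragments and a 750 bp/s fork, a new
    polymerase is recruited every 1.33 s, encoded by
    |DNAP_free| * r_recruitment = 3/4."""
    params = params or ExpressionParams()
    params.validate()
    balance = params.dnap_free * params.recruitment_rate
    expected = params.replication_translocation / params.okazaki_length
    if not math.isclose(balance, expected, rel_tol=1e-9):
        raise ValidationError(
            f"DNAP recruitment balance {balance} != fork speed / fragment "
            f"length = {expected}")
    system = ReactionSystem()
    dnap = system.add_free_chemical("DNAP", params.dnap_copies)
    genome_seq = system.add_sequence("genome", genome.letters, copies=1)
    for dntp in DNTP_FOR_BASE.values():
        system.add_free_chemical(dntp, params.dntp_pool, buffered=True)
        system.add_free_chemical(dntp + "_spent", 0)
    system.register_binding_site("ori", genome_seq, 0, 10,
                                 k_on=params.recruitment_rate, k_off=0.0,
                                 reading_offset=0)
    dnap_bound = system.add_bound_chemical("DNAP_bound")
    dnap_elong = system.add_bound_chemical("DNAP_elongating")
    dnap_loaded = system.add_bound_chemical("DNAP_loaded")
    dnap_ready = system.add_bound_chemical("DNAP_translocating")
    dnap_term = system.add_bound_chemical("DNAP_terminating")
    system.add_sequence_binding(dnap, dnap_bound, "ori")
    system.add_chemical_reaction([(dnap_bound, 1)], [(dnap_elong, 1)],
                                 k_forward=params.initiation_rate)
    dntp_const = params.replication_loading / params.dntp_pool
    system.add_loading(
        dnap_elong, 1,
        {base: (dntp, [dntp + "_spent"], dntp_const, dnap_loaded)
         for base, dntp in DNTP_FOR_BASE.items()})
    system.add_chemical_reaction([(dnap_loaded, 1)], [(dnap_ready, 1)],
                                 k_forward=params.replication_polymerization)
    system.add_translocation(dnap_ready, dnap_elong, step=1,
                             rate=params.replication_translocation)
    system.add_switch("replication_termination", dnap_elong, dnap_term)
    system.add_switch_site(genome_seq, genome.length - 1,
                           "replication_termination")
    replicated = system.add_sequence("replicated_strand", genome.letters, 0)
    system.add_release(dnap_term, params.termination_rate, [dnap],
                       [("ori", genome.length - 1, genome.length,
                         replicated)])
    system.observe("DNAP", "replicated_strand")
    return system


def build_single_polymerase_track(length: int = 10_000,
                                  loading_rate: float = 1000.0,
                                  polymerization_rate: float = 500.0,
                                  translocation_rate: float = 50.0
                                  ) -> ReactionSystem:
    """One polymerase traversing a homopolymer template through the full
    loading -> polymerization -> translocation cycle; used to measure the
    realized elongation speed against the harmonic cycle closed form.
    The binding and release steps are three orders of magnitude faster than
    a cycle, so the exhaustion time of the run is the transit time over
    ``length - 1`` positions."""
    if length < 2:
        raise ValidationError("template must have at least 2 positions")
    system = ReactionSystem()
    pol = system.add_free_chemical("P", 1)
    ntp = system.add_free_chemical("NTP", 1, buffered=True)
    seq = system.add_sequence("track", "A" * length, copies=1)
    system.register_binding_site("start", seq, 0, 1, k_on=1000.0, k_off=0.0,
                                 reading_offset=0)
    elong = system.add_bound_chemical("P_elongating")
    loaded = system.add_bound_chemical("P_loaded")
    ready = system.add_bound_chemical("P_translocating")
    term = system.add_bound_chemical("P_terminating")
    system.add_sequence_binding(pol, elong, "start")
    system.add_loading(elong, 1, {"A": (ntp, [], loading_rate, loaded)})
    system.add_chemical_reaction([(loaded, 1)], [(ready, 1)],
                                 k_forward=polymerization_rate)
    system.add_translocation(ready, elong, step=1, rate=translocation_rate)
    system.add_switch("track_end", elong, term)
    system.add_switch_site(seq, length - 1, "track_end")
    done = system.add_sequence("done", "A" * length, 0)
    system.add_release(term, 1000.0, [], [("start", length - 1, length, done)])
    system.observe("done")
    return system


# ----------------------------------------------------------------------
# case-study extensions
# ----------------------------------------------------------------------

def build_tetracycline_extension(system: ReactionSystem,
                                 injected_amount: int,
                                 t_inject: float = 200.0,
                                 t_purify: float = 400.0,
                                 k_on: float = 1e-5,
                                 k_off: float = 0.1,
                                 n_washes: int = 4,
                                 wash_interval: float = 50.0
                                 ) -> ReactionSystem:
    """Extend a gene-expression system with tetracycline, which competes
    with charged tRNAs for ribosomes in loading phase: loading-phase
    ribosomes are reversibly sequestered into a stalled class that cannot
    load.  Tetracycline is injected at ``t_inject`` and repeatedly washed
    out from ``t_purify`` on; only the free pool is washed, the bound form
    remains.  Base records are untouched."""
    rib_load = system.bound_chemical("70S_loading")  # raises if absent
    tet = system.add_free_chemical("tetracycline", 0)
    stalled = system.add_bound_chemical("70S_tet_stalled")
    system.add_chemical_reaction([(rib_load, 1), (tet, 1)], [(stalled, 1)],
                                 k_forward=k_on, k_backward=k_off,
                                 tag="tetracycline")
    if injected_amount > 0:
        system.add_event(t_inject, "ADD", tet, injected_amount)
    for i in range(n_washes):
        system.add_event(t_purify + i * wash_interval, "REMOVE_FREE", tet,
                         10 ** 9)
    system.observe("tetracycline", "70S_tet_stalled")
    return system


def build_tbox_extension(system: ReactionSystem,
                         regulated_gene: str,
                         t_deplete: float = 200.0,
                         t_reinject: float = 600.0,
                         leader_terminator_offset: int = 25,
                         tyrosine_pool: int = 1_000_000,
                         trna_tyr_pool: int = 1000,
                         charging_k: float = 1e-6,
                         usage_k: float = 0.05,
                         tbox_k: float = 0.01) -> ReactionSystem:
    """Extend a gene-expression system with T-box attenuation of one
    detailed gene.

    A switch site in the transcript leader moves elongating polymerases
    into a ``tbox_RNAP`` state.  Binding an uncharged tyrosine tRNA resumes
    elongation; binding a charged one aborts transcription through the
    early terminator, releasing an annotated aborted transcript.  Tyrosine
    is depleted (SET to zero) at ``t_deplete`` and re-injected at
    ``t_reinject``, so full-length transcripts accumulate only while
    tyrosine is scarce.
    """
    genome: SyntheticGenome = system.metadata.get("genome")
    if genome is None:
        raise ValidationError("system carries no genome metadata")
    if regulated_gene not in system.metadata.get("detailed_genes", ()):
        raise ValidationError(
            f"gene {regulated_gene!r} must be simulated in detailed mode "
            f"(pass detailed_genes=[...] to build_gene_expression)")
    gene = next(g for g in genome.genes if g.name == regulated_gene)

    tyr = system.add_free_chemical("tyrosine", tyrosine_pool)
    charged = system.add_free_chemical("tRNA_tyr_c", trna_tyr_pool)
    uncharged = system.add_free_chemical("tRNA_tyr_u", 0)
    system.add_chemical_reaction([(tyr, 1), (uncharged, 1)], [(charged, 1)],
                                 k_forward=charging_k, tag="tbox")
    system.add_chemical_reaction([(charged, 1)], [(uncharged, 1)],
                                 k_forward=usage_k, tag="tbox")

    rnap_elong = system.bound_chemical("RNAP_elongating")
    tbox_rnap = system.add_bound_chemical("tbox_RNAP")
    aborting = system.add_bound_chemical("RNAP_aborting")
    system.add_switch(f"tbox_{regulated_gene}", rnap_elong, tbox_rnap)
    tbox_pos = gene.tss + leader_terminator_offset
    system.add_switch_site("genome", tbox_pos, f"tbox_{regulated_gene}")
    # uncharged tRNA binding resumes transcription; charged aborts (the
    # tRNA acts as a sensor and is returned to its pool either way)
    system.add_chemical_reaction([(tbox_rnap, 1), (uncharged, 1)],
                                 [(rnap_elong, 1), (uncharged, 1)],
                                 k_forward=tbox_k, tag="tbox")
    system.add_chemical_reaction([(tbox_rnap, 1), (charged, 1)],
                                 [(aborting, 1), (charged, 1)],
                                 k_forward=tbox_k, tag="tbox")
    aborted = system.add_sequence(
        f"aborted_{regulated_gene}",
        gene.transcript(genome.letters)[:leader_terminator_offset], 0)
    system.add_release(aborting, 1.0, ["RNAP"],
                       [(f"promoter_{regulated_gene}", tbox_pos, tbox_pos + 1,
                         aborted)], tag="tbox")
    system.add_event(t_deplete, "SET", tyr, 0)
    system.add_event(t_reinject, "ADD", tyr, tyrosine_pool)
    system.observe("tyrosine", "tRNA_tyr_c", "tRNA_tyr_u",
                   f"aborted_{regulated_gene}", f"mRNA_{regulated_gene}")
    return system
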