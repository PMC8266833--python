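"""Synthetic genome generation.

Stands in for a real bacterial annotation set: random sequences over ACGT
with well-formed per-gene annotations (promoter interval, transcription
start, terminator, ribosome binding site, start/stop codons), deterministic
given the seed.  Transcript-level coordinates (RBS, start, stop) are
relative to the transcript, genomic coordinates (promoter, TSS, terminator)
to the genome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
from Bio.Seq import Seq

from .errors import ValidationError

PROMOTER_LEN = 10
LEADER_LEN = 30      # transcript leader before the start codon
RBS_OFFSET = 18      # RBS interval [18, 28) within the leader
RBS_LEN = 10
TRAILER_LEN = 15     # transcript tail after the stop codon
INTERGENIC_LEN = 10

STOP_CODONS = ("TAA", "TAG", "TGA")
SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in STOP_CODONS
)


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene with its transcription and translation annotations."""
    name: str
    promoter: Tuple[int, int]    # genomic, half-open
    tss: int                     # genomic transcription start
    terminator: int              # genomic position where the RNAP switches
    rbs: Tuple[int, int]         # transcript coordinates
    start_codon: int             # transcript coordinate of the A of AUG
    stop_codon: int              # transcript coordinate of the stop codon
    transcript_length: int

    @property
    def coding_length(self) -> int:
        return self.stop_codon - self.start_codon

    def transcript(self, genome_letters: str) -> str:
        return genome_letters[self.tss:self.tss + self.transcript_length]

    def protein(self, genome_letters: str) -> str:
        cds = genome_letters[self.tss + self.start_codon:
                             self.tss + self.stop_codon + 3]
        return str(Seq(cds).translate(to_stop=True))


@dataclass(frozen=True)
class SyntheticGenome:
    letters: str
    genes: Tuple[GeneAnnotation, ...]
    seed: int

    @property
    def length(self) -> int:
        return len(self.letters)

    def validate(self) -> None:
        for g in self.genes:
            if not g.promoter[0] < g.tss < g.terminator <= self.length:
                raise ValidationError(f"gene {g.name}: bad coordinate order")
            if g.coding_length % 3 != 0:
                raise ValidationError(
                    f"gene {g.name}: coding length not divisible by 3")
            tr = g.transcript(self.letters)
            if tr[g.start_codon:g.start_codon + 3] != "ATG":
                raise ValidationError(f"gene {g.name}: missing start codon")
            if tr[g.stop_codon:g.stop_codon + 3] not in STOP_CODONS:
                raise ValidationError(f"gene {g.name}: missing stop codon")


def synthesize_genome(n_genes: int,
                      gene_length_range: Tuple[int, int] = (300, 600),
                      rng_seed: int = 0) -> SyntheticGenome:
    """Generate a synthetic genome of ``n_genes`` genes whose transcript
    lengths fall in ``gene_length_range`` (min 150 to leave room for the
    leader, a coding region and the trailer)."""
    if n_genes < 1:
        raise ValidationError("need at least one gene")
    lo, hi = gene_length_range
    if lo > hi or lo < 150:
        raise ValidationError("degenerate gene length range (need >= 150)")
    rng = np.random.default_rng(rng_seed)
    bases = "ACGT"
    parts: List[str] = []
    genes: List[GeneAnnotation] = []
    pos = 0

    def random_letters(n: int) -> str:
        return "".join(bases[i] for i in rng.integers(0, 4, size=n))

    for i in range(n_genes):
        gap = random_letters(INTERGENIC_LEN)
        parts.append(gap)
        pos += len(gap)
        promoter = (pos, pos + PROMOTER_LEN)
        parts.append(random_letters(PROMOTER_LEN))
        pos += PROMOTER_LEN
        tss = pos
        target = int(rng.integers(lo, hi + 1))
        n_codons = max(1, (target - LEADER_LEN - 6 - TRAILER_LEN) // 3)
        leader = random_letters(LEADER_LEN)
        coding = "".join(SENSE_CODONS[j] for j in
                         rng.integers(0, len(SENSE_CODONS), size=n_codons))
        stop = STOP_CODONS[int(rng.integers(0, 3))]
        trailer = random_letters(TRAILER_LEN)
        transcript = leader + "ATG" + coding + stop + trailer
        parts.append(transcript)
        pos += len(transcript)
        genes.append(GeneAnnotation(
            name=f"gene{i:02d}",
            promoter=promoter,
            tss=tss,
            terminator=tss + len(transcript),
            rbs=(RBS_OFFSET, RBS_OFFSET + RBS_LEN),
            start_codon=LEADER_LEN,
            stop_codon=LEADER_LEN + 3 + 3 * n_codons,
            transcript_length=len(transcript),
        ))
    parts.append(random_letters(INTERGENIC_LEN))
    genome = SyntheticGenome("".join(parts), tuple(genes), int(rng_seed))
    genome.validate()
    return genome
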