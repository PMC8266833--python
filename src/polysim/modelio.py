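"""Plain-text model-definition dialect, trajectory and metadata output.

A model is a directory of ``*.in`` files read in lexicographic order; every
name must be declared before it is used across the concatenation of the
files, and duplicate declarations are rejected.  Records are one per line,
whitespace-delimited, with ``#`` comments; Loading and Release records open
a table whose rows follow on the next lines and end at a blank line (or end
of file).  The full grammar is documented in ``docs/model-format.md``.

Extension by adding a file never disturbs existing records: parsing a base
directory plus one extra file yields the base system plus the extra
records.
"""

from __future__ import annotations

import os
from typing import Dict, List

from Bio import SeqIO

from .errors import ParseError, PolysimError, ValidationError
from .reactions import EVENT_KINDS
from .system import ReactionSystem


def _int(token: str, fname: str, lineno: int, what: str) -> int:
    try:
        return int(token)
    except ValueError:
        raise ParseError(fname, lineno, f"expected integer {what}, got {token!r}")


def _float(token: str, fname: str, lineno: int, what: str) -> float:
    try:
        return float(token)
    except ValueError:
        raise ParseError(fname, lineno, f"expected number {what}, got {token!r}")


class _Lines:
    """Iterator over the logical lines of one model file."""

    def __init__(self, path: str):
        self.fname = os.path.basename(path)
        with open(path) as fh:
            self.raw = fh.readlines()
        self.i = 0

    def next_record(self):
        """(lineno, tokens) of the next non-blank, non-comment line."""
        while self.i < len(self.raw):
            line = self.raw[self.i]
            self.i += 1
            stripped = line.split("#", 1)[0].strip()
            if stripped:
                return self.i, stripped.split()
        return None

    def table_rows(self):
        """Rows until the first blank line (comments do not end a table)."""
        rows = []
        while self.i < len(self.raw):
            line = self.raw[self.i]
            if not line.strip():
                self.i += 1
                break
            self.i += 1
            stripped = line.split("#", 1)[0].strip()
            if stripped:
                rows.append((self.i, stripped.split()))
        return rows


def _parse_reaction_side(tokens, fname, lineno):
    if tokens == ["-"]:
        return []
    side = []
    pending = list(tokens)
    i = 0
    while i < len(pending):
        if pending[i] == "+":
            i += 1
            continue
        if i + 1 >= len(pending):
            raise ParseError(fname, lineno,
                             "reaction side must be '<stoich> <name>' pairs")
        st = _int(pending[i], fname, lineno, "stoichiometry")
        name = pending[i + 1]
        side.append((name, st))
        i += 2
    if not side:
        raise ParseError(fname, lineno, "empty reaction side (use '-')")
    return side


def parse_model(directory: str) -> ReactionSystem:
    """Parse every ``*.in`` file of ``directory`` (lexicographic order)
    into a fully linked :class:`ReactionSystem`."""
    if not os.path.isdir(directory):
        raise ParseError(str(directory), 0, "model directory does not exist")
    files = sorted(f for f in os.listdir(directory) if f.endswith(".in"))
    if not files:
        raise ParseError(str(directory), 0, "no .in model files in directory")
    system = ReactionSystem()
    for fname in files:
        _parse_file(system, directory, fname)
    return system


def _parse_file(system: ReactionSystem, directory: str, fname: str) -> None:
    lines = _Lines(os.path.join(directory, fname))
    while True:
        rec = lines.next_record()
        if rec is None:
            break
        lineno, tok = rec
        kind = tok[0]
        try:
            _dispatch(system, directory, lines, kind, tok[1:], fname, lineno)
        except ParseError:
            raise
        except PolysimError as exc:
            raise ParseError(fname, lineno, str(exc)) from exc


def _dispatch(system, directory, lines, kind, args, fname, lineno):
    if kind == "FreeChemical":
        if not args:
            raise ParseError(fname, lineno, "FreeChemical needs a name")
        name = args[0]
        buffered = False
        count = 0
        rest = args[1:]
        if rest and rest[-1] == "buffered":
            buffered = True
            rest = rest[:-1]
        if rest:
            count = _int(rest[0], fname, lineno, "count")
        system.add_free_chemical(name, count, buffered)
    elif kind == "Sequence":
        if len(args) < 3:
            raise ParseError(fname, lineno,
                             "Sequence needs: name inline|fasta ...")
        name, mode = args[0], args[1]
        if mode == "inline":
            letters = args[2]
            copies = _int(args[3], fname, lineno, "copies") if len(args) > 3 else 0
        elif mode == "fasta":
            if len(args) < 4:
                raise ParseError(fname, lineno,
                                 "Sequence fasta needs: file record [copies]")
            path = os.path.join(directory, args[2])
            record_id = args[3]
            copies = _int(args[4], fname, lineno, "copies") if len(args) > 4 else 0
            letters = _read_fasta_record(path, record_id, fname, lineno)
        else:
            raise ParseError(fname, lineno, f"unknown sequence mode {mode!r}")
        system.add_sequence(name, letters, copies)
    elif kind == "BoundChemical":
        if len(args) != 1:
            raise ParseError(fname, lineno, "BoundChemical needs exactly a name")
        system.add_bound_chemical(args[0])
    elif kind == "BindingSite":
        if len(args) != 7:
            raise ParseError(fname, lineno,
                             "BindingSite needs: family sequence first last "
                             "k_on k_off reading_offset")
        system.register_binding_site(
            args[0], args[1],
            _int(args[2], fname, lineno, "first"),
            _int(args[3], fname, lineno, "last"),
            _float(args[4], fname, lineno, "k_on"),
            _float(args[5], fname, lineno, "k_off"),
            _int(args[6], fname, lineno, "reading_offset"))
    elif kind == "Switch":
        if len(args) != 3:
            raise ParseError(fname, lineno,
                             "Switch needs: name input_class output_class")
        system.add_switch(args[0], args[1], args[2])
    elif kind == "SwitchSite":
        if len(args) != 3:
            raise ParseError(fname, lineno,
                             "SwitchSite needs: sequence position switch")
        system.add_switch_site(args[0],
                               _int(args[1], fname, lineno, "position"),
                               args[2])
    elif kind == "ChemicalReaction":
        if len(args) < 4:
            raise ParseError(fname, lineno, "truncated ChemicalReaction")
        kf = _float(args[0], fname, lineno, "k_forward")
        kb = _float(args[1], fname, lineno, "k_backward")
        rest = args[2:]
        rate_law = "mass_action"
        if rest and rest[0] == "threshold":
            rate_law = "threshold"
            rest = rest[1:]
        if "->" not in rest:
            raise ParseError(fname, lineno, "ChemicalReaction needs '->'")
        arrow = rest.index("->")
        reactants = _parse_reaction_side(rest[:arrow], fname, lineno)
        products = _parse_reaction_side(rest[arrow + 1:], fname, lineno)
        system.add_chemical_reaction(reactants, products, kf, kb, rate_law)
    elif kind == "SequenceBinding":
        if len(args) != 3:
            raise ParseError(fname, lineno,
                             "SequenceBinding needs: free bound family")
        system.add_sequence_binding(args[0], args[1], args[2])
    elif kind == "Translocation":
        if len(args) != 4:
            raise ParseError(fname, lineno,
                             "Translocation needs: mobile post step rate")
        system.add_translocation(args[0], args[1],
                                 _int(args[2], fname, lineno, "step"),
                                 _float(args[3], fname, lineno, "rate"))
    elif kind == "Loading":
        if len(args) != 2:
            raise ParseError(fname, lineno,
                             "Loading needs: loader_class motif_length")
        motif_length = _int(args[1], fname, lineno, "motif length")
        table = {}
        for row_lineno, row in lines.table_rows():
            if len(row) < 4:
                raise ParseError(fname, row_lineno,
                                 "Loading row needs: motif loaded rate post "
                                 "[byproducts...]")
            motif, loaded = row[0], row[1]
            rate = _float(row[2], fname, row_lineno, "rate")
            post = row[3]
            byproducts = row[4:]
            if motif in table:
                raise ParseError(fname, row_lineno,
                                 f"duplicate motif {motif!r}")
            table[motif] = (loaded, byproducts, rate, post)
        if not table:
            raise ParseError(fname, lineno, "Loading table is empty")
        system.add_loading(args[0], motif_length, table)
    elif kind == "Release":
        if len(args) != 3:
            raise ParseError(fname, lineno,
                             "Release needs: class rate freed-list")
        rate = _float(args[1], fname, lineno, "rate")
        freed = [] if args[2] == "-" else args[2].split(",")
        rows = []
        for row_lineno, row in lines.table_rows():
            if len(row) != 4:
                raise ParseError(fname, row_lineno,
                                 "Release row needs: family first last product")
            rows.append((row[0],
                         _int(row[1], fname, row_lineno, "first"),
                         _int(row[2], fname, row_lineno, "last"),
                         row[3]))
        system.add_release(args[0], rate, freed, rows)
    elif kind == "Event":
        if len(args) != 4:
            raise ParseError(fname, lineno,
                             "Event needs: time kind target amount")
        kind_ = args[1]
        if kind_ not in EVENT_KINDS:
            raise ParseError(fname, lineno, f"unknown event kind {kind_!r}")
        system.add_event(_float(args[0], fname, lineno, "time"), kind_,
                         args[2], _int(args[3], fname, lineno, "amount"))
    elif kind == "Init":
        if len(args) != 2:
            raise ParseError(fname, lineno, "Init needs: name count")
        count = _int(args[1], fname, lineno, "count")
        if count < 0:
            raise ParseError(fname, lineno, "Init count must be >= 0")
        name = args[0]
        if name in system.free_chemicals:
            system.free_chemicals[name].count = count
        elif name in system.sequences:
            system.sequences[name].copies = count
        else:
            raise ParseError(fname, lineno,
                             f"Init refers to unknown pool {name!r}")
    elif kind == "Observe":
        if not args:
            raise ParseError(fname, lineno, "Observe needs at least one name")
        system.observe(*args)
    else:
        raise ParseError(fname, lineno, f"unknown record kind {kind!r}")


def _read_fasta_record(path, record_id, fname, lineno):
    if not os.path.exists(path):
        raise ParseError(fname, lineno, f"FASTA file {path!r} not found")
    for record in SeqIO.parse(path, "fasta"):
        if record.id == record_id:
            return str(record.seq).upper()
    raise ParseError(fname, lineno,
                     f"record {record_id!r} not found in {path!r}")


# ----------------------------------------------------------------------
# serialization
# ----------------------------------------------------------------------

def _num(x: float) -> str:
    return repr(float(x))


def serialize_model(system: ReactionSystem, directory: str,
                    inline_limit: int = 200) -> None:
    """Write ``system`` as a model directory (``model.in`` plus
    ``sequences.fa`` for sequences longer than ``inline_limit``).  Names
    are declared before use, so the output always re-parses; round-tripping
    is structurally exact (see :func:`fingerprint`)."""
    os.makedirs(directory, exist_ok=True)
    out: List[str] = ["# polysim model (generated)", ""]
    fasta: List[str] = []
    for fc in system.free_chemicals.values():
        line = f"FreeChemical {fc.name} {fc.count}"
        if fc.buffered:
            line += " buffered"
        out.append(line)
    for seq in system.sequences.values():
        if seq.length > inline_limit:
            fasta.append(f">{seq.name}")
            for i in range(0, seq.length, 70):
                fasta.append(seq.letters[i:i + 70])
            out.append(f"Sequence {seq.name} fasta sequences.fa "
                       f"{seq.name} {seq.copies}")
        else:
            out.append(f"Sequence {seq.name} inline {seq.letters} {seq.copies}")
    for bc in system.bound_chemicals.values():
        out.append(f"BoundChemical {bc.name}")
    for sw in system.switches.values():
        out.append(f"Switch {sw.name} {sw.input_class.name} "
                   f"{sw.output_class.name}")
    for fam in system.families.values():
        for s in fam.sites:
            out.append(f"BindingSite {fam.name} {s.sequence.name} {s.first} "
                       f"{s.last} {_num(s.k_on)} {_num(s.k_off)} "
                       f"{s.reading_offset}")
    switch_names = {id(sw): name for name, sw in system.switches.items()}
    for seq in system.sequences.values():
        for ss in seq.switch_sites:
            out.append(f"SwitchSite {seq.name} {ss.position} "
                       f"{switch_names[id(ss.switch)]}")
    out.append("")
    for rxn in system.reactions:
        out.extend(_serialize_reaction(rxn))
    for ev in sorted(system.events, key=lambda e: e.time):
        out.append(f"Event {_num(ev.time)} {ev.kind} {ev.target.name} "
                   f"{ev.amount}")
    if system.observables:
        out.append("Observe " + " ".join(system.observables))
    with open(os.path.join(directory, "model.in"), "w") as fh:
        fh.write("\n".join(out) + "\n")
    if fasta:
        with open(os.path.join(directory, "sequences.fa"), "w") as fh:
            fh.write("\n".join(fasta) + "\n")


def _side_text(side) -> str:
    terms = []
    for fc, st in side.free:
        terms.append(f"{st} {fc.name}")
    if side.bound is not None:
        terms.append(f"1 {side.bound.name}")
    return " + ".join(terms) if terms else "-"


def _serialize_reaction(rxn) -> List[str]:
    kind = rxn.kind
    if kind == "chemical":
        law = " threshold" if rxn.rate_law == "threshold" else ""
        return [f"ChemicalReaction {_num(rxn.k_forward)} "
                f"{_num(rxn.k_backward)}{law} "
                f"{_side_text(rxn.reactants)} -> {_side_text(rxn.products)}"]
    if kind == "binding":
        return [f"SequenceBinding {rxn.free_form.name} {rxn.bound_form.name} "
                f"{rxn.family.name}"]
    if kind == "translocation":
        return [f"Translocation {rxn.mobile_class.name} {rxn.post_class.name} "
                f"{rxn.step} {_num(rxn.rate)}"]
    if kind == "loading":
        lines = [f"Loading {rxn.loader_class.name} {rxn.motif_length}"]
        for motif in sorted(rxn.table):
            rule = rxn.table[motif]
            bps = " " + " ".join(b.name for b in rule.byproducts) \
                if rule.byproducts else ""
            lines.append(f"{motif} {rule.loaded.name} {_num(rule.rate)} "
                         f"{rule.post_class.name}{bps}")
        lines.append("")
        return lines
    if kind == "release":
        freed = ",".join(f.name for f in rxn.freed) if rxn.freed else "-"
        lines = [f"Release {rxn.releasing_class.name} {_num(rxn.rate)} {freed}"]
        for rule in rxn.rules:
            lines.append(f"{rule.family} {rule.first} {rule.last} "
                         f"{rule.product.name}")
        lines.append("")
        return lines
    raise ValidationError(f"cannot serialize reaction kind {kind!r}")


def fingerprint(system: ReactionSystem):
    """Canonical structural digest used for round-trip comparisons."""
    rxns = []
    for rxn in system.reactions:
        rxns.append(tuple(_serialize_reaction(rxn)))
    return (
        tuple(sorted((f.name, f.count, f.buffered)
                     for f in system.free_chemicals.values())),
        tuple(sorted((s.name, s.letters, s.copies)
                     for s in system.sequences.values())),
        tuple(sorted(system.bound_chemicals)),
        tuple(sorted((fam.name, s.sequence.name, s.first, s.last, s.k_on,
                      s.k_off, s.reading_offset)
                     for fam in system.families.values()
                     for s in fam.sites)),
        tuple(sorted((name, sw.input_class.name, sw.output_class.name)
                     for name, sw in system.switches.items())),
        tuple(sorted((seq.name, ss.position, ss.switch.name)
                     for seq in system.sequences.values()
                     for ss in seq.switch_sites)),
        tuple(sorted(rxns)),
        tuple(sorted((e.time, e.kind, e.target.name, e.amount)
                     for e in system.events)),
        tuple(sorted(system.observables)),
    )


# ----------------------------------------------------------------------
# trajectory / metadata output
# ----------------------------------------------------------------------

def write_trajectory(trajectory, path: str) -> None:
    """TSV with a header row: column 1 is time (6 significant digits),
    one integer column per observable."""
    if not trajectory.times:
        raise ValidationError("cannot write an empty trajectory")
    names = list(trajectory.observables)
    with open(path, "w") as fh:
        fh.write("\t".join(["time"] + names) + "\n")
        for i, t in enumerate(trajectory.times):
            row = ["%.6g" % t]
            row.extend("%d" % trajectory.observables[n][i] for n in names)
            fh.write("\t".join(row) + "\n")


def write_run_metadata(path: str, metadata: Dict[str, object]) -> None:
    """Sidecar key-value text file (seed, solver, versions...)."""
    with open(path, "w") as fh:
        for key, value in metadata.items():
            fh.write(f"{key}\t{value}\n")
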