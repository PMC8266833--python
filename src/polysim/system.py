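"""The :class:`ReactionSystem` container: pools, sequences, particles,
reactions, filters and events, plus the channel/dependency wiring handed to
the solver."""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

from .core import (BindingSite, BoundChemical, BoundUnit, ChemicalSequence,
                   FamilyFilter, FreeChemical, SiteFamily, Switch, SwitchSite,
                   TemplateFilter)
from .errors import UnknownComponentError, ValidationError
from .reactions import (ChemicalReaction, Loading, LoadingRule, Release,
                        ReleaseRule, SequenceBinding, TimedEvent,
                        Translocation)


class Channel:
    """One propensity channel: a compute function, a fire function and the
    state keys whose change invalidates the stored propensity."""

    __slots__ = ("index", "reaction", "direction", "compute", "fire", "reads")

    def __init__(self, index, reaction, direction, compute, fire, reads):
        self.index = index
        self.reaction = reaction
        self.direction = direction
        self.compute = compute
        self.fire = fire
        self.reads = tuple(reads)


class ReactionSystem:
    """Full simulation state.

    Build one programmatically through the ``add_*`` helpers (or parse a
    model directory with :func:`polysim.modelio.parse_model`), then hand it
    to :func:`polysim.solver.run`.  ``finalize()`` validates the system and
    wires propensity channels and the dependency map; it is called lazily
    by the solver and is idempotent until new records are added.
    """

    def __init__(self):
        self.free_chemicals: Dict[str, FreeChemical] = {}
        self.sequences: Dict[str, ChemicalSequence] = {}
        self.bound_chemicals: Dict[str, BoundChemical] = {}
        self.families: Dict[str, SiteFamily] = {}
        self.switches: Dict[str, Switch] = {}
        self.reactions: List = []
        self.events: List[TimedEvent] = []
        self.observables: List[str] = []
        self.metadata: Dict[str, object] = {}
        self.channels: List[Channel] = []
        self.read_map: Dict[tuple, Tuple[int, ...]] = {}
        self._unit_pool: List[BoundUnit] = []
        self._finalized = False

    # ------------------------------------------------------------------
    # registration
    # ------------------------------------------------------------------
    def _check_new_name(self, name: str):
        if (name in self.free_chemicals or name in self.sequences
                or name in self.bound_chemicals):
            raise ValidationError(f"duplicate declaration of {name!r}")

    def add_free_chemical(self, name: str, count: int = 0,
                          buffered: bool = False) -> FreeChemical:
        self._check_new_name(name)
        fc = FreeChemical(name, count, buffered)
        self.free_chemicals[name] = fc
        self._finalized = False
        return fc

    def add_sequence(self, name: str, letters: str,
                     copies: int = 0) -> ChemicalSequence:
        self._check_new_name(name)
        seq = ChemicalSequence(name, letters, copies)
        self.sequences[name] = seq
        self._finalized = False
        return seq

    def add_bound_chemical(self, name: str) -> BoundChemical:
        self._check_new_name(name)
        bc = BoundChemical(name)
        self.bound_chemicals[name] = bc
        self._finalized = False
        return bc

    def add_switch(self, name: str, input_class, output_class) -> Switch:
        if name in self.switches:
            raise ValidationError(f"duplicate switch {name!r}")
        sw = Switch(name, self.bound_chemical(input_class),
                    self.bound_chemical(output_class))
        self.switches[name] = sw
        self._finalized = False
        return sw

    def add_switch_site(self, sequence, position: int, switch) -> SwitchSite:
        seq = self.sequence(sequence)
        if isinstance(switch, str):
            if switch not in self.switches:
                raise UnknownComponentError(f"unknown switch {switch!r}")
            switch = self.switches[switch]
        site = SwitchSite(seq, position, switch)
        seq.switch_sites.append(site)
        seq._switches_at.setdefault(site.position, []).append(site)
        self._finalized = False
        return site

    def register_binding_site(self, family: str, sequence, first: int,
                              last: int, k_on: float, k_off: float,
                              reading_offset: Optional[int] = None
                              ) -> BindingSite:
        """Attach a binding site to a sequence and index it under its
        family; availability starts at the sequence's copy number."""
        seq = self.sequence(sequence)
        if reading_offset is None:
            reading_offset = first
        site = BindingSite(family, seq, first, last, k_on, k_off,
                           reading_offset)
        fam = self.families.get(family)
        if fam is None:
            fam = self.families[family] = SiteFamily(family)
        fam.sites.append(site)
        seq.sites.append(site)
        if family not in seq.site_families:
            seq.site_families.append(family)
        self._finalized = False
        return site

    # ------------------------------------------------------------------
    # lookups
    # ------------------------------------------------------------------
    def free_chemical(self, name) -> FreeChemical:
        if isinstance(name, FreeChemical):
            return name
        try:
            return self.free_chemicals[name]
        except KeyError:
            raise UnknownComponentError(f"unknown free chemical {name!r}") from None

    def sequence(self, name) -> ChemicalSequence:
        if isinstance(name, ChemicalSequence):
            return name
        try:
            return self.sequences[name]
        except KeyError:
            raise UnknownComponentError(f"unknown sequence {name!r}") from None

    def bound_chemical(self, name) -> BoundChemical:
        if isinstance(name, BoundChemical):
            return name
        try:
            return self.bound_chemicals[name]
        except KeyError:
            raise UnknownComponentError(f"unknown bound class {name!r}") from None

    def species(self, name):
        if name in self.free_chemicals:
            return self.free_chemicals[name]
        if name in self.bound_chemicals:
            return self.bound_chemicals[name]
        raise UnknownComponentError(f"unknown species {name!r}")

    def family(self, name) -> SiteFamily:
        if isinstance(name, SiteFamily):
            return name
        try:
            return self.families[name]
        except KeyError:
            raise UnknownComponentError(f"unknown site family {name!r}") from None

    def available_site_count(self, family) -> int:
        """Total free binding capacity of a family:
        Σ over its sites of (sequence copies − occupied)."""
        return self.family(family).available_total()

    # ------------------------------------------------------------------
    # reactions and events
    # ------------------------------------------------------------------
    def _register(self, reaction):
        reaction.system = self
        self.reactions.append(reaction)
        self._finalized = False
        return reaction

    def add_chemical_reaction(self, reactants, products, k_forward,
                              k_backward=0.0, rate_law="mass_action",
                              tag="") -> ChemicalReaction:
        reactants = [(self.species(n) if isinstance(n, str) else n, st)
                     for n, st in reactants]
        products = [(self.species(n) if isinstance(n, str) else n, st)
                    for n, st in products]
        return self._register(ChemicalReaction(
            reactants, products, k_forward, k_backward, rate_law, tag))

    def add_sequence_binding(self, free_form, bound_form, family,
                             tag="") -> SequenceBinding:
        rxn = SequenceBinding(self.free_chemical(free_form),
                              self.bound_chemical(bound_form),
                              self.family(family), tag)
        # the family filter backs unbinding and occupancy accounting
        bc = rxn.bound_form
        filt = bc.family_filter(rxn.family.name)
        if filt is None:
            filt = FamilyFilter(rxn.family.name)
            bc.filters.append(filt)
            for unit in bc.members:
                filt.add(unit)
        rxn.filter = filt
        return self._register(rxn)

    def add_translocation(self, mobile_class, post_class, step, rate,
                          tag="") -> Translocation:
        return self._register(Translocation(
            self.bound_chemical(mobile_class),
            self.bound_chemical(post_class), step, rate, tag))

    def add_loading(self, loader_class, motif_length, table,
                    tag="") -> Loading:
        """``table`` maps motif -> (loaded, [byproducts], rate, post_class)
        with species given as names or objects, or LoadingRule values."""
        loader = self.bound_chemical(loader_class)
        rules = {}
        for motif, rule in table.items():
            if not isinstance(rule, LoadingRule):
                loaded, byproducts, rate, post = rule
                rule = LoadingRule(self.free_chemical(loaded),
                                   [self.free_chemical(b) for b in byproducts],
                                   rate, self.bound_chemical(post))
            rules[motif] = rule
        rxn = Loading(loader, motif_length, rules, tag)
        filt = loader.template_filter(rxn.motif_length)
        if filt is None:
            filt = TemplateFilter(rxn.motif_length)
            loader.filters.append(filt)
            for unit in loader.members:
                filt.add(unit)
        rxn.filter = filt
        return self._register(rxn)

    def add_release(self, releasing_class, rate, freed, products,
                    on_unmatched="error", tag="") -> Release:
        """``products`` is a list of (family, first, last, product_sequence)."""
        rules = []
        for entry in products:
            if isinstance(entry, ReleaseRule):
                rules.append(entry)
            else:
                family, first, last, product = entry
                fam = self.family(family).name
                rules.append(ReleaseRule(fam, first, last,
                                         self.sequence(product)))
        return self._register(Release(
            self.bound_chemical(releasing_class), rate,
            [self.free_chemical(f) for f in freed], rules, on_unmatched, tag))

    def add_event(self, time, kind, target, amount) -> TimedEvent:
        ev = TimedEvent(time, kind, self.free_chemical(target), int(amount))
        self.events.append(ev)
        self._finalized = False
        return ev

    def observe(self, *names):
        for name in names:
            if (name not in self.free_chemicals
                    and name not in self.bound_chemicals
                    and name not in self.sequences):
                raise UnknownComponentError(f"unknown observable {name!r}")
            if name not in self.observables:
                self.observables.append(name)

    def observable_getter(self, name):
        if name in self.free_chemicals:
            fc = self.free_chemicals[name]
            return lambda: fc.count
        if name in self.bound_chemicals:
            bc = self.bound_chemicals[name]
            return lambda: len(bc.members)
        seq = self.sequence(name)
        return lambda: seq.copies

    # ------------------------------------------------------------------
    # particle recycling
    # ------------------------------------------------------------------
    def new_unit(self) -> BoundUnit:
        if self._unit_pool:
            return self._unit_pool.pop()
        return BoundUnit()

    def recycle_unit(self, unit: BoundUnit) -> None:
        unit.sequence = None
        unit.origin_site = None
        unit.on_origin_site = False
        unit.position = 0
        self._unit_pool.append(unit)

    def live_units(self) -> List[BoundUnit]:
        out = []
        for bc in self.bound_chemicals.values():
            out.extend(bc.members)
        return out

    def total_bound(self) -> int:
        return sum(len(bc) for bc in self.bound_chemicals.values())

    # ------------------------------------------------------------------
    # wiring
    # ------------------------------------------------------------------
    def finalize(self) -> None:
        if self._finalized:
            return
        self.events.sort(key=lambda e: e.time)
        channels: List[Channel] = []
        read_lists: Dict[tuple, List[int]] = {}
        for rxn in self.reactions:
            if rxn.system is None:
                rxn.system = self
            for direction, reads, compute, fire in rxn.channels():
                ch = Channel(len(channels), rxn, direction, compute, fire,
                             reads)
                channels.append(ch)
                for key in ch.reads:
                    read_lists.setdefault(key, []).append(ch.index)
        self.channels = channels
        self.read_map = {k: tuple(v) for k, v in read_lists.items()}
        self._finalized = True

    def refresh_filters(self) -> None:
        """Rebuild every filter from scratch (consistency checks)."""
        for bc in self.bound_chemicals.values():
            for f in bc.filters:
                if isinstance(f, FamilyFilter):
                    fresh = FamilyFilter(f.family)
                else:
                    fresh = TemplateFilter(f.motif_length)
                for unit in bc.members:
                    fresh.add(unit)
                if isinstance(f, FamilyFilter):
                    f.by_site = fresh.by_site
                    f._where = fresh._where
                else:
                    f.partitions = fresh.partitions
                    f._where = fresh._where
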