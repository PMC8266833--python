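"""The six reaction classes and timed events.

Every reaction exposes one or more *propensity channels* to the solver.  A
channel knows how to compute its current propensity from the system state
and how to fire: firing mutates pools, particles, site occupancies and
filters, and returns the list of state keys it touched so the solver can
refresh exactly the dependent channels.

State keys are small tuples: ``("F", name)`` for a free-chemical pool,
``("B", name)`` for a bound-class population, ``("S", family)`` for the
occupancy / on-origin bookkeeping of a binding-site family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .core import (BoundChemical, ChemicalSequence, FamilyFilter,
                   FreeChemical, SiteFamily, TemplateFilter)
from .errors import (ImpossibleReactionError, UnmatchedReleaseError,
                     ValidationError)


def falling_factorial(n: int, k: int) -> int:
    """Number of ordered k-tuples of distinct molecules out of n."""
    out = 1
    for i in range(k):
        out *= n - i
        if out <= 0:
            return 0
    return out


class _Side:
    """One side of a chemical reaction, pre-split into free species and at
    most one bound class (stoichiometry 1)."""

    __slots__ = ("free", "bound")

    def __init__(self, terms: Sequence[Tuple[object, int]], label: str):
        self.free: List[Tuple[FreeChemical, int]] = []
        self.bound: Optional[BoundChemical] = None
        for species, stoich in terms:
            if stoich < 1:
                raise ValidationError(f"stoichiometry must be >= 1 ({label})")
            if isinstance(species, FreeChemical):
                self.free.append((species, int(stoich)))
            elif isinstance(species, BoundChemical):
                if self.bound is not None:
                    raise ValidationError(
                        f"at most one bound class per side ({label})")
                if stoich != 1:
                    raise ValidationError(
                        f"bound class stoichiometry must be 1 ({label})")
                self.bound = species
            else:
                raise ValidationError(
                    f"unsupported species type {type(species).__name__} ({label})")


class ChemicalReaction:
    """A standard (optionally reversible) reaction on pools, possibly
    carrying one bound particle across.

    Propensity follows mass action with falling factorials for repeated
    reactants (``A+A`` with n molecules fires at ``k*n*(n-1)``), so a
    channel can never fire with insufficient molecules.  ``k_backward = 0``
    encodes irreversibility.  A bound reactant with no bound product means
    the fired particle is destroyed and detached from its template.

    ``rate_law="threshold"`` replaces mass action by a gated zeroth-order
    law (propensity ``k`` iff every reactant count covers its
    stoichiometry), intended for stack-wise regeneration reactions with
    very large stoichiometries where falling factorials are meaningless.
    """

    kind = "chemical"

    def __init__(self, reactants, products, k_forward: float,
                 k_backward: float = 0.0, rate_law: str = "mass_action",
                 tag: str = ""):
        if k_forward < 0 or k_backward < 0:
            raise ValidationError("rate constants must be >= 0")
        if rate_law not in ("mass_action", "threshold"):
            raise ValidationError(f"unknown rate law {rate_law!r}")
        self.reactants = _Side(reactants, "reactants")
        self.products = _Side(products, "products")
        self.k_forward = float(k_forward)
        self.k_backward = float(k_backward)
        self.rate_law = rate_law
        self.tag = tag
        self.system = None  # set on registration (owns the particle pool)
        if k_forward > 0 and self.products.bound is not None \
                and self.reactants.bound is None:
            raise ValidationError(
                "a bound product requires a bound reactant to carry across")
        if k_backward > 0 and self.reactants.bound is not None \
                and self.products.bound is None:
            raise ValidationError(
                "reversible reaction cannot re-create a destroyed particle")

    # -- propensities ----------------------------------------------------
    def propensity(self, direction: str = "forward") -> float:
        src = self.reactants if direction == "forward" else self.products
        k = self.k_forward if direction == "forward" else self.k_backward
        if k <= 0.0:
            return 0.0
        if self.rate_law == "threshold":
            for fc, st in src.free:
                if fc.count < st:
                    return 0.0
            if src.bound is not None and not len(src.bound):
                return 0.0
            return k
        a = k
        for fc, st in src.free:
            n = fc.count
            if st == 1:
                a *= n
            else:
                a *= falling_factorial(n, st)
            if a == 0.0:
                return 0.0
        if src.bound is not None:
            a *= len(src.bound)
        return a

    # -- firing ----------------------------------------------------------
    def fire(self, direction: str, rng) -> List[tuple]:
        src = self.reactants if direction == "forward" else self.products
        dst = self.products if direction == "forward" else self.reactants
        touched: List[tuple] = []
        unit = None
        if src.bound is not None:
            unit = src.bound.sample_member(rng)
            src.bound.remove(unit)
            touched.append(src.bound.key)
        for fc, st in src.free:
            if not fc.buffered:
                fc.count -= st
                touched.append(fc.key)
        for fc, st in dst.free:
            if not fc.buffered:
                fc.count += st
                touched.append(fc.key)
        if dst.bound is not None:
            # particle carries its location/position across
            dst.bound.add(unit)
            touched.append(dst.bound.key)
        elif unit is not None:
            # destroyed and detached
            if unit.on_origin_site:
                site = unit.origin_site
                site.occupied -= 1
                touched.append(("S", site.family))
            self.system.recycle_unit(unit)
        return touched

    # -- channel wiring --------------------------------------------------
    def channels(self):
        out = []
        if self.k_forward > 0:
            reads = self._reads(self.reactants)
            out.append(("forward", reads,
                        lambda: self.propensity("forward"),
                        lambda rng: self.fire("forward", rng)))
        if self.k_backward > 0:
            reads = self._reads(self.products)
            out.append(("backward", reads,
                        lambda: self.propensity("backward"),
                        lambda rng: self.fire("backward", rng)))
        return out

    @staticmethod
    def _reads(side: _Side):
        keys = [fc.key for fc, _ in side.free]
        if side.bound is not None:
            keys.append(side.bound.key)
        return keys


def propensity_chemical(reaction: ChemicalReaction, direction: str = "forward",
                        state=None) -> float:
    """Mass-action propensity of one direction of a chemical reaction."""
    return reaction.propensity(direction)


class SequenceBinding:
    """Binding of a free chemical to an unoccupied site of one family,
    creating a particle; the reverse channel unbinds particles still on
    their origin site (exposed through the class's family filter)."""

    kind = "binding"

    def __init__(self, free_form: FreeChemical, bound_form: BoundChemical,
                 family: SiteFamily, tag: str = ""):
        self.free_form = free_form
        self.bound_form = bound_form
        self.family = family
        self.tag = tag
        self.system = None
        self.filter: Optional[FamilyFilter] = None  # attached on registration

    def propensity_forward(self) -> float:
        n = self.free_form.count
        if n == 0:
            return 0.0
        a = 0.0
        for site in self.family.sites:
            a += site.k_on * site.available()
        return n * a

    def propensity_reverse(self) -> float:
        a = 0.0
        for site, units in self.filter.by_site.items():
            a += site.k_off * len(units)
        return a

    def fire_forward(self, rng) -> List[tuple]:
        sites = self.family.sites
        weights = [s.k_on * s.available() for s in sites]
        total = sum(weights)
        if total <= 0.0 or self.free_form.count <= 0:
            raise ImpossibleReactionError(
                f"binding to family {self.family.name!r} has zero propensity")
        r = rng.random() * total
        cum = 0.0
        site = sites[-1]
        for s, w in zip(sites, weights):
            cum += w
            if cum >= r:
                site = s
                break
        touched = []
        if not self.free_form.buffered:
            self.free_form.count -= 1
            touched.append(self.free_form.key)
        site.occupied += 1
        unit = self.system.new_unit()
        unit.sequence = site.sequence
        unit.position = site.reading_offset
        unit.origin_site = site
        unit.on_origin_site = True
        self.bound_form.add(unit)
        touched.append(self.family.key)
        touched.append(self.bound_form.key)
        return touched

    def fire_reverse(self, rng) -> List[tuple]:
        items = list(self.filter.by_site.items())
        weights = [site.k_off * len(units) for site, units in items]
        total = sum(weights)
        if total <= 0.0:
            raise ImpossibleReactionError(
                f"no unbindable particle for family {self.family.name!r}")
        r = rng.random() * total
        cum = 0.0
        site, units = items[-1]
        for (s, u), w in zip(items, weights):
            cum += w
            if cum >= r:
                site, units = s, u
                break
        unit = units[int(rng.random() * len(units))]
        self.bound_form.remove(unit)
        site.occupied -= 1
        touched = [self.bound_form.key, self.family.key]
        if not self.free_form.buffered:
            self.free_form.count += 1
            touched.append(self.free_form.key)
        self.system.recycle_unit(unit)
        return touched

    def channels(self):
        out = [("forward", [self.free_form.key, self.family.key],
                self.propensity_forward, self.fire_forward)]
        if any(s.k_off > 0 for s in self.family.sites):
            out.append(("backward", [self.bound_form.key, self.family.key],
                        self.propensity_reverse, self.fire_reverse))
        return out


def propensity_binding(binding: SequenceBinding, state=None):
    """(forward, reverse) propensities of a sequence binding."""
    return binding.propensity_forward(), binding.propensity_reverse()


class Translocation:
    """Moves a uniformly drawn particle of ``mobile_class`` along its
    sequence by ``step`` positions (1 for nucleotide-wise processes, 3 for
    codon-wise ones), reassigning it to ``post_class``.  The first move
    clears the origin site.  If the landing position carries a switch whose
    input class is ``post_class``, the particle switches immediately."""

    kind = "translocation"

    def __init__(self, mobile_class: BoundChemical, post_class: BoundChemical,
                 step: int, rate: float, tag: str = ""):
        if step < 1:
            raise ValidationError("translocation step must be >= 1")
        if rate < 0:
            raise ValidationError("translocation rate must be >= 0")
        self.mobile_class = mobile_class
        self.post_class = post_class
        self.step = int(step)
        self.rate = float(rate)
        self.tag = tag
        self.system = None

    def propensity(self) -> float:
        return self.rate * len(self.mobile_class)

    def fire(self, rng) -> List[tuple]:
        unit = self.mobile_class.sample_member(rng)
        self.mobile_class.remove(unit)
        touched = [self.mobile_class.key]
        if unit.on_origin_site:
            site = unit.origin_site
            site.occupied -= 1
            unit.on_origin_site = False
            touched.append(("S", site.family))
        pos = unit.position + self.step
        if pos > unit.sequence.length:
            pos = unit.sequence.length
        unit.position = pos
        target = self.post_class
        for sw in unit.sequence.switches_at(pos):
            if sw.switch.input_class is target:
                target = sw.switch.output_class
                break
        target.add(unit)
        touched.append(target.key)
        return touched

    def channels(self):
        return [("forward", [self.mobile_class.key],
                 self.propensity, self.fire)]


@dataclass
class LoadingRule:
    """What a particle reading one motif loads, emits and becomes."""
    loaded: FreeChemical
    byproducts: List[FreeChemical]
    rate: float
    post_class: BoundChemical


class Loading:
    """Template-directed consumption of monomer carriers: a particle of
    ``loader_class`` reading motif *m* consumes ``table[m].loaded`` at
    ``table[m].rate`` per loaded molecule, releases the byproducts and
    moves to ``table[m].post_class``.

    The reaction owns a single propensity channel whose value is the total
    over motifs; the motif actually fired is drawn proportionally to the
    per-motif decomposition, then the particle uniformly within the
    partition.
    """

    kind = "loading"

    def __init__(self, loader_class: BoundChemical, motif_length: int,
                 table: Dict[str, LoadingRule], tag: str = ""):
        if motif_length < 1:
            raise ValidationError("motif length must be >= 1")
        for motif, rule in table.items():
            if len(motif) != motif_length:
                raise ValidationError(
                    f"motif {motif!r} does not have {motif_length} letters")
            if rule.rate < 0:
                raise ValidationError("loading rates must be >= 0")
        self.loader_class = loader_class
        self.motif_length = int(motif_length)
        self.table = dict(table)
        self.tag = tag
        self.system = None
        self.filter: Optional[TemplateFilter] = None  # attached on registration

    def propensity(self) -> float:
        table = self.table
        a = 0.0
        for motif, units in self.filter.partitions.items():
            rule = table.get(motif)
            if rule is not None:
                a += rule.rate * rule.loaded.count * len(units)
        return a

    def decomposition(self) -> List[Tuple[str, float]]:
        table = self.table
        out = []
        for motif, units in self.filter.partitions.items():
            rule = table.get(motif)
            if rule is not None:
                c = rule.rate * rule.loaded.count * len(units)
                if c > 0.0:
                    out.append((motif, c))
        return out

    def fire(self, rng) -> List[tuple]:
        decomp = self.decomposition()
        total = sum(c for _, c in decomp)
        if total <= 0.0:
            raise ImpossibleReactionError(
                f"loading on {self.loader_class.name!r} has zero propensity")
        r = rng.random() * total
        cum = 0.0
        motif = decomp[-1][0]
        for m, c in decomp:
            cum += c
            if cum >= r:
                motif = m
                break
        units = self.filter.partitions[motif]
        unit = units[int(rng.random() * len(units))]
        rule = self.table[motif]
        touched = []
        if not rule.loaded.buffered:
            rule.loaded.count -= 1
            touched.append(rule.loaded.key)
        for bp in rule.byproducts:
            if not bp.buffered:
                bp.count += 1
                touched.append(bp.key)
        self.loader_class.remove(unit)
        rule.post_class.add(unit)
        touched.append(self.loader_class.key)
        touched.append(rule.post_class.key)
        return touched

    def channels(self):
        reads = [self.loader_class.key]
        reads.extend({rule.loaded.key for rule in self.table.values()})
        return [("forward", reads, self.propensity, self.fire)]


def propensity_loading(loading: Loading, state=None):
    """(total, per-motif decomposition) of a loading reaction."""
    return loading.propensity(), dict(loading.decomposition())


@dataclass
class ReleaseRule:
    """Product interval: particles with this origin family whose position
    lies in [first, last) yield one copy of ``product``."""
    family: str
    first: int
    last: int
    product: ChemicalSequence


class Release:
    """Detaches a particle, frees the listed chemicals (e.g. the
    polymerase) and creates the product sequence determined by the
    particle's origin site family and current position (e.g. the RNA for a
    given promoter/terminator combination)."""

    kind = "release"

    def __init__(self, releasing_class: BoundChemical, rate: float,
                 freed: List[FreeChemical], rules: List[ReleaseRule],
                 on_unmatched: str = "error", tag: str = ""):
        if rate < 0:
            raise ValidationError("release rate must be >= 0")
        if on_unmatched not in ("error", "warn"):
            raise ValidationError("on_unmatched must be 'error' or 'warn'")
        self.releasing_class = releasing_class
        self.rate = float(rate)
        self.freed = list(freed)
        self.rules = list(rules)
        self.on_unmatched = on_unmatched
        self.tag = tag
        self.system = None
        self.by_family: Dict[str, List[ReleaseRule]] = {}
        for rule in self.rules:
            self.by_family.setdefault(rule.family, []).append(rule)
        for family, rules_ in self.by_family.items():
            ordered = sorted(rules_, key=lambda r: (r.first, r.last))
            for a, b in zip(ordered, ordered[1:]):
                if b.first < a.last:
                    raise ValidationError(
                        f"overlapping product intervals for family {family!r}")

    def propensity(self) -> float:
        return self.rate * len(self.releasing_class)

    def lookup(self, family: Optional[str], position: int):
        for rule in self.by_family.get(family, ()):  # few rules per family
            if rule.first <= position < rule.last:
                return rule
        return None

    def fire(self, rng) -> List[tuple]:
        unit = self.releasing_class.sample_member(rng)
        self.releasing_class.remove(unit)
        touched = [self.releasing_class.key]
        if unit.on_origin_site:
            site = unit.origin_site
            site.occupied -= 1
            touched.append(("S", site.family))
        for fc in self.freed:
            if not fc.buffered:
                fc.count += 1
                touched.append(fc.key)
        family = unit.origin_site.family if unit.origin_site else None
        rule = self.lookup(family, unit.position)
        if rule is None:
            msg = (f"release from {self.releasing_class.name!r}: no product "
                   f"interval matches origin family {family!r} at position "
                   f"{unit.position}")
            if self.on_unmatched == "error":
                raise UnmatchedReleaseError(msg)
            warnings.warn(msg, stacklevel=2)
        else:
            product = rule.product
            product.copies += 1
            for fam in product.site_families:
                touched.append(("S", fam))
        self.system.recycle_unit(unit)
        return touched

    def channels(self):
        return [("forward", [self.releasing_class.key],
                 self.propensity, self.fire)]


EVENT_KINDS = ("ADD", "SET", "REMOVE_FREE")


@dataclass(order=True)
class TimedEvent:
    """A scheduled change of a free pool: injection (ADD), clamping (SET)
    or wash-out of the free form only (REMOVE_FREE, clamped at zero; bound
    complexes are untouched)."""
    time: float
    kind: str = field(compare=False)
    target: FreeChemical = field(compare=False)
    amount: int = field(compare=False)

    def __post_init__(self):
        if self.time < 0:
            raise ValidationError("event times must be non-negative")
        if self.kind not in EVENT_KINDS:
            raise ValidationError(f"unknown event kind {self.kind!r}")
        if self.amount < 0:
            raise ValidationError("event amounts must be non-negative")

    def apply(self) -> List[tuple]:
        fc = self.target
        if self.kind == "ADD":
            fc.count += self.amount
        elif self.kind == "SET":
            fc.count = self.amount
        else:  # REMOVE_FREE
            fc.count = max(0, fc.count - self.amount)
        return [fc.key]


def apply_event(event: TimedEvent, state=None) -> None:
    event.apply()
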