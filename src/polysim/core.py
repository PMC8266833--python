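"""Domain types of the hybrid pool/particle state.

Freely diffusing chemicals and template sequences are *pools* (a molecule
count); chemicals bound to a template are *particles* (:class:`BoundUnit`),
each carrying the sequence it sits on, its current reading position, and the
binding site through which it arrived.  Reactions address particles through
their external state class (:class:`BoundChemical`) and through bookmarking
filters that expose the subsets eligible for a given reaction:

* :class:`FamilyFilter` — particles still sitting on the binding site they
  originally bound through (hence able to unbind), grouped per site;
* :class:`TemplateFilter` — particles partitioned by the template motif they
  are currently reading (hence able to load the matching monomer carrier).

Coordinates are 0-based and intervals are half-open ``[first, last)``;
``position`` is the index of the next letter to be read.
"""

from __future__ import annotations

from typing import Dict, List, Optional

from .errors import ConsistencyError, ImpossibleReactionError, ValidationError


class FreeChemical:
    """A freely diffusing chemical, represented only by its molecule count.

    ``buffered`` marks a constant-concentration species: its count still
    gates propensities and is formally "consumed", but firing a reaction
    leaves it unchanged (timed events may still modify it).
    """

    __slots__ = ("name", "count", "buffered", "key")

    def __init__(self, name: str, count: int = 0, buffered: bool = False):
        if count < 0:
            raise ValidationError(f"negative count for chemical {name!r}")
        self.name = name
        self.count = int(count)
        self.buffered = bool(buffered)
        self.key = ("F", name)

    def __repr__(self) -> str:
        flag = ", buffered" if self.buffered else ""
        return f"FreeChemical({self.name!r}, count={self.count}{flag})"


class ChemicalSequence:
    """A population of identical template copies with annotated sites.

    Sequences are immutable after registration: ``letters`` cannot be
    edited, only the population count ``copies`` changes (products of
    release reactions increment it).
    """

    __slots__ = ("name", "_letters", "copies", "sites", "switch_sites",
                 "_switches_at", "site_families", "key")

    def __init__(self, name: str, letters: str, copies: int = 0):
        if copies < 0:
            raise ValidationError(f"negative copy number for sequence {name!r}")
        if not letters:
            raise ValidationError(f"sequence {name!r} has no letters")
        self.name = name
        self._letters = str(letters)
        self.copies = int(copies)
        self.sites: List[BindingSite] = []
        self.switch_sites: List[SwitchSite] = []
        self._switches_at: Dict[int, List[SwitchSite]] = {}
        self.site_families: List[str] = []  # family names with sites here
        self.key = ("Q", name)

    @property
    def letters(self) -> str:
        return self._letters

    @property
    def length(self) -> int:
        return len(self._letters)

    def read(self, position: int, length: int) -> Optional[str]:
        """Letters in ``[position, position+length)``, or None on overrun."""
        if length < 1:
            raise ValidationError("motif length must be >= 1")
        if position < 0:
            raise ValidationError("negative read position")
        if position + length > len(self._letters):
            return None
        return self._letters[position:position + length]

    def switches_at(self, position: int) -> List["SwitchSite"]:
        return self._switches_at.get(position, _NO_SWITCHES)

    def __repr__(self) -> str:
        return (f"ChemicalSequence({self.name!r}, length={self.length}, "
                f"copies={self.copies})")


_NO_SWITCHES: List["SwitchSite"] = []


def read_motif(sequence: ChemicalSequence, position: int, length: int):
    """Motif of ``length`` letters read at ``position``; None on overrun."""
    return sequence.read(position, length)


class BindingSite:
    """A binding interval on a sequence, member of a named site family.

    Availability is tracked in aggregate over the sequence population:
    ``available = sequence.copies - occupied``.  A new-bound particle starts
    reading at ``reading_offset``.
    """

    __slots__ = ("family", "sequence", "first", "last", "k_on", "k_off",
                 "reading_offset", "occupied")

    def __init__(self, family: str, sequence: ChemicalSequence, first: int,
                 last: int, k_on: float, k_off: float, reading_offset: int):
        if not (0 <= first < last <= sequence.length):
            raise ValidationError(
                f"site [{first},{last}) out of bounds for sequence "
                f"{sequence.name!r} of length {sequence.length}")
        if k_on < 0 or k_off < 0:
            raise ValidationError("binding rates must be >= 0")
        if not (0 <= reading_offset <= sequence.length):
            raise ValidationError("reading offset outside the sequence")
        self.family = family
        self.sequence = sequence
        self.first = int(first)
        self.last = int(last)
        self.k_on = float(k_on)
        self.k_off = float(k_off)
        self.reading_offset = int(reading_offset)
        self.occupied = 0

    def available(self) -> int:
        avail = self.sequence.copies - self.occupied
        if avail < 0:
            raise ConsistencyError(
                f"site [{self.first},{self.last}) on {self.sequence.name!r}: "
                f"occupied={self.occupied} exceeds copies={self.sequence.copies}")
        return avail


class SiteFamily:
    """Named group of binding sites sharing binding semantics."""

    __slots__ = ("name", "sites", "key")

    def __init__(self, name: str):
        self.name = name
        self.sites: List[BindingSite] = []
        self.key = ("S", name)

    def available_total(self) -> int:
        return sum(s.available() for s in self.sites)


class Switch:
    """Annotation-triggered state change: when a particle of ``input_class``
    lands (by translocation) on a position annotated with this switch, it is
    reassigned to ``output_class``.  Transcription terminators are the
    canonical example (elongation -> termination)."""

    __slots__ = ("name", "input_class", "output_class")

    def __init__(self, name: str, input_class: "BoundChemical",
                 output_class: "BoundChemical"):
        if input_class is output_class:
            raise ValidationError(
                f"switch {name!r}: input and output class must differ")
        self.name = name
        self.input_class = input_class
        self.output_class = output_class


class SwitchSite:
    """A single annotated position where a switch applies."""

    __slots__ = ("sequence", "position", "switch")

    def __init__(self, sequence: ChemicalSequence, position: int, switch: Switch):
        if not (0 <= position < sequence.length):
            raise ValidationError(
                f"switch position {position} outside sequence {sequence.name!r}")
        self.sequence = sequence
        self.position = int(position)
        self.switch = switch


class BoundUnit:
    """A lightweight particle bound to a template.

    Internal state: the sequence it is on, its reading position, the site it
    bound through, and whether it is still sitting on that origin site
    (``on_origin_site`` gates unbinding and is cleared by the first
    translocation).  Units are recycled through a free-list owned by the
    system, so identity (not value) is what matters.
    """

    __slots__ = ("sequence", "position", "origin_site", "on_origin_site")

    def __init__(self):
        self.sequence: Optional[ChemicalSequence] = None
        self.position: int = 0
        self.origin_site: Optional[BindingSite] = None
        self.on_origin_site: bool = False


class FamilyFilter:
    """Members of the parent class still on an origin site of one family,
    partitioned per site (needed to weight unbinding by each site's k_off)."""

    __slots__ = ("family", "by_site", "_where")

    def __init__(self, family: str):
        self.family = family
        self.by_site: Dict[BindingSite, List[BoundUnit]] = {}
        self._where: Dict[BoundUnit, int] = {}

    def add(self, unit: BoundUnit) -> None:
        site = unit.origin_site
        if site is None or not unit.on_origin_site or site.family != self.family:
            return
        lst = self.by_site.get(site)
        if lst is None:
            lst = self.by_site[site] = []
        self._where[unit] = len(lst)
        lst.append(unit)

    def discard(self, unit: BoundUnit) -> None:
        idx = self._where.pop(unit, None)
        if idx is None:
            return
        lst = self.by_site[unit.origin_site]
        last = lst.pop()
        if last is not unit:
            lst[idx] = last
            self._where[last] = idx
        if not lst:
            del self.by_site[unit.origin_site]

    def count_on(self, site: BindingSite) -> int:
        return len(self.by_site.get(site, _EMPTY))

    def __len__(self) -> int:
        return len(self._where)

    def members(self):
        return list(self._where)


class TemplateFilter:
    """Members of the parent class partitioned by the motif (window of
    ``motif_length`` letters) they are currently reading.  Units whose
    window overruns the sequence end are not in any partition."""

    __slots__ = ("motif_length", "partitions", "_where")

    def __init__(self, motif_length: int):
        if motif_length < 1:
            raise ValidationError("motif length must be >= 1")
        self.motif_length = int(motif_length)
        self.partitions: Dict[str, List[BoundUnit]] = {}
        self._where: Dict[BoundUnit, tuple] = {}

    def add(self, unit: BoundUnit) -> None:
        motif = unit.sequence.read(unit.position, self.motif_length)
        if motif is None:
            return
        lst = self.partitions.get(motif)
        if lst is None:
            lst = self.partitions[motif] = []
        self._where[unit] = (motif, len(lst))
        lst.append(unit)

    def discard(self, unit: BoundUnit) -> None:
        entry = self._where.pop(unit, None)
        if entry is None:
            return
        motif, idx = entry
        lst = self.partitions[motif]
        last = lst.pop()
        if last is not unit:
            lst[idx] = last
            self._where[last] = (motif, idx)
        if not lst:
            del self.partitions[motif]

    def __len__(self) -> int:
        return len(self._where)


_EMPTY: List[BoundUnit] = []


class BoundChemical:
    """External state class of bound particles (e.g. "RNAP elongating").

    Reactions address the class; the particle actually fired is drawn
    uniformly from ``members``.  Attached filters are maintained
    incrementally on every add/remove.
    """

    __slots__ = ("name", "members", "_where", "filters", "key")

    def __init__(self, name: str):
        self.name = name
        self.members: List[BoundUnit] = []
        self._where: Dict[BoundUnit, int] = {}
        self.filters: List = []
        self.key = ("B", name)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, unit: BoundUnit) -> bool:
        return unit in self._where

    def add(self, unit: BoundUnit) -> None:
        if unit in self._where:
            raise ConsistencyError(
                f"unit already a member of {self.name!r}")
        self._where[unit] = len(self.members)
        self.members.append(unit)
        for f in self.filters:
            f.add(unit)

    def remove(self, unit: BoundUnit) -> None:
        idx = self._where.pop(unit, None)
        if idx is None:
            raise ConsistencyError(f"unit is not a member of {self.name!r}")
        last = self.members.pop()
        if last is not unit:
            self.members[idx] = last
            self._where[last] = idx
        for f in self.filters:
            f.discard(unit)

    def sample_member(self, rng) -> BoundUnit:
        """Uniformly drawn member; O(1)."""
        n = len(self.members)
        if n == 0:
            raise ImpossibleReactionError(
                f"no particle in class {self.name!r} to draw from")
        return self.members[int(rng.random() * n)]

    def family_filter(self, family: str) -> Optional[FamilyFilter]:
        for f in self.filters:
            if isinstance(f, FamilyFilter) and f.family == family:
                return f
        return None

    def template_filter(self, motif_length: int) -> Optional[TemplateFilter]:
        for f in self.filters:
            if isinstance(f, TemplateFilter) and f.motif_length == motif_length:
                return f
        return None

    def __repr__(self) -> str:
        return f"BoundChemical({self.name!r}, members={len(self.members)})"


def sample_member(bound_chemical: BoundChemical, rng) -> BoundUnit:
    return bound_chemical.sample_member(rng)


def reassign_unit(unit: BoundUnit, from_class: BoundChemical,
                  to_class: BoundChemical) -> None:
    """Detach a particle from its current class and re-attach it to a new
    one; all filters of both classes are kept consistent and the total
    particle count is unchanged."""
    from_class.remove(unit)
    to_class.add(unit)
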