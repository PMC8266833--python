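import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def binding_system():
    """A sequence with one promoter-like site and a minimal binding setup:
    10 free polymerases, one site on a 100-letter template (3 copies)."""
    from polysim import ReactionSystem

    system = ReactionSystem()
    system.add_free_chemical("pol", 10)
    system.add_sequence("tpl", "ATGC" * 25, copies=3)
    system.register_binding_site("prom", "tpl", 0, 10, k_on=0.1, k_off=0.5,
                                 reading_offset=0)
    system.add_bound_chemical("pol_bound")
    system.add_sequence_binding("pol", "pol_bound", "prom")
    return system


def filters_consistent(system):
    """Recompute every filter from scratch and compare with the
    incrementally maintained content."""
    from polysim import FamilyFilter, TemplateFilter

    for bc in system.bound_chemicals.values():
        for f in bc.filters:
            if isinstance(f, FamilyFilter):
                fresh = FamilyFilter(f.family)
            else:
                fresh = TemplateFilter(f.motif_length)
            for unit in bc.members:
                fresh.add(unit)
            if isinstance(f, FamilyFilter):
                got = {site: frozenset(map(id, units))
                       for site, units in f.by_site.items()}
                want = {site: frozenset(map(id, units))
                        for site, units in fresh.by_site.items()}
            else:
                got = {m: frozenset(map(id, units))
                       for m, units in f.partitions.items()}
                want = {m: frozenset(map(id, units))
                        for m, units in fresh.partitions.items()}
            if got != want:
                return False
    return True


def occupancy_consistent(system):
    """Site occupancies must equal the number of live on-origin units."""
    expected = {}
    for bc in system.bound_chemicals.values():
        for unit in bc.members:
            if unit.on_origin_site:
                site = unit.origin_site
                expected[id(site)] = expected.get(id(site), 0) + 1
    for fam in system.families.values():
        for site in fam.sites:
            if site.occupied != expected.get(id(site), 0):
                return False
    return True
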