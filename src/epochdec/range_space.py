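"""Geographic areas, range bitmasks, and the range state space.

A *range* is a subset of a fixed, ordered list of biogeographic areas and is
represented throughout the package as an integer bitmask: bit ``i`` set means
the range includes area ``codes[i]``.  The default area system is the six
Northern-Hemisphere regions used for temperate tree disjunctions -- western
North America (WNA), eastern North America (ENA), Japan (JP), Europe (EU),
East Asia (EA), and Central Asia (CA) -- with a configurable table deciding
which area pairs count as *adjacent* (same landmass / minor barrier) versus
*intercontinental* (major ocean or plateau barrier).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from typing import Iterable, Sequence

__all__ = [
    "ADJACENT",
    "INTERCONTINENTAL",
    "EXTINCTION_SCOPE",
    "AreaSet",
    "StateSpace",
    "northern_hemisphere_areas",
    "enumerate_states",
    "classify_pair",
    "dispersal_scope",
    "vicariance_scope",
    "transition_scope",
]

ADJACENT = "adjacent"
INTERCONTINENTAL = "intercontinental"
#: scope value used for range-loss (extinction) events, which have no pair scope
EXTINCTION_SCOPE = "n/a"

DEFAULT_CODES = ("WNA", "ENA", "JP", "EU", "EA", "CA")
DEFAULT_ADJACENT_PAIRS = (
    ("WNA", "ENA"),
    ("EA", "JP"),
    ("EA", "CA"),
    ("JP", "CA"),
    ("EU", "CA"),
)


def _bits(mask: int):
    """Yield set bit positions of ``mask`` in ascending order."""
    i = 0
    while mask:
        if mask & 1:
            yield i
        mask >>= 1
        i += 1


@dataclass(frozen=True)
class AreaSet:
    """An ordered set of area codes plus the adjacent/intercontinental pair table.

    Parameters
    ----------
    codes
        Unique short area codes; their order fixes bitmask bit positions.
    adjacent_pairs
        Unordered pairs of codes classified as adjacent; every other pair of
        distinct areas is intercontinental.
    """

    codes: tuple[str, ...]
    adjacent_pairs: frozenset[frozenset[str]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        codes = tuple(self.codes)
        object.__setattr__(self, "codes", codes)
        if len(set(codes)) != len(codes) or not codes:
            raise ValueError(f"area codes must be unique and non-empty: {codes!r}")
        pairs = frozenset(frozenset(p) for p in self.adjacent_pairs)
        object.__setattr__(self, "adjacent_pairs", pairs)
        for pair in pairs:
            if len(pair) != 2:
                raise ValueError(f"adjacent pair must name two distinct areas: {set(pair)!r}")
            for code in pair:
                self.index(code)

    def __len__(self) -> int:
        return len(self.codes)

    def index(self, code: str) -> int:
        try:
            return self.codes.index(code)
        except ValueError:
            raise KeyError(
                f"unknown area code {code!r}; valid codes: {', '.join(self.codes)}"
            ) from None

    def mask(self, codes: Iterable[str] | str) -> int:
        """Bitmask for a range given area codes (iterable or 'EA,EU' string)."""
        if isinstance(codes, str):
            codes = [c for c in codes.replace("+", ",").split(",") if c.strip()]
        m = 0
        for code in codes:
            m |= 1 << self.index(code.strip())
        return m

    def names(self, mask: int) -> tuple[str, ...]:
        return tuple(self.codes[i] for i in _bits(mask))

    def format_range(self, mask: int) -> str:
        """Human/TSV-friendly rendering of a range bitmask ('EA+EU'; null is '0')."""
        return "+".join(self.names(mask)) or "0"

    def classify_pair(self, a: str, b: str) -> str:
        """Scope of an unordered area pair: ADJACENT or INTERCONTINENTAL."""
        ia, ib = self.index(a), self.index(b)
        if ia == ib:
            raise ValueError(f"pair scope is undefined for identical areas ({a!r})")
        return ADJACENT if frozenset((a, b)) in self.adjacent_pairs else INTERCONTINENTAL

    def pair_is_adjacent(self, i: int, j: int) -> bool:
        return frozenset((self.codes[i], self.codes[j])) in self.adjacent_pairs


def northern_hemisphere_areas(
    adjacent_pairs: Sequence[tuple[str, str]] = DEFAULT_ADJACENT_PAIRS,
) -> AreaSet:
    """The six-region system (WNA, ENA, JP, EU, EA, CA) with its default adjacency.

    Adjacent pairs default to within-landmass / short-barrier neighbours
    {WNA-ENA, EA-JP, EA-CA, JP-CA, EU-CA}; all remaining pairs (all trans-Pacific,
    trans-Atlantic and Bering-strait pairs) are intercontinental.  The table is
    configuration, not inference: pass a different ``adjacent_pairs`` to change it.
    """
    return AreaSet(DEFAULT_CODES, frozenset(frozenset(p) for p in adjacent_pairs))


class StateSpace:
    """Deterministic enumeration of range states up to a maximum range size.

    States are ordered with the null (empty) range first, then non-empty ranges
    by size and, within a size, by ascending bitmask value.  Index lookup is a
    bijection (``index_of(state_at(i)) == i``).
    """

    def __init__(self, areas: AreaSet, max_range_size: int | None = None):
        n = len(areas)
        if max_range_size is None:
            max_range_size = n
        if not 1 <= max_range_size <= n:
            raise ValueError(
                f"max_range_size must lie in [1, {n}], got {max_range_size}"
            )
        self.areas = areas
        self.max_range_size = int(max_range_size)
        nonempty = sorted(
            (m for m in range(1, 1 << n) if m.bit_count() <= max_range_size),
            key=lambda m: (m.bit_count(), m),
        )
        self.states: tuple[int, ...] = (0, *nonempty)
        self._index = {s: i for i, s in enumerate(self.states)}
        assert len(self.states) == 1 + sum(comb(n, k) for k in range(1, max_range_size + 1))

    def __len__(self) -> int:
        return len(self.states)

    @property
    def n_areas(self) -> int:
        return len(self.areas)

    def index_of(self, mask: int) -> int:
        try:
            return self._index[mask]
        except KeyError:
            raise KeyError(
                f"range {self.areas.format_range(mask)} not in state space "
                f"(max_range_size={self.max_range_size})"
            ) from None

    def state_at(self, i: int) -> int:
        return self.states[i]

    def format_state(self, i: int) -> str:
        return self.areas.format_range(self.states[i])


def enumerate_states(areas: AreaSet, max_range_size: int) -> StateSpace:
    """Enumerate all range states of size <= ``max_range_size`` (plus the null range)."""
    return StateSpace(areas, max_range_size)


def classify_pair(areas: AreaSet, a: str, b: str) -> str:
    return areas.classify_pair(a, b)


def dispersal_scope(areas: AreaSet, source: int, gained: int | str) -> str:
    """Scope of a dispersal event gaining one area from a source range.

    Nearest-source semantics: the event is ADJACENT if *any* source area is
    adjacent to the gained area, INTERCONTINENTAL otherwise, so a single event
    is never double-counted across scopes.
    """
    b = areas.index(gained) if isinstance(gained, str) else int(gained)
    if not 0 <= b < len(areas):
        raise ValueError(f"gained area index {b} out of bounds")
    if source & (1 << b):
        raise ValueError(
            f"gained area {areas.codes[b]} already in source range "
            f"{areas.format_range(source)}"
        )
    if source == 0:
        raise ValueError("dispersal from the null range is undefined")
    for a in _bits(source):
        if areas.pair_is_adjacent(a, b):
            return ADJACENT
    return INTERCONTINENTAL


def vicariance_scope(areas: AreaSet, left: int, right: int) -> str:
    """Scope of a vicariant split: INTERCONTINENTAL if any cross-partition pair is."""
    if left == 0 or right == 0 or (left & right):
        raise ValueError(
            "vicariance requires two non-empty, disjoint daughter ranges; got "
            f"{areas.format_range(left)} | {areas.format_range(right)}"
        )
    for a in _bits(left):
        for b in _bits(right):
            if not areas.pair_is_adjacent(a, b):
                return INTERCONTINENTAL
    return ADJACENT


def transition_scope(areas: AreaSet, source: int, gained_or_partition) -> str:
    """Classify a range transition.

    ``gained_or_partition`` is either a single gained area (code or index) for a
    dispersal, or a ``(left, right)`` bitmask pair partitioning ``source`` for a
    vicariance.
    """
    if isinstance(gained_or_partition, tuple):
        left, right = gained_or_partition
        if (left | right) != source:
            raise ValueError(
                f"partition {areas.format_range(left)} | {areas.format_range(right)} "
                f"does not cover the parent range {areas.format_range(source)}"
            )
        return vicariance_scope(areas, left, right)
    return dispersal_scope(areas, source, gained_or_partition)
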