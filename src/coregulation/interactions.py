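"""Protein-protein interaction sets and group (complex/operon) tables.

Interactions are unordered, heterodimeric pairs of protein identifiers.
Pairs are stored canonically with the lexicographically smaller identifier
first, so equality is order-insensitive and sets deduplicate naturally.
Self-pairs (homodimers) are excluded everywhere: only the co-regulation of
*distinct* gene products is of interest, and a homodimer would contribute a
degenerate, perfectly correlated observation.

Group tables describe protein complexes or operons as ``group id ->
members``; expanding a group of size *k* into all unordered member pairs
yields ``k*(k-1)/2`` co-complex (or intra-operon) pairs.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from .params import ParamsTable, SYMBOLS

logger = logging.getLogger(__name__)

Pair = tuple[str, str]


def canonical_pair(a: str, b: str) -> Pair:
    """Order a pair canonically; raise on a self-pair."""
    a, b = str(a), str(b)
    if a == b:
        raise ValueError(f"self-pair ({a!r}, {b!r}) is not heterodimeric")
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class InteractionSet:
    """A labelled set of unordered heterodimeric protein pairs.

    Attributes
    ----------
    label
        Provenance tag, e.g. ``co-complex``, ``binary``, ``operon``,
        ``random``, ``shuffled`` or ``hub-control``.
    pairs
        Frozen set of canonically ordered pairs.
    source_note
        Free-text provenance (file path, generating seed, filter counts).
    """

    label: str
    pairs: frozenset[Pair]
    source_note: str = ""

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple[str, str]], label: str, source_note: str = ""
    ) -> "InteractionSet":
        """Build a set from raw (possibly unordered, duplicated) pairs.

        Self-pairs are dropped with a logged count rather than raised:
        real interactomes routinely contain homodimers that the analysis
        simply excludes.
        """
        kept: set[Pair] = set()
        dropped = 0
        for a, b in pairs:
            a, b = str(a), str(b)
            if a == b:
                dropped += 1
                continue
            kept.add((a, b) if a < b else (b, a))
        if dropped:
            logger.info("%s: dropped %d homodimeric pair(s)", label, dropped)
        return cls(label=label, pairs=frozenset(kept), source_note=source_note)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self) -> Iterator[Pair]:
        return iter(sorted(self.pairs))

    def __contains__(self, pair: tuple[str, str]) -> bool:
        a, b = str(pair[0]), str(pair[1])
        if a == b:
            return False
        return ((a, b) if a < b else (b, a)) in self.pairs

    @property
    def proteins(self) -> frozenset[str]:
        return frozenset(p for pair in self.pairs for p in pair)

    def degree_sequence(self) -> list[int]:
        """Sorted node degrees of the interaction graph."""
        deg: dict[str, int] = {}
        for a, b in self.pairs:
            deg[a] = deg.get(a, 0) + 1
            deg[b] = deg.get(b, 0) + 1
        return sorted(deg.values())

    def union(self, *others: "InteractionSet", label: str = "union") -> "InteractionSet":
        pairs = frozenset().union(self.pairs, *(o.pairs for o in others))
        return InteractionSet(label=label, pairs=pairs)

    def relabel(self, label: str) -> "InteractionSet":
        return InteractionSet(label=label, pairs=self.pairs, source_note=self.source_note)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for a, b in sorted(self.pairs):
                fh.write(f"{a}\t{b}\n")


def read_edge_list(path: str | Path, label: str = "edges") -> InteractionSet:
    """Read a two-column edge list (tab- or whitespace-separated).

    Duplicates collapse, orientation is ignored, and self-pairs are dropped
    with a logged count. A row with fewer than two fields is a hard error
    naming the row number.
    """
    path = Path(path)
    raw_pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise ValueError(f"{path}: row {lineno} has fewer than two fields")
            raw_pairs.append((fields[0].strip(), fields[1].strip()))
    edges = InteractionSet.from_pairs(raw_pairs, label=label, source_note=str(path))
    logger.info("%s: %d rows -> %d unique heterodimeric pairs", path, len(raw_pairs), len(edges))
    return edges


@dataclass(frozen=True)
class GroupTable:
    """Complex or operon membership: ``group id -> member identifiers``."""

    groups: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self):
        for gid, members in self.groups.items():
            if len(set(members)) != len(members):
                raise ValueError(f"group {gid!r} has duplicate members")
            if len(members) < 1:
                raise ValueError(f"group {gid!r} is empty")

    def __len__(self) -> int:
        return len(self.groups)

    def __contains__(self, group_id: str) -> bool:
        return group_id in self.groups

    def members(self, group_id: str) -> tuple[str, ...]:
        if group_id not in self.groups:
            raise KeyError(f"unknown group {group_id!r}")
        return tuple(self.groups[group_id])

    def sizes(self) -> list[int]:
        return [len(m) for m in self.groups.values()]

    @property
    def proteins(self) -> frozenset[str]:
        return frozenset(p for members in self.groups.values() for p in members)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for gid in sorted(self.groups):
                for member in self.groups[gid]:
                    fh.write(f"{gid}\t{member}\n")


def read_group_table(path: str | Path) -> GroupTable:
    """Read a two-column membership file (group id, member), one row each.

    A member repeated inside one group is deduplicated with a log message;
    real complex catalogues list some subunits more than once.
    """
    path = Path(path)
    groups: dict[str, list[str]] = {}
    dupes = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}: row {lineno} has fewer than two fields")
            gid, member = fields[0].strip(), fields[1].strip()
            bucket = groups.setdefault(gid, [])
            if member in bucket:
                dupes += 1
                continue
            bucket.append(member)
    if dupes:
        logger.info("%s: deduplicated %d repeated membership row(s)", path, dupes)
    return GroupTable(groups={gid: tuple(m) for gid, m in groups.items()})


def expand_group_pairs(groups: GroupTable, label: str) -> InteractionSet:
    """All non-redundant unordered member pairs, unioned over groups.

    A group of size *k* contributes ``k*(k-1)/2`` pairs; a pair occurring in
    several groups appears once (the union is deduplicated, and multiplicity
    is never used as a weight).
    """
    pairs: set[Pair] = set()
    for gid in sorted(groups.groups):
        members = groups.groups[gid]
        for a, b in itertools.combinations(members, 2):
            if a == b:  # impossible after GroupTable validation, kept defensive
                continue
            pairs.add((a, b) if a < b else (b, a))
    return InteractionSet(label=label, pairs=frozenset(pairs), source_note=f"{len(groups)} groups")


def restrict_to_analyzable(
    edges: InteractionSet, table: ParamsTable, parameter: str
) -> InteractionSet:
    """Keep pairs whose *both* members carry a value of ``parameter``.

    This is the analyzability funnel applied to every interaction set: from
    all heterodimeric pairs down to those where the statistic of interest
    can actually be evaluated for both partners. Retained/dropped counts
    are logged and recorded on the result's ``source_note``.
    """
    if parameter not in SYMBOLS:
        raise KeyError(f"unknown parameter symbol {parameter!r}")
    have = table.genes_with(parameter)
    kept = frozenset(p for p in edges.pairs if p[0] in have and p[1] in have)
    dropped = len(edges.pairs) - len(kept)
    logger.info(
        "%s/%s: retained %d pairs, dropped %d lacking %s on a partner",
        edges.label, parameter, len(kept), dropped, parameter,
    )
    return InteractionSet(
        label=edges.label,
        pairs=kept,
        source_note=f"{edges.source_note}; analyzable[{parameter}]: {len(kept)} kept / {dropped} dropped",
    )


def read_id_mapping(path: str | Path) -> dict[str, str]:
    """Read a two-column (source id, target id) mapping file."""
    path = Path(path)
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}: row {lineno} has fewer than two fields")
            src, dst = fields[0].strip(), fields[1].strip()
            if src in mapping and mapping[src] != dst:
                raise ValueError(f"{path}: source id {src!r} maps to multiple targets")
            mapping[src] = dst
    return mapping


def apply_id_mapping(edges: InteractionSet, mapping: Mapping[str, str]) -> InteractionSet:
    """Translate endpoints through an identifier mapping.

    Unmapped endpoints pass through unchanged (logged). Pairs collapsing to
    self-pairs after mapping are dropped and counted — two names for the
    same protein do not make a heterodimer.
    """
    mapped: set[Pair] = set()
    unmapped = 0
    collapsed = 0
    for a, b in edges.pairs:
        na, nb = mapping.get(a, a), mapping.get(b, b)
        if a not in mapping:
            unmapped += 1
        if b not in mapping:
            unmapped += 1
        if na == nb:
            collapsed += 1
            continue
        mapped.add((na, nb) if na < nb else (nb, na))
    if unmapped:
        logger.info("%s: %d endpoint(s) had no mapping entry", edges.label, unmapped)
    if collapsed:
        logger.info("%s: %d pair(s) collapsed to self-pairs after mapping", edges.label, collapsed)
    return InteractionSet(
        label=edges.label,
        pairs=frozenset(mapped),
        source_note=f"{edges.source_note}; id-mapped ({collapsed} collapsed)",
    )
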