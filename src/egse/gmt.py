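"""Gene set collections: GMT reading/writing and resolution against a gene universe.

A gene set collection arrives as a GMT file (one set per line: name, description,
then member gene IDs, all tab-separated).  Before testing, every collection is
*indexed* against the expression matrix's gene universe: member IDs absent from
the universe are dropped, sets falling below a minimum resolved size are removed,
and surviving members are stored as integer row positions.  Gene-ID matching is
exact, case-sensitive string equality — the tool is identifier-agnostic (Entrez,
symbol, Ensembl all work as long as the GMT and the matrix agree).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

__all__ = [
    "GeneSet",
    "CollectionIndex",
    "read_gmt",
    "write_gmt",
    "build_index",
    "get_set_by_name",
    "summarize_collection",
    "read_symbols_map",
]

DEFAULT_MIN_SIZE = 5


@dataclass
class GeneSet:
    """One named gene set with ordered, unique members."""

    name: str
    description: str = ""
    members: list[str] = field(default_factory=list)
    set_id: str = ""
    annotation: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"gene set {self.name!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class IndexedSet:
    """A gene set resolved to row positions of an expression matrix."""

    gene_set: GeneSet
    index: list[int]
    n_original: int

    @property
    def name(self) -> str:
        return self.gene_set.name

    @property
    def n_retained(self) -> int:
        return len(self.index)

    def counts_label(self) -> str:
        # the "NumGenes: 23/24" convention: retained/original
        return f"{self.n_retained}/{self.n_original}"


@dataclass
class CollectionIndex:
    """A gene set collection resolved against a fixed gene universe.

    ``sets`` keeps only sets with at least ``min_size`` members found in the
    universe; ``index[i]`` holds 0-based row positions into the expression
    matrix for ``sets[i]``.  Positions are internal — reports always show gene
    identifiers.
    """

    sets: list[IndexedSet]
    universe: list[str]
    name: str = "custom"
    label: str = "custom"
    version: str = ""
    date: str = ""
    species: str = ""
    min_size: int = DEFAULT_MIN_SIZE

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for s in self.sets:
            if s.name in seen:
                raise ValueError(f"duplicate set name {s.name!r} in collection {self.label!r}")
            seen.add(s.name)
            if any(not (0 <= i < self.universe_size) for i in s.index):
                raise ValueError(f"set {s.name!r} has index positions outside the universe")
            if len(set(s.index)) != len(s.index):
                raise ValueError(f"set {s.name!r} has duplicate index positions")
        self._by_name = {s.name: s for s in self.sets}

    @property
    def universe_size(self) -> int:
        return len(self.universe)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def set_names(self) -> list[str]:
        return [s.name for s in self.sets]

    def membership_matrix(self):
        """Boolean sets × universe membership matrix (dense, for vectorised tests)."""
        import numpy as np

        m = np.zeros((len(self.sets), self.universe_size), dtype=bool)
        for row, s in enumerate(self.sets):
            m[row, s.index] = True
        return m


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file into a list of :class:`GeneSet`.

    Each non-empty line must carry at least name, description and one member,
    tab-separated.  Duplicate member IDs within a line are dropped keeping the
    first occurrence; duplicate set names across lines are an error.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    names: set[str] = set()
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path.name}:{lineno}: malformed GMT line "
                    f"(expected >=3 tab-separated fields, got {len(fields)})"
                )
            name, desc = fields[0], fields[1]
            if name in names:
                raise ValueError(f"{path.name}:{lineno}: duplicate set name {name!r}")
            names.add(name)
            members = list(dict.fromkeys(g for g in fields[2:] if g != ""))
            if not members:
                raise ValueError(f"{path.name}:{lineno}: set {name!r} has no members")
            sets.append(GeneSet(name=name, description=desc, members=members))
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    """Write sets in the standard GMT dialect (tab-separated, newline-terminated)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *s.members]) + "\n")


def build_index(
    sets: Sequence[GeneSet],
    universe: Sequence[str],
    min_size: int = DEFAULT_MIN_SIZE,
    metadata: Mapping[str, str] | None = None,
) -> CollectionIndex:
    """Resolve a collection against ``universe`` (the expression matrix's gene IDs).

    Members absent from the universe are dropped; sets with fewer than
    ``min_size`` resolved members are excluded.  Retained/original member counts
    are kept per set (shown as e.g. ``23/24`` in summaries).
    """
    if len(universe) == 0:
        raise ValueError("empty gene universe")
    pos = {g: i for i, g in enumerate(universe)}
    if len(pos) != len(universe):
        raise ValueError("duplicate gene IDs in universe")
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    indexed: list[IndexedSet] = []
    for s in sets:
        idx = [pos[g] for g in s.members if g in pos]
        if len(idx) >= min_size:
            indexed.append(IndexedSet(gene_set=s, index=idx, n_original=len(s.members)))
    meta = dict(metadata or {})
    return CollectionIndex(
        sets=indexed,
        universe=list(universe),
        name=meta.get("name", "custom"),
        label=meta.get("label", "custom"),
        version=meta.get("version", ""),
        date=meta.get("date", ""),
        species=meta.get("species", ""),
        min_size=min_size,
    )


def get_set_by_name(ci: CollectionIndex, name: str) -> GeneSet:
    """Exact, case-sensitive lookup of a set in an indexed collection."""
    try:
        return ci._by_name[name].gene_set
    except KeyError:
        raise KeyError(
            f"gene set {name!r} not found in collection {ci.label!r}"
        ) from None


def summarize_collection(ci: CollectionIndex) -> str:
    """One-line collection summary: name, label, set count, version and date."""
    return (
        f"{ci.name} ({ci.label}): {len(ci)} gene sets - "
        f"Version: {ci.version}, Update date: {ci.date}"
    )


_SUMMARY_RE = re.compile(r"^(?P<name>.*) \((?P<label>[^)]*)\): (?P<n>\d+) gene sets - ")


def parse_summary(line: str) -> dict[str, str]:
    """Inverse of :func:`summarize_collection` (used by report assembly)."""
    m = _SUMMARY_RE.match(line)
    if m is None:
        raise ValueError(f"unparseable collection summary: {line!r}")
    return m.groupdict()


def read_symbols_map(path: str | Path) -> dict[str, str]:
    """Read a two-column feature-ID → display-symbol TSV with header line."""
    path = Path(path)
    out: dict[str, str] = {}
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline()
        if "\t" not in header:
            raise ValueError(f"{path.name}: expected a tab-separated two-column header")
        for raw in fh:
            line = raw.rstrip("\n")
            if not line:
                continue
            feat, sym = line.split("\t")[:2]
            out[feat] = sym
    return out
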