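"""Reading and writing gene-set collections in the tab-delimited GMT format.

A GMT line is ``name<TAB>description<TAB>gene1<TAB>gene2...``. Collections map
unique set names to nonempty member sets; member order is not significant, so
files are written with members sorted for reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, Mapping


class DuplicateSetNameError(ValueError):
    """Raised when a collection would contain two sets with the same name."""


@dataclass
class GeneSetCollection:
    """Named gene sets with optional free-text descriptions."""

    sets: Dict[str, FrozenSet[str]] = field(default_factory=dict)
    descriptions: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sets = {name: frozenset(members) for name, members in self.sets.items()}
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def add(self, name: str, members: Iterable[str], description: str = "") -> None:
        if name in self.sets:
            raise DuplicateSetNameError(f"duplicate gene set name: {name!r}")
        members = frozenset(members)
        if not members:
            raise ValueError(f"gene set {name!r} is empty")
        self.sets[name] = members
        self.descriptions[name] = description

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __getitem__(self, name: str) -> FrozenSet[str]:
        return self.sets[name]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return self.sets == other.sets

    def restrict(self, universe: Iterable[str]) -> "GeneSetCollection":
        """Intersect every set with ``universe``, dropping sets that vanish."""
        uni = frozenset(universe)
        out = GeneSetCollection()
        for name, members in self.sets.items():
            kept = members & uni
            if kept:
                out.add(name, kept, self.descriptions.get(name, ""))
        return out

    @classmethod
    def from_mapping(
        cls,
        mapping: Mapping[str, Iterable[str]],
        descriptions: Mapping[str, str] | None = None,
    ) -> "GeneSetCollection":
        out = cls()
        for name, members in mapping.items():
            out.add(name, members, (descriptions or {}).get(name, ""))
        return out


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file into a :class:`GeneSetCollection`.

    Blank lines are skipped; a duplicate set name raises
    :class:`DuplicateSetNameError`.
    """
    collection = GeneSetCollection()
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line (needs >= 3 fields): {line!r}")
            name, description = fields[0], fields[1]
            members = [g for g in fields[2:] if g]
            collection.add(name, members, description)
    return collection


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Write a collection as GMT; members are sorted so output is canonical."""
    with open(path, "w") as handle:
        for name in collection.sets:
            desc = collection.descriptions.get(name, "")
            members = "\t".join(sorted(collection.sets[name]))
            handle.write(f"{name}\t{desc}\t{members}\n")
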