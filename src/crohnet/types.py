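"""Domain containers shared across the pipeline.

Interaction networks are plain :class:`networkx.Graph` objects over opaque
string identifiers (Entrez IDs in real use); the lightweight dataclasses here
carry everything else: gene sets, scored rankings, functional annotation maps
and differential-expression tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence


class ValidationError(ValueError):
    """Raised when an input violates a domain invariant."""


@dataclass(frozen=True)
class GeneSet:
    """An unordered set of gene identifiers with a human-readable label."""

    label: str
    members: frozenset[str]

    def __init__(self, label: str, members: Iterable[str]):
        object.__setattr__(self, "label", label)
        object.__setattr__(self, "members", frozenset(members))

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members

    def __iter__(self):
        return iter(sorted(self.members))


@dataclass(frozen=True)
class RankedList:
    """Scored gene ranking with p-values, ordered by increasing p.

    Ties in p are broken lexicographically by identifier so the ordering is
    deterministic. Identifiers must be unique and p-values lie in [0, 1].
    """

    entries: tuple[tuple[str, float, float], ...]  # (identifier, score, p)

    def __init__(self, entries: Iterable[tuple[str, float, float]]):
        rows = [(str(g), float(s), float(p)) for g, s, p in entries]
        ids = [g for g, _, _ in rows]
        if len(ids) != len(set(ids)):
            raise ValidationError("ranked list contains duplicate identifiers")
        for g, _, p in rows:
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"p-value {p} for {g!r} outside [0, 1]")
        rows.sort(key=lambda r: (r[2], r[0]))
        object.__setattr__(self, "entries", tuple(rows))

    def __len__(self) -> int:
        return len(self.entries)

    def identifiers(self) -> list[str]:
        return [g for g, _, _ in self.entries]

    def below_p(self, threshold: float) -> set[str]:
        """Identifiers with p strictly below ``threshold``."""
        return {g for g, _, p in self.entries if p < threshold}


@dataclass(frozen=True)
class AnnotationMap:
    """Mapping from functional class name to the set of annotated genes.

    A gene may belong to several classes; class names are unique.
    """

    classes: Mapping[str, frozenset[str]]

    def __init__(self, classes: Mapping[str, Iterable[str]]):
        object.__setattr__(
            self, "classes", {str(k): frozenset(v) for k, v in classes.items()}
        )

    def __len__(self) -> int:
        return len(self.classes)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.classes[name]

    def items(self):
        return self.classes.items()

    def genes(self) -> set[str]:
        """Union of all annotated genes."""
        out: set[str] = set()
        for members in self.classes.values():
            out |= members
        return out


@dataclass(frozen=True)
class DETable:
    """Differential-expression table: identifier -> adjusted p-value."""

    rows: Mapping[str, float]

    def __init__(self, rows: Mapping[str, float]):
        clean = {}
        for g, p in rows.items():
            p = float(p)
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"adjusted p-value {p} for {g!r} outside [0, 1]")
            clean[str(g)] = p
        object.__setattr__(self, "rows", clean)

    def __len__(self) -> int:
        return len(self.rows)

    def significant(self, alpha: float = 0.05) -> set[str]:
        """Genes called differentially expressed at adjusted p < alpha."""
        return {g for g, p in self.rows.items() if p < alpha}


@dataclass
class LoadSummary:
    """Record counts from reading an edge list; conserved against input lines."""

    kept: int = 0
    dropped_self_loops: int = 0
    dropped_duplicates: int = 0
    dropped_malformed: int = 0

    @property
    def total(self) -> int:
        return (
            self.kept
            + self.dropped_self_loops
            + self.dropped_duplicates
            + self.dropped_malformed
        )
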