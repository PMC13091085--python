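"""Taxonomic lineage parsing, formatting and rank truncation.

Lineages run from phylum (outermost) to species. Two input dialects are
supported: Greengenes/QIIME-style rank-prefixed strings
(``p__Bacillota; c__Bacilli; ...``) and plain semicolon-separated names in
rank order. Taxon identity at a rank is always the full lineage truncated
to that rank, never the bare name, so that identically named genera in
different families never collide during aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Optional

__all__ = [
    "Rank",
    "RANKS",
    "LineageDialect",
    "LineageParseError",
    "TaxonLineage",
    "Taxon",
    "parse_lineage",
    "parse_taxon",
]


class Rank(str, Enum):
    """Taxonomic ranks handled by the pipeline, outermost first."""

    PHYLUM = "phylum"
    CLASS = "class"
    ORDER = "order"
    FAMILY = "family"
    GENUS = "genus"
    SPECIES = "species"

    @property
    def depth(self) -> int:
        return RANKS.index(self)


RANKS: tuple[Rank, ...] = (
    Rank.PHYLUM,
    Rank.CLASS,
    Rank.ORDER,
    Rank.FAMILY,
    Rank.GENUS,
    Rank.SPECIES,
)

_PREFIXES: dict[str, Rank] = {
    "p": Rank.PHYLUM,
    "c": Rank.CLASS,
    "o": Rank.ORDER,
    "f": Rank.FAMILY,
    "g": Rank.GENUS,
    "s": Rank.SPECIES,
}
_RANK_TO_PREFIX = {rank: pfx for pfx, rank in _PREFIXES.items()}


class LineageDialect(str, Enum):
    RANK_PREFIXED = "rank-prefixed"
    SEMICOLON_PLAIN = "semicolon-plain"


class LineageParseError(ValueError):
    """Raised when a lineage string cannot be interpreted."""


@dataclass(frozen=True)
class TaxonLineage:
    """A lineage from phylum down to an arbitrary deepest rank.

    Only a contiguous prefix of ranks may be populated: the phylum is
    mandatory and no rank may be present when a shallower one is absent.
    """

    phylum: str
    class_: Optional[str] = None
    order: Optional[str] = None
    family: Optional[str] = None
    genus: Optional[str] = None
    species: Optional[str] = None
    dialect: LineageDialect = field(
        default=LineageDialect.RANK_PREFIXED, compare=False
    )

    def __post_init__(self) -> None:
        names = [self.phylum, self.class_, self.order, self.family,
                 self.genus, self.species]
        if not self.phylum or not self.phylum.strip():
            raise LineageParseError("lineage must carry at least a phylum name")
        seen_gap = False
        for rank, name in zip(RANKS, names):
            if name is None:
                seen_gap = True
                continue
            if not name.strip():
                raise LineageParseError(f"empty name at rank {rank.value}")
            if seen_gap:
                raise LineageParseError(
                    f"rank {rank.value} present below an absent rank"
                )

    def name_at(self, rank: Rank) -> Optional[str]:
        return (self.phylum, self.class_, self.order, self.family,
                self.genus, self.species)[rank.depth]

    @property
    def deepest_rank(self) -> Rank:
        last = Rank.PHYLUM
        for rank in RANKS:
            if self.name_at(rank) is not None:
                last = rank
        return last

    def truncate(self, rank: Rank) -> "TaxonLineage":
        """Lineage cut down to ``rank`` (no-op if already shallower)."""
        names = [self.name_at(r) if r.depth <= rank.depth else None
                 for r in RANKS]
        return TaxonLineage(*names, dialect=self.dialect)

    def iter_names(self) -> Iterator[tuple[Rank, str]]:
        for rank in RANKS:
            name = self.name_at(rank)
            if name is not None:
                yield rank, name

    def format(self, dialect: Optional[LineageDialect] = None) -> str:
        """Canonical string form, ``'; '``-joined in rank order."""
        dialect = dialect or self.dialect
        if dialect is LineageDialect.RANK_PREFIXED:
            return "; ".join(
                f"{_RANK_TO_PREFIX[rank]}__{name}"
                for rank, name in self.iter_names()
            )
        return "; ".join(name for _, name in self.iter_names())

    def __str__(self) -> str:
        return self.format()


def parse_lineage(
    lineage_string: str,
    dialect: LineageDialect | str = LineageDialect.RANK_PREFIXED,
) -> TaxonLineage:
    """Parse a lineage string into a :class:`TaxonLineage`.

    Rank-prefixed tokens must appear in canonical order (phylum first);
    an out-of-order or unknown prefix is an error naming the token.
    Empty rank tokens (``g__``) are treated as absent.
    """
    dialect = LineageDialect(dialect)
    if not lineage_string or not lineage_string.strip():
        raise LineageParseError("empty lineage string")
    tokens = [t.strip() for t in lineage_string.split(";")]
    tokens = [t for t in tokens if t]

    names: dict[Rank, str] = {}
    if dialect is LineageDialect.RANK_PREFIXED:
        last_depth = -1
        for token in tokens:
            if len(token) < 3 or token[1:3] != "__" or token[0] not in _PREFIXES:
                # tolerate domain/kingdom prefixes above phylum
                if token[:3] in ("d__", "k__"):
                    continue
                raise LineageParseError(
                    f"malformed rank token {token!r}: expected "
                    "'<p|c|o|f|g|s>__Name'"
                )
            rank = _PREFIXES[token[0]]
            if rank.depth <= last_depth:
                raise LineageParseError(
                    f"rank token {token!r} out of canonical order"
                )
            last_depth = rank.depth
            name = token[3:].strip()
            if name:
                names[rank] = name
    else:
        for rank, name in zip(RANKS, tokens):
            names[rank] = name

    if Rank.PHYLUM not in names:
        raise LineageParseError(
            f"no phylum in lineage {lineage_string!r}"
        )
    # drop anything below the first gap so the prefix is contiguous
    kept: dict[Rank, str] = {}
    for rank in RANKS:
        if rank not in names:
            break
        kept[rank] = names[rank]
    return TaxonLineage(
        phylum=kept.get(Rank.PHYLUM),  # type: ignore[arg-type]
        class_=kept.get(Rank.CLASS),
        order=kept.get(Rank.ORDER),
        family=kept.get(Rank.FAMILY),
        genus=kept.get(Rank.GENUS),
        species=kept.get(Rank.SPECIES),
        dialect=dialect,
    )


@dataclass(frozen=True)
class Taxon:
    """A row label in an abundance table.

    Either a proper lineage, or a bare label (aggregate rows such as
    ``Others``) that stays outside all lineage logic.
    """

    label: str
    lineage: Optional[TaxonLineage] = None

    @property
    def key(self) -> str:
        """Canonical identity string used for joins and sorting."""
        return self.lineage.format(LineageDialect.RANK_PREFIXED) \
            if self.lineage else self.label

    def at_rank(self, rank: Rank) -> "Taxon":
        if self.lineage is None:
            return self
        trunc = self.lineage.truncate(rank)
        return Taxon(label=trunc.name_at(trunc.deepest_rank), lineage=trunc)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Taxon) and self.key == other.key

    def __hash__(self) -> int:
        return hash(self.key)

    def __str__(self) -> str:
        return self.key


def parse_taxon(
    text: str,
    dialect: LineageDialect | str = LineageDialect.RANK_PREFIXED,
) -> Taxon:
    """Parse a table row label: a lineage if possible, else a bare label.

    Labels with no rank separator and no prefix (``Others``) become
    lineage-free taxa.
    """
    stripped = text.strip()
    if not stripped:
        raise LineageParseError("empty taxon label")
    dialect = LineageDialect(dialect)
    looks_like_lineage = (
        ";" in stripped
        or (dialect is LineageDialect.RANK_PREFIXED and "__" in stripped)
    )
    if not looks_like_lineage:
        return Taxon(label=stripped)
    lineage = parse_lineage(stripped, dialect)
    return Taxon(
        label=lineage.name_at(lineage.deepest_rank), lineage=lineage
    )
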