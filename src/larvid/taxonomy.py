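"""Taxonomic lineages and rank arithmetic.

A lineage is the ordered chain order > family > genus > species. Ranks are
strictly nested: two lineages sharing a species share the genus, family and
order as well. Most of the pipeline's reconciliation logic reduces to two
primitives defined here: the lowest common ancestor (LCA) of a set of
lineages, and the parent of a rank.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, NamedTuple, Optional, Sequence

import pandas as pd

#: Ranks from shallowest to deepest.
RANKS: tuple[str, ...] = ("order", "family", "genus", "species")

_RANK_DEPTH = {r: i for i, r in enumerate(RANKS)}


class Lineage(NamedTuple):
    """One taxon's full rank chain."""

    order: str
    family: str
    genus: str
    species: str

    def name_at(self, rank: str) -> str:
        """Taxon name at ``rank`` (one of :data:`RANKS`)."""
        return getattr(self, rank)

    def truncate(self, rank: str) -> tuple[str, ...]:
        """Names from order down to ``rank`` inclusive."""
        return tuple(self[: _RANK_DEPTH[rank] + 1])


def rank_depth(rank: str) -> int:
    """0 for order … 3 for species; raises on an unknown rank."""
    try:
        return _RANK_DEPTH[rank]
    except KeyError:
        raise ValueError(f"unknown rank: {rank!r}") from None


def parent_rank(rank: str) -> Optional[str]:
    """The next-shallower rank; ``None`` above order."""
    d = rank_depth(rank)
    return None if d == 0 else RANKS[d - 1]


def child_rank(rank: str) -> Optional[str]:
    """The next-deeper rank; ``None`` below species."""
    d = rank_depth(rank)
    return None if d == len(RANKS) - 1 else RANKS[d + 1]


@dataclass(frozen=True)
class Taxonomy:
    """An immutable set of lineages with nesting guarantees.

    Parameters
    ----------
    entries:
        Lineages; species names must be unique and ranks strictly nested
        (a genus cannot appear under two families, etc.).
    """

    entries: tuple[Lineage, ...]

    def __post_init__(self) -> None:
        seen_species: dict[str, Lineage] = {}
        parent_of: dict[tuple[str, str], tuple[str, ...]] = {}
        for lin in self.entries:
            if lin.species in seen_species and seen_species[lin.species] != lin:
                raise ValueError(f"species {lin.species!r} has conflicting lineages")
            seen_species[lin.species] = lin
            for rank in ("family", "genus", "species"):
                key = (rank, lin.name_at(rank))
                parents = lin.truncate(rank)[:-1]
                if parent_of.setdefault(key, parents) != parents:
                    raise ValueError(
                        f"{rank} {lin.name_at(rank)!r} appears under two parents"
                    )

    @classmethod
    def from_lineages(cls, lineages: Iterable[Sequence[str]]) -> "Taxonomy":
        return cls(tuple(Lineage(*lin) for lin in lineages))

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[Lineage]:
        return iter(self.entries)

    def lineage_of(self, species: str) -> Lineage:
        for lin in self.entries:
            if lin.species == species:
                return lin
        raise KeyError(f"species {species!r} not in taxonomy")

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(lin.species for lin in self.entries)

    def congeners(self, species: str) -> tuple[str, ...]:
        """Other species of the same genus, in taxonomy order."""
        genus = self.lineage_of(species).genus
        return tuple(
            lin.species
            for lin in self.entries
            if lin.genus == genus and lin.species != species
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=list(RANKS))

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "Taxonomy":
        df = pd.read_csv(path, sep="\t", dtype=str)
        missing = set(RANKS) - set(df.columns)
        if missing:
            raise ValueError(f"taxonomy file lacks columns: {sorted(missing)}")
        return cls.from_lineages(df[list(RANKS)].itertuples(index=False, name=None))


def lca(lineages: Sequence[Lineage]) -> tuple[Optional[str], Optional[str]]:
    """Deepest (rank, taxon) shared by every lineage.

    Returns ``(None, None)`` when not even the order is shared.
    """
    if not lineages:
        raise ValueError("lca of an empty set is undefined")
    shared_rank = None
    shared_name = None
    for rank in RANKS:
        names = {lin.name_at(rank) for lin in lineages}
        if len(names) != 1:
            break
        shared_rank, shared_name = rank, names.pop()
    return shared_rank, shared_name


def cap_rank(rank: Optional[str], ceiling: str) -> Optional[str]:
    """``rank`` limited to be no deeper than ``ceiling``."""
    if rank is None:
        return None
    return ceiling if rank_depth(rank) > rank_depth(ceiling) else rank
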