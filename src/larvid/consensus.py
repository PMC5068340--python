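"""Reconciling two per-database verdicts into one hierarchical assignment.

Each query ends in one of six categories:

* **concordance** — both databases give the same taxon at the same rank;
* **discrepancy** — both give unambiguous but different taxa; recorded at
  the deeper of the two ranks, resolved to the taxa's lowest common
  ancestor;
* **ambiguity** — at least one database's best-hit tie spans several
  species; recorded at the rank where identification was attempted (the tie
  LCA's child), resolved to the tie LCA.  An ambiguity on either side makes
  the query ambiguous regardless of the other side;
* **genbank_only / bold_only** — only one database yields a verdict, or one
  reaches strictly deeper than the other along the same lineage (a species
  identification is not demoted because the other database stopped at the
  genus);
* **unassigned** — neither does.

The *final* rank follows the hierarchical fallback rule: concordant and
single-database cases keep their rank; discrepant and ambiguous cases are
promoted one rank up (species-level conflicts land at genus, and so on; an
order-level conflict stays at order, flagged).  The per-rank tally of
categories and finals is the pipeline's headline summary matrix.

:class:`DualDatabaseClassifier` packages two :class:`~larvid.matchdb.DatabaseMatcher`
estimators plus this reconciliation as one fit/predict estimator.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional, Sequence

import pandas as pd
from sklearn.base import BaseEstimator

from .matchdb import DatabaseMatcher, DbAssignment
from .seqio_qc import QueryRecord, ReferenceRecord
from .taxonomy import RANKS, Lineage, child_rank, lca, parent_rank, rank_depth

CATEGORIES = ("genbank_only", "bold_only", "concordance", "discrepancy", "ambiguity")
_SINGLE_DB = {"genbank_only", "bold_only"}


@dataclass(frozen=True)
class ConsensusAssignment:
    """Reconciled verdict for one query."""

    query_id: str
    category: str  # one of CATEGORIES or "unassigned"
    category_rank: Optional[str]
    final_rank: Optional[str]
    final_taxon: Optional[str]
    #: representative full lineage (for grouping summaries); None if unassigned
    lineage: Optional[Lineage] = None

    @property
    def categorised(self) -> bool:
        return self.category != "unassigned"


def finalize(category: str, category_rank: Optional[str]) -> Optional[str]:
    """Final rank implied by a category recorded at ``category_rank``.

    Concordant and single-database assignments keep their rank; discrepancy
    and ambiguity are promoted to the parent rank (order stays order).
    """
    if category == "unassigned":
        return None
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    if category_rank is None:
        return None
    rank_depth(category_rank)  # validates
    if category in ("discrepancy", "ambiguity"):
        return parent_rank(category_rank) or "order"
    return category_rank


def _single_db_category(a: DbAssignment) -> str:
    return "genbank_only" if a.database == "genbank" else "bold_only"


def reconcile(
    a1: DbAssignment, a2: DbAssignment, taxonomy=None
) -> ConsensusAssignment:
    """Reconcile the GenBank-like (``a1``) and BOLD-like (``a2``) verdicts.

    The lineages carried by the assignments' top tie sets are sufficient to
    take lowest common ancestors, so ``taxonomy`` is accepted only for
    interface symmetry.
    """
    if a1.query_id != a2.query_id:
        raise ValueError(f"mismatched query ids: {a1.query_id!r} vs {a2.query_id!r}")
    qid = a1.query_id
    del taxonomy

    if not a1.assigned and not a2.assigned:
        return ConsensusAssignment(qid, "unassigned", None, None, None)

    # an ambiguity on either side is unresolvable regardless of the other
    ambiguous = [a for a in (a1, a2) if a.status == "ambiguous"]
    if ambiguous:
        tie_lineages: list[Lineage] = []
        for a in ambiguous:
            tie_lineages.extend(a.tie_lineages)
        shared_rank, shared_name = lca(tie_lineages)
        category_rank = child_rank(shared_rank) if shared_rank else None
        return ConsensusAssignment(
            qid, "ambiguity", category_rank, shared_rank, shared_name,
            tie_lineages[0],
        )

    if a1.assigned != a2.assigned:  # exactly one database speaks
        a = a1 if a1.assigned else a2
        return ConsensusAssignment(
            qid, _single_db_category(a), a.rank, a.rank, a.taxon, a.lineage
        )

    # both unambiguous
    if a1.rank == a2.rank and a1.taxon == a2.taxon:
        return ConsensusAssignment(
            qid, "concordance", a1.rank, a1.rank, a1.taxon, a1.lineage
        )
    shallow, deep = sorted((a1, a2), key=lambda a: rank_depth(a.rank))
    if rank_depth(deep.rank) > rank_depth(shallow.rank) and (
        deep.lineage.name_at(shallow.rank) == shallow.taxon
    ):
        # nested (species vs its own genus): only the deeper database
        # identified the larva at that rank, so it stands alone
        return ConsensusAssignment(
            qid, _single_db_category(deep), deep.rank, deep.rank, deep.taxon,
            deep.lineage,
        )
    shared_rank, shared_name = lca(
        [a1.lineage._replace(**_mask_below(a1)), a2.lineage._replace(**_mask_below(a2))]
    )
    return ConsensusAssignment(
        qid, "discrepancy", deep.rank, shared_rank, shared_name, a1.lineage
    )


def _mask_below(a: DbAssignment) -> dict[str, str]:
    """Blank ranks deeper than the assignment's rank so the LCA of two
    assignments compares only what was actually asserted."""
    d = rank_depth(a.rank)
    return {r: f"<{a.query_id}:{a.database}>" for r in RANKS[d + 1 :]}


@dataclass
class AssignmentTally:
    """Category × rank count matrix plus the derived final-assignment vector."""

    matrix: pd.DataFrame  # index RANKS, columns CATEGORIES
    final_counts: pd.Series  # index RANKS
    n: int  # categorised queries
    unassigned: int = 0

    def to_frame(self) -> pd.DataFrame:
        out = self.matrix.copy()
        out["final_assignment"] = self.final_counts
        return out

    def percent_final_at_or_deeper(self, rank: str, total: Optional[int] = None) -> float:
        """Percent of queries whose final rank is ``rank`` or deeper,
        half-up rounded to 1 decimal (e.g. species 51.1%, genus 86.5%)."""
        total = self.n if total is None else total
        count = sum(
            self.final_counts[r] for r in RANKS if rank_depth(r) >= rank_depth(rank)
        )
        return percent(count, total)


def percent(count: int, total: int, decimals: int = 1) -> float:
    """Half-up percentage rounding (105/237 -> 44.3, not banker's)."""
    q = Decimal(1).scaleb(-decimals)
    return float(
        (Decimal(100) * Decimal(int(count)) / Decimal(int(total))).quantize(
            q, rounding=ROUND_HALF_UP
        )
    )


def final_counts_from_matrix(matrix: pd.DataFrame) -> pd.Series:
    """Apply the hierarchical fallback rule to a category × rank matrix."""
    finals = pd.Series(0, index=list(RANKS), dtype=int)
    for rank in RANKS:
        for cat in CATEGORIES:
            count = int(matrix.loc[rank, cat])
            if count:
                finals[finalize(cat, rank)] += count
    return finals


def tally(assignments: Sequence[ConsensusAssignment], strict: bool = True) -> AssignmentTally:
    """Count categories per rank and derive the final-assignment vector.

    The vector is recomputed independently from the matrix via
    :func:`finalize` and, when ``strict``, checked against the per-query
    final ranks (they can differ only for cross-family conflicts whose LCA
    jumps more than one rank).
    """
    matrix = pd.DataFrame(0, index=list(RANKS), columns=list(CATEGORIES), dtype=int)
    per_query = pd.Series(0, index=list(RANKS), dtype=int)
    unassigned = 0
    for a in assignments:
        # a categorised query with no shared rank at all (tie spanning
        # orders) cannot be placed in the matrix; it counts as unassigned
        if not a.categorised or a.category_rank is None:
            unassigned += 1
            continue
        matrix.loc[a.category_rank, a.category] += 1
        if a.final_rank is not None:
            per_query[a.final_rank] += 1
    finals = final_counts_from_matrix(matrix)
    if strict and not finals.equals(per_query):
        raise ValueError(
            "per-query final ranks disagree with the matrix-derived vector:\n"
            f"{pd.DataFrame({'from_matrix': finals, 'per_query': per_query})}"
        )
    return AssignmentTally(matrix, finals, int(matrix.values.sum()), unassigned)


def assignments_from_matrix(matrix: pd.DataFrame) -> list[ConsensusAssignment]:
    """Expand a category × rank count matrix into anonymous per-query
    records (the inverse of :func:`tally`, up to query identity)."""
    out = []
    i = 0
    for rank in RANKS:
        for cat in CATEGORIES:
            for _ in range(int(matrix.loc[rank, cat])):
                i += 1
                out.append(
                    ConsensusAssignment(f"q{i:04d}", cat, rank, finalize(cat, rank), None)
                )
    return out


def resolution_fractions(
    assignments: Sequence[ConsensusAssignment],
    groups: Mapping[str, str],
) -> pd.DataFrame:
    """Fraction of queries per group reaching each final rank.

    ``groups`` maps every query id to its group label (station, order, …).
    Rows are groups sorted by label; columns are final ranks plus
    ``unassigned``; each row sums to 1.
    """
    missing = [a.query_id for a in assignments if a.query_id not in groups]
    if missing:
        raise ValueError(f"queries missing group metadata: {missing}")
    cols = list(RANKS) + ["unassigned"]
    counts: dict[str, pd.Series] = {}
    for a in assignments:
        g = groups[a.query_id]
        row = counts.setdefault(g, pd.Series(0, index=cols, dtype=int))
        row[a.final_rank if a.final_rank else "unassigned"] += 1
    table = pd.DataFrame(
        {g: counts[g] / counts[g].sum() for g in sorted(counts)}
    ).T
    table.index.name = "group"
    return table[cols]


def consensus_frame(assignments: Sequence[ConsensusAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "query_id": a.query_id,
                "category": a.category,
                "category_rank": a.category_rank or "none",
                "final_rank": a.final_rank or "none",
                "final_taxon": a.final_taxon or "",
            }
            for a in assignments
        ]
    )


class DualDatabaseClassifier(BaseEstimator):
    """Two reference databases, one consensus taxonomic classifier.

    ``fit`` takes the GenBank-like and BOLD-like reference record sets;
    ``predict`` returns one :class:`ConsensusAssignment` per query.
    """

    def __init__(
        self,
        min_identity: float = 97.0,
        min_coverage: float = 80.0,
        rank_ladder=None,
        prefilter: bool = True,
    ):
        self.min_identity = min_identity
        self.min_coverage = min_coverage
        self.rank_ladder = rank_ladder
        self.prefilter = prefilter

    def fit(self, X: Sequence[ReferenceRecord], X2: Sequence[ReferenceRecord]):
        common = dict(
            min_identity=self.min_identity,
            min_coverage=self.min_coverage,
            rank_ladder=self.rank_ladder,
            prefilter=self.prefilter,
        )
        self.matcher1_ = DatabaseMatcher(label="genbank", **common).fit(X)
        self.matcher2_ = DatabaseMatcher(label="bold", **common).fit(X2)
        return self

    def predict(self, X: Sequence[QueryRecord]) -> list[ConsensusAssignment]:
        if not hasattr(self, "matcher1_"):
            raise ValueError("DualDatabaseClassifier is not fitted; call fit() first")
        per_db = zip(self.matcher1_.predict(X), self.matcher2_.predict(X))
        return [reconcile(a1, a2) for a1, a2 in per_db]

    def predict_per_db(
        self, X: Sequence[QueryRecord]
    ) -> tuple[list[DbAssignment], list[DbAssignment]]:
        return self.matcher1_.predict(X), self.matcher2_.predict(X)
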