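"""Query-against-reference matching with identity/coverage cutoffs.

Each query is aligned semi-globally (end gaps free on both sequences, affine
gap costs) against every reference.  Hits must clear strict ``>`` identity
and coverage cutoffs — the barcoding defaults are >97% identity and >80%
coverage.  All hits tied for the best identity (after rounding to 2
decimals) form the *top tie set*: one species means a species-level match,
several species mean an ambiguity resolved only to their lowest common
ancestor.  When nothing clears the species cutoffs, a configurable rank
ladder retries at progressively laxer thresholds and yields a rank-fallback
assignment (genus, family, order).

Exhaustive affine alignment of every query/reference pair is needless at
database scale, so a fast edit-distance prefilter (edlib) discards reference
sequences that cannot come near the identity cutoff; the exact aligner runs
only on surviving candidates.  Set ``prefilter=False`` to force exact
alignment of every pair.

:class:`DatabaseMatcher` wraps this as a scikit-learn style estimator:
``fit`` on reference records, ``predict`` taxonomic assignments for queries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import edlib
from Bio import Align
from sklearn.base import BaseEstimator

from .seqio_qc import QueryRecord, ReferenceRecord
from .taxonomy import Lineage, cap_rank, lca, rank_depth

#: rank -> (min identity %, min coverage %); species row is the headline
#: barcoding cutoff, the sub-species rows are this package's explicit,
#: configurable stand-in for shallower single-database assignments.
DEFAULT_RANK_LADDER: dict[str, tuple[float, float]] = {
    "species": (97.0, 80.0),
    "genus": (90.0, 80.0),
    "family": (85.0, 80.0),
    "order": (80.0, 80.0),
}

DEFAULT_SCORES = {"match": 1.0, "mismatch": -1.0, "gap_open": -2.0, "gap_extend": -0.5}


@dataclass(frozen=True)
class AlignmentResult:
    """Identity/coverage summary of one pairwise semi-global alignment."""

    query_id: str
    reference_id: str
    identity: float  # percent, over columns between first and last aligned pair
    coverage: float  # percent of query inside that span
    matches: int
    aligned_columns: int
    score: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 100.0 and 0.0 <= self.coverage <= 100.0):
            raise ValueError("identity and coverage must be percentages in [0, 100]")
        if self.matches > self.aligned_columns:
            raise ValueError("matches cannot exceed aligned columns")


@dataclass(frozen=True)
class DbAssignment:
    """One database's verdict for one query."""

    query_id: str
    database: str
    status: str  # species_match | ambiguous | rank_fallback | no_match
    rank: Optional[str]  # species/genus/family/order, or None for no_match
    taxon: Optional[str]
    hits: tuple[AlignmentResult, ...] = ()
    tie_lineages: tuple[Lineage, ...] = ()

    @property
    def assigned(self) -> bool:
        return self.status != "no_match" and self.rank is not None

    @property
    def best_identity(self) -> Optional[float]:
        return self.hits[0].identity if self.hits else None

    @property
    def best_coverage(self) -> Optional[float]:
        return self.hits[0].coverage if self.hits else None

    @property
    def tie_size(self) -> int:
        return len(self.hits)

    @property
    def lineage(self) -> Optional[Lineage]:
        """Representative full lineage of the top tie set (first hit)."""
        return self.tie_lineages[0] if self.tie_lineages else None


def _make_aligner(match: float, mismatch: float, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    # free end gaps on both sequences => semi-global
    aligner.end_insertion_score = 0.0
    aligner.end_deletion_score = 0.0
    return aligner


def align(
    query: str,
    reference: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -2.0,
    gap_extend: float = -0.5,
    query_id: str = "",
    reference_id: str = "",
) -> AlignmentResult:
    """Optimal semi-global alignment of ``query`` against ``reference``.

    Identity is matches over all columns between the first and last aligned
    pair (internal gap columns included); coverage is the percentage of the
    query inside that span.  A gap of length L costs
    ``gap_open + (L - 1) * gap_extend``; end gaps are free.
    """
    if not query or not reference:
        raise ValueError("cannot align an empty sequence")
    aligner = _make_aligner(match, mismatch, gap_open, gap_extend)
    aln = aligner.align(reference.upper(), query.upper())[0]
    blocks = aln.aligned  # [[target blocks], [query blocks]]
    t_blocks, q_blocks = blocks[0], blocks[1]
    if len(t_blocks) == 0:
        return AlignmentResult(query_id, reference_id, 0.0, 0.0, 0, 0, aln.score)
    matches = 0
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        for a, b in zip(reference.upper()[ts:te], query.upper()[qs:qe]):
            if a == b:
                matches += 1
    n_pairs = sum(int(te - ts) for ts, te in t_blocks)
    t_span = int(t_blocks[-1][1] - t_blocks[0][0])
    q_span = int(q_blocks[-1][1] - q_blocks[0][0])
    columns = t_span + q_span - n_pairs
    identity = 100.0 * matches / columns if columns else 0.0
    coverage = 100.0 * q_span / len(query)
    return AlignmentResult(
        query_id, reference_id, identity, coverage, matches, columns, float(aln.score)
    )


def _prefilter_ok(query: str, reference: str, min_identity: float, margin: float) -> bool:
    """Cheap edit-distance screen: can this pair plausibly reach the cutoff?

    Uses infix (free reference end gaps) unit-cost edit distance as an
    identity proxy with a safety margin; exact alignment decides the rest.
    """
    res = edlib.align(query, reference, mode="HW", task="distance")
    est = 100.0 * (1.0 - res["editDistance"] / len(query))
    return est >= min_identity - margin


def align_all(
    query: Union[str, QueryRecord],
    db: Sequence[ReferenceRecord],
    scores: Optional[Mapping[str, float]] = None,
    prefilter: bool = True,
    prefilter_margin: float = 5.0,
    min_identity_floor: float = 80.0,
) -> list[AlignmentResult]:
    """Align a query against every reference surviving the prefilter.

    ``min_identity_floor`` is the laxest identity any downstream consumer
    will apply (the bottom of the rank ladder); the prefilter keeps every
    reference that could clear it.
    """
    qid, qseq = (query.id, query.sequence) if isinstance(query, QueryRecord) else ("", query)
    sc = dict(DEFAULT_SCORES, **(scores or {}))
    out = []
    for ref in db:
        if prefilter and not _prefilter_ok(qseq, ref.sequence, min_identity_floor, prefilter_margin):
            continue
        out.append(
            align(
                qseq,
                ref.sequence,
                match=sc["match"],
                mismatch=sc["mismatch"],
                gap_open=sc["gap_open"],
                gap_extend=sc["gap_extend"],
                query_id=qid,
                reference_id=ref.id,
            )
        )
    return out


def best_hits(
    query: Union[str, QueryRecord],
    db: Sequence[ReferenceRecord],
    min_identity: float = 97.0,
    min_coverage: float = 80.0,
    **align_kwargs,
) -> list[AlignmentResult]:
    """Hits with identity and coverage strictly above the cutoffs, sorted by
    identity descending then reference id ascending."""
    if not db:
        raise ValueError("reference database is empty")
    hits = align_all(query, db, min_identity_floor=min_identity, **align_kwargs)
    return filter_hits(hits, min_identity, min_coverage)


def filter_hits(
    hits: Sequence[AlignmentResult], min_identity: float, min_coverage: float
) -> list[AlignmentResult]:
    kept = [h for h in hits if h.identity > min_identity and h.coverage > min_coverage]
    return sorted(kept, key=lambda h: (-h.identity, h.reference_id))


def top_tie_set(hits: Sequence[AlignmentResult]) -> list[AlignmentResult]:
    """All hits whose identity equals the maximum after rounding to 2 dp."""
    if not hits:
        return []
    best = max(round(h.identity, 2) for h in hits)
    tie = [h for h in hits if round(h.identity, 2) == best]
    return sorted(tie, key=lambda h: (-h.identity, h.reference_id))


def assign_from_db(
    hits: Sequence[AlignmentResult],
    ref_lineages: Mapping[str, Lineage],
    rank_ladder: Optional[Mapping[str, tuple[float, float]]] = None,
    query_id: str = "",
    database: str = "db",
) -> DbAssignment:
    """Turn raw alignment results into one database's taxonomic verdict.

    ``hits`` are *unfiltered* alignments; thresholds are applied here, species
    cutoffs first, then the rank ladder.  A species-level top tie set of one
    species is a ``species_match``; several species are ``ambiguous`` at
    their lowest common ancestor; a ladder hit is a ``rank_fallback`` at the
    ladder rank (or at the tie set's LCA if that is shallower).
    """
    ladder = dict(rank_ladder or DEFAULT_RANK_LADDER)
    for rank in sorted(ladder, key=rank_depth, reverse=True):  # species first
        min_id, min_cov = ladder[rank]
        kept = filter_hits(hits, min_id, min_cov)
        if not kept:
            continue
        tie = top_tie_set(kept)
        try:
            lineages = tuple(ref_lineages[h.reference_id] for h in tie)
        except KeyError as exc:
            raise ValueError(f"reference id {exc.args[0]!r} not in taxonomy") from None
        species = {lin.species for lin in lineages}
        if rank == "species":
            if len(species) == 1:
                return DbAssignment(
                    query_id, database, "species_match", "species",
                    next(iter(species)), tuple(tie), lineages,
                )
            shared_rank, shared_name = lca(lineages)
            return DbAssignment(
                query_id, database, "ambiguous", shared_rank, shared_name,
                tuple(tie), lineages,
            )
        shared_rank, shared_name = lca(lineages)
        if shared_rank is None:
            continue  # nothing shared even at order; try a laxer rung
        capped = cap_rank(shared_rank, rank)
        return DbAssignment(
            query_id, database, "rank_fallback", capped,
            lineages[0].name_at(capped), tuple(tie), lineages,
        )
    return DbAssignment(query_id, database, "no_match", None, None)


class DatabaseMatcher(BaseEstimator):
    """Assign queries to taxa by similarity to a fitted reference database.

    Parameters follow the barcoding defaults: strict >97% identity / >80%
    coverage at species level, with a configurable rank ladder below that.

    Examples
    --------
    >>> matcher = DatabaseMatcher(label="GenBank").fit(reference_records)
    >>> assignments = matcher.predict(query_records)      # doctest: +SKIP
    """

    def __init__(
        self,
        min_identity: float = 97.0,
        min_coverage: float = 80.0,
        rank_ladder: Optional[Mapping[str, tuple[float, float]]] = None,
        match: float = 1.0,
        mismatch: float = -1.0,
        gap_open: float = -2.0,
        gap_extend: float = -0.5,
        prefilter: bool = True,
        prefilter_margin: float = 5.0,
        label: str = "db",
    ):
        self.min_identity = min_identity
        self.min_coverage = min_coverage
        self.rank_ladder = rank_ladder
        self.match = match
        self.mismatch = mismatch
        self.gap_open = gap_open
        self.gap_extend = gap_extend
        self.prefilter = prefilter
        self.prefilter_margin = prefilter_margin
        self.label = label

    def _ladder(self) -> dict[str, tuple[float, float]]:
        ladder = dict(self.rank_ladder or DEFAULT_RANK_LADDER)
        ladder["species"] = (self.min_identity, self.min_coverage)
        return ladder

    def fit(self, X: Sequence[ReferenceRecord], y: Optional[Sequence[Lineage]] = None):
        """Store the reference database.

        ``X`` is either a sequence of :class:`ReferenceRecord`, or raw
        sequences with ``y`` the matching lineages.
        """
        if y is not None:
            X = [
                ReferenceRecord(f"{self.label}-R{i + 1:04d}", seq, lin)
                for i, (seq, lin) in enumerate(zip(X, y))
            ]
        X = list(X)
        if not X:
            raise ValueError("reference database is empty")
        self.references_ = X
        self.ref_lineages_ = {r.id: r.lineage for r in X}
        self.n_references_ = len(X)
        return self

    def predict(self, X: Sequence[Union[str, QueryRecord]]) -> list[DbAssignment]:
        """One :class:`DbAssignment` per query."""
        if not hasattr(self, "references_"):
            raise ValueError("DatabaseMatcher is not fitted; call fit() first")
        ladder = self._ladder()
        floor = min(t[0] for t in ladder.values())
        scores = {
            "match": self.match,
            "mismatch": self.mismatch,
            "gap_open": self.gap_open,
            "gap_extend": self.gap_extend,
        }
        out = []
        for i, q in enumerate(X):
            qid = q.id if isinstance(q, QueryRecord) else f"q{i + 1}"
            hits = align_all(
                q if isinstance(q, QueryRecord) else str(q),
                self.references_,
                scores=scores,
                prefilter=self.prefilter,
                prefilter_margin=self.prefilter_margin,
                min_identity_floor=floor,
            )
            out.append(
                assign_from_db(
                    hits, self.ref_lineages_, ladder, query_id=qid, database=self.label
                )
            )
        return out


def assignments_frame(assignments: Sequence[DbAssignment]):
    """Flat table of per-database assignments (one row per query × db)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "query_id": a.query_id,
                "db": a.database,
                "status": a.status,
                "rank": a.rank or "none",
                "taxon": a.taxon or "",
                "best_identity": round(a.best_identity, 2) if a.hits else "",
                "best_coverage": round(a.best_coverage, 2) if a.hits else "",
                "tie_size": a.tie_size,
            }
            for a in assignments
        ]
    )
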