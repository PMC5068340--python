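import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from larvid.matchdb import (
    DatabaseMatcher,
    align,
    assign_from_db,
    best_hits,
    top_tie_set,
)
from larvid.seqio_qc import QueryRecord, ReferenceRecord
from larvid.taxonomy import Lineage

NEG = float("-inf")


def gotoh_semiglobal_score(
    q: str, r: str, match=1.0, mismatch=-1.0, open_=-2.0, ext=-0.5
) -> float:
    """Independent affine-gap semi-global DP (free end gaps).

    A gap of length L costs open + (L-1)*ext; an end gap is free only in
    the first or last row/column of the DP matrix (skipping prefixes of
    *both* sequences at the same end charges one of the runs as internal),
    matching the aligner's convention.  Score-only oracle for short strings.
    """
    n, m = len(r), len(q)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    D = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in query (r consumed)
    I = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in reference
    M[0][0] = 0.0
    for i in range(1, n + 1):
        D[i][0] = 0.0  # free leading end gap
    for j in range(1, m + 1):
        I[0][j] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if r[i - 1] == q[j - 1] else mismatch
            M[i][j] = s + max(M[i - 1][j - 1], D[i - 1][j - 1], I[i - 1][j - 1])
            D[i][j] = max(M[i - 1][j] + open_, D[i - 1][j] + ext, I[i - 1][j] + open_)
            I[i][j] = max(M[i][j - 1] + open_, I[i][j - 1] + ext, D[i][j - 1] + open_)
    # trailing end gaps are free only along the last row/column
    best = max(
        max(M[i][m], D[i][m], I[i][m]) for i in range(n + 1)
    )
    best = max(best, max(max(M[n][j], D[n][j], I[n][j]) for j in range(m + 1)))
    return max(best, 0.0)


class TestAlign:
    def test_identical_sequences(self, clean_sim):
        seq = next(iter(clean_sim.refs.values()))
        res = align(seq, seq)
        assert res.identity == 100.0 and res.coverage == 100.0

    def test_single_substitution_identity(self):
        random.seed(0)
        ref = "".join(random.choice("ACGT") for _ in range(100))
        q = "T" + ref[1:] if ref[0] != "T" else "A" + ref[1:]
        res = align(q, ref)
        assert res.identity == pytest.approx(99.0)
        assert res.coverage == 100.0

    def test_exact_substring_free_end_gaps(self):
        random.seed(1)
        ref = "".join(random.choice("ACGT") for _ in range(300))
        q = ref[100:200]
        res = align(q, ref)
        assert res.identity == 100.0 and res.coverage == 100.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align("", "ACGT")

    def test_identity_symmetric_for_gap_free_pairs(self):
        random.seed(2)
        a = "".join(random.choice("ACGT") for _ in range(80))
        b = list(a)
        for i in random.sample(range(80), 4):
            b[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[i]]
        b = "".join(b)
        assert align(a, b).identity == pytest.approx(align(b, a).identity)

    @pytest.mark.parametrize("trial", range(20))
    def test_score_matches_dp_oracle_on_short_strings(self, trial):
        rng = random.Random(trial)
        q = "".join(rng.choice("ACGT") for _ in range(rng.randint(5, 30)))
        r = "".join(rng.choice("ACGT") for _ in range(rng.randint(5, 30)))
        assert align(q, r).score == pytest.approx(gotoh_semiglobal_score(q, r))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        q=st.text(alphabet="ACGT", min_size=3, max_size=25),
        r=st.text(alphabet="ACGT", min_size=3, max_size=25),
    )
    def test_score_matches_dp_oracle_property(self, q, r):
        assert align(q, r).score == pytest.approx(gotoh_semiglobal_score(q, r))

    def test_score_and_identity_match_exhaustive_enumeration(self):
        # enumerate every legal alignment of two tiny strings
        def enumerate_alignments(q, r):
            def rec(i, j, cols):
                if i == len(q) and j == len(r):
                    yield cols
                    return
                if i < len(q) and j < len(r):
                    yield from rec(i + 1, j + 1, cols + [(q[i], r[j])])
                if i < len(q):
                    yield from rec(i + 1, j, cols + [(q[i], "-")])
                if j < len(r):
                    yield from rec(i, j + 1, cols + [("-", r[j])])

            return rec(0, 0, [])

        def score_cols(cols, q, r):
            # positional end-gap rule: a gap column is free iff the gapped
            # sequence's counterpart run sits before anything of the other
            # sequence was consumed, or after all of it was
            total, gap_state = 0.0, None
            qi = ri = 0
            for a, b in cols:
                if a != "-" and b != "-":
                    total += 1.0 if a == b else -1.0
                    gap_state = None
                    qi += 1
                    ri += 1
                elif b == "-":  # query char against gap: gap run in reference
                    free = ri == 0 or ri == len(r)
                    if not free:
                        total += -0.5 if gap_state == "r" else -2.0
                    gap_state = "r"
                    qi += 1
                else:  # gap run in query
                    free = qi == 0 or qi == len(q)
                    if not free:
                        total += -0.5 if gap_state == "q" else -2.0
                    gap_state = "q"
                    ri += 1
            return total

        def identity_cols(cols):
            pairs = [k for k, (a, b) in enumerate(cols) if a != "-" and b != "-"]
            lo, hi = pairs[0], pairs[-1]
            span = cols[lo : hi + 1]
            m = sum(a == b for a, b in span if "-" not in (a, b))
            return 100.0 * m / len(span)

        for q, r in [("ACGT", "AGT"), ("ACGTA", "ACCTA"), ("GATTA", "GCAT")]:
            alns = [c for c in enumerate_alignments(q, r)]
            best = max(score_cols(c, q, r) for c in alns)
            res = align(q, r)
            assert res.score == pytest.approx(best)
            optimal_identities = [
                identity_cols(c)
                for c in alns
                if score_cols(c, q, r) == pytest.approx(best)
                and any("-" not in p for p in c)
            ]
            assert any(res.identity == pytest.approx(v) for v in optimal_identities)


class TestBestHits:
    def _db(self, seqs, lineages):
        return [
            ReferenceRecord(f"r{i + 1}", s, lin)
            for i, (s, lin) in enumerate(zip(seqs, lineages))
        ]

    def test_unique_identical_reference(self, toy_lineages):
        random.seed(3)
        seq = "".join(random.choice("ACGT") for _ in range(120))
        other = "".join(random.choice("ACGT") for _ in range(120))
        db = self._db([seq, other], [toy_lineages["A"], toy_lineages["D"]])
        hits = best_hits(seq, db)
        assert len(top_tie_set(hits)) == 1

    def test_below_cutoff_is_excluded(self, toy_lineages):
        ref = "ACGT" * 250  # 1000 nt
        q = list(ref)
        for i in range(8, 8 + 31 * 8, 8):  # 31 interior substitutions -> 96.9%
            q[i] = "T"
        q = "".join(q)
        db = self._db([ref], [toy_lineages["A"]])
        assert align(q, ref).identity == pytest.approx(96.9)
        assert best_hits(q, db) == []

    def test_duplicate_sequence_ties_two_species(self, toy_lineages):
        random.seed(4)
        seq = "".join(random.choice("ACGT") for _ in range(120))
        db = self._db([seq, seq], [toy_lineages["A"], toy_lineages["B"]])
        assert len(top_tie_set(best_hits(seq, db))) == 2

    def test_raising_identity_threshold_monotone(self, clean_sim):
        q = clean_sim.queries[0].sequence
        db = clean_sim.db1
        counts = [
            len(best_hits(q, db, min_identity=t, min_coverage=0.0, prefilter=False))
            for t in (80.0, 90.0, 97.0)
        ]
        assert counts == sorted(counts, reverse=True)


class TestAssignFromDb:
    def _hits_for(self, q, db):
        from larvid.matchdb import align_all

        return align_all(q, db, prefilter=False)

    def test_single_species_tie(self, toy_lineages):
        random.seed(5)
        seq = "".join(random.choice("ACGT") for _ in range(120))
        db = [ReferenceRecord("r1", seq, toy_lineages["A"])]
        a = assign_from_db(self._hits_for(seq, db), {"r1": toy_lineages["A"]})
        assert (a.status, a.rank, a.taxon) == ("species_match", "species", "GenA sp1")

    def test_congeneric_tie_is_genus_ambiguity(self, toy_lineages):
        random.seed(6)
        seq = "".join(random.choice("ACGT") for _ in range(120))
        db = [
            ReferenceRecord("r1", seq, toy_lineages["A"]),
            ReferenceRecord("r2", seq, toy_lineages["B"]),
        ]
        a = assign_from_db(
            self._hits_for(seq, db), {"r1": toy_lineages["A"], "r2": toy_lineages["B"]}
        )
        assert (a.status, a.rank, a.taxon) == ("ambiguous", "genus", "GenA")

    def test_cross_family_tie_resolves_at_order(self, toy_lineages):
        random.seed(7)
        seq = "".join(random.choice("ACGT") for _ in range(120))
        db = [
            ReferenceRecord("r1", seq, toy_lineages["A"]),
            ReferenceRecord("r2", seq, toy_lineages["D"]),  # different family
        ]
        a = assign_from_db(
            self._hits_for(seq, db), {"r1": toy_lineages["A"], "r2": toy_lineages["D"]}
        )
        assert (a.status, a.rank, a.taxon) == ("ambiguous", "order", "Ord1")

    def test_rank_ladder_genus_fallback(self, toy_lineages):
        random.seed(8)
        ref = "".join(random.choice("ACGT") for _ in range(200))
        q = list(ref)
        for i in range(0, 48, 4):  # 12 substitutions -> 94% identity
            q[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[q[i]]
        q = "".join(q)
        db = [ReferenceRecord("r1", ref, toy_lineages["A"])]
        a = assign_from_db(self._hits_for(q, db), {"r1": toy_lineages["A"]})
        assert (a.status, a.rank, a.taxon) == ("rank_fallback", "genus", "GenA")

    def test_unknown_reference_id_named(self, toy_lineages):
        random.seed(9)
        seq = "".join(random.choice("ACGT") for _ in range(120))
        db = [ReferenceRecord("mystery", seq, toy_lineages["A"])]
        with pytest.raises(ValueError, match="mystery"):
            assign_from_db(self._hits_for(seq, db), {})

    def test_no_hits_is_no_match(self, toy_lineages):
        random.seed(10)
        q = "".join(random.choice("ACGT") for _ in range(120))
        r = "".join(random.choice("ACGT") for _ in range(120))
        db = [ReferenceRecord("r1", r, toy_lineages["A"])]
        a = assign_from_db(self._hits_for(q, db), {"r1": toy_lineages["A"]})
        assert a.status == "no_match" and not a.assigned


class TestDatabaseMatcher:
    def test_sklearn_param_interface(self):
        m = DatabaseMatcher(min_identity=98.0)
        assert m.get_params()["min_identity"] == 98.0
        m.set_params(min_coverage=90.0)
        assert m.min_coverage == 90.0

    def test_unfitted_predict_raises(self, clean_sim):
        with pytest.raises(ValueError, match="not fitted"):
            DatabaseMatcher().predict(clean_sim.queries[:1])

    def test_species_recovery_on_clean_data(self, clean_sim):
        matcher = DatabaseMatcher(label="db1").fit(clean_sim.db1)
        out = matcher.predict(clean_sim.queries)
        correct = sum(
            a.status == "species_match"
            and a.taxon == clean_sim.truth.queries[a.query_id].species
            for a in out
        )
        assert correct >= 0.95 * len(out)

    def test_prefilter_matches_exact_mode(self, clean_sim):
        qs = clean_sim.queries[:8]
        fast = DatabaseMatcher(prefilter=True).fit(clean_sim.db1).predict(qs)
        exact = DatabaseMatcher(prefilter=False).fit(clean_sim.db1).predict(qs)
        assert [(a.status, a.rank, a.taxon) for a in fast] == [
            (a.status, a.rank, a.taxon) for a in exact
        ]
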