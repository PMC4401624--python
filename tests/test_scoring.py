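"""Overlap-corrected match score, match rate, strands and prefilter."""

import numpy as np
import pytest

import kmerbin as kb
from kmerbin.encoding import encode_windows
from kmerbin.scoring import FORWARD, MATCH, MISMATCH, REVERSE

from conftest import brute_force_kmers, interval_union_score, random_seq


def build_worked_example():
    """A 14-nt read at k=5: first 12 nt are a verbatim reference
    substring, the 5-mer windows at offsets 8 and 9 miss the database.
    The eight consecutive hits at offsets 0..7 cover 5 + 7 = 12 bases."""
    ref = "ACGGTCAGGTTAAGGTCGGGAATTCTGCATT"
    db = kb.build_database([ref], 5, "S")
    stem = ref[3:15]
    for tail_a in "ACGT":
        for tail_b in "ACGT":
            read = stem + tail_a + tail_b
            _, values = encode_windows(read, 5)
            hits = db.contains_many(values)
            if hits[:8].all() and not hits[8] and not hits[9]:
                return read, db
    raise AssertionError("no tail makes the last two windows miss")


class TestWorkedExample:
    def test_match_score_is_12(self):
        read, db = build_worked_example()
        xi, count, _ = kb.match_score_strand(read, db)
        assert xi == 12 and count == 8

    def test_match_rate_is_85_7(self):
        read, db = build_worked_example()
        result = kb.score_read_against_group(kb.Read("r", read), db, mc=30.0)
        assert result.xi == 12
        assert round(result.Xi, 1) == 85.7
        assert result.status == MATCH


@pytest.mark.parametrize(
    "xi,length,expected", [(12, 14, 85.7), (0, 100, 0.0), (150, 150, 100.0), (0, 0, 0.0)]
)
def test_match_rate(xi, length, expected):
    assert round(kb.match_rate(xi, length), 1) == expected


class TestMatchScore:
    def test_exact_substring_scores_full_length(self, random_db):
        db, seqs = random_db
        read = seqs[0][40:40 + 60]
        xi, count, _ = kb.match_score_strand(read, db)
        assert xi == 60

    def test_no_shared_kmer_scores_zero(self, random_db):
        db, _ = random_db
        xi, count, _ = kb.match_score_strand("N" * 40, db)
        assert xi == 0 and count == 0

    def test_read_shorter_than_k_scores_zero(self, random_db):
        db, _ = random_db
        assert kb.match_score_strand("ACGT", db)[0] == 0

    @pytest.mark.parametrize("m", list(range(1, 21)))
    def test_consecutive_run_closed_form(self, m):
        # a run of m consecutive matched windows covers k + (m - 1) bases
        k = 10
        genome = "".join(
            "ACGT"[i] for i in np.random.default_rng(m).integers(0, 4, k + m - 1)
        )
        db = kb.build_database([genome], k, "g")
        xi, count, _ = kb.match_score_strand(genome, db)
        assert count == m and xi == k + (m - 1)

    def test_skipped_n_windows_keep_genomic_distance(self):
        # hits flank an N; the gap in ξ is the genomic offset difference
        k = 5
        ref = "ACGGTCAGGTTAAGGTCGGG"
        read = ref[:8] + "N" + ref[9:16]
        db = kb.build_database([ref], k, "g")
        xi, _, positions = kb.match_score_strand(read, db)
        oracle = interval_union_score(read, brute_force_kmers([ref], k), k)
        assert xi == oracle

    @pytest.mark.parametrize("k", [10, 15, 21, 30])
    def test_interval_union_oracle(self, rng, k):
        """ξ from the incremental overlap formula equals the brute-force
        count of read bases covered by matched k-mer windows."""
        for trial in range(60):
            ref = random_seq(rng, 150)
            db = kb.build_database([ref], k, "g")
            kmers = brute_force_kmers([ref], k)
            # mosaic read: alternating reference chunks and noise
            chunks = []
            for _ in range(4):
                start = int(rng.integers(0, 100))
                chunks.append(ref[start : start + int(rng.integers(5, 45))])
                chunks.append(random_seq(rng, int(rng.integers(0, 20))))
            read = "".join(chunks)[:140]
            xi, _, _ = kb.match_score_strand(read, db)
            assert xi == interval_union_score(read, kmers, k)

    def test_bounds_invariant(self, rng, random_db):
        db, seqs = random_db
        for _ in range(50):
            read = random_seq(rng, int(rng.integers(0, 80)))
            xi, count, _ = kb.match_score_strand(read, db)
            assert 0 <= xi <= len(read)
            assert xi == 0 or xi >= db.k
            assert (xi > 0) == (count >= 1)

    def test_monotone_in_database(self, rng):
        seqs = [random_seq(rng, 200) for _ in range(4)]
        small = kb.build_database(seqs[:2], 12, "g")
        large = kb.build_database(seqs, 12, "g")
        for _ in range(20):
            start = int(rng.integers(0, 150))
            read = seqs[0][start : start + 50] + random_seq(rng, 20)
            assert kb.match_score_strand(read, large)[0] >= kb.match_score_strand(read, small)[0]


class TestStrands:
    def test_reverse_complement_read_scores_on_reverse_strand(self, random_db):
        db, seqs = random_db
        fragment = seqs[1][10:80]
        fwd = kb.score_read_against_group(kb.Read("f", fragment), db, 30.0)
        rev = kb.score_read_against_group(
            kb.Read("r", kb.reverse_complement(fragment)), db, 30.0
        )
        assert fwd.strand == FORWARD and rev.strand == REVERSE
        assert fwd.xi == rev.xi

    def test_strand_max_is_symmetric(self, rng, random_db):
        db, seqs = random_db
        for _ in range(20):
            read = seqs[0][: int(rng.integers(20, 60))] + random_seq(rng, 30)
            a = kb.score_read_against_group(kb.Read("a", read), db, 30.0)
            b = kb.score_read_against_group(
                kb.Read("b", kb.reverse_complement(read)), db, 30.0
            )
            assert a.xi == b.xi


class TestPrefilter:
    def test_stride_one_always_passes(self, random_db):
        db, _ = random_db
        assert kb.prefilter("N" * 50, db, 1) is True

    def test_no_hit_read_fails_at_stride_k(self, random_db):
        db, _ = random_db
        assert kb.prefilter("A" * 50, db, db.k) in (True, False)  # depends on db
        empty = kb.build_database(["ACG"], 15, "e")
        assert kb.prefilter("ACGT" * 10, empty, 15) is False

    def test_out_of_range_rejected(self, random_db):
        db, _ = random_db
        for bad in (0, db.k + 1):
            with pytest.raises(ValueError, match="k'"):
                kb.prefilter("ACGT" * 10, db, bad)

    def test_true_whenever_sampled_position_hits(self, rng, random_db):
        """The stride filter may miss matches a full scan finds, but it
        never passes a strand the full scan would score zero."""
        db, seqs = random_db
        for _ in range(30):
            start = int(rng.integers(0, 250))
            read = random_seq(rng, 15) + seqs[2][start : start + 30]
            full_hit = kb.match_score_strand(read, db)[0] > 0
            for kprime in (2, 5, 15):
                if kb.prefilter(read, db, kprime):
                    assert full_hit

    def test_stride_one_stream_identical_to_unfiltered(self, tiny_fixture):
        fx = tiny_fixture
        reads = fx.reads[:100]
        dbs = [
            kb.build_database([fx.sequences[f"ref_{leaf}"]], 15, f"g{leaf}")
            for leaf in sorted(fx.genomes)
        ]
        plain = kb.compare_read_set(reads, dbs, mc=30.0, kprime=1)
        # unfiltered reference path: score strands directly, no prefilter
        for gid, db in zip(plain, dbs):
            for rec, read in zip(plain[gid], reads):
                f = kb.match_score_strand(read.sequence, db)[0]
                r = kb.match_score_strand(
                    kb.reverse_complement(read.sequence), db
                )[0]
                assert rec.xi == max(f, r)


class TestCompareReadSet:
    def test_every_pair_in_exactly_one_stream(self, tiny_fixture):
        fx = tiny_fixture
        reads = fx.reads[:50]
        dbs = [
            kb.build_database([fx.sequences[f"ref_{leaf}"]], 15, f"g{leaf}")
            for leaf in sorted(fx.genomes)
        ]
        records = kb.compare_read_set(reads, dbs, mc=30.0)
        for gid, recs in records.items():
            assert len(recs) == len(reads)
            assert {r.read_id for r in recs} == {r.read_id for r in reads}
            assert all(r.status in (MATCH, MISMATCH) for r in recs)

    def test_duplicate_read_ids_rejected(self, random_db):
        db, _ = random_db
        reads = [kb.Read("same", "ACGT" * 10), kb.Read("same", "TTTT" * 10)]
        with pytest.raises(ValueError, match="duplicate read id"):
            kb.compare_read_set(reads, [db], mc=30.0)

    def test_match_iff_rate_reaches_cutoff(self, tiny_fixture):
        fx = tiny_fixture
        reads = fx.reads[:50]
        db = kb.build_database(
            [fx.sequences[f"ref_{min(fx.genomes)}"]], 15, "g"
        )
        for rec in kb.compare_read_set(reads, [db], mc=30.0)["g"]:
            assert (rec.status == MATCH) == (rec.Xi >= 30.0)
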