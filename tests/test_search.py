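import numpy as np
import pytest
from hypothesis import given, settings as hsettings, strategies as st

from readprobe import (
    CountTable,
    IndexSet,
    QueryRecord,
    QuerySet,
    SearchSettings,
    build_kmer_map,
    collate,
    kmers_centered,
    kmers_sliding,
    ksearch,
    reverse_complement,
    run_query_search,
    search_kmers,
    store_from_sequences,
)
from readprobe.simulate import make_genome, simulate_reads

from conftest import random_reads


def centered_oracle(seq, k, s):
    """All windows covering the center, filtered by stride from the leftmost
    feasible start, plus the rightmost feasible start."""
    c = len(seq) // 2
    feasible = [i for i in range(len(seq) - k + 1) if i <= c < i + k]
    lo, hi = feasible[0], feasible[-1]
    starts = sorted({i for i in feasible if (i - lo) % s == 0} | {hi})
    return [(seq[i : i + k], i) for i in starts]


def sliding_oracle(seq, k, s):
    starts = sorted({i for i in range(0, len(seq) - k + 1, s)} | {len(seq) - k})
    return [(seq[i : i + k], i) for i in starts]


class TestKmerGeneration:
    def test_centered_examples(self):
        assert kmers_centered("ACGTA", 3, 1) == [("ACG", 0), ("CGT", 1), ("GTA", 2)]
        assert kmers_centered("ACGTA", 3, 2) == [("ACG", 0), ("GTA", 2)]
        assert kmers_centered("ACGTA", 5, 1) == [("ACGTA", 0)]

    def test_sliding_examples(self):
        assert [i for _, i in kmers_sliding("ACGTACG", 3, 2)] == [0, 2, 4]
        assert [i for _, i in kmers_sliding("ACGTAC", 3, 2)] == [0, 2, 3]
        assert [i for _, i in kmers_sliding("ACGTAC", 3, 100)] == [0, 3]

    def test_k_longer_than_query_errors(self):
        with pytest.raises(ValueError):
            kmers_centered("ACG", 4, 1)
        with pytest.raises(ValueError):
            kmers_sliding("ACG", 4, 1)

    def test_every_centered_window_covers_center(self, rng):
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=33))
        for k in (5, 12, 33):
            for s in (1, 3, 7):
                c = len(seq) // 2
                for _, start in kmers_centered(seq, k, s):
                    assert start <= c < start + k

    @hsettings(deadline=None, derandomize=True, max_examples=200)
    @given(st.integers(1, 50), st.data())
    def test_generation_matches_enumeration_oracles(self, L, data):
        k = data.draw(st.integers(1, L))
        s = data.draw(st.integers(1, k))
        seq = "".join("ACGT"[i % 4] for i in range(L))
        assert kmers_centered(seq, k, s) == centered_oracle(seq, k, s)
        assert kmers_sliding(seq, k, s) == sliding_oracle(seq, k, s)


def qset(*seqs):
    return QuerySet(
        records=[QueryRecord(i, "SEQ", s, name=f"q{i}") for i, s in enumerate(seqs)]
    )


class TestKmerMap:
    def test_shared_kmer_dropped_and_flagged(self):
        s = SearchSettings(k=4, s=1, mode="SLIDING", search_rc=False,
                           ignore_nonunique_kmers=True)
        km = build_kmer_map(qset("ACGTA", "TACGT"), s)
        assert "ACGT" in km.dropped_nonunique
        assert km.query_ids_of("CGTA") == {0}
        assert km.query_ids_of("TACG") == {1}
        assert km.flagged_queries == {0, 1}

    def test_single_query_never_dropped(self):
        s = SearchSettings(k=4, s=1, mode="SLIDING", search_rc=False)
        km = build_kmer_map(qset("ACGTACGT"), s)
        assert not km.dropped_nonunique and not km.flagged_queries

    def test_palindromic_kmer_maps_once(self):
        s = SearchSettings(k=4, s=1, mode="SLIDING", search_rc=True)
        km = build_kmer_map(qset("AACGTT"), s)  # contains ACGT, its own RC
        assert km.entries["ACGT"] and len(km.query_ids_of("ACGT")) == 1

    def test_rc_collision_across_queries_dropped(self):
        # GGGG's RC CCCC belongs to the other query: both dropped
        s = SearchSettings(k=4, s=4, mode="SLIDING", search_rc=True,
                           ignore_nonunique_kmers=True)
        km = build_kmer_map(qset("GGGG", "CCCC"), s)
        assert km.flagged_queries == {0, 1}
        assert not km.entries

    def test_short_query_names_query(self):
        s = SearchSettings(k=10, s=1, mode="SLIDING")
        with pytest.raises(ValueError, match="q0"):
            build_kmer_map(qset("ACGT"), s)


def make_index(seqs, n_chunks=1, paired=False, include_rc=False):
    store = store_from_sequences(seqs, paired=paired, include_rc=include_rc)
    return IndexSet.from_store(store, n_chunks=n_chunks)


class TestSearchAndCollate:
    def test_multiple_kmers_one_read_count_once(self):
        read = "ACGTACGTAA"
        iset = make_index([read])
        s = SearchSettings(k=4, s=1, mode="SLIDING", search_rc=False, max_occ=100)
        ct = run_query_search(iset, qset(read), s)
        assert ct.rows[0].count == 1

    def test_absent_query_counts_zero(self):
        iset = make_index(["ACGTACGTAC"])
        s = SearchSettings(k=4, s=1, mode="SLIDING", max_occ=100)
        ct = run_query_search(iset, qset("GGGGGGGG"), s)
        assert ct.rows[0].count == 0

    def test_thread_invariance(self, rng):
        seqs = random_reads(rng, 40, 60)
        iset = make_index(seqs, n_chunks=3)
        qs = qset(seqs[0], seqs[10], seqs[20])
        base = None
        for threads in (1, 2, 8):
            s = SearchSettings(k=11, s=3, mode="SLIDING", threads=threads, max_occ=50)
            km = build_kmer_map(qs, s)
            raw = search_kmers(iset, km, s)
            ct = collate(raw, iset, km, s)
            if base is None:
                base = (raw, ct)
            else:
                assert raw == base[0]
                assert ct == base[1]

    def test_global_max_occ_across_chunks(self):
        # k-mer occurs 3x total (2+1 across chunks); per-chunk under max_occ
        seqs = ["AACGTT", "AACGTA", "CACGTC", "GGGGGG"]
        qs = qset("AACGT")
        s = SearchSettings(k=4, s=1, mode="SLIDING", search_rc=False, max_occ=2)
        ct_mono = run_query_search(make_index(seqs, 1), qs, s)
        ct_chunk = run_query_search(make_index(seqs, 4), qs, s)
        assert ct_mono == ct_chunk
        assert ct_mono.rows[0].flag_overmax_kmer  # "ACGT" occurs 3 > 2

    def test_unique_reads_drops_contested_from_all(self):
        # read matches both queries
        read = "ACGTAGGGCCAT"
        iset = make_index([read, "ACGTAGCACACA"])
        q = qset("ACGTAG", "GGGCCA")
        on = SearchSettings(k=6, s=1, mode="SLIDING", search_rc=False,
                            unique_reads=True, ignore_nonunique_kmers=False,
                            max_occ=100)
        off = SearchSettings(k=6, s=1, mode="SLIDING", search_rc=False,
                             unique_reads=False, ignore_nonunique_kmers=False,
                             max_occ=100)
        ct_on = run_query_search(iset, q, on)
        ct_off = run_query_search(iset, q, off)
        assert ct_off.rows[0].count == 2 and ct_off.rows[1].count == 1
        assert ct_on.rows[0].count == 1 and ct_on.rows[1].count == 0

    def test_paired_mode_counts_pairs(self):
        # both mates of pair 0 match the query -> one pair counted
        seqs = ["ACGTACGTAC", "GTACGTACGT", "TTTTTTTTTT", "CCCCCCCCCC"]
        iset = make_index(seqs, paired=True)
        s = SearchSettings(k=6, s=1, mode="SLIDING", paired_mode=True, max_occ=100)
        ct = run_query_search(iset, qset("ACGTACGTACGT"), s)
        assert ct.unit == "PAIRS"
        assert ct.rows[0].count == 1

    def test_chunk_merge_equivalence_randomized(self, rng):
        for trial in range(5):
            seqs = random_reads(rng, 24, 50)
            qs = qset(seqs[0] + seqs[1], seqs[5])
            s = SearchSettings(
                k=9, s=2, mode="SLIDING",
                max_occ=int(rng.choice([5, 200])),
                unique_reads=bool(trial % 2),
            )
            tables = [
                run_query_search(make_index(seqs, n), qs, s) for n in (1, 4)
            ]
            assert tables[0] == tables[1]

    def test_rc_symmetry(self, rng):
        """A read and its reverse complement contribute identically."""
        genome = make_genome(300, seed=3)
        read = genome[50:150]
        s = SearchSettings(k=21, s=5, mode="SLIDING", search_rc=True, max_occ=100)
        qs = qset(genome)
        ct_fwd = run_query_search(make_index([read]), qs, s)
        ct_rev = run_query_search(make_index([reverse_complement(read)]), qs, s)
        assert ct_fwd == ct_rev

    def test_rc_included_index_equivalent_to_query_side_rc(self, rng):
        """Indexing RC copies (D3) matches searching k-mer RCs (D16)."""
        genome = make_genome(400, seed=5)
        sim = simulate_reads([genome], 60, n_reads=30, seed=6)
        qs = qset(genome)
        a = SearchSettings(k=15, s=4, mode="SLIDING", search_rc=True, max_occ=1000)
        b = SearchSettings(k=15, s=4, mode="SLIDING", search_rc=False, max_occ=1000)
        ct_query_side = run_query_search(make_index(sim.sequences()), qs, a)
        ct_index_side = run_query_search(
            make_index(sim.sequences(), include_rc=True), qs, b
        )
        assert ct_query_side == ct_index_side

    def test_count_bounds_monotonicity(self, rng):
        seqs = random_reads(rng, 30, 50)
        qs = qset(seqs[0], seqs[1][:30])
        iset = make_index(seqs)
        base = SearchSettings(k=9, s=2, mode="SLIDING", max_occ=200)
        strict = SearchSettings(k=9, s=2, mode="SLIDING", max_occ=3)
        uniq = SearchSettings(k=9, s=2, mode="SLIDING", max_occ=200, unique_reads=True)
        ct, ct_strict, ct_uniq = (
            run_query_search(iset, qs, s) for s in (base, strict, uniq)
        )
        for qid in (0, 1):
            assert 0 <= ct.rows[qid].count <= len(seqs)
            assert ct_strict.rows[qid].count <= ct.rows[qid].count
            assert ct_uniq.rows[qid].count <= ct.rows[qid].count

    def test_simulated_reads_recovered(self):
        """Error-free reads from a query sequence are each counted once."""
        genome = make_genome(1500, seed=11)
        sim = simulate_reads([genome], 80, depth=15, seed=12)
        iset = make_index(sim.sequences())
        s = SearchSettings.pathogen_defaults(max_occ=100000)
        ct = run_query_search(iset, qset(genome), s)
        assert ct.rows[0].count == len(sim.records)


class TestKsearch:
    def test_per_kmer_read_counts(self):
        reads = ["AACGTACA", "TACGTACA", "CACGTGGG", "GGGGAAAA"]
        iset = make_index(reads)
        s = SearchSettings(search_rc=False, max_occ=100)
        res = ksearch(iset, [("ACGT", None), ("GGGG", None)], s)
        assert res.count("ACGT") == 3
        assert res.count("GGGG") == 1

    def test_group_tally_strictly_greater(self, rng):
        # five k-mers engineered to occur in 0,1,4,4,9 distinct reads
        kmers = ["AAAACCCCGG", "CCCCGGGGTT", "GGGGTTTTAA", "TTTTAAAACC", "ACACACGTGT"]
        counts = [0, 1, 4, 4, 9]
        reads = []
        for kmer, c in zip(kmers, counts):
            pad = random_reads(rng, c, 30)
            reads.extend(p[:10] + kmer + p[10:20] for p in pad)
        iset = make_index(reads)
        s = SearchSettings(search_rc=False, max_occ=1000,
                           ignore_nonunique_kmers=False)
        res = ksearch(iset, [(k, "KIR3DL1") for k in kmers], s, threshold=3)
        assert [res.count(k) for k in kmers] == counts
        assert res.group_tallies == {"KIR3DL1": 3}

    def test_duplicate_kmer_lines_collapse(self):
        iset = make_index(["ACGTACGT"])
        s = SearchSettings(search_rc=False, max_occ=100)
        res = ksearch(iset, [("ACGT", "g"), ("ACGT", "g")], s)
        assert res.kmers == ["ACGT"]


class TestCountTableIO:
    def test_counts_round_trip(self, tmp_path, rng):
        from readprobe import read_counts, write_counts

        seqs = random_reads(rng, 10, 40)
        qs = qset(seqs[0], seqs[3])
        iset = make_index(seqs)
        s = SearchSettings(k=9, s=3, mode="SLIDING", max_occ=100)
        ct = run_query_search(iset, qs, s)
        path = tmp_path / "counts.tsv"
        write_counts(qs, ct, path)
        qs2, ct2 = read_counts(path)
        assert qs2.records == qs.records
        assert ct2 == ct


def test_settings_validation_warns_on_gappy_stride():
    with pytest.warns(UserWarning, match="never"):
        SearchSettings(k=5, s=9).validate()
    with pytest.raises(ValueError):
        SearchSettings(k=0).validate()
    with pytest.raises(ValueError):
        SearchSettings(mode="DIAGONAL").validate()
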