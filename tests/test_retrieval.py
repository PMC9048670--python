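"""k-mer search: oracle equivalence, pigeonhole completeness, clonotypes."""

import numpy as np
import pytest

from abrep.imgt import ImgtPosition, cdr3_ladder
from abrep.io import NumberedSequence, Repertoire, StudyMetadata
from abrep.retrieval import (
    align_hits_imgt,
    build_index,
    hamming,
    load_index,
    save_index,
    search_cdr3,
    search_clonotype,
    search_variable,
    summarize_hits_by_metadata,
    write_alignment,
)
from abrep.simulate import SimulationConfig, simulate_repertoires, spike_neighbors

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def seq_from_cdr3(cdr3, seq_id, study_id="S1", chain="H",
                  v_call="IGHV901*01", j_call="IGHJ901*01"):
    residues = {p: c for p, c in zip(cdr3_ladder(len(cdr3)), cdr3)}
    return NumberedSequence(seq_id, study_id, chain, residues, v_call, j_call)


def cdr3_repertoire(cdr3s, study_id="S1", **meta_kw):
    meta = StudyMetadata(study_id, species="human", chain="H", **meta_kw)
    seqs = [seq_from_cdr3(c, f"{study_id}_{i}", study_id) for i, c in enumerate(cdr3s)]
    return Repertoire(meta, seqs)


def random_cdr3(rng, length):
    return "".join(rng.choice(list(AA20), size=length))


class TestHamming:
    def test_counts_substitutions(self):
        assert hamming("ARDYW", "ARDFW") == 1
        assert hamming("ARDYW", "ARDYW") == 0

    def test_x_always_mismatches(self):
        assert hamming("AXD", "AXD") == 1
        assert hamming("X", "X") == 1

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal lengths"):
            hamming("ARD", "ARDY")


class TestBuildIndex:
    def test_posting_count_is_L_minus_k_plus_1(self):
        rep = cdr3_repertoire(["CARDYWGQGTLV"])  # L=12, k=5 -> 8 postings
        idx = build_index([rep], k=5)
        ref = ("S1", "S1_0")
        assert sum(ref in refs for refs in idx.postings.values()) == 8

    def test_short_cdr3_goes_to_short_bucket(self):
        rep = cdr3_repertoire(["ARDYWGQG"])  # L=8 < 2k
        idx = build_index([rep], k=5)
        assert ("S1", "S1_0") in idx.short_buckets[8]

    def test_empty_repertoire_empty_index(self):
        idx = build_index([cdr3_repertoire([])], k=5)
        assert len(idx) == 0 and not idx.postings

    def test_build_deterministic(self, reps):
        a, b = build_index(reps), build_index(reps)
        assert a.postings == b.postings
        assert a.short_buckets == b.short_buckets
        assert a.clonotypes == b.clonotypes

    def test_round_trip_through_file(self, kmer_index, tmp_path):
        path = tmp_path / "idx.json"
        save_index(kmer_index, path)
        back = load_index(path)
        assert back.k == kmer_index.k
        assert back.postings == kmer_index.postings
        assert back.short_buckets == kmer_index.short_buckets
        assert back.clonotypes == kmer_index.clonotypes
        path2 = tmp_path / "idx2.json"
        save_index(back, path2)
        assert path.read_bytes() == path2.read_bytes()


class TestSearchCdr3:
    def test_mixed_set(self):
        rep = cdr3_repertoire(["ARDYWGQGTLVTV", "ARDFWGQGTLVTV", "SSSSWGQGTLVTV"])
        idx = build_index([rep], k=5)
        hits = search_cdr3(idx, "ARDYWGQGTLVTV", 1)
        assert [h.cdr3 for h in hits] == ["ARDYWGQGTLVTV", "ARDFWGQGTLVTV"]
        assert [h.cdr3_mismatches for h in hits] == [0, 1]

    def test_no_length_bucket(self, kmer_index):
        assert search_cdr3(kmer_index, "AAAA", 1) == []

    def test_exact_match_semantics_at_zero(self):
        rep = cdr3_repertoire(["ARDYWGQGTLVTV", "ARDFWGQGTLVTV"])
        idx = build_index([rep], k=5)
        hits = search_cdr3(idx, "ARDYWGQGTLVTV", 0)
        assert [h.cdr3 for h in hits] == ["ARDYWGQGTLVTV"]

    def test_oracle_equivalence_random_queries(self):
        """k-mer search equals exhaustive Hamming scan for 200 queries
        against 1000 indexed CDR3s."""
        rng = np.random.default_rng(101)
        cdr3s = [random_cdr3(rng, int(rng.integers(8, 24))) for _ in range(1000)]
        rep = cdr3_repertoire(cdr3s)
        idx = build_index([rep], k=5)
        by_id = {s.seq_id: s for s in rep.sequences}
        for _ in range(200):
            if rng.random() < 0.7:  # near-duplicate of an indexed CDR3
                base = cdr3s[int(rng.integers(len(cdr3s)))]
                query = list(base)
                for _ in range(int(rng.integers(0, 3))):
                    j = int(rng.integers(len(query)))
                    query[j] = AA20[int(rng.integers(20))]
                query = "".join(query)
            else:
                query = random_cdr3(rng, int(rng.integers(8, 24)))
            got = {h.seq_id for h in search_cdr3(idx, query, 1)}
            expect = {
                s.seq_id for s in by_id.values()
                if len(s.cdr3) == len(query) and hamming(s.cdr3, query) <= 1
            }
            assert got == expect

    @pytest.mark.parametrize("length", range(10, 26))
    def test_pigeonhole_completeness(self, length):
        """A single substitution at any position is always retrieved."""
        rng = np.random.default_rng(length)
        base = random_cdr3(rng, length)
        neighbors = []
        for i in range(length):
            alt = next(a for a in AA20 if a != base[i])
            neighbors.append(base[:i] + alt + base[i + 1 :])
        idx = build_index([cdr3_repertoire(neighbors)], k=5)
        hits = search_cdr3(idx, base, 1)
        assert len(hits) == length
        assert all(h.cdr3_mismatches == 1 for h in hits)


class TestSearchVariable:
    @pytest.fixture()
    def query(self, reps):
        return reps[0].sequences[0]

    def test_cdr3_neighbor_retrieved(self, reps, query):
        spike = spike_neighbors(query, 1, 1, seed=3)[0]
        extra = Repertoire(StudyMetadata("SPIKE", chain="H"), [spike])
        idx = build_index([*reps, extra])
        hits = search_variable(idx, query)
        assert spike.seq_id in {h.seq_id for h in hits}

    def test_cdr1_substitution_mode_dependent(self, reps, query):
        pos = next(p for p in query.residues if 27 <= p.number <= 38)
        alt = next(a for a in AA20 if a != query.residues[pos])
        variant = NumberedSequence(
            "cdr1var", "SPIKE", "H", {**query.residues, pos: alt},
            query.v_call, query.j_call,
        )
        extra = Repertoire(StudyMetadata("SPIKE", chain="H"), [variant])
        idx = build_index([*reps, extra])
        strict = {h.seq_id for h in search_variable(idx, query, "identical")}
        relaxed = {h.seq_id for h in search_variable(idx, query, "length_only")}
        assert "cdr1var" not in strict
        assert "cdr1var" in relaxed

    def test_chain_mismatch_always_excluded(self, reps, query):
        twin = NumberedSequence(
            "lighttwin", "SPIKE", "K", dict(query.residues), "IGKV901*01", "IGKJ901*01"
        )
        extra = Repertoire(StudyMetadata("SPIKE", chain="K"), [twin])
        idx = build_index([*reps, extra])
        for mode in ("identical", "length_only"):
            assert "lighttwin" not in {h.seq_id for h in search_variable(idx, query, mode)}

    def test_missing_cdr_rejected(self, kmer_index):
        bare = seq_from_cdr3("CARDYWGQGTLVW", "bare")
        with pytest.raises(ValueError, match="all three CDRs"):
            search_variable(kmer_index, bare)

    def test_identity_in_unit_interval_and_sorted(self, reps, query):
        idx = build_index(reps)
        hits = search_variable(idx, query)
        assert all(0.0 <= h.identity <= 1.0 for h in hits)
        assert [h.sort_key() for h in hits] == sorted(h.sort_key() for h in hits)


class TestSearchClonotype:
    def test_allele_difference_does_not_block(self, reps):
        q = reps[0].sequences[0]
        other_allele = q.v_call.replace("*01", "*02") if "*01" in q.v_call else q.v_call.replace("*02", "*01")
        twin = NumberedSequence(
            "alleletwin", "SPIKE", "H", dict(q.residues), other_allele, q.j_call
        )
        idx = build_index([*reps, Repertoire(StudyMetadata("SPIKE", chain="H"), [twin])])
        assert "alleletwin" in {h.seq_id for h in search_clonotype(idx, q)}

    def test_different_v_gene_blocks(self, reps):
        q = reps[0].sequences[0]
        twin = NumberedSequence(
            "genetwin", "SPIKE", "H", dict(q.residues), "IGHV903*01", q.j_call
        )
        assert twin.v_gene != q.v_gene
        idx = build_index([*reps, Repertoire(StudyMetadata("SPIKE", chain="H"), [twin])])
        assert "genetwin" not in {h.seq_id for h in search_clonotype(idx, q)}

    def test_cdr3_off_by_one_blocks(self, reps):
        q = reps[0].sequences[0]
        near = spike_neighbors(q, 1, 1, seed=9)[0]
        idx = build_index([*reps, Repertoire(StudyMetadata("SPIKE", chain="H"), [near])])
        assert near.seq_id not in {h.seq_id for h in search_clonotype(idx, q)}

    def test_equals_brute_force_on_simulated_data(self, reps, kmer_index):
        all_seqs = [s for rep in reps for s in rep.sequences]
        rng = np.random.default_rng(4)
        for i in rng.choice(len(all_seqs), size=30, replace=False):
            q = all_seqs[int(i)]
            got = {h.seq_id for h in search_clonotype(kmer_index, q)}
            expect = {
                s.seq_id for s in all_seqs
                if s.v_gene == q.v_gene and s.cdr3 == q.cdr3
            }
            assert got == expect

    def test_unparseable_v_call_rejected(self, kmer_index):
        q = seq_from_cdr3("CARDYWGQGTLVW", "q", v_call="", j_call="")
        with pytest.raises(ValueError, match="v_call"):
            search_clonotype(kmer_index, q)


class TestAlignment:
    def test_query_alone(self, reps):
        q = reps[0].sequences[0]
        idx = build_index(reps)
        table = align_hits_imgt(q, [], idx)
        assert list(table.index) == [q.seq_id]
        assert "".join(table.iloc[0]) == q.sequence()

    def test_insertion_column_gaps_query(self, reps, tmp_path):
        q = seq_from_cdr3("CARDYWGQGTLVW", "q13")  # length 13, no insertions
        long_hit = seq_from_cdr3("CARDYWGAGQGTLVW", "h15", study_id="SPIKE")  # 111A/112A
        idx = build_index([*reps, Repertoire(StudyMetadata("SPIKE", chain="H"), [long_hit])])
        hits = search_cdr3(idx, long_hit.cdr3, 0, query_id="q13")
        table = align_hits_imgt(q, hits, idx)
        assert "111A" in table.columns
        assert table.loc["q13", "111A"] == "-"
        out = tmp_path / "aln.txt"
        write_alignment(table, out)
        lines = out.read_text().splitlines()
        assert lines[0].startswith("# positions\t")
        assert lines[1] == ">q13"

    def test_identical_sequences_identical_rows(self, reps):
        q = reps[0].sequences[0]
        idx = build_index(reps)
        hits = search_cdr3(idx, q.cdr3, 0, query_id=q.seq_id)
        # the query itself is indexed, so row 0 (query) and its hit row agree
        assert any(h.seq_id == q.seq_id for h in hits)
        table = align_hits_imgt(q, hits, idx)
        hit_row = table.reset_index(drop=True).iloc[1 + [h.seq_id for h in hits].index(q.seq_id)]
        assert (hit_row.values == table.iloc[0].values).all()


class TestHitsWithAlignment:
    def test_aligned_row_holds_residues_even_when_query_is_its_own_hit(
        self, reps, tmp_path
    ):
        from abrep.io import write_hits_table

        q = reps[0].sequences[0]
        idx = build_index(reps)
        hits = search_cdr3(idx, q.cdr3, 0, query_id=q.seq_id)
        assert any(h.seq_id == q.seq_id for h in hits)  # duplicate row label
        table = align_hits_imgt(q, hits, idx)
        out = tmp_path / "hits.tsv"
        write_hits_table(hits, out, alignment=table)
        for line in out.read_text().splitlines()[1:]:
            aligned = line.split("\t")[-1]
            assert set(aligned) <= set("ACDEFGHIKLMNPQRSTVWYX-")
            assert len(aligned) == table.shape[1]


class TestThemeSummary:
    def hit(self, seq_id, study_id, disease):
        from abrep.retrieval import SearchHit

        return SearchHit("q", seq_id, study_id, "human", disease, None,
                         "IGHV901*01", "IGHJ901*01", "CARDYW", 0, 1.0, "cdr3")

    def test_counts_hits_and_studies(self):
        hits = [self.hit("a", "S1", "SARS-CoV-2"), self.hit("b", "S1", "SARS-CoV-2"),
                self.hit("c", "S2", "SARS-CoV-2")]
        table = summarize_hits_by_metadata(hits, "disease")
        assert table.to_dict("records") == [
            {"value": "SARS-CoV-2", "hit_count": 3, "study_count": 2}
        ]

    def test_empty_hits(self):
        assert summarize_hits_by_metadata([], "disease").empty

    def test_missing_values_pooled_as_unspecified(self):
        hits = [self.hit("a", "S1", None), self.hit("b", "S2", "")]
        table = summarize_hits_by_metadata(hits, "disease")
        assert list(table["value"]) == ["unspecified"]
        assert int(table["hit_count"].iloc[0]) == 2

    def test_unknown_field_rejected(self):
        with pytest.raises(ValueError, match="unknown metadata field"):
            summarize_hits_by_metadata([], "isotype")
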