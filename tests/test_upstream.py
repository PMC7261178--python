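"""Upstream consensus pipeline: stage rules, oracles, end-to-end recovery."""

import numpy as np
import pandas as pd
import pytest

import ighvkit as ik
from ighvkit.upstream import (
    DegenerateLengthsError,
    UpstreamCluster,
    _resolve_clusters,
    assemble_cohort_db,
    build_consensus,
    cluster_reads,
    extract_upstream,
    filter_clusters,
    infer_upstream_db,
    length_frequency_filter,
    pad_and_trim_95n,
    split_ambiguous,
    upstream_db_long,
)

from _bruteforce import (
    bf_cluster,
    bf_consensus,
    bf_length_filter,
    bf_pad_and_trim_95n,
    bf_split,
    random_reads,
)


class TestExtract:
    def test_splits_at_v_start(self):
        t = pd.DataFrame({"sequence": ["TTTACGT"], "v_call": ["X*01"],
                          "v_sequence_start": [4], "sample_id": ["S1"],
                          "batch_id": ["B1"]})
        out = extract_upstream(t)
        assert out["bases"].tolist() == ["TTT"]
        assert out["allele"].tolist() == ["X*01"]

    def test_empty_upstream_dropped(self):
        t = pd.DataFrame({"sequence": ["ACGT"], "v_call": ["X*01"],
                          "v_sequence_start": [1], "sample_id": ["S1"],
                          "batch_id": ["B1"]})
        assert extract_upstream(t).empty

    def test_zero_noise_upstreams_are_truth_suffixes(self, zero_noise_cohort):
        _, table, truth = zero_noise_cohort
        ups = extract_upstream(table.head(500))
        merged = table.head(500).merge(truth.per_read, on="sequence_id")
        for bases, (_, row) in zip(ups["bases"], merged.iterrows()):
            hap = truth.upstream_haplotypes[row["sample_id_x"]][row["true_allele"]]
            assert hap.endswith(bases)


class TestPadAndTrim:
    def test_equal_lengths_unchanged(self):
        reads = ["ACGTA"] * 30
        assert pad_and_trim_95n(reads) == reads

    def test_ninety_six_to_four_split_trims_long_tail(self):
        reads = ["A" * 50] * 96 + ["C" * 80] * 4
        out = pad_and_trim_95n(reads)
        assert max(len(s) for s in out) <= 50
        assert out[:96] == ["A" * 50] * 96
        assert out[96:] == ["C" * 50] * 4

    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(17)
        for _ in range(60):
            reads = random_reads(rng)
            assert pad_and_trim_95n(reads) == bf_pad_and_trim_95n(reads)


class TestLengthFilter:
    def test_documented_arithmetic(self):
        reads = (["A" * 120] * 14 + ["C" * 119] * 4 + ["G" * 60] * 1 + ["T" * 130] * 1)
        out = length_frequency_filter(reads)
        assert len(out) == 19  # the 60-mer is gone
        assert set(len(s) for s in out) == {119, 120}
        assert "T" * 120 in out  # 130-mer trimmed at the 5' end

    def test_single_length_unchanged(self):
        reads = ["ACG"] * 5
        assert length_frequency_filter(reads) == reads

    def test_all_infrequent_is_error(self):
        reads = ["A" * n for n in range(1, 12)]  # 11 lengths at 1/11 each
        with pytest.raises(DegenerateLengthsError):
            length_frequency_filter(reads)

    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(18)
        for _ in range(60):
            reads = random_reads(rng)
            expect = bf_length_filter(reads)
            if expect is None:
                with pytest.raises(DegenerateLengthsError):
                    length_frequency_filter(reads)
            else:
                assert length_frequency_filter(reads) == expect


class TestClustering:
    def test_identical_reads_one_cluster(self):
        assert cluster_reads(["ACGT"] * 10) == [list(range(10))]

    def test_single_mismatch_in_hundred_splits(self):
        a = "A" * 100
        b = "A" * 99 + "C"
        clusters = cluster_reads([a] * 3 + [b] * 2)
        assert sorted(map(len, clusters)) == [2, 3]

    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(19)
        for _ in range(40):
            reads = random_reads(rng, n_max=25, len_max=12, n_prob=0.1)
            assert cluster_reads(reads) == bf_cluster(reads)


class TestConsensus:
    def test_identical_reads_return_member(self):
        assert build_consensus(["ACGT"] * 4) == "ACGT"

    def test_sixty_percent_boundary_passes(self):
        reads = ["A"] * 6 + ["C"] * 4
        assert build_consensus(reads) == "A"  # 0.6 >= 0.6

    def test_even_split_is_ambiguous(self):
        assert build_consensus(["A"] * 5 + ["C"] * 5) == "N"

    def test_padding_not_counted_against_majority(self):
        reads = ["GACGT", "ACGT", "ACGT"]
        assert build_consensus(reads) == "GACGT"

    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(20)
        for _ in range(60):
            reads = random_reads(rng, n_prob=0.15)
            assert build_consensus(reads) == bf_consensus(reads)


class TestClusterFilter:
    def _cluster(self, members, freq):
        return UpstreamCluster("X*01", "S1", tuple(range(members)), "ACGT", freq)

    def test_boundaries(self):
        assert filter_clusters([self._cluster(9, 0.5)]) == []
        assert filter_clusters([self._cluster(50, 0.09)]) == []
        kept = filter_clusters([self._cluster(10, 0.1)])
        assert len(kept) == 1


class TestSplitAmbiguous:
    def test_even_mixture_splits_in_two(self):
        reads = ["AAGTT"] * 10 + ["AACTT"] * 10
        parts = split_ambiguous(reads)
        assert sorted(len(m) for m, _ in parts) == [10, 10]
        consensuses = sorted(c for _, c in parts)
        assert consensuses == ["AACTT", "AAGTT"]

    def test_unambiguous_cluster_is_identity(self):
        reads = ["ACGT"] * 7
        parts = split_ambiguous(reads)
        assert parts == [(list(range(7)), "ACGT")]

    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(21)
        for _ in range(60):
            reads = random_reads(rng, n_prob=0.1)
            assert split_ambiguous(reads) == bf_split(reads)

    def test_recursive_resolution_leaves_no_splittable_ambiguity(self):
        rng = np.random.default_rng(22)
        for _ in range(25):
            reads = random_reads(rng, n_max=60, len_max=10, n_prob=0.0, ragged=False)
            done = _resolve_clusters("X*01", "S1", reads, len(reads),
                                     ident=0.999, cons_freq=0.6,
                                     min_members=2, min_freq=0.0)
            for clu in done:
                member_seqs = [reads[i] for i in clu.members]
                assert split_ambiguous(member_seqs) == \
                    [(list(range(len(member_seqs))), clu.consensus)]

    def test_no_chimeras(self):
        # every consensus agrees with at least one member over all non-N positions
        def agrees(consensus, member):
            window = min(len(consensus), len(member))
            return all(
                consensus[-k] == "N" or member[-k] == "N" or consensus[-k] == member[-k]
                for k in range(1, window + 1)
            )

        rng = np.random.default_rng(23)
        for _ in range(25):
            reads = random_reads(rng, n_max=40, len_max=8, n_prob=0.05, ragged=False)
            done = _resolve_clusters("X*01", "S1", reads, len(reads),
                                     ident=0.999, cons_freq=0.6,
                                     min_members=1, min_freq=0.0)
            for clu in done:
                members = [reads[i] for i in clu.members]
                assert any(agrees(clu.consensus, m) for m in members)


class TestAssemble:
    def test_uniform_cohort_single_record(self):
        per_sample = pd.DataFrame({
            "allele": ["X*01"] * 5,
            "sample_id": [f"S{i}" for i in range(5)],
            "sequence": ["TTACG"] * 5,
        })
        records = assemble_cohort_db(per_sample)
        assert len(records) == 1
        assert records[0].n_individuals == 5
        assert records[0].start_coordinate == -5

    def test_trims_to_shortest_and_collapses(self):
        per_sample = pd.DataFrame({
            "allele": ["X*01"] * 3,
            "sample_id": ["S1", "S2", "S3"],
            "sequence": ["GGTTACG", "TTACG", "TACG"],
        })
        records = assemble_cohort_db(per_sample)
        assert [r.sequence for r in records] == ["TACG"]
        assert records[0].n_individuals == 3

    def test_variant_order_by_carrier_count(self):
        per_sample = pd.DataFrame({
            "allele": ["X*01"] * 4,
            "sample_id": ["S1", "S2", "S3", "S3"],
            "sequence": ["AAAA", "AAAA", "AAAA", "CCCC"],
        })
        records = assemble_cohort_db(per_sample)
        assert [(r.variant_index, r.sequence, r.n_individuals) for r in records] == \
            [(1, "AAAA", 3), (2, "CCCC", 1)]
        assert records[0].name == "X*01_1"

    def test_invariant_to_sample_order(self):
        rng = np.random.default_rng(3)
        per_sample = pd.DataFrame({
            "allele": ["X*01"] * 6 + ["Y*01"] * 4,
            "sample_id": [f"S{i}" for i in range(10)],
            "sequence": ["AAAA", "CCCC", "AAAA", "AAAA", "CCCC", "AAAA",
                         "GGG", "GGG", "TTT", "GGG"],
        })
        base = assemble_cohort_db(per_sample)
        shuffled = per_sample.sample(frac=1.0, random_state=5)
        assert assemble_cohort_db(shuffled) == base


class TestPipeline:
    def _run(self, db, cmap, config):
        table, truth = ik.simulate_cohort(config)
        analysis = ik.select_analysis_reads(ik.collapse_vcalls(table, cmap), db, cmap=cmap)
        records, per_sample = infer_upstream_db(analysis, db)
        return table, truth, records, per_sample

    def test_zero_noise_records_are_truth_haplotypes(self, db, cmap, zero_noise_cohort):
        config, table, truth = zero_noise_cohort
        analysis = ik.select_analysis_reads(ik.collapse_vcalls(table, cmap), db, cmap=cmap)
        records, _ = infer_upstream_db(analysis, db)
        assert records, "pipeline produced no records"
        for r in records:
            sources = [r.allele]
            for rule in cmap.rules:
                if rule.collapsed == r.allele:
                    sources = sorted(rule.labels)
            assert any(truth.truth_db[s].upstream.endswith(r.sequence) for s in sources)

    def test_two_haplotype_allele_yields_two_records(self, db, cmap):
        base = db["IGHV4-59*01"].upstream
        variant = base[:20] + ("A" if base[20] != "A" else "C") + base[21:]
        config = ik.SimConfig(
            germline_db=db, n_individuals=8,
            depth=ik.DepthLaw(kind="fixed", depth=600),
            mutation_probs=(1.0,), error_rate=0.0,
            upstream_variants={"IGHV4-59*01": [(base, 0.5), (variant, 0.5)]},
            seed=31)
        table, truth, records, _ = None, None, None, None
        table, truth = ik.simulate_cohort(config)
        analysis = ik.select_analysis_reads(ik.collapse_vcalls(table, cmap), db, cmap=cmap)
        records, _ = infer_upstream_db(analysis, db)
        recs = [r for r in records if r.allele == "IGHV4-59*01"]
        true_haps = {truth.upstream_haplotypes[s]["IGHV4-59*01"]
                     for s in truth.upstream_haplotypes
                     if "IGHV4-59*01" in truth.upstream_haplotypes[s]}
        assert len(recs) == len(true_haps)
        carriers_by_hap = {}
        for s, haps in truth.upstream_haplotypes.items():
            if "IGHV4-59*01" in haps:
                carriers_by_hap.setdefault(haps["IGHV4-59*01"], set()).add(s)
        for r in recs:
            matching = [h for h in true_haps if h.endswith(r.sequence)]
            assert len(matching) == 1
            assert r.carriers == frozenset(carriers_by_hap[matching[0]])

    def test_leader_segment_lengths_preserved(self, db, cmap, zero_noise_cohort):
        _, table, truth = zero_noise_cohort
        analysis = ik.select_analysis_reads(ik.collapse_vcalls(table, cmap), db, cmap=cmap)
        records, _ = infer_upstream_db(analysis, db)
        for r in records:
            allele = r.allele if r.allele in truth.truth_db else None
            if allele is None or len(r.sequence) < 55:
                continue
            a = truth.truth_db[allele]
            assert r.sequence[-10:] == a.l_part2
            assert r.sequence[-55:-10] == a.l_part1

    def test_duplicated_identical_alleles_not_merged(self, db, cmap, zero_noise_cohort):
        _, table, truth = zero_noise_cohort
        analysis = ik.select_analysis_reads(ik.collapse_vcalls(table, cmap), db, cmap=cmap)
        records, _ = infer_upstream_db(analysis, db)
        merged = [r for r in records if r.allele == "IGHV3-23*01D"]
        assert len(merged) == 2  # one upstream variant per source gene
        assert {r.sequence for r in merged} == {
            truth.truth_db["IGHV3-23*01"].upstream[-len(merged[0].sequence):],
            truth.truth_db["IGHV3-23D*01"].upstream[-len(merged[0].sequence):],
        }
        v64 = {r.allele for r in records if r.allele.startswith("IGHV3-64")}
        assert {"IGHV3-64*05", "IGHV3-64D*06"} <= v64

    def test_idempotent_on_its_own_output(self, db, cmap, zero_noise_cohort):
        _, table, _ = zero_noise_cohort
        analysis = ik.select_analysis_reads(ik.collapse_vcalls(table, cmap), db, cmap=cmap)
        records, per_sample = infer_upstream_db(analysis, db)
        rows = []
        for _, row in per_sample.iterrows():
            for i in range(20):
                rows.append({
                    "sequence": row["sequence"] + "ACGTACGT",
                    "v_call": row["allele"],
                    "v_sequence_start": len(row["sequence"]) + 1,
                    "sample_id": row["sample_id"],
                    "batch_id": "B1",
                })
        regenerated = pd.DataFrame(rows)
        records2, _ = infer_upstream_db(regenerated, db)
        assert [(r.allele, r.sequence, r.carriers) for r in records2] == \
            [(r.allele, r.sequence, r.carriers) for r in records]

    def test_long_format_output(self, db, cmap, zero_noise_cohort):
        _, table, _ = zero_noise_cohort
        analysis = ik.select_analysis_reads(ik.collapse_vcalls(table, cmap), db, cmap=cmap)
        records, _ = infer_upstream_db(analysis, db)
        long = upstream_db_long(records)
        assert set(long.columns) == {"position", "allele_variant", "base"}
        assert (long["position"] < 0).all()
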