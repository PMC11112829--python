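import numpy as np
import pytest

from cdh_prospector import align, curation
from cdh_prospector.curation import (CladeAssignment, anchor_to_reference,
                                     build_logo, clades_from_tree,
                                     curate_dataset, evaluate_record,
                                     predict_signal_peptide,
                                     reduce_redundancy, select_candidates,
                                     split_domains, trim_alignment_columns)
from cdh_prospector.seqio import ProteinRecord
from cdh_prospector.synthetic_data import (FamilySpec, FeaturePlan,
                                           generate_family, generate_tree)


class TestAnchoring:
    def test_reference_self_anchoring_is_identity(self, reference):
        result = anchor_to_reference(reference.reference, reference)
        assert result.anchorable and result.identity == 1.0
        assert result.landmarks["catalytic_his"] == 689
        assert result.landmarks["heme_met"] == 65
        assert result.landmarks["heme_his"] == 163

    def test_deletion_shifts_mapped_positions(self, reference):
        # remove 10 residues upstream of the heme Met: it must map 10 left
        seq = reference.reference.sequence
        query = ProteinRecord("del10", seq[:30] + seq[40:])
        result = anchor_to_reference(query, reference)
        assert result.landmarks["heme_met"] == 55
        assert query.sequence[55 - 1] == "M"

    def test_random_sequences_are_unanchorable(self, reference):
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for seed in range(10):
            rng = np.random.default_rng(seed)
            query = ProteinRecord(f"rnd{seed}",
                                  "".join(rng.choice(aas, 770)))
            assert not anchor_to_reference(query, reference).anchorable

    def test_short_query_rejected(self, reference):
        with pytest.raises(ValueError):
            anchor_to_reference(ProteinRecord("s", "MKVL"), reference)


class TestSignalPeptide:
    def test_planted_leaders_recovered(self):
        # >= 95 % recall over 200 independently sampled leaders
        spec = FamilySpec(n_classes=2, members_per_class=100,
                          within_identity=0.92, between_identity=0.85,
                          seed=11)
        records, _ = generate_family(spec)
        hits = sum(predict_signal_peptide(r).passed for r in records)
        assert hits / len(records) >= 0.95

    def test_ablated_leaders_rejected(self):
        overrides = {f"cls1_m{i + 1:03d}": FeaturePlan(signal_peptide=False)
                     for i in range(50)}
        spec = FamilySpec(n_classes=1, members_per_class=50,
                          within_identity=0.92, between_identity=0.85,
                          seed=12, feature_overrides=overrides)
        records, _ = generate_family(spec)
        assert not any(predict_signal_peptide(r).passed for r in records)

    def test_poly_aspartate_nterm_fails(self):
        call = predict_signal_peptide(ProteinRecord("d", "M" + "D" * 40))
        assert not call.passed
        assert "h-region" in call.reason

    def test_short_sequence_fails_with_reason(self):
        call = predict_signal_peptide(ProteinRecord("s", "MKWVTFISLL"))
        assert not call.passed and call.reason == "too short"


class TestCriteria:
    def test_reference_passes_every_criterion(self, reference):
        report = evaluate_record(reference.reference, reference)
        assert report.verdict == "kept"
        assert all(v == "pass" for v in report.flags.values())

    def test_single_planted_violation_flags_only_that_criterion(
            self, reference):
        overrides = {"cls1_m002": FeaturePlan(catalytic_his=False)}
        records, _ = generate_family(FamilySpec(
            n_classes=1, members_per_class=2, within_identity=0.92,
            between_identity=0.8, seed=31, feature_overrides=overrides))
        good = evaluate_record(records[0], reference)
        bad = evaluate_record(records[1], reference)
        assert good.verdict == "kept"
        assert bad.verdict == "excluded"
        assert bad.reasons == ["has_catalytic_his"]

    def test_dh_only_truncation_fails_cyt_criteria(self, reference):
        seq = reference.reference.sequence
        truncated = ProteinRecord("dh_only", seq[229:])
        report = evaluate_record(truncated, reference)
        assert report.verdict == "excluded"
        assert "has_cyt_domain" in report.reasons
        assert "has_heme_ligands" in report.reasons

    def test_unanchorable_query_reports_unknown_flags(self, reference):
        rng = np.random.default_rng(3)
        query = ProteinRecord(
            "rnd", "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 770)))
        report = evaluate_record(query, reference)
        assert report.verdict == "excluded"
        assert report.reasons == ["unanchorable"]
        assert report.flags["has_catalytic_his"] == "unknown"

    def test_external_predictor_call_overrides_heuristic(self, reference):
        report = evaluate_record(reference.reference, reference,
                                 sp_call=False)
        assert report.flags["has_signal_peptide"] == "fail"
        assert report.verdict == "excluded"


class TestCurateDataset:
    def test_planted_pass_fail_split(self, reference):
        ablations = {
            "cls1_m001": FeaturePlan(rossmann=False),
            "cls1_m002": FeaturePlan(heme_ligands=False),
            "cls1_m003": FeaturePlan(catalytic_his=False),
            "cls1_m004": FeaturePlan(signal_peptide=False),
            "cls1_m005": FeaturePlan(ydy=False),  # ydy is not a criterion
        }
        records, truth = generate_family(FamilySpec(
            n_classes=1, members_per_class=25, within_identity=0.92,
            between_identity=0.8, seed=33, feature_overrides=ablations))
        kept, reports, tallies = curate_dataset(records, reference)
        kept_acc = {r.accession for r in kept}
        assert kept_acc == {r.accession for r in records} - {
            "cls1_m001", "cls1_m002", "cls1_m003", "cls1_m004"}
        by_acc = {r.accession: r for r in reports}
        assert by_acc["cls1_m001"].reasons == ["has_rossmann"]
        assert by_acc["cls1_m002"].reasons == ["has_heme_ligands"]
        assert tallies["has_catalytic_his"] == 1

    def test_empty_input(self, reference):
        kept, reports, _ = curate_dataset([], reference)
        assert kept == [] and reports == []

    def test_verdicts_are_order_independent(self, reference, small_family):
        records, _ = small_family
        _, fwd, _ = curate_dataset(records, reference)
        _, rev, _ = curate_dataset(records[::-1], reference)
        assert {r.accession: r.verdict for r in fwd} == \
            {r.accession: r.verdict for r in rev}


class TestRedundancy:
    def test_identical_pair_collapses(self):
        a = ProteinRecord("a", "MKVLSTAG" * 40)
        b = ProteinRecord("b", "MKVLSTAG" * 40)
        clusters = reduce_redundancy([a, b])
        assert len(clusters) == 1
        assert clusters[0].members == ["a", "b"]

    def test_threshold_one_keeps_distinct_records(self):
        rng = np.random.default_rng(4)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        records = [ProteinRecord(f"r{i}", "".join(rng.choice(aas, 200)))
                   for i in range(5)]
        assert len(reduce_redundancy(records, 1.0)) == 5

    def test_planted_cluster_count_recovered(self):
        spec = FamilySpec(n_classes=10, members_per_class=5,
                          within_identity=0.996, between_identity=0.85,
                          root="random", ancestor_length=300, seed=44,
                          vary_signal_peptides=False)
        records, _ = generate_family(spec)
        clusters = reduce_redundancy(records, 0.99)
        assert len(clusters) == 10
        # no two representatives may remain redundant
        for i, ci in enumerate(clusters):
            for cj in clusters[i + 1:]:
                ident = align.global_identity(
                    ci.representative.sequence, cj.representative.sequence)
                assert ident < 0.99

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            reduce_redundancy([], 0.0)


class TestTrim:
    def test_boundary_gap_fraction_removed(self):
        rows = ["A-" + "C" * 3] * 9 + ["AA" + "C" * 3]
        trimmed, removed = trim_alignment_columns(rows, 0.9)
        assert removed == [1]
        assert trimmed[0] == "ACCC"

    def test_gap_free_alignment_unchanged(self):
        rows = ["ACDEF", "ACDEF", "ACDEG"]
        trimmed, removed = trim_alignment_columns(rows)
        assert trimmed == rows and removed == []

    def test_random_alignment_matches_recount(self):
        rng = np.random.default_rng(9)
        rows = ["".join(rng.choice(list("AC-"), 60, p=[0.3, 0.2, 0.5]))
                for _ in range(12)]
        trimmed, removed = trim_alignment_columns(rows, 0.75)
        expected = [j for j in range(60)
                    if sum(r[j] == "-" for r in rows) / 12 >= 0.75]
        assert removed == expected
        assert all(len(t) == 60 - len(removed) for t in trimmed)

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError):
            trim_alignment_columns(["AC", "A"])


class TestLogo:
    def test_perfectly_conserved_column(self, reference):
        records = [ProteinRecord(f"c{i}", reference.reference.sequence)
                   for i in range(4)]
        logo = build_logo(records, reference, (689, 689))
        assert logo.information[0] == pytest.approx(np.log2(20))
        assert logo.frequencies[0].max() == 1.0

    def test_planted_fifty_fifty_column_gives_one_bit(self, reference):
        seq = list(reference.reference.sequence)
        records = []
        for i in range(10):
            seq[500 - 1] = "D" if i < 5 else "S"
            records.append(ProteinRecord(f"v{i}", "".join(seq)))
        logo = build_logo(records, reference, (500, 500))
        d = logo.frequencies[0][curation.AMINO_ACIDS.index("D")]
        s = logo.frequencies[0][curation.AMINO_ACIDS.index("S")]
        assert d == pytest.approx(0.5) and s == pytest.approx(0.5)
        assert logo.information[0] == pytest.approx(np.log2(20) - 1.0)

    def test_frequencies_sum_to_one(self, reference, small_family):
        records, _ = small_family
        logo = build_logo(records, reference, (680, 700))
        sums = logo.frequencies.sum(axis=1)
        covered = logo.coverage > 0
        assert np.allclose(sums[covered], 1.0, atol=1e-9)
        assert np.all((logo.information >= -1e-9)
                      & (logo.information <= np.log2(20) + 1e-9))

    def test_region_outside_reference_rejected(self, reference):
        with pytest.raises(ValueError):
            build_logo([], reference, (0, 10))


class TestSplitDomains:
    def test_reference_split_matches_annotation(self, reference):
        split = split_domains(reference.reference, reference)
        assert split.dh_start == reference.dh_region[0]
        assert split.sp == (1, 18)
        assert split.cyt[1] == reference.cyt_region[1]
        assert not split.fallback

    def test_dh_starts_eight_before_ydy(self, reference, small_family):
        records, truth = small_family
        ydy_start = truth.data["layout"]["ydy"][0]
        for rec in records:
            split = split_domains(rec, reference)
            assert split.dh_start == ydy_start - 8
            assert rec.sequence[split.dh_start + 7:split.dh_start + 10] \
                == "YDY"

    def test_missing_ydy_falls_back_to_mapped_dh_start(self, reference):
        records, _ = generate_family(FamilySpec(
            n_classes=1, members_per_class=1, within_identity=0.92,
            between_identity=0.8, seed=35,
            feature_overrides={"cls1_m001": FeaturePlan(ydy=False)}))
        split = split_domains(records[0], reference)
        assert split.fallback
        assert split.dh_start == 230


class TestClades:
    def test_star_tree_with_zero_lengths_is_one_clade(self):
        assert clades_from_tree("(A:0,B:0,C:0);", 0.4).n_clades == 1

    def test_hand_built_two_subtree_tree(self):
        nwk = ("((A:0.05,B:0.05,C:0.05):0.5,"
               "(D:0.05,E:0.05,F:0.05):0.5);")
        assignment = clades_from_tree(nwk, 0.4)
        assert assignment.n_clades == 2
        clades = list(assignment.clades.values())
        assert sorted(map(tuple, clades)) == [("A", "B", "C"),
                                              ("D", "E", "F")]

    def test_threshold_above_diameter_gives_one_clade(self):
        nwk = "((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1);"
        assert clades_from_tree(nwk, 10.0).n_clades == 1

    def test_missing_branch_lengths_rejected(self):
        with pytest.raises(ValueError, match="branch length"):
            clades_from_tree("((A:0.1,B),C:0.2);", 0.4)

    def test_planted_clades_recovered(self):
        groups = [[f"c{i + 1}_t{j + 1}" for j in range(4)]
                  for i in range(11)]
        nwk, truth = generate_tree(groups, seed=4)
        assignment = clades_from_tree(nwk, 0.4)
        assert assignment.n_clades == 11
        planted = truth.data["assignment"]
        recovered = {frozenset(m) for m in assignment.clades.values()}
        expected = {frozenset(l for l, c in planted.items() if c == cl)
                    for cl in set(planted.values())}
        assert recovered == expected

    def test_outgroups_pruned(self):
        nwk = ("((A:0.05,B:0.05):0.5,(C:0.05,D:0.05):0.5,OG:2.0);")
        assignment = clades_from_tree(nwk, 0.4, outgroups={"OG"})
        assert "OG" not in assignment.assignment
        assert assignment.n_clades == 2

    def test_clade_count_non_increasing_in_threshold(self):
        groups = [[f"g{i}_l{j}" for j in range(3)] for i in range(6)]
        nwk, _ = generate_tree(groups, seed=8)
        counts = [clades_from_tree(nwk, t).n_clades
                  for t in (0.1, 0.4, 0.7, 2.0)]
        assert counts == sorted(counts, reverse=True)


class TestSelectCandidates:
    def _records(self, planted):
        return [ProteinRecord(acc, "M" * 100, lifestyle=ls)
                for acc, ls in planted]

    def test_priority_members_forced(self):
        assignment = CladeAssignment(
            {"a1": "c1", "a2": "c1", "b1": "c2", "b2": "c2"}, 0.4,
            frozenset())
        records = self._records([("a1", None), ("a2", "plant-associated"),
                                 ("b1", "plant-associated"), ("b2", None)])
        chosen = select_candidates(assignment, records)
        assert [r.accession for r in chosen] == ["a2", "b1"]

    def test_tie_break_is_alphabetical(self):
        assignment = CladeAssignment({"z": "c1", "a": "c1"}, 0.4,
                                     frozenset())
        chosen = select_candidates(assignment,
                                   self._records([("z", None), ("a", None)]))
        assert [r.accession for r in chosen] == ["a"]

    def test_eleven_clades_give_eleven_candidates(self):
        groups = [[f"c{i + 1}_t{j + 1}" for j in range(4)]
                  for i in range(11)]
        nwk, truth = generate_tree(groups, seed=4)
        assignment = clades_from_tree(nwk, 0.4)
        records = self._records([(l, None)
                                 for l in truth.data["assignment"]])
        assert len(select_candidates(assignment, records)) == 11
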