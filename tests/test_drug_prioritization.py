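"""Recalibration (harmonic mean of process p-values) and drug priority scoring."""

import numpy as np
import pandas as pd
import pytest

from gopriorit.activity_matrix import QueryDataset, build_activity_matrix
from gopriorit.drug_prioritization import (
    harmonic_mean,
    prioritize_drugs,
    recalibrate_all,
    recalibrate_gene,
    render_stratification,
    sensitive_samples,
)
from gopriorit.knowledge_base import (
    DrugTarget,
    GORegulation,
    KnowledgeBase,
    Study,
    StudySet,
)


def go_results(pmap):
    return pd.DataFrame(
        {"process_id": list(pmap), "p_value": list(pmap.values())}
    )


class TestHarmonicMean:
    def test_equal_pvalues_return_that_value_exactly(self):
        assert harmonic_mean([0.01, 0.01, 0.01]) == pytest.approx(0.01, abs=0)

    def test_worked_two_value_example(self):
        assert harmonic_mean([0.1, 0.001]) == pytest.approx(2 / (10 + 1000), abs=1e-12)

    def test_bounded_by_min_and_max(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            p = rng.uniform(1e-6, 1, rng.integers(1, 20))
            h = harmonic_mean(p)
            assert p.min() - 1e-15 <= h <= p.max() + 1e-15

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValueError):
            harmonic_mean([0.1, 0.0])


class TestRecalibration:
    def test_score_is_negative_log10_of_harmonic_mean(self):
        regs = [GORegulation("g", "GO:0000001", "positive"),
                GORegulation("g", "GO:0000002", "negative")]
        rec = recalibrate_gene("g", regs, go_results({"GO:0000001": 0.01, "GO:0000002": 0.01}))
        assert rec["harmonic_mean_p"] == pytest.approx(0.01)
        assert rec["score"] == pytest.approx(2.0)

    def test_bidirectional_process_excluded_as_ambiguous(self):
        regs = [
            GORegulation("g", "GO:0000001", "positive"),
            GORegulation("g", "GO:0000001", "negative"),
            GORegulation("g", "GO:0000002", "positive"),
        ]
        rec = recalibrate_gene("g", regs, go_results({"GO:0000001": 1e-9, "GO:0000002": 0.5}))
        assert rec["n_processes_used"] == 1
        assert rec["n_processes_ambiguous"] == 1
        assert rec["harmonic_mean_p"] == pytest.approx(0.5)

    def test_unambiguous_direction_counts_add_up(self):
        # nine positive and eight negative processes, no overlap -> 17 used
        regs = [GORegulation("g", f"GO:{i:07d}", "positive") for i in range(1, 10)]
        regs += [GORegulation("g", f"GO:{i:07d}", "negative") for i in range(10, 18)]
        pmap = {f"GO:{i:07d}": 0.05 for i in range(1, 18)}
        rec = recalibrate_gene("g", regs, go_results(pmap))
        assert rec["n_processes_used"] == 17

    def test_gene_with_no_usable_process_unscorable(self):
        regs = [GORegulation("g", "GO:0000001", "positive"),
                GORegulation("g", "GO:0000001", "negative")]
        assert recalibrate_gene("g", regs, go_results({"GO:0000001": 0.1})) is None

    def test_process_count_independence_given_equal_pvalues(self):
        p = 0.0123
        small = [GORegulation("a", f"GO:{i:07d}", "positive") for i in range(2)]
        large = [GORegulation("b", f"GO:{i:07d}", "positive") for i in range(100, 300)]
        pmap = {r.process_id: p for r in small + large}
        rec_a = recalibrate_gene("a", small, go_results(pmap))
        rec_b = recalibrate_gene("b", large, go_results(pmap))
        assert rec_a["harmonic_mean_p"] == rec_b["harmonic_mean_p"] == pytest.approx(p)


def drug_kb(targets, regulations=None):
    genes = sorted({t[1] for t in targets})
    return KnowledgeBase(
        studies={"s": Study("s", {g: i + 1 for i, g in enumerate(genes)})},
        study_sets={"set": StudySet("set", ["s"])},
        regulations=regulations or [],
        drug_targets=[DrugTarget(d, g, action=a) for d, g, a in targets],
    )


def activity_from_statuses(statuses: dict[str, list[str]], samples: list[str]):
    expr_map = {"active": "up", "inactive": "down", "unchanged": "unchanged"}
    expr = pd.DataFrame(
        {s: [expr_map[statuses[g][i]] for g in sorted(statuses)] for i, s in enumerate(samples)},
        index=sorted(statuses),
    )
    empty = pd.DataFrame(index=pd.Index([], dtype=object), columns=samples)
    return build_activity_matrix(QueryDataset(expression=expr, cna=empty, mutation=empty))


def recal_frame(scores: dict[str, float]):
    return pd.DataFrame(
        {
            "gene_id": list(scores),
            "harmonic_mean_p": [10 ** -s for s in scores.values()],
            "score": list(scores.values()),
            "n_processes_used": 1,
            "n_processes_ambiguous": 0,
        }
    )


class TestPrioritizeDrugs:
    def test_worked_score_one_altered_of_two_targets(self):
        kb = drug_kb([("d1", "gA", "inhibitor"), ("d1", "gB", "inhibitor")])
        am = activity_from_statuses(
            {"gA": ["active", "active", "unchanged", "unchanged"],
             "gB": ["unchanged"] * 4},
            ["s1", "s2", "s3", "s4"],
        )
        out = prioritize_drugs(kb, recal_frame({"gA": 3.0, "gB": 1.0}), am)
        assert len(out) == 1
        assert out.loc[0, "score"] == pytest.approx(3.0 * 0.5 / 2)
        assert out.loc[0, "n_altered_targets"] == 1

    def test_per_altered_targets_mode_changes_denominator(self):
        kb = drug_kb([("d1", "gA", "inhibitor"), ("d1", "gB", "inhibitor")])
        am = activity_from_statuses(
            {"gA": ["active"] * 2 + ["unchanged"] * 2, "gB": ["unchanged"] * 4},
            ["s1", "s2", "s3", "s4"],
        )
        recal = recal_frame({"gA": 3.0, "gB": 1.0})
        per_total = prioritize_drugs(kb, recal, am, drug_score_mode="per_total_targets")
        per_altered = prioritize_drugs(kb, recal, am, drug_score_mode="per_altered_targets")
        assert per_altered.loc[0, "score"] == pytest.approx(2 * per_total.loc[0, "score"])

    def test_drug_without_altered_targets_omitted(self):
        kb = drug_kb([("d1", "gA", "inhibitor"), ("d2", "gB", "inhibitor")])
        am = activity_from_statuses(
            {"gA": ["active", "unchanged"], "gB": ["unchanged", "unchanged"]}, ["s1", "s2"]
        )
        out = prioritize_drugs(kb, recal_frame({"gA": 1.0, "gB": 1.0}), am)
        assert list(out["drug_id"]) == ["d1"]

    def test_unscored_target_not_eligible(self):
        kb = drug_kb([("d1", "gA", "inhibitor")])
        am = activity_from_statuses({"gA": ["active", "active"]}, ["s1", "s2"])
        out = prioritize_drugs(kb, recal_frame({}), am)
        assert out.empty

    def test_activator_requires_inactive_status(self):
        kb = drug_kb([("d1", "gA", "activator")])
        am = activity_from_statuses({"gA": ["inactive", "unchanged"]}, ["s1", "s2"])
        out = prioritize_drugs(kb, recal_frame({"gA": 2.0}), am)
        assert out.loc[0, "score"] == pytest.approx(2.0 * 0.5 / 1)

    def test_identical_drugs_tie_broken_by_drug_id(self):
        kb = drug_kb([("dB", "gA", "inhibitor"), ("dA", "gA", "inhibitor")])
        am = activity_from_statuses({"gA": ["active", "unchanged"]}, ["s1", "s2"])
        out = prioritize_drugs(kb, recal_frame({"gA": 1.0}), am)
        assert list(out["drug_id"]) == ["dA", "dB"]
        assert out.loc[0, "score"] == out.loc[1, "score"]

    def test_empty_drug_table_gives_empty_ranking(self):
        kb = KnowledgeBase(
            studies={"s": Study("s", {"g": 1})},
            study_sets={"set": StudySet("set", ["s"])},
        )
        am = activity_from_statuses({"g": ["active"]}, ["s1"])
        assert prioritize_drugs(kb, recal_frame({"g": 1.0}), am).empty

    def test_lowering_a_process_p_never_decreases_any_drug_score(self):
        regs = [
            GORegulation("gA", "GO:0000001", "positive"),
            GORegulation("gB", "GO:0000002", "positive"),
        ]
        kb = drug_kb(
            [("d1", "gA", "inhibitor"), ("d2", "gB", "inhibitor")], regulations=regs
        )
        am = activity_from_statuses(
            {"gA": ["active", "unchanged"], "gB": ["active", "active"]}, ["s1", "s2"]
        )
        base_p = {"GO:0000001": 0.2, "GO:0000002": 0.4}
        base = prioritize_drugs(kb, recalibrate_all(kb, go_results(base_p)), am)
        improved = prioritize_drugs(
            kb, recalibrate_all(kb, go_results({**base_p, "GO:0000001": 0.01})), am
        )
        merged = base.set_index("drug_id")["score"].align(
            improved.set_index("drug_id")["score"]
        )
        assert (merged[1] >= merged[0] - 1e-12).all()


class TestSensitiveSamples:
    def test_single_target_strata(self):
        kb = drug_kb([("d1", "gA", "inhibitor")])
        am = activity_from_statuses({"gA": ["active", "unchanged", "active"]}, ["s1", "s2", "s3"])
        assert sensitive_samples("d1", kb, am) == {"s1", "s3"}

    def test_union_over_multiple_targets(self):
        kb = drug_kb([("d1", "gA", "inhibitor"), ("d1", "gB", "inhibitor")])
        am = activity_from_statuses(
            {"gA": ["active", "unchanged"], "gB": ["unchanged", "active"]}, ["s1", "s2"]
        )
        assert sensitive_samples("d1", kb, am) == {"s1", "s2"}

    def test_drugs_with_identical_eligible_targets_share_samples(self):
        kb = drug_kb([("d1", "gA", "inhibitor"), ("d2", "gA", "inhibitor")])
        am = activity_from_statuses({"gA": ["active", "unchanged"]}, ["s1", "s2"])
        recal = recal_frame({"gA": 1.0})
        assert sensitive_samples("d1", kb, am, recal=recal) == sensitive_samples(
            "d2", kb, am, recal=recal
        )

    def test_unknown_drug_rejected(self):
        kb = drug_kb([("d1", "gA", "inhibitor")])
        am = activity_from_statuses({"gA": ["active"]}, ["s1"])
        with pytest.raises(KeyError, match="nope"):
            sensitive_samples("nope", kb, am)

    def test_matches_prioritize_drugs_sample_sets(self):
        kb = drug_kb([("d1", "gA", "inhibitor"), ("d1", "gB", "inhibitor")])
        am = activity_from_statuses(
            {"gA": ["active", "unchanged"], "gB": ["unchanged", "active"]}, ["s1", "s2"]
        )
        recal = recal_frame({"gA": 1.0, "gB": 2.0})
        out = prioritize_drugs(kb, recal, am)
        listed = set(out.loc[0, "sensitive_samples"].split(";"))
        assert listed == sensitive_samples("d1", kb, am, recal=recal)


class TestRenderStratification:
    def setup_table(self, annotations=None):
        kb = drug_kb([("d1", "gA", "inhibitor")])
        am = activity_from_statuses(
            {"gA": ["active", "unchanged", "active", "unchanged"],
             "gB": ["inactive", "unchanged", "unchanged", "active"]},
            ["s1", "s2", "s3", "s4"],
        )
        return render_stratification(
            am, ["d1"], ["gA", "gB"], annotations, kb=kb, recal=recal_frame({"gA": 1.0})
        )

    def test_table_shape_rows_by_samples(self):
        table = self.setup_table()
        assert table.shape == (3, 4)
        assert list(table.index) == ["drug:d1", "gene:gA", "gene:gB"]

    def test_sensitive_samples_ordered_first(self):
        table = self.setup_table()
        assert list(table.loc["drug:d1"]) == ["sensitive", "sensitive", "insensitive", "insensitive"]
        assert list(table.columns) == ["s1", "s3", "s2", "s4"]

    def test_annotations_appended_and_order_stable(self):
        ann = pd.DataFrame({"subtype": ["lumA", "lumB", "basal", "lumA"]},
                           index=["s1", "s2", "s3", "s4"])
        t1 = self.setup_table(ann)
        t2 = self.setup_table(ann)
        assert "annotation:subtype" in t1.index
        pd.testing.assert_frame_equal(t1, t2)

    def test_missing_annotation_sample_rejected(self):
        ann = pd.DataFrame({"subtype": ["lumA"]}, index=["s1"])
        with pytest.raises(KeyError, match="s2"):
            self.setup_table(ann)
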