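"""Sequential rule-block classifiers and their evaluation."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from vestibattery.algorithms import (
    Criterion,
    DiagnosticAlgorithm,
    IncompleteRecordError,
    RuleBlock,
    aggregate_overall,
    build_blocks,
    classify,
    default_blocks,
    enumerate_algorithms,
    evaluate,
    recalls_to_counts,
)
from vestibattery.reference import (
    ALGORITHM_ORDERS,
    BATTERY_THRESHOLDS,
    RECONSTRUCTED_SIZES,
    REPORTED_OVERALL,
    REPORTED_RECALLS,
)

COMPLETE = {
    "NPQ_visual": 5, "NPQ_total": 20, "HADS_anxiety": 5, "age": 60,
    "CP_percent": 10.0, "cus_present": False,
}


def record(**overrides):
    return {**COMPLETE, **overrides}


class TestBlocks:
    def test_default_blocks_encode_published_rules(self):
        pppd, uvh, cda = default_blocks()
        assert {c.item for c in pppd.criteria} == {"NPQ_total", "NPQ_visual"}
        assert uvh.is_positive(record(CP_percent=19.8))  # >= 19.8 fires
        assert uvh.is_positive(record(cus_present=True))
        assert not uvh.is_positive(record(CP_percent=19.7))
        age_crit = [c for c in cda.criteria if c.item == "age"][0]
        assert age_crit.direction == "lt" and age_crit.threshold == 48.5

    def test_all_combinator_requires_both(self):
        _, uvh, _ = default_blocks(combinator="ALL")
        assert not uvh.is_positive(record(CP_percent=60.0, cus_present=False))
        assert uvh.is_positive(record(CP_percent=60.0, cus_present=True))

    def test_build_blocks_accepts_roc_analyses(self, cohort):
        from vestibattery.roc import derive_battery

        blocks = build_blocks(derive_battery(cohort))
        assert {b.disease for b in blocks} == {"PPPD", "UVH", "CDA"}

    def test_missing_battery_entry_rejected(self):
        partial = {k: v for k, v in BATTERY_THRESHOLDS.items() if k != "age"}
        with pytest.raises(KeyError):
            build_blocks(partial)

    def test_empty_block_rejected(self):
        with pytest.raises(ValueError):
            RuleBlock("PPPD", ())


class TestEnumeration:
    def test_six_algorithms_in_published_order(self):
        algos = enumerate_algorithms(default_blocks())
        assert len(algos) == 6
        for n, order in ALGORITHM_ORDERS.items():
            assert tuple(b.disease for b in algos[n].blocks) == order
        # 1 and 2 share the PPPD-first block
        assert algos[1].blocks[0] is algos[2].blocks[0]
        assert algos[1].blocks[0].disease == "PPPD"

    def test_duplicate_disease_rejected(self):
        p, u, _ = default_blocks()
        with pytest.raises(ValueError):
            DiagnosticAlgorithm("bad", (p, p, u))


class TestClassify:
    def test_first_positive_block_wins(self):
        algos = enumerate_algorithms(default_blocks())
        r = record(NPQ_visual=13, NPQ_total=38, CP_percent=10, HADS_anxiety=5, age=50)
        assert classify(r, algos[1]) == "PPPD"

    def test_fallback_is_ud(self):
        algos = enumerate_algorithms(default_blocks())
        for n in range(1, 7):
            assert classify(COMPLETE, algos[n]) == "UD"

    def test_order_dependence(self):
        algos = enumerate_algorithms(default_blocks())
        r = record(CP_percent=60.0, NPQ_total=40)
        assert classify(r, algos[1]) == "PPPD"
        assert classify(r, algos[3]) == "UVH"

    def test_missing_required_item_excluded(self):
        algos = enumerate_algorithms(default_blocks())
        r = record(CP_percent=float("nan"))
        with pytest.raises(IncompleteRecordError):
            classify(r, algos[1])
        assert classify(r, algos[1], missing_policy="missing_negative") == "UD"

    def test_missing_cus_is_negative_not_exclusion(self):
        algos = enumerate_algorithms(default_blocks())
        r = record(cus_present=None)
        assert classify(r, algos[3]) == "UD"
        assert classify(record(cus_present=True), algos[3]) == "UVH"

    @given(
        st.integers(min_value=0, max_value=24),
        st.integers(min_value=0, max_value=72),
        st.integers(min_value=0, max_value=21),
        st.integers(min_value=10, max_value=90),
        st.floats(min_value=0, max_value=100),
        st.booleans(),
        st.integers(min_value=1, max_value=6),
    )
    def test_total_on_complete_records(self, vis, tot, anx, age, cp, cus, n):
        """Every complete record gets exactly one of the four diagnoses."""
        algos = enumerate_algorithms(default_blocks())
        r = {"NPQ_visual": vis, "NPQ_total": tot, "HADS_anxiety": anx,
             "age": age, "CP_percent": cp, "cus_present": cus}
        assert classify(r, algos[n]) in ("PPPD", "CDA", "UVH", "UD")

    @given(
        st.integers(min_value=0, max_value=24),
        st.integers(min_value=0, max_value=72),
        st.integers(min_value=0, max_value=21),
        st.integers(min_value=10, max_value=90),
        st.floats(min_value=0, max_value=100),
        st.booleans(),
    )
    def test_single_positive_block_order_invariant(self, vis, tot, anx, age, cp, cus):
        """A record firing exactly one block gets that diagnosis under
        every ordering."""
        blocks = default_blocks()
        algos = enumerate_algorithms(blocks)
        r = {"NPQ_visual": vis, "NPQ_total": tot, "HADS_anxiety": anx,
             "age": age, "CP_percent": cp, "cus_present": cus}
        positive = [b.disease for b in blocks if b.is_positive(r)]
        if len(positive) != 1:
            return
        for n in range(1, 7):
            assert classify(r, algos[n]) == positive[0]


def synthetic_labeled_cohort(seed, n=120):
    """Small random labeled cohort with complete battery items."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "true_diagnosis": rng.choice(["PPPD", "CDA", "UVH", "UD"], size=n),
        "NPQ_visual": rng.integers(0, 25, n),
        "NPQ_total": rng.integers(0, 73, n),
        "HADS_anxiety": rng.integers(0, 22, n),
        "age": rng.integers(15, 90, n),
        "CP_percent": rng.uniform(0, 100, n),
        "cus_present": pd.array(rng.random(n) < 0.1, dtype="boolean"),
    })


class TestEvaluate:
    def test_perfect_cohort_all_recalls_100(self):
        rows = [
            {"true_diagnosis": "PPPD", **record(NPQ_total=50)},
            {"true_diagnosis": "UVH", **record(CP_percent=60)},
            {"true_diagnosis": "CDA", **record(HADS_anxiety=15)},
            {"true_diagnosis": "UD", **record()},
        ] * 3
        df = pd.DataFrame(rows)
        algos = enumerate_algorithms(default_blocks())
        for n in range(1, 7):
            rep = evaluate(algos[n], df)
            assert all(v == 100.0 for v in rep.per_class_recall.values())
            assert rep.overall_accuracy_excl_UD == 100.0

    def test_confusion_rows_sum_to_class_counts(self, cohort):
        algos = enumerate_algorithms(default_blocks())
        rep = evaluate(algos[1], cohort)
        four = cohort[cohort["true_diagnosis"].isin(["PPPD", "CDA", "UVH", "UD"])]
        from vestibattery.cohort import complete_case_mask

        counts = four[complete_case_mask(four)]["true_diagnosis"].value_counts()
        for d in ("PPPD", "CDA", "UVH", "UD"):
            assert rep.confusion.loc[d].sum() == counts.get(d, 0)
        assert rep.n_evaluated == int(counts.sum())

    def test_ud_true_patients_outside_overall_denominator(self):
        df = pd.DataFrame(
            [{"true_diagnosis": "UD", **record()}] * 5
            + [{"true_diagnosis": "PPPD", **record(NPQ_total=50)}] * 5
        )
        algos = enumerate_algorithms(default_blocks())
        rep = evaluate(algos[1], df)
        assert rep.overall_accuracy_excl_UD == 100.0  # the 5 UD rows don't count

    @pytest.mark.parametrize("seed", range(5))
    def test_first_block_recall_is_maximal(self, seed):
        """Putting a disease's block first can only gain it patients."""
        algos = enumerate_algorithms(default_blocks())
        df = synthetic_labeled_cohort(seed)
        recalls = {n: evaluate(algos[n], df).per_class_recall for n in range(1, 7)}
        firsts = {n: order[0] for n, order in ALGORITHM_ORDERS.items()}
        for n, first in firsts.items():
            best = max(recalls[m][first] for m in range(1, 7))
            assert recalls[n][first] == pytest.approx(best)

    def test_empty_cohort_rejected(self):
        algos = enumerate_algorithms(default_blocks())
        df = pd.DataFrame([{"true_diagnosis": "OTHER", **record()}])
        with pytest.raises(ValueError):
            evaluate(algos[1], df)


class TestAggregate:
    @pytest.mark.parametrize(
        "correct, expected",
        [((56, 12, 7), 72.8), ((39, 13, 7), 57.3), ((70, 14, 19), 100.0)],
    )
    def test_examples(self, correct, expected):
        c = dict(zip(("PPPD", "UVH", "CDA"), correct))
        n = {"PPPD": 70, "UVH": 14, "CDA": 19}
        assert aggregate_overall(c, n) == expected

    def test_reported_overall_accuracies_reproduce(self):
        """The six published overall accuracies follow from the published
        per-class recalls and one complete-case size vector."""
        sizes = {d: RECONSTRUCTED_SIZES[d] for d in ("PPPD", "UVH", "CDA")}
        for n, recalls in REPORTED_RECALLS.items():
            correct = recalls_to_counts(recalls, sizes)
            assert aggregate_overall(correct, sizes) == REPORTED_OVERALL[n]

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            aggregate_overall({"PPPD": 5}, {"PPPD": 4})
        with pytest.raises(ValueError):
            aggregate_overall({}, {"UD": 10})
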