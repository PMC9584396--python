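"""Percent-accuracy concordance: arithmetic, published-table fixture, panel rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ibstriage as ib
from ibstriage.concordance import InsufficientDataError, ReplicateMatch

PUBLISHED_ACCURACIES = {
    "SLC19A1": 100.0,
    "PPARD": 92.42,
    "TPH1": 84.85,
    "CD36": 81.82,
    "VIP": 81.82,
    "SERT": 75.76,
    "VSIG2": 72.73,
}


def _reps(xs, y, gene="G"):
    return [ReplicateMatch(gene, i + 1, x, y) for i, x in enumerate(xs)]


def _oracle(xs, ys):
    """Literal evaluation of the accuracy formula: 100 * mean of x/y."""
    return round(100.0 * sum(x / y for x, y in zip(xs, ys)) / len(xs), 2)


class TestPatientMatch:
    @pytest.mark.parametrize(
        "patient,array,expected",
        [
            (0.58, 0.93, True),   # both repressed
            (1.27, 1.14, True),   # both induced
            (0.96, 1.14, False),  # opposite directions
            (1.0, 0.5, False),    # patient fold exactly 1: no direction
            (0.5, 1.0, False),    # array fold exactly 1: no direction
        ],
    )
    def test_direction_semantics(self, patient, array, expected):
        assert ib.patient_match(patient, array) is expected

    def test_nonpositive_fold_rejected(self):
        with pytest.raises(ValueError):
            ib.patient_match(-0.5, 1.2)


class TestPercentAccuracy:
    @pytest.mark.parametrize(
        "xs,expected",
        [((9, 8, 8), 75.76), ((11, 11), 100.0), ((11, 10, 10, 10, 10, 10), 92.42),
         ((10, 9, 9), 84.85), ((9, 9, 9), 81.82), ((8, 8, 8), 72.73)],
    )
    def test_published_replicate_counts(self, xs, expected):
        assert ib.percent_accuracy(_reps(xs, 11)) == expected

    def test_empty_and_invalid_counts_rejected(self):
        with pytest.raises(InsufficientDataError):
            ib.percent_accuracy([])
        with pytest.raises(ValueError):
            ReplicateMatch("G", 1, 12, 11)

    @settings(max_examples=60, deadline=None)
    @given(st.data())
    def test_oracle_equality_bounds_and_replication_invariance(self, data):
        ys = data.draw(st.lists(st.integers(1, 11), min_size=1, max_size=8))
        xs = [data.draw(st.integers(0, y)) for y in ys]
        reps = [ReplicateMatch("G", i + 1, x, y) for i, (x, y) in enumerate(zip(xs, ys))]
        acc = ib.percent_accuracy(reps)
        assert acc == _oracle(xs, ys)
        assert 0.0 <= acc <= 100.0
        # replicate order must not matter
        assert ib.percent_accuracy(list(reversed(reps))) == acc
        # doubling every replicate leaves the statistic unchanged
        doubled = reps + [ReplicateMatch("G", len(reps) + i + 1, r.x, r.y) for i, r in enumerate(reps)]
        assert ib.percent_accuracy(doubled) == acc

    def test_all_match_and_no_match_extremes(self):
        assert ib.percent_accuracy(_reps((7, 7, 7), 7)) == 100.0
        assert ib.percent_accuracy(_reps((0, 0), 5)) == 0.0


class TestPublishedFixture:
    def test_fixture_counts_reproduce_every_published_accuracy(self):
        matches = ib.load_panel_replicate_matches()
        for gene, sub in matches.groupby("gene"):
            reps = [ReplicateMatch(gene, r.replicate, r.x, r.y) for r in sub.itertuples()]
            assert (sub["y"] == 11).all()
            assert ib.percent_accuracy(reps) == PUBLISHED_ACCURACIES[gene]

    def test_panel_mean_accuracy(self):
        panel = ib.load_published_panel()
        assert round(float(panel["percent_accuracy"].mean()), 1) == 84.2

    def test_published_folds_all_directionally_concordant(self):
        panel = ib.load_published_panel()
        for row in panel.itertuples():
            assert ib.patient_match(row.qpcr_fold, row.microarray_fold)


class TestScoreGene:
    def test_all_concordant_patients_give_hundred(self):
        folds = {1: {"p1": 0.5, "p2": 0.8}, 2: {"p1": 0.6, "p2": 0.7, "p3": 0.9}}
        matches, acc = ib.score_gene(folds, microarray_fold=0.7, gene="G1")
        assert acc == 100.0
        assert [(m.x, m.y) for m in matches] == [(2, 2), (3, 3)]

    def test_varying_patients_per_replicate(self):
        folds = {1: {"p1": 0.5, "p2": 1.4}, 2: {"p1": 0.5}}
        _, acc = ib.score_gene(folds, microarray_fold=0.7, gene="G1")
        assert acc == round(100 * (0.5 + 1.0) / 2, 2)

    def test_noise_free_end_to_end_scores_hundred(self):
        cfg = ib.SimulationConfig(seed=13, ct_noise_sd=1e-9)
        truth = {"A": 0.5, "B": 2.0}
        ct = ib.simulate_qpcr(cfg, truth)
        est = ib.ddct_fold(ct, "case_patient", "pooled_control")
        scores = ib.score_all(est, {"A": 0.8, "B": 1.3})  # array folds on truth's side of 1
        assert (scores["percent_accuracy"] == 100.0).all()

    def test_null_gene_accuracy_near_fifty(self):
        """A fold-1 gene under symmetric noise matches the array direction half the time."""
        accs = []
        for s in range(30):
            cfg = ib.SimulationConfig(seed=2000 + s, ct_noise_sd=0.15, plate_replicates=(3, 3))
            ct = ib.simulate_qpcr(cfg, {"N": 1.0})
            est = ib.ddct_fold(ct, "case_patient", "pooled_control")
            accs.append(ib.score_all(est, {"N": 0.8})["percent_accuracy"].iloc[0])
        assert np.mean(accs) == pytest.approx(50.0, abs=10.0)


class TestSelectPanel:
    def _inputs(self, acc_by_gene, n_plates=3):
        scores = pd.DataFrame(
            {"gene": list(acc_by_gene), "replicates": "", "percent_accuracy": list(acc_by_gene.values())}
        )
        summaries = pd.DataFrame(
            {"gene": list(acc_by_gene), "mean_fold": 0.5, "sem": 0.1,
             "n_plates": n_plates, "passes_replicate_filter": n_plates >= 2}
        )
        return scores, summaries

    def test_published_panel_mean(self):
        scores, summaries = self._inputs(PUBLISHED_ACCURACIES)
        flags = {g: True for g in PUBLISHED_ACCURACIES}
        panel, mean_acc = ib.select_panel(scores, summaries, flags=flags)
        assert panel["in_panel"].all() and len(panel) == 7
        assert mean_acc == 84.2

    def test_threshold_boundary_inclusive_at_seventy(self):
        scores, summaries = self._inputs({"A": 70.00, "B": 69.99})
        panel, _ = ib.select_panel(scores, summaries, flags={"A": True, "B": True})
        by = panel.set_index("gene")["in_panel"]
        assert bool(by["A"]) and not bool(by["B"])

    def test_all_three_criteria_required(self):
        scores, summaries = self._inputs({"A": 95.0, "B": 95.0, "C": 95.0})
        summaries.loc[summaries["gene"] == "B", "passes_replicate_filter"] = False
        panel, _ = ib.select_panel(scores, summaries, flags={"A": True, "B": True})
        by = panel.set_index("gene")["in_panel"]
        assert bool(by["A"])
        assert not bool(by["B"])  # fails replicate filter
        assert not bool(by["C"])  # no relevance flag

    def test_empty_panel_mean_is_nan(self):
        scores, summaries = self._inputs({"A": 60.0})
        panel, mean_acc = ib.select_panel(scores, summaries, flags={"A": True})
        assert not panel["in_panel"].any()
        assert np.isnan(mean_acc)
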