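"""Hit-list construction and screening metrics against brute-force oracles."""

import math

import numpy as np
import pytest

from qmrescore import (
    LibraryManifest,
    ScoreComponents,
    build_hitlist,
    enrichment_factor,
    enrichment_plot_data,
    hitlist_from_arrays,
    make_ranked_list,
    roc_auc,
)
from qmrescore.scoring import ScoreRecord
from qmrescore.screenmetrics import evaluate


def ef_oracle(scores, labels, x):
    """Brute-force counting: sort, take ceil(x*N/100), count ligands."""
    order = np.lexsort((np.arange(len(scores)), scores))
    labels = np.asarray(labels, bool)[order]
    n = len(labels)
    n_top = math.ceil(x * n / 100.0)
    hits_top = labels[:n_top].sum()
    return (hits_top / n_top) / (labels.sum() / n)


def auc_oracle(scores, labels):
    """Mann-Whitney pair counting; ties credited half (lower = better)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    lig = scores[labels]
    dec = scores[~labels]
    wins = sum((l < d) + 0.5 * (l == d) for l in lig for d in dec)
    return wins / (len(lig) * len(dec))


def record(state, parent, score, status="converged"):
    return ScoreRecord(
        state, parent, "qmds1", ScoreComponents(), qmds=score, status=status
    )


class TestBuildHitlist:
    def manifest(self):
        return LibraryManifest.from_records(
            [
                ("a_s1", "a", "ligand"),
                ("a_s2", "a", "ligand"),
                ("b_s1", "b", "decoy"),
                ("c_s1", "c", "decoy"),
            ]
        )

    def test_state_collapsing_takes_lowest(self):
        records = [
            record("a_s1", "a", -5.0),
            record("a_s2", "a", -7.0),
            record("b_s1", "b", -6.0),
            record("c_s1", "c", -1.0),
        ]
        hl = build_hitlist(records, self.manifest())
        assert hl.n_total == 3
        assert hl.parent_ids[0] == "a" and hl.scores[0] == -7.0

    def test_failed_only_molecule_excluded_entirely(self):
        records = [
            record("a_s1", "a", -5.0),
            record("b_s1", "b", None, status="failed"),
            record("c_s1", "c", -1.0),
        ]
        hl = build_hitlist(records, self.manifest())
        assert hl.n_total == 2
        assert "b" not in hl.parent_ids
        assert hl.excluded == ["b_s1"]

    def test_tie_break_stable_by_parent_id(self):
        records = [
            record("c_s1", "c", -3.0),
            record("b_s1", "b", -3.0),
            record("a_s1", "a", -5.0),
        ]
        hl = build_hitlist(records, self.manifest())
        assert hl.parent_ids == ["a", "b", "c"]

    def test_all_failed_raises(self):
        records = [record("a_s1", "a", None, status="failed")]
        with pytest.raises(ValueError):
            build_hitlist(records, self.manifest())

    def test_mixed_variants_rejected(self):
        records = [record("a_s1", "a", -5.0)]
        records.append(
            ScoreRecord("b_s1", "b", "qmds2", ScoreComponents(), qmds=-1.0)
        )
        with pytest.raises(ValueError):
            build_hitlist(records, self.manifest())


class TestEnrichmentFactor:
    def test_perfect_ranking_bound(self):
        scores = np.concatenate([np.arange(10) - 100.0, np.arange(990)])
        labels = np.concatenate([np.ones(10, bool), np.zeros(990, bool)])
        hl = hitlist_from_arrays(scores, labels)
        assert enrichment_factor(hl, 1.0) == pytest.approx(100.0)

    def test_derived_example(self):
        # 200 molecules, 20 ligands, 8 of them in the top 20 (=10%)
        scores = np.arange(200, dtype=float)
        labels = np.zeros(200, bool)
        labels[:8] = True  # 8 hits inside the top 20
        labels[50:62] = True  # remaining 12 hits outside
        hl = hitlist_from_arrays(scores, labels)
        assert enrichment_factor(hl, 10.0) == pytest.approx(4.0)
        assert enrichment_factor(hl, 10.0) == pytest.approx(
            ef_oracle(scores, labels, 10.0)
        )

    def test_ef_at_100_is_unity(self):
        for seed in range(5):
            scores, labels = make_ranked_list(seed, 137, 0.8)
            hl = hitlist_from_arrays(scores, labels)
            assert enrichment_factor(hl, 100.0) == pytest.approx(1.0)

    @pytest.mark.parametrize("x", [0.5, 1.0, 2.0, 5.0, 10.0, 33.3, 100.0])
    def test_matches_oracle_on_random_vectors(self, x):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = int(rng.integers(20, 500))
            scores = rng.normal(size=n)
            labels = rng.random(n) < 0.15
            if not labels.any():
                labels[0] = True
            hl = hitlist_from_arrays(scores, labels)
            assert enrichment_factor(hl, x) == pytest.approx(
                ef_oracle(scores, labels, x), abs=1e-12
            )

    def test_bounds(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=300)
        labels = rng.random(300) < 0.1
        labels[0] = True
        hl = hitlist_from_arrays(scores, labels)
        for x in (1.0, 5.0, 50.0):
            ef = enrichment_factor(hl, x)
            assert 0.0 <= ef <= min(100.0 / x, hl.n_total / hl.hits_total) + 1e-12

    def test_removing_tail_decoy_never_decreases_top_set_precision(self):
        """Dropping a decoy ranked below every ligand can shrink the EF
        normalization (N_total falls while Hits_total stays), so the raw
        EF may dip by that factor; the ligand fraction of the top set
        itself never decreases."""
        rng = np.random.default_rng(2)
        scores = rng.normal(size=100)
        labels = rng.random(100) < 0.2
        labels[np.argmax(scores)] = False  # worst-ranked molecule is a decoy
        hl_full = hitlist_from_arrays(scores, labels)
        keep = np.arange(100) != np.argmax(scores)
        hl_trim = hitlist_from_arrays(scores[keep], labels[keep])
        for x in (1.0, 5.0, 10.0, 50.0):
            precision_full = (
                enrichment_factor(hl_full, x) * hl_full.hits_total / hl_full.n_total
            )
            precision_trim = (
                enrichment_factor(hl_trim, x) * hl_trim.hits_total / hl_trim.n_total
            )
            assert precision_trim >= precision_full - 1e-12

    def test_no_ligands_rejected(self):
        hl = hitlist_from_arrays([1.0, 2.0], [False, False])
        with pytest.raises(ValueError):
            enrichment_factor(hl, 1.0)


class TestRocAuc:
    def test_perfect_separation(self):
        hl = hitlist_from_arrays([-2.0, -1.0, 1.0, 2.0], [True, True, False, False])
        _, _, auc = roc_auc(hl)
        assert auc == 1.0

    def test_derived_pair_counting_example(self):
        hl = hitlist_from_arrays([1.0, 3.0, 2.0, 4.0], [True, True, False, False])
        _, _, auc = roc_auc(hl)
        assert auc == pytest.approx(0.75)  # 3 of 4 ligand-decoy pairs correct

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            n = int(rng.integers(10, 120))
            scores = np.round(rng.normal(size=n), 1)  # rounding makes ties
            labels = rng.random(n) < 0.3
            if labels.all() or not labels.any():
                labels[0] = ~labels[0]
            hl = hitlist_from_arrays(scores, labels)
            _, _, auc = roc_auc(hl)
            assert auc == pytest.approx(auc_oracle(scores, labels), abs=1e-12)

    def test_shuffled_labels_near_half(self):
        aucs = []
        for seed in range(10):
            scores, labels = make_ranked_list(seed, 500, 0.5)
            hl = hitlist_from_arrays(scores, labels)
            aucs.append(roc_auc(hl)[2])
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)

    def test_single_class_rejected(self):
        hl = hitlist_from_arrays([1.0, 2.0], [True, True])
        with pytest.raises(ValueError):
            roc_auc(hl)


class TestEnrichmentPlot:
    def test_monotone_step_curve_from_origin_to_100(self):
        scores, labels = make_ranked_list(0, 200, 0.9)
        hl = hitlist_from_arrays(scores, labels)
        screened, found = enrichment_plot_data(hl)
        assert screened[0] == 0.0 and found[0] == 0.0
        assert screened[-1] == 100.0 and found[-1] == 100.0
        assert np.all(np.diff(found) >= 0)

    def test_perfect_ranking_saturates_early(self):
        scores, labels = make_ranked_list(0, 100, 1.0)
        hl = hitlist_from_arrays(scores, labels)
        screened, found = enrichment_plot_data(hl)
        frac = hl.hits_total / hl.n_total * 100.0
        k = np.searchsorted(screened, frac)
        assert found[k] == pytest.approx(100.0)

    def test_worst_ranking_finds_ligands_only_at_tail(self):
        labels = np.zeros(50, bool)
        labels[-5:] = True
        hl = hitlist_from_arrays(np.arange(50, dtype=float), labels)
        _, found = enrichment_plot_data(hl)
        assert found[45] == 0.0 and found[-1] == 100.0


class TestEvaluate:
    def test_default_report_keys(self):
        scores, labels = make_ranked_list(0, 300, 0.9)
        hl = hitlist_from_arrays(scores, labels)
        metrics = evaluate(hl)
        assert {"EF1", "EF2", "EF5", "EF10", "AUC"} <= set(metrics)
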