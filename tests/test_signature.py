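import numpy as np
import pandas as pd
import pytest

from nrf2screen import (
    NormalizedMatrix,
    classify,
    cross_validate,
    derive_cohort_signature,
    intersect_cohorts,
    select_high_confidence,
    train_centroid,
)
from nrf2screen.expression import DEResult
from nrf2screen.signature import (
    ACTIVE,
    INACTIVE,
    CentroidModel,
    CohortSignatureResult,
    DerivationConfig,
)
from nrf2screen.simulate import SimulationSpec, simulate_cohort, simulate_multi_cohort


def _norm(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, index=genes, columns=samples)
    return NormalizedMatrix(
        values=df, norm_factors=pd.Series(1.0, index=df.columns), mode="proteomic"
    )


@pytest.fixture
def separated():
    """Two clean clusters of 4 samples on a 3-gene panel, 1 z-unit apart."""
    rng = np.random.default_rng(0)
    base = rng.normal(size=(3, 8)) * 0.05
    base[:, :4] += 1.0
    norm = _norm(base)
    labels = pd.Series(
        [ACTIVE] * 4 + [INACTIVE] * 4, index=norm.values.columns
    )
    return norm, labels


class TestTrainCentroid:
    def test_one_sample_per_class_centroids_equal_samples(self):
        norm = _norm([[0.0, 2.0], [1.0, 3.0]])
        labels = pd.Series([ACTIVE, INACTIVE], index=["s0", "s1"])
        model = train_centroid(norm, labels, ["g0", "g1"])
        z = (norm.values.to_numpy() - model.standardize_mean[:, None]) / \
            model.standardize_sd[:, None]
        assert np.allclose(model.centroid_active, z[:, 0])
        assert np.allclose(model.centroid_inactive, z[:, 1])

    def test_refit_on_same_data_is_identical(self, separated):
        norm, labels = separated
        m1 = train_centroid(norm, labels, list(norm.values.index))
        m2 = train_centroid(norm, labels, list(norm.values.index))
        assert np.allclose(m1.centroid_active, m2.centroid_active)
        assert np.allclose(m1.standardize_sd, m2.standardize_sd)

    def test_zero_variance_gene_dropped(self, separated):
        norm, labels = separated
        vals = norm.values.copy()
        vals.loc["flat"] = 1.0
        m = train_centroid(_norm(vals.values, genes=list(vals.index)),
                           labels, list(vals.index))
        assert "flat" not in m.gene_panel

    def test_centroid_difference_tracks_planted_effect(self):
        rng = np.random.default_rng(3)
        effect = np.array([2.0, -2.0, 2.0, 0.0, -2.0] * 4)  # 20-gene panel
        x = rng.normal(size=(20, 60))
        x[:, :30] += effect[:, None]
        labels = pd.Series([ACTIVE] * 30 + [INACTIVE] * 30,
                           index=[f"s{j}" for j in range(60)])
        norm = _norm(x)
        m = train_centroid(norm, labels, list(norm.values.index))
        diff = m.centroid_active - m.centroid_inactive
        r = np.corrcoef(diff, effect)[0, 1]
        assert r > 0.9

    def test_serialization_roundtrip(self, separated):
        norm, labels = separated
        m = train_centroid(norm, labels, list(norm.values.index))
        m2 = CentroidModel.from_dict(m.to_dict())
        assert m2.gene_panel == m.gene_panel
        assert np.allclose(m2.centroid_active, m.centroid_active)


class TestClassify:
    @pytest.fixture
    def model(self, separated):
        norm, labels = separated
        return train_centroid(norm, labels, list(norm.values.index))

    def test_sample_at_active_centroid_has_margin_one(self, model):
        vec = pd.Series(
            model.centroid_active * model.standardize_sd + model.standardize_mean,
            index=model.gene_panel,
        )
        cls, margin = classify(model, vec)
        assert cls == ACTIVE and margin == pytest.approx(1.0)

    def test_midpoint_ties_to_inactive(self, model):
        mid = (model.centroid_active + model.centroid_inactive) / 2
        vec = pd.Series(
            mid * model.standardize_sd + model.standardize_mean,
            index=model.gene_panel,
        )
        cls, margin = classify(model, vec)
        assert cls == INACTIVE and margin == pytest.approx(0.0, abs=1e-12)

    def test_far_orthogonal_sample_still_classified_by_nearer_centroid(self, model):
        D = model.inter_centroid_distance
        axis = model.centroid_active - model.centroid_inactive
        ortho = np.array([axis[1], -axis[0], 0.0])
        ortho = ortho / np.linalg.norm(ortho) * 5 * D
        z = model.centroid_active + ortho
        vec = pd.Series(
            z * model.standardize_sd + model.standardize_mean,
            index=model.gene_panel,
        )
        cls, margin = classify(model, vec)
        d_act = np.linalg.norm(z - model.centroid_active)
        d_in = np.linalg.norm(z - model.centroid_inactive)
        assert cls == (ACTIVE if d_act < d_in else INACTIVE)
        assert 0 < margin < 1

    def test_missing_panel_gene_errors(self, model):
        vec = pd.Series([1.0], index=[model.gene_panel[0]])
        with pytest.raises(ValueError, match="missing"):
            classify(model, vec)


class TestSelectHighConfidence:
    def test_clean_clusters_nothing_removed(self, separated):
        norm, labels = separated
        model = train_centroid(norm, labels, list(norm.values.index), 0.25)
        retained, removed = select_high_confidence(model, norm, labels)
        assert removed == {} and len(retained) == 8

    def test_mislabeled_sample_removed_regardless_of_tau(self, separated):
        norm, labels = separated
        flipped = labels.copy()
        flipped.iloc[0] = INACTIVE  # sample sits on the active cluster
        model = train_centroid(norm, labels, list(norm.values.index), tau := 50.0)
        retained, removed = select_high_confidence(model, norm, flipped, tau=tau)
        assert removed.get(labels.index[0]) == "misclassified"

    def test_tau_zero_triggers_error_on_continuous_data(self, separated):
        norm, labels = separated
        model = train_centroid(norm, labels, list(norm.values.index))
        with pytest.raises(ValueError, match="tau"):
            select_high_confidence(model, norm, labels, tau=0.0)

    def test_shrinking_tau_never_grows_retained_set(self, separated):
        norm, labels = separated
        model = train_centroid(norm, labels, list(norm.values.index))
        prev = None
        for tau in (2.0, 1.0, 0.5, 0.3):
            retained, _ = select_high_confidence(model, norm, labels, tau=tau)
            if prev is not None:
                assert set(retained) <= prev
            prev = set(retained)


class TestDeriveAndIntersect:
    def test_recovers_planted_signature(self, reference_cohort):
        bundle, truth = reference_cohort
        res = derive_cohort_signature(bundle)
        top100 = set(
            res.final_de.table[res.final_de.table["log2fc"] > 0]
            .sort_values(["p", "gene"]).head(100)["gene"]
        )
        assert len(top100 & set(truth.signature_genes)) >= 90

    def test_deterministic(self, reference_cohort):
        bundle, _ = reference_cohort
        r1 = derive_cohort_signature(bundle)
        r2 = derive_cohort_signature(bundle)
        pd.testing.assert_frame_equal(r1.final_de.table, r2.final_de.table)
        assert r1.retained_samples == r2.retained_samples

    def test_undersized_active_class_skips_cohort(self):
        spec = SimulationSpec(
            n_genes=100, n_samples=40, n_signature_genes=10,
            frac_nrf2_active=0.05, seed=8,  # 2 active samples < min size 5
        )
        bundle, _ = simulate_cohort(spec)
        res = derive_cohort_signature(bundle)
        assert res.skipped and "active class size" in res.skip_reason

    def test_three_cohort_intersection_recovers_shared_core_only(self):
        spec = SimulationSpec(seed=1)
        cohorts = simulate_multi_cohort(spec, 3, shared_core=100)
        results = [derive_cohort_signature(b) for b, _ in cohorts]
        sig = intersect_cohorts(results)
        genes = set(sig.genes(sig.names()[0]))
        shared = (
            set(cohorts[0][1].signature_genes)
            & set(cohorts[1][1].signature_genes)
            & set(cohorts[2][1].signature_genes)
        )
        private = set().union(
            *(set(t.signature_genes) for _, t in cohorts)
        ) - shared
        assert len(genes & shared) >= 90
        assert not genes & private

    def test_sign_flip_excludes_gene(self):
        tab = pd.DataFrame(
            {"gene": ["a", "b"], "log2fc": [1.0, 1.0],
             "t": [5.0, 5.0], "p": [1e-6, 1e-6], "padj": [1e-5, 1e-5]}
        )
        flipped = tab.copy()
        flipped.loc[flipped["gene"] == "b", "log2fc"] = -1.0

        def mk(t, name):
            return CohortSignatureResult(
                cohort_name=name, preliminary_labels=pd.Series(dtype=object),
                initial_de=DEResult(t, 1, 1), panel=[], model=None,
                retained_samples=[], removed_samples={},
                final_de=DEResult(t, 1, 1),
            )

        sig = intersect_cohorts([mk(tab, "c1"), mk(flipped, "c2")])
        assert sig.genes(sig.names()[0]) == ["a"]

    def test_identical_tables_rank_by_padj(self):
        rng = np.random.default_rng(0)
        tab = pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(50)],
                "log2fc": 1.0,
                "t": 5.0,
                "p": rng.uniform(1e-8, 1e-3, 50),
            }
        )
        tab["padj"] = tab["p"] * 2

        def mk(name):
            from nrf2screen.signature import CohortSignatureResult
            return CohortSignatureResult(
                cohort_name=name, preliminary_labels=pd.Series(dtype=object),
                initial_de=DEResult(tab, 1, 1), panel=[], model=None,
                retained_samples=[], removed_samples={},
                final_de=DEResult(tab, 1, 1),
            )

        sig = intersect_cohorts([mk("a"), mk("b"), mk("c")], k=10)
        expected = list(tab.sort_values(["padj", "gene"]).head(10)["gene"])
        assert sig.genes(sig.names()[0]) == expected


class TestCrossValidate:
    def test_planted_cohort_high_accuracy(self, reference_cohort):
        bundle, _ = reference_cohort
        cv = cross_validate(bundle, n_folds=5, seed=0)
        assert cv["mean_accuracy"] >= 0.95

    def test_shuffled_labels_at_chance_on_balanced_cohort(self):
        bundle, truth = simulate_cohort(SimulationSpec(seed=1, frac_nrf2_active=0.5))
        labels = pd.Series(
            {s: (ACTIVE if s in truth.active_samples else INACTIVE)
             for s in bundle.shared_samples}
        )
        rng = np.random.default_rng(3)
        shuffled = pd.Series(rng.permutation(labels.values), index=labels.index)
        cv = cross_validate(bundle, n_folds=5, seed=0, labels=shuffled)
        se = np.sqrt(0.25 / len(labels))
        assert abs(cv["mean_accuracy"] - 0.5) < 3 * se

    def test_class_smaller_than_folds_errors(self):
        spec = SimulationSpec(
            n_genes=100, n_samples=40, n_signature_genes=10,
            frac_nrf2_active=0.05, seed=8,
        )
        bundle, _ = simulate_cohort(spec)
        with pytest.raises(ValueError, match="folds"):
            cross_validate(bundle, n_folds=5)

    def test_panel_leakage_inflates_null_accuracy(self):
        # selecting the top-k panel on ALL samples before CV leaks label
        # information; on pure-noise labels the leaky path must score higher
        from nrf2screen.expression import moderated_t_de
        from nrf2screen.signature import _top_panel

        leaky_acc, clean_acc = [], []
        for seed in range(4):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=(300, 40))
            norm = _norm(x)
            labels = pd.Series(
                [ACTIVE] * 20 + [INACTIVE] * 20, index=norm.values.columns
            )
            bundle = None
            cfg = DerivationConfig(panel_size=20, tau=10.0)
            # leakage-free CV (panel chosen inside folds)
            cv = _cv_on_matrix(norm, labels, cfg, n_folds=4, seed=0)
            clean_acc.append(cv)
            # leaky: panel + model from the full data, evaluated on the same data
            de = moderated_t_de(norm, list(labels.index[:20]),
                                list(labels.index[20:]))
            panel = _top_panel(de, 20)
            model = train_centroid(norm, labels, panel, 10.0)
            correct = sum(
                classify(model, norm.values[s])[0] == labels[s]
                for s in labels.index
            )
            leaky_acc.append(correct / len(labels))
        assert np.mean(leaky_acc) > np.mean(clean_acc) + 0.05


def _cv_on_matrix(norm, labels, cfg, n_folds, seed):
    """Minimal leakage-free CV over a bare matrix (helper for the test)."""
    from nrf2screen.expression import moderated_t_de
    from nrf2screen.signature import _top_panel

    rng = np.random.default_rng(seed)
    folds = [[] for _ in range(n_folds)]
    for cls in (ACTIVE, INACTIVE):
        members = list(labels.index[labels == cls])
        members = [members[i] for i in rng.permutation(len(members))]
        for i, s in enumerate(members):
            folds[i % n_folds].append(s)
    accs = []
    for i, test in enumerate(folds):
        train = [s for j, f in enumerate(folds) if j != i for s in f]
        tr = labels.loc[train]
        de = moderated_t_de(norm, list(tr.index[tr == ACTIVE]),
                            list(tr.index[tr == INACTIVE]))
        panel = _top_panel(de, cfg.panel_size)
        model = train_centroid(norm, tr, panel, cfg.tau)
        correct = sum(
            classify(model, norm.values[s])[0] == labels[s] for s in test
        )
        accs.append(correct / len(test))
    return float(np.mean(accs))
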