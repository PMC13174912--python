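import numpy as np
import pytest

from calixtda.discovery import (
    CandidateRecord,
    ConfigHashMismatch,
    EnthalpyComponents,
    TrainingSet,
    adsorption_enthalpy,
    augment_and_retrain,
    classify_conformation,
    rank_candidates,
    stratified_validation_sample,
    summarize_by_group,
    write_screening_report,
)
from calixtda.chemio import MoleculePointCloud
from calixtda.fixtures import synthetic_calixarene, synthetic_structure_set, synthetic_labels
from calixtda.surrogate import Hyperparams, fit


class TestAdsorptionEnthalpy:
    def test_additivity_null(self):
        assert adsorption_enthalpy(EnthalpyComponents(-100, -90, -10)) == 0.0

    def test_constructed_offset(self):
        dh = adsorption_enthalpy(EnthalpyComponents(-108.37, -90, -10))
        assert dh == pytest.approx(-8.37)

    def test_random_triples_match_arithmetic(self, rng):
        for _ in range(25):
            a, b, c = rng.normal(size=3) * 50
            assert adsorption_enthalpy(EnthalpyComponents(a, b, c)) == pytest.approx(
                a - b - c
            )

    def test_nonfinite_components_rejected(self):
        with pytest.raises(ValueError):
            EnthalpyComponents(np.inf, 0.0, 0.0)


@pytest.fixture(scope="module")
def trained_setup():
    """Small surrogate trained on synthetic structures plus a held-out pool."""
    clouds, _, _ = synthetic_structure_set(70, seed=21)
    labels, truth, X = synthetic_labels(clouds, seed=21)
    n_train = 55
    model = fit(X[:n_train], labels[:n_train], Hyperparams(0.05, 0.01), config_hash="h1")
    support = np.array(truth["support"])
    weights = np.array(truth["weights"])
    noiseless = X @ np.asarray(
        [weights[list(support).index(i)] if i in set(support) else 0.0 for i in range(X.shape[1])]
    ) + truth["intercept"]
    pool_ids = [f"pool-{i:02d}" for i in range(70 - n_train)]
    return model, pool_ids, X[n_train:], noiseless[n_train:]


class TestRanking:
    def test_pool_of_one(self, trained_setup):
        model, ids, X, _ = trained_setup
        (rec,) = rank_candidates(model, ids[:1], X[:1], "h1")
        assert rec.candidate_id == ids[0]
        assert rec.predicted_dh is not None

    def test_equal_predictions_tie_break_by_id(self):
        X = np.zeros((2, 4))
        model = fit(X, np.array([-3.0, -3.0]), Hyperparams(0.1, 0.1), config_hash="h")
        ranked = rank_candidates(model, ["b", "a"], X, "h")
        assert [r.candidate_id for r in ranked] == ["a", "b"]

    def test_best_true_binder_ranked_first(self, trained_setup):
        model, ids, X, truth_vals = trained_setup
        ranked = rank_candidates(model, ids, X, "h1")
        best_true = ids[int(np.argmin(truth_vals))]
        assert ranked[0].candidate_id == best_true

    def test_config_hash_mismatch_refused(self, trained_setup):
        model, ids, X, _ = trained_setup
        with pytest.raises(ConfigHashMismatch, match="refusing"):
            rank_candidates(model, ids, X, "other-hash")

    def test_ranking_is_stable_under_rerun(self, trained_setup):
        model, ids, X, _ = trained_setup
        a = [r.candidate_id for r in rank_candidates(model, ids, X, "h1")]
        b = [r.candidate_id for r in rank_candidates(model, ids, X, "h1")]
        assert a == b


def _records(preds):
    return [
        CandidateRecord(candidate_id=f"c{i:03d}", predicted_dh=float(p))
        for i, p in enumerate(preds)
    ]


class TestStratifiedSampling:
    @pytest.fixture
    def adequate_pool(self, rng):
        # predictions spanning all three strata around (-5, -7)
        preds = np.concatenate(
            [rng.uniform(-4.5, -1, 20), rng.uniform(-6.9, -5.1, 20), rng.uniform(-12, -7.1, 20)]
        )
        return _records(preds)

    def test_default_draw_is_3_3_5(self, adequate_pool):
        sel = stratified_validation_sample(adequate_pool, seed=5)
        assert len(sel) == 11
        weak = [r for r in sel if r.predicted_dh > -5]
        mid = [r for r in sel if -7 <= r.predicted_dh <= -5]
        strong = [r for r in sel if r.predicted_dh < -7]
        assert (len(weak), len(mid), len(strong)) == (3, 3, 5)

    def test_no_duplicate_selection(self, adequate_pool):
        sel = stratified_validation_sample(adequate_pool, seed=8)
        assert len({r.candidate_id for r in sel}) == len(sel)

    def test_single_strong_stratum_draw(self, adequate_pool):
        sel = stratified_validation_sample(adequate_pool, counts=(0, 0, 1), seed=1)
        assert len(sel) == 1
        assert sel[0].predicted_dh < -7

    def test_fixed_seed_reproducible(self, adequate_pool):
        a = stratified_validation_sample(adequate_pool, seed=3)
        b = stratified_validation_sample(adequate_pool, seed=3)
        assert [r.candidate_id for r in a] == [r.candidate_id for r in b]

    def test_understocked_stratum_named_in_error(self):
        pool = _records([-1.0, -2.0])  # weak stratum only
        with pytest.raises(ValueError, match="strong"):
            stratified_validation_sample(pool, counts=(1, 0, 1))


def _tiny_training_set(n, dim=6, seed=0, prefix="t"):
    r = np.random.default_rng(seed)
    X = r.normal(size=(n, dim))
    y = X[:, 0] * 1.5 - 5 + r.normal(size=n) * 0.2
    return TrainingSet(
        ids=[f"{prefix}{i:04d}" for i in range(n)],
        X=X,
        y=y,
        provenance=["initial"] * n,
        config_hash="h",
    )


SMALL_GRIDS = dict(alpha_grid=[0.05, 0.5], gamma_grid=[0.05, 0.5], k=3, seed=0)


class TestAugmentation:
    def test_paper_scale_counts_345_to_356_to_361(self):
        ts = _tiny_training_set(345)
        r = np.random.default_rng(99)
        model, fm, merged, _ = augment_and_retrain(
            ts, [f"v{i}" for i in range(11)], r.normal(size=(11, 6)),
            r.normal(size=11) - 7, provenance="augmentation_1", **SMALL_GRIDS
        )
        assert merged.n == 356
        model2, fm2, merged2, _ = augment_and_retrain(
            merged, [f"w{i}" for i in range(5)], r.normal(size=(5, 6)),
            r.normal(size=5) - 7, provenance="augmentation_2", **SMALL_GRIDS
        )
        assert merged2.n == 361
        assert merged2.provenance.count("augmentation_1") == 11
        assert merged2.provenance.count("augmentation_2") == 5
        assert len(model2.dual_coef) == 361

    def test_empty_augmentation_reproduces_metrics(self):
        ts = _tiny_training_set(40)
        _, fm1, m1, hp1 = augment_and_retrain(ts, [], np.zeros((0, 6)), [], **SMALL_GRIDS)
        _, fm2, m2, hp2 = augment_and_retrain(ts, [], np.zeros((0, 6)), [], **SMALL_GRIDS)
        assert m1.n == m2.n == 40
        assert hp1 == hp2
        assert fm1.mean_test_r2 == fm2.mean_test_r2

    def test_duplicate_id_rejected(self):
        ts = _tiny_training_set(10)
        with pytest.raises(ValueError, match="duplicate"):
            augment_and_retrain(ts, ["t0003"], np.zeros((1, 6)), [0.0], **SMALL_GRIDS)

    def test_augmenting_low_enthalpy_region_does_not_hurt_it(self):
        # evaluate a fixed strong-binder region before/after augmentation
        r = np.random.default_rng(12)
        clouds, _, _ = synthetic_structure_set(90, seed=12)
        labels, _, X = synthetic_labels(clouds, seed=12)
        order = np.argsort(labels)
        strong = order[:20]  # most negative labels
        rest = order[20:]
        eval_idx, aug_idx = strong[:10], strong[10:]
        ts = TrainingSet(
            ids=[f"s{i}" for i in rest], X=X[rest], y=labels[rest],
            provenance=["initial"] * len(rest), config_hash="h",
        )
        model_before, _, _, _ = augment_and_retrain(ts, [], np.zeros((0, X.shape[1])), [], **SMALL_GRIDS)
        model_after, _, _, _ = augment_and_retrain(
            ts, [f"a{i}" for i in aug_idx], X[aug_idx], labels[aug_idx], **SMALL_GRIDS
        )
        err_before = np.abs(model_before.predict(X[eval_idx]) - labels[eval_idx]).mean()
        err_after = np.abs(model_after.predict(X[eval_idx]) - labels[eval_idx]).mean()
        assert err_after <= err_before + 1e-9


class TestConformationClassifier:
    @pytest.mark.parametrize("conf", ["cone", "partial_cone", "alt12", "alt13"])
    def test_round_trip_on_noiseless_fixtures(self, conf):
        cloud, amap = synthetic_calixarene(conf)
        assert classify_conformation(cloud, amap) == conf

    def test_rotation_invariance(self, rng):
        cloud, amap = synthetic_calixarene("cone")
        # random rotation via QR
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        rotated = MoleculePointCloud(
            id="rot", elements=cloud.elements, coords=cloud.coords @ q.T + [5, 5, 5]
        )
        assert classify_conformation(rotated, amap) == "cone"

    def test_atom_reordering_with_consistent_map(self, rng):
        cloud, amap = synthetic_calixarene("alt12")
        perm = rng.permutation(cloud.n_atoms)
        inv = np.empty_like(perm)
        inv[perm] = np.arange(len(perm))
        shuffled = MoleculePointCloud(
            id="perm",
            elements=tuple(cloud.elements[i] for i in perm),
            coords=cloud.coords[perm],
        )
        assert classify_conformation(shuffled, amap.reindex(inv)) == "alt12"

    def test_coplanar_geometry_undetermined(self):
        cloud, amap = synthetic_calixarene("cone")
        flat = cloud.coords.copy()
        flat[:, 2] = 0.0  # squash everything into the bridge plane
        squashed = MoleculePointCloud(id="flat", elements=cloud.elements, coords=flat)
        assert classify_conformation(squashed, amap) == "undetermined"

    def test_map_beyond_cloud_errors(self):
        cloud, amap = synthetic_calixarene("cone")
        small = MoleculePointCloud(
            id="small", elements=cloud.elements[:4], coords=cloud.coords[:4]
        )
        with pytest.raises(ValueError, match="beyond"):
            classify_conformation(small, amap)


class TestGroupSummaries:
    def test_single_member_group(self):
        (g,) = summarize_by_group([("s1", "calix", "cone", -6.0)])
        assert g.median == g.q1 == g.q3 == -6.0
        assert g.n == 1 and g.outlier_ids == ()

    def test_far_value_flagged_outlier(self):
        rows = [(f"s{i}", "calix", "cone", v) for i, v in enumerate([1, 2, 3, 4, 100])]
        (g,) = summarize_by_group(rows)
        assert g.outlier_ids == ("s4",)
        assert g.q1 == pytest.approx(2.0) and g.q3 == pytest.approx(4.0)
        assert g.whisker_high <= g.q3 + 1.5 * (g.q3 - g.q1)

    def test_groups_partition_dataset(self, rng):
        rows = []
        for i in range(80):
            fam = ["calix", "aza", "oxa", "thia"][i % 4]
            conf = ["cone", "alt13"][i % 2]
            rows.append((f"s{i}", fam, conf, float(rng.normal(-5, 2))))
        summaries = summarize_by_group(rows)
        assert sum(g.n for g in summaries) == 80

    def test_quartile_order_invariant(self, rng):
        rows = [(f"s{i}", "thia", "cone", float(v)) for i, v in enumerate(rng.normal(size=30))]
        (g,) = summarize_by_group(rows)
        assert g.q1 <= g.median <= g.q3
        assert g.whisker_low <= g.q1 and g.whisker_high >= g.q3


class TestScreeningReport:
    def test_reports_are_byte_identical_under_same_seed(self, tmp_path, trained_setup):
        model, ids, X, _ = trained_setup
        paths = []
        for run in (1, 2):
            ranked = rank_candidates(model, ids, X, "h1")
            p = tmp_path / f"report{run}.csv"
            write_screening_report(ranked, ranked[:3], p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]
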