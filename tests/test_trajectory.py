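"""Error model, differential calls, divergence classification, dispersion."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from exitpaths import trajectory as tj
from exitpaths.datasets import CONTROL_LABEL, ControlErrorModel, ExpressionDataset
from exitpaths.synthetic import SimConfig, gen_expression_dataset


def _dataset(values: dict, days, detection=None):
    """Build a small dataset from {drug: {day: vector}} plus control columns."""
    cols, meta = {}, []
    for i, ctrl in enumerate(values.pop("_controls")):
        name = f"c{i}"
        cols[name] = ctrl
        meta.append((name, CONTROL_LABEL, 0))
    for drug, by_day in values.items():
        for day in days:
            name = f"{drug}_d{day}"
            cols[name] = by_day[day]
            meta.append((name, drug, day))
    frame = pd.DataFrame(cols)
    frame.index = [f"g{i}" for i in range(len(frame))]
    meta = pd.DataFrame(meta, columns=["sample_id", "drug", "day"]).set_index("sample_id")
    det = None
    if detection is not None:
        det = pd.DataFrame(detection, index=frame.index, columns=frame.columns)
    return ExpressionDataset(frame, meta, det)


class TestControlModel:
    def test_hand_computed_mean_and_sd(self):
        data = _dataset({"_controls": [[1.0], [2.0], [3.0]]}, days=[])
        model = tj.fit_control_model(data)
        assert model.mean.iloc[0] == pytest.approx(2.0)
        assert model.sd.iloc[0] == pytest.approx(1.0)  # sample SD, ddof=1

    def test_constant_gene_has_zero_sd(self):
        data = _dataset({"_controls": [[5.0], [5.0], [5.0]]}, days=[])
        model = tj.fit_control_model(data)
        assert model.sd.iloc[0] == 0.0
        assert list(model.degenerate_genes()) == ["g0"]

    def test_single_replicate_rejected(self):
        data = _dataset({"_controls": [[1.0]]}, days=[])
        with pytest.raises(ValueError, match=">= 2"):
            tj.fit_control_model(data)

    def test_sd_recovery_from_replicates(self):
        """With 14 replicates the median fitted SD should sit within 10% of
        the generating scale (chi-square sampling theory)."""
        cfg = SimConfig(n_genes=10_000, n_drugs=2, noise_sd=0.2, seed=8)
        data, _ = gen_expression_dataset(cfg)
        model = tj.fit_control_model(data)
        assert 0.9 * 0.2 <= model.sd.median() <= 1.1 * 0.2


class TestDetectionFilter:
    def test_single_good_day_keeps_gene(self):
        det = np.full((2, 5), 0.5)
        det[0, 3] = 0.01  # one day passes for gene g0
        data = _dataset(
            {"_controls": [[1, 1], [1, 1]], "a": {1: [1, 1], 3: [1, 1], 5: [1, 1]}},
            days=[1, 3, 5],
            detection=det,
        )
        kept = tj.filter_detected(data)
        assert list(kept.genes) == ["g0"]

    def test_planted_undetected_fraction_dropped(self, small_dataset, small_cfg):
        data, truth = small_dataset
        kept = tj.filter_detected(data)
        dropped = set(data.genes) - set(kept.genes)
        assert dropped == set(truth.undetected_genes)

    def test_requires_detection_matrix(self):
        data = _dataset({"_controls": [[1, 1]]}, days=[])
        with pytest.raises(ValueError, match="detection"):
            tj.filter_detected(data)


class TestDifferentialCall:
    @pytest.fixture()
    def model(self):
        genes = pd.Index(["g0", "g1"])
        return ControlErrorModel(
            mean=pd.Series([10.0, 10.0], index=genes),
            sd=pd.Series([0.5, 0.0], index=genes),
            n_replicates=14,
        )

    def test_within_noise_is_not_differential(self, model):
        assert tj.is_differential(10.0, model, "g0") is False

    def test_two_units_exceeds_threshold(self, model):
        # |12 - 10| = 2 > 3 * 0.5
        assert tj.is_differential(12.0, model, "g0") is True

    def test_exact_boundary_is_not_differential(self, model):
        assert tj.is_differential(11.5, model, "g0") is False  # strict >

    def test_zero_sd_surfaced_with_gene_id(self, model):
        with pytest.raises(ValueError, match="g1"):
            tj.is_differential(12.0, model, "g1")


class TestPairwiseDiffs:
    def test_sixteen_drugs_give_120_pairs(self):
        cfg = SimConfig(n_genes=10, n_drugs=16, seed=0)
        data, _ = gen_expression_dataset(cfg)
        assert tj.pairwise_diffs(data, 1).n_pairs == 120

    def test_two_drug_difference(self):
        data = _dataset(
            {"_controls": [[0.0], [0.0]], "a": {1: [5.0]}, "b": {1: [8.0]}}, days=[1]
        )
        d = tj.pairwise_diffs(data, 1)
        assert d.n_pairs == 1
        assert d.diffs.iloc[0, 0] == pytest.approx(3.0)

    def test_identical_drugs_give_zero(self):
        data = _dataset(
            {"_controls": [[0.0], [0.0]], "a": {1: [5.0]}, "b": {1: [5.0]}}, days=[1]
        )
        assert (tj.pairwise_diffs(data, 1).diffs == 0).all().all()

    def test_missing_sample_names_drug(self):
        data = _dataset(
            {"_controls": [[0.0], [0.0]],
             "a": {1: [5.0], 3: [5.0]}, "b": {1: [5.0], 3: [5.0]}},
            days=[1, 3],
        )
        # drug b keeps its day-3 sample but loses day 1
        broken = ExpressionDataset(
            data.values.drop(columns=["b_d1"]), data.meta.drop(index=["b_d1"])
        )
        with pytest.raises(KeyError, match="'b'"):
            tj.pairwise_diffs(broken, 1)


class TestDivergentConvergent:
    def _diffs(self, means_by_day, sd=1.0):
        """PairwiseDiffs stubs with constant per-day means for one gene."""
        genes = pd.Index(["g0"])
        model = ControlErrorModel(
            mean=pd.Series([0.0], index=genes),
            sd=pd.Series([sd], index=genes),
            n_replicates=14,
        )
        diffs = {
            day: tj.PairwiseDiffs(
                diffs=pd.DataFrame({"a|b": [m]}, index=genes), pairs=[("a", "b")], day=day
            )
            for day, m in means_by_day.items()
        }
        return diffs, model

    def test_divergence_then_convergence_is_flagged(self):
        diffs, model = self._diffs({1: 0.2, 3: 5.0, 5: 0.5})
        flags, _ = tj.classify_divergent_convergent(diffs, model)
        assert flags.loc["g0"]

    def test_constant_gene_not_flagged(self):
        diffs, model = self._diffs({1: 0.0, 3: 0.0, 5: 0.0})
        flags, _ = tj.classify_divergent_convergent(diffs, model)
        assert not flags.loc["g0"]

    def test_persistent_divergence_not_flagged(self):
        diffs, model = self._diffs({1: 5.0, 3: 5.0, 5: 5.0})
        flags, _ = tj.classify_divergent_convergent(diffs, model)
        assert not flags.loc["g0"]

    def test_zero_sd_gene_excluded(self):
        diffs, model = self._diffs({1: 5.0, 3: 5.0, 5: 0.1}, sd=0.0)
        flags, excluded = tj.classify_divergent_convergent(diffs, model)
        assert not flags.loc["g0"]
        assert excluded == ["g0"]

    def test_planted_divergent_classes_recovered(self, small_dataset):
        data, truth = small_dataset
        detected = tj.filter_detected(data)
        model = tj.fit_control_model(detected)
        days = [d for d in detected.days if d != 0]
        diffs = {d: tj.pairwise_diffs(detected, d) for d in days}
        flags, _ = tj.classify_divergent_convergent(diffs, model)
        truth_labels = truth.gene_categories.loc[detected.genes]
        planted = truth_labels.isin(["C1", "C3"])
        background = truth_labels == "background"
        assert flags[planted].mean() >= 0.95
        assert flags[background].mean() <= 0.05

    def test_invariant_to_drug_and_gene_order(self, small_dataset):
        data, _ = small_dataset
        detected = tj.filter_detected(data)
        model = tj.fit_control_model(detected)
        days = [d for d in detected.days if d != 0]
        flags, _ = tj.classify_divergent_convergent(
            {d: tj.pairwise_diffs(detected, d) for d in days}, model
        )
        rng = np.random.default_rng(0)
        perm_genes = rng.permutation(detected.values.index)
        perm_cols = rng.permutation(detected.values.columns)
        shuffled = ExpressionDataset(
            detected.values.loc[perm_genes, perm_cols],
            detected.meta.loc[perm_cols],
            detected.detection.loc[perm_genes, perm_cols],
        )
        model2 = tj.fit_control_model(shuffled)
        flags2, _ = tj.classify_divergent_convergent(
            {d: tj.pairwise_diffs(shuffled, d) for d in days}, model2
        )
        assert flags2.loc[flags.index].equals(flags)


class TestCategories:
    def test_planted_categories_recovered(self, small_dataset):
        data, truth = small_dataset
        detected = tj.filter_detected(data)
        model = tj.fit_control_model(detected)
        assignment = tj.assign_categories(detected, model)
        truth_labels = truth.gene_categories.loc[detected.genes]
        for cat in ("C1", "C3", "C4"):
            mask = truth_labels == cat
            assert (assignment.labels[mask] == cat).mean() >= 0.95

    def test_labels_exhaustive_and_exclusive(self, small_dataset):
        data, _ = small_dataset
        detected = tj.filter_detected(data)
        model = tj.fit_control_model(detected)
        assignment = tj.assign_categories(detected, model)
        assert set(assignment.labels.unique()) <= set(tj.CATEGORY_LABELS)
        assert assignment.labels.index.equals(model.genes)
        assert assignment.labels.notna().all()

    def test_flat_genes_stay_out_of_planted_classes(self):
        rng = np.random.default_rng(1)
        n_genes = 20
        controls = [list(rng.normal(0, 1, n_genes)) for _ in range(14)]
        flat = {f"d{i}": {day: list(rng.normal(0, 1, n_genes)) for day in (1, 3, 5)}
                for i in range(8)}
        data = _dataset({"_controls": controls, **flat}, days=[1, 3, 5])
        model = tj.fit_control_model(data)
        assignment = tj.assign_categories(data, model)
        # noise-only genes land in background (or residual C5 on a chance
        # single-sample excursion), never in the planted classes
        assert (assignment.labels.isin(["background", "C5"])).all()


class TestModifiedPearson:
    def test_identical_deviations_give_one(self):
        a = np.array([1.0, 2.0, 3.0])
        m = np.array([0.5, 1.0, 2.0])
        assert tj.modified_pearson(a, a, m) == pytest.approx(1.0)

    def test_opposite_deviations_give_minus_one(self):
        m = np.array([1.0, 1.0, 1.0])
        a = np.array([2.0, 3.0, 0.0])
        b = 2 * m - a
        assert tj.modified_pearson(a, b, m) == pytest.approx(-1.0)

    def test_reduces_to_standard_pearson_with_sample_means(self, rng):
        a, b = rng.normal(size=100), rng.normal(size=100)
        r = tj.modified_pearson(
            a, b, np.full(100, a.mean()), np.full(100, b.mean())
        )
        assert r == pytest.approx(stats.pearsonr(a, b).statistic)

    def test_zero_deviation_rejected(self):
        m = np.array([1.0, 2.0])
        with pytest.raises(ValueError, match="degenerate"):
            tj.modified_pearson(m, np.array([3.0, 4.0]), m)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_bounded_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 40))
        a, b, m = rng.normal(size=(3, n)) * rng.uniform(0.1, 10)
        if np.allclose(a, m) or np.allclose(b, m):
            return
        r = tj.modified_pearson(a, b, m)
        assert -1.0 <= r <= 1.0


class TestDispersion:
    def _identical_drug_dataset(self):
        rng = np.random.default_rng(2)
        course = {day: list(rng.normal(0, 1, 20)) for day in (1, 3, 5)}
        controls = [list(rng.normal(0, 1, 20)) for _ in range(4)]
        return _dataset(
            {"_controls": controls, "a": dict(course), "b": dict(course)}, days=[1, 3, 5]
        )

    def test_identical_drugs_fully_correlated(self):
        data = self._identical_drug_dataset()
        model = tj.fit_control_model(data)
        disp = tj.dispersion_by_day(data, model)
        assert np.allclose(disp["r"], 1.0)

    def test_two_drugs_one_correlation_per_day(self):
        data = self._identical_drug_dataset()
        model = tj.fit_control_model(data)
        disp = tj.dispersion_by_day(data, model)
        assert disp.groupby("day").size().eq(1).all()

    def test_planted_day3_divergence_minimizes_correlation(self, small_dataset):
        data, _ = small_dataset
        detected = tj.filter_detected(data)
        model = tj.fit_control_model(detected)
        means = tj.dispersion_by_day(detected, model).groupby("day")["r"].mean()
        assert means.idxmin() == 3

    def test_subsample_deterministic_under_seed(self, small_dataset):
        data, _ = small_dataset
        model = tj.fit_control_model(data)
        d1 = tj.subsample_dispersion(data, model, n_genes=50, n_reps=3, seed=4)
        d2 = tj.subsample_dispersion(data, model, n_genes=50, n_reps=3, seed=4)
        pd.testing.assert_frame_equal(d1, d2)

    def test_single_rep_shape(self, small_dataset):
        data, _ = small_dataset
        model = tj.fit_control_model(data)
        out = tj.subsample_dispersion(data, model, n_genes=50, n_reps=1, seed=0)
        n_drugs = len(data.drugs)
        assert len(out) == 3 * n_drugs * (n_drugs - 1) // 2

    def test_oversized_subsample_rejected(self, small_dataset):
        data, _ = small_dataset
        model = tj.fit_control_model(data)
        with pytest.raises(ValueError, match="requested"):
            tj.subsample_dispersion(data, model, n_genes=data.n_genes + 1)


class TestPCA:
    def test_duplicate_samples_coincide(self):
        rng = np.random.default_rng(3)
        course = {day: list(rng.normal(0, 1, 30)) for day in (1, 3, 5)}
        data = _dataset(
            {
                "_controls": [list(rng.normal(0, 1, 30)) for _ in range(3)],
                "a": dict(course),
                "b": dict(course),
            },
            days=[1, 3, 5],
        )
        coords, evr = tj.pca_project(data, n_components=2)
        assert np.allclose(coords.loc["a_d1"], coords.loc["b_d1"])
        assert evr.sum() <= 1.0 + 1e-9

    def test_two_cluster_data_separates_on_pc1(self, rng):
        from sklearn.metrics import silhouette_score

        n = 20
        base = rng.normal(0, 0.1, (2 * n, 50))
        base[n:] += 5.0
        values = pd.DataFrame(
            base.T,
            index=[f"g{i}" for i in range(50)],
            columns=[f"s{i}" for i in range(2 * n)],
        )
        meta = pd.DataFrame(
            {"drug": ["a"] * (2 * n), "day": [1] * (2 * n)},
            index=values.columns,
        )
        coords, _ = tj.pca_project(ExpressionDataset(values, meta), n_components=2)
        labels = [0] * n + [1] * n
        assert silhouette_score(coords[["PC1"]], labels) > 0
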