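"""Reference intervals, screening flags, phenotype panels and
cohort-structure summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import cophenet

from dbscreen.io import load_table1_fixture
from dbscreen.matrix import NormalizedMatrix, ReferenceStats, ValidationError
from dbscreen.preprocess import (
    ImputeParams,
    filter_by_evidence,
    impute_downshift,
    log2_transform,
    normalize_actb,
    zscore,
)
from dbscreen.screen import (
    FlagRule,
    PhenotypePanel,
    ReferenceIntervalScreen,
    compute_reference,
    correlation_matrix,
    flag_sample,
    hierarchical_cluster,
    cut_clusters,
    panel_score,
    panel_scores,
    pca_scores,
)


def _meta(groups: dict[str, str]) -> pd.DataFrame:
    from dbscreen.matrix import make_sample_meta

    return make_sample_meta(
        [{"sample_id": s, "group": g} for s, g in groups.items()]
    )


class TestComputeReference:
    def test_closed_form(self):
        values = pd.DataFrame(
            {"S1": [1.0], "S2": [2.0], "S3": [3.0]},
            index=pd.Index(["G"], name="protein"),
        )
        meta = _meta({s: "healthy_newborn" for s in values.columns})
        ref = compute_reference(NormalizedMatrix(values), meta, "healthy_newborn")
        row = ref.for_protein("G")
        assert (row["mean"], row["sd"], row["min"], row["n"]) == (2.0, 1.0, 1.0, 3)

    def test_single_sample_group_is_error(self):
        values = pd.DataFrame({"S1": [1.0]}, index=pd.Index(["G"], name="protein"))
        meta = _meta({"S1": "healthy_newborn"})
        with pytest.raises(ValidationError):
            compute_reference(NormalizedMatrix(values), meta, "healthy_newborn")

    def test_absent_group_is_error(self):
        values = pd.DataFrame({"S1": [1.0]}, index=pd.Index(["G"], name="protein"))
        meta = _meta({"S1": "healthy_newborn"})
        with pytest.raises(ValidationError):
            compute_reference(NormalizedMatrix(values), meta, "healthy_adult")

    def test_minimum_bounds_every_group_observation(self, demo_cohort):
        matrix, meta, _ = demo_cohort
        newborns = list(meta.index[meta["group"] == "healthy_newborn"])
        normalized = normalize_actb(filter_by_evidence(matrix, 2, newborns))
        ref = compute_reference(normalized, meta, "healthy_newborn")
        sub = normalized.values[newborns]
        ok = sub.ge(ref.table["min"], axis=0) | sub.isna()
        assert ok.all().all()


class TestFlagSample:
    def _ref_row(self, mean, sd, minimum):
        return pd.Series({"mean": mean, "sd": sd, "min": minimum, "n": 40})

    def test_fhl3_observation_flags_below_newborn_minimum(self):
        flag, why = flag_sample(0.143, False, self._ref_row(10.9, 2.6, 5.9))
        assert flag is True and "minimum" in why

    def test_perforin_observation_above_minimum_not_flagged(self):
        flag, _ = flag_sample(0.290, False, self._ref_row(0.33, 0.28, 0.28))
        assert flag is False

    def test_below_lod_flags_under_both_rules(self):
        ref = self._ref_row(10.0, 1.0, 5.0)
        assert flag_sample(np.nan, True, ref, FlagRule("below_group_min"))[0] is True
        assert flag_sample(np.nan, True, ref, FlagRule("zscore_threshold"))[0] is True

    def test_no_reference_is_not_evaluable(self):
        flag, why = flag_sample(1.0, False, None)
        assert flag is None and "not_evaluable" in why

    def test_zscore_rule(self):
        ref = self._ref_row(10.0, 1.0, 5.0)
        rule = FlagRule("zscore_threshold", z_cut=-3.0)
        assert flag_sample(6.5, False, ref, rule)[0] is True
        assert flag_sample(7.5, False, ref, rule)[0] is False


def test_reference_cohort_flag_bookkeeping_is_exact():
    """Every stored patient observation flags iff it prints below its
    newborn minimum (or below the detection limit); nothing else flags."""
    obs, refs = load_table1_fixture()
    newborn = refs["healthy_newborn"]
    n_flagged = n_not = n_ne = 0
    for _, row in obs.iterrows():
        ref_row = newborn.for_protein(row["gene"])
        flag, _ = flag_sample(row["value"], row["below_lod"], ref_row)
        if ref_row is None:
            expected = None
        elif row["below_lod"]:
            expected = True
        else:
            expected = bool(row["value"] < ref_row["min"])
        assert flag is expected, (row["sample"], row["gene"])
        n_flagged += flag is True
        n_not += flag is False
        n_ne += flag is None
    assert n_flagged + n_not + n_ne == 45
    assert n_ne == 2  # the two common-gamma-chain patients have no reference


class TestPanelScores:
    def _reference(self):
        table = pd.DataFrame(
            {"mean": [10.0, 20.0, 5.0], "sd": [2.0, 4.0, 1.0],
             "min": [5.0, 10.0, 2.0], "n": [40, 40, 40]},
            index=pd.Index(["M1", "M2", "M3"], name="protein"),
        )
        return ReferenceStats("healthy_newborn", table)

    def test_members_at_reference_mean_score_zero(self):
        sample = pd.Series({"M1": 10.0, "M2": 20.0, "M3": 5.0})
        panel = PhenotypePanel("toy", ["M1", "M2", "M3"])
        assert panel_score(sample, panel, self._reference()) == 0.0

    def test_members_two_sd_down_score_minus_two(self):
        sample = pd.Series({"M1": 6.0, "M2": 12.0, "M3": 3.0})
        panel = PhenotypePanel("toy", ["M1", "M2", "M3"])
        assert panel_score(sample, panel, self._reference()) == pytest.approx(-2.0)

    def test_unscorable_panel_is_error(self):
        sample = pd.Series({"X": 1.0})
        panel = PhenotypePanel("toy", ["M9"])
        with pytest.raises(ValidationError):
            panel_score(sample, panel, self._reference())

    def test_thrombocytopenia_pattern_in_synthetic_patients(self, demo_cohort):
        """Platelet-panel knockdown shows as platelet score below T-cell
        score in the WAS-like patients."""
        matrix, meta, _ = demo_cohort
        newborns = list(meta.index[meta["group"] == "healthy_newborn"])
        filtered = filter_by_evidence(matrix, 2, newborns)
        linear = NormalizedMatrix(
            np.exp2(
                impute_downshift(
                    log2_transform(normalize_actb(filtered)), ImputeParams(seed=0)
                ).values
            )
        )
        ref = compute_reference(linear, meta, "healthy_newborn")
        was = [s for s in meta.index if str(meta.loc[s, "disease"]) == "WASlike"]
        scores = panel_scores(linear.values[was], ref)
        assert (scores["platelet"] < scores["t_cell"]).mean() > 0.5
        assert scores["platelet"].mean() < -1.0


class TestCorrelation:
    def test_duplicate_and_negated_samples(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 30)
        df = pd.DataFrame({"a": x, "b": x, "c": -x})
        corr = correlation_matrix(df)
        assert corr.loc["a", "b"] == pytest.approx(1.0)
        assert corr.loc["a", "c"] == pytest.approx(-1.0)
        assert np.allclose(corr, corr.T)
        assert np.allclose(np.diag(corr), 1.0)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(0, 1, (20, 3)), columns=list("abc"))
        corr = correlation_matrix(df)
        for i in "abc":
            for j in "abc":
                x, y = df[i], df[j]
                manual = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
                    ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
                )
                assert abs(corr.loc[i, j] - manual) < 1e-12

    def test_zero_variance_sample_is_error(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 3.0]})
        with pytest.raises(ValidationError, match="b"):
            correlation_matrix(df)


class TestPca:
    def test_collinear_data_loads_one_component(self):
        t = np.linspace(0, 1, 6)
        values = pd.DataFrame(
            np.outer([1.0, 2.0, -1.0], t),
            index=pd.Index(["G1", "G2", "G3"], name="protein"),
            columns=[f"S{i}" for i in range(6)],
        )
        _, evr = pca_scores(values, n_components=1)
        assert evr[0] == pytest.approx(1.0)

    def test_explained_variance_fractions_behave(self, demo_cohort):
        matrix, meta, _ = demo_cohort
        newborns = list(meta.index[meta["group"] == "healthy_newborn"])
        z = zscore(
            impute_downshift(
                log2_transform(normalize_actb(filter_by_evidence(matrix, 2, newborns))),
                ImputeParams(seed=2),
            )
        )
        _, evr = pca_scores(z, n_components=5)
        assert evr.sum() <= 1.0 + 1e-12
        assert (np.diff(evr) <= 1e-12).all()

    def test_all_components_preserve_pairwise_distances(self):
        rng = np.random.default_rng(4)
        values = pd.DataFrame(
            rng.normal(0, 1, (30, 8)),
            index=pd.Index([f"G{i}" for i in range(30)], name="protein"),
            columns=[f"S{i}" for i in range(8)],
        )
        scores, _ = pca_scores(values, n_components=7)  # rank = n_samples - 1
        X = values.to_numpy().T
        Xc = X - X.mean(axis=0)
        for i in range(8):
            for j in range(i + 1, 8):
                d_orig = np.linalg.norm(Xc[i] - Xc[j])
                d_pca = np.linalg.norm(scores.iloc[i] - scores.iloc[j])
                assert d_pca == pytest.approx(d_orig, rel=1e-9)

    def test_rank_overflow_is_error(self):
        values = pd.DataFrame(
            np.ones((3, 2)) + np.eye(3, 2),
            index=pd.Index(["a", "b", "c"], name="protein"),
            columns=["S1", "S2"],
        )
        with pytest.raises(ValidationError):
            pca_scores(values, n_components=2)


class TestHierarchicalClustering:
    def test_identical_items_merge_at_zero(self):
        df = pd.DataFrame(
            {"S1": [1.0, 2.0], "S2": [1.0, 2.0], "S3": [5.0, 9.0]},
            index=pd.Index(["G1", "G2"], name="protein"),
        )
        Z, order = hierarchical_cluster(df, axis="sample", distance="euclidean")
        assert Z[0, 2] == 0.0  # first merge height
        assert set(order) == {"S1", "S2", "S3"}

    def test_two_tight_clusters_recovered(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0, 0.05, (10, 2))
        b = rng.normal(5, 0.05, (10, 2))
        df = pd.DataFrame(
            np.hstack([a, b]),
            index=pd.Index([f"G{i}" for i in range(10)], name="protein"),
            columns=["A1", "A2", "B1", "B2"],
        )
        Z, order = hierarchical_cluster(df, axis="sample", distance="euclidean",
                                        linkage="complete")
        parts = cut_clusters(Z, order and list(df.columns), 2)
        assert parts["A1"] == parts["A2"]
        assert parts["B1"] == parts["B2"]
        assert parts["A1"] != parts["B1"]

    def test_complete_linkage_cophenetic_is_ultrametric(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame(
            rng.normal(0, 1, (12, 6)),
            index=pd.Index([f"G{i}" for i in range(12)], name="protein"),
            columns=[f"S{i}" for i in range(6)],
        )
        Z, _ = hierarchical_cluster(df, axis="sample", distance="euclidean",
                                    linkage="complete")
        from scipy.spatial.distance import squareform

        coph = squareform(cophenet(Z))
        n = coph.shape[0]
        for a in range(n):
            for b in range(n):
                for c in range(n):
                    assert coph[a, c] <= max(coph[a, b], coph[b, c]) + 1e-9


def test_screen_estimator_predict_matches_rowwise_rule(demo_cohort):
    matrix, meta, _ = demo_cohort
    newborns = list(meta.index[meta["group"] == "healthy_newborn"])
    linear = NormalizedMatrix(
        np.exp2(
            impute_downshift(
                log2_transform(normalize_actb(filter_by_evidence(matrix, 2, newborns))),
                ImputeParams(seed=3),
            ).values
        )
    )
    screen = ReferenceIntervalScreen().fit(linear, meta)
    flags = screen.predict(linear.values)
    ref = screen.reference_.table
    rng = np.random.default_rng(0)
    for protein in rng.choice(linear.proteins, 15, replace=False):
        for sample in rng.choice(linear.samples, 5, replace=False):
            expected = bool(
                linear.values.loc[protein, sample] < ref.loc[protein, "min"]
            )
            assert flags.loc[protein, sample] == expected
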