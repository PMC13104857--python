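"""EMD metric properties and on-/off-score behavior."""

import itertools
import math

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from morphoscore import (
    ProfileTable,
    ScreenConfig,
    derive_signatures,
    emd,
    generate_screen,
    off_score,
    on_score,
    reference_distance,
    score_screen,
)
from conftest import make_table


def emd_oracle_enumeration(X, Y):
    """Equal-size uniform OT by exhaustive enumeration of all matchings."""
    cost = cdist(X, Y)
    n = len(X)
    return min(
        np.mean([cost[i, p[i]] for i in range(n)]) for p in itertools.permutations(range(n))
    )


def emd_oracle_replication(X, Y):
    """Unequal sizes: replicate each sample to the LCM size, then a minimum-
    cost perfect matching is exact for uniform weights."""
    n, m = len(X), len(Y)
    l = math.lcm(n, m)
    Xr = np.repeat(X, l // n, axis=0)
    Yr = np.repeat(Y, l // m, axis=0)
    cost = cdist(Xr, Yr)
    rows, cols = linear_sum_assignment(cost)
    return cost[rows, cols].mean()


class TestEMD:
    def test_identity_of_indiscernibles(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 3))
        assert emd(X, X) == pytest.approx(0.0, abs=1e-12)

    def test_one_dimensional_sorted_matching(self):
        # sorted matching: (|0-2| + |1-3|) / 2
        assert emd([0.0, 1.0], [2.0, 3.0]) == pytest.approx(2.0)

    def test_two_dimensional_crossed_pairs(self):
        # two possible matchings, both cost 1 per unit mass
        assert emd([[0, 0], [1, 1]], [[0, 1], [1, 0]]) == pytest.approx(1.0)

    def test_matches_enumeration_oracle_equal_sizes(self):
        rng = np.random.default_rng(1)
        for _ in range(60):
            n = rng.integers(2, 6)
            d = rng.integers(1, 4)
            X, Y = rng.normal(size=(n, d)), rng.normal(size=(n, d))
            assert emd(X, Y) == pytest.approx(emd_oracle_enumeration(X, Y))

    def test_matches_replication_oracle_unequal_sizes(self):
        rng = np.random.default_rng(2)
        for _ in range(40):
            n, m = rng.integers(2, 9, size=2)
            d = rng.integers(1, 4)
            X, Y = rng.normal(size=(n, d)), rng.normal(size=(m, d))
            assert emd(X, Y) == pytest.approx(emd_oracle_replication(X, Y), abs=1e-8)

    def test_metric_properties_on_random_instances(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            pts = [rng.normal(size=(int(rng.integers(2, 7)), 2)) for _ in range(3)]
            dab, dbc, dac = emd(pts[0], pts[1]), emd(pts[1], pts[2]), emd(pts[0], pts[2])
            assert dab >= 0
            assert emd(pts[1], pts[0]) == pytest.approx(dab, abs=1e-8)
            assert dac <= dab + dbc + 1e-8

    def test_per_feature_mode_is_mean_of_marginal_distances(self):
        from scipy.stats import wasserstein_distance

        rng = np.random.default_rng(4)
        X, Y = rng.normal(size=(20, 3)), rng.normal(size=(15, 3))
        expected = np.mean([wasserstein_distance(X[:, j], Y[:, j]) for j in range(3)])
        assert emd(X, Y, mode="per_feature") == pytest.approx(expected)

    @pytest.mark.parametrize(
        "X, Y, err",
        [
            ([[1, 2]], [[1, 2, 3]], "dimension"),
            ([], [[1.0]], "non-empty"),
            ([[np.nan]], [[1.0]], "non-finite"),
        ],
    )
    def test_input_validation(self, X, Y, err):
        with pytest.raises(ValueError, match=err):
            emd(X, Y)


class TestReferenceDistance:
    def test_positive_and_stable_on_planted_screen(self):
        values = []
        for seed in range(5):
            table, _ = generate_screen(ScreenConfig(seed=seed, n_treatments=1))
            ref = table.select({"treatment": "reference"})
            tgt = table.select({"treatment": "target"})
            sig = derive_signatures(ref, tgt)
            values.append(reference_distance(ref, tgt, sig))
        values = np.asarray(values)
        assert np.all(values > 0)
        assert values.std() / values.mean() < 0.10  # CV under resampling

    def test_identical_point_sets_rejected(self, two_state_signature):
        ref, _, sig, _ = two_state_signature
        with pytest.raises(ValueError, match="zero"):
            reference_distance(ref, ref, sig)

    def test_pure_noise_off_feature_does_not_enter(self, two_state_signature):
        ref, tgt, sig, ref_dist = two_state_signature
        rng = np.random.default_rng(5)
        ref2 = ProfileTable(ref.data.assign(extra_noise=rng.normal(size=ref.n_cells)))
        tgt2 = ProfileTable(tgt.data.assign(extra_noise=rng.normal(size=tgt.n_cells)))
        assert reference_distance(ref2, tgt2, sig) == pytest.approx(ref_dist)

    def test_empty_on_signature_is_a_hard_error(self, two_state_signature):
        from dataclasses import replace

        ref, tgt, sig, _ = two_state_signature
        empty = replace(
            sig, on_features=[], off_features=list(sig.per_feature["feature"])
        )
        with pytest.raises(ValueError, match="indistinguishable"):
            reference_distance(ref, tgt, empty)


class TestOnScore:
    def test_reference_sample_scores_exactly_one(self, two_state_signature):
        ref, tgt, sig, ref_dist = two_state_signature
        assert on_score(ref, tgt, sig, ref_dist) == 1.0

    def test_target_sample_scores_exactly_zero(self, two_state_signature):
        _, tgt, sig, ref_dist = two_state_signature
        assert on_score(tgt, tgt, sig, ref_dist) == 0.0

    def test_extrapolated_population_scores_above_one(self, two_state_signature):
        # mean displaced 2x the reference-target gap away from the target
        ref, tgt, sig, ref_dist = two_state_signature
        gap = tgt.values().mean(axis=0) - ref.values().mean(axis=0)
        pushed = ProfileTable(
            ref.data.assign(**{
                c: ref.data[c] - 2 * gap[i] for i, c in enumerate(ref.feature_columns)
            })
        )
        assert on_score(pushed, tgt, sig, ref_dist) > 1.0

    def test_fresh_target_draw_scores_strictly_positive(self, two_state_screen, two_state_signature):
        # an independent draw from the target distribution (full-efficacy
        # treatment) cannot reach exactly 0: sampling noise keeps EMD > 0
        table, truth = two_state_screen
        _, tgt, sig, ref_dist = two_state_signature
        full = [t for t, lam in truth.efficacies.items() if lam == 1.0][0]
        fresh = table.select({"treatment": full})
        score = on_score(fresh, tgt, sig, ref_dist)
        assert 0.0 < score < 0.5

    def test_nonpositive_reference_distance_rejected(self, two_state_signature):
        ref, tgt, sig, _ = two_state_signature
        with pytest.raises(ValueError, match="positive"):
            on_score(ref, tgt, sig, 0.0)

    def test_monotone_in_efficacy_grid(self):
        # mean on-score strictly decreasing in lambda across seeded replicates
        for seed in (101, 102, 103):
            table, truth = generate_screen(
                ScreenConfig(seed=seed, n_cells_per_group=200)
            )
            ref = table.select({"treatment": "reference"})
            tgt = table.select({"treatment": "target"})
            sig = derive_signatures(ref, tgt)
            rd = reference_distance(ref, tgt, sig)
            lam_sorted = sorted(truth.efficacies, key=truth.efficacies.get)
            scores = [
                on_score(table.select({"treatment": t}), tgt, sig, rd) for t in lam_sorted
            ]
            assert all(a > b for a, b in zip(scores, scores[1:]))


class TestOffScore:
    def test_identical_populations_score_zero(self, two_state_signature):
        _, tgt, sig, _ = two_state_signature
        score, flags = off_score(tgt, tgt, sig)
        assert score == 0.0
        assert not flags.any()

    def test_all_off_features_shifted_scores_one(self, two_state_signature):
        _, tgt, sig, _ = two_state_signature
        shifted = ProfileTable(
            tgt.data.assign(**{c: tgt.data[c] + 3.0 for c in sig.off_features})
        )
        score, _ = off_score(shifted, tgt, sig)
        assert score == 1.0

    def test_known_fraction_of_shifted_off_features(self):
        # off-signature of 10 with exactly 3 shifted features -> 0.3
        rng = np.random.default_rng(7)
        names = [f"f{i}" for i in range(12)]
        ref = make_table({n: rng.standard_normal(500) for n in names}, t=["x"] * 500)
        tgt_cols = {n: rng.standard_normal(500) for n in names}
        tgt_cols["f0"] = tgt_cols["f0"] + 3.0
        tgt_cols["f1"] = tgt_cols["f1"] + 3.0
        tgt = make_table(tgt_cols, t=["x"] * 500)
        sig = derive_signatures(ref, tgt)
        assert sig.on_features == ["f0", "f1"] and len(sig.off_features) == 10
        pert_cols = {n: rng.standard_normal(500) for n in names}
        for n in sig.off_features[:3]:
            pert_cols[n] = pert_cols[n] + 3.0
        pert = make_table(pert_cols, t=["x"] * 500)
        score, flags = off_score(pert, ref, sig)
        assert score == pytest.approx(0.3)
        assert set(flags[flags].index) == set(sig.off_features[:3])

    def test_invariant_to_on_feature_changes(self, two_state_signature):
        _, tgt, sig, _ = two_state_signature
        rng = np.random.default_rng(8)
        pert = ProfileTable(
            tgt.data.assign(**{c: rng.normal(5, 2, tgt.n_cells) for c in sig.on_features})
        )
        score, _ = off_score(pert, tgt, sig)
        assert score == 0.0

    def test_empty_off_signature_is_an_error(self, two_state_signature):
        from dataclasses import replace

        _, tgt, sig, _ = two_state_signature
        empty = replace(sig, on_features=list(sig.per_feature["feature"]), off_features=[])
        with pytest.raises(ValueError, match="off-signature"):
            off_score(tgt, tgt, empty)


@pytest.fixture(scope="module")
def screen():
    return generate_screen(ScreenConfig(seed=21, n_treatments=2, n_wells=6, n_cells_per_group=120))


class TestScoreScreen:
    def test_pooled_anchoring_rows(self, screen):
        table, _ = screen
        ref_sel, tgt_sel = {"treatment": "reference"}, {"treatment": "target"}
        sig = derive_signatures(table.select(ref_sel), table.select(tgt_sel))
        out = score_screen(table, sig, ref_sel, tgt_sel, group_by=["Metadata_treatment"])
        assert len(out) == 4
        by_trt = out.set_index("Metadata_treatment")
        assert by_trt.loc["reference", "on_score"] == 1.0
        assert by_trt.loc["target", "on_score"] == 0.0

    def test_unpooled_row_count(self, screen):
        table, _ = screen
        ref_sel, tgt_sel = {"treatment": "reference"}, {"treatment": "target"}
        sig = derive_signatures(table.select(ref_sel), table.select(tgt_sel))
        out = score_screen(
            table, sig, ref_sel, tgt_sel, group_by=["Metadata_treatment"], pool_wells=False
        )
        assert len(out) == 4 * 6  # 4 conditions x 6 wells

    def test_sparse_wells_score_farther(self):
        # per-well on-scores under heavy subsampling correlate negatively
        # with cell count: sparser wells drift from the target
        from morphoscore import spearman_rho

        table, _ = generate_screen(
            ScreenConfig(seed=33, n_treatments=1, efficacy_grid=(1.0,), n_wells=8, n_cells_per_group=400)
        )
        rng = np.random.default_rng(34)
        # thin each well of the treatment to a random size
        df = table.data
        keep = []
        for well, idx in df[df["Metadata_treatment"] == "trt_01"].groupby("Metadata_well").groups.items():
            n = int(rng.integers(5, len(idx)))
            keep.extend(rng.choice(idx, size=n, replace=False))
        thinned = ProfileTable(
            ProfileTable(df).data.loc[sorted(set(keep) | set(df[df["Metadata_treatment"] != "trt_01"].index))]
        )
        ref_sel, tgt_sel = {"treatment": "reference"}, {"treatment": "target"}
        sig = derive_signatures(thinned.select(ref_sel), thinned.select(tgt_sel))
        out = score_screen(
            thinned, sig, ref_sel, tgt_sel, group_by=["Metadata_treatment"], pool_wells=False
        )
        trt = out[out["Metadata_treatment"] == "trt_01"]
        rho = spearman_rho(trt["n_cells"], trt["on_score"]).statistic
        assert rho < 0

    def test_empty_group_skipped_not_crashed(self, screen, caplog):
        table, _ = screen
        df = table.data.copy()
        df.loc[df.index[-1], "Metadata_treatment"] = "singleton"
        table2 = ProfileTable(df)
        ref_sel, tgt_sel = {"treatment": "reference"}, {"treatment": "target"}
        sig = derive_signatures(table2.select(ref_sel), table2.select(tgt_sel))
        out = score_screen(table2, sig, ref_sel, tgt_sel, group_by=["Metadata_treatment"])
        assert "singleton" not in set(out["Metadata_treatment"])
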