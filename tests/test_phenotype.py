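"""Three-stage classifier: thresholds, profile matching, regression rescue."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ibexniche as ix
from ibexniche.phenotype import (
    STAGE_EXCL_LISTED,
    STAGE_EXCL_UNMATCHED,
    STAGE_PROFILE,
    STAGE_REGRESSION,
    apply_exclusions,
    elbow_threshold,
    match_profiles,
    regress_unmatched,
    triage_unmatched,
)


def _mfi_frame(panel, rows):
    """Build a cell table from explicit per-marker values."""
    df = pd.DataFrame(rows, columns=["mfi_" + m for m in panel.markers])
    df.insert(0, "cell_id", np.arange(len(df)))
    return df


class TestElbowThreshold:
    def test_constant_vector_warns_and_returns_constant(self):
        with pytest.warns(UserWarning):
            t = elbow_threshold(np.full(100, 3.0))
        assert t == 3.0

    def test_bimodal_mixture_threshold_between_components(self):
        rng = np.random.default_rng(0)
        low = rng.lognormal(np.log(1.0), 0.1, 900)
        high = rng.lognormal(np.log(100.0), 0.1, 100)
        v = np.concatenate([low, high])
        t = elbow_threshold(v)
        assert 1.0 < t < 100.0
        called_pos = (v > t).sum()
        assert abs(called_pos - 100) <= 0.02 * len(v)

    def test_majority_positive_marker_still_split(self):
        """The elbow must find the valley even when positives dominate."""
        rng = np.random.default_rng(1)
        v = np.concatenate([rng.lognormal(3.0, 0.35, 600),
                            rng.lognormal(6.2, 0.35, 9400)])
        t = elbow_threshold(v)
        assert np.exp(3.0 + 3 * 0.35) < t < np.exp(6.2 - 3 * 0.35)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(scale=st.floats(min_value=1e-3, max_value=1e6),
           seed=st.integers(0, 10))
    def test_scale_equivariance(self, scale, seed):
        rng = np.random.default_rng(seed)
        v = np.concatenate([rng.lognormal(0, 0.3, 400),
                            rng.lognormal(4, 0.3, 100)])
        assert elbow_threshold(v * scale) == pytest.approx(
            elbow_threshold(v) * scale, rel=1e-9)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            elbow_threshold(np.arange(10.0))


class TestMatchProfiles:
    def test_clean_cell_matches_its_type(self, panel):
        thresholds = {m: 100.0 for m in panel.markers}
        prof = panel.profiles["cd4_t"]
        row = [500.0 if prof[m] == "+" else 20.0 for m in panel.markers]
        cells = _mfi_frame(panel, [row] * 60)
        reps, calls = match_profiles(cells, panel, thresholds, min_matched=20)
        assert (calls["stage"] == STAGE_PROFILE).all()
        assert (calls["assigned_type"] == "cd4_t").all()
        assert reps.loc["cd4_t", "n_matched"] == 60

    def test_double_positive_cell_unmatched(self, panel):
        thresholds = {m: 100.0 for m in panel.markers}
        # positive for the union of cd4_t and cd8_t markers: matches neither
        pos = {m for m in panel.markers
               if panel.profiles["cd4_t"][m] == "+" or panel.profiles["cd8_t"][m] == "+"}
        row = [500.0 if m in pos else 20.0 for m in panel.markers]
        cells = _mfi_frame(panel, [row])
        _, calls = match_profiles(cells, panel, thresholds)
        assert calls["stage"].isna().all()

    def test_undersized_type_dropped_from_dictionary(self, panel):
        thresholds = {m: 100.0 for m in panel.markers}
        prof_a = panel.profiles["nk"]
        prof_b = panel.profiles["cd8_t"]
        rows = [[500.0 if prof_a[m] == "+" else 20.0 for m in panel.markers]] * 30
        rows += [[500.0 if prof_b[m] == "+" else 20.0 for m in panel.markers]] * 5
        reps, _ = match_profiles(_mfi_frame(panel, rows), panel, thresholds,
                                 min_matched=20)
        assert "nk" in reps.index
        assert "cd8_t" not in reps.index

    def test_stage1_recovery_on_default_simulation(self, default_dataset,
                                                   default_calls):
        cells, truth = default_dataset
        calls, _ = default_calls
        stage1 = (calls["stage"] == STAGE_PROFILE).mean()
        assert stage1 >= 0.95
        merged = calls.merge(truth.cells, on="cell_id")
        m1 = merged[merged["stage"] == STAGE_PROFILE]
        assert (m1["assigned_type"] == m1["true_type"]).mean() >= 0.98


class TestRegressUnmatched:
    @pytest.fixture()
    def representatives(self, panel):
        rng = np.random.default_rng(3)
        markers = panel.markers
        reps = {}
        for t, prof in panel.profiles.items():
            reps[t] = [500.0 * (prof[m] == "+") + 20.0 for m in markers]
        df = pd.DataFrame(reps, index=markers).T
        df["n_matched"] = 100
        return df

    def _calls_for(self, cells):
        return pd.DataFrame({
            "cell_id": cells["cell_id"],
            "stage": [None] * len(cells),
            "assigned_type": [None] * len(cells),
            "coef": np.nan, "pval": np.nan,
        })

    def test_exact_profile_recovers_unit_coefficient(self, panel, representatives):
        markers = panel.markers
        row = representatives.loc["nk", markers].to_numpy()
        cells = _mfi_frame(panel, [row])
        calls = regress_unmatched(cells, representatives, self._calls_for(cells))
        assert calls.loc[0, "stage"] == STAGE_REGRESSION
        assert calls.loc[0, "assigned_type"] == "nk"
        assert calls.loc[0, "coef"] == pytest.approx(1.0, abs=1e-6)

    def test_dominant_mixture_component_wins(self, panel, representatives):
        markers = panel.markers
        rng = np.random.default_rng(4)
        mix = (0.7 * representatives.loc["cd4_t", markers].to_numpy()
               + 0.3 * representatives.loc["macrophage", markers].to_numpy())
        ok = 0
        cells = _mfi_frame(panel, [mix + rng.normal(0, 5.0, len(markers))
                                   for _ in range(50)])
        calls = regress_unmatched(cells, representatives, self._calls_for(cells))
        assigned = calls["assigned_type"]
        assert (assigned == "cd4_t").mean() >= 0.9

    def test_agrees_with_normal_equations_oracle(self, panel, representatives):
        """Stage-2 assignment must equal a brute-force least-squares solve
        from the normal equations, cell by cell."""
        markers = panel.markers
        X = representatives[markers].to_numpy().T
        types = list(representatives.index)
        rng = np.random.default_rng(5)
        rows = []
        for _ in range(200):
            w = rng.dirichlet(np.ones(len(types)) * 0.3)
            rows.append(X @ w + rng.normal(0, 10.0, len(markers)))
        cells = _mfi_frame(panel, rows)
        calls = regress_unmatched(cells, representatives, self._calls_for(cells),
                                  alpha=0.05)
        # oracle: normal equations + classical t-tests
        from scipy import stats as sps
        XtX_inv = np.linalg.inv(X.T @ X)
        H = XtX_inv @ X.T
        dof = X.shape[0] - X.shape[1]
        for i, row in enumerate(rows):
            beta = H @ np.asarray(row)
            resid = row - X @ beta
            s2 = resid @ resid / dof
            se = np.sqrt(np.diag(XtX_inv) * s2)
            tstat = beta / se
            pv = 2 * sps.t.sf(np.abs(tstat), dof)
            sig = (pv < 0.05) & (beta > 0)
            call = calls.loc[i]
            if sig.any():
                k = int(np.argmax(np.where(sig, beta, -np.inf)))
                assert call["stage"] == STAGE_REGRESSION
                assert call["assigned_type"] == types[k]
                assert call["coef"] == pytest.approx(beta[k], abs=1e-8)
            else:
                assert call["stage"] == STAGE_EXCL_UNMATCHED

    def test_collinear_representatives_rejected(self, panel, representatives):
        reps = representatives.copy()
        reps.loc["nk"] = reps.loc["cd8_t"]
        cells = _mfi_frame(panel, [reps.loc["cd4_t", panel.markers].to_numpy()])
        with pytest.raises(ValueError, match="collinear"):
            regress_unmatched(cells, reps, self._calls_for(cells))

    def test_noise_cells_excluded_at_expected_rate(self, panel):
        """A dataset salted with 8% pure-noise cells excludes 6-10%."""
        cells, truth = ix.simulate_cells(ix.SimConfig(
            n_samples_per_genotype=1, n_lesions_per_sample=10,
            n_background_cells=2000, field_size=(3000.0, 3000.0), seed=33))
        rng = np.random.default_rng(34)
        n_noise = int(round(0.08 / 0.92 * len(cells)))
        noise = {}
        for m in panel.markers:
            hot = rng.random(n_noise) < 0.5
            noise["mfi_" + m] = np.where(hot, rng.lognormal(6.2, 0.35, n_noise),
                                         rng.lognormal(3.0, 0.35, n_noise))
        noise_df = pd.DataFrame(noise)
        noise_df.insert(0, "sample_id", "control_1")
        noise_df.insert(1, "genotype", "control")
        noise_df.insert(2, "cell_id",
                        np.arange(len(cells), len(cells) + n_noise))
        noise_df.insert(3, "x_um", rng.uniform(0, 3000, n_noise))
        noise_df.insert(4, "y_um", rng.uniform(0, 3000, n_noise))
        noise_df.insert(5, "nucleus_area_um2", 35.0)
        salted = pd.concat([cells, noise_df], ignore_index=True)
        calls, report = ix.classify_cells(salted, seed=0)
        frac = report["fraction_unmatched_excluded"]
        assert 0.06 <= frac <= 0.10


class TestTriageAndExclusions:
    def test_single_marker_noise_flagged(self, panel):
        # three noise populations, each hot in a single different marker
        rng = np.random.default_rng(6)
        markers = panel.markers
        rows = []
        for i in range(300):
            base = rng.lognormal(3.0, 0.2, len(markers))
            base[i % 3] = rng.lognormal(6.5, 0.2)
            rows.append(base)
        cells = _mfi_frame(panel, rows)
        calls = pd.DataFrame({
            "cell_id": cells["cell_id"], "stage": STAGE_EXCL_UNMATCHED,
            "assigned_type": None, "coef": np.nan, "pval": np.nan,
        })
        rep = triage_unmatched(cells, calls, markers, k=3, seed=0)
        assert rep["single_marker_dominant"].all()
        assert set(rep["top_marker"]) == set(markers[:3])

    def test_k_larger_than_cells_raises(self, panel):
        cells = _mfi_frame(panel, [[1.0] * len(panel.markers)] * 3)
        calls = pd.DataFrame({
            "cell_id": cells["cell_id"], "stage": STAGE_EXCL_UNMATCHED,
            "assigned_type": None, "coef": np.nan, "pval": np.nan,
        })
        with pytest.raises(ValueError):
            triage_unmatched(cells, calls, panel.markers, k=10)

    def test_fixed_seed_reproducible(self, panel):
        rng = np.random.default_rng(7)
        cells = _mfi_frame(panel, rng.lognormal(3, 1, (100, len(panel.markers))))
        calls = pd.DataFrame({
            "cell_id": cells["cell_id"], "stage": STAGE_EXCL_UNMATCHED,
            "assigned_type": None, "coef": np.nan, "pval": np.nan,
        })
        a = triage_unmatched(cells, calls, panel.markers, k=4, seed=5)
        b = triage_unmatched(cells, calls, panel.markers, k=4, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_exclusion_list_moves_cells(self, panel):
        calls = pd.DataFrame({
            "cell_id": np.arange(1000),
            "stage": STAGE_PROFILE,
            "assigned_type": ["gd_t"] * 4 + ["nk"] * 996,
            "coef": np.nan, "pval": np.nan,
        })
        out = apply_exclusions(calls, panel)
        assert (out["stage"] == STAGE_EXCL_LISTED).sum() == 4
        assert out["assigned_type"].isna().sum() == 4

    def test_empty_exclusion_list_is_identity(self, panel):
        p2 = ix.PhenotypePanel(profiles=panel.profiles,
                               tumor_type_name=panel.tumor_type_name,
                               exclusion_list=[])
        calls = pd.DataFrame({
            "cell_id": [0], "stage": STAGE_PROFILE,
            "assigned_type": ["gd_t"], "coef": np.nan, "pval": np.nan,
        })
        out = apply_exclusions(calls, p2)
        pd.testing.assert_frame_equal(out, calls)


class TestEndToEnd:
    def test_partition_property(self, default_calls):
        calls, _ = default_calls
        assert calls["stage"].notna().all()
        assigned_stages = calls["stage"].isin([STAGE_PROFILE, STAGE_REGRESSION])
        assert (calls.loc[assigned_stages, "assigned_type"].notna()).all()
        assert (calls.loc[~assigned_stages, "assigned_type"].isna()).all()

    def test_overall_accuracy(self, default_dataset, default_calls):
        cells, truth = default_dataset
        calls, _ = default_calls
        merged = calls.merge(truth.cells, on="cell_id")
        assigned = merged[merged["assigned_type"].notna()]
        assert (assigned["assigned_type"] == assigned["true_type"]).mean() >= 0.95
        assert len(assigned) / len(merged) >= 0.90

    def test_marker_rescaling_leaves_stage1_unchanged(self, panel, small_dataset):
        cells, _ = small_dataset
        calls_a, _ = ix.classify_cells(cells, seed=0)
        scaled = cells.copy()
        scaled["mfi_cd45"] = scaled["mfi_cd45"] * 7.0
        calls_b, _ = ix.classify_cells(scaled, seed=0)
        a = calls_a[calls_a["stage"] == STAGE_PROFILE]
        b = calls_b[calls_b["stage"] == STAGE_PROFILE]
        pd.testing.assert_frame_equal(a[["cell_id", "assigned_type"]],
                                      b[["cell_id", "assigned_type"]])
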