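"""Generator tests: determinism, ground-truth semantics, recovery."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from connrel.connectome import build_edge_panel, correlation_matrix, vectorize_upper
from connrel.preprocess import concatenate_session, regress_global_signal
from connrel.reliability import edgewise_icc
from connrel.synthetic import (
    CohortSpec,
    EdgePanelTruth,
    default_population_correlation,
    generate_edge_panel,
    generate_timeseries_cohort,
    nearest_valid_correlation,
)


class TestEdgePanelTruth:
    def test_true_icc_is_variance_ratio(self):
        truth = EdgePanelTruth(
            n_subjects=10, n_edges=3, sigma_b_e=[0.1, 0.2, 0.0],
            sigma_w_e=[0.1, 0.1, 0.2],
        )
        expected = np.array([0.5, 0.04 / 0.05, 0.0])
        np.testing.assert_allclose(truth.true_icc_e, expected, rtol=1e-12)
        assert np.all((truth.true_icc_e >= 0) & (truth.true_icc_e < 1))

    def test_from_true_icc_round_trips(self):
        icc = np.array([0.0, 0.25, 0.8])
        truth = EdgePanelTruth.from_true_icc(icc, n_subjects=5)
        np.testing.assert_allclose(truth.true_icc_e, icc, atol=1e-12)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_subjects": 1, "n_edges": 2},
            {"n_subjects": 5, "n_edges": 2, "sigma_b_e": -0.1},
            {"n_subjects": 5, "n_edges": 2, "sigma_b_e": 0.0, "sigma_w_e": 0.0},
        ],
    )
    def test_invalid_truth_rejected(self, kwargs):
        with pytest.raises(ValueError):
            EdgePanelTruth(**kwargs)


class TestGenerateEdgePanel:
    def test_deterministic_given_seed(self):
        truth = EdgePanelTruth(n_subjects=8, n_edges=20, seed=3)
        a1, a2 = generate_edge_panel(truth)
        b1, b2 = generate_edge_panel(truth)
        np.testing.assert_array_equal(a1.values, b1.values)
        np.testing.assert_array_equal(a2.values, b2.values)

    def test_zero_within_variance_gives_perfect_icc(self):
        truth = EdgePanelTruth(
            n_subjects=10, n_edges=15, sigma_b_e=0.2, sigma_w_e=0.0, seed=1
        )
        p1, p2 = generate_edge_panel(truth)
        res = edgewise_icc(p1, p2)
        np.testing.assert_allclose(res.icc, 1.0, atol=1e-12)

    def test_no_between_signal_gives_null_icc(self):
        truth = EdgePanelTruth(
            n_subjects=500, n_edges=200, sigma_b_e=0.0, sigma_w_e=0.1, seed=2
        )
        p1, p2 = generate_edge_panel(truth)
        res = edgewise_icc(p1, p2)
        assert abs(np.median(res.icc)) < 0.1

    def test_estimates_track_truth(self):
        rng = np.random.default_rng(4)
        icc = rng.uniform(0.1, 0.9, 400)
        truth = EdgePanelTruth.from_true_icc(icc, n_subjects=200, seed=5)
        p1, p2 = generate_edge_panel(truth)
        res = edgewise_icc(p1, p2)
        r = np.corrcoef(icc, res.icc)[0, 1]
        assert r > 0.9

    def test_estimates_unbiased_at_half(self):
        truth = EdgePanelTruth.from_true_icc(
            np.full(1000, 0.5), n_subjects=200, seed=6
        )
        p1, p2 = generate_edge_panel(truth)
        res = edgewise_icc(p1, p2)
        assert abs(float(res.icc.mean()) - 0.5) < 0.03


class TestNearestValidCorrelation:
    def test_identity_unchanged(self):
        eye = np.eye(4)
        np.testing.assert_array_equal(nearest_valid_correlation(eye), eye)

    def test_valid_input_idempotent(self):
        corr = default_population_correlation(12)
        out = nearest_valid_correlation(corr)
        np.testing.assert_allclose(out, corr, atol=1e-12)

    def test_projects_indefinite_matrix(self):
        a = np.array([[1.0, 0.9, 0.0], [0.9, 1.0, 0.9], [0.0, 0.9, 1.0]])
        assert np.linalg.eigvalsh(a).min() < 0
        out = nearest_valid_correlation(a)
        assert np.linalg.eigvalsh(out).min() >= -1e-10
        np.testing.assert_array_equal(np.diag(out), np.ones(3))
        out2 = nearest_valid_correlation(out)
        np.testing.assert_allclose(out, out2, atol=1e-12)

    def test_rejects_nonsquare_and_asymmetric(self):
        with pytest.raises(ValueError):
            nearest_valid_correlation(np.zeros((2, 3)))
        bad = np.array([[1.0, 0.5], [0.2, 1.0]])
        with pytest.raises(ValueError):
            nearest_valid_correlation(bad)

    @given(
        arrays(
            float,
            (5, 5),
            elements=st.floats(-1.5, 1.5, allow_nan=False, width=32),
        )
    )
    def test_output_always_valid_correlation(self, raw):
        a = 0.5 * (raw + raw.T)
        out = nearest_valid_correlation(a)
        np.testing.assert_array_equal(np.diag(out), np.ones(5))
        np.testing.assert_allclose(out, out.T, atol=1e-12)
        assert np.linalg.eigvalsh(out).min() >= -1e-10


class TestTimeseriesCohort:
    def test_deterministic_given_seed(self):
        spec = CohortSpec(n_subjects=3, n_regions=10,
                          n_timepoints_per_run=120, seed=9)
        a = generate_timeseries_cohort(spec)
        b = generate_timeseries_cohort(spec)
        for sa, sb in zip(a.subjects, b.subjects):
            for ses in (1, 2):
                for ra, rb in zip(sa.sessions[ses], sb.sessions[ses]):
                    np.testing.assert_array_equal(ra.signal, rb.signal)
                    np.testing.assert_array_equal(ra.rms, rb.rms)

    def test_subject_substreams_stable_under_cohort_growth(self):
        small = generate_timeseries_cohort(
            CohortSpec(n_subjects=2, n_regions=8, n_timepoints_per_run=80, seed=4)
        )
        large = generate_timeseries_cohort(
            CohortSpec(n_subjects=4, n_regions=8, n_timepoints_per_run=80, seed=4)
        )
        np.testing.assert_array_equal(
            small.subjects[1].sessions[2][0].signal,
            large.subjects[1].sessions[2][0].signal,
        )

    def test_spike_fraction_matches_rate(self):
        spec = CohortSpec(
            n_subjects=4, n_regions=8, n_timepoints_per_run=1000,
            spike_rate=0.2, spike_rms=0.5, seed=7,
        )
        cohort = generate_timeseries_cohort(spec)
        flagged = np.mean(
            [
                (run.rms > 0.30).mean()
                for subj in cohort.subjects
                for ses in (1, 2)
                for run in subj.sessions[ses]
            ]
        )
        # 32,000 Bernoulli(0.2) frames: 5 sigma ~ 0.011
        assert abs(flagged - 0.2) < 0.015

    def test_rms_trace_conventions(self):
        cohort = generate_timeseries_cohort(
            CohortSpec(n_subjects=2, n_regions=6, n_timepoints_per_run=200, seed=1)
        )
        run = cohort.subjects[0].sessions[1][0]
        assert run.rms[0] == 0.0
        spikes = run.rms > 0.30
        assert np.all(run.rms[~spikes] < 0.30)
        assert np.all(run.rms[spikes] == 0.5)

    def test_no_subject_variation_shares_latent_structure(self):
        spec = CohortSpec(
            n_subjects=4, n_regions=10, n_timepoints_per_run=600,
            subject_dev_sd=0.0, session_dev_sd=0.0, global_amp_sd=0.0,
            global_amp_mean=0.0, spike_rate=0.0, seed=3,
        )
        cohort = generate_timeseries_cohort(spec)
        latents = cohort.truth.subject_latents
        for latent in latents[1:]:
            np.testing.assert_allclose(latent, latents[0], atol=1e-12)
        # session FC matrices agree within sampling error, closer as T grows
        def session_gap(n_t):
            s = CohortSpec(
                n_subjects=3, n_regions=10, n_timepoints_per_run=n_t,
                subject_dev_sd=0.0, session_dev_sd=0.0, global_amp_sd=0.0,
                global_amp_mean=0.0, spike_rate=0.0, seed=3,
            )
            c = generate_timeseries_cohort(s)
            gaps = []
            for subj in c.subjects:
                fc = {}
                for ses in (1, 2):
                    ts = concatenate_session(subj.sessions[ses])
                    fc[ses] = vectorize_upper(
                        correlation_matrix(ts).values
                    )
                gaps.append(np.abs(fc[1] - fc[2]).mean())
            return np.mean(gaps)

        assert session_gap(1600) < session_gap(100)

    def test_global_component_inflates_fc_until_regressed(self):
        spec = CohortSpec(
            n_subjects=4, n_regions=12, n_timepoints_per_run=800,
            subject_dev_sd=0.0, session_dev_sd=0.0,
            global_amp_mean=1.0, global_amp_sd=0.3, spike_rate=0.0, seed=5,
        )
        cohort = generate_timeseries_cohort(spec)
        latent_mean = vectorize_upper(cohort.truth.subject_latents[0]).mean()
        raw_means, gsr_means = [], []
        for subj in cohort.subjects:
            run = subj.sessions[1][0]
            raw_means.append(
                vectorize_upper(np.corrcoef(run.signal, rowvar=False)).mean()
            )
            clean = regress_global_signal(run)
            gsr_means.append(
                vectorize_upper(np.corrcoef(clean.signal, rowvar=False)).mean()
            )
        raw_gap = np.mean(raw_means) - latent_mean
        gsr_gap = abs(np.mean(gsr_means) - latent_mean)
        assert raw_gap > 0.05
        assert gsr_gap < raw_gap

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(n_subjects=0)
        with pytest.raises(ValueError):
            CohortSpec(n_subjects=2, spike_rate=0.1, spike_rms=0.2)
        with pytest.raises(ValueError):
            CohortSpec(n_subjects=2, n_runs_per_session=0)
        bad_corr = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError):
            CohortSpec(n_subjects=2, pop_corr=bad_corr)


class TestFullPipelineRecovery:
    def test_dispersion_drives_estimated_icc(self, cohort100, panels100):
        """Edges whose latent FC varies more across subjects are estimated
        as more reliable (positive rank correlation)."""
        from connrel.inference import spearman

        p1, p2 = panels100[False]
        res = edgewise_icc(p1, p2)
        disp = cohort100.truth.between_subject_edge_sd()
        outcome = spearman(disp, res.icc)
        assert outcome.statistic > 0
        assert outcome.p_value < 0.01
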