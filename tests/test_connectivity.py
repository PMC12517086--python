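"""Symmetric orthogonalisation, envelopes, AEC, activity, feature tables."""

import itertools

import pandas as pd

import numpy as np
import pytest

from painconn.connectivity import (
    aec_matrix,
    amplitude_envelope,
    network_activity,
    symmetric_orthogonalise,
)
from painconn.representative import pca_representative

FS = 250.0


def _band_limited(rng, k, n, lo=8, hi=13):
    from painconn.datatypes import BandSpec
    from painconn.synthetic import _bandlimited_noise

    return _bandlimited_noise(k, n, FS, BandSpec("x", lo, hi), rng)


class TestSymmetricOrthogonalise:
    def test_orthogonal_input_is_fixed_point(self):
        rng = np.random.default_rng(0)
        Q, _ = np.linalg.qr(rng.standard_normal((100, 3)))
        X = (Q * [2.0, 3.0, 0.5]).T
        Y = symmetric_orthogonalise(X)
        np.testing.assert_allclose(Y, X, atol=1e-8)

    def test_output_gram_is_diagonal(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((4, 200))
        Y = symmetric_orthogonalise(X)
        G = Y @ Y.T
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8

    def test_near_duplicate_rows_keep_own_identity(self):
        rng = np.random.default_rng(2)
        s = rng.standard_normal(300)
        X = np.vstack([s + 0.05 * rng.standard_normal(300),
                       s + 0.05 * rng.standard_normal(300)])
        Y = symmetric_orthogonalise(X)
        assert abs(Y[0] @ Y[1]) < 1e-8
        for i in range(2):
            assert np.corrcoef(Y[i], X[i])[0, 1] > 0

    def test_symmetric_treatment_of_rows(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((3, 150))
        Y1 = symmetric_orthogonalise(X)
        Y2 = symmetric_orthogonalise(X[::-1])[::-1]
        np.testing.assert_allclose(Y1, Y2, atol=1e-7)

    def test_rank_deficient_errors(self):
        x = np.arange(50.0)
        with pytest.raises(ValueError, match="rank"):
            symmetric_orthogonalise(np.vstack([x, 2 * x]))


class TestAmplitudeEnvelope:
    def test_pure_sinusoid_envelope_is_amplitude(self):
        t = np.arange(2500) / FS
        x = 3.0 * np.sin(2 * np.pi * 10 * t)
        env = amplitude_envelope(x[None])[0]
        interior = env[250:-250]
        np.testing.assert_allclose(interior, 3.0, rtol=0.01)

    def test_am_carrier_demodulation(self):
        t = np.arange(5000) / FS
        a = 1.5 + np.sin(2 * np.pi * 0.3 * t)  # slow nonneg modulator
        x = a * np.cos(2 * np.pi * 11 * t)
        env = amplitude_envelope(x[None])[0]
        interior = slice(500, -500)
        assert np.max(np.abs(env[interior] - a[interior])) < 0.1

    def test_scaling_homogeneity(self):
        rng = np.random.default_rng(4)
        x = _band_limited(rng, 1, 2000)
        e1 = amplitude_envelope(x)
        e2 = amplitude_envelope(-2.5 * x)
        np.testing.assert_allclose(e2, 2.5 * e1, rtol=1e-10)


class TestAEC:
    def test_sixty_three_features_layout(self):
        from painconn.synthetic import connectivity_feature_names

        names = connectivity_feature_names()
        assert len(names) == 63
        per_band = [n for n in names if n.startswith("theta_")]
        assert len(per_band) == 21

    def test_independent_networks_near_zero(self):
        rng = np.random.default_rng(5)
        sigs = _band_limited(rng, 7, int(120 * FS))
        C = aec_matrix(sigs, FS)
        off = C[np.triu_indices(7, 1)]
        # null band: envelope autocorrelation leaves ~0.05-0.1 sampling sd
        assert np.nanmean(np.abs(off)) < 0.08
        assert np.nanmax(np.abs(off)) < 0.25
        assert np.all(np.isnan(np.diag(C)))

    def test_symmetry_and_range(self):
        rng = np.random.default_rng(6)
        sigs = _band_limited(rng, 4, int(30 * FS))
        C = aec_matrix(sigs, FS)
        np.testing.assert_allclose(C, C.T, atol=1e-12)
        off = C[np.triu_indices(4, 1)]
        assert np.all(np.abs(off) <= 1)

    def test_leakage_suppression_on_shared_source(self):
        # two sensors observing one common source: raw AEC is inflated,
        # symmetric orthogonalisation suppresses it
        rng = np.random.default_rng(7)
        s = _band_limited(rng, 1, int(60 * FS))[0]
        n1 = _band_limited(rng, 1, int(60 * FS))[0]
        n2 = _band_limited(rng, 1, int(60 * FS))[0]
        X = np.vstack([s + 0.6 * n1, 0.8 * s + 0.6 * n2])
        raw = aec_matrix(X, FS, orthogonalise=False)[0, 1]
        corrected = aec_matrix(X, FS, orthogonalise=True)[0, 1]
        assert raw > 0.4
        assert abs(corrected) < 0.15

    def test_planted_ordering_preserved(self):
        from painconn.synthetic import simulate_network_sources

        lo_vals, hi_vals = [], []
        for seed in range(5):
            C = np.eye(3)
            C[0, 1] = C[1, 0] = 0.2
            C[0, 2] = C[2, 0] = 0.5
            tr = simulate_network_sources(C, "alpha", 120, FS, seed)
            est = aec_matrix(tr.network_signals, FS, orthogonalise=False)
            lo_vals.append(est[0, 1])
            hi_vals.append(est[0, 2])
        assert np.mean(hi_vals) > np.mean(lo_vals)

    def test_epochwise_fisher_average(self):
        rng = np.random.default_rng(8)
        sigs = _band_limited(rng, 3, 3 * 500).reshape(3, 3, 500).transpose(1, 0, 2)
        C = aec_matrix(sigs, FS)
        assert C.shape == (3, 3)
        assert np.all(np.isfinite(C[np.triu_indices(3, 1)]))


class TestActivity:
    def test_single_row_full_explanation(self):
        rng = np.random.default_rng(9)
        s = rng.standard_normal(400)
        s -= s.mean()
        sol = pca_representative(s[None])
        act = network_activity(sol, s[None])
        assert act == pytest.approx(np.log(np.sum(s**2)))

    def test_scaling_adds_two_log_c(self):
        rng = np.random.default_rng(10)
        X = rng.standard_normal((3, 300))
        X -= X.mean(1, keepdims=True)
        sol = pca_representative(X)
        a1 = network_activity(sol, X)
        a2 = network_activity(sol, 5.0 * X)
        assert a2 - a1 == pytest.approx(2 * np.log(5.0))

    def test_orthogonal_representative_errors(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((2, 100))
        X -= X.mean(1, keepdims=True)
        q, _ = np.linalg.qr(np.vstack([X, rng.standard_normal((1, 100))]).T)
        from painconn.datatypes import RepresentativeSolution

        sol = RepresentativeSolution(
            r=q[:, 2], w=np.zeros(2), nu=0.0, objective=0.0, converged=True
        )
        with pytest.raises(ValueError, match="zero explained"):
            network_activity(sol, X)


class TestFeatureTable:
    def test_network7_connectivity_column_count(self, toy_leadfield):
        from painconn.connectivity import build_feature_table
        from painconn.synthetic import simulate_signal_cohort

        recs = list(simulate_signal_cohort(2, toy_leadfield, seed=3, duration_s=24))
        feats, meta = build_feature_table(
            recs, toy_leadfield, n_epochs_required=20, restarts=1
        )
        assert feats.shape == (2, 63)
        assert meta.loc[feats.index[0], "site"] == "sim"
        per_band = [c for c in feats.columns if c.startswith("alpha_")]
        assert len(per_band) == 21

    def test_activity_column_count(self, toy_leadfield):
        from painconn.connectivity import build_feature_table
        from painconn.synthetic import simulate_signal_cohort

        recs = list(simulate_signal_cohort(1, toy_leadfield, seed=4, duration_s=24))
        feats, _ = build_feature_table(
            recs, toy_leadfield, feature="activity", n_epochs_required=20, restarts=1
        )
        assert feats.shape == (1, 21)  # 7 networks x 3 bands

    def test_parcel_level_combinatorial_count(self, toy_leadfield):
        from painconn.connectivity import _structure_labels

        labels, names = _structure_labels(toy_leadfield, "parcel100")
        n = len(names)
        n_pairs = len(list(itertools.combinations(range(n), 2)))
        assert n == toy_leadfield.n_parcels
        assert n_pairs == n * (n - 1) // 2

    def test_exclusion_of_short_recordings(self, toy_leadfield):
        from painconn.connectivity import build_feature_table
        from painconn.synthetic import simulate_signal_cohort

        recs = list(simulate_signal_cohort(2, toy_leadfield, seed=5, duration_s=24))
        # second participant: too few epochs
        meta2, rec2 = recs[1]
        rec2.clean_flags[5:] = False
        feats, meta = build_feature_table(
            recs, toy_leadfield, n_epochs_required=20, restarts=1,
            bands={"alpha": (8.0, 13.0)},
        )
        assert len(feats) == 1
        assert meta2["participant_id"] not in feats.index


def test_diagnostics_dump_and_long_export(toy_leadfield):
    from painconn.connectivity import build_feature_table, connectivity_matrix_to_long
    from painconn.synthetic import simulate_signal_cohort

    recs = list(simulate_signal_cohort(1, toy_leadfield, seed=6, duration_s=24))
    diag = []
    build_feature_table(
        recs, toy_leadfield, n_epochs_required=20, restarts=1,
        bands={"alpha": (8.0, 13.0)}, diagnostics_out=diag,
    )
    tab = pd.DataFrame(diag)
    assert len(tab) == 7  # one entry per network for the single band
    assert tab["converged"].all()
    assert ((tab["nu"] > 0) & (tab["nu"] <= 1)).all()
    assert set(tab.columns) >= {"participant_id", "band", "structure",
                                "objective", "nu", "converged"}

    C = np.eye(3)
    C[0, 1] = C[1, 0] = 0.4
    long = connectivity_matrix_to_long(C, "alpha", ["a", "b", "c"])
    assert len(long) == 3
    assert long.loc[0, "aec"] == 0.4


def test_pairwise_and_per_epoch_feature_paths():
    from painconn.connectivity import build_feature_table, participant_band_features
    from painconn.datatypes import BandSpec
    from painconn.synthetic import make_toy_leadfield, simulate_signal_cohort

    lf = make_toy_leadfield(n_sensors=12, n_parcels=8, n_networks=4, seed=2)
    recs = list(simulate_signal_cohort(1, lf, seed=8, duration_s=16))
    meta, rec = recs[0]
    band = BandSpec("alpha", 8.0, 13.0)

    pw = participant_band_features(rec, lf, band, method="pairwise", restarts=1)
    assert len(pw) == 6  # C(4,2) pairs
    assert all(-1 <= v <= 1 for v in pw.values())

    pe = participant_band_features(
        rec, lf, band, epoch_mode="per_epoch", restarts=1, nc=2
    )
    assert len(pe) == 6
    assert all(np.isfinite(v) for v in pe.values())

    with pytest.raises(ValueError, match="activity"):
        participant_band_features(rec, lf, band, method="pairwise",
                                  feature="activity")
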