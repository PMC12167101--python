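"""Fusion network: scaling, splits, determinism and error correction."""

import numpy as np
import pytest

from nsa_vision.fusion import (
    FusionConfig,
    NsaRecord,
    load_model,
    predict_fused,
    records_from_csv,
    records_to_csv,
    save_model,
    scale_nsa,
    train_fusion,
    unscale_nsa,
)


def make_records(n, rng, truth_fn, lateral_sd=3.0):
    """Synthetic record cohort; clinician NSA given by ``truth_fn(ap, lat)``."""
    records = []
    for i in range(n):
        ap = float(rng.uniform(120, 160))
        lat = float(np.clip(ap + rng.normal(0, lateral_sd), 95, 175))
        records.append(
            NsaRecord(
                hip_id=f"h{i:03d}",
                patient_id=f"h{i:03d}",
                nsa_ap_cv=ap,
                nsa_lateral_cv=lat,
                nsa_ap_clinician=float(np.clip(truth_fn(ap, lat), 91, 179)),
            )
        )
    return records


class TestScaleNsa:
    def test_range_min_maps_to_zero(self):
        cfg = FusionConfig()
        assert scale_nsa(cfg.nsa_scale_min, cfg) == 0.0

    def test_midpoint_maps_to_half(self):
        cfg = FusionConfig()
        assert scale_nsa(135.0, cfg) == pytest.approx(0.5)

    def test_round_trip_exact(self):
        cfg = FusionConfig()
        assert unscale_nsa(scale_nsa(137.2, cfg), cfg) == pytest.approx(137.2, abs=1e-9)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            scale_nsa(89.0, FusionConfig())


class TestSplit:
    def test_57_records_split_45_12(self, rng):
        records = make_records(57, rng, lambda ap, lat: ap)
        cfg = FusionConfig(split_by="hip")
        _, report = train_fusion(records, cfg)
        assert len(report.train_ids) == 45
        assert len(report.test_ids) == 12

    def test_patient_split_keeps_bilateral_hips_together(self, rng):
        records = []
        for i in range(20):
            for side in ("L", "R"):
                ap = float(rng.uniform(120, 160))
                records.append(
                    NsaRecord(f"p{i:02d}_{side}", f"p{i:02d}", ap, ap + 1.0, ap)
                )
        _, report = train_fusion(records, FusionConfig(split_by="patient"))
        train_patients = {h[:3] for h in report.train_ids}
        test_patients = {h[:3] for h in report.test_ids}
        assert not train_patients & test_patients

    def test_too_few_records_rejected(self, rng):
        records = make_records(3, rng, lambda ap, lat: ap)
        with pytest.raises(ValueError):
            train_fusion(records, FusionConfig())

    def test_out_of_range_record_flagged_and_excluded(self, rng):
        records = make_records(20, rng, lambda ap, lat: ap)
        records.append(NsaRecord("weird", "weird", 35.0, 130.0, 130.0))
        with pytest.warns(UserWarning, match="excluded"):
            _, report = train_fusion(records, FusionConfig())
        assert report.excluded_ids == ["weird"]


class TestTrainingContracts:
    def test_same_seed_same_predictions(self, rng):
        records = make_records(30, rng, lambda ap, lat: 0.7 * ap + 0.3 * lat)
        cfg = FusionConfig(seed=5)
        m1, r1 = train_fusion(records, cfg)
        m2, r2 = train_fusion(records, cfg)
        assert r1.test_ids == r2.test_ids
        p1 = predict_fused(m1, 140.0, 138.0)
        p2 = predict_fused(m2, 140.0, 138.0)
        assert p1 == p2

    def test_prediction_bounded_by_scale_range(self, rng):
        records = make_records(30, rng, lambda ap, lat: ap)
        cfg = FusionConfig()
        model, _ = train_fusion(records, cfg)
        for ap, lat in [(91.0, 179.0), (179.0, 91.0), (135.0, 135.0)]:
            out = predict_fused(model, ap, lat)
            assert cfg.nsa_scale_min < out < cfg.nsa_scale_max

    def test_untrained_model_rejected(self):
        from nsa_vision.fusion import FusionModel

        with pytest.raises(RuntimeError):
            predict_fused(FusionModel(FusionConfig()), 135.0, 130.0)

    def test_inputs_are_not_symmetric(self, rng):
        records = make_records(40, rng, lambda ap, lat: 0.9 * ap + 0.1 * lat)
        model, _ = train_fusion(records, FusionConfig(seed=2))
        assert predict_fused(model, 150.0, 125.0) != predict_fused(model, 125.0, 150.0)

    @pytest.mark.parametrize("loss", ["bce_on_scaled", "mse"])
    def test_identity_task_converges_below_one_degree(self, loss, rng):
        # degenerate task: clinician NSA equals the AP input exactly
        records = make_records(60, rng, lambda ap, lat: ap)
        cfg = FusionConfig(loss=loss, seed=1, split_by="hip")
        model, report = train_fusion(records, cfg)
        test = [r for r in records if r.hip_id in set(report.test_ids)]
        errors = [
            abs(predict_fused(model, r.nsa_ap_cv, r.nsa_lateral_cv) - r.nsa_ap_clinician)
            for r in test
        ]
        assert np.mean(errors) <= 1.0

    def test_fusion_beats_single_view_when_truth_is_view_average(self):
        # cohort where the clinician value is the average of both views
        # plus noise: using both features must beat the AP feature alone
        rng = np.random.default_rng(7)
        records = []
        for i in range(200):
            truth = float(rng.uniform(120, 160))
            ap = truth + float(rng.normal(0, 3))
            lat = truth + float(rng.normal(0, 3))
            clin = 0.5 * (ap + lat) + float(rng.normal(0, 1))
            records.append(NsaRecord(f"h{i:03d}", f"h{i:03d}", ap, lat, clin))
        model, report = train_fusion(records, FusionConfig(seed=3, split_by="hip"))
        test = [r for r in records if r.hip_id in set(report.test_ids)]
        truth_vals = np.array([r.nsa_ap_clinician for r in test])
        fused = np.array(
            [predict_fused(model, r.nsa_ap_cv, r.nsa_lateral_cv) for r in test]
        )
        ap_only = np.array([r.nsa_ap_cv for r in test])
        assert np.mean(np.abs(fused - truth_vals)) < np.mean(np.abs(ap_only - truth_vals))


class TestSerialisation:
    def test_records_csv_round_trip(self, tmp_path, rng):
        records = make_records(6, rng, lambda ap, lat: ap)
        path = tmp_path / "records.csv"
        records_to_csv(records, path)
        loaded = records_from_csv(path)
        assert [r.hip_id for r in loaded] == [r.hip_id for r in records]
        assert loaded[0].nsa_ap_cv == pytest.approx(records[0].nsa_ap_cv, abs=1e-6)

    def test_model_save_load_identical_predictions(self, tmp_path, rng):
        records = make_records(20, rng, lambda ap, lat: ap)
        model, _ = train_fusion(records, FusionConfig(seed=4))
        path = tmp_path / "model.json"
        save_model(model, path)
        loaded = load_model(path)
        assert predict_fused(loaded, 140.0, 137.0) == pytest.approx(
            predict_fused(model, 140.0, 137.0), abs=1e-12
        )
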