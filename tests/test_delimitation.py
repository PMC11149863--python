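"""Hard and moderate negative filters."""

import numpy as np
import pytest

from ziphid.clustering import ClusterConfig
from ziphid.delimitation import (
    HardFilterConfig,
    ModerateFilterConfig,
    click_passes_hard_rules,
    hard_negative_filter,
    moderate_negative_filter,
)
from ziphid.features import ClickMetrics
from ziphid.simulate import SceneEvent, scene_detections
from ziphid.templates import template_by_name

FS = 200_000.0


def rising_envelope(n=120):
    """Envelope that rises through the first 0.1 ms and stays high."""
    return np.concatenate([np.linspace(0.3, 1.0, 30), np.full(n - 30, 0.95)])


def decaying_envelope(n=120):
    """Impulsive decay: negative initial slope."""
    return np.exp(-np.arange(n) / 15.0)


def metrics(duration=400.0, peak=40.0, center=30.0, sweep=30.0, envelope=None):
    return ClickMetrics(
        peak_freq=peak,
        center_freq=center,
        duration=duration,
        sweep_rate=sweep,
        envelope=rising_envelope() if envelope is None else envelope,
        rl_pp=130.0,
        sample_rate=FS,
    )


class TestHardRules:
    def test_compliant_click_passes(self):
        ok, flags = click_passes_hard_rules(metrics())
        assert ok and all(flags.values())

    @pytest.mark.parametrize(
        "kwargs, failing_rule",
        [
            (dict(duration=354.9), "duration"),
            (dict(peak=31.9), "peak_freq"),
            (dict(center=24.9), "center_freq"),
            (dict(sweep=22.9), "sweep_rate"),
            (dict(sweep=float("nan")), "sweep_rate"),
            (dict(envelope=decaying_envelope()), "envelope"),
        ],
    )
    def test_each_threshold_is_a_hard_gate(self, kwargs, failing_rule):
        ok, flags = click_passes_hard_rules(metrics(**kwargs))
        assert not ok
        assert not flags[failing_rule]
        assert all(v for k, v in flags.items() if k != failing_rule)

    @pytest.mark.parametrize(
        "kwargs",
        [dict(duration=355.0), dict(peak=32.0), dict(center=25.0), dict(sweep=23.0)],
    )
    def test_thresholds_are_inclusive(self, kwargs):
        ok, _ = click_passes_hard_rules(metrics(**kwargs))
        assert ok

    def test_envelope_sustain_rule(self):
        # rises for 0.1 ms then collapses below 50% during the sustain window
        env = np.concatenate([np.linspace(0.2, 1.0, 20), np.full(100, 0.3)])
        ok, flags = click_passes_hard_rules(metrics(envelope=env))
        assert not ok and not flags["envelope"]

    def test_envelope_too_short_fails(self):
        # 25 samples = 125 us: shorter than the 0.2-ms rise+sustain window
        ok, flags = click_passes_hard_rules(metrics(envelope=np.linspace(0.3, 1.0, 25)))
        assert not flags["envelope"]


def interval_scene(seed, n_intervals=12):
    """Mixed Zc / delphinid scene spanning several 75-s intervals."""
    rng = np.random.default_rng(seed)
    events = []
    for k in range(n_intervals):
        base = k * 75.0 + 1.0
        n_zc = int(rng.integers(0, 12))
        n_de = int(rng.integers(1, 15))
        if n_zc:
            events.append(SceneEvent(template_by_name("Zc"), base, n_zc, 130.0))
        events.append(SceneEvent(template_by_name("De spp"), base + 20.0, n_de, 130.0))
    return scene_detections(events, seed=seed)


class TestHardNegativeFilter:
    def test_interval_rule_arithmetic(self):
        cfg = HardFilterConfig()
        # 6 of 100 passing: dropped; 2 of 10 passing: retained
        assert not (6 >= cfg.min_candidates or 6 / 100 >= cfg.min_fraction)
        assert 2 / 10 >= cfg.min_fraction

    def test_retention_matches_direct_counting(self):
        dets, _ = interval_scene(seed=0)
        cfg = HardFilterConfig()
        kept, report = hard_negative_filter(dets, cfg)
        starts = np.array([d.start_time for d in dets])
        ivs = np.floor(starts / cfg.interval_length).astype(int)
        from ziphid.features import click_metrics

        passes = np.array([click_passes_hard_rules(click_metrics(d), cfg)[0] for d in dets])
        for _, row in report.iterrows():
            mask = ivs == row.interval_id
            n_pass = passes[mask].sum()
            expected = n_pass >= cfg.min_candidates or n_pass / mask.sum() >= cfg.min_fraction
            assert row.retained == expected
        kept_ids = {d.click_id for d in kept}
        retained_ivs = set(report.loc[report.retained, "interval_id"])
        assert kept_ids == {d.click_id for d, iv in zip(dets, ivs) if iv in retained_ivs}

    def test_subset_order_and_idempotence(self):
        dets, _ = interval_scene(seed=1)
        kept, _ = hard_negative_filter(dets)
        ids = [d.click_id for d in kept]
        assert ids == sorted(ids)
        assert set(ids) <= {d.click_id for d in dets}
        again, _ = hard_negative_filter(kept)
        assert [d.click_id for d in again] == ids

    def test_threshold_monotonicity(self):
        dets, _ = interval_scene(seed=2)
        counts = []
        for dur in (300.0, 355.0, 420.0, 500.0):
            kept, _ = hard_negative_filter(dets, HardFilterConfig(min_duration=dur))
            counts.append(len(kept))
        assert counts == sorted(counts, reverse=True)

    def test_delphinid_only_scene_removed(self):
        events = [
            SceneEvent(template_by_name("De spp"), k * 75.0 + 1.0, 40, 130.0)
            for k in range(4)
        ]
        dets, _ = scene_detections(events, seed=3)
        kept, _ = hard_negative_filter(dets)
        assert len(kept) <= 0.01 * len(dets)

    def test_beaked_whale_intervals_retained(self):
        events = [
            SceneEvent(template_by_name("Zc"), k * 75.0 + 1.0, 10, 130.0) for k in range(5)
        ]
        dets, _ = scene_detections(events, seed=4)
        kept, report = hard_negative_filter(dets)
        assert report.retained.mean() >= 0.95
        assert len(kept) >= 0.95 * len(dets)

    def test_empty_input(self):
        kept, report = hard_negative_filter([])
        assert kept == [] and report.empty


class TestModerateNegativeFilter:
    def test_small_bin_nothing_removed(self, trained_model):
        dets, _ = scene_detections(
            [SceneEvent(template_by_name("De spp"), 0.0, 30, 130.0)], seed=5
        )
        kept, report = moderate_negative_filter(
            dets, trained_model, ClusterConfig(), ModerateFilterConfig(), seed=0
        )
        assert len(kept) == len(dets)  # below the 50-click pass-1 minimum

    def test_beaked_whale_cluster_retained(self, trained_model):
        dets, _ = scene_detections(
            [SceneEvent(template_by_name("Zc"), 0.0, 60, 130.0)], seed=6
        )
        kept, report = moderate_negative_filter(
            dets, trained_model, ClusterConfig(), ModerateFilterConfig(), seed=0
        )
        assert len(kept) == len(dets)
        assert (report.action == "kept").all()

    def test_dominant_delphinid_cluster_removed(self, trained_model):
        dets, truth = scene_detections(
            [
                SceneEvent(template_by_name("De spp"), 0.0, 300, 130.0),
                SceneEvent(template_by_name("Zc"), 10.0, 15, 130.0),
            ],
            seed=7,
        )
        kept, report = moderate_negative_filter(
            dets, trained_model, ClusterConfig(), ModerateFilterConfig(), seed=0
        )
        kept_ids = {d.click_id for d in kept}
        zc_ids = set(truth.loc[truth.class_id == "Zc", "click_id"])
        assert zc_ids <= kept_ids
        removed = report.loc[report.action == "removed"]
        assert not removed.empty
        assert (removed.n_clicks >= 50).all()
        assert not removed.label.isin(["Zc", "Me", "Mm", "Mb", "Md", "BWG"]).any()

    def test_model_class_mismatch_rejected(self):
        class Stub:
            classes_ = np.array(["foo", "bar"])

        with pytest.raises(ValueError):
            moderate_negative_filter([], Stub(), ClusterConfig(), ModerateFilterConfig())

    def test_subset_and_order_preserved(self, trained_model):
        dets, _ = scene_detections(
            [
                SceneEvent(template_by_name("De spp"), 0.0, 120, 130.0),
                SceneEvent(template_by_name("Zc"), 5.0, 20, 130.0),
            ],
            seed=8,
        )
        kept, _ = moderate_negative_filter(
            dets, trained_model, ClusterConfig(), ModerateFilterConfig(), seed=1
        )
        ids = [d.click_id for d in kept]
        assert ids == sorted(ids)
        assert set(ids) <= {d.click_id for d in dets}
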