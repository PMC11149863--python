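"""Taxonomic-family delimitation: removal of non-beaked-whale detections.

Two strategies delimit the detection stream to the family Ziphiidae before
clustering. The *hard negative filter* applies the classical rule set for
beaked whale clicks — minimum duration 355 us, peak frequency >= 32 kHz,
center frequency >= 25 kHz, FM upsweep of >= 23 kHz/ms, and a waveform
envelope that slopes positively over the first 0.1 ms and stays at or above
50% energy for the following 0.1 ms — then retains each 75-second interval
only if it holds at least seven rule-passing candidates or if at least 13% of
its detections pass. The *moderate negative filter* is less restrictive: it
clusters each 5-minute bin with large-cluster settings (min 50 clicks, 95%
pruning), classifies the clusters with a trained network, and deletes the
members of every sizeable cluster labeled as a non-beaked-whale class; a
second standard clustering pass is then run by the pipeline on the survivors.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .clustering import ClusterConfig, cluster_bin
from .detector import ClickDetection
from .features import ClickMetrics, click_metrics
from .templates import BEAKED_WHALE_CLASSES

__all__ = [
    "HardFilterConfig",
    "ModerateFilterConfig",
    "click_passes_hard_rules",
    "hard_negative_filter",
    "moderate_negative_filter",
]


@dataclass
class HardFilterConfig:
    """Rule thresholds of the hard negative filter (classical beaked-whale
    detection criteria) and the per-interval retention rule."""

    min_duration: float = 355.0  # us
    min_peak_freq: float = 32.0  # kHz
    min_center_freq: float = 25.0  # kHz
    min_sweep_rate: float = 23.0  # kHz/ms
    envelope_rise: float = 1e-4  # s, window that must slope positively
    envelope_sustain: float = 1e-4  # s, following window at >= 50% energy
    sustain_energy_fraction: float = 0.5
    interval_length: float = 75.0  # s
    min_candidates: int = 7
    min_fraction: float = 0.13

    def __post_init__(self) -> None:
        if not 0.0 < self.min_fraction < 1.0:
            raise ValueError("min_fraction must be in (0, 1)")


@dataclass
class ModerateFilterConfig:
    """Settings of the moderate negative filter's first iteration."""

    pass1_min_cluster: int = 50
    pass1_prune: float = 95.0
    removal_min_clicks: int = 50
    beaked_whale_classes: frozenset = frozenset(BEAKED_WHALE_CLASSES)


def _envelope_rules(metrics: ClickMetrics, config: HardFilterConfig) -> tuple[bool, bool]:
    """(rise ok, sustain ok) on the click's smoothed normalized envelope.

    The rise window is the first 0.1 ms from the measured click start; its
    least-squares slope must be positive. The sustain window is the 0.1 ms
    that follows; the envelope must stay at or above 50% of its maximum
    throughout. Clicks too short to contain both windows fail."""
    env = np.asarray(metrics.envelope, dtype=float)
    fs = metrics.sample_rate
    n_rise = max(2, int(round(config.envelope_rise * fs)))
    n_sustain = max(1, int(round(config.envelope_sustain * fs)))
    if env.size < n_rise:
        return False, False
    t = np.arange(n_rise) / fs
    slope = np.polyfit(t, env[:n_rise], 1)[0]
    rise_ok = bool(slope > 0)
    if env.size < n_rise + n_sustain:
        return rise_ok, False
    window = env[n_rise : n_rise + n_sustain]
    sustain_ok = bool(np.all(window >= config.sustain_energy_fraction * env.max()))
    return rise_ok, sustain_ok


def click_passes_hard_rules(
    metrics: ClickMetrics,
    config: HardFilterConfig | None = None,
) -> tuple[bool, dict]:
    """Evaluate the five beaked-whale click criteria.

    Returns (all criteria hold, per-rule pass flags). An undefined sweep rate
    (NaN, snippet too short for the frame track) fails the sweep-rate rule.
    """
    config = config or HardFilterConfig()
    rise_ok, sustain_ok = _envelope_rules(metrics, config)
    flags = {
        "duration": metrics.duration >= config.min_duration,
        "peak_freq": metrics.peak_freq >= config.min_peak_freq,
        "center_freq": metrics.center_freq >= config.min_center_freq,
        "sweep_rate": bool(
            np.isfinite(metrics.sweep_rate) and metrics.sweep_rate >= config.min_sweep_rate
        ),
        "envelope": rise_ok and sustain_ok,
    }
    return all(flags.values()), flags


def hard_negative_filter(
    detections: list[ClickDetection],
    config: HardFilterConfig | None = None,
) -> tuple[list[ClickDetection], pd.DataFrame]:
    """Apply the hard negative filter to a time-sorted detection list.

    Detections are partitioned into consecutive half-open 75-s intervals
    anchored at the recording start. An interval is retained iff it holds at
    least ``min_candidates`` rule-passing clicks or the rule-passing fraction
    of all its detections is at least ``min_fraction``; every detection in a
    retained interval is forwarded (order preserved) and all others dropped.
    The operation is idempotent. Also returns a per-interval report.
    """
    config = config or HardFilterConfig()
    if not detections:
        return [], pd.DataFrame(columns=["interval_id", "n_clicks", "n_candidates", "fraction", "retained"])
    starts = np.array([d.start_time for d in detections])
    if np.any(np.diff(starts) < 0):
        raise ValueError("detections must be time-sorted")
    passes = np.array(
        [click_passes_hard_rules(click_metrics(d), config)[0] for d in detections]
    )
    interval_ids = np.floor(starts / config.interval_length).astype(int)
    retained: list[ClickDetection] = []
    rows = []
    for iv in np.unique(interval_ids):
        mask = interval_ids == iv
        n = int(mask.sum())
        n_pass = int(passes[mask].sum())
        frac = n_pass / n
        keep = n_pass >= config.min_candidates or frac >= config.min_fraction
        if keep:
            retained.extend(d for d, m in zip(detections, mask) if m)
        rows.append(
            {
                "interval_id": int(iv),
                "n_clicks": n,
                "n_candidates": n_pass,
                "fraction": frac,
                "retained": keep,
            }
        )
    return retained, pd.DataFrame(rows)


def moderate_negative_filter(
    detections: list[ClickDetection],
    model,
    cluster_config: ClusterConfig | None = None,
    config: ModerateFilterConfig | None = None,
    seed=0,
) -> tuple[list[ClickDetection], pd.DataFrame]:
    """First iteration of the moderate negative filter.

    Each 5-minute bin is clustered with the large-cluster settings
    (``pass1_min_cluster`` clicks minimum, ``pass1_prune`` pruning, no
    pseudo-clusters), the clusters are classified with the trained network,
    and the member detections of every cluster with at least
    ``removal_min_clicks`` clicks and a non-beaked-whale label are deleted.
    All other detections — including unclustered ones — survive. The second
    iteration (standard re-clustering of the survivors) belongs to the
    pipeline, not to this operation.

    Returns (surviving detections, removal report).
    """
    from .network import predict_clusters  # deferred: avoids module cycle

    cluster_config = cluster_config or ClusterConfig()
    config = config or ModerateFilterConfig()
    if not set(config.beaked_whale_classes) <= set(model.classes_):
        raise ValueError(
            "model class list does not cover the configured beaked whale classes"
        )
    pass1 = replace(
        cluster_config,
        min_cluster=config.pass1_min_cluster,
        prune_threshold=config.pass1_prune,
    )
    starts = np.array([d.start_time for d in detections])
    remove = np.zeros(len(detections), dtype=bool)
    rows = []
    if len(detections):
        bins = np.floor(starts / cluster_config.bin_length).astype(int)
        rng = np.random.default_rng(seed)
        for b in np.unique(bins):
            idx = np.flatnonzero(bins == b)
            members = [detections[i] for i in idx]
            clusters = cluster_bin(
                members, pass1, rng.integers(0, 2**31 - 1), bin_id=int(b), allow_pseudo=False
            )
            if not clusters:
                continue
            pred = predict_clusters(model, [c.summary for c in clusters])
            for cluster, (label, score) in zip(clusters, pred[["label", "score"]].itertuples(index=False)):
                removable = (
                    cluster.n_clicks >= config.removal_min_clicks
                    and label not in config.beaked_whale_classes
                )
                if removable:
                    remove[idx[cluster.member_indices]] = True
                rows.append(
                    {
                        "bin_id": int(b),
                        "n_clicks": cluster.n_clicks,
                        "label": label,
                        "score": float(score),
                        "action": "removed" if removable else "kept",
                    }
                )
    survivors = [d for d, r in zip(detections, remove) if not r]
    report = pd.DataFrame(rows, columns=["bin_id", "n_clicks", "label", "score", "action"])
    return survivors, report
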