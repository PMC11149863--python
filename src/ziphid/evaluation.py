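"""Pipeline orchestration and bin-level evaluation.

Three pipeline modes share the detect-cluster-classify backbone: the
*generalized* pipeline clusters and classifies every detection; the
*targeted-hard* pipeline first removes detections failing the beaked-whale
rule set (hard negative filter); the *targeted-moderate* pipeline first runs
the moderate negative filter (large-cluster classification pass that deletes
dominant non-beaked-whale clusters) and then re-clusters the survivors with
standard settings.

Evaluation compares true and predicted class-label sets per 5-minute bin.
When a bin has several true or predicted labels, every (true, predicted)
pairing contributes one bin count to the confusion matrix; bins without
prediction (or without annotation) count under the explicit class
``"No label"``. A lenient *full-bin* variant counts a bin as correct whenever
at least one prediction matches the true class, so partially misclassified
bins are not penalized; only fully misclassified bins count as errors.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .clustering import ClusterConfig, cluster_bin
from .delimitation import (
    HardFilterConfig,
    ModerateFilterConfig,
    hard_negative_filter,
    moderate_negative_filter,
)
from .detector import ClickDetection

__all__ = [
    "PIPELINE_MODES",
    "ConfusionMatrix",
    "run_pipeline",
    "bin_confusion",
    "precision_recall",
    "summarize",
    "truth_bin_table",
    "prediction_bin_table",
]

PIPELINE_MODES = ("generalized", "targeted_hard", "targeted_moderate")
NO_LABEL = "No label"


class ConfusionMatrix:
    """Bin-count confusion matrix (rows = true classes, columns = predicted).

    ``counts`` may contain special truth rows (ambiguous annotations, the
    ``"No label"`` row); per-class metrics use the full row/column sums, so
    false positives include hits on unannotated bins. ``full_bin`` optionally
    holds the lenient variant counts.
    """

    def __init__(self, counts: pd.DataFrame, full_bin: pd.DataFrame | None = None):
        self.counts = counts
        self.full_bin = full_bin
        if (counts.to_numpy() < 0).any():
            raise ValueError("confusion counts must be non-negative")

    def _frame(self, full_bin: bool) -> pd.DataFrame:
        if full_bin:
            if self.full_bin is None:
                raise ValueError("no full-bin counts available")
            return self.full_bin
        return self.counts

    def tp(self, cls: str, full_bin: bool = False) -> int:
        return int(self._frame(full_bin).loc[cls, cls])

    def fn(self, cls: str, full_bin: bool = False) -> int:
        frame = self._frame(full_bin)
        return int(frame.loc[cls].sum() - frame.loc[cls, cls])

    def fp(self, cls: str, full_bin: bool = False) -> int:
        frame = self._frame(full_bin)
        return int(frame[cls].sum() - frame.loc[cls, cls])


def truth_bin_table(truth: pd.DataFrame, bin_length: float = 300.0) -> dict[int, set]:
    """Reduce a click-level ground-truth table (``start_s``, ``class_id``) to
    per-bin true label sets (presence of a class in the bin)."""
    bins = np.floor(truth["start_s"].to_numpy(dtype=float) / bin_length).astype(int)
    table: dict[int, set] = {}
    for b, cls in zip(bins, truth["class_id"]):
        table.setdefault(int(b), set()).add(cls)
    return table


def prediction_bin_table(clusters: pd.DataFrame) -> dict[int, set]:
    """Per-bin predicted label sets from a labeled-cluster table."""
    table: dict[int, set] = {}
    for b, lbl in zip(clusters["bin_id"], clusters["label"]):
        table.setdefault(int(b), set()).add(lbl)
    return table


def run_pipeline(
    detections: list[ClickDetection],
    mode: str,
    model,
    cluster_config: ClusterConfig | None = None,
    hard_config: HardFilterConfig | None = None,
    moderate_config: ModerateFilterConfig | None = None,
    seed=0,
) -> pd.DataFrame:
    """Run one classification pipeline over a time-sorted detection list.

    Returns one row per labeled cluster: ``bin_id``, ``label``, ``score``,
    ``n_clicks``, ``pseudo`` and the member ``click_ids``. Deterministic for
    identical inputs and seed.
    """
    from .network import predict_clusters

    if mode not in PIPELINE_MODES:
        raise ValueError(f"mode must be one of {PIPELINE_MODES}")
    if model is None:
        raise ValueError("a trained model is required")
    cluster_config = cluster_config or ClusterConfig()

    root = np.random.SeedSequence(seed)
    filter_seq, cluster_seq = root.spawn(2)
    if mode == "targeted_hard":
        detections, _ = hard_negative_filter(detections, hard_config)
    elif mode == "targeted_moderate":
        detections, _ = moderate_negative_filter(
            detections,
            model,
            cluster_config,
            moderate_config,
            seed=np.random.default_rng(filter_seq).integers(0, 2**31 - 1),
        )

    rows = []
    if detections:
        starts = np.array([d.start_time for d in detections])
        bins = np.floor(starts / cluster_config.bin_length).astype(int)
        rng = np.random.default_rng(cluster_seq)
        for b in np.unique(bins):
            idx = np.flatnonzero(bins == b)
            members = [detections[i] for i in idx]
            clusters = cluster_bin(
                members, cluster_config, rng.integers(0, 2**31 - 1), bin_id=int(b)
            )
            if not clusters:
                continue
            pred = predict_clusters(model, [c.summary for c in clusters])
            for cluster, (label, score) in zip(
                clusters, pred[["label", "score"]].itertuples(index=False)
            ):
                rows.append(
                    {
                        "bin_id": int(b),
                        "label": label,
                        "score": float(score),
                        "n_clicks": cluster.n_clicks,
                        "pseudo": cluster.pseudo,
                        "click_ids": [
                            int(members[j].click_id) for j in cluster.member_indices
                        ],
                    }
                )
    return pd.DataFrame(
        rows, columns=["bin_id", "label", "score", "n_clicks", "pseudo", "click_ids"]
    )


def bin_confusion(
    truth: dict[int, set],
    predicted: dict[int, set],
    classes: list[str],
    bins: list[int] | None = None,
) -> ConfusionMatrix:
    """Confusion matrix over 5-min bins with the multi-label counting rule.

    Every (true label, predicted label) pairing within a bin contributes one
    bin count; bins absent from ``truth`` or ``predicted`` contribute under
    ``"No label"``. The full-bin variant counts a true label only on the
    diagonal when any prediction in the bin matched it.
    """
    if bins is None:
        bins = sorted(set(truth) | set(predicted))
    else:
        missing = (set(truth) | set(predicted)) - set(bins)
        if missing:
            raise ValueError(f"labels found outside the bin universe: {sorted(missing)[:5]}")
    labels = list(classes)
    if NO_LABEL not in labels:
        labels = labels + [NO_LABEL]
    counts = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    full = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for b in bins:
        t_set = sorted(truth.get(b) or {NO_LABEL})
        p_set = sorted(predicted.get(b) or {NO_LABEL})
        for t in t_set:
            for p in p_set:
                counts.loc[t, p] += 1
            if t in p_set:
                full.loc[t, t] += 1
            else:
                for p in p_set:
                    full.loc[t, p] += 1
    return ConfusionMatrix(counts, full)


def precision_recall(
    cm: ConfusionMatrix,
    classes: list[str] | None = None,
    full_bin: bool = False,
) -> pd.DataFrame:
    """Per-class precision and recall (percent).

    precision = TP / (TP + FP); recall = TP / (TP + FN). A zero denominator
    yields NaN (undefined), never 0.
    """
    frame = cm._frame(full_bin)
    if classes is None:
        classes = [c for c in frame.columns if c in frame.index and c != NO_LABEL]
    rows = []
    for c in classes:
        tp = cm.tp(c, full_bin)
        fn = cm.fn(c, full_bin)
        fp = cm.fp(c, full_bin)
        rows.append(
            {
                "class": c,
                "tp": tp,
                "fn": fn,
                "fp": fp,
                "precision": 100.0 * tp / (tp + fp) if tp + fp > 0 else float("nan"),
                "recall": 100.0 * tp / (tp + fn) if tp + fn > 0 else float("nan"),
            }
        )
    return pd.DataFrame(rows).set_index("class")


def summarize(metrics: pd.DataFrame, classes: list[str] | None = None) -> dict:
    """Report per-class rates (rounded to one decimal, as printed) and
    unweighted averages over the requested classes rounded to the nearest
    whole percent."""
    if classes is None:
        classes = [c for c in metrics.index]
    sub = metrics.loc[[c for c in classes if c in metrics.index]]
    per_class = {
        c: {
            "precision": round(float(sub.loc[c, "precision"]), 1),
            "recall": round(float(sub.loc[c, "recall"]), 1),
        }
        for c in sub.index
    }
    # averages computed from the rounded per-class rates, as printed
    rec = [v["recall"] for v in per_class.values() if np.isfinite(v["recall"])]
    prec = [v["precision"] for v in per_class.values() if np.isfinite(v["precision"])]
    return {
        "per_class": per_class,
        "average_recall": round(float(np.mean(rec))) if rec else None,
        "average_precision": round(float(np.mean(prec))) if prec else None,
    }
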