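"""Detection and cluster stores.

Detections travel as a CSV table (click_id, start_s, end_s, rl_pp_db) plus an
HDF5 sidecar holding the variable-length snippet/envelope arrays and the
fixed-length spectra. Cluster stores keep per-bin member id lists and summary
arrays, with a JSON manifest of the configuration used.
"""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass

import h5py
import numpy as np
import pandas as pd

from .detector import ClickDetection

__all__ = [
    "save_detections",
    "load_detections",
    "detections_frame",
    "save_clusters",
    "load_cluster_summaries",
]


def detections_frame(detections: list[ClickDetection]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "click_id": [d.click_id for d in detections],
            "start_s": [d.start_time for d in detections],
            "end_s": [d.end_time for d in detections],
            "rl_pp_db": [d.rl_pp for d in detections],
        }
    )


def save_detections(detections: list[ClickDetection], path) -> None:
    """Write detections to an HDF5 store (scalar table + snippet, envelope
    and spectrum arrays)."""
    vlen = h5py.vlen_dtype(np.float64)
    with h5py.File(path, "w") as f:
        n = len(detections)
        f.attrs["n_detections"] = n
        if n:
            f.attrs["sample_rate"] = detections[0].sample_rate
        f.create_dataset("click_id", data=np.array([d.click_id for d in detections], dtype=np.int64))
        f.create_dataset("start_s", data=np.array([d.start_time for d in detections]))
        f.create_dataset("end_s", data=np.array([d.end_time for d in detections]))
        f.create_dataset("rl_pp_db", data=np.array([d.rl_pp for d in detections]))
        snip = f.create_dataset("snippet", (n,), dtype=vlen)
        env = f.create_dataset("envelope", (n,), dtype=vlen)
        for i, d in enumerate(detections):
            snip[i] = np.asarray(d.snippet, dtype=np.float64)
            env[i] = np.asarray(d.envelope, dtype=np.float64)
        if n:
            f.create_dataset("spectrum", data=np.stack([d.spectrum for d in detections]))


def load_detections(path) -> list[ClickDetection]:
    with h5py.File(path, "r") as f:
        n = int(f.attrs["n_detections"])
        if n == 0:
            return []
        fs = float(f.attrs["sample_rate"])
        spectra = f["spectrum"][:]
        return [
            ClickDetection(
                start_time=float(f["start_s"][i]),
                end_time=float(f["end_s"][i]),
                snippet=np.asarray(f["snippet"][i]),
                envelope=np.asarray(f["envelope"][i]),
                spectrum=spectra[i],
                rl_pp=float(f["rl_pp_db"][i]),
                sample_rate=fs,
                click_id=int(f["click_id"][i]),
            )
            for i in range(n)
        ]


def save_clusters(clusters, path, config=None) -> None:
    """Write bin-level clusters (member ids + summary arrays) keyed by
    bin id / cluster index, with the configuration as a JSON manifest."""
    with h5py.File(path, "w") as f:
        if config is not None:
            manifest = asdict(config) if is_dataclass(config) else dict(config)
            f.attrs["config"] = json.dumps(manifest, default=str)
        for k, c in enumerate(clusters):
            g = f.create_group(f"bin{c.bin_id:06d}/cluster{k:04d}")
            g.attrs["bin_id"] = c.bin_id
            g.attrs["pseudo"] = c.pseudo
            g.attrs["n_clicks"] = c.n_clicks
            g.attrs["modal_ici"] = c.summary.modal_ici
            g.create_dataset("member_indices", data=np.asarray(c.member_indices, dtype=np.int64))
            g.create_dataset("mean_spectrum", data=c.summary.mean_spectrum)
            g.create_dataset("mean_envelope", data=c.summary.mean_envelope)
            g.create_dataset("ici_distribution", data=c.summary.ici_distribution)
            if c.summary.freqs_khz is not None:
                g.create_dataset("freqs_khz", data=c.summary.freqs_khz)


def load_cluster_summaries(path):
    """Load cluster summaries (with bin ids) from a cluster store."""
    from .features import ClusterSummary

    out = []
    with h5py.File(path, "r") as f:
        for bin_name in sorted(f):
            for cl_name in sorted(f[bin_name]):
                g = f[bin_name][cl_name]
                out.append(
                    (
                        int(g.attrs["bin_id"]),
                        ClusterSummary(
                            mean_spectrum=g["mean_spectrum"][:],
                            mean_envelope=g["mean_envelope"][:],
                            ici_distribution=g["ici_distribution"][:],
                            modal_ici=float(g.attrs["modal_ici"]),
                            n_clicks=int(g.attrs["n_clicks"]),
                            freqs_khz=g["freqs_khz"][:] if "freqs_khz" in g else None,
                        ),
                    )
                )
    return out
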