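"""File formats: multi-page TIFF movies, HDF5 trace and photon-stream files,
CSV/JSON exports of step calls, histograms and fits."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from oligocount.containers import FluorescenceTrace, ImageStack, PhotonStream
from oligocount.tirf import CATEGORIES, StepCall, StepHistogram


def write_movie(path: str | Path, stack: ImageStack) -> None:
    tifffile.imwrite(
        str(path),
        stack.frames.astype(np.float32),
        metadata={"pixel_size_um": stack.pixel_size, "frame_rate_hz": stack.frame_rate},
    )


def read_movie(path: str | Path, pixel_size: float | None = None, frame_rate: float | None = None) -> ImageStack:
    with tifffile.TiffFile(str(path)) as tif:
        frames = tif.asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    return ImageStack(
        frames=np.asarray(frames, dtype=float),
        pixel_size=pixel_size or float(meta.get("pixel_size_um", 0.16)),
        frame_rate=frame_rate or float(meta.get("frame_rate_hz", 20.0)),
    )


def write_traces(path: str | Path, traces: list[FluorescenceTrace], seed: int | None = None) -> None:
    """One HDF5 group per spot: /spots/<id>/intensity plus ground-truth
    attributes when present."""
    with h5py.File(str(path), "w") as f:
        if seed is not None:
            f.attrs["seed"] = seed
        grp = f.create_group("spots")
        for tr in traces:
            g = grp.create_group(str(tr.spot_id))
            g.create_dataset("intensity", data=tr.intensities)
            g.attrs["frame_rate"] = tr.frame_rate
            g.attrs["position"] = tr.position
            if tr.truth is not None:
                t = g.create_group("truth")
                for key, val in tr.truth.items():
                    if isinstance(val, np.ndarray):
                        t.create_dataset(key, data=val)
                    else:
                        t.attrs[key] = val


def read_traces(path: str | Path) -> list[FluorescenceTrace]:
    traces = []
    with h5py.File(str(path), "r") as f:
        for sid in sorted(f["spots"], key=int):
            g = f["spots"][sid]
            truth = None
            if "truth" in g:
                truth = dict(g["truth"].attrs)
                for key in g["truth"]:
                    truth[key] = g["truth"][key][()]
            traces.append(
                FluorescenceTrace(
                    spot_id=int(sid),
                    intensities=g["intensity"][()],
                    frame_rate=float(g.attrs["frame_rate"]),
                    position=tuple(g.attrs["position"]),
                    truth=truth,
                )
            )
    return traces


def traces_to_csv(path: str | Path, traces: list[FluorescenceTrace]) -> None:
    frames = {tr.spot_id: tr.intensities for tr in traces}
    pd.DataFrame(frames).to_csv(path, index_label="frame")


def write_photon_stream(path: str | Path, stream: PhotonStream, seed: int | None = None) -> None:
    with h5py.File(str(path), "w") as f:
        f.attrs["channel"] = stream.channel
        f.attrs["pulse_period_ns"] = stream.pulse_period
        f.attrs["duration_s"] = stream.duration
        if seed is not None:
            f.attrs["seed"] = seed
        f.create_dataset("macrotime_s", data=stream.arrival_times)
        f.create_dataset("microtime_ns", data=stream.microtimes)
        f.create_dataset("pulse_origin", data=stream.pulse_origin)
        if stream.labels is not None:
            f.create_dataset("labels", data=stream.labels)


def read_photon_stream(path: str | Path) -> PhotonStream:
    with h5py.File(str(path), "r") as f:
        return PhotonStream(
            arrival_times=f["macrotime_s"][()],
            microtimes=f["microtime_ns"][()],
            pulse_origin=f["pulse_origin"][()],
            channel=str(f.attrs["channel"]),
            pulse_period=float(f.attrs["pulse_period_ns"]),
            labels=f["labels"][()] if "labels" in f else None,
            meta={"duration": float(f.attrs["duration_s"])},
        )


def step_calls_to_csv(path: str | Path, calls: list[StepCall]) -> None:
    pd.DataFrame(
        {
            "spot_id": [c.spot_id for c in calls],
            "n_steps": [c.n_steps for c in calls],
            "category": [c.category for c in calls],
            "reject_reason": [c.reject_reason or "" for c in calls],
            "censored": [c.censored for c in calls],
        }
    ).to_csv(path, index=False)


def histogram_to_json(path: str | Path, hist: StepHistogram) -> None:
    payload = {
        "counts": hist.counts,
        "fractions": hist.fractions,
        "n_spots_analyzed": hist.n_spots_analyzed,
        "n_spots_rejected": hist.n_spots_rejected,
        "ci95": {k: list(v) for k, v in hist.ci.items()},
        "meta": hist.meta,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def histogram_from_json(path: str | Path) -> StepHistogram:
    payload = json.loads(Path(path).read_text())
    return StepHistogram(
        counts={k: int(v) for k, v in payload["counts"].items()},
        fractions=payload["fractions"],
        n_spots_analyzed=payload["n_spots_analyzed"],
        n_spots_rejected=payload["n_spots_rejected"],
        ci={k: tuple(v) for k, v in payload.get("ci95", {}).items()},
        meta=payload.get("meta", {}),
    )


def histogram_from_fractions(
    fractions: tuple[float, float, float], n_spots: int
) -> StepHistogram:
    """Build a StepHistogram from printed category fractions (for fitting
    published histograms where only fractions and totals are reported)."""
    counts = {c: int(round(f * n_spots)) for c, f in zip(CATEGORIES, fractions)}
    n = sum(counts.values())
    return StepHistogram(
        counts=counts,
        fractions={k: v / n for k, v in counts.items()},
        n_spots_analyzed=n,
        n_spots_rejected=0,
    )


def correlation_to_csv(path: str | Path, lags, G_gg, G_rr, G_x, se=None) -> None:
    df = pd.DataFrame({"lag_s": lags, "G_gg": G_gg, "G_rr": G_rr, "G_x": G_x})
    if se is not None:
        for name, vals in se.items():
            df[f"se_{name}"] = vals
    df.to_csv(path, index=False)
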