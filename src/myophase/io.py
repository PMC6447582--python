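"""Plain-text session formats.

Channels are stored one per CSV file: ``#`` header lines carrying channel
name, rate and units, then one sample per line.  Phase segments (detected or
ground truth) share a single CSV schema so the two can be diffed directly.
A YAML manifest ties a multi-participant session together.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

from .core import ChannelKind, ChannelRecording, GroundTruth, SquatPhaseSegment

__all__ = [
    "write_channel_csv",
    "read_channel_csv",
    "write_segments_csv",
    "read_segments_csv",
    "write_manifest",
    "read_manifest",
    "write_session",
]

_FLOAT_FMT = "%.9g"  # enough digits for float32-grade sensor data, byte-stable


def write_channel_csv(rec: ChannelRecording, path: str | os.PathLike,
                      extra_header: dict | None = None) -> None:
    path = Path(path)
    lines = [f"# channel={rec.kind.value}",
             f"# rate_hz={_FLOAT_FMT % rec.rate}",
             f"# units={rec.units}"]
    for key, val in (extra_header or {}).items():
        lines.append(f"# {key}={val}")
    lines.extend(_FLOAT_FMT % v for v in rec.samples)
    path.write_text("\n".join(lines) + "\n")


def read_channel_csv(path: str | os.PathLike) -> ChannelRecording:
    meta: dict[str, str] = {}
    samples: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, val = body.split("=", 1)
                    meta[key.strip()] = val.strip()
            else:
                samples.append(float(line))
    try:
        kind = ChannelKind(meta["channel"])
        rate = float(meta["rate_hz"])
    except KeyError as exc:
        raise ValueError(f"{path}: missing required header {exc}") from exc
    return ChannelRecording(np.asarray(samples), rate=rate, kind=kind,
                            units=meta.get("units", ""))


_SEG_COLS = "rep_index,phase,start_sample,stop_sample,start_s,stop_s"


def write_segments_csv(segments: Sequence[SquatPhaseSegment],
                       path: str | os.PathLike,
                       extra_header: dict | None = None) -> None:
    lines = [f"# {k}={v}" for k, v in (extra_header or {}).items()]
    lines.append(_SEG_COLS)
    for s in segments:
        lines.append(f"{s.rep_index},{s.phase},{s.start},{s.stop},"
                     f"{_FLOAT_FMT % s.start_s},{_FLOAT_FMT % s.stop_s}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_segments_csv(path: str | os.PathLike, rate: float) -> list[SquatPhaseSegment]:
    segs: list[SquatPhaseSegment] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("rep_index"):
                continue
            rep, phase, start, stop, *_ = line.split(",")
            segs.append(SquatPhaseSegment(int(rep), phase, int(start),
                                          int(stop), rate))
    return segs


def write_manifest(manifest: dict, path: str | os.PathLike) -> None:
    Path(path).write_text(yaml.safe_dump(manifest, sort_keys=True))


def read_manifest(path: str | os.PathLike) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_session(bundle: dict, out_dir: str | os.PathLike) -> Path:
    """Write a generated session bundle to disk; return the manifest path.

    Layout: ``<out_dir>/P01/pre_mmg.csv`` etc., one ground-truth segments CSV
    per stage, and a top-level ``manifest.yaml``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": bundle.get("seed"), "participants": []}
    for part in bundle["participants"]:
        pdir = out_dir / part["id"]
        pdir.mkdir(exist_ok=True)
        entry: dict = {"id": part["id"], "stages": {}}
        for stage, channels in part["stages"].items():
            stage_entry: dict[str, str] = {}
            for name, obj in channels.items():
                if isinstance(obj, GroundTruth):
                    fname = f"{stage}_truth.csv"
                    write_segments_csv(obj.phase_segments, pdir / fname)
                else:
                    fname = f"{stage}_{name.lower()}.csv"
                    write_channel_csv(obj, pdir / fname)
                stage_entry[name.lower()] = str(Path(part["id"]) / fname)
            entry["stages"][stage] = stage_entry
        manifest["participants"].append(entry)
    mpath = out_dir / "manifest.yaml"
    write_manifest(manifest, mpath)
    return mpath
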