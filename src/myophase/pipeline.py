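"""End-to-end orchestration: load or generate a session, preprocess, segment,
extract features, run the comparative statistics, and write reports.

Two analyses mirror the study design:

* :func:`run_prepost` — stages 1 and 3 (five squats before and after the
  exhausting wall squat): per-phase RMS/MPF averaged over repetitions, then
  participants; percent change pre vs post with Wilcoxon signed-rank tests.
* :func:`run_exertion` — stage 2 (the wall squat itself): 1-s window RMS/MPF
  over the hold, averaged across participants on a percentage-of-duration
  grid, with linear-trend statistics (r, P, b, first/last-10% change).

All outputs are tidy CSVs; every file header records the seed and a hash of
the configuration.  Plots are artifacts for inspection — the CSVs are the
canonical result.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .core import ChannelKind, ChannelRecording
from .features import (group_hold_average, hold_series, phase_features,
                       phase_means)
from .preprocessing import bandpass, smooth_accel
from .segmentation import (SegmentationConfig, estimate_flexion, isolate_hold,
                           segment_repetitions)
from .stats import PrePostComparison, TrendResult, trend_from_series
from .synthetic import ProtocolSpec, SignalModelSpec, generate_session

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PrePostReport", "ExertionReport",
           "run_prepost", "run_exertion", "run_all", "render_table"]

_MUSCLE = (ChannelKind.MMG.value, ChannelKind.EMG.value)
_METRICS = ("rms", "mpf")


@dataclass
class PipelineConfig:
    """Fully-defaulted pipeline configuration (YAML-serialisable)."""

    seed: int = 0
    out_dir: str = "myophase_out"
    n_participants: int = 5
    manifest: str | None = None  # load this session instead of generating
    protocol: dict = field(default_factory=dict)      # ProtocolSpec overrides
    mmg_model: dict = field(default_factory=dict)     # SignalModelSpec overrides
    emg_model: dict = field(default_factory=dict)
    segmentation: dict = field(default_factory=dict)  # SegmentationConfig overrides
    post_rms_scale: float = 1.0
    zero_phase: bool = True
    n_grid: int = 100
    make_plots: bool = True
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=True))

    @property
    def hash(self) -> str:
        """Hash of the scientific configuration (output location, plotting
        and log level excluded, so reruns into different directories keep the
        same provenance stamp)."""
        d = dataclasses.asdict(self)
        for key in ("out_dir", "make_plots", "log_level"):
            d.pop(key, None)
        blob = yaml.safe_dump(d, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def seg_config(self) -> SegmentationConfig:
        return SegmentationConfig(**self.segmentation)


# ---------------------------------------------------------------------------
# session loading
# ---------------------------------------------------------------------------

def _load_bundle(config: PipelineConfig,
                 stages: tuple[str, ...] = ("pre", "hold", "post")) -> dict:
    if config.manifest:
        return _read_session(Path(config.manifest))
    protocol = ProtocolSpec(**config.protocol)
    mmg = SignalModelSpec.mmg_default(**config.mmg_model)
    emg = SignalModelSpec.emg_default(**config.emg_model)
    return generate_session(protocol, mmg, emg,
                            n_participants=config.n_participants,
                            seed=config.seed,
                            post_rms_scale=config.post_rms_scale,
                            stages=stages)


def _read_session(manifest_path: Path) -> dict:
    manifest = mio.read_manifest(manifest_path)
    root = manifest_path.parent
    bundle: dict = {"seed": manifest.get("seed"), "participants": []}
    for part in manifest["participants"]:
        stages = {}
        for stage, files in part["stages"].items():
            chans = {}
            for name, rel in files.items():
                if name == "truth":
                    continue  # analysis never consumes ground truth
                rec = mio.read_channel_csv(root / rel)
                chans[rec.kind.value] = rec
            stages[stage] = chans
        bundle["participants"].append({"id": part["id"], "stages": stages})
    return bundle


def _write_df(df: pd.DataFrame, path: Path, config: PipelineConfig) -> None:
    header = f"# myophase seed={config.seed} config={config.hash}\n"
    path.write_text(header + df.to_csv(index=False))


# ---------------------------------------------------------------------------
# pre/post analysis
# ---------------------------------------------------------------------------

@dataclass
class PrePostReport:
    comparisons: list[PrePostComparison]
    features: pd.DataFrame            # participant, stage, channel, phase, rep, rms, mpf
    flexion_deg: dict[str, float]     # stage -> group-mean knee flexion
    excluded: list[str]

    def get(self, channel: str, metric: str) -> PrePostComparison:
        for c in self.comparisons:
            if c.channel == channel and c.metric == metric:
                return c
        raise KeyError((channel, metric))


def _stage_features(part: dict, stage: str, config: PipelineConfig,
                    seg_cfg: SegmentationConfig):
    """Segment one pre/post stage and compute its phase features.

    Returns (feature rows, per-phase means, mean flexion) or None when no
    repetition is detected."""
    chans = part["stages"][stage]
    ax = smooth_accel(chans["ACCEL_X"], seg_cfg.smoothing_window_s)
    segments = segment_repetitions(ax, seg_cfg)
    helds = [s for s in segments if s.phase == "held"]
    if not helds:
        return None
    axes = (chans["ACCEL_X"], chans["ACCEL_Y"], chans["ACCEL_Z"])
    baseline = (0, int(seg_cfg.min_stationary_s * ax.rate))
    flex = float(np.mean([estimate_flexion(axes, baseline, (h.start, h.stop)).angle_deg
                          for h in helds]))
    rows, means = [], {}
    for chan in _MUSCLE:
        filt = bandpass(chans[chan], zero_phase=config.zero_phase)
        feats = phase_features(filt, segments)
        means[chan] = phase_means(feats)
        for _, r in feats.iterrows():
            rows.append((part["id"], stage, chan, r["phase"], int(r["rep"]),
                         r["rms"], r["mpf"]))
    return rows, means, flex


def run_prepost(config: PipelineConfig) -> PrePostReport:
    """Pre/post-exertion comparison (stages 1 and 3)."""
    t0 = time.perf_counter()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seg_cfg = config.seg_config()
    bundle = _load_bundle(config, stages=("pre", "post"))

    feat_rows, excluded = [], []
    stage_means: dict[str, dict[str, list]] = {
        s: {c: [] for c in _MUSCLE} for s in ("pre", "post")}
    participants_kept: dict[str, list[str]] = {s: [] for s in ("pre", "post")}
    flexion: dict[str, list[float]] = {"pre": [], "post": []}
    for part in bundle["participants"]:
        results = {}
        for stage in ("pre", "post"):
            if stage not in part["stages"]:
                results = {}
                break
            results[stage] = _stage_features(part, stage, config, seg_cfg)
            if results[stage] is None:
                break
        if len(results) < 2 or any(v is None for v in results.values()):
            log.warning("participant %s excluded from pre/post (missing stage "
                        "or no repetitions detected)", part["id"])
            excluded.append(part["id"])
            continue
        for stage in ("pre", "post"):
            rows, means, flex = results[stage]
            feat_rows.extend(rows)
            flexion[stage].append(flex)
            participants_kept[stage].append(part["id"])
            for chan in _MUSCLE:
                stage_means[stage][chan].append(means[chan])

    features = pd.DataFrame(feat_rows, columns=["participant", "stage", "channel",
                                                "phase", "rep", "rms", "mpf"])
    comparisons = []
    for chan in _MUSCLE:
        for metric in _METRICS:
            def tidy(stage):
                frames = []
                for pid, df in zip(participants_kept[stage], stage_means[stage][chan]):
                    frames.append(pd.DataFrame({"participant": pid,
                                                "phase": df["phase"],
                                                "value": df[metric]}))
                return pd.concat(frames, ignore_index=True)
            comparisons.append(PrePostComparison.from_participant_means(
                chan, metric.upper(), tidy("pre"), tidy("post")))

    flex_means = {s: float(np.mean(v)) if v else float("nan")
                  for s, v in flexion.items()}
    report = PrePostReport(comparisons, features, flex_means, excluded)

    _write_df(features, out / "phase_features.csv", config)
    comp_rows = [(c.channel, c.metric, p.phase, p.pre_mean, p.post_mean,
                  p.pct_change, p.wilcoxon_p, c.average_pct_change)
                 for c in comparisons for p in c.phases]
    _write_df(pd.DataFrame(comp_rows, columns=[
        "channel", "metric", "phase", "pre_mean", "post_mean", "pct_change",
        "wilcoxon_p", "average_pct_change"]), out / "prepost_comparison.csv", config)
    _write_df(pd.DataFrame([flex_means]), out / "knee_flexion.csv", config)
    (out / "prepost_table.txt").write_text(render_table(comparisons))
    if config.make_plots:
        _plot_prepost(features, out)
    log.info("pre/post analysis finished in %.1f s (%d participants, %d excluded)",
             time.perf_counter() - t0, len(participants_kept["pre"]), len(excluded))
    return report


# ---------------------------------------------------------------------------
# during-exertion analysis
# ---------------------------------------------------------------------------

@dataclass
class ExertionReport:
    trends: list[TrendResult]
    series: pd.DataFrame              # participant, channel, window, time, rms, mpf
    group: dict[str, pd.DataFrame]    # channel -> grid frame
    hold_durations_s: dict[str, float]
    flexion_deg: float
    excluded: list[str]

    def get(self, channel: str, metric: str) -> TrendResult:
        for t in self.trends:
            if t.channel == channel and t.metric == metric.lower():
                return t
        raise KeyError((channel, metric))


def run_exertion(config: PipelineConfig) -> ExertionReport:
    """During-exertion trend analysis (stage 2, the wall squat)."""
    t0 = time.perf_counter()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seg_cfg = config.seg_config()
    bundle = _load_bundle(config, stages=("hold",))

    rows, excluded, holds, flexions = [], [], {}, []
    per_part: dict[str, list[pd.DataFrame]] = {c: [] for c in _MUSCLE}
    for part in bundle["participants"]:
        chans = part["stages"].get("hold")
        if chans is None:
            log.warning("participant %s has no hold stage; excluded", part["id"])
            excluded.append(part["id"])
            continue
        ax = smooth_accel(chans["ACCEL_X"], seg_cfg.smoothing_window_s)
        try:
            held = isolate_hold(ax, seg_cfg)
        except ValueError as exc:
            log.warning("participant %s excluded: %s", part["id"], exc)
            excluded.append(part["id"])
            continue
        holds[part["id"]] = held.duration_s
        axes = (chans["ACCEL_X"], chans["ACCEL_Y"], chans["ACCEL_Z"])
        baseline = (0, int(seg_cfg.min_stationary_s * ax.rate))
        flexions.append(estimate_flexion(axes, baseline,
                                         (held.start, held.stop)).angle_deg)
        for chan in _MUSCLE:
            filt = bandpass(chans[chan], zero_phase=config.zero_phase)
            series = hold_series(filt, held)
            per_part[chan].append(series)
            for _, r in series.iterrows():
                rows.append((part["id"], chan, int(r["window_index"]),
                             r["normalized_time"], r["rms"], r["mpf"]))

    if not holds:
        raise ValueError("no participant yielded an analysable hold")
    series_df = pd.DataFrame(rows, columns=["participant", "channel",
                                            "window_index", "normalized_time",
                                            "rms", "mpf"])
    group = {c: group_hold_average(per_part[c], config.n_grid) for c in _MUSCLE}
    trends = [trend_from_series(group[c], metric, channel=c)
              for c in _MUSCLE for metric in _METRICS]
    report = ExertionReport(trends, series_df, group, holds,
                            float(np.mean(flexions)), excluded)

    _write_df(series_df, out / "hold_series.csv", config)
    trend_rows = [(t.channel, t.metric, t.r, t.p, t.slope, t.intercept,
                   t.pct_change_first_last) for t in trends]
    _write_df(pd.DataFrame(trend_rows, columns=[
        "channel", "metric", "r", "P", "b", "intercept", "pct_change_first_last"]),
        out / "exertion_trends.csv", config)
    _write_df(pd.DataFrame({"participant": list(holds),
                            "hold_s": list(holds.values())}),
              out / "hold_durations.csv", config)
    if config.make_plots:
        _plot_exertion(group, trends, out)
    log.info("exertion analysis finished in %.1f s (%d participants, %d excluded)",
             time.perf_counter() - t0, len(holds), len(excluded))
    return report


def run_all(config: PipelineConfig) -> tuple[PrePostReport, ExertionReport]:
    return run_prepost(config), run_exertion(config)


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def render_table(comparisons: list[PrePostComparison]) -> str:
    """Text table of raw pre/post values and % change per phase."""
    phases = ("entering", "held", "exiting")
    lines = [f"{'':14s}" + "".join(f"{p.capitalize():>18s}" for p in phases)
             + f"{'Average':>18s}",
             f"{'':14s}" + "      Pre     Post" * 4]
    for c in comparisons:
        unit = "V" if c.metric.upper() == "RMS" else "Hz"
        by = {p.phase: p for p in c.phases}
        raw = "".join(f"{by[p].pre_mean:9.2f}{by[p].post_mean:9.2f}" for p in phases)
        pre_avg = np.mean([by[p].pre_mean for p in phases])
        post_avg = np.mean([by[p].post_mean for p in phases])
        lines.append(f"{c.channel:4s}{c.metric:>5s} {unit:>3s} " + raw
                     + f"{pre_avg:9.2f}{post_avg:9.2f}")
        pct = "".join(f"{by[p].pct_change:18.2f}" for p in phases)
        lines.append(f"{'':10s}  %  " + pct + f"{c.average_pct_change:18.2f}")
    return "\n".join(lines) + "\n"


def _plot_prepost(features: pd.DataFrame, out: Path) -> None:
    for metric, fname in (("rms", "fig_prepost_rms.png"),
                          ("mpf", "fig_prepost_mpf.png")):
        fig, axes = plt.subplots(2, 3, figsize=(9, 5), sharey="row")
        for i, chan in enumerate(_MUSCLE):
            for j, phase in enumerate(("entering", "held", "exiting")):
                ax = axes[i, j]
                for stage, color in (("pre", "tab:red"), ("post", "black")):
                    sel = features[(features.channel == chan)
                                   & (features.phase == phase)
                                   & (features.stage == stage)]
                    vals = sel.groupby("participant")[metric].mean()
                    ax.errorbar([stage], [vals.mean()],
                                yerr=[vals.std(ddof=1) if len(vals) > 1 else 0],
                                fmt="o", color=color, capsize=4)
                if i == 0:
                    ax.set_title(phase)
                if j == 0:
                    ax.set_ylabel(f"{chan} {metric.upper()}")
        fig.tight_layout()
        fig.savefig(out / fname, dpi=110)
        plt.close(fig)


def _plot_exertion(group: dict[str, pd.DataFrame],
                   trends: list[TrendResult], out: Path) -> None:
    fig, axes = plt.subplots(2, 2, figsize=(9, 6))
    for j, chan in enumerate(_MUSCLE):
        df = group[chan]
        for i, metric in enumerate(_METRICS):
            ax = axes[i, j]
            t = next(tr for tr in trends if tr.channel == chan and tr.metric == metric)
            x = df["normalized_time"]
            ax.fill_between(x, df[f"{metric}_mean"] - df[f"{metric}_sd"],
                            df[f"{metric}_mean"] + df[f"{metric}_sd"],
                            alpha=0.3, color="tab:blue")
            ax.plot(x, df[f"{metric}_mean"], color="tab:blue")
            ax.plot(x, t.intercept + t.slope * x, "k--",
                    label=f"r={t.r:.2f}, P={t.p:.2g}")
            ax.legend(fontsize=8)
            ax.set_xlabel("% of hold duration")
            ax.set_ylabel(f"{chan} {metric.upper()}")
    fig.tight_layout()
    fig.savefig(out / "fig_exertion_trends.png", dpi=110)
    plt.close(fig)
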