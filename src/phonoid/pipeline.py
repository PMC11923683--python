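"""End-to-end pipeline: stimulus -> response -> metrics/information reports.

A :class:`RunConfig` (usually loaded from YAML) names the stimulus to
generate, where the response comes from (the synthetic response model or a
recorded CSV), and the analysis options.  :func:`run_pipeline` writes the
stimulus and response CSVs, a metrics JSON, an information JSON and a
manifest carrying the seed and a hash of the configuration, so a rerun with
the same config is bit-identical for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import infodynamics, signal_metrics, stimuli, synthetic_data
from .rc_model import RCParams
from .signal_metrics import Signal

log = logging.getLogger(__name__)

SCHEMA_VERSION = 1

__all__ = ["RunConfig", "ConfigError", "PipelineError", "run_pipeline", "load_config"]


class ConfigError(ValueError):
    """Invalid run configuration."""


class PipelineError(RuntimeError):
    """A pipeline stage produced invalid (non-finite) output."""


_STIMULUS_KEYS = {
    "kind", "v0", "n_steps", "scale", "dt", "frequencies", "duration",
    "sample_rate", "amplitudes", "mode", "f0", "n_harmonics", "modulation_depth",
}
_RESPONSE_KEYS = {"source", "csv_path", "gain", "dc_offset", "noise_sd", "R", "C"}
_ANALYSIS_KEYS = {"n_bins", "bands", "fib_freqs", "segment_length"}
_TOP_KEYS = {"stimulus", "response", "analysis", "seed", "outdir", "plots"}


def _check_keys(mapping: dict, allowed: set, where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"unknown {where} key(s): {sorted(unknown)}")


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    stimulus: dict
    response: dict = field(default_factory=lambda: {"source": "synthetic"})
    analysis: dict = field(default_factory=dict)
    seed: int = 0
    outdir: str = "phonoid_run"
    plots: bool = False

    def __post_init__(self) -> None:
        _check_keys(self.stimulus, _STIMULUS_KEYS, "stimulus")
        _check_keys(self.response, _RESPONSE_KEYS, "response")
        _check_keys(self.analysis, _ANALYSIS_KEYS, "analysis")
        kind = self.stimulus.get("kind")
        if kind not in ("golden_decay", "fib_voltage", "fib_tones", "soundscape"):
            raise ConfigError(f"unknown stimulus kind: {kind!r}")
        source = self.response.get("source", "synthetic")
        if source not in ("synthetic", "csv"):
            raise ConfigError(f"response source must be 'synthetic' or 'csv', got {source!r}")
        if source == "csv" and not self.response.get("csv_path"):
            raise ConfigError("response source 'csv' requires csv_path")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        _check_keys(d, _TOP_KEYS, "top-level")
        if "stimulus" not in d:
            raise ConfigError("config requires a 'stimulus' section")
        return cls(
            stimulus=dict(d["stimulus"]),
            response=dict(d.get("response", {"source": "synthetic"})),
            analysis=dict(d.get("analysis", {})),
            seed=int(d.get("seed", 0)),
            outdir=str(d.get("outdir", "phonoid_run")),
            plots=bool(d.get("plots", False)),
        )

    def to_dict(self) -> dict:
        return {
            "stimulus": self.stimulus,
            "response": self.response,
            "analysis": self.analysis,
            "seed": self.seed,
            "outdir": self.outdir,
            "plots": self.plots,
        }


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return RunConfig.from_dict(data)


def _build_stimulus(cfg: RunConfig) -> Signal:
    s = cfg.stimulus
    kind = s["kind"]
    if kind == "golden_decay":
        series = stimuli.golden_ratio_decay(
            v0=s.get("v0", 10.0), n_steps=s.get("n_steps", 1000), scale=s.get("scale", 100.0)
        )
        return series.to_signal(dt=s.get("dt", 1e-3))
    if kind == "fib_voltage":
        series = stimuli.inverse_fibonacci_voltage(
            v0=s.get("v0", 10.0), n_steps=s.get("n_steps", 1000)
        )
        return series.to_signal(dt=s.get("dt", 1e-3))
    if kind == "fib_tones":
        _, combined = stimuli.fibonacci_tone_bank(
            frequencies=s.get("frequencies", stimuli.FIBONACCI_TONE_FREQUENCIES),
            duration=s.get("duration", 5.0),
            sample_rate=s.get("sample_rate", 44100.0),
            amplitudes=s.get("amplitudes"),
            mode=s.get("mode", "sum"),
        )
        return combined.to_signal()
    audio = stimuli.fractal_soundscape(
        f0=s.get("f0", 220.0),
        n_harmonics=s.get("n_harmonics", 10),
        sample_rate=s.get("sample_rate", 44100.0),
        duration=s.get("duration", 10.0),
        seed=cfg.seed,
        modulation_depth=s.get("modulation_depth", 1.0),
    )
    return audio.to_signal()


def _build_response(cfg: RunConfig, stimulus: Signal) -> Signal:
    r = cfg.response
    if r.get("source", "synthetic") == "csv":
        path = Path(r["csv_path"])
        if not path.exists():
            raise PipelineError(f"response CSV not found: {path}")
        return Signal.from_csv(path, sample_rate=stimulus.sample_rate)
    model = synthetic_data.ResponseModelConfig(
        gain=r.get("gain", 0.0108),
        dc_offset=r.get("dc_offset", -0.0104),
        rc=RCParams(R=r.get("R", 128.0), C=r.get("C", 2.888e-6)),
        noise_sd=r.get("noise_sd", 0.001),
        seed=cfg.seed,
    )
    return synthetic_data.gen_response_recording(stimulus, model)


def _assert_finite(name: str, values) -> None:
    arr = np.asarray(
        [v for v in np.atleast_1d(values).ravel() if isinstance(v, (int, float))],
        dtype=float,
    )
    bad = arr[~np.isfinite(arr)]
    # +/-inf sentinels (e.g. SNR of identical signals) are legal; NaN is not
    if np.any(np.isnan(bad)):
        raise PipelineError(f"stage {name!r} produced NaN output")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured run and return the manifest dictionary.

    Outputs written to ``config.outdir``: ``stimulus.csv``, ``response.csv``,
    ``metrics.json``, ``info.json``, ``manifest.json`` and optional plots.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    log.info("stage=stimulus kind=%s seed=%d", config.stimulus["kind"], config.seed)
    stim = _build_stimulus(config)
    _assert_finite("stimulus", stim.samples)
    stim.to_csv(outdir / "stimulus.csv")

    log.info("stage=response source=%s", config.response.get("source", "synthetic"))
    resp = _build_response(config, stim)
    if len(resp) != len(stim):
        raise PipelineError(
            f"response length {len(resp)} != stimulus length {len(stim)}"
        )
    _assert_finite("response", resp.samples)
    resp.to_csv(outdir / "response.csv")

    log.info("stage=metrics")
    fib_freqs = config.analysis.get("fib_freqs", [144.0, 233.0, 377.0, 610.0, 987.0])
    report = signal_metrics.metrics_report(stim, resp, fib_freqs=fib_freqs)
    metrics_dict = report.to_dict()
    _assert_finite("metrics", list(v for v in metrics_dict.values() if isinstance(v, float)))
    (outdir / "metrics.json").write_text(json.dumps(_json_safe(metrics_dict), indent=2))

    log.info("stage=info")
    bands = [tuple(b) for b in config.analysis.get("bands", [(0, 10), (30, 50), (100, None)])]
    n_bins = config.analysis.get("n_bins", infodynamics.DEFAULT_BINS)
    info = infodynamics.info_report(stim, resp, bands=bands, n_bins=n_bins, include_coherence=False)
    info_dict = info.to_dict()
    (outdir / "info.json").write_text(json.dumps(_json_safe(info_dict), indent=2))

    if config.plots:
        _write_plots(outdir, stim, resp)

    cfg_json = json.dumps(config.to_dict(), sort_keys=True)
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "outputs": {
            name: _sha256(outdir / name)
            for name in ("stimulus.csv", "response.csv", "metrics.json", "info.json")
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _json_safe(obj):
    """Replace non-finite floats with strings so JSON stays standard."""
    if isinstance(obj, dict):
        return {k: _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, float) and not math.isfinite(obj):
        return repr(obj)
    return obj


def _write_plots(outdir: Path, stim: Signal, resp: Signal) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 1, figsize=(8, 6), sharex=True)
    axes[0].plot(stim.times, stim.samples, lw=0.5)
    axes[0].set_ylabel("input (V)")
    axes[1].plot(resp.times, resp.samples, lw=0.5, color="C3")
    axes[1].set_ylabel("output (V)")
    axes[1].set_xlabel("time (s)")
    fig.tight_layout()
    fig.savefig(outdir / "timeseries.png", dpi=120)
    plt.close(fig)
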