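"""Configuration and the end-to-end pipeline runner.

`run_pipeline` chains every stage -- endpoint synthesis, continuum
morphing, acoustic profiling, trial-list design, simulated listeners, SDT
estimation and descriptive curves -- and writes all artifacts (WAV +
TextGrid tokens, CSV tables, a hash manifest, a stage log) under one output
directory.  Reruns with the same config are bit-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import acoustics, descriptives, design, fixtures, morph, observer, sdt
from .io import write_manifest, write_token

log = logging.getLogger("nearmerge")

VOWELS = ("i", "a")


@dataclass
class PipelineConfig:
    """All pipeline knobs; every stochastic stage has an explicit seed."""

    fixture_seed: int = 0
    design_seed: int = 1
    observer_seed: int = 2
    bootstrap_seed: int = 3
    n_listeners: int = 32
    sdt_mode: str = "standard"
    bootstrap_b: int = 10_000
    coart_span_ms: float = morph.COART_SPAN_MS
    intensity_db: float = morph.INTENSITY_TARGET_DB
    rt_lower_s: float = descriptives.RT_LOWER_S
    rt_upper_s: float = descriptives.RT_UPPER_S
    mad_mult: float = descriptives.MAD_MULT
    observer_params: dict = field(default_factory=lambda: {
        "dprime_by_vowel": dict(observer.POOLED_DEFAULTS.dprime_by_vowel),
        "k_by_vowel": dict(observer.POOLED_DEFAULTS.k_by_vowel),
        "lapse": 0.0})
    listener_k_sd: float = 0.3
    listener_dprime_sd: float = 0.3

    def validate(self) -> None:
        for name in ("fixture_seed", "design_seed", "observer_seed",
                     "bootstrap_seed"):
            value = getattr(self, name)
            if value is None or not isinstance(value, int):
                raise ValueError(f"config field {name} must be an integer seed")
        if self.sdt_mode not in sdt.MODES:
            raise ValueError(f"sdt_mode must be one of {sdt.MODES}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") \
                    from exc
            log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return result
        return inner
    return wrap


@_stage("continua")
def build_all_continua(config: PipelineConfig) -> dict[str, morph.ContinuumSet]:
    out = {}
    for vowel in VOWELS:
        nasal, lateral = fixtures.make_endpoint_pair(vowel,
                                                     seed=config.fixture_seed)
        out[vowel] = morph.build_continuum(
            nasal, lateral, coart_span_ms=config.coart_span_ms,
            intensity_db=config.intensity_db)
    return out


@_stage("behavior")
def simulate_behavior(config: PipelineConfig
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    params = observer.ObserverParams(mode=config.sdt_mode,
                                     **config.observer_params)
    ax_trials = design.build_ax_blocks(config.design_seed)
    ax = observer.simulate_ax_cohort(
        params, ax_trials, config.n_listeners, config.observer_seed,
        k_sd=config.listener_k_sd, dprime_sd=config.listener_dprime_sd)
    id_trials = design.build_id_blocks(config.design_seed)
    frames = []
    for i in range(config.n_listeners):
        frames.append(observer.simulate_identification(
            observer.ID_DEFAULTS, id_trials,
            seed=config.observer_seed + 10_000 + i,
            listener=f"L{i + 1:02d}"))
    ident = pd.concat(frames, ignore_index=True)
    rt = observer.RtParams()
    ax = observer.simulate_rt(rt, ax, seed=config.observer_seed + 1)
    ident = observer.simulate_rt(rt, ident, seed=config.observer_seed + 2)
    return ax, ident


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute every stage and write all artifacts under `out_dir`."""
    config.validate()
    out = Path(out_dir)
    stim_dir = out / "stimuli"
    stim_dir.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []

    continua = build_all_continua(config)
    profiles = []
    for vowel, continuum in continua.items():
        for step, token in enumerate(continuum.tokens):
            wav = stim_dir / f"cv_{vowel}_{step}.wav"
            write_token(token, wav)
            artifacts += [wav, wav.with_suffix(".TextGrid")]
        profiles.append(acoustics.profile_continuum(continuum))
    profile_table = pd.concat(profiles, ignore_index=True)
    profile_path = out / "acoustic_profiles.csv"
    profile_table.to_csv(profile_path, index=False)
    artifacts.append(profile_path)

    ax_trials = design.build_ax_blocks(config.design_seed)
    id_trials = design.build_id_blocks(config.design_seed)
    for name, df in (("trials_ax.csv", ax_trials),
                     ("trials_id.csv", id_trials)):
        path = out / name
        df.to_csv(path, index=False)
        artifacts.append(path)

    ax, ident = simulate_behavior(config)
    for name, df in (("responses_ax.csv", ax),
                     ("responses_id.csv", ident)):
        path = out / name
        df.to_csv(path, index=False)
        artifacts.append(path)

    estimates = sdt.estimate_cells(ax, mode=config.sdt_mode)
    ci = sdt.bootstrap_ci(estimates["per_listener"], b=config.bootstrap_b,
                          seed=config.bootstrap_seed)
    for name, df in (("sdt_per_listener.csv", estimates["per_listener"]),
                     ("sdt_listener_mean.csv", estimates["listener_mean"]),
                     ("sdt_pooled.csv", estimates["pooled"]),
                     ("sdt_bootstrap_ci.csv", ci)):
        path = out / name
        df.to_csv(path, index=False)
        artifacts.append(path)

    id_curve = descriptives.identification_curve(ident)
    acc_curve = descriptives.accuracy_curve(ax)
    filtered, report = descriptives.preprocess_rt(
        ax[ax["delta"] == 2], lower_s=config.rt_lower_s,
        upper_s=config.rt_upper_s, mad_mult=config.mad_mult,
        correct_only=True)
    for name, df in (("identification_curve.csv", id_curve),
                     ("accuracy_curve.csv", acc_curve)):
        path = out / name
        df.to_csv(path, index=False)
        artifacts.append(path)
    report_path = out / "rt_trim_report.json"
    report_path.write_text(json.dumps(vars(report), indent=2) + "\n")
    artifacts.append(report_path)

    config_path = out / "config.yaml"
    config.to_yaml(config_path)
    artifacts.append(config_path)
    write_manifest(artifacts, out / "manifest.csv")
    return out
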