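"""End-to-end orchestration: simulate -> decompose -> featurize -> baseline -> evaluate.

A run is a pure function of its configuration and seed: the run directory
receives the cohort ground truth, the per-step feature table, per-condition
baseline galleries, the identification evaluation report, and a manifest
recording the configuration, seed and SHA-256 checksum of every artifact.
Re-running with the same configuration reproduces identical bytes.

Two simulation modes are supported. ``signals`` (the default) draws step
force signals directly — the scale used for cohort-level identification
experiments.  ``recordings`` renders full 2D pressure recordings and pushes
them through the preprocessing chain (pass segmentation, direction
normalization, footprint detection, spatial integration) before feature
extraction; it exercises the whole pipeline at a smaller cohort size.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import features as feat
from . import identification as ident
from . import pressure, synthetic

_log = logging.getLogger(__name__)


def _checked(section: str, d: dict, allowed: set[str]) -> dict:
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) in config section '{section}': {sorted(unknown)}")
    return d


@dataclass
class RunConfig:
    """Validated per-stage parameters of one pipeline run."""

    seed: int = 0
    out_dir: str = "gaitdmd_run"
    mode: str = "signals"               # "signals" | "recordings"
    # simulate
    n_persons: int = 16
    n_modes: int = 6
    separation: float = 0.012
    steps_per_person: int = 30
    feet: tuple = ("l", "r")
    speeds: tuple = ("normal", "fast")
    n_passes: int = 4                   # recordings mode
    steps_per_pass: int = 8
    # preprocess
    min_gap: int = 5
    pad_to: int = 100
    # decomposition / features
    rows: int | None = feat.FEATURE_ROWS
    ranks: tuple = feat.RANK_SEQUENCE
    # evaluation
    fraction: float = 0.3
    n_repeats: int = 1000
    holdout: bool | str = False
    standardized: bool = False

    def validate(self) -> None:
        if self.mode not in ("signals", "recordings"):
            raise ValueError(f"mode must be 'signals' or 'recordings', got {self.mode!r}")
        if self.mode == "recordings" and self.n_persons > 6:
            _log.warning("recordings mode with %d persons is slow; consider 'signals'",
                         self.n_persons)
        synthetic.CohortSpec(self.n_persons, self.n_modes, self.separation,
                             self.steps_per_person, self.seed).validate()
        if not 0.0 < self.fraction <= 1.0:
            raise ValueError(f"fraction must be in (0, 1], got {self.fraction}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        allowed = {f.name for f in dataclasses.fields(cls)}
        _checked("run", raw, allowed)
        cfg = cls(**raw)
        for name in ("feet", "speeds", "ranks"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for name in ("feet", "speeds", "ranks"):
            d[name] = list(d[name])
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _steps_from_signals(cfg: RunConfig) -> dict:
    profiles = synthetic.make_cohort(synthetic.CohortSpec(
        cfg.n_persons, cfg.n_modes, cfg.separation, cfg.steps_per_person, cfg.seed))
    by_key = synthetic.simulate_cohort_steps(
        profiles, cfg.steps_per_person, seed=cfg.seed + 1, feet=cfg.feet,
        speeds=cfg.speeds, n_frames=cfg.pad_to)
    return profiles, by_key


def _steps_from_recordings(cfg: RunConfig) -> dict:
    profiles = synthetic.make_cohort(synthetic.CohortSpec(
        cfg.n_persons, cfg.n_modes, cfg.separation, cfg.steps_per_person, cfg.seed))
    by_key: dict = {}
    geometry = synthetic.WalkwayGeometry()
    for i, prof in enumerate(profiles):
        rec, _ = synthetic.simulate_recording(
            prof, geometry, n_passes=cfg.n_passes,
            steps_per_pass=cfg.steps_per_pass, seed=cfg.seed + 10 + i,
            pad_to=cfg.pad_to)
        steps = pressure.preprocess_recording(rec, min_gap=cfg.min_gap,
                                              pad_to=cfg.pad_to)
        for s in steps:
            s.person = prof.person_id
            s.speed = "normal"
            by_key.setdefault((prof.person_id, s.foot, "normal"), []).append(s)
    return profiles, by_key


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages and write artifacts plus a deterministic manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []

    try:
        # --- simulate ---
        if config.mode == "signals":
            profiles, by_key = _steps_from_signals(config)
        else:
            profiles, by_key = _steps_from_recordings(config)
        cohort_path = out / "cohort.json"
        synthetic.cohort_to_json(profiles, cohort_path)
        artifacts.append(cohort_path)
        _log.info("simulate: %d persons, %d step groups", len(profiles), len(by_key))

        # --- decompose & featurize ---
        feature_sets: dict = {}
        n_total = n_elig = 0
        for key, sigs in sorted(by_key.items()):
            fss = []
            for s in sigs:
                fs = feat.features_from_signal(
                    s, n_modes=config.n_modes, rows=config.rows,
                    rank_sequence=config.ranks, person=s.person, foot=s.foot,
                    speed=s.speed, cycle=s.cycle)
                n_total += 1
                if fs.eligible:
                    fss.append(fs)
                    n_elig += 1
            feature_sets[key] = fss
        _log.info("features: %d/%d steps eligible", n_elig, n_total)
        feat_path = out / "features.csv"
        feat.write_features_csv([fs for fss in feature_sets.values() for fs in fss],
                                feat_path)
        artifacts.append(feat_path)

        # --- baselines & evaluation per (foot, speed) ---
        conditions = sorted({(k[1], k[2]) for k in feature_sets})
        eval_out = {}
        for foot, speed in conditions:
            by_person = {k[0]: v for k, v in feature_sets.items()
                         if k[1] == foot and k[2] == speed and len(v) >= 2}
            gallery = ident.Gallery(
                [ident.compute_baseline(v, foot=foot, speed=speed)
                 for _, v in sorted(by_person.items())])
            gpath = out / f"baselines_{foot}_{speed}.json"
            gallery.to_json(gpath)
            artifacts.append(gpath)
            rep = ident.evaluate_identification(
                by_person, fraction=config.fraction, n_repeats=config.n_repeats,
                seed=config.seed + 2, holdout=config.holdout,
                standardized=config.standardized, foot=foot, speed=speed)
            eval_out[f"{foot}/{speed}"] = rep.to_dict()
            _log.info("evaluate %s/%s: accuracy %.4f", foot, speed, rep.accuracy)
        eval_path = out / "evaluation.json"
        with open(eval_path, "w") as fh:
            json.dump(eval_out, fh, indent=1, sort_keys=True)
        artifacts.append(eval_path)
    except Exception as exc:
        (out / "manifest.partial").write_text(
            f"pipeline aborted: {type(exc).__name__}: {exc}\n")
        raise

    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "artifacts": {p.name: _sha256(p) for p in artifacts},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return out
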