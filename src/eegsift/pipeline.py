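"""End-to-end orchestration: simulate -> extract -> select -> classify.

A single declarative :class:`PipelineConfig` carries every stage parameter
(defaults reproduce the full study settings); :func:`run_pipeline` runs the
stages in order, writing each artifact under the output directory stamped
with the config hash and seed, so identical configurations produce
bit-identical artifacts and stages can be resumed from persisted
intermediates.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bands import BandSpec, CANONICAL_BANDS
from .cohort import CohortConfig, EffectSpec, generate_cohort, read_cohort, write_cohort
from .evaluation import assign_distress_groups, holdout_evaluate, report
from .features import FeatureTable, extract_features, feature_census
from .selection import select_features

log = logging.getLogger("eegsift")


@dataclass
class PipelineConfig:
    """All stage parameters of one pipeline run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    bands: tuple[BandSpec, ...] = CANONICAL_BANDS
    psd_epoch_s: float = 4.0
    psd_overlap: float = 0.5
    lzc_epoch_s: float = 20.0
    pte_epoch_s: float = 4.0
    pte_delay: int = 1
    pte_bins: int | None = None
    sweep_start: float = 0.90
    sweep_stop: float = 0.10
    sweep_step: float = 0.025
    screen_alpha: float = 0.05
    nca_reps: int = 1000
    cv_folds: int = 5
    cv_reps: int = 1000
    stepdown_reps: int = 20
    holdout_frac: float = 0.7
    holdout_reps: int = 5000
    seed: int = 0
    contrasts: tuple[str, ...] = ("ct", "lh")

    @property
    def sweep_fractions(self) -> tuple[float, ...]:
        return tuple(
            float(f)
            for f in np.round(
                np.arange(self.sweep_start, self.sweep_stop - 1e-9, -self.sweep_step), 6
            )
        )

    def config_hash(self) -> str:
        blob = json.dumps(_to_jsonable(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (tuple, list)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def validate_config(config: PipelineConfig) -> list[str]:
    """Cross-field checks; returns the accumulated list of problems."""
    errors = []
    c = config.cohort
    nyq = c.fs / 2.0
    for b in config.bands:
        if b.f_high >= nyq:
            errors.append(f"band {b.name} upper edge {b.f_high} Hz >= Nyquist {nyq} Hz")
    for name, ep in (("psd", config.psd_epoch_s), ("lzc", config.lzc_epoch_s),
                     ("pte", config.pte_epoch_s)):
        if ep <= 0:
            errors.append(f"{name}_epoch_s must be positive")
        elif ep > c.duration_s:
            errors.append(f"{name}_epoch_s {ep}s exceeds recording duration {c.duration_s}s")
    if not (0 <= config.psd_overlap < 1):
        errors.append("psd_overlap must be in [0, 1)")
    if not (0 < config.sweep_stop <= config.sweep_start <= 1):
        errors.append("sweep bounds must satisfy 0 < stop <= start <= 1")
    if config.sweep_step <= 0:
        errors.append("sweep_step must be positive")
    if not (0 < config.holdout_frac < 1):
        errors.append("holdout_frac must be in (0, 1)")
    for name, v in (("screen_alpha", config.screen_alpha),):
        if not (0 < v < 1):
            errors.append(f"{name} must be in (0, 1)")
    for name, v in (("nca_reps", config.nca_reps), ("cv_folds", config.cv_folds),
                    ("cv_reps", config.cv_reps), ("holdout_reps", config.holdout_reps),
                    ("pte_delay", config.pte_delay)):
        if v < 1:
            errors.append(f"{name} must be >= 1")
    return errors


def load_config(path: str) -> PipelineConfig:
    """Load a PipelineConfig from a YAML file (missing keys take defaults)."""
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    cohort_raw = raw.pop("cohort", {})
    effects = tuple(
        EffectSpec(**{**e, "region": tuple(e["region"]) if isinstance(e["region"], list)
                      else e["region"]})
        for e in cohort_raw.pop("effect_specs", [])
    )
    bands_raw = raw.pop("bands", None)
    bands = (
        tuple(BandSpec(**b) for b in bands_raw) if bands_raw else CANONICAL_BANDS
    )
    cohort_kwargs = dict(cohort_raw)
    if "region_labels" in cohort_kwargs:
        cohort_kwargs["region_labels"] = tuple(cohort_kwargs["region_labels"])
    cohort = CohortConfig(effect_specs=effects, bands=bands, **cohort_kwargs)
    return PipelineConfig(cohort=cohort, bands=bands, **raw)


def _feature_csv(table: FeatureTable, path: Path) -> None:
    df = table.X.copy()
    df.insert(0, "label", table.y)
    df.to_csv(path, float_format="%.12g")


def _read_feature_csv(path: Path) -> FeatureTable:
    df = pd.read_csv(path, index_col=0)
    y = df.pop("label").to_numpy()
    return FeatureTable(df, y)


def run_pipeline(config: PipelineConfig, outdir: str | Path,
                 resume: bool = True) -> dict:
    """Run all stages, persisting artifacts; returns a summary dict.

    Artifacts: ``cohort.h5`` (+ metadata CSV), ``features.csv``,
    ``selection_<contrast>.json``, ``report_<contrast>.json`` (+ ``.txt``),
    and ``run.json`` with the config hash, seed and stage timings. With
    ``resume=True`` stages whose artifacts already exist are reloaded
    instead of recomputed.
    """
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid pipeline config: " + "; ".join(errors))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config.config_hash(), "seed": config.seed,
             "config": _to_jsonable(config), "timings_s": {}}
    rng = np.random.default_rng(config.seed)
    seeds = {name: int(rng.integers(2**31 - 1))
             for name in ("select_ct", "select_lh", "holdout_ct", "holdout_lh")}

    t0 = time.perf_counter()
    cohort_path = outdir / "cohort.h5"
    if resume and cohort_path.exists():
        cohort = read_cohort(str(cohort_path))
        log.info("reloaded cohort from %s", cohort_path)
    else:
        cohort = generate_cohort(config.cohort)
        write_cohort(str(cohort_path), cohort)
        log.info("simulated cohort of %d subjects", len(cohort))
    stamp["timings_s"]["simulate"] = round(time.perf_counter() - t0, 3)

    t0 = time.perf_counter()
    feat_path = outdir / "features.csv"
    if resume and feat_path.exists():
        table = _read_feature_csv(feat_path)
        log.info("reloaded feature table from %s", feat_path)
    else:
        table = extract_features(
            cohort, bands=config.bands,
            psd_epoch_s=config.psd_epoch_s, psd_overlap=config.psd_overlap,
            lzc_epoch_s=config.lzc_epoch_s, pte_epoch_s=config.pte_epoch_s,
            pte_delay=config.pte_delay, pte_bins=config.pte_bins,
            sweep=config.sweep_fractions,
        )
        _feature_csv(table, feat_path)
        log.info("extracted %d features x %d subjects", table.X.shape[1], len(table.X))
    stamp["timings_s"]["extract"] = round(time.perf_counter() - t0, 3)

    records = [r for r, _ in cohort]
    summary: dict = {"n_subjects": len(records),
                     "n_features": table.X.shape[1],
                     "reports": {}}
    for contrast in config.contrasts:
        t0 = time.perf_counter()
        if contrast == "ct":
            sub, y = table, table.y
            names = ("control", "tinnitus")
        elif contrast == "lh":
            patients = [r for r in records if r.group == "tinnitus"]
            grouping = assign_distress_groups(patients)
            ids = grouping.low_ids + grouping.high_ids
            if len(grouping.low_ids) < 2 or len(grouping.high_ids) < 2:
                log.warning("skipping lh contrast: not enough subjects per stratum")
                continue
            sub = FeatureTable(table.X.loc[ids],
                               np.array([0] * len(grouping.low_ids)
                                        + [1] * len(grouping.high_ids)))
            y = sub.y
            names = ("low_distress", "high_distress")
        else:
            raise ValueError(f"unknown contrast {contrast!r}")

        sel = select_features(
            sub.X.to_numpy(), y, columns=list(sub.X.columns),
            alpha=config.screen_alpha, nca_reps=config.nca_reps,
            cv_folds=config.cv_folds, cv_reps=config.cv_reps,
            stepdown_reps=config.stepdown_reps,
            seed=seeds[f"select_{contrast}"],
        )
        with open(outdir / f"selection_{contrast}.json", "w") as f:
            json.dump(sel.to_dict(), f, indent=2, sort_keys=True)
        if not sel.selected:
            log.warning("contrast %s: no features survived selection", contrast)
            summary["reports"][contrast] = None
            continue
        from .selection import zscore

        Xsel = zscore(sub.X[sel.selected].to_numpy())
        rep = holdout_evaluate(
            Xsel, y, train_frac=config.holdout_frac,
            n_reps=config.holdout_reps, rng=seeds[f"holdout_{contrast}"],
            class_names=names,
        )
        report(rep, str(outdir / f"report_{contrast}.json"))
        summary["reports"][contrast] = {
            "n_screened": len(sel.screened),
            "n_nca": len(sel.nca_selected),
            "n_selected": len(sel.selected),
            "selected": sel.selected,
            "mean_train_accuracy": rep.mean_train_accuracy,
            "mean_test_accuracy": rep.mean_test_accuracy,
            "test_tpr": rep.test_tpr,
            "test_tnr": rep.test_tnr,
        }
        stamp["timings_s"][f"classify_{contrast}"] = round(time.perf_counter() - t0, 3)

    with open(outdir / "run.json", "w") as f:
        json.dump({**stamp, "summary": summary}, f, indent=2, sort_keys=True)
    return summary


def default_feature_count(config: PipelineConfig) -> int:
    """Size of the feature census implied by the configuration."""
    return len(feature_census(config.cohort.region_labels, config.bands))
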