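"""Synthetic multi-region EEG-like cohorts with planted group effects.

Each subject's 68-region (configurable) signal matrix is synthesized in the
frequency domain as a 1/f^alpha background plus one stochastic band-limited
oscillation per canonical band, standardized to unit variance in the
baseline (no-effect) condition. Group effects are planted per feature kind:

* ``abs_psd`` / ``rel_psd`` — the band oscillation amplitude is multiplied
  by ``exp(sigma_band * d)`` where ``sigma_band`` is the between-subject
  log-amplitude jitter SD, so the planted shift equals *d* in log-amplitude
  units (and approximately *d* on the extracted log-power feature).
* ``lzc`` — the oscillation bandwidth is widened (narrowed) by a factor
  ``exp(+-0.35 d)``; broader band-limited noise has a less regular envelope
  and higher Lempel-Ziv complexity.
* ``coupling`` / ``if_in`` / ``if_out`` — a delayed copy of the source
  region's band component is added to the target region (unidirectional
  phase-lagged coupling, coefficient ``0.25 d``, lag 8 samples at 128 Hz).

TQ distress scores for patients are drawn from a three-stratum mixture with
mass below 30, in [30, 38] and above 38 (the low/excluded/high split used
downstream).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .atlas import make_atlas, validate_region
from .bands import BandSpec, CANONICAL_BANDS, get_band

_KINDS = ("abs_psd", "rel_psd", "lzc", "if_in", "if_out", "coupling")

#: Between-subject SD of a band oscillation's log-amplitude (natural log).
SIGMA_BAND = 0.2
#: Bandwidth modulation rate for lzc effects (log bandwidth per unit d).
LZC_BW_RATE = 0.35
#: Coupling coefficient per unit effect size; d=2 gives the default c=0.5.
COUPLING_RATE = 0.25
#: Coupling lag in samples (8 at 128 Hz ~ 62 ms).
COUPLING_LAG = 8
#: Number of partner regions wired up by an if_in / if_out effect.
IF_PARTNERS = 3

# variance budget of the baseline signal (background vs. six oscillations)
_BG_VAR = 0.5
_OSC_VAR_EACH = 0.5 / 6.0


@dataclass(frozen=True)
class EffectSpec:
    """A planted between-group difference in one feature.

    ``region`` is an atlas label, or an ``(source, target)`` pair for
    ``coupling`` effects. ``effect_size_d`` is the standardized mean
    difference aimed at; ``direction`` says which group sits higher.
    ``modulated_by`` selects the contrast that carries the effect: the
    control/patient split (default) or the low/high-distress split within
    patients.
    """

    feature_kind: str
    band: str
    region: str | tuple[str, str]
    effect_size_d: float
    direction: str = "patient_higher"
    modulated_by: str = "group"

    def __post_init__(self) -> None:
        if self.feature_kind not in _KINDS:
            raise ValueError(f"unknown feature kind {self.feature_kind!r}")
        if self.direction not in ("patient_higher", "patient_lower"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.modulated_by not in ("group", "distress"):
            raise ValueError(f"unknown modulation {self.modulated_by!r}")
        if self.effect_size_d < 0:
            raise ValueError("effect_size_d must be >= 0")
        if self.feature_kind == "coupling" and not (
            isinstance(self.region, tuple) and len(self.region) == 2
        ):
            raise ValueError("coupling effects need a (source, target) region pair")


@dataclass(frozen=True)
class SubjectRecord:
    """Per-subject metadata: group, distress score, demographics."""

    subject_id: str
    group: str
    tq_score: int | None = None
    age: float = 50.0
    gender: str = "F"
    hearing_threshold_db: float | None = None

    def __post_init__(self) -> None:
        if self.group not in ("control", "tinnitus"):
            raise ValueError(f"unknown group {self.group!r}")
        if (self.tq_score is not None) != (self.group == "tinnitus"):
            raise ValueError("tq_score must be present iff group is tinnitus")


@dataclass(frozen=True)
class CohortConfig:
    """Sizes, sampling and effect structure of a synthetic cohort.

    Defaults follow the study setup: 128 Hz sampling, 5-minute recordings,
    68 atlas regions, 142 controls vs. 129 patients, and TQ strata
    proportions 51 : 22 : 56 (low / excluded / high distress).
    """

    n_controls: int = 142
    n_patients: int = 129
    fs: float = 128.0
    duration_s: float = 300.0
    n_regions: int = 68
    seed: int = 0
    effect_specs: tuple[EffectSpec, ...] = ()
    tq_strata_probs: tuple[float, float, float] = (51 / 129, 22 / 129, 56 / 129)
    region_labels: tuple[str, ...] = field(default_factory=lambda: tuple(make_atlas()))
    bands: tuple[BandSpec, ...] = CANONICAL_BANDS
    background_alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.n_controls < 0 or self.n_patients < 0:
            raise ValueError("subject counts must be non-negative")
        if self.n_controls + self.n_patients == 0:
            raise ValueError("cohort must contain at least one subject")
        if self.fs <= 0 or self.duration_s <= 0 or self.n_regions <= 0:
            raise ValueError("fs, duration_s and n_regions must be positive")
        if len(self.region_labels) != self.n_regions:
            raise ValueError(
                f"n_regions={self.n_regions} does not match "
                f"{len(self.region_labels)} region labels"
            )
        if len(set(self.region_labels)) != len(self.region_labels):
            raise ValueError("region labels must be unique")
        for spec in self.effect_specs:
            regions = (
                spec.region if isinstance(spec.region, tuple) else (spec.region,)
            )
            for r in regions:
                validate_region(r, self.region_labels)
            get_band(spec.band, self.bands)

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration_s))


@dataclass
class RegionTimecourses:
    """One subject's region-by-samples signal matrix at a fixed rate."""

    subject_id: str
    data: np.ndarray
    fs: float
    region_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        d = np.asarray(self.data)
        if d.ndim != 2 or d.shape[0] != len(self.region_labels):
            raise ValueError("data must be [n_regions, n_samples]")
        if not np.isfinite(d).all():
            raise ValueError("signal contains NaN/Inf")


def _band_mask(freqs: np.ndarray, f_low: float, f_high: float) -> np.ndarray:
    """Tukey-tapered spectral mask over [f_low, f_high]."""
    mask = np.zeros_like(freqs)
    inside = (freqs >= f_low) & (freqs <= f_high)
    if inside.any():
        width = f_high - f_low
        taper_w = 0.15 * width
        x = freqs[inside]
        up = np.clip((x - f_low) / taper_w, 0, 1)
        down = np.clip((f_high - x) / taper_w, 0, 1)
        mask[inside] = np.sin(up * np.pi / 2) * np.sin(down * np.pi / 2)
    return mask


def _spectral_noise(rng: np.random.Generator, amp: np.ndarray, n: int) -> np.ndarray:
    """Real time series with spectral amplitude profile *amp* (rfft grid)."""
    coef = amp * (rng.standard_normal(len(amp)) + 1j * rng.standard_normal(len(amp)))
    coef[0] = 0.0
    return np.fft.irfft(coef, n=n)


def _effect_sign(spec: EffectSpec) -> float:
    return 1.0 if spec.direction == "patient_higher" else -1.0


def _effect_active(spec: EffectSpec, record: SubjectRecord) -> bool:
    if spec.modulated_by == "group":
        return record.group == "tinnitus"
    # distress-modulated: only the high-distress stratum carries the effect
    return record.group == "tinnitus" and record.tq_score is not None \
        and record.tq_score > 38


def generate_subject(
    config: CohortConfig,
    record: SubjectRecord,
    rng: np.random.Generator,
) -> RegionTimecourses:
    """Synthesize one subject's region time courses with planted effects.

    Baseline signals (all effect sizes zero, or a control subject) are drawn
    from one fixed distribution: 1/f^alpha background plus six band-limited
    oscillations, standardized so the expected baseline variance per region
    is 1. Effects perturb amplitude, bandwidth or cross-region coupling as
    described in the module docstring.
    """
    n = config.n_samples
    freqs = np.fft.rfftfreq(n, d=1.0 / config.fs)
    # background: power ~ 1/f^alpha above 0.5 Hz
    bg_amp = np.zeros_like(freqs)
    valid = freqs >= 0.5
    bg_amp[valid] = freqs[valid] ** (-config.background_alpha / 2.0)

    # index planted effects for fast lookup
    amp_fx: dict[tuple[str, str], float] = {}
    bw_fx: dict[tuple[str, str], float] = {}
    couplings: list[tuple[str, str, str, float]] = []  # (band, src, tgt, c)
    for spec in config.effect_specs:
        if not _effect_active(spec, record):
            continue
        s = _effect_sign(spec) * spec.effect_size_d
        if spec.feature_kind in ("abs_psd", "rel_psd"):
            key = (spec.band, spec.region)  # type: ignore[arg-type]
            amp_fx[key] = amp_fx.get(key, 0.0) + SIGMA_BAND * s
        elif spec.feature_kind == "lzc":
            key = (spec.band, spec.region)  # type: ignore[arg-type]
            bw_fx[key] = bw_fx.get(key, 0.0) + LZC_BW_RATE * s
        elif spec.feature_kind == "coupling":
            src, tgt = spec.region  # type: ignore[misc]
            couplings.append((spec.band, src, tgt, COUPLING_RATE * spec.effect_size_d))
        elif spec.feature_kind == "if_in":
            tgt = spec.region  # type: ignore[assignment]
            others = [r for r in config.region_labels if r != tgt][:IF_PARTNERS]
            for src in others:
                couplings.append((spec.band, src, tgt, COUPLING_RATE * spec.effect_size_d))
        elif spec.feature_kind == "if_out":
            src = spec.region  # type: ignore[assignment]
            others = [r for r in config.region_labels if r != src][:IF_PARTNERS]
            for tgt in others:
                couplings.append((spec.band, src, tgt, COUPLING_RATE * spec.effect_size_d))

    # synthesize per region: background + per-band oscillation components
    label_idx = {r: i for i, r in enumerate(config.region_labels)}
    bg = np.empty((config.n_regions, n))
    osc: dict[str, np.ndarray] = {}  # band -> [n_regions, n] components
    # expected SD of a unit-coefficient synthesis: 2*sqrt(sum(amp^2))/n
    bg_norm = 2.0 * np.sqrt((bg_amp**2).sum()) / n
    for i in range(config.n_regions):
        bg[i] = _spectral_noise(rng, bg_amp, n)
    bg *= np.sqrt(_BG_VAR) / bg_norm

    for b in config.bands:
        comp = np.empty((config.n_regions, n))
        for i, r in enumerate(config.region_labels):
            bw_shift = bw_fx.get((b.name, r), 0.0)
            if bw_shift:
                center = (b.f_low + b.f_high) / 2.0
                half = (b.f_high - b.f_low) / 2.0 * np.exp(bw_shift)
                mask = _band_mask(freqs, max(center - half, 0.5), center + half)
            else:
                mask = _band_mask(freqs, b.f_low, b.f_high)
            norm = 2.0 * np.sqrt((mask**2).sum()) / n
            if norm == 0:
                comp[i] = 0.0
                continue
            # between-subject amplitude jitter + planted log-amplitude shift
            log_amp = SIGMA_BAND * rng.standard_normal() + amp_fx.get((b.name, r), 0.0)
            amp = np.sqrt(_OSC_VAR_EACH) / norm * np.exp(log_amp)
            comp[i] = _spectral_noise(rng, amp * mask, n)
        osc[b.name] = comp

    for band_name, src, tgt, c in couplings:
        comp = osc[band_name]
        delayed = np.roll(comp[label_idx[src]], COUPLING_LAG)
        comp[label_idx[tgt]] = comp[label_idx[tgt]] + c * delayed

    data = bg + sum(osc.values())
    return RegionTimecourses(
        subject_id=record.subject_id,
        data=data.astype(np.float32),
        fs=config.fs,
        region_labels=config.region_labels,
    )


def _draw_tq(rng: np.random.Generator, probs: tuple[float, float, float]) -> int:
    """TQ score from the low (<30) / excluded ([30,38]) / high (>38) mixture."""
    stratum = rng.choice(3, p=np.asarray(probs) / np.sum(probs))
    if stratum == 0:
        return int(rng.integers(5, 30))
    if stratum == 1:
        return int(rng.integers(30, 39))
    return int(rng.integers(39, 77))


def generate_records(config: CohortConfig, rng: np.random.Generator) -> list[SubjectRecord]:
    """Metadata for all subjects (controls first, then patients)."""
    records = []
    for i in range(config.n_controls):
        records.append(
            SubjectRecord(
                subject_id=f"C{i:04d}",
                group="control",
                age=float(np.clip(rng.normal(47, 17), 18, 90).round(1)),
                gender="F" if rng.random() < 52 / 142 else "M",
            )
        )
    for i in range(config.n_patients):
        records.append(
            SubjectRecord(
                subject_id=f"T{i:04d}",
                group="tinnitus",
                tq_score=_draw_tq(rng, config.tq_strata_probs),
                age=float(np.clip(rng.normal(50, 15), 18, 90).round(1)),
                gender="F" if rng.random() < 38 / 129 else "M",
                hearing_threshold_db=float(np.clip(rng.normal(25, 15), 0, 90).round(1)),
            )
        )
    return records


def generate_cohort(
    config: CohortConfig,
) -> list[tuple[SubjectRecord, RegionTimecourses]]:
    """Full cohort: metadata plus signals, bit-reproducible under the seed.

    One child RNG stream per subject (spawned from the config seed) keeps
    subjects independent and the whole cohort deterministic.
    """
    master = np.random.SeedSequence(config.seed)
    meta_rng = np.random.default_rng(master.spawn(1)[0])
    records = generate_records(config, meta_rng)
    children = master.spawn(len(records) + 1)[1:]
    cohort = []
    for record, child in zip(records, children):
        rng = np.random.default_rng(child)
        cohort.append((record, generate_subject(config, record, rng)))
    return cohort


# ---------------------------------------------------------------------------
# container I/O: HDF5 signals + CSV metadata sidecar
# ---------------------------------------------------------------------------

_META_COLUMNS = ["subject_id", "group", "tq_score", "age", "gender",
                 "hearing_threshold_db"]


def write_cohort(path: str, cohort: list[tuple[SubjectRecord, RegionTimecourses]]) -> None:
    """Write a cohort container: ``<path>`` (HDF5) + ``<path>.meta.csv``.

    One float32 dataset per subject under ``/subjects``, with sampling rate
    and region labels as root attributes; metadata as a CSV sidecar with a
    nullable ``tq_score`` column. Timestamps are disabled so identical
    cohorts serialize to identical bytes.
    """
    if not cohort:
        raise ValueError("cannot write an empty cohort")
    first = cohort[0][1]
    with h5py.File(path, "w", track_order=True) as f:
        f.attrs["fs"] = first.fs
        f.attrs["region_labels"] = list(first.region_labels)
        grp = f.create_group("subjects", track_order=True)
        for record, ts in cohort:
            grp.create_dataset(
                record.subject_id, data=ts.data.astype(np.float32), track_times=False
            )
    rows = []
    for record, _ in cohort:
        rows.append(
            {
                "subject_id": record.subject_id,
                "group": record.group,
                "tq_score": record.tq_score,
                "age": record.age,
                "gender": record.gender,
                "hearing_threshold_db": record.hearing_threshold_db,
            }
        )
    pd.DataFrame(rows, columns=_META_COLUMNS).to_csv(str(path) + ".meta.csv", index=False)


def read_cohort(path: str) -> list[tuple[SubjectRecord, RegionTimecourses]]:
    """Read a cohort container written by :func:`write_cohort`."""
    meta = pd.read_csv(str(path) + ".meta.csv")
    cohort = []
    with h5py.File(path, "r") as f:
        fs = float(f.attrs["fs"])
        labels = tuple(str(x) for x in f.attrs["region_labels"])
        for row in meta.itertuples(index=False):
            sid = str(row.subject_id)
            try:
                data = f["subjects"][sid][()]
            except KeyError as exc:
                raise ValueError(f"corrupt cohort container: missing subject {sid}") from exc
            tq = None if pd.isna(row.tq_score) else int(row.tq_score)
            ht = None if pd.isna(row.hearing_threshold_db) else float(row.hearing_threshold_db)
            record = SubjectRecord(
                subject_id=sid,
                group=str(row.group),
                tq_score=tq,
                age=float(row.age),
                gender=str(row.gender),
                hearing_threshold_db=ht,
            )
            cohort.append(
                (record, RegionTimecourses(sid, np.asarray(data), fs, labels))
            )
    return cohort


def read_edf_regions(path: str, channel_map: dict[str, str] | None = None):
    """Convenience reader: raw multichannel EDF -> RegionTimecourses.

    Requires the optional ``mne`` dependency. ``channel_map`` renames EDF
    channels to region labels; unmapped channels keep their EDF names. This
    is an ingestion shim for real recordings, not part of the tested
    synthetic path.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading EDF requires the optional 'mne' dependency") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data()
    labels = [channel_map.get(ch, ch) if channel_map else ch for ch in raw.ch_names]
    return RegionTimecourses(
        subject_id=path, data=data, fs=float(raw.info["sfreq"]),
        region_labels=tuple(labels),
    )
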