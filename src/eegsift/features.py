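"""Feature identifiers and the subjects-by-features table.

Each scalar feature is addressed as ``{kind}:{band}:{region}`` — e.g.
``abs_psd:delta:Cu_L`` or ``graph:gamma:global_efficiency`` (graph metrics
are global, so their third field is the metric name and their region is
``"global"``). The default census is 5 region-wise kinds x 6 bands x 68
regions + 6 graph metrics x 6 bands = 2076 features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bands import BAND_NAMES, BandSpec, CANONICAL_BANDS, bandpass
from .complexity import lzc_feature
from .connectivity import information_flow, pte_matrix
from .graphs import METRIC_NAMES, metrics_over_sweep
from .spectral import absolute_psd, relative_psd

REGION_KINDS = ("abs_psd", "rel_psd", "lzc", "if_in", "if_out")


@dataclass(frozen=True)
class FeatureSpec:
    """Typed identifier of one scalar feature."""

    kind: str
    band: str
    region: str  # atlas label, or metric name for kind="graph"

    def __str__(self) -> str:
        return f"{self.kind}:{self.band}:{self.region}"

    @classmethod
    def parse(cls, s: str) -> "FeatureSpec":
        kind, band, region = s.split(":")
        return cls(kind, band, region)


@dataclass
class FeatureTable:
    """Subjects-by-features matrix with binary group labels.

    ``X`` is a DataFrame indexed by subject id with feature-spec string
    columns; ``y`` is an integer label array aligned with its rows.
    """

    X: pd.DataFrame
    y: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y)
        if len(self.y) != len(self.X):
            raise ValueError("labels do not match table rows")
        if self.X.isna().any().any():
            raise ValueError("feature table contains missing values")
        if len(self.X.columns) != len(set(self.X.columns)):
            raise ValueError("duplicate feature columns")

    @property
    def specs(self) -> list[FeatureSpec]:
        return [FeatureSpec.parse(c) for c in self.X.columns]

    def subset(self, columns: list[str]) -> "FeatureTable":
        return FeatureTable(self.X[columns].copy(), self.y.copy())


def feature_census(
    region_labels: tuple[str, ...],
    bands: tuple[BandSpec, ...] = CANONICAL_BANDS,
) -> list[FeatureSpec]:
    """Ordered list of all feature identifiers for a given atlas and bands."""
    specs = []
    for kind in REGION_KINDS:
        for b in bands:
            for r in region_labels:
                specs.append(FeatureSpec(kind, b.name, r))
    for b in bands:
        for m in METRIC_NAMES:
            specs.append(FeatureSpec("graph", b.name, m))
    return specs


def extract_subject_features(
    data: np.ndarray,
    fs: float,
    region_labels: tuple[str, ...],
    bands: tuple[BandSpec, ...] = CANONICAL_BANDS,
    psd_epoch_s: float = 4.0,
    psd_overlap: float = 0.5,
    lzc_epoch_s: float = 20.0,
    pte_epoch_s: float = 4.0,
    pte_delay: int = 1,
    pte_bins: int | None = None,
    sweep: tuple[float, ...] | None = None,
) -> dict[str, float]:
    """All features of one subject, keyed by feature-spec string.

    PSD features come from the broadband region signal (band-averaged
    periodogram bins); LZC and PTE operate on the Chebyshev-II band-filtered
    signal. Graph metrics are computed from each band's PTE matrix over the
    proportional-threshold sweep.
    """
    from .graphs import DEFAULT_SWEEP

    if sweep is None:
        sweep = DEFAULT_SWEEP
    out: dict[str, float] = {}
    for i, region in enumerate(region_labels):
        abs_p = absolute_psd(data[i], fs, bands, psd_epoch_s, psd_overlap)
        rel_p = relative_psd(data[i], fs, bands, psd_epoch_s, psd_overlap)
        for b in bands:
            out[f"abs_psd:{b.name}:{region}"] = abs_p[b.name]
            out[f"rel_psd:{b.name}:{region}"] = rel_p[b.name]
    for b in bands:
        filtered = bandpass(data, b, fs)
        for i, region in enumerate(region_labels):
            out[f"lzc:{b.name}:{region}"] = lzc_feature(filtered[i], fs, lzc_epoch_s)
        cm = pte_matrix(
            filtered, fs, epoch_length_s=pte_epoch_s, delay_samples=pte_delay,
            n_bins=pte_bins, band=b.name, region_labels=region_labels,
        )
        flow = information_flow(cm)
        for i, region in enumerate(region_labels):
            out[f"if_in:{b.name}:{region}"] = float(flow.if_in[i])
            out[f"if_out:{b.name}:{region}"] = float(flow.if_out[i])
        gm = metrics_over_sweep(cm, fractions=sweep, band=b.name)
        for m in METRIC_NAMES:
            out[f"graph:{b.name}:{m}"] = getattr(gm, m)
    return out


def extract_features(
    cohort,
    bands: tuple[BandSpec, ...] = CANONICAL_BANDS,
    **kwargs,
) -> FeatureTable:
    """Feature table for a whole cohort (labels: tinnitus=1, control=0)."""
    rows, index, labels = [], [], []
    for record, ts in cohort:
        rows.append(extract_subject_features(ts.data, ts.fs, ts.region_labels,
                                             bands=bands, **kwargs))
        index.append(record.subject_id)
        labels.append(1 if record.group == "tinnitus" else 0)
    X = pd.DataFrame(rows, index=index)
    census = [str(s) for s in feature_census(cohort[0][1].region_labels, bands)]
    return FeatureTable(X[census], np.asarray(labels))
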