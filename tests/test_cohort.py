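"""Atlas, synthetic cohort generation and container I/O."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import FS, small_labels
from eegsift.atlas import make_atlas
from eegsift.cohort import (CohortConfig, EffectSpec, SubjectRecord,
                            generate_cohort, generate_records, generate_subject,
                            read_cohort, write_cohort)
from eegsift.spectral import absolute_psd


class TestAtlas:
    def test_68_unique_labels_34_per_hemisphere(self):
        atlas = make_atlas()
        assert len(atlas) == 68
        assert len(set(atlas)) == 68
        assert sum(1 for a in atlas if a.endswith("_L")) == 34
        assert sum(1 for a in atlas if a.endswith("_R")) == 34

    def test_known_abbreviations_present(self):
        atlas = make_atlas()
        for label in ("Cu_L", "IT_R", "BSTS_L", "INS_R", "PTR_R", "IP_R"):
            assert label in atlas


class TestRecords:
    def test_tq_present_iff_patient(self):
        with pytest.raises(ValueError):
            SubjectRecord("x", "control", tq_score=10)
        with pytest.raises(ValueError):
            SubjectRecord("x", "tinnitus")

    def test_default_cohort_sizes(self):
        rng = np.random.default_rng(0)
        records = generate_records(CohortConfig(), rng)
        assert len(records) == 271
        assert sum(r.group == "control" for r in records) == 142

    def test_tq_strata_proportions(self):
        # pooled stratum counts over repeats stay near the configured
        # (51, 22, 56)/129 mixture (binomial CI on each stratum)
        counts = np.zeros(3)
        n_rep, n_pat = 20, 129
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            cfg = CohortConfig(n_controls=0, n_patients=n_pat, seed=seed)
            for r in generate_records(cfg, rng):
                q = r.tq_score
                counts[0 if q < 30 else (1 if q <= 38 else 2)] += 1
        total = n_rep * n_pat
        for k, expect in zip(counts, (51 / 129, 22 / 129, 56 / 129)):
            p_hat = k / total
            se = np.sqrt(expect * (1 - expect) / total)
            assert abs(p_hat - expect) < 1.96 * se * 1.5

    def test_all_three_strata_populated(self):
        rng = np.random.default_rng(1)
        recs = generate_records(CohortConfig(n_controls=0, n_patients=129), rng)
        qs = np.array([r.tq_score for r in recs])
        assert (qs < 30).any() and ((qs >= 30) & (qs <= 38)).any() and (qs > 38).any()


class TestGenerateSubject:
    def test_shape_matches_config(self):
        labels = small_labels(3)
        cfg = CohortConfig(n_controls=1, n_patients=0, duration_s=30.0,
                           n_regions=3, region_labels=labels, seed=0)
        rec = SubjectRecord("c0", "control")
        ts = generate_subject(cfg, rec, np.random.default_rng(0))
        assert ts.data.shape == (3, int(30 * FS))
        assert np.isfinite(ts.data).all()

    def test_default_duration_gives_38400_samples(self):
        assert CohortConfig().n_samples == 38400

    def test_baseline_unit_variance(self):
        labels = small_labels(2)
        cfg = CohortConfig(n_controls=1, n_patients=0, duration_s=60.0,
                           n_regions=2, region_labels=labels, seed=0)
        var = []
        for s in range(10):
            ts = generate_subject(cfg, SubjectRecord(f"c{s}", "control"),
                                  np.random.default_rng(s))
            var.append(ts.data.var(axis=1))
        assert np.mean(var) == pytest.approx(1.0, rel=0.25)

    def test_invalid_effect_region_rejected(self):
        labels = small_labels(2)
        with pytest.raises(ValueError):
            CohortConfig(n_regions=2, region_labels=labels,
                         effect_specs=(EffectSpec("abs_psd", "delta", "Cu_L", 1.0),))

    def test_null_effects_give_identical_group_distributions(self):
        # with all effect sizes zero, patient and control signal variances
        # are drawn from one distribution
        labels = small_labels(2)
        cfg = CohortConfig(n_controls=20, n_patients=20, duration_s=30.0,
                           n_regions=2, region_labels=labels, seed=3)
        v = {0: [], 1: []}
        for rec, ts in generate_cohort(cfg):
            v[1 if rec.group == "tinnitus" else 0].append(ts.data.var())
        assert stats.ks_2samp(v[0], v[1]).pvalue > 0.01

    def test_planted_power_effect_detectable(self):
        # delta-power effect at d=1.5, n=50/50: the screen's t-test rejects
        # in every simulated cohort (closed-form power at this d is ~1)
        labels = ("Cu_L", "IT_R")
        rejections = 0
        n_cohorts = 30
        for seed in range(n_cohorts):
            cfg = CohortConfig(n_controls=50, n_patients=50, duration_s=60.0,
                               n_regions=2, region_labels=labels, seed=seed,
                               effect_specs=(EffectSpec("abs_psd", "delta", "Cu_L", 1.5),))
            groups = {0: [], 1: []}
            for rec, ts in generate_cohort(cfg):
                groups[1 if rec.group == "tinnitus" else 0].append(
                    absolute_psd(ts.data[0], FS)["delta"])
            p = stats.ttest_ind(groups[0], groups[1], equal_var=True).pvalue
            rejections += p < 0.05
        assert rejections == n_cohorts

    def test_effect_monotone_in_requested_d(self):
        labels = ("Cu_L", "IT_R")
        mean_d = []
        for d in (0.0, 0.5, 1.0, 2.0):
            realized = []
            for seed in range(20):
                cfg = CohortConfig(
                    n_controls=10, n_patients=10, duration_s=40.0, n_regions=2,
                    region_labels=labels, seed=1000 + seed,
                    effect_specs=(EffectSpec("abs_psd", "alpha", "Cu_L", d),))
                g = {0: [], 1: []}
                for rec, ts in generate_cohort(cfg):
                    g[1 if rec.group == "tinnitus" else 0].append(
                        absolute_psd(ts.data[0], FS)["alpha"])
                a, b = np.array(g[0]), np.array(g[1])
                sp = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
                realized.append((b.mean() - a.mean()) / sp)
            mean_d.append(np.mean(realized))
        assert mean_d[0] < mean_d[1] < mean_d[2] < mean_d[3]


class TestDeterminismAndIO:
    def test_same_seed_reproduces_bits(self, tiny_cohort):
        cfg, cohort = tiny_cohort
        again = generate_cohort(cfg)
        for (r1, t1), (r2, t2) in zip(cohort, again):
            assert r1 == r2
            np.testing.assert_array_equal(t1.data, t2.data)

    def test_roundtrip(self, tiny_cohort, tmp_path):
        cfg, cohort = tiny_cohort
        path = tmp_path / "cohort.h5"
        write_cohort(str(path), cohort)
        back = read_cohort(str(path))
        assert len(back) == len(cohort)
        for (r1, t1), (r2, t2) in zip(cohort, back):
            assert r1 == r2
            np.testing.assert_array_equal(t1.data, t2.data)
            assert t2.fs == t1.fs
            assert tuple(t2.region_labels) == tuple(t1.region_labels)

    def test_metadata_has_nullable_tq(self, tiny_cohort, tmp_path):
        cfg, cohort = tiny_cohort
        path = tmp_path / "cohort.h5"
        write_cohort(str(path), cohort)
        meta = pd.read_csv(str(path) + ".meta.csv")
        assert "tq_score" in meta.columns
        assert meta.loc[meta.group == "control", "tq_score"].isna().all()
        assert meta.loc[meta.group == "tinnitus", "tq_score"].notna().all()

    def test_missing_file_errors(self, tmp_path):
        with pytest.raises((OSError, FileNotFoundError)):
            read_cohort(str(tmp_path / "nope.h5"))

    def test_zero_subject_config_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n_controls=0, n_patients=0)
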