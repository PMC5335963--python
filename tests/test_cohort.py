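"""Cohort container, CSV round-trip, background subtraction and the
univariate significance screen."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from breathscreen.cohort import (CANCER, HEALTHY, CohortError,
                                 read_voc_table, significance_screen,
                                 subtract_background, write_voc_table)
from conftest import make_table


class TestVOCTableIO:
    def test_small_csv_round_trip(self, tmp_path):
        csv = tmp_path / "c.csv"
        csv.write_text(
            "sample_id,label,vocA,vocB,vocC\n"
            "p1,cancer,1.5,2.0,0.1\n"
            "h1,healthy,0.5,1.0,0.2\n"
        )
        t = read_voc_table(csv)
        assert t.concentrations.shape == (2, 3)
        assert t.voc_names == ["vocA", "vocB", "vocC"]
        assert list(t.labels) == [CANCER, HEALTHY]

    def test_write_read_identity_random_table(self, tmp_path, rng):
        conc = rng.lognormal(1.0, 1.2, size=(17, 6))
        t = make_table(conc, [CANCER] * 9 + [HEALTHY] * 8)
        path = tmp_path / "t.csv"
        write_voc_table(t, path)
        back = read_voc_table(path)
        np.testing.assert_array_equal(back.concentrations, t.concentrations)
        assert back.voc_names == t.voc_names
        assert list(back.labels) == list(t.labels)
        assert back.sample_ids == t.sample_ids

    def test_invalid_label_names_offending_row(self, tmp_path):
        csv = tmp_path / "c.csv"
        csv.write_text("sample_id,label,v\np1,cancer,1\np2,tumour,2\n")
        with pytest.raises(CohortError, match="p2"):
            read_voc_table(csv)

    def test_missing_label_column(self, tmp_path):
        csv = tmp_path / "c.csv"
        csv.write_text("sample_id,v\np1,1\n")
        with pytest.raises(CohortError, match="label"):
            read_voc_table(csv)

    def test_non_numeric_cell(self, tmp_path):
        csv = tmp_path / "c.csv"
        csv.write_text("sample_id,label,v\np1,cancer,oops\np2,healthy,1\n")
        with pytest.raises(CohortError, match="non-numeric"):
            read_voc_table(csv)

    def test_duplicate_sample_ids(self, tmp_path):
        csv = tmp_path / "c.csv"
        csv.write_text("sample_id,label,v\np1,cancer,1\np1,healthy,2\n")
        with pytest.raises(CohortError, match="duplicate"):
            read_voc_table(csv)

    def test_missing_cell_errors_unless_imputed(self, tmp_path):
        csv = tmp_path / "c.csv"
        csv.write_text("sample_id,label,v\np1,cancer,\np2,healthy,1\n")
        with pytest.raises(CohortError, match="missing"):
            read_voc_table(csv)
        t = read_voc_table(csv, impute_missing_zero=True)
        assert t.concentrations[0, 0] == 0.0

    def test_schema_column_mapping(self, tmp_path):
        csv = tmp_path / "c.csv"
        csv.write_text("subject,diagnosis,v\np1,cancer,1\np2,healthy,2\n")
        t = read_voc_table(csv, schema={"sample_id": "subject",
                                        "label": "diagnosis"})
        assert t.sample_ids == ["p1", "p2"]
        assert t.voc_names == ["v"]

    def test_stage_requires_cancer_label(self):
        with pytest.raises(CohortError, match="stage"):
            make_table([[1.0], [2.0]], [CANCER, HEALTHY],
                       stage=[None, "II"])


class TestBackgroundSubtraction:
    def test_zero_background_is_identity(self, tiny_table):
        out = subtract_background(tiny_table, {v: 0.0 for v in tiny_table.voc_names})
        np.testing.assert_array_equal(out.concentrations,
                                      tiny_table.concentrations)

    def test_clamp_negative_to_zero(self):
        t = make_table([[5.0], [9.0]], [CANCER, HEALTHY])
        out = subtract_background(t, {"v0": 8.0})
        np.testing.assert_array_equal(out.concentrations, [[0.0], [1.0]])

    def test_floor_off_matches_elementwise_subtraction(self, rng):
        conc = rng.lognormal(1, 1, size=(10, 4))
        bg = dict(zip("abcd", rng.uniform(0, 5, 4)))
        t = make_table(conc, [CANCER] * 5 + [HEALTHY] * 5,
                       voc_names=list("abcd"))
        out = subtract_background(t, bg, floor_at_zero=False)
        expected = conc - np.array([bg[v] for v in "abcd"])[None, :]
        np.testing.assert_allclose(out.concentrations, expected, rtol=0, atol=0)

    def test_missing_voc_treated_as_zero(self, tiny_table):
        out = subtract_background(tiny_table, {"v0": 1.0})
        np.testing.assert_array_equal(out.concentrations[:, 1:],
                                      tiny_table.concentrations[:, 1:])

    def test_negative_background_rejected(self, tiny_table):
        with pytest.raises(CohortError, match="negative"):
            subtract_background(tiny_table, {"v0": -1.0})


class TestSignificanceScreen:
    def test_identical_class_distributions_not_flagged(self):
        vals = np.array([1.0, 2.5, 3.0, 4.2, 5.1])
        t = make_table(np.concatenate([vals, vals])[:, None],
                       [CANCER] * 5 + [HEALTHY] * 5)
        scr = significance_screen(t)
        assert not scr["wilcoxon_flag"].iloc[0]
        assert not scr["ks_flag"].iloc[0]

    def test_exact_rank_sum_small_sample(self):
        # cancer {1,2} vs healthy {3,4}: 2 of the C(4,2)=6 equally likely
        # rank assignments are at least this extreme -> p = 2/6
        t = make_table([[1.0], [2.0], [3.0], [4.0]],
                       [CANCER, CANCER, HEALTHY, HEALTHY])
        scr = significance_screen(t)
        assert scr["wilcoxon_p"].iloc[0] == pytest.approx(2 / 6, abs=1e-12)

    def test_planted_shift_is_flagged(self):
        from breathscreen import simulate
        cfg = simulate.small_panel(n_vocs=3, n_informative=1, n_cancer=100,
                                   n_healthy=100, delta=1.5, seed=4)
        t, truth = simulate.generate_cohort(cfg)
        scr = significance_screen(t)
        assert scr.loc[truth.informative[0], "wilcoxon_flag"]
        assert scr.loc[truth.informative[0], "ks_flag"]

    def test_invariant_to_sample_order_and_label_swap(self, random_table):
        scr = significance_screen(random_table)
        perm = np.random.default_rng(0).permutation(random_table.n_samples)
        scr_perm = significance_screen(random_table.take(perm))
        pd.testing.assert_frame_equal(scr, scr_perm)
        swapped = make_table(
            random_table.concentrations,
            [HEALTHY if l == CANCER else CANCER for l in random_table.labels],
        )
        scr_swap = significance_screen(swapped)
        np.testing.assert_allclose(scr["wilcoxon_p"], scr_swap["wilcoxon_p"])
        np.testing.assert_allclose(scr["ks_p"], scr_swap["ks_p"])

    def test_pvalues_bounded_and_flags_exact(self, random_table):
        scr = significance_screen(random_table)
        assert ((scr[["wilcoxon_p", "ks_p"]] >= 0).all().all()
                and (scr[["wilcoxon_p", "ks_p"]] <= 1).all().all())
        assert (scr["wilcoxon_flag"] == (scr["wilcoxon_p"] < 0.05)).all()
        assert (scr["ks_flag"] == (scr["ks_p"] < 0.05)).all()

    def test_constant_voc_never_nan(self):
        t = make_table([[1.0], [1.0], [1.0], [1.0]],
                       [CANCER, CANCER, HEALTHY, HEALTHY])
        scr = significance_screen(t)
        assert scr["wilcoxon_p"].iloc[0] == 1.0
        assert scr["ks_p"].iloc[0] == 1.0

    def test_synthetic_samples_excluded(self, rng):
        conc = rng.normal(10, 1, size=(12, 1))
        base = make_table(conc, [CANCER] * 6 + [HEALTHY] * 6)
        scr_base = significance_screen(base)
        # append extreme synthetic healthy rows; screen must not move
        conc2 = np.vstack([conc, np.full((4, 1), 1e3)])
        t2 = make_table(conc2, [CANCER] * 6 + [HEALTHY] * 10,
                        origin=["original"] * 12 + ["synthetic"] * 4)
        scr2 = significance_screen(t2)
        pd.testing.assert_frame_equal(scr_base, scr2)

    def test_requires_two_samples_per_class(self):
        t = make_table([[1.0], [2.0], [3.0]], [CANCER, CANCER, HEALTHY])
        with pytest.raises(CohortError, match=">= 2"):
            significance_screen(t)

    def test_matches_scipy_on_random_data(self, random_table):
        scr = significance_screen(random_table)
        x = random_table.concentrations[random_table.labels == CANCER, 0]
        y = random_table.concentrations[random_table.labels == HEALTHY, 0]
        expected = stats.mannwhitneyu(x, y, alternative="two-sided",
                                      method="asymptotic").pvalue
        assert scr["wilcoxon_p"].iloc[0] == pytest.approx(expected)
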