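"""Subset enumeration, screening, sweep, ranking and frequency tables."""

import itertools

import numpy as np
import pandas as pd
import pytest

from breathscreen import reference
from breathscreen.cohort import CANCER, HEALTHY
from breathscreen.evaluation import SubsetResult
from breathscreen.oversample import OversampleConfig
from breathscreen.search import (CacheMismatchError, ResultCache,
                                 SubsetScreen, competition_ranks,
                                 count_subsets, enumerate_subsets,
                                 rank_subsets, size_sweep, voc_frequency)
from conftest import make_table


class TestEnumeration:
    def test_full_20_voc_panel_count(self):
        names = [f"voc{i}" for i in range(20)]
        assert count_subsets(20) == 1_048_575
        assert sum(1 for _ in enumerate_subsets(names)) == 1_048_575

    def test_single_full_size_subset(self):
        subs = list(enumerate_subsets(list("abcde"), sizes={5}))
        assert subs == [tuple("abcde")]

    def test_powerset_matches_brute_force_oracle(self):
        names = [f"v{i}" for i in range(10)]
        subs = list(enumerate_subsets(names))
        assert len(subs) == 2**10 - 1 == 1023
        brute = set()
        for s in range(1, 11):
            brute.update(itertools.combinations(names, s))
        assert set(subs) == brute
        assert len(set(subs)) == len(subs)  # each exactly once

    def test_order_sizes_ascending_lexicographic(self):
        subs = list(enumerate_subsets(["b", "a", "c"], sizes=[2, 1]))
        assert subs == [("b",), ("a",), ("c",),
                        ("b", "a"), ("b", "c"), ("a", "c")]

    def test_errors(self):
        with pytest.raises(ValueError):
            list(enumerate_subsets([]))
        with pytest.raises(ValueError):
            list(enumerate_subsets(["a"], sizes=[2]))


def quick_cohort(n_vocs=4, seed=0):
    rng = np.random.default_rng(seed)
    n_c, n_h = 14, 8
    conc = rng.lognormal(2, 0.6, size=(n_c + n_h, n_vocs))
    conc[:n_c, 0] *= 3.0  # informative first VOC
    return make_table(conc, [CANCER] * n_c + [HEALTHY] * n_h)


class TestScreenAll:
    def test_four_voc_screen_yields_15_results(self):
        res = SubsetScreen(quick_cohort(),
                           oversample=OversampleConfig(seed=1)).fit()
        assert len(res.results) == 15
        sizes = sorted(len(r.subset) for r in res.results)
        assert sizes == sorted(len(s) for s in
                               enumerate_subsets([f"v{i}" for i in range(4)]))

    def test_warm_cache_rerun_identical_without_retraining(self, tmp_path,
                                                           monkeypatch):
        cache_path = tmp_path / "cache.json"
        t = quick_cohort()
        model = SubsetScreen(t, sizes=[1, 2], oversample=OversampleConfig(seed=1))
        r1 = model.fit(cache=ResultCache(cache_path))

        import breathscreen.search as search_mod
        calls = {"n": 0}
        real = search_mod.loocv_subset

        def counting(*a, **kw):
            calls["n"] += 1
            return real(*a, **kw)

        monkeypatch.setattr(search_mod, "loocv_subset", counting)
        r2 = model.fit(cache=ResultCache(cache_path))
        assert calls["n"] == 0
        assert [(r.subset, r.tp, r.tn, r.mean_sv_count) for r in r1.results] == \
            [(r.subset, r.tp, r.tn, r.mean_sv_count) for r in r2.results]

    def test_stale_cache_fingerprint_detected(self, tmp_path):
        cache_path = tmp_path / "cache.json"
        SubsetScreen(quick_cohort(seed=0), sizes=[1],
                     oversample=OversampleConfig(seed=1)).fit(
            cache=ResultCache(cache_path))
        other = SubsetScreen(quick_cohort(seed=99), sizes=[1],
                             oversample=OversampleConfig(seed=1))
        with pytest.raises(CacheMismatchError):
            other.fit(cache=ResultCache(cache_path))

    def test_deterministic_given_seed(self):
        t = quick_cohort()
        r1 = SubsetScreen(t, sizes=[1, 2], oversample=OversampleConfig(seed=3)).fit()
        r2 = SubsetScreen(t, sizes=[1, 2], oversample=OversampleConfig(seed=3)).fit()
        pd.testing.assert_frame_equal(r1.to_dataframe(), r2.to_dataframe())


def fake_results(metric_rows):
    """SubsetResults with prescribed (subset, tp, tn, sv) over P=107/N=29."""
    out = []
    for subset, tp, tn, sv in metric_rows:
        out.append(SubsetResult(subset=tuple(subset), tp=tp, fn=107 - tp,
                                tn=tn, fp=29 - tn, mean_sv_count=sv,
                                sv_fraction=sv / 213))
    return out


class TestSweepAndRank:
    def test_single_subset_is_best_for_all_metrics(self):
        res = fake_results([(("a", "b"), 90, 20, 30.0)])
        sw = size_sweep(res)
        assert sw.loc[2, "best_acc"] == res[0].acc
        assert sw.loc[2, "best_tpr"] == res[0].tpr
        assert sw.loc[2, "best_tnr"] == res[0].tnr

    def test_sweep_matches_linear_scan_oracle(self):
        rng = np.random.default_rng(0)
        rows = []
        names = list("abcdef")
        for s in (1, 2, 3):
            for sub in itertools.combinations(names, s):
                rows.append((sub, int(rng.integers(50, 108)),
                             int(rng.integers(10, 30)),
                             float(rng.uniform(10, 60))))
        res = fake_results(rows)
        sw = size_sweep(res)
        for s in (1, 2, 3):
            pool = [r for r in res if len(r.subset) == s]
            for metric in ("acc", "tpr", "tnr"):
                assert sw.loc[s, f"best_{metric}"] == max(
                    getattr(r, metric) for r in pool)

    def test_competition_rank_pattern(self):
        assert competition_ranks([89.0, 88.2, 88.2, 86.8]) == [1, 2, 2, 4]
        assert competition_ranks([5.0, 4.0, 3.0]) == [1, 2, 3]
        assert competition_ranks([9, 7, 7, 7, 7, 6]) == [1, 2, 2, 2, 2, 6]

    def test_rank_table_orders_and_ranks(self):
        res = fake_results([
            (("a",), 99, 22, 40.0),   # acc 88.97 -> 89.0
            (("b",), 98, 22, 50.0),   # acc 88.24 -> 88.2
            (("c",), 99, 21, 30.0),   # acc 88.24 -> 88.2 fewer SVs
            (("d",), 96, 22, 20.0),   # acc 86.76 -> 86.8
        ])
        tab = rank_subsets(res, "acc", size=1, top_k=4)
        assert list(tab["rank"]) == [1, 2, 2, 4]
        # among the tied pair, fewer support vectors is listed first
        assert list(tab["subset"]) == [("a",), ("c",), ("b",), ("d",)]

    def test_all_distinct_metrics_rank_1_to_k(self):
        res = fake_results([((f"v{i}",), 80 + i, 20, 10.0) for i in range(5)])
        tab = rank_subsets(res, "acc", size=1, top_k=5)
        assert list(tab["rank"]) == [1, 2, 3, 4, 5]

    def test_rank_table_matches_sort_oracle_random(self):
        rng = np.random.default_rng(42)
        res = fake_results([
            ((f"x{i}",), int(rng.integers(60, 108)), int(rng.integers(5, 30)),
             float(rng.uniform(5, 80))) for i in range(100)
        ])
        tab = rank_subsets(res, "tpr", size=1, top_k=20)
        oracle = sorted(res, key=lambda r: (-r.tpr, r.mean_sv_count, r.subset))
        assert list(tab["subset"]) == [r.subset for r in oracle[:20]]
        np.testing.assert_array_equal(
            tab["tpr"], [round(r.tpr, 1) for r in oracle[:20]])

    def test_rank_permutation_invariant(self):
        rng = np.random.default_rng(7)
        res = fake_results([
            ((f"x{i}",), int(rng.integers(60, 108)), int(rng.integers(5, 30)),
             float(rng.uniform(5, 80))) for i in range(30)
        ])
        t1 = rank_subsets(res, "acc", size=1, top_k=10)
        shuffled = list(res)
        rng.shuffle(shuffled)
        t2 = rank_subsets(shuffled, "acc", size=1, top_k=10)
        pd.testing.assert_frame_equal(t1, t2)

    def test_top_k_exceeding_pool_rejected(self):
        res = fake_results([(("a",), 90, 20, 10.0)])
        with pytest.raises(ValueError, match="top_k"):
            rank_subsets(res, "acc", size=1, top_k=2)


class TestFrequency:
    def test_single_subset(self):
        tab = pd.DataFrame({"rank": [1], "subset": [("a", "b")]})
        freq = voc_frequency(tab)
        assert dict(zip(freq["voc"], freq["count"])) == {"a": 1, "b": 1}

    def test_published_acc_ranking_frequencies(self):
        freq = voc_frequency(reference.rank_table_frame(reference.TOP10_ACC_5VOC))
        counts = dict(zip(freq["voc"], freq["count"]))
        assert counts["Isoprene"] == 9
        assert counts["CHN"] == 6
        assert counts["1-Propanol"] == 6
        assert counts["CH3CN"] == 6
        assert counts["Methanol"] == 4
        assert freq.iloc[0]["voc"] == "Isoprene"

    def test_published_tpr_ranking_frequencies(self):
        freq = voc_frequency(reference.rank_table_frame(reference.TOP10_TPR_5VOC))
        counts = dict(zip(freq["voc"], freq["count"]))
        assert counts["1-Propanol"] == 7
        assert counts["C2H3CN"] == 6
        assert counts["CH3CN"] == 6
        assert counts["Ethanol"] == 5
        assert counts["Isoprene"] == 5

    def test_published_tnr_ranking_frequencies(self):
        freq = voc_frequency(reference.rank_table_frame(reference.TOP10_TNR_4VOC))
        counts = dict(zip(freq["voc"], freq["count"]))
        assert counts["CHN"] == 7
        assert counts["CH3CN"] == 7
        assert counts["Methanol"] == 5
        assert counts["Isoprene"] == 5
        assert counts["CHCl3"] == 3

    def test_counts_sum_to_k_times_subset_size(self):
        tab = reference.rank_table_frame(reference.TOP10_ACC_5VOC)
        freq = voc_frequency(tab)
        assert freq["count"].sum() == 10 * 5
        assert freq["count"].between(0, 10).all()

    @pytest.mark.parametrize("rows,metric", [
        (reference.TOP10_ACC_5VOC, "acc"),
        (reference.TOP10_TPR_5VOC, "tpr"),
        (reference.TOP10_TNR_4VOC, "tnr"),
    ])
    def test_published_rank_patterns_follow_competition_numbering(self, rows,
                                                                  metric):
        tab = reference.rank_table_frame(rows)
        assert competition_ranks(list(tab[metric])) == list(tab["rank"])

    def test_empty_rank_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            voc_frequency(pd.DataFrame({"subset": []}))
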