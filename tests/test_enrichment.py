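"""The five-step enrichment procedure, auto-sweep, diagnostics and CLI."""

import math

import numpy as np
import pytest
from scipy.stats import norm

from tauset.cli import cli_main
from tauset.enrichment import (RankedSetEnrichment, RunConfig, run_enrichment,
                               sliding_window_profile)
from tauset.io import RankedGeneList, RankedGeneSet
from tauset.stats import AUTO_SHAPES, exhaustive_p_value


def _concordant_inputs(n=20, n_background=30):
    genes = [f"g{i}" for i in range(n)]
    bg = [f"b{i}" for i in range(n_background)]
    gset = RankedGeneSet("TOP", "", genes, np.arange(n, 0, -1, dtype=float))
    glist = RankedGeneList(genes + bg,
                           np.arange(n + n_background, 0, -1, dtype=float))
    return gset, glist


def test_perfectly_concordant_set_detected():
    gset, glist = _concordant_inputs()
    res = run_enrichment([gset], glist)
    (rec,) = res.records
    assert rec.tau == pytest.approx(1.0)
    assert rec.p_value < 0.05
    assert rec.direction == 1
    assert rec.fdr >= rec.p_value


def test_toy_uniform_p_against_exhaustive_oracle(toy_set, toy_list):
    """n=4 identity overlap: asymptotic p = 2*Phi(-6/sqrt(26/3)) ~ 0.0415."""
    from tauset.stats import tau_test
    res = tau_test([1, 2, 3, 4], weights=np.ones(4))
    assert res.tau == 1.0
    expected = 2 * norm.sf(6 / math.sqrt(26 / 3))
    assert res.p_value == pytest.approx(expected, abs=1e-12)
    assert res.p_value == pytest.approx(0.04154, abs=5e-5)
    # exhaustive oracle: only the identity and its reverse reach |tau| = 1
    p_exact = exhaustive_p_value([1, 2, 3, 4], weights=np.ones(4))
    assert p_exact == pytest.approx(2 / 24)


def test_toy_pipeline_overlap_reranked(toy_set, toy_list):
    res = run_enrichment([toy_set], toy_list, min_overlap=2)
    (rec,) = res.records
    assert rec.n_overlap == 4
    assert rec.tau == pytest.approx(1.0)
    assert rec.p_method == "permutation"  # n < 10 falls back to permutation


def test_absent_sets_skipped(toy_list):
    ghost = RankedGeneSet("GHOST", "", ["nope1", "nope2"], [2.0, 1.0])
    res = run_enrichment([ghost], toy_list)
    assert res.records == []
    assert res.skipped == [("GHOST", 0)]


def test_min_overlap_skips_small_sets(toy_set, toy_list):
    res = run_enrichment([toy_set], toy_list, min_overlap=5)
    assert res.records == []
    assert res.skipped == [("S1", 4)]


def test_within_overlap_reranking_ignores_background():
    """List ranks are recomputed inside the overlap, so adding background
    genes between the overlap genes leaves the statistic unchanged."""
    gset, glist_dense = _concordant_inputs(n=15, n_background=0)
    _, glist_sparse = _concordant_inputs(n=15, n_background=200)
    r1 = run_enrichment([gset], glist_dense).records[0]
    r2 = run_enrichment([gset], glist_sparse).records[0]
    assert r1.tau == r2.tau
    assert r1.p_value == r2.p_value


def test_set_order_invariance(rng):
    genes = [f"g{i}" for i in range(60)]
    glist = RankedGeneList(genes, rng.normal(size=60))
    sets = [RankedGeneSet(f"S{k}", "", list(rng.choice(genes, 15,
                                                       replace=False)),
                          rng.normal(size=15))
            for k in range(6)]
    f1 = run_enrichment(sets, glist, seed=3).frame
    f2 = run_enrichment(sets[::-1], glist, seed=3).frame
    assert f1.equals(f2)


def test_auto_sweep_enumerates_five_shapes_and_minimizes_fdr(rng):
    genes = [f"g{i}" for i in range(80)]
    glist = RankedGeneList(genes, rng.normal(size=80))
    sets = [RankedGeneSet(f"S{k}", "", list(rng.choice(genes, 25,
                                                       replace=False)),
                          rng.normal(size=25))
            for k in range(5)]
    auto = run_enrichment(sets, glist, auto=True, seed=1)
    assert auto.n_shapes == len(AUTO_SHAPES) == 5
    shapes_seen = set(auto.frame["p_param"])
    assert shapes_seen <= set(AUTO_SHAPES)
    for shape in AUTO_SHAPES:
        fixed = run_enrichment(sets, glist, shape=shape, seed=1)
        merged = auto.frame.set_index("set_id")["fdr"]
        for sid, fdr in fixed.frame.set_index("set_id")["fdr"].items():
            assert merged[sid] <= fdr + 1e-12


def test_tied_list_scores_use_permutation(rng):
    genes = [f"g{i}" for i in range(30)]
    scores = np.round(rng.normal(size=30), 0)  # heavy ties
    glist = RankedGeneList(genes, scores)
    gset = RankedGeneSet("S", "", genes[:15], rng.normal(size=15))
    res = run_enrichment([gset], glist, n_perm=500)
    assert res.records[0].p_method == "permutation"


def test_global_null_calibration(rng):
    """Under a shuffled list, the p < alpha rate stays near alpha."""
    n_genes, n_sets, alpha = 400, 300, 0.05
    genes = [f"g{i}" for i in range(n_genes)]
    glist = RankedGeneList(genes, rng.normal(size=n_genes))
    sets = [RankedGeneSet(f"S{k}", "",
                          list(rng.choice(genes, 30, replace=False)),
                          rng.normal(size=30))
            for k in range(n_sets)]
    res = run_enrichment(sets, glist)
    rate = float((res.frame["p_value"] < alpha).mean())
    # 99.7% binomial envelope around alpha
    bound = 3 * math.sqrt(alpha * (1 - alpha) / n_sets)
    assert abs(rate - alpha) < bound


class TestSlidingWindow:
    def test_window_sizes_even(self):
        gset, glist = _concordant_inputs(n=10)
        profile = sliding_window_profile(gset, glist)
        assert [len(w) for w in profile] == [2, 2, 2, 2, 2]

    def test_remainder_goes_to_last_window(self):
        gset, glist = _concordant_inputs(n=11)
        profile = sliding_window_profile(gset, glist)
        assert [len(w) for w in profile] == [2, 2, 2, 2, 3]

    def test_concordant_medians_decrease(self):
        gset, glist = _concordant_inputs(n=25)
        profile = sliding_window_profile(gset, glist)
        medians = [float(np.median(w)) for w in profile]
        assert all(a > b for a, b in zip(medians, medians[1:]))

    def test_too_small_overlap(self):
        gset, glist = _concordant_inputs(n=4)
        with pytest.raises(ValueError):
            sliding_window_profile(gset, glist)

    def test_available_from_results(self):
        gset, glist = _concordant_inputs(n=10)
        res = run_enrichment([gset], glist)
        assert [len(w) for w in res.sliding_window("TOP")] == [2] * 5


class TestCLI:
    @pytest.fixture
    def files(self, tmp_path):
        rnk = tmp_path / "list.rnk"
        rnk.write_text("".join(f"g{i}\t{50 - i}\n" for i in range(50)))
        gmt = tmp_path / "sets.gmt"
        tokens = "\t".join(f"g{i}|{20 - i}" for i in range(20))
        gmt.write_text(f"TOP\tdesc\t{tokens}\nGHOST\tdesc\tzz|1\tzy|2\n")
        return rnk, gmt, tmp_path / "out.tsv"

    def test_end_to_end(self, files):
        rnk, gmt, out = files
        code = cli_main(["-s", str(gmt), "-i", str(rnk), "-o", str(out)])
        assert code == 0
        from tauset.io import read_results
        df = read_results(out)
        assert list(df["set_id"]) == ["TOP"]
        assert df.loc[0, "tau"] == pytest.approx(1.0)
        assert df.loc[0, "weight_mode"] == 3

    def test_auto_sweep_flag(self, files):
        rnk, gmt, out = files
        assert cli_main(["-s", str(gmt), "-i", str(rnk), "-o", str(out),
                         "-p", "-w", "1"]) == 0

    def test_invalid_weight_mode_usage_error(self, files):
        rnk, gmt, out = files
        assert cli_main(["-s", str(gmt), "-i", str(rnk), "-o", str(out),
                         "-w", "4"]) == 2

    def test_missing_required_flag(self):
        assert cli_main(["-i", "x.rnk"]) == 2

    def test_unreadable_input_runtime_error(self, tmp_path):
        assert cli_main(["-s", str(tmp_path / "no.gmt"),
                         "-i", str(tmp_path / "no.rnk"),
                         "-o", str(tmp_path / "o.tsv")]) == 1

    def test_simulate_subcommand(self, tmp_path):
        prefix = str(tmp_path / "sim")
        code = cli_main(["simulate", "--out", prefix, "--q-grid", "0.2,0.4",
                         "--r-grid", "0.0,0.6", "--reps", "3",
                         "--n-perm", "0", "--m", "40", "--seed", "5"])
        assert code == 0
        import pandas as pd
        pairs = pd.read_csv(f"{prefix}_pairs.tsv", sep="\t")
        assert len(pairs) == 2 * 2 * 3
        rates = pd.read_csv(f"{prefix}_positive_rate.tsv", sep="\t")
        assert len(rates) == 2
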