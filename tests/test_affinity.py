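"""Affinity fits, AMI, success rates, prediction and filtering."""

import math
from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

from lc8screen import synth
from lc8screen.affinity import (
    TQT_MODEL,
    AffinityRecord,
    BinningStrategy,
    CandidateSite,
    adjust_pvalues,
    ami,
    ami_grid,
    filter_predictions,
    linear_fit,
    match_affinities,
    metric_table,
    predict_affinity,
    pseudo_kd,
    select_subset,
    success_rate,
)
from lc8screen.classify import EXCLUSIVE, ThresholdSet, classify
from lc8screen.colabfold import parse_run_dir
from lc8screen.interface import PARAM_NAMES, SCORE_FIELDS, score_run


class TestLinearFit:
    def test_exact_line(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = linear_fit(x, 2 * x + 1)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)
        assert res.r2 == pytest.approx(1.0)
        assert res.rmse == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations(self):
        """4-point fit equals the explicit normal-equation solution."""
        x = np.array([0.5, 1.5, 3.0, 4.0])
        y = np.array([2.0, 1.0, 5.0, 3.5])
        n = len(x)
        sx, sy, sxx, sxy = x.sum(), y.sum(), (x * x).sum(), (x * y).sum()
        slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
        intercept = (sy - slope * sx) / n
        res = linear_fit(x, y)
        assert res.slope == pytest.approx(slope)
        assert res.intercept == pytest.approx(intercept)

    def test_independent_noise_gives_near_zero_r2(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=3000)
        y = rng.normal(size=3000)
        assert linear_fit(x, y).r2 == pytest.approx(0.0, abs=0.01)

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            linear_fit([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            linear_fit([1.0, 2.0], [1.0, 2.0])

    def test_recovers_generated_relation(self):
        scores, kd = synth.gen_affinity_relation(2.5, 4.0, 0.5, n=200, seed=7)
        res = linear_fit(scores, kd)
        se_slope = res.rmse / (np.std(scores) * np.sqrt(len(scores)))
        assert abs(res.slope - 2.5) < 2 * se_slope + 1e-9
        assert res.rmse == pytest.approx(0.5, rel=0.3)


class TestAdjustPvalues:
    def test_bonferroni_doubles_two_pvalues(self):
        assert adjust_pvalues([0.01, 0.04], "bonferroni").tolist() == \
            pytest.approx([0.02, 0.08])

    @pytest.mark.parametrize("method", ["bonferroni", "benjamini_hochberg"])
    def test_single_p_unchanged(self, method):
        assert adjust_pvalues([0.03], method)[0] == pytest.approx(0.03)

    def test_bh_step_up_hand_computed(self):
        # raw p * m / rank = [.04, .04, .04, .04]; step-up keeps all at .04
        got = adjust_pvalues([0.01, 0.02, 0.03, 0.04], "benjamini_hochberg")
        assert got.tolist() == pytest.approx([0.04] * 4)

    def test_adjusted_at_least_raw(self):
        ps = [0.001, 0.2, 0.9, 0.04]
        for method in ("bonferroni", "benjamini_hochberg"):
            adj = adjust_pvalues(ps, method)
            assert (adj >= np.asarray(ps) - 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5, 1.5], "bonferroni")


# ---------------------------------------------------------------------------
# AMI oracle: direct formula with exhaustive hypergeometric expected MI


def oracle_ami(x_labels, y_labels):
    N = len(x_labels)
    xs, ys = sorted(set(x_labels)), sorted(set(y_labels))
    a = [x_labels.count(v) for v in xs]
    b = [y_labels.count(v) for v in ys]
    mi = 0.0
    for i, xv in enumerate(xs):
        for j, yv in enumerate(ys):
            nij = sum(1 for xx, yy in zip(x_labels, y_labels) if xx == xv and yy == yv)
            if nij:
                mi += nij / N * math.log(N * nij / (a[i] * b[j]))
    hx = -sum(ai / N * math.log(ai / N) for ai in a)
    hy = -sum(bj / N * math.log(bj / N) for bj in b)
    emi = 0.0
    for ai in a:
        for bj in b:
            for nij in range(max(1, ai + bj - N), min(ai, bj) + 1):
                lg = (math.lgamma(ai + 1) + math.lgamma(bj + 1)
                      + math.lgamma(N - ai + 1) + math.lgamma(N - bj + 1)
                      - math.lgamma(N + 1) - math.lgamma(nij + 1)
                      - math.lgamma(ai - nij + 1) - math.lgamma(bj - nij + 1)
                      - math.lgamma(N - ai - bj + nij + 1))
                emi += nij / N * math.log(N * nij / (ai * bj)) * math.exp(lg)
    return (mi - emi) / (max(hx, hy) - emi)


class TestAmi:
    def test_identical_partition_scores_one(self):
        kd = [0.5, 0.5, 5.0, 5.0, 50.0, 50.0]
        scores = [1.0, 1.0, 5.0, 5.0, 9.0, 9.0]
        strat = BinningStrategy(affinity_edges=(0, 1, 10, 100),
                                score_binning="linear", k_bins=3)
        assert ami(scores, kd, strat) == pytest.approx(1.0)

    def test_matches_exhaustive_formula_on_six_points(self):
        """The tiny-contingency case equals the direct AMI formula."""
        kd = [0.5, 0.5, 5.0, 5.0, 50.0, 50.0]     # bins 0,0,1,1,2,2
        scores = [1.0, 5.0, 5.0, 1.0, 9.0, 9.0]   # bins 0,1,1,0,2,2
        strat = BinningStrategy(affinity_edges=(0, 1, 10, 100),
                                score_binning="linear", k_bins=3)
        want = oracle_ami([0, 1, 1, 0, 2, 2], [0, 0, 1, 1, 2, 2])
        assert ami(scores, kd, strat) == pytest.approx(want, abs=1e-10)

    def test_independent_variables_near_zero(self):
        rng = np.random.default_rng(2)
        scores = rng.uniform(0, 10, size=10_000)
        kd = rng.uniform(0.1, 99, size=10_000)
        assert ami(scores, kd) == pytest.approx(0.0, abs=0.02)

    def test_single_bin_collapse_returns_zero_with_warning(self):
        kd = [2.0, 3.0, 2.5, 2.2]  # all in one affinity bin of [0,1,10,100]
        scores = [1.0, 2.0, 3.0, 4.0]
        strat = BinningStrategy(affinity_edges=(0, 1, 10, 100),
                                score_binning="linear", k_bins=2)
        with pytest.warns(UserWarning, match="single bin"):
            assert ami(scores, kd, strat) == 0.0

    def test_grid_evaluates_nine_strategies(self):
        rng = np.random.default_rng(3)
        scores = rng.uniform(1, 9, size=40)
        kd = np.clip(scores * 5 + rng.normal(0, 2, 40), 0.1, 99)
        grid = ami_grid(scores, kd)
        assert len(grid) == 9
        assert grid["ami"].max() <= 1.0 + 1e-12

    def test_bin_label_permutation_invariant(self):
        kd = [0.5, 5.0, 50.0, 0.5, 5.0, 50.0]
        scores = [9.0, 5.0, 1.0, 9.0, 5.0, 1.0]  # reversed ordering, same partition
        strat = BinningStrategy(affinity_edges=(0, 1, 10, 100),
                                score_binning="linear", k_bins=3)
        assert ami(scores, kd, strat) == pytest.approx(1.0)


class TestAffinityPrediction:
    def test_tqt_inversion(self):
        assert predict_affinity({"dimer_1c_best": 1.03}, "TQT") == pytest.approx(40.0)

    def test_tqt_negative_raw_clamps_to_one(self):
        assert predict_affinity({"dimer_1c_best": 0.50}, "TQT") == 1.0

    def test_not_tqt_inversion(self):
        assert predict_affinity({"ptol_1c_avg": 5.80}, "notTQT") == pytest.approx(10.0)

    def test_missing_predictor_rejected(self):
        with pytest.raises(ValueError, match="missing predictor"):
            predict_affinity({"ptol_1c_avg": 5.0}, "TQT")

    def test_predictions_never_below_one_micromolar(self):
        for pae in np.linspace(0.0, 2.0, 21):
            assert predict_affinity({"dimer_1c_best": pae}, "TQT") >= 1.0

    def test_model_fit_roundtrip(self):
        """A model fit on noiseless data reproduces the generating Kd values."""
        scores, kd = synth.gen_affinity_relation(8.0, 5.0, 0.0, n=50, seed=1)
        model = TQT_MODEL.__class__("TQT", "dimer_1c_best").fit(scores, kd)
        np.testing.assert_allclose(model.predict(scores), kd, rtol=1e-9)


class TestPseudoKd:
    def test_half_bound(self):
        assert pseudo_kd(25, 50) == pytest.approx(25.0)

    def test_none_bound_is_undefined(self):
        assert pseudo_kd(0, 50) is None

    def test_all_bound_is_zero(self):
        assert pseudo_kd(50, 50) == 0.0

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            pseudo_kd(1, 0)


def _passing_means():
    return {"conf": 0.90, "plddt": 96.0, "ltop": 4.0, "ptol": 8.0, "dimer": 0.90}


class TestSuccessRate:
    def _runs(self, tmp_path, means, sds=None, n=4, seed=70):
        runs = []
        for cc in (1, 2):
            cfg = synth.FixtureConfig(
                n_structures=n, client_count=cc, seed=seed,
                score_means=dict(means),
                score_sds=sds or {k: 0.0 for k in means},
            )
            runs.append(parse_run_dir(synth.gen_run_dir(cfg, tmp_path / f"{cc}c")))
        return runs

    def test_all_structures_pass(self, tmp_path):
        one, two = self._runs(tmp_path, _passing_means())
        assert success_rate(one, two, EXCLUSIVE) == 1.0

    def test_no_structures_pass(self, tmp_path):
        one, two = self._runs(tmp_path, {"conf": 0.5, "plddt": 60.0, "ltop": 15.0,
                                         "ptol": 18.0, "dimer": 1.3})
        assert success_rate(one, two, EXCLUSIVE) == 0.0

    def test_partial_rate_matches_per_structure_classification(self, tmp_path):
        sds = {"conf": 0.05, "plddt": 1.0, "ltop": 0.5, "ptol": 0.5, "dimer": 0.02}
        one, two = self._runs(tmp_path, _passing_means(), sds=sds, n=6, seed=71)
        got = success_rate(one, two, EXCLUSIVE)
        s1, s2 = score_run(one), score_run(two)
        attr = {"conf": "confidence", "plddt": "avg_plddt_bind",
                "ltop": "pae_ltop", "ptol": "pae_ptol", "dimer": "pae_dimer"}
        want = np.mean([
            classify({**{f"{f}_1c": getattr(a, attr[f]) for f in SCORE_FIELDS},
                      **{f"{f}_2c": getattr(b, attr[f]) for f in SCORE_FIELDS}},
                     EXCLUSIVE) == "binder"
            for a, b in zip(s1, s2)
        ])
        assert got == pytest.approx(want)

    def test_monotone_under_tightening(self, tmp_path):
        sds = {"conf": 0.08, "plddt": 3.0, "ltop": 1.5, "ptol": 1.5, "dimer": 0.05}
        one, two = self._runs(tmp_path, _passing_means(), sds=sds, n=8, seed=72)
        base = success_rate(one, two, EXCLUSIVE)
        tighter = dict(EXCLUSIVE.cuts)
        tighter["ltop_1c"] = tighter["ltop_1c"] - 2.0
        assert success_rate(one, two, ThresholdSet(tighter)) <= base


class TestMetricTable:
    def test_no_noise_best_equals_average(self, bound_run_dir, tmp_path):
        path, cfg = bound_run_dir
        one = parse_run_dir(path)
        cfg2 = synth.FixtureConfig(n_structures=3, client_count=2, seed=11)
        two = parse_run_dir(synth.gen_run_dir(cfg2, tmp_path / "2c"))
        row = metric_table(one, two, threshold=EXCLUSIVE)
        for f in SCORE_FIELDS:
            for sfx in ("1c", "2c"):
                assert row[f"{f}_{sfx}_best"] == pytest.approx(row[f"{f}_{sfx}_avg"])
        assert not row["incomplete"]
        assert "success_rate" in row and 0.0 <= row["success_rate"] <= 1.0

    def test_averages_match_score_run(self, tmp_path):
        sds = {"conf": 0.05, "plddt": 4.0, "ltop": 1.0, "ptol": 1.0, "dimer": 0.05}
        cfg = synth.FixtureConfig(n_structures=5, client_count=1, seed=73,
                                  score_sds=sds)
        run = parse_run_dir(synth.gen_run_dir(cfg, tmp_path / "r"))
        row = metric_table(run, None)
        scores = score_run(run)
        assert row["incomplete"]
        assert row["ltop_1c_avg"] == pytest.approx(
            np.mean([s.pae_ltop for s in scores])
        )
        best = max(scores, key=lambda s: s.avg_plddt_bind)
        assert row["plddt_1c_best"] == pytest.approx(best.avg_plddt_bind)


class TestMatchAffinities:
    def _run(self, sequence, run_id="r1", length=None):
        window = SimpleNamespace(protein_id="p", start=0, end=len(sequence),
                                 sequence=sequence, length=len(sequence),
                                 is_mutant=False)
        return SimpleNamespace(run_id=run_id, window=window, client_count=1)

    def test_substring_match_joins(self):
        rec = AffinityRecord("SRGTQTEM", "TQT", 1.2)
        joined = match_affinities([self._run("AAASRGTQTEMAAA")], [rec])
        assert len(joined) == 1
        assert joined.iloc[0]["kd"] == 1.2

    def test_no_match_excluded(self):
        rec = AffinityRecord("SRGTQTEM", "TQT", 1.2)
        assert match_affinities([self._run("A" * 16)], [rec]).empty

    def test_one_record_matches_two_windows(self):
        rec = AffinityRecord("SRGTQTEM", "TQT", 1.2)
        runs = [self._run("AAASRGTQTEMAAA", "r1"), self._run("SRGTQTEMCCCCC", "r2")]
        joined = match_affinities(runs, [rec])
        assert sorted(joined["run_id"]) == ["r1", "r2"]


class TestSubsetSelection:
    def _table(self):
        return pd.DataFrame({
            "anchor_class": ["TQT", "TQT", "notTQT", "notTQT", "TQT"],
            "length": [14, 16, 16, 12, 12],
        })

    @pytest.mark.parametrize("expr, expected_rows", [
        ("TQT", [0, 1, 4]),
        ("!TQT", [2, 3]),
        ("TQT&len=14", [0]),
        ("len<18", [0, 1, 2, 3, 4]),
        ("TQT&len=12||TQT&len=14", [0, 4]),
        ("TQT&!len=12", [0, 1]),
    ])
    def test_expressions(self, expr, expected_rows):
        got = select_subset(self._table(), expr)
        assert got.index.tolist() == expected_rows

    def test_bad_atom_rejected(self):
        with pytest.raises(ValueError, match="cannot parse"):
            select_subset(self._table(), "bogus=3")


class TestFilterPredictions:
    def _sites(self):
        return [
            CandidateSite("p", 10, "TQT", 50.0),   # too weak
            CandidateSite("p", 30, "TQT", 15.0),   # inside structured domain
            CandidateSite("p", 60, "TQT", 15.0),   # retained
            CandidateSite("q", 30, "notTQT", 2.0), # other protein, retained
        ]

    def _structured(self):
        return pd.DataFrame({"protein_id": ["p"], "start": [25], "end": [40]})

    def test_affinity_and_domain_filters(self):
        kept = filter_predictions(self._sites(), self._structured())
        assert [(s.protein_id, s.anchor_position) for s in kept] == \
            [("p", 60), ("q", 30)]

    def test_output_subset_of_input(self):
        sites = self._sites()
        kept = filter_predictions(sites, self._structured())
        assert all(s in sites for s in kept)

    def test_boundary_forty_micromolar_retained(self):
        kept = filter_predictions([CandidateSite("p", 0, "TQT", 40.0)], None)
        assert len(kept) == 1  # the rule drops strictly greater than 40

    def test_malformed_interval_rejected(self):
        bad = pd.DataFrame({"protein_id": ["p"], "start": [40], "end": [25]})
        with pytest.raises(ValueError, match="malformed interval"):
            filter_predictions(self._sites(), bad)
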