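"""X:A ratios, fold changes, MSL stratification, and regime verdicts."""
import numpy as np
import pandas as pd
import pytest

import germdose as gd
from germdose.dosage import XATable


def _annotation(chroms):
    ann = pd.DataFrame({"chromosome": chroms},
                       index=[f"g{i}" for i in range(len(chroms))])
    ann["cds_length"] = 300
    return ann


def _xatable_from_medians(medians_by_chrom, stages, ci_halfwidth=0.01):
    rows = []
    for chrom, meds in medians_by_chrom.items():
        for stage, m in zip(stages, meds):
            rows.append((chrom, stage, m, m - ci_halfwidth, m + ci_halfwidth, 100))
    medians = pd.DataFrame(
        rows, columns=["chromosome", "stage", "median", "ci_lo", "ci_hi", "n_genes"]
    ).set_index(["chromosome", "stage"])
    gene_ratios = pd.DataFrame(columns=stages)
    return XATable(gene_ratios=gene_ratios, chromosome=pd.Series(dtype=object),
                   medians=medians, reference=("MullerB", "MullerE"),
                   ci_level=0.95, n_boot=100, seed=0)


class TestXaRatios:
    def test_direct_evaluation(self):
        # reference median 20 at both stages, X gene count 10 -> r = 0.5
        ann = _annotation(["MullerB", "MullerB", "MullerB", "MullerA"])
        pb = pd.DataFrame({"GSC": [10, 20, 40, 10], "SG": [20, 20, 20, 10]},
                          index=ann.index)
        xa = gd.xa_ratios(pb, ann, n_boot=50)
        assert xa.gene_ratios.loc["g3", "GSC"] == pytest.approx(0.5)
        assert xa.median("MullerA", "GSC") == pytest.approx(0.5)
        assert xa.median("MullerA", "SG") == pytest.approx(0.5)

    def test_exchangeable_genes_ratio_near_one(self):
        rng = np.random.default_rng(0)
        vals = rng.lognormal(2, 1, size=600)
        ann = _annotation(["MullerB"] * 300 + ["MullerA"] * 300)
        pb = pd.DataFrame({"GSC": vals}, index=ann.index)
        xa = gd.xa_ratios(pb, ann, n_boot=50)
        assert xa.median("MullerA", "GSC") == pytest.approx(1.0, abs=0.2)

    def test_scale_invariance_within_stage(self):
        ann = _annotation(["MullerB", "MullerE", "MullerA"])
        pb = pd.DataFrame({"GSC": [10, 20, 5], "SG": [1, 2, 3]}, index=ann.index)
        scaled = pb.copy()
        scaled["GSC"] *= 17
        a = gd.xa_ratios(pb, ann, n_boot=20)
        b = gd.xa_ratios(scaled, ann, n_boot=20)
        pd.testing.assert_frame_equal(a.gene_ratios, b.gene_ratios)

    def test_zero_reference_median_names_stage(self):
        ann = _annotation(["MullerB", "MullerA"])
        pb = pd.DataFrame({"GSC": [0, 5]}, index=ann.index)
        with pytest.raises(ValueError, match="GSC"):
            gd.xa_ratios(pb, ann)

    def test_bootstrap_reproducible_given_seed(self):
        rng = np.random.default_rng(1)
        ann = _annotation(["MullerB"] * 50 + ["MullerA"] * 50)
        pb = pd.DataFrame({"GSC": rng.poisson(30, 100)}, index=ann.index)
        a = gd.xa_ratios(pb, ann, n_boot=200, seed=42)
        b = gd.xa_ratios(pb, ann, n_boot=200, seed=42)
        pd.testing.assert_frame_equal(a.medians, b.medians)

    def test_simulated_uncompensated_x_recovers_half(self):
        cfg = gd.SimConfig(
            seed=5,
            n_genes_per_chrom={"MullerA": 600, "MullerB": 800, "MullerE": 800},
            n_cells_per_type={s: 60 for s in gd.DEFAULT_STAGES},
            dc_boost_max={"MullerA": 1.0},
            baseline_logsd=0.5,
        )
        ann, _ = gd.make_annotation(cfg)
        adata, truth = gd.simulate_sc_counts(cfg, ann, "NONE")
        pb = gd.aggregate_pseudobulk(adata)
        xa = gd.xa_ratios(pb, ann, n_boot=100)
        for stage in cfg.stages:
            assert xa.median("MullerA", stage) == pytest.approx(
                gd.ground_truth_xa(truth, "MullerA", stage), abs=0.05)
            assert xa.median("MullerA", stage) == pytest.approx(0.5, abs=0.05)


class TestStageFoldChange:
    def test_doubling_is_one_log2(self):
        ann = _annotation(["MullerB"])
        pb = pd.DataFrame({"SC_early": [10], "SC_late1": [20]}, index=ann.index)
        fc, _ = gd.stage_fold_change(pb, ann, [("SC_early", "SC_late1")], eps=0.0)
        assert fc.iloc[0, 0] == pytest.approx(1.0)

    def test_identical_stages_give_zero(self):
        ann = _annotation(["MullerB", "MullerA"])
        pb = pd.DataFrame({"GSC": [3, 9], "SG": [3, 9]}, index=ann.index)
        fc, _ = gd.stage_fold_change(pb, ann, [("GSC", "SG")])
        assert np.allclose(fc.to_numpy(), 0.0)

    def test_unknown_stage_rejected(self):
        ann = _annotation(["MullerB"])
        pb = pd.DataFrame({"GSC": [3]}, index=ann.index)
        with pytest.raises(ValueError, match="unknown stage"):
            gd.stage_fold_change(pb, ann, [("GSC", "ST_late")])

    def test_neoy_late_amplification_detected(self):
        rng = np.random.default_rng(2)
        n = 250
        ann = _annotation(["neoY"] * n + ["MullerB"] * n + ["MullerE"] * n)
        early = rng.poisson(50, 3 * n).astype(float)
        late = early * np.where(np.arange(3 * n) < n, 4.0, 2.0)
        pb = pd.DataFrame(
            {"SC_early": early, "SC_late1": rng.poisson(late)}, index=ann.index)
        fc, tests = gd.stage_fold_change(pb, ann, [("SC_early", "SC_late1")])
        row = tests[(tests.chromosome == "neoY")].iloc[0]
        other = tests[tests.chromosome == "MullerB"].iloc[0]
        assert row.p < 0.01
        assert row.median_log2fc > other.median_log2fc
        assert row.median_log2fc == pytest.approx(2.0, abs=0.2)


class TestMslStratified:
    def _sim(self, profile_final):
        cfg = gd.SimConfig(
            seed=8,
            n_genes_per_chrom={"MullerA": 500, "MullerB": 600, "MullerE": 600},
            n_cells_per_type={s: 50 for s in gd.DEFAULT_STAGES},
            dc_boost_max={"MullerA": 2.0},
            dc_distance_scale=1000.0,
            baseline_logsd=0.5,
            dc_stage_profile=(1, 1, 1, 1, 1, 1, 1, profile_final),
        )
        ann, peaks = gd.make_annotation(cfg)
        adata, _ = gd.simulate_sc_counts(cfg, ann, "NONE")
        pb = gd.aggregate_pseudobulk(adata)
        xa = gd.xa_ratios(pb, ann, n_boot=50)
        msl = gd.annotate_msl(ann, peaks)
        return xa, msl

    def test_distance_decay_orders_categories_premeiotically(self):
        xa, msl = self._sim(profile_final=1)
        med, _ = gd.msl_stratified_trajectory(xa, msl, scheme="five",
                                              chromosomes=("MullerA",))
        assert (med.loc[("MullerA", "overlap", "GSC"), "median"]
                > med.loc[("MullerA", "gt20kb", "GSC"), "median"])

    def test_shutdown_closes_proximal_distal_gap(self):
        xa, msl = self._sim(profile_final=0)
        med, tests = gd.msl_stratified_trajectory(xa, msl, scheme="binary",
                                                  chromosomes=("MullerA",))
        gap_initial = abs(med.loc[("MullerA", "proximal", "GSC"), "median"]
                          - med.loc[("MullerA", "distal", "GSC"), "median"])
        gap_final = abs(med.loc[("MullerA", "proximal", "ST_early"), "median"]
                        - med.loc[("MullerA", "distal", "ST_early"), "median"])
        assert gap_final < 0.1
        assert gap_final < gap_initial

    def test_single_category_leaves_tests_undefined(self):
        ann = _annotation(["MullerA"] * 4 + ["MullerB"] * 4)
        pb = pd.DataFrame({"GSC": np.arange(8) + 1.0}, index=ann.index)
        xa = gd.xa_ratios(pb, ann, n_boot=20)
        msl = pd.DataFrame({
            "distance_bp": [0.0] * 4 + [np.nan] * 4,
            "category5": ["overlap"] * 4 + [None] * 4,
            "category2": ["proximal"] * 4 + [None] * 4,
            "no_peak_on_chrom": [False] * 4 + [True] * 4,
        }, index=ann.index)
        med, tests = gd.msl_stratified_trajectory(xa, msl,
                                                  chromosomes=("MullerA",))
        assert set(med.index.get_level_values(1)) == {"proximal"}
        assert tests.p.isna().all()


class TestDcGeneSummary:
    def test_matches_brute_force_tally(self, small_sc):
        adata, _ = small_sc
        gene_ids = list(adata.var_names[:3])
        summary = gd.dc_gene_summary(adata, gene_ids)
        X = np.asarray(adata.X)
        for gid in gene_ids:
            j = list(adata.var_names).index(gid)
            for stage in gd.DEFAULT_STAGES:
                mask = (adata.obs.cell_type == stage).to_numpy()
                vals = X[mask, j]
                row = summary.loc[(gid, stage)]
                assert row.fraction_expressing == pytest.approx((vals > 0).mean())
                assert row.mean_log1p == pytest.approx(np.log1p(vals).mean())

    def test_silent_gene_is_zero(self):
        import anndata
        X = np.array([[0, 1], [0, 1], [0, 1]], dtype=np.int32)
        obs = pd.DataFrame({"cell_type": pd.Categorical(
            ["GSC"] * 3, categories=list(gd.DEFAULT_STAGES))},
            index=["c0", "c1", "c2"])
        adata = anndata.AnnData(X=X, obs=obs,
                                var=pd.DataFrame(index=["silent", "on"]))
        s = gd.dc_gene_summary(adata, ["silent", "on"])
        assert s.loc[("silent", "GSC"), "fraction_expressing"] == 0
        assert s.loc[("silent", "GSC"), "mean_log1p"] == 0
        assert s.loc[("on", "GSC"), "fraction_expressing"] == 1
        assert s.loc[("on", "GSC"), "mean_log1p"] == pytest.approx(np.log1p(1))

    def test_missing_gene_warns_with_nan(self, small_sc):
        adata, _ = small_sc
        with pytest.warns(UserWarning, match="not in matrix"):
            s = gd.dc_gene_summary(adata, ["roX1"])
        assert s.fraction_expressing.isna().all()


class TestRegimeClassify:
    STAGES = ["GSC", "SG", "SC_late1", "ST_early"]

    def _call(self, medians, **kw):
        xa = _xatable_from_medians(medians, self.STAGES)
        return gd.regime_classify(xa, germline_stages=self.STAGES, **kw)

    def test_convergent_age_ordered_decline_is_shutdown(self):
        call = self._call({
            "MullerA": [1.0, 0.9, 0.7, 0.5],
            "MullerAD": [0.85, 0.8, 0.65, 0.5],
            "MullerC": [0.7, 0.7, 0.6, 0.5],
        })
        assert call.verdict == "DC_SHUTDOWN"
        assert not any(call.below_half_flags.values())
        assert call.age_order_initial
        assert call.convergence_index < 0.5

    def test_below_half_with_age_inverted_decline_is_msci(self):
        call = self._call({
            "MullerA": [1.0, 0.9, 0.3, 0.2],
            "MullerAD": [0.9, 0.8, 0.35, 0.3],
            "MullerC": [0.7, 0.7, 0.55, 0.5],
        })
        assert call.verdict == "MSCI"
        assert call.below_half_flags["MullerA"]
        assert call.below_half_flags["MullerAD"]

    def test_flat_trajectories_are_ambiguous(self):
        call = self._call({
            "MullerA": [1.0, 1.0, 1.0, 1.0],
            "MullerAD": [1.0, 1.0, 1.0, 1.0],
            "MullerC": [1.0, 1.0, 1.0, 1.0],
        })
        assert call.verdict == "AMBIGUOUS"

    def test_verdict_reproducible_from_recorded_statistics(self):
        call = self._call({
            "MullerA": [1.0, 0.9, 0.7, 0.5],
            "MullerAD": [0.85, 0.8, 0.65, 0.5],
            "MullerC": [0.7, 0.7, 0.6, 0.5],
        })
        d = call.to_dict()
        assert d["thresholds"]["delta"] == 0.1
        assert d["verdict"] == "DC_SHUTDOWN"
        # JSON round-trips
        import json
        assert json.loads(call.to_json())["verdict"] == "DC_SHUTDOWN"

    def test_missing_ci_rejected(self):
        xa = _xatable_from_medians(
            {"MullerA": [1, 1, 1, 1], "MullerAD": [1, 1, 1, 1],
             "MullerC": [1, 1, 1, 1]}, self.STAGES)
        xa.medians.loc[("MullerA", "ST_early"), "ci_hi"] = np.nan
        with pytest.raises(ValueError, match="missing bootstrap CI"):
            gd.regime_classify(xa, germline_stages=self.STAGES)


class TestModelFacade:
    def test_fit_summary_and_report(self, small_sc):
        adata, _ = small_sc
        res = gd.XADosage.from_counts(adata).fit(n_boot=100, seed=0)
        text = res.summary()
        assert "regime verdict" in text
        assert "MullerA" in text
        assert res.regime.verdict in ("DC_SHUTDOWN", "MSCI", "AMBIGUOUS")

    def test_plot_returns_axis(self, small_sc):
        import matplotlib
        matplotlib.use("Agg")
        adata, _ = small_sc
        res = gd.XADosage.from_counts(adata).fit(n_boot=50, seed=0)
        ax = res.plot_trajectories()
        assert ax.get_ylabel().startswith("X:A")
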