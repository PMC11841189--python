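import numpy as np
import pandas as pd
import pytest

from cadep.classifier import classify_gene
from cadep.de_stats import UC, call_deg
from cadep.io_formats import CONTRAST_H2O2, CONTRASTS
from cadep.network_paths import extract_paths, select_by_terms
from cadep.qpcr import concordance, delta_delta_ct
from cadep.synthetic import (
    CLASS_EFFECTS,
    EXPECTED_DEP_CLASS,
    LACL3_ARTIFACT,
    NULL,
    SimParams,
    simulate_counts,
    simulate_ct_table,
    simulate_de_tables,
    simulate_network,
)


class TestSimParams:
    def test_bad_dispersion_rejected(self):
        with pytest.raises(ValueError):
            SimParams(nb_dispersion=0.0)

    def test_bad_lfc_se_rejected(self):
        with pytest.raises(ValueError):
            SimParams(lfc_se=-1.0)

    def test_proportions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SimParams(class_proportions={NULL: 0.5})


class TestPlantedEffectsAreClassConsistent:
    @pytest.mark.parametrize("true_class", sorted(CLASS_EFFECTS))
    def test_noiseless_effects_satisfy_class_definition(self, true_class):
        """The canonical planted log2FCs must reproduce the intended
        dependency class under the default gates at zero noise."""
        lh, lc, ll = CLASS_EFFECTS[true_class]
        sh = call_deg(lh, 0.0 if lh else 1.0)
        sc = call_deg(lc, 0.0 if lc else 1.0)
        sl = call_deg(ll, 0.0 if ll else 1.0)
        expected = EXPECTED_DEP_CLASS[true_class]
        if true_class == NULL:
            assert sh == UC
        elif true_class == LACL3_ARTIFACT:
            assert sc != UC and sc == sl  # removed by the unique-DEG filter
        else:
            assert sh != UC
            assert classify_gene(sh, lh, sc, lc) == expected


class TestSimulateCounts:
    def test_null_only_truth_has_zero_effects(self):
        params = SimParams(n_genes=50, class_proportions={NULL: 1.0}, seed=1)
        _, truth = simulate_counts(params)
        assert (truth[["lfc_h2o2", "lfc_combined", "lfc_lacl3"]] == 0).all().all()

    def test_seeded_determinism(self):
        params = SimParams(n_genes=100, seed=42)
        c1, t1 = simulate_counts(params)
        c2, t2 = simulate_counts(params)
        pd.testing.assert_frame_equal(c1, c2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_nb_moments_in_control(self):
        params = SimParams(n_genes=2000, nb_dispersion=0.05, n_reps=3, seed=8)
        counts, truth = simulate_counts(params)
        rng = np.random.default_rng([params.seed, 1])
        mu = np.exp(rng.normal(params.baseline_log_mean, params.baseline_log_sd,
                               size=params.n_genes))
        ctrl = counts[[f"ctrl_{r}" for r in (1, 2, 3)]].to_numpy()
        se = np.sqrt((mu + params.nb_dispersion * mu**2) / params.n_reps)
        within = np.abs(ctrl.mean(axis=1) - mu) <= 3 * se
        assert within.mean() >= 0.99


class TestSimulateDETables:
    def test_three_contrasts_bh_within_contrast(self):
        tables, _ = simulate_de_tables(SimParams(n_genes=300, seed=2))
        assert set(tables) == set(CONTRASTS)
        for df in tables.values():
            assert (df["fdr"] >= df["pvalue"] - 1e-12).all()

    def test_seeded_determinism(self):
        params = SimParams(n_genes=200, seed=13)
        t1, _ = simulate_de_tables(params)
        t2, _ = simulate_de_tables(params)
        for c in CONTRASTS:
            pd.testing.assert_frame_equal(t1[c], t2[c])

    def test_null_simulation_controls_fdr(self):
        """BH at 0.01 on a full-null contrast rejects at most ~1% of genes."""
        params = SimParams(n_genes=20000, class_proportions={NULL: 1.0}, seed=17)
        tables, _ = simulate_de_tables(params)
        frac = float((tables[CONTRAST_H2O2]["fdr"] < 0.01).mean())
        se = np.sqrt(0.01 * 0.99 / params.n_genes)
        assert frac <= 0.01 + 3 * se


class TestSimulateNetwork:
    def test_planted_paths_recovered_without_decoys(self):
        net, ann, truth = simulate_network(40, 4, decoy_density=0.0, seed=21)
        sources = select_by_terms(net, ann, ["30.3", "34.21", "34.22"])
        assert sources == set(truth.sources)
        paths = extract_paths(net, sources, truth.targets, max_len=3)
        got = {p.nodes for ps in paths.values() for p in ps}
        assert got == {p.nodes for p in truth.paths}

    def test_rank3_parallel_route_filtered(self):
        """A rank-3 alternate TF edge into a target must not survive
        extraction at max_rank=2."""
        net, ann, truth = simulate_network(60, 3, decoy_density=1.0, seed=33)
        sources = set(truth.sources)
        paths = extract_paths(net, sources, truth.targets, max_len=3, max_rank=2)
        for ps in paths.values():
            for p in ps:
                assert all(e.rank <= 2 for e in p.edges)

    def test_capacity_error(self):
        with pytest.raises(ValueError):
            simulate_network(6, 10, seed=1)

    def test_determinism(self):
        n1, a1, t1 = simulate_network(30, 3, decoy_density=0.5, seed=9)
        n2, a2, t2 = simulate_network(30, 3, decoy_density=0.5, seed=9)
        assert n1.edges == n2.edges
        pd.testing.assert_frame_equal(a1, a2)
        assert [p.nodes for p in t1.paths] == [p.nodes for p in t2.paths]


class TestSimulateCtTable:
    def _truth(self, seed=4):
        params = SimParams(n_genes=200, seed=seed)
        _, truth = simulate_de_tables(params)
        return truth

    def test_noiseless_ratio_matches_planted_fold_change(self):
        truth = self._truth()
        ct, refs = simulate_ct_table(truth, 10, ct_noise_sd=0.0, seed=6)
        genes = [g for g in ct["gene_id"].unique() if g not in refs]
        lookup = truth.set_index("gene_id")
        for g in genes:
            rel = delta_delta_ct(ct, g, "h2o2", "ctrl", tuple(refs))
            assert rel.ratio == pytest.approx(
                2.0 ** lookup.loc[g, "lfc_h2o2"], rel=1e-9
            )

    def test_noiseless_concordance_is_perfect(self):
        truth = self._truth()
        ct, refs = simulate_ct_table(truth, 12, ct_noise_sd=0.0, seed=6)
        genes = [g for g in ct["gene_id"].unique() if g not in refs]
        lookup = truth.set_index("gene_id")
        q = [np.log2(delta_delta_ct(ct, g, "h2o2", "ctrl", tuple(refs)).ratio)
             for g in genes]
        r = [lookup.loc[g, "lfc_h2o2"] for g in genes]
        assert concordance(q, r)["pearson_r"] == pytest.approx(1.0, abs=1e-9)

    def test_noisy_regression_slope_is_calibrated(self):
        """Across seeds, the qPCR-vs-planted slope stays near 1."""
        truth = self._truth()
        lookup = truth.set_index("gene_id")
        ok = 0
        for seed in range(50):
            ct, refs = simulate_ct_table(truth, 10, ct_noise_sd=0.3, seed=seed)
            genes = [g for g in ct["gene_id"].unique() if g not in refs]
            q = [np.log2(delta_delta_ct(ct, g, "h2o2", "ctrl", tuple(refs)).ratio)
                 for g in genes]
            r = [lookup.loc[g, "lfc_h2o2"] for g in genes]
            slope = concordance(q, r)["slope"]
            ok += 0.8 <= slope <= 1.2
        assert ok >= 45

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            simulate_ct_table(self._truth(), 5, ct_noise_sd=-0.1)
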