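"""Local A/B density ratios, gene mapping, DE scores, perturbation analysis."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chromtrace import geometry as geom
from chromtrace import local_env as le
from chromtrace import synthetic as syn
from conftest import make_cell


def two_chrom_cell(points_cis, points_trans, labels_trans, seed_pos=0):
    """Cell with query loci on chr1 and labelled trans loci on chr2."""
    cis = make_cell(points_cis, chrom="chr1",
                    locus_ids=[f"q{i}" for i in range(len(points_cis))])
    trans = make_cell(points_trans, chrom="chr2",
                      locus_ids=[f"t{i}" for i in range(len(points_trans))])
    cell = pd.concat([cis, trans], ignore_index=True)
    labels = pd.Series(
        ["A"] * len(points_cis) + list(labels_trans),
        index=list(cis["locus_id"]) + list(trans["locus_id"]))
    return cell, labels


class TestLocalABRatio:
    def test_mirror_symmetric_clouds_give_unity(self):
        """A and B trans clouds mirror-symmetric about the query -> ratio 1."""
        rng = np.random.default_rng(0)
        cloud = rng.uniform(-2, 2, (20, 3))
        points_trans = np.vstack([cloud, -cloud])
        labels = ["A"] * 20 + ["B"] * 20
        cell, lab = two_chrom_cell([[0.0, 0.0, 0.0]], points_trans, labels)
        out = le.local_ab_density_ratio(cell, lab, kernel_scale=1.0)
        ratio = out.loc[out["chrom"] == "chr1", "local_ab_ratio"].iloc[0]
        assert ratio == pytest.approx(1.0, rel=1e-9)

    def test_all_a_trans_loci_hit_pseudocount_cap(self):
        rng = np.random.default_rng(1)
        cell, lab = two_chrom_cell([[0.0, 0.0, 0.0]],
                                   rng.uniform(-1, 1, (15, 3)), ["A"] * 15)
        out = le.local_ab_density_ratio(cell, lab, kernel_scale=1.0)
        ratio = out.loc[out["chrom"] == "chr1", "local_ab_ratio"].iloc[0]
        # denominator is the bare pseudocount
        assert ratio > 100

    def test_too_few_trans_loci_nan(self):
        rng = np.random.default_rng(2)
        cell, lab = two_chrom_cell([[0.0, 0.0, 0.0]],
                                   rng.uniform(-1, 1, (5, 3)),
                                   ["A", "A", "B", "B", "B"])
        out = le.local_ab_density_ratio(cell, lab, kernel_scale=1.0,
                                        min_trans=10)
        assert out["local_ab_ratio"].isna().all()

    def test_rigid_motion_invariance_and_label_swap_reciprocal(self):
        rng = np.random.default_rng(3)
        trans_pts = rng.uniform(-2, 2, (30, 3))
        labels = ["A"] * 15 + ["B"] * 15
        cell, lab = two_chrom_cell(rng.uniform(-1, 1, (4, 3)), trans_pts, labels)
        out0 = le.local_ab_density_ratio(cell, lab)
        rot = np.linalg.qr(rng.standard_normal((3, 3)))[0]
        moved = cell.copy()
        moved[["x", "y", "z"]] = cell[["x", "y", "z"]].to_numpy() @ rot.T + 11.0
        out1 = le.local_ab_density_ratio(moved, lab)
        np.testing.assert_allclose(out0["local_ab_ratio"],
                                   out1["local_ab_ratio"], rtol=1e-9)
        swapped = lab.map({"A": "B", "B": "A"})
        out2 = le.local_ab_density_ratio(cell, swapped)
        q = out0["chrom"] == "chr1"
        np.testing.assert_allclose(out2.loc[q, "local_ab_ratio"],
                                   1.0 / out0.loc[q, "local_ab_ratio"],
                                   rtol=1e-2)

    def test_missing_labels_rejected(self):
        rng = np.random.default_rng(4)
        cell, lab = two_chrom_cell([[0, 0, 0]], rng.uniform(-1, 1, (12, 3)),
                                   ["A"] * 12)
        with pytest.raises(ValueError, match="labels missing"):
            le.local_ab_density_ratio(cell, lab.drop("t3"))

    def test_interior_a_environment_gradient(self, planted):
        """With A planted interior, interior-decile loci live in higher
        local A/B ratio environments than peripheral-decile loci."""
        _, panel, truth, traces = planted
        sub = traces[traces["cell_id"].isin(traces["cell_id"].unique()[:120])]
        labels = truth.set_index("locus_id")["compartment"]
        env = le.local_env_table(sub, labels, kernel_scale=1.0)
        med = le.median_ratio_per_locus(env)
        radial = truth.set_index("locus_id")["truth_radial"]
        interior = radial <= radial.quantile(0.1)
        peripheral = radial >= radial.quantile(0.9)
        assert med[interior[med.index]].median() \
            > med[peripheral[med.index]].median()


class TestNormalization:
    def test_global_scale_invariance(self):
        base = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        out = le.normalize_ratio_across_groups({"g1": base, "g2": base * 2.0})
        pd.testing.assert_series_equal(out["g1"], out["g2"])
        assert out["g1"].mean() == pytest.approx(1.0)

    def test_per_locus_differences_survive(self):
        base = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        shifted = pd.Series([1.0, 2.0, 6.0], index=list("abc"))
        out = le.normalize_ratio_across_groups({"g1": base, "g2": shifted})
        delta = out["g2"] - out["g1"]
        assert delta["c"] > 0 > delta["a"]

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="two groups"):
            le.normalize_ratio_across_groups({"g1": pd.Series([1.0])})


class TestGeneMapping:
    def _panel(self):
        return pd.DataFrame({
            "locus_id": ["L0", "L1"], "chrom": "chr1",
            "start": [1_000_000, 2_000_000],
            "end": [1_020_000, 2_020_000]})

    def _genes(self, tss_list):
        return pd.DataFrame({"gene_id": [f"g{i}" for i in range(len(tss_list))],
                             "chrom": "chr1", "tss": tss_list,
                             "gene_length": 10_000})

    def test_gene_at_midpoint_mapped(self):
        mapping = le.map_genes_to_loci(self._genes([1_010_000]), self._panel())
        assert mapping["g0"] == "L0"

    def test_window_edge_inclusive_exclusive(self):
        # 100,000 bp beyond the interval edge maps; 100,001 does not
        mapping = le.map_genes_to_loci(self._genes([1_119_999, 1_120_000]),
                                       self._panel())
        assert mapping.get("g0") == "L0"
        assert "g1" not in mapping.index

    def test_equidistant_tie_goes_to_lower_coordinate(self):
        panel = pd.DataFrame({
            "locus_id": ["L0", "L1"], "chrom": "chr1",
            "start": [1_000_000, 1_200_000],
            "end": [1_020_000, 1_220_000]})
        # TSS equidistant (100 kb) from both midpoints and within window
        mapping = le.map_genes_to_loci(self._genes([1_110_000]), panel)
        assert mapping["g0"] == "L0"


class TestLocusActivity:
    def test_sum_and_nan_and_quartiles(self):
        panel = pd.DataFrame({
            "locus_id": [f"L{i}" for i in range(8)], "chrom": "chr1",
            "start": np.arange(8) * 1_000_000,
            "end": np.arange(8) * 1_000_000 + 20_000})
        genes = pd.DataFrame({
            "gene_id": ["g0", "g1"], "chrom": "chr1",
            "tss": [10_000, 10_500], "gene_length": 1000, "ct": [7, 5]})
        mapping = le.map_genes_to_loci(genes, panel)
        activity = le.locus_activity(genes, mapping, panel)["ct"]
        assert activity["L0"] == 12          # both genes sum onto L0
        assert activity.drop("L0").isna().all()

        act = pd.Series(np.arange(20, dtype=float),
                        index=[f"x{i}" for i in range(20)])
        classes = le.activity_classes(act)
        assert (classes == "high").sum() == 5
        assert (classes == "low").sum() == 5


class TestDeScore:
    def test_identical_groups_zero(self):
        counts = pd.DataFrame(np.tile([[5.0, 7, 9]], (4, 1)).T,
                              index=list("abc"))
        de = le.de_score(counts, counts.copy())
        np.testing.assert_allclose(de.fillna(0.0), 0.0)

    def test_matches_closed_form_welch(self):
        rng = np.random.default_rng(0)
        wt = pd.DataFrame(rng.normal(10, 2, (5, 30)),
                          index=[f"g{i}" for i in range(5)])
        ko = pd.DataFrame(rng.normal(12, 3, (5, 40)),
                          index=[f"g{i}" for i in range(5)])
        # equal per-cell totals so normalization is a common constant
        wt = wt / wt.sum(axis=0) * 100
        ko = ko / ko.sum(axis=0) * 100
        de = le.de_score(wt, ko)
        x, y = ko.loc["g0"].to_numpy(), wt.loc["g0"].to_numpy()
        t_manual = (x.mean() - y.mean()) / np.sqrt(
            x.var(ddof=1) / len(x) + y.var(ddof=1) / len(y))
        assert de["g0"] == pytest.approx(t_manual, rel=1e-9)

    def test_single_cell_group_rejected(self):
        counts = pd.DataFrame([[1.0, 2.0]], index=["g0"])
        with pytest.raises(ValueError, match="2 cells"):
            le.de_score(counts, counts.iloc[:, :1])


class TestRadialBins:
    def test_constant_values_flat(self):
        out = le.radial_bin_analysis(pd.Series(np.ones(100)),
                                     pd.Series(np.linspace(0, 1, 100)))
        np.testing.assert_allclose(out["mean"], 1.0)

    def test_identity_values_strictly_increasing(self):
        radial = pd.Series(np.random.default_rng(0).uniform(0, 1, 200))
        out = le.radial_bin_analysis(radial, radial)
        assert out["mean"].is_monotonic_increasing

    def test_equal_count_bins_within_one(self):
        radial = pd.Series(np.random.default_rng(1).uniform(0, 1, 103))
        out = le.radial_bin_analysis(pd.Series(np.zeros(103)), radial)
        assert out["n"].max() - out["n"].min() <= 1

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="bins"):
            le.radial_bin_analysis(pd.Series([1.0]), pd.Series([0.5]))

    def test_high_activity_fraction_decreases_with_radius(self, planted):
        """Interior-A populations put high-activity loci inside: the fraction
        of high-activity loci falls from interior to peripheral deciles."""
        params, panel, truth, traces = planted
        expr = syn.simulate_expression(panel, truth, params)
        gene_map = le.map_genes_to_loci(expr, panel)
        activity = le.locus_activity(expr, gene_map, panel)["neuron"]
        classes = le.activity_classes(activity)
        radial = truth.set_index("locus_id")["truth_radial"]
        frame = pd.DataFrame({"high": (classes == "high").astype(float),
                              "low": (classes == "low").astype(float),
                              "radial": radial}).dropna()
        high = le.radial_bin_analysis(frame["high"], frame["radial"], n_bins=5)
        low = le.radial_bin_analysis(frame["low"], frame["radial"], n_bins=5)
        rho_high = stats.spearmanr(high["bin"], high["mean"])[0]
        rho_low = stats.spearmanr(low["bin"], low["mean"])[0]
        assert rho_high < 0 < rho_low


@pytest.fixture(scope="module")
def ko_analysis(ko_pair):
    params, panel, truth, traces = ko_pair
    labels = truth.set_index("locus_id")["compartment"]
    env = le.local_env_table(traces, labels, kernel_scale=1.0)
    rad = {}
    for gt in ("WT", "KO"):
        prof = geom.radial_profile(traces[traces["genotype"] == gt])
        rad[gt] = prof.groupby("locus_id")["radial_position"].median()
    return params, panel, truth, env, labels, rad


class TestPerturbation:
    def test_ko_designed_sign_pattern(self, ko_analysis):
        """De-segregation lowers the A-locus and raises the B-locus local
        A/B ratio, with an interior-to-periphery increasing delta profile."""
        params, panel, truth, env, labels, rad = ko_analysis
        out = le.perturbation_comparison(
            env[env["genotype"] == "WT"], env[env["genotype"] == "KO"],
            labels, rad["WT"], radial_ko=rad["KO"])
        tests = out.compartment_tests.set_index("compartment")
        assert tests.loc["A", "mean_delta"] < 0 < tests.loc["B", "mean_delta"]
        assert tests["significant"].all()
        profile = out.decile_profile.set_index("radial_bin")["mean_delta_ratio"]
        assert profile.iloc[0] < 0 < profile.iloc[-1]
        rho = stats.spearmanr(profile.index, profile.values)[0]
        assert rho > 0.8

    def test_ko_moves_loci_toward_radial_middle(self, ko_analysis):
        params, panel, truth, env, labels, rad = ko_analysis
        delta = rad["KO"] - rad["WT"]
        is_a = labels.reindex(delta.index) == "A"
        # interior (A) loci move outward, peripheral (B) loci move inward
        assert delta[is_a].mean() > 0 > delta[~is_a].mean()

    def test_null_perturbation_alpha_controlled(self):
        """KO with zero mixing is statistically identical to WT: no
        significant per-compartment shifts at the Bonferroni level."""
        params = syn.SimulationParams(
            chromosomes=[syn.ChromosomeSpec("chr1", n_loci=60),
                         syn.ChromosomeSpec("chr2", n_loci=60)],
            cell_types=[syn.CellTypeParams("neuron", gamma=0.4)],
            n_cells_per_type=80, ko_mixing=0.0, seed=21)
        panel, truth = syn.make_truth_panel(params)
        traces = syn.simulate_population(panel, truth, params,
                                         genotypes=("WT", "KO"))
        labels = truth.set_index("locus_id")["compartment"]
        env = le.local_env_table(traces, labels)
        prof = geom.radial_profile(traces[traces["genotype"] == "WT"])
        rad_wt = prof.groupby("locus_id")["radial_position"].median()
        out = le.perturbation_comparison(
            env[env["genotype"] == "WT"], env[env["genotype"] == "KO"],
            labels, rad_wt)
        assert not out.compartment_tests["significant"].any()

    def test_de_coupling_positive_correlation(self, ko_analysis):
        """Loci whose local environment becomes more A-like upon KO also
        show transcriptional up-regulation (positive decile correlation)."""
        params, panel, truth, env, labels, rad = ko_analysis
        wt = syn.simulate_expression(panel, truth, params, "WT", per_cell=True,
                                     n_cells=80)
        ko = syn.simulate_expression(panel, truth, params, "KO", per_cell=True,
                                     n_cells=80)
        de = le.de_score(le.split_per_cell_columns(wt, "neuron", "WT"),
                         le.split_per_cell_columns(ko, "neuron", "KO"))
        gene_map = le.map_genes_to_loci(wt, panel)
        de_locus = de.groupby(gene_map.reindex(de.index)).mean()
        out = le.perturbation_comparison(
            env[env["genotype"] == "WT"], env[env["genotype"] == "KO"],
            labels, rad["WT"], de_scores=de_locus)
        assert out.de_correlation is not None and out.de_correlation > 0


class TestConservedFilter:
    def test_identical_calls_fully_conserved(self):
        lab = pd.Series(list("AABB"), index=list("wxyz"))
        conserved, frac = le.conserved_compartment_filter(lab, lab.copy())
        assert len(conserved) == 4 and frac["conserved"] == 1.0

    def test_two_of_twenty_flipped(self):
        idx = [f"L{i}" for i in range(20)]
        wt = pd.Series(["A"] * 10 + ["B"] * 10, index=idx)
        ko = wt.copy()
        ko.iloc[0] = "B"
        ko.iloc[19] = "A"
        conserved, frac = le.conserved_compartment_filter(wt, ko)
        assert len(conserved) == 18
        assert frac["conserved"] == pytest.approx(0.9)
        assert frac["A->B"] == pytest.approx(0.05)
        assert frac["B->A"] == pytest.approx(0.05)

    def test_restricted_analysis_keeps_sign_pattern(self, ko_pair):
        """Restricting the KO delta analysis to conserved-compartment loci
        reproduces the unrestricted sign pattern."""
        params, panel, truth, traces = ko_pair
        labels = truth.set_index("locus_id")["compartment"]
        # calls are truth-identical here; drop a fifth of loci to emulate
        # an imperfect conserved subset
        rng = np.random.default_rng(0)
        keep = rng.random(len(labels)) > 0.2
        subset = labels[keep]
        env = le.local_env_table(
            traces[traces["cell_id"].isin(traces["cell_id"].unique()[:160])],
            labels)
        env_wt = env[env["genotype"] == "WT"]
        env_ko = env[env["genotype"] == "KO"]
        med_wt = le.median_ratio_per_locus(env_wt)
        norm = le.normalize_ratio_across_groups({
            "WT": med_wt, "KO": le.median_ratio_per_locus(env_ko)})
        delta = (norm["KO"] - norm["WT"]).reindex(subset.index)
        assert delta[subset == "A"].mean() < 0 < delta[subset == "B"].mean()
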