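"""SNP filtering, HWE, PCA, partial RDA, permutation tests, Weir's theta."""

import itertools
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln

from thermoflex import SimConfig
from thermoflex.envwindows import standardize_2sd
from thermoflex.popgen import (
    GenoMatrix,
    correlation_prune,
    filter_sites,
    hwe_exact_test,
    impute_major,
    partial_rda,
    pca_genotypes,
    permutation_anova,
    read_matrix_csv,
    read_vcf,
    variance_partition,
    vif,
    weir_fst,
    weir_fst_components,
    write_matrix_csv,
    write_vcf,
)
from thermoflex.synthetic import GenotypeParams, gen_genotypes


def _gm(gt, pops=None, depth=None, species=None):
    gt = np.asarray(gt, float)
    n, m = gt.shape
    pops = np.asarray(pops if pops is not None else ["p0"] * n)
    depth = np.full(m, 20.0) if depth is None else np.asarray(depth, float)
    return GenoMatrix(gt, depth, [f"i{k}" for k in range(n)], pops, species)


# ---------------------------------------------------------------------------
# HWE exact test


def _hwe_bruteforce(n_aa, n_ab, n_bb):
    """Independent enumeration over all heterozygote counts."""
    n = n_aa + n_ab + n_bb
    na = 2 * n_aa + n_ab
    if na == 0 or na == 2 * n:
        return 1.0
    rare = min(na, 2 * n - na)
    probs = {}
    for h in range(rare % 2, rare + 1, 2):
        a = (na - h) // 2
        b = (2 * n - na - h) // 2
        logp = (h * np.log(2) + gammaln(n + 1)
                - gammaln(a + 1) - gammaln(h + 1) - gammaln(b + 1)
                + gammaln(na + 1) + gammaln(2 * n - na + 1) - gammaln(2 * n + 1))
        probs[h] = np.exp(logp)
    z = sum(probs.values())
    obs = probs[n_ab] / z
    return min(1.0, sum(p / z for p in probs.values() if p / z <= obs * (1 + 1e-12)))


class TestHweExact:
    def test_monomorphic_site_p_one(self):
        assert hwe_exact_test(10, 0, 0) == 1.0
        assert hwe_exact_test(0, 0, 7) == 1.0

    def test_two_individuals_enumeration(self):
        # (1,0,1): conditional outcomes het in {0, 2} with probs 1/3, 2/3
        assert hwe_exact_test(1, 0, 1) == pytest.approx(1 / 3, abs=1e-12)
        assert hwe_exact_test(0, 2, 0) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bruteforce_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        counts = tuple(int(x) for x in rng.integers(0, 12, 3))
        if sum(counts) == 0:
            counts = (1, 1, 1)
        assert hwe_exact_test(*counts) == pytest.approx(
            _hwe_bruteforce(*counts), abs=1e-10)

    def test_negative_counts_raise(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 3)


# ---------------------------------------------------------------------------
# Filtering


class TestFilterSites:
    def _toy(self):
        """10 sites, 12 individuals: 3 fail depth, 3 fail mac, 3 fail
        missingness, 1 passes everything (enumerated truth)."""
        n = 12
        rng = np.random.default_rng(0)
        cols, depth = [], []
        # 3 low-depth sites (otherwise fine)
        for _ in range(3):
            cols.append(rng.permutation([0] * 5 + [1] * 4 + [2] * 3))
            depth.append(2.0)
        # 3 minor-allele-count failures (single het)
        for _ in range(3):
            cols.append(np.array([1.0] + [0.0] * (n - 1)))
            depth.append(20.0)
        # 3 missingness failures (7/12 missing, called part polymorphic)
        for _ in range(3):
            c = np.array([1, 1, 1, 0, 0] + [np.nan] * 7)
            cols.append(c)
            depth.append(20.0)
        # 1 clean site
        cols.append(rng.permutation([0] * 5 + [1] * 4 + [2] * 3))
        depth.append(20.0)
        return _gm(np.column_stack(cols), depth=depth)

    def test_enumerated_toy_counts(self):
        g, report = filter_sites(self._toy(), ind_max_missing=0.9)
        steps = dict(report.steps)
        assert steps["mean_depth"] == 3
        assert steps["mac"] == 3
        assert steps["max_missing"] == 3
        assert g.n_sites == 1
        # invariant: counts sum to input - output sites
        assert sum(steps.values()) == report.n_input_sites - report.n_output_sites

    def test_all_passing_is_identity(self):
        rng = np.random.default_rng(1)
        gt = rng.integers(0, 3, size=(20, 6)).astype(float)
        gt[0] = [0, 1, 2, 1, 0, 1]  # keep every site comfortably polymorphic
        gt[1] = [2, 1, 0, 1, 2, 1]
        g, report = filter_sites(_gm(gt))
        assert g.n_sites == 6
        assert all(c == 0 for _, c in report.steps)

    def test_mac_boundary(self):
        # minor allele count 2 removed, count 3 retained
        n = 20
        site_mac2 = np.array([1, 1] + [0] * (n - 2), float)
        site_mac3 = np.array([1, 1, 1] + [0] * (n - 3), float)
        g, report = filter_sites(_gm(np.column_stack([site_mac2, site_mac3])),
                                 hwe_p=0.0)
        assert g.n_sites == 1
        assert dict(report.steps)["mac"] == 1

    def test_hwe_step_removes_disequilibrium_site(self):
        # strong heterozygote deficit: all homozygotes at p = 0.5
        n = 40
        bad = np.array([0.0] * (n // 2) + [2.0] * (n // 2))
        good = np.array(([0.0] * 1 + [1.0] * 2 + [2.0] * 1) * 10)
        g, report = filter_sites(_gm(np.column_stack([bad, good])))
        assert dict(report.steps)["hwe"] == 1
        assert g.n_sites == 1

    def test_individual_missingness_removal(self):
        gt = np.tile([0, 1, 2, 1.0], (10, 5)).reshape(10, 20)
        gt[3, :15] = np.nan  # 75% missing individual
        g, report = filter_sites(_gm(gt), strict_missing_frac=1.0, hwe_p=0.0)
        assert report.individuals_removed == ["i3"]
        assert g.n_individuals == 9


class TestImputeMajor:
    def test_no_missing_is_identity(self):
        gt = np.array([[0, 1], [2, 1], [1, 0.0]])
        out = impute_major(_gm(gt))
        assert np.array_equal(out.genotypes, gt)

    def test_mode_fills_missing(self):
        gt = np.array([[0.0], [0.0], [2.0], [np.nan]])
        out = impute_major(_gm(gt))
        assert out.genotypes[3, 0] == 0.0

    def test_tie_breaks_to_lower_code(self):
        gt = np.array([[0.0], [0.0], [2.0], [2.0], [np.nan]])
        out = impute_major(_gm(gt))
        assert out.genotypes[4, 0] == 0.0

    def test_imputation_is_per_species(self):
        gt = np.array([[0.0], [0.0], [2.0], [2.0], [np.nan]])
        species = np.array(["a", "a", "b", "b", "b"])
        out = impute_major(_gm(gt, species=species))
        assert out.genotypes[4, 0] == 2.0

    def test_all_missing_cell_raises(self):
        gt = np.array([[np.nan], [np.nan]])
        with pytest.raises(ValueError):
            impute_major(_gm(gt))


# ---------------------------------------------------------------------------
# PCA


class TestPca:
    def test_single_direction_explains_everything(self):
        col = np.array([1, 2, 3, 4, 5.0])
        X = np.column_stack([col, 2 * col, -col, 3 * col])
        scores, pct = pca_genotypes(X, 1)
        assert pct[0] == pytest.approx(100.0)

    def test_matches_covariance_eigendecomposition(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 12))
        scores, pct = pca_genotypes(X, 5)
        C = np.cov(X, rowvar=False, ddof=1)
        eig = np.sort(np.linalg.eigvalsh(C))[::-1]
        assert np.allclose(pct, 100 * eig[:5] / eig.sum(), atol=1e-8)
        assert pct.sum() <= 100 + 1e-9

    def test_column_offset_leaves_scores_unchanged(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(15, 6))
        s1, _ = pca_genotypes(X, 3)
        X2 = X.copy()
        X2[:, 2] += 37.0
        s2, _ = pca_genotypes(X2, 3)
        # axes defined up to sign
        for a in range(3):
            assert (np.allclose(s1[:, a], s2[:, a], atol=1e-8)
                    or np.allclose(s1[:, a], -s2[:, a], atol=1e-8))

    def test_excess_axes_truncated_with_warning(self):
        X = np.random.default_rng(4).normal(size=(5, 10))
        with pytest.warns(UserWarning):
            scores, pct = pca_genotypes(X, 8)
        assert scores.shape[1] <= 4


# ---------------------------------------------------------------------------
# Partial RDA


class TestPartialRda:
    def test_exact_linear_response_no_conditioning(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=20)
        G = np.outer(x, rng.normal(size=15))   # rank-1, exactly explained
        clim = pd.DataFrame({"x": x})
        rda = partial_rda(G, clim, condition=None, check_vif=False)
        assert rda.r2_constrained == pytest.approx(1.0, abs=1e-10)
        assert abs(rda.loadings.loc["x", "RDA1"]) == pytest.approx(1.0, abs=1e-8)

    def test_null_climate_explains_nothing(self):
        rng = np.random.default_rng(6)
        G = rng.normal(size=(60, 100))
        clim = pd.DataFrame(rng.normal(size=(60, 2)), columns=["a", "b"])
        scores, _ = pca_genotypes(G, 2)
        rda = partial_rda(G, clim, scores, check_vif=False)
        rda = permutation_anova(rda, 199, 99, seed=rng)
        assert rda.adj_r2_constrained == pytest.approx(0.0, abs=0.05)
        assert rda.p_model > 0.05

    def test_matches_projection_matrix_oracle(self):
        rng = np.random.default_rng(7)
        G = rng.normal(size=(10, 20))
        clim = pd.DataFrame(rng.normal(size=(10, 2)), columns=["a", "b"])
        Z = rng.normal(size=(10, 2))
        rda = partial_rda(G, clim, Z, check_vif=False)
        # oracle: dense hat-matrix computation
        Gc = G - G.mean(axis=0)
        Z1 = np.column_stack([np.ones(10), Z])
        Hz = Z1 @ np.linalg.inv(Z1.T @ Z1) @ Z1.T
        Gr = Gc - Hz @ Gc
        Xr = clim.to_numpy() - Hz @ clim.to_numpy()
        Hx = Xr @ np.linalg.inv(Xr.T @ Xr) @ Xr.T
        ss_tot = (Gc ** 2).sum()
        ss_fit = ((Hx @ Gr) ** 2).sum()
        ss_cond = ((Hz @ Gc) ** 2).sum()
        assert rda.r2_constrained == pytest.approx(ss_fit / ss_tot, abs=1e-10)
        assert rda.r2_conditional == pytest.approx(ss_cond / ss_tot, abs=1e-10)
        assert (rda.r2_constrained + rda.r2_conditional + rda.r2_residual
                ) == pytest.approx(1.0, abs=1e-10)

    def test_vif_guard_names_offenders(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=30)
        clim = pd.DataFrame({"a": x, "b": x + rng.normal(0, 1e-3, 30),
                             "c": rng.normal(size=30)})
        G = rng.normal(size=(30, 10))
        with pytest.raises(ValueError, match="a"):
            partial_rda(G, clim, None)

    def test_agrees_with_vegan_reference(self, tmp_path):
        """Cross-check constrained/conditional adjusted R^2 and pseudo-F
        against vegan's rda() on a small fixture."""
        rng = np.random.default_rng(9)
        G = rng.normal(size=(16, 25))
        clim = pd.DataFrame(rng.normal(size=(16, 3)), columns=["c1", "c2", "c3"])
        Z = pd.DataFrame(rng.normal(size=(16, 2)), columns=["z1", "z2"])
        pd.DataFrame(G).to_csv(tmp_path / "G.csv", index=False)
        clim.to_csv(tmp_path / "clim.csv", index=False)
        Z.to_csv(tmp_path / "Z.csv", index=False)
        rscript = textwrap.dedent("""
            suppressMessages(library(vegan))
            G <- as.matrix(read.csv("G.csv"))
            clim <- read.csv("clim.csv")
            Z <- read.csv("Z.csv")
            d <- cbind(clim, Z)
            m <- rda(G ~ c1 + c2 + c3 + Condition(z1 + z2), data = d)
            adj <- RsquareAdj(m)
            cat(sprintf("%.14f %.14f %.14f\\n", adj$adj.r.squared,
                m$pCCA$tot.chi / m$tot.chi, m$CCA$tot.chi / m$tot.chi))
        """)
        (tmp_path / "check.R").write_text(rscript)
        res = subprocess.run(["Rscript", "check.R"], cwd=tmp_path,
                             capture_output=True, text=True, timeout=300)
        assert res.returncode == 0, res.stderr
        adj_con, raw_cond, raw_con = map(float, res.stdout.split())
        rda = partial_rda(G, clim, Z.to_numpy(), check_vif=False)
        assert rda.adj_r2_constrained == pytest.approx(adj_con, abs=1e-6)
        assert rda.r2_conditional == pytest.approx(raw_cond, abs=1e-8)
        assert rda.r2_constrained == pytest.approx(raw_con, abs=1e-8)


class TestPermutationAnova:
    def test_saturated_association_attains_minimum_p(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=30)
        G = np.outer(x, rng.normal(size=20)) + rng.normal(0, 1e-6, (30, 20))
        clim = pd.DataFrame({"x": x})
        rda = partial_rda(G, clim, None, check_vif=False)
        rda = permutation_anova(rda, n_perm_model=199, seed=1)
        assert rda.p_model == pytest.approx(1 / 200)

    def test_matches_exact_enumeration_at_n4(self):
        """Monte-Carlo p at n = 4 vs the exact p over all 4! relabelings."""
        rng = np.random.default_rng(11)
        G = rng.normal(size=(4, 6))
        clim = pd.DataFrame({"x": rng.normal(size=4)})
        rda = partial_rda(G, clim, None, check_vif=False)

        # exact enumeration with an independent dense computation
        Gc = G - G.mean(axis=0)
        ss_tot = (Gc ** 2).sum()
        x = clim["x"].to_numpy()

        def pseudo_f(xp):
            xc = xp - xp.mean()
            H = np.outer(xc, xc) / (xc @ xc)
            ss_fit = ((H @ Gc) ** 2).sum()
            return (ss_fit / 1) / ((ss_tot - ss_fit) / (4 - 2))

        obs = pseudo_f(x)
        fs = [pseudo_f(x[list(p)]) for p in itertools.permutations(range(4))]
        p_exact = np.mean([f >= obs - 1e-12 for f in fs])

        rda = permutation_anova(rda, n_perm_model=999, seed=2)
        # Monte-Carlo estimate within 3 binomial sd of the exact probability
        se = np.sqrt(p_exact * (1 - p_exact) / 999)
        assert abs(rda.p_model - p_exact) <= 3 * se + 2 / 1000

    def test_null_p_uniform_over_replicates(self):
        hits = 0
        reps = 60
        for s in range(reps):
            rng = np.random.default_rng(300 + s)
            G = rng.normal(size=(30, 40))
            clim = pd.DataFrame(rng.normal(size=(30, 2)), columns=["a", "b"])
            rda = partial_rda(G, clim, None, check_vif=False)
            rda = permutation_anova(rda, 99, seed=rng)
            hits += rda.p_model <= 0.10
        # binomial 95% band around 0.10
        se = np.sqrt(0.1 * 0.9 / reps)
        assert abs(hits / reps - 0.10) <= 1.96 * se + 1e-9


class TestVariancePartition:
    def test_duplicate_variable_rejected_by_vif(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=25)
        clim = pd.DataFrame({"a": x, "b": x * 2})
        G = rng.normal(size=(25, 8))
        with pytest.raises(ValueError):
            variance_partition(G, clim, None, check_vif=True)

    def test_orthogonal_variables_fractions_additive(self):
        rng = np.random.default_rng(13)
        n = 80
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        x2 -= x1 * (x1 @ x2) / (x1 @ x1)  # orthogonalize
        G = (np.outer(x1, rng.normal(size=30))
             + np.outer(x2, rng.normal(size=30))
             + rng.normal(0, 1.0, (n, 30)))
        clim = pd.DataFrame({"x1": x1, "x2": x2})
        vp = variance_partition(G, clim, None, check_vif=False).set_index("variable")
        total = vp.loc["constrained_total", "adj_r2"]
        parts = vp.loc[["x1", "x2"], "adj_r2"].sum()
        assert parts == pytest.approx(total, abs=0.02)

    def test_marginal_and_unique_modes_agree_for_orthogonal_design(self):
        rng = np.random.default_rng(14)
        n = 60
        Q, _ = np.linalg.qr(rng.normal(size=(n, 2)))
        clim = pd.DataFrame(Q, columns=["a", "b"])
        G = rng.normal(size=(n, 20))
        vm = variance_partition(G, clim, None, mode="marginal", check_vif=False)
        vu = variance_partition(G, clim, None, mode="unique", check_vif=False)
        merged = vm.merge(vu, on="variable", suffixes=("_m", "_u"))
        rows = merged[~merged.variable.str.contains("total")]
        assert np.allclose(rows.adj_r2_m, rows.adj_r2_u, atol=0.02)


# ---------------------------------------------------------------------------
# Weir-Cockerham theta


def _wc_hand(counts1, counts2):
    """Independent hand computation of (a, b, c) for one site, two pops.

    counts = (n_hom_ref, n_het, n_hom_alt).
    """
    r = 2
    ns, ps, hs = [], [], []
    for c in (counts1, counts2):
        n = sum(c)
        ns.append(n)
        ps.append((2 * c[2] + c[1]) / (2 * n))
        hs.append(c[1] / n)
    nbar = sum(ns) / r
    nc = (sum(ns) - sum(x * x for x in ns) / sum(ns)) / (r - 1)
    pbar = sum(n * p for n, p in zip(ns, ps)) / sum(ns)
    s2 = sum(n * (p - pbar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * nbar)
    hbar = sum(n * h for n, h in zip(ns, hs)) / sum(ns)
    pq = pbar * (1 - pbar)
    a = (nbar / nc) * (s2 - (pq - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pq - (r - 1) / r * s2
                               - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c


class TestWeirFst:
    def test_hand_computed_two_pop_fixture(self):
        # p-hat 0.9 vs 0.1, one heterozygote each, five diploids per pop
        pop1 = [2, 2, 2, 2, 1.0]   # alt freq 0.9, 1 het
        pop2 = [0, 0, 0, 0, 1.0]   # alt freq 0.1, 1 het
        gt = np.array(pop1 + pop2)[:, None]
        pops = np.array(["A"] * 5 + ["B"] * 5)
        a, b, c = weir_fst_components(gt, pops)
        ah, bh, ch = _wc_hand((0, 1, 4), (4, 1, 0))
        assert a[0] == pytest.approx(ah, abs=1e-10)
        assert b[0] == pytest.approx(bh, abs=1e-10)
        assert c[0] == pytest.approx(ch, abs=1e-10)
        theta = weir_fst(_gm(gt, pops)).loc["A", "B"]
        assert theta == pytest.approx(ah / (ah + bh + ch), abs=1e-10)

    def test_identical_all_het_pops_give_exact_zero(self):
        gt = np.ones((8, 4))  # every individual heterozygous at every site
        pops = np.array(["A"] * 4 + ["B"] * 4)
        theta = weir_fst(_gm(gt, pops)).loc["A", "B"]
        assert theta == pytest.approx(0.0, abs=1e-12)

    def test_identical_generic_pops_give_small_theta(self):
        rng = np.random.default_rng(15)
        block = rng.integers(0, 3, size=(20, 200)).astype(float)
        gt = np.vstack([block, block])
        pops = np.array(["A"] * 20 + ["B"] * 20)
        theta = weir_fst(_gm(gt, pops)).loc["A", "B"]
        assert abs(theta) < 0.05

    def test_fixed_difference_is_one(self):
        gt = np.array([[0.0]] * 6 + [[2.0]] * 6)
        pops = np.array(["A"] * 6 + ["B"] * 6)
        assert weir_fst(_gm(gt, pops)).loc["A", "B"] == pytest.approx(1.0)

    def test_invariant_to_allele_label_swap(self):
        rng = np.random.default_rng(16)
        gt = rng.integers(0, 3, size=(30, 80)).astype(float)
        pops = np.repeat(["A", "B", "C"], 10)
        t1 = weir_fst(_gm(gt, pops))
        t2 = weir_fst(_gm(2.0 - gt, pops))
        assert np.allclose(t1.to_numpy(), t2.to_numpy(), atol=1e-12)

    def test_single_population_flagged_nan(self):
        gt = np.random.default_rng(17).integers(0, 3, (6, 10)).astype(float)
        with pytest.warns(UserWarning, match="single population"):
            out = weir_fst(_gm(gt))
        assert np.isnan(out.iloc[0, 0])

    def test_generator_calibration_hits_target_band(self):
        cfg = SimConfig(seed=21, geno=GenotypeParams(env_effect=0.0,
                                                     n_adaptive_loci=0))
        gm, _ = gen_genotypes(cfg)
        fst = weir_fst(gm)
        off = fst.to_numpy()[~np.eye(5, dtype=bool)]
        assert 0.02 <= off.mean() <= 0.08


# ---------------------------------------------------------------------------
# VIF and correlation pruning


class TestVifPrune:
    def test_orthogonal_variables_have_unit_vif(self):
        Q, _ = np.linalg.qr(np.random.default_rng(18).normal(size=(30, 3)))
        out = vif(pd.DataFrame(Q, columns=["a", "b", "c"]))
        assert np.allclose(out, 1.0, atol=1e-10)

    def test_collinear_pair_pruned_to_one(self):
        x = np.random.default_rng(19).normal(size=20)
        clim = pd.DataFrame({"a": x, "b": 2 * x})
        assert len(correlation_prune(clim)) == 1

    def test_three_variable_fixture_matches_exhaustive_search(self):
        rng = np.random.default_rng(20)
        x = rng.normal(size=50)
        clim = pd.DataFrame({
            "a": x,
            "b": 0.95 * x + 0.3 * rng.normal(size=50),
            "c": rng.normal(size=50),
        })
        kept = correlation_prune(clim, r_max=0.70)
        # exhaustive oracle: largest subset with all |r| < 0.70
        best = []
        for k in (3, 2, 1):
            for combo in itertools.combinations(clim.columns, k):
                R = clim[list(combo)].corr().abs().to_numpy()
                np.fill_diagonal(R, 0)
                if R.max() < 0.70 and len(combo) > len(best):
                    best = list(combo)
            if best:
                break
        assert len(kept) == len(best)
        assert set(kept) <= set(clim.columns)
        R = clim[kept].corr().abs().to_numpy()
        np.fill_diagonal(R, 0)
        assert R.max() < 0.70


# ---------------------------------------------------------------------------
# I/O


class TestIo:
    def test_vcf_roundtrip(self, tmp_path):
        cfg = SimConfig(seed=22, geno=GenotypeParams(n_pops=3, n_individuals=4,
                                                     n_loci=30, n_adaptive_loci=5))
        gm, _ = gen_genotypes(cfg)
        path = tmp_path / "g.vcf"
        write_vcf(gm, path)
        popmap = pd.DataFrame({"id": gm.individuals,
                               "population": gm.populations,
                               "species": gm.species})
        back = read_vcf(path, popmap)
        assert back.individuals == gm.individuals
        assert np.array_equal(np.isnan(back.genotypes), np.isnan(gm.genotypes))
        m = ~np.isnan(gm.genotypes)
        assert np.array_equal(back.genotypes[m], gm.genotypes[m])
        assert np.allclose(back.mean_depth, np.round(gm.mean_depth, 2))
        assert np.array_equal(back.populations, gm.populations)

    def test_matrix_csv_roundtrip(self, tmp_path):
        cfg = SimConfig(seed=23, geno=GenotypeParams(n_pops=2, n_individuals=3,
                                                     n_loci=12, n_adaptive_loci=0))
        gm, _ = gen_genotypes(cfg)
        path = tmp_path / "g.csv"
        write_matrix_csv(gm, path)
        back = read_matrix_csv(path, mean_depth=gm.mean_depth)
        m = ~np.isnan(gm.genotypes)
        assert np.array_equal(back.genotypes[m], gm.genotypes[m])
        assert list(back.populations) == list(gm.populations)
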