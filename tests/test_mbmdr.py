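"""MB-MDR: H/L/O categorization, max-Wald statistic, permutation p-values."""
from itertools import combinations

import numpy as np
import pytest
import statsmodels.api as sm
from scipy.stats import chi2

import snpepi as sp
from snpepi.data import MISSING
from snpepi.mbmdr import PairEngine

from conftest import build_dataset


def _null_dataset(seed=0, n=600, m=4, maf=0.35):
    rng = np.random.default_rng(seed)
    g = rng.binomial(2, maf, size=(n, m)).astype(np.int8)
    y = np.r_[np.ones(n // 2, dtype=int), np.zeros(n - n // 2, dtype=int)]
    return build_dataset(g, y)


def closed_form_2x2_wald(a, b, c, d):
    """Wald chi-square of the saturated 2x2 logistic fit:
    (cases in, controls in, cases out, controls out)."""
    beta = np.log(a * d / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return beta, (beta / se) ** 2


class TestCategorize:
    def test_nine_labels_three_categories(self):
        cat = sp.mbmdr_categorize(_null_dataset(), ("rs1", "rs2"))
        assert cat.labels.shape == (3, 3)
        assert set(np.unique(cat.labels)) <= {"H", "L", "O"}
        assert len(cat.label_string()) == 9

    def test_null_data_all_neutral(self):
        # with a stringent per-cell alpha no cell passes beyond chance
        cat = sp.mbmdr_categorize(_null_dataset(seed=5, n=2000), ("rs1", "rs2"), alpha_cell=0.001)
        assert cat.all_neutral

    def test_small_cell_forced_neutral(self):
        ds = _null_dataset(seed=1, maf=0.15)
        cat = sp.mbmdr_categorize(ds, ("rs1", "rs2"), min_cell=10)
        n_cell = cat.cell_n
        assert all(cat.labels.ravel()[k] == "O" for k in range(9) if n_cell.ravel()[k] < 10)

    def test_planted_high_risk_cell_labelled_high(self):
        """A planted high-risk genotype combination (the minor/minor double
        homozygote) is labelled H in the majority of seeded replicates."""
        cells = np.zeros((3, 3))
        cells[2, 2] = 2.0
        model = sp.PenetranceModel(epistatic_pair=(0, 1), epistatic_cells=cells)
        mafs = np.full(3, 0.45)
        hits = 0
        for seed in range(11):
            cfg = sp.SimConfig(mafs=mafs, n_cases=800, n_controls=800, model=model, seed=seed)
            ds = sp.simulate_case_control(cfg)
            cat = sp.mbmdr_categorize(ds, ("snp0001", "snp0002"))
            hits += cat.labels[2, 2] == "H"
        assert hits > 5

    def test_cell_walds_match_closed_form(self):
        """Unadjusted cell tests equal the closed-form 2x2 logistic Wald."""
        rng = np.random.default_rng(3)
        for seed in range(20):
            ds = _null_dataset(seed=seed, n=500)
            eng = PairEngine(
                ds, ("rs1", "rs2"), (), adjust_marginal=False, alpha_cell=1.0, min_cell=0
            )
            labels, betas, _ = eng.categorize_batch(eng.y)
            y = eng.y
            for c in range(9):
                in_cell = eng.cells == c
                a = int(y[in_cell].sum())
                b_ = int((1 - y[in_cell]).sum())
                cc = int(y[~in_cell].sum())
                d = int((1 - y[~in_cell]).sum())
                if min(a, b_, cc, d) == 0:
                    continue
                beta, _ = closed_form_2x2_wald(a, b_, cc, d)
                assert betas[0, c] == pytest.approx(beta, abs=1e-6)

    def test_cell_walds_match_statsmodels_with_covariates(self):
        """Adjusted cell Wald statistics match an independent IRLS fit (statsmodels)."""
        rng = np.random.default_rng(7)
        n = 400
        ds = _null_dataset(seed=2, n=n)
        sex = np.where(rng.random(n) < 0.7, "female", "male")
        ds.samples["sex"] = sex
        eng = PairEngine(
            ds, ("rs1", "rs2"), ("sex",), adjust_marginal=True, alpha_cell=1.0, min_cell=5
        )
        labels, betas, pvals = eng.categorize_batch(eng.y)
        g1 = ds.genotypes[:, 0].astype(float)
        g2 = ds.genotypes[:, 1].astype(float)
        y = ds.samples["phenotype"].to_numpy()
        for c in eng._testable_cells():
            ind = (eng.cells == c).astype(float)
            X = np.column_stack([np.ones(n), g1, g2, (sex == "male").astype(float), ind])
            fit = sm.Logit(y, X).fit(disp=0)
            assert betas[0, c] == pytest.approx(fit.params[-1], abs=1e-6)
            w2 = (fit.params[-1] / fit.bse[-1]) ** 2
            assert chi2.sf(w2, 1) == pytest.approx(pvals[0, c], abs=1e-6)


class TestStatistic:
    def test_all_neutral_is_na(self):
        ds = _null_dataset(seed=5, n=2000)
        cat = sp.mbmdr_categorize(ds, ("rs1", "rs2"), alpha_cell=0.001)
        assert cat.all_neutral
        W = sp.mbmdr_statistic(ds, cat)
        assert np.isnan(W)
        res = sp.mbmdr_permutation_p(ds, ("rs1", "rs2"), B=9, seed=0, alpha_cell=0.001)
        assert res.na and res.perm_p is None

    def test_single_h_cell_equals_2x2_wald_oracle(self):
        ds = _null_dataset(seed=8, n=500)
        cat = sp.mbmdr_categorize(ds, ("rs1", "rs2"), adjust_marginal=False, alpha_cell=1e-9)
        labels = np.full((3, 3), "O")
        labels[1, 1] = "H"
        from dataclasses import replace

        forced = replace(cat, labels=labels)
        W = sp.mbmdr_statistic(ds, forced, adjust_marginal=False)
        y = ds.samples["phenotype"].to_numpy()
        in_cell = (ds.genotypes[:, 0] == 1) & (ds.genotypes[:, 1] == 1)
        a = y[in_cell].sum()
        b = (1 - y[in_cell]).sum()
        c = y[~in_cell].sum()
        d = (1 - y[~in_cell]).sum()
        _, w2 = closed_form_2x2_wald(a, b, c, d)
        assert W == pytest.approx(w2, abs=1e-6)

    def test_null_w_small_for_fixed_phenotype_independent_membership(self):
        """With a fixed H set independent of phenotype, W behaves like a
        single 1-df Wald statistic: its median stays near the chi2(1) median."""
        labels = np.full((3, 3), "O")
        labels[0, 0] = "H"  # a well-populated, phenotype-independent H set
        Ws = []
        for seed in range(60):
            ds = _null_dataset(seed=100 + seed, n=400)
            eng = PairEngine(ds, ("rs1", "rs2"), (), adjust_marginal=False, min_cell=5)
            W = eng.fixed_label_statistic(labels)[0]
            if np.isfinite(W):
                Ws.append(W)
        med = np.median(Ws)
        assert med < chi2.ppf(0.75, 1)
        assert abs(med - chi2.ppf(0.5, 1)) < 0.45


def independent_mbmdr_oracle(g1, g2, y, alpha_cell, min_cell):
    """Naive loop reimplementation of categorization + max-Wald statistic."""
    cells = g1 * 3 + g2
    labels = {}
    for c in range(9):
        m = cells == c
        nc = m.sum()
        if nc < max(min_cell, 1) or nc == len(y):
            labels[c] = "O"
            continue
        a, b = y[m].sum(), (1 - y[m]).sum()
        cc, d = y[~m].sum(), (1 - y[~m]).sum()
        if min(a, b, cc, d) == 0:
            labels[c] = "O"
            continue
        beta, w2 = closed_form_2x2_wald(a, b, cc, d)
        p = chi2.sf(w2, 1)
        labels[c] = "H" if (p < alpha_cell and beta > 0) else ("L" if p < alpha_cell else "O")
    W = -np.inf
    found = False
    for code in ("H", "L"):
        member = np.isin(cells, [c for c in range(9) if labels[c] == code])
        if not member.any():
            continue
        found = True
        if member.all():
            continue
        a, b = y[member].sum(), (1 - y[member]).sum()
        cc, d = y[~member].sum(), (1 - y[~member]).sum()
        if min(a, b, cc, d) == 0:
            continue
        _, w2 = closed_form_2x2_wald(a, b, cc, d)
        W = max(W, w2)
    if not found or not np.isfinite(W):
        return np.nan
    return W


class TestPermutation:
    def test_floor_of_add_one_estimator(self):
        # a planted effect so strong the observed W beats all permutations
        mafs = np.full(2, 0.4)
        model = sp.make_pure_epistasis_model((0, 1), 2.5, "checkerboard", mafs)
        cfg = sp.SimConfig(mafs=mafs, n_cases=400, n_controls=400, model=model, seed=0)
        ds = sp.simulate_case_control(cfg)
        res = sp.mbmdr_permutation_p(ds, ("snp0001", "snp0002"), B=199, seed=1)
        assert res.perm_p == pytest.approx(1 / 200)

    def test_b_zero_rejected(self):
        with pytest.raises(ValueError):
            sp.mbmdr_permutation_p(_null_dataset(), ("rs1", "rs2"), B=0)

    def test_deterministic_given_seed(self):
        ds = _null_dataset(seed=3, n=200)
        a = sp.mbmdr_permutation_p(ds, ("rs1", "rs2"), B=99, seed=5, alpha_cell=0.5, min_cell=3)
        b = sp.mbmdr_permutation_p(ds, ("rs1", "rs2"), B=99, seed=5, alpha_cell=0.5, min_cell=3)
        assert a.perm_p == b.perm_p

    def test_exhaustive_equals_enumeration_oracle(self):
        """On tiny data the permutation p over all distinct phenotype
        assignments equals a naive enumeration oracle exactly."""
        rng = np.random.default_rng(12)
        for trial in range(6):
            n = 8
            g1 = rng.integers(0, 2, n)
            g2 = rng.integers(0, 2, n)
            y = np.array([1, 1, 1, 1, 0, 0, 0, 0])
            ds = build_dataset(np.column_stack([g1, g2]), y)
            res = sp.mbmdr_permutation_p(
                ds, ("rs1", "rs2"), B=1, seed=0, adjust_marginal=False,
                alpha_cell=0.9, min_cell=1, permutations="exhaustive",
            )
            W_obs = independent_mbmdr_oracle(g1, g2, y, 0.9, 1)
            if not np.isfinite(W_obs):
                assert res.perm_p is None
                continue
            count = 0
            total = 0
            for pos in combinations(range(n), int(y.sum())):
                yp = np.zeros(n)
                yp[list(pos)] = 1
                total += 1
                Wp = independent_mbmdr_oracle(g1, g2, yp, 0.9, 1)
                if np.isfinite(Wp) and Wp >= W_obs - 1e-9:
                    count += 1
            assert res.n_permutations == total
            assert res.perm_p == pytest.approx((1 + count) / (total + 1), abs=1e-12)

    def test_perm_p_invariant_to_case_control_relabeling(self):
        rng = np.random.default_rng(9)
        n = 10
        g = np.column_stack([rng.integers(0, 3, n), rng.integers(0, 3, n)])
        y = np.array([1] * 5 + [0] * 5)
        ds = build_dataset(g, y)
        flipped = build_dataset(g, 1 - y)
        kw = dict(B=1, seed=0, adjust_marginal=False, alpha_cell=0.9, min_cell=1,
                  permutations="exhaustive")
        a = sp.mbmdr_permutation_p(ds, ("rs1", "rs2"), **kw)
        b = sp.mbmdr_permutation_p(flipped, ("rs1", "rs2"), **kw)
        assert (a.perm_p is None) == (b.perm_p is None)
        if a.perm_p is not None:
            assert a.perm_p == pytest.approx(b.perm_p, abs=1e-12)
            assert a.statistic_W == pytest.approx(b.statistic_W, abs=1e-9)

    def test_marginal_adjustment_nulls_purely_additive_pairs(self):
        """Additive two-SNP models (no cell offsets) are rejected at ~nominal
        rate when marginal effects are adjusted for."""
        model = sp.PenetranceModel(
            snp_effects={
                0: sp.SnpEffect("log_additive", 0.5),
                1: sp.SnpEffect("log_additive", 0.4),
            }
        )
        rej = 0
        n_rep = 500
        for seed in range(n_rep):
            cfg = sp.SimConfig(
                mafs=np.array([0.3, 0.3]), n_cases=300, n_controls=300,
                model=model, seed=10_000 + seed,
            )
            ds = sp.simulate_case_control(cfg)
            res = sp.mbmdr_permutation_p(
                ds, ("snp0001", "snp0002"), B=99, seed=seed, adjust_marginal=True
            )
            rej += res.perm_p is not None and res.perm_p < 0.05
        assert 0.02 * n_rep <= rej <= 0.08 * n_rep


class TestScan:
    def test_single_pair_list(self):
        ds = _null_dataset(seed=4)
        out = sp.mbmdr_scan(ds, pairs=[("rs1", "rs3")], B_screen=19, seed=0)
        assert len(out) == 1 and out[0].pair == ("rs1", "rs3")

    def test_ranked_by_perm_p_then_w(self):
        ds = _null_dataset(seed=6, n=400, m=6)
        out = sp.mbmdr_scan(ds, B_screen=19, seed=0, alpha_cell=0.4, min_cell=3)
        keys = [
            (r.perm_p if r.perm_p is not None else np.inf,
             -r.statistic_W if np.isfinite(r.statistic_W) else np.inf)
            for r in out
        ]
        assert keys == sorted(keys)

    def test_deterministic(self):
        ds = _null_dataset(seed=6, n=300, m=5)
        a = sp.mbmdr_scan(ds, B_screen=49, seed=3, alpha_cell=0.4, min_cell=3)
        b = sp.mbmdr_scan(ds, B_screen=49, seed=3, alpha_cell=0.4, min_cell=3)
        assert [(r.pair, r.perm_p) for r in a] == [(r.pair, r.perm_p) for r in b]
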