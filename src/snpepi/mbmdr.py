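"""Model-Based Multifactor Dimensionality Reduction (MB-MDR).

For a SNP pair, each of the nine combined genotype cells is tested by a
covariate-adjusted logistic regression of case status on cell membership
(optionally also adjusting for both SNPs' log-additive marginal codings,
which removes purely additive two-SNP signals).  Cells are assigned to
High / Low / neutral (O) risk categories by the sign and significance of
the cell coefficient; the pair's association statistic is

    W = max(W_H, W_L)

where W_H is the squared Wald statistic of the H-membership indicator
(H cells vs all others) in a covariate-adjusted logistic fit, W_L the
analogue for L, and an absent category contributes -inf.  When every cell
is neutral the statistic — and its p-value — are not available (NA).
Significance comes from a permutation test: case/control labels are
permuted (covariates stay attached to samples), categorization and
statistic are recomputed from scratch, and

    perm_p = (1 + #{W_perm >= W_obs}) / (B + 1).

Samples missing either genotype of the pair are excluded for that pair
only.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy.stats import chi2

from ._logistic import logit_wald_grouped
from .assoc import _covariate_matrix
from .data import Dataset, MISSING

__all__ = [
    "RiskCategorization",
    "InteractionResult",
    "mbmdr_categorize",
    "mbmdr_statistic",
    "mbmdr_permutation_p",
    "mbmdr_scan",
]

LABELS = np.array(["O", "H", "L"])  # integer codes 0/1/2
_GROUPED_MAX_PATTERNS = 64  # collapse to binomial form when feasible
_W_TIE_TOL = 1e-9


@dataclass(frozen=True)
class RiskCategorization:
    """The 3x3 High/Low/neutral grid for a SNP pair.

    ``labels`` is a 3x3 array of 'H'/'L'/'O' in row-major minor-allele-count
    order (rows: first SNP's genotype).  ``cell_sign``, ``cell_p`` and
    ``cell_n`` record the per-cell logistic tests.  ``provenance`` is
    ``"discovery"`` for a fresh categorization and ``"fixed"`` once it is
    forced onto another series.  ``alleles`` freezes each SNP's
    (major, minor) coding so a stage mismatch can be detected.
    """

    pair: tuple[str, str]
    labels: np.ndarray
    cell_sign: np.ndarray
    cell_p: np.ndarray
    cell_n: np.ndarray
    provenance: str = "discovery"
    alleles: tuple[tuple[str, str], tuple[str, str]] | None = None

    def __post_init__(self):
        lab = np.asarray(self.labels, dtype="U1")
        if lab.shape != (3, 3) or not np.isin(lab, LABELS).all():
            raise ValueError("labels must be a 3x3 grid of H/L/O")
        object.__setattr__(self, "labels", lab)

    @property
    def all_neutral(self) -> bool:
        return bool((self.labels == "O").all())

    def label_string(self) -> str:
        """9-character H/L/O string, row-major."""
        return "".join(self.labels.ravel())

    def as_fixed(self) -> "RiskCategorization":
        return replace(self, provenance="fixed")


@dataclass(frozen=True)
class InteractionResult:
    """A SNP pair's MB-MDR association result at one analysis stage."""

    pair: tuple[str, str]
    statistic_W: float  # NaN when not available (all cells neutral)
    perm_p: float | None
    n_permutations: int
    categorization: RiskCategorization | None
    stage: str = "discovery"
    detectors_flagging: frozenset[str] = field(default_factory=frozenset)
    n_used: int = 0

    @property
    def na(self) -> bool:
        return not np.isfinite(self.statistic_W)

    @property
    def replicated(self) -> bool:
        return self.perm_p is not None and self.perm_p < 0.05


# ---------------------------------------------------------------------------
# engine
# ---------------------------------------------------------------------------

def covariate_cache(dataset: Dataset, covariates: Sequence[str]):
    """Precompute covariate columns + discrete-pattern codes for a dataset.

    Returns ``(C, bad_mask, pattern, n_patterns)``; ``n_patterns`` is None
    when the covariates are not all discrete (per-sample fits needed).
    Shared across the pair engines of a scan.
    """
    cov = _covariate_matrix(dataset.samples, covariates)
    C = cov.to_numpy(dtype=float) if cov.shape[1] else np.empty((len(cov), 0))
    bad = np.isnan(C).any(axis=1) if C.shape[1] else np.zeros(len(cov), dtype=bool)
    pattern = np.zeros(len(cov), dtype=np.int64)
    n_patterns = 1
    for k in range(C.shape[1]):
        vals, inv = np.unique(C[:, k], return_inverse=True)
        if vals.size > _GROUPED_MAX_PATTERNS:
            return C, bad, None, None  # continuous covariate
        pattern = pattern * vals.size + inv
        n_patterns *= vals.size
        if n_patterns > _GROUPED_MAX_PATTERNS:
            return C, bad, None, None
    return C, bad, pattern, n_patterns


class PairEngine:
    """Vectorised MB-MDR computations for one SNP pair.

    Evaluates categorization and the max-Wald statistic for batches of
    phenotype vectors (the observed one plus permutations).  When every
    design column is constant on a modest number of sample groups (no
    continuous covariates), fits collapse exactly to grouped-binomial
    likelihoods; otherwise per-sample fits are used.
    """

    def __init__(
        self,
        dataset: Dataset,
        pair: tuple[str, str],
        covariates: Sequence[str] = (),
        adjust_marginal: bool = True,
        alpha_cell: float = 0.1,
        min_cell: int = 10,
        _cov_cache=None,
    ):
        a, b = pair
        i, j = dataset.snp_index(a), dataset.snp_index(b)
        if i == j:
            raise ValueError("pair must be two distinct SNPs")
        self.pair = (a, b)
        self.alpha_cell = float(alpha_cell)
        self.min_cell = int(min_cell)
        self.adjust_marginal = bool(adjust_marginal)
        g1 = dataset.genotypes[:, i]
        g2 = dataset.genotypes[:, j]
        if _cov_cache is None:
            _cov_cache = covariate_cache(dataset, covariates)
        C, cov_bad, pattern, n_patterns = _cov_cache
        valid = (g1 != MISSING) & (g2 != MISSING) & ~cov_bad
        self.valid = valid
        self.y = dataset.samples["phenotype"].to_numpy(dtype=np.float64)[valid]
        self.n = int(valid.sum())
        cells = (g1[valid].astype(np.int64) * 3 + g2[valid]).astype(np.int64)
        self.cells = cells
        self.cell_n = np.bincount(cells, minlength=9)
        info = dataset.snps.iloc[[i, j]]
        self.alleles = tuple(
            (str(r["allele_major"]), str(r["allele_minor"])) for _, r in info.iterrows()
        )
        cols = [np.ones(self.n)]
        if self.adjust_marginal:
            cols.append(g1[valid].astype(float))
            cols.append(g2[valid].astype(float))
        if C.shape[1]:
            cols.append(C[valid])
        Xbase = np.column_stack(cols)  # intercept + marginal codings + covariates

        # grouped reformulation when the base design + cell id has few patterns
        if n_patterns is not None and 9 * n_patterns <= 9 * _GROUPED_MAX_PATTERNS:
            code = cells * n_patterns + pattern[valid]
            uniq_codes, first, gid = np.unique(code, return_index=True, return_inverse=True)
            G = uniq_codes.size
            self.grouped = True
            self.group_id = gid.astype(np.intp)
            self.n_trials = np.bincount(self.group_id, minlength=G).astype(np.float64)
            self.Xbase_u = Xbase[first]
            self.group_cell = cells[first]
            self._onehot = np.zeros((self.n, G))
            self._onehot[np.arange(self.n), self.group_id] = 1.0
        else:
            self.grouped = False
            self.group_id = np.arange(self.n, dtype=np.intp)
            self.n_trials = np.ones(self.n)
            self.Xbase_u = Xbase
            self.group_cell = cells
            self._onehot = None

    # -- helpers ---------------------------------------------------------
    def _successes(self, Y: np.ndarray) -> np.ndarray:
        """Per-group case counts for each phenotype vector in the batch."""
        if self._onehot is None:
            return Y
        return Y @ self._onehot

    def _testable_cells(self) -> list[int]:
        return [
            c for c in range(9)
            if self.cell_n[c] >= max(self.min_cell, 1) and self.cell_n[c] < self.n
        ]

    def categorize_batch(self, Y: np.ndarray):
        """Labels (B, 9) int8 (0=O, 1=H, 2=L) + per-cell (beta, p) for B batches."""
        K = self._successes(np.atleast_2d(Y))
        B = K.shape[0]
        labels = np.zeros((B, 9), dtype=np.int8)
        betas = np.full((B, 9), np.nan)
        pvals = np.full((B, 9), np.nan)
        cs = self._testable_cells()
        if not cs:
            return labels, betas, pvals
        G, p_base = self.Xbase_u.shape
        if B == 1 and self.grouped:
            # one var-X batch over the testable cells instead of 9 tiny fits
            Xb = np.empty((len(cs), G, p_base + 1))
            Xb[:, :, :-1] = self.Xbase_u
            for k, c in enumerate(cs):
                Xb[k, :, -1] = self.group_cell == c
            fit = logit_wald_grouped(Xb, self.n_trials, np.repeat(K, len(cs), axis=0), test_col=-1)
            beta_mat = fit.beta[None, :]
            w2_mat = fit.wald_sq[None, :]
            ok_mat = fit.converged[None, :]
        else:
            beta_mat = np.empty((B, len(cs)))
            w2_mat = np.empty((B, len(cs)))
            ok_mat = np.empty((B, len(cs)), dtype=bool)
            for k, c in enumerate(cs):
                ind = (self.group_cell == c).astype(float)
                Xu = np.column_stack([self.Xbase_u, ind])
                fit = logit_wald_grouped(Xu, self.n_trials, K, test_col=-1)
                beta_mat[:, k] = fit.beta
                w2_mat[:, k] = fit.wald_sq
                ok_mat[:, k] = fit.converged
        with np.errstate(invalid="ignore"):
            p_mat = chi2.sf(w2_mat, 1)
        ok_mat = ok_mat & np.isfinite(p_mat)
        sig = ok_mat & (p_mat < self.alpha_cell)
        lab = np.where(sig & (beta_mat > 0), 1, np.where(sig & (beta_mat < 0), 2, 0))
        labels[:, cs] = lab
        betas[:, cs] = np.where(ok_mat, beta_mat, np.nan)
        pvals[:, cs] = np.where(ok_mat, p_mat, np.nan)
        return labels, betas, pvals

    def statistic_batch(self, Y: np.ndarray, labels: np.ndarray) -> np.ndarray:
        """W = max(W_H, W_L) per batch; NaN when all cells are neutral."""
        K = self._successes(np.atleast_2d(Y))
        B = K.shape[0]
        W = np.full(B, -np.inf)
        any_label = np.zeros(B, dtype=bool)
        for code in (1, 2):  # H then L
            member = labels[:, self.group_cell] == code  # (B, G)
            has = member.any(axis=1)
            any_label |= has
            cnt = member @ self.n_trials
            usable = has & (cnt < self.n)
            if not usable.any():
                continue
            idx = np.flatnonzero(usable)
            Xb = np.empty((idx.size, self.Xbase_u.shape[0], self.Xbase_u.shape[1] + 1))
            Xb[:, :, :-1] = self.Xbase_u
            Xb[:, :, -1] = member[idx]
            fit = logit_wald_grouped(Xb, self.n_trials, K[idx], test_col=-1)
            w2 = np.where(fit.converged & np.isfinite(fit.wald_sq), fit.wald_sq, -np.inf)
            W[idx] = np.maximum(W[idx], w2)
        W = np.where(any_label, W, np.nan)  # all-neutral -> NA
        W = np.where(np.isfinite(W) | np.isnan(W), W, np.nan)  # both components degenerate -> NA
        return W

    def run_batch(self, Y: np.ndarray) -> np.ndarray:
        labels, _, _ = self.categorize_batch(Y)
        return self.statistic_batch(Y, labels)

    def observed(self):
        labels, betas, pvals = self.categorize_batch(self.y)
        W = self.statistic_batch(self.y, labels)
        cat = RiskCategorization(
            pair=self.pair,
            labels=LABELS[labels[0]].reshape(3, 3),
            cell_sign=np.sign(np.nan_to_num(betas[0])).reshape(3, 3),
            cell_p=pvals[0].reshape(3, 3),
            cell_n=self.cell_n.reshape(3, 3),
            alleles=self.alleles,
        )
        return cat, float(W[0])

    def fixed_label_statistic(self, labels_grid: np.ndarray, Y: np.ndarray | None = None) -> np.ndarray:
        """W under a *fixed* H/L/O grid (no re-categorization)."""
        codes = np.select(
            [np.asarray(labels_grid) == "H", np.asarray(labels_grid) == "L"], [1, 2], 0
        ).reshape(-1)
        Y = self.y if Y is None else Y
        B = np.atleast_2d(Y).shape[0]
        labels = np.broadcast_to(codes.astype(np.int8), (B, 9))
        return self.statistic_batch(Y, labels)

    def permutations(self, B: int, rng: np.random.Generator, chunk: int | None = None):
        """Yield chunks of permuted phenotype vectors (B total)."""
        if chunk is None:
            chunk = 2048 if self.grouped else 128  # per-sample fits carry (B, n, p) designs
        left = B
        while left > 0:
            b = min(chunk, left)
            Y = np.tile(self.y, (b, 1))
            Y = rng.permuted(Y, axis=1)
            yield Y
            left -= b

    def exhaustive_phenotypes(self) -> np.ndarray:
        """All distinct case-position assignments (tiny n only)."""
        n_case = int(self.y.sum())
        combos = list(combinations(range(self.n), n_case))
        Y = np.zeros((len(combos), self.n))
        for r, pos in enumerate(combos):
            Y[r, list(pos)] = 1.0
        return Y


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def mbmdr_categorize(
    dataset: Dataset,
    pair: tuple[str, str],
    covariates: Sequence[str] = (),
    adjust_marginal: bool = True,
    alpha_cell: float = 0.1,
    min_cell: int = 10,
) -> RiskCategorization:
    """Assign the pair's nine genotype cells to H / L / O risk categories.

    Each cell is tested by logistic regression of case status on the
    cell-membership indicator plus covariates (plus both SNPs' log-additive
    codings when ``adjust_marginal``): H for a significantly positive
    coefficient at ``alpha_cell``, L for negative, O otherwise.  Cells with
    fewer than ``min_cell`` samples, or whose test does not converge, are O.
    """
    eng = PairEngine(dataset, pair, covariates, adjust_marginal, alpha_cell, min_cell)
    cat, _ = eng.observed()
    return cat


def mbmdr_statistic(
    dataset: Dataset,
    categorization: RiskCategorization,
    covariates: Sequence[str] = (),
    adjust_marginal: bool = True,
    min_cell: int = 10,
) -> float:
    """max-Wald statistic W for a given categorization (NaN if all O)."""
    eng = PairEngine(
        dataset, categorization.pair, covariates, adjust_marginal, min_cell=min_cell
    )
    return float(eng.fixed_label_statistic(categorization.labels)[0])


def _perm_pvalue(engine: PairEngine, W_obs: float, B: int, rng, fixed_labels=None) -> float:
    count = 0
    for Y in engine.permutations(B, rng):
        if fixed_labels is None:
            Wp = engine.run_batch(Y)
        else:
            Wp = engine.fixed_label_statistic(fixed_labels, Y)
        Wp = np.where(np.isnan(Wp), -np.inf, Wp)
        count += int(np.sum(Wp >= W_obs - _W_TIE_TOL))
    return (1 + count) / (B + 1)


def mbmdr_permutation_p(
    dataset: Dataset,
    pair: tuple[str, str],
    covariates: Sequence[str] = (),
    B: int = 999,
    seed: int | None = None,
    adjust_marginal: bool = True,
    alpha_cell: float = 0.1,
    min_cell: int = 10,
    permutations: str = "random",
) -> InteractionResult:
    """MB-MDR permutation test for one SNP pair.

    The observed W comes from a fresh categorization; each permutation
    shuffles case/control labels (covariates stay attached to samples) and
    recomputes categorization and statistic from scratch.
    ``permutations="exhaustive"`` enumerates every distinct case
    assignment instead (tiny datasets), with B set accordingly.
    """
    if B < 1 and permutations == "random":
        raise ValueError("B must be >= 1")
    eng = PairEngine(dataset, pair, covariates, adjust_marginal, alpha_cell, min_cell)
    cat, W_obs = eng.observed()
    if not np.isfinite(W_obs):
        return InteractionResult(
            pair=eng.pair, statistic_W=np.nan, perm_p=None, n_permutations=0,
            categorization=cat, n_used=eng.n,
        )
    if permutations == "exhaustive":
        Y = eng.exhaustive_phenotypes()
        Wp = eng.run_batch(Y)
        B = Y.shape[0]
        Wp = np.where(np.isnan(Wp), -np.inf, Wp)
        count = int(np.sum(Wp >= W_obs - _W_TIE_TOL))
        p = (1 + count) / (B + 1)
    else:
        rng = np.random.default_rng(seed)
        p = _perm_pvalue(eng, W_obs, B, rng)
    return InteractionResult(
        pair=eng.pair, statistic_W=W_obs, perm_p=p, n_permutations=B,
        categorization=cat, n_used=eng.n,
    )


def mbmdr_scan(
    dataset: Dataset,
    pairs: Sequence[tuple[str, str]] | None = None,
    covariates: Sequence[str] = (),
    B_screen: int = 999,
    seed: int | None = None,
    adjust_marginal: bool = True,
    alpha_cell: float = 0.1,
    min_cell: int = 10,
    screen_quantile: float = 0.95,
) -> list[InteractionResult]:
    """Two-tier MB-MDR scan over SNP pairs.

    Tier 1 computes the observed W for every pair; tier 2 estimates
    permutation p-values at ``B_screen`` only for pairs whose W reaches the
    ``screen_quantile`` of the observed W distribution (all pairs when 20
    or fewer are scanned).  Ranked by permutation p, then W.  Deterministic
    given ``seed``.
    """
    snp_ids = list(dataset.snps["snp_id"])
    if pairs is None:
        pairs = [(snp_ids[i], snp_ids[j]) for i, j in combinations(range(len(snp_ids)), 2)]
    cache = covariate_cache(dataset, covariates)
    engines = []
    observed = []
    for pr in pairs:
        eng = PairEngine(
            dataset, pr, covariates, adjust_marginal, alpha_cell, min_cell, _cov_cache=cache
        )
        cat, W = eng.observed()
        engines.append(eng)
        observed.append((cat, W))
    Ws = np.array([w for _, w in observed])
    finite = np.isfinite(Ws)
    if len(pairs) <= 20:
        screen = finite
    else:
        thresh = np.quantile(Ws[finite], screen_quantile) if finite.any() else np.inf
        screen = finite & (Ws >= thresh)
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(len(pairs))
    results = []
    for k, (eng, (cat, W)) in enumerate(zip(engines, observed)):
        if screen[k]:
            rng = np.random.default_rng(child_seeds[k])
            p = _perm_pvalue(eng, W, B_screen, rng)
            res = InteractionResult(
                pair=eng.pair, statistic_W=W, perm_p=p, n_permutations=B_screen,
                categorization=cat, n_used=eng.n,
            )
        else:
            res = InteractionResult(
                pair=eng.pair, statistic_W=W, perm_p=None, n_permutations=0,
                categorization=cat, n_used=eng.n,
            )
        results.append(res)

    def rank_key(r: InteractionResult):
        p = r.perm_p if r.perm_p is not None else np.inf
        w = -r.statistic_W if np.isfinite(r.statistic_W) else np.inf
        return (p, w, r.pair)

    results.sort(key=rank_key)
    return results
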