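"""Classic Multifactor Dimensionality Reduction (MDR) for two-way scans.

Each two-SNP genotype cell is labelled high- or low-risk by its training
case:control ratio against a threshold T (the training case:control
ratio), collapsing the 3x3 grid to a binary classifier whose balanced
accuracy is estimated by stratified k-fold cross-validation.  Pairs are
ranked by mean testing balanced accuracy; cross-validation consistency
(CVC) counts the folds in which a pair was the best model.  MDR is
covariate-naive by construction.

The scan flag used by the consensus rule (CVC >= cvc_min and mean test BA
above the 95th percentile of a seeded permutation null of the top
statistic) is a declared, configurable convention.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

from .data import Dataset, MISSING

__all__ = ["MdrResult", "mdr_label_cells", "mdr_balanced_accuracy", "mdr_scan", "mdr_flagged_pairs"]


@dataclass(frozen=True)
class MdrResult:
    pair: tuple[str, str]
    grid_labels: np.ndarray  # 3x3 bool, True = high risk (full-data labelling)
    train_ba: float
    test_ba: float
    cvc: int
    threshold_T: float


def mdr_label_cells(cell_counts: np.ndarray, T: float) -> np.ndarray:
    """Label each 3x3 cell high (True) or low (False) risk.

    ``cell_counts`` is 3x3x2 of (cases, controls).  A cell is high when
    cases/controls >= T; controls=0 with cases>0 is high; an empty cell
    (0, 0) is low.
    """
    if T <= 0:
        raise ValueError("T must be positive")
    counts = np.asarray(cell_counts, dtype=float)
    if counts.shape != (3, 3, 2):
        raise ValueError("cell_counts must be 3x3x2 (cases, controls)")
    if (counts < 0).any():
        raise ValueError("negative cell counts")
    cases, controls = counts[..., 0], counts[..., 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        high = cases >= T * controls
    high &= ~((cases == 0) & (controls == 0))
    return high


def _pair_cells(dataset: Dataset, i: int, j: int) -> np.ndarray:
    """9-cell index per sample (row-major minor-allele counts), -1 = missing."""
    g1 = dataset.genotypes[:, i]
    g2 = dataset.genotypes[:, j]
    cells = g1.astype(np.int16) * 3 + g2
    cells[(g1 == MISSING) | (g2 == MISSING)] = -1
    return cells


def mdr_balanced_accuracy(grid_labels: np.ndarray, pair_genotypes: np.ndarray, phenotype: np.ndarray) -> float:
    """Balanced accuracy of a 3x3 high/low labelling on per-sample data.

    ``pair_genotypes``: (n, 2) genotype counts (MISSING allowed; excluded).
    high cells predict case.  BA = (sensitivity + specificity)/2.
    """
    g = np.asarray(pair_genotypes)
    y = np.asarray(phenotype)
    ok = (g[:, 0] != MISSING) & (g[:, 1] != MISSING)
    g, y = g[ok], y[ok]
    if (y == 1).sum() == 0 or (y == 0).sum() == 0:
        raise ValueError("evaluation split needs both cases and controls")
    pred = np.asarray(grid_labels, dtype=bool)[g[:, 0], g[:, 1]]
    sens = pred[y == 1].mean()
    spec = (~pred[y == 0]).mean()
    return float((sens + spec) / 2.0)


def _ba_from_counts(high: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Vectorised BA over pairs: ``high`` (P,9) bool, ``counts`` (P,9,2)."""
    cases = counts[..., 0]
    controls = counts[..., 1]
    tot_cases = cases.sum(axis=1)
    tot_controls = controls.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        sens = (cases * high).sum(axis=1) / tot_cases
        spec = (controls * ~high).sum(axis=1) / tot_controls
    return (sens + spec) / 2.0


def _stratified_folds(y: np.ndarray, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    fold = np.empty(y.size, dtype=np.int32)
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        fold[idx] = np.arange(idx.size) % n_folds
    return fold


def _flat_index(cells: np.ndarray) -> np.ndarray:
    """Flattened (cell, pair) index for fast bincount tabulation."""
    n, P = cells.shape
    c = np.where(cells < 0, 9, cells).astype(np.int64)  # slot 9 = missing
    return c * P + np.arange(P, dtype=np.int64)


def _tabulate_flat(flat: np.ndarray, y: np.ndarray, P: int) -> np.ndarray:
    """Counts (P, 9, 2)=(cases, controls) from a flat index matrix (n, P)."""
    w_case = np.repeat(y.astype(np.float64), P)
    idx = flat.ravel()
    cases = np.bincount(idx, weights=w_case, minlength=10 * P).reshape(10, P).T
    totals = np.bincount(idx, minlength=10 * P).reshape(10, P).T
    return np.stack([cases[:, :9], totals[:, :9] - cases[:, :9]], axis=-1)


def _tabulate(cells: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Counts (P, 9, 2) from cell indices (n, P) and phenotype (n,)."""
    return _tabulate_flat(_flat_index(cells), y, cells.shape[1])


def _scan_stats(cells: np.ndarray, y: np.ndarray, fold: np.ndarray, n_folds: int, flat=None):
    """Mean train/test BA per pair + per-fold best pair, for one phenotype."""
    P = cells.shape[1]
    if flat is None:
        flat = _flat_index(cells)
    total = _tabulate_flat(flat, y, P)
    train_ba = np.zeros(P)
    test_ba = np.zeros(P)
    best_per_fold = np.empty(n_folds, dtype=np.int64)
    for f in range(n_folds):
        te = fold == f
        counts_te = _tabulate_flat(flat[te], y[te], P)
        counts_tr = total - counts_te
        # per-pair training case/control totals (missing excluded per pair)
        tot_cases_tr = counts_tr[..., 0].sum(axis=1).astype(float)
        tot_ctrl_tr = counts_tr[..., 1].sum(axis=1).astype(float)
        T = tot_cases_tr / np.maximum(tot_ctrl_tr, 1.0)
        cases_tr = counts_tr[..., 0]
        ctrl_tr = counts_tr[..., 1]
        high = cases_tr >= T[:, None] * ctrl_tr
        high &= ~((cases_tr == 0) & (ctrl_tr == 0))
        tr = _ba_from_counts(high, counts_tr)
        te_ba = _ba_from_counts(high, counts_te)
        tr = np.nan_to_num(tr, nan=0.0)
        te_ba = np.nan_to_num(te_ba, nan=0.5)
        train_ba += tr
        test_ba += te_ba
        best_per_fold[f] = int(np.argmax(tr))  # argmax takes first (lexicographic) on ties
    return train_ba / n_folds, test_ba / n_folds, best_per_fold


def mdr_scan(
    dataset: Dataset,
    pairs: Sequence[tuple[str, str]] | None = None,
    n_folds: int = 10,
    seed: int | None = None,
) -> list[MdrResult]:
    """Exhaustive (or listed) two-way MDR scan with stratified k-fold CV.

    Within each training fold T is the fold's case:control ratio; the best
    pair per fold (by training BA, lexicographic tie-break) accrues CVC.
    Output is ranked by mean testing BA.  Deterministic given ``seed``.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    y = dataset.samples["phenotype"].to_numpy()
    if min((y == 1).sum(), (y == 0).sum()) < n_folds:
        raise ValueError("fewer cases or controls than folds")
    snp_ids = list(dataset.snps["snp_id"])
    if pairs is None:
        idx_pairs = list(combinations(range(len(snp_ids)), 2))
    else:
        idx_pairs = [tuple(sorted((dataset.snp_index(a), dataset.snp_index(b)))) for a, b in pairs]
    rng = np.random.default_rng(seed)
    fold = _stratified_folds(y, n_folds, rng)
    cells = np.column_stack([_pair_cells(dataset, i, j) for i, j in idx_pairs])
    train_ba, test_ba, best_per_fold = _scan_stats(cells, y, fold, n_folds)
    cvc = np.bincount(best_per_fold, minlength=len(idx_pairs))
    # full-data labelling for reporting
    total = _tabulate(cells, y)
    results = []
    for p, (i, j) in enumerate(idx_pairs):
        tot_cases = total[p, :, 0].sum()
        tot_ctrl = total[p, :, 1].sum()
        T = tot_cases / max(tot_ctrl, 1)
        labels = mdr_label_cells(total[p].reshape(3, 3, 2), T)
        results.append(
            MdrResult(
                pair=(snp_ids[i], snp_ids[j]),
                grid_labels=labels,
                train_ba=float(train_ba[p]),
                test_ba=float(test_ba[p]),
                cvc=int(cvc[p]),
                threshold_T=float(T),
            )
        )
    results.sort(key=lambda r: (-r.test_ba, r.pair))
    return results


def mdr_flagged_pairs(
    dataset: Dataset,
    pairs: Sequence[tuple[str, str]] | None = None,
    n_folds: int = 10,
    seed: int | None = None,
    n_perm: int = 100,
    cvc_min: int = 6,
) -> tuple[set[tuple[str, str]], float, list[MdrResult]]:
    """MDR flag for the consensus rule.

    A pair is flagged when CVC >= ``cvc_min`` and its mean test BA exceeds
    the 95th percentile of the permutation null of the *top* mean test BA
    (phenotype permuted, full CV scan re-run, ``n_perm`` times).  Returns
    (flagged pairs, null 95th percentile, full ranked scan).
    """
    results = mdr_scan(dataset, pairs, n_folds=n_folds, seed=seed)
    y = dataset.samples["phenotype"].to_numpy()
    snp_index = {s: k for k, s in enumerate(dataset.snps["snp_id"])}
    idx_pairs = [tuple(sorted((snp_index[a], snp_index[b]))) for a, b in (r.pair for r in results)]
    cells = np.column_stack([_pair_cells(dataset, i, j) for i, j in idx_pairs])
    flat = _flat_index(cells)
    rng = np.random.default_rng(seed)
    top_null = np.empty(n_perm)
    for b in range(n_perm):
        yp = rng.permutation(y)
        fold_p = _stratified_folds(yp, n_folds, rng)
        _, te, _ = _scan_stats(cells, yp, fold_p, n_folds, flat=flat)
        top_null[b] = te.max()
    thresh = float(np.quantile(top_null, 0.95))
    flagged = {
        tuple(sorted(r.pair)) for r in results if r.cvc >= cvc_min and r.test_ba > thresh
    }
    return flagged, thresh, results
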