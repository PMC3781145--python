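"""Per-SNP case-control association.

Covers the classic single-marker workflow for a candidate-gene panel:

* exact Hardy-Weinberg test in controls (conditional on allele counts);
* unconditional logistic regression of case status on a genetic coding of
  the genotype (dominant / recessive / log-additive / codominant), with
  homozygotes of the most frequent control allele as reference and
  age / sex / country adjustment; odds ratios with Wald 95% CIs;
* best-model selection by minimum AIC over dominant / recessive /
  log-additive (ties broken in that fixed order) — note the resulting
  p-value is *post-selection* and is labelled accordingly;
* a likelihood-ratio test for heterogeneity of the per-allele OR across
  disease subtypes, via a polytomous (multinomial) logistic model with the
  genotype coefficient either free per subtype or shared.

Missing genotypes/covariates are handled complete-case per test.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.special import gammaln
from scipy.stats import chi2, norm

from .data import CASE_GROUPS, Dataset, MISSING, stratify

__all__ = [
    "AssociationResult",
    "hwe_exact_test",
    "hwe_controls",
    "fit_genetic_model",
    "select_best_model",
    "heterogeneity_lr_test",
    "association_table",
]

GENETIC_MODELS = ("codominant", "dominant", "recessive", "log_additive")
_SELECTION_ORDER = ("dominant", "recessive", "log_additive")


class FitError(RuntimeError):
    """Logistic fit failed: non-convergence, separation or degenerate data."""


@dataclass(frozen=True)
class AssociationResult:
    """One SNP's association fit under one genetic model."""

    snp_id: str
    model: str
    or_point: float
    ci95: tuple[float, float]
    wald_p: float
    covariates_used: tuple[str, ...]
    n_used: int
    aic: float
    log_or: float
    se: float
    case_group: str = "all"
    #: True when the model was chosen by AIC: the p-value is then
    #: post-selection ("model-selected p") and anti-conservative under the null.
    model_selected: bool = False
    #: codominant fits additionally carry the heterozygote OR here.
    or_het: float | None = None

    @property
    def p_label(self) -> str:
        return "model-selected p" if self.model_selected else "Wald p"


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_het_distribution(n_minor: int, n_major: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact distribution of the heterozygote count given allele counts.

    Returns ``(het_values, probabilities)`` for all heterozygote counts
    compatible with ``n_minor`` minor and ``n_major`` major alleles in
    ``(n_minor + n_major)/2`` diploid individuals.
    """
    n = (n_minor + n_major) // 2
    hets = np.arange(n_minor % 2, min(n_minor, n_major) + 1, 2)
    n_hom_min = (n_minor - hets) // 2
    n_hom_maj = (n_major - hets) // 2
    logp = (
        gammaln(n + 1)
        - gammaln(n_hom_min + 1)
        - gammaln(hets + 1)
        - gammaln(n_hom_maj + 1)
        + hets * np.log(2.0)
        + gammaln(n_minor + 1)
        + gammaln(n_major + 1)
        - gammaln(2 * n + 1)
    )
    p = np.exp(logp - logp.max())
    return hets, p / p.sum()


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact Hardy-Weinberg test p-value for one SNP's genotype counts.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote configurations no more probable than the observed one
    (relative tie tolerance 1e-12).
    """
    for c in (n_AA, n_Aa, n_aa):
        if c < 0:
            raise ValueError("genotype counts must be nonnegative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("empty genotype table")
    n_a = 2 * n_aa + n_Aa
    n_A = 2 * n_AA + n_Aa
    hets, probs = hwe_het_distribution(n_a, n_A)
    p_obs = probs[hets == n_Aa][0]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def hwe_controls(dataset: Dataset) -> pd.DataFrame:
    """HWE exact test in controls for every SNP (panel QC table)."""
    ctrl = dataset.genotypes[dataset.is_control]
    rows = []
    for j, snp_id in enumerate(dataset.snps["snp_id"]):
        g = ctrl[:, j]
        g = g[g != MISSING]
        counts = np.bincount(g, minlength=3)
        p = hwe_exact_test(int(counts[0]), int(counts[1]), int(counts[2])) if g.size else np.nan
        rows.append((snp_id, int(counts[0]), int(counts[1]), int(counts[2]), p))
    return pd.DataFrame(rows, columns=["snp_id", "n_ref_hom", "n_het", "n_alt_hom", "hwe_p"])


# ---------------------------------------------------------------------------
# logistic fits
# ---------------------------------------------------------------------------

def _covariate_matrix(samples: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    cols = {}
    for cov in covariates:
        if cov == "age":
            cols["age"] = pd.to_numeric(samples["age"], errors="coerce")
        elif cov in ("sex", "gender"):
            cols["sex_male"] = (samples["sex"] == "male").astype(float)
        elif cov in samples.columns:
            vals = samples[cov].astype(str)
            levels = sorted(vals.unique())
            for lev in levels[1:]:
                cols[f"{cov}_{lev}"] = (vals == lev).astype(float)
        else:
            raise ValueError(f"unknown covariate {cov!r}")
    return pd.DataFrame(cols, index=samples.index)


def _code_genotype(g: np.ndarray, model: str) -> np.ndarray:
    if model == "dominant":
        return (g >= 1).astype(float)[:, None]
    if model == "recessive":
        return (g == 2).astype(float)[:, None]
    if model == "log_additive":
        return g.astype(float)[:, None]
    if model == "codominant":
        return np.column_stack([(g == 1).astype(float), (g == 2).astype(float)])
    raise ValueError(f"unknown genetic model {model!r}")


def _design(dataset: Dataset, snp_id: str, model: str, covariates: Sequence[str], case_group):
    ds = dataset if case_group in (None, "all") else stratify(dataset, case_group)
    g = ds.genotype_column(snp_id)
    cov = _covariate_matrix(ds.samples, covariates)
    keep = (g != MISSING) & ~cov.isna().any(axis=1).to_numpy()
    g = g[keep]
    if np.unique(g).size < 2:
        raise FitError(f"{snp_id}: monomorphic in the analysis subset")
    y = ds.samples["phenotype"].to_numpy(dtype=float)[keep]
    coded = _code_genotype(g, model)
    geno_names = ["geno_het", "geno_hom"] if model == "codominant" else ["geno"]
    X = np.column_stack([np.ones(g.size), coded, cov.to_numpy(dtype=float)[keep]])
    names = ["const"] + geno_names + list(cov.columns)
    if np.unique(coded[:, -1]).size < 2:
        raise FitError(f"{snp_id}: coded genotype has no variation under {model}")
    return y, X, names, geno_names


def fit_genetic_model(
    dataset: Dataset,
    snp_id: str,
    model: str = "log_additive",
    covariates: Sequence[str] = (),
    case_group=None,
    _selected: bool = False,
) -> AssociationResult:
    """Maximum-likelihood logistic fit of case status on a coded genotype.

    OR = exp(coefficient); 95% CI = exp(coefficient +/- 1.96 SE); p-value
    from the Wald statistic.  Separation and non-convergence raise
    :class:`FitError` rather than reporting a spurious finite OR.
    """
    y, X, names, geno_names = _design(dataset, snp_id, model, covariates, case_group)
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, X).fit(disp=0, method="newton", maxiter=100)
    except Exception as exc:  # PerfectSeparationError and kin
        raise FitError(f"{snp_id}: logistic fit failed ({exc})") from exc
    if not fit.mle_retvals.get("converged", False):
        raise FitError(f"{snp_id}: logistic fit did not converge")
    params = pd.Series(fit.params, index=names)
    bse = pd.Series(fit.bse, index=names)
    if np.abs(params[geno_names]).max() > 15 or not np.isfinite(bse[geno_names]).all():
        raise FitError(f"{snp_id}: separation (unbounded genotype coefficient)")
    key = geno_names[-1]  # homozygote term for codominant, the single term otherwise
    b, se = float(params[key]), float(bse[key])
    z = b / se
    res = AssociationResult(
        snp_id=snp_id,
        model=model,
        or_point=float(np.exp(b)),
        ci95=(float(np.exp(b - 1.96 * se)), float(np.exp(b + 1.96 * se))),
        wald_p=float(2 * norm.sf(abs(z))),
        covariates_used=tuple(covariates),
        n_used=int(y.size),
        aic=float(fit.aic),
        log_or=b,
        se=se,
        case_group=str(case_group) if case_group is not None else "all",
        model_selected=_selected,
        or_het=float(np.exp(params["geno_het"])) if model == "codominant" else None,
    )
    return res


def select_best_model(
    dataset: Dataset,
    snp_id: str,
    covariates: Sequence[str] = (),
    case_group=None,
) -> AssociationResult:
    """Best-fitting genetic model by minimum AIC.

    Fits dominant, recessive and log-additive; returns the minimum-AIC fit,
    ties broken in that fixed order.  The returned result is flagged
    ``model_selected`` — its p-value is post-selection and must be read as
    a "model-selected p", not a calibrated single-test p-value.
    """
    best: AssociationResult | None = None
    errors = []
    for model in _SELECTION_ORDER:
        try:
            res = fit_genetic_model(dataset, snp_id, model, covariates, case_group, _selected=True)
        except FitError as exc:
            errors.append(str(exc))
            continue
        if best is None or res.aic < best.aic - 1e-12:
            best = res
    if best is None:
        raise FitError(f"{snp_id}: no genetic model could be fitted ({'; '.join(errors)})")
    return best


# ---------------------------------------------------------------------------
# subtype heterogeneity (polytomous logistic LR test)
# ---------------------------------------------------------------------------

def _mnl_negloglik(theta, Z, g, y_cat, k, q, shared):
    """Multinomial logit over {control, subtype_1..k}; genotype coefficient
    per category (shared=False) or tied across categories (shared=True)."""
    A = theta[: k * q].reshape(k, q)
    beta = theta[k * q:]
    eta = Z @ A.T + (g[:, None] * (beta if not shared else beta[0]))
    m = np.maximum(0.0, eta.max(axis=1))
    lse = m + np.log(np.exp(-m) + np.exp(eta - m[:, None]).sum(axis=1))
    pick = np.where(y_cat > 0, eta[np.arange(len(y_cat)), np.maximum(y_cat - 1, 0)], 0.0)
    ll = pick.sum() - lse.sum()
    # gradient
    P = np.exp(eta - lse[:, None])  # (n, k) category probabilities
    Yk = np.zeros_like(P)
    rows = np.flatnonzero(y_cat > 0)
    Yk[rows, y_cat[rows] - 1] = 1.0
    R = Yk - P
    gA = (R.T @ Z).reshape(-1)
    if shared:
        gb = np.array([(R * g[:, None]).sum()])
    else:
        gb = (R * g[:, None]).sum(axis=0)
    return -ll, -np.concatenate([gA, gb])


def _fit_mnl(Z, g, y_cat, k, shared):
    q = Z.shape[1]
    n_beta = 1 if shared else k
    theta0 = np.zeros(k * q + n_beta)
    out = minimize(
        _mnl_negloglik,
        theta0,
        args=(Z, g, y_cat, k, q, shared),
        jac=True,
        method="BFGS",
        options={"maxiter": 500, "gtol": 1e-8},
    )
    if not np.isfinite(out.fun):
        raise FitError("multinomial fit did not converge")
    return -out.fun


def heterogeneity_lr_test(
    dataset: Dataset,
    snp_id: str,
    covariates: Sequence[str] = (),
    subtypes: Sequence[str] | None = None,
) -> float:
    """LR test for heterogeneity of the per-allele OR across case subtypes.

    Fits a polytomous logistic model over {control, subtype_1, ...} with a
    per-allele (allele count) genotype coding; the statistic is twice the
    log-likelihood gap between subtype-specific and shared genotype
    coefficients, referred to chi-square with k-1 df for k subtypes.
    """
    sub = dataset.samples["subtype"]
    if subtypes is None:
        subtypes = [s for s in sub.unique() if s != "control"]
    subtypes = list(subtypes)
    if len(subtypes) < 2:
        raise ValueError("need at least two case subtypes")
    counts = {s: int((sub == s).sum()) for s in subtypes}
    empty = [s for s, c in counts.items() if c == 0]
    if empty:
        raise ValueError(f"subtypes with zero cases: {empty}")
    keep_sub = sub.isin(["control"] + subtypes).to_numpy()
    g = dataset.genotype_column(snp_id)
    cov = _covariate_matrix(dataset.samples, covariates)
    keep = keep_sub & (g != MISSING) & ~cov.isna().any(axis=1).to_numpy()
    g_used = g[keep].astype(float)
    if np.unique(g_used).size < 2:
        raise FitError(f"{snp_id}: monomorphic in the analysis subset")
    cat = np.zeros(int(keep.sum()), dtype=int)
    for idx, s in enumerate(subtypes, start=1):
        cat[(sub[keep] == s).to_numpy()] = idx
    Z = np.column_stack([np.ones(g_used.size), cov.to_numpy(dtype=float)[keep]])
    k = len(subtypes)
    ll_full = _fit_mnl(Z, g_used, cat, k, shared=False)
    ll_red = _fit_mnl(Z, g_used, cat, k, shared=True)
    lr = max(0.0, 2.0 * (ll_full - ll_red))
    return float(chi2.sf(lr, df=k - 1))


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def association_table(
    dataset: Dataset,
    snp_ids: Iterable[str] | None = None,
    covariates: Sequence[str] = ("age", "sex"),
    case_group=None,
    model: str = "auto",
) -> pd.DataFrame:
    """Per-SNP association summary (one row per SNP).

    ``model="auto"`` performs AIC best-model selection per SNP; a named
    model fits that coding for every SNP.  SNPs whose fit fails are
    reported with NA results and the error message.
    """
    from .data import minor_allele_freq

    if snp_ids is None:
        snp_ids = list(dataset.snps["snp_id"])
    rows = []
    for snp_id in snp_ids:
        info = dataset.snps.set_index("snp_id").loc[snp_id]
        try:
            if model == "auto":
                res = select_best_model(dataset, snp_id, covariates, case_group)
            else:
                res = fit_genetic_model(dataset, snp_id, model, covariates, case_group)
            row = {
                "snp_id": snp_id,
                "gene": info["gene"],
                "model": res.model,
                "OR": res.or_point,
                "ci_low": res.ci95[0],
                "ci_high": res.ci95[1],
                "p": res.wald_p,
                "p_label": res.p_label,
                "n_used": res.n_used,
                "error": "",
            }
        except (FitError, ValueError) as exc:
            row = {
                "snp_id": snp_id, "gene": info["gene"], "model": "", "OR": np.nan,
                "ci_low": np.nan, "ci_high": np.nan, "p": np.nan, "p_label": "",
                "n_used": 0, "error": str(exc),
            }
        try:
            row["maf_controls"] = minor_allele_freq(dataset, snp_id, "controls")
            row["maf_cases"] = minor_allele_freq(dataset, snp_id, "cases")
        except ValueError:
            row["maf_controls"] = row["maf_cases"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
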