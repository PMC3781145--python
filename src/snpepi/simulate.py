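"""Synthetic case-control genotype data with controllable epistasis.

The generator emulates the statistical structure the analysis assumes:
independent biallelic SNPs in Hardy-Weinberg equilibrium, a logistic
penetrance on per-SNP genetic codings plus an optional 3x3 grid of cell
log-odds offsets for one designated SNP pair, covariates (age, sex,
country), and exact case/control ascertainment by rejection sampling.
Defaults mirror a thyroid-cancer candidate-gene study design: a discovery
series of 609 cases / 525 controls and a replication series of 969 cases /
1040 controls, case subtypes cPTC / fvPTC / otherPTC / FTC, mean age 47,
~4.5:1 female:male ratio.

"Pure epistasis" models have their 3x3 offsets balanced against the HWE
cell weights so that each single SNP's marginal penetrance — hence its
marginal odds ratio — is exactly 1: the pair is only detectable jointly.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq, fsolve
from scipy.special import expit

from .data import CASE_SUBTYPES, Dataset, MISSING, SAMPLE_COLUMNS

__all__ = [
    "SnpEffect",
    "PenetranceModel",
    "SimConfig",
    "simulate_genotypes",
    "make_pure_epistasis_model",
    "simulate_case_control",
    "hwe_cell_weights",
]

_CODINGS = ("dominant", "recessive", "log_additive")


@dataclass(frozen=True)
class SnpEffect:
    """Marginal effect of one SNP: genetic coding + log odds ratio."""

    coding: str
    log_or: float

    def __post_init__(self):
        if self.coding not in _CODINGS:
            raise ValueError(f"coding must be one of {_CODINGS}")

    def code(self, g: np.ndarray) -> np.ndarray:
        if self.coding == "dominant":
            return (g >= 1).astype(float)
        if self.coding == "recessive":
            return (g == 2).astype(float)
        return g.astype(float)


@dataclass(frozen=True)
class PenetranceModel:
    """Logistic disease model: baseline + marginal SNP effects + optional
    3x3 epistatic cell offsets for one SNP pair + covariate effects.

    ``covariate_effects`` keys: ``age`` (log-OR per year, centred at 47),
    ``male`` (log-OR vs female), ``country:<level>`` (log-OR vs first level).
    """

    baseline_logit: float = -2.5
    snp_effects: Mapping[int, SnpEffect] = field(default_factory=dict)
    epistatic_pair: tuple[int, int] | None = None
    epistatic_cells: np.ndarray | None = None  # 3x3 log-OR offsets
    covariate_effects: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if (self.epistatic_pair is None) != (self.epistatic_cells is None):
            raise ValueError("epistatic_pair and epistatic_cells go together")
        if self.epistatic_pair is not None:
            i, j = self.epistatic_pair
            if i == j:
                raise ValueError("epistatic pair must be two distinct SNPs")
            cells = np.asarray(self.epistatic_cells, dtype=float)
            if cells.shape != (3, 3) or not np.isfinite(cells).all():
                raise ValueError("epistatic_cells must be a finite 3x3 grid")
            object.__setattr__(self, "epistatic_cells", cells)

    def linear_predictor(self, genotypes: np.ndarray, covariates: pd.DataFrame | None = None) -> np.ndarray:
        lp = np.full(genotypes.shape[0], self.baseline_logit, dtype=float)
        for j, eff in self.snp_effects.items():
            lp += eff.log_or * eff.code(genotypes[:, j])
        if self.epistatic_pair is not None:
            i, j = self.epistatic_pair
            lp += self.epistatic_cells[genotypes[:, i], genotypes[:, j]]
        if covariates is not None:
            for key, b in self.covariate_effects.items():
                if key == "age":
                    lp += b * (covariates["age"].to_numpy(dtype=float) - 47.0)
                elif key == "male":
                    lp += b * (covariates["sex"] == "male").to_numpy(dtype=float)
                elif key.startswith("country:"):
                    lp += b * (covariates["country"] == key.split(":", 1)[1]).to_numpy(dtype=float)
                else:
                    raise ValueError(f"unknown covariate effect {key!r}")
        return lp

    def penetrance(self, genotypes: np.ndarray, covariates: pd.DataFrame | None = None) -> np.ndarray:
        return expit(self.linear_predictor(genotypes, covariates))


@dataclass(frozen=True)
class SimConfig:
    """Full description of one simulated case-control series.

    ``model`` may be a single :class:`PenetranceModel` or a mapping from
    case subtype to model (subtype-specific effects); controls are then
    drawn as non-diseased under ``control_model`` (default: the model of
    the first subtype).
    """

    mafs: np.ndarray
    n_cases: int = 609
    n_controls: int = 525
    case_subtype_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            # discovery-series-like mix; otherPTC absorbs cases outside the
            # named subtypes so the proportions close to 1
            "cPTC": 304 / 609,
            "fvPTC": 146 / 609,
            "otherPTC": 90 / 609,
            "FTC": 69 / 609,
        }
    )
    model: PenetranceModel | Mapping[str, PenetranceModel] = field(default_factory=PenetranceModel)
    control_model: PenetranceModel | None = None
    missing_rate: float = 0.0
    seed: int = 0
    age_mean: float = 47.0
    age_sd: float = 12.0
    age_range: tuple[float, float] = (18.0, 90.0)
    p_female: float = 0.82
    country_levels: tuple[str, ...] = ("ES", "IT")
    country_probs: tuple[float, ...] = (1.0, 0.0)
    max_draws: int = 50_000_000
    snp_ids: tuple[str, ...] | None = None
    genes: tuple[str, ...] | None = None

    def __post_init__(self):
        mafs = np.asarray(self.mafs, dtype=float)
        if ((mafs < 0) | (mafs > 0.5)).any():
            raise ValueError("MAFs must lie in [0, 0.5]")
        object.__setattr__(self, "mafs", mafs)
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        mix = dict(self.case_subtype_mix)
        if abs(sum(mix.values()) - 1.0) > 1e-8:
            raise ValueError("case_subtype_mix proportions must sum to 1")
        for s in mix:
            if s not in CASE_SUBTYPES:
                raise ValueError(f"unknown case subtype {s!r}")


def hwe_cell_weights(maf1: float, maf2: float) -> np.ndarray:
    """HWE probabilities of the 9 two-SNP genotype cells (3x3)."""
    def gfreq(p):
        return np.array([(1 - p) ** 2, 2 * p * (1 - p), p ** 2])

    return np.outer(gfreq(maf1), gfreq(maf2))


def simulate_genotypes(mafs, n: int, seed=None) -> np.ndarray:
    """HWE genotypes for independent SNPs: Binomial(2, MAF) per SNP."""
    mafs = np.asarray(mafs, dtype=float)
    if ((mafs < 0) | (mafs > 0.5)).any():
        raise ValueError("MAFs must lie in [0, 0.5]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.binomial(2, mafs, size=(n, mafs.size)).astype(np.int8)


def make_pure_epistasis_model(
    pair: tuple[int, int],
    cell_log_or: float,
    pattern: str,
    mafs,
    baseline_logit: float = -2.5,
    **model_kwargs,
) -> PenetranceModel:
    """Two-SNP interaction model with exactly null marginal effects.

    ``pattern="corner"`` elevates the corner block of the 3x3 grid where
    both SNPs carry at least one minor allele (a dominant x dominant
    interaction whose extreme cell is the minor/minor double homozygote);
    ``"checkerboard"`` alternates the sign cell by cell (an XOR-type model).
    Row/column offsets are solved numerically so that, under HWE cell
    weights at the given MAFs, the penetrance averaged over either SNP's
    genotype classes is constant — i.e. both marginal odds ratios equal 1
    in the source population.

    ``cell_log_or`` is the *realized* high-vs-low cell contrast of the
    final balanced grid: for the checkerboard the offsets are exactly
    +/- ``cell_log_or`` by symmetry, and the corner pattern is normalised
    so its high-risk block sits ``cell_log_or`` above the low-risk cross
    cells (one minor-allele-carrying SNP) after balancing.
    """
    i, j = pair
    if i == j:
        raise ValueError("pair must be two distinct SNPs")
    if not np.isfinite(cell_log_or):
        raise ValueError("cell_log_or must be finite")
    mafs = np.asarray(mafs, dtype=float)
    p1, p2 = float(mafs[i]), float(mafs[j])
    if pattern == "corner":
        base_pattern = np.zeros((3, 3))
        base_pattern[1:, 1:] = 1.0
    elif pattern == "checkerboard":
        g = np.arange(3)
        base_pattern = ((-1.0) ** (g[:, None] + g[None, :])).astype(float)
    else:
        raise ValueError("pattern must be 'corner' or 'checkerboard'")

    w = hwe_cell_weights(p1, p2)
    w1 = w.sum(axis=1)  # genotype weights SNP1
    w2 = w.sum(axis=0)

    def balanced_cells(scale: float) -> np.ndarray:
        if scale == 0.0:
            return np.zeros((3, 3))

        def cells_from(base, x):
            a = np.array([0.0, x[0], x[1]])
            b = np.array([0.0, x[2], x[3]])
            return base + a[:, None] + b[None, :]

        def residual(x, base):
            pen = expit(baseline_logit + cells_from(base, x))
            # marginal penetrance per genotype class of each SNP
            m1 = (pen * w).sum(axis=1) / w1
            m2 = (pen * w).sum(axis=0) / w2
            return [m1[1] - m1[0], m1[2] - m1[0], m2[1] - m2[0], m2[2] - m2[0]]

        # continuation in the scale keeps fsolve on track for strong effects
        x = np.zeros(4)
        n_steps = max(1, int(np.ceil(abs(scale))))
        for s in np.linspace(scale / n_steps, scale, n_steps):
            base = s * base_pattern
            x, info, ier, msg = fsolve(residual, x, args=(base,), full_output=True)
            if ier != 1 or np.max(np.abs(residual(x, base))) > 1e-10:
                raise ValueError(
                    f"marginal equalization infeasible for cell_log_or={cell_log_or}: {msg}"
                )
        return cells_from(scale * base_pattern, x)

    if cell_log_or == 0.0:
        cells = np.zeros((3, 3))
    elif pattern == "checkerboard":
        cells = balanced_cells(cell_log_or)
    else:
        # normalise the corner block so the realized block-vs-cross contrast
        # equals cell_log_or after balancing
        def contrast(scale):
            c = balanced_cells(scale)
            return (c[1, 1] - c[1, 0]) - cell_log_or

        # realized contrast is ~scale/2, monotone in scale: expand the
        # bracket from a near-target guess until it straddles the root
        hi = 2.0 * cell_log_or
        for _ in range(6):
            try:
                if contrast(0.0) * contrast(hi) <= 0:
                    break
            except ValueError:
                raise ValueError(
                    f"marginal equalization infeasible for cell_log_or={cell_log_or}"
                ) from None
            hi *= 1.5
        else:
            raise ValueError(
                f"marginal equalization infeasible for cell_log_or={cell_log_or}"
            )
        lo, hi = sorted((0.0, hi))
        scale = brentq(contrast, lo, hi, xtol=1e-12)
        cells = balanced_cells(scale)
    return PenetranceModel(
        baseline_logit=baseline_logit,
        epistatic_pair=(i, j),
        epistatic_cells=cells,
        **model_kwargs,
    )


# ---------------------------------------------------------------------------
# case-control ascertainment
# ---------------------------------------------------------------------------

def _draw_covariates(cfg: SimConfig, n: int, rng: np.random.Generator) -> pd.DataFrame:
    lo, hi = cfg.age_range
    age = rng.normal(cfg.age_mean, cfg.age_sd, size=n)
    # truncate by redrawing out-of-range values
    for _ in range(100):
        bad = (age < lo) | (age > hi)
        if not bad.any():
            break
        age[bad] = rng.normal(cfg.age_mean, cfg.age_sd, size=int(bad.sum()))
    age = np.clip(age, lo, hi)
    sex = np.where(rng.random(n) < cfg.p_female, "female", "male")
    country = rng.choice(cfg.country_levels, size=n, p=np.asarray(cfg.country_probs))
    return pd.DataFrame({"age": np.round(age, 1), "sex": sex, "country": country})


def _collect(cfg, model, want_cases: int, want_controls: int, rng):
    """Rejection-sample until the requested case/control counts are met."""
    got_g, got_cov, got_y = [], [], []
    n_cases = n_controls = 0
    drawn = 0
    batch = max(1024, 4 * (want_cases + want_controls))
    while n_cases < want_cases or n_controls < want_controls:
        if drawn > cfg.max_draws:
            raise RuntimeError(
                f"exceeded max_draws={cfg.max_draws}; disease prevalence too extreme "
                "for the requested case/control counts"
            )
        g = simulate_genotypes(cfg.mafs, batch, rng)
        cov = _draw_covariates(cfg, batch, rng)
        y = (rng.random(batch) < model.penetrance(g, cov)).astype(np.int8)
        drawn += batch
        need_case = want_cases - n_cases
        need_ctrl = want_controls - n_controls
        case_idx = np.flatnonzero(y == 1)[:need_case]
        ctrl_idx = np.flatnonzero(y == 0)[:need_ctrl]
        keep = np.concatenate([case_idx, ctrl_idx])
        got_g.append(g[keep])
        got_cov.append(cov.iloc[keep])
        got_y.append(y[keep])
        n_cases += case_idx.size
        n_controls += ctrl_idx.size
    return np.vstack(got_g), pd.concat(got_cov, ignore_index=True), np.concatenate(got_y)


def simulate_case_control(config: SimConfig) -> Dataset:
    """Simulate one case-control series to exact sample counts.

    Individuals are drawn from the population model (HWE genotypes +
    covariates), disease status sampled from the logistic penetrance, and
    sampling continues until exactly ``n_cases`` cases and ``n_controls``
    controls are collected.  With a single penetrance model, subtypes are
    assigned to cases at random by ``case_subtype_mix``; with a per-subtype
    model mapping, each subtype's cases are drawn under its own model.
    Genotype missingness is applied uniformly at random.  Fully
    reproducible from ``config.seed``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    mix_subtypes = list(cfg.case_subtype_mix.keys())
    mix_p = np.array([cfg.case_subtype_mix[s] for s in mix_subtypes], dtype=float)

    if isinstance(cfg.model, PenetranceModel):
        g, cov, y = _collect(cfg, cfg.model, cfg.n_cases, cfg.n_controls, rng)
        subtype = np.where(y == 1, "", "control").astype(object)
        case_rows = np.flatnonzero(y == 1)
        subtype[case_rows] = rng.choice(mix_subtypes, size=case_rows.size, p=mix_p)
    else:
        models = dict(cfg.model)
        unknown = set(models) - set(mix_subtypes)
        if unknown:
            raise ValueError(f"models given for subtypes outside the mix: {unknown}")
        # per-subtype case quotas (largest remainder)
        raw = mix_p * cfg.n_cases
        quota = np.floor(raw).astype(int)
        for k in np.argsort(-(raw - quota))[: cfg.n_cases - quota.sum()]:
            quota[k] += 1
        control_model = cfg.control_model or models.get(mix_subtypes[0]) or next(iter(models.values()))
        parts_g, parts_cov, parts_y, parts_sub = [], [], [], []
        for s, q in zip(mix_subtypes, quota):
            if q == 0:
                continue
            m = models.get(s, control_model)
            gg, cc, _ = _collect(cfg, m, q, 0, rng)
            parts_g.append(gg)
            parts_cov.append(cc)
            parts_y.append(np.ones(q, dtype=np.int8))
            parts_sub.append(np.full(q, s, dtype=object))
        gg, cc, _ = _collect(cfg, control_model, 0, cfg.n_controls, rng)
        parts_g.append(gg)
        parts_cov.append(cc)
        parts_y.append(np.zeros(cfg.n_controls, dtype=np.int8))
        parts_sub.append(np.full(cfg.n_controls, "control", dtype=object))
        g = np.vstack(parts_g)
        cov = pd.concat(parts_cov, ignore_index=True)
        y = np.concatenate(parts_y)
        subtype = np.concatenate(parts_sub)

    # shuffle sample order so stages/subtypes are interleaved
    order = rng.permutation(g.shape[0])
    g, y, subtype = g[order], y[order], subtype[order]
    cov = cov.iloc[order].reset_index(drop=True)

    if cfg.missing_rate > 0:
        mask = rng.random(g.shape) < cfg.missing_rate
        g = np.where(mask, MISSING, g).astype(np.int8)

    n = g.shape[0]
    m = cfg.mafs.size
    snp_ids = list(cfg.snp_ids) if cfg.snp_ids else [f"snp{j+1:04d}" for j in range(m)]
    genes = list(cfg.genes) if cfg.genes else [f"G{j // 8 + 1:03d}" for j in range(m)]
    samples = pd.DataFrame(
        {
            "sample_id": [f"ind{i+1:05d}" for i in range(n)],
            "phenotype": y.astype(int),
            "subtype": subtype,
            "age": cov["age"].to_numpy(),
            "sex": cov["sex"].to_numpy(),
            "country": cov["country"].to_numpy(),
        }
    )
    snps = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "gene": genes,
            "allele_major": "G",
            "allele_minor": "A",
            "functional_note": None,
        }
    )
    return Dataset(g, samples[SAMPLE_COLUMNS], snps)
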