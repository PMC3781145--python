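"""Two-stage discovery/replication orchestration.

Stage 1 (discovery) runs multiple interaction detectors — built-in MDR and
MB-MDR plus any plugged-in callables — per case group, and selects for
replication only the SNP pairs flagged by at least ``k_required``
detectors (the consensus rule).  Stage 2 (replication) *forces* each
selected pair's discovery H/L/O risk grid onto an independent series: no
re-categorization, only the max-Wald statistic and its permutation p are
recomputed, and a pair is replicated when that p < 0.05 (a single
pre-specified test per pair, so no multiplicity correction is applied; the
number of pairs tested is always reported).  Replicated pairs get a
combined-stage analysis: both series pooled with a series indicator added
to the covariates, fresh categorization, and a large permutation budget.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np

from .data import Dataset, concat_datasets, stratify
from .mbmdr import (
    InteractionResult,
    PairEngine,
    RiskCategorization,
    _perm_pvalue,
    mbmdr_categorize,
    mbmdr_scan,
)
from .mdr import mdr_flagged_pairs
from .simulate import SimConfig, simulate_case_control

__all__ = [
    "ConsensusRecord",
    "StageReport",
    "TwoStageConfig",
    "consensus_select",
    "replicate_interaction",
    "combined_analysis",
    "run_two_stage",
]

log = logging.getLogger("snpepi.pipeline")

Pair = tuple[str, str]
Detector = Callable[[Dataset], set[Pair]]


@dataclass(frozen=True)
class ConsensusRecord:
    pair: Pair
    detectors_flagging: frozenset[str]
    n_flagging: int
    selected: bool


@dataclass
class StageReport:
    """Results of one pipeline stage for one case group."""

    stage: str  # discovery | replication | combined
    case_group: str
    results: list[InteractionResult]
    config: dict
    seed: int | None
    consensus: list[ConsensusRecord] = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def _res(r: InteractionResult):
            return {
                "pair": list(r.pair),
                "W": None if not np.isfinite(r.statistic_W) else float(r.statistic_W),
                "perm_p": r.perm_p,
                "n_permutations": r.n_permutations,
                "labels": r.categorization.label_string() if r.categorization else None,
                "provenance": r.categorization.provenance if r.categorization else None,
                "stage": r.stage,
                "detectors": sorted(r.detectors_flagging),
                "n_used": r.n_used,
            }

        return {
            "stage": self.stage,
            "case_group": self.case_group,
            "seed": self.seed,
            "config": self.config,
            "consensus": [
                {
                    "pair": list(c.pair),
                    "detectors": sorted(c.detectors_flagging),
                    "n_flagging": c.n_flagging,
                    "selected": c.selected,
                }
                for c in self.consensus
            ],
            "results": [_res(r) for r in self.results],
            "extra": self.extra,
        }


def _norm_pair(pair: Pair) -> Pair:
    a, b = pair
    return (a, b) if a <= b else (b, a)


def consensus_select(
    detector_outputs: Mapping[str, Sequence[Pair]], k_required: int
) -> list[ConsensusRecord]:
    """Select SNP pairs flagged by at least ``k_required`` detectors.

    Order-independent: records are returned sorted by (-n_flagging, pair).
    """
    if not detector_outputs:
        raise ValueError("need at least one detector output")
    if k_required < 1:
        raise ValueError("k_required must be >= 1")
    if k_required > len(detector_outputs):
        raise ValueError(
            f"k_required={k_required} exceeds the {len(detector_outputs)} detectors supplied"
        )
    flags: dict[Pair, set[str]] = {}
    for name, pairs in detector_outputs.items():
        for p in pairs:
            flags.setdefault(_norm_pair(tuple(p)), set()).add(name)
    records = [
        ConsensusRecord(
            pair=p,
            detectors_flagging=frozenset(names),
            n_flagging=len(names),
            selected=len(names) >= k_required,
        )
        for p, names in flags.items()
    ]
    records.sort(key=lambda r: (-r.n_flagging, r.pair))
    return records


def replicate_interaction(
    replication_data: Dataset,
    fixed_cat: RiskCategorization,
    covariates: Sequence[str] = (),
    B: int = 999,
    seed: int | None = None,
    adjust_marginal: bool = True,
    min_cell: int = 10,
) -> InteractionResult:
    """Test a discovery categorization on an independent series.

    The discovery H/L/O grid is applied unchanged: each replication sample's
    H/L membership comes from ``fixed_cat``, the max-Wald statistic is
    computed under that fixed grid, and permutations (phenotype only)
    re-use the fixed labels.  Requires a compatible allele coding between
    stages (hard error otherwise).  ``replicated`` on the result means
    perm_p < 0.05.
    """
    eng = PairEngine(
        replication_data, fixed_cat.pair, covariates,
        adjust_marginal=adjust_marginal, min_cell=min_cell,
    )
    if fixed_cat.alleles is not None and eng.alleles != fixed_cat.alleles:
        raise ValueError(
            f"allele coding mismatch between stages for {fixed_cat.pair}: "
            f"{fixed_cat.alleles} vs {eng.alleles}"
        )
    fixed = fixed_cat.as_fixed()
    if fixed.all_neutral:
        return InteractionResult(
            pair=fixed.pair, statistic_W=np.nan, perm_p=None, n_permutations=0,
            categorization=fixed, stage="replication", n_used=eng.n,
        )
    W_obs = float(eng.fixed_label_statistic(fixed.labels)[0])
    if not np.isfinite(W_obs):
        return InteractionResult(
            pair=fixed.pair, statistic_W=np.nan, perm_p=None, n_permutations=0,
            categorization=fixed, stage="replication", n_used=eng.n,
        )
    rng = np.random.default_rng(seed)
    p = _perm_pvalue(eng, W_obs, B, rng, fixed_labels=fixed.labels)
    return InteractionResult(
        pair=fixed.pair, statistic_W=W_obs, perm_p=p, n_permutations=B,
        categorization=fixed, stage="replication", n_used=eng.n,
    )


def combined_analysis(
    datasets: Sequence[Dataset],
    pair: Pair,
    covariates: Sequence[str] = (),
    B_large: int = 9999,
    seed: int | None = None,
    adjust_marginal: bool = True,
    alpha_cell: float = 0.1,
    min_cell: int = 10,
) -> InteractionResult:
    """Pooled both-stages analysis for a replicated pair.

    Series are concatenated with a stage indicator appended to the
    covariates; categorization is re-derived on the pooled data and the
    permutation p uses the large confirmatory budget.
    """
    pooled = concat_datasets(list(datasets))
    covs = list(covariates)
    if "series" not in covs:
        covs.append("series")
    eng = PairEngine(pooled, pair, covs, adjust_marginal, alpha_cell, min_cell)
    cat, W_obs = eng.observed()
    if not np.isfinite(W_obs):
        return InteractionResult(
            pair=eng.pair, statistic_W=np.nan, perm_p=None, n_permutations=0,
            categorization=cat, stage="combined", n_used=eng.n,
        )
    rng = np.random.default_rng(seed)
    p = _perm_pvalue(eng, W_obs, B_large, rng)
    return InteractionResult(
        pair=eng.pair, statistic_W=W_obs, perm_p=p, n_permutations=B_large,
        categorization=cat, stage="combined", n_used=eng.n,
    )


# ---------------------------------------------------------------------------
# end-to-end study
# ---------------------------------------------------------------------------

@dataclass
class TwoStageConfig:
    """Configuration of a full two-stage interaction study.

    ``discovery`` / ``replication`` are Datasets or SimConfigs (simulated on
    demand).  Built-in detectors: ``"mdr"`` and ``"mbmdr"``; additional
    callables (Dataset -> set of pairs) can be plugged in via
    ``extra_detectors``, e.g. to reach a 3-of-5 consensus.
    """

    discovery: Dataset | SimConfig
    replication: Dataset | SimConfig
    case_groups: tuple[str, ...] = ("PTC", "cPTC")
    detectors: tuple[str, ...] = ("mdr", "mbmdr")
    extra_detectors: Mapping[str, Detector] = field(default_factory=dict)
    k_required: int = 2
    covariates_discovery: tuple[str, ...] = ("age", "sex")
    covariates_replication: tuple[str, ...] = ("age", "sex", "country")
    # MDR settings
    mdr_folds: int = 10
    mdr_perms: int = 100
    mdr_cvc_min: int = 6
    # MB-MDR settings
    alpha_cell: float = 0.1
    min_cell: int = 10
    adjust_marginal: bool = True
    B_screen: int = 999
    screen_quantile: float = 0.95
    flag_alpha: float = 0.05
    B_replication: int = 999
    B_combined: int = 9999
    seed: int = 0

    def summary(self) -> dict:
        d = {
            k: v
            for k, v in self.__dict__.items()
            if k not in ("discovery", "replication", "extra_detectors")
            and not isinstance(v, (Dataset, SimConfig))
        }
        d["extra_detectors"] = sorted(self.extra_detectors)
        return d


def _as_dataset(obj: Dataset | SimConfig) -> Dataset:
    return obj if isinstance(obj, Dataset) else simulate_case_control(obj)


def run_two_stage(config: TwoStageConfig) -> dict[str, list[StageReport]]:
    """Execute the full two-stage study; returns StageReports per case group.

    Per case group: discovery scans by every configured detector, consensus
    selection (>= k_required flags), category-forced replication of each
    selected pair on the second series, and a combined pooled analysis for
    each replicated pair.  Deterministic given ``config.seed``.
    """
    all_detectors = list(config.detectors) + sorted(config.extra_detectors)
    if len(set(all_detectors)) != len(all_detectors):
        raise ValueError("duplicate detector names")
    if config.k_required > len(all_detectors):
        raise ValueError(
            f"k_required={config.k_required} exceeds {len(all_detectors)} configured detectors"
        )
    for name in config.detectors:
        if name not in ("mdr", "mbmdr"):
            raise ValueError(f"unknown built-in detector {name!r}")

    discovery = _as_dataset(config.discovery)
    replication = _as_dataset(config.replication)
    rng = np.random.default_rng(config.seed)
    reports: dict[str, list[StageReport]] = {}

    for case_group in config.case_groups:
        log.info("case group %s: discovery scans", case_group)
        disc = stratify(discovery, case_group)
        repl = stratify(replication, case_group)
        seed_mdr, seed_mbmdr, seed_rep, seed_comb = (
            int(rng.integers(2**31 - 1)) for _ in range(4)
        )

        detector_flags: dict[str, set[Pair]] = {}
        mbmdr_results: list[InteractionResult] = []
        if "mdr" in config.detectors:
            flagged, thresh, mdr_results = mdr_flagged_pairs(
                disc, n_folds=config.mdr_folds, seed=seed_mdr,
                n_perm=config.mdr_perms, cvc_min=config.mdr_cvc_min,
            )
            detector_flags["mdr"] = flagged
        if "mbmdr" in config.detectors:
            mbmdr_results = mbmdr_scan(
                disc, covariates=config.covariates_discovery,
                B_screen=config.B_screen, seed=seed_mbmdr,
                adjust_marginal=config.adjust_marginal,
                alpha_cell=config.alpha_cell, min_cell=config.min_cell,
                screen_quantile=config.screen_quantile,
            )
            detector_flags["mbmdr"] = {
                _norm_pair(r.pair)
                for r in mbmdr_results
                if r.perm_p is not None and r.perm_p < config.flag_alpha
            }
        for name, fn in config.extra_detectors.items():
            detector_flags[name] = {_norm_pair(tuple(p)) for p in fn(disc)}

        consensus = consensus_select(detector_flags, config.k_required)
        selected = [c for c in consensus if c.selected]
        by_pair = {_norm_pair(r.pair): r for r in mbmdr_results}

        disc_results = []
        for c in consensus:
            base = by_pair.get(c.pair)
            if base is None:
                # pair flagged by a non-MB-MDR detector only: derive its
                # discovery categorization so replication can force it
                cat = mbmdr_categorize(
                    disc, c.pair, config.covariates_discovery,
                    config.adjust_marginal, config.alpha_cell, config.min_cell,
                )
                base = InteractionResult(
                    pair=c.pair, statistic_W=np.nan, perm_p=None, n_permutations=0,
                    categorization=cat,
                )
            disc_results.append(
                replace(base, detectors_flagging=c.detectors_flagging, stage="discovery")
            )
        disc_report = StageReport(
            stage="discovery", case_group=case_group, results=disc_results,
            config=config.summary(), seed=seed_mbmdr, consensus=consensus,
        )

        log.info("case group %s: %d consensus pairs -> replication", case_group, len(selected))
        rep_results = []
        for c in selected:
            fixed_cat = next(
                r.categorization for r in disc_results if _norm_pair(r.pair) == c.pair
            )
            rep_results.append(
                replicate_interaction(
                    repl, fixed_cat, config.covariates_replication,
                    B=config.B_replication, seed=seed_rep,
                    adjust_marginal=config.adjust_marginal, min_cell=config.min_cell,
                )
            )
        rep_report = StageReport(
            stage="replication", case_group=case_group, results=rep_results,
            config=config.summary(), seed=seed_rep,
            extra={"n_pairs_tested": len(rep_results)},
        )

        comb_results = []
        for r in rep_results:
            if r.replicated:
                comb_results.append(
                    combined_analysis(
                        [stratify(discovery, case_group), stratify(replication, case_group)],
                        r.pair, config.covariates_replication,
                        B_large=config.B_combined, seed=seed_comb,
                        adjust_marginal=config.adjust_marginal,
                        alpha_cell=config.alpha_cell, min_cell=config.min_cell,
                    )
                )
        comb_report = StageReport(
            stage="combined", case_group=case_group, results=comb_results,
            config=config.summary(), seed=seed_comb,
        )
        reports[case_group] = [disc_report, rep_report, comb_report]
    return reports


def summarize_reports(reports: dict[str, list[StageReport]]) -> str:
    """Human-readable multi-stage summary (one line per pair and stage)."""
    lines = []
    for group, stage_reports in reports.items():
        lines.append(f"== case group {group} ==")
        for rep in stage_reports:
            lines.append(f"-- {rep.stage} --")
            if rep.stage == "discovery":
                for c in rep.consensus:
                    mark = "*" if c.selected else " "
                    lines.append(
                        f" {mark} {c.pair[0]} x {c.pair[1]}: flagged by "
                        f"{','.join(sorted(c.detectors_flagging))} ({c.n_flagging})"
                    )
            for r in rep.results:
                w = "NA" if not np.isfinite(r.statistic_W) else f"{r.statistic_W:.3f}"
                p = "NA" if r.perm_p is None else f"{r.perm_p:.5f}"
                lines.append(
                    f"    {r.pair[0]} x {r.pair[1]}: W={w} perm_p={p} (B={r.n_permutations})"
                )
    return "\n".join(lines)
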