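"""Bootstrap uncertainty, Bayes-factor comparisons and model ranking.

The ranking procedure mirrors the challenge rules: a model is *eligible*
when its paired-bootstrap Bayes factor against the TMB baseline exceeds 3;
eligible models whose Bayes factor against the best eligible model is below
3 form the *tie set*; within the tie set, the basal metric from the ICI
arm breaks ties, and every tied model whose tie-break score is
close to the best one is declared a top performer.

The Bayes factor for "model A beats model B" is estimated from paired
bootstrap resamples as the continuity-corrected win odds

    K = (w + 1/2) / (B - w + 1/2),    w = #{i : DSS_A[i] > DSS_B[i]},

with ties split half-and-half and K capped at 2B.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from lifelines import KaplanMeierFitter

from .metrics import ArmBasalMetrics, MetricError, arm_basal_metrics
from .signatures import quantile_threshold
from .trial_data import ModelScore, TrialDataset

logger = logging.getLogger(__name__)

MAX_REDRAWS = 1000


class EvaluationError(ValueError):
    pass


@dataclass
class EvaluationResult:
    """Point estimates plus B bootstrap draws of (bm_ici, bm_ctrl, dss)."""

    model_name: str
    endpoint: str
    point: ArmBasalMetrics
    draws: np.ndarray  # shape (B, 3): columns bm_ici, bm_ctrl, dss
    seed: int
    n_redraws: int = 0

    @property
    def B(self) -> int:
        return self.draws.shape[0]

    @property
    def dss_draws(self) -> np.ndarray:
        return self.draws[:, 2]

    @property
    def bm_ici_draws(self) -> np.ndarray:
        return self.draws[:, 0]

    def summary(self) -> dict:
        q25, q75 = np.percentile(self.dss_draws, [25, 75])
        return {
            "model": self.model_name,
            "endpoint": self.endpoint,
            "bm_ici": self.point.bm_ici,
            "bm_ctrl": self.point.bm_ctrl,
            "dss": self.point.dss,
            "dss_boot_median": float(np.median(self.dss_draws)),
            "dss_boot_q25": float(q25),
            "dss_boot_q75": float(q75),
            "B": self.B,
            "seed": self.seed,
        }


@dataclass
class RankingResult:
    """Challenge ranking: eligible models, tie set, tie-breaks, top performers."""

    endpoint: str
    eligible: list[str]
    tie_set: list[str]
    tie_break_scores: dict[str, float]
    top_performers: list[str]
    k_vs_reference: dict[str, float] = field(default_factory=dict)
    k_vs_best: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not set(self.top_performers) <= set(self.tie_set) <= set(self.eligible):
            raise EvaluationError("ranking sets must nest: top <= tie <= eligible")


def bootstrap_evaluate(dataset: TrialDataset, score: ModelScore, endpoint: str,
                       B: int = 1000, seed: int = 0) -> EvaluationResult:
    """Arm-stratified bootstrap of the basal metrics and DSS.

    Resamples patients with replacement independently within each arm (arm
    sizes preserved, so the DSS arm contrast is not confounded by arm
    imbalance across resamples).  A resample on which a basal metric is
    undefined (no comparable pairs / single class) is redrawn and counted.
    Identical (dataset, score, endpoint, B, seed) give identical draws.
    """
    if B < 100:
        raise EvaluationError("B must be at least 100")
    point = arm_basal_metrics(dataset, score, endpoint)
    clin = dataset.clinical
    arm_indices = {arm: np.flatnonzero((clin["arm"] == arm).to_numpy())
                   for arm in ("ICI", "CHEMO")}
    rng = np.random.default_rng(seed)
    draws = np.empty((B, 3))
    n_redraws = 0
    for b in range(B):
        for _attempt in range(MAX_REDRAWS):
            idx = np.concatenate([rng.choice(ix, size=ix.size, replace=True)
                                  for ix in arm_indices.values()])
            resample = _take_rows(dataset, idx)
            try:
                bm = arm_basal_metrics(resample, _rescore(score, resample), endpoint)
            except MetricError:
                n_redraws += 1
                continue
            draws[b] = (bm.bm_ici, bm.bm_ctrl, bm.dss)
            break
        else:
            raise EvaluationError("could not draw a usable bootstrap resample")
    if n_redraws:
        logger.info("bootstrap: %d degenerate resample(s) redrawn", n_redraws)
    return EvaluationResult(score.model_name, endpoint.upper(), point, draws,
                            seed, n_redraws)


def _take_rows(dataset: TrialDataset, idx: np.ndarray) -> TrialDataset:
    """Row-resampled view of the clinical table (ids deduplicated for validity).

    Bootstrap resamples repeat patients; the repeated rows get suffixed ids
    so the resample still satisfies the dataset invariants, and scores are
    looked up by the original id.
    """
    clin = dataset.clinical.iloc[idx].reset_index(drop=True)
    counts: dict[str, int] = {}
    new_ids = []
    for pid in clin["patient_id"]:
        k = counts.get(pid, 0)
        counts[pid] = k + 1
        new_ids.append(pid if k == 0 else f"{pid}#{k}")
    clin = clin.assign(patient_id=new_ids)
    return TrialDataset(clin, dataset.expression.iloc[:, :0]
                        if not dataset.expression.empty else dataset.expression)


def _rescore(score: ModelScore, resample: TrialDataset) -> ModelScore:
    """Map the original per-patient scores onto a resample's suffixed ids."""
    values = {pid: score.scores[pid.split("#", 1)[0]]
              for pid in resample.patient_ids}
    return ModelScore(score.model_name, score.subchallenge, values, score.direction)


def bayes_factor(draws_a, draws_b) -> float:
    """Paired-bootstrap win odds that A's primary metric beats B's.

    K = (w + 0.5)/(B - w + 0.5) with ties counted 1/2 each; capped at 2B.
    K(x, x) = 1 exactly; K(a, b) * K(b, a) ~= 1 up to the continuity
    correction.
    """
    a = np.asarray(draws_a, dtype=float)
    b = np.asarray(draws_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise EvaluationError("draw lists must be 1-d and paired by resample index")
    B = a.size
    w = float((a > b).sum()) + 0.5 * float((a == b).sum())
    k = (w + 0.5) / (B - w + 0.5)
    return float(min(k, 2.0 * B))


def rank_models(results: list[EvaluationResult], reference: EvaluationResult,
                k_threshold: float = 3.0, tie_tol: float | None = None) -> RankingResult:
    """Apply the challenge ranking rules to a set of evaluated models.

    ``reference`` is the TMB-baseline evaluation on the same (dataset,
    endpoint, B, seed).  ``tie_tol`` defaults to one bootstrap standard
    error of the best tie-breaking (ICI-arm) basal metric.
    """
    if not results:
        raise EvaluationError("no results to rank")
    endpoint = reference.endpoint
    for r in results:
        if r.endpoint != endpoint or r.B != reference.B or r.seed != reference.seed:
            raise EvaluationError("all results must share endpoint, B and seed")
    k_ref = {r.model_name: bayes_factor(r.dss_draws, reference.dss_draws)
             for r in results}
    eligible = [r for r in results if k_ref[r.model_name] > k_threshold]
    if not eligible:
        return RankingResult(endpoint, [], [], {}, [], k_ref, {})
    best = max(eligible, key=lambda r: r.point.dss)
    k_best = {r.model_name: bayes_factor(best.dss_draws, r.dss_draws)
              for r in eligible}
    tie_set = [r for r in eligible if k_best[r.model_name] < k_threshold]
    tie_break = {r.model_name: r.point.bm_ici for r in tie_set}
    best_tb = max(tie_break.values())
    if tie_tol is None:
        winner = max(tie_set, key=lambda r: tie_break[r.model_name])
        tie_tol = float(np.std(winner.bm_ici_draws, ddof=1))
    top = [name for name, tb in tie_break.items() if best_tb - tb <= tie_tol]
    return RankingResult(endpoint,
                         [r.model_name for r in eligible],
                         [r.model_name for r in tie_set],
                         tie_break, top, k_ref, k_best)


def km_median(times, events) -> float | None:
    """Kaplan–Meier median: smallest time where the product-limit survival
    estimate drops to <= 0.5, or ``None`` when the curve never reaches it
    ("not reached")."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise EvaluationError("need at least one subject")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    surv = kmf.survival_function_.iloc[:, 0]
    crossed = surv[surv <= 0.5 + 1e-12]
    return None if crossed.empty else float(crossed.index[0])


def stratify_upper_tertile(score: ModelScore) -> dict[str, list[str]]:
    """Partition patients into upper-tertile vs middle/lower score groups."""
    values = score.scores
    if len(values) < 3:
        raise EvaluationError("need at least 3 patients to form tertiles")
    cut = quantile_threshold(list(values.values()), 2.0 / 3.0)
    upper = [p for p, v in values.items() if v >= cut]
    lower = [p for p, v in values.items() if v < cut]
    if not lower:
        logger.warning("degenerate tertile split: every score meets the "
                       "upper-tertile threshold %.4g", cut)
    return {"upper": upper, "middle_lower": lower}


def km_by_stratum(dataset: TrialDataset, score: ModelScore,
                  endpoint: str) -> dict[str, dict]:
    """Median survival by arm and score stratum (upper vs middle/lower tertile)."""
    endpoint = endpoint.upper()
    if endpoint not in ("PFS", "OS"):
        raise EvaluationError("Kaplan–Meier summaries need a survival endpoint")
    col = endpoint.lower()
    strata = stratify_upper_tertile(score)
    clin = dataset.clinical.set_index("patient_id")
    out: dict[str, dict] = {}
    for arm in sorted(clin["arm"].unique()):
        for name, pids in strata.items():
            sub = clin.loc[[p for p in pids if p in clin.index]]
            sub = sub[sub["arm"] == arm]
            key = f"{arm}:{name}"
            if len(sub) == 0:
                out[key] = {"n": 0, "median": None}
                continue
            med = km_median(sub[f"{col}_time"], sub[f"{col}_event"])
            out[key] = {"n": int(len(sub)), "median": med}
    return out
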