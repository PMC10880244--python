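"""Basal metrics and the primary arm-difference metric.

Each model is scored per trial arm with a *basal metric* (BM): Harrell's
concordance index against a time-to-event endpoint (PFS or OS), or the
ROC-AUC against the progressive-disease label (BOR sub-challenge).  The
primary metric is the difference in squared scaled BM between the ICI arm
and the chemotherapy arm,

    DSS = (2 (BM_ici - 1/2))^2 - (2 (BM_chemo - 1/2))^2,

which is ~0 for prognostic models (informative in both arms alike or in
neither), positive for models predictive of ICI benefit, and — because of
the squaring — indifferent to the direction in which a model ranks patients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .trial_data import ModelScore, TrialDataset

ENDPOINTS = ("PFS", "OS", "BOR")


class MetricError(ValueError):
    pass


class NoComparablePairsError(MetricError):
    """Survival data admits no usable pair (e.g. everything censored)."""


class SingleClassError(MetricError):
    """Binary endpoint has only one class present."""


@dataclass
class ArmBasalMetrics:
    """Per-arm basal metrics for one model on one endpoint."""

    bm_ici: float
    bm_ctrl: float
    metric_kind: str  # {"c_index", "roc_auc"}
    n_ici: int
    n_ctrl: int

    @property
    def dss(self) -> float:
        return dss(self.bm_ici, self.bm_ctrl)


def _oriented(scores: np.ndarray, direction: str) -> np.ndarray:
    """Flip scores so that larger always means 'better predicted outcome'."""
    scores = np.asarray(scores, dtype=float)
    return scores if direction == "benefit_high" else -scores


def concordance_index(times, events, scores, direction: str = "benefit_high") -> float:
    """Harrell's C-index over comparable patient pairs.

    A pair (i, j) with t_i < t_j is comparable when patient i had the event;
    pairs with tied times are comparable when exactly one of the two had the
    event (the censored/longer-lived one counts as surviving longer).  The
    pair is concordant when the predicted-survival score (after orienting by
    ``direction``) is larger for the longer-lived patient; tied scores count
    1/2.  Returns the concordant fraction in [0, 1].
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    s = _oriented(scores, direction)
    if not (t.shape == e.shape == s.shape):
        raise MetricError("times, events, scores must have equal length")
    # comparable[i, j]: i died strictly before j, or tied time with only i's event
    earlier = t[:, None] < t[None, :]
    tied_t = t[:, None] == t[None, :]
    comp = (earlier & (e[:, None] == 1)) | (tied_t & (e[:, None] == 1) & (e[None, :] == 0))
    n_comp = comp.sum()
    if n_comp == 0:
        raise NoComparablePairsError("no comparable pairs (all censored?)")
    # longer-lived patient j should carry the larger score
    conc = (s[None, :] > s[:, None]).astype(float) + 0.5 * (s[None, :] == s[:, None])
    return float((conc * comp).sum() / n_comp)


def roc_auc(labels, scores, direction: str = "high") -> float:
    """ROC-AUC via the Mann–Whitney U statistic with mid-rank tie handling.

    ``direction='high'`` means larger scores predict label 1; ``'low'`` the
    opposite.  Equals U / (n1 * n0).
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if direction == "low":
        s = -s
    elif direction != "high":
        raise MetricError(f"unknown direction {direction!r}")
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise SingleClassError("both classes must be present")
    ranks = rankdata(s)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def scaled_bm(bm: float) -> float:
    """Map a basal metric from [0, 1] to [-1, 1]: 2 (BM - 0.5)."""
    if not 0.0 <= bm <= 1.0:
        raise MetricError(f"basal metric {bm} outside [0, 1]")
    return 2.0 * (bm - 0.5)


def dss(bm_ici: float, bm_ctrl: float) -> float:
    """Difference in squared scaled basal metrics, ICI arm minus control arm."""
    return scaled_bm(bm_ici) ** 2 - scaled_bm(bm_ctrl) ** 2


def arm_basal_metrics(dataset: TrialDataset, score: ModelScore,
                      endpoint: str) -> ArmBasalMetrics:
    """Compute the endpoint's basal metric independently within each arm."""
    endpoint = endpoint.upper()
    if endpoint not in ENDPOINTS:
        raise MetricError(f"unknown endpoint {endpoint!r}")
    dataset.require_both_arms()
    clin = dataset.clinical
    bms = {}
    ns = {}
    for arm in ("ICI", "CHEMO"):
        sub = clin[clin["arm"] == arm]
        s = score.aligned_to(sub["patient_id"])
        if endpoint in ("PFS", "OS"):
            col = endpoint.lower()
            bms[arm] = concordance_index(sub[f"{col}_time"], sub[f"{col}_event"],
                                         s, score.direction)
            kind = "c_index"
        else:
            labels = sub["bor_pd"]
            keep = labels.notna().to_numpy()
            # benefit_high scores predict *non*-PD, i.e. they are 'low'
            # predictors of the PD label
            auc_dir = "low" if score.direction == "benefit_high" else "high"
            bms[arm] = roc_auc(labels[keep].astype(int), s[keep], auc_dir)
            kind = "roc_auc"
        ns[arm] = len(sub)
    return ArmBasalMetrics(bm_ici=bms["ICI"], bm_ctrl=bms["CHEMO"],
                           metric_kind=kind, n_ici=ns["ICI"], n_ctrl=ns["CHEMO"])
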