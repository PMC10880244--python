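"""Reference implementations of the top-performing challenge models.

Each model is a scikit-learn-style estimator: ``fit(dataset)`` derives the
cohort-level context (tertile/median cut points, min–max normalization
bounds, signature scores), ``predict(dataset)`` returns a per-patient score
array, and ``score_patients(dataset)`` wraps the result in a
:class:`~icibench.trial_data.ModelScore`.  Thresholds are always computed on
the cohort the model is scored on, so typical usage is
``model.fit(ds).predict(ds)`` (or :func:`score_dataset`).

Models
------
Netphar
    decision tree: TMB >= 243 missense mutations gates PD-L1;
    Y = 10*TMB_bin + TMB_bin*PD-L1; conservative 0 on the TMB-low branch.
I-MIRACLE
    rule-based 1/2/3 score from TMB-high (cohort upper tertile; proliferation
    signature proxy when TMB is missing) and PD-L1-high (>= 50%; ICR
    signature proxy when PD-L1 is missing).
Aginome-Amoy
    median-based three-group stratification on PD-L1/TMB with within-group
    linear scores on min–max-normalized values, ordered group3 > group1 > group2.
FICAN-OSCAR
    fixed-coefficient linear model over a panel enrichment score and clinical
    indicators (lower Y taken as better predicted ICI outcome).
DukeLKB1
    six derived features (TMB/PD-L1 67th-percentile indicators and four
    histology-stratified signature means) combined by a signed weighted sum.
Baselines
    the raw TMB or PD-L1 value (cohort-median imputation for missing).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.exceptions import NotFittedError

from .signatures import (
    SignatureScore,
    quantile_threshold,
    rank_enrichment_score,
    signature_mean_score,
    walk_enrichment_score,
    zscore_genes,
)
from .trial_data import GeneSet, ModelScore, TrialDataset

NETPHAR_TMB_CUT = 243  # missense mutations
PDL1_HIGH_CUT = 50.0   # percent
UPPER_TERTILE = 2.0 / 3.0
P67 = 0.67

FICAN_OSCAR_COEF = {
    "panel": -0.693,
    "tmb_high": -0.357,
    "male": -0.105,
    "squamous": -0.198,
    "squamous_pdl1_gt5": -0.05,
    "eversmoker": -0.223,
    "ecog0": -0.105,
}


class ModelInputError(ValueError):
    pass


@dataclass
class ModelContext:
    """Cohort-level quantities shared by the rule models."""

    tmb_upper_tertile: float | None = None
    tmb_median: float | None = None
    pdl1_median: float | None = None
    proliferation_upper_tertile: float | None = None
    icr_upper_tertile: float | None = None
    tmb_p67: float | None = None
    pdl1_p67: float | None = None
    tmb_bounds: tuple[float, float] | None = None
    pdl1_bounds: tuple[float, float] | None = None
    signature_scores: dict[str, SignatureScore] = field(default_factory=dict)


def _minmax(value: float, bounds: tuple[float, float]) -> float:
    lo, hi = bounds
    if hi == lo:  # constant variable: uninformative midpoint
        return 0.5
    return (value - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# scalar scoring rules (thin functional layer used by the estimators)
# ---------------------------------------------------------------------------

def netphar_score(tmb, pdl1) -> float:
    """Y = 10*TMB_bin + TMB_bin*PD-L1 with TMB_bin = 1[tmb >= 243].

    Missing TMB falls on the conservative low branch (score 0); PD-L1 is
    required.
    """
    if pdl1 is None or (isinstance(pdl1, float) and np.isnan(pdl1)):
        raise ModelInputError("Netphar requires a PD-L1 value")
    tmb_bin = 0 if tmb is None or (isinstance(tmb, float) and np.isnan(tmb)) \
        else int(tmb >= NETPHAR_TMB_CUT)
    return 10.0 * tmb_bin + tmb_bin * float(pdl1)


def imiracle_score(tmb, pdl1, proliferation, icr, ctx: ModelContext) -> int:
    """I-MIRACLE category in {1, 2, 3}.

    TMB-high: tmb >= cohort upper tertile, or, when TMB is missing,
    proliferation signature >= its upper tertile.  PD-L1-high: pdl1 >= 50,
    or, when PD-L1 is missing, ICR signature >= its upper tertile.  Both
    high -> 3, both low -> 1, otherwise 2.
    """
    tmb_missing = tmb is None or (isinstance(tmb, float) and np.isnan(tmb))
    if tmb_missing:
        if proliferation is None:
            raise ModelInputError("TMB and its proliferation proxy both missing")
        tmb_high = proliferation >= ctx.proliferation_upper_tertile
    else:
        tmb_high = tmb >= ctx.tmb_upper_tertile
    pdl1_missing = pdl1 is None or (isinstance(pdl1, float) and np.isnan(pdl1))
    if pdl1_missing:
        if icr is None:
            raise ModelInputError("PD-L1 and its ICR proxy both missing")
        pdl1_high = icr >= ctx.icr_upper_tertile
    else:
        pdl1_high = pdl1 >= PDL1_HIGH_CUT
    if tmb_high and pdl1_high:
        return 3
    if not tmb_high and not pdl1_high:
        return 1
    return 2


AGINOME_OFFSETS = {3: 20.0, 1: 10.0, 2: 0.0}


def aginome_score(tmb, pdl1, ctx: ModelContext) -> float:
    """Three-group rule with within-group linear scores.

    Group 1: PD-L1 below the cohort median; group 2: PD-L1 >= median and
    TMB below median; group 3: both >= medians.  Within-group scores use
    min–max-normalized TMB/PD-L1 (group 3: T + 2P; group 1: T + P;
    group 2: T - P); group offsets keep every group-3 score above every
    group-1 score above every group-2 score.
    """
    if tmb is None or pdl1 is None or np.isnan(tmb) or np.isnan(pdl1):
        raise ModelInputError("Aginome-Amoy requires both TMB and PD-L1")
    t = _minmax(float(tmb), ctx.tmb_bounds)
    p = _minmax(float(pdl1), ctx.pdl1_bounds)
    if pdl1 < ctx.pdl1_median:
        group, within = 1, t + p
    elif tmb < ctx.tmb_median:
        group, within = 2, t - p
    else:
        group, within = 3, t + 2.0 * p
    return AGINOME_OFFSETS[group] + within


def fican_oscar_score(sex, histology, smoking, ecog, tmb, pdl1, panel,
                      ctx: ModelContext) -> float:
    """Fixed-coefficient linear score; lower values = better predicted ICI outcome."""
    c = FICAN_OSCAR_COEF
    tmb_missing = tmb is None or (isinstance(tmb, float) and np.isnan(tmb))
    is_tmb_high = 0 if tmb_missing else int(tmb >= ctx.tmb_upper_tertile)
    is_squamous = int(histology == "squamous")
    pdl1_val = np.nan if pdl1 is None else float(pdl1)
    is_sq_pdl1 = int(is_squamous and not np.isnan(pdl1_val) and pdl1_val > 5.0)
    return (c["panel"] * float(panel)
            + c["tmb_high"] * is_tmb_high
            + c["male"] * int(sex == "male")
            + c["squamous"] * is_squamous
            + c["squamous_pdl1_gt5"] * is_sq_pdl1
            + c["eversmoker"] * int(smoking == "ever")
            + c["ecog0"] * int(ecog == 0))


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

class TrialModel(BaseEstimator):
    """Base class: maps a TrialDataset to per-patient prediction scores."""

    name: str = "model"
    direction: str = "benefit_high"

    def fit(self, dataset: TrialDataset, y=None):
        self._validate_input(dataset)
        self.context_ = self._build_context(dataset)
        self.n_patients_ = dataset.n_patients
        return self

    def predict(self, dataset: TrialDataset) -> np.ndarray:
        if not hasattr(self, "context_"):
            raise NotFittedError(f"{type(self).__name__} is not fitted yet")
        return self._score(dataset, self.context_)

    def fit_predict(self, dataset: TrialDataset) -> np.ndarray:
        return self.fit(dataset).predict(dataset)

    def score_patients(self, dataset: TrialDataset,
                       subchallenge: str = "PFS") -> ModelScore:
        values = self.predict(dataset)
        return ModelScore(self.name, subchallenge,
                          dict(zip(dataset.patient_ids, map(float, values))),
                          self.direction)

    # hooks ----------------------------------------------------------------
    def _validate_input(self, dataset: TrialDataset) -> None:
        pass

    def _build_context(self, dataset: TrialDataset) -> ModelContext:
        return ModelContext()

    def _score(self, dataset: TrialDataset, ctx: ModelContext) -> np.ndarray:
        raise NotImplementedError


class NetpharModel(TrialModel):
    """TMB-gated PD-L1 decision tree (PFS sub-challenge top performer).

    The scalar rule requires PD-L1; a whole-cohort submission must still
    score every patient, so the estimator imputes missing PD-L1 with the
    cohort median (missing TMB already falls on the conservative low
    branch).  Set ``impute_missing=False`` to keep the strict rule.
    """

    name = "netphar"

    def __init__(self, impute_missing: bool = True):
        self.impute_missing = impute_missing

    def _build_context(self, dataset):
        ctx = ModelContext()
        pdl1 = dataset.clinical["pdl1"]
        if pdl1.notna().any():
            ctx.pdl1_median = float(pdl1.median())
        return ctx

    def _score(self, dataset, ctx):
        clin = dataset.clinical
        pdl1 = clin["pdl1"]
        if self.impute_missing and ctx.pdl1_median is not None:
            pdl1 = pdl1.fillna(ctx.pdl1_median)
        return np.array([netphar_score(t, p)
                         for t, p in zip(clin["tmb"], pdl1)])


class IMiracleModel(TrialModel):
    """Rule-based 1/2/3 score from TMB and PD-L1 with signature proxies.

    Parameters
    ----------
    proliferation_genes, icr_genes : GeneSet, optional
        Signatures scored with the competitive mean-rank enrichment
        statistic; needed only when TMB resp. PD-L1 values are missing.
    """

    name = "imiracle"

    def __init__(self, proliferation_genes: GeneSet | None = None,
                 icr_genes: GeneSet | None = None):
        self.proliferation_genes = proliferation_genes
        self.icr_genes = icr_genes

    def _build_context(self, dataset):
        ctx = ModelContext()
        clin = dataset.clinical
        if clin["tmb"].notna().any():
            ctx.tmb_upper_tertile = quantile_threshold(clin["tmb"], UPPER_TERTILE)
        for attr, gs, key in (("proliferation_upper_tertile", self.proliferation_genes,
                               "proliferation"),
                              ("icr_upper_tertile", self.icr_genes, "icr")):
            if gs is not None and not dataset.expression.empty:
                sig = rank_enrichment_score(dataset.expression, gs)
                ctx.signature_scores[key] = sig
                setattr(ctx, attr, quantile_threshold(list(sig.values.values()),
                                                      UPPER_TERTILE))
        return ctx

    def _score(self, dataset, ctx):
        clin = dataset.clinical
        prolif = ctx.signature_scores.get("proliferation")
        icr = ctx.signature_scores.get("icr")
        out = []
        for _, row in clin.iterrows():
            pid = row["patient_id"]
            out.append(imiracle_score(
                row["tmb"], row["pdl1"],
                None if prolif is None else prolif.values[pid],
                None if icr is None else icr.values[pid], ctx))
        return np.array(out, dtype=float)


class AginomeModel(TrialModel):
    """Median-stratified three-group TMB/PD-L1 rule (BOR top performer).

    The rule needs both TMB and PD-L1; by default missing values are imputed
    with the cohort median (computed on the observed values) so the whole
    cohort is scored.  Set ``impute_missing=False`` to reject incomplete
    cohorts instead.
    """

    name = "aginome"

    def __init__(self, impute_missing: bool = True):
        self.impute_missing = impute_missing

    def _validate_input(self, dataset):
        if self.impute_missing:
            return
        clin = dataset.clinical
        if clin["tmb"].isna().any() or clin["pdl1"].isna().any():
            raise ModelInputError("Aginome-Amoy requires complete TMB and PD-L1; "
                                  "impute before fitting")

    def _build_context(self, dataset):
        clin = dataset.clinical
        tmb, pdl1 = clin["tmb"].dropna(), clin["pdl1"].dropna()
        if tmb.empty or pdl1.empty:
            raise ModelInputError("Aginome-Amoy needs observed TMB and PD-L1 values")
        return ModelContext(
            tmb_median=quantile_threshold(tmb, 0.5),
            pdl1_median=quantile_threshold(pdl1, 0.5),
            tmb_bounds=(float(tmb.min()), float(tmb.max())),
            pdl1_bounds=(float(pdl1.min()), float(pdl1.max())),
        )

    def _score(self, dataset, ctx):
        clin = dataset.clinical
        tmb, pdl1 = clin["tmb"], clin["pdl1"]
        if self.impute_missing:
            tmb = tmb.fillna(ctx.tmb_median)
            pdl1 = pdl1.fillna(ctx.pdl1_median)
        return np.array([aginome_score(t, p, ctx) for t, p in zip(tmb, pdl1)])


class FicanOscarModel(TrialModel):
    """Fixed-coefficient linear model over a panel signature and clinical indicators.

    The panel signature is scored with the weighted KS random-walk
    enrichment statistic.  All coefficients are negative; the estimator
    declares ``benefit_low`` (lower score = better predicted ICI outcome),
    an assumption made explicit here because the squared scaled basal
    metrics are direction-agnostic.
    """

    name = "fican_oscar"
    direction = "benefit_low"

    def __init__(self, panel_genes: GeneSet | None = None):
        self.panel_genes = panel_genes

    def _build_context(self, dataset):
        ctx = ModelContext()
        clin = dataset.clinical
        if clin["tmb"].notna().any():
            ctx.tmb_upper_tertile = quantile_threshold(clin["tmb"], UPPER_TERTILE)
        else:
            ctx.tmb_upper_tertile = np.inf  # all isTMBhigh = 0
        if self.panel_genes is not None and not dataset.expression.empty:
            ctx.signature_scores["panel"] = walk_enrichment_score(
                dataset.expression, self.panel_genes)
        return ctx

    def _score(self, dataset, ctx):
        clin = dataset.clinical
        panel = ctx.signature_scores.get("panel")
        out = []
        for _, row in clin.iterrows():
            pval = 0.0 if panel is None else panel.values[row["patient_id"]]
            out.append(fican_oscar_score(row["sex"], row["histology"],
                                         row["smoking"], row["ecog"],
                                         row["tmb"], row["pdl1"], pval, ctx))
        return np.array(out, dtype=float)


DUKE_SIGNATURES = ("inflammatory", "lkb1_loss", "nrf2", "neuroendocrine")
DUKE_DEFAULT_WEIGHTS = {
    "tmb_high": 1.0, "pdl1_high": 1.0, "inflammatory": 1.0,
    "lkb1_loss": -1.0, "nrf2": -1.0, "neuroendocrine": -1.0,
}


class DukeLKB1Model(TrialModel):
    """Six-feature model: TMB/PD-L1 67th-percentile indicators plus four
    signature means on histology-stratified z-scored expression.

    Signature means are averages of per-gene z-scores computed separately
    within the squamous and non-squamous subsets.  The combined score is a
    signed weighted sum; the default weights score immune features
    positively and the LKB1-loss, NRF2-activation and neuroendocrine
    resistance phenotypes negatively.
    """

    name = "dukelkb1"

    def __init__(self, gene_sets: dict[str, GeneSet] | None = None,
                 weights: dict[str, float] | None = None):
        self.gene_sets = gene_sets
        self.weights = weights

    def _validate_input(self, dataset):
        if dataset.clinical["histology"].isna().any():
            raise ModelInputError("DukeLKB1 requires histology for every patient")

    def _build_context(self, dataset):
        ctx = ModelContext()
        clin = dataset.clinical
        if clin["tmb"].notna().any():
            ctx.tmb_p67 = quantile_threshold(clin["tmb"], P67)
        if clin["pdl1"].notna().any():
            ctx.pdl1_p67 = quantile_threshold(clin["pdl1"], P67)
        if self.gene_sets and not dataset.expression.empty:
            strata = pd.Series(clin["histology"].to_numpy(),
                               index=clin["patient_id"].to_numpy())
            scaled = zscore_genes(dataset.expression, strata)
            for key in DUKE_SIGNATURES:
                if key in self.gene_sets:
                    ctx.signature_scores[key] = signature_mean_score(
                        scaled, self.gene_sets[key])
        return ctx

    def features(self, dataset: TrialDataset) -> pd.DataFrame:
        """Per-patient 6-column feature table (indicators + signature means)."""
        if not hasattr(self, "context_"):
            raise NotFittedError(f"{type(self).__name__} is not fitted yet")
        ctx = self.context_
        clin = dataset.clinical
        pids = clin["patient_id"]
        feats = pd.DataFrame(index=pids.to_numpy())
        tmb = clin["tmb"].to_numpy(dtype=float)
        pdl1 = clin["pdl1"].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            feats["tmb_high"] = np.where(np.isnan(tmb), 0,
                                         (tmb > (ctx.tmb_p67 if ctx.tmb_p67 is not None
                                                 else np.inf)).astype(int))
            feats["pdl1_high"] = np.where(np.isnan(pdl1), 0,
                                          (pdl1 > (ctx.pdl1_p67 if ctx.pdl1_p67 is not None
                                                   else np.inf)).astype(int))
        for key in DUKE_SIGNATURES:
            sig = ctx.signature_scores.get(key)
            feats[key] = 0.0 if sig is None else [sig.values[p] for p in pids]
        return feats

    def _score(self, dataset, ctx):
        feats = self.features(dataset)
        w = dict(DUKE_DEFAULT_WEIGHTS)
        if self.weights:
            w.update(self.weights)
        total = np.zeros(len(feats))
        for col in feats.columns:
            total = total + w.get(col, 0.0) * feats[col].to_numpy(dtype=float)
        return total


class BaselineModel(TrialModel):
    """Univariate comparator: the raw TMB or PD-L1 value.

    Missing values are imputed with the cohort median so every patient is
    scored (a submission requirement the baselines also had to meet).
    """

    def __init__(self, variable: str = "tmb"):
        self.variable = variable

    @property
    def name(self) -> str:  # type: ignore[override]
        return f"baseline_{self.variable}"

    def _build_context(self, dataset):
        col = dataset.clinical[self.variable]
        if col.isna().all():
            raise ModelInputError(f"variable {self.variable!r} entirely missing")
        return ModelContext(tmb_median=float(col.median()))

    def _score(self, dataset, ctx):
        col = dataset.clinical[self.variable].astype(float)
        return col.fillna(ctx.tmb_median).to_numpy()


def dukelkb1_features(dataset: TrialDataset, gene_sets: dict[str, GeneSet],
                      weights: dict[str, float] | None = None):
    """Fit a DukeLKB1 model on the dataset; return (feature table, ModelScore)."""
    model = DukeLKB1Model(gene_sets=gene_sets, weights=weights).fit(dataset)
    return model.features(dataset), model.score_patients(dataset)


def baseline_score(dataset: TrialDataset, variable: str,
                   subchallenge: str = "PFS") -> ModelScore:
    """TMB or PD-L1 univariate baseline as a ModelScore."""
    model = BaselineModel(variable=variable.lower()).fit(dataset)
    return model.score_patients(dataset, subchallenge)


MODEL_REGISTRY = {
    "netphar": NetpharModel,
    "imiracle": IMiracleModel,
    "aginome": AginomeModel,
    "fican_oscar": FicanOscarModel,
    "dukelkb1": DukeLKB1Model,
    "baseline_tmb": lambda: BaselineModel("tmb"),
    "baseline_pdl1": lambda: BaselineModel("pdl1"),
}


def make_model(name: str, **kwargs) -> TrialModel:
    """Instantiate a registered model by name."""
    try:
        factory = MODEL_REGISTRY[name]
    except KeyError:
        raise ModelInputError(f"unknown model {name!r}; choose from "
                              f"{sorted(MODEL_REGISTRY)}") from None
    return factory(**kwargs) if kwargs else factory()


def score_dataset(model: TrialModel, dataset: TrialDataset,
                  subchallenge: str = "PFS") -> ModelScore:
    """Fit the model's cohort context on the dataset and score it."""
    return model.fit(dataset).score_patients(dataset, subchallenge)
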