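"""Synthetic two-arm ICI-vs-chemotherapy trial generator.

Emulates the statistical structure of a first-line NSCLC checkpoint-inhibitor
trial with a chemotherapy control arm: 1:1 randomization, TMB (missense
mutation counts, log-normal), PD-L1 percentages (logit-normal), censored PFS
and OS endpoints, a progressive-disease response label, missing TMB/PD-L1,
and a genes x patients expression matrix with latent immune and
proliferation factors.

The outcome model is an exponential proportional-hazards model with a
treatment main effect, a prognostic biomarker effect, and a
treatment-by-biomarker interaction — the interaction term is what makes a
biomarker *predictive* rather than merely prognostic, and it is the handle
the effect-scenario presets turn:

    hazard_i = lambda0 * exp(-(theta * ici_i + beta_prog * b_i
                               + beta_pred * b_i * ici_i))

where ``b`` is the standardized designated biomarker (log TMB by default).
OS is PFS plus an independent exponential residual, so OS >= PFS and the two
endpoints are positively correlated.  All randomness flows from a single
seed through named substreams, so e.g. the expression draw does not shift
when outcome coefficients change.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .trial_data import GeneSet, TrialDataset

_SUBSTREAMS = ("covariates", "expression", "outcomes", "censoring", "missingness")


class SimulationError(ValueError):
    pass


@dataclass
class SignatureBlock:
    """A block of genes loading on one latent factor."""

    name: str
    size: int
    loading: float = 0.8


@dataclass
class SimulationConfig:
    """All generator parameters; defaults give a realistic mid-size trial.

    Defaults follow the shape of first-line NSCLC ICI trials: n=300
    randomized 1:1; TMB log-normal with median ~150 missense mutations and
    correlation ~0.5 with the proliferation factor; PD-L1 logit-normal with
    median ~50% and correlation ~0.6 with the immune factor; median PFS
    ~5 months under chemotherapy (exponential), OS = PFS + residual with
    ~9-month median; administrative censoring at 24 months plus light random
    censoring; ~40% progressive-disease rate; 20% missing TMB and 5% missing
    PD-L1 (TMB ascertainment is the leakier assay in practice).
    """

    n_patients: int = 300
    ici_fraction: float = 0.5
    n_genes: int = 200
    immune_block: SignatureBlock = field(
        default_factory=lambda: SignatureBlock("immune_signature", 20, 0.8))
    proliferation_block: SignatureBlock = field(
        default_factory=lambda: SignatureBlock("proliferation_signature", 10, 0.8))
    panel_block: SignatureBlock = field(
        default_factory=lambda: SignatureBlock("panel_signature", 5, 0.8))
    # covariate frequencies
    p_male: float = 0.6
    p_squamous: float = 0.3
    p_eversmoker: float = 0.85
    p_ecog0: float = 0.35
    # TMB: counts = round(exp(mu + sigma * z)), z correlated with proliferation
    tmb_log_mu: float = 5.0
    tmb_log_sigma: float = 0.8
    rho_tmb_proliferation: float = 0.5
    # PD-L1: 100 * expit(a + b * z), z correlated with immune factor
    pdl1_logit_loc: float = 0.0
    pdl1_logit_scale: float = 1.5
    rho_pdl1_immune: float = 0.6
    # outcome model
    biomarker: str = "tmb"  # {"tmb", "pdl1", "immune", "proliferation"}
    theta: float = 0.0          # treatment main effect
    beta_prog: float = 0.0      # prognostic coefficient
    beta_pred: float = 0.0      # predictive (interaction) coefficient
    baseline_hazard: float = np.log(2) / 5.0    # per month; median PFS 5 mo
    os_residual_hazard: float = np.log(2) / 8.0
    admin_censor_time: float = 24.0
    random_censor_rate: float = 0.02
    # BOR(PD) logistic model
    bor_alpha: float = -0.4
    bor_gamma_prog: float = 0.0
    bor_gamma_pred: float = 0.0
    # missingness (completely at random)
    tmb_missing_fraction: float = 0.2
    pdl1_missing_fraction: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        for name in ("ici_fraction", "tmb_missing_fraction", "pdl1_missing_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name} must lie in [0, 1], got {v}")
        if self.tmb_missing_fraction >= 1.0 or self.pdl1_missing_fraction >= 1.0:
            raise SimulationError("missingness fractions must be < 1")
        for name in ("tmb_log_sigma", "baseline_hazard", "os_residual_hazard"):
            if getattr(self, name) <= 0:
                raise SimulationError(f"{name} must be positive")
        for rho in (self.rho_tmb_proliferation, self.rho_pdl1_immune):
            if not -1.0 <= rho <= 1.0:
                raise SimulationError("copula correlations must lie in [-1, 1]")
        blocks = [self.immune_block, self.proliferation_block, self.panel_block]
        if sum(b.size for b in blocks) > self.n_genes:
            raise SimulationError("signature blocks exceed n_genes")
        if self.n_patients < 4:
            raise SimulationError("need at least 4 patients")


def _substreams(seed: int) -> dict[str, np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(_SUBSTREAMS))
    return {name: np.random.default_rng(child)
            for name, child in zip(_SUBSTREAMS, children)}


def signature_gene_sets(config: SimulationConfig) -> list[GeneSet]:
    """The true signature blocks of the generator, as GeneSets."""
    sets = []
    start = 0
    for block in (config.immune_block, config.proliferation_block, config.panel_block):
        genes = [f"G{g:05d}" for g in range(start, start + block.size)]
        sets.append(GeneSet(block.name, genes))
        start += block.size
    return sets


def _correlated(rng: np.random.Generator, anchor: np.ndarray, rho: float) -> np.ndarray:
    """Standard-normal vector with correlation rho to the (standard-normal) anchor."""
    eps = rng.standard_normal(anchor.size)
    return rho * anchor + np.sqrt(1.0 - rho ** 2) * eps


def simulate_trial(config: SimulationConfig) -> TrialDataset:
    """Draw one synthetic trial; identical config (incl. seed) -> identical data."""
    config.validate()
    rngs = _substreams(config.seed)
    n = config.n_patients

    # -- covariates and randomization --------------------------------------
    rng = rngs["covariates"]
    n_ici = int(round(n * config.ici_fraction))
    n_ici = min(max(n_ici, 2), n - 2)  # keep both arms populated
    arm = np.array(["ICI"] * n_ici + ["CHEMO"] * (n - n_ici))
    rng.shuffle(arm)
    sex = np.where(rng.random(n) < config.p_male, "male", "female")
    histology = np.where(rng.random(n) < config.p_squamous, "squamous", "nonsquamous")
    smoking = np.where(rng.random(n) < config.p_eversmoker, "ever", "never")
    ecog = np.where(rng.random(n) < config.p_ecog0, 0, 1)

    # -- latent factors and expression --------------------------------------
    erng = rngs["expression"]
    immune = erng.standard_normal(n)
    proliferation = erng.standard_normal(n)
    blocks = signature_gene_sets(config)
    factors = {config.immune_block.name: (immune, config.immune_block.loading),
               config.proliferation_block.name: (proliferation,
                                                 config.proliferation_block.loading),
               config.panel_block.name: (immune, config.panel_block.loading)}
    X = erng.standard_normal((config.n_genes, n))
    gene_ids = [f"G{g:05d}" for g in range(config.n_genes)]
    expr = pd.DataFrame(X, index=gene_ids)
    for gs in blocks:
        factor, loading = factors[gs.name]
        expr.loc[gs.genes] = loading * factor + expr.loc[gs.genes].to_numpy()

    # -- TMB and PD-L1 via Gaussian copula ----------------------------------
    z_tmb = _correlated(erng, proliferation, config.rho_tmb_proliferation)
    tmb = np.round(np.exp(config.tmb_log_mu + config.tmb_log_sigma * z_tmb))
    z_pdl1 = _correlated(erng, immune, config.rho_pdl1_immune)
    pdl1 = 100.0 * expit(config.pdl1_logit_loc + config.pdl1_logit_scale * z_pdl1)

    # -- designated biomarker, standardized ----------------------------------
    b = _standardized_biomarker(config, tmb, pdl1, immune, proliferation)

    # -- outcomes ------------------------------------------------------------
    orng = rngs["outcomes"]
    ici = (arm == "ICI").astype(float)
    eta = config.theta * ici + config.beta_prog * b + config.beta_pred * b * ici
    hazard = config.baseline_hazard * np.exp(-eta)
    pfs_raw = orng.exponential(1.0, size=n) / hazard  # inverse-CDF sampling
    os_raw = pfs_raw + orng.exponential(1.0 / config.os_residual_hazard, size=n)
    p_pd = expit(config.bor_alpha
                 - config.bor_gamma_prog * b
                 - config.bor_gamma_pred * b * ici)
    bor_pd = (orng.random(n) < p_pd).astype(float)

    # -- censoring ------------------------------------------------------------
    crng = rngs["censoring"]
    if config.random_censor_rate > 0:
        c_rand = crng.exponential(1.0 / config.random_censor_rate, size=n)
    else:
        c_rand = np.full(n, np.inf)
    censor = np.minimum(c_rand, config.admin_censor_time)
    pfs_time = np.minimum(pfs_raw, censor)
    pfs_event = (pfs_raw <= censor).astype(int)
    os_time = np.minimum(os_raw, censor)
    os_event = (os_raw <= censor).astype(int)
    tiny = 1e-6
    pfs_time = np.maximum(pfs_time, tiny)
    os_time = np.maximum(os_time, tiny)

    clinical = pd.DataFrame({
        "patient_id": [f"P{i:04d}" for i in range(n)],
        "arm": arm, "sex": sex, "histology": histology, "smoking": smoking,
        "ecog": ecog, "tmb": tmb, "pdl1": pdl1,
        "pfs_time": pfs_time, "pfs_event": pfs_event,
        "os_time": os_time, "os_event": os_event, "bor_pd": bor_pd,
    })
    expr.columns = clinical["patient_id"].tolist()
    dataset = TrialDataset(clinical, expr)

    mrng = rngs["missingness"]
    return _mask(dataset, config.tmb_missing_fraction,
                 config.pdl1_missing_fraction, mrng)


def _standardized_biomarker(config, tmb, pdl1, immune, proliferation) -> np.ndarray:
    """The designated biomarker on a standard-normal scale (population params)."""
    if config.biomarker == "tmb":
        # log(round(exp(.))) is monotone in the underlying normal; standardize
        # with the population parameters rather than the sample
        return (np.log(np.maximum(tmb, 1.0)) - config.tmb_log_mu) / config.tmb_log_sigma
    if config.biomarker == "pdl1":
        return (logit(np.clip(pdl1 / 100.0, 1e-9, 1 - 1e-9))
                - config.pdl1_logit_loc) / config.pdl1_logit_scale
    if config.biomarker == "immune":
        return immune
    if config.biomarker == "proliferation":
        return proliferation
    raise SimulationError(f"unknown biomarker {config.biomarker!r}")


def _mask(dataset: TrialDataset, tmb_fraction: float, pdl1_fraction: float,
          rng: np.random.Generator) -> TrialDataset:
    clin = dataset.clinical.copy()
    n = len(clin)
    if tmb_fraction > 0:
        clin.loc[rng.random(n) < tmb_fraction, "tmb"] = np.nan
    if pdl1_fraction > 0:
        clin.loc[rng.random(n) < pdl1_fraction, "pdl1"] = np.nan
    return TrialDataset(clin, dataset.expression)


def inject_missingness(dataset: TrialDataset, tmb_fraction: float = 0.0,
                       pdl1_fraction: float = 0.0, seed: int = 0) -> TrialDataset:
    """Mask TMB/PD-L1 completely at random; expression is always retained,
    so signature proxies remain computable for every patient."""
    for frac in (tmb_fraction, pdl1_fraction):
        if not 0.0 <= frac < 1.0:
            raise SimulationError("missingness fractions must lie in [0, 1)")
    return _mask(dataset, tmb_fraction, pdl1_fraction, np.random.default_rng(seed))


def effect_scenarios(seed: int = 0, n_patients: int = 300) -> dict[str, SimulationConfig]:
    """Named presets spanning the prognostic/predictive axis.

    * ``null`` — no treatment, prognostic or predictive effect;
    * ``prognostic_only`` — TMB shifts outcome equally in both arms
      (beta_prog = 0.8), so arm-wise rankings agree and DSS ~ 0;
    * ``predictive_only`` — TMB shifts outcome only under ICI
      (beta_pred = 1), the structure DSS is designed to reward;
    * ``mixed`` — treatment main effect plus both biomarker effects.
    """
    base = SimulationConfig(n_patients=n_patients, seed=seed)
    return {
        "null": replace(base),
        "prognostic_only": replace(base, beta_prog=0.8, bor_gamma_prog=0.8),
        "predictive_only": replace(base, beta_pred=1.0, bor_gamma_pred=1.0),
        "mixed": replace(base, theta=0.3, beta_prog=0.5, beta_pred=0.8,
                         bor_gamma_prog=0.5, bor_gamma_pred=0.8),
    }
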