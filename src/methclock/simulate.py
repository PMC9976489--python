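"""Synthetic DNA-methylation cohorts with the structure the pipeline assumes.

The generative scale is the M-value: each CpG's M-value is an intercept plus
an age trajectory (linear, quadratic in age, or log-age shaped — the latter
mimicking loci that change rapidly in early life and stabilise in
adulthood), an optional smoking effect proportional to pack years, a batch
offset, and Gaussian noise.  Beta values are derived exactly via the
logistic inverse and clipped to (0.001, 0.999), so the two scales used
downstream (M-values for association testing, betas for clocks) are linked
by construction.

Survival follows a Weibull-baseline proportional-hazards model whose linear
predictor combines centred age and standardized protein EpiScore signals,
with administrative censoring only (censor-at-last-update design; no
competing risks).

All randomness flows from a single :class:`numpy.random.Generator` seeded
from the config (protein EpiScore weights are seeded from (seed, protein
name) so a panel regenerated for projection matches the one used to drive
survival).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import MethylationMatrix, WeightTable, m_to_beta, beta_to_m

CELL_TYPE_NAMES = ("Bas", "Eos", "NK", "Mono", "CD4T", "CD8T")


@dataclass
class SurvivalConfig:
    """Weibull-baseline Cox survival model parameters.

    ``baseline_shape``/``baseline_scale`` parametrise the baseline hazard
    h0(t) = (shape/scale) * (t/scale)^(shape-1) with t in years;
    ``log_hr_age`` is the log hazard ratio per year of (centred) age;
    ``episcore_log_hrs`` maps protein names to per-SD log hazard ratios of
    their true EpiScore signal; follow-up is administratively censored at
    ``admin_censor_years``.
    """

    baseline_shape: float = 1.3
    baseline_scale: float = 40.0
    log_hr_age: float = 0.09
    episcore_log_hrs: dict = field(default_factory=dict)
    #: M-value shift per unit panel weight per SD of the latent protein
    #: level; gives each survival-driving protein its own variance
    #: component in its CpGs, so its EpiScore is not just a noise/age
    #: combination
    protein_signal_sd: float = 0.2
    admin_censor_years: float = 14.0


@dataclass
class SimulationConfig:
    n_samples: int = 500
    n_cpgs: int = 2000
    seed: int = 0
    age_range: tuple = (18.0, 99.0)
    fraction_linear_cpgs: float = 0.05
    fraction_quadratic_cpgs: float = 0.02
    fraction_logage_cpgs: float = 0.01
    fraction_smoking_cpgs: float = 0.02
    effect_size_sd: float = 0.02
    noise_sd: float = 0.1
    n_batches: int = 4
    batch_sd: float = 0.05
    n_cell_types: int = 6
    cohort: str = "SIM"
    #: seed for the CpG effect map and EpiScore panel; cohorts sharing an
    #: effect_seed share one age-methylation map (held-out cohorts in LOCO
    #: are exchangeable), while a different effect_seed simulates a
    #: distribution-shifted cohort.  Defaults to ``seed``.
    effect_seed: int | None = None
    survival: SurvivalConfig = field(default_factory=SurvivalConfig)

    @property
    def resolved_effect_seed(self) -> int:
        return self.seed if self.effect_seed is None else self.effect_seed

    def validate(self) -> None:
        if self.n_samples < 2:
            raise ConfigError("n_samples must be >= 2")
        if self.n_cpgs < 1:
            raise ConfigError("n_cpgs must be >= 1")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.batch_sd < 0:
            raise ConfigError("batch_sd must be >= 0")
        if self.n_batches < 1:
            raise ConfigError("n_batches must be >= 1")
        if self.n_cell_types < 1:
            raise ConfigError("n_cell_types must be >= 1")
        lo, hi = self.age_range
        if not (0 < lo < hi):
            raise ConfigError("age_range must satisfy 0 < min < max")
        fracs = {
            "fraction_linear_cpgs": self.fraction_linear_cpgs,
            "fraction_quadratic_cpgs": self.fraction_quadratic_cpgs,
            "fraction_logage_cpgs": self.fraction_logage_cpgs,
            "fraction_smoking_cpgs": self.fraction_smoking_cpgs,
        }
        for name, f in fracs.items():
            if not 0 <= f <= 1:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if sum(fracs.values()) > 1 + 1e-12:
            raise ConfigError("CpG class fractions must sum to <= 1")
        if self.survival.admin_censor_years <= 0:
            raise ConfigError("admin_censor_years must be > 0")
        if self.survival.baseline_shape <= 0 or self.survival.baseline_scale <= 0:
            raise ConfigError("baseline_shape and baseline_scale must be > 0")


@dataclass
class TruthRecord:
    """Ground truth for a simulated cohort.

    ``cpg_table`` holds one row per CpG with its class label and generative
    coefficients; ``episcore_weights`` the true panel used to drive
    survival; ``true_scores`` the raw projected protein scores; ``hazard_lp``
    the per-sample hazard linear predictor.
    """

    cpg_table: pd.DataFrame
    episcore_weights: dict
    true_scores: pd.DataFrame
    hazard_lp: pd.Series
    latent_proteins: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        """Sidecar-serializable per-CpG truth table."""
        return self.cpg_table


def _protein_rng(seed: int, name: str) -> np.random.Generator:
    # weights depend only on (effect seed, name): the panel projected at
    # analysis time is identical to the one that generated survival
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(name.encode())])


def _episcore_model(config: SimulationConfig, name: str) -> WeightTable:
    rng = _protein_rng(config.resolved_effect_seed, name)
    n_w = int(rng.integers(5, min(21, config.n_cpgs + 1)))
    idx = rng.choice(config.n_cpgs, size=n_w, replace=False)
    w = rng.normal(0.0, 0.5, size=n_w)
    if np.all(w == 0):  # degenerate draw; keep >= 1 nonzero weight
        w[0] = 0.5
    cpgs = [f"cg{j:08d}" for j in sorted(idx)]
    entries = pd.DataFrame(
        {"feature": cpgs, "transform": "linear", "weight": w[np.argsort(idx)]}
    )
    return WeightTable(name=name, intercept=0.0, entries=entries,
                       metadata={"name": name, "scale": "beta", "kind": "episcore"})


def simulate_episcore_panel(config: SimulationConfig, n_proteins: int) -> dict:
    """Synthetic protein EpiScore panel: name -> beta-scale weight table.

    Stands in for published protein EpiScore panels whose weights are
    external; each score is a sparse linear combination of beta values over
    a random CpG subset.
    """
    config.validate()
    if n_proteins < 1:
        raise ConfigError("n_proteins must be >= 1")
    # survival-driving proteins (named in the config) come first; weights
    # depend only on (seed, name) so they match the cohort's survival model
    names = sorted(config.survival.episcore_log_hrs)
    i = 1
    while len(names) < n_proteins:
        cand = f"prot_{i:03d}"
        if cand not in names:
            names.append(cand)
        i += 1
    return {name: _episcore_model(config, name) for name in names[:n_proteins] or names}


def project_panel(betas: pd.DataFrame, panel: dict) -> pd.DataFrame:
    """Project a panel onto a beta DataFrame (truth-side helper)."""
    out = {}
    for name, wt in panel.items():
        cols = wt.entries["feature"].tolist()
        out[name] = betas[cols].to_numpy() @ wt.entries["weight"].to_numpy() + wt.intercept
    return pd.DataFrame(out, index=betas.index)


def simulate_cohort(config: SimulationConfig):
    """Simulate one cohort; returns (MethylationMatrix, phenotypes, TruthRecord)."""
    config.validate()
    rng = np.random.default_rng(config.seed & 0x7FFFFFFF)
    n, p = config.n_samples, config.n_cpgs
    lo, hi = config.age_range
    age = rng.uniform(lo, hi, size=n)
    age_c = age - age.mean()
    sex = rng.integers(0, 2, size=n).astype(float)  # female=1, male=0
    batch = rng.integers(0, config.n_batches, size=n)

    probs = np.array([0.45, 0.20, 0.05, 0.25, 0.05])  # never/current/quit<1y/quit>1y/unknown
    levels = np.array(["never", "current", "quit<1y", "quit>1y", "unknown"])
    smoking = levels[rng.choice(5, size=n, p=probs)]
    ever = np.isin(smoking, ["current", "quit<1y", "quit>1y"])
    pack_years = np.where(ever, rng.gamma(2.0, 7.0, size=n), 0.0)

    k = config.n_cell_types
    cell_names = list(CELL_TYPE_NAMES[:k]) if k <= 6 else [f"cell_{i+1}" for i in range(k)]
    cell = rng.dirichlet(np.linspace(10, 2, k), size=n)

    # CpG class assignment: contiguous blocks after nothing depends on order
    counts = [
        int(round(config.fraction_linear_cpgs * p)),
        int(round(config.fraction_quadratic_cpgs * p)),
        int(round(config.fraction_logage_cpgs * p)),
        int(round(config.fraction_smoking_cpgs * p)),
    ]
    while sum(counts) > p:  # rounding overflow guard
        counts[int(np.argmax(counts))] -= 1
    classes = np.array(["null"] * p, dtype=object)
    start = 0
    for label, c in zip(["linear", "quadratic", "logage", "smoking"], counts):
        classes[start:start + c] = label
        start += c

    cpg_ids = [f"cg{j:08d}" for j in range(p)]
    # effect map drawn from its own stream so cohorts sharing effect_seed
    # share one age-methylation map
    rng_eff = np.random.default_rng([config.resolved_effect_seed & 0x7FFFFFFF, 104729])
    intercept = rng_eff.normal(0.0, 1.5, size=p)
    half_span = (hi - lo) / 2.0
    # theoretical moments of U(lo, hi), not sample moments: the effect map
    # must not depend on which samples a cohort drew
    sd_age = (hi - lo) / np.sqrt(12.0)
    grid = np.linspace(lo, hi, 10001)
    sd_logage = float(np.std(np.log(grid)))

    slope_age = np.zeros(p)
    slope_age2 = np.zeros(p)
    slope_logage = np.zeros(p)
    slope_pack = np.zeros(p)
    lin = classes == "linear"
    quad = classes == "quadratic"
    loga = classes == "logage"
    smk = classes == "smoking"
    slope_age[lin] = rng_eff.normal(0.0, config.effect_size_sd, size=lin.sum())
    # quadratic: curvature scaled so the age**2 contribution has spread
    # comparable to a linear CpG's over the cohort age range
    slope_age2[quad] = rng_eff.normal(0.0, config.effect_size_sd / half_span, size=quad.sum())
    slope_age[quad] = rng_eff.normal(0.0, config.effect_size_sd, size=quad.sum())
    # log-age slopes variance-matched to the linear class
    scale_log = sd_age / max(sd_logage, 1e-12)
    slope_logage[loga] = rng_eff.normal(0.0, config.effect_size_sd * scale_log, size=loga.sum())
    slope_pack[smk] = rng_eff.normal(0.0, config.effect_size_sd, size=smk.sum())

    M = (
        intercept[None, :]
        + np.outer(age, slope_age)
        + np.outer(age ** 2, slope_age2)
        + np.outer(np.log(age), slope_logage)
        + np.outer(pack_years, slope_pack)
    )
    if config.batch_sd > 0:
        offsets = rng.normal(0.0, config.batch_sd, size=(config.n_batches, p))
        M += offsets[batch]
    if config.noise_sd > 0:
        M += rng.normal(0.0, config.noise_sd, size=(n, p))

    # latent protein levels feed the survival-driving proteins' CpGs, so
    # their projected EpiScores carry protein-specific signal
    surv = config.survival
    proteins = sorted(surv.episcore_log_hrs)
    panel = {name: _episcore_model(config, name) for name in proteins}
    latent = rng.normal(size=(n, len(proteins)))
    cpg_pos = {c: j for j, c in enumerate(cpg_ids)}
    for k, name in enumerate(proteins):
        ent = panel[name].entries
        idx = [cpg_pos[c] for c in ent["feature"]]
        M[:, idx] += surv.protein_signal_sd * np.outer(latent[:, k],
                                                       ent["weight"].to_numpy())

    beta = np.clip(m_to_beta(M), 0.001, 0.999)
    sample_ids = [f"{config.cohort}_s{i:05d}" for i in range(n)]
    meth = MethylationMatrix(
        pd.DataFrame(beta, index=sample_ids, columns=cpg_ids), scale="beta"
    )

    # --- survival ---------------------------------------------------------
    scores = project_panel(meth.data, panel) if proteins else pd.DataFrame(index=meth.data.index)
    lp = surv.log_hr_age * age_c
    for name in proteins:
        s = scores[name].to_numpy()
        sd = s.std(ddof=1)
        z = (s - s.mean()) / sd if sd > 0 else np.zeros(n)
        lp = lp + surv.episcore_log_hrs[name] * z
    u = rng.uniform(size=n)
    t_event = surv.baseline_scale * (-np.log(u) * np.exp(-lp)) ** (1.0 / surv.baseline_shape)
    tte = np.minimum(t_event, surv.admin_censor_years)
    event = (t_event <= surv.admin_censor_years).astype(int)

    pheno = pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "cohort": config.cohort,
            "batch": [f"{config.cohort}_b{b}" for b in batch],
            "set": f"{config.cohort}_set1",
            "smoking_status": smoking,
            "pack_years": pack_years,
            **{name: cell[:, i] for i, name in enumerate(cell_names)},
            "tte": tte,
            "event": event,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    cpg_table = pd.DataFrame(
        {
            "cpg": cpg_ids,
            "class": classes,
            "intercept": intercept,
            "slope_age": slope_age,
            "slope_age2": slope_age2,
            "slope_logage": slope_logage,
            "slope_pack_years": slope_pack,
        }
    ).set_index("cpg")
    truth = TruthRecord(
        cpg_table=cpg_table,
        episcore_weights=panel,
        true_scores=scores,
        hazard_lp=pd.Series(lp, index=sample_ids, name="hazard_lp"),
        latent_proteins=pd.DataFrame(latent, index=sample_ids, columns=proteins),
    )
    return meth, pheno, truth


def linear_power_oracle(config: SimulationConfig, slopes, ages, alpha: float = 3.6e-8):
    """Analytic power, per CpG, of the single-CpG linear age EWAS.

    For a CpG with M = a + b*age + e, e ~ N(0, noise_sd^2), the squared
    age-CpG correlation is rho2 = b^2 Var(age) / (b^2 Var(age) + noise_sd^2)
    and the EWAS t-test (either regression direction) is a noncentral
    F(1, n-2) with ncp = n * rho2 / (1 - rho2).  Returns the power at level
    ``alpha`` for each slope.
    """
    from scipy import stats

    slopes = np.asarray(slopes, dtype=float)
    n = len(ages)
    var_age = np.var(ages)
    sigma2 = config.noise_sd ** 2
    rho2 = slopes ** 2 * var_age / (slopes ** 2 * var_age + sigma2)
    ncp = n * rho2 / np.clip(1 - rho2, 1e-300, None)
    fcrit = stats.f.isf(alpha, 1, n - 2)
    return stats.ncf.sf(fcrit, 1, n - 2, ncp)
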