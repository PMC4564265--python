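"""Synthetic leaf spectra, field-survey tables and greenhouse experiments.

The generator emulates the statistical structure of a wild-cabbage survey so
every analysis stage can be exercised without field data:

* Leaf spectra come in three archetypes on the 300-700 nm grid: a green leaf
  dominated by chlorophyll (reflectance peak near 550 nm, absorption troughs
  near 430 and 662 nm, red edge beyond 690 nm), a bluish leaf adding
  broadband 400-500 nm reflectance (epicuticular wax), and a reddish leaf
  adding reflectance above 550 nm (long-wavelength pigments).  Components
  are additive Gaussian/logistic band shapes with multiplicative log-normal
  noise -- a phenomenological model, not radiative transfer.
* The field survey samples 12 populations in 4 counties (Cornwall, Devon,
  Dorset, Kent), 20-50 plants per population.  Glucosinolate concentrations
  are log-normal with rank correlations to colour channels imposed through a
  Gaussian copula on normal scores, so Spearman-level structure is
  controlled directly.  Herbivore presence follows a logistic model with a
  single colour effect and population-in-county random intercepts; the
  aphid is absent from Kent.
* Greenhouse tables reproduce the paired-plant design: rank-paired choice
  trials with Bernoulli choices, and larval/aphid performance records at
  configurable group means.

The random seed fully determines every output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .receptors import build_receptor_set, catch_profile
from .spectra import CANONICAL_GRID, Spectrum
from .survey import GS_ALIPHATIC, GS_INDOLE, GS_NAMES

__all__ = [
    "SimConfig",
    "PerformanceConfig",
    "PerformanceTables",
    "generate_leaf_spectrum",
    "generate_field_survey",
    "generate_choice_trials",
    "generate_performance",
    "logit_effect_for_marginal_r2",
]

ARCHETYPES = ("bluish", "green", "reddish")
COUNTIES = ("Cornwall", "Devon", "Dorset", "Kent")

# Default colour-channel driver and Spearman sign/magnitude per glucosinolate,
# following the dominant field correlation of each compound (rho magnitudes
# are configurable; the signs are the structural content).
DEFAULT_GS_CORR: dict[str, tuple[str, float]] = {
    "glucoiberin": ("prg_ratio", 0.16),
    "gluconapin": ("drg_ratio", -0.23),
    "glucoraphanin": ("drg_ratio", 0.20),
    "progoitrin": ("bg_ratio", 0.07),
    "sinigrin": ("brightness", 0.17),
    "glucobrassicin": ("prg_ratio", 0.23),
    "neoglucobrassicin": ("drg_ratio", 0.30),
    "4-methoxyglucobrassicin": ("drg_ratio", 0.12),
}

# Log-scale location/spread for constitutive concentrations (umol per g),
# anchored to greenhouse constitutive means.
_GS_LOGNORM: dict[str, tuple[float, float]] = {
    "glucoiberin": (np.log(0.02), 0.9),
    "gluconapin": (np.log(0.70), 0.9),
    "glucoraphanin": (np.log(0.06), 0.9),
    "progoitrin": (np.log(0.08), 0.9),
    "sinigrin": (np.log(0.25), 0.8),
    "glucobrassicin": (np.log(0.035), 0.7),
    "neoglucobrassicin": (np.log(0.10), 0.9),
    "4-methoxyglucobrassicin": (np.log(0.80), 0.8),
}

DEFAULT_COVARIATE_CORR: dict[str, tuple[str, float]] = {
    "size_mm": ("bg_ratio", -0.09),
    "density": ("prg_ratio", -0.10),
    "cn_ratio": ("bg_ratio", -0.29),
}


def logit_effect_for_marginal_r2(r2: float, sd_county: float, sd_pop: float) -> float:
    """Logistic coefficient on a unit-variance predictor giving marginal R2 ``r2``.

    Inverts r2 = beta^2 / (beta^2 + sd_c^2 + sd_p^2 + pi^2/3).
    """
    if not 0 <= r2 < 1:
        raise ValueError("r2 must lie in [0, 1)")
    other = sd_county**2 + sd_pop**2 + np.pi**2 / 3.0
    return float(np.sqrt(r2 * other / (1.0 - r2)))


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for the synthetic field survey."""

    seed: int = 0
    n_pops_per_county: int = 3
    plants_per_pop: tuple[int, int] = (40, 50)   # uniform range per transect
    archetype_mix: tuple[float, float, float] = (0.30, 0.50, 0.20)  # bluish/green/reddish
    gs_corr: Mapping[str, tuple[str, float]] = field(
        default_factory=lambda: dict(DEFAULT_GS_CORR)
    )
    covariate_corr: Mapping[str, tuple[str, float]] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_CORR)
    )
    # presence model: response -> (intercept, colour channel, coefficient on the
    # z-scored channel).  Defaults give marginal R2 of about 0.04.
    presence_effects: Mapping[str, tuple[float, str, float]] = field(
        default_factory=lambda: {
            "pieris": (-0.4, "bg_ratio", 0.39),
            "brassicae": (0.0, "brightness", -0.39),
        }
    )
    sd_county: float = 0.3
    sd_pop: float = 0.5
    gs_subsample: tuple[int, int] | None = (4, 15)   # plants per population assayed; None = all
    cn_fraction: float = 179.0 / 548.0
    flowering_base_logit: float = -1.0
    flowering_prg_effect: float = 0.5
    illuminant: str = "flat"

    def __post_init__(self) -> None:
        if abs(sum(self.archetype_mix) - 1.0) > 1e-9:
            raise ValueError("archetype_mix proportions must sum to 1")
        if self.sd_county < 0 or self.sd_pop < 0:
            raise ValueError("random-intercept SDs must be >= 0")
        for name, (channel, rho) in {**self.gs_corr, **self.covariate_corr}.items():
            if abs(rho) > 0.95:
                raise ValueError(
                    f"target Spearman correlation {rho} for {name!r} is infeasibly large"
                )


def _gauss(wl: np.ndarray, centre: float, width: float) -> np.ndarray:
    return np.exp(-((wl - centre) ** 2) / (2.0 * width**2))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_leaf_spectrum(
    archetype: str,
    rng: np.random.Generator,
    sample_id: str = "",
) -> Spectrum:
    """Draw one synthetic leaf reflectance spectrum of the given archetype."""
    if archetype not in ARCHETYPES:
        raise ValueError(f"unknown archetype {archetype!r}; known: {ARCHETYPES}")
    wl = CANONICAL_GRID
    base = (
        0.04
        + 0.20 * rng.lognormal(0.0, 0.15) * _gauss(wl, 550.0, 35.0)
        + 0.50 * _sigmoid((wl - 705.0) / 10.0)
    )
    # chlorophyll absorption troughs
    base *= 1.0 - 0.35 * _gauss(wl, 430.0, 25.0) - 0.35 * _gauss(wl, 662.0, 18.0)
    if archetype == "bluish":
        base = base + 0.12 * rng.lognormal(0.0, 0.25) * _gauss(wl, 455.0, 48.0)
    elif archetype == "reddish":
        base = base + 0.10 * rng.lognormal(0.0, 0.25) * _sigmoid((wl - 600.0) / 22.0)
    refl = base * rng.lognormal(0.0, 0.08)          # overall intensity jitter
    refl = refl * np.exp(rng.normal(0.0, 0.01, wl.size))  # fine-grained noise
    refl = np.clip(refl, 0.0, 1.2)
    return Spectrum(wl, refl, sample_id=sample_id)


def _normal_scores(x: np.ndarray) -> np.ndarray:
    from scipy.stats import norm, rankdata

    ranks = rankdata(x, method="average")
    return norm.ppf((ranks - 0.5) / x.size)


def _copula_transform(
    driver: np.ndarray, rho_spearman: float, rng: np.random.Generator
) -> np.ndarray:
    """Latent standard-normal scores with target Spearman correlation to ``driver``."""
    r = 2.0 * np.sin(np.pi * rho_spearman / 6.0)  # Spearman -> latent Pearson
    z = _normal_scores(driver)
    eps = rng.normal(size=driver.size)
    return r * z + np.sqrt(1.0 - r**2) * eps


def generate_field_survey(cfg: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Generate one field-survey table of plant records.

    Hierarchy: county -> population intercepts -> plants.  Each plant gets an
    archetype, a spectrum, colour metrics through both eye models, copula-
    linked glucosinolates and covariates, and simulated herbivore presence.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    pieris_set = build_receptor_set("pieris", illuminant=cfg.illuminant)
    aphid_set = build_receptor_set("aphid", illuminant=cfg.illuminant)

    rows = []
    pop_labels = []
    for county in COUNTIES:
        for j in range(cfg.n_pops_per_county):
            pop_labels.append((county, f"{county[:3]}{j + 1}"))
    u_county = {c: rng.normal(0.0, cfg.sd_county) for c in COUNTIES}
    v_pop = {p: rng.normal(0.0, cfg.sd_pop) for _, p in pop_labels}

    plant_no = 0
    for county, pop in pop_labels:
        n_plants = int(rng.integers(cfg.plants_per_pop[0], cfg.plants_per_pop[1] + 1))
        archetypes = rng.choice(ARCHETYPES, size=n_plants, p=cfg.archetype_mix)
        for arch in archetypes:
            plant_no += 1
            pid = f"P{plant_no:04d}"
            spec = generate_leaf_spectrum(arch, rng, sample_id=pid)
            prof_p = catch_profile(spec, pieris_set)
            prof_a = catch_profile(spec, aphid_set)
            rows.append(
                {
                    "plant_id": pid,
                    "county": county,
                    "population": pop,
                    "archetype": arch,
                    "bg_ratio": prof_p.bg_ratio,
                    "prg_ratio": prof_p.prg_ratio,
                    "drg_ratio": prof_p.drg_ratio,
                    "bg_ratio_aphid": prof_a.bg_ratio,
                    "brightness": prof_a.brightness,
                }
            )
    df = pd.DataFrame(rows)
    n = len(df)

    # Glucosinolates via Gaussian copula on the driving colour channel.
    for gs in GS_NAMES:
        channel, rho = cfg.gs_corr[gs]
        mu, sd = _GS_LOGNORM[gs]
        z = _copula_transform(df[channel].to_numpy(), rho, rng)
        df[gs] = np.exp(mu + sd * z)
    df["total_aliphatic"] = df[list(GS_ALIPHATIC)].sum(axis=1)
    df["total_indole"] = df[list(GS_INDOLE)].sum(axis=1)
    df["total"] = df["total_aliphatic"] + df["total_indole"]

    # Covariates.
    ch, rho = cfg.covariate_corr["size_mm"]
    df["size_mm"] = np.exp(np.log(8.0) + 0.4 * _copula_transform(df[ch].to_numpy(), rho, rng))
    ch, rho = cfg.covariate_corr["density"]
    lam = np.exp(np.log(2.0) + 0.5 * _copula_transform(df[ch].to_numpy(), rho, rng))
    df["density"] = rng.poisson(lam)
    ch, rho = cfg.covariate_corr["cn_ratio"]
    df["cn_ratio"] = 20.0 + 4.0 * _copula_transform(df[ch].to_numpy(), rho, rng)
    z_prg = (df["prg_ratio"] - df["prg_ratio"].mean()) / df["prg_ratio"].std(ddof=0)
    p_flower = 1.0 / (1.0 + np.exp(-(cfg.flowering_base_logit + cfg.flowering_prg_effect * z_prg)))
    df["flowering"] = rng.random(n) < p_flower

    # Herbivore presence from the logistic model with nested intercepts.
    for resp, (intercept, channel, beta) in cfg.presence_effects.items():
        x = df[channel].to_numpy()
        zx = (x - x.mean()) / x.std()
        eta = (
            intercept
            + beta * zx
            + df["county"].map(u_county).to_numpy()
            + df["population"].map(v_pop).to_numpy()
        )
        present = rng.random(n) < 1.0 / (1.0 + np.exp(-eta))
        col = f"presence_{resp}"
        df[col] = present.astype(float)
        if resp == "brassicae":
            df.loc[df["county"] == "Kent", col] = 0.0  # the aphid is absent from Kent

    # Assay subsampling: chemistry on a per-population subset, C:N on a fraction.
    if cfg.gs_subsample is not None:
        assay = np.zeros(n, dtype=bool)
        for _, pop in pop_labels:
            idx = np.flatnonzero((df["population"] == pop).to_numpy())
            k = int(rng.integers(cfg.gs_subsample[0], cfg.gs_subsample[1] + 1))
            k = min(k, idx.size)
            assay[rng.choice(idx, size=k, replace=False)] = True
        gs_cols = list(GS_NAMES) + ["total_aliphatic", "total_indole", "total"]
        df.loc[~assay, gs_cols] = np.nan
    cn_mask = rng.random(n) < cfg.cn_fraction
    df.loc[~cn_mask, "cn_ratio"] = np.nan
    return df


def generate_choice_trials(
    n_pairs: int = 30,
    p_choose_high: float = 0.5,
    rng: np.random.Generator | None = None,
    metric: str = "bg_ratio",
) -> pd.DataFrame:
    """Bernoulli choice trials between rank-paired high/low plants."""
    rng = np.random.default_rng(0) if rng is None else rng
    if not 0.0 <= p_choose_high <= 1.0:
        raise ValueError("p_choose_high must be a probability")
    side = rng.choice(["left", "right"], size=n_pairs)
    chose_high = rng.random(n_pairs) < p_choose_high
    return pd.DataFrame(
        {
            "pair_id": [f"pair{i + 1:02d}" for i in range(n_pairs)],
            "metric": metric,
            "high_plant_id": [f"H{i + 1:02d}" for i in range(n_pairs)],
            "low_plant_id": [f"L{i + 1:02d}" for i in range(n_pairs)],
            "side_of_high": side,
            "chosen": np.where(chose_high, "high", "low"),
        }
    )


@dataclass(frozen=True)
class PerformanceConfig:
    """Group means and SEMs for the larval and aphid performance experiments.

    Defaults follow the greenhouse comparison of high vs low blue:green
    plants: growth rate in mg/mg/day x 1e-2, pupal mass in mg, time to
    pupation in days, and colony counts for the aphid experiment.
    """

    n_plants_per_group: int = 30
    larvae_per_plant: int = 2
    # response -> (mean_high, mean_low, sem_high, sem_low) at the plant level
    larval_effects: Mapping[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: {
            "growth_rate": (12.46, 10.42, 0.69, 0.55),
            "pupal_mass_mg": (146.9, 129.2, 3.89, 4.00),
            "time_to_pupation_days": (22.25, 23.25, 0.75, 0.73),
        }
    )
    aphid_pairs: int = 15
    aphid_total_mean: tuple[float, float] = (1721.0, 1886.0)
    aphid_total_cv: float = 0.55
    aphid_alate_prop: tuple[float, float] = (0.055, 0.045)
    aphid_dead_prop: tuple[float, float] = (0.30, 0.33)
    aphid_overdispersion: float = 0.05   # beta-binomial intra-class correlation


@dataclass(frozen=True)
class PerformanceTables:
    larvae: pd.DataFrame
    aphids: pd.DataFrame


def _beta_binomial(rng, n, p, rho, size):
    if rho <= 0:
        return rng.binomial(n, np.broadcast_to(p, size))
    a = p * (1.0 - rho) / rho
    b = (1.0 - p) * (1.0 - rho) / rho
    pp = rng.beta(a, b, size=size)
    return rng.binomial(n, pp)


def generate_performance(
    cfg: PerformanceConfig, rng: np.random.Generator | None = None, metric: str = "bg_ratio"
) -> PerformanceTables:
    """Generate larval performance records and aphid colony counts.

    Plant-level means are normal at the configured group means with
    SEM-implied SDs; individual larvae add within-plant noise and are
    truncated at zero.  Aphid totals are log-normal; morph and mortality
    counts are beta-binomial to carry overdispersion.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    npl = cfg.n_plants_per_group
    rows = []
    for group, col in (("high", 0), ("low", 1)):
        for i in range(npl):
            pid = f"{metric}-{group}-{i + 1:02d}"
            plant_vals = {}
            for resp, (mh, ml, sh, sl) in cfg.larval_effects.items():
                mean = (mh, ml)[col]
                sem = (sh, sl)[col]
                sd_plant = sem * np.sqrt(npl)
                plant_vals[resp] = rng.normal(mean, sd_plant)
            for larva in range(cfg.larvae_per_plant):
                row = {"plant_id": pid, "group": group, "metric": metric, "larva": larva + 1}
                for resp, centre in plant_vals.items():
                    # within-plant larval noise at half the plant-level SD
                    sem = cfg.larval_effects[resp][2 + col]
                    val = rng.normal(centre, 0.5 * sem * np.sqrt(npl))
                    row[resp] = max(val, 0.05 * abs(centre) + 1e-6)
                rows.append(row)
    larvae = pd.DataFrame(rows)

    arows = []
    for group, col in (("bright", 0), ("dull", 1)):
        for i in range(cfg.aphid_pairs):
            mu = np.log(cfg.aphid_total_mean[col]) - 0.5 * np.log(1 + cfg.aphid_total_cv**2)
            sd = np.sqrt(np.log(1 + cfg.aphid_total_cv**2))
            total = max(int(np.round(np.exp(rng.normal(mu, sd)))), 1)
            alate = int(_beta_binomial(rng, total, cfg.aphid_alate_prop[col],
                                       cfg.aphid_overdispersion, None))
            dead = int(_beta_binomial(rng, total, cfg.aphid_dead_prop[col],
                                      cfg.aphid_overdispersion, None))
            arows.append(
                {
                    "plant_id": f"brightness-{group}-{i + 1:02d}",
                    "group": group,
                    "total": total,
                    "alate": alate,
                    "apterate": max(total - alate - dead, 0),
                    "dead": dead,
                }
            )
    return PerformanceTables(larvae=larvae, aphids=pd.DataFrame(arows))
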