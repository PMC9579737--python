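"""Synthetic trait pools, designed assemblages and multi-year surveys.

Emulates the statistical structure of a 4-year flower-strip experiment so
that every pipeline stage is testable without the field data: a mixed-type
species pool (151 species by default) with weakly correlated traits, eight
assemblages (two disjoint species lists x four richness/FD types, six
replicate plots each), and an annual survey of percent cover generated by a
mechanism-level succession model:

* every species persists from year to year with probability
  ``logistic(survival_base + redundancy_effect * FR)`` where FR is the sown
  assemblage's functional redundancy, with extra penalties for annuals and
  biennials after their lifespan and for unsown species;
* surviving covers drift multiplicatively with a selection gradient on
  standardised leaf dry matter content (dominance shift toward high-LDMC
  species) plus lognormal growth noise;
* unsown invaders arrive as ``Poisson(mu0 * exp(-gamma * FDis_sown))`` draws
  from the rest of the pool, so invasion declines with realized sown
  functional dispersion;
* covers are rescaled to a total-cover trajectory and observed with
  multiplicative noise plus transect and plot random intercepts on log
  cover.

Defaults are calibrated so that sown-species persistence in year 4 falls in
the 0.60-0.75 band and annual species hold roughly 60% of total cover in the
first survey year.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .assemblage_design import DesignSpec, design_assemblages
from .data_model import (AssemblageDesign, SurveyTable, TraitSchema, TraitTable)
from .diversity_metrics import CommunityVector, fdis, functional_redundancy
from .trait_space import embed, gower_distance, prepare_traits

__all__ = ["SimConfig", "pool_schema", "generate_pool", "simulate_succession",
           "make_benchmark", "Benchmark"]

STRATEGIES = ("annual", "biennial", "stationary_perennial",
              "aboveground_creeping_perennial", "belowground_creeping_perennial")


@dataclass
class SimConfig:
    """All generator knobs; every field is recorded in output metadata.

    The defaults are the study conditions: 151-species pool, 8 assemblages x
    6 replicates x 4 annual surveys, equal initial seed proportions.
    """

    n_pool: int = 151
    trait_preset: str = "arthropod11"       # preset for FR / design metrics
    invasion_preset: str = "competition9"   # preset steering invasion
    replicates: int = 6
    years: int = 4
    richness_targets: tuple = (9, 14, 29)
    sowing_density: float = 240.0
    # succession mechanism
    survival_base: float = 0.3          # logit of annual persistence at FR = 0
    redundancy_effect: float = 10.0     # logit slope of persistence on FR
    ldmc_dominance: float = 1.20        # per-year selection on z(LDMC)
    annual_advantage: float = 20.0      # year-1 cover multiplier, annuals
    biennial_advantage: float = 3.0     # year-1/2 cover multiplier, biennials
    annual_penalty: float = -3.0        # logit persistence penalty, year >= 2
    biennial_penalty: float = -3.0      # logit penalty, year >= 3
    unsown_penalty: float = -2.0        # logit penalty for unsown species
    invasion_rate: float = 50.0         # mu0: mean invaders at FDis_sown = 0
    invasion_fd_effect: float = 6.0     # gamma: decay with sown FDis
    invader_cover_mu: float = -0.7      # log mean initial invader cover (% scale)
    growth_noise: float = 0.35          # lognormal sd of yearly growth
    cover_noise: float = 0.20           # lognormal sd of observation noise
    transect_sd: float = 0.15           # random intercept sd on log cover
    plot_sd: float = 0.15
    total_cover: tuple = (90.0, 100.0, 110.0, 115.0)   # per survey year, %
    detection_threshold: float = 0.002  # minimum recordable percent cover
    missing_year: bool = False          # survey only transects 4-6 in year 2
    max_pool_corr: float = 0.70         # numeric-trait |r| screen
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["richness_targets"] = list(self.richness_targets)
        d["total_cover"] = list(self.total_cover)
        return d

    @classmethod
    def null_effects(cls, **kw) -> "SimConfig":
        """Config with every assemblage-linked effect removed.

        Zeroes the redundancy moderation of survival, the LDMC dominance
        gradient and the FDis dependence of invasion, while holding the
        realized invader load at the level the defaults produce (the raw
        ``invasion_rate`` is the rate at FDis = 0, so zeroing the decay
        without rescaling it would flood the plots with invaders).
        """
        base = cls(**kw)
        typical_fr, typical_fdis = 0.53, 0.65
        typical_rate = base.invasion_rate * float(
            np.exp(-base.invasion_fd_effect * typical_fdis))
        return dataclasses.replace(
            base, redundancy_effect=0.0, ldmc_dominance=0.0,
            invasion_fd_effect=0.0, invasion_rate=typical_rate,
            survival_base=base.survival_base + base.redundancy_effect * typical_fr)


def pool_schema() -> TraitSchema:
    """Schema of the 16 synthetic traits (kinds and log flags)."""
    kinds = {
        "nectar_amount": "ordinal",
        "extrafloral_nectar": "binary",
        "flower_diameter": "numeric",
        "flower_color": "categorical",
        "uv_pattern": "categorical",
        "flowering_onset": "numeric",
        "flowering_duration": "numeric",
        "nectar_depth": "numeric",
        "flowering_height": "numeric",
        "leaf_distribution": "categorical",
        "raunkiaer": "categorical",
        "grime_c": "numeric",
        "grime_r": "numeric",
        "sla": "numeric",
        "ldmc": "numeric",
        "regeneration_strategy": "categorical",
    }
    log = frozenset({"flowering_height", "flowering_duration",
                     "flower_diameter", "nectar_depth"})
    return TraitSchema(kinds, log)


_STRATEGY_P = np.array([0.15, 0.10, 0.40, 0.175, 0.175])
_COLORS = ("white", "yellow", "blue", "purple", "pink")
_LEAF = ("rosette", "semi_rosette", "along_stem")
_RAUNKIAER_PERENNIAL = ("hemicryptophyte", "geophyte", "chamaephyte")


def _draw_pool(rng: np.random.Generator, n: int) -> pd.DataFrame:
    strat = rng.choice(STRATEGIES, size=n, p=_STRATEGY_P)
    raunk = np.where(
        strat == "annual", "therophyte",
        rng.choice(_RAUNKIAER_PERENNIAL, size=n))
    df = pd.DataFrame({
        "nectar_amount": rng.choice([0, 1, 2], size=n, p=[0.2, 0.5, 0.3]).astype(float),
        "extrafloral_nectar": rng.choice([0, 1], size=n, p=[0.9, 0.1]),
        "flower_diameter": np.exp(rng.normal(2.3, 0.8, n)),          # mm
        "flower_color": rng.choice(_COLORS, size=n),
        "uv_pattern": rng.choice(["present", "absent"], size=n, p=[0.3, 0.7]),
        "flowering_onset": np.clip(rng.normal(22, 5, n), 10, 40),    # week
        "flowering_duration": np.exp(rng.normal(np.log(8), 0.5, n)), # weeks
        "nectar_depth": np.exp(rng.normal(np.log(2), 0.7, n)),       # mm
        "flowering_height": np.exp(rng.normal(np.log(60), 0.6, n)),  # cm
        "leaf_distribution": rng.choice(_LEAF, size=n),
        "raunkiaer": raunk,
        "grime_c": np.clip(rng.normal(50, 22, n), 0, 100),
        "grime_r": np.clip(rng.normal(50, 22, n), 0, 100),
        "sla": np.clip(rng.normal(25, 6, n), 5, 45),                 # mm^2/mg
        "ldmc": np.clip(rng.normal(230, 55, n), 100, 400),           # mg/g
        "regeneration_strategy": strat,
    }, index=[f"sp{i + 1:03d}" for i in range(n)])
    # nectar depth is the one incomplete trait (~81% coverage in the field data)
    miss = rng.random(n) < 0.19
    df.loc[miss, "nectar_depth"] = np.nan
    return df


def generate_pool(config: SimConfig, max_attempts: int = 20) -> TraitTable:
    """Mixed-type trait pool with pairwise numeric |r| <= ``max_pool_corr``.

    Trait ranges bracket field scales (LDMC 100-400 mg/g, SLA 5-45 mm^2/mg,
    heights in cm, flowering weeks); the composite regeneration strategy has
    the five lifespan/propagation levels. Enforced by rejection: the whole
    pool is redrawn until the correlation screen passes. Same seed -> same
    pool.
    """
    rng = np.random.default_rng(config.seed)
    schema = pool_schema()
    numeric = [t for t, k in schema.kinds.items() if k == "numeric"]
    worst = 0.0
    for _ in range(max_attempts):
        df = _draw_pool(rng, config.n_pool)
        corr = df[numeric].corr().to_numpy()
        np.fill_diagonal(corr, 0.0)
        m = float(np.nanmax(np.abs(corr)))
        if m <= config.max_pool_corr:
            return TraitTable(df, schema)
        worst = max(worst, m)
    raise RuntimeError(
        f"could not draw a pool with numeric |r| <= {config.max_pool_corr} "
        f"in {max_attempts} attempts (max |r| reached: {worst:.3f})"
    )


def _logistic(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_succession(designs: dict, pool: TraitTable, config: SimConfig,
                        seed: int | None = None) -> SurveyTable:
    """Generate the multi-year survey for all assemblages and replicates.

    Plots are numbered globally (1..8 per transect, six transects, two
    transects per block); each assemblage appears twice per block. Survey
    years are 1..``config.years`` (years since sowing). A plot that loses
    every species stays in the output as a zero-cover plot-year (warning).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    prepared = prepare_traits(pool, config.trait_preset)
    d = gower_distance(prepared)
    inv_emb = embed(gower_distance(prepare_traits(pool, config.invasion_preset)))

    ldmc = pool.data["ldmc"]
    z_ldmc = (ldmc - ldmc.mean()) / ldmc.std(ddof=0)
    strategy = pool.data["regeneration_strategy"]

    fr = {aid: functional_redundancy(
        CommunityVector(list(des.species),
                        np.array([des.sown_proportion[s] for s in des.species])), d)
        for aid, des in designs.items()}

    # layout: 6 transects x 8 plots, assemblages assigned twice per block
    aids = sorted(designs)
    n_transects = config.replicates
    plots = []
    plot_id = 0
    for tr in range(1, n_transects + 1):
        block = (tr + 1) // 2
        order = list(rng.permutation(aids))
        for pos in range(len(aids)):
            plot_id += 1
            plots.append({"plot": plot_id, "transect": tr, "block": block,
                          "assemblage": order[pos]})

    b_transect = rng.normal(0.0, config.transect_sd, n_transects + 1)
    b_plot = rng.normal(0.0, config.plot_sd, plot_id + 1)

    records = []
    warned_empty = False
    for info in plots:
        des = designs[info["assemblage"]]
        state = {s: {"cover": 100.0 / des.richness, "sown": True} for s in des.species}
        for year in range(1, config.years + 1):
            # survival
            survivors = {}
            for s, st in state.items():
                lp = config.survival_base + config.redundancy_effect * fr[info["assemblage"]]
                if strategy[s] == "annual" and year >= 2:
                    lp += config.annual_penalty
                if strategy[s] == "biennial" and year >= 3:
                    lp += config.biennial_penalty
                if not st["sown"]:
                    lp += config.unsown_penalty
                if rng.random() < _logistic(lp):
                    survivors[s] = st
            state = survivors
            # growth / dominance shift
            for s, st in state.items():
                mult = np.exp(config.ldmc_dominance * z_ldmc[s]
                              + rng.normal(0.0, config.growth_noise))
                if year == 1 and strategy[s] == "annual":
                    mult *= config.annual_advantage
                if year <= 2 and strategy[s] == "biennial":
                    mult *= config.biennial_advantage
                st["cover"] *= mult
            # invasion, driven by realized sown FDis
            sown_now = [s for s, st in state.items() if st["sown"]]
            if sown_now:
                com = CommunityVector(sown_now,
                                      np.array([state[s]["cover"] for s in sown_now]))
                fd_sown = fdis(com, inv_emb)
            else:
                fd_sown = 0.0
            rate = config.invasion_rate * np.exp(-config.invasion_fd_effect * fd_sown)
            n_new = rng.poisson(rate)
            # sown species cannot re-arrive as spontaneous colonists
            candidates = [s for s in pool.species
                          if s not in state and s not in des.species]
            if n_new > 0 and candidates:
                picks = rng.choice(candidates, size=min(n_new, len(candidates)),
                                   replace=False)
                for s in picks:
                    cov = np.exp(rng.normal(config.invader_cover_mu, 0.5))
                    if year == 1 and strategy[s] == "annual":
                        cov *= config.annual_advantage
                    state[s] = {"cover": cov, "sown": False}
            # observation: rescale to the total-cover trajectory, add noise
            if config.missing_year and year == 2 and info["transect"] <= 3:
                continue
            total_target = config.total_cover[min(year, len(config.total_cover)) - 1]
            latent_total = sum(st["cover"] for st in state.values())
            if latent_total <= 0:
                if not warned_empty:
                    warnings.warn("plot lost all species; zero-cover plot-year kept",
                                  stacklevel=2)
                    warned_empty = True
                records.append({**info, "year": year, "species": "__none__",
                                "cover": 0.0, "sown": False})
                continue
            scale = total_target / latent_total
            for s, st in state.items():
                obs = (st["cover"] * scale
                       * np.exp(b_transect[info["transect"]] + b_plot[info["plot"]]
                                + rng.normal(0.0, config.cover_noise)))
                obs = round(obs, 3)
                if obs >= config.detection_threshold:
                    records.append({**info, "year": year, "species": s,
                                    "cover": obs, "sown": st["sown"]})
    # a lost plot keeps one zero-cover placeholder record so the plot-year
    # stays visible downstream (richness 0, NaN metrics)
    return SurveyTable(pd.DataFrame(records))


# ---------------------------------------------------------------------------
# Benchmark bundle
# ---------------------------------------------------------------------------


@dataclass
class Benchmark:
    """Self-describing input bundle: pool, designs, survey and config."""

    pool: TraitTable
    designs: dict
    survey: SurveyTable
    config: SimConfig

    def write(self, out_dir) -> dict:
        """Write pool CSV, one design JSON per assemblage, survey CSV and the
        config YAML; returns the path map."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {"pool": out / "pool.csv", "survey": out / "survey.csv",
                 "config": out / "config.yaml"}
        self.pool.write_csv(paths["pool"])
        self.survey.write_csv(paths["survey"])
        paths["config"].write_text(yaml.safe_dump(self.config.to_dict()))
        for aid, des in self.designs.items():
            p = out / f"design_{aid}.json"
            des.write_json(p)
            paths[f"design_{aid}"] = p
        return {k: str(v) for k, v in paths.items()}


def make_benchmark(config: SimConfig | None = None,
                   succession_seed: int | None = None) -> Benchmark:
    """Full input bundle: pool, eight designed assemblages, 48-plot survey.

    ``succession_seed`` re-runs the stochastic field years on a fixed pool
    and design set (replicate simulations of the same experiment).
    """
    config = config or SimConfig()
    pool = generate_pool(config)
    mandatory = tuple(pool.species[:3])
    spec = DesignSpec(pool=pool, richness_targets=config.richness_targets,
                      mandatory=mandatory, sowing_density=config.sowing_density,
                      trait_subset=config.trait_preset,
                      thousand_seed_weight={s: 1.0 for s in pool.species})
    designs = design_assemblages(spec, seed=config.seed)
    survey = simulate_succession(designs, pool, config, seed=succession_seed)
    return Benchmark(pool, designs, survey, config)
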