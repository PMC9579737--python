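"""End-to-end analyses: functional dynamics, standardised FDis, invasion.

Each function takes in-memory objects (survey, trait table, designs) and
returns tidy tables plus averaged-model objects; the CLI wraps these with
file IO and a run manifest. The three analyses mirror the study design:

* :func:`run_dynamics_analysis` - realized functional dispersion (Gaussian),
  species richness (Poisson) and Simpson's evenness (Gaussian) against
  initial richness (3-level), initial functional dispersion (2-level) and
  time since sowing (continuous), with two robustness subsets (medium
  richness only; high functional dispersion only).
* :func:`run_ses_analysis` - standardised effect sizes of FDis from the
  name-shuffling null, modelled with survey year as a categorical term.
* :func:`run_invasion_analysis` - unsown cover (Gaussian) and unsown
  richness (Poisson) against initial assemblage characteristics, and
  against the realized richness and functional dispersion of the sown
  species (computed on the 9-trait competition preset).
"""

from __future__ import annotations

import hashlib
import json
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data_model import SurveyTable, TraitTable
from .diversity_metrics import CommunityVector, fdis, metrics_table
from .model_inference import (enumerate_candidates, fit_all, full_average,
                              rank_and_select)
from .null_models import ses_table
from .trait_space import embed, gower_distance, prepare_traits

__all__ = ["run_dynamics_analysis", "run_ses_analysis", "run_invasion_analysis",
           "RunManifest", "attach_design_factors"]

_RICHNESS_ORDER = ["low", "medium", "high"]
_FD_ORDER = ["low", "high"]


def attach_design_factors(df: pd.DataFrame, designs: dict) -> pd.DataFrame:
    """Add ordered categorical initial_richness / initial_fd and time columns."""
    missing = sorted(set(df["assemblage"]) - set(designs))
    if missing:
        raise KeyError(f"no design for assemblage id(s): {missing}")
    out = df.copy()
    out["initial_richness"] = pd.Categorical(
        [designs[a].richness_level for a in out["assemblage"]],
        categories=_RICHNESS_ORDER, ordered=True)
    out["initial_fd"] = pd.Categorical(
        [designs[a].fd_level for a in out["assemblage"]],
        categories=_FD_ORDER, ordered=True)
    out["time"] = out["year"].astype(float)
    return out


def _multimodel(data: pd.DataFrame, response: str, predictors: list,
                family: str, time: str = "time"):
    terms = enumerate_candidates(predictors, time=time)
    models = fit_all(terms, data, response, family=family)
    return full_average(rank_and_select(models))


def run_dynamics_analysis(survey: SurveyTable, traits: TraitTable, designs: dict,
                          trait_subset="arthropod11", correction: str = "cailliez"):
    """Multimodel inference of the temporal dynamics of diversity.

    Returns ``(metrics, results)``: the per plot-year metric table and a dict
    ``results[response][run]`` of averaged models, where run is ``full``,
    ``medium_richness`` or ``high_fd`` and response is ``fdis``, ``richness``
    or ``evenness``.
    """
    prepared = prepare_traits(traits, trait_subset)
    d = gower_distance(prepared)
    emb = embed(d, correction=correction)
    met = attach_design_factors(
        metrics_table(survey, traits, d, emb, cwm_traits=("ldmc",)
                      if "ldmc" in traits.schema.kinds else ()), designs)
    results = {}
    specs = {"fdis": "gaussian", "richness": "poisson", "evenness": "gaussian"}
    subsets = {
        "full": (met, ["initial_richness", "initial_fd"]),
        "medium_richness": (met[met["initial_richness"] == "medium"], ["initial_fd"]),
        "high_fd": (met[met["initial_fd"] == "high"], ["initial_richness"]),
    }
    for response, family in specs.items():
        results[response] = {}
        for run, (sub, predictors) in subsets.items():
            data = sub.dropna(subset=[response]).reset_index(drop=True).copy()
            if family == "poisson":
                data[response] = data[response].astype(int)
            results[response][run] = _multimodel(data, response, predictors, family)
    return met, results


def run_ses_analysis(survey: SurveyTable, traits: TraitTable, designs: dict,
                     trait_subset="arthropod11", correction: str = "cailliez",
                     pool: list | None = None, n_iter: int = 1000, seed: int = 0):
    """SES of FDis per plot-year, then inference with year as categorical.

    Undefined-SES plot-years are excluded from the model; the exclusion
    count is returned alongside. Year enters the design matrix as indicator
    terms (one level per survey year), not as a slope.
    """
    prepared = prepare_traits(traits, trait_subset)
    emb = embed(gower_distance(prepared), correction=correction)
    ses = ses_table(survey, emb, pool=pool, n_iter=n_iter, seed=seed)
    ses = attach_design_factors(ses, designs)
    ses["year_cat"] = pd.Categorical(ses["year"].astype(str),
                                     categories=[str(y) for y in survey.years])
    usable = ses[~ses["undefined"] & np.isfinite(ses["ses"])].reset_index(drop=True)
    n_excluded = len(ses) - len(usable)
    model = _multimodel(usable, "ses", ["initial_richness", "initial_fd"],
                        "gaussian", time="year_cat")
    return ses, model, n_excluded


def invasion_table(survey: SurveyTable, traits: TraitTable, designs: dict,
                   competition_subset="competition9",
                   correction: str = "cailliez") -> pd.DataFrame:
    """Per plot-year unsown cover/richness and realized sown metrics.

    ``sown_fdis`` is the functional dispersion of the sown species actually
    present, on the competition-trait preset; a plot-year without unsown
    species gets richness 0 and cover 0.
    """
    prepared = prepare_traits(traits, competition_subset)
    emb = embed(gower_distance(prepared), correction=correction)
    rows = []
    for (plot, year), grp in survey.plot_year_groups():
        grp_live = grp[grp["cover"] > 0]
        unsown = grp_live[~grp_live["sown"]]
        sown = grp_live[grp_live["sown"]]
        row = {"assemblage": grp.iloc[0]["assemblage"], "plot": plot, "year": year,
               "transect": grp.iloc[0]["transect"], "block": grp.iloc[0]["block"],
               "unsown_richness": int(len(unsown)),
               "unsown_cover": float(unsown["cover"].sum()),
               "sown_richness": int(len(sown))}
        if len(sown):
            com = CommunityVector(list(sown["species"]),
                                  sown["cover"].to_numpy(dtype=float))
            row["sown_fdis"] = fdis(com, emb)
        else:
            row["sown_fdis"] = np.nan
        rows.append(row)
    return attach_design_factors(pd.DataFrame(rows), designs)


def run_invasion_analysis(survey: SurveyTable, traits: TraitTable, designs: dict,
                          competition_subset="competition9",
                          correction: str = "cailliez"):
    """Resistance to spontaneous colonisation.

    Per plot-year responses: unsown species richness and unsown total cover.
    Two runs per response: against the initial (sown) assemblage
    characteristics, and against the realized richness and functional
    dispersion of the sown species (competition-trait preset). Returns
    ``(table, results)`` with ``results[response][run]`` averaged models.
    """
    tab = invasion_table(survey, traits, designs, competition_subset, correction)
    results = {}
    for response, family in (("unsown_cover", "gaussian"),
                             ("unsown_richness", "poisson")):
        data_init = tab.dropna(subset=[response]).reset_index(drop=True)
        data_real = tab.dropna(subset=[response, "sown_fdis"]).reset_index(drop=True)
        results[response] = {
            "initial": _multimodel(data_init, response,
                                   ["initial_richness", "initial_fd"], family),
            "realized": _multimodel(data_real, response,
                                    ["sown_richness", "sown_fdis"], family),
        }
    return tab, results


# ---------------------------------------------------------------------------
# Run manifest
# ---------------------------------------------------------------------------


@dataclass
class RunManifest:
    """Reproducibility record: config, input digests, seeds, outputs, timings."""

    config: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)     # path -> sha256
    seeds: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)    # stage -> [paths]
    timings: dict = field(default_factory=dict)    # stage -> seconds
    version: str = __version__

    def add_input(self, path) -> None:
        p = Path(path)
        self.inputs[str(p)] = hashlib.sha256(p.read_bytes()).hexdigest()

    def time_stage(self, stage: str):
        manifest = self

        class _Timer:
            def __enter__(self):
                self.t0 = _time.perf_counter()
                return self

            def __exit__(self, *exc):
                manifest.timings[stage] = round(_time.perf_counter() - self.t0, 3)

        return _Timer()

    def record(self, stage: str, *paths) -> None:
        self.outputs.setdefault(stage, []).extend(str(p) for p in paths)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps({
            "version": self.version, "config": self.config, "inputs": self.inputs,
            "seeds": self.seeds, "outputs": self.outputs, "timings": self.timings,
        }, indent=1, default=str))
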