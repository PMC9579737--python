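"""Community-level taxonomic and functional diversity metrics.

Implements the metric set used throughout the analysis: species richness S,
Gini-Simpson diversity D = 1 - sum(p^2), Simpson's evenness E (inverse
Simpson over richness), Rao's quadratic entropy Q, functional redundancy
FR = D - Q, functional dispersion FDis (abundance-weighted mean distance to
the community centroid in the embedded trait space), community-weighted
trait means (CWM), and per-year cover shares of regeneration-strategy
categories.

Relative abundances come from raw percent cover without capping at 100:
species cover overlaps, so plot-year totals above 100% are legitimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import SurveyTable, TraitTable
from .trait_space import DissimilarityMatrix, TraitEmbedding

__all__ = [
    "CommunityVector",
    "simpson_diversity",
    "simpson_evenness",
    "rao_q",
    "functional_redundancy",
    "fdis",
    "cwm",
    "strategy_proportions",
    "metrics_table",
]


@dataclass
class CommunityVector:
    """Species abundances (percent cover or seed proportions) for one community."""

    species: list
    abundance: np.ndarray

    def __post_init__(self):
        self.species = list(self.species)
        a = np.asarray(self.abundance, dtype=float)
        if a.ndim != 1 or len(a) != len(self.species):
            raise ValueError("abundance must be 1-D, one entry per species")
        if (a < 0).any() or not np.isfinite(a).all():
            raise ValueError("abundances must be finite and non-negative")
        self.abundance = a

    @classmethod
    def from_series(cls, s: pd.Series) -> "CommunityVector":
        return cls(list(s.index), s.to_numpy(dtype=float))

    def present(self) -> "CommunityVector":
        """Drop zero-abundance species."""
        keep = self.abundance > 0
        return CommunityVector(
            [s for s, k in zip(self.species, keep) if k], self.abundance[keep]
        )

    @property
    def total(self) -> float:
        return float(self.abundance.sum())

    @property
    def richness(self) -> int:
        return int((self.abundance > 0).sum())

    @property
    def p(self) -> np.ndarray:
        """Relative abundances; requires a non-empty community."""
        tot = self.total
        if tot <= 0:
            raise ValueError("empty community: total abundance is zero")
        return self.abundance / tot


def simpson_diversity(community: CommunityVector) -> float:
    """Gini-Simpson index D = 1 - sum(p_j^2)."""
    p = community.p
    return float(1.0 - np.sum(p ** 2))


def simpson_evenness(community: CommunityVector) -> float:
    """Inverse-Simpson diversity divided by richness; 1 for equal abundances."""
    com = community.present()
    if com.richness == 0:
        raise ValueError("empty community")
    p = com.p
    return float((1.0 / np.sum(p ** 2)) / com.richness)


def _pair_matrix(community: CommunityVector, d: DissimilarityMatrix,
                 convention: str) -> tuple:
    com = community.present()
    missing = [s for s in com.species if s not in d._index]
    if missing:
        raise KeyError(f"species not in dissimilarity matrix: {missing}")
    sub = d.loc(com.species)
    if convention == "divc":
        sub = sub ** 2 / 2.0
    elif convention != "linear":
        raise ValueError(f"unknown Rao convention {convention!r}")
    return com, sub


def rao_q(community: CommunityVector, d: DissimilarityMatrix,
          convention: str = "linear") -> float:
    """Rao's quadratic entropy Q = sum_ij d_ij p_i p_j.

    ``convention="linear"`` uses the dissimilarities as given (the textbook
    form; equals Gini-Simpson when all d_ij = 1). ``convention="divc"`` uses
    d_ij^2 / 2, the convention of the redundancy framework's reference
    implementation lineage.
    """
    com, sub = _pair_matrix(community, d, convention)
    p = com.p
    return float(p @ sub @ p)


def functional_redundancy(community: CommunityVector, d: DissimilarityMatrix,
                          convention: str = "linear") -> float:
    """Functional redundancy FR = D - Q (Gini-Simpson minus Rao's Q).

    High FR means abundant species are functionally similar, so species loss
    can be compensated by functional equivalents.
    """
    return simpson_diversity(community) - rao_q(community, d, convention)


def fdis(community: CommunityVector, embedding: TraitEmbedding) -> float:
    """Functional dispersion: abundance-weighted mean distance to the
    abundance-weighted centroid in the embedded trait space."""
    com = community.present()
    if com.richness == 0:
        raise ValueError("empty community")
    missing = [s for s in com.species if s not in embedding._index]
    if missing:
        raise KeyError(f"species not in embedding: {missing}")
    x = embedding.loc(com.species)
    p = com.p
    centroid = p @ x
    dist = np.sqrt(np.sum((x - centroid) ** 2, axis=1))
    return float(p @ dist)


def cwm(community: CommunityVector, traits: TraitTable, trait: str) -> float:
    """Community-weighted mean of a numeric trait.

    Species with a missing value are excluded and the relative abundances of
    the remainder renormalised; an all-missing community is an error.
    """
    if trait not in traits.schema.kinds:
        raise KeyError(f"unknown trait {trait!r}")
    if traits.schema.kinds[trait] not in ("numeric", "ordinal"):
        raise ValueError(f"CWM requires a numeric trait, got {trait!r}")
    com = community.present()
    vals = traits.data[trait].reindex(com.species)
    ok = vals.notna().to_numpy()
    if not ok.any():
        raise ValueError(f"trait {trait!r} missing for every present species")
    a = com.abundance[ok]
    p = a / a.sum()
    return float(p @ vals.to_numpy(dtype=float)[ok])


def strategy_proportions(records: SurveyTable, traits: TraitTable,
                         strategy_trait: str = "regeneration_strategy") -> pd.DataFrame:
    """Per-year cover fraction of each regeneration-strategy category.

    Returns a tidy frame (year, category, fraction, excluded_cover_share);
    fractions sum to 1 per year over species whose strategy is known.
    Species lacking the strategy are excluded with a warning, and their cover
    share is reported per year.
    """
    if traits.schema.kinds.get(strategy_trait) != "categorical":
        raise ValueError(f"{strategy_trait!r} must be a categorical trait")
    strat = traits.data[strategy_trait]
    rows = []
    warned = False
    for year, grp in records.data.groupby("year"):
        s = strat.reindex(grp["species"]).to_numpy(dtype=object)
        cover = grp["cover"].to_numpy(dtype=float)
        known = pd.notna(s)
        total = cover.sum()
        excl = float(cover[~known].sum() / total) if total > 0 else 0.0
        if (~known).any() and not warned:
            warnings.warn(
                f"species without {strategy_trait!r} excluded from strategy "
                "proportions", stacklevel=2,
            )
            warned = True
        ktotal = cover[known].sum()
        if ktotal <= 0:
            continue
        frame = pd.DataFrame({"cat": s[known], "cover": cover[known]})
        for cat, sub in frame.groupby("cat"):
            rows.append({
                "year": year, "category": cat,
                "fraction": float(sub["cover"].sum() / ktotal),
                "excluded_cover_share": excl,
            })
    return pd.DataFrame(rows)


def metrics_table(survey: SurveyTable, traits: TraitTable,
                  d: DissimilarityMatrix, embedding: TraitEmbedding,
                  cwm_traits: tuple = (), sown_only: bool = False,
                  rao_convention: str = "linear") -> pd.DataFrame:
    """Per plot-year metric report, tidy, keyed by (assemblage, plot, year).

    Columns: richness, simpson, evenness, rao_q, redundancy, fdis, plus one
    ``cwm_<trait>`` column per requested trait. Empty plot-years (all cover
    zero) yield NaN metrics with richness 0.
    """
    meta_cols = ["assemblage", "transect", "block"]
    rows = []
    for (plot, year), grp in survey.plot_year_groups():
        if sown_only:
            grp = grp[grp["sown"]]
        meta = {c: grp.iloc[0][c] for c in meta_cols} if len(grp) else {}
        com = CommunityVector(list(grp["species"]), grp["cover"].to_numpy(dtype=float))
        row = {"plot": plot, "year": year, **meta}
        if com.present().richness == 0:
            row.update(richness=0, simpson=np.nan, evenness=np.nan, rao_q=np.nan,
                       redundancy=np.nan, fdis=np.nan)
        else:
            row["richness"] = com.richness
            row["simpson"] = simpson_diversity(com)
            row["evenness"] = simpson_evenness(com)
            row["rao_q"] = rao_q(com, d, rao_convention)
            row["redundancy"] = row["simpson"] - row["rao_q"]
            row["fdis"] = fdis(com, embedding)
            for t in cwm_traits:
                row[f"cwm_{t}"] = cwm(com, traits, t)
        rows.append(row)
    return pd.DataFrame(rows)
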