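"""Name-shuffling null models and standardised effect sizes for FDis.

The null model permutes species names on the trait matrix: each species keeps
its abundance but receives the full trait vector of another pool member, so
trait covariance and community structure are preserved exactly while the
trait-community association is broken. The standardised effect size is

    SES = (observed FDis - mean null FDis) / sd null FDis,

from ``n_iter`` (default 1000) shuffles. The shuffle pool defaults to the
study-wide species list (all observed species), not the per-community list.

Because a name shuffle only relabels which coordinates belong to which
species, null FDis values are computed by permuting rows of one precomputed
trait-space embedding rather than redoing Gower + PCoA per iteration; the
result is identical to the naive recomputation (asserted in tests).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import SurveyTable, TraitTable
from .diversity_metrics import CommunityVector, fdis
from .trait_space import TraitEmbedding, embed, gower_distance, prepare_traits

__all__ = ["NullResult", "shuffle_names", "ses_fdis", "ses_table"]


@dataclass
class NullResult:
    """Observed metric, null distribution summary, and SES for one community."""

    observed: float
    null_mean: float
    null_sd: float
    ses: float            # NaN when undefined
    n_iter: int
    seed: int
    undefined: bool = False


def shuffle_names(traits: TraitTable, pool: list, rng: np.random.Generator) -> TraitTable:
    """Permute entire trait vectors among the pool's species labels.

    Species outside the pool keep their own traits. The returned table has
    the same multiset of trait vectors as the input.
    """
    pool = list(pool)
    if len(pool) < 2:
        raise ValueError("shuffle pool must contain at least two species")
    missing = [s for s in pool if s not in traits]
    if missing:
        raise KeyError(f"pool species not in trait table: {missing}")
    perm = rng.permutation(len(pool))
    mapping = {pool[i]: pool[perm[i]] for i in range(len(pool))}
    data = traits.data.copy()
    data.loc[pool] = traits.data.loc[[mapping[s] for s in pool]].to_numpy()
    return TraitTable(data, traits.schema)


def ses_fdis(community: CommunityVector, embedding: TraitEmbedding,
             pool: list | None = None, n_iter: int = 1000,
             seed: int = 0) -> NullResult:
    """SES of functional dispersion under the name-shuffling null.

    ``embedding`` is the trait-space embedding of the full pool (one PCoA,
    shared by observed and null computations, as in the distance-based FD
    workflow). ``pool`` defaults to every species in the embedding. The same
    (inputs, seed) always return the same result; a zero null standard
    deviation flags the SES undefined rather than returning +/-inf.
    """
    if n_iter < 2:
        raise ValueError("n_iter must be >= 2")
    pool = list(pool) if pool is not None else list(embedding.species)
    com = community.present()
    outside = [s for s in com.species if s not in pool]
    if outside:
        raise KeyError(f"community species not in shuffle pool: {outside}")
    observed = fdis(com, embedding)

    pool_idx = {s: i for i, s in enumerate(pool)}
    coords = embedding.loc(pool)                 # pool x axes
    member = np.array([pool_idx[s] for s in com.species])
    p = com.p
    rng = np.random.default_rng(seed)
    nulls = np.empty(n_iter)
    for it in range(n_iter):
        perm = rng.permutation(len(pool))
        x = coords[perm[member]]
        centroid = p @ x
        nulls[it] = p @ np.sqrt(np.sum((x - centroid) ** 2, axis=1))
    mean, sd = float(nulls.mean()), float(nulls.std(ddof=1))
    if sd == 0.0:
        return NullResult(observed, mean, 0.0, float("nan"), n_iter, seed, True)
    return NullResult(observed, mean, sd, (observed - mean) / sd, n_iter, seed)


def ses_fdis_naive(community: CommunityVector, traits: TraitTable,
                   trait_subset, pool: list, n_iter: int, seed: int,
                   correction: str = "cailliez") -> NullResult:
    """Reference implementation recomputing Gower + PCoA per shuffle.

    Slow; exists as the optimisation contract for :func:`ses_fdis` (the two
    must agree when the shared-embedding route is exact) and for tests.
    """
    prepared = prepare_traits(traits, trait_subset)
    observed = fdis(community, embed(gower_distance(prepared), correction=correction))
    rng = np.random.default_rng(seed)
    nulls = np.empty(n_iter)
    for it in range(n_iter):
        shuffled = shuffle_names(prepared, pool, rng)
        emb_it = embed(gower_distance(shuffled), correction=correction)
        nulls[it] = fdis(community, emb_it)
    mean, sd = float(nulls.mean()), float(nulls.std(ddof=1))
    if sd == 0.0:
        return NullResult(observed, mean, 0.0, float("nan"), n_iter, seed, True)
    return NullResult(observed, mean, sd, (observed - mean) / sd, n_iter, seed)


def ses_table(survey: SurveyTable, embedding: TraitEmbedding,
              pool: list | None = None, n_iter: int = 1000, seed: int = 0,
              sown_only: bool = False) -> pd.DataFrame:
    """SES of FDis per plot-year, tidy, keyed by (assemblage, plot, year).

    Per-community seeds are drawn deterministically from ``seed`` and
    recorded in the output, so any single row can be recomputed in
    isolation.
    """
    root = np.random.default_rng(seed)
    rows = []
    for (plot, year), grp in survey.plot_year_groups():
        if sown_only:
            grp = grp[grp["sown"]]
        sub_seed = int(root.integers(0, 2 ** 31 - 1))
        com = CommunityVector(list(grp["species"]), grp["cover"].to_numpy(dtype=float))
        row = {"assemblage": grp.iloc[0]["assemblage"] if len(grp) else None,
               "transect": grp.iloc[0]["transect"] if len(grp) else None,
               "block": grp.iloc[0]["block"] if len(grp) else None,
               "plot": plot, "year": year}
        if com.present().richness == 0:
            row.update(observed=np.nan, null_mean=np.nan, null_sd=np.nan,
                       ses=np.nan, n_iter=n_iter, seed=sub_seed, undefined=True)
        else:
            res = ses_fdis(com, embedding, pool=pool, n_iter=n_iter, seed=sub_seed)
            row.update(observed=res.observed, null_mean=res.null_mean,
                       null_sd=res.null_sd, ses=res.ses, n_iter=res.n_iter,
                       seed=res.seed, undefined=res.undefined)
        rows.append(row)
    return pd.DataFrame(rows)
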