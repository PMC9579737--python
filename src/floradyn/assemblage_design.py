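"""Design of seed assemblages crossing richness with functional dispersion.

The published designs were hand-built; here the same design logic is
implemented as a best-of-N random subset search. For each of two disjoint
dicot lists, four assemblage types are constructed (low FD x medium richness,
high FD x low/medium/high richness by default), always including the
mandatory grass backbone. High-FD subsets maximise sown functional
dispersion, low-FD subsets minimise it, and the returned set must satisfy
the verification criteria applied to the original designs: every high-FD
assemblage out-disperses the low-FD assemblage at equal richness, and
functional redundancy increases with richness within the high-FD series.

Seed mixes follow the equal-seed-number rule: each species is sown at
density / S seeds per m^2, converted to mass through its thousand-seed
weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import AssemblageDesign, GRASSES, TraitTable
from .diversity_metrics import CommunityVector, fdis, functional_redundancy
from .trait_space import embed, gower_distance, prepare_traits

__all__ = ["DesignSpec", "design_assemblages", "seed_mix", "verification_report"]

_RICHNESS_LABEL = {0: "low", 1: "medium", 2: "high"}


@dataclass
class DesignSpec:
    """Inputs and targets for the assemblage search.

    ``cells`` lists the (fd_level, richness_target) combinations realised per
    species list; the default mirrors the published unbalanced crossing.
    """

    pool: TraitTable
    richness_targets: tuple = (9, 14, 29)
    fd_levels: tuple = ("low", "high")
    n_lists: int = 2
    mandatory: tuple = GRASSES
    sowing_density: float = 240.0
    thousand_seed_weight: dict | None = None
    trait_subset: object = "arthropod11"
    correction: str = "cailliez"
    n_candidates: int = 300
    cells: tuple = None   # filled in __post_init__

    def __post_init__(self):
        if min(self.richness_targets) < len(self.mandatory):
            raise ValueError("richness targets below the mandatory species count")
        if self.sowing_density <= 0:
            raise ValueError("sowing density must be positive")
        if self.cells is None:
            lo, mid, hi = sorted(self.richness_targets)
            self.cells = (("low", mid), ("high", lo), ("high", mid), ("high", hi))


def _equal_community(species) -> CommunityVector:
    return CommunityVector(list(species), np.ones(len(species)))


def design_assemblages(spec: DesignSpec, seed: int = 0) -> dict:
    """Best-of-N random-subset search for the full design, keyed by id.

    Ids follow the published convention, e.g. ``HFMS1`` = high FD, medium
    richness, list 1. Raises if, after ``n_candidates`` draws per cell, the
    verification criteria cannot be met; the error reports the best achieved
    margin.
    """
    rng = np.random.default_rng(seed)
    prepared = prepare_traits(spec.pool, spec.trait_subset)
    emb = embed(gower_distance(prepared), correction=spec.correction)
    d = gower_distance(prepared)

    mandatory = [s for s in spec.mandatory]
    missing = [s for s in mandatory if s not in spec.pool]
    if missing:
        raise KeyError(f"mandatory species not in pool: {missing}")
    dicots = [s for s in spec.pool.species if s not in mandatory]
    max_r = max(r for _, r in spec.cells) - len(mandatory)
    if len(dicots) < spec.n_lists * max_r:
        raise ValueError(
            f"pool too small: need {spec.n_lists}x{max_r} disjoint dicots, "
            f"have {len(dicots)}"
        )

    # disjoint dicot lists
    shuffled = list(rng.permutation(dicots))
    lists = [shuffled[i * max_r:(i + 1) * max_r] for i in range(spec.n_lists)]

    rich_sorted = sorted(spec.richness_targets)
    rlabel = {r: _RICHNESS_LABEL[rich_sorted.index(r)] for r in rich_sorted}
    short = {"low": "LS", "medium": "MS", "high": "HS"}

    designs = {}
    for li, list_dicots in enumerate(lists, start=1):
        for fd_level, richness in spec.cells:
            k = richness - len(mandatory)
            if k == len(list_dicots):
                best = list(list_dicots)          # search degenerate
            else:
                best, best_score = None, None
                for _ in range(spec.n_candidates):
                    pick = list(rng.choice(list_dicots, size=k, replace=False))
                    score = fdis(_equal_community(mandatory + pick), emb)
                    better = (best_score is None
                              or (fd_level == "high" and score > best_score)
                              or (fd_level == "low" and score < best_score))
                    if better:
                        best, best_score = pick, score
            aid = f"{'HF' if fd_level == 'high' else 'LF'}{short[rlabel[richness]]}{li}"
            designs[aid] = AssemblageDesign.equal_proportions(
                aid, fd_level=fd_level, richness_level=rlabel[richness],
                list_id=li, species=tuple(mandatory) + tuple(sorted(best)),
                sowing_density=spec.sowing_density,
                thousand_seed_weight=(
                    None if spec.thousand_seed_weight is None
                    else {s: spec.thousand_seed_weight[s]
                          for s in tuple(mandatory) + tuple(sorted(best))}
                ),
            )

    _verify(designs, d, emb)
    return designs


def _verify(designs: dict, d, emb) -> None:
    """Check the design-gradient criteria; raise with the worst margin."""
    margins = []
    for li in sorted({v.list_id for v in designs.values()}):
        sub = {k: v for k, v in designs.items() if v.list_id == li}
        lows = [v for v in sub.values() if v.fd_level == "low"]
        highs = [v for v in sub.values() if v.fd_level == "high"]
        fd = {k: fdis(_equal_community(v.species), emb) for k, v in sub.items()}
        fr = {k: functional_redundancy(_equal_community(v.species), d)
              for k, v in sub.items()}
        for lo in lows:
            for hi in highs:
                if hi.richness == lo.richness:
                    margins.append((f"FDis {hi.assemblage_id} - {lo.assemblage_id}",
                                    fd[hi.assemblage_id] - fd[lo.assemblage_id]))
        hs = sorted(highs, key=lambda v: v.richness)
        for a, b in zip(hs, hs[1:]):
            margins.append((f"FR {b.assemblage_id} - {a.assemblage_id}",
                            fr[b.assemblage_id] - fr[a.assemblage_id]))
    bad = [(name, m) for name, m in margins if m <= 0]
    if bad:
        worst = min(bad, key=lambda t: t[1])
        raise RuntimeError(
            f"design verification failed: margin {worst[0]} = {worst[1]:.4g}; "
            "increase n_candidates or enlarge the pool"
        )


def verification_report(designs: dict, pool: TraitTable,
                        trait_subset="arthropod11",
                        correction: str = "cailliez",
                        rao_convention: str = "linear") -> pd.DataFrame:
    """Recompute sown FDis and redundancy for every design.

    Uses the same trait preset and correction as the analysis, so the table
    is directly comparable with realized (survey-based) metrics.
    """
    prepared = prepare_traits(pool, trait_subset)
    d = gower_distance(prepared)
    emb = embed(d, correction=correction)
    rows = []
    for aid, des in sorted(designs.items()):
        com = CommunityVector(list(des.species),
                              np.array([des.sown_proportion[s] for s in des.species]))
        rows.append({
            "assemblage": aid, "fd_level": des.fd_level,
            "richness_level": des.richness_level, "richness": des.richness,
            "fdis": fdis(com, emb),
            "redundancy": functional_redundancy(com, d, rao_convention),
        })
    return pd.DataFrame(rows)


def seed_mix(design: AssemblageDesign) -> pd.DataFrame:
    """Sowing recipe: seeds/m^2 and g/m^2 per species (equal seed numbers).

    seeds/m^2 = density / S for every species; mass = seeds x TSW / 1000.
    """
    if design.thousand_seed_weight is None:
        raise ValueError(
            f"{design.assemblage_id}: thousand-seed weights required for a seed mix"
        )
    missing = [s for s in design.species
               if design.thousand_seed_weight.get(s) in (None, 0)
               or design.thousand_seed_weight.get(s, 0) <= 0]
    if missing:
        raise ValueError(f"missing/invalid thousand-seed weight for: {missing}")
    seeds = design.sowing_density / design.richness
    rows = [{
        "species": s,
        "seeds_per_m2": seeds,
        "g_per_m2": seeds * design.thousand_seed_weight[s] / 1000.0,
    } for s in design.species]
    return pd.DataFrame(rows)
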