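"""From trait tables to a species dissimilarity space.

Pipeline: select and log-transform traits (:func:`prepare_traits`), compute a
mixed-type Gower dissimilarity matrix (:func:`gower_distance`), then realise
the trait space as Euclidean coordinates by principal-coordinates analysis
with an optional Cailliez or square-root correction (:func:`embed`). The
embedding is what centroid-based metrics (functional dispersion) operate on.

Gower's coefficient handles the mixed trait kinds: numeric and ordinal traits
contribute range-normalised absolute differences, categorical and binary
traits contribute 0/1 mismatch, and weights are renormalised per species pair
over the traits where both species are non-missing (Gower's original rule),
so partial missingness never biases a distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from .data_model import NUMERIC_KINDS, TraitTable

__all__ = [
    "DissimilarityMatrix",
    "TraitEmbedding",
    "prepare_traits",
    "gower_distance",
    "embed",
    "PRESET_ARTHROPOD_10",
    "PRESET_ARTHROPOD_11",
    "PRESET_COMPETITION_9",
    "TRAIT_PRESETS",
]

# Named trait subsets. The arthropod-interaction set exists in a 10- and an
# 11-trait variant (the wider one adds the Raunkiaer life form); the 9-trait
# competition set covers morphology, phenology and resource-use strategy.
PRESET_ARTHROPOD_10 = (
    "nectar_amount", "extrafloral_nectar", "flower_diameter", "flower_color",
    "uv_pattern", "flowering_onset", "flowering_duration", "nectar_depth",
    "flowering_height", "leaf_distribution",
)
PRESET_ARTHROPOD_11 = PRESET_ARTHROPOD_10 + ("raunkiaer",)
PRESET_COMPETITION_9 = (
    "flowering_height", "leaf_distribution", "raunkiaer", "grime_c", "grime_r",
    "flowering_onset", "flowering_duration", "sla", "ldmc",
)
TRAIT_PRESETS = {
    "arthropod10": PRESET_ARTHROPOD_10,
    "arthropod11": PRESET_ARTHROPOD_11,
    "competition9": PRESET_COMPETITION_9,
}


@dataclass
class DissimilarityMatrix:
    """Square species x species dissimilarity matrix, entries in [0, 1]."""

    species: list
    values: np.ndarray

    def __post_init__(self):
        self.species = list(self.species)
        v = np.asarray(self.values, dtype=float)
        n = len(self.species)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} != ({n}, {n})")
        if np.isnan(v).any():
            raise ValueError("dissimilarity matrix contains missing entries")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("dissimilarity matrix not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("dissimilarity matrix diagonal not zero")
        if v.min() < -1e-12:
            raise ValueError("negative dissimilarity")
        self.values = v
        self._index = {s: i for i, s in enumerate(self.species)}

    def loc(self, species: list) -> np.ndarray:
        """Sub-matrix for the given species, in the given order."""
        idx = [self._index[s] for s in species]
        return self.values[np.ix_(idx, idx)]

    def relabel(self, mapping: dict) -> "DissimilarityMatrix":
        return DissimilarityMatrix([mapping.get(s, s) for s in self.species],
                                   self.values.copy())

    def write_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.species,
                     columns=self.species).to_csv(path, index_label="species_id")

    @classmethod
    def read_csv(cls, path) -> "DissimilarityMatrix":
        df = pd.read_csv(path, index_col="species_id")
        return cls(list(df.index), df.to_numpy(dtype=float))


def prepare_traits(traits: TraitTable, trait_subset) -> TraitTable:
    """Restrict to ``trait_subset`` and natural-log the flagged traits.

    ``trait_subset`` may be a preset name from :data:`TRAIT_PRESETS` or an
    explicit list of trait names. Traits flagged ``log_transform`` in the
    schema must be strictly positive wherever present.
    """
    if isinstance(trait_subset, str):
        try:
            trait_subset = TRAIT_PRESETS[trait_subset]
        except KeyError:
            raise KeyError(
                f"unknown preset {trait_subset!r}; presets: {sorted(TRAIT_PRESETS)}"
            ) from None
    sub = traits.subset_traits(list(trait_subset))
    data = sub.data.copy()
    for t in sub.schema.log_transform:
        col = data[t]
        bad = col[col.notna() & (col <= 0)]
        if len(bad):
            raise ValueError(
                f"non-positive value under log transform: trait {t!r}, "
                f"species {list(bad.index)}"
            )
        data[t] = np.log(col)
    return TraitTable(data, sub.schema)


def gower_distance(traits: TraitTable, weights: dict | None = None) -> DissimilarityMatrix:
    """Mixed-type Gower dissimilarity over all species pairs.

    Per trait: numeric/ordinal -> |x_i - x_j| / range over the whole table;
    categorical -> 0/1 mismatch; binary -> 0/1 symmetric mismatch. The
    dissimilarity is the weighted mean of per-trait contributions over traits
    where both species are non-missing (weights renormalised per pair).

    Raises if fewer than two species, if any pair shares no non-missing
    trait; a zero-range numeric trait contributes 0 with a warning.
    """
    n = len(traits)
    if n < 2:
        raise ValueError("need at least two species")
    names = traits.traits
    if weights is None:
        weights = {t: 1.0 for t in names}
    w = np.array([float(weights.get(t, 1.0)) for t in names])
    if (w < 0).any():
        raise ValueError("trait weights must be non-negative")

    num = np.zeros((n, n))     # sum of w * contribution
    den = np.zeros((n, n))     # sum of w over comparable traits
    for t, wt in zip(names, w):
        kind = traits.schema.kinds[t]
        col = traits.data[t]
        if kind in NUMERIC_KINDS:
            x = col.to_numpy(dtype=float)
            ok = np.isfinite(x)
            rng = np.nanmax(x) - np.nanmin(x) if ok.any() else np.nan
            diff = np.abs(x[:, None] - x[None, :])
            if not np.isfinite(rng) or rng == 0:
                if ok.any():
                    warnings.warn(
                        f"trait {t!r} has zero range; its contribution is 0",
                        stacklevel=2,
                    )
                contrib = np.zeros((n, n))
            else:
                contrib = diff / rng
        else:
            vals = col.to_numpy(dtype=object)
            ok = pd.notna(col).to_numpy()
            contrib = (vals[:, None] != vals[None, :]).astype(float)
        both = np.outer(ok, ok)
        num += np.where(both, np.nan_to_num(contrib), 0.0) * wt
        den += both * wt

    off = ~np.eye(n, dtype=bool)
    bad = off & (den == 0)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"species pair ({traits.species[i]}, {traits.species[j]}) shares "
            "no non-missing trait"
        )
    d = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(d, 0.0)
    return DissimilarityMatrix(traits.species, d)


# ---------------------------------------------------------------------------
# Principal-coordinates embedding
# ---------------------------------------------------------------------------


@dataclass
class TraitEmbedding:
    """Euclidean coordinates realising a dissimilarity matrix (PCoA axes)."""

    species: list
    coords: np.ndarray            # species x axes
    eigenvalues: np.ndarray       # retained, descending
    correction: str
    warnings: list = field(default_factory=list)

    def __post_init__(self):
        self.species = list(self.species)
        self._index = {s: i for i, s in enumerate(self.species)}

    @property
    def n_axes(self) -> int:
        return self.coords.shape[1]

    def loc(self, species: list) -> np.ndarray:
        idx = [self._index[s] for s in species]
        return self.coords[idx]

    def relabel(self, mapping: dict) -> "TraitEmbedding":
        return TraitEmbedding([mapping.get(s, s) for s in self.species],
                              self.coords, self.eigenvalues, self.correction,
                              list(self.warnings))

    def distances(self) -> np.ndarray:
        """Pairwise Euclidean distances between embedded species."""
        sq = np.sum(self.coords ** 2, axis=1)
        d2 = sq[:, None] + sq[None, :] - 2.0 * self.coords @ self.coords.T
        return np.sqrt(np.clip(d2, 0.0, None))


def _gram(d: np.ndarray) -> np.ndarray:
    """Double-centred Gram matrix B = -1/2 J d^2 J."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ (d ** 2) @ j


def _cailliez_constant(d: np.ndarray) -> float:
    """Smallest c such that d_ij + c (i != j) is Euclidean.

    Largest real eigenvalue of the 2n x 2n block matrix
    ``[[0, 2*B2], [-I, -4*B1]]`` with B2 = -1/2 J d^2 J and B1 = -1/2 J d J.
    """
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b2 = -0.5 * j @ (d ** 2) @ j
    b1 = -0.5 * j @ d @ j
    top = np.hstack([np.zeros((n, n)), 2.0 * b2])
    bot = np.hstack([-np.eye(n), -4.0 * b1])
    ev = np.linalg.eigvals(np.vstack([top, bot]))
    c = max(ev.real.max(), 0.0)
    return float(c)


def embed(d: DissimilarityMatrix, correction: str = "cailliez",
          eig_tol: float = 1e-10) -> TraitEmbedding:
    """Classical PCoA of a dissimilarity matrix, with optional correction.

    If the matrix is non-Euclidean (negative eigenvalues beyond tolerance)
    and ``correction`` is ``cailliez`` (add the Cailliez constant to
    off-diagonal dissimilarities) or ``sqrt`` (element-wise square root), the
    correction is applied and the decomposition redone. With
    ``correction="none"`` a warning is recorded on the embedding instead.
    Axes with eigenvalue > ``eig_tol`` x max eigenvalue are retained.
    """
    if correction not in ("none", "cailliez", "sqrt"):
        raise ValueError(f"unknown correction {correction!r}")
    mat = d.values
    notes: list = []

    def decompose(m):
        lam, vec = scipy.linalg.eigh(_gram(m))
        order = np.argsort(lam)[::-1]
        return lam[order], vec[:, order]

    lam, vec = decompose(mat)
    neg_tol = eig_tol * max(lam.max(), 1.0)
    applied = "none"
    if lam.min() < -neg_tol and correction != "none":
        if correction == "cailliez":
            c = _cailliez_constant(mat)
            mat = mat + c
            np.fill_diagonal(mat, 0.0)
            notes.append(f"cailliez constant {c:.6g} added")
        else:
            mat = np.sqrt(mat)
            notes.append("sqrt correction applied")
        lam, vec = decompose(mat)
        applied = correction
    elif lam.min() < -neg_tol:
        notes.append(
            f"non-Euclidean input left uncorrected (min eigenvalue {lam.min():.3g})"
        )

    keep = lam > eig_tol * max(lam.max(), eig_tol)
    if not keep.any():       # all species coincide
        coords = np.zeros((len(d.species), 1))
        return TraitEmbedding(d.species, coords, np.zeros(1), applied, notes)
    coords = vec[:, keep] * np.sqrt(lam[keep])
    return TraitEmbedding(d.species, coords, lam[keep], applied, notes)
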