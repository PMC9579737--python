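"""Core domain types for flower-strip community analysis.

Three kinds of input move through the pipeline:

* a species x trait table with mixed-type traits (:class:`TraitTable`),
* a long-format vegetation survey of percent ground cover per plot, year and
  species (:class:`SurveyTable`),
* seed-mixture designs crossing sown species richness with sown functional
  dispersion (:class:`AssemblageDesign`).

Species identifiers are normalised scientific names (``genus_species``,
lowercase, underscores) so that trait, survey and design files key
consistently. Missing trait values stay missing (NaN / None) at read time;
whether and how to handle them is the metric layer's decision.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TraitKind",
    "TraitSchema",
    "TraitTable",
    "SurveyTable",
    "AssemblageDesign",
    "read_trait_table",
    "read_survey",
    "table2_fixtures",
    "TABLE2_SPECIES",
    "GRASSES",
]

NUMERIC_KINDS = frozenset({"numeric", "ordinal"})
VALID_KINDS = frozenset({"numeric", "ordinal", "categorical", "binary"})

#: The three Poaceae shared by every assemblage.
GRASSES = (
    "arrhenatherum_elatius",
    "dactylis_glomerata",
    "schedonorus_arundinaceus",
)


@dataclass(frozen=True)
class TraitSchema:
    """Per-trait metadata: measurement kind and transform flag.

    Parameters
    ----------
    kinds
        Mapping trait name -> kind, one of ``numeric``, ``ordinal``,
        ``categorical``, ``binary``.
    log_transform
        Trait names whose values are natural-log transformed before distance
        computation (strictly positive where present).
    """

    kinds: Mapping[str, str]
    log_transform: frozenset = frozenset()

    def __post_init__(self):
        bad = {k: v for k, v in self.kinds.items() if v not in VALID_KINDS}
        if bad:
            raise ValueError(f"unknown trait kind(s): {bad}; valid kinds are {sorted(VALID_KINDS)}")
        unknown = set(self.log_transform) - set(self.kinds)
        if unknown:
            raise ValueError(f"log_transform names not in schema: {sorted(unknown)}")

    @property
    def traits(self) -> list:
        return list(self.kinds)

    def subset(self, names: Sequence[str]) -> "TraitSchema":
        missing = [n for n in names if n not in self.kinds]
        if missing:
            raise KeyError(
                f"unknown trait(s) {missing}; valid names: {sorted(self.kinds)}"
            )
        return TraitSchema(
            {n: self.kinds[n] for n in names},
            frozenset(n for n in self.log_transform if n in names),
        )


class TraitTable:
    """Species x trait table with per-trait kinds attached.

    ``data`` is a DataFrame indexed by species id. Numeric/ordinal columns are
    floats with NaN for missing; categorical/binary columns are objects with
    None/NaN for missing.
    """

    def __init__(self, data: pd.DataFrame, schema: TraitSchema):
        if data.index.has_duplicates:
            dups = sorted(data.index[data.index.duplicated()].unique())
            raise ValueError(f"duplicate species id(s): {dups}")
        missing_cols = [t for t in schema.traits if t not in data.columns]
        if missing_cols:
            raise ValueError(f"trait column(s) missing from data: {missing_cols}")
        data = data[schema.traits].copy()
        for t in schema.traits:
            if schema.kinds[t] in NUMERIC_KINDS:
                col = pd.to_numeric(data[t], errors="coerce")
                finite = np.isfinite(col.to_numpy(dtype=float)) | col.isna().to_numpy()
                if not finite.all():
                    raise ValueError(f"non-finite value in numeric trait {t!r}")
                data[t] = col.astype(float)
        self.data = data
        self.schema = schema

    # -- basic protocol ----------------------------------------------------
    @property
    def species(self) -> list:
        return list(self.data.index)

    @property
    def traits(self) -> list:
        return list(self.schema.traits)

    def __len__(self) -> int:
        return len(self.data)

    def __contains__(self, species_id) -> bool:
        return species_id in self.data.index

    # -- derived views -----------------------------------------------------
    def completeness(self) -> pd.Series:
        """Fraction of species with a non-missing value, per trait."""
        return self.data.notna().mean(axis=0)

    def subset_traits(self, names: Sequence[str]) -> "TraitTable":
        return TraitTable(self.data, self.schema.subset(names))

    def subset_species(self, species: Iterable[str]) -> "TraitTable":
        species = list(species)
        missing = [s for s in species if s not in self.data.index]
        if missing:
            raise KeyError(f"species not in trait table: {missing}")
        return TraitTable(self.data.loc[species], self.schema)

    def relabel(self, mapping: Mapping[str, str]) -> "TraitTable":
        """Return a copy whose species ids are renamed through ``mapping``."""
        return TraitTable(self.data.rename(index=dict(mapping)), self.schema)

    # -- IO ----------------------------------------------------------------
    def write_csv(self, path) -> None:
        self.data.to_csv(path, index_label="species_id")

    def __repr__(self) -> str:  # pragma: no cover
        return f"TraitTable({len(self)} species, {len(self.traits)} traits)"


def read_trait_table(path, schema: TraitSchema) -> TraitTable:
    """Read a species x trait CSV and attach per-trait kinds.

    The header must contain a ``species_id`` column plus every trait named in
    ``schema``. Empty cells are recorded as missing, never as zero. Duplicate
    species ids are a hard error.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"species_id": str})
    if "species_id" not in df.columns:
        raise ValueError(f"{path}: no 'species_id' column")
    df = df.set_index("species_id")
    return TraitTable(df, schema)


# ---------------------------------------------------------------------------
# Vegetation surveys
# ---------------------------------------------------------------------------

SURVEY_COLUMNS = ["plot", "transect", "block", "assemblage", "year", "species", "cover", "sown"]


class SurveyTable:
    """Long-format vegetation survey: one row per (plot, year, species).

    Columns: plot (1-9), transect (1-6), block (1-3), assemblage label, year,
    species id, percent cover >= 0, sown flag. Total cover per plot-year may
    exceed 100 because species cover overlaps in the eye-estimate convention.
    """

    def __init__(self, data: pd.DataFrame):
        missing = [c for c in SURVEY_COLUMNS if c not in data.columns]
        if missing:
            raise ValueError(f"survey missing column(s): {missing}")
        data = data[SURVEY_COLUMNS].copy()
        for c in ("plot", "transect", "block", "year"):
            data[c] = data[c].astype(int)
        data["cover"] = data["cover"].astype(float)
        data["sown"] = data["sown"].astype(bool)
        if (data["cover"] < 0).any():
            bad = data.loc[data["cover"] < 0].iloc[0]
            raise ValueError(
                f"negative cover {bad['cover']} for {bad['species']} "
                f"(plot {bad['plot']}, year {bad['year']})"
            )
        key = data[["plot", "year", "species"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0]
            raise ValueError(
                f"duplicate record for plot {dup['plot']}, year {dup['year']}, "
                f"species {dup['species']}"
            )
        self.data = data.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def years(self) -> list:
        return sorted(self.data["year"].unique())

    @property
    def species(self) -> list:
        return sorted(self.data["species"].unique())

    def plot_year_groups(self):
        """Iterate (keys, records) per plot-year; keys include design metadata."""
        for (plot, year), grp in self.data.groupby(["plot", "year"], sort=True):
            yield (plot, year), grp

    def community(self, plot: int, year: int, sown_only: bool = False) -> pd.Series:
        """Percent cover per species for one plot-year, indexed by species id."""
        grp = self.data[(self.data["plot"] == plot) & (self.data["year"] == year)]
        if sown_only:
            grp = grp[grp["sown"]]
        return grp.set_index("species")["cover"]

    def write_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    def __repr__(self) -> str:  # pragma: no cover
        return f"SurveyTable({len(self)} records, years {self.years})"


def read_survey(path, year_range: tuple | None = None,
                designs: Mapping[str, "AssemblageDesign"] | None = None) -> SurveyTable:
    """Read and validate a long-format survey CSV.

    Parameters
    ----------
    year_range
        Optional (lo, hi); years outside it trigger a warning, not an error.
    designs
        Optional assemblage designs keyed by id; the sown flag of each record
        is cross-checked against membership of the species in its
        assemblage's sown list (mismatch warns).
    """
    df = pd.read_csv(path)
    table = SurveyTable(df)
    if year_range is not None:
        lo, hi = year_range
        out = table.data[(table.data["year"] < lo) | (table.data["year"] > hi)]
        if len(out):
            warnings.warn(
                f"{len(out)} record(s) outside declared year range {year_range}",
                stacklevel=2,
            )
    if designs is not None:
        for aid, grp in table.data.groupby("assemblage"):
            if aid not in designs:
                continue
            sown_set = set(designs[aid].species)
            mism = grp[grp["sown"] != grp["species"].isin(sown_set)]
            if len(mism):
                warnings.warn(
                    f"assemblage {aid}: {len(mism)} record(s) with sown flag "
                    "inconsistent with the design species list",
                    stacklevel=2,
                )
    return table


# ---------------------------------------------------------------------------
# Assemblage designs
# ---------------------------------------------------------------------------


@dataclass
class AssemblageDesign:
    """A seed mixture: species list with sown proportions and design labels.

    ``sown_proportion`` is in seed numbers (not mass) and sums to one; within
    an assemblage all species are sown in equal seed numbers, so proportions
    are uniform.
    """

    assemblage_id: str
    fd_level: str                      # "low" | "high"
    richness_level: str                # "low" | "medium" | "high"
    list_id: int                       # 1 | 2
    species: tuple
    sown_proportion: dict
    sowing_density: float = 240.0      # seeds per m^2
    thousand_seed_weight: dict | None = None   # g per 1000 seeds, per species

    def __post_init__(self):
        self.species = tuple(self.species)
        total = sum(self.sown_proportion.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(
                f"{self.assemblage_id}: sown proportions sum to {total}, expected 1"
            )
        if set(self.sown_proportion) != set(self.species):
            raise ValueError(f"{self.assemblage_id}: proportion keys != species list")
        if self.sowing_density <= 0:
            raise ValueError("sowing density must be positive")

    @property
    def richness(self) -> int:
        return len(self.species)

    @classmethod
    def equal_proportions(cls, assemblage_id, fd_level, richness_level, list_id,
                          species, **kw) -> "AssemblageDesign":
        species = tuple(species)
        prop = {s: 1.0 / len(species) for s in species}
        return cls(assemblage_id, fd_level, richness_level, list_id, species, prop, **kw)

    # -- IO ----------------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "assemblage_id": self.assemblage_id,
            "fd_level": self.fd_level,
            "richness_level": self.richness_level,
            "list_id": self.list_id,
            "species": list(self.species),
            "sown_proportion": self.sown_proportion,
            "sowing_density": self.sowing_density,
            "thousand_seed_weight": self.thousand_seed_weight,
        }

    def write_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "AssemblageDesign":
        return cls(
            d["assemblage_id"], d["fd_level"], d["richness_level"], d["list_id"],
            tuple(d["species"]), dict(d["sown_proportion"]),
            d.get("sowing_density", 240.0), d.get("thousand_seed_weight"),
        )

    @classmethod
    def read_json(cls, path) -> "AssemblageDesign":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# The published eight assemblages
# ---------------------------------------------------------------------------

# Dicot membership of the eight assemblages. List-1 and list-2 mixtures share
# no dicots; the three grasses are common to all. Ids are normalised names; a
# synonym map to the published (TaxRef v12) binomials is provided below.
_LIST1_LFMS_ONLY = (
    "anthriscus_sylvestris", "arctium_minus", "foeniculum_vulgare",
    "hesperis_matronalis", "leucanthemum_vulgare", "medicago_sativa",
    "coronilla_varia", "trifolium_pratense",
)
_LIST1_CORE3 = ("achillea_millefolium", "alliaria_petiolata", "heracleum_sphondylium")
_LIST1_HFLS_EXTRA = ("cyanus_segetum", "trifolium_repens", "veronica_hederifolia")
_LIST1_HFMS_EXTRA = (
    "centaurea_scabiosa", "euphorbia_cyparissias", "hypericum_perforatum",
    "tanacetum_vulgare", "verbascum_densiflorum",
)
_LIST1_HFHS_EXTRA = (
    "ajuga_reptans", "bellis_perennis", "capsella_bursa_pastoris",
    "echium_vulgare", "galium_odoratum", "malva_sylvestris", "potentilla_reptans",
)

_LIST2_LFMS_ONLY = (
    "carum_carvi", "cynoglossum_officinale", "daucus_carota",
    "hypochaeris_radicata", "jacobaea_vulgaris", "lotus_corniculatus",
    "onobrychis_viciifolia", "melilotus_altissimus",
)
_LIST2_CORE3 = ("barbarea_vulgaris", "cota_tinctoria", "pastinaca_sativa")
_LIST2_HFLS_EXTRA = ("medicago_lupulina", "stellaria_media", "vicia_sativa")
_LIST2_HFMS_EXTRA = (
    "cichorium_intybus", "galium_mollugo", "knautia_arvensis",
    "plantago_lanceolata", "verbascum_lychnitis",
)
_LIST2_HFHS_EXTRA = (
    "geum_urbanum", "glechoma_hederacea", "lamium_album", "ranunculus_repens",
    "reseda_luteola", "taraxacum_ruderalia", "veronica_persica",
)

#: Dicot species per assemblage id (grasses added separately).
TABLE2_SPECIES = {
    "LFMS1": _LIST1_LFMS_ONLY + _LIST1_CORE3,
    "LFMS2": _LIST2_LFMS_ONLY + _LIST2_CORE3,
    "HFLS1": _LIST1_CORE3 + _LIST1_HFLS_EXTRA,
    "HFLS2": _LIST2_CORE3 + _LIST2_HFLS_EXTRA,
    "HFMS1": _LIST1_CORE3 + _LIST1_HFLS_EXTRA + _LIST1_HFMS_EXTRA,
    "HFMS2": _LIST2_CORE3 + _LIST2_HFLS_EXTRA + _LIST2_HFMS_EXTRA,
    "HFHS1": _LIST1_LFMS_ONLY + _LIST1_CORE3 + _LIST1_HFLS_EXTRA
             + _LIST1_HFMS_EXTRA + _LIST1_HFHS_EXTRA,
    "HFHS2": _LIST2_LFMS_ONLY + _LIST2_CORE3 + _LIST2_HFLS_EXTRA
             + _LIST2_HFMS_EXTRA + _LIST2_HFHS_EXTRA,
}

#: Normalised id -> published binomial, for the less obvious renamings.
SYNONYMS = {
    "capsella_bursa_pastoris": "Capsella bursa-pastoris",
    "taraxacum_ruderalia": "Taraxacum sect. Ruderalia",
    "cota_tinctoria": "Cota tinctoria",
    "cyanus_segetum": "Cyanus segetum",
    "jacobaea_vulgaris": "Jacobaea vulgaris",
    "schedonorus_arundinaceus": "Schedonorus arundinaceus",
}

_DESIGN_LABELS = {
    "LF": "low", "HF": "high",
    "LS": "low", "MS": "medium", "HS": "high",
}


def _placeholder_tsw(species: Iterable[str]) -> dict:
    """Synthetic thousand-seed weights (g), deterministic per species name.

    The study measured TSW per seed batch but did not publish the values, so
    fixtures carry these synthetic placeholders (log-uniform on 0.2-5 g).
    """
    out = {}
    for s in species:
        h = (abs(hash_name(s)) % 10_000) / 10_000.0
        out[s] = round(0.2 * (25.0 ** h), 4)   # 0.2 .. 5 g
    return out


def hash_name(s: str) -> int:
    """Stable (non-salted) string hash for placeholder generation."""
    h = 2166136261
    for ch in s.encode():
        h = ((h ^ ch) * 16777619) % (1 << 32)
    return h


def table2_fixtures(placeholder_tsw: bool = False) -> dict:
    """The eight published assemblage designs, keyed by id.

    Every design contains the three grasses plus its dicot list; proportions
    are uniform in seed numbers (1/S). With ``placeholder_tsw=True``, attach
    synthetic thousand-seed weights (the measured batch values were not
    published).
    """
    designs = {}
    for aid, dicots in TABLE2_SPECIES.items():
        species = tuple(dicots) + GRASSES
        tsw = _placeholder_tsw(species) if placeholder_tsw else None
        designs[aid] = AssemblageDesign.equal_proportions(
            aid,
            fd_level=_DESIGN_LABELS[aid[:2]],
            richness_level=_DESIGN_LABELS[aid[2:4]],
            list_id=int(aid[4]),
            species=species,
            thousand_seed_weight=tsw,
        )
    return designs
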