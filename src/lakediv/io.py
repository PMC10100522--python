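"""Data model, delimited-text IO, validation, and compilation rules.

Three tables drive everything downstream:

* **lake table** — one row per sampling location with geography, optional
  habitat (area, depth), sampling effort and climate columns;
* **taxon table** — one row per taxon with its 5-rank Linnaean lineage,
  lowest identified rank, and the two functional traits (body length in mm,
  ordinal feeding guild 1-4);
* **occurrence matrix** — binary lake x taxon incidence, stored wide
  (matrix) or long (lake_id, taxon_id, presence); the canonical on-disk
  form is long, sorted by (lake_id, taxon_id).

The compilation rules mirror how cumulative species lists from mixed
historical sources are cleaned: union semantics for duplicate records,
removal of non-target benthic/littoral groups, and a juvenile counting rule
in which a coarse (genus-or-higher) taxon adds to richness only when no
finer-ranked representative of the same clade is present in the same lake.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .trees import RANKS

LAKE_REQUIRED = ("lake_id", "elevation", "latitude")
LAKE_OPTIONAL = (
    "longitude", "area", "depth", "n_events", "n_years", "mat", "seasonal_diff",
)
TAXON_REQUIRED = ("taxon_id", "genus", "family", "order", "class", "rank")
TAXON_OPTIONAL = ("species", "body_length", "guild")

#: Non-target groups removed before analysis: benthic groups poorly caught
#: by tow nets plus large fast-moving shrimps known to be undersampled.
#: Laevicaudata (a suborder in some classifications) is scoped at the order
#: rank here because the lineage schema carries exactly five ranks.
DEFAULT_EXCLUSIONS = (
    ("class", "Ostracoda"),
    ("order", "Harpacticoida"),
    ("order", "Laevicaudata"),
    ("order", "Amphipoda"),
    ("order", "Anostraca"),
    ("order", "Notostraca"),
    ("order", "Mysida"),
)


class ValidationError(ValueError):
    """A table failed schema or content validation."""


# ---------------------------------------------------------------- validation

def validate_lake_table(df: pd.DataFrame) -> pd.DataFrame:
    for col in LAKE_REQUIRED:
        if col not in df.columns:
            raise ValidationError(f"lake table missing required column {col!r}")
    if df["lake_id"].duplicated().any():
        dup = df.loc[df["lake_id"].duplicated(), "lake_id"].iloc[0]
        raise ValidationError(f"duplicate lake_id {dup!r}")
    if not np.isfinite(df["elevation"].to_numpy(dtype=float)).all():
        raise ValidationError("non-finite elevation")
    lat = df["latitude"].to_numpy(dtype=float)
    if np.any((lat < -90) | (lat > 90)):
        raise ValidationError("latitude outside [-90, 90]")
    for col in ("n_events", "n_years"):
        if col in df.columns:
            vals = df[col].dropna()
            if (vals < 1).any():
                raise ValidationError(f"{col} must be >= 1 where present")
    return df


def validate_taxon_table(df: pd.DataFrame) -> pd.DataFrame:
    for col in TAXON_REQUIRED:
        if col not in df.columns:
            raise ValidationError(f"taxon table missing required column {col!r}")
    if df["taxon_id"].duplicated().any():
        dup = df.loc[df["taxon_id"].duplicated(), "taxon_id"].iloc[0]
        raise ValidationError(f"duplicate taxon_id {dup!r}")
    bad_rank = set(df["rank"]) - set(RANKS)
    if bad_rank:
        raise ValidationError(f"unknown rank values: {sorted(bad_rank)}")
    sp = df[df["rank"] == "species"]
    if "species" not in df.columns or sp["species"].isna().any():
        if len(sp):
            raise ValidationError("species-rank taxa must carry a species name")
    if "guild" in df.columns:
        g = df["guild"].dropna()
        if not g.isin([1, 2, 3, 4]).all():
            raise ValidationError("guild values must be in {1,2,3,4}")
    if "body_length" in df.columns:
        bl = df["body_length"].dropna()
        if (bl <= 0).any():
            raise ValidationError("body_length must be positive")
    return df


def validate_occurrences(
    occ: pd.DataFrame,
    lakes: pd.DataFrame | None = None,
    taxa: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Check a wide incidence matrix: binary values, resolvable indices."""
    vals = occ.to_numpy()
    bad = ~np.isin(vals, (0, 1))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValidationError(
            f"non-binary incidence {vals[i, j]!r} at lake {occ.index[i]!r}, "
            f"taxon {occ.columns[j]!r}"
        )
    if lakes is not None:
        unknown = set(occ.index) - set(lakes["lake_id"])
        if unknown:
            raise ValidationError(f"occurrence rows not in lake table: {sorted(unknown)[:5]}")
    if taxa is not None:
        unknown = set(occ.columns) - set(taxa["taxon_id"])
        if unknown:
            raise ValidationError(f"occurrence columns not in taxon table: {sorted(unknown)[:5]}")
    return occ.astype(np.int8)


# ------------------------------------------------------------- readers/writers

def read_lake_table(path, sep: str = ",") -> pd.DataFrame:
    return validate_lake_table(
        pd.read_csv(path, sep=sep, float_precision="round_trip"))


def write_lake_table(df: pd.DataFrame, path, sep: str = ",") -> None:
    validate_lake_table(df).to_csv(path, sep=sep, index=False)


def read_taxon_table(path, sep: str = ",") -> pd.DataFrame:
    return validate_taxon_table(
        pd.read_csv(path, sep=sep, float_precision="round_trip"))


def write_taxon_table(df: pd.DataFrame, path, sep: str = ",") -> None:
    validate_taxon_table(df).to_csv(path, sep=sep, index=False)


def read_occurrences(path, layout: str = "long", sep: str = ",") -> pd.DataFrame:
    """Read incidence as a wide 0/1 DataFrame (index lake_id, columns taxon_id).

    ``layout='long'`` expects columns (lake_id, taxon_id, presence); duplicate
    (lake, taxon) records collapse to a single presence (union semantics of
    cumulative species lists).  ``layout='wide'`` expects a matrix with a
    lake_id first column.
    """
    if layout == "long":
        long = pd.read_csv(path, sep=sep, float_precision="round_trip")
        for col in ("lake_id", "taxon_id", "presence"):
            if col not in long.columns:
                raise ValidationError(f"long occurrence file missing column {col!r}")
        if not long["presence"].isin([0, 1]).all():
            bad = long.loc[~long["presence"].isin([0, 1])].iloc[0]
            raise ValidationError(
                f"non-binary incidence {bad['presence']!r} at lake "
                f"{bad['lake_id']!r}, taxon {bad['taxon_id']!r}"
            )
        wide = (
            long.pivot_table(
                index="lake_id", columns="taxon_id", values="presence",
                aggfunc="max", fill_value=0,
            )
            .rename_axis(index="lake_id", columns=None)
        )
    elif layout == "wide":
        wide = pd.read_csv(path, sep=sep, index_col=0,
                           float_precision="round_trip")
        wide.index.name = "lake_id"
    else:
        raise ValueError(f"unknown layout {layout!r}")
    return validate_occurrences(wide)


def write_occurrences(occ: pd.DataFrame, path, layout: str = "long", sep: str = ",") -> None:
    """Write incidence; canonical long form keeps only presences, sorted."""
    validate_occurrences(occ)
    if layout == "long":
        long = (
            occ.rename_axis(index="lake_id")
            .stack()
            .rename("presence")
            .reset_index()
            .rename(columns={"level_1": "taxon_id"})
        )
        long.columns = ["lake_id", "taxon_id", "presence"]
        long = long[long["presence"] == 1].sort_values(["lake_id", "taxon_id"])
        long.to_csv(path, sep=sep, index=False)
    elif layout == "wide":
        occ.rename_axis(index="lake_id").to_csv(path, sep=sep)
    else:
        raise ValueError(f"unknown layout {layout!r}")


# --------------------------------------------------------- compilation rules

def filter_nontarget(
    occ: pd.DataFrame,
    taxa: pd.DataFrame,
    exclusions=DEFAULT_EXCLUSIONS,
) -> tuple[pd.DataFrame, pd.DataFrame, list]:
    """Remove non-target taxa by rank-scoped name matches.

    Returns (occurrences, taxon table, report) where the report lists the
    removed taxon_ids with the exclusion that matched.  Idempotent.
    """
    lineage_ranks = set(RANKS)
    removed: list[tuple[str, tuple[str, str]]] = []
    drop = set()
    for rank, name in exclusions:
        if rank not in lineage_ranks:
            raise ValueError(f"exclusion rank {rank!r} not in lineage schema {RANKS}")
        if rank not in taxa.columns:
            continue
        hits = taxa.loc[taxa[rank] == name, "taxon_id"]
        for tid in hits:
            if tid not in drop:
                removed.append((tid, (rank, name)))
                drop.add(tid)
    taxa_out = taxa[~taxa["taxon_id"].isin(drop)].reset_index(drop=True)
    keep_cols = [c for c in occ.columns if c not in drop]
    return occ[keep_cols], taxa_out, removed


def effective_richness_taxa(present_ids, taxa: pd.DataFrame) -> set:
    """Countable taxa for species richness under the juvenile rule.

    All species-level taxa present count.  A coarse taxon (identified to
    genus or higher, e.g. juveniles) counts only when no species-level taxon
    sharing its lowest named rank is present in the same lake — a coarse
    record shadowed by a congeneric adult adds nothing.
    """
    present_ids = list(present_ids)
    if not present_ids:
        return set()
    sub = taxa.set_index("taxon_id").loc[present_ids]
    species_level = sub[sub["rank"] == "species"]
    countable = set(species_level.index)
    coarse = sub[sub["rank"] != "species"]
    for tid, row in coarse.iterrows():
        scope_rank = row["rank"]  # lowest named rank of the coarse taxon
        scope_name = row[scope_rank]
        shadowed = (species_level[scope_rank] == scope_name).any()
        if not shadowed:
            countable.add(tid)
    return countable


def effective_richness(occ: pd.DataFrame, taxa: pd.DataFrame) -> pd.Series:
    """Per-lake species richness applying the juvenile counting rule."""
    out = {}
    cols = np.asarray(occ.columns)
    mat = occ.to_numpy(dtype=bool)
    for i, lake in enumerate(occ.index):
        out[lake] = len(effective_richness_taxa(cols[mat[i]], taxa))
    return pd.Series(out, name="richness").rename_axis("lake_id")
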