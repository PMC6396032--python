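"""Data model, delimited-table IO, validation and environment standardization.

All tables are plain delimited text (comma by default, tab accepted) with a
header row and string site/species labels.  The in-memory containers are
pandas DataFrames bundled in :class:`Dataset`:

* ``occurrence`` — sites x species incidence in {0, 1}
* ``traits``     — species x (4 categorical traits + adult_weight)
* ``taxonomy``   — species x 6 nested ranks (genus ... phylum)
* ``environment``— sites x real-valued predictors
* ``coords``     — sites x (x, y) planar centroid coordinates
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("macrofacets")

TRAIT_LEVELS: dict[str, set[str]] = {
    "life_form": {"free-floating", "emergent", "floating-leaved", "submerged"},
    "life_cycle": {"annual", "perennial"},
    "morphology": {"turion", "stem", "rosette", "leafy"},
    "sexual_propagation": {"monoecism", "dioecy"},
}
TAXONOMY_RANKS = ["genus", "family", "order", "subclass", "class", "phylum"]


@dataclass
class ValidationReport:
    """Record of every drop or coercion applied during validation."""

    messages: list[str] = field(default_factory=list)
    dropped_sites: list[str] = field(default_factory=list)
    dropped_species: list[str] = field(default_factory=list)

    def log(self, msg: str) -> None:
        self.messages.append(msg)
        logger.warning(msg)


@dataclass
class Dataset:
    occurrence: pd.DataFrame
    traits: pd.DataFrame
    taxonomy: pd.DataFrame
    environment: pd.DataFrame
    coords: pd.DataFrame

    @property
    def site_ids(self) -> list[str]:
        return list(self.occurrence.index)

    @property
    def species_ids(self) -> list[str]:
        return list(self.occurrence.columns)


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"table not found: {path}")
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    return df


def validate_dataset(
    occurrence: pd.DataFrame,
    traits: pd.DataFrame,
    taxonomy: pd.DataFrame,
    environment: pd.DataFrame,
    coords: pd.DataFrame,
) -> tuple[Dataset, ValidationReport]:
    """Validate and harmonize the five tables into a consistent bundle.

    Enforces: binary incidence, known trait levels, positive adult weight,
    nesting-consistent taxonomy, complete environment, distinct coordinate
    pairs.  Species lacking trait/taxonomy rows and sites lacking
    environment/coordinate rows are dropped with a report entry (the
    intersection policy); empty rows/columns of the occurrence matrix are
    dropped likewise.  Validation never silently alters data.
    """
    report = ValidationReport()
    occurrence = occurrence.copy()

    vals = occurrence.to_numpy()
    bad = ~np.isin(vals, (0, 1))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"occurrence matrix must be binary; cell "
            f"(site={occurrence.index[i]!r}, species={occurrence.columns[j]!r}) "
            f"has value {vals[i, j]!r}"
        )
    occurrence = occurrence.astype(int)

    for col, levels in TRAIT_LEVELS.items():
        if col not in traits.columns:
            raise ValueError(f"trait table missing column {col!r}")
        seen = set(traits[col].dropna().unique())
        extra = seen - levels
        if extra:
            raise ValueError(
                f"trait {col!r} has unknown level(s) {sorted(extra)}; "
                f"allowed: {sorted(levels)}"
            )
    if "adult_weight" not in traits.columns:
        raise ValueError("trait table missing column 'adult_weight'")
    if (traits["adult_weight"] <= 0).any():
        bad_sp = traits.index[traits["adult_weight"] <= 0][0]
        raise ValueError(f"adult_weight must be > 0 (species {bad_sp!r})")

    missing_ranks = [r for r in TAXONOMY_RANKS if r not in taxonomy.columns]
    if missing_ranks:
        raise ValueError(f"taxonomy table missing rank column(s) {missing_ranks}")
    for lo, hi in zip(TAXONOMY_RANKS[:-1], TAXONOMY_RANKS[1:]):
        parents = taxonomy.groupby(lo)[hi].nunique()
        broken = parents[parents > 1]
        if len(broken):
            raise ValueError(
                f"taxonomy nesting violated: {lo} {broken.index[0]!r} maps to "
                f"{broken.iloc[0]} different {hi} values"
            )

    if environment.isna().any().any():
        col = environment.columns[environment.isna().any()][0]
        raise ValueError(f"environment table has missing values (column {col!r})")
    if not {"x", "y"}.issubset(coords.columns):
        raise ValueError("coordinate table must have columns 'x' and 'y'")
    dup = coords.duplicated(subset=["x", "y"])
    if dup.any():
        raise ValueError(
            f"duplicated coordinate pair for site {coords.index[dup][0]!r}; "
            "duplicate centroids make the spanning-tree threshold degenerate"
        )

    # intersection policy on labels
    sp_keep = occurrence.columns.intersection(traits.index).intersection(taxonomy.index)
    sp_drop = occurrence.columns.difference(sp_keep)
    if len(sp_drop):
        report.dropped_species += list(sp_drop)
        report.log(
            f"dropped {len(sp_drop)} species absent from traits/taxonomy: "
            f"{list(sp_drop)[:5]}..."
        )
    site_keep = occurrence.index.intersection(environment.index).intersection(
        coords.index
    )
    site_drop = occurrence.index.difference(site_keep)
    if len(site_drop):
        report.dropped_sites += list(site_drop)
        report.log(
            f"dropped {len(site_drop)} sites absent from environment/coords: "
            f"{list(site_drop)[:5]}..."
        )
    occurrence = occurrence.loc[site_keep, sp_keep]

    empty_sp = occurrence.columns[occurrence.sum(axis=0) == 0]
    if len(empty_sp):
        report.dropped_species += list(empty_sp)
        report.log(f"dropped {len(empty_sp)} species with no presences")
        occurrence = occurrence.drop(columns=empty_sp)
    empty_sites = occurrence.index[occurrence.sum(axis=1) == 0]
    if len(empty_sites):
        report.dropped_sites += list(empty_sites)
        report.log(f"dropped {len(empty_sites)} sites with no presences")
        occurrence = occurrence.drop(index=empty_sites)

    ds = Dataset(
        occurrence=occurrence,
        traits=traits.loc[occurrence.columns],
        taxonomy=taxonomy.loc[occurrence.columns, TAXONOMY_RANKS],
        environment=environment.loc[occurrence.index],
        coords=coords.loc[occurrence.index, ["x", "y"]].astype(float),
    )
    return ds, report


def read_dataset(
    occurrence: str | Path,
    traits: str | Path,
    taxonomy: str | Path,
    environment: str | Path,
    coords: str | Path,
) -> tuple[Dataset, ValidationReport]:
    """Read and validate the five delimited tables of one study."""
    return validate_dataset(
        _read_table(occurrence),
        _read_table(traits),
        _read_table(taxonomy),
        _read_table(environment),
        _read_table(coords),
    )


def standardize_environment(
    environment: pd.DataFrame,
    transforms: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Transform (optionally) then center/scale each predictor to mean 0, var 1.

    ``transforms`` maps column name to one of ``none``/``log``/``sqrt``;
    the transform is applied before standardization.  The sample variance
    uses denominator ``n - 1``.  Standardization is idempotent.
    """
    transforms = transforms or {}
    out = environment.astype(float).copy()
    for col, how in transforms.items():
        if col not in out.columns:
            raise KeyError(f"transform given for unknown column {col!r}")
        if how == "none":
            continue
        if how == "log":
            if (out[col] <= 0).any():
                raise ValueError(f"log transform requires strictly positive {col!r}")
            out[col] = np.log(out[col])
        elif how == "sqrt":
            if (out[col] < 0).any():
                raise ValueError(f"sqrt transform requires nonnegative {col!r}")
            out[col] = np.sqrt(out[col])
        else:
            raise ValueError(f"unknown transform {how!r} for column {col!r}")
    sd = out.std(ddof=1)
    zero = sd[sd == 0]
    if len(zero):
        raise ValueError(f"cannot standardize zero-variance column {zero.index[0]!r}")
    out = (out - out.mean()) / sd
    out.attrs["standardized"] = True
    return out


def write_results(results, out_dir: str | Path) -> list[Path]:
    """Write every result table of a pipeline run plus a run manifest.

    ``results`` is the :class:`~macrofacets.pipeline.PipelineResults`
    bundle.  Returns the list of files written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _w(name: str, df: pd.DataFrame) -> None:
        p = out_dir / name
        df.to_csv(p, float_format="%.10g")
        written.append(p)

    _w("diversity_profile.csv", results.profile)
    _w("congruence.csv", results.congruence.set_index(["index_a", "index_b"]))
    _w("correlation_r.csv", results.correlation_r)
    _w("correlation_p.csv", results.correlation_p)
    _w("selection_table.csv", results.table1.set_index(["index", "factor"]))
    _w("variation_partition.csv", results.partition)
    _w("correlograms.csv", results.correlograms.set_index(["series", "class"]))
    _w("dbmem_basis.csv", results.dbmem_basis)
    _w("vif.csv", results.vif.to_frame("VIF"))

    manifest = {
        "config": results.config.to_dict(),
        "n_sites": int(results.profile.shape[0]),
        "versions": _versions(),
        "validation": results.validation_messages,
    }
    mpath = out_dir / "manifest.json"
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    written.append(mpath)
    return written


def _versions() -> dict[str, str]:
    import scipy
    import sklearn
    import statsmodels

    return {
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "scikit-learn": sklearn.__version__,
        "statsmodels": statsmodels.__version__,
    }


def warn_once(msg: str) -> None:
    warnings.warn(msg, stacklevel=3)
    logger.warning(msg)
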