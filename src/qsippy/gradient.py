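"""Gradient fractionation data model and I/O.

CsCl density-gradient SIP experiments produce, per soil core, a series of
gradient fractions (or pooled density groups) whose buoyant density is
measured by refractive index. This module holds the domain records for
those samples, the refractive-index -> density conversion, the
light/medium/heavy density-group scheme, and readers/writers for the
taxon-by-sample feature table and its companion metadata and qPCR tables.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RiCalibration",
    "DensityGroupScheme",
    "FractionSample",
    "QpcrMeasurement",
    "FeatureTable",
    "ri_to_density",
    "assign_density_group",
    "read_feature_table",
    "write_feature_table",
    "read_metadata",
    "read_qpcr",
]

#: Plausible buoyant-density window for DNA in a CsCl gradient (g/mL).
DENSITY_RANGE = (1.60, 1.85)

#: Plausible refractive-index window for CsCl gradient fractions.
RI_RANGE = (1.3, 1.5)

VALID_UNITS = ("read_count", "relative_abundance", "copies_per_ng_dna")


class DataError(ValueError):
    """Raised when input tables violate a structural invariant."""


@dataclass(frozen=True)
class RiCalibration:
    """Linear refractive-index -> buoyant-density calibration.

    The default slope/intercept is the standard CsCl relation at 20 degC
    (rho = 10.9276 * RI - 13.593). Instruments and gradient buffers vary,
    so both constants are configurable.
    """

    slope: float = 10.9276
    intercept: float = -13.593
    temperature_reference: float = 20.0

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError(f"calibration slope must be positive, got {self.slope}")


def ri_to_density(ri, cal: RiCalibration | None = None):
    """Convert refractive index to buoyant density (g/mL).

    Accepts scalars or arrays. Out-of-range refractive indices are
    converted anyway but trigger a warning so the caller can flag the
    record.
    """
    if cal is None:
        raise ValueError("an RiCalibration is required")
    ri_arr = np.asarray(ri, dtype=float)
    bad = (ri_arr <= RI_RANGE[0]) | (ri_arr >= RI_RANGE[1])
    if np.any(bad):
        warnings.warn(
            f"{int(np.sum(bad))} refractive index value(s) outside {RI_RANGE}; "
            "converted but flagged",
            stacklevel=2,
        )
    out = cal.slope * ri_arr + cal.intercept
    return float(out) if np.isscalar(ri) or out.ndim == 0 else out


@dataclass(frozen=True)
class DensityGroupScheme:
    """Ordered half-open density bins pooling gradient fractions.

    The default scheme pools fractions into light [1.65, 1.69), medium
    [1.69, 1.75) and heavy [1.75, 1.80] g/mL groups; the final bin is
    closed above so the full observed range is covered.
    """

    bins: tuple[tuple[str, float, float], ...] = (
        ("light", 1.65, 1.69),
        ("medium", 1.69, 1.75),
        ("heavy", 1.75, 1.80),
    )

    def __post_init__(self) -> None:
        prev_high = -np.inf
        for name, low, high in self.bins:
            if not low < high:
                raise ValueError(f"bin {name!r} has non-positive width [{low}, {high})")
            if low < prev_high:
                raise ValueError(f"bin {name!r} overlaps the previous bin")
            prev_high = high

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _, _ in self.bins)

    @property
    def span(self) -> tuple[float, float]:
        return (self.bins[0][1], self.bins[-1][2])

    def midpoints(self) -> dict[str, float]:
        """Design density of each group: the midpoint of its bin."""
        return {name: 0.5 * (low + high) for name, low, high in self.bins}

    def edges(self) -> np.ndarray:
        return np.array([self.bins[0][1]] + [high for _, _, high in self.bins])


def assign_density_group(density: float, scheme: DensityGroupScheme | None = None,
                         sample_id: str | None = None) -> str:
    """Assign a buoyant density to its (unique) density group.

    Bins are half-open [low, high); the topmost bin is closed above.
    """
    if scheme is None:
        scheme = DensityGroupScheme()
    last = len(scheme.bins) - 1
    for i, (name, low, high) in enumerate(scheme.bins):
        if low <= density < high or (i == last and density == high):
            return name
    who = f" (sample {sample_id})" if sample_id else ""
    raise DataError(f"density {density} g/mL outside all density-group bins{who}")


@dataclass
class FractionSample:
    """One density fraction (or pooled density group) of one soil core."""

    sample_id: str
    core_id: str
    isotope: str  # "12C", "13C" or "H2O"
    density: float | None = None
    refractive_index: float | None = None
    wetland: str | None = None  # "natural" / "restored"
    redox: str | None = None  # "anoxic" / "oxic" / "oxic-anoxic"
    fraction_index: int | None = None  # 1..12; absent for pre-grouped data
    dna_mass: float | None = None  # ng recovered
    density_group: str | None = None
    flagged: bool = False

    def __post_init__(self) -> None:
        if not self.core_id or not self.isotope:
            raise ValueError(f"sample {self.sample_id}: core_id and isotope are required")
        if self.density is not None and not (
            DENSITY_RANGE[0] < self.density < DENSITY_RANGE[1]
        ):
            warnings.warn(
                f"sample {self.sample_id}: density {self.density} g/mL outside "
                f"{DENSITY_RANGE}; record flagged",
                stacklevel=2,
            )
            self.flagged = True


@dataclass
class QpcrMeasurement:
    """Mean 16S rRNA gene copies per ng DNA for one sample."""

    sample_id: str
    copies_per_ng_dna: float
    replicate_values: list[float] | None = None

    def __post_init__(self) -> None:
        if not self.copies_per_ng_dna > 0:
            raise ValueError(
                f"sample {self.sample_id}: qPCR total must be positive, "
                f"got {self.copies_per_ng_dna}"
            )


class FeatureTable:
    """Taxon-by-sample abundance matrix with unit and taxonomy.

    Thin wrapper over a pandas DataFrame (rows = taxa, columns = samples)
    carrying the abundance unit (``read_count``, ``relative_abundance`` or
    ``copies_per_ng_dna``) and an optional taxonomy table indexed by
    taxon id with rank columns (phylum ... genus).
    """

    def __init__(self, data: pd.DataFrame, unit: str = "read_count",
                 taxonomy: pd.DataFrame | None = None):
        if unit not in VALID_UNITS:
            raise ValueError(f"unit must be one of {VALID_UNITS}, got {unit!r}")
        if data.index.has_duplicates:
            dupes = data.index[data.index.duplicated()].unique().tolist()
            raise DataError(f"duplicate taxon ids: {dupes}")
        if data.columns.has_duplicates:
            dupes = data.columns[data.columns.duplicated()].unique().tolist()
            raise DataError(f"duplicate sample ids: {dupes}")
        if (data.to_numpy() < 0).any():
            raise DataError("feature table contains negative values")
        self.data = data
        self.unit = unit
        self.taxonomy = taxonomy

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def copy(self) -> "FeatureTable":
        tax = None if self.taxonomy is None else self.taxonomy.copy()
        return FeatureTable(self.data.copy(), self.unit, tax)

    def select_samples(self, sample_ids: Sequence[str]) -> "FeatureTable":
        return FeatureTable(self.data[list(sample_ids)], self.unit, self.taxonomy)

    def select_taxa(self, taxon_ids: Sequence[str]) -> "FeatureTable":
        return FeatureTable(self.data.loc[list(taxon_ids)], self.unit, self.taxonomy)

    def __eq__(self, other) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        same = self.unit == other.unit and self.data.shape == other.data.shape
        if not same:
            return False
        a = self.data.sort_index(axis=0).sort_index(axis=1)
        b = other.data.sort_index(axis=0).sort_index(axis=1)
        return bool(
            a.index.equals(b.index)
            and a.columns.equals(b.columns)
            and np.array_equal(a.to_numpy(dtype=float), b.to_numpy(dtype=float))
        )

    def __repr__(self) -> str:
        t, s = self.shape
        return f"<FeatureTable {t} taxa x {s} samples [{self.unit}]>"


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_feature_table(table: FeatureTable, path, format: str | None = None) -> None:
    """Write a feature table to TSV/CSV (with a JSON sidecar) or BIOM.

    TSV/CSV stores taxa as rows and samples as columns; the unit and
    taxonomy ride along in ``<path>.meta.json`` so round trips are
    lossless. BIOM output uses the JSON (text) BIOM format with taxonomy
    as observation metadata.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt in ("tsv", "csv"):
        sep = "\t" if fmt == "tsv" else ","
        table.data.rename_axis("taxon_id").to_csv(path, sep=sep)
        meta: dict = {"unit": table.unit}
        if table.taxonomy is not None:
            meta["taxonomy"] = {
                "columns": list(table.taxonomy.columns),
                "rows": {
                    str(i): [None if pd.isna(v) else v for v in row]
                    for i, row in table.taxonomy.iterrows()
                },
            }
        _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    elif fmt == "biom":
        import biom

        obs_md = None
        if table.taxonomy is not None:
            tax = table.taxonomy.reindex(table.taxon_ids)
            obs_md = [
                {"taxonomy": [None if pd.isna(v) else v for v in row]}
                for _, row in tax.iterrows()
            ]
        bt = biom.Table(
            table.data.to_numpy(dtype=float),
            observation_ids=table.taxon_ids,
            sample_ids=table.sample_ids,
            observation_metadata=obs_md,
        )
        Path(path).write_text(bt.to_json(f"qsippy unit={table.unit}"))
    else:
        raise ValueError(f"unsupported format {fmt!r}")


def read_feature_table(path, format: str | None = None,
                       unit: str | None = None) -> FeatureTable:
    """Read a feature table written by :func:`write_feature_table`."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt in ("tsv", "csv"):
        sep = "\t" if fmt == "tsv" else ","
        data = pd.read_csv(path, sep=sep, index_col=0)
        data.index = data.index.astype(str)
        taxonomy = None
        table_unit = unit or "read_count"
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            table_unit = unit or meta.get("unit", table_unit)
            if "taxonomy" in meta:
                tx = meta["taxonomy"]
                taxonomy = pd.DataFrame.from_dict(
                    tx["rows"], orient="index", columns=tx["columns"]
                )
        return FeatureTable(data, table_unit, taxonomy)
    if fmt == "biom":
        import biom.parse

        with open(path) as fh:
            bt = biom.parse.parse_biom_table(fh)
        data = pd.DataFrame(
            bt.matrix_data.toarray(),
            index=[str(i) for i in bt.ids("observation")],
            columns=[str(i) for i in bt.ids("sample")],
        )
        taxonomy = None
        md = bt.metadata(axis="observation")
        if md is not None and any(m and "taxonomy" in m for m in md):
            ranks = ["domain", "phylum", "class", "order", "family", "genus"]
            rows = {}
            for tid, m in zip(data.index, md):
                lineage = list((m or {}).get("taxonomy") or [])
                rows[tid] = lineage[: len(ranks)] + [None] * (len(ranks) - len(lineage))
            taxonomy = pd.DataFrame.from_dict(rows, orient="index", columns=ranks)
        table_unit = unit or "read_count"
        # unit travels in the generated-by string when written by qsippy
        gen = getattr(bt, "generated_by", "") or ""
        if unit is None and "unit=" in gen:
            table_unit = gen.split("unit=")[1].split()[0]
        return FeatureTable(data, table_unit, taxonomy)
    raise ValueError(f"unsupported format {fmt!r}")


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("tsv", "txt"):
        return "tsv"
    if suffix == "csv":
        return "csv"
    if suffix == "biom":
        return "biom"
    raise ValueError(f"cannot infer table format from {path.name!r}")


REQUIRED_METADATA_COLUMNS = ("sample_id", "core_id", "isotope")


def read_metadata(path, cal: RiCalibration | None = None,
                  scheme: DensityGroupScheme | None = None) -> pd.DataFrame:
    """Read sample metadata, deriving density and density group as needed.

    The CSV must carry sample_id, core_id and isotope plus either a
    ``density`` column (g/mL) or a ``refractive_index`` column to be
    converted through ``cal``. Rows without a ``density_group`` get one
    assigned from ``scheme``; pre-grouped rows pass through untouched.
    """
    md = pd.read_csv(path)
    missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in md.columns]
    if missing:
        raise DataError(f"metadata is missing required column(s): {missing}")
    if md["sample_id"].duplicated().any():
        raise DataError("metadata contains duplicate sample_id values")
    md = md.set_index("sample_id", drop=False)
    if "density" not in md.columns or md["density"].isna().any():
        if "refractive_index" not in md.columns:
            raise DataError("metadata needs a density or refractive_index column")
        cal = cal or RiCalibration()
        converted = ri_to_density(md["refractive_index"].to_numpy(dtype=float), cal)
        if "density" in md.columns:
            md["density"] = md["density"].fillna(pd.Series(converted, index=md.index))
        else:
            md["density"] = converted
    scheme = scheme or DensityGroupScheme()
    if "density_group" not in md.columns:
        md["density_group"] = [
            assign_density_group(rho, scheme, sid)
            for rho, sid in zip(md["density"], md["sample_id"])
        ]
    else:
        need = md["density_group"].isna()
        md.loc[need, "density_group"] = [
            assign_density_group(rho, scheme, sid)
            for rho, sid in zip(md.loc[need, "density"], md.loc[need, "sample_id"])
        ]
    return md


def read_qpcr(path) -> dict[str, QpcrMeasurement]:
    """Read a qPCR table (sample_id, copies_per_ng_dna) into measurements."""
    df = pd.read_csv(path)
    for col in ("sample_id", "copies_per_ng_dna"):
        if col not in df.columns:
            raise DataError(f"qPCR table is missing column {col!r}")
    out: dict[str, QpcrMeasurement] = {}
    for _, row in df.iterrows():
        m = QpcrMeasurement(str(row["sample_id"]), float(row["copies_per_ng_dna"]))
        if m.sample_id in out:
            raise DataError(f"duplicate qPCR record for sample {m.sample_id}")
        out[m.sample_id] = m
    return out
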