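"""Readers and writers for every external format the pipeline touches.

Slice stacks arrive as directories of single-channel BMP/PNG/TIFF images
(one per cross-section, sortable by zero-padded numeric suffix); tabular
inputs (traits, genetic map, genotype matrix, DEG table) are headered CSV.
Downstream modules only ever see the in-memory domain types.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Callable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .types import DomainError, LabelVolume, Tissue, VoxelVolume

SLICE_EXTENSIONS = {".bmp", ".png", ".tif", ".tiff"}

LABEL_META_NAME = "labels_meta.txt"


class SchemaError(ValueError):
    """CSV table fails its declared schema."""


# ---------------------------------------------------------------------------
# slice stacks


def read_slice_stack(directory_path, voxel_size_um: float) -> VoxelVolume:
    """Read a directory of single-channel slice images into a VoxelVolume.

    Slices are stacked in ascending filename order (zero-padded numeric
    suffixes make lexicographic order the slice order); axis order of the
    result is (slice, row, column).
    """
    directory = Path(directory_path)
    files = sorted(
        p for p in directory.iterdir()
        if p.suffix.lower() in SLICE_EXTENSIONS and p.is_file()
    )
    if not files:
        raise DomainError(f"no readable slice images in {directory}")
    slices = []
    for p in files:
        img = iio.imread(p)
        if img.ndim != 2:
            raise DomainError(f"{p.name}: multi-channel image, expected grayscale")
        slices.append(img)
    shapes = {s.shape for s in slices}
    if len(shapes) > 1:
        raise DomainError(f"mixed slice dimensions: {sorted(shapes)}")
    stack = np.stack(slices, axis=0)
    bit_depth = 16 if stack.dtype.itemsize > 1 else 8
    return VoxelVolume(stack.astype(np.int64), voxel_size_um, bit_depth)


def write_slice_stack(vv: VoxelVolume, directory_path, fmt: str = "png") -> None:
    """Write a VoxelVolume as zero-padded numbered slice images."""
    directory = Path(directory_path)
    directory.mkdir(parents=True, exist_ok=True)
    dtype = np.uint8 if vv.bit_depth == 8 else np.uint16
    width = max(4, len(str(vv.shape[0] - 1)))
    for i, sl in enumerate(vv.data):
        iio.imwrite(directory / f"slice_{i:0{width}d}.{fmt}", sl.astype(dtype))


def write_label_volume(lv: LabelVolume, path) -> None:
    """Write labels as one indexed PNG per slice plus a sidecar metadata file.

    Round-trips losslessly through :func:`read_label_volume`.
    """
    directory = Path(path)
    directory.mkdir(parents=True, exist_ok=True)
    width = max(4, len(str(lv.shape[0] - 1)))
    for i, sl in enumerate(lv.labels):
        iio.imwrite(directory / f"label_{i:0{width}d}.png", sl.astype(np.uint8))
    legend = ", ".join(f"{int(t)}={t.name}" for t in Tissue)
    meta = (
        f"voxel_size_um={lv.voxel_size_um!r}\n"
        f"n_slices={lv.shape[0]}\n"
        f"legend={legend}\n"
    )
    (directory / LABEL_META_NAME).write_text(meta)


def read_label_volume(path) -> LabelVolume:
    directory = Path(path)
    meta_file = directory / LABEL_META_NAME
    if not meta_file.exists():
        raise DomainError(f"missing {LABEL_META_NAME} in {directory}")
    meta = dict(
        line.split("=", 1)
        for line in meta_file.read_text().splitlines()
        if "=" in line
    )
    files = sorted(directory.glob("label_*.png"))
    if not files:
        raise DomainError(f"no label slices in {directory}")
    stack = np.stack([iio.imread(p) for p in files], axis=0)
    return LabelVolume(stack, float(meta["voxel_size_um"]))


# ---------------------------------------------------------------------------
# CSV tables with schemas


@dataclasses.dataclass
class ColumnSpec:
    name: str
    dtype: str = "float"  # "float" | "str" | "category"
    allowed: Sequence | None = None      # for category columns
    check: Callable[[pd.Series], pd.Series] | None = None  # bool mask of valid rows
    allow_na: bool = False


@dataclasses.dataclass
class TableSchema:
    """Declares required columns and value domains for one CSV format."""

    name: str
    columns: list[ColumnSpec]
    table_check: Callable[[pd.DataFrame], None] | None = None


def _check_map_ordering(df: pd.DataFrame) -> None:
    for chrom, sub in df.groupby("chrom", sort=False):
        for col in ("cM", "Mb"):
            if not sub[col].is_monotonic_increasing:
                raise SchemaError(
                    f"non-monotone {col} within chromosome {chrom}"
                )


DEG_SCHEMA = TableSchema("deg", [
    ColumnSpec("gene_id", "str"),
    ColumnSpec("chrom", "str"),
    ColumnSpec("pos_mb", "float", check=lambda s: s >= 0),
    ColumnSpec("log2fc", "float"),
    ColumnSpec("pvalue", "float", check=lambda s: (s > 0) & (s <= 1)),
])

MAP_SCHEMA = TableSchema("map", [
    ColumnSpec("chrom", "str"),
    ColumnSpec("marker", "str"),
    ColumnSpec("cM", "float", check=lambda s: s >= 0),
    ColumnSpec("Mb", "float", check=lambda s: s >= 0),
], table_check=_check_map_ordering)

GENOTYPE_CODES = ("A", "B", "NA")


def genotype_schema(markers: Sequence[str]) -> TableSchema:
    cols = [ColumnSpec("line_id", "str")]
    cols += [ColumnSpec(m, "category", allowed=GENOTYPE_CODES, allow_na=True)
             for m in markers]
    return TableSchema("genotypes", cols)


def trait_schema(trait_columns: Sequence[str]) -> TableSchema:
    cols = [ColumnSpec("line_id", "str"), ColumnSpec("grain_id", "str")]
    cols += [ColumnSpec(t, "float") for t in trait_columns]
    return TableSchema("traits", cols)


def read_table(path, schema: TableSchema) -> pd.DataFrame:
    """Read a headered CSV and validate it against ``schema``.

    Rows violating a column's value domain are rejected with their (1-based,
    header excluded) row numbers listed in the error.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c.name for c in schema.columns if c.name not in df.columns]
    if missing:
        raise SchemaError(f"{schema.name}: missing required columns {missing}")
    parts: dict[str, pd.Series] = {}
    for spec in schema.columns:
        raw = df[spec.name].str.strip()
        if spec.dtype == "float":
            vals = pd.to_numeric(raw, errors="coerce")
            bad = vals.isna() & (raw != "")
            if bad.any():
                rows = [(i + 1, raw.iloc[i]) for i in np.flatnonzero(bad.to_numpy())]
                raise SchemaError(
                    f"{schema.name}: unparseable numeric in column "
                    f"'{spec.name}' at rows {rows}"
                )
            if spec.check is not None:
                ok = spec.check(vals) | vals.isna()
                if not ok.all():
                    rows = (np.flatnonzero(~ok.to_numpy()) + 1).tolist()
                    raise SchemaError(
                        f"{schema.name}: column '{spec.name}' out of domain "
                        f"at rows {rows}"
                    )
            parts[spec.name] = vals
        elif spec.dtype == "category":
            vals = raw.where(raw != "", "NA")
            bad = ~vals.isin(spec.allowed)
            if bad.any():
                cells = [(i + 1, vals.iloc[i]) for i in np.flatnonzero(bad.to_numpy())]
                raise SchemaError(
                    f"{schema.name}: column '{spec.name}' has values outside "
                    f"{tuple(spec.allowed)} at (row, value): {cells}"
                )
            parts[spec.name] = vals.replace("NA", np.nan) if spec.allow_na else vals
        else:
            if (raw == "").any() and not spec.allow_na:
                rows = (np.flatnonzero((raw == "").to_numpy()) + 1).tolist()
                raise SchemaError(
                    f"{schema.name}: empty '{spec.name}' at rows {rows}"
                )
            parts[spec.name] = raw
    out = pd.concat(parts, axis=1)
    if schema.table_check is not None:
        schema.table_check(out)
    return out


def write_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
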