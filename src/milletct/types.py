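"""Core domain types shared across the pipeline.

A grain stack is carried as a :class:`VoxelVolume` (grayscale intensities
plus physical voxel size), segmentation results as a :class:`LabelVolume`
(hard five-class partition), and per-grain morphometry as
:class:`GrainTraits` (the 15 structural traits). Genetic inputs live in
:class:`GeneticMap` / :class:`RILPopulation`; a mapped locus is a
:class:`QTLResult`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
import pandas as pd


class Tissue(IntEnum):
    """Voxel label codes. BACKGROUND is air outside the grain; CAVITY is the
    air gap between the caryopsis and the hull."""

    BACKGROUND = 0
    EMBRYO = 1
    ENDOSPERM = 2
    CAVITY = 3
    HULL = 4


#: The four grain tissues (everything but background).
GRAIN_TISSUES = (Tissue.EMBRYO, Tissue.ENDOSPERM, Tissue.CAVITY, Tissue.HULL)


class DomainError(ValueError):
    """Invalid domain object or operation precondition violation."""


@dataclass
class VoxelVolume:
    """A 3D grayscale stack with isotropic physical voxel size.

    Axis order is (slice, row, column) = (z, y, x); physical coordinates are
    ``index * voxel_size_um``.
    """

    data: np.ndarray
    voxel_size_um: float
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise DomainError(f"volume must be 3D, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise DomainError("all three dimensions must be >= 1")
        if self.voxel_size_um <= 0:
            raise DomainError("voxel_size_um must be positive")
        if self.bit_depth not in (8, 16):
            raise DomainError("bit_depth must be 8 or 16")
        if self.data.size and (
            self.data.min() < 0 or self.data.max() > 2**self.bit_depth - 1
        ):
            raise DomainError(
                f"intensities must lie in [0, {2**self.bit_depth - 1}]"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def dynamic_range(self) -> int:
        return 2**self.bit_depth - 1


@dataclass
class LabelVolume:
    """Per-voxel tissue labels: a hard partition into the five Tissue codes."""

    labels: np.ndarray
    voxel_size_um: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.ndim != 3:
            raise DomainError("label volume must be 3D")
        if self.voxel_size_um <= 0:
            raise DomainError("voxel_size_um must be positive")
        valid = {int(t) for t in Tissue}
        present = set(np.unique(self.labels).tolist())
        if not present <= valid:
            raise DomainError(f"unknown label codes: {sorted(present - valid)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def mask(self, tissue: Tissue) -> np.ndarray:
        return self.labels == int(tissue)


#: Canonical trait column order used in every trait CSV.
TRAIT_COLUMNS = [
    "K-Volume", "EM-Volume", "EN-Volume", "C-Volume", "H-Volume",
    "K-Area", "EM-Area", "EN-Area", "C-Area", "H-Area",
    "H-A-T",
    "EM-Ratio", "EN-Ratio", "C-Ratio", "H-Ratio",
]


@dataclass
class GrainTraits:
    """The 15 structural traits of one grain.

    Volumes in mm^3, areas in mm^2, mean hull thickness in um, ratios
    dimensionless in [0, 1]. The whole grain (K) is the union of the four
    tissues, so the four ratios sum to exactly 1.
    """

    k_volume_mm3: float
    em_volume_mm3: float
    en_volume_mm3: float
    c_volume_mm3: float
    h_volume_mm3: float
    k_area_mm2: float
    em_area_mm2: float
    en_area_mm2: float
    c_area_mm2: float
    h_area_mm2: float
    h_a_t_um: float
    em_ratio: float
    en_ratio: float
    c_ratio: float
    h_ratio: float

    def as_row(self) -> dict[str, float]:
        return dict(zip(TRAIT_COLUMNS, [
            self.k_volume_mm3, self.em_volume_mm3, self.en_volume_mm3,
            self.c_volume_mm3, self.h_volume_mm3,
            self.k_area_mm2, self.em_area_mm2, self.en_area_mm2,
            self.c_area_mm2, self.h_area_mm2,
            self.h_a_t_um,
            self.em_ratio, self.en_ratio, self.c_ratio, self.h_ratio,
        ]))


@dataclass
class GeneticMap:
    """Ordered marker map: chromosome, marker name, cM and Mb positions.

    Within each chromosome both the genetic (cM) and physical (Mb) positions
    are non-decreasing in marker order.
    """

    table: pd.DataFrame  # columns: chrom, marker, cM, Mb

    def __post_init__(self) -> None:
        required = {"chrom", "marker", "cM", "Mb"}
        missing = required - set(self.table.columns)
        if missing:
            raise DomainError(f"map table missing columns: {sorted(missing)}")
        for chrom, sub in self.table.groupby("chrom", sort=False):
            if len(sub) < 2:
                raise DomainError(f"chromosome {chrom} has <2 markers")
            if not sub["cM"].is_monotonic_increasing:
                raise DomainError(f"cM positions not sorted on chromosome {chrom}")
            if not sub["Mb"].is_monotonic_increasing:
                raise DomainError(f"Mb positions not sorted on chromosome {chrom}")

    @property
    def chromosomes(self) -> list:
        return list(dict.fromkeys(self.table["chrom"]))

    @property
    def markers(self) -> list[str]:
        return list(self.table["marker"])

    def chrom_table(self, chrom) -> pd.DataFrame:
        return self.table[self.table["chrom"] == chrom]

    def cm_to_mb(self, chrom, pos_cm: float) -> float:
        """Piecewise-linear cM -> Mb interpolation, clamped to chromosome ends."""
        sub = self.chrom_table(chrom)
        return float(np.interp(pos_cm, sub["cM"].to_numpy(), sub["Mb"].to_numpy()))


@dataclass
class RILPopulation:
    """Biparental recombinant-inbred population.

    Genotypes are coded 'A' (parent-1 homozygote), 'B' (parent-2 homozygote)
    or missing (NaN); RILs are treated as fully inbred, no heterozygote class.
    """

    genotypes: pd.DataFrame          # lines x markers, values 'A'/'B'/NaN
    phenotypes: pd.DataFrame         # lines x traits
    map: GeneticMap

    def __post_init__(self) -> None:
        if list(self.genotypes.columns) != self.map.markers:
            raise DomainError("genotype columns must match map marker order")
        if len(self.genotypes) != len(self.phenotypes):
            raise DomainError("genotype and phenotype line counts differ")
        miss = self.genotypes.isna().mean()
        bad = miss[miss >= 0.5]
        if len(bad):
            raise DomainError(
                f"markers with >=50% missing genotypes: {list(bad.index)}"
            )

    @property
    def n_lines(self) -> int:
        return len(self.genotypes)

    def coded(self) -> np.ndarray:
        """Numeric coding A -> +1, B -> -1, missing -> NaN."""
        g = self.genotypes.to_numpy(dtype=object)
        out = np.full(g.shape, np.nan)
        out[g == "A"] = 1.0
        out[g == "B"] = -1.0
        return out


@dataclass
class QTLResult:
    """One mapped locus: peak position, LOD, support interval, effect size."""

    name: str
    chromosome: object
    trait: str
    peak_cM: float
    interval_cM: tuple[float, float]
    interval_Mb: tuple[float, float]
    lod: float
    pve_percent: float
    add: float

    def as_row(self) -> dict:
        return {
            "QTL": self.name,
            "Chromosome": self.chromosome,
            "Physical Interval (Mb)": f"{self.interval_Mb[0]:.3f}-{self.interval_Mb[1]:.3f}",
            "Traits": self.trait,
            "LOD": self.lod,
            "PVE (%)": self.pve_percent,
            "Add": self.add,
            "Peak (cM)": self.peak_cM,
            "Interval (cM)": f"{self.interval_cM[0]:.1f}-{self.interval_cM[1]:.1f}",
        }
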