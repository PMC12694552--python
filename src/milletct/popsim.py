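"""Simulated biparental RIL populations and DEG tables.

Genotypes are generated chromosome-wise as a two-state Markov chain along
ordered markers. Adjacent-marker recombination uses the Haldane map
function, r = (1 - exp(-2d/100))/2 for distance d in cM, corrected for
repeated selfing to the RIL (F-infinity) recombination fraction
R = 2r / (1 + 2r). Phenotypes are additive: planted QTL effects (coded +-1
at the marker nearest each planted position) plus Gaussian noise scaled so
the realized genetic-variance fraction matches the target heritability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import DomainError, GeneticMap, RILPopulation

#: Approximate physical chromosome lengths (Mb) of the foxtail millet genome.
SETARIA_CHROM_MB = {
    "1": 42.0, "2": 49.5, "3": 50.7, "4": 40.4, "5": 47.3,
    "6": 36.0, "7": 36.3, "8": 40.9, "9": 59.2,
}


def haldane_r(d_cm) -> np.ndarray:
    """Haldane inverse: cM distance -> single-meiosis recombination fraction."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


def ril_R(r) -> np.ndarray:
    """F-infinity RIL correction R = 2r/(1+2r) for selfed inbred lines."""
    r = np.asarray(r, dtype=float)
    return 2.0 * r / (1.0 + 2.0 * r)


def make_grid_map(
    n_chrom: int = 9,
    length_cm: float = 100.0,
    spacing_cm: float = 5.0,
    mb_per_cm: float = 0.4,
) -> GeneticMap:
    """Regular marker grid: ``n_chrom`` chromosomes with markers every
    ``spacing_cm``; physical positions scale linearly at ``mb_per_cm``."""
    rows = []
    for c in range(1, n_chrom + 1):
        cms = np.arange(0.0, length_cm + 1e-9, spacing_cm)
        for i, cm in enumerate(cms):
            rows.append({
                "chrom": str(c),
                "marker": f"m{c}_{i:03d}",
                "cM": float(cm),
                "Mb": float(cm * mb_per_cm),
            })
    return GeneticMap(pd.DataFrame(rows))


@dataclass
class SimCrossSpec:
    n_lines: int
    map: GeneticMap
    planted_qtls: list = field(default_factory=list)  # (chrom, pos_cM, additive effect)
    heritability: float = 0.5
    trait_name: str = "trait"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lines < 10:
            raise DomainError("n_lines must be >= 10")
        if not 0.0 <= self.heritability <= 1.0:
            raise DomainError("heritability must lie in [0, 1]")
        for chrom, pos, _eff in self.planted_qtls:
            sub = self.map.chrom_table(chrom)
            if len(sub) == 0:
                raise DomainError(f"planted QTL on unknown chromosome {chrom}")
            if not sub["cM"].min() <= pos <= sub["cM"].max():
                raise DomainError(
                    f"planted QTL at {pos} cM outside map range of chromosome {chrom}"
                )


def simulate_ril_population(spec: SimCrossSpec) -> RILPopulation:
    """Simulate genotypes and one additive phenotype for a RIL population."""
    rng = np.random.default_rng(spec.seed)
    gmap = spec.map
    n = spec.n_lines

    cols = {}
    for chrom in gmap.chromosomes:
        sub = gmap.chrom_table(chrom)
        cms = sub["cM"].to_numpy()
        R = ril_R(haldane_r(np.diff(cms)))
        # two-state Markov chain over {+1, -1}, stationary at 1/2 each
        state = rng.choice([1.0, -1.0], size=n)
        cols[sub["marker"].iloc[0]] = state.copy()
        for k, Rk in enumerate(R, start=1):
            flip = rng.random(n) < Rk
            state = np.where(flip, -state, state)
            cols[sub["marker"].iloc[k]] = state.copy()

    codes = pd.DataFrame(cols, columns=gmap.markers)
    genotypes = codes.replace({1.0: "A", -1.0: "B"})
    genotypes.index = [f"RIL{i + 1:03d}" for i in range(n)]

    g = np.zeros(n)
    for chrom, pos, eff in spec.planted_qtls:
        sub = gmap.chrom_table(chrom)
        nearest = sub.iloc[(sub["cM"] - pos).abs().argmin()]["marker"]
        g = g + eff * codes[nearest].to_numpy()

    h2 = spec.heritability
    var_g = float(np.var(g, ddof=1)) if n > 1 else 0.0
    if h2 == 0.0 or var_g == 0.0:
        if h2 == 1.0:
            raise DomainError("heritability 1 with zero genetic variance")
        y = (g if h2 > 0 else 0.0) + rng.normal(0.0, 1.0, n)
    elif h2 == 1.0:
        y = g.copy()
    else:
        # scale the noise so the REALIZED genetic-variance fraction equals
        # the target: the draw is orthogonalized against g in-sample and
        # rescaled to the exact variance ratio var_e = var_g (1-h2)/h2.
        e = rng.normal(0.0, 1.0, n)
        gc = g - g.mean()
        e = e - e.mean()
        e = e - (e @ gc) / (gc @ gc) * gc
        e *= np.sqrt(var_g * (1.0 - h2) / h2 / np.var(e, ddof=1))
        y = g + e

    phenotypes = pd.DataFrame({spec.trait_name: y}, index=genotypes.index)
    return RILPopulation(genotypes=genotypes, phenotypes=phenotypes, map=gmap)


def simulate_deg_table(
    n_genes: int,
    qtl_intervals: list,
    n_planted: int,
    seed: int,
    chrom_sizes_mb: dict | None = None,
) -> pd.DataFrame:
    """Simulated differential-expression table with planted candidates.

    ``qtl_intervals`` is a list of (chromosome, lo_Mb, hi_Mb). Exactly
    ``n_planted`` genes are placed inside the intervals with
    |log2FC| >= 1 and p < 0.05; every other gene fails at least one of the
    two thresholds, so downstream filtering + intersection recovers the
    planted genes exactly.
    """
    if not qtl_intervals:
        raise DomainError("need at least one interval")
    if n_planted > n_genes:
        raise DomainError("n_planted cannot exceed n_genes")
    sizes = {str(k): float(v) for k, v in (chrom_sizes_mb or SETARIA_CHROM_MB).items()}
    for chrom, lo, hi in qtl_intervals:
        size = sizes.get(str(chrom))
        if size is None or lo < 0 or hi > size or lo > hi:
            raise DomainError(
                f"interval {chrom}:{lo}-{hi} outside chromosome bounds"
            )

    rng = np.random.default_rng(seed)
    chroms = sorted(sizes)
    lengths = np.array([sizes[c] for c in chroms])
    rows = []
    # planted candidates, uniform within the stated intervals
    for i in range(n_planted):
        chrom, lo, hi = qtl_intervals[i % len(qtl_intervals)]
        pos = float(rng.uniform(lo, hi))
        lfc = float((1.0 + rng.exponential(0.8)) * rng.choice([1.0, -1.0]))
        rows.append((str(chrom), pos, lfc, float(rng.uniform(1e-6, 0.049))))
    # background genes: fail |log2FC| >= 1 or p < 0.05 (or both)
    for _ in range(n_genes - n_planted):
        c = chroms[int(rng.integers(len(chroms)))]
        pos = float(rng.uniform(0.0, sizes[c]))
        mode = rng.random()
        if mode < 0.5:
            lfc = float(rng.uniform(-0.99, 0.99))
            p = float(rng.uniform(1e-6, 1.0))
        else:
            lfc = float(rng.normal(0.0, 1.5))
            p = float(rng.uniform(0.05, 1.0))
        rows.append((c, pos, lfc, p))

    order = rng.permutation(len(rows))
    df = pd.DataFrame(
        [rows[i] for i in order],
        columns=["chrom", "pos_mb", "log2fc", "pvalue"],
    )
    df.insert(0, "gene_id", [f"Si{df['chrom'].iloc[i]}g{10000 + i * 10}"
                             for i in range(len(df))])
    return df
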