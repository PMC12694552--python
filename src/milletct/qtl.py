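"""Inclusive composite interval mapping (ICIM) for biparental RIL populations.

Two-step additive ICIM: (1) forward-backward stepwise regression of the
phenotype on marker codes selects background cofactors at an entry
threshold PIN (removal at POUT = 2 x PIN); (2) a genome scan on a cM grid
regresses the cofactor-adjusted phenotype on the expected QTL dosage given
the flanking markers (Haley-Knott style), excluding at each interval the
cofactors at its own flanking markers so the scanned signal is not absorbed
by the background model. LOD = (n/2) log10(RSS0/RSS1).

Expected dosages use the Haldane map function with the F-infinity RIL
correction R = 2r/(1+2r); loci are called above a fixed LOD threshold with
confidence intervals from the LOD-drop rule, and genome-wide thresholds can
also be obtained by phenotype permutation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .popsim import haldane_r, ril_R
from .types import DomainError, GeneticMap, QTLResult, RILPopulation


@dataclass
class ScanParams:
    step_cM: float = 1.0
    pin: float = 0.01
    n_permutations: int = 1000
    lod_min: float = 2.5
    lod_drop: float = 2.0
    peak_merge_cM: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.step_cM <= 0:
            raise DomainError("step_cM must be positive")
        if not 0.0 < self.pin < 1.0:
            raise DomainError("pin must lie in (0, 1)")
        if self.n_permutations < 1:
            raise DomainError("n_permutations must be >= 1")


# trait name -> abbreviation used in locus names (qKV2 etc.): first letter
# of each hyphen-separated component.
def trait_abbreviation(trait: str) -> str:
    return "".join(part[0] for part in trait.split("-") if part)


def _coded_imputed(pop: RILPopulation) -> np.ndarray:
    """Marker codes A->+1, B->-1 with per-marker mean imputation of missing."""
    x = pop.coded()
    col_mean = np.nanmean(x, axis=0)
    col_mean[np.isnan(col_mean)] = 0.0
    nan_r, nan_c = np.where(np.isnan(x))
    x[nan_r, nan_c] = col_mean[nan_c]
    return x


def select_cofactors(
    pop: RILPopulation, trait: str, pin: float = 0.01, pout: float | None = None,
) -> tuple[list[int], np.ndarray]:
    """Forward-backward stepwise marker selection.

    A marker enters when its partial-F p-value is the smallest and
    <= ``pin``; after each entry, included markers with partial-F p-value
    > ``pout`` (default 2 x pin) are removed. Deterministic: ties break
    toward the lower marker index (map order). Returns (selected marker
    indices, OLS coefficients on the selected markers, intercept excluded).
    """
    if trait not in pop.phenotypes.columns:
        raise DomainError(f"unknown trait {trait!r}")
    pout = 2.0 * pin if pout is None else pout
    y = pop.phenotypes[trait].to_numpy(dtype=float)
    if np.var(y) == 0:
        raise DomainError("zero-variance phenotype")
    X = _coded_imputed(pop)
    n, m = X.shape

    selected: list[int] = []
    for _step in range(min(n - 3, m)):
        # residualize y and candidate columns on current model
        if selected:
            Q, _ = np.linalg.qr(np.column_stack(
                [np.ones(n)] + [X[:, j] for j in selected]))
        else:
            Q, _ = np.linalg.qr(np.ones((n, 1)))
        ry = y - Q @ (Q.T @ y)
        RX = X - Q @ (Q.T @ X)
        ssy = ry @ ry
        ssx = np.einsum("ij,ij->j", RX, RX)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (RX.T @ ry) / np.sqrt(ssx * ssy)
        r[~np.isfinite(r)] = 0.0
        r[selected] = 0.0
        r2 = r**2
        dfree = n - len(selected) - 2
        if dfree < 1 or ssy <= 0:
            break
        j = int(np.argmax(r2))
        with np.errstate(divide="ignore"):
            F = r2[j] * dfree / max(1.0 - r2[j], 1e-300)
        p_enter = stats.f.sf(F, 1, dfree)
        if p_enter > pin:
            break
        selected.append(j)
        # backward: drop included markers whose partial F exceeds pout
        while len(selected) > 1:
            p_vals = _partial_p(y, X, selected)
            worst = int(np.argmax(p_vals))
            if p_vals[worst] > pout:
                selected.pop(worst)
            else:
                break
        selected.sort()

    if not selected:
        return [], np.zeros(0)
    beta = _ols_beta(y, X, selected)
    return selected, beta


def _design(X, selected):
    return np.column_stack([np.ones(X.shape[0])] + [X[:, j] for j in selected])


def _ols_beta(y, X, selected) -> np.ndarray:
    A = _design(X, selected)
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return coef[1:]


def _partial_p(y, X, selected) -> np.ndarray:
    """Partial-F p-value of each currently included marker."""
    A = _design(X, selected)
    n, k = A.shape
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    rss = resid @ resid
    dfree = n - k
    if dfree < 1:
        return np.zeros(len(selected))
    ps = np.empty(len(selected))
    for i in range(len(selected)):
        sub = [j for j in selected if j != selected[i]]
        A0 = _design(X, sub)
        c0, *_ = np.linalg.lstsq(A0, y, rcond=None)
        r0 = y - A0 @ c0
        rss0 = r0 @ r0
        F = (rss0 - rss) / max(rss / dfree, 1e-300)
        ps[i] = stats.f.sf(F, 1, dfree)
    return ps


# ---------------------------------------------------------------------------
# genome scan


@dataclass
class ScanGrid:
    """Precomputed scan geometry: positions and expected QTL dosages.

    Dosages depend only on the genotypes, so the grid is reusable across
    phenotype permutations.
    """

    chrom: np.ndarray          # per-position chromosome id (object)
    pos_cM: np.ndarray         # per-position cM
    dosage: np.ndarray         # n_lines x n_positions expected code in [-1, 1]
    flank_left: np.ndarray     # per-position global marker index
    flank_right: np.ndarray


def build_scan_grid(pop: RILPopulation, step_cM: float = 1.0) -> ScanGrid:
    gmap = pop.map
    X = _coded_imputed(pop)
    marker_index = {m: i for i, m in enumerate(gmap.markers)}
    chroms, poss, doss, fl, fr = [], [], [], [], []
    for chrom in gmap.chromosomes:
        sub = gmap.chrom_table(chrom)
        cms = sub["cM"].to_numpy()
        idx = np.array([marker_index[m] for m in sub["marker"]])
        grid = np.unique(np.concatenate([
            np.arange(cms[0], cms[-1] + 1e-9, step_cM), cms,
        ]).round(9))
        for p in grid:
            k = int(np.searchsorted(cms, p, side="right")) - 1
            k = min(max(k, 0), len(cms) - 2)
            jl, jr = idx[k], idx[k + 1]
            d1, d2 = p - cms[k], cms[k + 1] - p
            if d1 <= 1e-9:
                dos = X[:, jl].copy()
            elif d2 <= 1e-9:
                dos = X[:, jr].copy()
            else:
                dos = _expected_dosage(X[:, jl], X[:, jr], d1, d2)
            chroms.append(chrom)
            poss.append(float(p))
            doss.append(dos)
            fl.append(jl)
            fr.append(jr)
    return ScanGrid(
        chrom=np.array(chroms, dtype=object),
        pos_cM=np.array(poss),
        dosage=np.column_stack(doss),
        flank_left=np.array(fl),
        flank_right=np.array(fr),
    )


def _expected_dosage(gl, gr, d1_cm, d2_cm) -> np.ndarray:
    """E[QTL code | flanking genotypes] for an F-infinity RIL.

    The chromosome is a two-state Markov chain in RIL recombination
    fractions: P(Q | GL, GR) proportional to P(Q | GL) P(GR | Q) with
    transition probabilities R1 (left flank to locus) and R2 (locus to
    right flank). Mean-imputed (fractional) flank codes enter linearly via
    the state probabilities.
    """
    R1 = float(ril_R(haldane_r(d1_cm)))
    R2 = float(ril_R(haldane_r(d2_cm)))
    pl = (1.0 + gl) / 2.0   # P(GL = A)
    pr = (1.0 + gr) / 2.0
    # enumerate the two flank states weighted by their probabilities
    dos = np.zeros_like(pl)
    for sl, wl in ((1.0, pl), (-1.0, 1.0 - pl)):
        for sr, wr in ((1.0, pr), (-1.0, 1.0 - pr)):
            t1 = 1.0 - R1 if sl > 0 else R1      # P(Q=A | GL=sl)
            t2 = 1.0 - R2 if sr > 0 else R2      # P(GR=sr | Q=A)
            t2b = R2 if sr > 0 else 1.0 - R2     # P(GR=sr | Q=B)
            pa = t1 * t2
            pb = (1.0 - t1) * t2b
            tot = pa + pb
            cond = (pa - pb) / tot if tot > 0 else 0.0
            dos = dos + wl * wr * cond
    return dos


def _adjusted_phenotypes(y, X, selected, beta, grid: ScanGrid) -> np.ndarray:
    """Per-position cofactor-adjusted phenotype (n_lines x n_positions).

    At each scanned interval the cofactors sitting on its two flanking
    markers are excluded from the adjustment.
    """
    n_pos = grid.pos_cM.size
    if not selected:
        return np.broadcast_to(y[:, None], (y.size, n_pos))
    sel = np.array(selected)
    contrib = X[:, sel] * beta  # n x k terms
    total = contrib.sum(axis=1)
    y_all = y - total
    out = np.repeat(y_all[:, None], n_pos, axis=1)
    for t, j in enumerate(sel):
        hit = (grid.flank_left == j) | (grid.flank_right == j)
        if hit.any():
            out[:, hit] += contrib[:, t][:, None]
    return out


def _lod_from_adjusted(y_adj: np.ndarray, dosage: np.ndarray) -> np.ndarray:
    """LOD per position from simple regression of adjusted phenotype on
    dosage: LOD = -(n/2) log10(1 - rho^2)."""
    n = y_adj.shape[0]
    yc = y_adj - y_adj.mean(axis=0)
    dc = dosage - dosage.mean(axis=0)
    num = np.einsum("ij,ij->j", yc, dc)
    den = np.sqrt(np.einsum("ij,ij->j", yc, yc) * np.einsum("ij,ij->j", dc, dc))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho2 = np.where(den > 0, (num / np.maximum(den, 1e-300)) ** 2, 0.0)
    rho2 = np.clip(rho2, 0.0, 1.0 - 1e-15)
    return -(n / 2.0) * np.log10(1.0 - rho2)


def icim_scan(
    pop: RILPopulation,
    trait: str,
    params: ScanParams | None = None,
    grid: ScanGrid | None = None,
    y: np.ndarray | None = None,
) -> pd.DataFrame:
    """Genome-wide LOD profile on a ``step_cM`` grid (marker positions
    included). Returns a DataFrame with columns chrom, pos_cM, lod."""
    params = params or ScanParams()
    if grid is None:
        grid = build_scan_grid(pop, params.step_cM)
    if y is None:
        y = pop.phenotypes[trait].to_numpy(dtype=float)
    X = _coded_imputed(pop)
    selected, beta = _select_on_y(pop, trait, params.pin, y)
    y_adj = _adjusted_phenotypes(y, X, selected, beta, grid)
    lod = _lod_from_adjusted(y_adj, grid.dosage)
    return pd.DataFrame({"chrom": grid.chrom, "pos_cM": grid.pos_cM, "lod": lod})


def _select_on_y(pop, trait, pin, y):
    """Cofactor selection on an arbitrary phenotype vector (used so
    permutations re-run the full ICIM procedure)."""
    tmp = pop.phenotypes.copy()
    tmp[trait] = y
    pop2 = RILPopulation(pop.genotypes, tmp, pop.map)
    return select_cofactors(pop2, trait, pin)


def permutation_threshold(
    pop: RILPopulation,
    trait: str,
    params: ScanParams | None = None,
    alpha: float = 0.05,
    grid: ScanGrid | None = None,
) -> float:
    """Genome-wide LOD threshold: (1 - alpha) empirical quantile of the
    max-LOD null distribution over seeded phenotype permutations. The full
    procedure (cofactor selection + scan) is re-run per permutation."""
    if not 0.0 < alpha < 1.0:
        raise DomainError("alpha must lie in (0, 1)")
    params = params or ScanParams()
    if grid is None:
        grid = build_scan_grid(pop, params.step_cM)
    rng = np.random.default_rng(params.seed)
    y = pop.phenotypes[trait].to_numpy(dtype=float)
    maxes = np.empty(params.n_permutations)
    for b in range(params.n_permutations):
        yp = y[rng.permutation(y.size)]
        prof = icim_scan(pop, trait, params, grid=grid, y=yp)
        maxes[b] = prof["lod"].max()
    return float(np.quantile(maxes, 1.0 - alpha))  # type-7 interpolation


def call_qtls(
    profile: pd.DataFrame,
    pop: RILPopulation,
    trait: str,
    params: ScanParams | None = None,
    grid: ScanGrid | None = None,
) -> list[QTLResult]:
    """Call loci from a LOD profile.

    Peaks are local maxima above ``lod_min``; peaks closer than
    ``peak_merge_cM`` on one chromosome are merged (higher kept). The
    support interval spans the outermost grid positions around the peak
    with LOD >= peak - lod_drop; PVE and the additive effect are computed
    at the peak from the cofactor-adjusted regression.
    """
    params = params or ScanParams()
    if profile.empty:
        raise DomainError("empty LOD profile")
    if grid is None:
        grid = build_scan_grid(pop, params.step_cM)
    y = pop.phenotypes[trait].to_numpy(dtype=float)
    X = _coded_imputed(pop)
    selected, beta = select_cofactors(pop, trait, params.pin)
    y_adj_all = _adjusted_phenotypes(y, X, selected, beta, grid)

    results: list[QTLResult] = []
    for chrom in dict.fromkeys(profile["chrom"]):
        sub = profile[profile["chrom"] == chrom].reset_index()
        lod = sub["lod"].to_numpy()
        pos = sub["pos_cM"].to_numpy()
        peaks = [i for i in range(len(lod))
                 if lod[i] > params.lod_min
                 and (i == 0 or lod[i] >= lod[i - 1])
                 and (i == len(lod) - 1 or lod[i] > lod[i + 1])]
        # merge peaks closer than peak_merge_cM, keeping the higher
        merged: list[int] = []
        for i in sorted(peaks, key=lambda i: -lod[i]):
            if all(abs(pos[i] - pos[j]) >= params.peak_merge_cM for j in merged):
                merged.append(i)
        for i in sorted(merged, key=lambda i: pos[i]):
            floor = lod[i] - params.lod_drop
            left = i
            while left > 0 and lod[left - 1] >= floor:
                left -= 1
            right = i
            while right < len(lod) - 1 and lod[right + 1] >= floor:
                right += 1
            gi = int(sub["index"].iloc[i])  # position index in the grid
            dos = grid.dosage[:, gi]
            ya = y_adj_all[:, gi]
            yc = ya - ya.mean()
            dc = dos - dos.mean()
            rss0 = float(yc @ yc)
            denom = float(dc @ dc)
            b1 = float(yc @ dc) / denom if denom > 0 else 0.0
            rss1 = float(((yc - b1 * dc) ** 2).sum())
            pve = 100.0 * (1.0 - rss1 / rss0) if rss0 > 0 else 0.0
            a_class = dos > 0
            add = 0.5 * (y[a_class].mean() - y[~a_class].mean()) \
                if a_class.any() and (~a_class).any() else 0.0
            results.append(QTLResult(
                name=f"q{trait_abbreviation(trait)}{chrom}",
                chromosome=chrom,
                trait=trait,
                peak_cM=float(pos[i]),
                interval_cM=(float(pos[left]), float(pos[right])),
                interval_Mb=(
                    pop.map.cm_to_mb(chrom, float(pos[left])),
                    pop.map.cm_to_mb(chrom, float(pos[right])),
                ),
                lod=float(lod[i]),
                pve_percent=float(pve),
                add=float(add),
            ))
    return results


def qtl_table(results: list[QTLResult]) -> pd.DataFrame:
    cols = ["QTL", "Chromosome", "Physical Interval (Mb)", "Traits",
            "LOD", "PVE (%)", "Add", "Peak (cM)", "Interval (cM)"]
    return pd.DataFrame([r.as_row() for r in results], columns=cols)
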