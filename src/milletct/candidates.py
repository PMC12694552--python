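"""Candidate-gene nomination: DEG thresholding and QTL-interval overlap.

A gene is differentially expressed when |log2FC| >= 1 (boundary inclusive)
and raw p < 0.05; a surviving gene becomes a candidate for every mapped
locus on the same chromosome whose physical support interval contains the
gene's position (closed interval at both ends). One record is emitted per
(gene, locus) pair.
"""

from __future__ import annotations

import warnings

import pandas as pd

from .types import QTLResult


def filter_degs(
    table: pd.DataFrame,
    min_abs_log2fc: float = 1.0,
    max_p: float = 0.05,
) -> pd.DataFrame:
    """Keep rows with |log2fc| >= min_abs_log2fc and pvalue < max_p.

    Adds an 'direction' column (up/down by the sign of log2fc). Idempotent;
    the result is always a subset of the input rows.
    """
    keep = (table["log2fc"].abs() >= min_abs_log2fc) & (table["pvalue"] < max_p)
    out = table.loc[keep].copy()
    out["direction"] = out["log2fc"].map(lambda v: "up" if v > 0 else "down")
    return out.reset_index(drop=True)


def deg_counts(filtered: pd.DataFrame) -> dict[str, int]:
    return {
        "total": int(len(filtered)),
        "up": int((filtered["log2fc"] > 0).sum()),
        "down": int((filtered["log2fc"] < 0).sum()),
    }


def intersect_qtl_degs(
    qtls: list[QTLResult],
    degs: pd.DataFrame,
) -> pd.DataFrame:
    """Candidate genes: DEGs lying inside a locus's physical interval.

    Both interval endpoints are inclusive. Chromosome ids present in only
    one of the two inputs trigger a naming-mismatch warning listing them.
    Returns one row per (gene, QTL) pair with columns gene_id, qtl_name,
    chrom, pos_mb, log2fc, pvalue.
    """
    rows = []
    if qtls and len(degs):
        qc = {str(q.chromosome) for q in qtls}
        dc = set(degs["chrom"].astype(str))
        orphans = sorted(qc ^ dc)
        if orphans and not (qc & dc):
            warnings.warn(
                f"chromosome ids do not overlap between QTL and DEG tables: "
                f"{orphans}", stacklevel=2,
            )
    for q in qtls:
        lo, hi = q.interval_Mb
        sub = degs[
            (degs["chrom"].astype(str) == str(q.chromosome))
            & (degs["pos_mb"] >= lo)
            & (degs["pos_mb"] <= hi)
        ]
        for _, g in sub.iterrows():
            rows.append({
                "gene_id": g["gene_id"],
                "qtl_name": q.name,
                "chrom": g["chrom"],
                "pos_mb": g["pos_mb"],
                "log2fc": g["log2fc"],
                "pvalue": g["pvalue"],
            })
    return pd.DataFrame(
        rows, columns=["gene_id", "qtl_name", "chrom", "pos_mb", "log2fc", "pvalue"],
    )
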