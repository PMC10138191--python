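"""Nearest-TSS annotation and promoter-window gene lists.

Distance sign convention: negative = upstream of the gene, positive =
downstream/into the gene body, i.e. on the + strand dist = pos - tss and
on the - strand dist = tss - pos. ``flip_sign=True`` inverts it. The
promoter window is boundary-inclusive: |dist| <= window (default 2000 bp).
Nearest-gene assignment minimizes |dist| over all annotation rows on the
unit's chromosome; exact ties go to the lexicographically smaller gene_id.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .differential import DIRECTION_HYPO_IN_B

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 2000


def signed_distance(pos: int, tss: int, strand: str, flip_sign: bool = False) -> int:
    """Strand-aware signed distance from a 1-based position to a TSS."""
    if strand == "+":
        d = pos - tss
    elif strand == "-":
        d = tss - pos
    else:
        raise DataError(f"unknown strand {strand!r}")
    return -d if flip_sign else d


def nearest_gene(
    pos: int, chrom: str, annotation: pd.DataFrame, flip_sign: bool = False
) -> tuple[pd.Series, int] | None:
    """Nearest-TSS gene on the same chromosome, or None if there is none.

    Returns (annotation row, signed distance). Ties on |distance| break
    to the smaller gene_id.
    """
    sub = annotation[annotation["chrom"] == chrom]
    if sub.empty:
        return None
    absdist = (sub["tss"] - pos).abs()
    dmin = absdist.min()
    candidates = sub[absdist == dmin].sort_values("gene_id", kind="mergesort")
    row = candidates.iloc[0]
    return row, signed_distance(pos, int(row["tss"]), str(row["strand"]), flip_sign)


def annotate_nearest(
    units: pd.DataFrame,
    annotation: pd.DataFrame,
    window: int = DEFAULT_WINDOW,
    flip_sign: bool = False,
) -> pd.DataFrame:
    """Vectorized nearest-TSS annotation for a table of genomic units.

    ``units`` needs columns unit_id, chrom, pos (1-based). Adds gene_id,
    gene_name, dist_to_tss and is_promoter; units on chromosomes with no
    annotated gene stay unannotated (NaN gene, missing distance,
    is_promoter False) rather than erroring.
    """
    if window <= 0:
        raise ConfigurationError(f"window must be > 0, got {window}")
    out = units[["unit_id", "chrom", "pos"]].copy()
    gene_id = np.full(len(out), None, dtype=object)
    gene_name = np.full(len(out), None, dtype=object)
    dist = np.full(len(out), np.nan)

    by_chrom = {
        chrom: sub.sort_values(["tss", "gene_id"], kind="mergesort").reset_index(drop=True)
        for chrom, sub in annotation.groupby("chrom", sort=False)
    }
    for chrom, idx in out.groupby("chrom", sort=False).groups.items():
        ann = by_chrom.get(chrom)
        if ann is None:
            continue
        tss = ann["tss"].to_numpy(np.int64)
        pos = out.loc[idx, "pos"].to_numpy(np.int64)
        right = np.searchsorted(tss, pos)
        left = np.clip(right - 1, 0, len(tss) - 1)
        right = np.clip(right, 0, len(tss) - 1)
        dmin = np.minimum(np.abs(pos - tss[left]), np.abs(tss[right] - pos))
        for j, (p, d) in enumerate(zip(pos, dmin)):
            lo = np.searchsorted(tss, p - d, side="left")
            hi = np.searchsorted(tss, p - d, side="right")
            lo2 = np.searchsorted(tss, p + d, side="left")
            hi2 = np.searchsorted(tss, p + d, side="right")
            cand = list(range(lo, hi)) + [i for i in range(lo2, hi2) if not lo <= i < hi]
            best = min(cand, key=lambda i: ann["gene_id"].iat[i])
            row_idx = idx[j]
            gene_id[out.index.get_loc(row_idx)] = ann["gene_id"].iat[best]
            gene_name[out.index.get_loc(row_idx)] = ann["gene_name"].iat[best]
            dist[out.index.get_loc(row_idx)] = signed_distance(
                int(p), int(ann["tss"].iat[best]), str(ann["strand"].iat[best]), flip_sign
            )
    out["gene_id"] = gene_id
    out["gene_name"] = gene_name
    out["dist_to_tss"] = dist
    out["is_promoter"] = promoter_flag(out["dist_to_tss"], window)
    n_un = out["gene_id"].isna().sum()
    if n_un:
        logger.info("%d unit(s) unannotated (no gene on chromosome)", int(n_un))
    return out


def promoter_flag(dist_to_tss, window: int = DEFAULT_WINDOW):
    """Boundary-inclusive promoter membership: |dist| <= window.

    Missing distances flag False. Accepts scalars or array-likes.
    """
    if window <= 0:
        raise ConfigurationError(f"window must be > 0, got {window}")
    if np.isscalar(dist_to_tss):
        return bool(abs(dist_to_tss) <= window)
    d = pd.Series(np.asarray(dist_to_tss, dtype=float))
    return (d.abs() <= window).fillna(False).to_numpy()


def annotate_results(
    results: pd.DataFrame,
    manifest: pd.DataFrame,
    annotation: pd.DataFrame,
    window: int = DEFAULT_WINDOW,
    flip_sign: bool = False,
) -> pd.DataFrame:
    """Join differential results with nearest-TSS annotation by unit_id."""
    coords = manifest.set_index("probe_id")[["chrom", "pos"]]
    missing = [u for u in results["unit_id"] if u not in coords.index]
    if missing:
        raise DataError(f"units absent from manifest: {missing[:5]}{'...' if len(missing) > 5 else ''}")
    units = pd.DataFrame(
        {
            "unit_id": results["unit_id"],
            "chrom": coords.loc[results["unit_id"], "chrom"].to_numpy(),
            "pos": coords.loc[results["unit_id"], "pos"].to_numpy(),
        }
    )
    ann = annotate_nearest(units, annotation, window, flip_sign)
    merged = results.merge(ann, on="unit_id", how="left", validate="one_to_one")
    merged.attrs.update(results.attrs)
    return merged


def promoter_gene_list(
    annotated: pd.DataFrame,
    alpha: float = 0.05,
    direction_filter: str | None = DIRECTION_HYPO_IN_B,
) -> list[str]:
    """Unique, lexicographically sorted gene ids whose promoter window
    holds >= 1 significant unit with the requested direction."""
    mask = (annotated["p_value"] < alpha) & annotated["is_promoter"] & annotated["gene_id"].notna()
    if direction_filter is not None:
        mask &= annotated["direction"] == direction_filter
    return sorted(annotated.loc[mask, "gene_id"].unique().tolist())


def table1_style(annotated: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Significant annotated units in a probeID/geneID/distToTSS/p-value
    layout (the per-probe gene-mapping table)."""
    sig = annotated[annotated["p_value"] < alpha]
    out = sig[["unit_id", "gene_id", "dist_to_tss", "p_value"]].rename(
        columns={
            "unit_id": "probeID",
            "gene_id": "geneID",
            "dist_to_tss": "distToTSS",
            "p_value": "p-value",
        }
    )
    return out.reset_index(drop=True)
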