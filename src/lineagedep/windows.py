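"""Accessibility-expression coupling via sequential window enrichment.

Around each differential-accessibility region, windows of increasing
half-width are drawn and the genes whose TSS falls inside any window are
collected. If chromatin changes drive expression changes, the captured
set should be enriched for differentially expressed genes of the matching
direction (lower accessibility ~ downregulation, higher ~ upregulation);
the one-tailed hypergeometric test quantifies that enrichment against the
expressed-gene universe.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def _region_centers(regions) -> pd.DataFrame:
    """Normalise peaks / DA tables / intervals to (chrom, center) rows."""
    rows = []
    for r in regions if not isinstance(regions, pd.DataFrame) else regions.itertuples(index=False):
        if hasattr(r, "summit"):            # ConsensusPeak or DA row
            center = int(r.summit)
            chrom = r.chrom
        elif hasattr(r, "center"):          # GenomicInterval
            center = r.center
            chrom = r.chrom
        else:
            raise TypeError(f"cannot locate a center for {r!r}")
        rows.append((chrom, center))
    return pd.DataFrame(rows, columns=["chrom", "center"])


def capture_genes(regions, genes: pd.DataFrame, window_half_width: int) -> set[str]:
    """Genes whose TSS lies within half-width ``h`` of any region center.

    The window per region is [center - h, center + h), half-open like all
    coordinates here; capture is strand-blind and deduplicated.
    """
    centers = _region_centers(regions)
    h = int(window_half_width)
    captured: set[str] = set()
    for chrom, grp in centers.groupby("chrom"):
        cs = np.sort(grp["center"].to_numpy())
        sub = genes[genes["chrom"] == chrom]
        if sub.empty:
            continue
        tss = sub["tss"].to_numpy()
        # TSS in [c-h, c+h)  <=>  a center exists in (tss-h, tss+h]
        lo = np.searchsorted(cs, tss - h, side="right")
        hi = np.searchsorted(cs, tss + h, side="right")
        captured.update(sub.loc[sub.index[hi > lo], "gene_id"])
    return captured


def window_enrichment(
    regions,
    genes: pd.DataFrame,
    window_sizes,
    de_direction: str,
    region_class: str = "",
) -> pd.DataFrame:
    """Capture ratio and hypergeometric p across increasing window sizes.

    The universe is every expressed gene (``de_status != 'not_expressed'``)
    and the success set is the genes differential in ``de_direction``
    ('down' or 'up'). For each half-width h: n = captured expressed genes,
    k = captured DE genes, ratio = k/n, and p = P(X >= k) for X
    hypergeometric with population |universe|, |DE| successes and n draws
    (enrichment tail only).
    """
    if de_direction not in ("down", "up"):
        raise ValueError(f"de_direction must be 'down' or 'up', got {de_direction!r}")
    universe = set(genes.loc[genes["de_status"] != "not_expressed", "gene_id"])
    if not universe:
        raise ValueError("empty expressed-gene universe")
    de_set = set(genes.loc[genes["de_status"] == de_direction, "gene_id"])

    rows = []
    for h in window_sizes:
        captured = capture_genes(regions, genes, h)
        n = len(captured & universe)
        k = len(captured & de_set)
        ratio = k / n if n else 0.0
        p = float(stats.hypergeom.sf(k - 1, len(universe), len(de_set), n)) if n else 1.0
        rows.append({
            "window_half_width": int(h),
            "region_class": region_class,
            "de_direction": de_direction,
            "n_universe_captured": n,
            "n_de_captured": k,
            "ratio": ratio,
            "p_value": min(max(p, 0.0), 1.0),
        })
    return pd.DataFrame(rows)
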