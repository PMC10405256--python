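"""Lineage-dependency (LD) scoring and the core-regulatory-circuitry filter.

For each transcription factor *t* and cancer lineage *x* the LD score is
the difference of mean gene-knockout fitness effects (CERES scores)

    LD(t, x) = mean(CERES[lines in x, t]) - mean(CERES[lines not in x, t])

so a strongly negative score marks a dependency specific to that lineage.
Significance comes from the two-group Kruskal-Wallis test (the rank-sum
chi-square form, with tie correction) on the same in/out partition, with
Benjamini-Hochberg adjustment across the TF family of each lineage.

A three-stage filter then defines each lineage's dependency set:

1. LD score below ``ld_cutoff`` (-1.2) and adjusted p below ``ld_p_cutoff``;
2. a strict majority (>50%) of the lineage's lines must be strong
   dependencies (CERES <= -0.5) for the TF;
3. pan-essential TFs — median CERES across ALL cell lines <= -0.2 — are
   removed even if lineage-enriched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import RunConfig

logger = logging.getLogger(__name__)


@dataclass
class LineageDependencySet:
    """The TFs surviving all three filters for one lineage.

    ``filter_trace`` records, for every candidate TF that was removed,
    which single filter (1, 2 or 3) removed it.
    """

    lineage: str
    tfs: list[str]
    filter_trace: dict[str, int] = field(default_factory=dict)


def eligible_lineages(annotations: pd.DataFrame, min_lineage_size: int = 10) -> list[str]:
    """Lineages represented by at least ``min_lineage_size`` cell lines, sorted."""
    counts = annotations.groupby("lineage")["cell_line"].size()
    return sorted(counts.index[counts >= min_lineage_size])


def _tie_terms(X: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per-column sum of (t^3 - t) over tied groups, for the KW correction."""
    n_col = X.shape[1]
    T = np.zeros(n_col)
    for j in range(n_col):
        vals = X[mask[:, j], j]
        if vals.size == 0:
            continue
        _, counts = np.unique(vals, return_counts=True)
        ties = counts[counts > 1]
        if ties.size:
            T[j] = np.sum(ties.astype(float) ** 3 - ties)
    return T


def compute_ld_scores(
    ceres: pd.DataFrame,
    annotations: pd.DataFrame,
    tf_list: list[str],
    min_lineage_size: int = 10,
    outgroup: str = "all",
    bh_scope: str = "per-lineage",
) -> pd.DataFrame:
    """LD score, Kruskal-Wallis p and BH-adjusted p for every TF x lineage.

    Parameters
    ----------
    ceres
        Gene-effect matrix, cell lines (rows) x genes (columns); NaN cells
        are excluded pairwise.
    annotations
        Columns ``cell_line``, ``lineage``; every line maps to one lineage.
    tf_list
        The transcription-factor family to score (must be CERES columns).
    outgroup
        ``"all"``: the out-of-lineage pool is every annotated line;
        ``"eligible"``: only lines of lineages meeting the size cutoff.

    Returns a DataFrame with columns
    ``tf, lineage, ld_score, p_value, p_adj, n_in, n_out``; TFs with fewer
    than two usable values in either group carry a missing p (flagged via
    ``p_value`` NaN).
    """
    missing_tfs = [t for t in tf_list if t not in ceres.columns]
    if missing_tfs:
        raise KeyError(f"TFs absent from the gene-effect matrix: {missing_tfs[:5]}")

    ann = annotations.set_index("cell_line")["lineage"]
    lines = ceres.index.intersection(ann.index)
    eligible = eligible_lineages(
        annotations[annotations["cell_line"].isin(lines)], min_lineage_size
    )
    if not eligible:
        raise ValueError("no lineage meets the minimum size; nothing to score")
    if outgroup == "eligible":
        lines = lines[ann.loc[lines].isin(eligible)]
    elif outgroup != "all":
        raise ValueError(f"outgroup must be 'all' or 'eligible', got {outgroup!r}")

    X = ceres.loc[lines, list(tf_list)]
    lineage_of = ann.loc[lines]

    Xv = X.to_numpy(dtype=float)
    M = ~np.isnan(Xv)
    X0 = np.where(M, Xv, 0.0)
    # in/out groups always partition the same pool, so each column is
    # ranked once over its non-missing entries and shared by all lineages
    R = X.rank(axis=0).to_numpy(dtype=float)
    R0 = np.where(M, R, 0.0)
    S_all = X0.sum(axis=0)
    N_all = M.sum(axis=0)
    Rsum_all = R0.sum(axis=0)
    T = _tie_terms(Xv, M)

    frames = []
    with np.errstate(invalid="ignore", divide="ignore"):
        for lin in eligible:
            g = (lineage_of == lin).to_numpy().astype(float)
            n_in = g @ M
            n_out = N_all - n_in
            sum_in = g @ X0
            mean_in = sum_in / n_in
            mean_out = (S_all - sum_in) / n_out
            ld = mean_in - mean_out

            rank_in = g @ R0
            rank_out = Rsum_all - rank_in
            N = N_all.astype(float)
            H = 12.0 / (N * (N + 1)) * (
                rank_in**2 / n_in + rank_out**2 / n_out
            ) - 3.0 * (N + 1)
            correction = 1.0 - T / (N**3 - N)
            p = np.where(correction > 0, stats.chi2.sf(H / np.where(correction > 0, correction, 1.0), 1), 1.0)
            # a column constant within the pool has no rank information
            p = np.where(correction <= 0, 1.0, p)
            p = np.where((n_in < 2) | (n_out < 2), np.nan, p)
            ld = np.where((n_in == 0) | (n_out == 0), np.nan, ld)

            frames.append(pd.DataFrame({
                "tf": list(tf_list),
                "lineage": lin,
                "ld_score": ld,
                "p_value": p,
                "n_in": n_in,
                "n_out": n_out,
            }))
    records = pd.concat(frames, ignore_index=True)
    records["p_adj"] = _bh_adjust(records, bh_scope)
    return records[["tf", "lineage", "ld_score", "p_value", "p_adj", "n_in", "n_out"]]


def _bh_adjust(records: pd.DataFrame, scope: str) -> pd.Series:
    out = pd.Series(np.nan, index=records.index)

    def adjust(idx):
        ok = records.loc[idx, "p_value"].notna()
        if ok.any():
            out.loc[idx[ok]] = multipletests(
                records.loc[idx[ok], "p_value"], method="fdr_bh"
            )[1]

    if scope == "per-lineage":
        for _, grp in records.groupby("lineage"):
            adjust(grp.index)
    elif scope == "global":
        adjust(records.index)
    else:
        raise ValueError(f"bh_scope must be 'per-lineage' or 'global', got {scope!r}")
    return out


def max_ld_per_tf(records: pd.DataFrame) -> pd.DataFrame:
    """The most negative LD score of each TF with the lineage achieving it.

    Ties on the score are broken by lexicographic lineage. This is the
    per-TF "maximum possible LD" used to set the effect-size cutoff.
    """
    if records.empty:
        raise ValueError("no LD records supplied")
    ordered = records.sort_values(["tf", "ld_score", "lineage"], kind="mergesort")
    best = ordered.drop_duplicates("tf", keep="first")
    return best[["tf", "lineage", "ld_score"]].reset_index(drop=True)


def filter_lineage_dependencies(
    records: pd.DataFrame,
    ceres: pd.DataFrame,
    annotations: pd.DataFrame,
    config: RunConfig | None = None,
) -> dict[str, LineageDependencySet]:
    """Apply the three-stage filter cascade to the LD records.

    Returns a map lineage -> :class:`LineageDependencySet` for lineages
    with at least one surviving TF. Lines with a missing CERES value for a
    TF are excluded from filter 2's denominator.
    """
    cfg = config or RunConfig()
    if records.empty:
        return {}
    ann = annotations.set_index("cell_line")["lineage"]
    lines = ceres.index.intersection(ann.index)
    lineage_of = ann.loc[lines]
    p_col = "p_adj" if cfg.ld_use_adjusted_p else "p_value"

    out: dict[str, LineageDependencySet] = {}
    for lin, grp in records.groupby("lineage"):
        trace: dict[str, int] = {}
        survivors: list[str] = []
        lin_lines = lines[(lineage_of == lin).to_numpy()]
        for row in grp.itertuples(index=False):
            tf = row.tf
            p = getattr(row, p_col)
            if not (pd.notna(row.ld_score) and row.ld_score < cfg.ld_cutoff
                    and pd.notna(p) and p < cfg.ld_p_cutoff):
                trace[tf] = 1
                continue
            vals = ceres.loc[lin_lines, tf].dropna()
            frac_strong = (vals <= cfg.strong_dep_ceres).mean() if len(vals) else 0.0
            if not frac_strong > cfg.strong_dep_fraction:
                trace[tf] = 2
                continue
            if ceres[tf].median(skipna=True) <= cfg.pan_essential_median:
                trace[tf] = 3
                continue
            survivors.append(tf)
        if survivors:
            out[lin] = LineageDependencySet(lineage=lin, tfs=sorted(survivors),
                                            filter_trace=trace)
    return out
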