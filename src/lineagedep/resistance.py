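"""Resistance classification and the permutation-FDR acquired-dependency scan.

A cell line is *resistant* to its lineage's factor program when its average
CERES score over the lineage's dependency set exceeds the bimodality-derived
cutoff (-0.45 by default); otherwise it is *sensitive*. Genes whose
knockout effect differs between the two groups are detected with a
permutation test on Cohen's D:

    d_i = (mean_resistant - mean_sensitive) / s_pooled

For each gene *i* the estimated FDR divides the mean (over permutations)
count of permuted effect sizes at least as extreme as |d_i| by the count of
observed effect sizes at least as extreme. The q-value monotonizes that
estimate — the running minimum over all genes no more extreme than *i* —
so q never increases with |d| and significance calls are monotone.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: mutation classes treated as loss-of-function in DepMap annotations
DISRUPTIVE_CLASSES = frozenset({"damaging", "other non-conserving"})
SILENT_CLASSES = frozenset({"silent"})


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_cell_lines(
    ceres: pd.DataFrame,
    ld_sets: dict,
    annotations: pd.DataFrame,
    resistance_cutoff: float = -0.45,
) -> pd.DataFrame:
    """Label every line of a lineage with a dependency set sensitive/resistant.

    ``avg_ceres`` is the mean CERES over the lineage's dependency TFs
    (missing values excluded); a line is resistant iff avg_ceres is above
    the cutoff. Lines whose lineage has no dependency set are skipped, as
    are lines with no usable value over the set (warned).
    """
    ann = annotations.set_index("cell_line")["lineage"]
    rows = []
    n_all_missing = 0
    for line in ceres.index:
        if line not in ann.index:
            continue
        lineage = ann.loc[line]
        dep = ld_sets.get(lineage)
        if dep is None:
            continue
        tfs = dep.tfs if hasattr(dep, "tfs") else list(dep)
        if not tfs:
            raise ValueError(f"lineage {lineage!r} has an empty dependency set")
        vals = ceres.loc[line, tfs].dropna()
        if vals.empty:
            n_all_missing += 1
            continue
        avg = float(vals.mean())
        rows.append({
            "cell_line": line, "lineage": lineage, "avg_ceres": avg,
            "label": "resistant" if avg > resistance_cutoff else "sensitive",
        })
    if n_all_missing:
        logger.warning("skipped %d lines with no CERES values over their dependency set",
                       n_all_missing)
    return pd.DataFrame(rows, columns=["cell_line", "lineage", "avg_ceres", "label"])


# ---------------------------------------------------------------------------
# Cohen's D
# ---------------------------------------------------------------------------

def cohens_d(group_a, group_b) -> float:
    """Classic pooled-SD Cohen's D, (mean_a - mean_b) / s_pooled.

    Sample variances use n-1 denominators. Degenerate cases: zero pooled
    SD with equal means gives 0; with unequal means gives signed infinity.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least two non-missing values")
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    diff = a.mean() - b.mean()
    if sp2 == 0.0:
        return 0.0 if diff == 0.0 else float(np.sign(diff) * np.inf)
    return float(diff / np.sqrt(sp2))


def _group_stats(indicator: np.ndarray, X0: np.ndarray, X0sq: np.ndarray,
                 M: np.ndarray):
    """Count / mean / variance per column for rows selected by ``indicator``.

    ``indicator`` may be a vector (one grouping) or a matrix (one grouping
    per row, used for the permutation batch).
    """
    ind = indicator.astype(float)
    n = ind @ M
    s = ind @ X0
    ss = ind @ X0sq
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = s / n
        var = (ss - n * mean**2) / (n - 1)
    var = np.where(n >= 2, np.maximum(var, 0.0), np.nan)
    return n, mean, var


def _cohens_d_matrix(X: np.ndarray, group_a: np.ndarray):
    """Vectorised Cohen's D per column; ``group_a`` rows vs the rest.

    ``group_a`` may be 1-D (returns a vector) or 2-D with one grouping per
    row (returns a matrix, one row per grouping).
    """
    M = ~np.isnan(X)
    X0 = np.where(M, X, 0.0)
    X0sq = X0**2
    ga = np.atleast_2d(group_a)
    gb = ~ga
    na, ma, va = _group_stats(ga, X0, X0sq, M)
    nb, mb, vb = _group_stats(gb, X0, X0sq, M)
    with np.errstate(invalid="ignore", divide="ignore"):
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        d = (ma - mb) / np.sqrt(sp2)
    diff = ma - mb
    d = np.where(sp2 == 0.0, np.where(diff == 0.0, 0.0, np.sign(diff) * np.inf), d)
    d = np.where((na < 2) | (nb < 2), np.nan, d)
    return d if group_a.ndim > 1 else d[0]


# ---------------------------------------------------------------------------
# permutation FDR
# ---------------------------------------------------------------------------

def permutation_fdr(
    ceres: pd.DataFrame,
    calls: pd.DataFrame,
    genes: list[str],
    n_permutations: int = 1000,
    q_threshold: float = 0.1,
    seed: int | np.random.Generator = 0,
    exhaustive: bool = False,
) -> pd.DataFrame:
    """Permutation-based FDR for resistant-vs-sensitive effect sizes.

    ``calls`` must come from a single lineage (labels are shuffled within
    the lineage, preserving the two group sizes). With ``exhaustive=True``
    every distinct label assignment is used exactly once instead of
    ``n_permutations`` random draws (small cohorts only). Returns one row
    per gene with ``d_obs``, ``fdr_hat`` (capped at 1), ``q_value`` and
    ``significant`` (q below threshold).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if calls["lineage"].nunique() > 1:
        raise ValueError("calls span multiple lineages; scan one lineage at a time "
                         "(see acquired_dependency_scan)")
    # sorted so results do not depend on the order calls were supplied in
    lines = sorted(l for l in calls["cell_line"] if l in ceres.index)
    labels = calls.set_index("cell_line").loc[lines, "label"]
    resistant = (labels == "resistant").to_numpy()
    n_res = int(resistant.sum())
    if n_res == 0 or n_res == len(lines):
        raise ValueError("both resistant and sensitive lines are required")

    X = ceres.loc[lines, list(genes)].to_numpy(dtype=float)
    d_obs = _cohens_d_matrix(X, resistant)

    if exhaustive:
        from itertools import combinations
        from math import comb

        if comb(len(lines), n_res) > 100_000:
            raise ValueError("too many label assignments to enumerate exhaustively")
        perm = np.zeros((comb(len(lines), n_res), len(lines)), dtype=bool)
        for r, combo in enumerate(combinations(range(len(lines)), n_res)):
            perm[r, list(combo)] = True
        n_permutations = len(perm)
    else:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        # each permutation reassigns exactly n_res lines to the resistant group
        perm = rng.random((n_permutations, len(lines))).argsort(axis=1) < n_res
    d_perm = _cohens_d_matrix(X, perm)

    abs_obs = np.abs(d_obs)
    abs_perm = np.abs(d_perm).ravel()
    abs_perm = np.sort(abs_perm[~np.isnan(abs_perm)])
    valid = ~np.isnan(abs_obs)

    fdr = np.full(len(genes), np.nan)
    # numerator: mean over permutations of #{j: |d_perm_j| >= |d_obs_i|}
    num = (len(abs_perm) - np.searchsorted(abs_perm, abs_obs[valid], side="left")) / n_permutations
    sorted_abs_obs = np.sort(abs_obs[valid])
    den = len(sorted_abs_obs) - np.searchsorted(sorted_abs_obs, abs_obs[valid], side="left")
    fdr[valid] = np.minimum(num / den, 1.0)

    q = _running_min_q(abs_obs, fdr)
    return pd.DataFrame({
        "gene": list(genes),
        "d_obs": d_obs,
        "fdr_hat": fdr,
        "q_value": q,
        "significant": (q < q_threshold) & ~np.isnan(q),
    })


def _running_min_q(abs_obs: np.ndarray, fdr: np.ndarray) -> np.ndarray:
    """Storey-style monotone q: q_i = min of fdr over genes with |d| <= |d_i|.

    Equivalently the running minimum of the FDR estimate walking from the
    least extreme gene toward the most extreme, so q is non-increasing in
    |d| and significance calls are monotone (anything more extreme than a
    significant gene is itself significant). Ties share one q.
    """
    q = np.full_like(fdr, np.nan)
    valid = np.where(~np.isnan(abs_obs) & ~np.isnan(fdr))[0]
    if valid.size == 0:
        return q
    order = valid[np.argsort(abs_obs[valid], kind="mergesort")]
    cmin = np.minimum.accumulate(fdr[order])
    a = abs_obs[order]
    # genes tied on |d| have identical comparison sets -> the group's
    # q is the cumulative min at the END of the tie block
    block_end = np.r_[a[1:] != a[:-1], True]
    end_idx = np.where(block_end)[0]
    group_q = cmin[end_idx]
    group_of = np.searchsorted(end_idx, np.arange(len(order)))
    q[order] = group_q[group_of]
    return q


def acquired_dependency_scan(
    ceres: pd.DataFrame,
    calls: pd.DataFrame,
    genes: list[str] | None = None,
    n_permutations: int = 1000,
    q_threshold: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Run the permutation scan independently within every lineage in ``calls``.

    The scan covers all genes of the matrix by default (acquired
    dependencies need not be TFs); pass ``genes`` to restrict it.
    """
    genes = list(genes) if genes is not None else list(ceres.columns)
    out = []
    rng = np.random.default_rng(seed)
    for lin in sorted(calls["lineage"].unique()):
        sub = calls[calls["lineage"] == lin]
        if sub["label"].nunique() < 2:
            logger.warning("lineage %s has a single class; skipped", lin)
            continue
        res = permutation_fdr(ceres, sub, genes, n_permutations, q_threshold, rng)
        res.insert(0, "lineage", lin)
        out.append(res)
    if not out:
        return pd.DataFrame(columns=["lineage", "gene", "d_obs", "fdr_hat",
                                     "q_value", "significant"])
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# mutation enrichment & CCLE-style mutation rules
# ---------------------------------------------------------------------------

def mutation_enrichment(mutations: pd.DataFrame, calls: pd.DataFrame, gene: str):
    """Fisher's exact test of mutation status against resistance class.

    Returns ``(odds_ratio, p_value, table)`` where ``table`` is the 2x2
    array [[resistant&mutant, resistant&wt], [sensitive&mutant, sensitive&wt]].
    A zero margin yields p = 1 with an undefined (NaN) odds ratio.
    """
    mutant_lines = set(mutations.loc[mutations["gene"] == gene, "cell_line"])
    is_res = (calls["label"] == "resistant").to_numpy()
    is_mut = calls["cell_line"].isin(mutant_lines).to_numpy()
    table = np.array([
        [int((is_res & is_mut).sum()), int((is_res & ~is_mut).sum())],
        [int((~is_res & is_mut).sum()), int((~is_res & ~is_mut).sum())],
    ])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return float("nan"), 1.0, table
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p), table


def _functional_mask(mut: pd.DataFrame) -> pd.Series:
    """Loss-of-function call: disruptive class, or non-silent with a
    TCGA/COSMIC hotspot annotation."""
    cls = mut["variant_classification"].str.lower()
    disruptive = cls.isin(DISRUPTIVE_CLASSES)
    hotspot = (mut["is_tcga_hotspot"] | mut["is_cosmic_hotspot"]) & ~cls.isin(SILENT_CLASSES)
    return disruptive | hotspot


def classify_ccle_mutants(mutations: pd.DataFrame, ceres: pd.DataFrame) -> pd.DataFrame:
    """Per-line flags for the kidney-cancer mutation rules.

    ``is_ccRCC``: a disruptive (damaging / other non-conserving) VHL
    mutation together with resistance to VHL knockout (CERES(VHL) > -0.5),
    the signature of a VHL-null clear-cell line. ``smarcb1_functional`` /
    ``arid1a_functional``: a disruptive mutation, or any non-silent
    mutation flagged as a TCGA or COSMIC hotspot.
    """
    if "VHL" not in ceres.columns:
        raise KeyError("gene-effect matrix lacks a VHL column")
    cls = mutations["variant_classification"].str.lower()
    vhl = mutations[(mutations["gene"] == "VHL") & cls.isin(DISRUPTIVE_CLASSES)]
    vhl_mut_lines = set(vhl["cell_line"])

    out = pd.DataFrame(index=ceres.index)
    out.index.name = "cell_line"
    vhl_ceres = ceres["VHL"]
    out["is_ccRCC"] = [
        (line in vhl_mut_lines) and bool(vhl_ceres.loc[line] > -0.5)
        for line in ceres.index
    ]
    for gene in ("SMARCB1", "ARID1A"):
        gmut = mutations[mutations["gene"] == gene]
        functional_lines = set(gmut.loc[_functional_mask(gmut), "cell_line"])
        out[f"{gene.lower()}_functional"] = out.index.isin(functional_lines)
    return out.reset_index()
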