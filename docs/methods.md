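# Methods

This note documents the statistical procedures `lineagedep` implements,
the choices made where the design was genuinely open, and what the
synthetic benchmark does and does not demonstrate.

## Lineage-dependency (LD) scoring

Given a gene-effect matrix of CERES scores (cell lines × genes; more
negative = stronger knockout fitness cost), lineage annotations and a
transcription-factor family, the LD score of TF *t* in lineage *x* is

    LD(t, x) = mean(CERES[lines in x, t]) − mean(CERES[lines not in x, t])

Lineages with fewer than `min_lineage_size` (default 10) cell lines are
not scored. The out-of-lineage pool defaults to **every** annotated line,
including lines of undersized lineages (`ld_outgroup = "all"`); a switch
restricts the pool to eligible lineages. Missing CERES values are
excluded pairwise, never imputed.

Significance is the two-group Kruskal–Wallis test on the same in/out
partition. Because the partition always splits the same pool, each TF
column is ranked once and the rank-sum chi-square form

    H = 12 / (N(N+1)) · (R_in²/n_in + R_out²/n_out) − 3(N+1)

is evaluated for every lineage by matrix products, with the standard tie
correction `1 − Σ(t³−t)/(N³−N)`; a column constant within the pool gets
p = 1. This is algebraically identical to `scipy.stats.kruskal` per cell
(the test suite asserts agreement to 1e-12) but runs the full 1,600 TF ×
25 lineage grid in well under a second. Benjamini–Hochberg adjustment is
applied per lineage across its TF family by default (`bh_scope`), since
dependency sets are consumed per lineage; a global-family switch exists.

### The three-stage filter

1. **Effect and significance** — LD < −1.2 and adjusted p < 0.05. The
   adjusted/raw choice is a switch (`ld_use_adjusted_p`, default
   adjusted).
2. **Strong dependency in the majority** — a strict majority (> 50%) of
   the lineage's lines must have CERES ≤ −0.5 for the TF; lines with a
   missing value are excluded from the denominator.
3. **Pan-essentiality** — TFs whose median CERES across *all* cell lines
   is ≤ −0.2 are removed: genes essential everywhere, merely more
   depleted in one lineage, are not lineage identities.

The cascade records, for every removed candidate, the single filter that
removed it, and is monotone: relaxing any threshold can only grow a
lineage's surviving set (property-tested).

## Resistance and acquired dependencies

A line's `avg_ceres` is its mean CERES over its lineage's dependency set;
lines with `avg_ceres > −0.45` are *resistant* (lineage-factor
independent), the rest *sensitive*. The cutoff is the bimodality-derived
value used for the published analysis and is configurable.

The acquired-dependency scan compares resistant vs sensitive lines per
gene with the pooled-SD Cohen's D. Group labels are permuted *within the
lineage* (preserving both group sizes); the pooled-vs-within choice is
not documented upstream and within-lineage matches the comparison being
made. For each gene *i*:

    FDR_i = mean_perms #{j : |d_j^perm| ≥ |d_i^obs|} / #{j : |d_j^obs| ≥ |d_i^obs|}

capped at 1 (the raw estimator is unbounded; the cap never affects calls
at the 0.1 threshold). The q-value is the running minimum of `FDR_j` over
genes **no more extreme** than *i*, the standard Storey-style
monotonization, so q is non-increasing in |d| and significance calls are
monotone: anything more extreme than a significant gene is significant.
(The running minimum taken in the opposite direction degenerates — every
gene inherits the most extreme gene's FDR — and violates monotonicity,
so it is not offered.) Ties in |d| share one q. An `exhaustive` mode
enumerates all C(n, n_res) label assignments for small cohorts, which is
what the enumeration-oracle tests exercise.

Inclusive ties (`≥`) mean a gene always counts itself in its denominator,
so FDR is well-defined and in [0, 1] after capping.

Mutation enrichment between the two groups is the two-sided Fisher exact
test on the 2×2 (class × mutant) table; a zero margin returns p = 1 with
an undefined odds ratio. The kidney-cancer mutation rules: a line is
ccRCC-like when it carries a disruptive ("damaging" / "other
non-conserving") VHL mutation *and* tolerates VHL knockout
(CERES > −0.5); SMARCB1/ARID1A mutations count as functional when
disruptive, or non-silent with a TCGA/COSMIC hotspot annotation.

## Consensus peaks and differential accessibility

Every called peak proposes a 501-bp window centered on its summit
(summit ± 250). Candidates are ranked by −log10(q) descending — ties
broken by (chrom, summit) so the result is independent of input order —
and kept greedily iff they overlap no already-kept window (overlap = ≥ 1
shared base in half-open coordinates). Windows that would start before
base 0 are dropped by default (`boundary="clip"` anchors them at 0 with
full width). The significance filter retains peaks with
−log10(q) ≥ 20 by default; the literal complementary direction is
available by switch because the upstream description of this filter is
ambiguous about its direction.

Reads (BED6) are extended to the 250-bp modal fragment length from their
5′ end in strand direction, clipped at 0; unstranded reads are treated as
forward with a warning. A read increments every (disjoint) consensus peak
its extension touches. Differential-accessibility calls simply threshold
an externally computed table: |FC| ≥ 2 (|log2fc| ≥ 1) and padj < 0.001,
split into LA (lower accessibility) and HA (higher). Matched controls are
a uniform without-replacement sample of non-DA consensus peaks, defaulting
to the DA set's size.

## Window enrichment

Windows of half-width h ∈ {5, 10, 25, 50, 100, 250, 500, 1000} kb are
drawn around each region's summit; the sizes are configuration, not
constants, because the published axis does not print them. A gene is
captured when its TSS lies in `[center − h, center + h)` of any window —
TSS capture rather than gene-body overlap, isolated behind the
`capture_genes` surface. With universe = expressed genes and successes =
genes differential in the matching direction (LA↔down, HA↔up), the
p-value is the upper hypergeometric tail P(X ≥ k) with n = captured
expressed genes and k = captured DE genes (enrichment tail only).
Capture sets are nested in h by construction, so counts are monotone.

## Profile clustering

Binary open/closed accessibility profiles (regions × samples) are
restricted to the `top_variable_regions` most variable rows (binary
variance p(1−p), ties by coordinate), correlated pairwise (Pearson;
constant columns flagged and recorded as 0), and clustered greedily:
rank remaining samples by the number of remaining partners with
PCC > 0.6, seed a cluster with the top-ranked sample (ties by id), absorb
every remaining sample correlated with *the seed* (seed-linked, not
all-pairs — the documented variant is a switch), and stop the whole loop
at the first cluster smaller than 5. Cluster-specific regions are open in
≥ 80% of a cluster's samples and "present", by the same 80% rule, in at
most two other clusters. Note a structural consequence: a region open in
every sample is formally "specific" to all clusters when three or fewer
clusters exist, and excluded everywhere with four or more.

DA-association of a cluster's region set requires 100% containment of the
summit ± 25 bp window in a cluster region; the hypergeometric universe is
the consensus peak list (the upstream universe is unstated; the consensus
list is the natural population from which DA peaks are drawn).

## Synthetic data

The dependency generator writes CERES = Normal(0, σ = 0.15) plus planted
shifts: lineage-dependency TFs shift the *sensitive* lines of one lineage
by δ = −1.5; pan-essential decoys shift all lines by −1.0 *plus* the
in-lineage δ, so they clear filter 1 yet must fall to filter 3;
acquired-dependency genes shift resistant lines only, by −0.8. Gaussian
noise suffices because every downstream statistic is rank- or mean-based.
A resistant fraction ρ of each lineage's lines carries no LD shift, so
the observable LD score dilutes to ≈ (1 − ρ)δ: dependency-recovery
experiments therefore run at ρ = 0 and resistance/acquired-dependency
experiments at ρ = 0.3 (≈ the 19-of-49 resistant share of the motivating
melanoma comparison, which also fixes the 47% vs 28% mutation-rate
contrast planted for the Fisher test).

The regulatory generator plants: peak summits uniform on a toy genome
with −log10(q) = 1 + Pareto(1.5)·8 (heavy-tailed; no upstream
distribution is documented) and a stated fraction of summit pairs < 501 bp
apart to exercise consensus de-overlap; reads Normal(summit, 80 bp);
LA/HA labels at 15%/5% (≈ the 3:1 LA:HA split of the motivating study)
with a differential table realizing them; DE labels enriched near DA
summits by logistic odds (default 5×) within 50 kb; and binary profiles
built from a 100-row shared-open backbone plus 50 cluster-specific rows
per cluster, with every bit flipped with probability ε = 0.02 and 25% of
samples left as unrelated Bernoulli(½) profiles (the motivating
clustering left ~25% of samples unassigned). Half of cluster 1's specific
regions are centered on LA summits so the end-to-end overlap enrichment
has a planted positive.

What the benchmark does *not* show: real screens have gene–gene effect
correlations, copy-number artifacts and non-Gaussian tails; real
accessibility profiles have continuous signal, batch structure and
correlated (not independent) noise. Passing tests certify the estimators
and their decision rules, not performance on any particular data release.

## Problem sizes and numerics

Default test/benchmark sizes: 25 lineages × 20 lines × 1,600 TFs for
dependency analyses (the published lineage grid shape); 500 peaks /
20,000 reads / 2,000 genes for the accessibility arm; 60 samples × 4
clusters for profiles. The acceptance script uses 5 null seeds, 10
calibration seeds, 25 power seeds and 25 clustering seeds — enough for
the reported rates to be stable to a few percent while the whole script
runs in seconds. All randomness flows through `numpy` generators derived
from one base seed and a per-operation label (CRC32 of the label as a
spawn key), so adding an operation never perturbs another's draws and
fixed-seed runs are bit-reproducible.

Degenerate inputs: constant TF columns give LD = 0, p = 1; groups with
fewer than two usable values yield flagged missing p; zero pooled SD
gives Cohen's D of 0 (equal means) or signed infinity (unequal); zero
Fisher margins give p = 1; empty gene universes are an error.

## Known limitations

- The LD out-group convention ("all" vs "eligible") changes scores
  slightly when many lines live in undersized lineages; both are exposed.
- The q-filter direction for peaks, the BH family, adjusted-vs-raw p in
  filter 1, and the presence rule for "additional clusters" are upstream
  ambiguities; each is a documented switch with the defensible default.
- `greedy_cluster` is quadratic in samples and intended for cohorts of
  hundreds, not tens of thousands.
- The permutation scan assumes exchangeability of lines within a lineage
  under the null; confounders (media, ploidy) are not modeled.
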