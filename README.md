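# txaxis

Pathway-level analysis of the **transcriptional axis**: the empirical
observation, in large compendia of normalized microarray studies, that
metabolic pathways (oxidative phosphorylation, TCA cycle, fatty-acid
metabolism, ...) and cell-signaling pathways (MAPK, JAK-STAT, Wnt, ...)
are regulated in opposite directions, so that a single latent dimension —
anchored by OXPHOS expression — organizes most pathway-level expression
change. `txaxis` is for computational biologists who want to score that
axis in their own gene-by-sample expression matrices, or to study the
behavior of the procedure itself on simulated data with known ground
truth.

## What it computes

**SAM differential expression.** For an unpaired two-group comparison,
each gene *i* gets the moderated statistic

    d_i = (x̄_A − x̄_B) / (s_i + s₀)

with `s_i` the pooled standard error and the fudge factor `s₀` chosen
among the percentiles {0, 5, ..., 100} of the `s_i` distribution to
minimize the coefficient of variation of `d` across windows of `s`. The
false discovery rate is estimated by permuting group labels (exhaustively
when the design is small enough): for a threshold `t`, the mean number of
permuted `|d| ≥ t` per permutation is divided by the observed count, and
each gene's q-value is the smallest such ratio at or below its own `|d|`.
Genes with `q < 0.05` are called up or down by the sign of `d`.

**Net direction of regulation.** A pathway's score for one comparison is

    score(P) = 100 · (n_up(P) − n_down(P)) / N_regulated

where `N_regulated` counts all called genes study-wide, so scores live in
[−100, +100] percent and are comparable across studies.

**The two axis procedures.**

- *Extreme groups*: rank samples by mean OXPHOS expression, compare the
  top 10 against the bottom 10 with SAM, score every pathway, and — across
  studies — order pathways by the Pearson correlation of their score rows
  with the OXPHOS row.
- *Sequential bins*: pair the i-th-highest against the i-th-lowest group
  of samples (i = 1..10) and count DE transcripts per pair; on
  axis-structured data the counts fall off as the compared groups
  approach the middle of the ranking.

The **axis fraction** is the share of pathways whose score row is
significantly Pearson-correlated (two-sided p < 0.05) with the OXPHOS
row across studies; **cross-study correlation** tests specific pathway
pairs (e.g. TCA cycle vs OXPHOS positive, MAPK vs OXPHOS negative).

**Synthetic studies.** `generate_study` / `generate_multi_study` simulate
gene-by-sample matrices in which each sample carries a latent axis score
z ~ N(0,1), metabolic pathways load `+β` and signaling pathways `−β` on
z, background genes load 0, and Gaussian noise sits on the log2 scale —
so every downstream stage can be checked against exact ground truth.

## Worked example

```python
import txaxis as tx

# one synthetic study under the canonical conditions:
# 5,000 genes, 200 samples, 10 metabolic pathways at +1 and
# 10 signaling at -1, 30 null pathways, noise SD 0.7
cfg = tx.default_axis_config(seed=42)
study, sets, truth = tx.generate_study(cfg)

res = tx.run_figure1(study, sets, k=10, target_fdr=0.05,
                     n_permutations=200, seed=7)
print(f"genes called at q<0.05: {res.calls.n_called}")
print(f"net score OXPHOS:         {res.profile.score('OXPHOS'):+.2f} %")
print(f"net score MAPK signaling: {res.profile.score('MAPK signaling'):+.2f} %")

ranking = tx.rank_by_pathway_expression(study, sets)
bins = tx.sequential_bins(ranking)          # 10 comparisons of 10 vs 10
curve = tx.de_count_curve(study, bins, sets, n_permutations=200, seed=7)
print("DE counts, comparisons 1..10:", list(curve.curve.de_counts))
```

prints

```
genes called at q<0.05: 1029
net score OXPHOS:         +4.86 %
net score MAPK signaling: -4.86 %
DE counts, comparisons 1..10: [1029, 1007, 1008, 1005, 956, 649, 325, 58, 0, 0]
```

The extreme-group comparison recovers essentially all 1,000 axis-loaded
genes; metabolic and signaling pathways get equal and opposite net
scores (each holds 50 of the ~1,029 regulated genes: 100·50/1029 ≈
4.9%), null pathways sit at zero, and the sequential-comparison counts
fall from ~1,000 toward zero as the compared groups converge on the
middle of the OXPHOS ranking.

The same pipelines are available from the shell (`txaxis simulate`,
`rank`, `fig1`, `curve`, `correlate`, `axisfrac`); every output
directory carries a `manifest.json` with the configuration, seeds and
input digests needed to reproduce it.

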