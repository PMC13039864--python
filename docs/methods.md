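# Methods

## The problem

Human pluripotent stem cells (hPSCs) differentiated toward pancreatic
β-like cells pass through defined stages: undifferentiated hPSCs at day 0
(D0), endocrine progenitors around day 20 (D20), and β-like cells around
day 35 (D35). Bulk RNA-seq at those stages, in two independent cell-model
backgrounds (hESC- and hiPSC-derived differentiations), yields for every
gene a pair of fold changes against D0. `betatraj` stratifies the
transcriptome by the *shape* of each gene's temporal response, overlays a
transcription-factor (TF) catalogue on the resulting classes, and provides
the supporting machinery: differential expression (DE), gene-set
over-representation, heatmap ordering, the cross-hairpin knockdown filter,
and the 2^−ΔΔCt qPCR utility. A synthetic-data generator plants genes with
known trajectory classes so every stage has a ground-truth oracle.

## The stratification procedure

For each model independently, and for each target stage t ∈ {D20, D35},
a gene's differential status is

- UP if FC_t > 2.0 and p_t < 0.05,
- DOWN if FC_t < 0.5 and p_t < 0.05,
- NS otherwise,

where FC_t is the linear fold change of mean abundance versus D0.
Fold-change inequalities are strict by default (`Thresholds.strict_fc`);
an inclusive variant (≥ / ≤) is one flag away because boundary genes are
the only ones affected and conventions differ.

Genes UP at both stages are split by the change-in-FC ratio
r = FC_D35 / FC_D20:

- increasing if r > 1.5,
- decreasing if r < 0.5,
- near-constant if 0.5 ≤ r ≤ 1.5 (boundaries inclusive to near-constant).

A gene with FC 2 at D20 and FC 6 at D35 has r = 6/2 = 3: increasing.

The (D20, D35) status pair plus the ratio bin maps every gene to exactly
one of eight categories — UP_D20_ONLY, UP_D35_ONLY, the three UP_BOTH_\*
bins, DOWN_BOTH, DOWN_D20_ONLY, DOWN_D35_ONLY — plus two bookkeeping
labels: DISCORDANT (UP at one stage, DOWN at the other) and UNCLASSIFIED
(NS, NS). The eight-category algebra is silent about discordant genes; we
report them separately by default, and
`count_discordant_in_only` additionally counts them into the two matching
single-stage sets for users who prefer that accounting. The p filter is
applied per contrast (each stage's own p-value), the natural reading of a
per-stage UP/DOWN call.

Per-category gene lists are then intersected across models: a gene
survives only if every model assigned it the *same* category, which for
up-both genes means the same ratio bin in every model. The ratio is always
computed per model from that model's own fold changes.

## Differential expression

No specific DE engine is assumed. The built-in default is deliberately
plain: FC = (mean(target) + c) / (mean(baseline) + c) with pseudocount
c = 0.01 FPKM (avoids division by zero without distorting expressed
genes), and a Welch two-sample t-test on log2(x + 1)-transformed replicate
values. Degenerate cases follow fixed rules: fewer than two replicates in
either group gives p = 1 (uninformative); two zero-variance groups give
p = 1 when their means agree and p = 0 when they differ (perfect
separation — this is what makes noiseless synthetic data fully
recoverable). No multiple-testing correction is applied at this stage: the
time-course filter is a raw p < 0.05, while the knockdown filter uses
adjusted p. Externally computed DE tables (gene, fold change, p) can be
passed straight to the stratifier, keeping it independent of any one DE
method.

## TF overlay

Category gene lists are intersected with a user-supplied registry of human
TF symbols (e.g. the Lambert catalogue) after the same normalization used
everywhere (strip, uppercase). The report carries n_genes, n_tf and
tf_percent = 100·n_tf/n_genes per category (0 for an empty category), and
lists registry symbols never seen in any category rather than dropping
them silently — symbol-vocabulary drift between catalogues is the main
failure mode of this step.

## Gene-set over-representation

A desk-scale replacement for a web enrichment service: each set S in a GMT
collection is tested against a query list Q and background universe B with
the hypergeometric upper tail

P = P[X ≥ k],  X ~ Hypergeom(N = |B|, K = |S ∩ B|, n = |Q ∩ B|),

and q-values are Benjamini–Hochberg adjusted across all tested sets. BH is
a deliberate substitution for g:SCS-style corrections: standard,
reproducible and testable. The default background is the set of all
detected genes (the expression matrix), not the genome — that is the
universe the study design actually samples; callers may supply any other
background. Query genes outside the background are dropped with a count.

## Reporting

Heatmap rows are ordered by one of two rules: mean FPKM across the D20 and
D35 samples of all models, descending (single-stage and downregulated
categories), or the difference mean(D35) − mean(D20) — largest increase
first for increasing categories, most negative first for decreasing ones.
Ties break lexicographically by symbol, so orderings are deterministic.
The averaging window (which timepoints enter the mean) is configurable;
D20+D35 is the default because those are the stages the heatmaps display.

The knockdown filter takes one DE table per shRNA condition (three
hairpins against a scrambled control in the motivating design) and keeps,
per condition, genes with p_adjusted < 0.05 and |log2 FC| > 0.5 (strict
inequalities), then intersects the up and down lists across all
conditions. An "absolute FC" threshold of 0.5 is not interpretable on the
linear scale — every upregulated gene would trivially pass — so the filter
is defined on |log2 FC|. By default the table's fold_change column is
linear (the DE-table contract, positive values) and is log2'd internally;
`fc_scale="log2"` declares a signed log2 column instead (pass a plain
DataFrame in that case).

The 2^−ΔΔCt utility computes, per sample, ΔCt = Ct_target − Ct_reference,
ΔΔCt = ΔCt − mean ΔCt of the control condition, and relative expression
2^−ΔΔCt; the control group's geometric mean is 1 by construction.

## Synthetic data

The generator emulates the study design: 2 models × 3 timepoints
(D0/D20/D35) × 3 replicates, FPKM-like abundances. Each gene is planted in
one category (or as unclassified background); its mean at stage t is
baseline_mean × planted_fc(t) and replicates multiply the mean by 2^ε,
ε ~ Normal(0, noise_sd) — multiplicative log-normal noise, the simplest
positive-valued model consistent with log-scale heatmap practice. Defaults,
chosen once as a realistic desk-scale design: baseline_mean 100 FPKM (a
well-expressed gene), noise_sd 0.25 (replicate spread ≈ 1.2-fold, typical
of good bulk RNA-seq replicates), 50 genes per category plus 200
background, tf_fraction 0.1 (inside the 5–17% per-category TF range
reported for real data).

Planted fold changes must clear every threshold they depend on by a safety
factor (default 1.5×) — e.g. UP calls use FC ≥ 3 against the 2.0 cut —
because the classification thresholds are sharp and recovery under noise
needs margin; a config violating its category's inequalities is rejected
before simulation. Both models share planted FCs by default, so the
cross-model intersection keeps all planted genes; `discordance_fraction`
reassigns that fraction of genes to a different category in the second
model to exercise intersection loss. `plant_enriched_sets` emits one gene
set per category (80% of the category's genes plus 10 random background
members by default), enriched by construction, as the oracle for the
enrichment stage.

What the generator does *not* emulate: count-level sampling noise
(negative-binomial dispersion), library-size or gene-length artefacts,
correlated genes, batch effects, or symbol ambiguity. Passing tests
therefore demonstrate correctness of the classification algebra and the
statistical calibration of the test under the stated noise model — not
robustness to every pathology of real RNA-seq.

## Numerical choices and degenerate inputs

- Welch p-values are clipped to [0, 1]; NaN (pathological inputs) maps to 1.
- The expression reader rejects non-numeric cells naming the offending row
  and column, and duplicate sample headers; duplicate gene symbols are
  collapsed by keeping the row with the largest mean abundance
  (configurable: error | first | max-mean).
- Enrichment rows are sorted by p-value with set-name tie-break;
  category output order is fixed; all sorts use stable algorithms.
- Seeding: a single integer seed drives one `numpy` Generator per
  simulation; identical configs are bit-identical.

## Known limitations

- The stratification is specific to a three-timepoint design (baseline +
  two targets); generalization to k timepoints is out of scope.
- The built-in DE test is a two-group Welch test, not a count-based GLM;
  for real count data an external DE engine's tables should be passed
  through.
- Enrichment ignores gene-set topology (no GO DAG, term redundancy or
  ordered queries).

## Test-suite problem sizes

Unit and property tests run on matrices of 600 genes (8 × 50 planted +
200 background); the statistical-calibration tests use 2000-gene null
simulations and 10–20 simulation seeds. The full suite completes in well
under a minute.
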