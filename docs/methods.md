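# Methods

## Scope and model

The toolkit evaluates chemical-induced transcriptional perturbations at the
level of curated biomarker gene sets rather than individual probes. A
*condition* is one compound × dose × timepoint group with matched controls.
For each condition the per-probe change is the difference of group means on
the log2 scale, so scores are ratio-based and require expression values
that are already normalized and log2-transformed (a `--linear` escape hatch
applies log2(max(x, 1)) for linear-scale inputs; preprocessing proper is
out of scope).

### TGP1 score

TGP1 = direction × magnitude with direction (n_up − n_down)/n and magnitude
mean |e_i|. The literature describing this score names its two ingredients
but not their formulas; the forms used here are the minimal ones with the
score's three defining behaviors: the sign follows the majority direction,
the score approaches zero as the set's probes diverge in direction, and it
grows with the size of the changes. Zero effects (e_i = 0) count in n but
in neither tally, which pulls the direction index toward zero — the
conservative reading of "divergent". |TGP1| ≤ max|e_i| always, since
|direction| ≤ 1 and magnitude ≤ max|e_i|.

### D-score

D-score = C · mean(w_i e_i) with detection-call weights P = 1, M = 0.5,
A = 0 and default C = 10. The quality weight of a probe is the mean call
weight over *all* samples of the condition, controls included: a probe must
be reliably detected on both sides of the comparison to count fully.
The published description of this score specifies its two ingredients
(expression changing level and data quality) but not the formula; the
weighted mean is the minimal combination of both, and C = 10 puts a uniform
2-fold, full-quality change at 20 — the reference level drawn on radar
charts. Consequences worth knowing: an all-Absent set scores exactly 0
however large its apparent effects, and padding a set with undetected
probes dilutes the score through the 1/n normalizer but never inflates it.
The numerator is accumulated with correctly rounded summation (`math.fsum`)
so exactly sign-symmetric effect patterns cancel to 0.0 rather than to
rounding noise, and score(−e) = −score(e) holds bit-exactly.

Per-probe significance filtering is deliberately *not* applied before
scoring; an optional `min_abs_effect` threshold (default 0) exists for
users who want it. Scoring operates at probe level throughout; collapsing
probes to genes is the caller's responsibility if desired. Set members
absent from the array are dropped with a warning (biomarker sets and
platforms evolve independently); only a set with no member on the array is
an error.

## Network inference

Gene-set scores and phenotype changing levels are joined on conditions,
rows with any missing phenotype dropped listwise (the simplest defensible
policy; more elaborate imputation is not warranted at these sample sizes),
zero-variance columns dropped, and every column standardized so scores and
phenotypes are commensurate. Partial correlations come from the inverse of
the shrunken correlation matrix S* = (1 − λ)S + λI. The automatic λ is the
analytic variance-ratio estimator: λ = Σ_{i<j} Var̂(r_ij) / Σ_{i<j} r_ij²,
with Var̂(r_ij) computed from the empirical variance of the per-observation
products of standardized variables, clipped to [0, 1]. This is the standard
small-n-large-p GGM workhorse for this problem scale (~64 features on ~150
conditions) and is substitutable behind `estimate_pcor` should a graphical
lasso ever be wanted. At λ = 0 the estimate equals the defining
regression-residual construction of partial correlation (verified to 1e−8
in tests against an independent brute-force oracle); at λ = 1 the network
is empty. Inversion is refused when the shrunken matrix's condition number
exceeds 1e12, with advice to raise λ.

### Edge selection

Three rules: `abs_threshold` (default t = 0.1), `top_k`, and `perm_fdr`.
The permutation rule destroys all dependence by permuting each column
independently B times (seeded generator, bit-reproducible), re-estimates
the partial-correlation matrix at the observed λ each time, pools all
permuted off-diagonal |ρ| values as the null, and keeps edges whose
plug-in empirical FDR — (#null ≥ t / B) / (#observed ≥ t), made monotone by
the usual step-up pass — is at most q. A pooled null was chosen over a
per-permutation max-|ρ| null because the latter controls family-wise error,
which is stricter than the FDR semantics the rule advertises. No
significance rule is canonical for shrinkage GGMs at this scale; all three
are honest stand-ins and the exports always carry ρ so users can re-filter.

Exports: GraphML with node `kind` (gene_set/phenotype) and edge
`weight`/`sign` attributes; DOT with positive edges purple, negative green,
penwidth 0.5 + 4.5·|ρ|; TSV edge list (round-trips exactly).

## Visualization conventions

Radar charts plot |score| with a constant reference circle (default 20);
heat maps and supervised networks plot signed scores on a diverging
red–white–blue scale centered at zero with symmetric limits at the global
|score| maximum — per-figure global scaling keeps cross-set comparison
honest. The two conventions intentionally differ: radar charts answer "how
strongly is each endpoint affected", the signed displays answer "in which
direction". The supervised network's topology is a curated input (TSV edge
list), never inferred; missing nodes get a neutral fill and a warning. All
renderers are deterministic (fixed SVG hash salt, no timestamps), so
identical inputs give byte-identical files — which is what makes the flow
manifest's output hashing meaningful.

## Synthetic data

The generator exists so every claim above is testable against planted
truth; it is first-class, seeded, and fully determined by its config.

*Expression level.* Probe baselines ~ N(8, 2) on the log2 scale, sample
values = baseline + planted treated effect + N(0, 0.3) replicate noise,
3 replicates per group, 58 sets of 8–15 probes on a 1,200-probe array —
magnitudes typical of a rodent liver biomarker screen. Detection calls link
quality to intensity: Present with probability logistic((v − 6)/1), else
Marginal within ±1 of the center, else Absent, so dim probes are
low-quality and quality weighting has real signal. Sets are disjoint by
default (crisp recovery attribution); an overlap option exists because real
biomarker sets overlap. Noise is homoscedastic Gaussian — deliberately
simpler than real microarray noise (no intensity-dependent variance, probe
effects, or batch structure), so passing recovery tests demonstrate the
statistics, not robustness to platform artifacts.

*Feature level.* Condition rows are drawn i.i.d. from N(0, Ω⁻¹) for a known
sparse precision matrix Ω, built by planting edges with magnitudes in
[0.2, 0.4] and random signs, shifting the diagonal past the most negative
eigenvalue (margin 0.1) and re-standardizing to unit diagonal — the pattern
is preserved exactly and population partial correlations are computable in
closed form. Real score matrices are not exactly Gaussian and conditions
from a shared compound are not independent; edge-recovery results are about
estimator correctness, not about those violations.

*Case study.* A four-timepoint (2, 6, 12, 24 h) hepatotoxicant time course
with named biomarker themes and a planted log2-effect schedule: glutathione
depletion (+1.8) and DNA damage (+1.5) at 6 h; oxidative stress (+1.6),
inflammation (+1.4) and feedback glutathione homeostasis (+1.2) at 12 h;
peak inflammation (+2.2) with suppressed cholesterol synthesis (−1.2) and
glycolysis (−1.0) at 24 h. Magnitudes were chosen once to give clear rank
separation at the default noise level while staying in the 1–2 log2-unit
range typical of acute hepatotoxicant responses.

## Flow and provenance

`run_flow` executes load → score → radar (one per condition) → heat map →
network → optional supervised network. Each stage failure aborts with the
stage name; outputs already written stay on disk and the manifest flags the
failed stage. The manifest records tool version, a hash of the scientific
configuration (output paths and log level excluded so relocated reruns
compare equal), input and output SHA-256 checksums and per-stage status.
Tabular outputs carry version and config hash as `#` comment headers,
which all readers skip.

## Problem sizes and tolerances

Tests and the acceptance script use the study-scale defaults directly: 100
seeds for the rank-recovery and case-study rates, 20 seeds × (p = 20,
n = 150) for edge recovery, n = 5,000 for the estimator-vs-oracle check
(tolerance 1e−8; observed agreement is at machine precision). Exact
identities (anti-symmetry, symmetric-set cancellation, all-Absent
annihilation) are asserted bit-exactly, not approximately.

## Known limitations

- The probe→gene relationship is ignored; sets are probe-ID lists.
- Phenotype changing levels are consumed as given; any per-endpoint
  transform (log-ratio vs % change) is the caller's duty.
- The GGM is undirected and static; no causal or time-lagged structure.
- With very few conditions (e.g. a single time course) the auto shrinkage
  is large and the inferred network is near-empty — as it should be; the
  network stage is meant for database-scale inputs (~150 conditions).
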