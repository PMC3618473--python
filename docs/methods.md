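# Methods

This note records the models, defaults, numerical choices and known
limitations of the package. It is the place where design decisions that
were genuinely open are explained.

## Genomic events and the event matrix

A *genomic event* at a locus in a cell line is a mutation (coding
sequence variant) and/or a copy-number aberration, defined as gene-level
total copy number equal to 0 (homozygous deletion) or ≥ 8
(amplification). Both thresholds are parameters of
`build_event_matrix` (`deletion_value=0`, `amplification_threshold=8`).
Sub-loci such as `CDKN2A(p14)` are independent loci and are never merged
into the parent symbol — the p14 reading frame can be lost while the
p16 transcript is intact, and published event tables list them
separately.

Cell lines and loci are kept in lexicographic order everywhere; all
downstream outputs inherit this canonical ordering, so re-ordering input
rows cannot change any result. A cell line present in a screen but
absent from the genomic tables is retained for response calling and
excluded from association tests (its genotype is unknown, its GI value
is still informative for the curve). Loci with zero events in the
analyzed panel are dropped before co-event enumeration and the drop is
recorded in the scan's metadata — a zero-frequency locus has predicted
co-occurrence 0 with everything and would only inflate the potential
space.

## Independence model and the disequilibrium statistic

The predicted co-event count for loci with panel marginal frequencies
f₁…f_k over N lines is E_raw = N·∏fᵢ (pairs use the two-way, triples
the three-way product). The observed count O is compared with E by a
two-cell goodness of fit over {co-event, no co-event}:

    chi2 = (O − E)²·(1/E + 1/(N − E)),    p = upper tail of χ² with 1 df.

Two rounding modes exist:

* `paper_compat` (default for population scans): E is the nearest
  integer to E_raw, half away from zero. This is what reproduces
  published per-pair p-values digit-for-digit (O=8, E=20, N=294 ⇒
  p = 0.005444485); printed tables round the predicted count before
  testing.
* `exact`: E = E_raw.

No continuity correction is applied anywhere — the printed p-values
reproduce without one. Configurations with E ≤ 0 or E ≥ N are flagged
*untestable* and carry no p-value; they are never silently dropped or
reported as NaN.

Classes at level α (default 0.05): *mutually exclusive* — O = 0 and
p ≤ α; *partially exclusive* — 0 < obs freq < pred freq and p ≤ α;
*co-selected* — obs freq > pred freq and p ≤ α; otherwise *none*. The
pair scan scores the full C(G,2) potential space including zero-count
pairs (that is where mutual exclusivity lives); the triple scan scores
observed triples only, because the cubic potential space is dominated
by pairs with negligible expected counts.

### Calibration properties (and a deliberate caveat)

With marginals estimated from the same panel, the two-cell statistic is
*conservative* for common events: the variance of O − N·f̂A·f̂B under
independence is N·fA·fB·(1−fA)(1−fB), while the statistic normalizes by
N·p(1−p) with p = fA·fB, a deflation factor (1−fA)(1−fB)/(1−fA·fB).
At fA = fB = 0.3 the rejection rate at nominal 0.05 is ≈ 0.01; in the
rare-event regime the factor approaches 1 and the test is close to
nominal. The calibration study in the acceptance suite therefore draws
marginals from U[0.03, 0.15] — which is also the realistic regime for
curated panels (a few hundred loci, ~10 events per line, mean marginal
≈ 0.04) — and observes rejection ≈ 0.05. Users scanning panels rich in
very common events should expect the scan to be conservative there.

## Response calling

Per drug, GI values are rank-ordered ascending (ties broken by
cell-line identifier) and fitted by least squares with a polynomial of
degree 9 (configurable; "high order") on the rank axis rescaled to
[0, 1]. A rank-deficient fit triggers automatic degree reduction with a
logged warning. The inflection point is the smallest interior rank at
which |f''| of the fitted polynomial attains its maximum (relative
tolerance 1e-9 for "first instance"; the two endpoint ranks are
excluded as edge artifacts). The call is degenerate when the interior
maximum of |f''| falls below a floor of 1e-8 × max(GI range, 1) — a
linear or constant profile has no curvature structure — or when fewer
than `min_lines` (default 10) lines were tested.

Cutoffs: in gIC50 mode the cutoff is the GI value at the inflection
rank; in viability mode it is min(GI at inflection, 0.78) — whichever
gives the greater sensitivity. Sensitive = lines with GI strictly below
the cutoff; lines sharing the cutoff GI value are all assigned
resistant (ties never straddle the boundary; the conservative side was
chosen because a tie at the cutoff is indistinguishable from the
resistant bulk). Inflection points are computed independently per drug
and per cohort.

### Resolution and bias of the inflection estimator

A least-squares polynomial of degree d on n ranks smooths structure on
the scale of ~n/d ranks. Two consequences, both verified by simulation
and both inherent to the method rather than to this implementation:

* **Localization.** The estimator resolves a knee to ±2 ranks only
  when the rank grid is fine relative to the smoothing scale (n ≲ 2d).
  The knee-recovery validation therefore uses 20-line profiles with
  degree 9, where agreement with the discrete second-difference oracle
  is exact to ±2 ranks; at n ≈ 300 the |f''| extremum of a sharp knee
  is displaced by ~n/(2d) ranks.
* **Shoulder bias.** For a two-plateau (jump) profile the |f''| lobe
  peaks on the low-plateau shoulder, so the recovered sensitive group
  undershoots the knee by up to ~2 ranks and does not overshoot.
* **Heavy tails.** On unbounded, right-skewed GI distributions (raw
  gIC50 with no upper censoring) the largest curvature of the rank
  curve can sit in the extreme right tail rather than at the sensitive
  knee, and the global-max reading then picks the tail. Real gIC50
  screens are censored at the top tested dose, which flattens that
  tail; the viability-mode 0.78 cap serves the same stabilizing role.
  Viability-mode panels are the recommended synthetic testbed, and the
  cap is why the published procedure includes one.

## Per-drug association

Denominators are always the genomically characterized lines tested
with the drug. Singles use the two-sided Fisher's exact test on
[[count_S, n_S−count_S], [count_R, n_R−count_R]] with a prevalence
filter (*powered* iff frequency > 0.12 in S or in R). Co-events use the
Pearson chi-square on the 2×2 presence × S/R table (the Yates-corrected
variant is reported alongside, because the exact published per-drug
test is ambiguous — neither variant reproduces the published per-drug
co-event p-values from back-derived counts, so both are emitted and the
ambiguity documented rather than resolved). Secondary diagnostics rerun
the observed-vs-predicted goodness of fit inside the S and R
subpopulations, with marginals computed *within* each subpopulation by
default (whole-population marginals behind a flag; the within reading
asks "are these events co-selected among the sensitive lines", which is
the question the reciprocity observation — co-selection in S mirrored
by deficit in R — is about).

The S/R ratio is (count_S/n_S)/(count_R/n_R), +inf when the event is
absent from resistant lines but present in sensitive ones. Selection
requires p ≤ α and the ratio strictly outside [1/1.5, 1.5]. Co-events
carried by fewer than `min_count` = 4 tested lines are skipped (the
smallest tuple count a practitioner would trust in a printed table).
Ranking of selected events: ascending p, then descending carrier count,
then |log ratio| descending with the infinite sentinel ranking first,
then the locus tuple for determinism.

## Lineage interaction and subtraction

The default (tuple, lineage) test is the proportional goodness of fit:
the pair's m carriers are split against the expectation
(m·n_S/n, m·n_R/n) with the same two-cell chi-square — matching the
observed-vs-expected style of the rest of the pipeline; a Fisher 2×2
(carriers vs non-carriers × S/R) is selectable, and the two agree in
direction on small tables. Pairs with fewer than 3 carriers are not
tested (a 1-df chi-square on 1–2 carriers is meaningless).

Subtraction removes *every* cell line of each significant lineage, then
re-tests the tuple on the remainder with the default test. The
remainder was never used to select the interacting lineages, so it is
an internal cross-validation set. "No power" (event in < 12 % of both
remaining groups, or absent, or empty remainder) is a first-class
output state, never an exception and never silently dropped. The
summary table reports, per α ∈ {0.05, 0.10}, the fraction of powered
tuples that stay significant regardless of lineage, optionally after
excluding tuples containing caller-supplied ubiquitous loci.

## Response-profile clustering

Per compound (column): median-center, then normalize to unit sum of
squares (the Cluster-3.0 convention for expression-style matrices; the
unit-variance alternative is deliberately not the default because the
published scaled scores follow the former). Missing GI values stay
missing; correlations are pairwise-complete (≥ 3 shared positions) and
distance is d = 1 − r ∈ [0, 2]. Clustering is average linkage (UPGMA)
over that distance, entities pre-sorted lexicographically so ties break
deterministically; entities with any undefined distance are appended as
singletons and logged. Both the drug and the cell-line axes can be
clustered. Subcluster coherence is the mean pairwise r over a member
set.

## Synthetic panels

The generator emulates the structure of a curated screen: N = 300
lines (default), 260 loci, 20 lineages. Default marginals are drawn
from Beta(1.1, 25) clipped to [0.005, 0.6] (mean ≈ 0.04 — mostly rare
events with a common-driver tail). Pairwise couplings follow
P(A∧B) = λ·f_A·f_B exactly, sampled from the 2×2 joint law; couplings
are restricted to disjoint pairs so the joint law stays exact without
graphical-model machinery, and an infeasible (λ, f_A, f_B) raises an
error naming the pair. Lineage enrichment multiplies the in-lineage
odds of a locus (clipped to (0,1)) and is applied before coupling, so
a locus cannot be both enriched and coupled.

Drug screens follow GI = baseline · ∏(applicable shifts) · exp(ε),
ε ~ N(0, σ²). gIC50 baselines are log-normal with median 650 nM
(the scale of reported inflection cutoffs) and log-sd 0.8; viability
baselines have median 0.92 and log-sd 0.2, so the bulk sits just above
the 0.78 cap and the cap rule is exercised. Shifts < 1 sensitize.
Effects can be single-locus, epistatic (all loci of a tuple required),
per-lineage, or lineage-conditional (locus × lineage) — the last is
what a genuinely lineage-confined biomarker is, and is what the
subtraction cross-validation is validated against.

What the generator does *not* emulate: mutational signatures, clonal
structure, locus–locus correlation beyond disjoint pairs, dose-series
measurement error, and batch effects between screens. Passing tests on
these panels show the statistics and the pipeline plumbing are correct
under the stated generative model; they do not show that real panels
satisfy that model.

### Validation study designs

Chosen once, from the analyses above, and fixed:

* *Type-I calibration*: 100 independence panels, N = 300, 30 loci,
  marginals U[0.03, 0.15]; rejection at α = 0.05 expected in
  [0.03, 0.07].
* *Coupling recovery*: λ ∈ {0, 0.2, 3} pairs at marginals 0.25,
  N = 300 (at marginals 0.15 a λ = 0.2 pair is unobserved in ~26 % of
  panels and would be indistinguishable from strict exclusivity).
* *Epistasis recovery*: N = 600 viability panel, pair marginals 0.75,
  epistatic shift 0.83, noise 0.05. The requirement that the pair pass
  the 1.5-fold filter while *neither* single locus does is impossible
  when the sensitive set coincides with the double-carrier set (the
  single-locus ratio is then at least (1+f)/f > 2); it needs a diluted
  sensitive group, which the broad viability baseline plus the 0.78 cap
  produce.
* *Knee recovery*: 20-line two-regime profiles (plateaus 0.3/1.0,
  σ = 0.02, knee fraction 0.10–0.20), per the resolution analysis.
* *Lineage subtraction*: a confined design (locus enriched 12× in a
  double-weight lineage, effect only inside it) and an independent
  design (uniform locus, panel-wide effect), 50 replicates each.

## Known limitations

* The disequilibrium test is conservative for common events (above).
* The inflection rule is unreliable on heavy-tailed uncensored GI
  distributions at large n (above); prefer viability mode or censored
  gIC50 inputs.
* The exact per-drug co-event test of the original tables is ambiguous;
  both candidate tests are reported side by side.
* Triple-event scans cover observed triples only.
* Locus identity is exact string matching; alias harmonization and
  cross-database identity checks are out of scope.
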