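# Methods

This note records the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic cohorts do and do not
emulate, and the numerical decisions a maintainer would otherwise have to
reverse-engineer.

## Ingestion and filtering

Profiling reports are accepted in two tab-separated dialects,
auto-detected from the header: the Kraken2 report style (percent, clade
reads, direct reads, rank code, taxid, indented name — hierarchy is
reconstructed from the indentation, and the *clade* count, reads assigned
at or below the taxon, is used) and the Bracken re-estimation style
(headered; the re-estimated read count is used). Bracken reports carry no
hierarchy, so an optional taxonomy sidecar TSV (taxid → lineage) can be
attached; a taxon with no lineage is **retained** with a warning, because
its exclusion cannot be established.

Two filters precede analysis:

1. **Lineage exclusion** removes mitochondrial and chloroplast taxa
   (matched anywhere in the name or lineage) and eukaryotes outside the
   fungal kingdom. Bacteria, archaea, viruses and fungi survive.
2. **Rare-taxon filtering** removes a taxon iff its share of the grand
   total read count is below `min_global_fraction` (default 1e-7, i.e.
   0.00001% of the whole dataset) **or** it is detected in fewer than
   `min_sample_count` samples (default 5). The two conditions are
   disjunctive, evaluated once against the table as given (single pass,
   no iteration after removals — re-evaluating thresholds on the shrunken
   table could cascade and would make results depend on removal order).
   Prevalence is counted after the lineage exclusion, an explicit
   assumption documented here because the order is not otherwise forced.

Alpha diversity is computed on the lineage-excluded but **not**
rare-filtered counts; the rare filter exists to stabilise multivariate
and differential statistics, while richness estimators specifically need
the rare tail. Everything downstream of alpha diversity uses the filtered
table.

## Rarefaction and alpha diversity

Rarefaction draws, per sample, a uniform subsample of reads without
replacement (a multivariate hypergeometric draw) summing exactly to the
target depth. The default depth is **6172 reads**, the floor set by the
lowest valid-read sample of the cohort design this pipeline targets; an
`auto` mode uses the current table's minimum sample total instead.
Samples below the depth are dropped with a warning (note that lineage
exclusion can legitimately push a sample below the floor). One seeded
draw is taken per sample — no averaging over repeated draws, keeping the
output a true count table and the procedure exactly reproducible from
the seed.

Four measures per sample:

- observed richness S = #{i : cᵢ > 0};
- Shannon H = −Σ pᵢ ln pᵢ in **nats** (base-e; the base is a convention
  and only rescales comparisons);
- inverse Simpson 1/Σ pᵢ² (effective number of dominant taxa);
- Chao1 in the **bias-corrected** form S + F₁(F₁−1)/(2(F₂+1)), defined
  even when no doubletons exist; the classical S + F₁²/(2F₂) form is
  available via `bias_corrected_chao1=False` and refuses the undefined
  F₂ = 0 case rather than guessing.

Two-group comparisons use the Wilcoxon rank-sum test: the exact null
distribution when the pooled size is ≤ 12 with no ties, otherwise the
normal approximation with tie and continuity corrections (delegated to
scipy with the method forced accordingly; the exact path is verified in
the tests against full enumeration of all C(n₁+n₂, n₁) assignments).
Multi-group comparisons use Dunn's post hoc test on joint mid-ranks with
the tie-corrected variance N(N+1)/12 − Σ(t³−t)/(12(N−1)), two-sided
normal p-values, and Benjamini–Hochberg adjustment by default
(configurable; BH because the site pairs are many and correlated, and
Bonferroni would be needlessly conservative for a screening readout).

## Compositional ordination and PERMANOVA

Counts are compositions, so all multivariate geometry happens after the
centred log-ratio transform clr(x)ᵢ = ln(xᵢ/g(x)). Zeros are handled by a
**pseudocount of 1 added to counts** by default — simple, reproducible,
and with deviation from the ideal log-ratio that shrinks as depth grows
(tested at 10×). Multiplicative replacement on proportions (zeros → 0.65
× the row's smallest nonzero proportion, nonzeros rescaled) is available
for workflows that need exact scale invariance.

PCA is the SVD of the column-centred clr matrix; because column centring
does not change differences between rows and the rotation is orthogonal,
Euclidean distances among the full score vectors equal Aitchison
distances exactly (asserted to 1e-8 in tests). PCA is deliberately *not*
computed via classical scaling of the distance matrix — the clr route
also yields loadings and is numerically better conditioned.

PERMANOVA is implemented from first principles: the squared distance
matrix is Gower-centred to an inner-product matrix G (trace = total sum
of squares); each factor's SS is tr(ΔH·G) where ΔH is the increment of
the hat (projection) matrix as the factor enters the design — a
**sequential** decomposition in the order the factors are given, recorded
in the result, matching by-terms multivariate ANOVA. pseudo-F =
(SS_f/df_f)/(SS_res/df_res) with the residual from the full model.
Significance permutes raw sample labels (freely exchangeable — no
strata, since the tested designs are simple one- and two-factor
layouts); p = (#{F_perm ≥ F_obs}+1)/(n_perm+1) with default n_perm = 999,
giving a p floor of 0.001. Permuted statistics within a relative 1e-9 of
the observed one count as ties, so permutations that merely reproduce the
observed grouping are never lost to floating-point rounding. For n ≤ 9,
`permutations="exact"` enumerates all n! relabelings and reports the
exact tail fraction.

Adjacent-site similarity reports, per subject and adjacent pair with
both sites sampled, the Bray–Curtis dissimilarity Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ) of
the two relative-abundance profiles and the Spearman correlation over
the **union** of taxa detected in either sample (zeros included, ties
mid-ranked); a shared-taxa-only mode exists because the two readings
differ when one-sided detections are common.

## The adjacent-site migration screen

The screen is subject-paired: for each subject with both sites of a pair,
each taxon yields one directional call —

- detected at both sites: `up`/`down` when |log₂(RA_b) − log₂(RA_a)| ≥
  0.5 (the *difference of log₂ abundances*, i.e. the log fold change —
  not the log of the arithmetic difference; the companion one-side rule
  exists precisely because the ratio is undefined with zeros);
- detected at exactly one site: `one_side_only_*` toward the present
  side, provided that side's RA ≥ 0.05% (5e-4); fainter one-sided
  detections are omitted as unreliable presence calls;
- detected nowhere: omitted.

A taxon is reported as increased (decreased) along the tract within a
condition group when same-direction calls occur in **≥ 75% of the
group's evaluable subjects** (boundary inclusive). The prevalence
denominator is the evaluable-subject count — the subject-paired reading
of the design; a looser reading (taxon detected in ≥ 75% of the group's
samples at the two sites, with calls favouring the direction) is
available via `prevalence_over="samples"`. Fewer than 4 evaluable
subjects is refused by default (75% of 3 subjects is a degenerate
criterion). Each reported taxon is then confirmed by an unpaired
Wilcoxon rank-sum test of its relative abundance between the two sites'
samples, within the group by default (a pooled option exists since the
design admits both readings). Confirmation p-values are reported raw;
BH adjustment is available but off by default, because the screen's
prevalence gate — not the p-value — is the discovery criterion and the
test is a per-taxon check.

`clr_condition_comparison` (per-taxon clr Wilcoxon between conditions at
one site) is plain plumbing: a simple rank test on clr values with BH
adjustment, with no bias correction for compositional sampling effects.
It is provided so a per-taxon condition contrast exists in the toolkit,
not as a substitute for purpose-built differential-abundance estimators,
which are out of scope here.

## Synthetic cohorts

The generator emulates the paired low-biomass study design so that every
stage has a testable ground truth:

- **Cohort scale** (defaults): 35 malignant + 30 benign subjects, up to
  four sites each, 10% of sites missing independently — the scale and
  missingness pattern of the targeted design.
- **Depths**: log-normal with log-mean ln 20000 and log-sd 0.5, clipped
  below at 6172 (the rarefaction floor; the floor *is* the lowest
  valid-read sample by construction).
- **Community**: a log-normal rank-abundance profile over `n_taxa`
  (default 300) species with simple genus/phylum/domain lineages. A
  contaminant block (default 30 taxa, 30% of expected reads, named after
  recurrent kitome genera) has a shared cross-sample expectation and no
  subject effect — the signature of reagent contamination.
- **Subject effect**: each subject's community composition is a Dirichlet
  draw around the global profile (concentration 200 × profile), so
  between-subject variation dominates between-site variation, as in real
  paired designs. Because the migration screen compares sites *within*
  subjects, this effect cancels there by design.
- **Planted effects**: gradient taxa are multiplied by
  2^(direction × step × site index) along CCT=0 → OCT=3 (so "increased
  along the tract" means increasing toward the ovary); signature taxa are
  multiplied by 2^effect in their enriched condition. Planted taxa are
  drawn from the moderately abundant community ranks — the regime a
  relative-abundance screen can resolve — and the roles are disjoint.
- **Counts**: Dirichlet-multinomial with concentration 2000 × the
  sample's composition. The choice is a design calculation: at RA ≈ 0.5%
  this gives site-to-site log₂ noise with sd ≈ 0.6, so a planted
  one-log₂-unit step is detectable but not trivial at the screen's 0.5
  threshold — overdispersed relative to multinomial sampling, as
  low-biomass profiling is.
- Two extra taxa (a chloroplast lineage and a non-fungal eukaryote, 0.5%
  of reads each) exercise the exclusion filter end to end.

Everything is drawn from one `numpy` Generator seeded by the config, so
cohorts are bitwise reproducible. Reports are emitted in the Bracken
dialect with a taxonomy sidecar, so the file-parsing path is exercised
end to end.

**What the simulator does not emulate** — and hence what passing recovery
tests do not establish about real data: taxonomic misclassification and
database bias in the profiler; reads shared between related taxa;
within-subject longitudinal variation; batch effects beyond the single
shared contaminant block; realistic phylogenetic lineage structure; and
any mechanistic coupling between condition and the gradient taxa. The
recovery results are statements about the statistical machinery under a
plausible noise model, not about biological sensitivity.

## Pipeline and reproducibility

The workflow expands one root seed into per-stage child seeds via
`numpy.random.SeedSequence`, so a single integer reproduces a whole run.
Every stage writes plain TSV; the manifest records the package version,
the thresholds each stage actually applied (echoed from the stage, not
from the config), the per-stage seeds, and SHA-256 digests of every
output. Two runs with the same config and seed produce identical
digests — asserted in the tests byte for byte.

Problem sizes used by the test suite and the acceptance script (1000
random communities for formula agreement; 1000 simulated datasets × 99
permutations for PERMANOVA calibration at n = 20; five 48-subject,
200-taxon cohorts for screen recovery; 6-subject smoke cohorts for
end-to-end checks) were chosen so each check completes in seconds while
keeping its Monte-Carlo error well inside the asserted bounds.

## Known limitations

- The Kraken2 parser trusts two-space indentation for hierarchy, as the
  format provides; exotic rank codes outside the standard letter set are
  skipped with a warning rather than guessed.
- The pseudocount clr is not scale-invariant at finite depth (by
  construction); use the multiplicative strategy when exact invariance
  matters more than zero-handling simplicity.
- PERMANOVA assumes freely exchangeable samples; with repeated measures
  per subject (all four sites in one model) its p-values are
  anticonservative. The shipped workflow tests condition and site on the
  full table the way the targeted design reports them; a
  subject-stratified permutation scheme is a possible extension.
- The screen's Wilcoxon confirmation is unpaired across samples and is
  reported raw; it is a consistency check on the prevalence call, not an
  error-controlled discovery procedure.
- Dunn's test uses the large-sample normal approximation; for very small
  groups (< 5 per group) its p-values are approximate.
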