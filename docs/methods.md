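# Methods

This note records the models implemented, the defaults and why they were
chosen, what the synthetic generators do and do not emulate, and the
numerical choices that affect results.

## Sequon detection and detectability scoring

An N-glycosylation sequon is N-X-S/T with X ≠ P; glycans attach to the N.
N-X-C is a rare, biologically real variant and is available behind
`include_nxc` (default off, matching common practice). A motif window
containing the unknown residue X never matches: an unknown residue makes the
sequon unverifiable, and a false positive here propagates into surface
classification, so the conservative call is to reject. Windows truncated by
the C-terminus cannot match for the same reason.

Digestion models a Trypsin/Lys-C mixture: cleavage after every K, and after
R unless followed by P. Lys-C cleaves K-P bonds that trypsin alone would
skip, which is why the proline rule applies only to R. Missed-cleavage
products are concatenations of adjacent fully cleaved peptides; the default
for detectability scoring is 0 missed cleavages (configurable 0–2), the
strictest and most reproducible choice.

Peptide masses are monoisotopic: residue masses from standard atomic masses
plus one water (18.010565 Da). Carbamidomethyl-C (+57.02146 Da) is applied
as the default fixed modification because CSC protocols alkylate cysteines;
deamidation (+0.98402 Da) is available as a variable modification. The
proton mass used for m/z is 1.007276 Da. The detectability filter is
length ≥ 6 ("more than five amino acids", read strictly) and
min(m/z at 2+, m/z at 3+) < 2,000; only an upper m/z bound is applied
because instruments' lower limits vary and short peptides are already
removed by the length rule.

The per-protein detectability (N-gly-CIRFESS) score counts distinct tryptic
peptides that pass the filter and contain at least one sequon whose
**asparagine** lies in an extracellular region. Extracellular regions from
multiple topology predictors are combined by union: transmembrane predictors
disagree on boundaries at a few-percent false-classification rate, and
requiring agreement would silently zero real surface proteins. A protein
with a signal peptide and no transmembrane segment is treated as a
secreted/anchored ectodomain: its whole mature chain (after any annotated
signal-peptide region) counts as extracellular. With no topology and no
signal peptide the extracellular set is empty and the score is 0 — missing
annotation is deliberately the worst case.

## Classification

A protein (identified with at least one deamidated-sequon peptide) is
surface when: detectability score > 0; or score = 0 and SPC ∈ {3, 4}; or
score = 0 and a predicted signal peptide. The recorded decision branch is
the first satisfied clause in that order; precedence affects only the
reported rationale, never the verdict. The signal-peptide aggregate defaults
to "any of up to three predictors positive" (`majority` available): the
criterion exists to rescue proteins the detectability filter cannot see, so
a single positive call is accepted at the cost of specificity on this
branch.

Master proteins require at least one peptide unique to the accession;
proteins with identical peptide sets collapse to the lexicographically
smallest accession, and shared-only proteins attach to the master with the
largest peptide overlap. Protein-level specificity uses masters only in both
numerator and denominator — grouped accessions are not independent evidence.
I and L are distinct residues for uniqueness by default.

## Orientation inference

Glycosylation is extracellular, and membrane-protein topology alternates
sides at each transmembrane segment. A glycosite in inter-TM loop *k*
(N-terminal segment = loop 0) therefore implies an extracellular N-terminus
("N-out") when *k* is even. Sites agreeing on one parity give a verdict;
sites on both parities are a conflict (impossible topology, usually a wrong
TM annotation); a glycosite falling inside an annotated TM segment is
excluded from the vote and reported. The verdict is compared against a
database orientation when one is supplied.

## Marker scores

Dispersion uses the population Gini coefficient
G = Σᵢⱼ |xᵢ − xⱼ| / (2 n² x̄) (computed by the equivalent sorted form),
scale-invariant, 0 for uniform and (n−1)/n for one-hot profiles; the
population form is used so closed-form test values are exact. Signal
strength is min(log2(1 + max x), 30) / 30 — the cap corresponds to the
practical ceiling of MS intensity readouts (~2³⁰) and is configurable since
the upstream tools do not publish their scaling. The surface-aware score
multiplies dispersion × strength × SPC/4; the "omni" variant omits the SPC
factor. Ranking is descending with lexicographic tie-breaks. Restricted
markers are proteins present in the target group only and absent from every
supplied external catalog; UniProt isoform suffixes are stripped by default
when comparing catalogs.

## Quantification

* **log2 transform** — zero/negative intensities become missing (counted and
  logged) rather than erroring: they are below-detection artifacts.
* **Equalize-median normalization** — each run is shifted so all run medians
  equal the median of the original run medians; a pure shift, leaving
  within-run structure untouched.
* **Median polish** — Tukey's alternating row/column median sweep
  (rows first, matching the classical implementation), tolerance 1e-6 on
  the residual absolute sum, ≤ 100 iterations; run summary = overall +
  column effect; missing entries are ignored in medians; even-length medians
  use the midpoint. A run with no observed feature for a protein gets a
  missing summary.
* **Censored imputation** — per protein, a normal accelerated-failure-time
  regression on the log2 scale with feature and run effects; observed cells
  contribute the normal density, missing cells the left-tail probability at
  the censoring threshold (per-feature minimum observed value, configurable).
  Imputed values are the fitted cell means truncated at the threshold, so an
  imputed entry never exceeds it. Effects carry a weak L2 penalty (0.01):
  when a protein is censored in every cell of a run, that run's effect is
  otherwise unidentified and its MLE diverges to −∞, producing arbitrarily
  low imputations and inflated within-group variance. Proteins with fewer
  than two observed values are left unimputed and flagged. A complete matrix
  is a fixed point.
* **Differential testing** — equal-variance two-sample *t*-test on run-level
  summaries (a deliberate simplification of the full mixed linear model;
  with run-level summaries and a two-group design the two coincide up to the
  variance estimator), Benjamini–Hochberg adjustment across all tested
  proteins, significance at |log2 FC| ≥ 1.5 and adjusted *P* < 0.05. The
  threshold is read on the log2 scale by default because that is how volcano
  thresholds are conventionally drawn; `fc_scale="ratio"` reads it as a raw
  fold change.
* **Replicate QC** — per-feature %CV (100·sd/mean, sample sd) on **raw**
  intensities, reported as the median across features; pairwise Pearson
  correlation of log2 intensities between replicates.

## Synthetic fixtures

The generators are pure functions of (parameters, seed) and produce
byte-identical files on repeat. Sequences are weighted residue samples with
planted cleavage sites and sequons — controllable truth, not
natural-sequence mimicry. Surface proteins are assigned to classification
branches at 60% detectability-positive / 25% SPC-consensus / 15%
signal-peptide: the mixture is not a measured quantity; it was fixed once so
every branch is exercised while the direct-evidence branch dominates, as in
real capture data. SPC/signal-peptide-branch proteins contain no asparagine
so their detectability score is provably 0 and the planted branch is exact.
PSM tables plant a Bernoulli(specificity) mixture of deamidated-sequon
peptides and background tryptic peptides (default specificity 0.8, the
order of magnitude real capture experiments report). Intensity matrices are
Normal on the log2 scale (protein mean N(22, 2), feature offset N(0, 1), run
shift N(0, 0.5), residual σ = 0.3 by default) with left-censoring below a
per-feature quantile; differential proteins receive a ±effect on one group.

What a green test on these fixtures does **not** establish: robustness to
chimeric spectra, wrong identifications, shared peptides across paralogs,
glycan heterogeneity, retention-time effects, intensity-dependent missing
mechanisms other than hard left-truncation, or real predictor error
structure. The fixtures establish that the bookkeeping, decision rules, and
statistics are implemented exactly as specified.

## Degenerate inputs and tie-breaks

Empty sequences, all-zero abundance profiles, all-missing blocks, empty PSM
lists, and zero denominators raise errors rather than returning sentinel
values. Equal-score markers and identical peptide sets break ties
lexicographically. Duplicate glycosite evidence merges PSM id lists;
orientation inference is invariant to glycosite order and duplicates.

## Known limitations

- The *t*-test replaces the full feature-level linear model; confidence
  intervals for proteins quantified by a single feature are optimistic.
- The censored-normal fit is per protein; information is not shared across
  proteins (no empirical-Bayes shrinkage of variances).
- Orientation inference trusts the TM segment count; a missed TM flips
  parity downstream of the omission.
- The SPC score is consumed as an opaque 0–4 integer; its provenance is not
  modeled.
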