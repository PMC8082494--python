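# Methods

## The analysis model

The pipeline couples two measurements of the same cells under two
conditions (control vs treated, e.g. interferon-γ stimulation):

* a **TMT proteome**: six reporter channels per protein, three control
  (`tmt126, tmt127n, tmt128c`) and three treated (`tmt129n, tmt130c,
  tmt131`);
* an **immunopeptidome** per MHC class: identified peptides with MS1 peak
  areas, over 3 biological replicates × 3 technical injections per
  condition.

The central statistic is the **fractional abundance rank**. Within each
sample, peptides are ranked by descending MS1 area (most abundant = rank 1,
ties get the average rank) and divided by the number of quantified peptides
in that sample, giving a value in (0, 1] that is comparable across samples
of different depth without any normalisation model. A peptide is *changed*
between conditions when it is exclusive to one condition or its mean
fractional rank moves by at least `rank_threshold` (default 0.2). A protein
is *changed* when it is called differentially expressed (Welch t-test on
log2 intensities, p < 0.01, fold ≥ 1.2, BH q-values reported). The category
decision table is:

| protein measured? | peptide changed | protein DE | same direction | category |
|---|---|---|---|---|
| no | – | – | – | `protein_unmapped` |
| yes | no | no | – | `mirrored` (unchanged) |
| yes | yes | yes | yes | `mirrored` (abundance_shift / novel) |
| yes | yes | yes | no | `independent` |
| yes | yes | no | – | `independent` |
| yes | no | yes | – | `independent` |

Directions: a peptide is "up in treated" when its mean fractional rank is
lower in treated (or it is treated-exclusive); a protein's direction is the
sign of its log2 fold-change. Peptides whose replicate ranks spread by
≥ `variance_threshold` (default 0.2, the same scale) within a condition, or
that are not seen in ≥2 biological replicates of any condition, are excluded
from categorization and reported separately — they are too noisy to
interpret, not evidence of any category.

### Assumptions

* Between-condition rank movement is attributable to presentation changes
  once the low-variance filter has removed unstable peptides; the 0.2
  between-condition threshold deliberately reuses the replicate-variance
  scale so one number controls both "stable" and "moved".
* Protein change is binary (DE call + sign). An alternative — comparing
  peptide rank deltas against a continuous protein rank delta — would use
  more information but needs a cross-assay rank calibration the binary
  design avoids.
* Condition exclusivity is read from presence/absence after replicate
  filtering; with three injections per replicate, absence from all
  measurements of a condition is treated as biological, not dropout.

## Statistical components

* **Differential expression / presentation**: unpaired two-sample t-tests
  on log2 values; Welch by default (`welch=True`) since equal variances are
  not guaranteed; zero-variance equal-mean rows get p = 1 by convention.
  Thresholds: proteome p < 0.01 with fold ≥ 1.2 (the 1.2 is a *linear*
  fold-change — a 1.55-fold protein must be callable); core epitopes
  p < 0.05 with |log2fc| > 1, with both raw-p and BH-adjusted calls
  reported.
* **Benjamini–Hochberg** q-values via `statsmodels` (`fdr_bh`), validated
  in the tests against an independent brute-force step-up implementation.
* **AQUA panel**: technical injections averaged per biological replicate;
  two replicate means per condition compared by a *Student* t-test (with
  n=2 per group the Welch degrees-of-freedom estimate is unstable, so the
  pooled test is the default here — the one place the Welch default is not
  used); per-peptide z-scores standardize the four means with the
  population (ddof=0) convention, so they sum to 0 with unit variance.
  Significance: p < 0.05 and q < 0.49 over the panel. Output carries a
  low-power warning at n=2.

## Core-epitope consolidation

Replicate-consistent peptides of one protein are grouped into connected
components of the interval-overlap graph (1-based inclusive coordinates;
overlap = sharing ≥ 1 position). A component's core is the intersection of
its member intervals when that intersection is at least
`min_epitope_length` residues (9 for class I; class II is run at both 9 and
13 and both outputs are kept). Components with an empty or short
intersection are split greedily at the position of minimal peptide
coverage: candidate positions are scanned in (coverage, position) order —
so minimal coverage wins and ties break leftmost — and the first position
that actually separates the component is used; peptides covering the split
position join the side with the larger overlap (ties left). Components that
no position can separate are logged as *unresolvable* rather than forced
into a core. Consolidated abundance is the **sum** of member MS1 areas per
sample, so total area is conserved between input and (cores +
unresolvable), a property asserted in every consolidation test. This
consolidation is a documented reimplementation of the landscape-consensus
idea, not a clone of any external tool's internals; the tests pin these
stated semantics.

Missing core abundances are imputed with the lowest measured value of the
same sample column (imputed cells flagged); a column with no measurement at
all is an error, not a silent zero.

## Binding models and motifs

External neural-network predictors are replaced by an internal scorer so
the pipeline has no network dependency: per allele, a 9×20 log-odds PWM
scores the best 9-mer window of a peptide (8-mers are scored by deleting
the single PWM position that maximizes the remainder; an optional
`length_penalty` per residue of deviation from 9 is off by default). The
**percentile rank** is the percentage of `background_n` (default 10,000)
random proteome 9-mers scoring strictly higher; lower rank = stronger.
Thresholds follow class conventions: class I strong < 0.500, weak < 2.000;
class II binder < 10; exact rank ties below the class-I reporting threshold
are reported for all tied alleles. An adapter accepts externally computed
rank tables in the same peptide×allele schema, so real predictions can be
dropped in without code change.

The Gibbs clusterer partitions fixed-length cores into k motifs by
single-sequence reassignment moves at a fixed temperature (default 0.25),
maximizing the size-weighted sum of per-cluster KLDs (bits, log2) against a
background (uniform by default), with a final greedy sweep and best of 50
restarts (the pipeline uses 10 for speed). Position probabilities use a
+0.05 pseudocount per residue per position before normalization, so an
empty cluster has exactly zero KLD. k=1 reduces to the direct PSSM/KLD
formula, which the tests verify independently.

Class-II cross-contamination: a class-II peptide of length ≤ 9 whose best
class-I rank beats its best class-II rank is flagged as carry-over from the
serial class-I immunoprecipitation; flagged peptides are categorized but
tagged.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes —
not spectra, retention times or TMT ratio compression.

* **Proteome**: per-protein base log2 abundance ~ Normal(20, 2) (a typical
  MS dynamic range; any heavy-tailed positive choice would do and the
  defaults are config fields); channel values add Normal(0,
  `channel_noise_sd`=0.2) noise; `n_de_proteins` (default 60 of 2,000, ~3%,
  in line with a modest-stimulus experiment) get a ±`de_log2fc` (default
  1.5) mean shift in the treated channels with random sign.
* **Peptides** are substrings of the simulated proteins: class I lengths
  8–12 with mode 9, class II 13–25 peaked at 15. Window choice is biased by
  a softmax over allele-PWM window scores plus a C-terminal cleavage bonus,
  so emitted peptides carry allele anchor motifs. Three generation modes
  per peptide (categorical draw per peptide):
  `expression_coupled` (default mass) — present in both conditions, MS1
  area = source protein's per-replicate abundance × peptide efficiency
  (log2-normal) × replicate/injection noise;
  `processing_shifted` (fraction 0.10) — drawn from *non-DE* proteins under
  a second C-terminal cleavage preference and emitted only in the treated
  condition (minimal stand-in for immunoproteasome induction);
  `protein_undetected` (fraction 0.05) — drawn from proteins absent from
  the proteome matrix. Per-injection dropout `missingness`=0.05. A 2%
  fraction of class-I-style 9-mers is injected into the class-II tables as
  a contamination fixture.
* **Variants**: `n_variants` single-residue substitutions planted on
  detected proteins; when a sampled peptide's protein carries variants, the
  window deliberately spans a variant position with probability 0.5, so a
  labelled subset of emitted peptides carries the alternate residue.
* **AQUA**: a 25 class-I + 5 class-II panel (variant peptides first),
  spiked into two of three biological replicates at 250 fmol, light areas
  following the peptide's simulated abundance and a noise-floor area where
  it was not presented.
* **Determinism**: one master seed; each stage draws from its own
  deterministic child stream, so outputs are a pure function of the config
  and stages can be re-run independently.

What a green test does *not* establish: the generator has no shared-peptide
ambiguity (each peptide maps to one protein), no modification isoforms, no
ratio compression, no depth-saturation model (`peptides_per_condition` is
set directly), and Gaussian log2 noise — real data violate all of these to
varying degrees, so recovery rates here are upper bounds on what the same
thresholds achieve on real measurements.

## Numerical conventions

* Coordinates 1-based inclusive everywhere (protein positions, peptide and
  core intervals).
* log2 throughout; intensities must be positive before log-transform.
* Peptide identity for set logic is the bare sequence.
* Set outputs sorted lexicographically; cluster output sorted by size then
  KLD; all TSVs written with a config-hash + seed header and fixed float
  formatting so identical configs give byte-identical bundles.
* Exit codes: 0 success, 2 configuration error, 3 data error.

## Known limitations

* The t-test at 3-vs-3 (and 2-vs-2 for AQUA) has low power; the paper-style
  thresholds, not the power, are what is being reproduced.
* The greedy coverage split is one of several defensible consolidation
  rules; components it cannot separate are surfaced, not resolved.
* The locus-bias test is a goodness-of-fit construction against supplied
  reference proportions; other constructions (contingency tables) answer
  slightly different questions.
* Only missense substitutions produce variant sequences; frameshifts,
  stop-gains and indels are parsed, counted and skipped with a log message.
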