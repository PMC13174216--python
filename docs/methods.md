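# Methods

## The screening problem

In a pooled prime-editing resistance screen, a library of engineered
prime-editing guides (epegRNAs) is delivered lentivirally into a
drug-sensitive, prime-editor-expressing cell line at low multiplicity of
infection, so that most cells carry a single integrated guide.  Each
guide encodes both its genomic target and a specific programmed edit;
some constructs program known or candidate resistance mutations, others
program synonymous (protein-silent) edits that act as negative controls.
After selection of transduced cells the pool is split into a vehicle arm
and one or more drug arms and sampled over a harvest time course.  The
integrated guides are amplified from genomic DNA and sequenced: the
spacer on Read 1 identifies the construct, the 3' extension on Read 2
confirms it, and a random 8-mer barcode adjacent to the guide terminator
tags the individual lentiviral integration (the clonal lineage).

A variant that confers resistance lets its *edited* carrier cells expand
under drug while everything else declines, so its guide's read counts
rise in the drug arm relative to the vehicle arm over time.  Because
editing efficiencies are modest and guide-specific — some guides never
install their edit at all — a present guide does not imply a present
edit, and structural false negatives are expected.

## Count model and testing

Counts `y_ij` for unit `i` (a variant, summing its 1–4 constructs, or a
single construct) in sample `j` are modelled as negative binomial with
`Var = mu + alpha * mu^2`, log link and per-sample offset `log s_j`:

    log mu_ij = log s_j + x_j . beta_i

The full design is `{1, t, drug, drug*t}` with harvest day `t` in days
and `drug` the arm indicator; the reduced design is `{1, t}`.  The
likelihood-ratio test (2 df with continuous time) asks whether drug
treatment changes a unit's abundance as a function of time.  A factor
coding of time is available (`time_as_factor=True`); continuous time is
the default because it yields an interpretable per-day drug effect and a
2-df test.  Each drug arm is tested separately against the vehicle arm.

Per-unit GLMs are fitted by iteratively reweighted least squares with
Fisher-scoring weights `mu/(1 + alpha*mu)`, step-halving so the
likelihood never decreases, and a relative tolerance of 1e-8 (at most
100 iterations).  `alpha = 0` degenerates to Poisson regression.  The
one-sided Wald statistic for the contrast `drug + t_final * drug:t`
(the drug effect at the final harvest day, standard error from the
Fisher information) gives the enrichment direction, and the same
contrast divided by `ln 2` is the reported model log2 fold change.
Hits are units with FDR below threshold (default 0.01) **and** positive
model log2 fold change; depleted units are never hits.

### Normalization and compositionality

Sequencing measures proportions, so "abundance" is always relative to a
reference.  The classic median-of-ratios size factors (implemented in
`diffabund.size_factors`, rescaled to geometric mean 1) anchor on the
typical unit.  Under strong positive selection this anchor breaks: by
the late harvests the non-resistant population — synonymous controls
included — can be extinct in the drug arm, the only all-positive count
rows are the resistant units themselves, and a median-of-ratios
reference then makes every below-median resistant variant look
depleted.  The model layer therefore defaults to *total-count* size
factors (testing changes in sequencing proportions, the same reference
the Z-score layer uses); `median_ratio` and `controls` (median-of-ratios
over control units only) are available for gentler selection regimes.

### Dispersion moderation

Per-unit dispersions are estimated by method of moments within groups of
samples sharing a design row: pooling `(s^2 - mu)/mu^2` on
size-factor-scaled counts across groups (the squared group mean is
debiased by `var/n_g`).  A trend `alpha(mu) = a0/mu + a1` is fitted
across units by least squares on the *unclipped* moment estimates (the
zero-clipped values would bias the trend upward, asymmetric outlier
trimming downward; one symmetric 5-MAD trim pass guards against gross
outliers).  Final dispersions shrink the raw estimate toward the trend
in log space with weight `df/(df + prior_df)`, where `df` is the
residual degrees of freedom of the grouping.  The default
`prior_df = 60` is deliberately wide: with triplicate groups the raw
moment estimate is mostly noise, and a likelihood-ratio test run on
under-shrunk dispersions is visibly anti-conservative.  Null calibration
is demonstrated by simulation (see the acceptance suite): with 2,000
null units the rejection fraction at p < 0.05 stays within 0.05 ± 0.015
and a Kolmogorov–Smirnov test against uniformity is not rejected.

### False discovery control

Benjamini–Hochberg q-values are computed on the two-sided LRT p-values.
The control-based empirical FDR is computed on *directional* evidence:
the LRT p folded to the enrichment side by the Wald sign
(`p/2` if enriched, `1 - p/2` otherwise).  This matters because under
positive selection the controls are themselves strongly *depleted* —
their two-sided p-values are tiny and carry no information about the
false-enrichment rate.  At threshold `t` the empirical FDR is
`(#controls <= t / N_controls) * N_tested / #units <= t`, clipped at 1
and monotonized by a cumulative minimum from the largest p down.

## Printed-statistics layer

The lighter-weight per-timepoint statistics mirror the screen's
conventional readout: log2 counts-per-million with a pseudocount of 1
(the minimal depth correction consistent with per-sample log2
normalization), log2 fold change of each construct between a drug
sample and the vehicle sample of the *same replicate and day* (pairing
chosen to preserve replicate structure), and Z-scores standardized
against the synonymous-control distribution with the sample standard
deviation (ddof = 1; the standardization identity — control Z-scores
have mean 0, sd 1 — is exact by construction).  Variant-level statistics
are arithmetic means over a variant's constructs.  Group comparisons use
the pooled-variance two-sample t-test with Bonferroni correction over
the number of tested variants; screen window quality is the strictly
standardized mean difference `(m1 - m2)/sqrt(v1 + v2)` with sample
variances; MOI is estimated from the marker-positive fraction as
`-ln(1 - f)` under Poisson integrations.

## Synthetic screens

The generator produces ground-truthed screens with the statistical
structure the analysis assumes, one independent transduction per
replicate:

1. **Library**: `n_variants` variants with 1–4 constructs each (random
   distinct spacers/extensions), a synonymous-control fraction (default
   0.2), a resistant fraction (default 0.05–0.15 depending on use), and
   log-normal plasmid abundance skew (sigma 0.5).
2. **Editing efficiency**: per construct, zero with probability `p_zero`
   (default 0.2 — the "guide that never edits" failure mode), otherwise
   Beta(2, 8); a variant's *effective editing* is the
   plasmid-abundance-weighted mean over its constructs.
3. **Transduction**: cells receive Poisson(MOI = 0.35) integrations;
   in the default low-MOI mode each transduced cell founds one lineage
   with one construct (chosen proportional to plasmid abundance) and an
   i.i.d. random 8-mer barcode.  Barcode collisions over the 4^8 space
   are allowed and reported.  Cell numbers are set so transduced
   lineages give the requested per-construct coverage (default 500x).
4. **Editing** is resolved once at time zero as a lineage-level
   Bernoulli(e_i); no editing kinetics, no copy-number effects.
5. **Growth**: lineages expand for 4 days at the baseline rate (the
   selection window before the arm split), are split multinomially
   across arms, then evolve by Galton–Watson branching,
   `size(t+dt) ~ Poisson(size(t) * 2^(g*dt))`, with `g` = 0.5
   doublings/day in the vehicle arm (about 10 doublings over the ~20-day
   course) and, under drug, +0.5 for edited-resistant lineages versus
   -0.5 for everything else.  The drug-arm rates are package defaults
   chosen to produce decisive selection on this time scale.
6. **Harvests** at days 3/7/11/15/19: reads are multinomial at the
   configured depth over lineage sizes, after which the culture is
   bottlenecked to `bottleneck_coverage` cells per construct.
7. **Sequencing**: paired FASTQ with the spacer on Read 1 and the
   reverse-complemented cassette 3' end on Read 2 (constant suffix,
   barcode, the poly-T terminator visible as a 7-A run, linker,
   extension), i.i.d. substitution errors at `base_error_rate`, constant
   quality strings (the pipeline never uses base qualities).

A deterministic-growth mode replaces every Poisson draw by its mean so
simulated proportions match the two-type exponential closed form
exactly; a null-counts generator (`simulate_null_counts`) emits i.i.d.
NB counts with no arm or time effect for calibration studies.

What the generator does **not** emulate: PCR jackpotting and chimeras,
guide-specific amplification bias, off-target or byproduct edits, copy
number at the target locus, editing kinetics over time, and
cross-contamination between samples.  Passing tests therefore show the
statistical machinery is correct under the stated generative
assumptions, not that real screens are free of these artifacts.

## Quantification

Read 1 is matched by exact hash of the 20-nt spacer at its configured
offset (a 1-mismatch neighbourhood mode enumerates the 60 single-edit
variants of the observed k-mer).  On Read 2 the 7-A run anchors the
cassette: because a barcode beginning with T extends the run, positions
are keyed off the run *end*, which is fixed relative to the linker.  The
extension region (after the run and linker) must match the R1-implied
construct's reverse-complemented extension within `max_mismatch_ext`
(default 1); the 8-mer before the terminator is recorded verbatim as the
barcode (unreadable barcodes are counted but the pair still counts).  A
pair is assigned only when both reads agree; everything whose spacer
matched but whose Read 2 failed confirmation is "discordant" (this
includes chimeric PCR-style pairs), so
`assigned + unassigned_r1 + discordant == total_pairs` holds exactly and
is asserted on every run.  Amplicon edit frequencies use exact flank
anchoring (default 5 bases each side) rather than alignment; reads with
indels through the window simply fail anchoring and leave the
denominator.

## Clonal barcodes

Within each (construct, sample), barcodes are error-collapsed by the
directional-adjacency rule: `b` merges into `a` when `Hamming(a, b) <= 1`
and `reads(a) >= 2*reads(b) - 1`; canonical barcodes with fewer than
`min_reads` (default 2) reads are then dropped.  Reported per unit and
sample: unique barcodes, inverse-Simpson effective diversity, top-barcode
fraction, and a clonality class — `recurrent` (>= 3 unique barcodes,
i.e. repeated independent editing events), `monoclonal` (1),
`oligoclonal` (2), `unpowered` (below the read threshold).  The class
thresholds operationalize the qualitative distinction between recurrent
editing and single-clone expansion; they are conventions, not estimates.

## Numerical and degenerate-input conventions

* Sample standard deviation (ddof = 1) throughout; "within 1 sd" bands
  use inclusive bounds so the all-equal case is well defined.
* Z-scores require >= 2 controls with nonzero sd; degenerate t-tests
  (both variances zero) report p = 0 with an explicit flag rather than
  NaN; SSMD with both variances zero is flagged infinite.
* All-zero count rows are excluded from testing with NA statistics;
  all-zero samples normalize to uniform CPM with a warning.
* Non-converged GLM fits are retained in the table but flagged and
  excluded from hit calling.
* Every stochastic component draws from a single seeded generator; fixed
  seeds give byte-identical outputs, including FASTQ.

## Problem sizes

The test and acceptance workloads run at desk scale by design: null
calibration at 2,000 units x 30 samples; the planted-truth screen at 500
variants (~1,250 constructs), 500x coverage, 2 arms x 3 replicates x 5
harvests at 500,000 reads per sample; the lossless round trip at ~200
constructs and 100,000 read pairs.  These sizes match the screens the
package targets within small factors while keeping a full run in tens of
seconds.

## Known limitations

* The NB engine is not a port of any existing differential-abundance
  tool; numeric identity with such tools is a non-goal (rank agreement
  is checked against an independent implementation in the test suite).
* The empirical FDR needs a reasonable number of controls (default
  minimum 10) and assumes controls behave like non-resistant variants.
* Under near-total selection the late-timepoint counts of non-resistant
  units are zero-inflated beyond the NB model; the LRT still ranks
  enrichment correctly but late-day depletion p-values should not be
  over-interpreted.
* Barcode collisions (birthday effect over 4^8) slightly undercount
  founder lineages for heavily-founded variants; the collision rate is
  reported in the simulation truth.
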