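# prisge

Analysis of pooled prime-editing drug-resistance screens.

In these screens a library of engineered prime-editing guides
(epegRNAs), each programming a specific point mutation and carrying a
random 8-mer clonal barcode, is lentivirally integrated into a
drug-sensitive cancer cell line at low MOI.  The pool is split into a
vehicle arm and drug arms, harvested over a multi-week time course, and
the integrated guides are sequenced: Read 1 carries the 20-nt spacer,
Read 2 the extension (which encodes the edit) and the barcode.  A
variant that confers resistance expands in the drug arm; a guide that
fails to edit produces a structural false negative.  `prisge` covers the
computational side of such screens end to end:

* **library** — epegRNA design tables and sample sheets: I/O,
  validation (spacer/extension consistency, control presence), and
  plasmid-pool representation QC;
* **simulate** — a ground-truthed synthetic-screen generator (Poisson
  low-MOI transduction, zero-inflated Beta editing efficiencies, clonal
  barcodes, Galton–Watson growth under selection, bottleneck passaging,
  multinomial sequencing, paired FASTQ output);
* **quantify** — streaming paired-end guide counting with spacer/
  extension agreement, discordant-pair rejection, barcode extraction,
  and amplicon edit-frequency calling;
* **scores** — log2-CPM normalization (pseudocount 1), per-replicate
  log2 fold change versus the vehicle arm, synonymous-control Z-scores,
  t-tests, SSMD, MOI estimation, false-negative-rate accounting;
* **diffabund / screen** — a negative-binomial GLM engine testing each
  unit's count time course: full model `~ time + drug + drug:time`
  versus reduced `~ time` by likelihood-ratio test, one-sided Wald
  enrichment contrast, Benjamini–Hochberg and synonymous-control
  empirical FDR, hit calling at FDR < 0.01 with positive log2FC;
* **clonality** — directional-adjacency barcode collapse and
  unique-barcode/diversity reporting that distinguishes recurrent
  independent editing events from single-clone expansions.

## The model at the core

Counts `y_ij` (variant `i`, sample `j`) follow a negative binomial with
`Var = mu + alpha mu^2` and

    log mu_ij = log s_j + beta_0 + beta_t t_j + beta_d d_j + beta_dt d_j t_j

where `t_j` is harvest day, `d_j` the drug-arm indicator, and `s_j` a
size factor.  The LRT compares this against the reduced model without
the drug terms (2 df).  Dispersions are moderated method-of-moments
estimates shrunk toward an `a0/mu + a1` trend; the enrichment effect is
reported as `(beta_d + beta_dt t_final)/ln 2` — the drug effect at the
final harvest day in log2 units.  Hits require FDR < 0.01 **and**
positive effect.  Details, including why total-count size factors are
the default under strong positive selection and why the empirical FDR
uses direction-aware p-values, are in `docs/methods.md`.

## Worked example

Simulate a 40-variant screen (6 planted resistant variants, 10
synonymous controls, triplicate, harvests at days 3–19) and test the
drug arm:

```python
from prisge import (CountMatrix, ResistanceScreenModel, SimConfig,
                    simulate_library, simulate_screen)

cfg = SimConfig(n_variants=40, frac_resistant=0.15, frac_synonymous=0.25,
                depth_per_sample=200_000, coverage=300,
                bottleneck_coverage=300, n_replicates=3, seed=7)
lib, truth = simulate_library(cfg)
sim = simulate_screen(lib, truth, cfg)
model = ResistanceScreenModel(CountMatrix(sim.counts, sim.samples), lib, "drug")
res = model.fit(fdr_threshold=0.01)
print(res.summary())
```

prints

```
Resistance screen differential abundance (NB GLM LRT)
========================================================
Drug arm:           drug vs vehicle
Testing unit:       variant
Units tested:       40 of 40
Controls:           10
Design:             full=['intercept', 'time', 'drug', 'drug:time'] reduced=['intercept', 'time']
LRT df:             2
Dispersion trend:   a0/mu + a1 with (a0, a1) = (10.29, 0.001931)
Hit rule:           efdr < 0.01 and log2FC > 0.0
Hits:               6
Hits per gene:      GENE1=6

Top hits (by LRT p):
       base_mean  log2fc_model  p_lrt  p_bh  efdr
unit
V0010   8.36e+03          2.11      0     0     0
V0011   2.26e+04          2.97      0     0     0
V0012   2.76e+04          3.43      0     0     0
V0013   7.55e+03          4.36      0     0     0
V0014   9.84e+03           3.2      0     0     0
V0015   2.16e+04          2.77      0     0     0
```

The six hits are exactly the six planted resistant variants
(`truth.resistant_variants`), each with a positive model log2 fold
change (the drug effect at day 19); none of the ten synonymous controls
is called.  `res.results` holds the full per-variant table
(`lrt_stat`, `p_lrt`, `p_bh`, `efdr`, `log2fc_model`, `hit`, ...),
`res.plot_volcano()` / `res.plot_qq()` draw the standard diagnostics,
and `prisge.clonality` joins Z-scores and FDR with unique-barcode counts
per variant.

The same pipeline is available from the shell:

```sh
prisge demo -o run/            # simulate -> score -> test -> clonality -> report
prisge simulate --fastq -o sim/
prisge quantify --library sim/library.tsv --samples sim/samples.tsv -o counts/
prisge test --counts counts/counts.tsv --samples sim/samples.tsv \
            --library sim/library.tsv --fdr 0.01 -o results/
```

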