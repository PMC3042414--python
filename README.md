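# mtbarcode

Tools for deciding **which mitochondrial protein-coding gene makes the best
DNA barcode**.  Animal barcoding standardised on the 5' fragment of *CO1*,
but there was never a strong a-priori reason to prefer it over the other
mitochondrial protein-coding genes (PCGs).  `mtbarcode` implements a
four-way evaluation of candidate loci on taxonomy-labelled mitochondrial
genome collections — and ships a synthetic-data generator with known ground
truth so the entire pipeline is testable without downloading a single
genome.

The package targets researchers in molecular systematics and barcoding who
want to score candidate loci on their own clade, and methods developers who
need a fully verifiable reference pipeline.

## What it computes

For each of 14 *profiles* (the 12 heavy-strand PCGs — *ND6* is excluded as
a light-strand gene — their concatenation, and the canonical 648 bp
barcoding fragment at CO1 alignment positions 58–705):

1. **Species recovery.**  Pairwise Kimura two-parameter distances

   *d* = −½ ln(1 − 2*P* − *Q*) − ¼ ln(1 − 2*Q*)

   (*P*, *Q* the transition and transversion proportions, pairwise
   deletion) feed a Saitou–Nei neighbor-joining tree, rooted on outgroups.
   A species is a recovered *barcode species* when its sequences form a
   monophyletic cluster; a genus with ≥ 2 species is a *cohesive group*
   when its sequences do.  Failures are classified paraphyletic vs
   polyphyletic.
2. **Variability.**  Mean intraspecific and congeneric interspecific K2P
   distances (multi-sequence species collapsed to IUPAC union consensi,
   ambiguous sites redistributed proportionally to unambiguous changes),
   compared across profiles by one-way ANOVA with Tukey–Kramer HSD; plus
   sliding-window nucleotide diversity π and divergence Dxy (uncorrected
   p-distance, 600 bp windows, 5 bp steps) along the concatenated genome.
3. **Higher-level resolution.**  Principal-coordinates analysis (Gower
   double-centering B = −½ J D² J, full eigendecomposition with negative
   eigenvalues reported) of nucleotide K2P and amino-acid Kimura distance
   matrices, with a per-super-order overlap summary.
4. **Model fit and saturation.**  Maximum-likelihood substitution-model
   fitting (Felsenstein pruning on the fixed NJ tree; discrete-gamma rate
   heterogeneity and invariable sites) ranked by BIC = −2 lnL + *k* ln *n*
   over a 16-model grid {JC69, K80, HKY85, GTR} × {–, +I, +G, +I+G}; GC
   content; and %Ti-versus-K2P saturation profiles (low %Ti ≤ 50% flags
   saturated pairs).

The simulator (`mtbarcode.simulate`) generates taxonomy-structured
multi-gene datasets on one shared genealogy — four super-orders, ~35
genera, configurable intra/interspecific depths (defaults 1.5% / 8%),
transition-biased GTR/HKY substitution with gamma + invariable-site rate
heterogeneity, stop-codon-free coding genes — and optional introgression
events that break species monophyly in a controlled way.

## Worked example

```python
from mtbarcode import PipelineConfig, run_evaluation, SyntheticConfig, simulate_dataset
from mtbarcode.profiles import (
    PCG_GENES, ProfileSet, build_genome_profile, extract_barcoding_region,
)

cfg = SyntheticConfig(n_genera=8, species_per_genus=2, seqs_per_species=2,
                      gene_lengths={g: 1200 for g in PCG_GENES}, seed=42)
ds = simulate_dataset(cfg)
profiles = dict(ds.profiles.profiles)
profiles["genome"] = build_genome_profile(ds.profiles)
profiles["barcoding_region"] = extract_barcoding_region(profiles["CO1"])
pset = ProfileSet(profiles, ds.profiles.outgroup_accessions)

report = run_evaluation(pset, PipelineConfig(focal_genus="Genus01"))
print(report.summary_frame()[["profile", "species_no", "recovery_rate",
                              "cohesive_rate", "mean_intra", "mean_inter",
                              "gc_percent"]].head(5).to_string(index=False))
f, p, _ = report.anova_intra
print(f"ANOVA intra: F={f:.3f} p={p:.3f}")
```

prints

```
profile  species_no  recovery_rate  cohesive_rate  mean_intra  mean_inter  gc_percent
   ATP6          16          100.0          100.0    0.010629    0.041065       42.28
   ATP8          16          100.0          100.0    0.010993    0.041600       38.95
    CO1          16          100.0          100.0    0.011280    0.040880       38.50
    CO2          16          100.0          100.0    0.010623    0.038987       39.58
    CO3          16          100.0          100.0    0.011208    0.037170       41.60
ANOVA intra: F=0.735 p=0.728
```

Every one of the 16 species (two sequences each) is recovered as a barcode
species in every profile — the simulated barcoding gap is wide — mean
intraspecific distances sit near the configured 1.5% (biased slightly low
by rate heterogeneity), interspecific means are several-fold larger, and
the ANOVA confirms the genes share one genealogy: no significant
between-gene differences in intraspecific variability.  Injecting
`IntrogressionEvent`s into the config breaks exactly the chosen species in
every profile at once.

A thin CLI wraps the same machinery:

```bash
barcode-eval simulate --config sim.yaml --seed 3 --out data/
barcode-eval run --profiles data/ --taxonomy data/taxonomy.tsv --out results/
```

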