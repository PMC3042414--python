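# Methods

This note documents the models, estimators and design choices behind
`mtbarcode`, in the spirit of the model documentation that simulation and
statistics packages ship alongside their APIs.

## Profiles and coordinates

A *profile* is one aligned gene region across all sampled genomes.  From
annotated genomes the package builds the 12 heavy-strand protein-coding
genes (*ND6* is excluded: it sits on the light strand and aligns poorly),
the concatenated "genome" profile (genes joined in alphabetic name order,
restricted to accessions present in all 12 genes), and the 648 bp
barcoding fragment cut from CO1 alignment columns 58–705 (1-based
inclusive).  All internal coordinates are 0-based half-open; 1-based
inclusive conventions are converted once, at the boundary, to avoid
off-by-one drift.

Quality filtering removes gene sequences whose ungapped length falls below
`min_len_frac` (default 0.8) of the profile median, or which contain an
N-run of at least `max_ambig_run` (default 30) bp.  The thresholds are
deliberate, config-exposed choices: "obviously too short" and "large
ambiguous region" have no canonical numeric definition, and 80% of the
median / 30 bp are the values a curator would reach for first.  Alignment
itself is pluggable (an external command template such as
`mafft --quiet {in} > {out}`), never embedded: multiple sequence alignment
is not this package's contribution.  Finalisation trims a terminal stop
codon column (when at least half the gap-free terminal codons are
vertebrate-mitochondrial stops), validates the reading frame, and rejects
profiles in which more than 5% of sequences carry internal stops — the
signature of frame shifts or nuclear pseudogene contamination.

## Distances

Site patterns are counted under pairwise deletion: each pair is scored
over columns where both sequences carry an unambiguous base.  K2P distance
is d = −½ln(1−2P−Q) − ¼ln(1−2Q).  Log-domain violations mark the pair
*undefined* (saturated); they are reported, never silently clamped — only
the NJ stage substitutes a configurable cap (default 5.0
substitutions/site) because the agglomeration must be total.  The
amino-acid Kimura distance is d = −ln(1 − p − 0.2p²).

With `ambiguity_mode="infer"`, ambiguity-bearing columns are kept: the
resolutions consistent with the IUPAC code are weighted proportionally to
the identity / transition / transversion proportions observed at the
pair's unambiguous columns (renormalised over the consistent resolutions;
uniform fallback when no unambiguous signal exists).  The rule is fully
deterministic so tests can pin exact fractional counts.  `exclude` is the
default everywhere except the consensus-based variability tables.

## Trees and recovery statistics

Neighbor joining follows Saitou–Nei exactly: join the pair minimising
Q(i,j) = (r−2)d(i,j) − Σd(i,·) − Σd(j,·), with ties broken by the lowest
(row, column) index pair so results are deterministic and
permutation-equivariant.  Negative branch lengths are retained (only
topology feeds the monophyly statistics; a writer option clamps them for
display).  Rooting bisects the edge separating the outgroup; when the
outgroup is not monophyletic in the unrooted tree, the edge with the best
split purity is used and a warning logged.

Monophyly classification on the rooted tree: the smallest clade containing
the query leaves is located; the set is monophyletic if the clade contains
nothing else, paraphyletic if the extra leaves themselves form one nested
clade, polyphyletic otherwise.  Zero-length internal edges are treated as
resolved bifurcations, matching NJ output semantics.  Species with ≥ 2
sequences enter the barcode-species denominator; singletons are excluded
by default (they still sit in the tree and can break other species), with
an `include_singletons` switch because the opposite bookkeeping convention
is equally defensible.

## Variability

Per-species intraspecific means average K2P over all conspecific pairs;
per-genus interspecific means average over congeneric species pairs after
collapsing multi-sequence species to a strict union-to-IUPAC consensus (no
majority threshold; a majority option exists but is non-default).  One
consequence worth knowing: a union consensus behaves like the species'
*ancestral* sequence, so consensus-based interspecific distances estimate
the ancestor-to-ancestor path — roughly the leaf-path distance minus the
two within-species depths.  The test suite asserts exactly that quantity.

Cross-profile comparisons use one-way ANOVA with Tukey–Kramer HSD
(unequal group sizes supported); zero within-group variance everywhere is
reported as an undefined F, not an error.

Sliding windows (default 600 bp window, 5 bp step, wholly-contained
windows only — genes shorter than the window yield no values) use the
*uncorrected* p-distance: π is the mean pairwise proportion of differing
sites among conspecific sequences (n-choose-2 denominator, no n/(n−1)
correction), Dxy the mean over between-species pairs.  The K2P-vs-p
discrepancy between the tables and the windows is deliberate and
preserved: the two analyses answer different questions and each keeps the
convention of its home analysis.  Windows where a pair has fewer than 50%
comparable sites contribute a missing value, never a zero.

## Ordination

PCoA double-centers the squared distances, B = −½ J D² J, and
eigendecomposes B.  Genetic distance matrices are generally non-Euclidean,
so negative eigenvalues occur; the full spectrum is always reported and
variance fractions are computed over the positive part only (a Lingoes
correction is available but off by default).  Group separation is
summarised by the own-centroid fraction — the share of objects whose
nearest group centroid in the first k axes is their own — plus the
cumulative variance fraction of those axes; no formal cluster test is
attempted.

## Model fitting

Likelihoods use Felsenstein pruning with column pattern compression and
per-node rescaling.  Rate heterogeneity is the 4-category discrete gamma
(category rate = mean of its quartile, mean 1); invariable sites enter as
a rate-zero mixture component.  Fitting follows the classic
model-selection protocol: the NJ-K2P tree is held fixed and a single
global branch-length scale is optimised with the model parameters
(L-BFGS-B on log/logit-transformed parameters, three starts over (α, I),
relative lnL tolerance 1e-6, bounds α ∈ [0.02, 100], I ∈ [0, 0.99]).
Base frequencies are empirical counts by default.  The model grid is the
16-model family {JC69, K80, HKY85, GTR} × {–, +I, +G, +I+G}, ranked by
BIC with n = alignment columns; this covers the realistic outcome space
for mitochondrial protein-coding data at a fraction of the cost of the
historical 56-model grids.  k_free counts substitution parameters,
frequencies (3 when unequal), I, α, and the branch scale.

Saturation profiles plot %Ti = Ti/(Ti+Tv) against pairwise K2P distance,
excluding zero-distance pairs (%Ti undefined) and saturated pairs
(undefined K2P), each counted separately so the bookkeeping identity
points + exclusions = n(n−1)/2 always holds.

## Synthetic data

The generator emulates a multi-genome mitochondrial dataset: four
super-orders splitting deepest, ~35 genera, species pairs at the
congeneric level, and conspecific lineages coalescing shallowest, with two
outgroup lineages attached basally.  Depths are configured as expected
**pairwise** divergences in substitutions/site (defaults: 1.5% within
species, 8% between congeners, 30% at the deepest ingroup splits), so
configured values are directly comparable to pipeline distance output;
node heights are depth/2 on the ultrametric scaffold.  Heights are
jittered by a mean-one shifted-exponential multiplier (0.7 + Exp(0.3)),
clamped to preserve the species < genus < super-order hierarchy — an
unconstrained multiplier routinely inverts the hierarchy and destroys the
gap structure the generator exists to produce.

Sequences evolve along the single shared genealogy (mirroring maternally
inherited, non-recombining mtDNA: lineage-sorting failures hit every gene
identically) under a reversible substitution model — default HKY-flavoured
with κ = 8, mammal-mtDNA-like frequencies (GC ≈ 0.39), gamma shape 0.5 and
20% invariable sites.  Site rates are drawn from the same discrete
(mean-of-quartile) gamma representation the likelihood machinery fits
(continuous gamma is available); this keeps the generating model inside
the fitted model class, which is what makes parameter-recovery
experiments a consistency check rather than a robustness study.  Coding
genes are kept stop-free by rejection at the root and codon resampling
along branches, so the finaliser's internal-stop screen stays meaningful.
No indels are simulated: the pipeline's target machinery is distances and
trees, not alignment.

Introgression events re-simulate a fraction of a recipient species'
lineages from inside the donor's clade.  The donor's coalescence is first
deepened toward its parent node so the nested structure remains resolvable
on real-length genes — echoing the unusually deep intraspecific divergence
introgressed species show in real data.  With fraction 1.0 the recipient
becomes a monophyletic clade nested inside the donor: exactly one species
(the donor, now paraphyletic) is broken per event, which is what gives the
controlled 100/98/94/90% recovery series its arithmetic.  Ground-truth
monophyly flags are computed directly from the modified genealogy, never
assumed.

### What passing tests do and do not show

The simulator captures the statistical skeleton of real data — taxonomy
structure, a barcoding gap, transition bias, rate heterogeneity, shared
genealogy, controlled monophyly violations — but not alignment error,
NUMT contamination, sequencing error, indels, taxonomic misassignment, or
base-composition heterogeneity among lineages.  Green tests certify the
estimators and bookkeeping; they do not certify that any locus is a good
barcode for a particular real clade.

## Problem sizes and numerical choices

The test and acceptance runs use deliberately scaled study conditions: 25
genera × 2 species × 2 sequences (50 evaluated species) with 1.2 kb genes
for the recovery series — the package's own sufficiency analysis puts
reliable per-gene monophyly resolution at roughly ≥ 1 kb for these depths,
and sub-kilobase genes (ATP8 at 216 bp) genuinely cannot guarantee exact
recovery of a nested introgression pattern, which is a property of the
data, not the code; 20 taxa × 10 kb for GTR+I+Γ parameter recovery; and
10–22 taxa × 2–8 kb for BIC selection consistency.  Likelihood evaluation
guards against underflow by per-node rescaling; distances are computed in
double precision with exact symmetry by construction.

## Known limitations

- K2P systematically underestimates distances generated under strong rate
  heterogeneity (the fitted global branch scale on NJ-K2P trees runs
  ~1.8–2.2× at deep divergences); the package preserves this because the
  estimator, not a corrected surrogate, is the object of study.
- PAUP*-style ambiguity inference is not publicly specified; the
  proportional-redistribution rule here is a precise, deterministic
  reconstruction, not a bit-exact reimplementation.
- The fixed-tree, global-scale model-fitting protocol trades some accuracy
  in α̂ and Î for speed; full per-branch re-optimisation is out of scope.
- Identical duplicate sequences are not collapsed before distance
  computation (no-collapsing default; the alternative convention would
  change pair counts).
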