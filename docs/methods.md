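# Methods

This note records the models behind each module, the parameters that
matter, and the design decisions taken where the published procedure left
room — in the spirit of the methods appendices of simulation and
statistics packages.

## Sequence evolution simulator

`simulate_codon_pair` evolves a descendant CDS from a uniformly random
sense-codon ancestor by a Gillespie jump process over single-nucleotide
changes. Relative rates: 1 for transversions, `kappa` for transitions,
multiplied by `omega` for nonsynonymous changes; changes creating a stop
codon have rate zero, so sequences remain translatable by construction
(rejection happens at the proposal level, not by masking). The process
stops when the time-integrated synonymous rate reaches
`branch_ks × S_anc`, where `S_anc = (L2 + 3·L4)/3` is the ancestor's
LWL85 synonymous site count; by the Poisson thinning argument the
expected number of synonymous substitutions per synonymous site then
equals `branch_ks` exactly, up to the slow drift of the synonymous rate
as the sequence composition evolves. There is no indel process and no
codon-usage bias; both branches of divergence are placed on one lineage
(the "ancestor" doubles as the first sequence), which is equivalent for a
time-reversible-style symmetric process at the divergences used.

Defaults used in the recovery experiments: 1000 codons, true Ks 0.5,
50 replicates — large enough that the Monte-Carlo standard error on the
mean ratio is ~0.01, small enough to run in seconds.

### A note on LWL85 bias and the neutral recovery experiment

LWL85 weights twofold-degenerate sites as 1/3 synonymous and assigns
their transitions to Ks and transversions to Ka. One can show directly
from the combination formulas that, for a process in which every site
evolves at the same per-nucleotide rate (true omega = 1), the estimator
returns

    Ka/Ks ≈ [(3·L0 + 3f·L2)/(3·L0 + 2·L2)] / [(3f·L2 + 3·L4)/(L2 + 3·L4)]

where `f` is the transition fraction of substitutions. This equals 1
exactly when f = 1/3 (no transition bias, kappa = 1) and drops to ≈ 0.89
at f = 1/2 (kappa = 2), a known structural bias of the method (addressed
historically by its successors, which re-estimate the twofold-site
weighting). Accordingly the purifying-regime recovery experiment runs at
kappa = 2 (where the band ±0.1 absorbs the proportionally small bias) and
the neutral-regime experiment at kappa = 1, where neutrality is the clean
null for this estimator. The residual ≈ 0.05 downward shift observed at
kappa = 1 comes from stop-codon exclusion: positions whose alternatives
include a stop count fully as nonsynonymous sites but offer fewer
realizable nonsynonymous changes.

## Orthology

The aligner is an affine-gap BLOSUM62 pairwise aligner (gap open 10,
extend 1, Biopython's convention of `open + (L−1)·extend` per gap of
length L). Identity is computed over gap-free aligned columns; coverage
is the aligned span divided by sequence length, evaluated on the query
(*A. thaliana*) side — the conservative reading of a query-anchored
search — with a `min(both)` option. In place of a database-size-dependent
E-value, raw scores are converted to bits with fixed ungapped
Karlin–Altschul constants (λ = 0.267, K = 0.041) and thresholded at 50
bits by default; random ~200-residue protein pairs score far below this,
true orthologs at ≤ 20% divergence far above, so the threshold is not
delicate at desk scale.

Domain annotations are consumed as a precomputed table (gene → domain
IDs); the logical contribution preserved here is the *intersection* of
the domain-sharing condition with a passing alignment, not profile
search itself. All passing domain-track assignments are kept (duplicated
family members are all true orthologs); Brassica genes assigned to
multiple queries are flagged rather than resolved, since no published
tie-break exists. Reciprocal best hit uses deterministic tie-breaking:
higher score first, then lexicographically smaller gene id.

## Ka/Ks estimation

Codon alignment is protein-guided: global protein alignment, gaps
back-translated as whole-codon gaps; gapped codon columns are excluded
from both site and difference counts (the conservative standard when the
source procedure is silent). Site classes follow the LWL85 degeneracy
rule — fourfold if all three alternatives are synonymous, nondegenerate
if none, twofold otherwise (the threefold Ile position collapses to
twofold; substitutions to stops count as nonsynonymous). When the two
codons of a column disagree on a position's class, the difference is
split half-and-half (the averaging-over-sequences convention also used
for the L_i themselves). For codons differing at 2–3 positions, all
orderings of the changes that avoid stop intermediates are enumerated and
averaged with equal weight; if every ordering crosses a stop, the
restriction is lifted for that pair. Equal weighting (instead of LWL85's
frequency-based pathway weights) is a deliberate simplification;
at the divergences simulated here (Ks ≤ 0.8) the difference is well
inside the recovery tolerances, and the brute-force oracle tests pin the
single-difference arithmetic exactly.

Saturation (1 − 2P − Q ≤ 0 or 1 − 2Q ≤ 0) makes the K2P logs undefined;
the result is reported as undefined (`NA` in tables) rather than clamped.
The neutral band for classification is `[1 − tol, 1 + tol]` with
tolerance 0 by default — the strict reading of "equal to one" — with the
tolerance exposed because published practice sometimes calls ratios like
0.9989 neutral.

## Expansion statistics

Γ pathway counts use the shared-inclusive ("parenthetical") totals, in
which each dual-pathway gene counts in both pathways: this is the choice
that reproduces the published per-pathway Γ values exactly, and the
report emits both exclusive- and total-based columns since published
tables are not always explicit. Display rounding is decimal half-up
(2 decimals by default, 3 supported). The chromosome census treats empty
labels, `Ann`/`Cnn`-style subgenome placeholders and `Scaffold*` names
as unanchored.

## Phylogeny

p-distances use pairwise gap deletion by default (the common default in
desktop phylogenetics tools), with complete deletion available. Neighbor
joining is the standard Saitou–Nei agglomeration on the Q-criterion,
with taxa sorted lexicographically and the smallest index pair winning
ties, so results are fully deterministic; negative branch-length
estimates are clamped to zero. Bootstrap support resamples alignment
columns with replacement and reports, for each internal bipartition of
the point-estimate tree, the percentage of replicate NJ trees containing
it. Maximum-likelihood and Bayesian inference, substitution-model
selection and topology testing are out of scope; the retained method is
the NJ tree.

## Expression statistics

FPKM values are normalized as log2(FPKM+1). Breadth counts organs
*strictly above* 0.5 on that scale (the wording "higher than" is read as
strict); average expression is the mean over those organs only and is
undefined (NaN) for silent genes — which therefore drop out of
correlations pairwise. Replicate columns (suffix `.R<n>`/`.rep<n>`) are
averaged before statistics; purely numeric suffixes like `Se.10` are
timepoints and stay distinct columns. The high/weak/organ-specific
trichotomy has no published thresholds; the reconstruction here — silent
if breadth 0; organ-specific if breadth ≤ 2 or max/mean over expressed
organs ≥ 4; high if average ≥ 2.0 (log2 scale); else weak — is
parameterized and should be read qualitatively. Correlations are Pearson
on untransformed statistics by default (matching linear-fit practice),
with Spearman as an option.

## Synthetic expression generator

`simulate_expression` plants the selection–expression coupling through a
latent Gaussian: standardized omega `u_i` enters
`m_i = ρ·u_i + √(1−ρ²)·ε_i`, the per-gene mean log2 level is
`2.0 + 1.2·m_i` (clipped at 0), and organ values add N(0, 0.8) noise
before transforming back to FPKM. Organ noise and the
threshold-restricted averaging attenuate the recovered correlation below
|ρ|, so recovery tests assert sign and significance, not magnitude. The
generator does not emulate organ-specific regulatory programs, replicate
structure, count noise, or the mean–variance relationship of real
RNA-seq — passing tests demonstrate that the *pipeline* recovers planted
structure, not that real data would show it.

## Study-scale defaults

The pipeline's synthetic study uses 200 families with 20 lost and 30
duplicated, per-gene true dN/dS lognormal around 0.2 (the purifying
regime typical of these orthologs, range clipped to [0.01, 1.5]), true Ks
lognormal around 0.5 (clipped to [0.05, 1.5], below saturation), CDS
lengths 80–300 codons, a 19/295 domainless fraction and 34/295
dual-pathway rate mirroring the query-census proportions, 10% unanchored
genes, planted expression correlation −0.5, and 1000 bootstrap
replicates. Smaller configurations used in unit tests change only scale,
never the generating mechanisms.

## Known limitations

- LWL85 only; no NG86/YN00/ML estimators, so transition-bias effects on
  Ka/Ks are a property of the method (documented above), not corrected.
- No profile-HMM search, multiple-sequence alignment, or indel handling;
  family alignments consumed by the tree stage must be pre-aligned (the
  simulator guarantees this by construction).
- The Karlin–Altschul bit conversion uses ungapped constants as a fixed
  calibration; it is a configurable threshold, not a statistical E-value.
- Real-genome headline counts and correlation magnitudes require the
  actual proteomes and RNA-seq and are outside what the synthetic study
  can or should reproduce.
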