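# Methods

## The birth–death gain/loss model

Gene gain and loss on a branch are modelled with per-gene intensities:
with *N(t) = A₀ + g(t) − l(t)* genes present, gains arrive at rate
*N β* and losses at *N δ* (per MY). The means obey
dg/dt = Nβ, dl/dt = Nδ, so *N(T) = A₀ e^{(β−δ)T}* and the endpoint
counts (G, L) invert in closed form to (β, δ); at G = L the analytic
limit β = G/(A₀T) applies. `estimate_rates` implements the inversion
with `log1p` so the formula is numerically continuous through G ≈ L
(the closed form at G − L = ±1 differs from the limit by < 1 % for
A₀ ≥ 100, which a test asserts). Degenerate branches: a branch that
loses its entire repertoire with G = 0 reports δ = +inf with a warning
(the log diverges); total loss with G > 0 leaves the logarithm undefined
and raises. `ode_forward_oracle` integrates the same ODEs numerically
(DOP853, rtol = atol = 1e-12) and serves as the independent oracle: the
inversion recovers (β, δ) to ≤ 1e-6 relative error over
β, δ ∈ [0, 0.05], A₀ ∈ [10, 1000], T ∈ [1, 100].

Whether G and L count gene copies or whole OGGs is a modelling choice;
`count_mode="genes"` (default) counts copies, matching rates defined as
genes gained/lost per gene per MY; `count_mode="oggs"` counts groups,
matching branch bookkeeping reported at the OGG level.

## Ancestral content reconstruction

Tip OGG copy numbers are projected onto the rooted, dated species tree
in two steps. Presence/absence follows Dollo parsimony: an OGG
originates once at the MRCA of the tips carrying it and may only be lost
below that node (no regain). Copy numbers at Dollo-present nodes then
minimise total |parent − child| change (Sankoff, unit cost per copy,
vectorised over OGGs; ties resolve to the smallest count, root ties to
the smallest state, so the reconstruction is deterministic). Per-branch
A₀ + G − L equals the child count as an exact integer identity.

Parsimony is a floor on the true event count: a gain and a loss of the
same copy inside one branch cancel, and events smear across adjacent
internal branches. At the study-scale regime (830 families, β = δ =
0.003) the estimator itself is unbiased given true event counts (< 20 %
pooled relative bias, asserted in a test), while the reconstruction
compresses per-branch estimates toward zero by roughly a factor of two —
the group *contrast* (marine vs terrestrial loss) survives essentially
intact, which is what the recovery test measures. Rates are estimated on
every branch but group means use terminal branches only, where tip data
pin the child state.

## Mining filters

The miner is a self-contained translated search: six-frame translation,
exact 5-aa seed words chained on diagonals, Smith–Waterman verification
(BLOSUM62, gap open 11 / extend 1) restricted to seed windows, and a
Karlin–Altschul E-value approximation (gapped BLOSUM62 constants
λ = 0.267, K = 0.041). Windows that overlap on a frame are verified with
their two best-seeded queries only; a cluster needs ≥ 2 seeds, which at
the 60 %-identity/100-aa detection contract still yields ~8 expected
seeds. All thresholds are config keys with the standard values: E ≤
1e-10 (pass 1) and ≤ 1e-20 (pass 2), ≥ 250 aa, ≤ 5 aa gap per TM helix,
N-terminus 21–34 aa, < 30 bp contig-end rule, < 50 % query
dereplication identity.

Decisions the filters leave open, resolved here:

- Overlapping hits collapse when they share ≥ 1 bp on the same strand;
  ties break by score, then lower start, then query id.
- ORF extension stops at the first upstream in-frame stop; among
  multiple viable ATGs the one giving the longest N-terminus inside
  [21, 34] aa wins.
- TM intervals transfer through a pairwise global alignment to the
  closest reference by k-mer similarity (not a full MSA); a gap is the
  longest indel run inside a transferred helix, checked in both
  directions.
- Pseudogene disruptions: an internal stop in the dominant reading
  frame, or hits on ≥ 2 frames of one locus (frameshift). A truncated
  call requires a disruption-free region near a contig end; a region can
  carry both flags, and the pseudogene flag is also set for
  disruption-free regions that fail the contig-end rule.
- Contig-end rule: the matched region ends < 30 bp from a contig
  boundary, **or** its reading frame continues stop-free from the region
  boundary to the contig end within 30 codons. The run-off clause
  tolerates local-alignment tail trimming against a diverged query
  (a genuine interior remnant terminates at a stop codon long before the
  contig does); the 30-codon cap keeps interior remnants from
  qualifying by chance.
- OR identity confirmation roots an NJ tree (Poisson distances) at an
  OR reference and removes candidates inside the outgroup MRCA clade;
  with < 4 sequences, < 2 outgroups, or an impure outgroup clade the
  nearest-neighbor distance rule decides. Pass 2 additionally screens
  each region with the nearest-neighbor rule and skips loci already
  confirmed non-OR, so GPCR decoys never surface as OR pseudogenes.

## Classification

Intact proteins are clustered by MCL (expansion 2, inflation 1.5,
config-exposed) on a normalized local-alignment score graph
(score / min self-score), with a 4-mer Jaccard prefilter and an edge
floor of 0.35 normalized score — within-family pairs at ≥ 80 % identity
score ≈ 0.75, between-family pairs at ≤ 40 % identity ≈ 0.25, so the
floor separates the regimes the clustering is asked to resolve.
Clusters of ≥ 2 become OGGs; singletons go to a bootstrapped NJ tree
(star alignment to the longest member for columns; non-OR GPCRs as
outgroups) where maximal all-singleton clades with support strictly
greater than 70 merge; 1000 replicates by default, 100–200 in tests for
speed. Singletons are never merged into pre-existing MCL clusters.
Class I/II labels come from the nearest labeled anchor by patristic
distance on an NJ tree over genes + anchors (root-invariant; sequence
distance when too few sequences for a tree). Non-intact genes attach to
the OGG of their single best-scoring intact hit (ties: identity, then
gene id). Naming ranks OGGs within class by intact size, then mean
similarity, then smallest member id: OGG1-1, OGG2-1, ...

## Selective-pressure proxy

Per-OGG ω is the median of pairwise Nei–Gojobori (1986) dN/dS values
with Jukes–Cantor correction, over OGGs with ≥ 3 members; pairs with
dS = 0 are excluded and an OGG with no synonymous change anywhere is
flagged rather than valued. Mutational pathways through stop codons are
skipped (unless no stop-free pathway exists), and mutations to stops are
excluded from site counts, so neutral simulation centres the estimator
near 1 (median within [0.8, 1.25], asserted). The median damps the
instability of near-zero dS pairs. This is a counting proxy chosen for
self-containment; a maximum-likelihood codon model would differ in level
but the analyses using ω here are rank-based (correlations, group
comparisons).

## Statistics

Mann–Whitney U is exact by full enumeration of group assignments
(midranks for ties) when the combined n ≤ 20, otherwise the normal
approximation with tie correction; two-sided throughout; an
all-tied pooled sample returns p = 1. Pearson correlations use the
product-moment form with the t-transform p value. Both match
brute-force oracles on all tested inputs with n ≤ 10.

## Synthetic data: what it emulates, and what it does not

The generator plays the role of the study inputs: a dated 23-taxon
mammal tree (11 marine species across three independent aquatic
lineages, 11 terrestrial relatives, one outgroup; ages in MY in the
TimeTree range), an ancestral repertoire of 830 OGGs, and per-branch
(β, δ) defaulting to the terrestrial-like 0.003/0.003 with an optional
marine loss elevation (0.017). Family evolution is a Gillespie process
whose per-gene intensities make the closed-form estimator's assumptions
literally true; with β = δ the expected gains on a branch are A₀βT
(= 249 for A₀ = 830, β = 0.003, T = 100), asserted against replicate
means.

Genomes are emitted as random-background contigs (GC 0.42) carrying each
surviving gene as an intronless ATG..stop ORF of 301 aa on a fixed
seven-TM template grid (hydrophobic-biased helix residues, 26-aa
N-terminus — inside the miner's window by construction). Substitutions
are uniform (Jukes–Cantor-like) at 5e-4 /nt/MY with no indels in intact
genes; draws that would create or destroy a start/stop are resampled, so
planted intact genes always satisfy the miner's intactness definition
and planted pseudogenes (premature stop or 1–2 bp frameshift) never do.
Truncated copies are disruption-free fragments placed flush against a
contig boundary. Later copies within an expanded OGG receive extra
divergence (4 MY-equivalents per copy index by default), standing in for
their longer duplication history, which reproduces the lower mean
similarity of larger families. Decoy non-OR GPCRs share the fold
scaffold but form their own sequence neighbourhood; their undiverged
prototypes double as the outgroup reference set. Interior genes keep
80 bp clear of contig ends and 150 bp of each other so the contig-end
rule and region merging are exercised only where intended; the 8 codons
immediately upstream of a planted start are cleared of in-frame ATGs so
the longest-qualifying-N-terminus rule is decided by the planted start.

Not emulated: introns and UTRs, repeats and segmental duplications,
GC-isochore structure, assembly gaps and sequencing error, indel
evolution within coding regions, and within-branch rate variation.
Passing tests therefore demonstrate correctness of the algorithms under
the stated generative assumptions, not robustness to real-assembly
artefacts (fragmented or low-coverage assemblies will move the
intact/truncated boundary in ways this generator does not probe).

## Problem sizes

Test and acceptance runs use desk-scale conditions chosen to keep every
property measurable: 20 replicates of the 23-taxon/830-OGG contrast for
rate recovery; one 200-gene two-species genome (48 × 22 kb contigs,
25 % pseudogenized, 10 % truncated, ≤ 15 % protein divergence,
`ogg_divergence = 0.2` so every planted gene shares ≥ 60 % identity with
some query, the miner's stated detection contract) for miner fidelity;
60 three-member families of 150 codons for the neutral-ω calibration;
200 random regimes for the rate inversion. The pipeline's own defaults
(830 OGGs, 1000 bootstrap replicates) remain the study-scale values.

## Known limitations

- Parsimony reconstruction underestimates per-branch G and L (events
  cancel within branches); rate levels are compressed toward zero while
  contrasts between groups are preserved. A probabilistic gene-content
  model would trade determinism for calibrated levels and is out of
  scope.
- The internal translated search is seeded; homologs below ~60 %
  identity to every query fall outside its detection contract.
- The star alignment used for bootstrap columns drops insertions
  relative to the reference; adequate for near-full-length proteins,
  not for heavily gapped families.
- ω is a pairwise counting estimate; absolute values are not comparable
  to ML codon-model output.
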