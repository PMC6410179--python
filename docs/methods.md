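# Methods

This note documents the models and procedures `famchar` implements, the
parameter defaults and why they were chosen, what the synthetic-data
generators do and do not emulate, and the numerical decisions that matter for
reproducing results.

## Family assignment

Genes enter the family roster through Pfam domain evidence: a fixed bijective
map from nine accessions to nine groups (PF03760→LEA1, PF03168→LEA2,
PF03242→LEA3, PF02987→LEA4, PF00477→LEA5, PF10714→LEA6, PF02496→ASR,
PF00257→DHN, PF04927→SMP). Hits are kept when their e-value is **strictly
below 0.05** (the survey threshold). A gene with hits to several groups is
assigned to the group of its smallest e-value; an exact tie between two
groups raises an error carrying the gene id rather than breaking the tie
silently — the original survey resolved such cases by manual curation, and a
pipeline should surface them, not guess. Within a group, members are named
sequentially (`LEA2-1`, `LEA2-2`, …) in (chromosome, start) order when loci
are supplied. This rule is reproducible but is *not* guaranteed to match any
published numbering, which is never stated alongside such tables.

## Physicochemical descriptors

All five descriptors follow the ProtParam definitions and are undefined for
ambiguity codes (X, B, Z, U), which the FASTA reader rejects (or skips on
request):

* **Molecular weight**: sum of average (not monoisotopic) residue masses plus
  one water; masses embedded from the ExPASy reference table.
* **Theoretical pI**: the root of the Henderson–Hasselbalch net-charge model
  with Bjellqvist pKa values (N-terminus 7.5 with residue-specific values for
  A/M/S/P/T/V/E, C-terminus 3.55 with residue-specific D/E, side chains
  D 4.05, E 4.45, C 9.0, Y 10.0, H 5.98, K 10.0, R 12.0), found by bisection
  on [0, 14] to |charge| < 1e-4. The charge is strictly decreasing in pH, so
  the root is unique. Note that Biopython's ProtParam stops its search on an
  interval-width criterion; for charge-poor peptides the two can differ by
  ~0.2 pH units, while for protein-length sequences they agree to < 0.01
  (asserted in the test suite).
* **Instability index**: `(10/L) · Σ DIWV(x_i, x_{i+1})` over consecutive
  dipeptides. The 400-entry DIWV weight matrix (Guruprasad et al. 1990) is
  imported from `Bio.SeqUtils.ProtParamData` rather than re-transcribed;
  the formula is implemented here and is order-sensitive by construction.
* **Aliphatic index**: `X_Ala + 2.9·X_Val + 3.9·(X_Ile + X_Leu)` in mole
  percent.
* **GRAVY**: mean Kyte–Doolittle hydropathy per residue.

Family summaries round to reporting precision — mean MW to 0.1 kDa, pI to
0.01, percentages to 0.1 — so that equality tests against printed tables are
meaningful. `validate_against_table` compares computed profiles against a
printed table cell-by-cell at printed precision (MW/pI/indices 0.01,
GRAVY 0.001) and returns the match fraction with the mismatch list; it is the
harness for validating the constant tables against published values when the
underlying sequences are available.

A documented inconsistency in the source material: the survey's prose calls
15.36 a "stability index" for DHN-1 and 118.43 the "highest stability index"
(LEA2-23), but in its own table those numbers sit in the aliphatic-index
column (DHN-1's instability index is 34.82). The package follows the table's
column semantics.

## Phylogeny

Distances: per pair, the proportion `p` of differing sites with **pairwise
deletion** of any column where either row is gapped (the default behaviour of
mainstream distance-phylogeny software; complete deletion would discard most
columns of a gappy family alignment), then Poisson correction
`d = −ln(1 − p)`, which assumes equal substitution rates across sites and no
back-substitution accounting beyond the Poisson model. `p ≥ 0.99` is treated
as saturated: a direct distance-matrix computation fails loudly, while a
bootstrap replicate containing a saturated pair is skipped and counted in the
run metadata rather than propagating infinities.

Tree building is Saitou–Nei neighbour joining on the Q-criterion, with ties
broken by first index order (deterministic). Negative branch-length estimates
are clamped to zero and counted on the returned tree. NJ provably recovers
additive matrices; the test suite checks this against an independent oracle
(exhaustive enumeration of all unrooted topologies with least-squares
branch-length fitting for n ≤ 6, the generating tree for n = 7, 8) and
cross-checks topologies against scikit-bio's NJ on random matrices.

Bootstrap supports: alignment columns are resampled with replacement, one
index block per replicate drawn in replicate order from
`numpy.random.default_rng(seed)` — fixing the seed makes the output Newick
byte-identical across runs and platforms. Each replicate tree's bipartitions
are mapped onto the full-data tree's internal edges; support is the
percentage of usable replicates containing the edge (majority-rule consensus
trees are deliberately not built — supports annotate the full-data topology,
matching how distance-phylogeny GUIs annotate their NJ tree). Sister pairs
are cherries whose subtending edge support is **strictly greater** than the
cutoff (default 90).

## Duplication classification

Candidate pairs are within-group pairs whose global Needleman–Wunsch
alignment (BLOSUM62, gap open 10, gap extend 0.5 — ClustalW-flavoured protein
defaults; no parameters are published for this step) shows > 75% identity.
"Similarity" is implemented as percent identity of alignment columns; the
source material does not distinguish the two. Identity is identical residue
pairs over all alignment columns; coverage is residue-pair columns over the
longer sequence's length.

Classification is a pure function of the recorded evidence, evaluated tandem
first (the more specific event): **tandem** = same chromosome AND
nearest-ends gap ≤ 100 kb (inclusive) AND fewer than 10 intervening
non-family genes strictly between the two spans; otherwise **segmental** =
coverage > 80% AND identity > 70%; otherwise none. Genomic distance is the
gap between nearest gene ends, not midpoints. Whole-genome synteny detection
(MCScanX-style collinearity) is out of scope; the classifier operates on the
family's own loci.

## Gene structure

CDS-to-genome mapping is exact-match chaining: maximal exact blocks of the
remaining CDS are matched left-to-right onto the genomic sequence, enforcing
a minimum intron length (default 20 bp) between consecutive exons.
Minus-strand genes are reverse-complemented before mapping, so exon
coordinates refer to the transcript orientation. If no chain consumes the
whole CDS the gene is reported unmappable; if two distinct maximal chains
exist, an error lists both. Exact matching is correct when CDS and genomic
sequence come from one consistent annotation (and for the synthetic
generator); it is a documented limitation for real, polymorphic data, where
a tolerant spliced aligner would be required. The mapping contract —
concatenated exon sequence equals the CDS — is asserted on every model.

## Expression and qPCR

FPKM values get a 1e-5 pseudocount (a monotone shift) before
`log2(treatment/control)`, making fold changes finite for dropout genes; the
induced/inhibited call threshold defaults to |log2FC| ≥ 1 (2-fold), a
conventional cutoff the source material never states — it is configurable.
The square-root transform is the display transform used for expression
heights. CV% uses the sample (n−1) standard deviation over the mean; the
choice of denominator is likewise unstated upstream and documented here.

qPCR quantification is plain 2^−ΔCt with ΔCt = Ct(target) − Ct(reference),
no amplification-efficiency (Pfaffl) correction and no ΔΔCt calibrator
normalization. Replicates are paired target/reference by replicate index;
relative expression is computed per replicate and the mean ± sample SD taken
over those expression values (not over ΔCt), matching "mean ± SD of
replicates" applied to plotted expression levels. SD is reported as 0 for a
single replicate.

## Synthetic data generators

All generators are pure functions of (seed, parameters) via
`numpy.random.default_rng`; identical inputs give byte-identical files, and
every planted event is recorded in a truth table serialized next to the data,
so downstream tests read only generator output plus truth.

`simulate_family` defaults emulate the surveyed family: group sizes
{LEA1 5, LEA2 45, LEA3 4, LEA4 3, LEA5 3, LEA6 1, ASR 4, DHN 5, SMP 4}
(74 genes), 12 chromosomes, 4 tandem pairs placed on chromosomes 4/8/9/10
(mirroring the surveyed tandem pairs' chromosomes), 2 segmental pairs in the
largest group, a 39/29/6 split of 0/1/2-intron genes, and the dehydrin
K-segment `EKGMMEKIKEKLPGHH` frozen verbatim in every DHN sequence (other
groups get a random 12-residue motif, likewise frozen). Each group grows from
a random 150–400-residue ancestor by per-site substitution, uniform over the
19 alternative residues — no indels, no substitution matrix, no rate
heterogeneity; adequate for threshold-crossing tests, explicitly not a
molecular-evolution model. Background divergence defaults to 0.30 per copy,
putting typical paralog identity near 55–60%, comfortably below the 75%
candidate threshold — emulating the low mutual similarity of the real family
— while planted tandem (3%) and segmental (8%) copies sit far above it.
Tandem pairs are placed within a 5–80 kb gap with 0–9 interleaved non-family
genes; all other genes occupy 500 kb-spaced slots so no unplanted pair can
satisfy the tandem geometry. Decoy genes carry either a non-family accession
or an above-threshold e-value.

`simulate_expression` plants per-gene log2 effects δ (default drawn once from
U(−4, 4)): treatment = control · 2^δ · lognormal(0, noise). Because the log
of the noise is exactly N(0, noise²), the estimated fold change is unbiased
with SD noise/ln 2 ≈ 0.144 at noise 0.1, so the mean absolute recovery error
is ≈ 0.115 — the basis of the 0.15 acceptance bound. `simulate_ct` draws the
reference Ct per replicate (N(20, 0.5²)) and sets the target Ct to
`ct_ref − log2(r) + N(0, noise_sd²)`, so 2^−ΔCt recovers the planted r
exactly at zero noise.

What passing these tests shows: the inference rules are implemented
correctly and recover planted signal under the stated noise models. What
they do not show: performance on real alignments (with indels and rate
variation), real annotations (polymorphism, mis-annotation), or real
expression data (overdispersion, batch effects).

## Pipeline and problem sizes

`run_all` executes classify → physchem → phylo → dupscan → structure → expr →
qpcr from one YAML config holding every threshold exactly once (e-value 0.05,
candidate identity 75, tandem 100 kb / < 10 genes, segmental 80/70, bootstrap
1000, support 90, pseudocount 1e-5, fold-change threshold 1) plus the seed;
the JSON report contains versions, seed, thresholds and per-stage row counts
but no timestamps, so identical configs give identical reports. Distance and
bootstrap computations are vectorised (alignments held as uint8 matrices), so
1000 replicates on the 45-member default group run in seconds. The analysis
drivers and acceptance script use desk-scale sizes — the 74-gene default
family, 200-gene expression matrices, 10–18-taxon alignments with up to 1000
bootstrap replicates — chosen so the whole evidence chain reruns in well
under a minute while keeping every statistical margin (identity separation,
noise propagation) intact.

## Known limitations

* Exact-match gene-structure mapping fails on any CDS/genomic mismatch
  (deliberate; see above).
* The pI model ignores cysteine oxidation state, phosphorylation and
  electrostatic interactions — as does the tool it mirrors.
* NJ with Poisson correction underestimates large distances when rates vary
  across sites; no gamma correction is offered.
* The duplication classifier does not date events (no Ka/Ks) and sees only
  the family's loci, so "intervening gene" counts depend on the completeness
  of the supplied locus table.
* MSA construction is out of scope: alignments are inputs, and the per-group
  "alignments" the simulator emits are exact because it introduces no indels.
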