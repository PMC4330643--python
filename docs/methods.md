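# Methods

`capclade` re-implements, as a self-contained and testable pipeline, a
survey of the eIF4E cap-binding protein family across core dinoflagellates
and their relatives (syndineans, *Perkinsus*, apicomplexans, ciliates,
heterokonts). This note records the models, the conventions, and the
design choices made where the design was genuinely open.

## The census model

Family membership is decided by iterative homology search. In place of a
BLAST service the package uses exact Smith–Waterman local alignment
(BLOSUM62, affine gaps with open 11 / extend 1; a length-*k* gap costs
`11 + (k-1)·1`) and Karlin–Altschul e-values

    E = K · m · n · exp(−λ · S)

with the standard gapped-BLOSUM62 parameters λ = 0.267 and K = 0.041, so
the conventional e-value cutoff of 1e−10 keeps its usual meaning. A
subject is accepted when any current query reaches e ≤ 1e−10 with more
than 130 aligned columns; accepted subjects join the query set and the
search iterates to a fixpoint. Unknown residues (X) score zero against
everything; a terminal stop `*` is stripped at parse time. The
min-aligned-length rule is implemented as a configurable filter (default
130) — the original description is ambiguous about whether it was a
filter or an observation. Nucleotide input is out of scope: the census
operates on protein sequences (or six-frame translations prepared
upstream).

Exhaustiveness: the Smith–Waterman score is verified in the test suite
against a brute-force enumeration of all monotone matchings on random
short pairs — an oracle with no dynamic programming in common with the
implementation (which delegates the DP to biopython's `PairwiseAligner`).

## Reference-anchored alignment

Instead of a simultaneous multiple alignment, every sequence is aligned
pairwise to the murine eIF4E reference (1L8B numbering; the packaged
reference is the 217-residue sequence whose anchors W43, W46, W56, W73,
W102, E103, R112, W130, R157, K162 and W166 were verified against the
published positions) using global alignment with free end gaps and the
census scoring. Each residue receives either a murine position or an
insertion code `(after_position, offset)`. Sequences are trimmed to the
core window — five residues upstream of W43 through ten downstream of
W166, murine 38..176, 139 positions — and stacked into a column-consistent
alignment whose column *j* is exactly murine position `38 + j`; insertions
ride along as per-row annotations and never occupy columns.

Consequences worth knowing: column semantics are unambiguous and
deterministic (every downstream statistic is per-murine-position), at the
price that insertion content is invisible to the tree and the logos, and
columns adjacent to insertions inherit the pairwise aligner's placement
choice rather than a cross-row consensus. Alignments covering less than
half the core are flagged `partial` but not dropped.

## Diagnostic annotation

The cap-binding pocket is read off at ten anchors (43, 46, 56, 73, 102,
103, 112, 157, 162, 166), the two insertion windows (73,102) and
(130,166) are measured, and the eIF4G-recognition hexamer at murine 68..73
is matched against `[ST]V..[FWYL][WFYL]`, with the variable third/fourth
positions classifying the motif flavour (Q/N polar, D/E acidic, K/R
basic). Clade typing applies ordered rules, first match wins:

1. Y/F/L at 43 → metazoan Class II-like (aromatic-loss diagnostic);
2. insertions ≥ 5 aa in both windows and H112 → clade 1-like;
3. C112 and V/A at 162 → clade 2-like;
4. W56, R112, K162 and no long window insertions → clade 3-like;
5. otherwise unclassified.

The rule order and the 5-residue insertion threshold are package choices
that make the three clade descriptions mutually exclusive; both are
configurable. The canonical murine residue set satisfies rule 4 — a known
artifact of the rule table, asserted as such in the tests. Sub-clade-level
states (the 3b arginine at 102, terminal extensions) are reported as
evidence but never drive the label: sub-clade resolution belongs to the
tree.

## Phylogeny

The tree stage is a deliberate desk-scale stand-in for a maximum-
likelihood topology search, and published bootstrap percentages are not
expected to be matched numerically. Components:

- **Distances** over the 139 match columns: Poisson, Kimura
  (`d = −ln(1 − p − 0.2p²)`, capped at 5.2 with a warning when the
  argument is non-positive, i.e. p ≳ 0.854), or a 1-D maximum-likelihood
  branch length under the substitution model. Gaps and X are missing
  data; the denominator is the mutually resolved columns.
- **Neighbor joining** (Saitou–Nei) with deterministic tie-breaking
  (lowest index pair) and negative branch lengths clamped to zero with
  the deficit moved to the sister edge. Verified to recover additive
  matrices exactly and cross-checked against scikit-bio's implementation.
- **Bootstrap**: nonparametric resampling of the 139 match columns
  (insertions excluded), support = percentage of replicate NJ trees
  containing each bipartition of the full-data tree; reproducible per
  seed.
- **Likelihood**: Felsenstein pruning with LG (or WAG/JTT)
  exchangeabilities, model or empirical frequencies, and discrete-gamma
  rates (4 categories, mean-of-quantile rates). The rate matrix is
  normalized to one expected substitution per site per unit length;
  transition matrices come from the symmetrized eigendecomposition, and
  per-node scaling guards against underflow. Gaps are missing data. A
  single stationary model is assumed across the tree; no covarion or
  heterotachy options. The gamma shape is estimated by bounded 1-D search
  of the fixed-topology likelihood on [0.05, 10].
- **Model-frequency comparison**: `compare_frequency_models` scores a
  fixed tree under the model's own frequencies versus alignment-derived
  ones. Note that on data simulated *at* model equilibrium the empirical
  frequencies win in-sample by roughly half the parameter count in
  log-likelihood units (the usual overfitting margin), so the comparison
  is informative about real, compositionally unusual data rather than a
  check that model frequencies always win.

## Clade partition

Major clades are the codified version of a post-hoc definition: root the
tree, then descend — when at least two child subtrees each contain both
core dinoflagellates and heterokonts, recurse into them; otherwise the
node is a major-clade root. Clades are numbered by decreasing
core-dinoflagellate content. Rooting options: midpoint (the
`partition_major_clades` default), `outgroup:GROUP`, `none` (honor the
input rooting), and MAD (minimal ancestor deviation). The pipeline
defaults to MAD because the composition-biased, long-branch ciliate
lineages make the single longest path — and therefore the midpoint —
unstable, occasionally pulling the root inside a clade; MAD scores all
leaf pairs and is far less sensitive to one aberrant branch.

Sub-clades are monophyletic core-dinoflagellate groups within a major
clade, extracted under a dual criterion of monophyly *and* species
representation:

- syndinean and *Perkinsus* leaves are masked — they never break
  core-dinoflagellate monophyly and are reported separately;
- up to two isolated foreign *singleton* leaves are tolerated inside a
  group (a lone aberrant long branch nested in an otherwise uniform,
  species-complete group does not dissolve it), while any multi-leaf
  foreign clade still separates groups;
- a pure group is split when at least two of its child subtrees each
  hold ≥ 5 core-dinoflagellate species on stems ≥ 0.1 substitutions/site
  — two adjacent species-rich blocks count as two sub-clades even when
  they are sisters, but fragments connected by near-zero edges are one.

Groups need ≥ 2 members except a singleton lineage attached directly at
the clade root (so one-copy-per-species sub-clades survive). Letters a,
b, c… are assigned by decreasing species count, then size, then traversal
order; this convention need not reproduce any particular published
lettering even when the groups coincide.

## Statistics

- **Composition χ²** (Tree-Puzzle convention): each row's residue counts
  against expected counts under the alignment-wide pooled frequencies;
  gaps and X excluded everywhere; expected cells < 1 pooled into one
  "rare" cell with df reduced; flag at α = 0.05.
- **Percent identity**: matches over mutually non-gap columns (X counts
  as a residue here, unlike in distances); a whole-sequence mode aligns
  the untrimmed sequences with free end gaps first.
- **Column variability**: share of columns with ≥ 2 non-gap residues that
  hold ≥ 2 distinct residues.
- **Logos**: per column, `R = max(0, log2 20 − H − e_n)` with
  `e_n = 19/(2 ln2 · n)`; letter heights `p_a · R`. At n = 1 the
  correction exceeds log2 20, so single-sequence columns carry zero
  information by construction. A minimal stacked-bar rendering is
  provided; the matrices are the product.

## The synthetic family generator

The generator is the package's ground truth and emulates the surveyed
family's structure; its defaults are the study conditions.

- **Taxa**: eleven core dinoflagellate species in four related groups;
  six heterokonts (three photosynthetic, three oomycetes); four ciliates;
  four apicomplexans; two syndineans; *Perkinsus*.
- **Structure**: three ancestral clades, each containing heterokonts and
  core dinoflagellates. Nine sub-clades arranged 4 + 2 + 3. Outgroup
  lineages interleave where the survey placed them: the ciliate clade and
  syndinean second copies inside clade 1 between 1a and 1b, the two
  apicomplexan lineages beside 1c, the ciliate and heterokont eIF4E-2
  clades between 2a and 2b with the Class II heterokonts outside, and the
  photosynthetic/non-photosynthetic heterokont clades between 3a/3b/3c.
  Diatoms carry no clade-2 member; *P. infestans* carries two.
- **Representation**: 1a–1d, 2a and 3a in all eleven species (six fully
  represented sub-clades); 2b in eight, 3b in six, 3c in five. Copy
  numbers per species rank 1a > 1d > 1b > 1c, with 1c single-copy;
  *Perkinsus* carries 2 + 1 + 4 members across the three clades. Totals
  land near 120–126 core-dinoflagellate members, 8–15 per species.
- **Evolution**: i.i.d. per-site substitution under LG along the guide
  tree; no indel process (insertions and terminal extensions enter only
  through clade signatures, keeping the murine-numbering truth exact —
  a documented limitation). The structural core (murine 38..176) evolves
  at 0.6× rate and the termini/insertions at 1.7× (length-weighted mean
  ≈ 1), encoding that the core is the conserved domain and the termini
  the poorly alignable parts.
- **Calibration**: per-sub-clade divergence scalars are set so closely
  related species pairs show approximately the reported full-length
  identities — 86% (1a), 70% (1d), 60% (1b), 53% (1c) — via the LG
  expected-identity curve; the clade-2/-3 sub-clades follow the reported
  conserved-versus-partial ordering. Sub-clade stems (0.30) exceed
  within-sub-clade depths, consistent with duplications predating the
  core-dinoflagellate radiation.
- **Signatures**: stamped at each clade's ancestral node — conserved
  W43/W46/W102/E103/W166 plus the clade-diagnostic states at 56/112/162,
  the clade-1 ten-residue insertions in both windows, per-sub-clade motif
  flavours, the 2a carboxy-terminal extension (230 aa) and the 3b
  amino-terminal extension with R102. Stamped positions are frozen
  (invariant) below the stamping point — purifying selection at
  functional sites, without which the diagnostic classifier would face
  neutral drift at its anchors.
- **Composition bias**: the clade-1 ciliates, two of the eIF4E-2
  ciliates and the 3b lineage are biased by post-hoc site resampling
  (weight 0.35) toward a lysine/asparagine-rich target — a flag-level
  emulation, not a mechanistic model, because the surveyed biased taxa
  are characterized only by the χ² flag. Bias also corrupts stamped
  sites, so biased lineages are motif-divergent and hard to place, as
  observed.

What passing the end-to-end tests shows: the pipeline machinery recovers
a *planted* structure whose signal strength was calibrated to reported
summary statistics. It does not show that the inference would resolve
real transcriptome data with the same confidence — real data carry
alignment ambiguity, missing fragments, paralog loss and rate variation
that the generator does not emulate.

## Problem sizes and determinism

Default runs use the full synthetic family (~165–175 sequences), 139
match columns, and 100 bootstrap replicates; the test suite uses smaller
replicate counts where support values are not under test. All randomness
flows through a single integer seed (NumPy `default_rng`); pipelines,
the simulator and the bootstrap are bit-reproducible per seed.

## Known limitations

- No heuristic seeding: the census is exact Smith–Waterman, quadratic per
  pair — appropriate for thousands, not millions, of sequences.
- NJ + bootstrap is not an ML topology search; deep backbone supports are
  systematically weaker and should be read qualitatively.
- The anchored stacking cannot re-align insertion content across rows.
- The generator's guide tree is one concrete realization of the described
  structure; alternative placements of the outgroup lineages would be
  equally consistent with the qualitative descriptions it follows.
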