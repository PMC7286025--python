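# Methods

## Class model

A GST class is defined by (i) a degenerate 5-residue motif ("architecture"),
written in bracket notation (`SD(DRV)I(IL)` ≡ `SD[DRV]I[IL]`; the Asx code
`B` is read as `[ND]`), (ii) optional order-specific motif variants — a class
is considered present in an order exactly when a variant exists for it,
(iii) optional N-/C-terminal signature motifs, and (iv) a catalytic rule:
residue Y, S or C accepted at fixed 1-based sequence positions (Y at 5 or 7
in β-strand 1; S at 8 or 66 and C at 12, 26 or 74 near helix 1). The twelve
shipped definitions live in `src/cyanogst/data/gst_classes.cfg`, a
human-editable config; every order variant is checked by the test suite to
be a refinement (expansion subset) of its class architecture.

The global architecture `S[GLNTARS][ADE]I[LAI]` is exposed only as a
permissive "GST-like" pre-filter, never for class assignment: four class
motifs (SDDII, SAIIN, SAVIN, SKDIL) fall outside it. A leading glutamate
sometimes written before this pattern is omitted here. Motif search is
position-free (the whole sequence is scanned) and uses set-membership
semantics per column, so no regex dialect is involved.

## Classification

Candidates are all classes whose architecture matches anywhere. Chi and
cyGSTX1 share `SGAIL`; when both are candidates the signature motifs decide
(evidence = number of that class's signatures found). Any remaining
multi-candidate tie is resolved by a deterministic numeric-aware class
ordering (Chi < X1 < … < X11) **with an explicit `ambiguous` flag** — the
original clade-inspection tie-breaking is replaced by a reproducible desk
rule, and ambiguity is never silent. `SAIIN` matches both cyGSTX8
(`SAI(IV)N`) and cyGSTX10 (`SA(IV)IN`) and therefore resolves, flagged, to
cyGSTX8. A `strict` policy that refuses ties is also available. Catalytic
typing checks the assigned class's residue at its allowed positions first,
then the generic Y/S/C rules; `catalytic_concordant` records whether the
class's own rule fired.

## Synthetic data generator

The generator emulates the curated sequence panel the analysis was designed
for, with a truth table (class, order, catalytic type) for every record.

* **Templates.** One random "family master" background (default 220
  residues, uniform residue frequencies; configurable) is diverged once per
  class at per-site probability `class_divergence` (default 0.6, leaving
  ~20% between-class identity). This mirrors the field rule of thumb that
  GSTs under ~25% identity belong to different classes, keeps classes
  alignable as homologues, and keeps between-class E-values above the 1e-11
  network threshold. Records of a class are copies of its class template.
* **Embedding.** One expansion of the class motif at `motif_start`
  (default 60); the catalytic residue at a type-appropriate 0-based position
  (Y→4, S→7, C→11, i.e. 1-based 5/8/12, all accepted catalytic sites);
  for Chi and cyGSTX1 one expansion of each signature (N-terminal at 25,
  C-terminal at `length − 20`). Expansions are drawn uniformly **among the
  expansions distinctive to the class**: concrete motifs shared across
  classes (STAIA in X4/X7, SAIIN in X8/X10) are excluded so the truth is
  learnable by the classifier itself; the fully shared Chi/X1 `SGAIL` is
  kept because signatures resolve it, exactly as in the classification rule.
* **Noise.** Point substitutions at `mutation_rate` (default 0.05),
  skipping motif/signature/catalytic columns when `protect_motifs` is on.
  RNG consumption per record is independent of the rate, so runs differing
  only in `mutation_rate` share substitution decisions (monotone coupling,
  used by the degradation trend test). Chance occurrences of any class
  motif or signature outside the intended windows are scrubbed by
  resampling one background residue, so truth labels stay unambiguous.
* **Orders.** Each record's order is drawn uniformly from the class's
  allowed orders (overridable per class).

Everything derives from a single `numpy` `SeedSequence`; the same seed gives
byte-identical FASTA output. The generator simulates substitutions only —
no indels, no secondary-structure constraints, no realistic residue
composition by default — so passing tests demonstrate correctness of the
algorithms under the stated model, not performance on real proteomes.

## Alignment and E-values

Global pairwise alignment is an affine-gap Gotoh dynamic program (row-
vectorised in numpy) maximising the substitution-matrix score with gap cost
`gap_open + k·gap_extend` for a gap of length `k`; defaults BLOSUM62, open
11, extend 1. Traceback precedence is fixed (substitution, then gap-in-a,
then gap-in-b; closing a gap beats extending it), making equal-scoring
alignments resolve identically. The test suite proves score equality with
exhaustive alignment enumeration for short pairs.

Bit scores and expectations use `bit = (λ·S − ln K)/ln 2`,
`E = m·n·2^{−bit}` with the standard gapped-BLOSUM62 calibration λ = 0.267,
K = 0.041. Applying this local-alignment statistic to global scores is an
acknowledged approximation: only the ordering of E-values against the
network threshold matters downstream.

## Multiple alignment and trimming

The progressive aligner is center-star: the center maximises total pairwise
score; each other sequence is pairwise-aligned to the center and merged
under "once a gap, always a gap". The MSA stage defaults to a stiffer
gap-open (30) than the pairwise-scoring default: GST domains align nearly
end-to-end, and at twilight-zone identity a cheap gap-open lets optimal
pairwise alignments scatter gaps inconsistently across near-identical
sequences, corrupting the merged columns. Poorly aligned regions are
removed by a gap-fraction column filter (default: drop columns with > 50%
gaps), a simple stand-in for alignment-trimming tools.

## Distances

All methods use pairwise deletion (columns where both residues are one of
the 20 standard codes). `p` is the mismatch fraction; `gamma-poisson` is the
closed form `d = α[(1−p)^{−1/α} − 1]` (default shape α = 1.0 — the source
analysis states gamma-distributed rates but no shape value — with a
delta-method SE; as α→∞ it approaches the Poisson distance −ln(1−p));
`ml-jtt-gamma` maximises the per-pair likelihood under the JTT
exchangeabilities and frequencies (shipped as plain-text published
constants, `src/cyanogst/data/jtt.dat`) with k = 4 equal-probability
discrete gamma categories, via bounded 1-D search; its SE comes from the
numerical curvature (observed information) of the log-likelihood. Distances
above 10 substitutions/site are reported as 10 and flagged as saturated.
Parameter-recovery tests simulate pairs under the same discretised model at
5,000 sites and require the mean estimate within 10% at d ∈ {0.1, 0.3, 0.6}.

Between-order divergence is the arithmetic mean of all cross pairs for each
order pair (zero diagonal by convention); its reported SE is the standard
error of the contributing pairwise distances. The published between-order
table ships as printed (lower triangle distances, upper triangle read as
standard errors); its caption-level "percent" wording is preserved, not
applied, since the values are on the substitutions-per-site scale.

## Trees

Neighbor joining follows the standard Q-criterion agglomeration with the
usual branch-length formulas; ties break to the first pair in label order,
and negative length estimates are clamped to zero and counted. NJ is exact
on additive matrices, which the suite verifies against randomly generated
trees (topology via Robinson–Foulds = 0 and exact path lengths). Trees are
dendropy objects; Newick output carries branch lengths and, after
bootstrapping, % supports as internal labels. Bootstrap resamples columns
with replacement, re-estimates distances and the NJ tree per replicate, and
scores each original internal split by the percentage of replicates
containing it. An alignment of (near-)identical rows returns the star tree
by convention. Full maximum-likelihood topology search is out of scope; the
NJ + bootstrap engine is the package's tree method. Monophyly is tested
under bipartition semantics (a group is a clade if it forms one side of
some split), appropriate for unrooted trees built without an outgroup.

## Similarity network

All-vs-all global alignment (the BLAST all-vs-all of the original workflow
is replaced by the in-house aligner; documented approximation); an edge is
kept when E ≤ threshold. Three thresholds appear in the source workflow
(1e-11, 1e-10, 1e-5); the strictest, stated in its methods, is the default
and all are exposed as flags — relaxing the threshold can only add edges,
which the suite checks. Components come from an in-house union-find,
cross-checked against graph-library traversal.

## Pipeline

`run-all` executes generate/load → classify → incidence → center-star MSA →
trim → distances → between-order means → NJ + bootstrap (default 500
replicates) → SSN (default 1e-11) → summary, writing every artefact as
plain text plus a manifest (config, seed, versions). Runs are byte-
deterministic from the seed. Default problem sizes used throughout the
tests — 12–36 sequences of 220 residues, 20–100 bootstrap replicates,
5,000-site distance simulations — keep each stage in seconds while leaving
every statistic well-resolved.

## Known limitations

* E-values from global scores are heuristic; absolute values should not be
  compared with BLAST output, only thresholded consistently.
* The center-star MSA is O(n²) pairwise alignments and offers no iterative
  refinement; it is a desk-scale stand-in for production aligners.
* Catalytic typing beyond the residue-position rule (e.g. structural
  verification of the G-site) is out of scope, as are homology modelling
  and docking stages of the original study.
* The classifier's tie rule is a reproducible replacement for manual clade
  inspection; sequences matching only a shared concrete motif (e.g. SAIIN)
  are resolved deterministically but remain flagged ambiguous.
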