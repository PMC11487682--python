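# Methods

This note records the models, conventions and design choices behind
`vhhkit`, in the spirit of a methods appendix: what is computed, under
which assumptions, and where the genuinely open choices were resolved.

## IMGT numbering by germline profile transfer

Raw amino-acid sequences (90–180 residues, 20-letter alphabet plus `X`)
are placed on the IMGT 1–128 scaffold by global alignment
(BLOSUM62, gap open −11 / extend −1, free terminal overhangs so that
purification tags do not shift the core) against every entry of a
germline database; the best-scoring entry provides the column
assignment. Sequences whose identity to the best germline falls below a
configurable floor (default 40%) are rejected as unnumberable — this
cheaply filters non-antibody input before any downstream statistics.

Alignment-based transfer is used only for the framework: the three
hypervariable loops are renumbered from their *lengths*, measured
between the conserved anchors (26/39 for CDR1, 55/66 for CDR2, 104/118
for CDR3), because indel placement inside loops is an artifact of the
scoring scheme, not a biological statement. Loops fill their IMGT spans
(27–38, 56–65, 105–117) from both ends, vacating middle columns first
(111 first for CDR3). CDR3s longer than 13 residues receive insertion
codes between 111 and 112, assigned alternately (111.1, 112.1,
111.2, …) and ordered `111 < 111.1 < … < 112.1 < 112` in the sequence —
a fixed convention, since numbering tools differ only in bookkeeping
here. Raw residues aligning outside the germline (terminal tags) and
rare framework insertions are left unnumbered rather than invented
positions.

"Fully annotated" is operationalized as: all four frameworks populated,
cysteines at 23 and 104, and the FR4 anchor position 118 present. Each
part of the rule can be relaxed by callers; the default is deliberately
strict because every repertoire statistic assumes the canonical
disulfide scaffold.

## Region definitions

CDR boundaries are shipped as explicit IMGT column sets for four
schemes. Kabat and Chothia boundaries were pre-converted to IMGT columns
with the standard no-insertion heavy-chain correspondence (Kabat H1
31–35 → IMGT 36–40; Kabat H2 50–65 → IMGT 55–74; H3 95–102 → IMGT
105–117; Chothia H1 → 27–36, H2 → 57–64). Exact conversion at CDR edges
for unusual loop lengths is not uniquely defined in the literature; the
shipped table is the fixed, documented choice and satisfies the two
structurally load-bearing facts: position 40 is CDR1 under Kabat and
under the combined (union) definition, and position 55 is CDR2 under
both. The combined definition is the default everywhere because
framework-based humanization under it cannot touch either position.

The default Vernier set is the Foote–Winter VH Vernier zone mapped to
IMGT columns, {2, 28, 29, 30, 53, 54, 76, 78, 80, 82, 87, 103}, shipped
as data and overridable. It contains the two Vernier positions most
often probed by point humanization (78 and 87) and is disjoint from the
Hallmark set by construction.

## Entropy, mutual information, clustering

All estimators are plain empirical plug-ins — no pseudocounts, no
phylogenetic down-weighting, no average-product correction. The
alignment matrix holds one row per fully annotated sequence over the
fixed 128 scaffold columns (21-symbol alphabet: 20 residues + gap);
CDR3 insertion-coded residues are excluded from the matrix and
contribute only to length statistics, so all rows are commensurable.

Per column, `H` is Shannon entropy in bits and `NH = H/log₂21 ∈ [0,1]`
(the 21-symbol ceiling). Pairwise `MI` comes from the joint symbol
histogram; `NMI = 2·MI/(H(X)+H(Y))`, defined as 0 when both columns are
constant (no information exists to share). Positions are clustered by
Ward's linkage on the precomputed distance `d = 1 − NMI` (the
minimal-assumption similarity-to-distance transform), cutting the merge
tree at a fixed height, default 1.1 — note Ward heights can exceed 1
because the linkage inflates with cluster size, so a cutoff above 1 is
meaningful. Cluster ids are renumbered by each cluster's smallest member
so assignments are deterministic and permutation-equivariant.

A caveat the test suite makes explicit: the plug-in MI of two
*independent* k-symbol columns is biased upward by roughly
(k−1)²/(2N ln 2) bits, i.e. mean off-diagonal NMI ≈ 0.066 at N = 1000
for k = 21, decaying like 1/N. Small NMI values at moderate depth are
bias, not signal; the clustering results reported here rest on values an
order of magnitude above that floor.

## Humanization model

Given a parental sequence and a germline database, the closest human
germline maximizes percent identity over *framework* columns of the
active scheme (frameworks are what grafting replaces; ties break by
allele name). Grafting takes the germline at non-CDR columns and the
parental at CDR columns (byte-identical, insertions included) plus any
retained positions. The low-risk variant retains Hallmark ∪ Vernier ∪
non-canonical-cysteine positions and applies the anti-preADA
substitution L12V — only when the parental itself carries the leucine
the substitution targets; otherwise the grafted germline residue
stands.

Candidate humanizations ("key mutations") are the retained framework
positions where parental and germline differ. Each maps to exactly one
risk tier, with strict precedence: Hallmark 42/52 (highest; antigen
binding or CDR3 stabilization) > CDR3-bridged non-canonical cysteines >
Hallmark 49/50 (solubility) > Vernier > DE loop (80–87) > rest.
Stepwise enumeration yields one variant per key position; combinatorial
enumeration yields all subsets up to a cap, ordered by (risk-tier sum,
size, notation) so cheap-risk designs come first. Humanness is percent
framework identity to the closest human germline; by construction it is
monotone under humanizing substitutions, which the tests assert.

The liability scan is sequence-level only: deamidation `N[GSTA]`,
isomerization `D[GSTD]`, N-glycosylation `N[^P][ST]` (all configurable
regexes, conservative industry-standard defaults), unpaired cysteines
(odd Cys count or a non-canonical Cys without a putative partner), and
methionines inside the active scheme's CDRs. No structural
surface-exposure filtering is attempted; sequence-level findings are an
over-approximation of the structure-aware ones.

## SAR conventions

KD fold changes are variant/reference ratios, reported at full precision
and rounded to one decimal for prose-style reporting. A reduction
strictly above 2-fold is "relevant" — below that, biolayer
interferometry noise and batch effects dominate. Matched molecular
pairs are unordered variant pairs whose mutation sets (relative to one
common parental; series must not be mixed) differ by exactly one
mutation; the member lacking it is the reference. Per-mutation effects
aggregate MMP ratios by geometric mean (fold effects are
multiplicative) with min/max range; pairs whose mutated member is a
non-binder are tallied as qualitative knockouts and excluded from the
mean, and pairs with a non-binding *reference* are excluded entirely.

The bundled example dataset is the measured affinity series of two
NKp30-binding VHH humanization campaigns; the accompanying per-variant
mutation sets are a *reconstruction* (the original per-variant designs
are available only graphically) constrained to reproduce every matched
pair discussed for the series, and are marked as such in the data
module. One arithmetic nuance: the F42V mutation has exactly one
measurable pair (ratio 9.5) and seven knockout pairs in that series.

## The synthetic repertoire generator

The generator emulates, at desk scale, the statistical structure of
large camelid VHH NGS repertoires — the structure the analyses assume:

* **Hallmark motif mixture.** Named motifs FERF/FERG/VGLW/YQRL at
  0.21/0.17/0.13/0.10 (the four dominant motifs jointly 61% of
  sequences, matching their reported share; their individual frequencies
  are not published, so the split within 61% is a modeling choice), plus
  VEHG (0.03) and FARS (0.02), plus an `OTHER` remainder (0.34) whose
  four Hallmark letters are drawn independently from per-position pools
  (rejecting named motifs). The remainder is essential, not cosmetic:
  without a rare-motif long tail the four Hallmark columns become almost
  mutually deterministic (pairwise NMI 0.4–0.7), unlike real
  repertoires, whose Hallmark coupling is moderate (~0.15–0.37) — and
  Ward clustering behaves qualitatively differently on the two regimes.
* **Position-40 coupling.** Every motif carries its own position-40
  distribution (`OTHER` conditions on its sampled residue 42). The
  distributions were chosen subject to the repertoire-wide marginals
  (Gly 63.9%, Ala 13.7%, Ser 10.6%) and the VGLW-conditional ones
  (Ser 51.2%, Thr 14.1%, Tyr 10.9%, Asn 10.0%). With
  `position40_coupling=False` position 40 is drawn from the
  motif-independent marginal — the null used to show the extended
  Hallmark cluster is signal, not artifact.
* **Non-canonical cysteines.** With motif-dependent probability
  (highest for FERG, whose germlines carry Cys55) a cysteine is written
  at 55 and at a uniformly random CDR3 position; the marginal Cys-subset
  fraction is ~29.9%.
* **CDR3 lengths.** Shifted negative binomial (minimum 3, dispersion 8;
  only subset means are published, so the shape is a modeling choice)
  with motif means 18.4 (FERG), 14.4 (VGLW), 14.6 (YQRL), 16.3 (FERF)
  and remainder means set so the overall mean is 16.6. Because the Cys
  and motif subsets overlap, Cys carriers receive a within-motif mean
  shift (+d·(1−p) for carriers, −d·p for non-carriers, d solved in
  closed form at config time) that leaves every motif-subset mean
  unchanged while raising the pooled Cys-subset mean to 19.0.
* **Background noise.** Point substitutions at rate 0.01 per position
  outside the anchors and model-assigned sites, never introducing stray
  cysteines.

All randomness flows from a single integer seed; identical configs give
byte-identical output. What the generator does *not* model: somatic
hypermutation hotspots, V(D)J recombination, insertions outside CDR3,
sequencing error, and within-motif residue correlations beyond position
40 — so passing tests demonstrate correctness of the estimators and the
recoverability of the encoded structure, not performance on every
property of real NGS data. Dataset-scale quantities quoted for real
repertoires (e.g. millions of sequences) are reproduced here only at
desk scale (2000–5000 sequences), chosen so the full analysis runs in
seconds.

The SAR generator assigns each variant a random subset of mutations with
known multiplicative KD effects, lognormal noise (σ = 0.1) and optional
knockout mutations emitted as non-binders. Recovery accuracy scales with
the number of matched pairs per mutation; the acceptance script uses the
full 63-variant combinatorial series over 6 mutations (~16 pairs per
mutation), which brings the maximum per-mutation relative error
comfortably under 15% across seeds.

## Germline database

The packaged database contains five synthetic consensus scaffolds
written for this package (llama FERG with germline Cys55, llama FERF,
llama VEHG, alpaca YQRL, human VH3-like VGLW differing from the camelid
consensus at twelve framework/fringe positions) — deliberately *not*
copies of curated germline records, but faithful to the structural
features the analyses need (canonical Cys23/Cys104, vacant position 10,
8-residue CDR1/CDR2 gapping, Trp118). User germlines load from FASTA
with `species|allele` descriptions and are renumbered on ingestion.

## Numerical and degenerate-input conventions

* Entropy uses base-2 logs throughout; 0·log 0 := 0; probability vectors
  are validated to sum to 1 within 1e-6.
* NMI of two constant columns is 0 by convention; the NMI matrix is
  symmetrized and clipped to [0, ∞) before clustering.
* Clustering requires ≥2 columns; empty alignments, empty subsets and
  empty FASTA inputs raise typed errors; an empty CDR3 returns length 0
  with a warning.
* Fold changes against a non-binding variant are flagged infinite rather
  than raised; non-binding references are an error.
* The relevance threshold is strict (ratio > 2.0): a ratio of exactly
  2.0 is not relevant.
* Combinatorial enumeration past the cap truncates with a warning, never
  silently.
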