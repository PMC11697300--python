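# Methods

This note documents the models and procedures implemented in `gaingrn`,
the parameters that matter, the numerical choices, and what the
synthetic-data tests do and do not establish.

## Detection model

Detection operates on a 3-class secondary-structure string, never on
coordinates. The per-residue classes are mapped to a numeric signal —
+1 for helix, −1 for strand, 0 for coil — and smoothed by linear
convolution with a uniform (box) kernel. Sign changes of the smoothed
signal are segment boundaries; maximal runs of one sign are helix/strand
blocks. Coil contributes 0 so that it biases neither class.

Subdomain B is the contiguous run of strand blocks after the last helical
block; subdomain A is the helical region (run of consecutive helical
blocks) with the greatest total helical residue count among regions
N-terminal of B, ties resolved toward the C-terminal region. The domain's
N-terminal boundary is placed where the smoothed signal first decays
below ε scanning N-ward from subdomain A — a single sub-ε position
suffices; demanding a full kernel-width of quiet signal proved too strict
next to short N-terminal tails, pushing the boundary to the chain start.

Parameters (all configurable):

| parameter | default | role |
|---|---|---|
| `kernel_width` | 9 residues | box-kernel width; sets boundary resolution ±⌈w/2⌉ |
| `eps` | 0.05 | signal magnitude below which a position is a separator |
| `min_block` | 3 residues | shortest run kept as a segment block |

A domain is *valid* iff both subdomains and the GPS are present; the
first missing piece is reported (`no-subdomain-B`, `no-subdomain-A`,
`no-GPS`). GPS localization prefers an alignment reference column (any
sequence occupied at the GPS.-1 column passes); the fallback scans the
C-terminal third of subdomain B for the canonical H-L-[T/S] motif, then
for the degenerate x-L-[T/S] at lower confidence, taking the most
C-terminal hit since the triad directly precedes the last strand.

Secondary structure normally comes from STRIDE or DSSP files (7/8-class
codes collapsed as G/H/I→H, E/B→E, rest→C; 3₁₀ and π helices count as
helical because the detection signal is binary). The builtin fallback
classifies a residue by whether it sits in a run of ≥4 residues whose
φ/ψ fall in a standard Ramachandran basin (helix φ∈[−100°,−30°],
ψ∈[−80°,−5°]; strand φ∈[−170°,−70°], ψ∈[80°,180°]∪[−180°,−170°]). Note
that backbone dihedrals are extremely sensitive to independent
per-atom coordinate noise (σ=0.3 Å already moves φ/ψ by tens of
degrees), so the builtin assigner is appropriate for experimental-quality
geometry, not for heavily perturbed synthetic ensembles — those carry
their planted assignment in STRIDE format instead.

## Pairwise alignment

The aligner provides what the indexing pipeline actually consumes:
order-preserving residue matches plus a least-squares RMSD. Candidate
correspondences are seeded from secondary-structure blocks: all
order-preserving, kind-respecting pairings of the smaller structure's
blocks into the larger one's are enumerated (capped at 2000; an LCS
pairing is the fallback) and scored by the Kabsch RMSD of block
start/center/end Cα triplets — the geometrically best pairing wins. This
matters when architectures differ: a two-helix subdomain A must seed
against the right two of six template helices, which order alone cannot
decide. Refinement then alternates (i) Kabsch superposition on the
current matches with (ii) dynamic-programming re-matching on the Cα
distance matrix (match allowed under `d_match` = 3 Å, gap cost 0,
score = d_match − d), until the match set is stable or 50 iterations.
RMSD matrices mark pairs that fail to align with an infinite sentinel,
which clustering excludes.

No attempt is made to reproduce any particular external alignment
program's scores; published RMSD values for experimental GAIN structures
are reference points, not targets.

## Templates and anchors

Per receptor group, a random sub-selection (default 400 per group,
seeded) bounds the cost of the pairwise RMSD matrix. The matrix is
clustered with scikit-learn agglomerative clustering (average linkage,
k=3 by default — the clustering method is fixed by the workflow, the
linkage and count were open choices) and the candidate template is the
member of the largest cluster with the smallest mean RMSD to its
co-members; every tie breaks to the lexicographically smallest id so
reruns are reproducible.

Anchors: every ensemble member is aligned onto the template and the
pairwise matches are stacked into per-template-column tables. A column's
score is occupancy × top-residue fraction — the simplest combination
monotone in both of the two stated criteria (occupancy and residue
identity) — and the best column inside each segment becomes the `.50`
anchor (ties to the most N-terminal column). Validation reports, per
segment, anchor occupancy (fraction of members whose alignment matches
the anchor column) and the mean matched Cα distance after superposition;
segments under 50% occupancy are flagged. Manual curation (anchor moves,
extra segment spans, dropped segments) lives in the registry's override
table, applied on load, rather than in code; re-running selection after
an override round is the user's loop to drive.

## GRN assignment

Templates resolve by group, or — for ungrouped domains — by aligning to
every template and taking the lowest-RMSD one per subdomain. For each
template segment, the matched query residue of the anchor column is
labeled `.50`; if the anchor column itself is unmatched, the match
nearest to it (template-ordinal distance, ties to the N-terminal side)
anchors the segment with the offset applied, e.g. three residues
N-terminal → `.47`. Enumeration extends over the query's own
secondary-structure block containing the anchored residue, one index per
residue, within the admissible range [1, 99] (longer stretches are
truncated with a warning).

When one query block matches two template anchors (two elements merged
by the SSE assignment), the block is split at the first residue between
the anchors satisfying, in decreasing priority: a coil residue (split
residue excluded from both halves), backbone dihedrals more than five
standard deviations from the element's distribution (canonical basins
helix φ −63°±10°, ψ −42°±10°, strand φ −120°±25°, ψ 130°±25° serve as
the distribution when the ensemble is too small to estimate one),
proline/glycine, then a manually defined element; for the non-coil rules
the split residue joins the C-terminal half. An unresolvable block stays
unsplit and is flagged for curation; assignment then falls back to a
midpoint split so both segments keep their anchors.

Structured labels are injective and contiguous within each segment —
both are asserted on every produced map. Loop residues receive only the
region membership of their flanking segments (21 canonical regions,
`h1h2` … `s14tm1`); segment identity is inherited entirely from the
template match, so no cross-segment sequence-order invariant is assumed
or enforced. GPS triad labels override whatever structured label would
otherwise fall on those three ordinals. If both subdomain templates fail
to align, assignment aborts with a diagnostic rather than emitting a
partial map.

## Contacts and enrichment

Residue contacts use the closest heavy-atom pair under 4 Å with a
minimum sequence separation of 4 (nearer pairs are trivially in contact
and would dominate). Consensus frequency of a GRN label pair is the
number of domains in which the pair touches divided by the **total**
domain count — not the count of domains where both labels exist — so a
contact of a rare segment is rare in the consensus too. Coarse-graining
to segments sums frequencies (within-segment contacts reported
separately), so a segment pair's weight reflects both how many residue
pairs touch and how conserved each contact is.

Mutation records (UniProt positions) are reconciled to structure
numbering by a constant offset or a per-range offset table, then each
record is classed structured / loop / outside (the three tallies always
sum to the input count). Optional SIFT (keep ≤ threshold) and PolyPhen
(keep ≥ threshold) filters drop and count records missing a requested
score. The enrichment score at a position is

    score = log2((c+p)/(C+pN)) − log2((v+p)/(V+pN))

with c, v the cancer/variant counts at the position, C, V their totals,
N the number of positions and p a pseudocount (default 1). Positive is
cancer-enriched; the variant-enrichment score is its negative. The
formula sits behind a single function so an alternative normalization
can be swapped in one place. Positions with c+v < 3 keep their score but
are ineligible for ranking — sparsely covered segments would otherwise
rank on noise.

## Synthetic data

The generator builds single-chain backbones (N, CA, C, O) from ideal
internal coordinates: α-helices at φ=−57°, ψ=−47° (1.5 Å rise, ~100°
twist), strands at φ=−120°, ψ=130° (~3.3 Å/residue). Each segment id has
a fixed canonical position in space — helices on a 2×3 bundle grid,
strands on two stacked sheets (4.8 Å strand spacing, 10 Å sheet
separation) with consecutive strands alternating sheets, the GPS triad
in the crossover before S14 — and loops are routed as smooth bulged
paths between the fixed endpoints. Deleting a segment therefore leaves
every other segment exactly where it was, which is the property the
spatial indexing scheme depends on and what makes cross-architecture
template transfer testable (a two-helix subdomain A indexes correctly
against the six-helix template).

Sequences are drawn from a 14-letter background alphabet that excludes
G/P (reserved for the split rules) and H/L/S/T (so the planted GPS triad
is the only H-L-[T/S] motif in the chain); each segment plants a fixed
conserved residue at its anchor. Presets mirror the observed archetypes:
`canonical` (6 helices, 14 strands), `minimal-a` (H4 and H6 only), and
`pkd-like` (4 helices, 12 strands with extended S10/S14). Default loop
length is 10 residues and perturbation is isotropic Gaussian atom noise
with planted truth unchanged.

What passing these tests shows — and does not. The ensembles exercise
the full pipeline against known answers: signal-based detection,
seeding and refinement of the aligner, anchor derivation, offset and
split handling, contact aggregation and the enrichment arithmetic. They
do not emulate real structural variation: loops are geometrically naive,
sheet twist and helix packing are idealized, coordinate noise is
independent per atom (unlike correlated model error), and segment
lengths vary much less than in real GAIN domains. Recovery rates on
synthetic ensembles are therefore upper bounds, not estimates, of
performance on predicted structural models.

## Problem sizes and determinism

The test suite and the acceptance script use 30-domain ensembles at
σ=0.3 Å for label recovery, 100 seeded fixtures across the three presets
for detection, 50 seeded matrices for the clustering oracle, and 5×40
residue chains for the brute-force contact oracle — sizes at which every
oracle can be exhaustive while the whole acceptance run stays under a
minute. Every stochastic step takes an explicit seed; tabular outputs
are sorted (ordinal, then label string) so identical configurations
produce byte-identical files.
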