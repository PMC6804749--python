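# Methods

This note documents the models and procedures implemented in
`panplastome`, the parameters that matter, the numerical choices made
where the design was genuinely open, and what the synthetic data do and
do not establish about real plastomes.

## Coordinates and alphabets

All coordinates are 0-based half-open; conversion to 1-based happens only
at report boundaries. Sequences are upper-case over `{A,C,G,T,-,N}` plus
the IUPAC ambiguity letters; `U` is folded to `T` on input. In site
classification and distance computation, `N` and the non-N ambiguity
letters are treated as missing data; in haplotype comparison `N` is a
wildcard that matches any residue. Gaps are a separate category
throughout, never missing data.

## Quadripartite structure

Plastomes are circular with two single-copy regions separated by an
inverted-repeat pair (IRa/IRb, exact reverse complements). Detection
finds the longest exact inverted-repeat pair of at least `min_ir` bp
(default 1000, safely below the ~25 kb of real plastome IRs and above
incidental repeats): the sequence is doubled to handle circularity,
candidate pairs are seeded by 24-mer matches against the reverse
complement, grouped by anti-diagonal (which is invariant along one
repeat pair), and extended outward with `N` as a wildcard. Mismatches are
not tolerated — plastome IRs are near-identical, and a tolerance
parameter would have to be invented. Among equal-length candidates the
pair minimizing the LSC start is chosen (deterministic). The partition is
normalized by rotation so the LSC begins at 0; the rotation offset is
reported so callers can rotate the sequence into the same frame.

IRb trimming removes the IRb except the prefix required to keep the
SSC/IRb junction-spanning locus (default `ycf1`) fully contained — the
retained fragment is exactly the locus overlap, unpadded; with no
junction locus the whole IRb is removed (with a warning). Trimming an
already-trimmed sequence is a no-op because no repeat above `min_ir`
remains.

## Alignment operations

*Gap filtering* removes columns whose gap fraction reaches the threshold
(default 0.996, i.e. columns gapped in ≥ 99.6% of rows), emitting an
old→new column map so downstream coordinates remain translatable.

*Site classification*: a column's states are its A/C/G/T counts. A
variable column is a singleton when at most one state occurs twice or
more (so counts (n−2, 1, 1) are a singleton, (2, 2, 1) is
parsimony-informative), parsimony-informative when two states each reach
count 2. η adds (states − 1) per variable column, so η ≥ S with equality
when every variable site is biallelic.

*InDel events* are maximal runs of contiguous columns sharing one exact
gap-presence pattern with at least one gap. Strict pattern identity is
used — adjacent blocks with nested patterns are separate events — because
that is the only definition under which events are recoverable without an
explicit evolutionary model of the gaps.

*Haplotype collapsing* supports two conventions: `gaps_as_state` compares
gap characters as a fifth state; `gaps_ignored` compares only columns
where neither sequence is gapped. Both relations can be intransitive
(through `N` wildcards or complementary gaps), so classes are the
single-linkage closure; closures that merge non-matching pairs are
logged. The representative is the first member in input order. Ignoring
gaps can only coarsen the partition, so the gaps-ignored haplotype count
never exceeds the gaps-as-state count.

## Pan-plastome construction and masking

Per group and column: all members agree → that residue; ≥ 2 distinct
residues → the minimal IUPAC code covering them; any gap or `N` among
members → `N`. Where the last two rules collide (disagreement *and* a
gap), `N` wins as the more conservative encoding; the per-column
provenance flag (`fixed` / `ambiguous` / `indel_masked`) preserves the
distinction. Masking replaces every column that carries any non-ACGT
character in any pan with `N` in all pans. Consequences used throughout
the pipeline: the masked alignment's alphabet is `{A,C,G,T,N}`, every
retained variant is fixed within every group, and classification after
masking equals classification restricted to the kept columns.

The synthetic path keeps all pan-plastomes in one shared coordinate frame
so no realignment step is needed; for real data the pans should be
realigned externally (e.g. MAFFT) before masking, and the length check in
`mask_ambiguous_columns` enforces this.

## Repeats

Both scanners report maximal perfect runs only, found as maximal runs of
the self-match `seq[i] == seq[i+p]`. SSRs cover motif lengths 1–6 with
MISA-style minimum copy numbers `{1:10, 2:6, 3:5, 4:5, 5:5, 6:5}`
(configurable — the thresholds behind the published counts are not
stated, so they are reported in output headers); tandem repeats cover
primitive units of 7–200 bp at ≥ 2 copies. The 6/7 bp split prevents
double reporting. Partial trailing copies are not counted but their
length is reported (a 101 bp AT run is 50 copies + 1 bp). SSR motifs are
strand-canonical: the lexicographically minimal rotation over the motif
and its reverse complement, so hits are identical on either strand.
Copy-number tables across pan-plastomes flag a locus polymorphic when
≥ 2 distinct copy numbers occur (absence counting as 0), and flag
within-group polymorphism separately when per-accession sequences are
supplied.

## Diversity and neutrality

Hd = n/(n−1)(1 − Σp²) over haplotype frequencies under the gap mode used
for collapsing (recorded in the output). π is the mean over pairs of
(differences / comparable sites) with pairwise deletion. S and η are
computed listwise (columns with any gap/N excluded), matching the
masked-pan workflow; Tajima's D uses S (not η) in the Watterson term —
the choice is recorded in output metadata. Significance is flagged (ns /
p<0.05 / p<0.01, two-tailed) from the beta approximation of D's null
distribution: D rescaled to its large-S bounds
D ∈ [(2/n − 1/a₁)/√e₂, (n/(2(n−1)) − 1/a₁)/√e₂] follows a beta law with
mean 0 and variance 1, evaluated analytically rather than by table
interpolation. Flags rather than p-values are reported because the
approximation is not exact in the far tails.

The package's neutral null for testing is genealogy-free: S sites placed
uniformly with derived-allele counts drawn from the 1/i frequency
spectrum. Under this null E[π] = S/a₁ exactly, so D is centered near zero
— which the tests verify — without requiring a coalescent simulator.

## Phylogenetics

Neighbor joining is the standard Saitou–Nei agglomeration with one
documented deviation: a negative branch length is clamped to zero and the
deficit moved to its sister branch, preserving the cherry span. Ties in
the Q criterion resolve to the smallest index pair. On additive matrices
the generating topology and branch lengths are recovered exactly (tested
over random trees).

Species delimitation is tree-based: the input tree is rerooted on the
outgroup (edge split halfway), and per group the report gives monophyly
(the group MRCA's leaf set equals the group), the mean within-group
patristic distance, the mean distance to the closest other group, their
ratio (0 for singletons), and the mean MRCA-to-tip path length.
Patristic rather than raw p-distances are used because the delimitation
statistics are defined on the tree.

The minimum spanning network uses substitution distances (differing
columns where both sequences have A/C/G/T — InDels excluded, as is
conventional for haplotype networks). The edge set is the union of all
minimum spanning trees: an edge belongs iff its endpoints are not
connected by strictly lighter edges, so tied alternatives are retained;
`epsilon > 0` additionally admits edges within epsilon of the
component-merge threshold. Haplotypes at substitution distance 0 (gap-only
differences) are merged into one node so edge weights stay ≥ 1.

Tree congruence: with patristic matrices D_a, D_b over tip pairs,
K = Σ(D_a·D_b)/Σ(D_b²) is the least-squares factor scaling b onto a, and
the K-score is the RMS residual √(Σ(D_a − K·D_b)²/n_pairs). The RMS
normalization is a documented choice (the cited program's exact
normalization is not restated anywhere); it preserves the two properties
the pipeline relies on — the score is 0 iff the matrices are
proportional, and K recovers arbitrary scalings. RF distance is the
unrooted bipartition count.

## Locus-level variation and markers

Variants on the masked pan alignment are polarized against the reference
(outgroup) group: its allele is ancestral, and each derived allele is
classified by its exact carrier set — unique (one leaf group), common
(exactly the leaves of a named composite), else shared-unclassified.
Multi-allelic columns classify each derived state independently; columns
are counted (not alleles) in per-locus SNP totals, noted in output.
Amino-acid changes translate each CDS per pan with genetic code table 11,
skipping codons containing any non-ACGT character, loci on the exclusion
list (default `accD`, `rpl20`, `ycf1`, whose large InDel tracts would
dominate), and CDSs whose length is not a multiple of 3 (flagged).

Locus size deviation is the mean |length_g − length_ref| over
non-reference groups, computed from per-group modal ungapped locus
lengths in the member alignment (pan sequences encode InDels as `N` and
so carry no length signal); loci above 25 bp are flagged as candidates
for gel-based length genotyping. Hypervariability of a locus consensus
against its pan counterpart is a global alignment score (match +2,
mismatch −3, gap open −5, extend −2) normalized by twice the query length
and clamped to [0, 1]: < 0.5 indicates InDel/SSR-driven divergence,
≥ 0.5 SNP-only, with < 0.25 / > 0.75 bands for plotting. The affine
parameters are fixed and documented because the original screening used
an external local-alignment tool with unstated normalization; the
qualitative 0.5 split is what the classification relies on.

Marker candidates must (a) vary in ≥ 4 groups (counting leaf groups and
named composites that carry derived alleles), (b) have > 4 haplotypes
across the pan-plastomes, and (c) be neutral (non-significant D); loci
failing only (c) are listed separately. The haplotype criterion is
computed with gaps included (selection) and excluded (reported), since
the convention is not fixed by the criteria themselves. "Signal
retrieved" is operationalized as RF = 0 *and* K-score < 0.01 between the
candidate-set NJ tree and the reference tree — an explicit, testable
version of a judgment originally made visually. Trees for signal checks
use the internal NJ so the check is deterministic and hermetic; the CLI
accepts an externally inferred reference tree.

## Synthetic data: what it emulates, and what it does not

The generator emits an aligned matrix in one shared frame (insertions
pre-gapped in non-carriers), a locus table tiling a quadripartite genome
with realistic plastid locus names, and a complete truth record. Default
study conditions, chosen once: 7 ingroup groups + 1 outgroup × 4
accessions (enough for within-group polymorphism while keeping every
all-pairs computation instant), a 15 kb frame with 1.5 kb IRs (a 1/10
scale plastome preserving all structural relationships), 2 haplotypes per
group differing by one private SNP, 4 SNPs per tree branch, 4 free InDel
events of 6–18 bp, a 44 bp tandem locus at 3–6 copies in `rpl23-trnI`,
and an AT microsatellite spanning 30–101 bp in `rps16-trnQ`. SNPs and
InDels are placed only in single-copy regions so the IR pair stays exact,
and features carry guard bases so planted runs are maximal and planted
event boundaries cannot merge.

The study-shape preset fixes the group tree
`(((CAA,CAG),((CC,CF),CG)),(CCha,CB)),CP` and places each branch's four
SNPs as two inside the `rps16-trnQ`/`rbcL-accD`/`ycf3-trnS` trio and two
outside. Two consequences are engineered: the trio jointly covers every
branch (so the three-locus set retrieves the full tree, while no single
locus both matches the topology and discriminates all groups), and
per-branch SNP counts are proportional between the trio and the full
alignment (so the congruence K-score is ~0, not merely the RF). Pinned
codon changes recreate the qualitative amino-acid pattern of interest —
a Leu→Ile change common to the B complex, a Val→Ile change common to the
A complex, and a synonymous control.

What passing these tests shows: every operation recovers exactly what was
planted, under the package's own definitions, including the interactions
(masking removes precisely the within-group signal; repeat length
variation produces the predicted InDel events). What it does not show:
robustness to alignment error (the frame is shared by construction),
rate heterogeneity, recombination, imperfect repeats, or IR
expansion/contraction — none of which the statistics here are designed to
address. Real-data paths (external alignment, externally inferred trees)
are exercised only structurally.

## Problem sizes

Default test and acceptance runs use the scales above: 32 × 15 kb
alignments, 100 structure seeds, 500 random instances per brute-force
oracle, and 200 neutral-null replicates — sizes at which every check runs
in seconds while still exercising each code path at study-like shape.
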