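# Methods

## Gene models and intron extraction

Gene structures are read from GFF3 (gene → mRNA → exon/CDS; exactly one
mRNA per gene, ambiguous genes rejected with a message) against a FASTA of
contig or gene-span sequence. All coordinates are 0-based half-open
internally; GFF3's 1-based inclusive convention is converted only at the
boundary. Minus-strand genes are reverse-complemented on load and their
features remapped, so every `GeneModel` reads 5′→3′; the original strand is
kept as provenance only. A CDS whose length is not divisible by 3 flags the
gene *incomplete*: it still contributes intron lengths and counts but is
excluded from phase statistics and from protein alignment.

An intron's phase is `(coding nucleotides 5′ of the insertion point) mod 3`.
An insertion point at or before the first coding base is classified 5′-UTR
(this fixes the boundary case of an intron exactly at the CDS start), and
at or beyond the CDS end 3′-UTR. Splice classes are read off the terminal
dinucleotides (GT-AG, GC-AG, AT-AC, other — "other" is reported, not
discarded). GC content is (G+C)/(A+C+G+T) with N excluded from both sides;
an all-N sequence is an error rather than a silent zero. Introns more than
10% N (configurable) are kept for length/phase but dropped from GC
averages. For even-sized samples the median is the **lower** central value,
the convention common in genome summary tables; per-gene GC is reported for
the CDS alone (whole-exon GC can be derived separately, since UTR inclusion
is a genuine ambiguity in published per-gene tables).

## Progressive alignment

One engine aligns proteins (BLOSUM62, gap open 10, gap extend 0.5) and DNA
(match +2, mismatch −1, same gaps): pairwise k-mer distances
(1 − shared/min k-mers; k=3 protein, k=4 DNA) feed a neighbor-joining guide
tree (scikit-bio), and profiles are merged up the tree with affine-gap
profile–profile dynamic programming (Gotoh recurrences; the insert-in-row
state is unrolled to a running maximum so each DP row is vectorized).
Column scores between profiles are expected substitution scores
(`A·S·Bᵀ`). Ties break in a fixed order (diagonal, then up, then left),
making alignments pure functions of inputs and parameters; tests verify
that pairwise alignments score identically to Biopython's global aligner
under the same penalties. Externally produced alignments can be substituted
anywhere a `ProteinMSA` is accepted, so conclusions can be re-checked for
aligner sensitivity.

## Intron-site conservation

CDS introns are projected through the gapped protein row: residue
`r = ⌊t/3⌋`, phase `p = t mod 3`, site column = alignment column of residue
`r` (phase 0 sits on the boundary *before* codon `r`; a phase-0 intron at
the stop-codon boundary anchors to a virtual column past the last residue).
Sites are keyed by exact (column, phase). Near-miss sites (±1 column, same
phase) are listed in a diagnostics table but never merged — conservative
and reproducible, at the cost of occasionally splitting a genuinely
homologous site that alignment slippage displaced. Species absent from a
family (or excluded for an incomplete/internal-stop CDS) are uninformative
for that family and leave its denominators. `share(A,B)` counts species-A
introns with the site present in B; subset counts partition distinct sites
by their exact presence set.

## Consensus divergence

Orthologous intron sets are aligned with the DNA engine; the consensus is
the per-column plurality over {A,C,G,T,−} with ties resolved to the largest
symbol in the fixed order gap < A < C < G < T (a base always beats a gap;
N carries no weight). Percent change excludes gap–gap columns from both
numerator and denominator and counts base-vs-gap as change. Ties are rare
at three rows but the rule must be deterministic; the (A,C,−) → C case is a
pinned regression test. Concatenated per-species values are computed two
ways — concatenating the per-intron alignments, and aligning the
concatenated raw sequences — because "aligning concatenated sequences"
admits both readings; both are reported and on the synthetic data they
agree to within a couple of percentage points. Concatenation order is
lexicographic in the intron key; introns missing a species are excluded
from concatenation with a warning.

The tolerant FASTA-like reader for intron collections takes
whitespace/underscore-separated headers, recognizes species tokens
(SD/SF/SP/AQ by default), decomposes keys like `4L28` (4th intron of RPL28)
and passes unrecognized names through verbatim; U is read as T.

## snoRNA screen

The detectors implement the canonical C/D and H/ACA grammars with explicit,
deliberately non-stringent defaults (an unpublished screener
parameterization cannot be reproduced, so every threshold here is an owned,
documented choice):

* **C/D**: box C = RUGAUGA with ≤1 mismatch; box D = CUGA exact; core span
  (box C start → box D end) 40–180 nt, read as the candidate core since
  full C/D snoRNAs run ~70–200 nt; terminal stem ≥4 consecutive pairs
  (G·U allowed) with arms within 10 nt outside the boxes; guide = ≥9
  contiguous pairs (≤1 G·U) against a target, ending 0–2 nt upstream of
  box D or an internal D′ (D′ is lower-weighted by entering only through
  the same scoring); predicted methylation site = target base paired to
  the guide position 5 nt upstream of the box start ("N+5"). Candidates
  are emitted per (box C, box D) pair and scored stem + duplex − wobbles;
  with no targets supplied they are kept and flagged *orphan*.
* **H/ACA**: ACA ending exactly 3 nt before the candidate 3′ end; H box
  ANANNA in the hinge; two hairpins of ≥8 pairs each by base-pair
  maximization (tabulated Nussinov DP, minimum loop 3 — a deliberate
  structural stand-in: the screen asks "can this region pair enough",
  not for a free-energy-optimal fold); pocket guides are two 4–10-nt
  segments pairing the target antiparallel around an unpaired "UN", the 3′
  arm ending 14–16 nt upstream of the downstream box; the U is the
  predicted pseudouridine.

Guide and pocket searches are vectorized sliding-window pairing scans.
Every reported candidate is re-checkable by an independent constraint
walker (`revalidate_cd` / `revalidate_haca`), and both detectors are tested
for set-equivalence against exhaustive brute-force enumerations on
sequences ≤300 nt. Guide ranking prefers net score (length − wobbles) with
fewer wobbles on ties, so a perfect Watson–Crick duplex outranks a longer
wobbled one of equal net score.

False positives: on dinucleotide-shuffled snoRNA-rich intron background
the defaults yield roughly five chance candidate loci per kb (boxes are
short and a 9-pair duplex against ~5 kb of rRNA is not rare). This rate is
regression-tracked in the tests; the screen is a *candidate generator*
whose specificity comes from downstream evidence (library matches, target
conservation, duplication), not from the grammar alone. Shuffling
destroys every planted element; the negative control counts how often a
chance candidate in a shuffled host intron coincides with that intron's
planted guide site — typically zero, though a minimal-arm H/ACA pocket can
land on a planted U by coincidence (targets are U-rich), so an occasional
single collision across a whole bundle is background, not leakage.

Library matching and target-footprint conservation use Biopython's local
pairwise aligner (match 2, mismatch −1, open −5, extend −2); a footprint
is "conserved" at ≥90% identity over its columns (mirroring a qualitative
well/poor split), "not determined" when its ±15-nt context cannot be
located in the query. Cis-duplication compares candidate spans in adjacent
introns by global alignment identity, default threshold 70%.

## Synthetic data

The generator is the package's model of the study conditions: ortholog
families evolve along a newick species tree from an ancestral gene with
Poisson(4.0) CDS introns (echoing the measured 4.01 introns/gene), intron
lengths log-normal with median 68 nt (σ=0.7, floor 37 nt), phases drawn
0.50/0.30/0.20, intron GC targeted at 31.2% against CDS GC 44.2% (codon
weights exponentially tilted to the GC target; intron bodies from a
first-order chain whose stationary composition is adjusted for the fixed
GT/AG ends), a 5′-UTR intron probability of 0.08, and per-branch intron
loss (default 0.1) with a low gain rate (0.1/branch) at fresh
(codon, phase) positions. Exon substitutions never create stops and leave
start/stop codons fixed, so CDS lengths — and therefore site coordinates —
stay comparable; intron indels avoid snoRNA-bearing introns so planted
elements stay intact while background drifts. Planted C/D and H/ACA
snoRNAs are built to satisfy the detector grammar by construction, with
guides cut from synthetic 1.8-kb and 3.5-kb rRNA targets (low-complexity
target windows rejected so the planted register is identifiable);
cis-duplication copies a snoRNA into a neighboring intron. One master seed
is split by SeedSequence spawning, so each family is an independent,
reproducible stream; truth (ancestral sites, per-branch gain/loss events,
realized tip sites, planted elements) replays exactly.

What the generator does **not** emulate: isoforms, realistic codon
evolution (dN/dS), transposable-element sequence families, exon indels, or
rRNA divergence between species. Passing tests therefore demonstrate
correctness of the measurement machinery under controlled conditions, not
performance on real annotation noise.

The three-species intron collection used by the divergence stage
(`make_suberites_like_set`) is a synthetic stand-in: 42 orthologous intron
triples (126 sequences) from a star tree with per-species substitution
probabilities 0.20/0.20/0.36 and a small indel rate, one intron carrying a
400-nt lineage-specific insertion as the divergence outlier. Expected
per-species divergence follows from an exact trinomial enumeration of the
consensus rule, and the tests hold the pipeline to that derivation.

## Problem sizes and numerics

Test and acceptance runs use 6–200 families of 90–240 codons over 2–5
species — large enough for binomial checks at 3 standard errors, small
enough to rerun casually. Alignments are exact DP (no heuristics, no
banding); detector scans are exhaustive within their windows. Percentages
are reported to one decimal. Degenerate inputs fail loudly: empty intron
lists, all-N sequences, zero considered columns and empty table sets raise
rather than return placeholder zeros.
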