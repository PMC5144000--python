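# Methods

## The detection model

A back-splice junction (BSJ) is evidence of a circRNA: a read crossing it
splits into two exact-matching genomic segments in inverted order (the later
part of the read maps transcript-upstream of the earlier part). Two
properties make naïve calling unreliable. First, short spurious split
segments arise by chance; second, identical bases flanking both breakpoints
(microhomology) make several read partitions equally consistent with the
alignment. `backsplice` treats breakpoint placement as a model-selection
problem: among all partitions inside the microhomology window, report the one
whose implied donor/acceptor pair looks most like real splice sites, and only
if it clears an absolute evidence threshold.

### Splice-strength score

Donor sites are modelled as 9-mers (last 3 exonic + first 6 intronic bases),
acceptors as 23-mers (last 20 intronic + first 3 exonic bases), both in
transcript orientation. Each window follows a maximum-entropy distribution
subject to empirical marginal constraints; the default constraint set is all
position singletons plus all adjacent position pairs, which makes the
distribution chain-factorized. Training uses iterative proportional scaling
(IPS): each constraint's factor is multiplied by the ratio of empirical to
current model marginal until the maximum absolute marginal deviation falls
below `tol`.

Numerical choices:

- **Pseudocounts.** Marginals are smoothed by mixing the empirical
  distribution with the uniform one at a rate equivalent to 0.5 observations
  per cell of the largest constraint table. Adding 0.5 directly to each cell
  of each table would make singleton and pair marginals mutually
  inconsistent (their implied totals differ), and IPS would oscillate
  indefinitely; mixing at a single rate keeps every marginal realizable by
  one joint distribution.
- **Factored computation.** The 23-mer acceptor space (4^23 outcomes) is
  never materialized: normalizer, marginals, probabilities and samples are
  computed by transfer-matrix dynamic programming over the chain. The 9-mer
  donor table (4^9) can be enumerated, which the tests exploit to check
  normalization (sum of probabilities = 1 within 1e-6) against the chain
  normalizer — two independent computation routes. Non-adjacent pair
  constraints are supported by exhaustive enumeration for windows ≤ 10 nt
  (used by the oracle tests), not for production windows.
- **Convergence.** `tol = 1e-6` (max absolute marginal deviation),
  `max_iter = 500`; on chain models IPS converges in a few sweeps.

The score of a window is `log2(P_model / P_background)` in bits, with a
0th-order background (uniform by default, configurable). A window containing
`N` is unscorable and treated as −∞ by callers. Scoring is strand-symmetric
by construction: a minus-strand site scores exactly as the plus-strand score
of the reverse-complemented locus.

### Threshold

The default threshold of **10 bits** applies to the donor+acceptor *total*.
Per-site minima are available but default to off: thresholding the total is
the less aggressive choice, and the calibration test shows that a model
trained on half of a genome's annotated sites passes ≥95 % of the held-out
annotated donor/acceptor pairs at 10 bits. Running the same calibration on a
real genome requires its FASTA and GTF (`maxent.extract_annotated_sites` +
`maxent.calibration_fraction`); it is not part of the offline test suite. No
GT/AG dinucleotide requirement is imposed anywhere — the score alone decides,
so non-canonical sites are eligible.

### Candidate selection and arbitration

Segment pairs must each cover ≥ `min_segment` = 15 read bases, be
read-adjacent (gap ≤ 5 nt between their read intervals — a junction is a
single point in the read; pairs separated by another aligned block are
linear-splice artifacts), and the read as a whole must be ≥ 90 % aligned.
Coverage is assessed over the union of all the read's segments rather than
the pair alone, because a read wrapping around a circle shorter than itself
legitimately splits into three blocks. Same-chromosome same-strand pairs
more than 1 Mb apart are treated as fusion candidates rather than BSJs.

If the two segments overlap on the read (aligners often place microhomology
bases on both sides), the partition is normalized to the later segment's
start before arbitration. Every partition offset within ±10 nt that keeps
both flanks exact-matching is scored; ties are broken by smallest |offset|,
then leftmost genomic acceptor position, making output deterministic. A read
admitting several interpretations (multiple pairs, BSJ and fusion) is
assigned to the one explaining the most read bases, then the highest splice
strength; reads whose best interpretation is shared by distinct junctions are
dropped with a counter. All reported calls carry splice strength ≥ threshold
and circle length ≥ 100 nt (configurable).

With 15-nt minimum segments on a megabase-scale genome, a rare class of
false calls survives every filter: a chance exact 15-mer match pairing with a
genuine splice site (about 1 supporting read per ~15,000 in the benchmarks,
always at support 1). This is inherent to the anchor length; raising
`min_segment` or enabling per-site minima suppresses it at some cost in
sensitivity.

### Quantification

Each called circle's monomer (annotated exons intersected with the BSJ span
and clipped to it when a GTF is provided, otherwise the genomic span;
reverse-complemented for minus-strand calls) is doubled; the seam between the
two copies is the BSJ image. A read counts toward a circle iff it has an
exact full-length placement spanning the seam with ≥ `min_overhang` = 4 nt on
both sides — the same overhang used for independent fusion-junction read
counting — and placements at `p` and `p + L` are collapsed before counting so
doubling never double-counts. Each read (or pair, via its pair weight) is
assigned to at most one circle; reads with seam-spanning placements in more
than one circle are left unassigned and reported, never fractionally split.
The bundled realignment is exact seed-and-extend (32-nt seeds, no indels),
sufficient for error-free synthetic reads; real data should be realigned
with an external aligner through the same SAM parsing path.

## Split alignment of synthetic reads

The bundled `SplitAligner` segments error-free reads greedily: at each
unaligned read position, the longest exact genomic extension (either strand)
of a 14-nt seed becomes a segment. The seed is deliberately shorter than
`min_segment` (15), so every flank long enough to be callable is also long
enough to be seeded. Ambiguous equally-long seeds are flagged with mapping
quality 0. This aligner exists to make pipelines reproducible offline on
synthetic genomes; it does not handle mismatches or indels, and real-data
runs should use a split-read mapper (e.g. `bwa mem`), whose SAM —
primary + supplementary records, soft or hard clips, either strand — is
consumed by the same parser.

## The simulator, and what passing its tests does and does not show

`simulate.make_genome` lays multi-exon genes (default 3–6 exons of 60–200 nt,
introns 80–400 nt, both strands) on uniform-random chromosomes. Every
internal exon boundary receives a donor or acceptor window sampled from the
trained model, rejection-sampled until its own score is at least threshold
+ 2 bits, so every annotated junction is callable by construction and planted
sites are the only strong splice signals in an otherwise random background.
The synthetic consensus used to train the default model mimics the canonical
mammalian site structure (near-invariant GT/AG core, A-rich donor tail,
polypyrimidine tract).

Circles take 1–2 consecutive internal exons per eligible (≥3-exon)
transcript; 5 % of transcripts get a second distinct circle, reflecting that
multiple circles can arise from one host transcript (the fraction is a free
parameter); circles under 100 nt are discarded. Each circle and each linear transcript longer than
300 nt receives 20 error-free reads; fusion events number 10 with 10 reads
per junction. Paired-end inserts are drawn from N(200, 50) truncated to
[read length, monomer length] with up to 100 redraws before the definition is
skipped. Junction reads are placed uniformly among positions spanning the
junction with at least `min_flank` = 4 nt on each side — the quantifier's
counting overhang — so the simulated truth count is recoverable by the
counting rule: a read with 1–3 dangling bases is not informative of the
junction and would make "exact abundance recovery" unattainable by
construction. Fusion events draw internal exon ranges from two genes on
different chromosomes, each range at least as long as the read so every
fusion read crosses exactly one junction, and events duplicating an existing
junction are redrawn so the 2 × n_events true junctions are distinct.

Because reads are error-free, sites are planted well above threshold, and
the background is uniform random sequence, benchmark recall/precision here
are upper bounds: real data adds sequencing error, paralogy and repeats
(which defeat exact seed matching), expression skew, and splice sites far
weaker than the planted floor. What the tests *do* establish is the internal
correctness of the machinery: breakpoint arbitration equals exhaustive
enumeration, the trainer equals a direct convex-program solution, counting
rules conserve read weight, and the geometry conventions (strands, 0-based
half-open coordinates, breakpoints as inter-base positions) are mutually
consistent across simulator, caller and quantifier.

## Benchmark problem sizes

The fusion benchmark uses a 30-gene, 2-chromosome genome (~75 kb) with 10
events × 2 junctions × 10 reads at read lengths 50/100/150. The end-to-end
benchmark uses 500 genes on 4 chromosomes (~0.9 Mb), 200 circles and ~490
linear decoys at 20 reads each (~14,000 reads), which completes in well under
a minute. Both scale linearly in reads and genome size; the procedure is
genome-agnostic once exon models exist.

## Downstream metrics

Relative contribution is the quotient of circle abundance over host-gene
abundance; it is reported as missing (not zero) when the host has no
measured expression, since 0/0 and x/0 are not evidence of absence of bias.
The pipeline derives host-gene abundance from the linear read pool when a GTF
is provided. miRNA cleavage sites are counted by sliding each miRNA's reverse
complement over the doubled monomer restricted to start offsets 0..L−1: a
site needs ≤ 4 total mismatches and none at miRNA positions 2–8 (the standard
seed definition; configurable). Counting on the
doubled sequence finds BSJ-spanning sites exactly once — a deliberate
generalization, since a circle has no 5′/3′ ends. A `folding_energy` column
is reserved in the output schema for ingesting external secondary-structure
predictions; no folding is computed here.

## Known limitations

- The bundled aligner requires exact matches; any sequencing error in a
  segment truncates it. Real-data sensitivity is bounded by the external
  aligner's chimeric-alignment behavior.
- Reads are assigned to whole circles only; internal isoform structure
  (skipped exons, retained introns within a circle) is not deconvolved.
- Multi-mapping junction reads are dropped, not rescued; abundance is
  therefore conservative in repeat-rich loci.
- The PE path detects a junction only through merged fragments or a mate
  individually crossing it; pairs that straddle a BSJ without either mate
  crossing it contribute no call.
- Host-gene abundance for RC is a simple weighted read count over gene
  spans, not a length-normalized expression estimate; RC values are
  comparable across samples, not across genes.
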