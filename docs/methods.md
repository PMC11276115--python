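# Methods

`editscan` detects and characterizes adenosine-to-inosine (A-to-I) RNA
editing from RNA-seq of an organism that has no endogenous editing
machinery, by comparing an ADAR-expressing strain against a non-editing
control strain. Because inosine base-pairs like guanosine, an edited
adenosine appears as an A→G mismatch against the reference (or T→C when the
edited transcript is antisense to the reference strand). The package
implements the full desk-side analysis — site calling, sequence-context
(motif) analysis, codon-consequence annotation, and temperature-dependent
RNA-structure analysis — together with a ground-truth simulator that the
test suite and the acceptance script use to measure how well the pipeline
recovers what was planted.

## Site calling

Reads are cleaned by a fixed 5′ trim (the first 10 sequencing cycles are
discarded), exact duplicate-pair removal, and a 3′ trim back to the last
position where the mean Phred quality over a 10-nt window is ≥ 30; pairs are
dropped if a mate falls under 50 nt or contains an N. The pipeline consumes
coordinate-assigned SAM alignments (the simulator emits exact truth
alignments; splice-aware alignment of real reads is outside the package's
scope), so the cleaning stage contributes a QC report rather than feeding
the pileup when simulator output is analyzed.

The pileup counts, at every covered reference position, the bases with
quality ≥ 20 (spliced gaps, soft clips, insertions and deletions contribute
nothing; overlapping mates are counted independently). A variant call is
emitted for every non-reference base with at least one supporting read; its
*variance rate* is the supporting-read count divided by the quality-filtered
depth. This deliberately simple count-based caller leaves the discrimination
to four downstream criteria:

1. **Control subtraction** — any case position carrying a variant in the
   control strain is removed (position-keyed by default; an allele-keyed
   mode exists). The subtraction set is built from control variants above a
   small noise floor (alt count ≥ 2 and rate ≥ 5%, both configurable):
   a single mismatching control read is overwhelmingly a sequencing error,
   not evidence of genomic variation, and subtracting on singletons would
   remove ~1 − (1 − e)^depth ≈ 14% of all sites at 30× and e = 0.005. This
   emulates the behavior of a likelihood-based caller on the control strain
   while keeping the case side purely count-based.
2. **Depth ≥ 10** at the site (quality-filtered depth; whether the original
   tools used filtered or raw depth is not documented, filtered was chosen).
3. **Variance rate ≥ 10%**; the editing level of an accepted site *is* its
   variance rate.
4. **A→G only**, strand-resolved: A→G anywhere is reported on the + strand;
   T→C is reported as an A→G event on the − strand only when the position
   lies inside an annotated minus-strand transcript (without an antisense
   transcript the strand is undecidable and the variant is dropped). A
   position covered by genes on both strands takes the A→G interpretation
   with an ambiguity flag.

No multiple-testing correction is applied anywhere; the procedure is a
filter cascade, not a hypothesis test per site.

Site sets (e.g. two enzymes, or one enzyme at several growth temperatures)
are compared by exact key intersection (chrom, pos, strand); shared
percentages are reported as 100·|common|/|set|, rounded half away from zero
to one decimal. Editing levels at common sites are classified as
higher-in-A / higher-in-B / similar with a 10-percentage-point threshold
(a difference of exactly 10 points counts as similar).

## Sequence-context analysis

For every site a ±15-nt window on the transcript strand is extracted
(reverse-complemented for − sites, N-padded at contig edges) and stacked
into a position probability matrix: column j gives the base frequencies at
offset j−15 among non-N observations, so edge padding does not distort
probabilities. The center column is A by construction. Per-column
information content is reported as 2 − H (Shannon entropy, bits), without
small-sample correction; probabilities (not bits) are the primary output.
Matrix comparison reports each set's most probable base and per-base
probability differences position by position — no significance test, since
the question is descriptive (e.g. a 5′ preference of U > A > C > G, or a
−3 preference for U in one enzyme versus A in the other).

## Coding-consequence annotation

A site is assigned exactly one region class per transcript, reduced over
transcripts by fixed precedence:

    splicing > CDS > UTR5 > UTR3 > intronic > ncRNA > intergenic

"Splicing" is a ±2-nt window at each exon–intron junction:

    exon        intron                 exon
    ... x x | d d ... a a | x x ...
        ^^^   ^^^     ^^^   ^^^        all eight positions are "splicing"

i.e. the first and last two intronic nucleotides plus the terminal two
exonic nucleotides on either side of the junction.

For CDS sites the spliced CDS is assembled on the coding strand, the A→G
substitution applied at the in-codon offset, and both codons translated
with the standard genetic code. Classes: synonymous, nonsynonymous,
start-loss (initiator ATG→GTG), stop-loss (terminal TAG/TGA→TGG; TAA→TGA
remains a stop and is synonymous). CDSs whose length is not a multiple of 3
are flagged and skipped rather than guessed at. Recoding events are scored
two ways: amino-acid polarity (default categories — nonpolar G A V L I P F
M W; polar-uncharged S T C Y N Q; basic K R H; acidic D E; the table is
replaceable since polarity schemes vary between sources), with "Same"
meaning both residues share a category and stop-involving changes "NA";
and the BLOSUM80 matrix in its standard half-bit integer scaling (loaded
from Biopython, symmetry and positive diagonal asserted), where a positive
entry marks a substitution common among evolutionarily related proteins.
The set of amino-acid substitutions reachable by editing one A per codon is
enumerated exhaustively from the genetic code and used as a closure check
on observed spectra; the enumeration is reported, not forced to match any
particular observed count.

## RNA structure versus temperature

Editing requires a double-stranded substrate, and duplex stability depends
on growth temperature. For each site a 201-nt window (100 nt each side,
truncated and flagged at contig edges) is folded at 20, 30 and 35 °C with a
self-contained minimum-free-energy folder:

- Zuker-style dynamic programming over hairpins, stacks, bulges, internal
  loops (≤ 30 nt, tabulated penalties with linear interpolation and
  logarithmic extrapolation) and multibranch loops (linear penalty
  a + b·branches), minimum hairpin loop 3, O(n³) with numba compilation
  when available.
- Stacking free energies are ΔG(T) = ΔH − T·ΔS with the published
  Watson–Crick nearest-neighbor enthalpies and entropies (Xia et al. 1998);
  since every stack has ΔH < 0 and ΔS < 0 and the loop penalties are
  temperature-independent constants, every structure's energy — and hence
  the MFE — increases monotonically with temperature, the property the
  comparative analysis rests on.
- G·U wobble pairs are excluded by default (the `--noGU` convention);
  enabling them uses coarse uniform wobble-stack parameters and is intended
  for sensitivity checks only.
- The loop tables are lightly smoothed to be non-decreasing in loop size
  (the raw published tables are not monotone), which is what the model's
  stated invariants assume.
- Deliberately **not** modeled: dangling ends, coaxial stacking,
  sequence-dependent loop terms, special hairpins. Absolute kcal/mol values
  are therefore not comparable with full-parameter folders such as RNAfold;
  distribution *shifts* across temperature are the supported readout.
- Traceback is deterministic: unpaired is preferred, then the 5′-most
  pairing; re-scoring the traceback structure by explicit loop
  decomposition reproduces the DP energy to 1e-6.

MFE distributions between groups are compared with a two-sided
Mann–Whitney U test: exact when min(n, m) ≤ 8 and the data are tie-free,
tie-corrected normal approximation otherwise (via scipy).

Expression is quantified as TPM with effective length equal to the mature
transcript length (no fragment-length correction — the package's use of TPM
is relative comparison). Reads are assigned to the transcript whose exons
contain their leftmost aligned block; ambiguous assignments split equally.

## The synthetic experiment

The simulator generates the conditions the analysis assumes, with full
ground truth:

- **Genome/genes**: 2 chromosomes × 40 kb, 40 genes tiling without overlap,
  half on the minus strand, ~10% ncRNA; coding genes have a 40–150 nt
  5′ UTR, 100–400 codons (ATG, sense codons, one stop), an 80–250 nt
  3′ UTR, and Poisson(0.8) introns (60–200 nt, GT..AG). All coordinates are
  exact by construction, so truth alignments need no aligner.
- **Editing sites**: 200 adenosines in mature transcripts, sampled without
  replacement with probability ∝ w5(−1 base) × w3(+1 base), defaults
  w5 = {U 0.6, A 0.2, C 0.15, G 0.05} and w3 = {G 0.5, C 0.2, A 0.2,
  U 0.1} — the classical 5′ U > A > C > G preference and 3′ G bias. True
  levels are Beta(2, 2) truncated at 0.05, so the set straddles the 10%
  call threshold and sub-threshold sites exist by design. Sites are planted
  in mature-transcript space only: reads are drawn from mature transcripts,
  so an intronic site would be unobservable by construction (intronic and
  intron-side splicing classes are exercised by unit tests instead).
  Weighted sampling without replacement makes inclusion probabilities
  slightly less skewed than the weights themselves (a few percent relative
  at these sizes); recovery checks use a 3σ multinomial band.
- **Reads**: 150 bp paired-end, fragments 250–400 nt; fragment placement
  may overhang the transcript ends (clipped, never below one read length),
  mirroring the fact that fragmentation yields the terminal pieces of each
  molecule — this keeps coverage near-uniform along the transcript.
  Editing is applied per read as Bernoulli(true level), independent across
  reads, matching the binomial sampling model behind the level estimator;
  uniform substitution errors at 0.005; constant Q37 base qualities.
- **Expression**: per-transcript relative abundance is log-normal(σ = 0.5)
  (~7-fold middle-95% spread), normalized so the mean transcript depth is
  `mean_depth` (default 30×). The spread creates depth heterogeneity around
  the depth-10 filter while keeping ~97% of transcripts above it; a wider
  (e.g. 100-fold) spread would put almost half the transcriptome below the
  filter and make recovery of uniformly-planted sites impossible at this
  depth. Both strains share the expression profile and a set of 30
  homozygous SNPs injected into the *reads* of both strains (never the
  reference), so control subtraction — not alignment — is what removes
  them; SNP positions are excluded from editing-site planting.
- Everything is deterministic given the config: all randomness flows from
  `numpy.random.default_rng([seed, salt])` streams.

What the simulator does **not** emulate — quality-dependent or indel error
profiles, PCR duplicates, fragment-size biases, repeat elements,
hyper-editing clusters, partially spliced pre-mRNA — bounds what passing
tests show about real data: they validate the analysis logic and its
statistical behavior under the stated model, not robustness to artifacts
the model excludes.

Recovery is scored by matching called sites to truth on (chrom, pos,
strand): precision over all called sites, recall over truth sites at or
above a level threshold (0.2 in the headline check), RMSE of called versus
true levels over matches, plus an exhaustive audit that attributes every
miss to low depth, sub-threshold observed rate, or a control collision.
At the default conditions the pipeline recovers ≥ 90% of sites with true
level ≥ 0.2 at ≥ 95% precision with level RMSE ≈ 0.09 — consistent with
pure binomial sampling noise at 30× depth.

## Numerical and design choices

- Internal coordinates are 0-based half-open everywhere; every file format
  boundary (SAM, GFF3, VCF, site TSVs) converts to/from 1-based exactly
  once, in `seqio`.
- Only CIGAR ops M, I, D, N, S are accepted; anything else is an error.
- Reference N bases are never counted as matches nor called as variants.
- The GFF3 dialect requires ID/Parent attributes with gene → mRNA|ncRNA →
  exon/CDS structure; gene_id falls back to the transcript ID.
- Variance-rate denominators use quality-filtered depth (the alternative —
  raw depth — is not what a pileup with a quality cutoff naturally yields).
- Percentages intended for reporting round half away from zero.
- Folding problem sizes: windows are 201 nt; the oracle suite enumerates
  all structures exhaustively up to length 14, where enumeration is exact
  and cheap; the pipeline folds up to 200 sites per run at three
  temperatures.

## Known limitations

- The folder's absolute energies are a simplified model (see above).
- The count-based caller admits a single mismatching read at exactly depth
  10 as a rate-0.10 variant; with depth ≥ 10 and rate ≥ 0.10 as stated
  thresholds this is the faithful behavior, and it bounds precision on
  error-containing data (~97% at default conditions).
- T→C strand collapse depends entirely on the annotation; unannotated
  antisense transcription is invisible.
- TPM uses transcript length, not effective fragment-corrected length.
- The preprocessing stage's fixed 5′ trim is not idempotent by nature
  (re-running it trims again); the quality/duplicate stages are.
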