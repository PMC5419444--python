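# Methods

This note documents the models and procedures implemented in `umicall`,
the parameters that matter, the numerical conventions, and what the
bundled simulator does and does not emulate.

## UMI extraction

Primer/adapter patterns are strings over IUPAC codes in which `N` marks a
UMI position. Matching is substitution-only (no indels), because an indel
inside the pattern would shift the UMI positions and make the extracted
barcode ambiguous. The mismatch tolerance defaults to 2 and is
configurable (`max_primer_mismatches`); there is no canonical value for
this tolerance, so it is exposed rather than fixed. Patterns given in
reverse orientation are canonicalised to their reverse complement at parse
time, and every pattern is tried against both the read and its reverse
complement, which makes extraction strand-consistent by construction. A
read matching patterns of two different samples equally well is rejected
as ambiguous rather than assigned arbitrarily.

UMIs with minimum base quality strictly below Phred 20 are discarded; a
UMI exactly at the threshold is kept. For read pairs, the UMI comes from
whichever mate carries an N-bearing pattern; if both do, the two UMIs are
concatenated in first-mate-then-second order.

## MIG formation and collision correction

Reads sharing a (sample, UMI) pair form a molecular identifier group
(MIG). Sequencing errors inside the UMI create spurious satellite MIGs: a
MIG whose UMI is 1 substitution from a ≥20-fold larger MIG (2
substitutions, ≥400-fold) is considered erroneously tagged and discarded.
Raw (pre-threshold) sizes are compared. The discarded MIG's reads are
dropped by default — merging them into the parent is available behind
`merge=True` but off, since dropping is the conservative reading and MIG
sizes are not otherwise used quantitatively. Candidate pairs are found by
two-wildcard key hashing (linear in MIG count), processed
largest-parent-first with lexicographic tie-breaks; a discarded MIG can
never absorb others. This makes the surviving set independent of input
order.

### Size threshold

Unique UMIs are dominated by tiny erroneous MIGs, but reads concentrate
in a clear peak, so the threshold is derived from the read-weighted
histogram of log2 MIG size (bin width 0.2; the mode is the center of the
highest-weight bin, first bin on ties). The threshold is the square root
of the peak size — half the log-peak — with base-2 logs so that the
"half the log peak" rule is exactly a square root, floored at 5 reads.
Five reads suffice to remove nearly all sequencing errors (see the
dominance bound below).

## Consensus assembly

Within a MIG, each read is anchored by the MIG's core: the most frequent
30-base window among windows taken at offsets −5..+5 around each read's
centre (ties broken lexicographically). Anchoring uses the best
approximate occurrence of the core in each read (minimum Hamming
distance over all offsets, earliest offset on ties); a read whose best
offset still has more than `core_len/6` (= 5) mismatches has no reliable
placement — typically an indel or chimera — and is dropped. Exact-match
anchoring was rejected because it would discard any read with a single
sequencing error inside the core window.

Columns are called by majority vote; ties break by summed Phred quality,
then alphabetical base order, so output is deterministic. A read with
more than 2 consecutive mismatches against the first-pass majority (3
under the `torrent` preset, whose rejects are additionally routed to
Smith-Waterman re-alignment and flagged) carries an indel signature and
is dropped; the consensus is then recomputed from the survivors. Ragged
edge columns covered by fewer than half the surviving reads are trimmed.
If fewer than the size threshold of reads survive, the MIG is rejected.
Paired-end MIGs are assembled as two sub-consensuses, one per mate;
overlap merging is not attempted.

The consensus quality score maps the dominant-base fraction
f ∈ [0.25, 1] linearly onto [0, 40]:

    CQS = (40/3) · (4f − 1)

Minor variants — read bases disagreeing with the consensus at quality ≥
Q_minor (default 30 for short high-quality reads, 20 recommended for
longer lower-quality runs) and within-MIG frequency > 10^(−Q_minor/10) —
are tallied per (position, from, to) and pooled per substitution class,
together with per-base observation totals, for error-rate estimation.

### Sequencing-error dominance bound

With per-base error rate p and MIG size m, a sequencing error reaches the
consensus only if a strict majority of reads share the same erroneous
base: P = Σ_{j≥⌈(m+1)/2⌉} C(m,j) p^j (1−p)^{m−j}. At p = 0.01 (Phred 20)
and m = 5 this is 9.85×10⁻⁶ ≈ 10⁻⁵ — consensus-level errors are therefore
attributed to PCR, not sequencing, which motivates the error model below.

## Alignment

Targeted panels have few references, so alignment is two-staged. The
K-mer index covers both strands of every reference; f_k is the frequency
of a K-mer among all K-mer instances in the database (Σ f_k = 1 over
distinct K-mers). A query's score against a reference is
I = Σ −f_k ln f_k over the *distinct* shared K-mers — counting
multiplicity would let a repeat inside one reference dominate the score.
Natural logs are used; only differences matter, and the choice fixes the
MAPQ scale. MAPQ = 10·(I_best − I_next), with I_next = 0 when only one
reference exists; ties give MAPQ 0. Default k = 11: long enough to be
specific at exon scale, short enough to tolerate consensus errors.

Smith-Waterman uses match +1, mismatch −3, gap open −6, gap extend −1,
affine convention "open + extend per gap base" (a length-g gap costs
6 + g). Traceback is deterministic: the end cell is the maximum-score
cell with smallest reference then query coordinate; on ties, diagonal is
preferred over gap-in-reference over gap-in-query. Alignments with
substitution-only identity < 90% (matches over non-gap columns) or query
span < 70% are discarded; boundary values pass. SAM output is 1-based
with soft-clipped flanks, MAPQ capped at 254, and UM/MS tags carrying the
UMI and MIG size. BED input is 0-based half-open; a consensus's genomic
position is the reference's BED start plus the local offset.

## Error model and variant calling

Twelve directed substitutions collapse into six strand-symmetric classes
(A>C/T>G, A>G/T>C, A>T/T>A, C>A/G>T, C>G/G>C, C>T/G>A). Per class, the
per-position error rate is ε ~ Beta(α, β), hence an observed count at
coverage N is BetaBinomial(N, α, β), and a candidate variant with n
supporting consensuses scores

    Q = −10·log10 P(X ≥ n),  capped at 100 (P = 10⁻¹⁰).

The inclusive tail makes the P-value superuniform, so the Q ≥ 20
threshold admits at most 1% of null positions by construction; the
calibration benchmark confirms ≤ 2% empirically. The tail is evaluated by
chunked log-space pmf summation, which stays meaningful far below where
the plain survival function underflows (the enumeration benchmark agrees
to < 10⁻¹⁴ for N ≤ 12).

Fitting uses the method of moments (α = m(m(1−m)/v − 1), etc.) on pooled
per-position frequencies, zeros included; an MLE refinement is available.
Variance at or beyond Bernoulli variance m(1−m) means the data are more
dispersed than any Beta and fitting errors out with advice to pool.

The shipped default (α, β) per class are placeholders chosen only to
reproduce the qualitative polymerase spectrum — C>T/G>A and A>G/T>C
transitions orders of magnitude above transversions (means 10⁻⁴ and
4×10⁻⁵ versus ~10⁻⁶, shapes α ∈ {1, 2} for realistic overdispersion).
They are labelled `default` in provenance and should be refit with
`fit_beta` on a known-template UMI dataset for production use.

### Ligation (first-cycle) adjustment

When the UMI is attached by ligation, the tagging step itself introduces
no PCR errors; the earliest heritable errors occur in the first PCR
cycle. A ligation-tagged molecule contributes two template strands under
one UMI. In cycle 1 the expected number of new (error-eligible) strands
is λ = efficiency − 1 against an expected pool of 2(1+λ) strands, and
both the first-cycle-copy lineage and the rest grow by (1+λ) per later
cycle, so the expected share of the final pool descended from a
first-cycle copy is

    g(λ) = λ / (2(1+λ))

at every cycle count. Since a consensus reports an error in proportion to
the error lineage's share of the sampled pool, class error rates are
scaled by g: β := β/g with α unchanged (scaling the mean α/(α+β) ≈ α/β by
g in the rare-error regime). At the typical efficiency 1.8, g = 0.222 —
a ~4.5-fold rate reduction. The factor is validated by a Monte-Carlo
Galton-Watson oracle (`simdata.first_cycle_error_share`): the
ratio-of-means estimator Σ(mutant strands)/Σ(total strands) over 10⁵
replicate pools matches g(λ) within Monte-Carlo error, and exactly in
expectation. Note the factor is *not* the probability that the error
lineage is a strict pool majority — that quantity is λ/2 for a
single-template two-lineage process and has the wrong limit (0) at λ = 1
— but the expected pool share, which is the quantity that scales observed
consensus error rates. Applying the adjustment twice is guarded against.

### Pileup and calls

Coverage counts consensuses covering a position with M/X/= CIGAR
operations; deleted-over positions are not covered. One UMI contributes
at most one observation per position (interval bookkeeping guards paired
sub-consensuses). Multi-allelic sites emit one record per alt. Indels are
left-normalized with a one-base anchor and flagged NO_QUAL — no indel
quality model is provided, and indel calls should be screened by raising
the MIG size threshold instead. No matched normal is consulted and no
multiple-testing correction is applied; Q scores are raw, as documented
in the VCF header. A rank-based empirical P per class (upper tail) is
attached as a diagnostic, and a shared-UMI co-occurrence table is
emitted for variant pairs without any phasing test.

An optional minor-based estimator infers per-class error rates as pooled
minor count over per-class base observations, flagged low-confidence
below 10 mean reads per MIG or 1000 molecules.

## Synthetic data generator

`simdata` emulates: per-locus template molecules carrying configured
variants (independent Bernoulli per molecule), distinct random UMIs,
branching-process PCR (each molecule duplicates per cycle with
probability efficiency − 1; each duplication acquires at most one
substitution error with probability 1 − (1−rate)^L — multi-error copies
are second-order and neglected — with full lineage tracking in memory
linear in error events), and reads sampled per molecule with a log-normal
MIG-size distribution (median 10, σ = 0.5 — a right-skewed distribution
whose read-weighted log histogram shows the clear peak the size threshold
relies on) plus flat-Phred sequencing errors over the whole read
including the UMI. Defaults: 12-base UMIs, 20 PCR cycles at efficiency
1.8, PCR error rate 10⁻⁵/base/duplication (high-fidelity polymerase
scale), 140-base reads at Phred 30 over a built-in panel of three
synthetic 200-base references whose first 20 bases serve as locus
primers.

Not emulated: polymerase context effects, chimeras/primer dimers,
quality decay along the read, flow-space homopolymer errors, and strand
asymmetries. Passing end-to-end tests therefore demonstrates correctness
of the pipeline's bookkeeping and statistics under the model's own
generative assumptions, not robustness to every artefact of real
instruments.

## Benchmark problem sizes

The end-to-end benchmark uses 30,000 molecules (10,000 per locus, three
loci) with variants at 0.1/1/5%, ~340,000 reads — large enough that the
0.1% variant is represented by ~10 molecules and recovery within 3
binomial standard errors is meaningful. Oracle checks use 500 random
pairs (alignment), a 4×4×12 parameter grid (Beta-Binomial), and 10⁵
Galton-Watson replicates (propagation factor). The ROC benchmark draws
800 null and 800 signal trials per class at coverages 2,000–10,000.

## Known limitations

- Substitutions only in the error model; indels are reported unscored.
- The consensus drops indel-bearing reads rather than realigning them
  (except for flagging under the `torrent` preset), so true indels at low
  MIG counts can be under-represented.
- Default Beta parameters are illustrative placeholders, not fits.
- Reference selection assumes a targeted panel; it is not a genome-scale
  aligner and offers no split/chimeric alignments.
- The duplex double-strand consensus pairing step of duplex sequencing is
  out of scope; only single-strand consensuses are produced.
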