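# Methods

## Coordinate conventions

All internal intervals are 0-based half-open (`[start, end)`, BED
arithmetic). SNPs are stored as 1-based points and converted exactly once,
at overlap time, by the single rule

    snp overlaps interval  <=>  start <= pos - 1 < end.

GTF (1-based inclusive) and SNP tables are converted at the I/O boundary;
nothing downstream performs coordinate arithmetic on external conventions.
Chromosome names are canonically `chr`-prefixed with a normalization switch
for un-prefixed sources.

## Variant sets

A trait's variant set is its GWAS lead SNPs plus LD proxies with
r² ≥ `r2_min` (default 0.8, **inclusive**: a proxy at exactly 0.80 is kept).
A proxy reachable from two leads is stored once, attributed to the higher-r²
lead, ties broken by lexicographically smaller lead rsid so output is
deterministic. Lowering `r2_min` can only grow a set (monotonicity), and
re-expanding the same leads with the same table is idempotent; both are
property-tested.

## Differential m6A peaks

A peak is an *increased* DMP when its BH-adjusted p < α (default 0.05,
strict) **and** log2 fold-change > 0, *decreased* with the opposite sign.
Adjusted p-values missing from the input are recomputed by BH over all rows
of the table. Peaks significant with log2FC exactly 0 remain unclassified
and are logged. A raw-p mode (`use_adjusted=False`) applies the same α to
unadjusted p-values; the adjusted mode is the default because it is the
stricter of the two conventions in circulation for exomePeak-style output.

## Metagene profile

Each peak is represented by its interval midpoint. The midpoint is assigned
to the coding transcript whose exon union contains it; among multiple
candidates the longest CDS wins, then the longest transcript, then the
lexicographically smallest id — deterministic and in line with common
metagene practice. The midpoint's transcript coordinate is scaled within its
segment and offset by segment index: 5′UTR → [0, 1), CDS → [1, 2),
3′UTR → [2, 3). Peaks hitting no transcript, only introns, or only
noncoding transcripts count as unmapped. The histogram is density-normalized
(`∫ density = 1` whenever ≥ 1 peak maps), so total mass is invariant to bin
refinement. Midpoints rather than coverage summits are used because summits
require coverage tracks the pipeline does not consume.

## DRACH scanning

The DRACH consensus (D = A/G/U, R = A/G, H = A/C/U) is scanned in DNA space
as the regex `[AGT][AG]AC[ACT]` over the strand-aware peak sequence
(reverse-complemented for minus-strand peaks). A peak counts if it contains
≥ 1 match; matches straddling the peak boundary do not count, since only the
within-peak sequence is scanned.

## VSEA

Observed statistic: the number of **distinct** SNPs of the set inside the
region set (a SNP in two regions counts once — the statistic is a frequency
of SNPs, not of pairs). Null model: each permutation redraws every region
with its original length on its original chromosome, start uniform on
`[0, chrom_len − len]`; regions may overlap each other. This is the
least-assuming random-region null that still controls for region size and
per-chromosome region load. The permutation p uses the add-one estimator
`(1 + b) / (1 + n)` so it is never zero. The enrichment score is the
permutation z-score; a fold change `(obs+1)/(null_mean+1)` is reported
alongside. Degenerate cases: an empty region set yields observed 0,
p = 1, and a `degenerate` flag; a zero null sd yields score 0 when
observed equals the null mean, otherwise a max-finite sentinel with an
`es_capped` flag instead of ±inf. BH adjustment spans all trait × direction
tests of a batch jointly.

The null template is put in canonical coordinate order before sampling, so
the p-value is invariant to how the caller ordered SNPs or regions. Each
permutation consumes its own RNG substream spawned from the caller's
generator; results are therefore independent of how permutations are
scheduled across threads, and bitwise reproducible for a fixed seed.

### Known small-genome bias

Because null regions may overlap each other while observed peak sets are
(near-)disjoint, each permutation's union coverage falls short of the
template total by roughly Σwᵢ²/2L per chromosome. On a real genome
(DMPs ≪ 0.1% of 3 Gb) this is negligible; on a very peak-dense toy genome
it produces a small anti-conservative mean shift. The synthetic defaults
below keep increased-DMP coverage near 2.5% of the toy genome, where the
shift is far below one null standard deviation; calibration at these
conditions is verified by test.

## Subset permutation tests

Given a subset of SNPs (those overlapping DMPs) within a full trait set,
the test draws `n_iter` (default 100,000 for both the chromosome and the
annotation test) equal-size subsets uniformly without replacement and
compares per-category counts one-sided (enrichment; a depletion mode
exists). The per-category null count under such sampling is exactly
multivariate hypergeometric, so draws are generated directly from that
distribution — identical in law to drawing SNPs and tabulating labels, and
fast at 10⁵ iterations. The closed-form hypergeometric upper tail
(`hypergeom_tail`, evaluated through scipy's log-space-stable survival
function) is the exact oracle the permutation p converges to; agreement
within Monte-Carlo error is part of the acceptance suite. BH adjustment
spans all categories present in the full set.

## Genomic-context annotation

Categories: promoter (TSS −1000/+100 bp, strand-aware), TTS (transcription
end ± 1000 bp), exonic, intronic, intergenic; windows configurable and
recorded in output headers. Fixed precedence promoter > TTS > exonic >
intronic > intergenic over all transcripts touching the SNP — regulatory
windows outrank exonic because they are rarer and more specific; the order
is configurable. Host gene = gene of the transcript granting the winning
category, ties broken by lexicographic gene id. Every SNP receives exactly
one category; `intergenic` iff no host gene.

## Candidate-gene triage

DEG thresholds: padj < 0.05 **and** |log2FC| > 0.58, both strict — a gene at
exactly 0.58 is excluded; records lacking padj are excluded and logged.
Splicing: events with FDR < 0.05 (strict), grouped by gene and event type
(SE, RI, A5SS, A3SS, MXE); all significant event types per gene are
reported without reconciliation. QTL rows are taken as authoritative for
their own target gene (a target absent from the annotation is kept with a
warning); rows whose rsid is not among the overlapping SNPs are ignored.
Candidates are sorted by (number of QTL types, number of supporting SNPs,
gene id).

## Synthetic-study generator

The generator emulates the *shape and statistical structure* of the
pipeline's inputs: a toy multi-chromosome genome, non-overlapping
transcript models with 5′UTR/CDS/3′UTR structure (~15%/50%/35% of exonic
length), non-overlapping exonic m6A peaks with log-normal lengths (median
200 bp, clipped to [50, 2000] — typical m6A-seq peak widths), planted DMP
directions, per-trait lead SNPs with LD blocks, and DEG/splicing/QTL tables
with planted candidate genes. Every planted fact is written to a truth
record whose counts are recoverable from the emitted files.

Key defaults and why:

| parameter | default | rationale |
|---|---|---|
| `n_chroms` × `chrom_length` | 4 × 500 kb | large enough that increased DMPs cover ~2.5% of the genome (see bias note) yet hundreds of replicate studies run in seconds |
| `n_transcripts` | 500 | fills ~60% of the genome with gene territory, leaving real intergenic space for annotation tests |
| `n_peaks` | 900 | ~25% occupancy of exonic space; placement never fails |
| `frac_dmp_increased` / `frac_dmp_decreased` | 0.30 / 0.15 | hypermethylation-skewed, as in tumor m6A comparisons |
| `n_lead_snps` | 350 | with ~1.6 passing proxies per lead, expected in-DMP overlap ≈ 20–25 — enough count resolution for a well-mixed permutation null |
| `ld_block_size_mean` | 4 proxies/lead | proxies placed ± 50 kb with r² ~ U(0.5, 1), so the r² ≥ 0.8 filter has passers and failers |
| `planted_enrichment` | 1 (null) | a lead falls in an increased DMP with probability min(1, e·D/L); at e = 1 placement is exactly uniform over the genome (when `chrom_skew` is unset — the skew applies to the background branch) |
| `drach_plant_prob` | 0.7 | non-planted peaks are scrubbed of DRACH matches, so the observed fraction estimates the plant probability directly |
| `n_traits` | 2 | one planted trait plus a matched null trait for batch-ranking checks |

Randomness: one master seed spawns a named substream per component
(genome, transcripts, peaks, drach, snps, ld, deg, splice, qtl), so e.g.
changing only `planted_enrichment` leaves the genome and GTF byte-identical.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: read-level noise and peak-calling uncertainty
(peaks are exact intervals with planted p-values), realistic LD structure
from population panels (proxies are uniform in a window, r² is not derived
from genotypes), isoform complexity (one transcript per gene), inter-gene
regulatory structure, and genome-scale base composition. Calibration and
power results transfer to real data only to the extent that the
random-region null is an adequate model of real peak placement.

## Problem sizes used in the checks

The statistical suite uses 500 random instances for the overlap oracle,
200 simulated studies (n_perm = 1,000) for null calibration against the
exact binomial 99% band at α = 0.05, 100 studies for planted-enrichment
ranking power, 50 random instances at n_iter = 100,000 for
permutation-vs-hypergeometric agreement, 1,000 random vectors for BH
reference equivalence, and 1,000 peaks for DRACH recovery.
`scripts/acceptance.py` reports the same machinery at 100/30 studies —
sizes chosen as a deliberate compromise between Monte-Carlo resolution and
a test suite that completes in minutes on one core.

## Known limitations

- The VSEA null is length- and chromosome-matched but not
  annotation-matched by default; an expressed-region-restricted null is a
  natural sensitivity analysis (the sampler accepts any template) but
  genome-wide placement is the default.
- SNP-in-peak containment is pointwise; indels or proxy windows are not
  modeled.
- The union-coverage bias of overlapping null regions (above) grows with
  regionset density; interpret enrichment on small custom genomes
  accordingly.
- Permutation p-values are floored at 1/(n_perm + 1); claims below that
  resolution require more permutations.
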