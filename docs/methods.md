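# Methods

## The problem

Transposable elements (TEs) and endogenous/exogenous retroviruses create
structural polymorphisms that short-read pipelines routinely miss: a read
that spans the junction between host DNA and an inserted element (a
*chimeric* read) maps poorly or not at all, and the insertion itself may be
present in the sample but absent from the reference (non-reference, "novel"),
or present in the reference but absent from the sample (a polymorphic
reference integration). `tescreen` detects both situations from the chimeric
reads alone, so it works on single-end data, long-fragment libraries and
target-enrichment experiments as well as ordinary paired-end WGS.

## Pipeline model

1. **Baits.** From a TE/virus reference (for retroviruses, typically the
   LTR) the first and last *L* bases and their reverse complements form four
   probes. A junction read must contain one of these edges, whichever strand
   and junction side it comes from.
2. **Screening.** Every read is compared against the four baits. A read is
   chimeric when some placement aligns at least `min_match_len` bait bases at
   `min_identity` or better, where identity is counted over aligned *bait*
   positions (matches / bait span). With the 20-bp / 0.90 parameterisation
   used for degraded elements such as HERV-K HML-2, this admits up to two
   mismatches in a full-length bait match.
3. **Trimming.** The TE-matching portion and everything TE-ward of it are
   removed; the host flank (if at least `min_trimmed_len` bases) is kept
   with its qualities, along with the removed TE portion and, for paired
   input, the read's mate.
4. **Remapping.** Host flanks are remapped to the host reference either
   single-end or together with their mates ("guided"), where a uniquely
   mapping mate can rescue a flank that is ambiguous on its own.
5. **Calling.** Remapped flanks are chained into clusters; annotated loci
   are marked present on a single read of evidence, absent at zero support;
   clusters of at least five reads away from annotated TE/SVA intervals
   become novel candidates.

## Detection details and numerical choices

**Alignment routes.** Each read/bait pair is evaluated by two routes and the
best *passing* placement wins:

* optimal Smith–Waterman local alignment with match +2, mismatch −3, linear
  gap −4 (tolerates indels between read and bait);
* an exhaustive ungapped scan of the bait across every offset, with partial
  bait overhang permitted only at the read boundaries (a junction near a
  read end leaves only part of the bait on the read).

The second route exists because an *optimal* local alignment always trims a
mismatched terminal position: a 20-bp bait copy with substitutions at its
outermost bases would otherwise shrink to an 18-bp span and fail a 20-bp
`min_match_len`, even though it carries only two mismatches. The ungapped
scan restores exactly the "20-bp match at 90 % = up to two mismatches"
arithmetic. Under this scoring a full-length 20-bp match at the 0.90 floor
scores ≥ 18·2 − 2·3 = 30.

**Tie-breaking.** Everything is deterministic: among equal-scoring local
alignments the smallest read start wins, then the smallest bait start, then
the smallest end coordinates; across baits the fixed order (5′ forward,
5′ reverse-complement, 3′ forward, 3′ reverse-complement); across routes the
gapped alignment before the scan. Identical inputs and parameters give
byte-identical outputs.

**Side of the junction.** An edge bait implies which side of the match is
element interior: for the 5′-forward and 3′-reverse-complement baits the TE
body extends rightward, so the host flank is the read prefix left of the
match; for the other two baits it is the suffix right of the match. The
flank is always taken from the designated host side — the opposite side of
the match is element interior by construction and is never retained, even
when it is the longer side. Flank plus TE portion reassemble the whole read.

**N handling.** Bases are upper-cased on ingest; `N` never matches anything
(including another `N`) in any comparison.

**k-mer prefilter.** Before alignment, reads can be gated on sharing an
exact k-mer with some bait, with `k = floor(min_match_len /
(max_mismatches + 1))` and `max_mismatches = floor(min_match_len × (1 −
min_identity))`. By pigeonhole this never rejects a read containing an
in-budget substitution-only bait copy; the guarantee does not extend to
gapped matches, but a junction read carries a contiguous element segment, so
a gapped-but-passing copy without any shared k-mer requires several errors
inside one 20-bp window. In `auto` mode the gate is active when k ≥ 4
(shorter seeds pass almost every read and save nothing); `off` sends every
read to the aligner. The gate is derived, never user-set.

**CIGAR gate for mapped input.** When screening an already-mapped library
for novel integrations, only records whose CIGAR match fraction (bases under
M or `=` over the query-consuming length; hard clips excluded, `X` counted
in the denominator) is below 1.0 — plus unmapped records and mapped records
with an undefined CIGAR — are searched; reads supporting reference
integrations map perfectly, so the gate is bypassed when annotating
presence/absence.

## The test-scale mapper

The built-in mapper exists so the pipeline and its tests need no external
aligner; SAM from any aligner can be substituted. Candidate loci come from
exact 17-mer seeds (both read strands; a seed hitting more than 200 loci is
skipped as repetitive) and are scored by gapless end-to-end comparison under
the same +2/−3 scheme, requiring 90 % identity; the paired mode demands
opposite orientations and a fragment length in [100, 700] bp (the fragment
model is 350 ± 50). Gapless extension is sufficient here because the read
model is substitution-only and the paired mode is end-to-end with no
clipping; the mapper makes no claim of production accuracy. MAPQ is a
binary surrogate — 60 when the best placement strictly beats the runner-up,
0 otherwise — because downstream only the uniqueness distinction is used. A
guided pair placement is unique when all top-scoring placements agree on the
read's position; without any compatible placement both reads fall back to
their single-end results.

## Calling

Clustering is single-linkage chaining: consecutive position-sorted reads
join one cluster while their starts are within `cluster_gap` (default
10 kb, inclusive). For well-separated integrations this coincides with a
fixed-window reading; chaining is the deterministic choice. Cluster-to-
annotation distance is the minimum gap between intervals (0 when
overlapping), and "within 1,000 bp" excludes inclusively (a gap of exactly
1,000 excludes; 1,001 does not). Known-locus support counts reads whose
alignment lies within `known_window` (default 100 bp, inclusive) of either
annotated edge. Absence is declared purely from zero junction support; no
coverage model distinguishes "absent" from "no data" — a locus with no
coverage at all is also reported absent, a known limitation. Non-unique
(MAPQ 0) reads never support calls; guided rescue makes a read usable by
making its pair placement unique. Excluded clusters are written to an
exclusions table with their reason (`sva_overlap` for clusters overlapping
an SVA interval, `near_known_element` for proximity), never silently
dropped.

Truth-set evaluation (simulations) matches calls to simulated sites
nearest-first, each call to at most one site, requiring a call edge within
100 bp of the site; unmatched calls are false positives.

## The simulator

The generator emulates whole-genome resequencing of an insertion-carrying
haplotype: a uniform-random A/C/G/T host contig (a desk-scale stand-in for a
human chromosome), full-length element or solo-LTR insertions with a 5-bp
target-site duplication (the integration machinery's footprint; the
detection code never depends on it), and paired 2×100-bp reads at the
requested coverage with fragment length Normal(350, 50) truncated below one
read length, uniform fragment starts, strand flips with probability 1/2,
and independent per-base substitution errors at 0.002 that are *silent*
(qualities are constant "I"; the detection algorithm never reads
qualities). The pair count is `ceil(coverage × genome / (2 ×
read_length))`. Indel sequencing errors and sequencer-specific quality
decay are out of scope; at these error rates substitutions dominate.

Insertion sites are kept at least 25 kb apart (and never closer than twice
the fragment mean). The emulated designs scatter 10–20 insertions over a
whole chromosome, where two sites within the 10-kb clustering range
essentially never occur; on a 1-Mb host that sparsity must be imposed, or
merged clusters would misrepresent the method rather than the data.

What passing simulations do **not** show: recovery inside real repeat
landscapes. A uniform-random host has no segmental duplications or repeat
families, so ambiguity is rare and guided detection usually ties single-end
detection; the guided advantage is exercised by explicitly constructed
duplications in the tests. Random cross-matches do occur — a host 20-mer
matching a bait edge at ≥ 90 % arises by chance every few megabases and
produces a well-supported spurious cluster, which is exactly the
cross-reaction (e.g. SVA with HERV-K baits) the annotation-proximity filters
address in real genomes; on an unannotated random host such clusters appear
as false positives.

## Default parameters

| parameter | default | notes |
| --- | --- | --- |
| bait length | 15 bp | 20 bp for degraded-element screens |
| min identity | 0.95 | 0.90 for degraded-element screens |
| min match length | 15 bp | 20 bp in the same setting |
| min trimmed flank | 20 bp | shorter flanks rarely map uniquely |
| scoring | +2 / −3 / −4 linear | makes the mismatch budget exact |
| cluster gap | 10 kb | single-linkage chaining distance |
| min novel reads | 5 | single-read evidence for *known* loci |
| known window | 100 bp | distance to an annotated edge |
| proximity exclusion | 1,000 bp | inclusive |
| seed k (mapper) | 17 | unique in a megabase-scale random host |
| fragment bounds | 100–700 bp | ≈ mean ± 7 s.d. of the fragment model |

## Problem sizes used in the shipped runs

The acceptance script runs the provirus analog at its full stated
conditions (1-Mb host, 20 × 9,719-bp elements, 2×100 bp at 50×), the
solo-LTR analog (600-kb host, 10 × 968-bp LTRs, 2×101 bp at 50×) and the
presence/absence design (300-kb reference, 4 annotated elements, 30×). The
test suite runs the provirus analog at 30× and smaller variants of the other
designs; coverages between 30× and 50× give identical recovery on these
designs, with per-site support scaling proportionally.

## Known limitations

* No zygosity calls and no exact breakpoint intervals; cluster coordinates
  localise an integration to roughly a fragment length.
* Target-site-duplication identification and pre-integration reconstruction
  are downstream analyses outside this package.
* Absence calls do not model coverage (see above).
* The built-in mapper is a test harness, not a production aligner.
* Identity uses aligned bait positions as its denominator; when indels
  occur, alternative denominators (bait length, alignment columns) would
  give slightly different budgets.
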