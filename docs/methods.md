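# Methods

This note documents the models, conventions and parameter choices behind
`sarclone`, what the synthetic-data generator does and does not emulate, and
the limitations a user should keep in mind.

## Coordinates and interval algebra

All internal coordinates are 0-based half-open, so `length = end - start`
with no off-by-one ambiguity. Conversions happen only at format boundaries:
SEG tables are treated as 1-based inclusive, VCF `POS` as 1-based. Before
any arithmetic, a segment profile is *normalised*: per chromosome and copy
state, overlapping **and book-ended** intervals are merged. Normalising
first means union lengths never double-count bases; whether adjacent
same-state segments should instead be kept distinct is a judgment call the
upstream segmentation already made, so we do not second-guess it.

**Jaccard.** `J(A,B)` is overlapping base pairs over union base pairs,
computed by a two-pointer sweep over merged spans. By default the copy state
is ignored — a gain in one sample overlapping a loss in the other still
counts as overlap, matching how bedtools' `jaccard` subcommand (the
conventional tool for this statistic) treats plain intervals. A
`match_state=True` variant intersects per state and sums, for users who
want the stricter reading. Two empty profiles have an undefined ratio; we
return 0.0 with a warning rather than raise, since cohort loops hit this
case routinely. The implementation is checked against base-by-base boolean
arrays on randomized small genomes and against bedtools itself.

**Size filter.** Only events strictly longer than 500 kb count as genomic
changes (GCS); the boundary is exclusive, so a segment of exactly 500,000 bp
is dropped.

**Shared breakpoints.** On SNP arrays a breakpoint's position is only known
to the resolution of the probe grid, so two samples share a breakpoint iff
the copy-number shift falls between the same two probes in both. Each
segment contributes its start and end; positions are deduplicated per
sample at the gap level (two states changing in the same gap are one
breakpoint call). A uniform probe grid (default spacing 1,150 bp, the
density of a ~2.6M-marker array over the 22 autosomes) is represented
arithmetically and never materialised. When no probe map is available, a
positional tolerance (default ±1,150 bp, one grid spacing) approximates the
same-gap rule with greedy one-to-one matching.

**Minimal common region.** The intersection across all profiles of segments
matching a state filter (default gain/amplification), computed by folding
pairwise span intersections; anti-monotone by construction — adding a
profile can only shrink it. This is the operation that recovers a patient's
core amplicon. Copy-neutral LOH participates in Jaccard and breakpoint
sharing but not in the default amplification filter, since cnLOH is not an
amplification.

## The ESV filter cascade

A call record carries tumor/normal depths, orientation-split tumor alt
counts, normal alt count, a mean base quality and a consequence class. The
cascade keeps a record iff **all** of: tumor depth ≥ 20; normal depth ≥ 10;
mean base quality ≥ 20; tumor MAF ≥ 0.10 (inclusive); normal MAF < 0.01
(strictly); consequence non-synonymous exonic; and ≥ 2 alt reads in each
orientation. Choices worth flagging:

* *Non-synonymous exonic* is the set {missense, stop gain, stop loss,
  frameshift, in-frame indel}. Splice-site variants are excluded on a
  literal reading: splice sites are intronic. Indels run through the same
  cascade as SNVs.
* A zero normal depth fails the cascade — somatic status cannot be
  verified — and a zero tumor depth makes MAF undefined (NaN), which also
  fails.
* The orientation rule is the programmatic stand-in for the manual IGV
  review a human would otherwise do; no visual inspection step exists here.
* Whether "mean base quality" should average over alt reads only or the
  whole site is ambiguous in array practice; the record's provided mean is
  trusted as-is.

**Cross-sample rescue.** Within one patient, a variant identity
(chrom, pos, ref, alt) that fully passes in at least one sample is kept in
any other sample where it has ≥ 3 supporting alt reads, in any orientation
split. Rescue is a single pass: rescued records are labelled and can never
themselves rescue a third sample, so the kept set is the fixed point after
one pass. Raising any threshold can only shrink the kept set (verified by
property-based search).

## Patient-level metrics

Lesion-level variant sets default to the **union** of the lesion's samples'
kept sets (a variant found in any biopsy of a lesion was present in it); a
strict-intersection option exists for conservative analyses. Trunk = in
every lesion, shared = in ≥ 2 but not all, private = in exactly one.
Intra-lesional concordance is |intersection| / |union| over a lesion's k ≥ 2
samples; an empty union counts as fully concordant.

**Relapse origin.** Given PT, LR and Met, the Met's variants below a 5% MAF
floor are dropped (strictly > 0.05 survives), then two evidence lines are
computed: uniquely shared counts |(Met∩PT)\LR| vs |(Met∩LR)\PT|, and the
GCS Jaccard of each candidate pair. A parent is named only when both lines
strictly agree; any tie or disagreement returns "inconclusive". This is
deliberately conservative: each line alone is confoundable (a hypermutable
Met inflates private counts; a ploidy change distorts overlap), and the
joint rule mirrors how such cases are argued in practice.

**Chromosome-level counts.** Array segments and karyotype events are
combined by counting merged GCS intervals plus banding events not already
explained by the array: a banding event on a named arm is a duplicate when
the profile covers ≥ 50% of that arm. The 50% rule is coarse; no principled
reconciliation of banding and array event boundaries exists, and users with
better arm-level calls should deduplicate upstream. When a relapse *loses*
an aberration relative to its parent, the difference counts symmetrically.

**Group summaries.** Medians use the midpoint of the two central order
statistics for even n (so {22, 151} → 86.5 and half-integer medians like
87.5 are representable); missing values ("ND", not done) are excluded from
n, never treated as zero, and an all-missing metric is reported as absent.
Per-sample and per-lesion summaries are separate metrics: a lesion's value
is the median over its samples. Censored karyotype entries (e.g. ">10")
stay strings and never enter numerics.

## The simulator

The generator produces multi-lesion patients under three modes that
caricature the three pathogenetic groups, with complete ground truth
(trunk/private identities, true segment sets, the origin tree, per-cell
profiles in amplicon mode). Lesions form a tree rooted at the PT; the
default topology is a chain PT → LR → Met, and sampling times default to 0,
60 and 120 months — within the 1–25-year follow-up windows typical of
longitudinal sarcoma cohorts.

**Mutation accrual.** Each branch of length Δt months accrues
Poisson(snv_rate·Δt) new exonic variants, and (fusion/complex modes)
Poisson(bp_rate·Δt/2) new focal segment events, each event carrying two
breakpoints so that breakpoints arrive at bp_rate per month. Focal events
are uniform over the genome (chromosome weighted by length), 1–30 Mb long,
snapped to the probe grid, and rejected against overlap with same-state
events so that event counts are unambiguous. Complex mode adds a heritable
whole-genome ploidy-shift event with probability 0.05 per branch (three
whole-chromosome gains, recorded separately in truth as a distinct
mechanism from focal accrual).

Mode presets (chosen to match the observed burdens of each group and then
left alone):

| mode | founder events | founder ESV | snv_rate /mo | bp_rate /mo |
|---|---|---|---|---|
| fusion | 3 (cap 6 total) | 15 | 0.08 | 0.07 |
| amplicon | ring content | 2 | 0.05 | — |
| complex | 40 | 20 | 0.15 | 0.10 |

Fusion patients are genetically quiet: ~1–6 chromosome-level events
patient-wide (hard-capped at 6) and a bp_rate equivalent to a median of
about one new aberration per ~28-month relapse interval. Complex founders
carry ~80 breakpoints and ~20 ESV, with steady accrual. Amplicon-mode ESV
are few and mostly private.

**Ring-chromosome model (amplicon mode).** A cell is a subset of a fixed
amplicon universe: the core segments (default: two 12q14–15 segments of
500 kb and 356 kb, 856 kb combined, at the CDK4 and MDM2 loci) plus
`n_peripheral` (12) random 1–5 Mb segments on the same chromosome. Each
division toggles every segment with `flux_prob` (0.10), and any cell
missing a core segment dies with `selection_penalty` (0.95) per division —
mutation–selection balance keeps core-less cells around
flux·(1−penalty)/penalty ≈ 0.5% of the population, while peripheral content
drifts freely. Lesion founders are single surviving lineages evolved along
the branch (0.5 divisions/month); each lesion then grows a population
(50 cells sampled, 30 within-lesion divisions) whose **consensus profile**
keeps segments present in ≥ 50% of sampled cells — the operational
definition of the stemline, which no cytogenetic convention pins down
numerically. With penalty 1.0, core loss is strictly lethal and every cell
retains the core.

**Subclone replacement (fusion mode).** An optional scenario in which the
metastases descend from a minor PT subclone: trunk variants are emitted in
the PT at allele fraction ccf/2 (default ccf 0.15 → AF 0.075, in the 5–10%
band such cases show) while the PT's dominant clone carries a large private
burden (150 variants) absent from every Met, where trunk variants are
clonal.

**Read model.** A clonal heterozygous variant has true allele fraction
0.5 × purity (purity defaults to 1, matching pipelines that report raw
MAFs). Per record: tumor depth ~ Poisson(98) (the coverage class of the
exome data emulated; the matched normal defaults to 60×, a typical normal
coverage), alt count ~ Binomial(depth, AF), orientation split ~
Binomial(alt, 0.5), base quality failing the 20 threshold with probability
0.02, and normal contamination alt reads at AF 5·10⁻⁴. Each sample also
emits Poisson(3) synonymous somatic records (real but filtered) and
Poisson(20) artifact records with true AF 0 (forced to ≥ 1 supporting read,
since a caller only reports sites with some evidence; half get low base
quality). This is the simplest model that exercises every clause of the
cascade; it has **no** mapping artifacts, strand bias, FFPE damage, CNV-AF
coupling, tumor-in-normal contamination or subclonal AF structure beyond
the explicit subclone scenario. Passing recovery tests therefore shows the
pipeline's logic is sound at realistic depths, not that real-data artifact
modes are handled.

Everything is drawn from one seeded NumPy generator in a fixed order, so a
config plus seed reproduces every file byte for byte.

## Numerical and degenerate-input conventions

Jaccard of two empty sets → 0.0 with a warning; empty-union concordance →
1.0; zero assessed cells, mixed-patient record lists, fewer than two
lesions/profiles, and missing lesions in origin inference all raise with
the offending field named. Non-clonal cell fractions are reported to one
decimal, as cytogenetic tables print them. Breakpoint fractions with an
empty breakpoint set are 0. Ring populations that go extinct (possible only
when the founder lacks the core under full penalty) raise rather than
silently resample.

## Problem sizes used in validation

The test suite and the acceptance script run at desk scale, sized so the
statistical checks are sharp while the whole suite stays fast: oracle
equivalence on 200 randomized ≤ 10 kb genomes; trunk recovery over 50
seeded patients at 60× depth; the breakpoint rate law over 200 replicates
(3-standard-error band); core-amplicon recovery over 100 replicates;
relapse-origin accuracy over 100 replicates (complex mode, where lesions
actually diverge — a fusion-mode patient frequently has identical PT and LR
profiles, and the joint-evidence verdict is then correctly inconclusive).
The cross-patient intersection of per-patient common amplified regions over
25 replicates isolates the 856 kb core exactly, because peripheral content
is patient-specific.

## Known limitations

* No segmentation from raw log-ratios, no allele-specific copy number, no
  caller or aligner: the pipeline starts at call-level records, and the
  simulator fabricates them directly (no FASTQ/read-level simulation).
* Karyotype strings (ISCN) are not parsed; banding enters only as arm-level
  event lists or summary counts.
* How ploidy shifts should be handled when computing overlap between two
  samples is genuinely unresolved; the Jaccard here treats all segments at
  face value, and the simulator's truth labels let users exclude
  ploidy-shift segments if they prefer.
* The consequence class must be provided in the input; no annotation is
  performed.
* Consensus/stemline thresholds (≥ 50% of cells) and the ring flux and
  selection defaults are tuning knobs with sensible behaviour, not
  estimates of biological rates — no measurement of per-division ring
  segregation error exists to calibrate against.
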