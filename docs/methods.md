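# Methods

## Study system and scope

The package models a panel of six False Horn plantain cultivars: a
single-bunching control ('Agbagba', a stable triploid) and five
inflorescence-dichotomous cultivars (double-bunching DB1P/DB2P,
triple-bunching TB1P–TB3P, predominantly diploid). Three measurement
layers are implemented: bunch-phenotype concordance across crop cycles,
SNP/deletion detection in a gene-region alignment, and ploidy
determination by chromosome counting and flow cytometry. Because no
sequences or raw cytometry were deposited for this system, a synthetic
generator emulates every input kind with truth labels; the built-in panel
parameters (`musavar.profiles`) are the published per-cultivar values and
are treated as fixed study conditions, not tuning knobs.

## Concordance of bunch phenotypes

A cultivar's concordance coefficient is
CC = ΣNᵢᵢ / (ΣNᵢᵢ + ΣNᵢⱼ) over all live ratoon observations, comparing
each observation's bunch count with the same plant's plant-crop count.
Choices:

* **Scale.** CC is reported on [0, 1] (the scale on which the panel's
  classifications are defined), with a `percent=True` option.
* **Pooling.** First- and second-ratoon observations share one
  denominator; this pooled reading reproduces every panel row from its
  printed counts (10 plants, 20 pooled observations).
* **Counts only.** Peduncle orientation is recorded in
  `PhenologyRecord` but never enters CC: the persistence classes are
  defined on bunch number alone.
* **Classification.** Occurrence/persistence is `Normal/Persistent` iff
  CC ≥ threshold, with threshold defaulting to 1.0 — a single reversal
  disqualifies persistence. The boundary is inclusive.
* **Degenerate input.** No live ratoon observations raises
  `UndefinedConcordanceError`; CC is undefined there, never 0.

The phenology generator gives every plant its cultivar's plant-crop
phenotype and flips each ratoon observation away from it with probability
1 − p (p = the cultivar's concordance probability), choosing uniformly
between the two other bunch counts. By construction the concordant count
is Binomial(n_obs, p), so CC converges to p; the test suite checks the
mean over 1000 seeds.

## Variant calling and classification

SNPs are alignment columns where the reference and the sample both carry
an unambiguous A/C/G/T and differ; `-` and `N` columns yield no call.
Positions are 1-based in the ungapped reference; codon 1 begins at
`frame_offset` (default 1). A substitution is a transition iff it
preserves the purine/pyrimidine class ({A,G} vs {C,T}); the 12 ordered
base pairs therefore split 4/8. Codon effects substitute the alternate
base into the reference codon alone (so two hits in one codon are each
annotated against the reference) and translate under the standard genetic
code via Biopython; a change is synonymous iff the amino acid is
preserved. Sites outside a complete codon keep `None` codon fields rather
than failing the whole call.

Deletions are maximal sample-gap runs opposite reference bases, merged per
run and reported with ungapped start and length. Gaps in the *reference*
opposite sample bases are insertions, detected separately
(`detect_insertions`) and excluded from substitution summaries, which
follow the deletion-only reporting convention of the study system.

**Reference choice.** All six cultivars — including the control — are
compared against a single synthetic ancestral reference row (default
label `Ancestral`). The published per-cultivar spectra (55–86 sites each,
the control's included) are only mutually consistent against a common
baseline: calling the dichotomous cultivars against the control would
convolve two spectra. Any row can be designated the reference for other
analyses.

**Spectrum summaries.** `summarize_cultivar` reports the total site
count, the two most frequent substitution types (ties broken
lexicographically), the modal Pu/Py pattern within the majority
transition/transversion class, a representative amino-acid change (the
first non-synonymous call in positional order, else the first annotated
call), and `non-synonymous` iff any call is non-synonymous. Listed types
are a "top two", not an exhaustive spectrum — the published rows
under-sum their totals, so the remainder is not attributable to named
types.

## Variant implantation (synthetic alignments)

`implant_variants` places exactly `n_snp_sites` single-column
substitutions:

1. **Named amino-acid change first.** Placed at the profile's stated
   codon index when that reference codon encodes the source amino acid,
   else at the first feasible codon. Two of the panel's named changes
   (Val→Lys, Leu→Gly) are impossible as single-base edits under the
   standard code; these are realized as the minimal (two-base) change of
   one codon, each base recorded as its own truth event, so the codon
   translates to the named target while per-site annotations remain
   single-substitution effects against the reference.
2. **Listed types at exact counts**, at uniformly chosen positions whose
   reference base matches (and, for a wholly synonymous profile, whose
   single-base change is silent).
3. **Filler sites** for the unattributed remainder keep the spectrum's
   transition/transversion character but never reuse a listed pair, and
   each filler pair is capped strictly below the smaller listed count —
   the listed types are, by definition, the two most frequent, so a
   faithful simulation must keep every other type behind them. Pairs of
   the profile's stated Pu/Py direction are preferred; remaining
   same-character pairs are the fallback (the purely transitional profile
   must fall back to pyrimidine transitions, since both purine
   transitions are already listed).

A reference that cannot host a spectrum raises `PlacementFailureError`
rather than silently truncating; with the default 600-base reference
(uniform over the 61 sense codons, hence stop-free) this is a rare
tail event, handled in batch scripts by deterministically redrawing the
reference. Deletion intervals are blocked from substitution placement,
since a gapped column cannot also be a SNP site.

## Flow-cytometry model and caller

The histogram generator emulates a chopped-leaf propidium-iodide
preparation read against a co-chopped internal standard: two discretized
Gaussian peaks — sample at channel c₀·(ploidy/control_ploidy), control at
c₀ — each with standard deviation cv × center, plus a debris tail decaying
geometrically (ratio 0.7) over the lowest 20 % of channels. Non-debris
nuclei split evenly between sample and control. Counts are one
multinomial draw of `n_nuclei` (default 5000, a typical acquisition), so
totals are conserved exactly. Defaults cv = 3 % and debris = 10 % are
ordinary values for fresh leaf tissue on a ploidy analyzer; the control
channel defaults to 75 on a 256-channel axis so a diploid sample sits at
channel 50, but it is a mandatory per-run input for real data because the
channel scale is instrument- and gain-dependent.

The caller smooths with a coverage-normalized moving average (window 5;
normalization keeps flat histograms flat instead of creating phantom edge
plateaus) and takes local maxima with prominence ≥ 5 % of the smoothed
maximum. Channels below 0.25 × control channel are treated as debris and
cannot yield a sample peak — the debris tail itself is prominent at high
debris loads, and any cutoff between the debris region and the lowest
biological peak (haploid at c₀/3) behaves identically. Peaks within 10 %
of the control channel are attributed to the internal standard; the
highest remaining peak p gives ploidy = round(control_ploidy · p/c₀),
refused (`UnresolvedPloidyError`) if p deviates more than 20 % from the
implied integer-ploidy channel. A sample indistinguishable from the
control (only a control-band peak) is called at the control's ploidy.
Calls are invariant under a common gain factor applied to all channels
and the control channel.

Chromosome counting uses the modal per-plant count (ties to the lower
value — squash damage loses chromosomes more often than it gains them),
calls ploidy = round(m/x) with x = 11, and refuses counts farther than
`tolerance` (default 1) from every multiple of x as
aneuploid-or-miscount. The cytology generator gives each cell the exact
2n count with a 10 % chance of a ±1 miscount, so the mode stays exact.

## Pipeline, seeding and problem sizes

The pipeline derives one sub-seed per stage from the master seed
(`seed·1000003 + crc32(stage) mod 2³¹`), so stages rerun in isolation
reproducibly; cohort members draw independent sub-seeds from their
stage seed. Default problem sizes mirror the study design: 10 plants per
cultivar × 2 pooled ratoon observations, a 600-base gene region, a
100-plant flow cohort (95 diploid + 5 tetraploid) at 5000 nuclei per
histogram, ≥ 10 metaphase cells per plant. Outputs are plain text (FASTA,
CSV, TSV, minimal VCF, JSON report) and byte-reproducible per
configuration.

## What the synthetic data does and does not show

The generators reproduce the *structure* of the real inputs — spectrum
composition, peak geometry, phenotype reversion rates — with known truth,
so passing tests demonstrate that the callers are exact inverses of the
generating model within its envelope (cv ≤ 5 %, debris ≤ 20 %,
well-separated peaks). They do not emulate sequencing error, alignment
artifacts, aggregate/doublet peaks or G2 populations in cytometry,
aneuploid cytotypes beyond ±1 miscounts, within-cultivar sequence
heterogeneity, or any evolutionary process (the single deletion block is
specified, not evolved). Results on real data therefore depend on
upstream alignment and instrument quality in ways these tests cannot
certify. The published per-cycle counting-vs-flow disagreements are data
to be reported side by side, not reconciled by the software.
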