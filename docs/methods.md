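# Methods

## The provenance model

A heteroduplex dsRNA trigger consists of a sense strand and an antisense
strand that are deliberately mismatched against each other (and against the
target mRNA) within a central *mismatch area*, flanked on both sides by
regions identical on both strands and to the mRNA. Both strands are stored
projected into mRNA-sense orientation; the physically applied antisense ssRNA
is reverse-complemented at input. "Sense"/"antisense" always refers to read
orientation relative to the endogenous mRNA, which makes the provenance call
a pure lookup on the (reference, orientation) pair of a unique exact hit:

- (senseHD, sense) and (antisenseHD, antisense): the read carries a strand's
  mismatch signature in that strand's native orientation → exogenous RNA.
- (senseHD, antisense) and (antisenseHD, sense): the read carries one
  strand's signature in the opposite orientation, which only an RDR
  (RNA-dependent RNA polymerase) copy of that strand can produce.
- Concordant double hits (same start, same orientation, one hit per strand)
  occur exactly in the mismatch-free flanks, where strand of origin is
  undecidable; they are retained as orientation-only `flank_sense` /
  `flank_antisense` calls rather than discarded as multimappers. Any other
  multi-hit configuration is discarded.
- Unique hits on the target gene wholly outside the feeding fragment are
  secondary siRNAs (`secondary_mRNA`); the pipeline only maps to the target
  after the heteroduplex search fails, so feeding-fragment reads never reach
  this branch.

Single-stranded-trigger experiments are the same pipeline with one applied
strand; no separate code path exists.

### Design validation

The length filter's lower bound exists to guarantee that every retained
in-area read covers at least one diagnostic inter-strand mismatch. The
validator checks exactly that: a design passes for minimum read length
L iff every window of length L fully contained in the mismatch area contains
≥ 1 inter-strand mismatch — equivalently, the largest diagnostic-free
stretch (area boundaries included) is shorter than L. Pass implies every
error-free in-area read ≥ L nt maps uniquely, a property the suite verifies
with 10,000 randomized reads. The validator does not *place* mismatches
(no forward design) and ignores thermodynamics.

The package ships `toy_model()`, a representative synthetic design on a
random 1.2-kb target: a 500-nt duplex covering target positions 300–800 with
a 300-nt mismatch area carrying diagnostics every 12 nt (plus periodic
sense-strand-only edits versus the mRNA, which the model records but no
operation depends on). It is a stand-in for a real design, not a
reproduction of one.

## Mapping policy

Exact matching only, both orientations, against both strands simultaneously;
no mismatch tolerance anywhere, so sequencing errors surface as `unmapped`.
References are a few kb at most, so the implementation is a full overlapping
scan (`str.find` loop); the test suite holds it equal, field by field, to an
independent position-by-position oracle. Uniqueness is required for a strand
call; the two-tier flank verdict above is the single deliberate exception,
and it is what lets one mapping pass serve both the strand dissection and
the flank analysis.

## Non-templated 3' nucleotides

Reads failing to map are trimmed by one 3' base and remapped, up to four
mapping iterations in total, so 0–3 non-templated nucleotides are
detectable; reads still unmapped after iteration four are unclassified. The
first successful iteration wins. Consequences worth knowing:

- The reported tail is the *shortest suffix whose removal restores an exact
  match*. A genuinely added nucleotide that happens to equal the template's
  next base is, by construction, templated — the method cannot and does not
  distinguish it. On simulations this appears as calls whose tail is a
  strict suffix of the generated tail (~25% per boundary base); category
  recovery is unaffected because the extended core stays on the same strand.
- Flank placements are accepted at every iteration (same two-tier policy as
  the primary mapper), so flank reads receive tail calls too.
- Trimmed cores shorter than 15 nt (the 18-nt filter floor minus three
  trims) are never attempted.
- Reads without a heteroduplex placement get the same iterative search
  against the target gene, i.e. each read is tail-called on the reference
  set of its own provenance.

Tail calls are stratified by (orientation, original read length, tail count)
into position frequency matrices over the full read, with per-column
information content IC = 2 + Σ_b p_b·log₂ p_b bits (0·log 0 := 0), without
small-sample correction — with ~20 reads per stratum the expected IC
inflation is ≈ 0.1 bit, far below the 2-bit poly-U signal the logos exist to
show. Tails are reported in the RNA alphabet (U, not T).

## Overlap signature

For each sense hit s and antisense hit a on a common reference, the
5'-to-5' inclusive distance is o = a.start + a.length − s.start. Pairs with
1 ≤ o ≤ 30 are tallied exhaustively, weighted by read multiplicity, and
normalized to probabilities. A 23-nt Dicer duplex with 2-nt 3' overhangs has
its partners' 5' ends 21 positions apart, so a peak at 21 diagnoses Dicer
processing; a blunt duplex would peak at the duplex length. Counting unique
read *species* instead of read multiplicities is the main alternative
weighting; multiplicity counting was chosen because the probability
histogram is the headline output and abundance carries signal. Z-scores over
the 1–30 range are available as a secondary statistic.

## Synthetic libraries

The generator emulates the structure the analysis assumes, with ground truth
in a side table keyed by read id (never in FASTQ headers, so the pipeline
cannot cheat). Per read, in fixed draw order (category, core length,
placement, tail length, tail bases) from one seeded generator — identical
seeds give byte-identical FASTQ:

- **Core lengths** peak at 23 nt: {21: 0.05, 22: 0.15, 23: 0.60, 24: 0.15,
  25: 0.05}.
- **Wild-type composition**: antisense-oriented siRNA classes 2.5× their
  sense counterparts (senseHD_sense 0.08, senseHD_antisense 0.20,
  antisenseHD_sense 0.08, antisenseHD_antisense 0.20, flank_sense 0.03,
  flank_antisense 0.075), secondary siRNAs at a 0.03 secondary/primary
  ratio, remainder degradation. The antisense preference and the 2–5%
  secondary range are observed qualities of such libraries; the exact 2.5×
  factor and the 0.03 default are this package's chosen representative
  values, not measurements.
- **Tails**: lengths 0–3 with probabilities {0.55, 0.20, 0.18, 0.07};
  sense-oriented reads get poly-U tails, antisense-oriented reads get
  i.i.d. uniform random bases. Secondary and degradation reads are
  generated tail-free (tailing is analyzed for the trigger-derived
  populations).
- **Placement**: strand-category cores lie fully inside the mismatch area
  (hence strand-diagnostic), flank cores fully outside it, secondary cores
  on the target outside the feeding fragment (always antisense);
  degradation fragments are unmodified substrings of either strand in
  either orientation with lengths uniform on 15–35, deliberately straddling
  the 18–30 filter.
- **Mutant presets**: `rdr1_null` and `rdr2_truncation` zero every siRNA
  class (strand, flank and secondary) and emit only degradation;
  `rdr2_hypomorph` scales the siRNA classes to 15% of wild type. Quality
  strings are constant 'I'; the pipeline never reads them.

What the generator does *not* emulate — and hence what green tests do not
establish about real data: sequencing errors (which the no-mismatch policy
turns into unmapped reads), adapter remnants, UMIs, abundance hotspots or
phasing along the duplex, paired duplex placement (sense and antisense reads
are placed independently, so a simulated library's own overlap histogram is
diffuse; the 21-nt Dicer diagnostic is exercised on explicitly constructed
duplex geometries), and 5' phosphorylation chemistry (out of computational
scope; only its downstream read tables are representable).

## Numerical and reporting conventions

- Coordinates 0-based half-open internally; 1-based closed in exported
  coverage tables and design reports. U→T at every input boundary; tails
  rendered back as U.
- "Between 18 and 30 nt" is inclusive on both ends: the 23-nt core plus a
  3-nt tail must survive the filter, which requires 26 ≤ max, consistent
  with inclusive bounds and standard small-RNA practice.
- The 23-nt siRNA class used in ratios is exact core length 23 *after* tail
  removal. The secondary/primary ratio uses 23-nt cores in both numerator
  and denominator, which keeps mapped degradation fragments (length ≠ 23
  almost always) out of the ratio; denominators are recorded in the output
  metadata. The 23-nt-vs-total ratio divides by all reads entering
  classification (post-trim, pre-length-filter).
- Category weight vectors must sum to 1 within 1e-9; empty denominators
  yield explicitly null ratios, never NaN.
- Replicate aggregation reports mean and sample SD (ddof = 1) per scalar;
  SD is null for a single replicate.
- Adapter trimming is exact-match-only at the leftmost full occurrence, a
  deliberate simplification of error-tolerant trimmers; no quality trimming
  exists because no quality model is simulated.

## Problem sizes

Simulation-based tests and the recovery checks run at n = 10,000 reads with
fixed seeds — large enough that binomial 3-standard-error bands around the
generator's parameters are tight (SE ≈ 0.002 on a 0.03 ratio), small enough
to keep the whole suite near ten seconds. The acceptance script uses 150
duplexes (t1) and 200 tailed reads (t2), comfortably past the point where
both modes are deterministic in practice.

## Known limitations

- No gapped or mismatch-tolerant alignment; genome-scale references are out
  of scope (the scan is quadratic in the worst case).
- The tail caller cannot see 5' additions, internal edits, or tails longer
  than three nucleotides, and reports shortest-consistent tails (above).
- The flank verdict assumes the flanks are *identical* on both strands;
  build_model enforces this at construction, so partially homologous flanks
  are rejected rather than handled.
- `secondary_mRNA` requires the hit to lie wholly outside the feeding
  fragment; reads straddling the boundary are unassigned rather than
  counted to either side.
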