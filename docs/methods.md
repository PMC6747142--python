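# Methods

This note records the models, conventions, parameter choices and known
limitations behind `editscan`, in the order the pipeline runs.

## Guide matching (`editscan.guides`)

**Model.** A target site is protospacer + PAM. Matching tolerates up to
`max_mismatches` substitutions in the protospacer (default 6 — sites with up
to six mismatches are known to be cleavable, so the default errs toward
sensitivity), or exactly one single-nucleotide bulge carrying at most
`bulge_mismatch_cap` substitutions (default 0). A DNA bulge is an extra
genomic base, an RNA bulge an unpaired guide base; either may sit anywhere
*strictly inside* the protospacer — at a terminus a bulge is
indistinguishable from a 1-nt shift of a gapless alignment, so terminal
bulges are not enumerated (the Cas-OFFinder convention). PAM matching is an
IUPAC pattern test; PAM positions do not count toward the mismatch total
unless `pam_mismatch_counted` is set (off by default, matching the common
reporting convention for off-target mismatch counts).

**Coordinates.** 0-based half-open internally and in BED output; 1-based in
VCF-facing I/O. The blunt cut falls between positions 3 and 4 counting
5′-ward from the PAM; `cut_position` is the reference base immediately 5′ of
the cut in forward coordinates (the cut lies between `cut_position` and
`cut_position + 1`), on either strand.

**Degenerate bases.** Any genomic ambiguity code (including N) mismatches
every protospacer base and fails every concrete PAM position. This is
deliberately conservative: masked or ambiguous regions cannot produce
phantom hits, at the cost of missing sites that straddle an N.

**One site, one hit.** Alternative alignments (gapless / DNA bulge / RNA
bulge) sharing one physical PAM on one strand are collapsed to the best:
fewest mismatches, then bulge-free, then leftmost. Without this rule every
bulged site would also be reported as a high-mismatch gapless hit.

**Implementation and verification.** The scanner is a NumPy prefix-sum
formulation: with M[i,j] = [genome[i+j] ≠ protospacer[j]], gapless mismatch
counts are row sums and every bulge placement is a prefix + suffix sum, so
all offsets and gap positions are evaluated as array operations. The test
suite checks exact agreement with an independent, purely enumerative
brute-force matcher on hundreds of random sequences across all parameter
combinations; monotonicity in `max_mismatches`, strand involution and
cut-position geometry are asserted as properties.

## Variant consensus (`editscan.variants`)

**Normalization.** Callers disagree on indel representation, so every call
is reduced to the canonical minimal left-aligned form before comparison:
trim shared suffix, extend left through repeat context when an allele
empties, trim shared prefix (the standard VCF normalization algorithm;
idempotent). Identity for matching is the normalized
(contig, pos, ref, alt); genotype fields are ignored because caller
genotype encodings are not comparable. Multi-allelic records are split
first. Tests compare normalization against an independent oracle that
applies the variant to the sequence and rediscovers the canonical form by
string diff.

**Thresholds.** Defaults: SNVs in ≥2 of 3 SNV callers, indels in ≥2 of 3
indel callers ("repeatedly reported" is read as "by more than one
program"; `snv_min_callers=3` is selectable for the stricter reading), SVs
in 2 of 2 SV callers. The depth filter requires *variant-supporting* reads
≥2 in at least one caller's record — at 50–100× sequencing a total-depth 2×
filter would exclude nothing, so the supporting-read reading is the one
that does the work the filter is meant to do. SV records match across
callers with ±10 bp breakpoint wobble and identical SV type (SV callers
rarely agree to the base), and SVs longer than 10 kb are excluded.

**Control subtraction** removes any variant whose normalized key appears in
a wild-type or different-target control consensus (SVs again with ±10 bp
tolerance); it is order-independent in the control list.

## Editing-site detection (`editscan.detect`)

Candidate windows span the variant's reference footprint ±50 nt (clipped at
contig edges). The footprint is the substituted base for SNVs, the single
anchor base for insertions, and the deleted bases for deletions, so an SNV
window is 101 nt and a 10-nt deletion window 110 nt. The 50 nt default
follows the observed span of CRISPR indels around the cut (deletions
starting up to ~40 nt upstream, ending up to ~30 nt downstream);
it is configurable. Both breakpoints of an SV are windowed — the editing
question can be asked at either end and nothing says which breakpoint the
nuclease made.

Per (variant, guide) the best window hit is chosen by: fewest mismatches,
bulge-free, cut position nearest the variant footprint, leftmost. A variant
matched by two guides is reported once per guide (double-edited plants make
this reachable); there is no cross-guide arbitration. A call whose window
sequence occurs more than once in the reference (exact text match, either
strand) carries an informational `repeat_flag` — matches inside repeats are
suspect, but flagging rather than filtering leaves the decision to the
analyst.

`site_mutation_frequency` is supporting depth / total depth at the
max-support record; zero total depth yields NaN (a flagged record, not an
exception).

## Digenome cleavage calling (`editscan.digenome`)

The in-vitro signature of a blunt cut between p and p+1 is a cluster of
forward-read 5′ starts at p+1 mirrored by reverse-read ends at p. The
caller is an explicit two-strand test with all thresholds in config:

* `min_reads` (default 5) read starts on *each* strand;
* forward signal may sit within ±`window` (default 1) of p+1 — staggered
  end repair shifts starts by a base — while the reverse signal anchors the
  call at p exactly (applying slack to both strands smears one cut into
  several candidate positions);
* combined start fraction (f + r) / local depth ≥ `min_start_fraction`
  (default 0.2), with local depth = max(depth[p], depth[p+1]) — reads
  stopping at the cut cover only one flank, so the denominator is the
  better-covered flank and the fraction is capped at 1;
* runs of adjacent qualifying positions reduce to the strongest (local
  maximum of f + r).

Called sites are then filtered with the guide matcher (defaults: ≤6
mismatches or one clean bulge) requiring the predicted blunt cut of the
match to fall within ±1 of the observed cut; a per-guide mismatch histogram
summarizes the survivors. The original Digenome-seq scoring formula is not
reproduced; this operationalisation reproduces the qualitative signature
while being fully specified and testable. Simulations show zero calls on
uniform background (20 replicates at 20× depth) and 100% recovery of
simulated cuts with 10 + 10 clustered starts over that background.

## Amplicon quantification (`editscan.amplicon`)

A read is mutant iff its alignment to the amplicon contains ≥1 insertion or
deletion overlapping the counting window `cut_offset ± count_flank`
(default ±10 nt: wide enough for the indel hotspot, narrow enough to exclude
amplicon-end artefacts). Substitution-only reads are never mutant by default
(SNPs and sequencing errors dominate them); an opt-in flag includes them.
Reads that do not span the whole counting window are excluded from the
denominator — an edit that could not have been observed must not deflate
efficiency. Efficiency = mutant reads / total spanning reads.

Two noise filters: a distinct indel signature needs ≥`min_variant_reads`
(default 2, applied per distinct allele; per-site is configurable via the
same knob) to count at all, and signatures below `bona_fide_threshold`
(default 1‰) stay in the mutant count but are excluded from the reported
spectrum, since frequencies that low are indistinguishable from sequencing
error.

**Alignment.** Reads identical to an amplicon substring take a fast exact
path. Other reads are aligned with edlib (edit distance, infix mode). Edit
distance has no gap-open penalty, so when equal-cost paths exist it can
scatter one multi-nt indel into several 1-nt gaps; a path containing a
single contiguous indel run is kept as-is (it is already affine-optimal up
to placement), and any read whose edit path holds ≥2 indel runs is
realigned with an affine-gap aligner (match 2, mismatch −3, gap open −6,
extend −0.2, amplicon overhangs free). All indels are then left-normalized
against the amplicon, mirroring VCF convention, before being encoded as
signatures.

**Coordinates.** Mutation positions are PAM-relative: −1 is the base
immediately 5′ of the PAM, +1 the first PAM base, 0 unused; the blunt cut
falls between −4 and −3. Minus-strand guide sites are mapped through the
same convention so spectra from either orientation are comparable.

## Synthetic fixtures (`editscan.simulate`)

The generators define the conditions under which the toolkit is validated:

* **Reference**: i.i.d. bases with a GC dial (default 0.36, the Arabidopsis
  genome-wide value); no repeat structure by default. Contigs of 10–100 kb
  stand in for chromosomes — matching statistics (per-window mismatch
  counts) are local, so desk-scale contigs exercise the same code paths as
  a 135 Mb genome, only the background match rate scales.
* **Site implantation**: mutated/bulged protospacer copies with concrete
  PAMs are spliced in at random positions (≥500 nt apart, away from contig
  edges), then the genome is re-scanned: each implant must be recovered
  with exactly its requested mismatch count and bulge state, and accidental
  background matches (a 19-mer with ≤6 mismatches + NGG occurs by chance
  roughly every ~10⁵ bp) are re-randomized until the scan returns the truth
  table exactly. All placement is seeded.
* **Caller VCFs**: each caller reports the truth variants of its classes
  with configurable sensitivity; background variants are SNVs private to a
  single caller; indel representations are randomly right-shifted through
  repeat context to exercise normalization. Supporting depth of emitted
  truth variants is floored at 2 so simulated true calls are detectable by
  construction (the depth filter is tested with separately constructed
  calls).
* **Amplicon reads**: full-length amplicon copies; mutant status
  Bernoulli(efficiency), signatures multinomial over the given spectrum,
  substitution noise i.i.d. per base (default 10⁻³, a typical Illumina
  post-filter rate). No PCR chimeras, primer dimers, quality-correlated
  errors or read-length variation are modelled — recovery results bound
  sampling plus substitution-noise effects only, not amplification
  artefacts.
* **Digenome read starts**: uniform background reads at a target depth plus
  clustered starts at the given cuts, emitted as a plain alignment table
  (SAM is also accepted by the profile builder).

What passing tests therefore show: the algorithms are exact on their own
model (correct windows, thresholds, labels, arithmetic) and robust to the
modelled noise. What they do not show: performance under alignment
artefacts, repeat-mediated mismapping, PCR bias, or somaclonal variation
beyond simple shared SNVs.

## Problem sizes and numerics

Defaults used by the test suite and `scripts/acceptance.py`: 200 random
sequences of 0.5–5 kb for matcher/oracle agreement; a 3 × 100 kb genome
with 0/2/3/6-mismatch implants, 100 background variants and a 20-SNV
wild-type set for end-to-end recovery; 4 efficiencies × 100 (tests) or 25
(script) seeds × 10,000 reads for amplicon recovery; 20 (tests) or 10
(script) replicates for digenome specificity and sensitivity. These sizes
give binomial sampling error well inside the asserted tolerances (e.g.
σ ≈ 0.005 for efficiency at n = 10⁴ against a ±0.02 acceptance band).
Ties are broken deterministically everywhere (documented per module above);
all generators are reproducible from a single integer seed.

## Known limitations

* No biophysical off-target scoring (CFD/MIT) and no multi-bulge
  alignments; the matcher is combinatorial, not thermodynamic.
* Linear-scan genome search; appropriate at desk scale, not FM-indexed for
  many-guide × whole-genome screens.
* Digenome calling is a threshold test, not a likelihood score; its
  absolute site counts on real libraries depend on digestion completeness
  and DNA integrity, which the simulator does not model.
* Amplicon mode assumes pre-merged single reads; no UMI handling.
* Complex alleles whose minimal edit path hides an indel pair behind
  equal-cost substitutions can escape the edlib prefilter; such reads are
  rare in NHEJ spectra but would be undercounted.
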