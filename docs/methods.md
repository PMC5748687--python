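# Methods

This note documents the models, conventions and design choices behind each
stage, what the synthetic generator does and does not emulate, and the known
limitations.

## Preprocessing

Reads pass a quality filter (drop any read containing N or with more than
10% of bases below Q20 — "low quality" is not standardised, this is the
package's operational rule), 3′ adapter trimming (left-most match of at
least 6 adapter nucleotides with at most one substitution; adapter at
position 0 is an adapter-dimer and is rejected, as are reads with no match),
and an inclusive 15–30 nt insert length filter. Clean reads are collapsed to
unique tags with counts; the clean-read total is the per-million (TPM)
denominator for that library.

Tag annotation is exact-substring lookup against per-class reference pools
in a fixed priority order — structural RNA classes (rRNA, tRNA, snRNA,
snoRNA), then sequence-database classes (known miRNA, repeat), then the
polyA rule — so each tag receives exactly one class. polyA is defined as a
3′ A-run covering at least 80% of the tag; the degradome variant uses the
polyN rule instead (any single base strictly over 70% of positions).

## Hairpin evaluation and novel miRNA calling

Candidate precursors are folded to their minimum-free-energy structure.
The default backend is the ViennaRNA (RNA) bindings; a Nussinov base-pair
maximisation with a simplified energy model (GC=3, AU=2, GU=1 weight units,
−1 kcal/mol per unit, minimum loop 3) is available where a thermodynamic
folder is not wanted. The backend is recorded in each fold result.

Duplex evaluation works on the pair table. The duplex region is the mature
minus its own 2-nt 3′ overhang. Because MFE folds fray at helix ends and
may absorb a substitution as a 1-nt bulge, the evaluation first restricts
mature pairs to the dominant pairing register (in an antiparallel duplex
i + partner(i) is nearly constant; pairs more than 2 nt off the median
register — for example mature bases captured by a spurious loop hairpin —
count as mismatches). The star span is extrapolated from that register and
given the canonical 2-nt 3′ offset, so terminal fraying does not shift it.
miRNA\* evidence admits sequenced tags starting within 3 nt of the nominal
star span with up to 2 nt length difference, mirroring how real pipelines
match star reads. A pass requires: fewer than six duplex mismatches
(strict), mature disjoint from the terminal loop (the single hairpin loop
enclosed by the mature's innermost pair; branched structures are rejected),
the star span inside the precursor, and star evidence when a tag index is
supplied.

Novel calling excises windows [tag−L, tag+R] for L, R ∈ {20, 60, 100, 150}
around each perfectly-mapping candidate tag. Windows are tried
smallest-first and the first passing window is kept: folding energy
decreases monotonically with window length, so "lowest MFE among passing
windows" would simply select the largest window while costing a fold
(~10–200 ms) for every window; the tightest passing window is the sharper
precursor call and an order of magnitude cheaper. A window is folded only
if it contains a plausible star region (≤5 substitutions against the
reverse-complemented mature core, located by exact 6-mers — a 19-nt core
with ≤2 substitutions always retains an intact 6-mer). Loci sharing a
transcript region are collapsed to the most abundant mature, which removes
the star strand's mirror-image call.

MFEI is reported with no hard threshold (reference values for tRNA/rRNA/mRNA
folds sit near 0.6–0.66, miRNA precursors above ~0.85); AMFE and MFEI are
presented at two decimals, half-up.

Conserved matching aligns a tag end-to-end against a bundled miniature
reference of conserved plant mature miRNAs, allowing ≤2 substitutions and
≤2 nt terminal length variation; ties break on fewest mismatches, then
lexicographic family name. The bundled reference is a test-scale stand-in
for a full miRBase mature set.

## Differential expression

TPM = 10⁶ · count / clean-read total. The Audic–Claverie conditional test
is evaluated through the identity P(y|x) = NB(x+1, n₁/(n₁+n₂)) pmf(y),
giving log-space stability to counts ≥10⁷ via scipy's distribution
functions. The two-sided p doubles the smaller conditional tail; because
that construction is directional on a discrete lattice (conditioning on x
versus on y gives different tails at extreme splits), the reported p is the
smaller of the two directions, which is exactly symmetric in the two
libraries and preserves the doubled-tail form. Under an equal-mean Poisson
null the realised p < 0.01 rate is ≤0.015 (discrete conservativeness).

Calls: up/down need p < 0.01 and |log₂ ratio| strictly > 1 with both counts
positive; a feature with zero reads in exactly one library and at least 2 in
the other is library-specific (the minimum of 2 suppresses singletons);
zero/one pairs stay non-significant; features absent from both libraries are
dropped. No multiple-testing correction by default, matching the raw
threshold convention for this design; a Benjamini–Hochberg option exists.
The 2^(−ΔΔCt) helper converts qRT-PCR Ct differences to relative expression.

## siRNA duplexes

With both 3′ overhangs fixed at 2 nt and exact core complementarity, the
duplex relation is revcomp(a[:-2]) == b[:-2], which forces equal strand
lengths and is symmetric. The finder indexes 5′ cores by reverse
complement (linear time); an O(n²) oracle is the correctness reference in
tests. Repeat mapping requires both strands to match an element perfectly,
one per element strand; multi-element duplexes increment every matching
element. Duplex length classes use the longer strand.

## Degradome

Tags are 20–21 nt 5′ ends of cleavage fragments; preparation trims the
adapter, filters length, drops polyN tags and annotated tags. Profiles map
tags to transcripts by exact sense-strand match only; a tag matching k
transcripts contributes its full count to each (no fractional weighting).

Alignment scoring is antisense with mismatch=1, G:U=0.5, gap position=1;
equal lengths score ungapped, a 1–2 nt length difference is absorbed by one
contiguous gap placed optimally. Genome-wide site scanning searches
ungapped windows of the small RNA's length with a vectorised scorer; the
single-gap path is exercised through the scalar scorer. The default
acceptance threshold is 4.5: a strict "<4" rule conflicts with reported
results that include 4.5-scoring targets, so 4.5 is the default and the
threshold is configurable.

Cleavage site = alignment end − 9. Categories: 0 unique maximum (>1 read),
1 shared maximum (>1 read), 2 above the median of positions, 3 at/below the
median (>1 read), 4 exactly one read; assignment uses the library-summed
profile, with raw per-library site counts reported. Events require at least
one read at the predicted site; distinct miRNAs cleaving one site are
distinct events.

## tasiRNA phasing

Trigger sites come from the same scanner. Overlapping sites drop the
higher-scoring one (tie: keep the 5′-most); the closest compliant
non-overlapping pair with ≥1 phase forms the locus. Spacing counts
nucleotides strictly between the site spans and phase count =
round(spacing / 21) — the only rule consistent with the published
174 nt → 8 and 261 nt → 12 phase examples, neither being an exact multiple
of 21. The default register anchors at the 3′-proximal site's predicted
cleavage position and counts toward the 5′ site (the canonical two-hit
model); a 5′-anchored alternative is available because which site is
cleaved varies between systems. Dk(+) windows are reported with per-library
exact-match abundances, including zero-support windows; windows running off
the register are truncated and flagged. A locus is "validated" when exactly
one site has degradome support. tasiRNA targets are genes with one or two
antisense sites at score ≤2.0 (same scorer; "<2 nt mismatches" is
implemented as ≤2.0 with G:U=0.5, favouring recall since degradome
confirmation sits downstream). Expression anti-correlation uses Pearson r
over the condition series with classes at |r| > 0.5; constant series are an
error.

## Synthetic data

The generator emulates the statistical structure of a three-condition salt
time-course: log-normally skewed tag abundances with 21- and 24-nt length
modes, planted miRNA hairpins (mature + ≥8 nt loop + near-revcomp star with
2-nt 3′ overhang geometry and ≤2 planted duplex substitutions), TAS3-like
two-hit loci with 8–12 phase spacings and tasiRNA-ARF content in the D7/D8
windows, repeat elements in two transcript copies shedding duplex pairs
(24-nt class weight 0.6), planted cleavage targets whose degradome tags
pile at the predicted site (~85% of the transcript's degradome weight),
ARF-like target genes, condition fold changes of log₂FC = 2 for 40% of
planted miRNAs, four control-absent (library-specific) miRNAs, and
substitution-only sequencing error at 10⁻³ per base. Default problem
sizes — 250 background transcripts, 30 hairpins, 2 loci, 4 repeats, 20
targets, 120,000 reads per library, 40,000 degradome reads — keep a full
run around ten seconds while leaving planted features with the count depths
(≥50 reads for DE features) the detectors assume.

Counts are multinomial over planted weights, so library totals equal the
configured depth exactly; one RNG stream per output library is derived from
the master seed, so adding a library never perturbs earlier ones. Reads can
be expanded to adapter-carrying FASTQ with configured adapter-dimer and
low-quality fractions, giving a known expected rejection rate for the
preprocessing cascade.

What the generator does not emulate: real genome sequence or repeat
families, ligation and PCR biases, indel errors, replicate structure, or
degradome background correlated with transcript abundance. Passing the
planted-recovery benchmarks therefore demonstrates algorithmic correctness
under the stated statistical assumptions, not performance on real tissue
libraries.

## Numerical conventions and degenerate inputs

DNA alphabet internally (U→T on input); 1-based inclusive spans in all
reports; table ordering count-descending then lexicographic; MFEI/AMFE at
two decimals half-up; N bases never match or pair and sequences >10% N are
not folded; empty libraries are valid but unusable as TPM denominators;
constant series, zero GC, positive ΔG and empty reference sets raise
errors rather than returning sentinels.

## Known limitations

Novel miRNA discovery is transcript-based; intergenic precursors absent
from the transcript set cannot be found. The gapped alignment path is not
searched during site scanning (only scored on demand). The conserved
reference is miniature by design. The five degradome categories follow the
standard convention; published tables using 0–4 without definition may
differ in edge cases. High-quality read counts depend on an operational
quality rule and are not comparable across pipelines.
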