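# Methods

`neotadkit` models the downstream genomics of an inter-chromosomal
insertional duplication — the class of structural variant in which a donor
block (here, a chr2-like block carrying eight genes and active enhancers)
is copied into an acceptor TAD (here, a chrX-like locus whose two genes
flank the insertion point) — and provides the statistics used to decide
whether the event caused enhancer hijacking: derivative-genome
construction and Hi-C remapping, neo-TAD and ectopic trans-contact
scoring, trio-based parent-of-origin inference, X-inactivation skew, and
per-gene expression statistics. Because primary patient data for such
cases is typically under restricted access, the package carries a
synthetic-data module that generates the whole case with truth labels;
every claim the test suite makes is a claim about recovery of those
constructions.

## Coordinate model and derivative construction

All coordinates are 0-based half-open, BED-compatible; VCF positions are
converted on read. An insertional duplication is
(donor_chrom, [donor_start, donor_end), acceptor_chrom, insertion_pos,
orientation, donor_copy_retained). The derivative chromosome is composed
of three segments — acceptor-left, donor insert (reverse-complemented for
reverse orientation), acceptor-right — with degenerate segments dropped
and adjacent same-source segments merged, so an empty insert yields the
identity. Total length is always acceptor length + insert length.

The custom reference used for Hi-C remapping replaces the acceptor
chromosome by the derivative and masks the original donor interval with
an equal-length run of `N`. Masking is length-preserving (rather than a
deletion) so that every bin table and annotation defined on the reference
remains valid; its purpose in the real analysis is mappability — reads
from the duplicated sequence can then only align to the derivative
insert. In masked mode the forward coordinate map is single-valued
everywhere; in unmasked mode donor-interval positions have exactly two
images (original + insert copy). The derivative-to-reference map is total
and single-valued in both modes. Liftover is arithmetic on segments, and
is property-tested against exhaustive per-base dictionaries built from
toy sequences.

ORF-duplication classification is purely interval logic: a gene is
`complete` iff its body lies inside the donor interval, `partial` iff the
interval truncates it. The packaged eight-gene fixture encodes the
published topology of the motivating case (six complete, two partial,
breakpoints inside the outermost genes) with approximate hg19-scale
coordinates, since exact breakpoints of such cases are generally not
printed; files are labelled synthetic.

## Hi-C binning, remapping and scoring

Pairs (4DN text format) are binned at a fixed resolution into a symmetric
sparse matrix in which each pair is counted once (upper-triangle +
diagonal sum equals the pair count) — conservation that is asserted,
together with symmetry, after every operation. Remapping onto the
derivative is the same per-end liftover the segment map defines and
requires masked mode; record counts are conserved.

**Ectopic trans score.** Between two regions on different chromosomes:
observed mean trans count over the region x region bin pairs, divided by
the mean over all other trans bin pairs between the two chromosomes after
excluding the tested regions extended by a flank (default in the
pipeline: twice the width of the larger tested region, the toy-scale
analogue of excluding a couple of megabases around an ~1 Mb locus — the
junction-proximal distance-decay leakage must not sit in the background).
The empirical p-value draws `n_permutations` background bin-pair sets of
matching size without replacement and reports
(#{perm mean >= observed} + 1)/(n_permutations + 1). Balancing is not
applied by default: the score is a ratio and is balance-invariant under
uniform coverage; an optional iterative-proportional-fitting pass
(tolerance 1e-5, <= 200 iterations) is available.

**Fusion-domain (neo-TAD) enrichment.** For each breakpoint, the mean
count in the window x window quadrant spanning it, divided by a
distance-matched expectation: per-diagonal means over cis bin pairs that
neither cross nor touch any breakpoint window. A fused domain shows as a
higher ratio at that breakpoint than at the other. On remapped proband
maps the absolute ratios sit below 1 because the donor-insert rows carry
overlaid coverage from both the original and the derivative copy of the
duplication (the same overlay the custom-reference construction produces
in the real analysis), so the left/right *comparison*, not the absolute
level, is the read-out.

**Insulation.** Value at bin *i* is the mean count in the
`w x w` square straddling the bin (rows `[i-w, i)`, columns `[i, i+w)`);
edge bins are undefined. Boundaries are local minima more than one
population standard deviation (default delta) below the profile mean.

**Display.** Counts above the percentile threshold (default 99.2, linear
interpolation over nonzero entries) are clamped to the threshold —
truncation, not removal — and the matrix can be rotated 45 degrees into
the triangular array used for heatmaps. The percentile definition over
nonzero entries is a package choice; the convention the display emulates
states only the percentile itself.

## Parent-of-origin inference

Trio genotypes are classified by the transmission truth table: a site is
informative when the proband is heterozygous and only one
(maternal-allele, paternal-allele) decomposition is consistent with the
parents; Mendelian-inconsistent sites are flagged and excluded rather
than repaired. Reads are labelled maternal/paternal by majority vote over
their informative-site alleles (a ref allele votes for the parent that
did *not* transmit the alt); ties are ambiguous. Sequencing error is
absorbed by the vote rather than modelled explicitly.

The carrier call compares Poisson likelihoods of the labelled-read depths
inside the duplicated region under two hypotheses — maternal carrier
(maternal:paternal = 2:1) vs paternal carrier (1:2) — with the
per-haplotype rate profiled at its maximum-likelihood value; flank depths
calibrate the 1:1 baseline and must be nonzero for both clusters. The
log-likelihood ratio reduces to (N_m − N_p)·ln 2 on the in-region depths;
a call requires |LLR| >= 3 nats (i.e. an imbalance of five reads or
more). The published description of this tool is two sentences; the
majority-vote + Poisson-LLR formulation here is a documented stand-in
chosen as the simplest model in which cluster coverage decides the
parent, not a reconstruction of the original implementation.

X-inactivation skew is the median haplotype-A fraction over X-linked
genes with total haplotype-resolved depth >= 10 reads; the sample is
called skewed at median >= 0.80 or <= 0.20 (a common clinical convention;
no threshold is fixed by the analyses this emulates). Per-gene two-sided
exact binomial tests against 0.5 are attached.

## Expression statistics

Benjamini-Hochberg adjustment is the standard step-up procedure
(delegated to statsmodels, checked against the hand-applied formula).
DEGs require adjusted p strictly < 0.001 and |log2FC| strictly > 2.
Pathway enrichment is the Pearson chi-square on the 2x2 DEG x pathway
table over the universe of all tested genes (the universe convention is a
package choice), Yates correction off by default, with the in-pathway DEG
percentage reported. Co-expression clustering z-scores each gene across
samples and partitions genes with seeded k-means into k clusters labelled
K1..Kk by decreasing size; constant genes are excluded. The clustering
method behind the published K1–K10-style cluster sets is unstated in this
class of analysis, so the z-score + k-means choice is documented as a
stand-in. ddCt fold change is 2^-((target−ref)_sample −
(target−ref)_calibrator); control normalisation divides each value by the
same-timepoint control mean, which therefore maps to exactly 1.0.

## Synthetic study conditions

The toy case uses 1 Mb chromosomes (10 kb bins in all default analyses)
with a fixed fractional layout: donor interval at [0.30, 0.60) of the
chromosome (the ~820 kb block scaled down), eight donor genes of which
the first and last straddle the breakpoints, three enhancers inside the
first gene body, insertion at 0.50 of the acceptor chromosome between the
two genes of a [0.35, 0.65) acceptor TAD. The derivative TAD list places
one neo-TAD across the left breakpoint only ([0.40, 0.66) of the
derivative, covering the hijacked gene and the enhancer-bearing insert
segment); the right-breakpoint domains abut without fusing. Only
sequences vary with the seed; the structure is the condition under test.

Contact pairs draw cis distance from density ∝ (s + s0)^-alpha with
alpha = 1 (the standard mammalian decay regime) and s0 = 1 kb to avoid
the zero-distance singularity; same-TAD pairs are enriched 3-fold at
matched distance by thinning cross-TAD candidates; trans contacts are
uniform at rate 0.1. Proband maps mix the intact reference view and the
derivative view 50:50 (heterozygosity), with derivative-view ends lifted
back to reference coordinates — which is exactly what creates the ectopic
donor x acceptor trans block. Trio simulation places 60% of 50
informative sites inside the duplication; flank coverage is
Poisson(depth/2) per haplotype and the carrier haplotype doubles inside
the region (diploid depth 30 by default, 1% allele error). XCI counts
draw a per-cell haplotype choice (500 cells) at probability rho, then
per-gene binomial reads at depth 50. The DE table has 5000 genes with 155
perturbed (the 3.1% DEG rate of the motivating dataset); perturbed genes
get p in [1e-15, 1e-6] and |log2FC| in (2.05, 5.5], and the hijacked gene
takes log2FC = +6 with the smallest p, so it ranks first by construction
— what the tests verify is that the filtering and ranking machinery
recovers it. Pathway sets of 88/102/88 genes contain 18/11/14 perturbed
genes, emulating in-pathway DEG rates near 20.5%, 10.8% and 15.9%.

What the generators do *not* emulate: read-level sequence error profiles
and mapping ambiguity, non-uniform Hi-C coverage (restriction-site and
GC bias — hence matrix balancing stays optional and off), loop- and
compartment-level contact structure, linkage between the expression table
and the contact maps, and real hg19 coordinates. Passing tests therefore
demonstrate that the statistics recover the planted structure under
idealised noise, not performance on raw sequencing data.

## Numerical choices and degenerate inputs

Percentiles use linear interpolation; the ectopic permutation p uses a +1
pseudo-count so it is never 0; the fusion background refuses matrices too
small to supply distance-matched diagonals; insulation requires the
window to fit twice into the matrix; zero-length derivative segments are
dropped; empty donor intervals give identity derivatives; all-zero trans
backgrounds, zero flank depths, zero control means, constant expression
rows and out-of-range probabilities raise errors rather than propagate.
All simulators and the pipeline are pure functions of (parameters, seed);
the pipeline splits one root seed into per-stage seeds via a seed
sequence.

Problem sizes in the default pipeline and the reproduction script
(100k pairs, 10 kb bins, 100 trios, 200 XCI draws, 1000 permutations)
were chosen so a full run completes in seconds on one CPU while keeping
every recovery rate comfortably away from its decision boundary.

## Known limitations

- The ectopic and fusion scores assume a single insertional duplication;
  chained or nested rearrangements are out of scope.
- The parent-of-origin model ignores read-pair structure and assumes
  independent site coverage; mapping bias between haplotypes is not
  modelled (the flank check guards only against gross dropout).
- The chi-square enrichment inherits the usual large-sample caveats for
  sparse pathways; no exact-test fallback is provided.
- BED/pairs parsing covers the dialects the package itself writes; exotic
  header variants are not handled.
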