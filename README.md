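# neotadkit

Structural-variant-aware Hi-C analysis and downstream statistics for
**enhancer hijacking by insertional duplication** — the situation in
which a duplicated genomic block lands inside a distant topologically
associating domain (TAD), fuses regulatory content across the breakpoint
into a *neo-TAD* (a "Shuffled-TAD"), and misexpresses a gene of the
acceptor locus.

The package is written for genomicists analysing a de novo
inter-chromosomal insertional duplication (the motivating configuration
is a der(X)-type event: an ~820 kb donor block carrying eight genes, two
of them truncated by the breakpoints, inserted between the two genes of
an ~0.8 Mb acceptor TAD). It provides, as composable library modules and
a thin CLI:

- **`sv_genome`** — derivative-chromosome construction, the masked
  "custom reference" (donor copy N-masked so reads map to the chimeric
  junctions), bidirectional coordinate liftover, and ORF-duplication
  classification of genes against the duplicated interval
  (complete / partial / none);
- **`hic`** — 4DN pairs binning into symmetric contact matrices,
  remapping of pairs onto the derivative genome, an **ectopic
  trans-contact score** with permutation p-value, per-breakpoint
  **fusion-domain enrichment** against a distance-matched background,
  insulation profiles with boundary calls, and the percentile-truncated
  (default 99.2th), 45°-rotated display matrix;
- **`phasing`** — trio transmission truth table, per-read
  maternal/paternal clustering by majority vote, a Poisson
  log-likelihood-ratio **parent-of-origin call** for the duplicated
  region (2:1 vs 1:2 cluster-depth hypotheses, threshold 3 nats), and
  X-inactivation skew from haplotype-resolved expression;
- **`expression`** — Benjamini-Hochberg adjustment, DEG filtering
  (padj < 0.001, |log2FC| > 2), 2×2 chi-square pathway enrichment with
  in-pathway DEG percentages, seeded co-expression clustering (K1..Kk),
  2^−ΔΔCt quantification and control-normalised fold changes;
- **`synthetic`** — generators for the whole toy case (genome, SV,
  annotations, Hi-C pairs with power-law decay + TAD enrichment +
  neo-TAD, trio reads with the 2:1 duplication signature, ASE counts, DE
  table) with truth labels;
- **`pipeline`** — a YAML-configured end-to-end run with a JSON report
  and a truth-recovery summary.

The key statistics, in brief: the ectopic score between donor region *A*
and acceptor region *B* is
`mean(counts[A×B]) / mean(trans background)` with an empirical
permutation p-value; the fusion enrichment at a breakpoint is the mean
cross-breakpoint count in a window divided by the distance-matched cis
expectation; the parent-of-origin LLR reduces to `(N_mat − N_pat)·ln 2`
on labelled read depths inside the duplication; pathway enrichment is
Pearson's χ² on the DEG × pathway 2×2 table.

## Worked example

```python
from neotadkit import synthetic, hic, phasing
from neotadkit.sv_genome import classify_gene_overlap

case = synthetic.make_toy_case(seed=1)           # 2 × 1 Mb chromosomes
_, counts = classify_gene_overlap(case.genes, case.sv)
print(dict(counts))

pairs = synthetic.simulate_case_pairs(case, n_pairs=100_000, seed=1)
bt = hic.BinTable(10_000, case.reference_chromsizes)
cm = hic.bin_pairs(pairs, bt)
ra = tuple(case.truth["ectopic_region_donor"])
rb = tuple(case.truth["ectopic_region_acceptor"])
score = hic.ectopic_contact_score(
    cm, (ra[0], int(ra[1]), int(ra[2])), (rb[0], int(rb[1]), int(rb[2])),
    flank_exclusion=320_000, n_permutations=500, seed=1,
)
print(round(score.score, 2), score.empirical_p)
```

prints

```
{'complete': 6, 'partial': 2, 'none': 2}
4.08 0.001996007984031936
```

i.e. the duplication carries six completely and two partially
ORF-duplicated genes (the two acceptor genes do not overlap it), and the
proband map shows a ~4-fold ectopic trans-contact enrichment between the
donor block and the acceptor TAD that no background resample reaches
(p ≈ 0.002 at 500 permutations). A control simulation without the SV
scores ≈ 1.0. The full pipeline is one call:

```bash
neotadkit run --config cfg.yaml          # cfg.yaml: "resolution: 10000"
```

whose JSON report includes the derivative summary (length 1,300,000 = 1 Mb
acceptor + 300 kb insert), the fusion enrichment at the two breakpoints
(left ≈ 0.67 vs right ≈ 0.27 — the neo-TAD forms across the left
breakpoint only), the parent-of-origin call with its LLR, the XCI
classification, the DEG count (3.1%) and the per-pathway χ² results, plus
a `truth_recovery` block comparing every call with the generator's truth
labels.

`neotadkit synth case`, `neotadkit hic bin|remap|score|insulate|render`
expose the individual steps on files.

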