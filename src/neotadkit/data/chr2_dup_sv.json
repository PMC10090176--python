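{
  "_comment": "Synthetic fixture: der(X)ins(X;2)(q26.1;p13.3)-like insertional duplication with approximate hg19-scale coordinates encoding the published topology; true breakpoints are not public.",
  "donor_chrom": "chr2",
  "donor_start": 69330000,
  "donor_end": 70150000,
  "acceptor_chrom": "chrX",
  "insertion_pos": 130400000,
  "orientation": "forward",
  "donor_copy_retained": true
}
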