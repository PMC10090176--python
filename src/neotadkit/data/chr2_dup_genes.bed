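# Synthetic fixture: the eight 2p13.3 genes overlapping the ~820 kb duplicated
# interval, in genomic order. Coordinates are approximate hg19-scale positions
# chosen to encode the published topology (outermost two genes truncated by the
# breakpoints); the true base-pair breakpoints are not public.
chr2	69240000	69480000	ANTXR1	0	-
chr2	69546000	69614000	GFPT1	0	+
chr2	69616000	69650000	NFU1	0	+
chr2	69685000	69870000	AAK1	0	-
chr2	69871000	69928000	ANXA4	0	+
chr2	69940000	70010000	GMCL1	0	-
chr2	70012000	70035000	SNRNP27	0	+
chr2	70142000	70170000	MXD1	0	-
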