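"""Packaged example data."""

from importlib import resources

from .sv_genome import GeneInterval, InsertionalDuplication, read_bed_genes, read_sv_json


def load_dup_gene_fixture() -> tuple[list[GeneInterval], InsertionalDuplication]:
    """The eight-gene duplicated-block fixture with its insertional duplication.

    A synthetic encoding of a 2p13.3 -> Xq26.1 insertional duplication
    topology: eight genes in genomic order, the outermost two
    straddling the duplication breakpoints. Coordinates are approximate.
    """
    data = resources.files("neotadkit") / "data"
    with resources.as_file(data / "chr2_dup_genes.bed") as p:
        genes = read_bed_genes(p)
    with resources.as_file(data / "chr2_dup_sv.json") as p:
        sv = read_sv_json(p)
    return genes, sv
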