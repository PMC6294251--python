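import numpy as np
import pytest

from trendseq.annotation import GeneModel, GenomeSequence, PolyASite, TrendIsoform


@pytest.fixture
def flat_genome():
    """1 kb genome of repeating CGT (adenosine-free) on one contig."""
    return GenomeSequence({"chr1": "CGT" * 334})


def make_genome(length=2000, seed=0, planted=()):
    """Random A-poor genome with optional (pos, seq) plantings."""
    rng = np.random.default_rng(seed)
    seq = list("".join(rng.choice(list("CGT"), size=length)))
    for pos, sub in planted:
        seq[pos:pos + len(sub)] = list(sub)
    return GenomeSequence({"chr1": "".join(seq)})


def make_gene(gene_id="geneA", start=100, cds_len=300, utr_len=600, strand="+",
              biotype="coding", contig="chr1"):
    end = start + cds_len + utr_len
    if strand == "+":
        cds_end, ann3 = start + cds_len, end
    else:
        cds_end, ann3 = start + utr_len, start
    return GeneModel(gene_id, contig, strand, ((start, end),), cds_end, ann3, biotype)


def make_isoform(gene, position, rank=1, cls="tandem", support=10, ip_flag=False):
    site = PolyASite(gene.contig, gene.strand, position, support, ip_flag)
    return TrendIsoform(f"{gene.gene_id}.{rank}", gene.gene_id, site, cls, rank)
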