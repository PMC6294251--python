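"""File-format I/O for the pipeline.

Readers and writers for the external interfaces: genome FASTA, gene-model
GTF, alignments SAM (soft-clipped poly(A) tails recovered from CIGAR + SEQ),
paired FASTQ, the annotation BED6 (+ TSV side table with the internal-priming
flag), and the tabular counts / contrast / probe / survival files. All
tabular formats are plain TSV/CSV handled by pandas; sequence formats go
through Biopython and pysam. Internally everything is 0-based half-open; GTF
(1-based, closed) is converted at this boundary.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation import (
    AlignedRead3p,
    GeneModel,
    GenomeSequence,
    PolyASite,
    TrendIsoform,
    reverse_complement,
)
from .quant import RawRead, SampleSheet


# ----------------------------------------------------------------------- FASTA

def write_fasta(genome: GenomeSequence, path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in genome.contigs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> GenomeSequence:
    return GenomeSequence({rec.id: str(rec.seq).upper()
                           for rec in SeqIO.parse(str(path), "fasta")})


# ------------------------------------------------------------------------- GTF

def write_gtf(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models as GTF (1-based closed), one gene + exon features.

    ``cds_end`` (0-based) and biotype travel in the attribute column.
    """
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; gene_biotype "{g.biotype}";'
            if g.cds_end is not None:
                attrs += f' cds_end "{g.cds_end}";'
            span = g.span
            fh.write("\t".join([g.contig, "trendseq", "gene", str(span[0] + 1),
                                str(span[1]), ".", g.strand, ".", attrs]) + "\n")
            for s, e in g.exons:
                fh.write("\t".join([g.contig, "trendseq", "exon", str(s + 1),
                                    str(e), ".", g.strand, ".", attrs]) + "\n")


def read_gtf(path: str | Path) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True, keep_order=True,
                            merge_strategy="create_unique",
                            disable_infer_genes=True,
                            disable_infer_transcripts=True)
    genes = []
    for g in db.features_of_type("gene"):
        exons = sorted((e.start - 1, e.end)
                       for e in db.children(g, featuretype="exon"))
        if not exons:
            exons = [(g.start - 1, g.end)]
        if g.strand == "-":
            exons = exons[::-1]  # transcription order
        biotype = (g.attributes.get("gene_biotype") or ["coding"])[0]
        cds_attr = g.attributes.get("cds_end")
        cds_end = int(cds_attr[0]) if cds_attr else None
        ann3 = max(e for _, e in exons) if g.strand == "+" else min(s for s, _ in exons)
        genes.append(GeneModel(g.id, g.seqid, g.strand, tuple(exons),
                               cds_end, ann3, biotype))
    return genes


# ------------------------------------------------------------------------- SAM

def write_sam(reads: Sequence[AlignedRead3p], genome: GenomeSequence,
              path: str | Path) -> None:
    """Write 3'-end alignments as SAM; the poly(A) tail becomes a 3'-side
    soft clip (A's for forward reads, leading T's for reverse reads)."""
    header = {"HD": {"VN": "1.6"},
              "SQ": [{"SN": name, "LN": len(seq)}
                     for name, seq in genome.contigs.items()]}
    tid = {name: i for i, name in enumerate(genome.contigs)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in reads:
            a = pysam.AlignedSegment()
            a.query_name = r.read_id
            a.reference_id = tid[r.contig]
            a.reference_start = r.aln_start
            a.mapping_quality = 60
            aligned = genome.contigs[r.contig][r.aln_start:r.aln_end]
            m = r.aln_end - r.aln_start
            if r.strand == "+":
                a.flag = 0
                a.query_sequence = aligned + "A" * r.soft_tail_A
                a.cigar = [(0, m)] + ([(4, r.soft_tail_A)] if r.soft_tail_A else [])
            else:
                a.flag = 16
                a.query_sequence = "T" * r.soft_tail_A + aligned
                a.cigar = ([(4, r.soft_tail_A)] if r.soft_tail_A else []) + [(0, m)]
            out.write(a)


def read_sam(path: str | Path) -> list[AlignedRead3p]:
    """Read 3'-end alignments; ``soft_tail_A`` is the run of strand-sense A's
    in the soft clip adjacent to the alignment's 3' end."""
    reads = []
    with pysam.AlignmentFile(str(path), "r") as fh:
        for a in fh:
            if a.is_unmapped:
                continue
            strand = "-" if a.is_reverse else "+"
            cig = a.cigartuples or []
            seq = a.query_sequence or ""
            tail = 0
            if strand == "+" and cig and cig[-1][0] == 4:
                clip = seq[len(seq) - cig[-1][1]:]
                for base in clip:
                    if base != "A":
                        break
                    tail += 1
            elif strand == "-" and cig and cig[0][0] == 4:
                clip = seq[:cig[0][1]]
                for base in reversed(clip):
                    if base != "T":
                        break
                    tail += 1
            reads.append(AlignedRead3p(a.query_name, a.reference_name, strand,
                                       a.reference_start, a.reference_end, tail))
    return reads


# ----------------------------------------------------------------------- FASTQ

def write_fastq(reads: Sequence[RawRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.qualities)
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual}\n")


def read_fastq(path: str | Path) -> list[RawRead]:
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        out.append(RawRead(rec.id, str(rec.seq),
                           tuple(rec.letter_annotations["phred_quality"])))
    return out


# -------------------------------------------------------------- annotation BED

def write_annotation(isoforms: Sequence[TrendIsoform], bed_path: str | Path,
                     tsv_path: str | Path | None = None) -> None:
    """BED6 (name = gene|isoform|class, score = support) + ip_flag side TSV."""
    with open(bed_path, "w") as fh:
        for iso in isoforms:
            s = iso.site
            name = f"{iso.gene_id}|{iso.isoform_id}|{iso.cls}"
            fh.write(f"{s.contig}\t{s.position}\t{s.position + 1}\t{name}\t"
                     f"{s.support}\t{s.strand}\n")
    if tsv_path is not None:
        pd.DataFrame(
            {"isoform_id": [i.isoform_id for i in isoforms],
             "gene_id": [i.gene_id for i in isoforms],
             "cls": [i.cls for i in isoforms],
             "rank_3p": [i.rank_3p for i in isoforms],
             "contig": [i.site.contig for i in isoforms],
             "strand": [i.site.strand for i in isoforms],
             "position": [i.site.position for i in isoforms],
             "support": [i.site.support for i in isoforms],
             "ip_flag": [i.site.ip_flag for i in isoforms]},
        ).to_csv(tsv_path, sep="\t", index=False)


def read_annotation(tsv_path: str | Path) -> list[TrendIsoform]:
    df = pd.read_csv(tsv_path, sep="\t")
    out = []
    for _, row in df.iterrows():
        site = PolyASite(row["contig"], row["strand"], int(row["position"]),
                         int(row["support"]), bool(row["ip_flag"]))
        out.append(TrendIsoform(row["isoform_id"], row["gene_id"], site,
                                row["cls"], int(row["rank_3p"])))
    return out


# ---------------------------------------------------------------------- tables

def write_counts(counts: pd.DataFrame, meta: pd.DataFrame, path: str | Path) -> None:
    keep = [c for c in ("gene_id", "rank_3p", "cls", "contig", "strand",
                        "position") if c in meta.columns]
    merged = meta[keep].join(counts)
    merged.to_csv(path, sep="\t", index_label="isoform_id")


def read_counts(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    df = pd.read_csv(path, sep="\t", index_col="isoform_id")
    meta_cols = [c for c in ("gene_id", "rank_3p", "cls", "contig", "strand",
                             "position") if c in df.columns]
    return df.drop(columns=meta_cols), df[meta_cols]


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Two-column TSV: barcode <tab> sample_id."""
    df = pd.read_csv(path, sep="\t", header=None, names=["barcode", "sample_id"])
    return SampleSheet(dict(zip(df["barcode"], df["sample_id"])))
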