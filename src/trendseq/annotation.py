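"""Assembly of the TREND annotation from 3'-end read alignments.

The annotation stage turns poly(A)-site-supporting (PASS) read evidence into a
catalogue of 3'-end isoforms per gene:

1. :func:`filter_pass_reads` keeps reads whose soft-clipped terminal adenosines
   cannot be explained by genome-templated A's (evidence of a real poly(A)
   tail rather than internal oligo-dT priming).
2. :func:`cluster_sites` collapses PASS read 3' ends into poly(A) sites by
   single-linkage clustering along each contig and strand.
3. :func:`assign_sites_to_genes` attaches sites to gene models, allowing novel
   isoforms up to a configurable distance downstream of the annotated 3' end.
4. :func:`classify_isoform` partitions isoforms into tandem / internal /
   novel / non-coding classes.
5. :func:`flag_internal_priming` marks sites whose downstream genomic window
   is adenosine-rich and therefore prone to internal-priming artefacts.

Coordinates are 0-based half-open throughout; strand-aware "downstream" means
increasing coordinates on ``+`` and decreasing on ``-``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# defaults, overridable at every call site
MIN_UNTEMPLATED_A = 2
CLUSTER_WINDOW = 25
MIN_SUPPORT = 2
MAX_DOWNSTREAM = 5000
IP_WINDOW = 20
IP_MAX_A = 12
IP_MAX_RUN = 6


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class AnnotationError(ValueError):
    """Raised for malformed inputs or configuration in the annotation stage."""


@dataclass(frozen=True)
class GenomeSequence:
    """Genome as a mapping of contig name to an uppercase nucleotide string."""

    contigs: Mapping[str, str]

    def fetch(self, contig: str, start: int, end: int, strand: str = "+") -> str:
        """Return the sequence of ``[start, end)``; reverse complement on ``-``.

        Out-of-bounds portions are truncated (never padded), so the returned
        string may be shorter than ``end - start`` at contig edges.
        """
        if contig not in self.contigs:
            raise AnnotationError(f"unknown contig: {contig!r}")
        seq = self.contigs[contig]
        s, e = max(0, start), min(len(seq), end)
        if e <= s:
            return ""
        sub = seq[s:e]
        return reverse_complement(sub) if strand == "-" else sub

    def length(self, contig: str) -> int:
        if contig not in self.contigs:
            raise AnnotationError(f"unknown contig: {contig!r}")
        return len(self.contigs[contig])


@dataclass(frozen=True)
class GeneModel:
    """Minimal gene model: exon structure, stop-codon boundary, 3' terminus."""

    gene_id: str
    contig: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_end: int | None
    annotated_3p_end: int
    biotype: str = "coding"  # "coding" | "non_coding"

    @property
    def span(self) -> tuple[int, int]:
        return (min(s for s, _ in self.exons), max(e for _, e in self.exons))


@dataclass(frozen=True)
class AlignedRead3p:
    """A mapped 3'-end read; ``soft_tail_A`` is the soft-clipped A-tail length."""

    read_id: str
    contig: str
    strand: str
    aln_start: int
    aln_end: int
    soft_tail_A: int = 0

    @property
    def end3(self) -> int:
        """Genomic coordinate of the read's 3'-terminal aligned base."""
        return self.aln_end - 1 if self.strand == "+" else self.aln_start


@dataclass(frozen=True)
class PolyASite:
    contig: str
    strand: str
    position: int
    support: int
    ip_flag: bool = False


@dataclass(frozen=True)
class TrendIsoform:
    isoform_id: str
    gene_id: str
    site: PolyASite
    cls: str  # tandem | internal | novel | non_coding
    rank_3p: int = 0


def count_templated_a(genome: GenomeSequence, contig: str, strand: str, end3: int,
                      limit: int) -> int:
    """Number of consecutive strand-sense A's immediately downstream of ``end3``."""
    if strand == "+":
        window = genome.fetch(contig, end3 + 1, end3 + 1 + limit, "+")
    else:
        window = genome.fetch(contig, end3 - limit, end3, "-")
    n = 0
    for base in window:
        if base != "A":
            break
        n += 1
    return n


def filter_pass_reads(reads: Sequence[AlignedRead3p], genome: GenomeSequence,
                      min_untemplated_a: int = MIN_UNTEMPLATED_A) -> list[AlignedRead3p]:
    """Keep poly(A)-site-supporting reads.

    A read passes when its soft-clipped terminal A count exceeds the number of
    genome-templated A's immediately downstream of the alignment 3' end by at
    least ``min_untemplated_a``. Input order is preserved.
    """
    kept: list[AlignedRead3p] = []
    for read in reads:
        if read.contig not in genome.contigs:
            raise AnnotationError(f"read {read.read_id!r} on unknown contig {read.contig!r}")
        if read.soft_tail_A <= 0:
            continue
        templated = count_templated_a(genome, read.contig, read.strand, read.end3,
                                      read.soft_tail_A)
        if read.soft_tail_A - templated >= min_untemplated_a:
            kept.append(read)
    return kept


def cluster_sites(pass_reads: Sequence[AlignedRead3p], window: int = CLUSTER_WINDOW,
                  min_support: int = MIN_SUPPORT) -> list[PolyASite]:
    """Single-linkage clustering of read 3' ends into poly(A) sites.

    Per contig and strand, sorted 3'-end coordinates are joined while the gap
    between neighbours is at most ``window``. The site position is the modal
    coordinate of the cluster; a tie is resolved to the strand-aware
    downstream-most mode. Clusters with fewer than ``min_support`` reads are
    dropped.
    """
    if window < 0:
        raise AnnotationError(f"cluster window must be non-negative, got {window}")
    by_key: dict[tuple[str, str], list[int]] = {}
    for read in pass_reads:
        by_key.setdefault((read.contig, read.strand), []).append(read.end3)

    sites: list[PolyASite] = []
    for (contig, strand), coords in sorted(by_key.items()):
        coords.sort()
        cluster: list[int] = []
        for pos in coords:
            if cluster and pos - cluster[-1] > window:
                sites.extend(_emit_cluster(contig, strand, cluster, min_support))
                cluster = []
            cluster.append(pos)
        if cluster:
            sites.extend(_emit_cluster(contig, strand, cluster, min_support))
    return sites


def _emit_cluster(contig: str, strand: str, coords: list[int],
                  min_support: int) -> list[PolyASite]:
    if len(coords) < min_support:
        return []
    counts: dict[int, int] = {}
    for c in coords:
        counts[c] = counts.get(c, 0) + 1
    top = max(counts.values())
    modes = [c for c, n in counts.items() if n == top]
    position = max(modes) if strand == "+" else min(modes)
    return [PolyASite(contig, strand, position, len(coords))]


def _downstream_distance(site_pos: int, gene: GeneModel) -> int:
    """Strand-aware distance of a site past the gene's annotated 3' end (>0 = downstream)."""
    if gene.strand == "+":
        return site_pos - (gene.annotated_3p_end - 1)
    return gene.annotated_3p_end - site_pos


def assign_sites_to_genes(sites: Sequence[PolyASite], genes: Sequence[GeneModel],
                          max_downstream: int = MAX_DOWNSTREAM) -> list[TrendIsoform]:
    """Assign poly(A) sites to genes and emit ranked, classified isoforms.

    A site goes to the same-contig, same-strand gene whose span contains it;
    failing that, to the gene whose annotated 3' end lies strand-aware upstream
    of the site within ``max_downstream`` nt (a novel 3' UTR isoform). Among
    several candidates the nearest annotated 3' end wins, ties broken by
    lexicographically smaller ``gene_id``. Unassignable sites are dropped and
    logged. Isoforms receive ``rank_3p`` 1..k per gene in 5'→3' order.
    """
    by_loc: dict[tuple[str, str], list[GeneModel]] = {}
    for gene in genes:
        by_loc.setdefault((gene.contig, gene.strand), []).append(gene)

    assigned: dict[str, list[PolyASite]] = {}
    gene_by_id = {g.gene_id: g for g in genes}
    n_dropped = 0
    for site in sites:
        candidates = by_loc.get((site.contig, site.strand), [])
        containing = [g for g in candidates if g.span[0] <= site.position < g.span[1]]
        pool = containing
        if not pool:
            pool = [g for g in candidates
                    if 0 < _downstream_distance(site.position, g) <= max_downstream]
        if not pool:
            n_dropped += 1
            continue
        best = min(pool, key=lambda g: (abs(site.position - (g.annotated_3p_end - 1))
                                        if g.strand == "+"
                                        else abs(site.position - g.annotated_3p_end),
                                        g.gene_id))
        assigned.setdefault(best.gene_id, []).append(site)
    if n_dropped:
        logger.info("assign_sites_to_genes: %d site(s) unassignable, dropped", n_dropped)

    isoforms: list[TrendIsoform] = []
    for gene_id in sorted(assigned):
        gene = gene_by_id[gene_id]
        ordered = sorted(assigned[gene_id], key=lambda s: s.position,
                         reverse=(gene.strand == "-"))
        for rank, site in enumerate(ordered, start=1):
            iso = TrendIsoform(
                isoform_id=f"{gene_id}.{rank}",
                gene_id=gene_id,
                site=site,
                cls="unclassified",
                rank_3p=rank,
            )
            isoforms.append(replace(iso, cls=classify_isoform(iso, gene)))
    return isoforms


def classify_isoform(iso: TrendIsoform, gene: GeneModel) -> str:
    """Classify an assigned isoform as tandem / internal / novel / non_coding.

    Non-coding genes always yield ``non_coding``. Otherwise a site strand-aware
    beyond the annotated 3' end is ``novel``; between the stop codon boundary
    and the annotated 3' end it is ``tandem`` (3' UTR shortening/lengthening);
    upstream of the stop codon it is ``internal`` (altered C-terminus).
    """
    if gene.biotype == "non_coding":
        return "non_coding"
    if gene.cds_end is None:
        raise AnnotationError(f"coding gene {gene.gene_id!r} lacks cds_end")
    pos = iso.site.position
    if _downstream_distance(pos, gene) > 0:
        return "novel"
    if gene.strand == "+":
        return "tandem" if pos >= gene.cds_end else "internal"
    return "tandem" if pos < gene.cds_end else "internal"


def flag_internal_priming(site: PolyASite, genome: GenomeSequence,
                          win: int = IP_WINDOW, max_a: int = IP_MAX_A,
                          max_run: int = IP_MAX_RUN) -> bool:
    """True when the downstream genomic window of a site is adenosine-rich.

    The strand-aware window of length ``win`` immediately downstream of the
    cleavage position is scanned; a site is flagged when it contains more than
    ``max_a`` A's in total or a run of more than ``max_run`` consecutive A's.
    Truncated windows at contig ends scale ``max_a`` proportionally.
    """
    if site.strand == "+":
        window = genome.fetch(site.contig, site.position + 1, site.position + 1 + win, "+")
    else:
        window = genome.fetch(site.contig, site.position - win, site.position, "-")
    if not window:
        return False
    a_limit = max_a * len(window) / win
    n_a = window.count("A")
    if n_a > a_limit:
        return True
    run = best = 0
    for base in window:
        run = run + 1 if base == "A" else 0
        best = max(best, run)
    return best > max_run


def flag_sites(isoforms: Iterable[TrendIsoform], genome: GenomeSequence,
               win: int = IP_WINDOW, max_a: int = IP_MAX_A,
               max_run: int = IP_MAX_RUN) -> list[TrendIsoform]:
    """Return isoforms with their site's internal-priming flag filled in."""
    out = []
    for iso in isoforms:
        flagged = flag_internal_priming(iso.site, genome, win, max_a, max_run)
        out.append(replace(iso, site=replace(iso.site, ip_flag=flagged)))
    return out


def build_annotation(reads: Sequence[AlignedRead3p], genome: GenomeSequence,
                     genes: Sequence[GeneModel], *,
                     min_untemplated_a: int = MIN_UNTEMPLATED_A,
                     window: int = CLUSTER_WINDOW, min_support: int = MIN_SUPPORT,
                     max_downstream: int = MAX_DOWNSTREAM,
                     ip_win: int = IP_WINDOW, ip_max_a: int = IP_MAX_A,
                     ip_max_run: int = IP_MAX_RUN) -> list[TrendIsoform]:
    """Full annotation pipeline: PASS filter → cluster → assign → classify → flag."""
    pass_reads = filter_pass_reads(reads, genome, min_untemplated_a)
    sites = cluster_sites(pass_reads, window, min_support)
    isoforms = assign_sites_to_genes(sites, genes, max_downstream)
    return flag_sites(isoforms, genome, ip_win, ip_max_a, ip_max_run)
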