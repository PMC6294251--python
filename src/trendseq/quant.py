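"""Read-level processing and isoform counting for 3'-end sequencing libraries.

Reads arrive as pairs: read 1 carries a short in-lane sample barcode, read 2
the RNA insert ending at the cleavage site followed by (part of) the poly(A)
tail. The stages here are:

* :func:`demultiplex` — exact barcode matching plus a mean-quality filter on
  the insert read.
* :func:`trim_stretches` — removal of the 3' A-stretch (recorded as the
  soft-clipped tail used later for PASS filtering) and of the 5' T-stretch
  left by oligo-dT priming.
* :func:`drop_internal_priming_reads` — removal of alignments explained by
  genomic A-rich stretches rather than true poly(A) sites.
* :func:`count_isoforms` — intersection-strict assignment of read 3' ends to
  isoform counting windows; reads hitting zero or more than one window are
  tallied as ``no_feature`` / ``ambiguous``.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotation import (
    AlignedRead3p,
    AnnotationError,
    GenomeSequence,
    TrendIsoform,
    count_templated_a,
    flag_internal_priming,
    PolyASite,
)

MIN_MEAN_Q = 20.0
MIN_STRETCH = 5
MIN_LEN = 15
COUNT_FLANK = 50


class QuantError(ValueError):
    pass


@dataclass(frozen=True)
class RawRead:
    read_id: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self):
        if len(self.sequence) != len(self.qualities):
            raise QuantError(f"read {self.read_id!r}: sequence/quality length mismatch")

    @property
    def mean_q(self) -> float:
        return sum(self.qualities) / len(self.qualities) if self.qualities else 0.0


@dataclass(frozen=True)
class SampleSheet:
    """Barcode → sample map; barcodes must be unique and of equal length."""

    barcodes: Mapping[str, str]

    def __post_init__(self):
        lengths = {len(b) for b in self.barcodes}
        if len(lengths) > 1:
            raise QuantError("barcodes must all have the same length")
        if any(set(b) - set("ACGT") for b in self.barcodes):
            raise QuantError("barcodes must be over the alphabet {A,C,G,T}")
        if len(set(self.barcodes.values())) != len(self.barcodes):
            raise QuantError("sample ids must be unique")

    @property
    def barcode_length(self) -> int:
        return len(next(iter(self.barcodes)))


@dataclass
class DemuxResult:
    by_sample: dict[str, list[RawRead]]
    n_low_quality: int = 0
    n_unmatched: int = 0


def demultiplex(reads_r1: Sequence[RawRead], reads_r2: Sequence[RawRead],
                sheet: SampleSheet, min_mean_q: float = MIN_MEAN_Q) -> DemuxResult:
    """Assign insert reads to samples by exact in-lane barcode match.

    The barcode is the first ``barcode_length`` bases of read 1; the quality
    filter requires the mean Phred score over read 2 to exceed ``min_mean_q``.
    Every input pair lands in exactly one bin (a sample, low-quality, or
    unmatched).
    """
    if len(reads_r1) != len(reads_r2):
        raise QuantError(f"paired streams differ in length: "
                         f"{len(reads_r1)} vs {len(reads_r2)}")
    k = sheet.barcode_length
    result = DemuxResult(by_sample={s: [] for s in sheet.barcodes.values()})
    for r1, r2 in zip(reads_r1, reads_r2):
        if r2.mean_q <= min_mean_q:
            result.n_low_quality += 1
            continue
        sample = sheet.barcodes.get(r1.sequence[:k])
        if sample is None:
            result.n_unmatched += 1
            continue
        result.by_sample[sample].append(r2)
    return result


def trim_stretches(read: RawRead, min_stretch: int = MIN_STRETCH,
                   min_len: int = MIN_LEN) -> tuple[RawRead, int] | None:
    """Trim the 5' T-stretch and the 3' A-stretch from an insert read.

    A leading run of ≥ ``min_stretch`` T's is removed; the first A-run of
    ≥ ``min_stretch`` is removed together with everything 3' of it, and its
    length is returned as the soft-clipped tail (``soft_tail_A``) for PASS
    evidence downstream. Returns ``None`` when the trimmed read is shorter
    than ``min_len``.
    """
    seq, qual = read.sequence, read.qualities
    start = 0
    while start < len(seq) and seq[start] == "T":
        start += 1
    if start < min_stretch:
        start = 0

    tail_a = 0
    end = len(seq)
    i = start
    while i < len(seq):
        if seq[i] == "A":
            j = i
            while j < len(seq) and seq[j] == "A":
                j += 1
            if j - i >= min_stretch:
                tail_a = j - i
                end = i
                break
            i = j
        else:
            i += 1

    if end - start < max(1, min_len):
        return None
    if start == 0 and end == len(seq):
        return read, 0
    return RawRead(read.read_id, seq[start:end], qual[start:end]), tail_a


def drop_internal_priming_reads(alignments: Sequence[AlignedRead3p],
                                annot: Sequence[TrendIsoform],
                                genome: GenomeSequence,
                                flank: int = COUNT_FLANK,
                                ip_win: int = 20, ip_max_a: int = 12,
                                ip_max_run: int = 6) -> list[AlignedRead3p]:
    """Remove alignments attributable to internal priming.

    A read is removed when its 3' end falls in the counting window of a site
    flagged as internal-priming-prone, or when its own downstream genomic
    window is A-rich while the read matches no unflagged annotated site.
    """
    flagged = _interval_index(a for a in annot if a.site.ip_flag)
    clean = _interval_index(a for a in annot if not a.site.ip_flag)
    kept: list[AlignedRead3p] = []
    for read in alignments:
        key = (read.contig, read.strand)
        pos = read.end3
        if _hits(flagged.get(key, []), pos, flank):
            continue
        if not _hits(clean.get(key, []), pos, flank):
            probe = PolyASite(read.contig, read.strand, pos, support=1)
            if flag_internal_priming(probe, genome, ip_win, ip_max_a, ip_max_run):
                continue
        kept.append(read)
    return kept


def _interval_index(annot: Iterable[TrendIsoform]) -> dict[tuple[str, str], list[tuple[int, str]]]:
    idx: dict[tuple[str, str], list[tuple[int, str]]] = {}
    for iso in annot:
        idx.setdefault((iso.site.contig, iso.site.strand), []).append(
            (iso.site.position, iso.isoform_id))
    for positions in idx.values():
        positions.sort()
    return idx


def _sites_hit(positions: list[tuple[int, str]], pos: int, flank: int) -> list[str]:
    """Isoform ids whose window [site-flank, site+flank) contains ``pos``."""
    # pos in window  <=>  pos - flank < site <= pos + flank
    lo = bisect.bisect_right(positions, (pos - flank, "￿"))
    hi = bisect.bisect_right(positions, (pos + flank, "￿"))
    return [iso for _, iso in positions[lo:hi]]


def _hits(positions: list[tuple[int, str]], pos: int, flank: int) -> bool:
    return bool(_sites_hit(positions, pos, flank))


@dataclass
class CountResult:
    """Isoform × sample count matrix with per-isoform metadata and drop tallies."""

    counts: pd.DataFrame          # index isoform_id, one column per sample
    meta: pd.DataFrame            # index isoform_id; columns gene_id, rank_3p, cls, position
    tallies: pd.DataFrame         # index sample; columns assigned/ambiguous/no_feature


def count_isoforms(alignments_by_sample: Mapping[str, Sequence[AlignedRead3p]],
                   annot: Sequence[TrendIsoform],
                   flank: int = COUNT_FLANK) -> CountResult:
    """Intersection-strict counting of read 3' ends against isoform windows.

    Each isoform owns the window ``[site - flank, site + flank)`` on its
    strand. A read contributes one count to an isoform iff its 3'-terminal
    coordinate lies in exactly one window; reads in zero or several windows
    are tallied as ``no_feature`` / ``ambiguous``.
    """
    ids = [a.isoform_id for a in annot]
    if len(set(ids)) != len(ids):
        raise QuantError("isoform ids are not unique")

    windows = _interval_index(annot)

    samples = list(alignments_by_sample)
    counts = pd.DataFrame(0, index=ids, columns=samples, dtype=int)
    tallies = pd.DataFrame(0, index=samples,
                           columns=["assigned", "ambiguous", "no_feature"], dtype=int)
    for sample, reads in alignments_by_sample.items():
        for read in reads:
            hits = _sites_hit(windows.get((read.contig, read.strand), []),
                              read.end3, flank)
            if len(hits) == 1:
                counts.loc[hits[0], sample] += 1
                tallies.loc[sample, "assigned"] += 1
            elif not hits:
                tallies.loc[sample, "no_feature"] += 1
            else:
                tallies.loc[sample, "ambiguous"] += 1

    meta = pd.DataFrame(
        {
            "gene_id": [a.gene_id for a in annot],
            "rank_3p": [a.rank_3p for a in annot],
            "cls": [a.cls for a in annot],
            "contig": [a.site.contig for a in annot],
            "strand": [a.site.strand for a in annot],
            "position": [a.site.position for a in annot],
        },
        index=pd.Index(ids, name="isoform_id"),
    )
    return CountResult(counts=counts, meta=meta, tallies=tallies)
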