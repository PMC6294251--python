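"""Differential 3'-end isoform usage statistics.

For every gene in a knockdown-vs-control comparison, each isoform is tested
with a two-sided Fisher's exact test of its read count against the pooled
count of the gene's remaining isoforms; p-values are Benjamini–Hochberg
adjusted across all isoform tests of the comparison. Isoform usage is
expressed as a percentage of the gene's reads per condition, and the
fold-regulation of an isoform is the ratio of those percentages
(knockdown / control) — invariant to library-size scaling by construction.

Gene-level direction is summarised by the log2 *shortening index*: the
fold-regulation of the shorter of the gene's two most significantly affected
isoforms divided by that of the longer one. A positive index means the
shorter 3'-end isoform gained relative abundance upon perturbation
(3' UTR shortening); a negative index means lengthening. Relative positions
and fold changes of significant isoforms are reported against the
*Zero-isoform* — the longest significantly affected annotated isoform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

ALPHA = 0.05
PSEUDOCOUNT = 0.5
MIN_GENE_READS = 10

ANNOTATED_CLASSES = {"tandem", "internal", "non_coding"}


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class IsoformContingency:
    """2×2 table: tested isoform vs rest of gene, knockdown vs control."""

    a: int  # tested isoform, knockdown
    b: int  # other isoforms, knockdown
    c: int  # tested isoform, control
    d: int  # other isoforms, control


def fisher_isoform_test(tbl: IsoformContingency) -> float:
    """Two-sided Fisher exact p for one isoform against the rest of its gene.

    The two-sided p sums hypergeometric probabilities of all tables with the
    observed margins that are at most as probable as the observed one (the
    point-probability rule).
    """
    cells = (tbl.a, tbl.b, tbl.c, tbl.d)
    if any(x < 0 for x in cells):
        raise StatsError(f"negative cell in contingency table: {cells}")
    if tbl.a + tbl.b == 0 or tbl.c + tbl.d == 0:
        return 1.0
    return float(sps.fisher_exact([[tbl.a, tbl.b], [tbl.c, tbl.d]],
                                  alternative="two-sided")[1])


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr
    if np.any((arr < 0) | (arr > 1) | np.isnan(arr)):
        raise StatsError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def fold_regulation(counts_kd: Sequence[float], counts_ctrl: Sequence[float],
                    pseudocount: float = PSEUDOCOUNT) -> pd.DataFrame:
    """Per-isoform usage percentages and fold-regulation for one gene.

    Gene totals are normalised to 100% per condition (after adding
    ``pseudocount`` to every isoform count), and the knockdown percentage is
    divided by the control percentage. Scaling either condition's counts by a
    positive constant leaves the result unchanged.
    """
    kd = np.asarray(counts_kd, dtype=float) + pseudocount
    ctrl = np.asarray(counts_ctrl, dtype=float) + pseudocount
    if kd.shape != ctrl.shape or kd.ndim != 1 or kd.size < 2:
        raise StatsError("need matched per-isoform count vectors of length >= 2")
    if kd.sum() <= 0 or ctrl.sum() <= 0:
        raise StatsError("gene has no reads in one condition; untestable")
    pct_kd = 100.0 * kd / kd.sum()
    pct_ctrl = 100.0 * ctrl / ctrl.sum()
    return pd.DataFrame({"pct_kd": pct_kd, "pct_ctrl": pct_ctrl,
                         "fc": pct_kd / pct_ctrl})


@dataclass(frozen=True)
class IsoformTestResult:
    isoform_id: str
    gene_id: str
    rank_3p: int
    cls: str
    strand: str
    position: int
    p: float
    p_adj: float
    pct_kd: float
    pct_ctrl: float
    fc: float


@dataclass(frozen=True)
class GeneTrendSummary:
    gene_id: str
    zero_isoform_id: str | None
    si: float | None
    direction: str  # shortened | lengthened | none
    rel_positions: tuple[tuple[str, int, float], ...]  # (isoform_id, signed nt, fc)


def _dist3p(pos: int, strand: str) -> float:
    """Key that orders positions 5'→3' in transcript orientation."""
    return pos if strand == "+" else -pos


def zero_isoform(results: Sequence[IsoformTestResult], alpha: float = ALPHA) -> str | None:
    """The longest significantly affected *annotated* isoform, or None.

    Novel isoforms (past the annotated gene end) are excluded; among
    BH-significant annotated isoforms the strand-aware most-distal 3' end wins.
    """
    eligible = [r for r in results if r.p_adj <= alpha and r.cls in ANNOTATED_CLASSES]
    if not eligible:
        return None
    return max(eligible, key=lambda r: _dist3p(r.position, r.strand)).isoform_id


def relative_profile(results: Sequence[IsoformTestResult], zero_id: str,
                     alpha: float = ALPHA) -> tuple[tuple[str, int, float], ...]:
    """Signed distance (nt) of each significant isoform's 3' end from the
    Zero-isoform (negative = upstream, i.e. a shorter transcript), with fc."""
    zero = next(r for r in results if r.isoform_id == zero_id)
    out = []
    for r in results:
        if r.p_adj > alpha:
            continue
        delta = r.position - zero.position
        if r.strand == "-":
            delta = -delta
        out.append((r.isoform_id, delta, r.fc))
    return tuple(out)


def shortening_index(results: Sequence[IsoformTestResult],
                     alpha: float = ALPHA) -> tuple[float, str] | None:
    """log2 shortening index from a gene's two most significant isoforms.

    The two isoforms with the smallest adjusted p (ties → smaller raw p, then
    more distal 3' end) are ordered by 3' position; the index is
    log2(fc_shorter / fc_longer). Positive → relative gain of the shorter
    isoform upon perturbation ("shortened"); negative → "lengthened".
    Returns None when fewer than two isoforms are significant.
    """
    sig = [r for r in results if r.p_adj <= alpha]
    if len(sig) < 2:
        return None
    sig.sort(key=lambda r: (r.p_adj, r.p, -_dist3p(r.position, r.strand)))
    pair = sorted(sig[:2], key=lambda r: _dist3p(r.position, r.strand))
    shorter, longer = pair
    si = math.log2(shorter.fc / longer.fc)
    direction = "shortened" if si > 0 else ("lengthened" if si < 0 else "none")
    return si, direction


def set_enrichment(hits: set, universe: set, category: set) -> float:
    """Upper-tail hypergeometric enrichment p of ``hits`` in ``category``."""
    if not hits <= universe:
        raise StatsError("hits must be a subset of the universe")
    category = category & universe
    k = len(hits & category)
    return float(sps.hypergeom.sf(k - 1, len(universe), len(category), len(hits)))


def run_differential(counts: pd.DataFrame, meta: pd.DataFrame,
                     kd_samples: Sequence[str], ctrl_samples: Sequence[str],
                     alpha: float = ALPHA, pseudocount: float = PSEUDOCOUNT,
                     min_gene_reads: int = MIN_GENE_READS,
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full knockdown-vs-control isoform usage analysis.

    ``counts`` is an isoform × sample matrix; ``meta`` carries per-isoform
    ``gene_id``, ``rank_3p``, ``cls``, ``strand`` and ``position`` (as
    produced by :func:`trendseq.quant.count_isoforms`). Counts are pooled per
    condition; genes need at least two isoforms and ``min_gene_reads`` pooled
    reads in each condition to be testable. Returns the per-isoform result
    table and the per-gene summary table, both sorted by gene then rank.
    """
    kd = counts[list(kd_samples)].sum(axis=1)
    ctrl = counts[list(ctrl_samples)].sum(axis=1)

    records: list[IsoformTestResult] = []
    pvals: list[float] = []
    keep: list[str] = []
    for gene_id, iso_ids in meta.groupby("gene_id").groups.items():
        iso_ids = list(iso_ids)
        if len(iso_ids) < 2:
            continue
        gk, gc = kd[iso_ids], ctrl[iso_ids]
        if gk.sum() < min_gene_reads or gc.sum() < min_gene_reads:
            continue
        fr = fold_regulation(gk.to_numpy(), gc.to_numpy(), pseudocount)
        tot_k, tot_c = int(gk.sum()), int(gc.sum())
        for i, iso in enumerate(iso_ids):
            a, c = int(gk[iso]), int(gc[iso])
            p = fisher_isoform_test(IsoformContingency(a, tot_k - a, c, tot_c - c))
            m = meta.loc[iso]
            records.append(IsoformTestResult(
                isoform_id=iso, gene_id=gene_id, rank_3p=int(m["rank_3p"]),
                cls=str(m["cls"]), strand=str(m["strand"]), position=int(m["position"]),
                p=p, p_adj=np.nan, pct_kd=fr["pct_kd"][i], pct_ctrl=fr["pct_ctrl"][i],
                fc=fr["fc"][i]))
            pvals.append(p)
            keep.append(iso)

    p_adj = bh_adjust(pvals)
    records = [IsoformTestResult(**{**r.__dict__, "p_adj": float(q)})
               for r, q in zip(records, p_adj)]

    iso_df = pd.DataFrame([r.__dict__ for r in records]).set_index("isoform_id") \
        if records else pd.DataFrame(columns=["gene_id", "rank_3p", "cls", "strand",
                                              "position", "p", "p_adj", "pct_kd",
                                              "pct_ctrl", "fc"])
    gene_rows = []
    by_gene: dict[str, list[IsoformTestResult]] = {}
    for r in records:
        by_gene.setdefault(r.gene_id, []).append(r)
    for gene_id in sorted(by_gene):
        rs = by_gene[gene_id]
        zid = zero_isoform(rs, alpha)
        si_dir = shortening_index(rs, alpha)
        rel = relative_profile(rs, zid, alpha) if zid else ()
        gene_rows.append({
            "gene_id": gene_id,
            "zero_isoform_id": zid,
            "si": si_dir[0] if si_dir else np.nan,
            "direction": si_dir[1] if si_dir else "none",
            "n_significant": sum(r.p_adj <= alpha for r in rs),
            "rel_positions": ";".join(f"{i}:{d}:{fc:.4g}" for i, d, fc in rel),
        })
    gene_df = pd.DataFrame(gene_rows).set_index("gene_id") if gene_rows else \
        pd.DataFrame(columns=["zero_isoform_id", "si", "direction",
                              "n_significant", "rel_positions"])
    if not iso_df.empty:
        iso_df = iso_df.sort_values(["gene_id", "rank_3p"])
    return iso_df, gene_df
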