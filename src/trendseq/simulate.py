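"""Synthetic data for every stage of the 3'-end diversification pipeline.

The generator plants a ground truth and emulates the data the pipeline
consumes: a genome with genes carrying several tandem poly(A) sites and
intergenic adenosine-rich internal-priming decoys; Dirichlet-distributed
isoform usage with a condition-dependent proximal→distal shift in perturbed
genes; multinomial read counts at a set depth; barcoded paired reads with
quality strings and poly(A) tails; lognormal probe intensities resolving a
short/common and a long isoform per gene; and survival times whose hazard
follows the proximal-to-distal isoform ratio.

A single global seed fans out into named sub-streams so each stage can be
regenerated independently and deterministically.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import (
    AlignedRead3p,
    GeneModel,
    GenomeSequence,
    PolyASite,
    TrendIsoform,
    reverse_complement,
)
from .quant import RawRead, SampleSheet


class SimulationError(ValueError):
    pass


DEFAULT_BARCODES = ("ACGTACGTA", "TGCTGCTGC", "CAGCAGCAG", "GTCGTCGTC",
                    "AATTCCGGA", "TTGGCCAAT", "CCAATTGGC", "GGCCAATTG")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic screen and clinical stages."""

    seed: int = 0
    n_genes: int = 300
    isoforms_per_gene: tuple[int, int] = (2, 4)
    utr_len: tuple[int, int] = (600, 1500)
    cds_len: int = 500
    intergenic_gap: int = 400
    usage_alpha: float = 2.0
    effect: float = 0.3            # usage mass moved to the distal-most isoform
    frac_perturbed: float = 0.3
    depth: int = 200               # reads per gene per condition
    poisson_depth: bool = False
    decoy_rate: float = 0.2        # A-rich decoys per kb of intergenic sequence
    decoy_read_frac: float = 0.02  # fraction of extra reads from decoys
    barcodes: tuple[str, ...] = DEFAULT_BARCODES[:2]
    read_len: int = 50
    tail_len: tuple[int, int] = (5, 15)
    qual_mean: float = 30.0
    array_noise_sd: float = 0.25   # log2 scale
    n_clinical_samples: int = 100
    baseline_hazard: float = 0.1
    surv_beta: float = 1.0
    censor_rate: float = 0.05

    def __post_init__(self):
        if not 0.0 <= self.frac_perturbed <= 1.0:
            raise SimulationError("frac_perturbed must lie in [0, 1]")
        if min(self.depth, self.n_genes + 1, self.usage_alpha,
               self.utr_len[0], self.read_len) <= 0:
            raise SimulationError("rates and lengths must be positive")


def stream_rng(seed: int, name: str) -> np.random.Generator:
    """Named deterministic sub-stream of the global seed."""
    digest = hashlib.blake2s(f"{seed}:{name}".encode(), digest_size=4).digest()
    return np.random.default_rng([seed % 2 ** 31, int.from_bytes(digest, "big")])


@dataclass
class ReferenceTruth:
    genome: GenomeSequence
    genes: list[GeneModel]
    isoforms: list[TrendIsoform]          # planted true isoforms, ranked
    decoys: list[tuple[str, str, int]]    # (contig, strand, first base of A-run)


@dataclass
class GroundTruth:
    usage_ctrl: dict[str, np.ndarray]
    usage_kd: dict[str, np.ndarray]
    perturbed: dict[str, bool]
    direction: dict[str, str]             # expected per-gene trend on perturbation


_GC = np.array(list("CG"))
_BASES = np.array(list("ACGT"))
MIN_SITE_SPACING = 100
DECOY_RUN = 20
_IP_GUARD = 20  # strand-sense A-free window planted downstream of every true site


def _random_sequence(rng: np.random.Generator, n: int, max_run: int = 4) -> np.ndarray:
    """Uniform random sequence with A- and T-runs capped below the trimming
    threshold, so genuine inserts on either strand survive stretch trimming."""
    seq = rng.choice(_BASES, size=n)
    run = 0
    for i in range(n):
        if seq[i] in ("A", "T") and i > 0 and seq[i] == seq[i - 1]:
            run += 1
            if run >= max_run - 1:
                seq[i] = rng.choice(_GC)
                run = 0
        else:
            run = 0
    return seq


def simulate_reference(cfg: SimConfig) -> ReferenceTruth:
    """Genome + gene models with planted tandem poly(A) sites and decoys."""
    rng = stream_rng(cfg.seed, "reference")
    k_lo, k_hi = cfg.isoforms_per_gene
    genes: list[GeneModel] = []
    isoforms: list[TrendIsoform] = []
    pieces: list[np.ndarray] = []
    decoys: list[tuple[str, str, int]] = []
    contig = "chr1"
    cursor = 0

    def _advance_gap(length: int) -> None:
        nonlocal cursor
        gap = _random_sequence(rng, length)
        n_decoys = int(round(cfg.decoy_rate * length / 1000.0))
        for _ in range(n_decoys):
            start = int(rng.integers(50, length - DECOY_RUN - 50))
            gap[start:start + DECOY_RUN] = "A"
            decoys.append((contig, "+", cursor + start))
        pieces.append(gap)
        cursor += length

    _advance_gap(cfg.intergenic_gap)
    for g in range(cfg.n_genes):
        strand = "+" if g % 2 == 0 else "-"
        utr = int(rng.integers(cfg.utr_len[0], cfg.utr_len[1] + 1))
        k = int(rng.integers(k_lo, k_hi + 1))
        if utr < MIN_SITE_SPACING * (k + 1):
            raise SimulationError(
                f"UTR of {utr} nt cannot hold {k} sites spaced >= {MIN_SITE_SPACING} nt")
        gene_len = cfg.cds_len + utr
        seq = _random_sequence(rng, gene_len)
        start, end = cursor, cursor + gene_len
        gene_id = f"g{g:04d}"

        # tandem sites evenly spread through the 3' UTR, proximal -> distal
        offsets = np.linspace(MIN_SITE_SPACING, utr - _IP_GUARD - 5, k).round().astype(int)
        if strand == "+":
            cds_end = start + cfg.cds_len
            positions = [start + cfg.cds_len + int(o) for o in offsets]
            ann3 = end
        else:
            cds_end = start + utr
            positions = [start + utr - 1 - int(o) for o in offsets]
            ann3 = start
        for rank, pos in enumerate(positions, start=1):
            local = pos - cursor
            # sanitise the downstream window plus the last 4 transcript bases:
            # reads then carry no genomic A's at the cleavage site, so the
            # trimmed 3' end is exact and templated-A counts are zero
            if strand == "+":
                window = slice(local - 3, local + 1 + _IP_GUARD)
            else:
                window = slice(max(0, local - _IP_GUARD), local + 4)
            # C/G only: strand-sense A-free on both strands, and run-safe
            seq[window] = rng.choice(_GC, size=len(range(*window.indices(gene_len))))
            site = PolyASite(contig, strand, pos, support=0, ip_flag=False)
            isoforms.append(TrendIsoform(f"{gene_id}.{rank}", gene_id, site,
                                         "tandem", rank))
        genes.append(GeneModel(gene_id, contig, strand, ((start, end),),
                               cds_end, ann3, "coding"))
        pieces.append(seq)
        cursor += gene_len
        _advance_gap(cfg.intergenic_gap)

    genome = GenomeSequence({contig: "".join(np.concatenate(pieces))}) if pieces \
        else GenomeSequence({contig: ""})
    return ReferenceTruth(genome, genes, isoforms, decoys)


def shift_usage_distal(usage: np.ndarray, effect: float, cap: float = 0.97) -> np.ndarray:
    """Move ``effect`` probability mass onto the distal-most isoform.

    The distal usage is increased additively (capped at ``cap``) and the
    remaining isoforms are rescaled proportionally; a negative effect moves
    mass the other way (distal → proximal-ward).
    """
    u = np.asarray(usage, dtype=float).copy()
    target = min(max(u[-1] + effect, 1.0 - cap), cap)
    rest = 1.0 - target
    if u[:-1].sum() > 0:
        u[:-1] *= rest / u[:-1].sum()
    u[-1] = target
    return u


def simulate_counts(cfg: SimConfig, ref: ReferenceTruth,
                    ) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Two-condition isoform count matrix from Dirichlet-multinomial sampling.

    Control usage per gene is Dirichlet(``usage_alpha``); perturbed genes get
    the distal shift of size ``effect`` in the knockdown condition. Counts are
    multinomial at ``depth`` per gene and condition (Poisson-jittered when
    ``poisson_depth``). Returns (counts, meta, truth) with samples ``kd`` and
    ``ctrl``.
    """
    rng = stream_rng(cfg.seed, "counts")
    truth = GroundTruth({}, {}, {}, {})
    rows, ids, meta_rows = [], [], []
    gene_ids = sorted({iso.gene_id for iso in ref.isoforms})
    n_pert = int(round(cfg.frac_perturbed * len(gene_ids)))
    perturbed_set = set(rng.choice(gene_ids, size=n_pert, replace=False)) if n_pert else set()

    by_gene: dict[str, list[TrendIsoform]] = {}
    for iso in ref.isoforms:
        by_gene.setdefault(iso.gene_id, []).append(iso)

    for gene_id in gene_ids:
        isos = sorted(by_gene[gene_id], key=lambda i: i.rank_3p)
        k = len(isos)
        u_ctrl = rng.dirichlet(np.full(k, cfg.usage_alpha))
        pert = gene_id in perturbed_set and cfg.effect != 0 and k >= 2
        u_kd = shift_usage_distal(u_ctrl, cfg.effect) if pert else u_ctrl.copy()
        truth.usage_ctrl[gene_id] = u_ctrl
        truth.usage_kd[gene_id] = u_kd
        truth.perturbed[gene_id] = bool(pert)
        truth.direction[gene_id] = (
            "none" if not pert else ("lengthened" if cfg.effect > 0 else "shortened"))
        for cond, u in (("kd", u_kd), ("ctrl", u_ctrl)):
            depth = rng.poisson(cfg.depth) if cfg.poisson_depth else cfg.depth
            counts = rng.multinomial(depth, u)
            for iso, c in zip(isos, counts):
                rows.append((iso.isoform_id, cond, int(c)))
        for iso in isos:
            ids.append(iso.isoform_id)
            meta_rows.append({"gene_id": gene_id, "rank_3p": iso.rank_3p,
                              "cls": iso.cls, "contig": iso.site.contig,
                              "strand": iso.site.strand,
                              "position": iso.site.position})

    counts = pd.DataFrame(0, index=pd.Index(ids, name="isoform_id"),
                          columns=["kd", "ctrl"], dtype=int)
    for iso_id, cond, c in rows:
        counts.loc[iso_id, cond] = c
    meta = pd.DataFrame(meta_rows, index=pd.Index(ids, name="isoform_id"))
    return counts, meta, truth


def simulate_fastq(cfg: SimConfig, ref: ReferenceTruth, counts: pd.DataFrame,
                   ) -> tuple[list[RawRead], list[RawRead], SampleSheet]:
    """Paired barcode/insert reads realising a planted count matrix.

    Column ``i`` of ``counts`` is emitted under barcode ``cfg.barcodes[i]``.
    Insert reads end at the isoform's cleavage site with an appended poly(A)
    tail; a ``decoy_read_frac`` fraction of extra reads per sample instead
    terminates at planted genomic A-runs (internal-priming truth).
    """
    if counts.shape[1] > len(cfg.barcodes):
        raise SimulationError("not enough barcodes for the requested samples")
    rng = stream_rng(cfg.seed, "fastq")
    iso_by_id = {iso.isoform_id: iso for iso in ref.isoforms}
    sheet = SampleSheet({cfg.barcodes[i]: str(col)
                         for i, col in enumerate(counts.columns)})
    r1_out: list[RawRead] = []
    r2_out: list[RawRead] = []
    serial = 0

    def _emit(sample_barcode: str, insert: str, tail: int, tag: str) -> None:
        nonlocal serial
        seq = insert + "A" * tail
        mean_q = float(np.clip(rng.normal(cfg.qual_mean, 2.0), 3, 40))
        quals = tuple(int(q) for q in
                      np.clip(rng.normal(mean_q, 2.0, len(seq)).round(), 2, 40))
        rid = f"r{serial:07d}|{tag}"
        serial += 1
        r1_out.append(RawRead(rid, sample_barcode, tuple([35] * len(sample_barcode))))
        r2_out.append(RawRead(rid, seq, quals))

    for i, col in enumerate(counts.columns):
        barcode = cfg.barcodes[i]
        n_true = 0
        for iso_id, n in counts[col].items():
            iso = iso_by_id[iso_id]
            for _ in range(int(n)):
                tail = int(rng.integers(cfg.tail_len[0], cfg.tail_len[1] + 1))
                L = cfg.read_len - tail
                pos = iso.site.position
                if iso.site.strand == "+":
                    insert = ref.genome.fetch(iso.site.contig, pos - L + 1, pos + 1, "+")
                else:
                    insert = ref.genome.fetch(iso.site.contig, pos, pos + L, "-")
                _emit(barcode, insert, tail, f"{col}|{iso_id}")
                n_true += 1
        n_decoy = int(round(cfg.decoy_read_frac * n_true)) if ref.decoys else 0
        for _ in range(n_decoy):
            contig, strand, run_start = ref.decoys[int(rng.integers(len(ref.decoys)))]
            tail = int(rng.integers(cfg.tail_len[0], cfg.tail_len[1] + 1))
            L = cfg.read_len - tail
            end3 = run_start - 1  # last non-A genomic base before the planted run
            insert = ref.genome.fetch(contig, end3 - L + 1, end3 + 1, "+")
            _emit(barcode, insert, tail, f"{col}|decoy")
    return r1_out, r2_out, sheet


def exact_align(trimmed: Sequence[tuple[RawRead, int]], genome: GenomeSequence,
                k: int = 24) -> list[AlignedRead3p]:
    """Exact-match placement of trimmed reads on a small synthetic genome.

    This is a k-mer-anchored exact substring locator for synthetic
    round-trip experiments, not a general-purpose aligner (real data is
    aligned externally and consumed as SAM). Reads whose sequence does not
    occur uniquely in either orientation are skipped.
    """
    index: dict[str, list[tuple[str, int]]] = {}
    for contig, seq in genome.contigs.items():
        for i in range(len(seq) - k + 1):
            index.setdefault(seq[i:i + k], []).append((contig, i))

    out: list[AlignedRead3p] = []
    for read, soft_tail in trimmed:
        seq = read.sequence
        if len(seq) < k:
            continue
        placed = None
        for strand, query in (("+", seq), ("-", reverse_complement(seq))):
            for contig, i in index.get(query[:k], []):
                ref_seq = genome.contigs[contig]
                if ref_seq[i:i + len(query)] == query:
                    placed = AlignedRead3p(read.read_id, contig, strand,
                                           i, i + len(query), soft_tail)
                    break
            if placed:
                break
        if placed:
            out.append(placed)
    return out


def simulate_array(cfg: SimConfig, ref: ReferenceTruth, truth: GroundTruth,
                   ) -> tuple[list, pd.DataFrame, pd.Series]:
    """Probe table + lognormal expression matrix resolving two isoforms per gene.

    Half the samples follow the knockdown (perturbed) usage pattern, half the
    control pattern. Each gene gets a common/short probe upstream of its
    proximal site (signal ∝ total gene abundance) and a long-isoform probe
    between the two distal-most sites (signal ∝ distal isoform abundance),
    with Gaussian log2 noise of ``array_noise_sd``.
    """
    from .clinic import ProbeRecord

    rng = stream_rng(cfg.seed, "array")
    n = cfg.n_clinical_samples
    samples = [f"s{i:03d}" for i in range(n)]
    groups = pd.Series([1] * (n // 2) + [0] * (n - n // 2), index=samples)

    by_gene: dict[str, list[TrendIsoform]] = {}
    for iso in ref.isoforms:
        by_gene.setdefault(iso.gene_id, []).append(iso)

    probes: list[ProbeRecord] = []
    rows: dict[str, np.ndarray] = {}
    for gene_id, isos in sorted(by_gene.items()):
        isos.sort(key=lambda i: i.rank_3p)
        if len(isos) < 2:
            continue
        s = isos[0].site
        prox, dist = isos[-2].site.position, isos[-1].site.position
        if s.strand == "+":
            short_iv = (s.position - 90, s.position - 30)
            long_iv = (min(prox, dist) + 20, min(prox, dist) + 80)
        else:
            short_iv = (s.position + 30, s.position + 90)
            long_iv = (max(prox, dist) - 80, max(prox, dist) - 20)
        p_short = ProbeRecord(f"{gene_id}_short", s.contig, s.strand, *short_iv)
        p_long = ProbeRecord(f"{gene_id}_long", s.contig, s.strand, *long_iv)
        probes.extend([p_short, p_long])

        u_kd, u_ctrl = truth.usage_kd[gene_id], truth.usage_ctrl[gene_id]
        short_sig = np.empty(n)
        long_sig = np.empty(n)
        for j, samp in enumerate(samples):
            u = u_kd if groups[samp] == 1 else u_ctrl
            total = cfg.depth
            short_sig[j] = total
            long_sig[j] = max(total * u[-1], 0.25)
        noise = rng.normal(0.0, cfg.array_noise_sd, size=(2, n))
        rows[p_short.probe_id] = 2.0 ** (np.log2(short_sig) + noise[0])
        rows[p_long.probe_id] = 2.0 ** (np.log2(long_sig) + noise[1])

    expr = pd.DataFrame(rows, index=samples).T
    expr.columns = samples
    return probes, expr, groups


def simulate_survival(cfg: SimConfig, truth: GroundTruth,
                      ) -> pd.DataFrame:
    """Survival table whose hazard follows the proximal-to-distal usage ratio.

    Each sample's covariate ``log_pd_ratio`` is its mean log proximal-to-
    distal usage ratio over perturbed genes (knockdown pattern for the first
    half of samples, control for the rest) plus sampling noise; event times
    are exponential with hazard ``baseline_hazard·exp(surv_beta·x)`` and
    censoring is exponential at ``censor_rate``. Decoy covariates
    ``noise1``/``noise2`` are independent standard normals.
    """
    rng = stream_rng(cfg.seed, "survival")
    n = cfg.n_clinical_samples
    pert_genes = [g for g, f in truth.perturbed.items() if f]
    if not pert_genes:
        pert_genes = list(truth.usage_ctrl)
    log_ratio_kd = np.mean([np.log(truth.usage_kd[g][0] / truth.usage_kd[g][-1])
                            for g in pert_genes])
    log_ratio_ctrl = np.mean([np.log(truth.usage_ctrl[g][0] / truth.usage_ctrl[g][-1])
                              for g in pert_genes])
    rows = []
    for i in range(n):
        base = log_ratio_kd if i < n // 2 else log_ratio_ctrl
        x = base + rng.normal(0.0, 0.3)
        hazard = cfg.baseline_hazard * np.exp(cfg.surv_beta * x)
        t_event = rng.exponential(1.0 / hazard)
        t_censor = rng.exponential(1.0 / cfg.censor_rate) if cfg.censor_rate > 0 \
            else np.inf
        rows.append({"sample_id": f"s{i:03d}",
                     "time": float(min(t_event, t_censor)),
                     "event": int(t_event <= t_censor),
                     "log_pd_ratio": float(x),
                     "noise1": float(rng.normal()),
                     "noise2": float(rng.normal())})
    return pd.DataFrame(rows).set_index("sample_id")
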