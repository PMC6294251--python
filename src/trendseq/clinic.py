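"""Clinical 3'-end signature analysis from expression-array data.

3'-end sequencing defines tandem poly(A) sites per gene; array probes that
map between two sites read out long-isoform-specific signal, while probes
upstream of the proximal site read the common region shared by all isoforms
(a proxy for the shortest isoform). The per-sample *lengthening index* of a
gene is the expression of a long isoform divided by that of the shortest
isoform; it feeds group comparisons (t-test on log2 ratios), per-gene ROC
curves, a ridge-logistic multifactor ROC over a signature of discriminative
genes (AUC > threshold), paired AUC comparisons (DeLong / bootstrap), and
survival analysis: Kaplan–Meier with log-rank tests and a bootstrapped Cox
proportional-hazards pipeline scored by Harrell's concordance index on
held-out splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve

from .annotation import TrendIsoform
from .stats import bh_adjust

AUC_THRESHOLD = 0.7
TRAIN_FRAC = 0.7
N_BOOT_AUC = 2000
N_BOOT_COX = 100
UPSTREAM_SPAN = 2000
BG_PERCENTILE = 5.0
BG_FLOOR = 1e-3


class ClinicError(ValueError):
    pass


# ---------------------------------------------------------------- probe mapping

@dataclass(frozen=True)
class ProbeRecord:
    probe_id: str
    contig: str
    strand: str
    start: int
    end: int  # half-open


@dataclass
class IsoformProbeMap:
    """gene_id → ordered (proximal→distal) isoforms with their probe ids."""

    genes: dict[str, list[tuple[str, list[str]]]] = field(default_factory=dict)


def map_probes_to_isoforms(probes: Sequence[ProbeRecord],
                           annot: Sequence[TrendIsoform],
                           upstream_span: int = UPSTREAM_SPAN) -> IsoformProbeMap:
    """Associate array probes with tandem 3'-end isoform regions.

    Per gene the tandem sites partition the 3' UTR in transcript orientation:
    the region upstream of the proximal site (bounded by ``upstream_span``)
    is common to all isoforms and proxies the shortest one; the region between
    consecutive sites is specific to the longer isoform ending at its distal
    boundary. A probe overlapping exactly one region is assigned there;
    probes straddling regions or matching none are dropped, and genes whose
    probes resolve fewer than two isoforms are dropped.
    """
    by_gene: dict[str, list[TrendIsoform]] = {}
    for iso in annot:
        if iso.cls == "tandem":
            by_gene.setdefault(iso.gene_id, []).append(iso)

    result = IsoformProbeMap()
    for gene_id, isos in sorted(by_gene.items()):
        if len(isos) < 2:
            continue
        isos.sort(key=lambda i: i.rank_3p)
        strand = isos[0].site.strand
        contig = isos[0].site.contig
        pos = [i.site.position for i in isos]
        # genomic half-open region per isoform, proximal→distal
        regions: list[tuple[int, int]] = []
        if strand == "+":
            regions.append((pos[0] - upstream_span, pos[0] + 1))
            for a, b in zip(pos, pos[1:]):
                regions.append((a + 1, b + 1))
        else:
            regions.append((pos[0], pos[0] + upstream_span + 1))
            for a, b in zip(pos, pos[1:]):
                regions.append((b, a))

        assigned: list[list[str]] = [[] for _ in isos]
        for probe in probes:
            if probe.contig != contig or probe.strand != strand:
                continue
            hits = [k for k, (s, e) in enumerate(regions)
                    if probe.start < e and s < probe.end]
            if len(hits) == 1:
                assigned[hits[0]].append(probe.probe_id)
        n_resolved = sum(bool(lst) for lst in assigned)
        if n_resolved >= 2 and assigned[0]:
            result.genes[gene_id] = [(iso.isoform_id, sorted(lst))
                                     for iso, lst in zip(isos, assigned)]
    return result


# ------------------------------------------------------------ expression matrix

def preprocess_expression(raw: pd.DataFrame, bg_percentile: float = BG_PERCENTILE,
                          floor: float = BG_FLOOR) -> pd.DataFrame:
    """Background-correct and quantile-normalise a probe × array matrix.

    Per array the lower ``bg_percentile`` percentile is subtracted as
    background and values are floored at a small positive constant; columns
    are then quantile-normalised to the mean sorted distribution, so all
    arrays share identical sorted values afterwards.
    """
    if (raw <= 0).any().any():
        raise ClinicError("raw intensities must be positive")
    bg = raw.quantile(bg_percentile / 100.0, axis=0)
    corrected = (raw - bg).clip(lower=floor)
    ranked = corrected.rank(method="average")
    mean_sorted = np.sort(corrected.to_numpy(), axis=0).mean(axis=1)
    # interpolate mean distribution at (possibly tied, fractional) ranks
    grid = np.arange(1, len(mean_sorted) + 1, dtype=float)
    out = {col: np.interp(ranked[col].to_numpy(), grid, mean_sorted)
           for col in corrected.columns}
    return pd.DataFrame(out, index=corrected.index)


def lengthening_index(expr: pd.DataFrame, probe_map: IsoformProbeMap) -> pd.DataFrame:
    """Per-sample long/shortest isoform expression ratios.

    For every gene and every detectable long isoform, li = expression(long) /
    expression(shortest); multi-probe signals are averaged. Zero denominators
    yield NaN for that sample. Rows are indexed by (gene_id, long_isoform_id).
    """
    rows, index = [], []
    for gene_id, isos in probe_map.genes.items():
        short_probes = isos[0][1]
        if not short_probes:
            continue
        denom = expr.loc[short_probes].mean(axis=0)
        denom = denom.where(denom != 0)
        for iso_id, probes in isos[1:]:
            if not probes:
                continue
            rows.append(expr.loc[probes].mean(axis=0) / denom)
            index.append((gene_id, iso_id))
    if not rows:
        return pd.DataFrame(columns=expr.columns)
    return pd.DataFrame(rows, index=pd.MultiIndex.from_tuples(
        index, names=["gene_id", "isoform_id"]))


def group_compare_li(li: pd.Series, groups: pd.Series) -> tuple[float, float]:
    """Two-sided Welch-free two-sample t-test on log2 lengthening indices."""
    labels = groups.unique()
    if len(labels) != 2:
        raise ClinicError("exactly two group labels required")
    x = np.log2(li[groups == labels[0]].dropna())
    y = np.log2(li[groups == labels[1]].dropna())
    if len(x) < 2 or len(y) < 2:
        raise ClinicError("need at least two samples per group")
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        return np.nan, np.nan
    t, p = sps.ttest_ind(x, y)
    return float(t), float(p)


# ------------------------------------------------------------------------- ROC

@dataclass
class RocResult:
    auc: float
    n_pos: int
    n_neg: int
    fpr: np.ndarray
    tpr: np.ndarray
    scores: np.ndarray
    labels: np.ndarray


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> RocResult:
    """ROC curve and AUC as the normalised Mann–Whitney statistic (ties ½)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ClinicError("both classes must be present")
    # rank-based AUC: U statistic with half-credit for ties
    ranks = sps.rankdata(scores)
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    fpr, tpr, _ = roc_curve(labels, scores)
    return RocResult(float(auc), n_pos, n_neg, fpr, tpr, scores, labels)


def select_signature_genes(rocs: Mapping[str, RocResult],
                           threshold: float = AUC_THRESHOLD) -> list[str]:
    """Genes whose AUC strictly exceeds the threshold, descending by AUC."""
    chosen = [(g, r.auc) for g, r in rocs.items() if r.auc > threshold]
    chosen.sort(key=lambda t: (-t[1], t[0]))
    return [g for g, _ in chosen]


def _train_test_split(labels: np.ndarray, train_frac: float,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Stratified index split (per label class)."""
    train_idx: list[int] = []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        n_train = max(1, int(round(train_frac * len(idx))))
        n_train = min(n_train, len(idx) - 1)
        train_idx.extend(idx[:n_train])
    mask = np.zeros(len(labels), dtype=bool)
    mask[train_idx] = True
    return np.flatnonzero(mask), np.flatnonzero(~mask)


def multifactor_roc(features: pd.DataFrame, labels: Sequence[int], seed: int = 0,
                    train_frac: float = TRAIN_FRAC, ridge_c: float = 1.0) -> RocResult:
    """Held-out ROC of a combined signature score.

    ``features`` is gene × sample (log2 short-to-long ratios). A ridge-
    penalised logistic model is fitted on a stratified ``train_frac`` split
    and the ROC is evaluated on the held-out samples.
    """
    if features.shape[0] < 2:
        raise ClinicError("multifactor ROC needs at least two genes")
    labels = np.asarray(labels, dtype=int)
    x = features.to_numpy(dtype=float).T
    rng = np.random.default_rng(seed)
    train, test = _train_test_split(labels, train_frac, rng)
    model = LogisticRegression(C=ridge_c, max_iter=2000)  # ridge (l2) penalty
    model.fit(x[train], labels[train])
    combined = model.decision_function(x[test])
    return roc_auc(combined, labels[test])


def _placements(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values V10 (per positive) and V01 (per negative)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    cmp = (pos[:, None] > neg[None, :]) + 0.5 * (pos[:, None] == neg[None, :])
    return cmp.mean(axis=1), 1.0 - cmp.mean(axis=0)


def delong_variance(roc: RocResult) -> float:
    """DeLong variance of a single AUC from placement values."""
    v10, v01 = _placements(roc.scores, roc.labels)
    return float(np.var(v10, ddof=1) / len(v10) + np.var(v01, ddof=1) / len(v01))


def compare_auc(roc_a: RocResult, roc_b: RocResult, method: str = "delong",
                n_boot: int = N_BOOT_AUC, seed: int = 0) -> float:
    """Two-sided p for a paired AUC difference (same samples under both ROCs).

    ``delong`` uses placement-value covariances and a z-test; ``bootstrap``
    draws paired resamples and returns the percentile p of the AUC difference.
    Identical scores give p = 1.
    """
    if len(roc_a.labels) != len(roc_b.labels) or np.any(roc_a.labels != roc_b.labels):
        raise ClinicError("paired comparison requires identical samples and labels")
    if np.array_equal(roc_a.scores, roc_b.scores):
        return 1.0
    if method == "delong":
        va10, va01 = _placements(roc_a.scores, roc_a.labels)
        vb10, vb01 = _placements(roc_b.scores, roc_b.labels)
        m, n = len(va10), len(va01)
        s10 = np.cov(np.vstack([va10, vb10]), ddof=1)
        s01 = np.cov(np.vstack([va01, vb01]), ddof=1)
        var = ((s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
               + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n)
        if var <= 0:
            return 1.0
        z = (roc_a.auc - roc_b.auc) / np.sqrt(var)
        return float(2.0 * sps.norm.sf(abs(z)))
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        labels = roc_a.labels
        idx_all = np.arange(len(labels))
        deltas = np.empty(n_boot)
        for r in range(n_boot):
            idx = rng.choice(idx_all, size=len(idx_all), replace=True)
            while len(np.unique(labels[idx])) < 2:
                idx = rng.choice(idx_all, size=len(idx_all), replace=True)
            da = roc_auc(roc_a.scores[idx], labels[idx]).auc
            db = roc_auc(roc_b.scores[idx], labels[idx]).auc
            deltas[r] = da - db
        frac = min((deltas <= 0).mean(), (deltas >= 0).mean())
        return float(min(1.0, 2.0 * frac))
    raise ClinicError(f"unknown method {method!r}")


# -------------------------------------------------------------------- survival

@dataclass(frozen=True)
class SurvivalRecord:
    sample_id: str
    time: float
    event: int
    covariates: Mapping[str, float] = field(default_factory=dict)


def survival_frame(records: Sequence[SurvivalRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        if r.time < 0 or r.event not in (0, 1):
            raise ClinicError(f"bad survival record {r.sample_id!r}")
        rows.append({"sample_id": r.sample_id, "time": r.time, "event": r.event,
                     **r.covariates})
    return pd.DataFrame(rows).set_index("sample_id")


def km_logrank(surv: pd.DataFrame, grouping: pd.Series,
               ) -> tuple[float, float, dict[str, pd.DataFrame]]:
    """Kaplan–Meier curves per group and the two-group log-rank test.

    Returns (chi-square statistic, p, group → KM survival table). With a
    single event-free group the statistic is reported as NaN.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    labels = grouping.unique()
    if len(labels) != 2:
        raise ClinicError("log-rank comparison requires exactly two groups")
    curves = {}
    for lab in labels:
        sel = surv.loc[grouping[grouping == lab].index]
        kmf = KaplanMeierFitter()
        kmf.fit(sel["time"], sel["event"], label=str(lab))
        curves[str(lab)] = kmf.survival_function_
    a = surv.loc[grouping[grouping == labels[0]].index]
    b = surv.loc[grouping[grouping == labels[1]].index]
    if a["event"].sum() == 0 and b["event"].sum() == 0:
        return float("nan"), float("nan"), curves
    res = logrank_test(a["time"], b["time"], a["event"], b["event"])
    return float(res.test_statistic), float(res.p_value), curves


def km_logrank_scan(surv: pd.DataFrame, groupings: Mapping[str, pd.Series]
                    ) -> pd.DataFrame:
    """Log-rank over a family of candidate groupings, BH-adjusted."""
    rows = []
    for name, grouping in groupings.items():
        chi2, p, _ = km_logrank(surv, grouping)
        rows.append({"grouping": name, "chi2": chi2, "p": p})
    df = pd.DataFrame(rows).set_index("grouping")
    df["p_adj"] = bh_adjust(df["p"].fillna(1.0))
    return df


def harrell_c(time: Sequence[float], risk: Sequence[float],
              event: Sequence[int]) -> float:
    """Harrell's C: P(higher risk fails earlier) over comparable pairs."""
    from lifelines.utils import concordance_index

    return float(concordance_index(time, -np.asarray(risk, dtype=float), event))


def cox_bootstrap(surv: pd.DataFrame, covariate_sets: Mapping[str, Sequence[str]],
                  train_frac: float = TRAIN_FRAC, n_boot: int = N_BOOT_COX,
                  seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bootstrapped Cox proportional-hazards model comparison.

    For each replicate an event-stratified random ``train_frac`` split is
    drawn; each named covariate set is fitted by Cox partial likelihood
    (Efron tie handling) on the training part and scored by Harrell's C-index
    on the held-out part. Replicates where a fit fails to converge are
    dropped (a hard error if more than 20% drop). Returns the replicate ×
    model C-index table and the matrix of paired two-sided t-test p-values
    between models.
    """
    from lifelines import CoxPHFitter

    rng_master = np.random.default_rng(seed)
    labels = surv["event"].to_numpy()
    c_rows = []
    n_failed = 0
    for rep in range(n_boot):
        rng = np.random.default_rng(rng_master.integers(2 ** 31))
        train, test = _train_test_split(labels, train_frac, rng)
        row = {}
        try:
            for name, covs in covariate_sets.items():
                cph = CoxPHFitter()
                cph.fit(surv.iloc[train][["time", "event", *covs]],
                        duration_col="time", event_col="event")
                risk = cph.predict_partial_hazard(surv.iloc[test][list(covs)])
                row[name] = harrell_c(surv.iloc[test]["time"], risk,
                                      surv.iloc[test]["event"])
        except Exception:
            n_failed += 1
            continue
        c_rows.append(row)
    if n_failed > 0.2 * n_boot:
        raise ClinicError(f"{n_failed}/{n_boot} bootstrap replicates failed to converge")
    c_df = pd.DataFrame(c_rows)

    names = list(covariate_sets)
    pmat = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if np.allclose(c_df[a], c_df[b]):
                p = 1.0
            else:
                p = float(sps.ttest_rel(c_df[a], c_df[b]).pvalue)
            pmat.loc[a, b] = pmat.loc[b, a] = p
    return c_df, pmat
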