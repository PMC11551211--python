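"""Two-group testing, BH correction, TMM normalization and LEfSe.

The discriminant-taxon stage is a simplified two-class LEfSe: a
Mann-Whitney screen at alpha = 0.05 followed by a bootstrapped linear
discriminant effect size, reported as a log10 LDA score with the
conventional threshold of 2.  The subclass (within-group Wilcoxon) stage of
the original tool is omitted because a plain two-group design never
exercises it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .community import FeatureTable

logger = logging.getLogger("micage")


@dataclass
class DifferentialRecord:
    feature_id: str
    test: str
    statistic: float
    p: float
    q: float | None = None
    direction: str | None = None
    lda_score: float | None = None


@dataclass
class TmmFactors:
    factors: pd.Series
    reference: str
    logratio_trim: float = 0.30
    sum_trim: float = 0.05


# ---------------------------------------------------------------------------
# two-group tests
# ---------------------------------------------------------------------------

def two_group_test(x, y, kind: str = "auto") -> tuple[float, float, str]:
    """Welch t or two-sided Mann-Whitney U on two samples.

    ``auto`` applies the parametric/non-parametric split: Mann-Whitney
    whenever either group fails a Shapiro-Wilk normality screen at
    alpha = 0.05 (or is too small / too degenerate to screen).
    Identical constant groups return p = 1 by convention.

    Returns ``(statistic, p, test_name)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs n >= 2")
    if np.ptp(np.concatenate([x, y])) == 0:
        return 0.0, 1.0, "degenerate"
    if kind == "auto":
        kind = "t"
        for g in (x, y):
            if len(g) < 3 or np.ptp(g) == 0:
                kind = "mann_whitney"
                break
            if stats.shapiro(g).pvalue < 0.05:
                kind = "mann_whitney"
                break
    if kind == "t":
        res = stats.ttest_ind(x, y, equal_var=False)
        return float(res.statistic), float(res.pvalue), "welch_t"
    if kind == "mann_whitney":
        res = stats.mannwhitneyu(x, y, alternative="two-sided")
        return float(res.statistic), float(res.pvalue), "mann_whitney"
    raise ValueError(f"unknown test kind {kind!r}")


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1; output matches input
    order.
    """
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# TMM normalization (edgeR algorithm)
# ---------------------------------------------------------------------------

def _tmm_pair_factor(obs: np.ndarray, ref: np.ndarray,
                     logratio_trim: float, sum_trim: float) -> float:
    n_o, n_r = obs.sum(), ref.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        log_r = np.log2((obs / n_o) / (ref / n_r))
        abs_e = (np.log2(obs / n_o) + np.log2(ref / n_r)) / 2
        v = (n_o - obs) / n_o / obs + (n_r - ref) / n_r / ref
    fin = np.isfinite(log_r) & np.isfinite(abs_e)
    log_r, abs_e, v = log_r[fin], abs_e[fin], v[fin]
    if log_r.size == 0:
        raise ValueError("sample shares no nonzero features with reference")
    if np.abs(log_r).max() < 1e-6:
        return 1.0
    n = len(log_r)
    lo_l = np.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * sum_trim) + 1
    hi_s = n + 1 - lo_s
    rank_m = stats.rankdata(log_r)
    rank_a = stats.rankdata(abs_e)
    keep = ((rank_m >= lo_l) & (rank_m <= hi_l) &
            (rank_a >= lo_s) & (rank_a <= hi_s))
    if not keep.any():
        return 1.0
    f = np.sum(log_r[keep] / v[keep]) / np.sum(1.0 / v[keep])
    if np.isnan(f):
        f = 0.0
    return float(2.0 ** f)


def tmm_normalize(table: FeatureTable,
                  logratio_trim: float = 0.30,
                  sum_trim: float = 0.05) -> tuple[TmmFactors, FeatureTable]:
    """Trimmed mean of M-values normalization factors (edgeR convention).

    The reference sample is the one whose scaled upper quartile is closest
    to the mean upper quartile; each sample's factor is 2 to the
    precision-weighted mean of M-values after trimming the most extreme 30%
    of M and 5% of A; factors are rescaled to geometric mean 1.  Returns the
    factors and the table divided by (library size x factor), scaled back to
    the mean library size.
    """
    x = table.data.T.values.astype(float)  # features x samples, edgeR layout
    if x.shape[1] < 2:
        raise ValueError("TMM needs >= 2 samples")
    lib = x.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("sample with zero total")
    f75 = np.percentile(x, 75, axis=0) / lib
    if np.median(f75) < 1e-20:
        ref_idx = int(np.argmax(np.sqrt(x).sum(axis=0)))
    else:
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.array([
        _tmm_pair_factor(x[:, i], x[:, ref_idx], logratio_trim, sum_trim)
        for i in range(x.shape[1])
    ])
    factors = factors / np.exp(np.mean(np.log(factors)))
    fac = pd.Series(factors, index=table.data.index, name="tmm_factor")
    eff_lib = lib * factors
    normalized = table.data.div(eff_lib, axis=0) * lib.mean()
    return (TmmFactors(fac, reference=str(table.data.index[ref_idx]),
                       logratio_trim=logratio_trim, sum_trim=sum_trim),
            FeatureTable(normalized, table.groups, kind=table.kind))


# ---------------------------------------------------------------------------
# LEfSe
# ---------------------------------------------------------------------------

def _lda_effect_sizes(x: np.ndarray, y: np.ndarray, rng) -> np.ndarray:
    """One bootstrap round of LDA effect sizes per feature.

    Projects onto the unit discriminant axis; per-feature effect is the
    mean of |scaled axis loading| and |raw group-mean difference|, the
    effect-size combination of the original tool.
    """
    n_feat = x.shape[1]
    labels = np.unique(y)
    idx = np.concatenate([
        rng.choice(np.flatnonzero(y == g), size=(y == g).sum(), replace=True)
        for g in labels
    ])
    xb, yb = x[idx].copy(), y[idx]
    # jitter degenerate columns so the within-class scatter is invertible
    for j in range(n_feat):
        col_sd = max(np.std(xb[:, j]), 1e-10)
        for g in labels:
            sub = xb[yb == g, j]
            if np.ptp(sub) == 0:
                xb[yb == g, j] = sub + rng.normal(0, col_sd * 0.05 + 1e-8,
                                                  size=len(sub))
    lda = LinearDiscriminantAnalysis(solver="svd", tol=1e-10)
    try:
        lda.fit(xb, yb)
    except np.linalg.LinAlgError:
        return np.zeros(n_feat)
    w = lda.coef_[0]
    norm = np.sqrt((w ** 2).sum())
    if norm == 0:
        return np.zeros(n_feat)
    w_unit = w / norm
    proj = xb @ w_unit
    sep = abs(proj[yb == labels[0]].mean() - proj[yb == labels[1]].mean())
    mean_diff = np.abs(xb[yb == labels[0]].mean(axis=0) -
                       xb[yb == labels[1]].mean(axis=0))
    return (np.abs(w_unit * sep) + mean_diff) / 2.0


def lefse(table: FeatureTable, alpha: float = 0.05,
          lda_threshold: float = 2.0, n_boot: int = 30,
          seed: int = 0) -> list[DifferentialRecord]:
    """Two-class LEfSe: Mann-Whitney screen then bootstrapped LDA score.

    Abundances are rescaled to one million per sample before testing.
    Features pass when the Mann-Whitney p < ``alpha`` AND
    log10(max(1, mean bootstrap effect size)) > ``lda_threshold``; the
    returned records cover every screened feature, flagged ones carry
    ``direction`` = the enriched group.
    """
    groups = table.groups
    labels = groups.unique()
    if len(labels) != 2:
        raise ValueError("LEfSe requires exactly two groups")
    if min((groups == g).sum() for g in labels) < 3:
        raise ValueError("bootstrap refused: each group needs n >= 3")
    # per-sample rescale to 1e6 (counts-per-million scale)
    totals = table.data.sum(axis=1)
    if (totals <= 0).any():
        raise ValueError("all-zero sample")
    x = table.data.div(totals, axis=0).values * 1e6
    y = groups.values
    rng = np.random.default_rng(seed)

    records: list[DifferentialRecord] = []
    screened: list[int] = []
    for j, fid in enumerate(table.feature_ids):
        a = x[y == labels[0], j]
        b = x[y == labels[1], j]
        if np.ptp(np.concatenate([a, b])) == 0:
            stat, p = 0.0, 1.0
        else:
            res = stats.mannwhitneyu(a, b, alternative="two-sided")
            stat, p = float(res.statistic), float(res.pvalue)
        rec = DifferentialRecord(fid, "mann_whitney", stat, p)
        records.append(rec)
        if p < alpha:
            screened.append(j)

    if screened:
        xs = x[:, screened]
        effects = np.mean([_lda_effect_sizes(xs, y, rng)
                           for _ in range(n_boot)], axis=0)
        for k, j in enumerate(screened):
            score = float(np.log10(max(1.0, effects[k])))
            rec = records[j]
            rec.lda_score = score
            if score > lda_threshold:
                a = x[y == labels[0], j]
                b = x[y == labels[1], j]
                rec.direction = str(labels[0] if a.mean() > b.mean()
                                    else labels[1])
    return records


def discriminant_features(records: list[DifferentialRecord]) -> list[DifferentialRecord]:
    """The subset of LEfSe records that passed both stages."""
    return [r for r in records if r.direction is not None]


def records_to_frame(records: list[DifferentialRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records]).set_index("feature_id")
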