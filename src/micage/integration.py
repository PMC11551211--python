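"""Metagenome-metabolome integration by customized GSEA.

Significantly altered predicted pathways are pooled into MetaCyc-style
superclasses; the LC-MS features annotated to each superclass's
metabolites form a "metabolite set"; gene-set enrichment analysis then
asks whether each set is concentrated at either extreme of the LC-MS
features ranked by a two-sample t metric.

The enrichment score is the weighted Kolmogorov-Smirnov-like running-sum
extremum: walking the ranked list, member features add |r_j|^p / N_R
(N_R = sum of member |r_j|^p), non-members subtract 1/(N - N_H), and ES is
the maximum-magnitude deviation.  Significance comes from phenotype
permutation (group relabeling; exhaustively enumerated when the number of
distinct splits is at most n_perm, e.g. C(10,5)=252 for a 5-vs-5 design)
with NES and FDR computed by the standard GSEA normalization: NES divides
ES by the mean |null ES| of matching sign, and FDR compares tail fractions
of the pooled sign-matched null NES against the observed NES.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .differential import DifferentialRecord
from .metabolome import MetaboliteReference, PeakTable

logger = logging.getLogger("micage")


@dataclass
class MetaboliteSet:
    superclass_id: str
    members: list[str]            # LC-MS feature ids (deduplicated, sorted)
    source_pathways: list[str]

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class RankedList:
    feature_ids: list[str]        # sorted by metric, descending
    metric: pd.Series             # indexed by feature id, original order
    metric_name: str = "t_test"


@dataclass
class GseaSetResult:
    superclass_id: str
    size: int
    es: float
    nes: float
    p: float
    fdr: float
    leading_edge: list[str]


# ---------------------------------------------------------------------------
# set construction
# ---------------------------------------------------------------------------

def build_sets(diff_pathways: list[DifferentialRecord],
               ref: MetaboliteReference,
               annotation: dict[str, str],
               superclass_map: dict[str, str],
               min_set_size: int = 10,
               alpha: float = 0.05,
               use_adjusted: bool = False) -> list[MetaboliteSet]:
    """Metabolite sets from significantly altered predicted pathways.

    Pathways with p < ``alpha`` (raw by default; BH-adjusted with
    ``use_adjusted``) contribute their metabolites' annotated LC-MS
    features, pooled per superclass with set-union deduplication; sets
    smaller than ``min_set_size`` are dropped with a log notice.
    """
    missing = {r.feature_id for r in diff_pathways} - set(superclass_map)
    if missing:
        raise ValueError(f"superclass map missing pathways: {sorted(missing)}")
    sig = [r for r in diff_pathways
           if (r.q if use_adjusted else r.p) is not None
           and (r.q if use_adjusted else r.p) < alpha]
    if not sig:
        return []
    pw_members = ref.pathway_members()
    met_features: dict[str, set[str]] = {}
    for feat, met in annotation.items():
        met_features.setdefault(met, set()).add(feat)

    per_super: dict[str, tuple[set[str], set[str]]] = {}
    for rec in sig:
        sc = superclass_map[rec.feature_id]
        feats, pws = per_super.setdefault(sc, (set(), set()))
        pws.add(rec.feature_id)
        for met in pw_members.get(rec.feature_id, ()):
            feats |= met_features.get(met, set())

    sets = []
    for sc in sorted(per_super):
        feats, pws = per_super[sc]
        if len(feats) < min_set_size:
            logger.info("build_sets: superclass %s has %d < %d mapped "
                        "features, excluded", sc, len(feats), min_set_size)
            continue
        sets.append(MetaboliteSet(sc, sorted(feats), sorted(pws)))
    return sets


# ---------------------------------------------------------------------------
# ranking metric
# ---------------------------------------------------------------------------

def _t_metric(x: np.ndarray, pos: np.ndarray, sd_floor: float = 0.2) -> np.ndarray:
    """Per-feature two-sample t metric, columns of x, boolean pos mask.

    Difference of means scaled by sqrt(s1^2/n1 + s2^2/n2), with the GSEA
    minimum-SD floor s >= sd_floor * |mean| (and an absolute floor of
    sd_floor when the mean is ~0) to keep near-constant features finite.
    """
    a, b = x[pos], x[~pos]
    mu_a, mu_b = a.mean(axis=0), b.mean(axis=0)
    s_a = np.std(a, axis=0, ddof=1)
    s_b = np.std(b, axis=0, ddof=1)
    s_a = np.maximum(s_a, np.maximum(sd_floor * np.abs(mu_a), 1e-8))
    s_b = np.maximum(s_b, np.maximum(sd_floor * np.abs(mu_b), 1e-8))
    return (mu_a - mu_b) / np.sqrt(s_a ** 2 / len(a) + s_b ** 2 / len(b))


def rank_features(peaks: PeakTable, positive_group: str | None = None,
                  sd_floor: float = 0.2) -> RankedList:
    """Rank LC-MS features by the two-sample t metric on log10 intensities.

    ``positive_group`` is the class whose enrichment gives positive metric
    values (defaults to the first group label).  Ties are broken by feature
    id, so the order is fully deterministic.
    """
    labels = list(peaks.groups.unique())
    if len(labels) != 2:
        raise ValueError("ranking needs exactly two groups")
    if positive_group is None:
        positive_group = labels[0]
    if positive_group not in labels:
        raise ValueError(f"unknown group {positive_group!r}")
    if min((peaks.groups == g).sum() for g in labels) < 2:
        raise ValueError("each group needs n >= 2")
    logx = peaks.log_intensities()
    # lexicographic feature order makes the stable sort's tie-break the id
    logx = logx[sorted(logx.columns)]
    pos = (peaks.groups == positive_group).values
    r = _t_metric(logx.values, pos, sd_floor)
    metric = pd.Series(r, index=logx.columns, name="t_metric")
    order = np.argsort(-r, kind="stable")
    return RankedList([str(logx.columns[i]) for i in order], metric)


# ---------------------------------------------------------------------------
# enrichment score
# ---------------------------------------------------------------------------

_TIE_TOL = 1e-9  # exact +/- extremum ties resolve to the positive side


def _extremum(profile: np.ndarray) -> float:
    pos, neg = profile.max(), profile.min()
    return float(pos if pos >= -neg - _TIE_TOL else neg)


def enrichment_score(ranked: RankedList, mset: MetaboliteSet,
                     p: float = 1.0) -> tuple[float, np.ndarray]:
    """ES and the full running-sum profile for one set."""
    member = np.isin(np.asarray(ranked.feature_ids), np.asarray(mset.members))
    if not member.any():
        raise ValueError("set has no members in the ranked list")
    if member.all():
        raise ValueError("set equals the entire ranked list")
    r = ranked.metric.loc[ranked.feature_ids].values
    profile = _running_sum(r, member, p)
    return _extremum(profile), profile


def _running_sum(r_sorted: np.ndarray, member: np.ndarray, p: float) -> np.ndarray:
    w = np.abs(r_sorted) ** p
    n_r = w[member].sum()
    if n_r == 0:
        w = np.ones_like(w)        # all-zero metrics: unweighted walk
        n_r = member.sum()
    n_miss = len(r_sorted) - member.sum()
    hit = np.cumsum(np.where(member, w, 0.0)) / n_r
    miss = np.cumsum(~member) / n_miss
    return hit - miss


def _es_matrix(r: np.ndarray, membership: np.ndarray, p: float) -> np.ndarray:
    """ES for several sets against one metric vector (vectorized).

    ``r`` in feature-id order; ``membership`` boolean (n_sets x n_features)
    in the same order.
    """
    order = np.argsort(-r, kind="stable")
    rs = r[order]
    m = membership[:, order]
    w = np.abs(rs) ** p
    n_r = (m * w).sum(axis=1)
    n_h = m.sum(axis=1)
    safe_w = np.where(n_r[:, None] > 0, w, 1.0)
    n_r = np.where(n_r > 0, n_r, n_h)
    hit = np.cumsum(m * safe_w, axis=1) / n_r[:, None]
    miss = np.cumsum(~m, axis=1) / (len(rs) - n_h)[:, None]
    dev = hit - miss
    pos, neg = dev.max(axis=1), dev.min(axis=1)
    return np.where(pos >= -neg - _TIE_TOL, pos, neg)


def leading_edge(ranked: RankedList, mset: MetaboliteSet,
                 p: float = 1.0) -> list[str]:
    """Members at or before (positive ES) / at or after (negative) the extremum."""
    es, profile = enrichment_score(ranked, mset, p)
    idx = int(np.argmax(profile) if es >= 0 else np.argmin(profile))
    ids = np.asarray(ranked.feature_ids)
    member = np.isin(ids, np.asarray(mset.members))
    if es >= 0:
        sel = member & (np.arange(len(ids)) <= idx)
    else:
        sel = member & (np.arange(len(ids)) >= idx)
    return [str(f) for f in ids[sel]]


# ---------------------------------------------------------------------------
# permutation GSEA
# ---------------------------------------------------------------------------

def _phenotype_masks(n: int, n_pos: int, n_perm: int, seed: int
                     ) -> tuple[np.ndarray, bool]:
    """Positive-class masks for phenotype permutation.

    Exhaustive enumeration of all C(n, n_pos) splits when that count is at
    most ``n_perm``; otherwise ``n_perm`` random relabelings.
    """
    n_distinct = math.comb(n, n_pos)
    if n_distinct <= n_perm:
        masks = np.zeros((n_distinct, n), dtype=bool)
        for i, combo in enumerate(itertools.combinations(range(n), n_pos)):
            masks[i, list(combo)] = True
        return masks, True
    rng = np.random.default_rng(seed)
    masks = np.zeros((n_perm, n), dtype=bool)
    base = np.zeros(n, dtype=bool)
    base[:n_pos] = True
    for i in range(n_perm):
        masks[i] = rng.permutation(base)
    return masks, False


def gsea(peaks: PeakTable, sets: list[MetaboliteSet],
         positive_group: str | None = None, n_perm: int = 1000,
         perm_type: str = "phenotype", weight: float = 1.0,
         sd_floor: float = 0.2, seed: int = 0) -> list[GseaSetResult]:
    """Permutation GSEA of metabolite sets over the ranked LC-MS features.

    Phenotype permutation recomputes the t metric under group relabelings
    (the preferred null, preserving feature correlations); with fewer than
    7 samples it falls back to set permutation (random same-size sets),
    logged.  Exhaustive enumeration replaces sampling whenever the distinct
    relabelings fit within ``n_perm``.
    """
    if not sets:
        return []
    if perm_type not in ("phenotype", "set"):
        raise ValueError("perm_type must be 'phenotype' or 'set'")
    labels = list(peaks.groups.unique())
    if positive_group is None:
        positive_group = labels[0]
    logx = peaks.log_intensities()
    logx = logx[sorted(logx.columns)]
    feat_ids = np.asarray(logx.columns, dtype=object)
    x = logx.values
    n = x.shape[0]
    pos_obs = (peaks.groups == positive_group).values

    min_group = min(int(pos_obs.sum()), int(n - pos_obs.sum()))
    if perm_type == "phenotype" and min_group < 7:
        # with so few samples per group the relabeling null retains most of
        # any real signal (high-overlap splits), so it cannot separate true
        # sets; random same-size sets are the standard fallback
        logger.warning("gsea: smallest group has %d < 7 samples; falling "
                       "back to set permutation", min_group)
        perm_type = "set"

    membership = np.vstack([np.isin(feat_ids, np.asarray(s.members))
                            for s in sets])
    for s, m in zip(sets, membership):
        if not m.any() or m.all():
            raise ValueError(f"set {s.superclass_id}: invalid membership")

    r_obs = _t_metric(x, pos_obs, sd_floor)
    es_obs = _es_matrix(r_obs, membership, weight)

    if perm_type == "phenotype":
        masks, exhaustive = _phenotype_masks(n, int(pos_obs.sum()),
                                             n_perm, seed)
        es_null = np.empty((len(masks), len(sets)))
        for i, mask in enumerate(masks):
            es_null[i] = _es_matrix(_t_metric(x, mask, sd_floor),
                                    membership, weight)
    else:
        rng = np.random.default_rng(seed)
        sizes = membership.sum(axis=1)
        es_null = np.empty((n_perm, len(sets)))
        for i in range(n_perm):
            fake = np.zeros((len(sets), len(feat_ids)), dtype=bool)
            for j, size in enumerate(sizes):
                fake[j, rng.choice(len(feat_ids), int(size),
                                   replace=False)] = True
            es_null[i] = _es_matrix(r_obs, fake, weight)

    results = _summarize(es_obs, es_null, sets)
    ranked = rank_features(peaks, positive_group, sd_floor)
    for res, s in zip(results, sets):
        res.leading_edge = leading_edge(ranked, s, weight)
    return results


def _summarize(es_obs: np.ndarray, es_null: np.ndarray,
               sets: list[MetaboliteSet]) -> list[GseaSetResult]:
    """Nominal p, NES and FDR from a (n_perm x n_sets) null ES matrix."""
    n_sets = len(sets)
    nes_obs = np.empty(n_sets)
    p_nom = np.empty(n_sets)
    nes_null = np.full_like(es_null, np.nan)
    for j in range(n_sets):
        null = es_null[:, j]
        pos_mean = null[null >= 0].mean() if (null >= 0).any() else np.nan
        neg_mean = np.abs(null[null < 0]).mean() if (null < 0).any() else np.nan
        same = null >= 0 if es_obs[j] >= 0 else null < 0
        denom = pos_mean if es_obs[j] >= 0 else neg_mean
        if not same.any() or not np.isfinite(denom) or denom == 0:
            p_nom[j], nes_obs[j] = 1.0, 0.0
        else:
            p_nom[j] = (np.abs(null[same]) >= abs(es_obs[j])).mean()
            nes_obs[j] = es_obs[j] / denom
        with np.errstate(invalid="ignore", divide="ignore"):
            nes_null[:, j] = np.where(null >= 0, null / pos_mean,
                                      null / neg_mean)

    pool = nes_null[np.isfinite(nes_null)]
    fdr = np.empty(n_sets)
    for j in range(n_sets):
        v = nes_obs[j]
        if v >= 0:
            null_frac_den = (pool >= 0).sum()
            null_frac = ((pool >= v).sum() / null_frac_den
                         if null_frac_den else 1.0)
            obs_den = (nes_obs >= 0).sum()
            obs_frac = (nes_obs >= v).sum() / obs_den if obs_den else 1.0
        else:
            null_frac_den = (pool < 0).sum()
            null_frac = ((pool <= v).sum() / null_frac_den
                         if null_frac_den else 1.0)
            obs_den = (nes_obs < 0).sum()
            obs_frac = (nes_obs <= v).sum() / obs_den if obs_den else 1.0
        fdr[j] = min(1.0, null_frac / obs_frac) if obs_frac > 0 else 1.0

    # enforce FDR monotone nonincreasing in |NES| within each sign class:
    # each set's q becomes the minimum over all sets at or below its |NES|
    for positive in (True, False):
        idx = [j for j in range(n_sets) if (nes_obs[j] >= 0) == positive]
        idx.sort(key=lambda j: abs(nes_obs[j]))  # weakest first
        cummin = np.inf
        for j in idx:
            cummin = min(cummin, fdr[j])
            fdr[j] = cummin
    return [GseaSetResult(s.superclass_id, len(s), float(es_obs[j]),
                          float(nes_obs[j]), float(p_nom[j]), float(fdr[j]), [])
            for j, s in enumerate(sets)]


def gsea_to_frame(results: list[GseaSetResult]) -> pd.DataFrame:
    rows = [{**vars(r), "leading_edge": ";".join(r.leading_edge)}
            for r in results]
    return pd.DataFrame(rows).set_index("superclass_id")
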