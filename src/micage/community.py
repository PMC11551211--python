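"""Community-level statistics for sample-by-taxon tables.

Alpha diversity (Shannon, Simpson, Chao1), rarefaction, the four beta
diversity metrics used in gut-microbiome aging studies (Bray-Curtis,
Jaccard, unweighted and weighted UniFrac), principal coordinate analysis,
PERMANOVA with free label permutation, and relative-abundance summaries
including the Firmicutes/Bacteroidetes ratio.

Counts live in a :class:`FeatureTable` (samples x features) carrying the
age-group label of every sample.  Phylogenetic metrics take a rooted
:class:`skbio.TreeNode` whose leaves are the table's feature ids.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import skbio
from skbio.diversity import beta_diversity as _skbio_beta_diversity

logger = logging.getLogger("micage")

BETA_METRICS = ("bray_curtis", "jaccard", "unweighted_unifrac", "weighted_unifrac")
_UNIFRAC_METRICS = ("unweighted_unifrac", "weighted_unifrac")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """Non-negative sample-by-feature abundance matrix with group labels.

    Parameters
    ----------
    data
        DataFrame indexed by sample id, columns are feature ids.
    groups
        Mapping sample id -> group label (e.g. ``young`` / ``old``).
    kind
        What the features are: ``taxa``, ``pathway`` or ``peak``.
    """

    data: pd.DataFrame
    groups: pd.Series
    kind: str = "taxa"

    def __post_init__(self) -> None:
        self.data = pd.DataFrame(self.data).astype(float)
        if (self.data.values < 0).any():
            r, c = np.argwhere(self.data.values < 0)[0]
            raise ValueError(
                f"negative abundance at sample {self.data.index[r]!r}, "
                f"feature {self.data.columns[c]!r}"
            )
        if self.data.index.duplicated().any():
            raise ValueError("duplicate sample ids")
        if self.data.columns.duplicated().any():
            raise ValueError("duplicate feature ids")
        self.data = self.data.rename_axis(index=None, columns=None)
        self.groups = pd.Series(self.groups)
        missing = self.data.index.difference(self.groups.index)
        if len(missing):
            raise ValueError(f"samples missing group labels: {list(missing)}")
        self.groups = self.groups.loc[self.data.index]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def matrix(self) -> np.ndarray:
        return self.data.values

    def group_arrays(self) -> dict[str, np.ndarray]:
        """Per-group sub-matrices, keyed by group label."""
        return {g: self.data.loc[self.groups == g].values
                for g in self.groups.unique()}


@dataclass
class AlphaDiversityResult:
    shannon: pd.Series
    simpson: pd.Series
    chao1: pd.Series
    s_obs: pd.Series
    rarefaction_depth: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "shannon": self.shannon, "simpson": self.simpson,
            "chao1": self.chao1, "s_obs": self.s_obs,
        })


@dataclass
class PermanovaResult:
    pseudo_f: float
    p_value: float
    n_permutations: int
    group_sizes: dict[str, int]
    exhaustive: bool = False


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray


# ---------------------------------------------------------------------------
# rarefaction
# ---------------------------------------------------------------------------

def rarefy(table: FeatureTable, depth: int | None = None, seed: int = 0,
           drop_below_depth: bool = True) -> FeatureTable:
    """Subsample each sample without replacement to exactly ``depth`` reads.

    ``depth=None`` uses the minimum sample total.  Samples with fewer than
    ``depth`` reads are dropped (with a warning) when ``drop_below_depth``,
    otherwise an error is raised.
    """
    totals = table.data.sum(axis=1)
    if depth is None:
        depth = int(totals.min())
    if depth < 1:
        raise ValueError("rarefaction depth must be >= 1")
    if depth > totals.max():
        raise ValueError(f"depth {depth} exceeds every sample total")
    keep = totals >= depth
    if not keep.all():
        dropped = list(totals.index[~keep])
        if not drop_below_depth:
            raise ValueError(f"samples below depth {depth}: {dropped}")
        logger.warning("rarefy: dropping %d samples below depth %d: %s",
                       len(dropped), depth, dropped)
    rng = np.random.default_rng(seed)
    counts = table.data.loc[keep].round().astype(np.int64)
    out = np.empty_like(counts.values)
    for i, row in enumerate(counts.values):
        # exact multivariate hypergeometric draw = subsampling w/o replacement
        out[i] = rng.multivariate_hypergeometric(row, depth)
    rarefied = pd.DataFrame(out, index=counts.index, columns=counts.columns)
    return FeatureTable(rarefied, table.groups.loc[keep], kind=table.kind)


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

def shannon(counts: np.ndarray) -> float:
    """Shannon entropy H = -sum p_i ln p_i (natural log)."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("all-zero sample")
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum())


def simpson(counts: np.ndarray) -> float:
    """Gini-Simpson index 1 - sum p_i^2 (probability two reads differ)."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("all-zero sample")
    p = counts / total
    return float(1.0 - (p ** 2).sum())


def chao1(counts: np.ndarray) -> float:
    """Chao1 richness S_obs + F1(F1-1)/(2(F2+1)) from singletons/doubletons."""
    counts = np.asarray(counts)
    s_obs = int((counts > 0).sum())
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def alpha_diversity(table: FeatureTable) -> AlphaDiversityResult:
    """Shannon, Simpson and Chao1 per sample.

    Chao1's singleton/doubleton correction only makes sense on integer
    counts; callers wanting rarefied indices rarefy first.
    """
    if (table.data.sum(axis=1) <= 0).any():
        raise ValueError("all-zero sample in table")
    rows = table.data.values
    idx = table.data.index
    return AlphaDiversityResult(
        shannon=pd.Series([shannon(r) for r in rows], index=idx),
        simpson=pd.Series([simpson(r) for r in rows], index=idx),
        chao1=pd.Series([chao1(r) for r in rows], index=idx),
        s_obs=pd.Series([(r > 0).sum() for r in rows], index=idx),
    )


# ---------------------------------------------------------------------------
# beta diversity
# ---------------------------------------------------------------------------

def beta_diversity(table: FeatureTable, metric: str,
                   tree: skbio.TreeNode | None = None) -> skbio.DistanceMatrix:
    """Pairwise sample distances under one of the four study metrics.

    Bray-Curtis uses abundances, Jaccard presence/absence; the UniFrac
    variants additionally need a rooted tree over the feature ids
    (weighted UniFrac is the branch-length-normalized form, so all four
    qualitative/normalized metrics lie in [0, 1]).
    """
    if metric not in BETA_METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {BETA_METRICS}")
    counts = table.data.values
    ids = table.sample_ids
    if metric in _UNIFRAC_METRICS:
        if tree is None:
            raise ValueError(f"{metric} requires a phylogenetic tree")
        leaves = {t.name for t in tree.tips()}
        missing = set(table.feature_ids) - leaves
        if missing:
            raise ValueError(f"tree is missing table features: {sorted(missing)}")
        kwargs = dict(tree=tree, taxa=table.feature_ids)
        if metric == "weighted_unifrac":
            kwargs["normalized"] = True
        return _skbio_beta_diversity(metric, counts, ids=ids, **kwargs)
    if metric == "jaccard":
        return _skbio_beta_diversity("jaccard", counts > 0, ids=ids)
    return _skbio_beta_diversity("braycurtis", counts, ids=ids)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _pseudo_f_stats(sqd: np.ndarray, labels: np.ndarray) -> float:
    """Pseudo-F from squared distances for one labelling (1-D int labels)."""
    n = sqd.shape[0]
    ss_t = sqd[np.triu_indices(n, 1)].sum() / n
    ss_w = 0.0
    groups = np.unique(labels)
    for g in groups:
        idx = np.flatnonzero(labels == g)
        if len(idx) < 2:
            continue
        sub = sqd[np.ix_(idx, idx)]
        ss_w += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    g = len(groups)
    return ((ss_t - ss_w) / (g - 1)) / (ss_w / (n - g))


def _distinct_relabelings(labels: np.ndarray) -> int:
    """Number of distinct assignments of the label multiset to positions."""
    n = len(labels)
    total = math.factorial(n)
    for g in np.unique(labels):
        total //= math.factorial(int((labels == g).sum()))
    return total


def permanova(dm: skbio.DistanceMatrix, groups, n_perm: int = 999,
              seed: int = 0) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    pseudo-F follows the classical partition of squared inter-point
    distances into total and within-group sums; the p-value is
    (1 + #{F_perm >= F_obs}) / (1 + n_perm).  When the number of distinct
    relabelings does not exceed ``n_perm`` every relabeling is enumerated
    instead, giving an exact p on the lattice of multiples of
    1/(#relabelings).
    """
    groups = pd.Series(groups)
    if hasattr(dm, "ids"):
        groups = groups.loc[list(dm.ids)]
    labels, uniq = pd.factorize(groups.values)
    sizes = {str(u): int((labels == i).sum()) for i, u in enumerate(uniq)}
    if len(uniq) < 2:
        raise ValueError("PERMANOVA needs >= 2 groups")
    if min(sizes.values()) < 2:
        raise ValueError("every group needs >= 2 samples")
    d = np.asarray(dm.data if hasattr(dm, "data") else dm, dtype=float)
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix is not symmetric")
    sqd = d ** 2
    f_obs = _pseudo_f_stats(sqd, labels)

    n_distinct = _distinct_relabelings(labels)
    if n_distinct <= n_perm:
        # exhaustive: enumerate every distinct assignment of the label
        # multiset (two-group case: choose positions of group 0)
        f_null = [_pseudo_f_stats(sqd, np.asarray(perm))
                  for perm in _iter_relabelings(labels)]
        f_null = np.asarray(f_null)
        p = float((f_null >= f_obs - 1e-12).sum() / n_distinct)
        return PermanovaResult(f_obs, p, n_distinct, sizes, exhaustive=True)

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        hits += _pseudo_f_stats(sqd, rng.permutation(labels)) >= f_obs - 1e-12
    p = (1 + hits) / (1 + n_perm)
    return PermanovaResult(f_obs, float(p), n_perm, sizes)


def _iter_relabelings(labels: np.ndarray):
    """Yield each distinct arrangement of the label multiset (small n only)."""
    n = len(labels)
    counts = {g: int((labels == g).sum()) for g in np.unique(labels)}

    def rec(remaining: dict, prefix: list):
        if len(prefix) == n:
            yield list(prefix)
            return
        for g in sorted(remaining):
            if remaining[g] > 0:
                remaining[g] -= 1
                prefix.append(g)
                yield from rec(remaining, prefix)
                prefix.pop()
                remaining[g] += 1

    yield from rec(counts, [])


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

def pcoa(dm: skbio.DistanceMatrix) -> OrdinationResult:
    """Classical principal coordinate analysis (metric MDS).

    Eigendecomposition of the Gower-centered matrix -1/2 J D^2 J.  Axes are
    scaled by sqrt(eigenvalue); negative eigenvalues (non-Euclidean input)
    are reported as-is and simply contribute no axis.
    """
    ids = list(dm.ids) if hasattr(dm, "ids") else list(range(len(dm.data)))
    d = np.asarray(dm.data if hasattr(dm, "data") else dm, dtype=float)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > 1e-10 * max(abs(evals).max(), 1.0)
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    denom = evals[evals > 0].sum()
    prop = np.where(evals > 0, evals, 0.0) / denom if denom > 0 else np.zeros_like(evals)
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return OrdinationResult(pd.DataFrame(coords, index=ids, columns=cols),
                            evals, prop)


# ---------------------------------------------------------------------------
# relative abundance / F-B ratio
# ---------------------------------------------------------------------------

def collapse_taxonomy(table: FeatureTable, taxonomy: dict[str, str],
                      level: int) -> FeatureTable:
    """Sum features into taxa at one rank of a semicolon-delimited lineage.

    ``taxonomy`` maps feature id -> lineage string like
    ``"Firmicutes;Lactobacillaceae;Lactobacillus"``.  Features unassigned at
    ``level`` are grouped at the deepest assigned rank, mirroring the common
    practice of pushing unassigned genera up to family/order.
    """
    missing = set(table.feature_ids) - set(taxonomy)
    if missing:
        raise ValueError(f"taxonomy missing features: {sorted(missing)}")

    def name_at(lineage: str) -> str:
        ranks = [r.strip() for r in lineage.split(";")]
        ranks = [r for r in ranks if r and not r.endswith("__")]
        if level < len(ranks):
            return ";".join(ranks[:level + 1])
        return ";".join(ranks)  # fall back to deepest assigned rank

    grouped = table.data.T.groupby(
        [name_at(taxonomy[f]) for f in table.feature_ids]).sum().T
    return FeatureTable(grouped, table.groups, kind=table.kind)


def relative_abundance(table: FeatureTable) -> FeatureTable:
    """Row-normalize counts to proportions (each sample sums to 1)."""
    totals = table.data.sum(axis=1)
    if (totals <= 0).any():
        raise ValueError("all-zero sample")
    return FeatureTable(table.data.div(totals, axis=0), table.groups,
                        kind=table.kind)


def fb_ratio(table: FeatureTable, taxonomy: dict[str, str],
             firmicutes: str = "Firmicutes",
             bacteroidetes: str = "Bacteroidetes") -> pd.Series:
    """Firmicutes/Bacteroidetes phylum ratio per sample.

    Samples with zero Bacteroidetes get NaN (undefined), never infinity.
    """
    phylum = collapse_taxonomy(table, taxonomy, level=0)
    rel = relative_abundance(phylum).data
    f = rel.get(firmicutes, pd.Series(0.0, index=rel.index))
    b = rel.get(bacteroidetes, pd.Series(0.0, index=rel.index))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = f / b
    return ratio.where(b > 0, np.nan).rename("fb_ratio")
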