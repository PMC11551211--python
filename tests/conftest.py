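import numpy as np
import pandas as pd
import pytest
import skbio

from micage import FeatureTable, MetaboliteReference


@pytest.fixture
def small_table():
    """5 samples x 8 taxa with two groups."""
    rng = np.random.default_rng(7)
    data = pd.DataFrame(rng.integers(0, 50, size=(5, 8)),
                        index=[f"s{i}" for i in range(5)],
                        columns=[f"t{i}" for i in range(8)])
    groups = pd.Series(["a", "a", "a", "b", "b"], index=data.index)
    return FeatureTable(data, groups)


@pytest.fixture
def toy_tree():
    """((A:1,B:1):1,(C:1,D:1):1); the standard hand-worked UniFrac tree."""
    return skbio.TreeNode.read(["((A:1.0,B:1.0):1.0,(C:1.0,D:1.0):1.0);"])


@pytest.fixture
def mini_reference():
    """Tiny reference including glucose with its true monoisotopic mass."""
    table = pd.DataFrame({
        "hmdb_id": ["HMDB0000122", "HMDB0000190", "HMDB0000687"],
        "kegg_id": ["C00031", "C00186", "C00123"],
        "mass": [180.0634, 90.0317, 131.0946],
        "pathways": [["glycolysis"], ["glycolysis"], ["bcaa"]],
        "superclass": ["carbohydrate", "carbohydrate", "amino_acid"],
    }, index=pd.Index(["glucose", "lactate", "leucine"], name="name"))
    return MetaboliteReference(table)


def brute_force_bray_curtis(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    return np.abs(x - y).sum() / (x + y).sum()


def brute_force_jaccard(x, y):
    a = set(np.flatnonzero(np.asarray(x) > 0))
    b = set(np.flatnonzero(np.asarray(y) > 0))
    if not a and not b:
        return 0.0
    return 1.0 - len(a & b) / len(a | b)


def _branches(tree, feature_ids):
    """(branch length, descendant-leaf index set) for every non-root node."""
    idx = {f: i for i, f in enumerate(feature_ids)}
    out = []
    for node in tree.traverse(include_self=False):
        leaves = {idx[t.name] for t in (node.tips() or [])} \
            if not node.is_tip() else {idx[node.name]}
        out.append((float(node.length), leaves))
    return out


def brute_force_unweighted_unifrac(x, y, tree, feature_ids):
    x, y = np.asarray(x, float), np.asarray(y, float)
    unique = shared = 0.0
    for length, leaves in _branches(tree, feature_ids):
        in_x = any(x[i] > 0 for i in leaves)
        in_y = any(y[i] > 0 for i in leaves)
        if in_x or in_y:
            if in_x and in_y:
                shared += length
            else:
                unique += length
    return unique / (unique + shared)


def brute_force_weighted_unifrac(x, y, tree, feature_ids):
    """Normalized (Lozupone) weighted UniFrac."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    px, py = x / x.sum(), y / y.sum()
    num = 0.0
    for length, leaves in _branches(tree, feature_ids):
        pa = sum(px[i] for i in leaves)
        pb = sum(py[i] for i in leaves)
        num += length * abs(pa - pb)
    idx = {f: i for i, f in enumerate(feature_ids)}
    den = 0.0
    for tip in tree.tips():
        d = tip.accumulate_to_ancestor(tree)
        i = idx[tip.name]
        den += d * (px[i] + py[i])
    return num / den
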