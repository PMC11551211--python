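"""LC-MS feature annotation, differential testing and pathway ORA.

Untargeted LC-MS features (m/z, retention time, ion mode, per-sample
intensities) are matched to a metabolite reference by adduct mass at a ppm
tolerance, tested for group differences on log intensities with BH
correction, and summarized by pathway over-representation with
hypergeometric p-values and enrichment factors (observed significant hits
over expected).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .differential import DifferentialRecord, bh_adjust, two_group_test

logger = logging.getLogger("micage")


# ---------------------------------------------------------------------------
# adduct rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AdductRule:
    """Ionization rule: m/z = (M + shift) / charge, strictly increasing in M."""
    name: str
    mode: str
    charge: int
    shift: float

    def mz(self, mass: float) -> float:
        return (mass + self.shift) / self.charge

    def neutral_mass(self, mz: float) -> float:
        return mz * self.charge - self.shift


def load_adduct_rules() -> dict[str, AdductRule]:
    """The supported positive/negative mode adducts (versioned data file)."""
    raw = json.loads(
        resources.files("micage").joinpath("data/adducts.json").read_text())
    return {a["name"]: AdductRule(a["name"], a["mode"], a["charge"], a["shift"])
            for a in raw["adducts"]}


ADDUCT_RULES = load_adduct_rules()


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class PeakTable:
    """LC-MS feature table: m/z, RT, ion mode plus per-sample intensities."""

    features: pd.DataFrame        # index feature id; columns mz, rt, mode
    intensities: pd.DataFrame     # samples x features, positive reals
    groups: pd.Series

    def __post_init__(self) -> None:
        need = {"mz", "rt", "mode"}
        if not need <= set(self.features.columns):
            raise ValueError(f"feature frame needs columns {sorted(need)}")
        if (self.features["mz"] <= 0).any():
            raise ValueError("non-positive m/z")
        bad = set(self.features["mode"]) - {"positive", "negative"}
        if bad:
            raise ValueError(f"unknown ion mode(s): {sorted(bad)}")
        self.features = self.features.rename_axis(index=None)
        self.intensities = self.intensities.rename_axis(index=None,
                                                        columns=None)
        self.groups = pd.Series(self.groups).loc[self.intensities.index]

    @property
    def feature_ids(self) -> list[str]:
        return list(self.features.index)

    def log_intensities(self, base: float = 10.0) -> pd.DataFrame:
        return np.log(self.intensities) / np.log(base)


@dataclass
class MetaboliteReference:
    """Reference metabolites: ids, monoisotopic mass, pathways, superclass."""

    table: pd.DataFrame  # index name; columns hmdb_id, kegg_id, mass,
                         # pathways (list or ;-joined str), superclass

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            raise ValueError("duplicate metabolite names")
        if (self.table["mass"] <= 0).any():
            raise ValueError("non-positive monoisotopic mass")
        self.table = self.table.copy()
        self.table["pathways"] = self.table["pathways"].apply(
            lambda p: list(p) if isinstance(p, (list, tuple))
            else [s for s in str(p).split(";") if s])

    def __len__(self) -> int:
        return len(self.table)

    def pathways_of(self, metabolite: str) -> list[str]:
        return self.table.loc[metabolite, "pathways"]

    def pathway_members(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for name, row in self.table.iterrows():
            for pw in row["pathways"]:
                out.setdefault(pw, set()).add(name)
        return out


@dataclass
class AnnotationHit:
    feature_id: str
    metabolite: str
    adduct: str
    theoretical_mz: float
    ppm_error: float


@dataclass
class PathwayEnrichmentRecord:
    pathway_id: str
    n_total: int          # annotated features hitting the pathway
    n_significant: int
    expected: float
    enrichment_factor: float
    p: float


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def annotate_peaks(peaks: PeakTable, ref: MetaboliteReference,
                   ppm: float = 10.0) -> pd.DataFrame:
    """Match features to (metabolite, adduct) candidates within ppm.

    For each feature every mode-appropriate adduct of every reference
    metabolite is checked; candidates with relative mass error
    |obs - theo| / theo <= ppm * 1e-6 are kept and ranked by |ppm error|.
    Ambiguous features (several candidates) retain all of them.
    """
    if ppm <= 0:
        raise ValueError("ppm tolerance must be positive")
    if len(ref) == 0:
        raise ValueError("empty metabolite reference")
    masses = ref.table["mass"].values
    names = ref.table.index.to_numpy()
    hits: list[AnnotationHit] = []
    for fid, row in peaks.features.iterrows():
        obs = float(row["mz"])
        for rule in ADDUCT_RULES.values():
            if rule.mode != row["mode"]:
                continue
            theo = (masses + rule.shift) / rule.charge
            err = (obs - theo) / theo * 1e6
            for k in np.flatnonzero(np.abs(err) <= ppm):
                hits.append(AnnotationHit(str(fid), str(names[k]), rule.name,
                                          float(theo[k]), float(err[k])))
    frame = pd.DataFrame([vars(h) for h in hits],
                         columns=["feature_id", "metabolite", "adduct",
                                  "theoretical_mz", "ppm_error"])
    return frame.sort_values(
        ["feature_id", "ppm_error"],
        key=lambda s: s.abs() if s.name == "ppm_error" else s,
    ).reset_index(drop=True)


def best_annotation(annotation: pd.DataFrame) -> dict[str, str]:
    """feature id -> lowest-|ppm| candidate metabolite."""
    if annotation.empty:
        return {}
    ordered = annotation.reindex(
        annotation["ppm_error"].abs().sort_values(kind="stable").index)
    return ordered.drop_duplicates("feature_id").set_index(
        "feature_id")["metabolite"].to_dict()


# ---------------------------------------------------------------------------
# differential features
# ---------------------------------------------------------------------------

def differential_features(peaks: PeakTable, alpha_adj: float = 0.05,
                          kind: str = "t") -> list[DifferentialRecord]:
    """Per-feature two-sample test on log10 intensities with BH adjustment.

    ``direction`` is the group with the higher mean log intensity, set only
    for features significant at adjusted p < ``alpha_adj``.
    """
    labels = peaks.groups.unique()
    if len(labels) != 2:
        raise ValueError("need exactly two groups")
    logx = peaks.log_intensities()
    y = peaks.groups.values
    records = []
    for fid in peaks.feature_ids:
        a = logx.loc[y == labels[0], fid].values
        b = logx.loc[y == labels[1], fid].values
        stat, p, name = two_group_test(a, b, kind=kind)
        rec = DifferentialRecord(str(fid), name, stat, p)
        rec.direction = str(labels[0] if a.mean() > b.mean() else labels[1])
        records.append(rec)
    q = bh_adjust([r.p for r in records])
    for rec, qi in zip(records, q):
        rec.q = float(qi)
        if rec.q >= alpha_adj:
            rec.direction = None
    return records


# ---------------------------------------------------------------------------
# pathway over-representation
# ---------------------------------------------------------------------------

def pathway_ora(diff: list[DifferentialRecord],
                annotation: dict[str, str],
                ref: MetaboliteReference,
                alpha_adj: float = 0.05) -> list[PathwayEnrichmentRecord]:
    """Hypergeometric over-representation of significant features per pathway.

    The universe is the annotated features; a pathway's hits are features
    whose metabolite belongs to it.  expected = pathway size x overall
    significant fraction; enrichment factor = observed / expected; p is the
    upper hypergeometric tail P(X >= observed).
    """
    if not annotation:
        raise ValueError("empty annotation")
    annotated = [r for r in diff if r.feature_id in annotation]
    n_univ = len(annotated)
    sig_ids = {r.feature_id for r in annotated
               if r.q is not None and r.q < alpha_adj}
    n_sig = len(sig_ids)
    members = ref.pathway_members()
    records = []
    for pw, mets in sorted(members.items()):
        feats = [r.feature_id for r in annotated if annotation[r.feature_id] in mets]
        n_total = len(feats)
        if n_total == 0:
            logger.info("pathway_ora: %s has no mapped features, skipped", pw)
            continue
        n_hit = sum(f in sig_ids for f in feats)
        expected = n_total * n_sig / n_univ if n_univ else 0.0
        ef = n_hit / expected if expected > 0 else np.nan
        p = float(stats.hypergeom.sf(n_hit - 1, n_univ, n_sig, n_total))
        records.append(PathwayEnrichmentRecord(pw, n_total, n_hit,
                                               expected, ef, p))
    return records


def ora_to_frame(records: list[PathwayEnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records]).set_index("pathway_id")
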