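"""Synthetic inputs with known ground truth for every pipeline stage.

Generators emulate the study design the pipeline targets: 8-vs-8
young/old 16S feature tables with planted old-age taxon shifts (e.g. a
Lactobacillus-like bloom), a random phylogeny for UniFrac, 5-vs-5
positive/negative-mode LC-MS peak tables with planted differential
metabolites, predicted-pathway tables with planted up/down pathways, qPCR
Ct panels consistent with known absolute abundances, and backscatter-SEM
bone phantoms with known mineralization mode, FWHM and pore geometry.

Counts are Dirichlet-multinomial (overdispersed, as real 16S data are);
peak intensities are log-normal.  Every generator takes an explicit seed
and is deterministic given it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import skbio

from .community import FeatureTable
from .metabolome import ADDUCT_RULES, MetaboliteReference, PeakTable
from .qpcr import MAX_CYCLE_DEFAULT, StandardCurve
from .qbsem import BseImage

logger = logging.getLogger("micage")

_PHYLA = ("Firmicutes", "Bacteroidetes", "Actinobacteria",
          "Proteobacteria", "Deferribacteres")
_PHYLUM_WEIGHTS = (0.45, 0.35, 0.08, 0.08, 0.04)


# ---------------------------------------------------------------------------
# 16S community tables
# ---------------------------------------------------------------------------

@dataclass
class CommunitySimSpec:
    """Dirichlet-multinomial two-group 16S simulation.

    ``effect_map`` multiplies the old-group concentration of selected taxa
    (fold-change > 1 means an old-age bloom).  ``dispersion`` is the total
    Dirichlet concentration: larger = less sample-to-sample overdispersion.
    Defaults mirror an 8-vs-8 design at a typical rarefied depth.
    """

    n_taxa: int = 50
    n_per_group: int = 8
    sequencing_depth: int = 10_000
    baseline_log_abundance: np.ndarray | None = None
    dispersion: float = 200.0
    effect_map: dict[str, float] = field(default_factory=dict)
    group_labels: tuple[str, str] = ("young", "old")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 2:
            raise ValueError("need >= 2 taxa")
        if self.sequencing_depth < 1:
            raise ValueError("sequencing depth must be >= 1")
        if self.n_per_group < 1:
            raise ValueError("empty groups")
        if any(f <= 0 for f in self.effect_map.values()):
            raise ValueError("fold-changes must be positive")


def taxon_ids(n_taxa: int) -> list[str]:
    return [f"taxon_{i:03d}" for i in range(n_taxa)]


def sim_taxonomy(n_taxa: int, seed: int = 0) -> dict[str, str]:
    """Random phylum;family;genus lineages over a mouse-gut-like phylum mix."""
    rng = np.random.default_rng(seed)
    lineages = {}
    for tid in taxon_ids(n_taxa):
        ph = rng.choice(_PHYLA, p=_PHYLUM_WEIGHTS)
        fam = f"{ph[:4]}_family_{rng.integers(1, 4)}"
        genus = f"{ph[:4]}_genus_{rng.integers(1, 8)}"
        lineages[tid] = f"{ph};{fam};{genus}"
    # the first taxon is the canonical planted-bloom target: give it a
    # fixed Lactobacillus-like lineage so the emulated old-age Firmicutes
    # shift is what the effect map produces
    lineages[taxon_ids(n_taxa)[0]] = \
        "Firmicutes;Lactobacillaceae;Lactobacillus"
    return lineages


def sim_community(spec: CommunitySimSpec
                  ) -> tuple[FeatureTable, pd.DataFrame]:
    """Two-group Dirichlet-multinomial count table plus truth table.

    Per group, sample proportions are Dirichlet with concentration
    ``dispersion x baseline`` ("old" baseline multiplied by the effect
    map); counts are multinomial at ``sequencing_depth``.  The truth table
    lists each planted taxon's fold-change and direction.
    """
    rng = np.random.default_rng(spec.seed)
    ids = taxon_ids(spec.n_taxa)
    if spec.baseline_log_abundance is None:
        base_log = rng.normal(0.0, 1.5, size=spec.n_taxa)
    else:
        base_log = np.asarray(spec.baseline_log_abundance, dtype=float)
        if len(base_log) != spec.n_taxa:
            raise ValueError("baseline length != n_taxa")
    base = np.exp(base_log)
    base /= base.sum()

    unknown = set(spec.effect_map) - set(ids)
    if unknown:
        raise ValueError(f"effect_map names unknown taxa: {sorted(unknown)}")
    fold = np.ones(spec.n_taxa)
    for tid, fc in spec.effect_map.items():
        fold[ids.index(tid)] = fc
    old = base * fold
    old /= old.sum()

    rows, samples, groups = [], [], []
    young_lbl, old_lbl = spec.group_labels
    for g_lbl, props in ((young_lbl, base), (old_lbl, old)):
        alpha = spec.dispersion * props
        for k in range(spec.n_per_group):
            pi = rng.dirichlet(alpha)
            rows.append(rng.multinomial(spec.sequencing_depth, pi))
            samples.append(f"{g_lbl}_{k + 1}")
            groups.append(g_lbl)
    table = FeatureTable(
        pd.DataFrame(rows, index=samples, columns=ids),
        pd.Series(groups, index=samples), kind="taxa")
    truth = pd.DataFrame(
        {"taxon": list(spec.effect_map),
         "fold_change": list(spec.effect_map.values()),
         "direction": [old_lbl if fc > 1 else young_lbl
                       for fc in spec.effect_map.values()]})
    return table, truth


def sim_tree(n_taxa: int, seed: int = 0,
             mean_branch_length: float = 0.1) -> skbio.TreeNode:
    """Random bifurcating rooted tree over the taxon ids.

    Built by repeatedly joining two uniformly chosen clades; branch lengths
    are exponential with the given mean.
    """
    if n_taxa < 2:
        raise ValueError("need >= 2 taxa for a tree")
    rng = np.random.default_rng(seed)
    # labels are quoted so underscores survive newick's underscore-to-space rule
    clades = [f"'{tid}':{rng.exponential(mean_branch_length):.6f}"
              for tid in taxon_ids(n_taxa)]
    while len(clades) > 2:
        i, j = sorted(rng.choice(len(clades), size=2, replace=False))
        b = clades.pop(j)
        a = clades.pop(i)
        clades.append(f"({a},{b}):{rng.exponential(mean_branch_length):.6f}")
    newick = f"({clades[0]},{clades[1]});"
    return skbio.TreeNode.read([newick])


# ---------------------------------------------------------------------------
# predicted pathway tables
# ---------------------------------------------------------------------------

def sim_pathway_table(pathway_ids: list[str], n_per_group: int = 8,
                      effect_map: dict[str, float] | None = None,
                      base_mean: float = 1000.0, noise_cv: float = 0.25,
                      group_labels: tuple[str, str] = ("young", "old"),
                      seed: int = 0) -> tuple[FeatureTable, pd.DataFrame]:
    """Log-normal pathway-abundance table with planted up/down pathways."""
    rng = np.random.default_rng(seed)
    effect_map = effect_map or {}
    unknown = set(effect_map) - set(pathway_ids)
    if unknown:
        raise ValueError(f"unknown pathways in effect map: {sorted(unknown)}")
    sigma = np.sqrt(np.log1p(noise_cv ** 2))
    base = base_mean * np.exp(rng.normal(0, 0.5, size=len(pathway_ids)))
    rows, samples, groups = [], [], []
    young_lbl, old_lbl = group_labels
    for g_lbl in (young_lbl, old_lbl):
        mult = np.ones(len(pathway_ids))
        if g_lbl == old_lbl:
            for pw, fc in effect_map.items():
                mult[pathway_ids.index(pw)] = fc
        for k in range(n_per_group):
            rows.append(base * mult * np.exp(rng.normal(0, sigma,
                                                        len(pathway_ids))))
            samples.append(f"{g_lbl}_{k + 1}")
            groups.append(g_lbl)
    table = FeatureTable(pd.DataFrame(rows, index=samples,
                                      columns=pathway_ids),
                         pd.Series(groups, index=samples), kind="pathway")
    truth = pd.DataFrame({"pathway": list(effect_map),
                          "fold_change": list(effect_map.values())})
    return table, truth


# ---------------------------------------------------------------------------
# metabolite reference
# ---------------------------------------------------------------------------

def make_reference(n_metabolites: int = 120, n_pathways: int = 12,
                   n_superclasses: int = 4, seed: int = 0
                   ) -> tuple[MetaboliteReference, dict[str, str]]:
    """Synthetic metabolite reference plus pathway -> superclass map.

    Masses are uniform on 100-600 Da (small-molecule range); each
    metabolite joins 1-3 pathways; pathways are assigned round-robin to
    superclasses.  Purely synthetic identifiers in HMDB/KEGG-like shapes.
    """
    rng = np.random.default_rng(seed)
    pathways = [f"PWY-{1000 + i}" for i in range(n_pathways)]
    superclasses = [f"SC-{i + 1}" for i in range(n_superclasses)]
    superclass_map = {pw: superclasses[i % n_superclasses]
                      for i, pw in enumerate(pathways)}
    rows = []
    for i in range(n_metabolites):
        n_pw = int(rng.integers(1, 4))
        mem = sorted(rng.choice(pathways, size=n_pw, replace=False))
        rows.append({
            "name": f"met_{i:04d}",
            "hmdb_id": f"HMDB{7000000 + i:07d}",
            "kegg_id": f"C{90000 + i:05d}",
            "mass": float(rng.uniform(100.0, 600.0)),
            "pathways": list(mem),
            "superclass": superclass_map[mem[0]],
        })
    table = pd.DataFrame(rows).set_index("name")
    return MetaboliteReference(table), superclass_map


# ---------------------------------------------------------------------------
# LC-MS peak tables
# ---------------------------------------------------------------------------

@dataclass
class PeakSimSpec:
    """Planted-effect LC-MS peak simulation (5-vs-5 design by default)."""

    reference: MetaboliteReference
    n_features: int = 200
    n_per_group: int = 5
    frac_differential: float = 0.1
    log_fold_change: float = 0.301       # log10 of a 2-fold shift
    noise_sd: float = 0.1                # log10 intensity SD
    base_log_intensity: float = 6.0
    mz_ppm_jitter: float = 5.0
    adduct_assignment: dict[str, tuple[str, str]] | None = None
    group_labels: tuple[str, str] = ("young", "old")
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_differential <= 1.0:
            raise ValueError("frac_differential must lie in [0, 1]")
        if self.adduct_assignment:
            for met, add in self.adduct_assignment.values():
                if add not in ADDUCT_RULES:
                    raise ValueError(f"unsupported adduct {add!r}")
                if met not in self.reference.table.index:
                    raise ValueError(f"metabolite {met!r} not in reference")


def sim_peak_table(spec: PeakSimSpec) -> tuple[PeakTable, pd.DataFrame]:
    """Peak table whose m/z derive from assigned (metabolite, adduct) pairs.

    Observed m/z are the theoretical adduct m/z perturbed by a uniform
    error within ±``mz_ppm_jitter`` ppm; log10 intensities are Gaussian
    with the old group shifted by ``log_fold_change`` for planted
    differential features.  The truth table records assignment, planted
    status and direction.
    """
    rng = np.random.default_rng(spec.seed)
    ref = spec.reference
    fids = [f"feat_{i:04d}" for i in range(spec.n_features)]

    assignment = spec.adduct_assignment
    if assignment is None:
        adduct_names = list(ADDUCT_RULES)
        mets = rng.choice(ref.table.index.to_numpy(), size=spec.n_features)
        adds = rng.choice(adduct_names, size=spec.n_features)
        assignment = {fid: (str(m), str(a))
                      for fid, m, a in zip(fids, mets, adds)}
    else:
        fids = list(assignment)

    n_diff = int(round(spec.frac_differential * len(fids)))
    diff_idx = set(rng.choice(len(fids), size=n_diff, replace=False))
    signs = {i: (1 if rng.random() < 0.5 else -1) for i in diff_idx}

    feat_rows, inten_rows = [], []
    young_lbl, old_lbl = spec.group_labels
    samples = [f"{g}_{k + 1}" for g in (young_lbl, old_lbl)
               for k in range(spec.n_per_group)]
    groups = pd.Series([s.rsplit("_", 1)[0] for s in samples], index=samples)

    log_mu = rng.normal(spec.base_log_intensity, 0.5, size=len(fids))
    truth_rows = []
    intensities = np.empty((len(samples), len(fids)))
    for j, fid in enumerate(fids):
        met, add = assignment[fid]
        rule = ADDUCT_RULES[add]
        theo = rule.mz(float(ref.table.loc[met, "mass"]))
        ppm_err = rng.uniform(-spec.mz_ppm_jitter, spec.mz_ppm_jitter)
        feat_rows.append({"feature_id": fid,
                          "mz": theo * (1.0 + ppm_err * 1e-6),
                          "rt": float(rng.uniform(0.5, 20.0)),
                          "mode": rule.mode})
        shift = spec.log_fold_change * signs.get(j, 0)
        for i, s in enumerate(samples):
            mu = log_mu[j] + (shift if groups[s] == old_lbl else 0.0)
            intensities[i, j] = 10.0 ** (mu + rng.normal(0, spec.noise_sd))
        truth_rows.append({"feature_id": fid, "metabolite": met,
                           "adduct": add, "theoretical_mz": theo,
                           "differential": j in diff_idx,
                           "direction": (old_lbl if signs.get(j, 0) > 0
                                         else young_lbl)
                           if j in diff_idx else None})

    features = pd.DataFrame(feat_rows).set_index("feature_id")
    peaks = PeakTable(features,
                      pd.DataFrame(intensities, index=samples,
                                   columns=features.index),
                      groups)
    return peaks, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# qPCR panels
# ---------------------------------------------------------------------------

def sim_qpcr(true_total: float, taxa_fractions: dict[str, float],
             efficiencies: dict[str, float], noise_sd: float = 0.0,
             n_samples: int = 1, n_replicates: int = 3,
             curve: StandardCurve | None = None, fecal_mass_g: float = 0.1,
             max_cycle: float = MAX_CYCLE_DEFAULT, seed: int = 0
             ) -> tuple[pd.DataFrame, StandardCurve, pd.DataFrame]:
    """Ct panel consistent with a known absolute composition.

    Universal-primer Ct comes from inverting the standard curve at
    ``true_total x fecal_mass_g`` copies per reaction; taxon Ct values
    invert the efficiency-corrected quantification formula at
    X = fraction x total.  Gaussian noise (``noise_sd`` cycles) is added
    per technical replicate (default triplicate, the bench convention).
    Zero-abundance taxa are censored at ``max_cycle``.
    """
    if not all(0 <= f <= 1 for f in taxa_fractions.values()):
        raise ValueError("fractions must lie in [0, 1]")
    if not all(1.0 < e <= 2.2 for e in efficiencies.values()):
        raise ValueError("efficiencies must lie in (1, 2.2]")
    if "universal" not in efficiencies:
        raise ValueError("need a 'universal' primer efficiency")
    rng = np.random.default_rng(seed)
    eff_uni = efficiencies["universal"]
    if curve is None:
        curve = StandardCurve(slope=-1.0 / np.log10(eff_uni),
                              intercept=38.0, r_squared=1.0)
    rows, truth_rows = [], []
    for s in range(n_samples):
        sample = f"sample_{s + 1}"
        q_rxn = true_total * fecal_mass_g
        ct_uni = curve.intercept + curve.slope * np.log10(q_rxn)
        for r in range(n_replicates):
            rows.append({"sample": sample, "primer_set": "universal",
                         "ct": ct_uni + rng.normal(0, noise_sd),
                         "fecal_mass_g": fecal_mass_g})
        truth_rows.append({"sample": sample, "taxon": "total",
                           "abundance": true_total})
        for taxon, frac in taxa_fractions.items():
            eff_spec = efficiencies[taxon]
            if frac == 0:
                ct_spec = max_cycle
                logger.info("sim_qpcr: %s %s absent -> censored at %.0f",
                            sample, taxon, max_cycle)
            else:
                # invert X = Eff_uni^Ct_uni / Eff_spec^Ct_spec * total
                ct_spec = ((ct_uni * np.log(eff_uni) - np.log(frac))
                           / np.log(eff_spec))
            for r in range(n_replicates):
                noise = rng.normal(0, noise_sd) if frac > 0 else 0.0
                rows.append({"sample": sample, "primer_set": taxon,
                             "ct": min(ct_spec + noise, max_cycle),
                             "fecal_mass_g": fecal_mass_g})
            truth_rows.append({"sample": sample, "taxon": taxon,
                               "abundance": frac * true_total})
    return pd.DataFrame(rows), curve, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# backscatter-SEM phantoms
# ---------------------------------------------------------------------------

@dataclass
class BseSimSpec:
    """Bone cross-section phantom with embedded calibration truth.

    ``pores`` are (row, col, radius_px) disks; ``standard_means`` are the
    raw gray levels the carbon and aluminum patches were acquired at (the
    calibration must map their average back to 25/225).
    """

    image_shape: tuple[int, int] = (512, 512)
    pixel_size_um: float = 1.5
    matrix_mode_gray: float = 150.0      # calibrated scale
    matrix_sigma: float = 10.0
    pores: list[tuple[int, int, float]] = field(default_factory=list)
    pore_gray: float = 5.0               # calibrated scale
    standard_means: tuple[float, float] = (30.0, 230.0)
    standard_drift: float = 0.0          # before/after asymmetry, raw gray
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")
        c, a = self.standard_means
        if c >= a:
            raise ValueError("carbon standard must be darker than aluminum")
        for i, (r1, c1, rad1) in enumerate(self.pores):
            h, w = self.image_shape
            if not (rad1 <= r1 <= h - rad1 and rad1 <= c1 <= w - rad1):
                raise ValueError(f"pore {i} extends outside the image")
            for r2, c2, rad2 in self.pores[i + 1:]:
                if np.hypot(r1 - r2, c1 - c2) < rad1 + rad2:
                    raise ValueError("overlapping pores (truth areas would "
                                     "not be exact)")


def sim_bse_image(spec: BseSimSpec) -> tuple[BseImage, pd.DataFrame, dict]:
    """Phantom raster plus per-pore truth table and summary truth dict.

    The matrix is Gaussian around ``matrix_mode_gray`` on the calibrated
    scale, rendered in raw units via the inverse of the two-point standard
    calibration; pores are low-gray disks.  Truth porosity uses the exact
    rendered pixel masks.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_shape
    c_raw, a_raw = spec.standard_means
    # inverse of the calibration the analysis will apply
    slope = (225.0 - 25.0) / (a_raw - c_raw)
    intercept = 25.0 - slope * c_raw

    cal = rng.normal(spec.matrix_mode_gray, spec.matrix_sigma, size=(h, w))
    mask = np.ones((h, w), dtype=bool)
    yy, xx = np.mgrid[0:h, 0:w]
    pore_mask = np.zeros((h, w), dtype=bool)
    truth_rows = []
    for r, c, rad in spec.pores:
        disk = (yy - r) ** 2 + (xx - c) ** 2 <= rad ** 2
        pore_mask |= disk
        area_um2 = disk.sum() * spec.pixel_size_um ** 2
        d_um = 2.0 * np.sqrt(area_um2 / np.pi)
        truth_rows.append({
            "row": r, "col": c, "radius_px": rad,
            "nominal_diameter_um": 2.0 * rad * spec.pixel_size_um,
            "area_um2": area_um2,
            "equivalent_diameter_um": d_um,
            "kind": "vascular" if d_um > 15.0 else "lacunar"})
    cal[pore_mask] = rng.normal(spec.pore_gray, 1.0, size=pore_mask.sum())
    raw = np.clip((cal - intercept) / slope, 0, 65535)
    drift = spec.standard_drift
    image = BseImage(raster=raw.round().astype(np.uint16),
                     pixel_size_um=spec.pixel_size_um,
                     bone_mask=mask,
                     carbon_means=(c_raw - drift, c_raw + drift),
                     aluminum_means=(a_raw - drift, a_raw + drift))
    truth = {
        "matrix_mode_gray": spec.matrix_mode_gray,
        "matrix_sigma": spec.matrix_sigma,
        "expected_fwhm": 2.0 * np.sqrt(2.0 * np.log(2.0)) * spec.matrix_sigma,
        "porosity_pct": 100.0 * pore_mask.sum() / mask.sum(),
        "calibration_slope": slope,
        "calibration_intercept": intercept,
    }
    return image, pd.DataFrame(truth_rows), truth
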