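"""Absolute qPCR quantification of fecal bacteria.

Total bacterial load comes from a dilution-series standard curve
(Ct = slope * log10 quantity + intercept, efficiency Eff = 10^(-1/slope));
taxon-specific abundance uses the efficiency-corrected ratio

    X = [ Eff_uni^Ct_uni / Eff_spec^Ct_spec ] x total bacteria abundance

with the exponents applied exactly as written (positive Ct exponents; the
form reduces to the familiar Eff^(-dCt) ratio whenever the two primer
efficiencies are equal).  Ct values at the censoring cycle (default 40)
propagate as below-detection, never as zero abundance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("micage")

MAX_CYCLE_DEFAULT = 40.0


@dataclass
class StandardCurve:
    slope: float                 # Ct per log10 quantity, negative
    intercept: float
    r_squared: float

    @property
    def efficiency(self) -> float:
        """Per-cycle amplification factor, 10^(-1/slope); 2 is ideal."""
        return float(10.0 ** (-1.0 / self.slope))

    def quantity(self, ct: float) -> float:
        """Invert the curve: quantity per reaction at a given Ct."""
        return float(10.0 ** ((ct - self.intercept) / self.slope))


@dataclass
class QpcrMeasurement:
    sample_id: str
    primer_set: str
    ct: float
    efficiency: float
    fecal_mass_g: float = 1.0
    censored: bool = False

    def __post_init__(self) -> None:
        if not self.censored and not (0 < self.ct <= 100):
            raise ValueError(f"Ct {self.ct} out of range")
        if not (1.0 < self.efficiency <= 2.2):
            raise ValueError(f"efficiency {self.efficiency} outside (1, 2.2]")


@dataclass
class TaxonAbundance:
    sample_id: str
    taxon: str
    abundance: float             # organisms per g feces
    total: float
    below_detection: bool = False


def fit_standard_curve(log10_quantity, ct) -> StandardCurve:
    """Least-squares Ct vs log10(quantity) line from >= 3 dilution points."""
    x = np.asarray(log10_quantity, dtype=float)
    y = np.asarray(ct, dtype=float)
    if len(x) < 3:
        raise ValueError("need >= 3 dilution points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate dilution series (single quantity)")
    res = stats.linregress(x, y)
    if res.slope >= 0:
        raise ValueError("nonnegative slope: invalid amplification")
    return StandardCurve(float(res.slope), float(res.intercept),
                         float(res.rvalue ** 2))


def total_abundance(uni: QpcrMeasurement, curve: StandardCurve) -> float:
    """Total bacteria per g feces from the universal-primer Ct."""
    if uni.fecal_mass_g <= 0:
        raise ValueError("fecal mass must be positive")
    if uni.censored:
        logger.info("total_abundance: %s censored -> below detection",
                    uni.sample_id)
        return float("nan")
    return curve.quantity(uni.ct) / uni.fecal_mass_g


def taxon_abundance(uni: QpcrMeasurement, spec: QpcrMeasurement,
                    total: float) -> TaxonAbundance:
    """Efficiency-corrected taxon abundance from paired Ct measurements."""
    if uni.sample_id != spec.sample_id:
        raise ValueError(f"sample mismatch: {uni.sample_id} vs {spec.sample_id}")
    if spec.censored or uni.censored or not np.isfinite(total):
        return TaxonAbundance(uni.sample_id, spec.primer_set, float("nan"),
                              total, below_detection=True)
    if abs(uni.efficiency - spec.efficiency) > 0.1:
        warnings.warn(
            "universal and taxon primer efficiencies differ substantially; "
            "the positive-exponent formula is sensitive to this difference",
            stacklevel=2)
    # computed exactly as printed: Eff_uni^Ct_uni / Eff_spec^Ct_spec
    # (work in logs to dodge overflow at high Ct)
    log_ratio = uni.ct * np.log(uni.efficiency) - spec.ct * np.log(spec.efficiency)
    x = float(np.exp(log_ratio) * total)
    return TaxonAbundance(uni.sample_id, spec.primer_set, x, total)


def quantify_panel(ct_table: pd.DataFrame, curve: StandardCurve,
                   efficiencies: dict[str, float],
                   max_cycle: float = MAX_CYCLE_DEFAULT) -> pd.DataFrame:
    """Quantify a long-format Ct panel (sample, primer_set, ct, fecal_mass_g).

    Technical replicates (duplicate sample/primer rows) are averaged on the
    Ct scale.  Returns one row per sample x taxon with abundance and total.
    """
    need = {"sample", "primer_set", "ct"}
    if not need <= set(ct_table.columns):
        raise ValueError(f"Ct table needs columns {sorted(need)}")
    tab = ct_table.copy()
    if "fecal_mass_g" not in tab:
        tab["fecal_mass_g"] = 1.0
    tab = (tab.groupby(["sample", "primer_set"], as_index=False)
              .agg(ct=("ct", "mean"), fecal_mass_g=("fecal_mass_g", "first")))
    rows = []
    for sample, sub in tab.groupby("sample"):
        sub = sub.set_index("primer_set")
        if "universal" not in sub.index:
            raise ValueError(f"sample {sample}: no universal-primer Ct")
        u = sub.loc["universal"]
        uni = QpcrMeasurement(str(sample), "universal", float(u["ct"]),
                              efficiencies["universal"],
                              float(u["fecal_mass_g"]),
                              censored=float(u["ct"]) >= max_cycle)
        total = total_abundance(uni, curve)
        for primer in sub.index:
            if primer == "universal":
                continue
            m = sub.loc[primer]
            spec = QpcrMeasurement(str(sample), str(primer), float(m["ct"]),
                                   efficiencies[primer],
                                   float(m["fecal_mass_g"]),
                                   censored=float(m["ct"]) >= max_cycle)
            res = taxon_abundance(uni, spec, total)
            rows.append({"sample": res.sample_id, "taxon": res.taxon,
                         "abundance": res.abundance, "total": res.total,
                         "below_detection": res.below_detection})
    return pd.DataFrame(rows)
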