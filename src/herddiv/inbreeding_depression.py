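"""Inbreeding depression: phenotype quality control and regression.

The depression coefficient is the slope ``beta1`` of an ordinary
least-squares fit of a weight trait on an individual inbreeding
measure, with sex and birth-year as categorical fixed effects:

    y = mu + sex + birth_year + beta1 * F + e

``beta1`` is reported in kg per 1% of inbreeding.  Phenotype QC
mirrors routine beef-recording practice: weaning ages outside
240 +/- 45 d are removed, surviving weaning weights are adjusted to
240 d by a linear-gain correction, and a single-pass +/-3 SD filter is
applied on the (adjusted) values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

__all__ = ["qc_phenotypes", "fit_depression", "DepressionFit", "adjust_ww_to_240"]

WW_AGE_TARGET = 240
WW_AGE_TOL = 45


def adjust_ww_to_240(ww: float, age_d: float, bw: float | None = None) -> float:
    """Adjust a weaning weight to 240 days of age.

    With the animal's birth weight available the linear-gain correction
    ``WW240 = BW + ((WW - BW) / age) * 240`` is used; otherwise the
    plain proportional rescale ``WW * 240 / age``.
    """
    if bw is not None and np.isfinite(bw):
        return float(bw + (ww - bw) / age_d * WW_AGE_TARGET)
    return float(ww * WW_AGE_TARGET / age_d)


def qc_phenotypes(pt: pd.DataFrame) -> pd.DataFrame:
    """Phenotype quality control, trait by trait.

    Birth weight: single-pass +/-3 SD filter (mean/SD from the
    unfiltered trait).  Weaning weight: (1) ages outside
    [195, 285] d removed; (2) weights adjusted to 240 d (using the
    animal's own birth-weight record when present); (3) +/-3 SD filter
    on the adjusted values.  The adjusted value replaces ``value`` and
    the applied formula is recorded in ``df.attrs``.
    """
    out_frames = []
    attrs = {}
    bw_lookup = (
        pt.loc[pt["trait"] == "birth_weight"]
        .drop_duplicates("animal_id")
        .set_index("animal_id")["value"]
    )
    for trait, grp in pt.groupby("trait", sort=True):
        grp = grp.copy()
        if trait == "weaning_weight":
            ok = grp["age_d"].between(WW_AGE_TARGET - WW_AGE_TOL,
                                      WW_AGE_TARGET + WW_AGE_TOL)
            attrs["ww_removed_age"] = int((~ok).sum())
            grp = grp.loc[ok].copy()
            bw = grp["animal_id"].map(bw_lookup)
            grp["value"] = [
                adjust_ww_to_240(v, a, b if np.isfinite(b) else None)
                for v, a, b in zip(grp["value"], grp["age_d"], bw.fillna(np.nan))
            ]
            attrs["ww_adjustment"] = "WW240 = BW + ((WW - BW)/age)*240; WW*240/age when BW absent"
        if len(grp):
            mu, sd = grp["value"].mean(), grp["value"].std(ddof=1)
            if np.isfinite(sd) and sd > 0:
                keep = (grp["value"] - mu).abs() <= 3.0 * sd
                attrs[f"{trait}_removed_3sd"] = int((~keep).sum())
                grp = grp.loc[keep]
        out_frames.append(grp)
    out = pd.concat(out_frames, ignore_index=True) if out_frames else pt.iloc[0:0]
    if out.empty:
        raise ValueError("phenotype QC removed every record")
    out.attrs.update(attrs)
    return out


@dataclass
class DepressionFit:
    """OLS fit of a trait on an inbreeding measure.

    ``beta1`` is in kg per 1% inbreeding; ``fixed_effects`` carries the
    sex and birth-year estimates; ``pooled_year_levels`` lists year
    classes merged to protect against rank deficiency.
    """

    trait: str
    measure: str
    beta1: float
    se: float
    p_value: float
    n: int
    fixed_effects: dict = field(default_factory=dict)
    pooled_year_levels: list = field(default_factory=list)

    def to_row(self) -> dict:
        return {
            "trait": self.trait, "measure": self.measure,
            "beta1_kg_per_pct": self.beta1, "se": self.se,
            "p_value": self.p_value, "n": self.n,
        }


def fit_depression(pt: pd.DataFrame, F: "pd.Series | dict", measure_name: str,
                   trait: str | None = None) -> DepressionFit:
    """Regress a trait on an inbreeding measure with sex/year fixed effects.

    Parameters
    ----------
    pt : DataFrame
        QC'd phenotype records for a single trait (or pass ``trait`` to
        select one); must carry sex and birth_year.
    F : Series or mapping
        animal_id -> inbreeding coefficient on the 0-1 fraction scale.
    measure_name : str
        Label (e.g. ``"FPED"``, ``"FGRM"``, ``"FROH"``).

    Records without an inbreeding value are dropped.  Birth-year
    classes with a single record are pooled into one level before
    fitting (rank-deficiency guard); the action is recorded on the
    returned fit.
    """
    df = pt.copy()
    if trait is not None:
        df = df.loc[df["trait"] == trait]
    traits = df["trait"].unique()
    if len(traits) != 1:
        raise ValueError("fit_depression expects records of exactly one trait")
    trait = str(traits[0])
    fmap = pd.Series(F) if not isinstance(F, pd.Series) else F
    df["F_pct"] = df["animal_id"].map(fmap) * 100.0
    df = df.dropna(subset=["F_pct", "value", "sex", "birth_year"])
    if df.empty:
        raise ValueError("no records with phenotype and inbreeding value")
    df["birth_year"] = df["birth_year"].astype(int).astype(str)
    counts = df["birth_year"].value_counts()
    singles = sorted(counts.index[counts < 2])
    if singles:
        df.loc[df["birth_year"].isin(singles), "birth_year"] = "pooled"
        warnings.warn(f"pooled singleton birth-year classes: {singles}")
    model = smf.ols("value ~ C(sex) + C(birth_year) + F_pct", data=df)
    res = model.fit()
    fixed = {k: float(v) for k, v in res.params.items() if k != "F_pct"}
    return DepressionFit(
        trait=trait,
        measure=measure_name,
        beta1=float(res.params["F_pct"]),
        se=float(res.bse["F_pct"]),
        p_value=float(res.pvalues["F_pct"]),
        n=int(res.nobs),
        fixed_effects=fixed,
        pooled_year_levels=singles,
    )
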