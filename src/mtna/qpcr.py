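"""Relative expression by the ΔΔCt method and two-factor ANOVA.

A Ct table holds one row per technical replicate of a qPCR well pair
(target gene + reference gene) for each biological replicate of each
genetic background x genotype group. Technical replicates are averaged,
ΔCt = Ct_target − Ct_reference normalizes by the reference gene, and the
non-deletion group within the same background is the calibrator, so the
fold change of the deletion genotype is 2^(mean ΔCt_non − mean ΔCt_del).
Amplification efficiency is fixed at 2 (classic ΔΔCt).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .genotyping import DELETION, NON_DELETION

CT_COLUMNS = ["background", "genotype", "bio_rep", "tech_rep", "ct_target", "ct_ref"]


def collapse_technical(ct: pd.DataFrame) -> pd.DataFrame:
    """Average technical replicates to one Ct pair per biological replicate.

    Rows with a missing target or reference Ct are dropped with a warning.
    """
    missing = [c for c in CT_COLUMNS[:3] + CT_COLUMNS[4:] if c not in ct.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    bad = ct["ct_target"].isna() | ct["ct_ref"].isna()
    if bad.any():
        warnings.warn(
            f"dropping {int(bad.sum())} technical replicate(s) with missing Ct",
            stacklevel=2,
        )
        ct = ct[~bad]
    if ct.empty:
        raise ValueError("no complete Ct measurements")
    out = (
        ct.groupby(["background", "genotype", "bio_rep"], sort=False)[
            ["ct_target", "ct_ref"]
        ]
        .mean()
        .reset_index()
    )
    return out


def relative_expression(
    collapsed: pd.DataFrame, calibrator: str = NON_DELETION
) -> pd.DataFrame:
    """Per-biological-replicate ΔCt, ΔΔCt and fold change.

    ΔΔCt is taken against the mean ΔCt of the calibrator genotype *within
    the same background*, so the calibrator group's geometric-mean fold is 1.
    """
    df = collapsed.copy()
    df["delta_ct"] = df["ct_target"] - df["ct_ref"]
    out = []
    for background, grp in df.groupby("background", sort=False):
        cal = grp.loc[grp["genotype"] == calibrator, "delta_ct"]
        if cal.empty:
            raise ValueError(f"no calibrator ({calibrator}) replicates in {background}")
        g = grp.copy()
        g["delta_delta_ct"] = g["delta_ct"] - cal.mean()
        g["fold"] = 2.0 ** (-g["delta_delta_ct"])
        out.append(g)
    return pd.concat(out, ignore_index=True)


def ddct_fold(
    ct_or_collapsed: pd.DataFrame, calibrator: str = NON_DELETION
) -> dict[str, float]:
    """Group fold change of the deletion genotype per background.

    fold = 2^(mean ΔCt_calibrator − mean ΔCt_deletion) within each
    background. Accepts a raw Ct table (technical replicates are collapsed
    first) or an already-collapsed one.
    """
    df = ct_or_collapsed
    if "tech_rep" in df.columns:
        df = collapse_technical(df)
    df = df.copy()
    df["delta_ct"] = df["ct_target"] - df["ct_ref"]
    folds = {}
    for background, grp in df.groupby("background", sort=False):
        mean_cal = grp.loc[grp["genotype"] == calibrator, "delta_ct"].mean()
        mean_del = grp.loc[grp["genotype"] == DELETION, "delta_ct"].mean()
        if np.isnan(mean_cal) or np.isnan(mean_del):
            raise ValueError(f"empty genotype group in background {background}")
        folds[background] = float(2.0 ** (mean_cal - mean_del))
    return folds


def two_factor_anova(relexp: pd.DataFrame, response: str = "fold") -> pd.DataFrame:
    """Two-way ANOVA of relative expression on background x genotype.

    Type II sums of squares (equal to the classical decomposition on
    balanced data); ``response`` is ``fold``, ``log2_fold`` (= −ΔΔCt) or
    ``delta_delta_ct``. Returns a table with sum_sq, df, F, p and eta²
    (SS_factor / total centered SS) per term. With an empty design cell the
    interaction term is dropped with a warning.
    """
    df = relexp.copy()
    if response == "log2_fold":
        df["_y"] = -df["delta_delta_ct"]
    elif response in ("fold", "delta_delta_ct"):
        df["_y"] = df[response]
    else:
        raise ValueError(f"unknown response {response!r}")
    for factor in ("background", "genotype"):
        if df[factor].nunique() < 2:
            raise ValueError(f"factor {factor!r} needs >= 2 levels")
    cells = df.groupby(["background", "genotype"]).size()
    n_cells = df["background"].nunique() * df["genotype"].nunique()
    formula = "_y ~ C(background) * C(genotype)"
    if len(cells) < n_cells:
        warnings.warn("empty design cell: interaction term dropped", stacklevel=2)
        formula = "_y ~ C(background) + C(genotype)"
    model = smf.ols(formula, data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    rename = {
        "C(background)": "background",
        "C(genotype)": "genotype",
        "C(background):C(genotype)": "interaction",
        "Residual": "residual",
    }
    table = table.rename(index=rename)
    ss_total = float(((df["_y"] - df["_y"].mean()) ** 2).sum())
    table["eta_sq"] = table["sum_sq"] / ss_total
    return table[["sum_sq", "df", "F", "PR(>F)", "eta_sq"]].rename(
        columns={"PR(>F)": "p"}
    )


def variance_explained(values, labels) -> float:
    """One-way eta²: between-group SS over total SS (= squared point-biserial
    correlation for two groups)."""
    y = np.asarray(values, dtype=float)
    g = np.asarray(labels)
    if y.size != g.size or y.size < 2:
        raise ValueError("values and labels must be equal length, n >= 2")
    ss_total = float(((y - y.mean()) ** 2).sum())
    if ss_total == 0:
        raise ValueError("zero total variance")
    ss_between = 0.0
    for level in np.unique(g):
        sel = y[g == level]
        if sel.size == 0:
            continue
        ss_between += sel.size * (sel.mean() - y.mean()) ** 2
    return float(ss_between / ss_total)


__all__ = [
    "CT_COLUMNS",
    "collapse_technical",
    "relative_expression",
    "ddct_fold",
    "two_factor_anova",
    "variance_explained",
]
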