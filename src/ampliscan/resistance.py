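"""Phenotypic resistance models and gene-family copy-number expansion.

Resistance is scored as a visual-injury rating from 0 (highly sensitive) to
5 (no injury); plants rated 2 or higher are classified resistant.  The
rating is modeled as a continuous response in OLS — the quantities of
interest are variance explained (R^2) by focal-gene copy number and the
increment from adding the target-site resistance (TSR) allele dosage — with
a logistic variant on the binary classification exposed as an option.

Gene-family expansion between regions is tested with a two-way fixed-effects
ANOVA of per-gene median CN on region and gene with interaction; per-region
least-squares means weight every gene equally, which keeps unbalanced gene
panels from dominating the regional contrast.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

__all__ = [
    "classify_resistant",
    "fit_rating_regression",
    "expansion_anova",
]


def classify_resistant(rating: int) -> bool:
    """True iff the 0-5 injury rating is 2 or higher."""
    if not 0 <= rating <= 5:
        raise ValueError(f"rating {rating} outside the 0-5 scale")
    return rating >= 2


def fit_rating_regression(
    sheet: pd.DataFrame,
    by_region: bool = True,
    binary: bool = False,
    min_samples: int = 10,
) -> pd.DataFrame:
    """OLS of rating on focal CN, per region, with the TSR increment.

    ``sheet`` needs columns sample_id, region, rating, cn, tsr (dosage
    0/1/2; NaN allowed and dropped).  For each region the base model is
    rating ~ cn and the full model adds tsr; reported are the CN slope, its
    two-sided p-value, R^2 of the base model and delta-R^2 from adding tsr.
    ``binary=True`` substitutes the resistant/susceptible classification as
    the response (logit link), reporting pseudo-R^2 instead.
    """
    required = {"region", "rating", "cn", "tsr"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns {sorted(missing)}")
    groups = sheet.groupby("region") if by_region else [("all", sheet)]
    rows = []
    for region, df in groups:
        df = df.dropna(subset=["rating", "cn"]).copy()
        if len(df) < min_samples:
            raise ValueError(
                f"region {region!r} has {len(df)} complete samples (< {min_samples})"
            )
        if df["cn"].std(ddof=0) == 0:
            raise ValueError(f"region {region!r} has zero CN variance")
        y = (
            df["rating"].map(classify_resistant).astype(float)
            if binary
            else df["rating"].astype(float)
        )
        X = sm.add_constant(df[["cn"]].astype(float))
        if binary:
            base = sm.Logit(y, X).fit(disp=0)
            r2 = float(base.prsquared)
        else:
            base = sm.OLS(y, X).fit()
            r2 = float(base.rsquared)
        slope = float(base.params["cn"])
        pval = float(base.pvalues["cn"])

        dtsr = df.dropna(subset=["tsr"])
        if len(dtsr) >= min_samples and dtsr["tsr"].std(ddof=0) > 0:
            yf = (
                dtsr["rating"].map(classify_resistant).astype(float)
                if binary
                else dtsr["rating"].astype(float)
            )
            Xf = sm.add_constant(dtsr[["cn", "tsr"]].astype(float))
            Xb = sm.add_constant(dtsr[["cn"]].astype(float))
            if binary:
                full = sm.Logit(yf, Xf).fit(disp=0)
                basef = sm.Logit(yf, Xb).fit(disp=0)
                delta_r2 = float(full.prsquared - basef.prsquared)
            else:
                full = sm.OLS(yf, Xf).fit()
                basef = sm.OLS(yf, Xb).fit()
                delta_r2 = float(full.rsquared - basef.rsquared)
        else:
            delta_r2 = float("nan")
        rows.append(
            {
                "region": region,
                "n": len(df),
                "slope_cn": slope,
                "p_cn": pval,
                "r2_cn": r2,
                "delta_r2_tsr": delta_r2,
            }
        )
    return pd.DataFrame(rows)


def expansion_anova(cn_long: pd.DataFrame) -> dict:
    """Two-way ANOVA of gene median CN on region and gene with interaction.

    ``cn_long`` needs columns sample, region, gene, cn (one row per
    individual x gene).  Returns the ANOVA table, per-region least-squares
    means (equal gene weights) with 95% CIs from the residual variance, and
    the fitted model.  If some region x gene cells are empty the interaction
    is dropped with a warning so the main effects stay estimable.
    """
    import logging

    logger = logging.getLogger(__name__)
    required = {"sample", "region", "gene", "cn"}
    if required - set(cn_long.columns):
        raise ValueError(f"need columns {sorted(required)}")
    regions = sorted(cn_long["region"].unique())
    genes = sorted(cn_long["gene"].unique())
    if len(regions) < 2 or len(genes) < 2:
        raise ValueError("need >= 2 regions and >= 2 genes")

    cells = cn_long.groupby(["region", "gene"]).size()
    full_grid = len(cells) == len(regions) * len(genes)
    formula = "cn ~ C(region) * C(gene)" if full_grid else "cn ~ C(region) + C(gene)"
    if not full_grid:
        logger.warning("empty region x gene cells: interaction term dropped")
    model = smf.ols(formula, data=cn_long).fit()
    table = anova_lm(model, typ=2)

    # LS means: average the predicted cell means over genes with equal weight
    ls_means = {}
    for region in regions:
        grid = pd.DataFrame({"region": region, "gene": genes})
        pred = model.get_prediction(grid)
        mean = float(pred.predicted_mean.mean())
        # variance of the equal-weight average of cell predictions
        from patsy import build_design_matrices

        design_info = model.model.data.design_info
        X = np.asarray(build_design_matrices([design_info], grid)[0])
        xbar = X.mean(axis=0)
        var = float(xbar @ model.cov_params().values @ xbar)
        half = 1.96 * np.sqrt(var)
        ls_means[region] = {
            "mean": mean,
            "ci_low": mean - half,
            "ci_high": mean + half,
        }
    return {"anova": table, "ls_means": ls_means, "model": model}
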