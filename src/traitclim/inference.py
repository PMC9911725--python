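"""Habitat-specific slopes, significance tallies and R² decompositions.

A habitat's marginal slope for climate PC j is the fixed slope plus the
habitat's BLUP deviation; its standard error combines the fixed-effect
variance, the BLUP's conditional variance and (when the solver exposes it)
twice their covariance.  Confidence intervals are slope ± 1.96·SE and an
interval excluding zero is called significant (approximately p < 0.05,
separate two-sided tests, no multiplicity correction by default).  Slopes
estimated from fewer than ``min_n`` plots are suppressed: reported without
any significance claim.

The variance decomposition follows the variance-components formulation of
marginal/conditional R² extended to random slopes: each slope block
contributes its estimated variance times the mean squared covariate (the
mean diagonal of the induced covariance).  The climate share (the blue
bars of the habitat-vs-climate split) is the fixed part plus all
habitat × PC slope components; the habitat share (red bars) is the random
intercept component.  The spatial smooth counts toward the conditional R²
but neither the marginal R² nor the climate share — it models spatial
dependence, not climate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control

from .models import FittedModel, ModelDesign

__all__ = ["marginal_slopes", "classify_and_tally", "r2_partition",
           "VarianceDecomposition"]

Z_CRIT = 1.96


def marginal_slopes(
    fit: FittedModel,
    design: ModelDesign,
    min_n: int = 100,
    include_cov_term: bool = True,
    fdr: bool = False,
) -> pd.DataFrame:
    """Habitat-specific and across-habitat slopes with CIs and flags.

    Only defined for the random-slope models (3–5).  Returns one row per
    (habitat, PC) plus one across-habitat row per PC with the fixed slope.
    ``fdr=True`` applies a Benjamini–Hochberg correction across the
    habitat-specific tests (off by default).
    """
    if fit.model_id < 3:
        raise ValueError(
            f"model {fit.model_id} has no habitat-specific slopes; "
            "marginal slopes require models 3-5")
    level = design.habitat_level
    sizes = pd.Series(design.habitat_labels).value_counts()

    rows = []
    for j in range(1, 5):
        beta_j = float(fit.beta[f"pc{j}"])
        se_beta = float(fit.beta_se[f"pc{j}"])
        rows.append(dict(habitat="(all)", level=level, pc=j,
                         n_plots=len(design.y), slope=beta_j, se=se_beta,
                         se_formula="fixed", suppressed=False))
        block = fit.blups[f"habitat_slope_pc{j}_l{level}"]
        bidx = j  # position of pc j in (intercept, pc1..pc4)
        for g, lab in enumerate(block["labels"]):
            b = float(block["estimate"][g])
            cond_se = float(block["cond_se"][g])
            if include_cov_term and block.get("cov_with_beta") is not None:
                cov = float(block["cov_with_beta"][g, bidx])
                var = se_beta**2 + cond_se**2 + 2.0 * cov
                formula = "fixed+blup+2cov"
                if var <= 0:  # numerically degenerate; fall back
                    var = se_beta**2 + cond_se**2
                    formula = "fixed+blup"
            else:
                var = se_beta**2 + cond_se**2
                formula = "fixed+blup"
            n_g = int(sizes.get(lab, 0))
            rows.append(dict(habitat=lab, level=level, pc=j, n_plots=n_g,
                             slope=beta_j + b, se=float(np.sqrt(var)),
                             se_formula=formula, suppressed=n_g < min_n))
    out = pd.DataFrame(rows)
    out["ci_low"] = out["slope"] - Z_CRIT * out["se"]
    out["ci_high"] = out["slope"] + Z_CRIT * out["se"]
    if fdr:
        from scipy.stats import norm

        mask = out["habitat"] != "(all)"
        p = 2 * norm.sf(np.abs(out.loc[mask, "slope"] / out.loc[mask, "se"]))
        out.loc[mask, "p_adj"] = false_discovery_control(p, method="bh")
        signif = out.get("p_adj", pd.Series(np.nan, index=out.index)) < 0.05
    else:
        signif = (out["ci_low"] > 0) | (out["ci_high"] < 0)
    out["significant"] = signif.fillna(False) & ~out["suppressed"]
    out["trait"] = fit.trait
    out["model_id"] = fit.model_id
    return out


def classify_and_tally(slopes: pd.DataFrame, habitats: pd.DataFrame) -> pd.DataFrame:
    """Count slope classes per (trait, PC, level-1 parent habitat).

    Each unsuppressed habitat estimate is classified positive-significant,
    negative-significant or nonsignificant; suppressed estimates are
    counted separately.  Counts sum to the number of child habitats.
    """
    df = slopes[slopes["habitat"] != "(all)"].copy()
    if df.empty:
        return pd.DataFrame(columns=["trait", "pc", "parent", "n_pos_sig",
                                     "n_neg_sig", "n_nonsig", "n_suppressed"])
    level = int(df["level"].iloc[0])
    parent_map = _parent_map(habitats, level)
    missing = set(df["habitat"]) - set(parent_map)
    if missing:
        raise ValueError(f"habitat(s) missing a level-1 parent mapping: "
                         f"{sorted(missing)[:5]}")
    df["parent"] = df["habitat"].map(parent_map)

    def cls(row):
        if row.suppressed:
            return "n_suppressed"
        if row.significant:
            return "n_pos_sig" if row.slope > 0 else "n_neg_sig"
        return "n_nonsig"

    df["class"] = [cls(r) for r in df.itertuples()]
    tally = (df.groupby(["trait", "pc", "parent"])["class"]
             .value_counts().unstack(fill_value=0).reset_index())
    for col in ("n_pos_sig", "n_neg_sig", "n_nonsig", "n_suppressed"):
        if col not in tally.columns:
            tally[col] = 0
    tally.columns.name = None
    return tally[["trait", "pc", "parent", "n_pos_sig", "n_neg_sig",
                  "n_nonsig", "n_suppressed"]]


def _parent_map(habitats: pd.DataFrame, level: int) -> dict:
    if level == 1:
        labs = habitats["level1"].dropna().unique()
        return {h: h for h in labs}
    sub = habitats[[f"level{level}", "level1"]].dropna().drop_duplicates()
    return dict(zip(sub[f"level{level}"], sub["level1"]))


@dataclass
class VarianceDecomposition:
    model_id: int
    trait: str
    sigma2_fixed: float
    sigma2_random: dict          # component name -> induced variance
    sigma2_residual: float
    r2_marginal: float
    r2_conditional: float
    r2_climate: float
    r2_habitat: float

    def to_row(self) -> dict:
        row = dict(model_id=self.model_id, trait=self.trait,
                   sigma2_fixed=self.sigma2_fixed,
                   sigma2_residual=self.sigma2_residual,
                   r2_marginal=self.r2_marginal,
                   r2_conditional=self.r2_conditional,
                   r2_climate=self.r2_climate, r2_habitat=self.r2_habitat)
        for k, v in self.sigma2_random.items():
            row[f"sigma2_{k}"] = v
        return row


def r2_partition(fit: FittedModel, design: ModelDesign) -> VarianceDecomposition:
    """Variance-components marginal/conditional R² with the climate split."""
    for name, v in fit.varcomp.items():
        if not np.isfinite(v):
            raise ValueError(f"non-finite variance component {name!r}")
    if not np.isfinite(fit.sigma2):
        raise ValueError("non-finite residual variance")

    fixed_pred = design.X @ fit.beta.to_numpy()
    sigma2_f = float(np.var(fixed_pred))

    induced: dict[str, float] = {}
    for block in design.all_blocks():
        Z = block.Z
        if hasattr(Z, "multiply"):  # sparse
            row_ss = np.asarray(Z.multiply(Z).sum(axis=1)).ravel()
        else:
            row_ss = (np.asarray(Z) ** 2).sum(axis=1)
        induced[block.name] = float(fit.varcomp[block.name] * row_ss.mean())

    spatial = induced.get("spatial", 0.0)
    slope_sum = sum(v for k, v in induced.items() if k.startswith("habitat_slope"))
    intercept = sum(v for k, v in induced.items()
                    if k.startswith("habitat_intercept"))
    total = sigma2_f + sum(induced.values()) + fit.sigma2

    return VarianceDecomposition(
        model_id=fit.model_id, trait=fit.trait,
        sigma2_fixed=sigma2_f, sigma2_random=induced,
        sigma2_residual=float(fit.sigma2),
        r2_marginal=sigma2_f / total,
        r2_conditional=(sigma2_f + sum(induced.values())) / total,
        r2_climate=(sigma2_f + slope_sum) / total,
        r2_habitat=intercept / total,
    )
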