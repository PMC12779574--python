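"""Hierarchical land-use models for assemblage-level functional metrics.

Responses are variance-stabilised by a signed square root (vulnerability can
be negative) and scaled by their standard deviation, then modelled with a
univariate linear mixed-effects model: a fixed land-use factor (10 fine or 4
coarse levels, contrasts against a reference level — pristine primary or
primary vegetation) and random intercepts for study landscape and study
block nested within landscape.  Fitting is restricted maximum likelihood via
``statsmodels`` MixedLM; confidence intervals and p-values are Wald-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf


def zscore_transform(values: np.ndarray, ddof: int = 0) -> np.ndarray:
    """Signed square root then scaling by the standard deviation.

    ``y = sign(x) * sqrt(|x|)``, divided by ``std(y)``; the signed form admits
    negative responses such as vulnerability.  Raises on zero variance.
    """
    x = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    y = np.sign(x) * np.sqrt(np.abs(x))
    sd = y.std(ddof=ddof)
    if sd <= 1e-12 * max(1.0, float(np.abs(y).max())):
        raise ValueError("zero variance after transformation")
    return y / sd


@dataclass
class ModelResult:
    """Fitted land-use contrasts for one response metric."""

    response: str
    subset: str
    land_use_levels: int  # 10 or 4
    reference_level: str
    coefficients: dict[str, dict[str, float]]  # level -> estimate/se/ci_low/ci_high/p
    intercept: float
    n_obs: int
    random_effect_variances: dict[str, float]
    converged: bool = True
    singular: bool = False
    dropped_levels: list[str] = field(default_factory=list)

    def estimate(self, level: str) -> float:
        return self.coefficients[level]["estimate"]


def fit_landuse_model(
    table: pd.DataFrame,
    response: str,
    factor_resolution: int = 10,
    reference: str | None = None,
    subset: str = "all",
    transform: bool = True,
    reml: bool = True,
) -> ModelResult:
    """Fit the univariate mixed model ``response ~ land_use + (1|landscape/block)``.

    ``table`` needs columns ``response``, ``land_use`` (fine labels),
    ``landscape_id`` and ``block_id``.  ``factor_resolution`` 10 uses the fine
    labels; 4 collapses them to primary/secondary/agriculture/urban.  The
    reference level defaults to ``pristine_primary`` (10) or ``primary`` (4).
    Levels absent from the data are dropped with a warning.  Set
    ``transform=False`` if the response is already on the analysis scale.
    """
    from .datamodel import LandUse

    needed = {response, "land_use", "landscape_id", "block_id"}
    missing = needed - set(table.columns)
    if missing:
        raise ValueError(f"table missing columns: {sorted(missing)}")
    df = table.dropna(subset=[response]).copy()
    lu = df["land_use"].map(lambda v: v.value if isinstance(v, LandUse) else str(v))
    if factor_resolution == 4:
        lu = lu.map(lambda v: LandUse(v).coarse)
        reference = reference or "primary"
    elif factor_resolution == 10:
        reference = reference or "pristine_primary"
    else:
        raise ValueError("factor_resolution must be 10 or 4")
    df["lu"] = lu
    if reference not in set(df["lu"]):
        raise ValueError(f"reference level {reference!r} absent from data")

    if factor_resolution == 10:
        expected = [m.value for m in LandUse]
    else:
        expected = ["primary", "secondary", "agriculture", "urban"]
    dropped = [lv for lv in expected if lv not in set(df["lu"])]
    if dropped:
        warnings.warn(f"land-use level(s) absent from data, dropped: {dropped}", stacklevel=2)

    y = df[response].to_numpy(dtype=float)
    df["_y"] = zscore_transform(y) if transform else y
    # block nested in landscape: unique block labels avoid accidental pooling
    df["_block"] = df["landscape_id"].astype(str) + ":" + df["block_id"].astype(str)

    model = smf.mixedlm(
        f"_y ~ C(lu, Treatment(reference='{reference}'))",
        data=df,
        groups=df["landscape_id"],
        re_formula="1",
        vc_formula={"block": "0 + C(_block)"},
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=reml, method=["lbfgs", "cg"])

    coefs: dict[str, dict[str, float]] = {}
    conf = fit.conf_int()
    prefix = f"C(lu, Treatment(reference='{reference}'))[T."
    intercept = float(fit.params["Intercept"])
    for name in fit.params.index:
        if name.startswith(prefix):
            level = name[len(prefix):-1]
            coefs[level] = {
                "estimate": float(fit.params[name]),
                "se": float(fit.bse[name]),
                "ci_low": float(conf.loc[name, 0]),
                "ci_high": float(conf.loc[name, 1]),
                "p": float(fit.pvalues[name]),
            }
    re_var = {"landscape": float(fit.cov_re.iloc[0, 0])}
    if fit.vcomp is not None and len(fit.vcomp):
        re_var["block"] = float(fit.vcomp[0])
    singular = any(v < 1e-10 for v in re_var.values())
    return ModelResult(
        response=response,
        subset=subset,
        land_use_levels=factor_resolution,
        reference_level=reference,
        coefficients=coefs,
        intercept=intercept,
        n_obs=int(len(df)),
        random_effect_variances=re_var,
        converged=bool(fit.converged),
        singular=singular,
        dropped_levels=dropped,
    )


__all__ = ["ModelResult", "zscore_transform", "fit_landuse_model"]
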