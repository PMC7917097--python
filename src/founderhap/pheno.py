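"""Year-adjusted phenotypes via a mixed linear model.

Multi-year trait records are adjusted with ``value ~ year (fixed) +
genotype (random intercept) + residual``; the BLUP of the genotype effect
becomes the working phenotype for genomic prediction and GWAS.  The model
is fit by REML (statsmodels MixedLM).  Traits observed in a single year
degenerate gracefully to shrunken centered means (the genotype/residual
variance split is not identifiable there), with a warning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .datamodel import PhenotypeTable

logger = logging.getLogger(__name__)


@dataclass
class AdjustedPhenotypes:
    trait: str
    blups: pd.Series  # individual -> genotype BLUP
    var_genotype: float
    var_residual: float
    year_effects: pd.Series
    degenerate: bool = False

    def aligned(self, individuals) -> np.ndarray:
        """BLUP vector aligned to an individual list (NaN where absent)."""
        return self.blups.reindex(list(individuals)).to_numpy(float)


def _shrunken_centered_means(sub: pd.DataFrame, trait: str, year_effects) -> AdjustedPhenotypes:
    overall = sub["value"].mean()
    g = sub.groupby("individual")["value"].agg(["mean", "count"])
    shrink = g["count"] / (g["count"] + 1.0)
    blups = (g["mean"] - overall) * shrink
    return AdjustedPhenotypes(
        trait, blups, float("nan"), float("nan"), year_effects, degenerate=True
    )


def year_adjust_blup(pheno: PhenotypeTable, trait: str) -> AdjustedPhenotypes:
    """Genotype BLUPs for one trait after absorbing year effects."""
    sub = pheno.trait_records(trait)
    if len(sub) < 2:
        raise ValueError(f"trait {trait!r} needs at least 2 records")
    years = sorted(sub["year"].unique())
    if len(years) == 1 or sub["individual"].nunique() == len(sub) == sub["year"].nunique():
        logger.warning(
            "trait %r: variance separation impossible, returning shrunken centered means",
            trait,
        )
        return _shrunken_centered_means(sub, trait, pd.Series(0.0, index=years))
    exog = pd.get_dummies(sub["year"].astype("category"), prefix="year", drop_first=True)
    exog.insert(0, "const", 1.0)
    exog = exog.astype(float)
    res = None
    last_err: Exception | None = None
    for method in ("lbfgs", "bfgs", "powell"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.MixedLM(sub["value"].to_numpy(float), exog, groups=sub["individual"])
                res = model.fit(reml=True, method=method, maxiter=500)
            break
        except (np.linalg.LinAlgError, ValueError) as err:
            last_err = err
            res = None
    try:
        if res is None:
            raise ValueError(f"all optimizers failed: {last_err}")
        blups = pd.Series(
            {ind: float(re.iloc[0]) for ind, re in res.random_effects.items()}
        )
        var_g = float(res.cov_re.iloc[0, 0])
        var_e = float(res.scale)
        fe = res.fe_params
        year_effects = pd.Series(
            {years[0]: 0.0, **{y: float(fe.get(f"year_{y}", 0.0)) for y in years[1:]}}
        )
        return AdjustedPhenotypes(trait, blups, var_g, var_e, year_effects)
    except (np.linalg.LinAlgError, ValueError) as err:  # pragma: no cover
        logger.warning("trait %r: mixed model failed (%s); falling back", trait, err)
        centered = sub.copy()
        centered["value"] -= centered.groupby("year")["value"].transform("mean")
        return _shrunken_centered_means(centered, trait, pd.Series(0.0, index=years))
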