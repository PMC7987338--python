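"""Generalized linear models for dispersal, reproduction, and dominance.

Binomial (logit) GLMs for natal dispersal and first-offspring infant
survival, a Gaussian GLM on the variance-stabilized age at first birth,
and the descriptive dominance-attainment summary.  Fitting is IRLS via
statsmodels GLM; p-values are two-sided normal-based (the Wald z is
estimate / SE from the observed information), matching how class-level
dispersal tables are conventionally reported.

``load_dispersal_counts`` ships the class-level natal-dispersal counts of
the Karisoke mountain-gorilla population, reconstructed from the published
class percentages and sample sizes (females dispersing before first birth:
37.5% of 32 non-orphans, 54.5% of 11 infant orphans, 75.0% of 8
juvenile/subadult orphans; males dispersing before age 16: 37.5% of 40
non-orphans, 84.6% of 13 juvenile/subadult orphans).  On grouped counts
from a saturated one-factor design the logistic fit has a closed form —
coefficients are log-odds differences and SEs are square roots of summed
reciprocal cell counts — which the tests use as an oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "GlmFit",
    "load_dispersal_counts",
    "fit_binomial_glm",
    "fit_female_dispersal",
    "fit_male_dispersal",
    "fit_age_first_birth",
    "fit_first_offspring_survival",
    "dominance_attainment_summary",
]

_SEPARATION_CAP = 15.0


@dataclass
class GlmFit:
    """Coefficients on the link scale with Wald inference."""

    coefficients: pd.Series
    se: pd.Series
    z: pd.Series
    p: pd.Series
    family: str
    n: int
    separation_flag: bool = False

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({"est": self.coefficients, "se": self.se,
                             "z": self.z, "p": self.p})


def load_dispersal_counts() -> pd.DataFrame:
    """Class-level natal-dispersal counts (see module docstring)."""
    with resources.files("silverback.datasets").joinpath(
        "dispersal_counts.csv"
    ).open() as fh:
        return pd.read_csv(fh)


def _wrap(res, family: str, n: int) -> GlmFit:
    from scipy.stats import norm

    coef = res.params
    se = res.bse
    z = coef / se
    p = pd.Series(2 * norm.sf(np.abs(z)), index=coef.index)
    sep = bool((coef.abs() > _SEPARATION_CAP).any())
    if sep:
        warnings.warn(
            "coefficient beyond +-15 on the link scale: probable complete "
            "separation; estimates capped in interpretation", stacklevel=3,
        )
    return GlmFit(coefficients=coef, se=se, z=z, p=p, family=family, n=n,
                  separation_flag=sep)


def fit_binomial_glm(data: pd.DataFrame, formula: str) -> GlmFit:
    """Logistic GLM on binary outcomes or grouped successes/failures.

    ``formula`` is a statsmodels formula; for grouped counts use the
    two-column response ``successes + failures ~ ...``.  IRLS is run to a
    deviance tolerance of 1e-10.  Empty factor levels are rejected.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    model = smf.glm(formula, data=data, family=sm.families.Binomial())
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        raise ValueError("design matrix is rank deficient (empty factor level?)")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(tol=1e-10, maxiter=200)
    trials = getattr(model, "n_trials", None)
    n = int(np.sum(trials)) if trials is not None else len(model.endog)
    return _wrap(res, "binomial-logit", n)


_CLASS_ORDER = "C(orphan_class, Treatment('non_orphan'))"


def fit_female_dispersal(counts: pd.DataFrame | None = None) -> GlmFit:
    """Female natal dispersal before first birth on orphan class.

    Grouped-count logistic GLM with infant and juvenile/subadult dummies,
    reference non-orphan.  Defaults to the packaged Karisoke counts.
    """
    counts = load_dispersal_counts() if counts is None else counts
    d = counts[counts.sex == "F"].copy()
    d["stayed"] = d.n - d.dispersed
    return fit_binomial_glm(d, f"dispersed + stayed ~ {_CLASS_ORDER}")


def fit_male_dispersal(counts: pd.DataFrame | None = None) -> GlmFit:
    """Male natal dispersal before age 16 on orphan class.

    Only the juvenile/subadult contrast is estimable: too few males
    orphaned as infants reached 16 for that class to be modelled.
    """
    counts = load_dispersal_counts() if counts is None else counts
    d = counts[(counts.sex == "M")
               & counts.orphan_class.isin(["non_orphan", "juv_subadult"])].copy()
    d["stayed"] = d.n - d.dispersed
    return fit_binomial_glm(d, f"dispersed + stayed ~ {_CLASS_ORDER}")


def fit_age_first_birth(records: pd.DataFrame) -> GlmFit:
    """Gaussian GLM of sqrt(age at first birth - 8) on orphan class and dispersal.

    8 years is the earliest recorded age at first birth, so the transform
    requires every age strictly above 8; the square root symmetrizes the
    positive skew.  ``records`` needs columns ``age_first_birth``,
    ``orphan_class`` (merged juvenile/subadult coding) and ``dispersed``.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    if (records.age_first_birth <= 8).any():
        bad = records.loc[records.age_first_birth <= 8, "age_first_birth"].tolist()
        raise ValueError(
            f"age at first birth must exceed 8 years for the sqrt(age - 8) "
            f"transform; got {bad}"
        )
    data = records.copy()
    data["response"] = np.sqrt(data.age_first_birth - 8.0)
    formula = f"response ~ {_CLASS_ORDER} + dispersed"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = smf.glm(formula, data=data, family=sm.families.Gaussian()).fit()
        except ValueError:
            # zero-variance response: the identity-link Gaussian GLM equals
            # OLS, which handles the degenerate case
            res = smf.ols(formula, data=data).fit()
    return _wrap(res, "gaussian-identity", len(data))


def fit_first_offspring_survival(records: pd.DataFrame) -> GlmFit:
    """Logistic GLM of first-offspring survival through infancy.

    Outcome 1 if the female's first offspring survived to 4 years, 0 if it
    died before; design: age at first birth, dispersal before first birth,
    and (merged) orphan class.
    """
    return fit_binomial_glm(
        records, f"offspring_survived ~ age_first_birth + dispersed + {_CLASS_ORDER}"
    )


def dominance_attainment_summary(
    roster: pd.DataFrame, min_age: float = 23.0, min_tenure_years: float = 0.5
) -> pd.DataFrame:
    """Proportion of males attaining dominance, by orphan class.

    A male scores 1 if he held dominant status of a stable group for at
    least six *consecutive* months (two shorter tenures do not qualify).
    The comparison is restricted to males that survived and remained in
    the study population to at least ``min_age`` (by then every male who
    will attain dominance has).  Descriptive only — no test is attached,
    as class counts are far too small for one.
    """
    males = roster[roster.sex == "M"].copy()
    last_obs = males.death_age.fillna(males.censor_age)
    males = males[last_obs >= min_age]
    scores = []
    for rec in males.itertuples(index=False):
        tenures = rec.dominance_tenures or ()
        scores.append(int(any(e - s >= min_tenure_years for s, e in tenures)))
    males["dominant_score"] = scores
    out = males.groupby("orphan_class", observed=True).agg(
        n=("id", "size"), attained=("dominant_score", "sum"),
    )
    out["proportion"] = out.attained / out.n
    return out
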