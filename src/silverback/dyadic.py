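"""Dyadic relationship-change models around maternal-loss incidents.

Each record is one (immature, group member) dyad with the change in its
Simple Ratio Index between the pre- and post-loss windows
(``delta_sri = SRI_post - SRI_pre``).  Three mixed models, fitted
separately for affiliative contact and proximity:

* *all-immature model* — orphans and non-orphan immatures, with an
  orphan x partner-class interaction: did orphans' relationships change
  differently from their peers', and with whom?
* *orphan-only model* — orphan dyads only; fixed effects orphan age and
  sex, partner age-mate status, maternal sibling status, partner age-sex
  class (reference: dominant male) and the class x sibling interaction.
* *adult-male model* — orphan dyads with adult males of known paternity;
  fixed effects dominance, sibling, paternity and dominance x sibling
  (no dominance x paternity term: collinear in practice).

The smooth sampling-effort term is a cubic B-spline in the dyad's mean
focal-scan count; random effects follow the nesting of the study design
(immature within incident within group, plus a partner intercept).
Reported p-values are normal-based (z = estimate / SE).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import AGE_SEX_CLASSES, age_sex_class, years_between
from .networks import InadequateDataError, build_paired_networks
from .permutation import bspline_basis

logger = logging.getLogger(__name__)

__all__ = [
    "build_dyad_table",
    "fit_all_immature_model",
    "fit_orphan_only_model",
    "fit_adult_male_model",
    "DyadicModelFit",
]

_ADULT_MALE_CLASSES = ("dominant_male", "subordinate_adult_male")
_CLASS_LEVELS = AGE_SEX_CLASSES


def build_dyad_table(
    scans: pd.DataFrame,
    roster: pd.DataFrame,
    incidents: pd.DataFrame,
    assoc_type: str = "proximity",
    window_days: int = 183,
    min_scans: int = 12,
    swap_periods: bool = False,
) -> pd.DataFrame:
    """One record per (immature, partner) dyad across all usable incidents.

    Immatures are 2-8 years old at the loss date; partners are every other
    node of the incident's paired networks (the orphans' mother is already
    excluded from those).  Records pairing a non-orphan immature with an
    orphan partner are dropped, as are incidents without adequate scan
    coverage.  ``sibling`` means shared known mother; ``age_mate`` means
    strictly less than 2 years age difference; ``father`` is 1/0 where
    paternity is known and NaN otherwise; ``mean_scans`` is the dyad mean
    of total focal scans over both periods.  ``swap_periods`` exchanges the
    pre and post networks (diagnostic: it negates every delta).
    """
    info = roster.set_index("id")
    rows = []
    for inc in incidents.itertuples(index=False):
        inc_d = inc._asdict()
        try:
            pre_net, post_net = build_paired_networks(
                scans[scans.group == inc.group], inc_d, assoc_type,
                window_days=window_days, min_scans=min_scans,
            )
        except InadequateDataError as err:
            logger.info("dropping incident: %s", err)
            continue
        if swap_periods:
            pre_net, post_net = post_net, pre_net
        nodes = pre_net.nodes
        ages = {n: years_between(info.loc[n, "birth_date"], inc.date) for n in nodes}
        classes = {}
        for n in nodes:
            try:
                classes[n] = age_sex_class(ages[n], info.loc[n, "sex"],
                                           info.loc[n, "dominant"])
            except (KeyError, TypeError):
                classes[n] = None
        orphans = set(inc.orphan_ids)
        total = pre_net.focal_counts + post_net.focal_counts
        immature = [n for n in nodes if 2.0 <= ages[n] < 8.0]
        for im in immature:
            for pt in nodes:
                if pt == im:
                    continue
                if im not in orphans and pt in orphans:
                    continue  # non-orphan relationships with orphan partners
                if classes[pt] is None:
                    logger.warning("dropping dyad (%s, %s): partner class unresolvable",
                                   im, pt)
                    continue
                mother_im = info.loc[im, "mother_id"]
                mother_pt = info.loc[pt, "mother_id"]
                father = info.loc[im, "father_id"]
                rows.append(dict(
                    incident=inc.incident,
                    group=inc.group,
                    immature=im,
                    partner=pt,
                    orphan=int(im in orphans),
                    delta_sri=post_net.weight(im, pt) - pre_net.weight(im, pt),
                    assoc_type=assoc_type,
                    immature_age=ages[im],
                    immature_sex=info.loc[im, "sex"],
                    partner_class=classes[pt],
                    sibling=int(mother_im != "unknown" and mother_im == mother_pt),
                    age_mate=int(abs(ages[im] - ages[pt]) < 2.0),
                    father=(np.nan if father is None or pd.isna(father)
                            else float(father == pt)),
                    mean_scans=float((total[im] + total[pt]) / 2.0),
                ))
    return pd.DataFrame(rows)


@dataclass
class DyadicModelFit:
    """Coefficient table (est, se, z, p) and fit metadata for one model."""

    coef_table: pd.DataFrame
    n_records: int
    converged: bool
    random_effects_sd: dict
    result: object = field(repr=False)


def _spline_columns(data: pd.DataFrame, spline_df: int) -> pd.DataFrame:
    B = bspline_basis(data.mean_scans.to_numpy(float), df=spline_df)
    return pd.DataFrame({f"s_mean_scans_{k}": B[:, k] for k in range(B.shape[1])},
                        index=data.index)


def _class_dummies(data: pd.DataFrame, prefix: str = "class") -> pd.DataFrame:
    """Treatment-coded partner-class dummies, reference = dominant male."""
    levels = [c for c in _CLASS_LEVELS if c in set(data.partner_class)]
    out = {}
    for c in levels:
        if c == "dominant_male":
            continue
        out[f"{prefix}_{c}"] = (data.partner_class == c).astype(float)
    return pd.DataFrame(out, index=data.index)


def _prune_design(X: pd.DataFrame, min_sv: float = 1e-4) -> tuple[pd.DataFrame, list]:
    """Drop constant and (near-)linearly dependent columns, keeping order.

    A column is kept only while the smallest singular value of the
    column-normalized design stays above ``min_sv``; empty interaction
    cells and spline columns degenerate at small n are dropped rather than
    fitted at unbounded variance.
    """
    keep: list[str] = []
    dropped: list[str] = []
    mat = np.empty((len(X), 0))
    for col in X.columns:
        v = X[col].to_numpy(float)
        norm = np.linalg.norm(v)
        if norm == 0 or (col != "intercept" and np.ptp(v) == 0):
            dropped.append(col)
            continue
        trial = np.column_stack([mat, v / norm])
        if np.linalg.svd(trial, compute_uv=False)[-1] > min_sv:
            keep.append(col)
            mat = trial
        else:
            dropped.append(col)
    if dropped:
        logger.info("dropped unidentifiable design columns: %s", dropped)
    return X[keep], dropped


def _fit_mixed(data: pd.DataFrame, design_cols: list, groups_col: str, vc: dict):
    """MixedLM of delta_sri on pruned design columns.

    Random structure: intercept per ``groups_col`` plus an identity
    variance component for each id column in ``vc`` (e.g. immature and
    partner identity), evaluated within groups.
    """
    import statsmodels.formula.api as smf

    formula = "delta_sri ~ 0 + " + " + ".join(design_cols)
    # fallback ladder: drop variance components one by one if the REML
    # surface sends one to infinity (singular GLS solve at small n)
    attempts = [dict(vc)]
    names = list(vc)
    for k in range(1, len(names) + 1):
        attempts.append({n: vc[n] for n in names[k:]})
    last_err = None
    for trial in attempts:
        vc_formula = {name: f"0 + C({col})" for name, col in trial.items()} or None
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = smf.mixedlm(formula, data, groups=data[groups_col],
                                    vc_formula=vc_formula)
                res = model.fit(reml=True, method=["lbfgs", "powell"])
            if trial != attempts[0]:
                warnings.warn(
                    f"random structure reduced to {list(trial) or ['group intercept']} "
                    "(variance component unidentifiable at this sample size)",
                    stacklevel=3,
                )
            return res
        except (np.linalg.LinAlgError, ValueError) as err:
            last_err = err
    raise last_err


def _coef_table(res, data: pd.DataFrame) -> pd.DataFrame:
    names = list(res.fe_params.index)
    table = pd.DataFrame({"est": np.asarray(res.fe_params),
                          "se": np.asarray(res.bse_fe)}, index=names)
    table["z"] = table.est / table.se
    from scipy.stats import norm

    table["p"] = 2 * norm.sf(np.abs(table.z))
    # flag contrasts backed by fewer than 2 records
    counts = data.partner_class.value_counts() if "partner_class" in data else pd.Series()
    table["unstable"] = [
        any(str(cls) in name and cnt < 2 for cls, cnt in counts.items())
        for name in table.index
    ]
    return table


def _summarize(res, data) -> DyadicModelFit:
    vc_names = getattr(res.model.exog_vc, "names", []) if res.model.exog_vc else []
    re_sd = {k: float(np.sqrt(max(v, 0.0)))
             for k, v in zip(vc_names, np.atleast_1d(res.vcomp))}
    cov_re = np.asarray(res.cov_re)
    if cov_re.size:
        re_sd["group_intercept"] = float(np.sqrt(max(cov_re[0, 0], 0.0)))
    return DyadicModelFit(
        coef_table=_coef_table(res, data),
        n_records=int(res.nobs),
        converged=bool(res.converged),
        random_effects_sd=re_sd,
        result=res,
    )


def _degenerate_fit(records: pd.DataFrame) -> DyadicModelFit:
    """All-zero fit for a response without variation (no-signal case)."""
    table = pd.DataFrame(0.0, index=["intercept"], columns=["est", "se", "z"])
    table["p"] = 1.0
    table["unstable"] = False
    return DyadicModelFit(coef_table=table, n_records=len(records), converged=True,
                          random_effects_sd={}, result=None)


def fit_all_immature_model(records: pd.DataFrame, spline_df: int = 4) -> DyadicModelFit:
    """Relationship change of all immatures, with orphan x class interaction.

    ``delta_sri ~ age + sex + class + orphan + orphan x class +
    s(mean_scans)`` with a random intercept per incident and variance
    components for immature and partner identity within incidents.
    Requires both orphan and non-orphan records.  Unidentifiable contrasts
    (empty cells) are dropped from the design rather than fitted at
    infinite variance.
    """
    if records.orphan.nunique() < 2:
        raise ValueError("all-immature model needs orphan and non-orphan records")
    if np.ptp(records.delta_sri.to_numpy(float)) == 0:
        return _degenerate_fit(records)
    data = records.copy()
    cls = _class_dummies(data)
    X = pd.concat(
        [
            pd.Series(1.0, index=data.index, name="intercept"),
            data.immature_age.rename("age"),
            (data.immature_sex == "M").astype(float).rename("sex_male"),
            cls,
            data.orphan.astype(float),
            cls.mul(data.orphan, axis=0).add_prefix("orphan_x_"),
            _spline_columns(data, spline_df),
        ],
        axis=1,
    )
    X, _ = _prune_design(X)
    data = pd.concat([data[["delta_sri", "incident", "immature", "partner"]], X], axis=1)
    res = _fit_mixed(data, list(X.columns), "incident",
                     vc={"immature": "immature", "partner": "partner"})
    return _summarize(res, data)


def fit_orphan_only_model(records: pd.DataFrame, spline_df: int = 4) -> DyadicModelFit:
    """Orphan-dyad model: who provides the post-loss social support?

    ``delta_sri ~ age_O + sex_O + age_mate + class_GM + sibling +
    class_GM x sibling + s(mean_scans)`` with a random intercept per group
    and variance components for orphan and partner identity (orphans
    nested in groups).  Reference class is the dominant male: the
    intercept estimates the mean change for a non-sibling dominant-male
    partner at covariate baseline, and each class contrast is relative to
    him.
    """
    data = records[records.orphan == 1].copy()
    if not len(data):
        raise ValueError("no orphan records")
    cls = _class_dummies(data)
    X = pd.concat(
        [
            pd.Series(1.0, index=data.index, name="intercept"),
            data.immature_age.rename("age"),
            (data.immature_sex == "M").astype(float).rename("sex_male"),
            data.age_mate.astype(float),
            data.sibling.astype(float),
            cls,
            cls.mul(data.sibling, axis=0).add_prefix("sibling_x_"),
            _spline_columns(data, spline_df),
        ],
        axis=1,
    )
    X, _ = _prune_design(X)
    data = pd.concat([data[["delta_sri", "group", "immature", "partner"]], X], axis=1)
    res = _fit_mixed(data, list(X.columns), "group",
                     vc={"orphan_id": "immature", "partner": "partner"})
    return _summarize(res, data)


def fit_adult_male_model(records: pd.DataFrame, spline_df: int = 4) -> DyadicModelFit:
    """Orphan-adult male model with kinship effects.

    Restricted to orphan dyads whose partner is an adult male and whose
    paternity is known.  Fixed effects: orphan age and sex, partner
    dominance, maternal sibling, paternity, and dominance x sibling.  The
    dominance x paternity interaction is deliberately absent (collinear
    with paternity where the dominant male sires most offspring).  Random
    effects: orphan identity and male identity (crossed).
    """
    data = records[(records.orphan == 1)
                   & records.partner_class.isin(_ADULT_MALE_CLASSES)].copy()
    if not len(data):
        raise ValueError("no orphan-adult male records")
    if data.father.isna().all():
        raise ValueError("paternity unknown for every record")
    data = data[data.father.notna()].copy()
    dominant = (data.partner_class == "dominant_male").astype(float)
    X = pd.concat(
        [
            pd.Series(1.0, index=data.index, name="intercept"),
            data.immature_age.rename("age"),
            (data.immature_sex == "M").astype(float).rename("sex_male"),
            dominant.rename("dominant_partner"),
            data.sibling.astype(float),
            data.father.astype(float),
            (dominant * data.sibling).rename("dominant_x_sibling"),
            _spline_columns(data, spline_df),
        ],
        axis=1,
    )
    X, _ = _prune_design(X)
    if len(data) < X.shape[1] + 5:
        raise ValueError(
            f"adult-male model: {len(data)} records cannot support "
            f"{X.shape[1]} fixed effects"
        )
    data = pd.concat([data[["delta_sri", "immature", "partner"]], X], axis=1)
    data["pooled"] = 1
    res = _fit_mixed(data, list(X.columns), "pooled",
                     vc={"orphan_id": "immature", "male": "partner"})
    return _summarize(res, data)
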