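"""Survival analysis of maternal loss: Cox models and Bayesian Siler fits.

Two complementary analyses of the same left-truncated, right-censored age
intervals:

* A Cox proportional-hazards model in which orphan class is a time-varying
  covariate — every individual contributes non-orphan exposure from age 2
  up to maternal loss (if any), and class-specific exposure thereafter.
  Fitting is delegated to :class:`lifelines.CoxTimeVaryingFitter` on
  episode-split records (Efron tie handling); episode construction and the
  class coding live here.

* A Bayesian survival-trajectory analysis with a Siler (bathtub) baseline
  hazard, three covariate structures — (a) none, (b) proportional hazards
  per orphan class, (c) class effects on every Siler parameter — sampled
  with an affine-invariant ensemble (emcee) and compared by DIC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .config import ORPHAN_CLASSES, ORPHAN_CLASSES_MERGED, orphan_class_at_loss

__all__ = [
    "SilerParams",
    "SilerFit",
    "build_survival_records",
    "episode_split",
    "fit_cox_ph",
    "fit_siler_bayes",
    "compare_dic",
]


# ---------------------------------------------------------------------------
# Siler mortality model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SilerParams:
    """Five-parameter Siler bathtub hazard.

    h(x) = a0 * exp(-a1 * x) + c + b0 * exp(b1 * x)

    ``a0`` (1/yr) and ``a1`` (1/yr) give a declining infant-mortality term,
    ``c`` (1/yr) an age-independent term, and ``b0`` (1/yr), ``b1`` (1/yr)
    an exponentially increasing senescent term.  All parameters must be
    non-negative, which guarantees h(x) >= 0.
    """

    a0: float = 0.35
    a1: float = 1.1
    c: float = 0.015
    b0: float = 0.0025
    b1: float = 0.10

    def __post_init__(self):
        for name in ("a0", "a1", "c", "b0", "b1"):
            if getattr(self, name) < 0:
                raise ValueError(f"Siler parameter {name} must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.a0, self.a1, self.c, self.b0, self.b1])


def siler_hazard(params: SilerParams, age) -> np.ndarray:
    """Hazard h(x) at (non-negative) age x."""
    x = np.asarray(age, dtype=float)
    if np.any(x < 0):
        raise ValueError("age must be non-negative")
    return params.a0 * np.exp(-params.a1 * x) + params.c + params.b0 * np.exp(params.b1 * x)


def siler_cumulative_hazard(params: SilerParams, age) -> np.ndarray:
    """Closed-form H(x) = integral of the hazard from 0 to x."""
    x = np.asarray(age, dtype=float)
    a0, a1, c, b0, b1 = params.as_array()
    # -expm1 keeps precision for small rates; the a1 -> 0 / b1 -> 0 limits
    # are the linear terms a0*x and b0*x.
    infant = a0 * (-np.expm1(-a1 * x)) / a1 if a1 > 0 else a0 * x
    senescent = b0 * np.expm1(b1 * x) / b1 if b1 > 0 else b0 * x
    return infant + c * x + senescent


def siler_survival(params: SilerParams, entry, exit) -> np.ndarray:
    """Conditional survival S(exit | alive at entry) = exp(H(entry) - H(exit))."""
    entry = np.asarray(entry, dtype=float)
    exit = np.asarray(exit, dtype=float)
    if np.any(exit < entry):
        raise ValueError("exit age before entry age")
    return np.exp(siler_cumulative_hazard(params, entry) - siler_cumulative_hazard(params, exit))


def sample_siler(
    params: SilerParams,
    n: int,
    rng: np.random.Generator,
    entry_age: float | np.ndarray = 0.0,
    log_hr: float | np.ndarray = 0.0,
) -> np.ndarray:
    """Draw death ages from the Siler law, conditional on survival to entry.

    ``log_hr`` applies a proportional-hazards shift exp(log_hr) to the whole
    hazard (used for orphan-class effects).  Inversion: solve
    e^{log_hr} * (H(t) - H(entry)) = E with E ~ Exp(1) by bracketed
    root-finding; the senescent term guarantees a finite solution.
    """
    entry = np.broadcast_to(np.asarray(entry_age, dtype=float), (n,))
    hr = np.exp(np.broadcast_to(np.asarray(log_hr, dtype=float), (n,)))
    targets = rng.exponential(size=n) / hr + siler_cumulative_hazard(params, entry)
    out = np.empty(n)
    for i, tgt in enumerate(targets):
        hi = max(entry[i] + 1.0, 10.0)
        while siler_cumulative_hazard(params, hi) < tgt:
            hi *= 2.0
        out[i] = brentq(
            lambda t: siler_cumulative_hazard(params, t) - tgt, entry[i], hi, xtol=1e-10
        )
    return out


# ---------------------------------------------------------------------------
# Survival records and Cox model
# ---------------------------------------------------------------------------


def build_survival_records(roster: pd.DataFrame, merged: bool = False) -> pd.DataFrame:
    """Left-truncated, right-censored records from a demographic roster.

    Requires columns ``id, sex, death_age, censor_age, loss_age`` where
    ``death_age`` is NaN for individuals alive at last monitoring and
    ``loss_age`` is NaN for non-orphans.  Analysis time starts at age 2
    (orphan status before 2 is not defined): individuals dying or censored
    before age 2 are excluded.  Orphans enter the risk set at their age of
    maternal loss, non-orphans at age 2 (the Bayesian trajectory
    truncation); the Cox model re-expands the pre-loss exposure from age 2
    via :func:`episode_split`.  ``orphan_class`` is the class at maternal
    loss, or ``non_orphan``.
    """
    rows = []
    for rec in roster.itertuples(index=False):
        death = getattr(rec, "death_age", np.nan)
        censor = getattr(rec, "censor_age", np.nan)
        event = int(np.isfinite(death))
        exit_age = death if event else censor
        if not np.isfinite(exit_age):
            raise ValueError(f"{rec.id}: neither death_age nor censor_age present")
        if exit_age <= 2.0:
            continue
        loss = getattr(rec, "loss_age", np.nan)
        if np.isfinite(loss) and loss < exit_age:
            klass = orphan_class_at_loss(loss, merged=merged)
            entry = float(loss)
        else:
            klass, loss, entry = "non_orphan", np.nan, 2.0
        rows.append(
            dict(id=rec.id, sex=rec.sex, entry_age=entry, exit_age=float(exit_age),
                 event=event, orphan_class=klass, loss_age=loss)
        )
    out = pd.DataFrame(rows)
    if len(out) and (out.exit_age <= out.entry_age).any():
        raise ValueError("exit age before entry age")
    return out


def episode_split(records: pd.DataFrame) -> pd.DataFrame:
    """Start/stop episodes encoding orphan class as a time-varying covariate.

    Everybody enters the risk set at age 2 with all class dummies at zero;
    orphans switch into their class dummy at the age of maternal loss.
    """
    classes = [c for c in records.orphan_class.unique() if c != "non_orphan"]
    rows = []
    for rec in records.itertuples(index=False):
        dummies = {f"class_{c}": 0.0 for c in classes}
        if rec.orphan_class == "non_orphan":
            rows.append(dict(id=rec.id, start=2.0, stop=rec.exit_age, event=rec.event,
                             **dummies))
            continue
        if rec.loss_age > 2.0:
            rows.append(dict(id=rec.id, start=2.0, stop=rec.loss_age, event=0,
                             **dummies))
        post = dict(dummies)
        post[f"class_{rec.orphan_class}"] = 1.0
        rows.append(dict(id=rec.id, start=max(rec.loss_age, 2.0), stop=rec.exit_age,
                         event=rec.event, **post))
    return pd.DataFrame(rows)


def fit_cox_ph(records: pd.DataFrame, class_coding: str = "four") -> pd.DataFrame:
    """Cox proportional hazards of death on orphan class (time-varying).

    ``class_coding='four'`` uses infant/juvenile/subadult dummies (reference
    non-orphan); ``'merged'`` pools juveniles and subadults.  Returns a
    table with log-hazard estimates, SEs and two-sided p per class.
    """
    from lifelines import CoxTimeVaryingFitter
    from lifelines.exceptions import ConvergenceWarning

    if class_coding not in ("four", "merged"):
        raise ValueError(f"unknown class coding {class_coding!r}")
    if records.event.sum() == 0:
        raise ValueError("no events in records; Cox model undefined")
    recs = records.copy()
    if class_coding == "merged":
        recs["orphan_class"] = recs.orphan_class.replace(
            {"juvenile": "juv_subadult", "subadult": "juv_subadult"}
        )
    episodes = episode_split(recs)
    covariates = [c for c in episodes.columns if c.startswith("class_")]
    ctv = CoxTimeVaryingFitter(penalizer=0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        ctv.fit(episodes, id_col="id", start_col="start", stop_col="stop",
                event_col="event",
                fit_options=dict(precision=1e-11, r_precision=1e-12, max_steps=200))
    summ = ctv.summary
    out = pd.DataFrame(
        {
            "est": summ["coef"],
            "se": summ["se(coef)"],
            "p": summ["p"],
        }
    )
    out.index = [c.removeprefix("class_") for c in out.index]
    out.index.name = "orphan_class"
    flagged = out.est.abs() > 15
    if flagged.any():
        warnings.warn(
            f"possible monotone likelihood (separation) for classes "
            f"{list(out.index[flagged])}", stacklevel=2,
        )
    order = [c.removeprefix("class_") for c in covariates]
    return out.loc[[c for c in order if c in out.index]]


# ---------------------------------------------------------------------------
# Bayesian Siler trajectory analysis
# ---------------------------------------------------------------------------

_PRIOR_SCALES = np.array([1.0, 2.0, 1.0, 1.0, 2.0])  # a0, a1, c, b0, b1
_PARAM_NAMES = ("a0", "a1", "c", "b0", "b1")


@dataclass
class SilerFit:
    """Posterior sample of a Siler survival model plus DIC bookkeeping."""

    variant: str
    param_names: tuple
    samples: np.ndarray          # (n_draws, n_params), post burn-in
    log_likelihoods: np.ndarray  # log-likelihood per retained draw
    dic: float
    p_d: float
    mean_deviance: float
    rhat: np.ndarray
    n_records: int
    converged: bool

    def posterior_mean(self) -> np.ndarray:
        return self.samples.mean(axis=0)

    def credible_interval(self, level: float = 0.95) -> pd.DataFrame:
        lo, hi = np.quantile(self.samples, [(1 - level) / 2, 1 - (1 - level) / 2], axis=0)
        return pd.DataFrame({"lower": lo, "mean": self.samples.mean(axis=0), "upper": hi},
                            index=list(self.param_names))


def _class_matrix(records: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    order = dict.fromkeys((*ORPHAN_CLASSES_MERGED, *ORPHAN_CLASSES, "orphan"))
    present = set(records.orphan_class) - {"non_orphan"}
    classes = [c for c in order if c in present] + sorted(
        c for c in present if c not in order
    )
    Z = np.column_stack([(records.orphan_class == c).to_numpy(float) for c in classes]) \
        if classes else np.zeros((len(records), 0))
    return Z, classes


def siler_loglik(theta: np.ndarray, variant: str, entry: np.ndarray, exit: np.ndarray,
                 event: np.ndarray, Z: np.ndarray) -> float:
    """Log-likelihood of left-truncated, right-censored ages under a variant.

    L = prod h(exit)^event * S(exit | entry), with class effects entering as
    a proportional log-hazard shift (variant ``prop_hazards``) or as
    log-scale shifts of all five Siler parameters (variant ``all_params``).
    """
    k = Z.shape[1]
    base = SilerParams(*theta[:5])
    if variant == "null":
        haz = siler_hazard(base, exit)
        cum = siler_cumulative_hazard(base, exit) - siler_cumulative_hazard(base, entry)
    elif variant == "prop_hazards":
        shift = Z @ theta[5:5 + k]
        haz = siler_hazard(base, exit) * np.exp(shift)
        cum = (siler_cumulative_hazard(base, exit)
               - siler_cumulative_hazard(base, entry)) * np.exp(shift)
    elif variant == "all_params":
        haz = siler_hazard(base, exit).copy()
        cum = siler_cumulative_hazard(base, exit) - siler_cumulative_hazard(base, entry)
        for j in range(k):
            mask = Z[:, j] > 0
            if not mask.any():
                continue
            eff = theta[5 + 5 * j: 10 + 5 * j]
            pj = SilerParams(*(theta[:5] * np.exp(eff)))
            haz[mask] = siler_hazard(pj, exit[mask])
            cum[mask] = (siler_cumulative_hazard(pj, exit[mask])
                         - siler_cumulative_hazard(pj, entry[mask]))
    else:
        raise ValueError(f"unknown variant {variant!r}")
    with np.errstate(divide="ignore"):
        return float(np.sum(event * np.log(haz)) - np.sum(cum))


def _log_posterior(phi, variant, entry, exit, event, Z):
    """Log posterior in the sampling parameterization.

    The five baseline Siler parameters are sampled on the log scale
    (``theta[:5] = exp(phi[:5])``), which removes the positivity boundary
    and makes the posterior far closer to Gaussian; the half-normal prior
    on the natural scale picks up the Jacobian term ``+phi``.  Covariate
    effects are sampled directly with N(0, 1) priors.
    """
    phi = np.asarray(phi, dtype=float)
    if np.any(phi[:5] < -14) or np.any(phi[:5] > 4):
        return -np.inf
    base = np.exp(phi[:5])
    lp = float(np.sum(-0.5 * (base / _PRIOR_SCALES) ** 2 + phi[:5]))
    effects = phi[5:]
    lp += -0.5 * np.sum(effects ** 2)                    # N(0,1) on covariate effects
    theta = np.concatenate([base, effects])
    try:
        ll = siler_loglik(theta, variant, entry, exit, event, Z)
    except (ValueError, FloatingPointError):
        return -np.inf
    if not np.isfinite(ll):
        return -np.inf
    return lp + ll


def _split_rhat(chains: np.ndarray) -> np.ndarray:
    """Gelman-Rubin split-R-hat; ``chains`` is (n_chains, n_draws, n_params)."""
    m, n, p = chains.shape
    half = n // 2
    split = np.concatenate([chains[:, :half], chains[:, half:2 * half]], axis=0)
    means = split.mean(axis=1)
    w = split.var(axis=1, ddof=1).mean(axis=0)
    b = half * means.var(axis=0, ddof=1)
    var_plus = (half - 1) / half * w + b / half
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.sqrt(var_plus / w)


def fit_siler_bayes(
    records: pd.DataFrame,
    variant: str = "null",
    n_walkers: int = 24,
    n_steps: int = 1500,
    burn_frac: float = 0.5,
    thin: int = 2,
    seed: int = 0,
) -> SilerFit:
    """Sample the posterior of a Siler survival model and compute its DIC.

    ``variant`` is one of ``null`` (no covariates), ``prop_hazards``
    (one log-hazard-ratio per orphan class) or ``all_params`` (per-class
    log-scale effects on all five Siler parameters).  Priors: half-normal
    (scale 1) on a0, c, b0; half-normal (scale 2) on a1, b1; N(0, 1) on
    covariate effects.  DIC = mean posterior deviance + pD with
    pD = mean deviance - deviance at the posterior mean (Spiegelhalter).
    A split-R-hat > 1.1 on any parameter flags non-convergence.
    """
    import emcee

    entry = records.entry_age.to_numpy(float)
    exit = records.exit_age.to_numpy(float)
    event = records.event.to_numpy(float)
    Z, classes = _class_matrix(records)
    if variant == "null":
        Z = np.zeros((len(records), 0))
        classes = []
    names = list(_PARAM_NAMES)
    if variant == "prop_hazards":
        names += [f"log_hr[{c}]" for c in classes]
    elif variant == "all_params":
        names += [f"log_{p}[{c}]" for c in classes for p in _PARAM_NAMES]
    ndim = len(names)

    n_walkers = max(n_walkers, 2 * ndim + 2)
    rng = np.random.default_rng(seed)
    # start the ensemble around the posterior mode: crude constant-hazard
    # guess refined by bounded optimization of the log posterior
    from scipy.optimize import minimize

    c0 = max(event.sum() / np.sum(exit - entry), 1e-3)
    center = np.concatenate([np.log([0.2, 1.0, c0, 0.01, 0.1]), np.zeros(ndim - 5)])
    bounds = [(-13.0, 3.5)] * 5 + [(-8.0, 8.0)] * (ndim - 5)
    opt = minimize(
        lambda t: -_log_posterior(t, variant, entry, exit, event, Z),
        center, method="L-BFGS-B", bounds=bounds,
    )
    if np.isfinite(opt.fun):
        center = opt.x
    p0 = center + rng.normal(scale=0.05, size=(n_walkers, ndim))

    sampler = emcee.EnsembleSampler(
        n_walkers, ndim, _log_posterior, args=(variant, entry, exit, event, Z),
        moves=[(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)],
    )
    sampler.random_state = np.random.RandomState(seed).get_state()
    sampler.run_mcmc(p0, n_steps, progress=False)

    burn = int(burn_frac * n_steps)
    chain = sampler.get_chain(discard=burn, thin=thin)          # (draws, walkers, dim)
    chain = chain.copy()
    chain[..., :5] = np.exp(chain[..., :5])                      # back to natural scale
    samples = chain.reshape(-1, ndim)
    rhat = _split_rhat(np.moveaxis(chain, 0, 1))
    converged = bool(np.all(rhat < 1.1))
    if not converged:
        warnings.warn(
            f"Siler MCMC ({variant}): split-R-hat up to {np.nanmax(rhat):.3f} > 1.1; "
            "DIC may be unreliable", stacklevel=2,
        )

    lls = np.array([siler_loglik(t, variant, entry, exit, event, Z) for t in samples])
    mean_dev = float(np.mean(-2.0 * lls))
    dev_at_mean = -2.0 * siler_loglik(samples.mean(axis=0), variant, entry, exit, event, Z)
    p_d = mean_dev - dev_at_mean
    dic = mean_dev + p_d
    return SilerFit(
        variant=variant, param_names=tuple(names), samples=samples,
        log_likelihoods=lls, dic=float(dic), p_d=float(p_d),
        mean_deviance=mean_dev, rhat=rhat, n_records=len(records),
        converged=converged,
    )


def compare_dic(fits: Mapping[str, SilerFit] | Sequence[SilerFit]) -> pd.DataFrame:
    """DIC comparison table: DIC, pD and delta-DIC versus the best model.

    Deltas are differences of unrounded DICs.  Requires at least two fits on
    the same records.
    """
    if not isinstance(fits, Mapping):
        fits = {f.variant: f for f in fits}
    if len(fits) < 2:
        raise ValueError("DIC comparison needs at least two fitted models")
    sizes = {f.n_records for f in fits.values()}
    if len(sizes) > 1:
        raise ValueError("fits were made on different record sets")
    table = pd.DataFrame(
        {
            "dic": {k: f.dic for k, f in fits.items()},
            "p_d": {k: f.p_d for k, f in fits.items()},
        }
    )
    table["delta_dic"] = table.dic - table.dic.min()
    table.index.name = "model"
    return table.sort_values("dic")
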