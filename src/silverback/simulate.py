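"""Synthetic demography, focal-scan streams and maternal-loss incidents.

The generator emulates the sampling design of long-term mountain-gorilla
monitoring: stable social groups followed daily, with behaviour recorded as
instantaneous focal scans (one focal at a time, cycling through a randomly
ordered group list) that note every group member within 2 m of the focal
and every member in affiliative physical contact.

Association is modelled as a latent per-scan Bernoulli probability per dyad
(independent across scans, so the Simple Ratio Index is an unbiased
estimate of the latent probability).  A maternal-loss incident removes the
mother from the post-loss period and additively boosts the latent
association probabilities of orphan dyads according to an
:class:`~silverback.config.OrphanEffectConfig`; lifespans follow a Siler
law with optional proportional-hazard effects of orphan class; dispersal is
Bernoulli on a per-class logit scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import (
    DAYS_PER_YEAR,
    OrphanEffectConfig,
    age_sex_class,
    orphan_class_at_loss,
    substream,
    years_between,
)
from .survival import SilerParams, sample_siler

logger = logging.getLogger(__name__)

__all__ = [
    "PopulationConfig",
    "LatentAssociation",
    "LatentAssociations",
    "SimulatedStudy",
    "simulate_population",
    "simulate_latent_associations",
    "apply_maternal_loss",
    "simulate_focal_scans",
    "simulate_dispersal",
    "simulate_lifespans",
    "simulate_incident_dataset",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


def _default_dispersal_logit() -> dict:
    # Log-odds matching the observed female class-level dispersal rates
    # (37.5% non-orphans, 54.5% infant orphans, 75% juvenile/subadult orphans).
    return {"intercept": -0.511, "infant": 0.693, "juv_subadult": 1.609}


@dataclass
class PopulationConfig:
    """Study conditions for the synthetic population.

    Defaults reproduce the scale of the mountain-gorilla study population:
    19 maternal-loss incidents in groups of 12-18 members, roughly 1-2
    orphans and ~6 non-orphan immatures (2-8 years old) per incident, and a
    focal-scan effort of ~145 scans per individual per 6-month window.
    """

    n_groups: int = 19
    group_size_range: tuple[int, int] = (12, 18)
    sex_ratio: float = 0.5
    siler_params: SilerParams = field(default_factory=SilerParams)
    orphan_effects: OrphanEffectConfig = field(default_factory=OrphanEffectConfig.study_defaults)
    #: proportional-hazard shift (log scale) of mortality per orphan class
    orphan_log_hr: Mapping[str, float] = field(default_factory=dict)
    dispersal_logit: Mapping[str, float] = field(default_factory=_default_dispersal_logit)
    window_days: int = 183
    scans_per_day: int = 12
    followup_years: float = 8.0
    start_date: str = "2008-01-01"
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.group_size_range
        if lo < 3:
            raise ValueError("group sizes below 3 cannot hold an orphan and a "
                             "non-orphan immature alongside an adult")
        if hi < lo:
            raise ValueError("group_size_range must be (low, high) with high >= low")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must be a probability")
        for v in self.dispersal_logit.values():
            if not np.isfinite(v) and abs(v) != np.inf:
                raise ValueError("dispersal log-odds must be real")


# ---------------------------------------------------------------------------
# Latent dyadic associations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LatentAssociation:
    """Latent per-scan association probabilities of one unordered dyad."""

    dyad: tuple[str, str]
    p_proximity: float
    p_contact: float

    def __post_init__(self):
        if not 0.0 <= self.p_contact <= self.p_proximity <= 1.0:
            raise ValueError(
                f"dyad {self.dyad}: need 0 <= p_contact <= p_proximity <= 1, "
                f"got contact={self.p_contact}, proximity={self.p_proximity}"
            )


class LatentAssociations:
    """Latent association probabilities for every dyad of one group.

    Backed by symmetric matrices (zero diagonal) with the invariant
    ``0 <= p_contact <= p_proximity <= 1`` enforced elementwise.
    """

    def __init__(self, ids: Sequence[str], p_proximity: np.ndarray, p_contact: np.ndarray):
        ids = list(ids)
        p_prox = np.asarray(p_proximity, dtype=float)
        p_cont = np.asarray(p_contact, dtype=float)
        if p_prox.shape != (len(ids), len(ids)) or p_cont.shape != p_prox.shape:
            raise ValueError("probability matrices must be square over ids")
        for m in (p_prox, p_cont):
            if not np.allclose(m, m.T):
                raise ValueError("latent association matrices must be symmetric")
        if np.any(p_cont > p_prox + 1e-12) or np.any(p_prox > 1) or np.any(p_cont < 0):
            raise ValueError("need 0 <= p_contact <= p_proximity <= 1 for every dyad")
        np.fill_diagonal(p_prox, 0.0)
        np.fill_diagonal(p_cont, 0.0)
        self.ids = ids
        self._index = {i: k for k, i in enumerate(ids)}
        self.p_proximity = p_prox
        self.p_contact = np.minimum(p_cont, p_prox)

    def get(self, a: str, b: str) -> LatentAssociation:
        i, j = self._index[a], self._index[b]
        return LatentAssociation(tuple(sorted((a, b))),
                                 float(self.p_proximity[i, j]),
                                 float(self.p_contact[i, j]))

    def set(self, a: str, b: str, p_proximity: float, p_contact: float) -> None:
        LatentAssociation((a, b), p_proximity, p_contact)  # validate
        i, j = self._index[a], self._index[b]
        self.p_proximity[i, j] = self.p_proximity[j, i] = p_proximity
        self.p_contact[i, j] = self.p_contact[j, i] = p_contact

    def drop(self, member: str) -> "LatentAssociations":
        if member not in self._index:
            raise KeyError(f"{member} not in latent association set")
        keep = [k for k, i in enumerate(self.ids) if i != member]
        return LatentAssociations(
            [self.ids[k] for k in keep],
            self.p_proximity[np.ix_(keep, keep)].copy(),
            self.p_contact[np.ix_(keep, keep)].copy(),
        )

    def copy(self) -> "LatentAssociations":
        return LatentAssociations(list(self.ids), self.p_proximity.copy(),
                                  self.p_contact.copy())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i in range(len(self.ids)):
            for j in range(i + 1, len(self.ids)):
                rows.append(dict(id_a=self.ids[i], id_b=self.ids[j],
                                 p_proximity=self.p_proximity[i, j],
                                 p_contact=self.p_contact[i, j]))
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Population and incidents
# ---------------------------------------------------------------------------


def _sample_group(cfg: PopulationConfig, gi: int, rng: np.random.Generator):
    """One group with a designated maternal-loss incident."""
    group = f"G{gi:02d}"
    size = int(rng.integers(cfg.group_size_range[0], cfg.group_size_range[1] + 1))
    incident_date = (pd.Timestamp(cfg.start_date)
                     + pd.Timedelta(days=int(rng.integers(0, int(4 * DAYS_PER_YEAR)))))

    n_sub = int(rng.binomial(2, 0.3))
    n_bb = int(rng.binomial(2, 0.4))
    n_af = max(2, int(round(0.30 * size)))
    n_imm = size - 1 - n_sub - n_bb - n_af
    while n_imm < 3 and n_af > 2:
        n_af -= 1
        n_imm += 1
    n_imm = max(n_imm, 3)

    members: list[dict] = []

    def add(prefix, k, sex, age, mother=None, father=None, dominant=False):
        members.append(dict(
            id=f"{group}-{prefix}{k:02d}", group=group, sex=sex,
            age_at_incident=float(age), mother_id=mother or "unknown",
            father_id=father, dominant=bool(dominant),
        ))
        return members[-1]["id"]

    dom_id = add("DM", 0, "M", rng.uniform(15, 30), dominant=True)
    # the incident mother (AF00) is an established female with prior
    # offspring, so orphans can have adult maternal siblings in the group
    af_ages = [rng.uniform(20, 28)] + [rng.uniform(9, 28) for _ in range(n_af - 1)]

    def natal_mother(child_age):
        # philopatric males sometimes co-reside with their (older) mother
        candidates = [k for k, a in enumerate(af_ages) if a > child_age + 8]
        if not candidates or rng.random() >= 0.4:
            return None
        if 0 in candidates and rng.random() < 0.5:
            return f"{group}-AF00"
        return f"{group}-AF{int(rng.choice(candidates)):02d}"

    def add_male(prefix, k, age):
        return add(prefix, k, "M", age, mother=natal_mother(age))

    sub_ids = [add_male("SM", k, rng.uniform(12, 25)) for k in range(n_sub)]
    for k in range(n_bb):
        add_male("BB", k, rng.uniform(8, 12))
    af_ids = [add("AF", k, "F", age) for k, age in enumerate(af_ages)]

    adult_males = [dom_id] + sub_ids

    def pick_father():
        if rng.random() >= 0.6:        # paternity unknown for ~40%
            return None
        if rng.random() < 0.7 or not sub_ids:
            return dom_id
        return str(rng.choice(sub_ids))

    # the incident mother and her 2-8 year-old offspring (the orphans)
    mother_id = af_ids[0]
    n_orphans = 1 + int(rng.random() < 0.45)
    orphan_ids = []
    for k in range(n_orphans):
        sex = "M" if rng.random() < cfg.sex_ratio else "F"
        orphan_ids.append(add("IM", k, sex, rng.uniform(2.1, 7.9),
                              mother=mother_id, father=pick_father()))

    # remaining immatures, mothered by the other adult females; the first is
    # guaranteed to be a 2-8 year-old so every incident has a non-orphan peer
    other_mothers = af_ids[1:] or [af_ids[0]]
    for k in range(n_orphans, n_imm):
        sex = "M" if rng.random() < cfg.sex_ratio else "F"
        age = rng.uniform(2.1, 7.9) if k == n_orphans else rng.uniform(0.5, 7.9)
        add("IM", k, sex, age, mother=str(rng.choice(other_mothers)),
            father=pick_father())

    return group, incident_date, mother_id, orphan_ids, members


def simulate_population(config: PopulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a demographic roster and its maternal-loss incident list.

    Each group holds one incident: the designated mother dies (or, with
    ``transfer`` semantics, permanently leaves — the network consequences
    are identical) on the incident date, orphaning her offspring aged 2-8.
    Death ages are Siler draws conditional on survival past the post-loss
    observation window, with optional per-class proportional-hazard shifts
    for orphans; individuals alive at the study end (incident +
    ``followup_years``) are censored there.  Dominant males carry dominance
    tenure intervals (decimal ages) for the dominance-attainment summary.
    """
    rosters, incidents = [], []
    window_years = config.window_days / DAYS_PER_YEAR
    for gi in range(config.n_groups):
        rng = substream(config.seed, "population", gi)
        group, date, mother_id, orphan_ids, members = _sample_group(config, gi, rng)
        incidents.append(dict(incident=f"INC{gi:02d}", group=group, date=date,
                              mother_id=mother_id, orphan_ids=tuple(orphan_ids)))
        for m in members:
            age = m["age_at_incident"]
            m["birth_date"] = (date - pd.Timedelta(days=age * DAYS_PER_YEAR)).normalize()
            m["birth_date_uncertain"] = bool(rng.random() < 0.1)
            is_orphan = m["id"] in orphan_ids
            m["loss_age"] = age if is_orphan else np.nan
            m["orphan_class"] = orphan_class_at_loss(age) if is_orphan else "non_orphan"
            if m["id"] == mother_id:
                m["death_age"] = age
                m["censor_age"] = np.nan
            else:
                log_hr = (config.orphan_log_hr.get(m["orphan_class"], 0.0)
                          if is_orphan else 0.0)
                death = sample_siler(config.siler_params, 1, rng,
                                     entry_age=age + window_years + 0.1,
                                     log_hr=log_hr)[0]
                censor = age + config.followup_years
                if death <= censor:
                    m["death_age"], m["censor_age"] = death, np.nan
                else:
                    m["death_age"], m["censor_age"] = np.nan, censor
            if m["dominant"]:
                start = min(float(rng.uniform(15, min(20, age))), age)
                end = m["death_age"] if np.isfinite(m["death_age"]) else m["censor_age"]
                m["dominance_tenures"] = ((start, float(end)),)
            else:
                m["dominance_tenures"] = ()
        rosters.extend(members)
    roster = pd.DataFrame(rosters)
    incidents = pd.DataFrame(incidents)
    return roster, incidents


# ---------------------------------------------------------------------------
# Latent association structure
# ---------------------------------------------------------------------------

# Baseline mean per-scan proximity probabilities by dyad type.  The
# mother-offspring rates match the observed time budgets (39% of scans in
# proximity, 13% in affiliative contact with the mother).
_MOTHER_PROX, _MOTHER_CONTACT_FRAC = 0.39, 1.0 / 3.0
_CONTACT_FRAC = 0.25


def _base_proximity(class_a: str, class_b: str) -> float:
    imm = {"infant", "juvenile", "subadult_male", "subadult_female"}
    a_imm, b_imm = class_a in imm, class_b in imm
    if a_imm and b_imm:
        return 0.10
    if a_imm or b_imm:
        other = class_b if a_imm else class_a
        if other == "dominant_male":
            return 0.08
        if other == "adult_female":
            return 0.05
        return 0.04
    if "dominant_male" in (class_a, class_b) and "adult_female" in (class_a, class_b):
        return 0.07
    return 0.03


def simulate_latent_associations(
    roster: pd.DataFrame, group: str, date, seed: int, concentration: float = 40.0
) -> LatentAssociations:
    """Latent dyadic probabilities for one group at a reference date.

    Dyad-level heterogeneity: each proximity probability is a Beta draw
    around a class-pair mean (concentration ~40); contact is a fixed
    fraction of proximity (one third for mother-offspring dyads, one
    quarter otherwise), so contact implies proximity by construction.
    """
    sub = roster[roster.group == group]
    ids = list(sub.id)
    ages = {r.id: years_between(r.birth_date, date) for r in sub.itertuples()}
    classes = {r.id: age_sex_class(ages[r.id], r.sex, r.dominant) for r in sub.itertuples()}
    mothers = dict(zip(sub.id, sub.mother_id))
    rng = substream(seed, "latent", group)
    g = len(ids)
    p_prox = np.zeros((g, g))
    for i in range(g):
        for j in range(i + 1, g):
            a, b = ids[i], ids[j]
            if mothers.get(a) == b or mothers.get(b) == a:
                mean = _MOTHER_PROX
            else:
                mean = _base_proximity(classes[a], classes[b])
                if (classes[a] in ("infant", "juvenile", "subadult_male", "subadult_female")
                        and classes[b] in ("infant", "juvenile", "subadult_male",
                                           "subadult_female")
                        and abs(ages[a] - ages[b]) < 2.0):
                    mean += 0.03
            draw = rng.beta(mean * concentration, (1 - mean) * concentration)
            p_prox[i, j] = p_prox[j, i] = draw
    p_cont = p_prox * _CONTACT_FRAC
    for i in range(g):
        for j in range(i + 1, g):
            a, b = ids[i], ids[j]
            if mothers.get(a) == b or mothers.get(b) == a:
                p_cont[i, j] = p_cont[j, i] = p_prox[i, j] * _MOTHER_CONTACT_FRAC
    return LatentAssociations(ids, p_prox, p_cont)


def apply_maternal_loss(
    latent: LatentAssociations,
    incident: Mapping,
    roster: pd.DataFrame,
    effects: OrphanEffectConfig,
) -> LatentAssociations:
    """Post-loss latent associations: mother removed, orphan dyads boosted.

    For each orphan-partner dyad the proximity probability gains
    ``boost_by_class[partner class] + age_mate_boost (if |age diff| < 2) +
    sibling_boost_by_class[partner class] (if maternal sibling)``; the
    contact probability gains the same total scaled by ``contact_scale``.
    Boosts accumulate over both perspectives of an orphan-orphan dyad.
    Probabilities are clipped to [0, 1] (with a log message) and contact is
    kept at or below proximity.  Non-orphan dyads are untouched.
    """
    mother = incident["mother_id"]
    if mother not in latent._index:
        raise ValueError(f"mother {mother} absent from the pre-loss latent set")
    post = latent.drop(mother)
    orphans = list(incident["orphan_ids"])
    missing = [o for o in orphans if o not in post._index]
    if missing:
        raise KeyError(f"unknown orphan ids {missing}")
    date = incident["date"]
    sub = roster.set_index("id")
    ages = {i: years_between(sub.loc[i, "birth_date"], date) for i in post.ids}
    classes = {i: age_sex_class(ages[i], sub.loc[i, "sex"], sub.loc[i, "dominant"])
               for i in post.ids}
    mothers_of = {i: sub.loc[i, "mother_id"] for i in post.ids}

    boost = np.zeros_like(post.p_proximity)
    idx = post._index
    for o in orphans:
        for j in post.ids:
            if j == o:
                continue
            b = effects.boost_by_class.get(classes[j], 0.0)
            if abs(ages[o] - ages[j]) < 2.0:
                b += effects.age_mate_boost
            if (mothers_of[o] != "unknown" and mothers_of[o] == mothers_of[j]):
                b += effects.sibling_boost_by_class.get(classes[j], 0.0)
            boost[idx[o], idx[j]] += b
            boost[idx[j], idx[o]] += b
    boost = (boost + boost.T) / 2.0  # already symmetric; guard rounding

    new_prox = post.p_proximity + boost
    if np.any(new_prox > 1.0):
        logger.warning("maternal-loss boost pushed %d dyad probabilities above 1; clipped",
                       int(np.sum(np.triu(new_prox > 1.0, 1))))
    new_prox = np.clip(new_prox, 0.0, 1.0)
    new_cont = np.clip(post.p_contact + effects.contact_scale * boost, 0.0, 1.0)
    new_cont = np.minimum(new_cont, new_prox)
    return LatentAssociations(post.ids, new_prox, new_cont)


# ---------------------------------------------------------------------------
# Focal scans
# ---------------------------------------------------------------------------


def simulate_focal_scans(
    latent: LatentAssociations,
    window: tuple,
    scans_per_day: int,
    seed: int,
    group: str = "G00",
) -> pd.DataFrame:
    """Simulate 10-minute focal scans over a date window.

    The focal identity cycles through a freshly shuffled group list on each
    pass (observers systematically work through a randomly ordered list).
    Given focal f, each other member j enters the 2-m proximity set with
    probability ``p_proximity[f, j]`` and, conditionally on proximity, the
    affiliative-contact set with probability ``p_contact / p_proximity``,
    so the contact set is a subset of the proximity set for every scan.

    ``window`` is a (start, end) date pair, end exclusive.  Returns one row
    per scan with ``date, group, focal, proximity_partners,
    contact_partners`` (partner fields are tuples of ids).
    """
    start, end = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    n_days = (end - start).days
    if n_days <= 0:
        raise ValueError("empty scan window")
    if scans_per_day <= 0:
        raise ValueError("scans_per_day must be positive")
    rng = substream(seed, "scans", group, str(start.date()))
    ids = np.array(latent.ids)
    g = len(ids)
    n_scans = n_days * scans_per_day

    order = np.concatenate([rng.permutation(g) for _ in range(n_scans // g + 1)])
    focal_idx = order[:n_scans]

    P = latent.p_proximity
    with np.errstate(invalid="ignore", divide="ignore"):
        cond = np.where(P > 0, latent.p_contact / np.where(P > 0, P, 1.0), 0.0)
    prox = rng.random((n_scans, g)) < P[focal_idx]
    cont = prox & (rng.random((n_scans, g)) < cond[focal_idx])
    prox[np.arange(n_scans), focal_idx] = False
    cont[np.arange(n_scans), focal_idx] = False

    dates = start + pd.to_timedelta(np.arange(n_scans) // scans_per_day, unit="D")
    return pd.DataFrame({
        "date": dates,
        "group": group,
        "focal": ids[focal_idx],
        "proximity_partners": [tuple(ids[row]) for row in prox],
        "contact_partners": [tuple(ids[row]) for row in cont],
    })


# ---------------------------------------------------------------------------
# Dispersal and lifespans
# ---------------------------------------------------------------------------

_LOGIT_CAP = 20.0


def simulate_dispersal(
    roster: pd.DataFrame, logit_params: Mapping[str, float], seed: int
) -> pd.DataFrame:
    """Bernoulli natal-dispersal outcomes on a per-class logit scale.

    Log-odds = intercept + offset for the individual's (merged) orphan
    class; offsets are capped at +/-20 before the logistic transform.
    """
    rng = substream(seed, "dispersal")
    merged = roster.orphan_class.replace({"juvenile": "juv_subadult",
                                          "subadult": "juv_subadult"})
    eta = np.clip(
        logit_params.get("intercept", 0.0)
        + merged.map(lambda c: logit_params.get(c, 0.0)).to_numpy(float),
        -_LOGIT_CAP, _LOGIT_CAP,
    )
    p = 1.0 / (1.0 + np.exp(-eta))
    return pd.DataFrame({
        "id": roster.id,
        "orphan_class": merged,
        "dispersed": (rng.random(len(roster)) < p).astype(int),
    })


def simulate_lifespans(
    n: int,
    params: SilerParams,
    orphan_frac: float = 0.0,
    log_hr: float = 0.0,
    entry_age: float = 2.0,
    loss_age_range: tuple[float, float] = (2.0, 8.0),
    censor_age: float = 50.0,
    seed: int = 0,
    merged_classes: bool = True,
) -> pd.DataFrame:
    """Left-truncated Siler lifespans ready for the survival models.

    Non-orphans enter at ``entry_age``; a fraction ``orphan_frac`` are
    orphans entering at a uniform age of loss in ``loss_age_range`` with a
    proportional-hazard shift ``log_hr`` from that age on.  Deaths beyond
    ``censor_age`` are censored there.
    """
    rng = substream(seed, "lifespans")
    is_orphan = rng.random(n) < orphan_frac
    entry = np.where(is_orphan, rng.uniform(*loss_age_range, size=n), entry_age)
    death = sample_siler(params, n, rng, entry_age=entry,
                         log_hr=np.where(is_orphan, log_hr, 0.0))
    event = death <= censor_age
    exit_age = np.minimum(death, censor_age)
    classes = [
        orphan_class_at_loss(e, merged=merged_classes) if o else "non_orphan"
        for o, e in zip(is_orphan, entry)
    ]
    return pd.DataFrame({
        "id": [f"L{i:05d}" for i in range(n)],
        "sex": "F",
        "entry_age": entry,
        "exit_age": exit_age,
        "event": event.astype(int),
        "orphan_class": classes,
        "loss_age": np.where(is_orphan, entry, np.nan),
    })


# ---------------------------------------------------------------------------
# End-to-end dataset
# ---------------------------------------------------------------------------


@dataclass
class SimulatedStudy:
    """A full synthetic study: roster, incidents, and pre/post focal scans."""

    config: PopulationConfig
    roster: pd.DataFrame
    incidents: pd.DataFrame
    scans: pd.DataFrame

    def scans_for_group(self, group: str) -> pd.DataFrame:
        return self.scans[self.scans.group == group]


def simulate_incident_dataset(config: PopulationConfig) -> SimulatedStudy:
    """Simulate the complete observational design for every incident.

    For each group: latent associations are drawn, scans are generated for
    the 6-month (``window_days``) pre-loss window with the mother present,
    the maternal-loss incident is applied (mother removed, orphan dyads
    boosted per ``config.orphan_effects``), and scans are generated for the
    post-loss window.  The boundary day belongs to the post window.
    """
    roster, incidents = simulate_population(config)
    frames = []
    wd = pd.Timedelta(days=config.window_days)
    for inc in incidents.itertuples(index=False):
        latent_pre = simulate_latent_associations(roster, inc.group, inc.date, config.seed)
        latent_post = apply_maternal_loss(
            latent_pre, inc._asdict(), roster, config.orphan_effects
        )
        frames.append(simulate_focal_scans(
            latent_pre, (inc.date - wd, inc.date), config.scans_per_day,
            config.seed, group=inc.group,
        ))
        frames.append(simulate_focal_scans(
            latent_post, (inc.date, inc.date + wd), config.scans_per_day,
            config.seed, group=inc.group,
        ))
    scans = pd.concat(frames, ignore_index=True)
    return SimulatedStudy(config=config, roster=roster, incidents=incidents, scans=scans)
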