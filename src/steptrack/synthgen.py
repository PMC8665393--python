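"""Synthetic cohort generator.

Generative model, per patient:

* ECOG level drawn from ``ecog_probs``; expected daily steps are
  log-normal around the ECOG group's level (``group_log_mean_steps`` is
  the log of the group's *mean* daily steps; the patient-effect median
  is shifted by -sd^2/2 so the group mean comes out on target).
* Daily counts are negative binomial around the latent daily mean.  The
  day after treatment (study day +1) is scaled by
  ``treatment_day_effect`` with a linear return to baseline over
  ``recovery_days`` days.
* Wear is Bernoulli with probability
  ``wear_prob_start * (1 - wear_decay_per_day) ** days_into_phase``;
  non-worn days are emitted as explicit absent markers.  Worn days are
  additionally "partial" (a 0..100 count) with ``partial_day_prob``.
* Questionnaire items at both visits come from a thresholded latent
  logistic variable whose location shifts by ``symptom_coupling`` times
  the patient's standardized activity level; at the second visit a
  subset of patients receives an additional downward (improvement)
  shift of ``improvement_shift``; the probability of that shift is
  ``improvement_prob_base`` moved on the logit scale by
  ``-improvement_activity_gain * symptom_coupling * z``.  With negative
  coupling, more active patients both carry a lower symptom burden and
  are more likely to improve.

Everything is reproducible from ``seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from importlib import resources
from typing import Optional

import numpy as np
import yaml

from .cohort import Cohort, PatientMeta, StepSeries, ValidationError
from .msas import MsasResponse, default_catalog

_DAYS = tuple(range(-7, 15))
_ITEM_CUTPOINTS = np.array([-0.5, 0.5, 1.5, 2.5])


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of the generator; see the module docstring."""

    n_patients: int = 40
    ecog_probs: dict[int, float] = field(
        default_factory=lambda: {0: 0.63, 1: 0.37}
    )
    group_log_mean_steps: dict[int, float] = field(
        default_factory=lambda: {0: math.log(7000.0), 1: math.log(5400.0)}
    )
    between_patient_sd: float = 0.30
    nb_dispersion: float = 8.0
    treatment_day_effect: float = 1.0
    recovery_days: int = 0
    symptom_coupling: float = 0.0
    symptom_base_loc: float = -0.8
    improvement_prob_base: float = 0.5
    improvement_shift: float = 0.6
    improvement_activity_gain: float = 2.5
    wear_prob_start: float = 1.0
    wear_decay_per_day: float = 0.0
    partial_day_prob: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValidationError("n_patients must be >= 1")
        probs = list(self.ecog_probs.values())
        if not probs or any(p < 0 or p > 1 for p in probs):
            raise ValidationError("ecog_probs must be probabilities in [0, 1]")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ValidationError("ecog_probs must sum to 1")
        for level in self.ecog_probs:
            if not 0 <= level <= 5:
                raise ValidationError(f"ECOG level {level} outside 0..5")
            if level not in self.group_log_mean_steps:
                raise ValidationError(f"no group_log_mean_steps for ECOG {level}")
        if self.between_patient_sd < 0:
            raise ValidationError("between_patient_sd must be >= 0")
        if self.nb_dispersion <= 0:
            raise ValidationError("nb_dispersion must be > 0")
        if self.treatment_day_effect <= 0:
            raise ValidationError("treatment_day_effect must be > 0")
        if self.recovery_days < 0:
            raise ValidationError("recovery_days must be >= 0")
        for name in ("improvement_prob_base", "wear_prob_start", "wear_decay_per_day", "partial_day_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.improvement_prob_base < 1.0:
            raise ValidationError("improvement_prob_base must be in (0, 1)")


def _day_factor(day: int, effect: float, recovery_days: int) -> float:
    """Multiplicative activity factor; day +1 is scaled by ``effect`` with a
    linear return to 1.0 over ``recovery_days`` days."""
    if day < 1:
        return 1.0
    if day == 1:
        progress = 0.0
    elif recovery_days == 0:
        progress = 1.0
    else:
        progress = min(1.0, (day - 1) / recovery_days)
    return effect + (1.0 - effect) * progress


def _wear_prob(day: int, start: float, decay: float) -> float:
    if day < 0:
        idx = day + 7
    elif day == 0:
        idx = 0
    else:
        idx = day - 1
    return start * (1.0 - decay) ** idx


def _draw_items(
    rng: np.random.Generator, loc: np.ndarray, n_items: int
) -> np.ndarray:
    latent = loc[:, None] + rng.logistic(size=(len(loc), n_items))
    return (latent[:, :, None] > _ITEM_CUTPOINTS).sum(axis=2)


def gen_cohort(config: SimConfig) -> Cohort:
    """Generate a full cohort (metadata, wear logs, both questionnaires)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    levels = sorted(config.ecog_probs)
    probs = np.array([config.ecog_probs[v] for v in levels], dtype=float)
    probs = probs / probs.sum()
    ecog = rng.choice(np.array(levels), size=n, p=probs)

    sd = config.between_patient_sd
    group_log = np.array([config.group_log_mean_steps[int(e)] for e in ecog])
    # -sd^2/2 keeps the group mean of exp(log_mu) on target
    log_mu = group_log - sd * sd / 2.0 + rng.normal(0.0, sd, size=n)
    spread = float(np.std(log_mu))
    z = (log_mu - float(np.mean(log_mu))) / spread if spread > 0 else np.zeros(n)

    days = np.array(_DAYS)
    factor = np.array(
        [_day_factor(int(d), config.treatment_day_effect, config.recovery_days) for d in days]
    )
    mu = np.exp(log_mu)[:, None] * factor[None, :]
    k = config.nb_dispersion
    steps = rng.negative_binomial(k, k / (k + mu))

    wearp = np.array(
        [_wear_prob(int(d), config.wear_prob_start, config.wear_decay_per_day) for d in days]
    )
    worn = rng.random((n, len(days))) < wearp[None, :]
    partial = worn & (rng.random((n, len(days))) < config.partial_day_prob)
    partial_steps = rng.integers(0, 101, size=(n, len(days)))

    ages = np.clip(np.round(rng.normal(58.0, 10.0, size=n)), 35, 85).astype(int)
    sexes = rng.choice(np.array(["M", "F"]), size=n, p=[0.63, 0.37])
    chemo = rng.choice(
        np.array(["adjuvant", "neoadjuvant", "metastatic"]),
        size=n,
        p=[8 / 27, 6 / 27, 13 / 27],
    )

    catalog = default_catalog()
    items = catalog.all_items
    loc_pre = config.symptom_base_loc + config.symptom_coupling * z
    base_logit = math.log(config.improvement_prob_base / (1 - config.improvement_prob_base))
    p_improve = 1.0 / (
        1.0
        + np.exp(
            -(base_logit - config.improvement_activity_gain * config.symptom_coupling * z)
        )
    )
    improved = rng.random(n) < p_improve
    loc_post = loc_pre - config.improvement_shift * improved
    pre_items = _draw_items(rng, loc_pre, len(items))
    post_items = _draw_items(rng, loc_post, len(items))

    patients: list[PatientMeta] = []
    series: list[StepSeries] = []
    msas_pre: dict[str, MsasResponse] = {}
    msas_post: dict[str, MsasResponse] = {}
    width = len(str(n))
    for i in range(n):
        pid = f"P{i + 1:0{width}d}"
        patients.append(
            PatientMeta(
                patient_id=pid,
                ecog=int(ecog[i]),
                age=float(ages[i]),
                sex=str(sexes[i]),
                chemo_type=str(chemo[i]),
            )
        )
        records: dict[int, Optional[int]] = {}
        for j, d in enumerate(_DAYS):
            if not worn[i, j]:
                records[d] = None
            elif partial[i, j]:
                records[d] = int(partial_steps[i, j])
            else:
                records[d] = int(steps[i, j])
        series.append(StepSeries(patient_id=pid, records=records))
        msas_pre[pid] = MsasResponse(
            patient_id=pid,
            items={name: int(pre_items[i, t]) for t, name in enumerate(items)},
        )
        msas_post[pid] = MsasResponse(
            patient_id=pid,
            items={name: int(post_items[i, t]) for t, name in enumerate(items)},
        )
    return Cohort(patients=patients, steps=series, msas_pre=msas_pre, msas_post=msas_post)


@lru_cache(maxsize=1)
def _raw_scenarios() -> dict:
    return yaml.safe_load(
        resources.files("steptrack.data").joinpath("scenarios.yaml").read_text()
    )


def reference_scenarios() -> dict[str, SimConfig]:
    """Named presets shipped with the package (reference / null / high-dropout)."""
    out = {}
    for name, params in _raw_scenarios().items():
        params = dict(params)
        params["ecog_probs"] = {int(k): float(v) for k, v in params["ecog_probs"].items()}
        params["group_log_mean_steps"] = {
            int(k): float(v) for k, v in params["group_log_mean_steps"].items()
        }
        out[str(name)] = SimConfig(**params)
    return out


def scenario(name: str, **overrides) -> SimConfig:
    """Look up a preset, optionally overriding fields (e.g. seed=...)."""
    presets = reference_scenarios()
    if name not in presets:
        raise KeyError(f"unknown scenario {name!r}; available: {sorted(presets)}")
    cfg = presets[name]
    return replace(cfg, **overrides) if overrides else cfg
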