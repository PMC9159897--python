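"""Synthetic cohorts of PASAT-like attention-training trajectories.

Emulates the measurement design of the early-rehabilitation trial the
pipeline targets: each patient is measured at baseline, after every third
hour of a 20-hour attention-training block and at completion (nine sessions
by default), scores are bounded counts of correct responses, both arms show
a learning effect over the first three administrations, and a latent
responder subpopulation gains a sustained step from a change-point session
onwards.

The generative model for patient i at session t is

    score_t = baseline_i + drift * min(t - 1, 3)
              + responder_i * delta * noise_sd * 1[t >= changepoint]
              + eps_t,    eps_t ~ N(0, noise_sd^2) i.i.d.

clipped to the valid score range and rounded to integers.  Covariates
(treatment arm, diagnosis, lesion side/distribution, cognitive-reserve
class) are sampled independently at the frequencies observed in the
reference cohort.  This is a deliberately simple additive model: it
reproduces the qualitative trajectory shapes (early learning, sustained
responder improvement, session-to-session fluctuation), not any specific
patient's dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .charts import PatientSeries

__all__ = ["SimConfig", "Cohort", "generate_cohort", "operating_characteristics"]


def _check_prob(name: str, p: float) -> None:
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"{name} must be in [0, 1], got {p}")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohort generator.

    Defaults mirror the reference trial: 59 patients allocated 32/27 to
    APT/ABAT, responder fractions 27/32 and 15/27 per arm, nine sessions,
    78% stroke, 71% high cognitive reserve, and a learning drift confined
    to the first three administrations.  ``effect_size_delta`` is the
    sustained responder step in units of the session-to-session noise SD,
    switched on from ``changepoint_session`` (the fourth administration,
    where group differences emerged in the source data).
    """

    n_patients: int = 59
    apt_probability: float = 32 / 59
    n_sessions: int = 9
    responder_probability_by_arm: Mapping[str, float] = field(
        default_factory=lambda: {"APT": 27 / 32, "ABAT": 15 / 27}
    )
    baseline_mean: float = 30.0
    baseline_sd: float = 8.0
    noise_sd: float = 2.5
    learning_drift: float = 0.5
    learning_sessions: int = 3
    effect_size_delta: float = 4.0
    changepoint_session: int = 4
    stroke_fraction: float = 46 / 59
    high_cr_fraction: float = 42 / 59
    lesion_side_frequencies: Mapping[str, float] = field(
        default_factory=lambda: {"left": 25 / 59, "right": 22 / 59, "bilateral": 12 / 59}
    )
    lesion_distribution_frequencies: Mapping[str, float] = field(
        default_factory=lambda: {"unifocal": 29 / 63, "multifocal": 34 / 63}
    )
    score_min: float = 0.0
    score_max: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError(f"n_patients must be >= 1, got {self.n_patients}")
        if self.n_sessions < 2:
            raise ValueError(f"n_sessions must be >= 2, got {self.n_sessions}")
        _check_prob("apt_probability", self.apt_probability)
        _check_prob("stroke_fraction", self.stroke_fraction)
        _check_prob("high_cr_fraction", self.high_cr_fraction)
        for arm, p in self.responder_probability_by_arm.items():
            _check_prob(f"responder_probability_by_arm[{arm}]", p)
        for freq_name in ("lesion_side_frequencies", "lesion_distribution_frequencies"):
            freqs = getattr(self, freq_name)
            for k, p in freqs.items():
                _check_prob(f"{freq_name}[{k}]", p)
            total = sum(freqs.values())
            if not np.isclose(total, 1.0, atol=1e-9):
                raise ValueError(f"{freq_name} must sum to 1, got {total}")
        if self.noise_sd < 0 or self.baseline_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.score_min >= self.score_max:
            raise ValueError("score_min must be below score_max")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["responder_probability_by_arm"] = dict(self.responder_probability_by_arm)
        d["lesion_side_frequencies"] = dict(self.lesion_side_frequencies)
        d["lesion_distribution_frequencies"] = dict(self.lesion_distribution_frequencies)
        return d


@dataclass(frozen=True)
class Cohort:
    """A simulated cohort: per-patient covariates plus measurement series."""

    covariates: pd.DataFrame
    series: tuple[PatientSeries, ...]
    config: SimConfig

    def series_frame(self) -> pd.DataFrame:
        """Long-format (patient_id, session, score) view of the series."""
        rows = [
            (s.patient_id, sess, score)
            for s in self.series
            for sess, score in zip(s.session_index, s.scores)
        ]
        return pd.DataFrame(rows, columns=["patient_id", "session", "score"])


def _sample_categorical(rng, freqs: Mapping[str, float], n: int) -> np.ndarray:
    labels = list(freqs)
    p = np.array([freqs[k] for k in labels], dtype=float)
    p = p / p.sum()
    return rng.choice(labels, size=n, p=p)


def generate_cohort(config: SimConfig | None = None, seed: int | None = None) -> Cohort:
    """Draw a full synthetic cohort from ``config``.

    ``seed`` overrides ``config.seed``.  Identical config + seed gives an
    identical cohort.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_patients

    arm = np.where(rng.random(n) < config.apt_probability, "APT", "ABAT")
    p_resp = np.array([config.responder_probability_by_arm[a] for a in arm])
    responder = rng.random(n) < p_resp
    diagnosis = np.where(rng.random(n) < config.stroke_fraction, "stroke", "TBI")
    cr_class = np.where(rng.random(n) < config.high_cr_fraction, "high", "low")
    side = _sample_categorical(rng, config.lesion_side_frequencies, n)
    distribution = _sample_categorical(rng, config.lesion_distribution_frequencies, n)

    ids = [f"P{i+1:04d}" for i in range(n)]
    covariates = pd.DataFrame(
        {
            "patient_id": ids,
            "arm": arm,
            "diagnosis": diagnosis,
            "lesion_side": side,
            "lesion_distribution": distribution,
            "cr_class": cr_class,
            "responder": responder.astype(int),
        }
    )

    t = np.arange(1, config.n_sessions + 1)
    learning = config.learning_drift * np.minimum(t - 1, config.learning_sessions)
    step_on = (t >= config.changepoint_session).astype(float)

    baselines = rng.normal(config.baseline_mean, config.baseline_sd, size=n)
    noise = rng.normal(0.0, config.noise_sd, size=(n, config.n_sessions))
    step = (
        responder[:, None]
        * config.effect_size_delta
        * config.noise_sd
        * step_on[None, :]
    )
    raw = baselines[:, None] + learning[None, :] + step + noise
    scores = np.clip(np.rint(raw), config.score_min, config.score_max).astype(int)

    series = tuple(
        PatientSeries(patient_id=pid, scores=tuple(int(v) for v in row))
        for pid, row in zip(ids, scores)
    )
    return Cohort(covariates=covariates, series=series, config=config)


def operating_characteristics(
    deltas: Sequence[float] = (0.0, 1.0, 2.0, 4.0),
    n_sessions_grid: Sequence[int] = (9,),
    n_replicates: int = 200,
    n_patients: int = 50,
    seed: int = 0,
    base_config: SimConfig | None = None,
) -> pd.DataFrame:
    """Monte-Carlo detection power and false-alarm rate of the chart rules.

    For each (delta, n_sessions) grid cell, simulates ``n_replicates``
    cohorts of ``n_patients`` and reports the empirical probability of a
    CHANGE label among responders (``detection_rate``) and among
    non-responders (``false_alarm_rate``), with binomial standard errors.
    The chart sigma is the cohort-pooled baseline estimate, as in the
    analysis pipeline.
    """
    from .cohort import CohortChangeModel

    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    base = base_config or SimConfig()
    rng = np.random.default_rng(seed)
    rows = []
    for n_sessions in n_sessions_grid:
        for delta in deltas:
            cfg = SimConfig(
                **{
                    **base.to_dict(),
                    "n_patients": n_patients,
                    "n_sessions": int(n_sessions),
                    "effect_size_delta": float(delta),
                }
            )
            det_hits = det_n = fa_hits = fa_n = 0
            for _ in range(n_replicates):
                cohort = generate_cohort(cfg, seed=int(rng.integers(2**31 - 1)))
                res = CohortChangeModel.from_cohort(cohort).fit()
                merged = res.outcomes.merge(cohort.covariates, on="patient_id")
                changed = merged["label"].eq("CHANGE")
                resp = merged["responder"].eq(1)
                det_hits += int((changed & resp).sum())
                det_n += int(resp.sum())
                fa_hits += int((changed & ~resp).sum())
                fa_n += int((~resp).sum())
            det = det_hits / det_n if det_n else np.nan
            fa = fa_hits / fa_n if fa_n else np.nan
            rows.append(
                {
                    "delta": float(delta),
                    "n_sessions": int(n_sessions),
                    "detection_rate": det,
                    "detection_se": np.sqrt(det * (1 - det) / det_n) if det_n else np.nan,
                    "false_alarm_rate": fa,
                    "false_alarm_se": np.sqrt(fa * (1 - fa) / fa_n) if fa_n else np.nan,
                    "n_responders": det_n,
                    "n_nonresponders": fa_n,
                }
            )
    return pd.DataFrame(rows)
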