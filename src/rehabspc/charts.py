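"""Individual (I) control charts for repeated cognitive outcome measures.

A patient's repeated test scores (here: PASAT correct-response counts,
measured at baseline, after every third hour of attention training and at
completion) are monitored on a Shewhart individuals chart with a
rehabilitation-specific modification: only the first two observations form
the baseline.  The centreline is their mean and the chart sigma is, by
default, a pooled within-pair standard deviation computed across the whole
cohort's baseline pairs, which stabilises a two-point spread estimate.

Two run rules flag a significant shift:

* rule i  — a single point strictly outside the 3-sigma control limit;
* rule ii — 2 of 3 consecutive points at or beyond the 2-sigma warning
  line on the same side of the centreline.

A patient whose series fires at least one rule on the improvement side
(above the centreline; a higher score is better) is classified CHANGE,
otherwise NO CHANGE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "MIN_RECOMMENDED_SESSIONS",
    "SeriesTooShortError",
    "ShortSeriesWarning",
    "Rule",
    "Side",
    "Direction",
    "PatientSeries",
    "ControlChart",
    "Signal",
    "Outcome",
    "estimate_centreline",
    "pooled_sigma",
    "moving_range_sigma",
    "build_chart",
    "detect_signals",
    "classify_outcome",
    "IndividualsChart",
    "IndividualsChartResults",
]

#: The single-case design the chart supports calls for at least eight
#: repeated measurements; shorter series are analysable but flagged.
MIN_RECOMMENDED_SESSIONS = 8

#: Number of leading observations that define the frozen baseline.
BASELINE_N = 2


class SeriesTooShortError(ValueError):
    """Raised when a series has fewer than two observations."""


class ShortSeriesWarning(UserWarning):
    """Emitted when a series has fewer than eight observations."""


class Rule(str, Enum):
    SINGLE_POINT_3SD = "single-point-3sd"
    TWO_OF_THREE_2SD = "two-of-three-2sd"


class Side(str, Enum):
    ABOVE = "above"
    BELOW = "below"


class Direction(str, Enum):
    #: only above-centreline signals count (improvement on a higher-is-better scale)
    IMPROVEMENT_ONLY = "improvement-only"
    #: report deterioration signals too
    BOTH_SIDES = "both-sides"


@dataclass(frozen=True)
class PatientSeries:
    """Ordered repeated measurements for one patient.

    Parameters
    ----------
    patient_id
        Opaque identifier.
    scores
        Measurement values in session order (finite).
    session_index
        Strictly increasing session numbers; defaults to ``1..n``.
    """

    patient_id: str
    scores: tuple[float, ...]
    session_index: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        scores = tuple(float(s) for s in self.scores)
        object.__setattr__(self, "scores", scores)
        if len(scores) < BASELINE_N:
            raise SeriesTooShortError(
                f"patient {self.patient_id!r}: need >= {BASELINE_N} observations "
                f"to build a chart, got {len(scores)}"
            )
        if not np.all(np.isfinite(scores)):
            raise ValueError(f"patient {self.patient_id!r}: non-finite score")
        sessions = self.session_index or tuple(range(1, len(scores) + 1))
        sessions = tuple(int(s) for s in sessions)
        if len(sessions) != len(scores):
            raise ValueError(
                f"patient {self.patient_id!r}: session_index length "
                f"{len(sessions)} != number of scores {len(scores)}"
            )
        if any(b <= a for a, b in zip(sessions, sessions[1:])):
            raise ValueError(
                f"patient {self.patient_id!r}: session_index must be strictly increasing"
            )
        object.__setattr__(self, "session_index", sessions)
        if len(scores) < MIN_RECOMMENDED_SESSIONS:
            warnings.warn(
                f"patient {self.patient_id!r}: {len(scores)} observations; the "
                f"design calls for at least {MIN_RECOMMENDED_SESSIONS} repeated "
                "measurements",
                ShortSeriesWarning,
                stacklevel=2,
            )

    def __len__(self) -> int:
        return len(self.scores)

    @property
    def baseline(self) -> tuple[float, float]:
        """The first two observations (the frozen baseline pair)."""
        return self.scores[0], self.scores[1]


@dataclass(frozen=True)
class ControlChart:
    """Centreline and control/warning limits for one patient's I-chart."""

    centreline: float
    sigma: float
    baseline_n: int = BASELINE_N
    sigma_strategy: str = "pooled-cohort"

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"sigma must be non-negative, got {self.sigma}")

    @property
    def ucl(self) -> float:
        return self.centreline + 3.0 * self.sigma

    @property
    def lcl(self) -> float:
        return self.centreline - 3.0 * self.sigma

    @property
    def uwl(self) -> float:
        return self.centreline + 2.0 * self.sigma

    @property
    def lwl(self) -> float:
        return self.centreline - 2.0 * self.sigma


@dataclass(frozen=True)
class Signal:
    """A run-rule violation at one evaluated observation.

    ``index`` is the 1-based position in the series (not the session label);
    for rule ii it is the last point of the qualifying 3-window.
    """

    rule: Rule
    index: int
    side: Side


@dataclass(frozen=True)
class Outcome:
    """CHANGE/NO CHANGE label for one patient, with the signals behind it."""

    patient_id: str
    label: str  # "CHANGE" | "NO_CHANGE"
    signals: tuple[Signal, ...] = field(default_factory=tuple)


def estimate_centreline(series: PatientSeries) -> float:
    """Mean of the first two observations (the modified baseline)."""
    x1, x2 = series.baseline
    return (x1 + x2) / 2.0


def pooled_sigma(baseline_pairs: Iterable[tuple[float, float]]) -> float:
    """Pooled within-pair SD across a cohort of baseline pairs.

    Each pair contributes its within-pair sum of squares ``(x1-x2)**2 / 2``
    (the two-point sample variance with 1 df); pooling averages these over
    the ``m`` pairs:

        sigma = sqrt( sum_i (x1_i - x2_i)**2 / 2 / m )

    Raises
    ------
    ValueError
        If no pairs are supplied or any value is non-finite.
    """
    pairs = np.asarray(list(baseline_pairs), dtype=float)
    if pairs.size == 0:
        raise ValueError("pooled_sigma needs at least one baseline pair")
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError(f"expected an iterable of (x1, x2) pairs, got shape {pairs.shape}")
    if not np.all(np.isfinite(pairs)):
        raise ValueError("baseline pairs must be finite")
    diffs = pairs[:, 0] - pairs[:, 1]
    return float(np.sqrt(np.mean(diffs**2 / 2.0)))


#: d2 constant for subgroups of size 2 (mean of the range of two standard normals).
D2_N2 = 1.128


def moving_range_sigma(pair: tuple[float, float]) -> float:
    """Individual moving-range sigma estimate ``|x1 - x2| / 1.128``.

    The per-patient alternative to :func:`pooled_sigma`: the classic
    range-based estimate from a single subgroup of size two.
    """
    x1, x2 = pair
    return abs(float(x1) - float(x2)) / D2_N2


def build_chart(
    series: PatientSeries,
    sigma: float,
    sigma_strategy: str = "pooled-cohort",
) -> ControlChart:
    """I-chart for one patient: centreline from the baseline pair, limits at
    centreline +/- 3*sigma and warning lines at +/- 2*sigma."""
    if sigma < 0:
        raise ValueError(f"sigma must be non-negative, got {sigma}")
    return ControlChart(
        centreline=estimate_centreline(series),
        sigma=float(sigma),
        sigma_strategy=sigma_strategy,
    )


def detect_signals(
    chart: ControlChart,
    series: PatientSeries,
    direction: Direction | str = Direction.IMPROVEMENT_ONLY,
) -> list[Signal]:
    """Scan the post-baseline observations for the two run rules.

    Only positions ``>= 3`` (after the baseline pair) are evaluated; the
    baseline defines the limits and cannot signal against itself.  Gaps in
    the session labels are ignored for windowing: observed order is what
    counts.  Rule i requires a point strictly outside a 3-sigma limit; rule
    ii requires 2 of 3 consecutive evaluated points at or beyond the
    2-sigma warning line on the same side, and is reported at the last
    point of the window.  With ``direction="improvement-only"`` only
    above-centreline signals are returned.
    """
    direction = Direction(direction)
    scores = np.asarray(series.scores, dtype=float)
    eval_idx = np.arange(BASELINE_N, len(scores))  # 0-based positions evaluated

    signals: list[Signal] = []
    for i in eval_idx:
        if scores[i] > chart.ucl:
            signals.append(Signal(Rule.SINGLE_POINT_3SD, int(i) + 1, Side.ABOVE))
        elif scores[i] < chart.lcl:
            signals.append(Signal(Rule.SINGLE_POINT_3SD, int(i) + 1, Side.BELOW))

    # rule ii windows run over consecutive *evaluated* observations only;
    # a qualifying point must also lie strictly off the centreline, which
    # only matters in the degenerate sigma = 0 chart
    for w_end in range(2, len(eval_idx)):
        window = scores[eval_idx[w_end - 2 : w_end + 1]]
        n_above = int(np.sum((window >= chart.uwl) & (window > chart.centreline)))
        n_below = int(np.sum((window <= chart.lwl) & (window < chart.centreline)))
        last = int(eval_idx[w_end]) + 1
        if n_above >= 2:
            signals.append(Signal(Rule.TWO_OF_THREE_2SD, last, Side.ABOVE))
        if n_below >= 2:
            signals.append(Signal(Rule.TWO_OF_THREE_2SD, last, Side.BELOW))

    if direction is Direction.IMPROVEMENT_ONLY:
        signals = [s for s in signals if s.side is Side.ABOVE]
    signals.sort(key=lambda s: (s.index, s.rule.value, s.side.value))
    return signals


def classify_outcome(signals: Sequence[Signal], patient_id: str = "") -> Outcome:
    """CHANGE iff at least one signal exists (improvement-only signal list)."""
    label = "CHANGE" if len(signals) > 0 else "NO_CHANGE"
    return Outcome(patient_id=patient_id, label=label, signals=tuple(signals))


class IndividualsChart:
    """Model object: one patient's I-chart analysis.

    Parameters
    ----------
    scores
        The patient's measurement series, or a :class:`PatientSeries`.
    sigma
        Chart sigma on the score scale.  When ``None``, the per-patient
        moving-range estimate ``|x1 - x2| / 1.128`` is used (fitting a
        whole cohort with a pooled sigma is the job of
        :class:`~rehabspc.cohort.CohortChangeModel`).
    direction
        ``"improvement-only"`` (default) or ``"both-sides"``.

    Examples
    --------
    >>> res = IndividualsChart([50, 50, 51, 63, 52], sigma=4.0).fit()
    >>> res.outcome.label
    'CHANGE'
    """

    def __init__(
        self,
        scores: Sequence[float] | PatientSeries,
        sigma: float | None = None,
        direction: Direction | str = Direction.IMPROVEMENT_ONLY,
        patient_id: str = "patient",
    ) -> None:
        if isinstance(scores, PatientSeries):
            self.series = scores
        else:
            self.series = PatientSeries(patient_id=patient_id, scores=tuple(scores))
        self.sigma = sigma
        self.direction = Direction(direction)

    def fit(self) -> "IndividualsChartResults":
        if self.sigma is None:
            sigma = moving_range_sigma(self.series.baseline)
            strategy = "individual-moving-range"
        else:
            sigma = float(self.sigma)
            strategy = "fixed"
        chart = build_chart(self.series, sigma, sigma_strategy=strategy)
        signals = detect_signals(chart, self.series, self.direction)
        outcome = classify_outcome(signals, patient_id=self.series.patient_id)
        return IndividualsChartResults(self, chart, signals, outcome)


class IndividualsChartResults:
    """Fitted I-chart: limits, detected signals and the CHANGE label."""

    def __init__(
        self,
        model: IndividualsChart,
        chart: ControlChart,
        signals: list[Signal],
        outcome: Outcome,
    ) -> None:
        self.model = model
        self.series = model.series
        self.chart = chart
        self.signals = signals
        self.outcome = outcome

    @property
    def label(self) -> str:
        return self.outcome.label

    def summary(self) -> str:
        c = self.chart
        lines = [
            f"I-chart for patient {self.series.patient_id!r}",
            f"  observations: {len(self.series)}",
            f"  centreline:   {c.centreline:.3f}  (mean of first {c.baseline_n} observations)",
            f"  sigma:        {c.sigma:.3f}  [{c.sigma_strategy}]",
            f"  control lims: [{c.lcl:.3f}, {c.ucl:.3f}]  (+/- 3 sigma)",
            f"  warning lims: [{c.lwl:.3f}, {c.uwl:.3f}]  (+/- 2 sigma)",
            f"  signals:      {len(self.signals)}",
        ]
        for s in self.signals:
            lines.append(f"    {s.rule.value:18s} at observation {s.index} ({s.side.value})")
        lines.append(f"  outcome:      {self.outcome.label}")
        return "\n".join(lines)

    def plot(self, ax=None):
        from .plotting import plot_chart

        return plot_chart(self, ax=ax)
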