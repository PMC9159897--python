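"""Cohort-level change classification and outcome association.

`CohortChangeModel` ties the per-patient control charts together: it pools
the baseline pairs of the whole cohort into one sigma estimate (or uses
per-patient moving ranges), classifies every patient CHANGE / NO CHANGE,
and exposes the downstream association battery on the resulting outcome
table joined to covariates.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import association as assoc
from .charts import (
    Direction,
    IndividualsChart,
    IndividualsChartResults,
    PatientSeries,
    build_chart,
    classify_outcome,
    detect_signals,
    moving_range_sigma,
    pooled_sigma,
)
from .tables import ContingencyTable

__all__ = ["CohortChangeModel", "CohortChangeResults", "classify_cohort"]

SIGMA_STRATEGIES = ("pooled-cohort", "individual-moving-range")


def _series_from_frame(frame: pd.DataFrame) -> list[PatientSeries]:
    required = {"patient_id", "session", "score"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"series table is missing columns: {sorted(missing)}")
    out = []
    for pid, grp in frame.groupby("patient_id", sort=False):
        grp = grp.sort_values("session")
        out.append(
            PatientSeries(
                patient_id=str(pid),
                scores=tuple(float(v) for v in grp["score"]),
                session_index=tuple(int(v) for v in grp["session"]),
            )
        )
    return out


class CohortChangeModel:
    """Classify a cohort of measurement series into CHANGE / NO CHANGE.

    Parameters
    ----------
    series
        One :class:`PatientSeries` per patient (unique ids).
    covariates
        Optional per-patient table with a ``patient_id`` column; joined to
        the outcome table for association analysis.
    sigma_strategy
        ``"pooled-cohort"`` (default): one sigma pooled over every
        patient's baseline pair; ``"individual-moving-range"``: per-patient
        ``|x1-x2|/1.128``.
    direction
        Passed to the signal scan; default improvement-only.
    """

    def __init__(
        self,
        series: Iterable[PatientSeries],
        covariates: pd.DataFrame | None = None,
        sigma_strategy: str = "pooled-cohort",
        direction: Direction | str = Direction.IMPROVEMENT_ONLY,
    ) -> None:
        self.series = list(series)
        if not self.series:
            raise ValueError("cohort is empty")
        from collections import Counter

        ids = Counter(s.patient_id for s in self.series)
        dupes = {i for i, k in ids.items() if k > 1}
        if dupes:
            raise ValueError(f"duplicate patient ids: {sorted(dupes)}")
        if sigma_strategy not in SIGMA_STRATEGIES:
            raise ValueError(
                f"sigma_strategy must be one of {SIGMA_STRATEGIES}, got {sigma_strategy!r}"
            )
        if covariates is not None:
            if "patient_id" not in covariates.columns:
                raise ValueError("covariates table needs a patient_id column")
            covariates = covariates.copy()
            covariates["patient_id"] = covariates["patient_id"].astype(str)
        self.covariates = covariates
        self.sigma_strategy = sigma_strategy
        self.direction = Direction(direction)

    @classmethod
    def from_frames(
        cls,
        series: pd.DataFrame,
        covariates: pd.DataFrame | None = None,
        **kwargs,
    ) -> "CohortChangeModel":
        """Build from a long-format (patient_id, session, score) table."""
        return cls(_series_from_frame(series), covariates=covariates, **kwargs)

    # alias in the statsmodels from_* idiom
    from_dataframe = from_frames

    @classmethod
    def from_cohort(cls, cohort, **kwargs) -> "CohortChangeModel":
        """Build from a simulated :class:`~rehabspc.simulate.Cohort`."""
        return cls(cohort.series, covariates=cohort.covariates, **kwargs)

    def fit(self) -> "CohortChangeResults":
        if self.sigma_strategy == "pooled-cohort":
            sigma = pooled_sigma([s.baseline for s in self.series])
            sigmas = {s.patient_id: sigma for s in self.series}
        else:
            sigma = None
            sigmas = {s.patient_id: moving_range_sigma(s.baseline) for s in self.series}

        per_patient: dict[str, IndividualsChartResults] = {}
        rows = []
        for s in self.series:
            chart = build_chart(s, sigmas[s.patient_id], sigma_strategy=self.sigma_strategy)
            signals = detect_signals(chart, s, self.direction)
            outcome = classify_outcome(signals, patient_id=s.patient_id)
            model = IndividualsChart(s, sigma=sigmas[s.patient_id], direction=self.direction)
            per_patient[s.patient_id] = IndividualsChartResults(model, chart, signals, outcome)
            first = signals[0] if signals else None
            rows.append(
                {
                    "patient_id": s.patient_id,
                    "label": outcome.label,
                    "n_signals": len(signals),
                    "first_signal_session": (
                        s.session_index[first.index - 1] if first else pd.NA
                    ),
                    "rule_of_first_signal": first.rule.value if first else pd.NA,
                }
            )
        outcomes = pd.DataFrame(rows)
        return CohortChangeResults(self, outcomes, per_patient, pooled=sigma)


class CohortChangeResults:
    """Outcome table for a fitted cohort plus association helpers."""

    def __init__(
        self,
        model: CohortChangeModel,
        outcomes: pd.DataFrame,
        per_patient: dict[str, IndividualsChartResults],
        pooled: float | None,
    ) -> None:
        self.model = model
        self.outcomes = outcomes
        self.per_patient = per_patient
        self.pooled_sigma = pooled

    @property
    def n_change(self) -> int:
        return int(self.outcomes["label"].eq("CHANGE").sum())

    @property
    def n_patients(self) -> int:
        return len(self.outcomes)

    def joined(self) -> pd.DataFrame:
        """Outcomes merged with covariates (inner join on patient_id)."""
        if self.model.covariates is None:
            raise ValueError("no covariates table was supplied")
        merged = self.outcomes.merge(self.model.covariates, on="patient_id", how="outer", indicator=True)
        unmatched = merged.loc[merged["_merge"] != "both", "patient_id"]
        if len(unmatched):
            raise ValueError(
                f"unmatched patient ids between outcomes and covariates: "
                f"{sorted(unmatched.astype(str))}"
            )
        return merged.drop(columns="_merge")

    def contingency(
        self,
        covariate: str = "arm",
        row_order: Sequence[str] | None = None,
        subset: pd.Series | None = None,
    ) -> ContingencyTable:
        """Covariate-by-outcome table (columns CHANGE, NO_CHANGE)."""
        data = self.joined()
        if subset is not None:
            data = data.loc[np.asarray(subset, dtype=bool)]
        if covariate not in data.columns:
            raise ValueError(f"unknown covariate {covariate!r}")
        rows = row_order or sorted(data[covariate].astype(str).unique())
        counts = np.array(
            [
                [
                    int(((data[covariate].astype(str) == r) & (data["label"] == lab)).sum())
                    for lab in ("CHANGE", "NO_CHANGE")
                ]
                for r in rows
            ]
        )
        return ContingencyTable(
            counts, tuple(rows), ("CHANGE", "NO_CHANGE"), name=f"{covariate}_outcome"
        )

    def associate(self, covariate: str = "arm", row_order: Sequence[str] | None = None):
        """Chi-square / Fisher / V / OR bundle for covariate vs outcome."""
        table = self.contingency(covariate, row_order=row_order)
        if table.shape == (2, 2):
            return assoc.analyze_2x2(table)
        chi2, df, p = assoc.pearson_chi_square(table)
        v = assoc.cramers_v(chi2, table.n, *table.shape)
        return assoc.AssociationResult(chi2, df, p, v, table.n)

    def summary(self) -> str:
        lines = [
            "Cohort change classification",
            f"  patients:        {self.n_patients}",
            f"  sigma strategy:  {self.model.sigma_strategy}",
        ]
        if self.pooled_sigma is not None:
            lines.append(f"  pooled sigma:    {self.pooled_sigma:.3f}")
        lines += [
            f"  CHANGE:          {self.n_change}",
            f"  NO CHANGE:       {self.n_patients - self.n_change}",
        ]
        if self.model.covariates is not None and "arm" in self.model.covariates.columns:
            t = self.contingency("arm", row_order=("APT", "ABAT"))
            lines.append(f"  arm x outcome:   {t.counts.tolist()} (rows APT, ABAT)")
        return "\n".join(lines)


def classify_cohort(
    series: Iterable[PatientSeries] | pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    sigma_strategy: str = "pooled-cohort",
    direction: Direction | str = Direction.IMPROVEMENT_ONLY,
) -> pd.DataFrame:
    """One-call wrapper: outcome table (joined to covariates if given)."""
    if isinstance(series, pd.DataFrame):
        model = CohortChangeModel.from_frames(
            series, covariates, sigma_strategy=sigma_strategy, direction=direction
        )
    else:
        model = CohortChangeModel(
            series, covariates, sigma_strategy=sigma_strategy, direction=direction
        )
    res = model.fit()
    return res.joined() if covariates is not None else res.outcomes
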