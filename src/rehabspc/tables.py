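"""Contingency tables and the packaged reference tables.

The reference tables are transcribed from the published randomized trial of
early attention training after acquired brain injury (APT vs. ABAT, N = 59)
that this pipeline operationalises.  Rows are the exposure (treatment arm,
APT first), columns the outcome (CHANGE first).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ContingencyTable", "DegenerateTableError", "reference_tables"]


class DegenerateTableError(ValueError):
    """A table with a zero row or column margin cannot be tested."""


@dataclass(frozen=True)
class ContingencyTable:
    """An r x c table of non-negative integer counts with labelled margins."""

    counts: np.ndarray
    row_labels: tuple[str, ...] = ()
    col_labels: tuple[str, ...] = ()
    name: str = ""
    note: str = ""

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError(f"counts must be 2-D, got shape {counts.shape}")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if not np.allclose(counts, np.round(counts)):
            raise ValueError("counts must be integers")
        counts = counts.astype(np.int64)
        counts.setflags(write=False)
        object.__setattr__(self, "counts", counts)
        r, c = counts.shape
        row_labels = self.row_labels or tuple(f"row{i+1}" for i in range(r))
        col_labels = self.col_labels or tuple(f"col{j+1}" for j in range(c))
        if len(row_labels) != r or len(col_labels) != c:
            raise ValueError("label lengths must match table shape")
        object.__setattr__(self, "row_labels", tuple(row_labels))
        object.__setattr__(self, "col_labels", tuple(col_labels))
        if counts.sum() == 0:
            raise ValueError("table total must be positive")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def require_nondegenerate(self) -> None:
        if np.any(self.counts.sum(axis=1) == 0) or np.any(self.counts.sum(axis=0) == 0):
            raise DegenerateTableError(
                f"table {self.name or self.counts.tolist()} has a zero margin"
            )

    def transpose(self) -> "ContingencyTable":
        return ContingencyTable(
            self.counts.T.copy(), self.col_labels, self.row_labels, self.name, self.note
        )

    def swap_columns(self) -> "ContingencyTable":
        """Reverse column order (for 2x2: invert the outcome reference)."""
        return ContingencyTable(
            self.counts[:, ::-1].copy(),
            self.row_labels,
            self.col_labels[::-1],
            self.name,
            self.note,
        )


_ARMS = ("APT", "ABAT")
_OUTCOMES = ("CHANGE", "NO_CHANGE")


def reference_tables() -> dict[str, ContingencyTable]:
    """Treatment-by-outcome tables transcribed from the source trial.

    Returns
    -------
    dict
        ``treatment_outcome`` — full cohort (N = 59);
        ``stroke_treatment_outcome`` — stroke patients only (N = 46);
        ``highCR_treatment_outcome`` — high-cognitive-reserve patients only
        (N = 42).
    """
    return {
        "treatment_outcome": ContingencyTable(
            np.array([[27, 5], [15, 12]]),
            _ARMS,
            _OUTCOMES,
            name="treatment_outcome",
            note="full cohort, N=59; transcribed subgroup sizes",
        ),
        "stroke_treatment_outcome": ContingencyTable(
            np.array([[22, 4], [9, 11]]),
            _ARMS,
            _OUTCOMES,
            name="stroke_treatment_outcome",
            note="stroke aetiology only, N=46; transcribed counts",
        ),
        "highCR_treatment_outcome": ContingencyTable(
            np.array([[19, 2], [13, 8]]),
            _ARMS,
            _OUTCOMES,
            name="highCR_treatment_outcome",
            note="high cognitive reserve only, N=42; transcribed counts",
        ),
    }
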