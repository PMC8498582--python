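"""Ordered per-case turnaround-time (TAT) series.

The fundamental data structure of the package: one record per
chronologically ordered case, holding the wet-lab (sequencing assay)
TAT, the dry-lab (bioinformatics) TAT and the overall
accession-to-report TAT, all in whole days.  Case numbering is 1-based
throughout the package, matching the way laboratories count cases
("the 82nd case").
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["TATSeries", "ValidationError", "COMPONENTS", "read_tat_csv", "write_tat_csv"]

#: analysable components, in reporting order
COMPONENTS = ("overall", "wet", "dry")

_COLUMNS = ("case_index", "wet_days", "dry_days", "overall_days")

_COMPONENT_COLUMN = {"overall": "overall_days", "wet": "wet_days", "dry": "dry_days"}


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


class TATSeries:
    """Chronologically ordered per-case TAT records.

    Parameters
    ----------
    frame:
        DataFrame with columns ``case_index, wet_days, dry_days,
        overall_days``.  ``case_index`` must be the consecutive integers
        1..n; day counts are non-negative integers.  ``wet_days`` and
        ``dry_days`` may be missing (NA) only when
        ``allow_missing_components`` is set; ``overall_days`` is always
        required and must be >= max(wet, dry) where both are present.
    provenance:
        Free-text origin tag, e.g. ``"real"`` or ``"synthetic seed=7"``.
    allow_missing_components:
        Permit NA wet/dry values (overall-only analyses).
    """

    def __init__(
        self,
        frame: pd.DataFrame,
        provenance: str = "real",
        allow_missing_components: bool = False,
    ) -> None:
        missing = [c for c in _COLUMNS if c not in frame.columns]
        if missing:
            raise ValidationError(f"missing required column(s): {', '.join(missing)}")
        frame = frame.loc[:, list(_COLUMNS)].copy()
        frame = frame.sort_values("case_index", kind="stable").reset_index(drop=True)
        self._validate(frame, allow_missing_components)
        self.frame = frame
        self.provenance = provenance
        self.allow_missing_components = allow_missing_components

    @staticmethod
    def _validate(frame: pd.DataFrame, allow_missing: bool) -> None:
        n = len(frame)
        if n == 0:
            raise ValidationError("series is empty")
        idx = frame["case_index"].to_numpy()
        if not np.issubdtype(np.asarray(idx).dtype, np.number) or np.any(idx != np.round(idx)):
            raise ValidationError("case_index must be integer")
        if not np.array_equal(idx.astype(np.int64), np.arange(1, n + 1)):
            dupes = frame["case_index"][frame["case_index"].duplicated()].tolist()
            if dupes:
                raise ValidationError(f"duplicate case_index value(s): {dupes}")
            raise ValidationError(
                "case_index must be the consecutive integers 1..n "
                f"(got range {idx.min()}..{idx.max()} over {n} rows)"
            )
        for col in ("wet_days", "dry_days", "overall_days"):
            vals = frame[col]
            na = vals.isna()
            if na.any():
                if col == "overall_days" or not allow_missing:
                    row = int(frame.loc[na.idxmax(), "case_index"])
                    raise ValidationError(f"missing {col} at row {row}")
                continue
            arr = vals.to_numpy(dtype=float)
            bad = (arr < 0) | (arr != np.round(arr))
            if bad.any():
                row = int(frame.loc[np.flatnonzero(bad)[0], "case_index"])
                raise ValidationError(
                    f"{col} must be a non-negative whole number of days (row {row})"
                )
        both = frame["wet_days"].notna() & frame["dry_days"].notna()
        if both.any():
            sub = frame.loc[both]
            comp_max = np.maximum(sub["wet_days"].to_numpy(float), sub["dry_days"].to_numpy(float))
            bad = sub["overall_days"].to_numpy(float) < comp_max
            if bad.any():
                row = int(sub.iloc[int(np.flatnonzero(bad)[0])]["case_index"])
                raise ValidationError(
                    f"overall_days < max(wet_days, dry_days) at row {row}"
                )

    # -- accessors ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def case_index(self) -> np.ndarray:
        return self.frame["case_index"].to_numpy(dtype=np.int64)

    def has_component(self, component: str) -> bool:
        col = self._column(component)
        return bool(self.frame[col].notna().all())

    def component(self, component: str) -> np.ndarray:
        """Day counts for ``component`` in {'overall', 'wet', 'dry'}."""
        col = self._column(component)
        vals = self.frame[col]
        if vals.isna().any():
            raise ValidationError(f"component '{component}' has missing values")
        return vals.to_numpy(dtype=np.int64)

    @staticmethod
    def _column(component: str) -> str:
        try:
            return _COMPONENT_COLUMN[component]
        except KeyError:
            raise ValidationError(
                f"unknown component {component!r}; expected one of {COMPONENTS}"
            ) from None

    def with_overall(self, overall: Sequence[int], provenance: str | None = None) -> "TATSeries":
        """Copy of the series with ``overall_days`` replaced."""
        frame = self.frame.copy()
        frame["overall_days"] = np.asarray(overall, dtype=np.int64)
        return TATSeries(
            frame,
            provenance=provenance if provenance is not None else self.provenance,
            allow_missing_components=self.allow_missing_components,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TATSeries):
            return NotImplemented
        return self.frame.equals(other.frame)

    def __repr__(self) -> str:
        return f"TATSeries(n={len(self)}, provenance={self.provenance!r})"

    # -- I/O ---------------------------------------------------------------

    def to_csv(self, path) -> None:
        """Write the standard TAT CSV (UTF-8, header row)."""
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_records(
        cls,
        wet: Iterable[int],
        dry: Iterable[int],
        overall: Iterable[int],
        provenance: str = "real",
    ) -> "TATSeries":
        wet = np.asarray(list(wet))
        frame = pd.DataFrame(
            {
                "case_index": np.arange(1, len(wet) + 1),
                "wet_days": wet,
                "dry_days": np.asarray(list(dry)),
                "overall_days": np.asarray(list(overall)),
            }
        )
        return cls(frame, provenance=provenance)


def read_tat_csv(path, allow_missing_components: bool = False) -> TATSeries:
    """Read a TAT series from the standard CSV layout.

    The file must carry the header
    ``case_index,wet_days,dry_days,overall_days``.  Rows are sorted by
    case number and validated; violations are reported with the
    offending row's case number.
    """
    frame = pd.read_csv(path)
    return TATSeries(frame, provenance=str(path), allow_missing_components=allow_missing_components)


def write_tat_csv(series: TATSeries, path) -> None:
    series.to_csv(path)
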