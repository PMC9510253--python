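"""Patient-by-disease health matrix container.

The matrix ``M`` holds one row per patient and one column per disease or
health indicator; entry ``a[i, j]`` is patient ``i``'s nonnegative
health-monitoring value on indicator ``j``.  Entries may be missing
(unobserved); downstream hashing resolves missing entries with a fixed
policy so that every patient is treated identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

MISSING_POLICIES = ("zero", "column_mean")


@dataclass
class PatientHealthMatrix:
    """An m x n real matrix of per-patient, per-disease health values.

    Parameters
    ----------
    patient_ids
        Ordered, duplicate-free patient identifiers (length m).
    disease_ids
        Ordered, duplicate-free disease identifiers (length n).
    values
        Float array of shape (m, n).  Cells where ``observed_mask`` is
        False are ignored; by convention they hold ``nan``.
    observed_mask
        Boolean array of shape (m, n); True marks an observed cell.
        Defaults to everything observed.
    """

    patient_ids: list[str]
    disease_ids: list[str]
    values: np.ndarray
    observed_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.patient_ids = [str(p) for p in self.patient_ids]
        self.disease_ids = [str(d) for d in self.disease_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        m, n = self.values.shape
        if m < 1 or n < 1:
            raise ValueError("matrix must have at least one patient and one disease")
        if len(self.patient_ids) != m:
            raise ValueError(f"{len(self.patient_ids)} patient ids for {m} rows")
        if len(self.disease_ids) != n:
            raise ValueError(f"{len(self.disease_ids)} disease ids for {n} columns")
        if len(set(self.patient_ids)) != m:
            raise ValueError("duplicate patient ids")
        if len(set(self.disease_ids)) != n:
            raise ValueError("duplicate disease ids")
        if self.observed_mask is None:
            self.observed_mask = ~np.isnan(self.values)
        self.observed_mask = np.asarray(self.observed_mask, dtype=bool)
        if self.observed_mask.shape != (m, n):
            raise ValueError("observed_mask shape does not match values")
        if not np.all(np.isfinite(self.values[self.observed_mask])):
            raise ValueError("observed values must be finite")

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]

    def patient_index(self, patient_id: str) -> int:
        try:
            return self.patient_ids.index(patient_id)
        except ValueError:
            raise KeyError(f"unknown patient id {patient_id!r}") from None

    def disease_index(self, disease_id: str) -> int:
        try:
            return self.disease_ids.index(disease_id)
        except ValueError:
            raise KeyError(f"unknown disease id {disease_id!r}") from None

    def resolved_values(self, missing_policy: str = "zero") -> np.ndarray:
        """Dense copy of ``values`` with missing entries imputed.

        ``"zero"`` substitutes 0 (an unobserved indicator contributes
        nothing to any projection); ``"column_mean"`` substitutes the
        column's observed mean (0 for fully unobserved columns).  The
        same substitution is applied to every patient, so the hash
        remains a function of the stored record alone.
        """
        if missing_policy not in MISSING_POLICIES:
            raise ValueError(
                f"unknown missing policy {missing_policy!r}; expected one of {MISSING_POLICIES}"
            )
        out = np.where(self.observed_mask, self.values, 0.0)
        if missing_policy == "column_mean":
            counts = self.observed_mask.sum(axis=0)
            sums = out.sum(axis=0)
            col_means = np.divide(sums, counts, out=np.zeros_like(sums), where=counts > 0)
            out = np.where(self.observed_mask, self.values, col_means[None, :])
        return out

    def copy(self) -> "PatientHealthMatrix":
        return PatientHealthMatrix(
            list(self.patient_ids),
            list(self.disease_ids),
            self.values.copy(),
            self.observed_mask.copy(),
        )


def from_dense(
    values: np.ndarray,
    patient_ids: Sequence[str] | None = None,
    disease_ids: Sequence[str] | None = None,
) -> PatientHealthMatrix:
    """Wrap a dense array, auto-naming patients ``p1..pm`` and diseases ``d1..dn``."""
    values = np.asarray(values, dtype=float)
    m, n = values.shape
    if patient_ids is None:
        patient_ids = [f"p{i + 1}" for i in range(m)]
    if disease_ids is None:
        disease_ids = [f"d{j + 1}" for j in range(n)]
    return PatientHealthMatrix(list(patient_ids), list(disease_ids), values)
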