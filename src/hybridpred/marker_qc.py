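"""Quality control for parental SNP dosage matrices.

Markers are coded as minor-allele dosages 0/1/2 (inbred parents are expected
to be homozygous, i.e. 0/2, but heterozygous calls are accepted).  The QC
pipeline applies, in order: a per-marker missingness filter, mean imputation
of the remaining missing cells, and a minor-allele-frequency filter computed
from the post-imputation column mean.  Mean imputation leaves the column mean
unchanged, so computing MAF before or after imputation is equivalent; the
post-imputation convention is used because it is the one the code can assert.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class MarkerQCError(ValueError):
    """Raised when a dosage matrix cannot be QC'd or is structurally invalid."""


@dataclass
class MarkerMatrix:
    """A lines x markers dosage table with missing values stored as NaN.

    Parameters
    ----------
    line_ids
        Ordered unique line identifiers (rows).
    marker_ids
        Ordered unique marker identifiers (columns).
    dosages
        Float array of shape ``(len(line_ids), len(marker_ids))`` with values
        in ``[0, 2]`` or NaN for missing.  Fractional values (from mean
        imputation) are allowed.
    """

    line_ids: list[str]
    marker_ids: list[str]
    dosages: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.line_ids = [str(x) for x in self.line_ids]
        self.marker_ids = [str(x) for x in self.marker_ids]
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise MarkerQCError("dosages must be a 2-D matrix")
        if self.dosages.shape != (len(self.line_ids), len(self.marker_ids)):
            raise MarkerQCError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.line_ids)} lines x {len(self.marker_ids)} markers"
            )
        if len(set(self.line_ids)) != len(self.line_ids):
            raise MarkerQCError("duplicate line ids")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise MarkerQCError("duplicate marker ids")
        finite = self.dosages[np.isfinite(self.dosages)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise MarkerQCError("dosage values must lie in [0, 2]")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def p(self) -> int:
        """Number of markers (columns)."""
        return len(self.marker_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosages)

    def subset_markers(self, keep: np.ndarray) -> "MarkerMatrix":
        """Return a new matrix restricted to the boolean column mask ``keep``."""
        keep = np.asarray(keep, dtype=bool)
        ids = [m for m, k in zip(self.marker_ids, keep) if k]
        return MarkerMatrix(list(self.line_ids), ids, self.dosages[:, keep].copy())


@dataclass(frozen=True)
class QCSummary:
    """Per-step accounting of the QC pipeline."""

    n_markers_in: int
    n_dropped_missingness: int
    n_cells_imputed: int
    n_dropped_maf: int
    n_markers_out: int

    def as_dict(self) -> dict[str, int]:
        return {
            "markers_in": self.n_markers_in,
            "dropped_missingness": self.n_dropped_missingness,
            "cells_imputed": self.n_cells_imputed,
            "dropped_maf": self.n_dropped_maf,
            "markers_out": self.n_markers_out,
        }


def column_maf(dosages: np.ndarray) -> np.ndarray:
    """Minor allele frequency per column: ``min(q, 1 - q)`` with ``q = mean/2``.

    NaNs are ignored in the mean; an all-NaN column yields NaN.
    """
    with np.errstate(invalid="ignore"):
        q = np.nanmean(np.asarray(dosages, dtype=float), axis=0) / 2.0
    return np.minimum(q, 1.0 - q)


def qc_pipeline(
    markers: MarkerMatrix,
    max_missing_frac: float = 0.15,
    min_maf: float = 0.05,
    return_summary: bool = False,
) -> MarkerMatrix | tuple[MarkerMatrix, QCSummary]:
    """Clean a dosage matrix: missingness filter, mean imputation, MAF filter.

    Steps, applied strictly in order:

    1. drop markers whose missing fraction is ``>= max_missing_frac``
       (markers with *less than* the threshold are kept);
    2. impute each remaining missing cell with its column's observed mean;
    3. drop markers whose post-imputation MAF is ``< min_maf``.

    The row (line) set is never changed.

    Raises
    ------
    MarkerQCError
        ``"no markers"`` for an empty input matrix; ``"no markers survive QC"``
        when every marker is filtered out; also for invalid thresholds.
    """
    if not 0.0 < max_missing_frac < 1.0:
        raise MarkerQCError("max_missing_frac must be in (0, 1)")
    if not 0.0 <= min_maf < 0.5:
        raise MarkerQCError("min_maf must be in [0, 0.5)")
    if markers.p == 0 or markers.n_lines == 0:
        raise MarkerQCError("no markers")

    n_in = markers.p

    # step 1: missingness filter
    miss_frac = markers.missing_mask.mean(axis=0)
    keep1 = miss_frac < max_missing_frac
    n_drop_miss = int((~keep1).sum())
    kept = markers.subset_markers(keep1)
    if kept.p == 0:
        raise MarkerQCError("no markers survive QC")

    # step 2: mean imputation of surviving columns
    dosages = kept.dosages.copy()
    nan_mask = np.isnan(dosages)
    n_imputed = int(nan_mask.sum())
    if n_imputed:
        col_mean = np.nanmean(dosages, axis=0)
        dosages[nan_mask] = np.broadcast_to(col_mean, dosages.shape)[nan_mask]
    imputed = MarkerMatrix(kept.line_ids, kept.marker_ids, dosages)

    # step 3: MAF filter on the complete matrix
    keep2 = column_maf(imputed.dosages) >= min_maf
    n_drop_maf = int((~keep2).sum())
    out = imputed.subset_markers(keep2)
    if out.p == 0:
        raise MarkerQCError("no markers survive QC")

    if return_summary:
        summary = QCSummary(n_in, n_drop_miss, n_imputed, n_drop_maf, out.p)
        return out, summary
    return out
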