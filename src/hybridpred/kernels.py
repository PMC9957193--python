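"""Relationship and covariance kernels for hybrid prediction models.

The model distinguishes four layers of kernels:

* parental genomic relationship matrices (GRMs) ``G_M`` (males) and ``G_F``
  (females), each ``G = W W' / p`` from centered, standardized dosages;
* the hybrid SCA kernel ``H``, the observed-cross sub-matrix of the Kronecker
  product ``G_M (x) G_F``;
* observation-level expansions ``Z K Z'`` that lift an entity-level kernel
  (over lines, hybrids or environments) to the phenotype records;
* Hadamard (entrywise) products of an expanded genetic kernel with the
  expanded environment-block kernel, giving genotype-by-environment
  interaction covariances.

Identity analogues (for the non-genomic model types) go through the same
code paths so that a single fitting engine serves all model families.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .marker_qc import MarkerMatrix

SYMMETRY_ATOL = 1e-10
PSD_RTOL = 1e-8


class KernelError(ValueError):
    """Raised for structurally invalid kernels or unresolved entity ids."""


@dataclass
class RelationshipKernel:
    """A labelled symmetric PSD matrix over lines, hybrids or records.

    ``kind`` is one of ``GRM``, ``SCA``, ``EXPANDED``, ``INTERACTION``,
    ``IDENTITY`` and is informational (it records how the kernel was built).
    """

    entity_ids: list[str]
    values: np.ndarray = field(repr=False)
    kind: str = "GRM"

    def __post_init__(self) -> None:
        self.entity_ids = [str(x) for x in self.entity_ids]
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.entity_ids)
        if len(set(self.entity_ids)) != n:
            raise KernelError("duplicate entity ids in kernel")
        if self.values.shape != (n, n):
            raise KernelError(
                f"kernel shape {self.values.shape} does not match {n} entities"
            )
        if n and not np.allclose(self.values, self.values.T, atol=SYMMETRY_ATOL):
            raise KernelError("kernel is not symmetric within 1e-10")

    @property
    def n(self) -> int:
        return len(self.entity_ids)

    def index_of(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {e: i for i, e in enumerate(self.entity_ids)}
        missing = [str(x) for x in ids if str(x) not in lookup]
        if missing:
            raise KernelError(f"unknown entity ids: {sorted(set(missing))}")
        return np.array([lookup[str(x)] for x in ids], dtype=int)

    def min_eigenvalue_ratio(self) -> float:
        """min eigenvalue / max eigenvalue; >= -1e-8 for PSD up to round-off."""
        if self.n == 0:
            return 0.0
        w = np.linalg.eigvalsh((self.values + self.values.T) / 2.0)
        top = max(w.max(), np.finfo(float).tiny)
        return float(w.min() / top)

    def is_psd(self, rtol: float = PSD_RTOL) -> bool:
        return self.min_eigenvalue_ratio() >= -rtol


@dataclass
class HybridPedigree:
    """Cross table: one row per hybrid with its male and female parent."""

    hybrid_ids: list[str]
    male_ids: list[str]
    female_ids: list[str]

    def __post_init__(self) -> None:
        self.hybrid_ids = [str(x) for x in self.hybrid_ids]
        self.male_ids = [str(x) for x in self.male_ids]
        self.female_ids = [str(x) for x in self.female_ids]
        if not (len(self.hybrid_ids) == len(self.male_ids) == len(self.female_ids)):
            raise KernelError("pedigree columns have unequal lengths")
        if len(set(self.hybrid_ids)) != len(self.hybrid_ids):
            raise KernelError("duplicate hybrid ids in pedigree")

    @property
    def n_hybrids(self) -> int:
        return len(self.hybrid_ids)

    def parents_of(self, hybrid_ids: Sequence[str]) -> tuple[list[str], list[str]]:
        lookup = {h: (m, f) for h, m, f in
                  zip(self.hybrid_ids, self.male_ids, self.female_ids)}
        missing = [str(h) for h in hybrid_ids if str(h) not in lookup]
        if missing:
            raise KernelError(f"unknown hybrid ids: {sorted(set(missing))}")
        pairs = [lookup[str(h)] for h in hybrid_ids]
        return [p[0] for p in pairs], [p[1] for p in pairs]


def compute_grm(markers: MarkerMatrix, population_sd: bool = True) -> RelationshipKernel:
    """Genomic relationship matrix ``G = W W' / p`` (VanRaden-style).

    Each dosage column is centered by its mean and divided by its standard
    deviation to form ``W``.  With the population (denominator-``n``) standard
    deviation — the default — the mean of the diagonal of ``G`` is exactly 1.
    ``population_sd=False`` uses the sample (denominator ``n-1``) sd instead.

    Raises
    ------
    KernelError
        If any value is missing (QC must run first) or any column is
        monomorphic; the error names the offending marker ids.
    """
    X = markers.dosages
    if np.isnan(X).any():
        raise KernelError("dosage matrix contains missing values; run qc_pipeline first")
    if markers.p == 0:
        raise KernelError("no markers")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0 if population_sd else 1)
    mono = sd == 0
    if mono.any():
        bad = [m for m, b in zip(markers.marker_ids, mono) if b]
        raise KernelError(f"monomorphic markers (zero variance): {bad}")
    W = (X - mean) / sd
    G = W @ W.T / markers.p
    G = (G + G.T) / 2.0  # enforce exact symmetry against round-off
    return RelationshipKernel(list(markers.line_ids), G, kind="GRM")


def identity_kernel(entity_ids: Sequence[str]) -> RelationshipKernel:
    """Identity relationship over the given entities (non-genomic analogue)."""
    ids = [str(x) for x in entity_ids]
    return RelationshipKernel(ids, np.eye(len(ids)), kind="IDENTITY")


def sca_kernel(
    pedigree: HybridPedigree,
    G_M: RelationshipKernel,
    G_F: RelationshipKernel,
) -> RelationshipKernel:
    """Hybrid SCA kernel: the observed-cross block of ``G_M (x) G_F``.

    ``H[i, j] = G_M[male_i, male_j] * G_F[female_i, female_j]``.  Only the
    hybrids in the pedigree are materialized, never the full Kronecker
    product over all male-female combinations.
    """
    mi = G_M.index_of(pedigree.male_ids)
    fi = G_F.index_of(pedigree.female_ids)
    H = G_M.values[np.ix_(mi, mi)] * G_F.values[np.ix_(fi, fi)]
    return RelationshipKernel(list(pedigree.hybrid_ids), H, kind="SCA")


def expand_to_records(
    kernel: RelationshipKernel, record_entities: Sequence[str]
) -> RelationshipKernel:
    """Lift an entity kernel to observation records: ``(Z K Z')[r, s] = K[e_r, e_s]``.

    ``record_entities[r]`` names the entity of record ``r``; every record maps
    to exactly one entity that must exist in the kernel.  Record ids are the
    positional indices ``"0", "1", ...``.
    """
    idx = kernel.index_of(record_entities)
    V = kernel.values[np.ix_(idx, idx)]
    rec_ids = [str(i) for i in range(len(idx))]
    return RelationshipKernel(rec_ids, V, kind="EXPANDED")


def interaction_kernel(
    main_expanded: RelationshipKernel, env_expanded: RelationshipKernel
) -> RelationshipKernel:
    """Hadamard product of two record-level kernels (G-by-E covariance).

    With ``env_expanded = Z_E Z_E'`` the result zeroes every entry whose two
    records sit in different environments and is PSD by the Schur product
    theorem.
    """
    if main_expanded.entity_ids != env_expanded.entity_ids:
        raise KernelError("interaction inputs must share the identical record set")
    V = main_expanded.values * env_expanded.values
    return RelationshipKernel(list(main_expanded.entity_ids), V, kind="INTERACTION")
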