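"""Mid-parent phenotypic covariates for hybrid prediction.

For each trait ``t`` and each hybrid with male parent value ``P_M,t`` and
female parent value ``P_F,t``, two covariates are built:

* additive: ``(P_M,t + P_F,t) / 2`` — the mid-parent value;
* dominance: ``|P_M,t - P_F,t| / 2`` by default (``half_abs_diff``), the
  half parental divergence that tracks heterotic deviation; the alternative
  ``half_abs_sum`` rule, ``|P_M,t + P_F,t| / 2``, is available by flag.

Mode ``C`` emits the two columns of the target trait only; mode ``AC`` emits
two columns per configured trait (the target trait plus its correlated
traits).  Columns are centered afterwards so the model intercept absorbs
their mean; they are deliberately not variance-scaled because the covariate
coefficients carry a flat prior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kernels import HybridPedigree

DOMINANCE_RULES = ("half_abs_diff", "half_abs_sum")


class CovariateError(ValueError):
    pass


@dataclass
class ParentalPhenotypes:
    """Long-format parent-level trait values: one value per (parent, trait)."""

    table: pd.DataFrame  # columns: parent_id, trait, value

    def __post_init__(self) -> None:
        required = {"parent_id", "trait", "value"}
        if not required.issubset(self.table.columns):
            raise CovariateError(f"parental phenotype table needs columns {sorted(required)}")
        dup = self.table.duplicated(subset=["parent_id", "trait"])
        if dup.any():
            keys = self.table.loc[dup, ["parent_id", "trait"]].values.tolist()
            raise CovariateError(f"duplicate (parent, trait) records: {keys}")

    def value(self, parent_id: str, trait: str) -> float:
        sub = self.table[
            (self.table["parent_id"] == parent_id) & (self.table["trait"] == trait)
        ]
        if sub.empty:
            raise CovariateError(f"no phenotype for parent {parent_id!r}, trait {trait!r}")
        return float(sub["value"].iloc[0])

    def pivot(self) -> pd.DataFrame:
        return self.table.pivot(index="parent_id", columns="trait", values="value")


@dataclass
class CovariateMatrix:
    """Hybrids x covariates matrix with (trait, component) column labels."""

    hybrid_ids: list[str]
    columns: list[tuple[str, str]]  # (trait, "additive" | "dominance")
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.hybrid_ids), len(self.columns)):
            raise CovariateError("covariate matrix shape mismatch")
        if np.isnan(self.values).any():
            raise CovariateError("covariate matrix contains missing values")

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    def column(self, trait: str, component: str) -> np.ndarray:
        try:
            j = self.columns.index((trait, component))
        except ValueError:
            raise CovariateError(f"no covariate column ({trait!r}, {component!r})") from None
        return self.values[:, j]


def build_covariates(
    pedigree: HybridPedigree,
    parents: ParentalPhenotypes,
    target_trait: str,
    traits: list[str] | None = None,
    mode: str = "AC",
    dominance_rule: str = "half_abs_diff",
    center: bool = True,
) -> CovariateMatrix:
    """Build the parental covariate matrix X_C (mode ``C``) or X_AC (mode ``AC``).

    Parameters
    ----------
    traits
        The configured trait list for mode ``AC`` (must contain the target
        trait).  Ignored for mode ``C``.
    center
        Center each column to mean zero (default); disable to inspect the
        raw mid-parent values.

    Raises
    ------
    CovariateError
        If any required parental phenotype is missing; the error lists the
        offending (hybrid, parent, trait) triples.
    """
    if mode not in ("C", "AC"):
        raise CovariateError(f"mode must be 'C' or 'AC', got {mode!r}")
    if dominance_rule not in DOMINANCE_RULES:
        raise CovariateError(f"dominance_rule must be one of {DOMINANCE_RULES}")
    if mode == "C":
        use_traits = [target_trait]
    else:
        if not traits:
            raise CovariateError("mode 'AC' requires the configured trait list")
        if target_trait not in traits:
            raise CovariateError(f"target trait {target_trait!r} not in trait list {traits}")
        use_traits = list(traits)

    wide = parents.pivot()
    missing: list[tuple[str, str, str]] = []
    for h, m, f in zip(pedigree.hybrid_ids, pedigree.male_ids, pedigree.female_ids):
        for t in use_traits:
            for parent in (m, f):
                if (
                    parent not in wide.index
                    or t not in wide.columns
                    or pd.isna(wide.at[parent, t])
                ):
                    missing.append((h, parent, t))
    if missing:
        raise CovariateError(f"missing parental phenotypes for: {missing[:20]}")

    pm = wide.loc[pedigree.male_ids, use_traits].to_numpy(dtype=float)
    pf = wide.loc[pedigree.female_ids, use_traits].to_numpy(dtype=float)

    additive = (pm + pf) / 2.0
    if dominance_rule == "half_abs_diff":
        dominance = np.abs(pm - pf) / 2.0
    else:
        dominance = np.abs(pm + pf) / 2.0

    cols: list[tuple[str, str]] = []
    blocks: list[np.ndarray] = []
    for j, t in enumerate(use_traits):
        cols.append((t, "additive"))
        blocks.append(additive[:, j])
        cols.append((t, "dominance"))
        blocks.append(dominance[:, j])
    values = np.column_stack(blocks)
    if center:
        values = values - values.mean(axis=0)
    return CovariateMatrix(list(pedigree.hybrid_ids), cols, values)
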