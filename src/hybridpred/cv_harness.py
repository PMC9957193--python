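"""Cross-validation harness: untested lines in tested environments (CV1).

Hybrids, not records, are partitioned into k folds: when a hybrid is held
out, *all* of its records across environments are masked, so the test
hybrids carry no phenotypic information anywhere, while every environment
stays represented in training through the other hybrids.  Prediction error
is the mean squared error (MSE), pooled over test records per environment
and globally; models are compared by the relative efficiency
``RE = MSE_reference / MSE_candidate`` (RE > 1 means the candidate predicts
better) and the associated percent gain ``(RE - 1) * 100``.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd

from .mixed_model import (
    ModelSpec,
    ModelTerms,
    SamplerSettings,
    enumerate_model_specs,
    fit_gibbs,
)

if TYPE_CHECKING:  # pragma: no cover
    from .synth import HybridDataset


class CVError(ValueError):
    pass


@dataclass(frozen=True)
class FoldAssignment:
    """A seeded k-fold partition of hybrids (folds indexed 1..k)."""

    assignment: dict[str, int]
    k: int
    seed: int

    def fold_of(self, hybrid_id: str) -> int:
        return self.assignment[str(hybrid_id)]

    def hybrids_in_fold(self, fold: int) -> list[str]:
        return [h for h, f in self.assignment.items() if f == fold]

    def digest(self) -> str:
        """Stable hash of the partition, used to assert shared folds."""
        payload = ";".join(f"{h}:{f}" for h, f in sorted(self.assignment.items()))
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def make_folds(hybrid_ids: Sequence[str], k: int = 7, seed: int = 0) -> FoldAssignment:
    """Seeded uniform shuffle + round-robin assignment into k folds.

    Fold sizes differ by at most one.  All records of a hybrid share its
    fold by construction (assignment is per hybrid).
    """
    ids = [str(h) for h in hybrid_ids]
    if len(set(ids)) != len(ids):
        raise CVError("duplicate hybrid ids")
    if k < 2:
        raise CVError("k must be >= 2")
    if k > len(ids):
        raise CVError(f"k={k} exceeds number of hybrids ({len(ids)})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    assignment = {ids[j]: (i % k) + 1 for i, j in enumerate(order)}
    return FoldAssignment(assignment, k, seed)


@dataclass
class CVReport:
    """Per-fold and pooled prediction errors for one model."""

    model: str
    seed: int
    fold_digest: str
    cell_mse: pd.DataFrame = field(repr=False)  # environment, fold, mse, n
    predictions: pd.DataFrame = field(repr=False)  # hybrid, env, fold, y, yhat

    @property
    def per_environment_mse(self) -> pd.Series:
        """MSE pooled over each environment's test records across folds."""
        sq = (self.predictions["y"] - self.predictions["yhat"]) ** 2
        return sq.groupby(self.predictions["environment"]).mean()

    @property
    def global_mse(self) -> float:
        """MSE pooled over all test records."""
        sq = (self.predictions["y"] - self.predictions["yhat"]) ** 2
        return float(sq.mean())

    @property
    def fold_mean_mse(self) -> float:
        """Unweighted mean of per-fold MSEs (the alternative averaging rule)."""
        sq = (self.predictions["y"] - self.predictions["yhat"]) ** 2
        return float(sq.groupby(self.predictions["fold"]).mean().mean())

    @property
    def n_test_records(self) -> int:
        return len(self.predictions)


def _mask_for_fold(records: pd.DataFrame, folds: FoldAssignment, fold: int) -> np.ndarray:
    hybrids = records["hybrid"].astype(str)
    test = {h for h, f in folds.assignment.items() if f == fold}
    return hybrids.isin(test).to_numpy()


def run_cv(
    terms: ModelTerms,
    folds: FoldAssignment,
    settings: SamplerSettings | None = None,
    seed: int = 0,
    predictor=None,
) -> CVReport:
    """Run the CV1 scheme for one assembled model.

    For each fold, the responses of every record of the fold's hybrids are
    masked, the model is fitted by ``fit_gibbs``, and the masked predictions
    are collected.  ``predictor`` may replace the sampler with any callable
    ``(terms, mask) -> predictions over masked records`` (used for oracle
    injection in tests).
    """
    records = terms.records
    missing = sorted(
        set(records["hybrid"].astype(str)) - set(folds.assignment)
    )
    if missing:
        raise CVError(f"hybrids without fold assignment: {missing[:10]}")

    rows = []
    preds = []
    for fold in range(1, folds.k + 1):
        mask = _mask_for_fold(records, folds, fold)
        if not mask.any():
            continue
        envs = records["environment"].astype(str)
        for env in sorted(envs.unique()):
            if not ((~mask) & (envs == env)).any():
                raise CVError(
                    f"fold {fold} leaves environment {env!r} with no training records"
                )
        if predictor is not None:
            yhat = np.asarray(predictor(terms, mask), dtype=float)
        else:
            fit = fit_gibbs(terms, mask=mask, settings=settings, seed=seed + fold)
            yhat = fit.predicted()
        y_test = terms.y[mask]
        sub = records.loc[mask, ["hybrid", "environment"]].copy()
        sub["fold"] = fold
        sub["y"] = y_test
        sub["yhat"] = yhat
        preds.append(sub)
        sq = (y_test - yhat) ** 2
        for env, grp in sub.assign(sq=sq).groupby("environment"):
            rows.append(
                {"environment": env, "fold": fold,
                 "mse": float(grp["sq"].mean()), "n": len(grp)}
            )

    predictions = pd.concat(preds, ignore_index=True)
    cell = pd.DataFrame(rows)
    return CVReport(
        model=terms.spec.name,
        seed=seed,
        fold_digest=folds.digest(),
        cell_mse=cell,
        predictions=predictions,
    )


def relative_efficiency(mse_reference: float, mse_candidate: float) -> tuple[float, float]:
    """RE = reference MSE / candidate MSE, with the percent gain (RE-1)*100.

    RE > 1 flags the candidate model as the better predictor; RE = 1 means
    the two are equally efficient.
    """
    if mse_reference <= 0 or mse_candidate <= 0:
        raise CVError("MSE values must be positive")
    re = mse_reference / mse_candidate
    return re, (re - 1.0) * 100.0


def percent_gain(re: float) -> float:
    return (re - 1.0) * 100.0


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal rounding with ties away from zero, as used in reported gains."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def mean_percent_gain(res: Iterable[float], decimals: int = 1) -> float:
    """Average percent gain over a set of REs, rounded half-up.

    Computed in decimal arithmetic so that printed three-decimal REs produce
    exactly reproducible one-decimal summary gains.
    """
    gains = [(Decimal(repr(float(r))) - 1) * 100 for r in res]
    if not gains:
        raise CVError("no RE values supplied")
    mean = sum(gains) / len(gains)
    q = Decimal(10) ** -decimals
    return float(mean.quantize(q, rounding=ROUND_HALF_UP))


#: the three within-family comparisons reported per model family
FAMILY_COMPARISONS = (("", "_C"), ("", "_AC"), ("_C", "_AC"))


@dataclass
class ModelComparison:
    """Shared-fold comparison of model specs: MSE table plus RE panels."""

    mse_table: pd.DataFrame  # model, environment ('Global' row), mse, n
    re_table: pd.DataFrame  # reference, candidate, environment, re, gain_pct
    fold_digest: str
    seed: int

    def global_re(self, reference: str, candidate: str) -> float:
        sub = self.re_table[
            (self.re_table["reference"] == reference)
            & (self.re_table["candidate"] == candidate)
            & (self.re_table["environment"] == "Global")
        ]
        if sub.empty:
            raise CVError(f"no comparison {reference} vs {candidate}")
        return float(sub["re"].iloc[0])


def compare_models(
    data: "HybridDataset",
    folds: FoldAssignment,
    trait: str,
    families: str = "ABCD",
    settings: SamplerSettings | None = None,
    seed: int = 0,
    specs: Sequence[ModelSpec] | None = None,
) -> ModelComparison:
    """Fit a set of model specs on shared folds and tabulate MSEs and REs.

    By default all 12 specs (4 families x 3 covariate modes) are run; pass
    ``families`` or an explicit ``specs`` list to restrict.  All models see
    the identical fold partition (paired design, asserted via the fold
    digest in the output).
    """
    if specs is None:
        specs = [s for s in enumerate_model_specs(trait) if s.model_type in families]
    reports: dict[str, CVReport] = {}
    mse_rows = []
    for spec in specs:
        terms = data.assemble(spec)
        rep = run_cv(terms, folds, settings=settings, seed=seed)
        reports[spec.name] = rep
        per_env = rep.per_environment_mse
        counts = rep.predictions.groupby("environment").size()
        for env, mse in per_env.items():
            mse_rows.append(
                {"model": spec.name, "environment": env,
                 "mse": float(mse), "n": int(counts[env])}
            )
        mse_rows.append(
            {"model": spec.name, "environment": "Global",
             "mse": rep.global_mse, "n": rep.n_test_records}
        )
    mse_table = pd.DataFrame(mse_rows)

    re_rows = []
    names = {s.name for s in specs}
    for fam in families:
        for ref_suf, cand_suf in FAMILY_COMPARISONS:
            ref, cand = f"M{fam}{ref_suf}", f"M{fam}{cand_suf}"
            if ref not in names or cand not in names:
                continue
            envs = list(reports[ref].per_environment_mse.index) + ["Global"]
            for env in envs:
                if env == "Global":
                    m_ref = reports[ref].global_mse
                    m_cand = reports[cand].global_mse
                else:
                    m_ref = float(reports[ref].per_environment_mse[env])
                    m_cand = float(reports[cand].per_environment_mse[env])
                re, gain = relative_efficiency(m_ref, m_cand)
                re_rows.append(
                    {"reference": ref, "candidate": cand, "environment": env,
                     "re": re, "gain_pct": gain}
                )
    re_table = pd.DataFrame(re_rows)
    return ModelComparison(mse_table, re_table, folds.digest(), seed)
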