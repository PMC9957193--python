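"""Multi-kernel Gaussian mixed models for hybrid prediction.

The response is modelled as

    y = X beta + sum_k u_k + eps,   u_k ~ N(0, sigma_k^2 K_k),   eps ~ N(0, sigma_e^2 I)

where each ``K_k`` is a record-level covariance kernel (environment block,
male/female GCA, hybrid SCA, and their Hadamard interactions with the
environment block) and ``X`` holds the intercept plus any parental
covariates.  Four model families are supported:

* **A** — GCA + SCA + interactions with identity kernels (no markers);
* **B** — the same structure with genomic kernels (G_M, G_F, H = G_M (x) G_F);
* **C** — SCA + its interaction only, identity kernels;
* **D** — SCA + its interaction only, genomic kernels.

Each family optionally carries parental covariates of the target trait
(``C``) or of all configured traits (``AC``), giving 12 models in total.

Fitting is by a Gibbs sampler equivalent to Bayesian reproducing-kernel
regression: each kernel is eigendecomposed once, ``K = U D U'``, the random
effect is re-parameterized as ``u = U D^{1/2} delta`` with iid prior
``delta ~ N(0, sigma_k^2 I)``, and the conditional for ``delta`` is then
diagonal.  Variances carry scaled-inverse-chi-square priors; masked
responses are imputed each sweep, so cross-validation predictions come out
of the sampler directly.  A closed-form GLS/BLUP solver is provided as an
independent oracle for testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kernels import (
    HybridPedigree,
    RelationshipKernel,
    expand_to_records,
    identity_kernel,
    interaction_kernel,
    sca_kernel,
)
from .parental_covariates import CovariateMatrix

MODEL_TYPES = ("A", "B", "C", "D")
COVARIATE_MODES = ("none", "C", "AC")
EIG_TRUNCATION_RTOL = 1e-10


class ModelError(ValueError):
    pass


class SamplerError(RuntimeError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    """One of the 12 predictors: family A-D crossed with covariate mode."""

    model_type: str
    covariate_mode: str = "none"
    trait: str = "GY"

    def __post_init__(self) -> None:
        if self.model_type not in MODEL_TYPES:
            raise ModelError(f"model_type must be one of {MODEL_TYPES}")
        if self.covariate_mode not in COVARIATE_MODES:
            raise ModelError(f"covariate_mode must be one of {COVARIATE_MODES}")

    @property
    def genomic(self) -> bool:
        """Families B and D use marker-derived kernels."""
        return self.model_type in ("B", "D")

    @property
    def has_parental_terms(self) -> bool:
        """Families A and B carry male/female GCA main effects and interactions."""
        return self.model_type in ("A", "B")

    @property
    def name(self) -> str:
        suffix = {"none": "", "C": "_C", "AC": "_AC"}[self.covariate_mode]
        return f"M{self.model_type}{suffix}"


def enumerate_model_specs(trait: str) -> list[ModelSpec]:
    """All 12 (family, covariate mode) combinations for one target trait."""
    return [
        ModelSpec(t, m, trait) for t in MODEL_TYPES for m in COVARIATE_MODES
    ]


@dataclass
class RandomTerm:
    """One random effect: a named record-level covariance kernel.

    ``entities`` maps each record to its entity label for main-effect terms
    (environment, male, female, hybrid); interaction terms have none.
    """

    name: str
    kernel: np.ndarray = field(repr=False)
    entities: list[str] | None = None
    _eig: tuple[np.ndarray, np.ndarray] | None = field(
        default=None, repr=False, compare=False
    )

    def eig(self) -> tuple[np.ndarray, np.ndarray]:
        """Truncated eigendecomposition (U, d); cached across sampler calls."""
        if self._eig is None:
            K = (self.kernel + self.kernel.T) / 2.0
            w, U = np.linalg.eigh(K)
            top = w.max() if w.size else 0.0
            if top <= 0:
                raise SamplerError(f"kernel {self.name!r} has no positive eigenvalue")
            if w.min() < -1e-8 * top:
                raise SamplerError(f"kernel {self.name!r} is not PSD")
            keep = w > EIG_TRUNCATION_RTOL * top
            self._eig = (U[:, keep], w[keep])
        return self._eig


@dataclass
class ModelTerms:
    """Assembled design: records, fixed-effect columns and random terms."""

    records: pd.DataFrame  # columns hybrid, environment, value; fixed row order
    X: np.ndarray = field(repr=False)
    x_labels: list[str]
    random: list[RandomTerm]
    spec: ModelSpec

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def y(self) -> np.ndarray:
        return self.records["value"].to_numpy(dtype=float)


def assemble_model(
    spec: ModelSpec,
    records: pd.DataFrame,
    pedigree: HybridPedigree,
    G_M: RelationshipKernel | None = None,
    G_F: RelationshipKernel | None = None,
    covariates: CovariateMatrix | None = None,
    literal_uh: bool = False,
) -> ModelTerms:
    """Build the fixed design and record-level kernels for one model spec.

    ``records`` is the long phenotype table for the target trait with columns
    ``hybrid``, ``environment``, ``value``.  Genomic kernels are required iff
    the family is B or D; covariates are required iff the mode is not
    ``none``.  ``literal_uh=True`` reproduces the variant in which the
    non-genomic families keep the genomic SCA kernel inside the
    hybrid-by-environment interaction (it then also needs G_M and G_F).
    """
    required = {"hybrid", "environment", "value"}
    if not required.issubset(records.columns):
        raise ModelError(f"records need columns {sorted(required)}")
    records = records.reset_index(drop=True)
    if spec.genomic and (G_M is None or G_F is None):
        raise ModelError(f"model {spec.name} requires genomic kernels G_M and G_F")
    if spec.covariate_mode != "none" and covariates is None:
        raise ModelError(f"model {spec.name} requires parental covariates")

    hybrids = [str(h) for h in records["hybrid"]]
    envs = [str(e) for e in records["environment"]]
    males, females = pedigree.parents_of(hybrids)

    env_ids = sorted(set(envs))
    env_exp = expand_to_records(identity_kernel(env_ids), envs)

    # hybrid SCA kernel over the hybrids present in the records
    present = sorted(set(hybrids), key=hybrids.index)
    sub_m, sub_f = pedigree.parents_of(present)
    sub_ped = HybridPedigree(present, sub_m, sub_f)

    random: list[RandomTerm] = [RandomTerm("env", env_exp.values, envs)]

    if spec.genomic or literal_uh:
        if G_M is None or G_F is None:
            raise ModelError("literal_uh requires genomic kernels G_M and G_F")
        H = sca_kernel(sub_ped, G_M, G_F)

    if spec.has_parental_terms:
        KM = G_M if spec.genomic else identity_kernel(sorted(set(males)))
        KF = G_F if spec.genomic else identity_kernel(sorted(set(females)))
        gm_exp = expand_to_records(KM, males)
        gf_exp = expand_to_records(KF, females)
        random.append(RandomTerm("g_M", gm_exp.values, males))
        random.append(RandomTerm("g_F", gf_exp.values, females))

    Kh = H if spec.genomic else identity_kernel(present)
    h_exp = expand_to_records(Kh, hybrids)
    random.append(RandomTerm("h", h_exp.values, hybrids))

    if spec.has_parental_terms:
        random.append(
            RandomTerm("u_M", interaction_kernel(gm_exp, env_exp).values)
        )
        random.append(
            RandomTerm("u_F", interaction_kernel(gf_exp, env_exp).values)
        )
    uh_base = expand_to_records(H, hybrids) if (spec.genomic or literal_uh) else h_exp
    random.append(RandomTerm("u_H", interaction_kernel(uh_base, env_exp).values))

    X_cols: list[np.ndarray] = [np.ones(len(records))]
    x_labels = ["intercept"]
    if covariates is not None and spec.covariate_mode != "none":
        lookup = {h: i for i, h in enumerate(covariates.hybrid_ids)}
        missing = sorted({h for h in hybrids if h not in lookup})
        if missing:
            raise ModelError(f"covariates missing for hybrids: {missing[:10]}")
        idx = np.array([lookup[h] for h in hybrids])
        C = covariates.values[idx, :]
        X_cols.extend(C.T)
        x_labels.extend(f"{t}:{c}" for t, c in covariates.columns)
    X = np.column_stack(X_cols)

    return ModelTerms(records, X, x_labels, random, spec)


@dataclass(frozen=True)
class SamplerSettings:
    """Gibbs sampler run configuration (iterations, burn-in, thinning)."""

    n_iter: int = 12_000
    burn_in: int = 2_000
    thin: int = 5
    prior_df: float = 5.0
    prior_r2: float = 0.5  # share of var(y) assigned to the random terms a priori

    def __post_init__(self) -> None:
        if self.n_iter <= self.burn_in:
            raise ModelError("n_iter must exceed burn_in")
        if self.thin < 1:
            raise ModelError("thin must be >= 1")


@dataclass
class PosteriorFit:
    """Posterior summaries of one Gibbs run."""

    spec: ModelSpec
    beta_mean: np.ndarray
    x_labels: list[str]
    variance_mean: dict[str, float]
    variance_mcse: dict[str, float]
    effect_record_mean: dict[str, np.ndarray]
    entity_effects: dict[str, pd.Series]
    eta_mean: np.ndarray
    predictions: pd.DataFrame  # masked records: hybrid, environment, prediction
    n_samples: int
    settings: SamplerSettings
    seed: int

    def predicted(self) -> np.ndarray:
        return self.predictions["prediction"].to_numpy(dtype=float)


def _check_training_coverage(records: pd.DataFrame, mask: np.ndarray) -> None:
    envs = records["environment"].astype(str)
    for env in sorted(envs.unique()):
        in_env = (envs == env).to_numpy()
        if not (~mask & in_env).any():
            raise ModelError(f"environment {env!r} has no training records")


def fit_gibbs(
    terms: ModelTerms,
    mask: np.ndarray | None = None,
    settings: SamplerSettings | None = None,
    seed: int = 0,
    fixed_variances: dict[str, float] | None = None,
) -> PosteriorFit:
    """Sample the posterior; masked records are imputed and predicted.

    Parameters
    ----------
    mask
        Boolean vector over records; ``True`` marks responses to hide from
        the likelihood.  Their predictions are the posterior mean of the
        linear predictor at those records.
    fixed_variances
        Optional map from term name (or ``"residual"``) to a value at which
        that variance is held instead of being sampled — used for oracle
        comparisons where the variance components are known.

    Raises
    ------
    SamplerError
        On a non-finite variance draw (divergence), an all-masked response,
        or a non-PSD kernel.
    """
    settings = settings or SamplerSettings()
    fixed_variances = fixed_variances or {}
    y_full = terms.y
    n = terms.n_records
    if mask is None:
        mask = np.zeros(n, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.all():
        raise SamplerError("all responses are masked; nothing to fit")
    _check_training_coverage(terms.records, mask)

    rng = np.random.default_rng(seed)
    obs = ~mask
    var_y = float(np.var(y_full[obs]))
    if var_y == 0.0:
        var_y = 1.0  # constant response; priors still need a positive scale

    X = terms.X
    q = X.shape[1]
    # per-column updates (flat prior); zero-norm columns stay at coefficient 0
    col_norm2 = (X**2).sum(axis=0)

    K = len(terms.random)
    eigs = [t.eig() for t in terms.random]
    sqrt_d = [np.sqrt(d) for _, d in eigs]
    Phi = [U * sd for (U, _), sd in zip(eigs, sqrt_d)]  # n x r_k

    df0 = settings.prior_df
    # prior mode for each variance: equal split of prior_r2 * var(y) across terms
    mode_k = settings.prior_r2 * var_y / max(K, 1)
    tau2_k = mode_k * (df0 + 2.0) / df0
    mode_e = (1.0 - settings.prior_r2) * var_y
    tau2_e = mode_e * (df0 + 2.0) / df0

    # state
    yw = y_full.copy()
    yw[mask] = y_full[obs].mean()
    beta = np.zeros(q)
    beta[0] = yw.mean()
    delta = [np.zeros(len(d)) for _, d in eigs]
    u = [np.zeros(n) for _ in range(K)]
    sigma2 = np.full(K, mode_k)
    sigma2_e = mode_e if mode_e > 0 else var_y
    for k, t in enumerate(terms.random):
        if t.name in fixed_variances:
            sigma2[k] = float(fixed_variances[t.name])
    if "residual" in fixed_variances:
        sigma2_e = float(fixed_variances["residual"])

    e = yw - X @ beta  # running residual y - eta

    n_keep = 0
    eta_sum = np.zeros(n)
    eta_sumsq = np.zeros(n)
    beta_sum = np.zeros(q)
    u_sum = [np.zeros(n) for _ in range(K)]
    var_samples: list[np.ndarray] = []

    for it in range(settings.n_iter):
        # fixed effects: scalar Gibbs update per column (flat prior)
        for j in range(q):
            if col_norm2[j] == 0.0:
                continue
            xj = X[:, j]
            e_j = e + xj * beta[j]
            mean_j = (xj @ e_j) / col_norm2[j]
            beta[j] = mean_j + rng.standard_normal() * np.sqrt(
                sigma2_e / col_norm2[j]
            )
            e = e_j - xj * beta[j]

        # random terms: diagonal conditional in eigen coordinates
        for k in range(K):
            e_k = e + u[k]
            Utr = eigs[k][0].T @ e_k
            zk = sqrt_d[k] * Utr
            prec = eigs[k][1] / sigma2_e + 1.0 / sigma2[k]
            mean_d = zk / sigma2_e / prec
            delta[k] = mean_d + rng.standard_normal(len(prec)) / np.sqrt(prec)
            u[k] = Phi[k] @ delta[k]
            e = e_k - u[k]

        # variance components
        for k, t in enumerate(terms.random):
            if t.name in fixed_variances:
                continue
            r_k = len(delta[k])
            ss = float(delta[k] @ delta[k])
            sigma2[k] = (df0 * tau2_k + ss) / rng.chisquare(df0 + r_k)
        if "residual" not in fixed_variances:
            sigma2_e = (df0 * tau2_e + float(e @ e)) / rng.chisquare(df0 + n)
        if not np.isfinite(sigma2_e) or not np.all(np.isfinite(sigma2)):
            raise SamplerError(
                f"divergent variance draw at iteration {it}: "
                f"sigma2={sigma2}, sigma2_e={sigma2_e}"
            )

        # impute masked responses: predictor + fresh residual noise
        if mask.any():
            eta = yw - e
            noise = np.sqrt(sigma2_e) * rng.standard_normal(int(mask.sum()))
            yw[mask] = eta[mask] + noise
            e[mask] = noise

        if it >= settings.burn_in and (it - settings.burn_in) % settings.thin == 0:
            eta = yw - e
            n_keep += 1
            eta_sum += eta
            eta_sumsq += eta**2
            beta_sum += beta
            for k in range(K):
                u_sum[k] += u[k]
            var_samples.append(np.append(sigma2.copy(), sigma2_e))

    eta_mean = eta_sum / n_keep
    vs = np.array(var_samples)
    names = [t.name for t in terms.random] + ["residual"]
    variance_mean = {nm: float(vs[:, j].mean()) for j, nm in enumerate(names)}
    variance_mcse = {
        nm: float(vs[:, j].std(ddof=1) / np.sqrt(n_keep)) for j, nm in enumerate(names)
    }

    effect_record_mean = {
        t.name: u_sum[k] / n_keep for k, t in enumerate(terms.random)
    }
    entity_effects: dict[str, pd.Series] = {}
    for k, t in enumerate(terms.random):
        if t.entities is not None:
            # expanded main-effect draws are constant within entity, so the
            # first record of each entity carries the entity-level effect
            first = {}
            for r, ent in enumerate(t.entities):
                first.setdefault(ent, r)
            vals = effect_record_mean[t.name]
            entity_effects[t.name] = pd.Series(
                {ent: vals[r] for ent, r in first.items()}, name=t.name
            )

    pred_rows = terms.records.loc[mask, ["hybrid", "environment"]].copy()
    pred_rows["prediction"] = eta_mean[mask]

    return PosteriorFit(
        spec=terms.spec,
        beta_mean=beta_sum / n_keep,
        x_labels=list(terms.x_labels),
        variance_mean=variance_mean,
        variance_mcse=variance_mcse,
        effect_record_mean=effect_record_mean,
        entity_effects=entity_effects,
        eta_mean=eta_mean,
        predictions=pred_rows.reset_index(drop=True),
        n_samples=n_keep,
        settings=settings,
        seed=seed,
    )


@dataclass
class BlupResult:
    """Closed-form GLS/BLUP solution at fixed variance components."""

    beta: np.ndarray
    yhat: np.ndarray  # fitted/predicted linear predictor for every record
    effects: dict[str, np.ndarray]


def blup_oracle(
    terms: ModelTerms,
    variances: dict[str, float],
    residual_variance: float,
    mask: np.ndarray | None = None,
    jitter: float = 1e-8,
) -> BlupResult:
    """Best linear unbiased prediction at known variances (testing oracle).

    Solves GLS on the unmasked records with ``V = sum_k sigma_k^2 K_k +
    sigma_e^2 I`` (a diagonal jitter guards against singularity), then
    extrapolates every record's linear predictor via the kernel cross-blocks:
    ``yhat = X beta + sum_k sigma_k^2 K_k[:, train] V^-1 (y_train - X_train beta)``.
    """
    n = terms.n_records
    if mask is None:
        mask = np.zeros(n, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    train = ~mask
    if not train.any():
        raise ModelError("no training records")
    for t in terms.random:
        if t.name not in variances:
            raise ModelError(f"no variance supplied for term {t.name!r}")
    if residual_variance <= 0:
        raise ModelError("residual variance must be positive")

    V_full = residual_variance * np.eye(n)
    for t in terms.random:
        V_full += float(variances[t.name]) * t.kernel
    Vtt = V_full[np.ix_(train, train)] + jitter * np.eye(int(train.sum()))

    X = terms.X
    y = terms.y
    Xt, yt = X[train], y[train]
    Vinv_X = np.linalg.solve(Vtt, Xt)
    Vinv_y = np.linalg.solve(Vtt, yt)
    XtVinvX = Xt.T @ Vinv_X
    beta = np.linalg.solve(XtVinvX, Xt.T @ Vinv_y)
    resid = yt - Xt @ beta
    alpha = np.linalg.solve(Vtt, resid)

    yhat = X @ beta
    effects: dict[str, np.ndarray] = {}
    for t in terms.random:
        u_hat = float(variances[t.name]) * (t.kernel[:, train] @ alpha)
        effects[t.name] = u_hat
        yhat = yhat + u_hat
    return BlupResult(beta=beta, yhat=yhat, effects=effects)
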