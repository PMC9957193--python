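"""Synthetic hybrid-breeding datasets with known ground truth.

The generator emulates a two-pool hybrid wheat program: a small male pool
and a larger female pool of fully inbred (homozygous) parents, crossed into
hybrids that are evaluated in several consecutive environments (years) with
partially overlapping hybrid sets.  Three genetically correlated traits are
simulated from shared-architecture marker effects, with additive GCA for
each pool, a kernel-structured SCA deviation, genotype-by-environment
interactions drawn from the model's own Hadamard kernels, and iid residual
noise.  Parental phenotypes are each parent's own additive value plus a
small measurement noise, so mid-parent covariates are informative about
hybrid performance.

Each realized effect vector is rescaled so its population variance hits the
configured variance component exactly; this makes parameter-recovery tests
well posed at small pool sizes.  Marker columns are guaranteed polymorphic
in both pools; missing data for QC testing is injected afterwards with
``corrupt_markers``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .kernels import HybridPedigree, RelationshipKernel, compute_grm, sca_kernel
from .marker_qc import MarkerMatrix, qc_pipeline
from .mixed_model import ModelSpec, ModelTerms, assemble_model
from .parental_covariates import CovariateMatrix, ParentalPhenotypes, build_covariates

DEFAULT_VARIANCES: dict[str, float] = {
    "env": 1.0,
    "g_M": 0.5,
    "g_F": 0.5,
    "h": 0.25,
    "u_M": 0.15,
    "u_F": 0.15,
    "u_H": 0.15,
    "residual": 1.0,
}


class SynthError(ValueError):
    pass


@dataclass(frozen=True)
class SynthConfig:
    """Scaled-down mimic of a two-pool hybrid trial series.

    Defaults: 6 males x 40 females, 300 markers, 3 environments of 60
    hybrids with 30% overlap between consecutive environments, 3 traits with
    genetic correlation 0.5, unit-scale variance components, and parental
    phenotypes measured with variance-0.05 noise.
    """

    n_males: int = 6
    n_females: int = 40
    n_markers: int = 300
    n_environments: int = 3
    n_hybrids_per_env: int = 60
    overlap_fraction: float = 0.3
    traits: tuple[str, ...] = ("GY", "DTF", "DTH")
    trait_correlation: float = 0.5
    variance_components: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_VARIANCES))
    parental_noise_var: float = 0.05
    mu: float = 0.0
    inbred: bool = True
    seed: int = 0

    def correlation_matrix(self) -> np.ndarray:
        T = len(self.traits)
        R = np.full((T, T), float(self.trait_correlation))
        np.fill_diagonal(R, 1.0)
        w = np.linalg.eigvalsh(R)
        if w.min() < -1e-10:
            raise SynthError("trait correlation matrix is not PSD")
        return R

    def validate(self) -> None:
        if any(v < 0 for v in self.variance_components.values()):
            raise SynthError("variance components must be >= 0")
        n_overlap = round(self.overlap_fraction * self.n_hybrids_per_env)
        if n_overlap >= self.n_hybrids_per_env and self.n_environments > 1:
            raise SynthError("overlap_fraction leaves no new hybrids per environment")
        n_unique = (
            self.n_environments * self.n_hybrids_per_env
            - (self.n_environments - 1) * n_overlap
        )
        if n_unique > self.n_males * self.n_females:
            raise SynthError(
                f"need {n_unique} distinct crosses but only "
                f"{self.n_males * self.n_females} are possible"
            )
        self.correlation_matrix()


@dataclass
class SynthTruth:
    """Ground truth behind one simulated dataset."""

    g_M: pd.DataFrame  # males x traits
    g_F: pd.DataFrame  # females x traits
    h: pd.DataFrame  # hybrids x traits
    env_effects: pd.DataFrame  # environments x traits
    marker_effects_M: np.ndarray = field(repr=False)
    marker_effects_F: np.ndarray = field(repr=False)
    record_components: pd.DataFrame = field(repr=False)  # per record x trait breakdown
    variance_components: dict[str, float] = field(default_factory=dict)

    def genetic_values(self, trait: str) -> pd.Series:
        sub = self.record_components[self.record_components["trait"] == trait]
        return sub.set_index(["hybrid", "environment"])["genetic_value"]


@dataclass
class HybridDataset:
    """A complete analysis-ready dataset (real or simulated).

    ``assemble`` wires the pieces into :class:`ModelTerms` for a given model
    spec, computing and caching genomic kernels (after QC) and parental
    covariates on demand.
    """

    male_markers: MarkerMatrix
    female_markers: MarkerMatrix
    pedigree: HybridPedigree
    phenotypes: pd.DataFrame  # hybrid, environment, trait, value
    parental_phenotypes: ParentalPhenotypes
    traits: list[str]
    truth: SynthTruth | None = None
    config: SynthConfig | None = None
    _grm_cache: dict[str, RelationshipKernel] = field(default_factory=dict, repr=False)
    _cov_cache: dict[tuple[str, str], CovariateMatrix] = field(
        default_factory=dict, repr=False
    )

    def records_for_trait(self, trait: str) -> pd.DataFrame:
        sub = self.phenotypes[self.phenotypes["trait"] == trait]
        if sub.empty:
            raise SynthError(f"no phenotype records for trait {trait!r}")
        return sub[["hybrid", "environment", "value"]].reset_index(drop=True)

    def hybrid_ids(self) -> list[str]:
        return sorted(self.phenotypes["hybrid"].astype(str).unique())

    def grm(self, pool: str) -> RelationshipKernel:
        if pool not in ("male", "female"):
            raise SynthError("pool must be 'male' or 'female'")
        if pool not in self._grm_cache:
            markers = self.male_markers if pool == "male" else self.female_markers
            clean = qc_pipeline(markers)
            self._grm_cache[pool] = compute_grm(clean)
        return self._grm_cache[pool]

    def covariates(self, trait: str, mode: str) -> CovariateMatrix:
        key = (trait, mode)
        if key not in self._cov_cache:
            self._cov_cache[key] = build_covariates(
                self.pedigree,
                self.parental_phenotypes,
                target_trait=trait,
                traits=self.traits,
                mode=mode,
            )
        return self._cov_cache[key]

    def assemble(self, spec: ModelSpec, literal_uh: bool = False) -> ModelTerms:
        records = self.records_for_trait(spec.trait)
        G_M = self.grm("male") if (spec.genomic or literal_uh) else None
        G_F = self.grm("female") if (spec.genomic or literal_uh) else None
        cov = (
            self.covariates(spec.trait, spec.covariate_mode)
            if spec.covariate_mode != "none"
            else None
        )
        return assemble_model(
            spec, records, self.pedigree, G_M=G_M, G_F=G_F,
            covariates=cov, literal_uh=literal_uh,
        )


def _polymorphic_dosages(
    rng: np.random.Generator, n_lines: int, n_markers: int, inbred: bool
) -> np.ndarray:
    """Sample dosage columns polymorphic in this pool; freq ~ U(0.1, 0.9)."""
    cols: list[np.ndarray] = []
    while len(cols) < n_markers:
        batch = max(n_markers - len(cols), 16)
        q = rng.uniform(0.1, 0.9, size=batch)
        if inbred:
            d = 2.0 * (rng.random((n_lines, batch)) < q)
        else:
            d = rng.binomial(2, q, size=(n_lines, batch)).astype(float)
        poly = d.std(axis=0) > 0
        for j in np.flatnonzero(poly):
            cols.append(d[:, j])
            if len(cols) == n_markers:
                break
    return np.column_stack(cols)


def _scale_to_variance(x: np.ndarray, target: float) -> np.ndarray:
    """Rescale so the population variance of x equals target exactly."""
    if target == 0.0:
        return np.zeros_like(x)
    v = float(np.var(x))
    if v == 0.0:
        raise SynthError("cannot rescale a constant effect vector")
    return x * np.sqrt(target / v)


def _standardize(X: np.ndarray) -> np.ndarray:
    return (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)


def _kernel_draw(rng: np.random.Generator, K: np.ndarray, n_traits: int) -> np.ndarray:
    L = np.linalg.cholesky(K + 1e-8 * np.eye(K.shape[0]))
    return L @ rng.standard_normal((K.shape[0], n_traits))


def simulate_dataset(config: SynthConfig | None = None, **overrides) -> HybridDataset:
    """Simulate a full dataset (markers, pedigree, phenotypes, truth).

    Keyword overrides are applied on top of ``config`` (or the defaults),
    e.g. ``simulate_dataset(seed=3, n_markers=100)``.
    """
    config = replace(config or SynthConfig(), **overrides)
    config.validate()
    rng = np.random.default_rng(config.seed)
    vc = {**DEFAULT_VARIANCES, **config.variance_components}
    traits = list(config.traits)
    T = len(traits)
    R = config.correlation_matrix()
    L_R = np.linalg.cholesky(R + 1e-12 * np.eye(T))

    male_ids = [f"M{i+1:02d}" for i in range(config.n_males)]
    female_ids = [f"F{i+1:03d}" for i in range(config.n_females)]
    marker_ids = [f"m{j+1:04d}" for j in range(config.n_markers)]

    Xm = _polymorphic_dosages(rng, config.n_males, config.n_markers, config.inbred)
    Xf = _polymorphic_dosages(rng, config.n_females, config.n_markers, config.inbred)
    male_markers = MarkerMatrix(male_ids, marker_ids, Xm)
    female_markers = MarkerMatrix(female_ids, marker_ids, Xf)

    # cross-correlated marker effects: each marker's T-vector ~ N(0, R)
    alpha_M = rng.standard_normal((config.n_markers, T)) @ L_R.T
    alpha_F = rng.standard_normal((config.n_markers, T)) @ L_R.T
    Wm, Wf = _standardize(Xm), _standardize(Xf)
    g_M = np.column_stack(
        [_scale_to_variance(Wm @ alpha_M[:, t], vc["g_M"]) for t in range(T)]
    )
    g_F = np.column_stack(
        [_scale_to_variance(Wf @ alpha_F[:, t], vc["g_F"]) for t in range(T)]
    )

    # distinct crosses, then sliding-window environment sets with overlap
    n_overlap = round(config.overlap_fraction * config.n_hybrids_per_env)
    step = config.n_hybrids_per_env - n_overlap
    n_unique = config.n_hybrids_per_env + (config.n_environments - 1) * step
    all_pairs = [(m, f) for m in range(config.n_males) for f in range(config.n_females)]
    chosen = rng.choice(len(all_pairs), size=n_unique, replace=False)
    crosses = [all_pairs[i] for i in chosen]
    hybrid_ids = [f"H{i+1:04d}" for i in range(n_unique)]
    pedigree = HybridPedigree(
        hybrid_ids,
        [male_ids[m] for m, _ in crosses],
        [female_ids[f] for _, f in crosses],
    )
    env_ids = [f"E{e+1}" for e in range(config.n_environments)]
    env_sets = {
        env_ids[e]: hybrid_ids[e * step : e * step + config.n_hybrids_per_env]
        for e in range(config.n_environments)
    }

    G_M = compute_grm(male_markers)
    G_F = compute_grm(female_markers)
    H = sca_kernel(pedigree, G_M, G_F)
    h = np.column_stack(
        [_scale_to_variance(col, vc["h"])
         for col in _kernel_draw(rng, H.values, T).T]
    )

    env_eff = np.column_stack(
        [_scale_to_variance(rng.standard_normal(config.n_environments), vc["env"])
         for _ in range(T)]
    )

    # interactions: independent kernel draws per environment, then one global
    # rescale per trait so the stacked vector hits its variance component
    hyb_index = {hid: i for i, hid in enumerate(hybrid_ids)}
    male_index = {mid: i for i, mid in enumerate(male_ids)}
    female_index = {fid: i for i, fid in enumerate(female_ids)}
    uM_raw = np.stack(
        [_kernel_draw(rng, G_M.values, T) for _ in env_ids]
    )  # env x males x T
    uF_raw = np.stack([_kernel_draw(rng, G_F.values, T) for _ in env_ids])
    uH_raw: dict[str, np.ndarray] = {}
    for env in env_ids:
        idx = [hyb_index[hid] for hid in env_sets[env]]
        uH_raw[env] = _kernel_draw(rng, H.values[np.ix_(idx, idx)], T)

    rows = []
    for env_pos, env in enumerate(env_ids):
        for hyb_pos, hid in enumerate(env_sets[env]):
            m, f = crosses[hyb_index[hid]]
            for t in range(T):
                rows.append(
                    {
                        "hybrid": hid,
                        "environment": env,
                        "trait": traits[t],
                        "env_effect": env_eff[env_pos, t],
                        "g_M": g_M[m, t],
                        "g_F": g_F[f, t],
                        "h": h[hyb_index[hid], t],
                        "u_M": uM_raw[env_pos, m, t],
                        "u_F": uF_raw[env_pos, f, t],
                        "u_H": uH_raw[env][hyb_pos, t],
                    }
                )
    comp = pd.DataFrame(rows)
    for name in ("u_M", "u_F", "u_H"):
        for t in traits:
            sel = comp["trait"] == t
            comp.loc[sel, name] = _scale_to_variance(
                comp.loc[sel, name].to_numpy(), vc[name]
            )
    comp["residual"] = np.sqrt(vc["residual"]) * rng.standard_normal(len(comp))
    comp["genetic_value"] = (
        config.mu
        + comp[["env_effect", "g_M", "g_F", "h", "u_M", "u_F", "u_H"]].sum(axis=1)
    )
    comp["value"] = comp["genetic_value"] + comp["residual"]

    phenotypes = comp[["hybrid", "environment", "trait", "value"]].copy()

    # parental phenotypes: own additive value + measurement noise
    parent_rows = []
    sd_noise = np.sqrt(config.parental_noise_var)
    for i, pid in enumerate(male_ids):
        for t in range(T):
            parent_rows.append(
                {"parent_id": pid, "trait": traits[t],
                 "value": config.mu + g_M[i, t] + sd_noise * rng.standard_normal()}
            )
    for i, pid in enumerate(female_ids):
        for t in range(T):
            parent_rows.append(
                {"parent_id": pid, "trait": traits[t],
                 "value": config.mu + g_F[i, t] + sd_noise * rng.standard_normal()}
            )
    parental = ParentalPhenotypes(pd.DataFrame(parent_rows))

    truth = SynthTruth(
        g_M=pd.DataFrame(g_M, index=male_ids, columns=traits),
        g_F=pd.DataFrame(g_F, index=female_ids, columns=traits),
        h=pd.DataFrame(h, index=hybrid_ids, columns=traits),
        env_effects=pd.DataFrame(env_eff, index=env_ids, columns=traits),
        marker_effects_M=alpha_M,
        marker_effects_F=alpha_F,
        record_components=comp,
        variance_components=dict(vc),
    )
    return HybridDataset(
        male_markers=male_markers,
        female_markers=female_markers,
        pedigree=pedigree,
        phenotypes=phenotypes,
        parental_phenotypes=parental,
        traits=traits,
        truth=truth,
        config=config,
    )


def corrupt_markers(
    markers: MarkerMatrix, missing_rate: float, seed: int = 0
) -> MarkerMatrix:
    """Inject iid missingness (NaN) at the given rate; for QC testing."""
    if not 0.0 <= missing_rate < 1.0:
        raise SynthError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    dosages = markers.dosages.copy()
    hit = rng.random(dosages.shape) < missing_rate
    dosages[hit] = np.nan
    return MarkerMatrix(list(markers.line_ids), list(markers.marker_ids), dosages)
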