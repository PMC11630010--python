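"""Synthetic county tables with known correlation blocks and known effects.

The generator emulates the structure of county-level chronic-disease
surveillance data: ~3,000 county rows, disease prevalence columns on the
percent scale, block-correlated disease groups, and a linear dependence of
each disease on a small set of risk factors.

Model: risk factors are Gaussian on the percent scale (independent by
default, optionally correlated). Each disease is built from a standardized
latent variable

    y_d = sum_f beta_df * z(F_f) + e_d ,

where the residuals e are multivariate normal with unit-free block
correlation (within_block_r inside a block, between_block_r across blocks)
scaled by noise_sd, and the percent column is base_mean_d + base_sd_d * y_d,
clipped to [0, 100]. Clipping beyond 1% of cells aborts generation because
heavy clipping distorts the target correlations. A plain multivariate normal
(no copula) is deliberate: downstream analysis is correlation/OLS-based and
real prevalence columns are approximately continuous percentages.

Everything the pipeline is later asked to find is known here: the implied
disease correlation matrix, the implied standardized regression
coefficients, and a planted community cover (one community per disease
block, augmented with the factors that act on it).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .community import Community, CommunityCover
from .tables import PrevalenceTable, RiskFactorTable

DISEASES = [
    "arthritis", "asthma", "cancer", "chd", "ckd", "copd",
    "depression", "diabetes", "high_cholesterol", "hypertension",
    "obesity", "stroke",
]
FACTORS = [
    "minority", "ageing_population", "lacking_education", "poor_mental_health",
    "impoverishment", "uninsured", "smoking", "binge_drinking",
    "sleep_deficiency", "sedentary_behavior",
]

# percent-scale locations/spreads typical of US county surveillance tables
_DISEASE_STATS = {
    "arthritis": (23.9, 4.5), "asthma": (9.7, 1.5), "cancer": (6.1, 1.2),
    "chd": (6.3, 1.5), "ckd": (2.8, 0.6), "copd": (7.0, 2.2),
    "depression": (21.8, 3.5), "diabetes": (9.5, 2.5),
    "high_cholesterol": (29.6, 3.0), "hypertension": (31.7, 5.0),
    "obesity": (36.7, 4.0), "stroke": (3.0, 0.8),
}
# spreads for minority and lacking_education are tightened relative to the
# real tables: those distributions are heavily right-skewed, and a Gaussian
# at the real SD would clip >1% of cells at zero
_FACTOR_STATS = {
    "minority": (24.25, 10.0), "ageing_population": (19.23, 4.80),
    "lacking_education": (12.40, 5.0), "poor_mental_health": (15.73, 2.04),
    "impoverishment": (24.49, 8.50), "uninsured": (16.80, 6.61),
    "smoking": (20.04, 4.10), "binge_drinking": (17.84, 3.02),
    "sleep_deficiency": (34.47, 3.64), "sedentary_behavior": (25.71, 5.19),
}

_DEFAULT_BLOCKS = {
    "cardiometabolic_renal": ["diabetes", "ckd", "stroke", "hypertension"],
    "cardiovascular": ["chd", "high_cholesterol", "arthritis"],
    "respiratory_metabolic": ["asthma", "copd", "obesity"],
    "psychosocial": ["depression", "cancer"],
}
_DEFAULT_EFFECTS = {
    "diabetes": {"minority": 0.4, "sedentary_behavior": 0.35, "smoking": 0.3},
    "ckd": {"minority": 0.4, "sedentary_behavior": 0.35, "smoking": 0.3},
    "stroke": {"minority": 0.4, "sedentary_behavior": 0.35, "sleep_deficiency": 0.3},
    "hypertension": {"minority": 0.35, "sedentary_behavior": 0.3, "smoking": 0.3},
    "chd": {"smoking": 0.4, "poor_mental_health": 0.35},
    "high_cholesterol": {"smoking": 0.4, "poor_mental_health": 0.3},
    "arthritis": {"smoking": 0.35, "poor_mental_health": 0.35},
    "asthma": {"smoking": 0.35, "impoverishment": 0.3, "lacking_education": 0.3},
    "copd": {"smoking": 0.4, "impoverishment": 0.3, "lacking_education": 0.3},
    "obesity": {"smoking": 0.3, "impoverishment": 0.3, "binge_drinking": 0.3},
    "depression": {"poor_mental_health": 0.4, "ageing_population": 0.3, "sleep_deficiency": 0.3},
    "cancer": {"poor_mental_health": 0.35, "ageing_population": 0.3},
}


class GenerationError(ValueError):
    """The spec implies an invalid covariance or excessive clipping."""


@dataclass
class SyntheticSpec:
    n_counties: int = 3143
    disease_names: list = field(default_factory=lambda: list(DISEASES))
    factor_names: list = field(default_factory=lambda: list(FACTORS))
    #: block name -> disease members; a cover (overlap allowed), need not be a partition
    disease_blocks: dict = field(default_factory=lambda: {k: list(v) for k, v in _DEFAULT_BLOCKS.items()})
    #: residual correlation of same-block disease pairs
    within_block_r: float = 0.8
    #: residual correlation of cross-block pairs
    between_block_r: float = 0.05
    #: disease -> {factor: coefficient on the z-scored factor, latent scale}
    factor_effects: dict = field(default_factory=lambda: {d: dict(e) for d, e in _DEFAULT_EFFECTS.items()})
    noise_sd: float = 0.8
    base_mean: dict = field(default_factory=dict)
    base_sd: dict = field(default_factory=dict)
    #: optional factor correlation matrix (factor x factor, order of factor_names)
    factor_corr: np.ndarray | None = None
    rng_seed: int = 0
    max_clip_fraction: float = 0.01

    def __post_init__(self) -> None:
        if self.n_counties <= 0:
            raise GenerationError("n_counties must be positive")
        if not 0 < self.within_block_r < 1:
            raise GenerationError("within_block_r must lie in (0, 1)")
        if not 0 <= self.between_block_r < self.within_block_r:
            raise GenerationError("between_block_r must lie in [0, within_block_r)")
        if self.noise_sd <= 0:
            raise GenerationError("noise_sd must be positive")
        unknown = set(n for b in self.disease_blocks.values() for n in b) - set(self.disease_names)
        if unknown:
            raise GenerationError(f"blocks reference unknown diseases: {sorted(unknown)}")
        for d, eff in self.factor_effects.items():
            if d not in self.disease_names:
                raise GenerationError(f"factor_effects references unknown disease {d!r}")
            bad = set(eff) - set(self.factor_names)
            if bad:
                raise GenerationError(f"factor_effects[{d!r}] references unknown factors {sorted(bad)}")
        for name in self.disease_names:
            m, s = _DISEASE_STATS.get(name, (20.0, 4.0))
            self.base_mean.setdefault(name, m)
            self.base_sd.setdefault(name, s)
        for name in self.factor_names:
            m, s = _FACTOR_STATS.get(name, (20.0, 4.0))
            self.base_mean.setdefault(name, m)
            self.base_sd.setdefault(name, s)
        # fail early on an impossible residual correlation structure
        self.residual_corr()

    # -- implied quantities -------------------------------------------------

    def residual_corr(self) -> np.ndarray:
        d = len(self.disease_names)
        idx = {n: i for i, n in enumerate(self.disease_names)}
        r = np.full((d, d), self.between_block_r)
        for block, members in self.disease_blocks.items():
            for a in members:
                for b in members:
                    if a != b:
                        r[idx[a], idx[b]] = self.within_block_r
        np.fill_diagonal(r, 1.0)
        eig = np.linalg.eigvalsh(r)
        if eig.min() < -1e-10:
            raise GenerationError(
                "implied residual correlation is not positive semi-definite "
                f"(min eigenvalue {eig.min():.3g}); offending blocks: "
                f"{sorted(self.disease_blocks)}"
            )
        return r

    def _factor_corr(self) -> np.ndarray:
        p = len(self.factor_names)
        if self.factor_corr is None:
            return np.eye(p)
        rf = np.asarray(self.factor_corr, dtype=float)
        if rf.shape != (p, p):
            raise GenerationError(f"factor_corr must be {p}x{p}")
        if np.linalg.eigvalsh(rf).min() < -1e-10:
            raise GenerationError("factor_corr is not positive semi-definite")
        return rf

    def beta_matrix(self) -> np.ndarray:
        """diseases x factors matrix of latent-scale coefficients."""
        b = np.zeros((len(self.disease_names), len(self.factor_names)))
        fi = {n: i for i, n in enumerate(self.factor_names)}
        di = {n: i for i, n in enumerate(self.disease_names)}
        for d, eff in self.factor_effects.items():
            for f, beta in eff.items():
                b[di[d], fi[f]] = beta
        return b

    def implied_disease_cov(self) -> np.ndarray:
        b = self.beta_matrix()
        return b @ self._factor_corr() @ b.T + self.noise_sd**2 * self.residual_corr()

    def implied_disease_corr(self) -> pd.DataFrame:
        cov = self.implied_disease_cov()
        sd = np.sqrt(np.diag(cov))
        corr = cov / np.outer(sd, sd)
        return pd.DataFrame(corr, index=self.disease_names, columns=self.disease_names)

    def implied_standardized_effects(self) -> dict:
        """disease -> {factor: coefficient after z-scoring both sides}.

        The latent response has SD sqrt(beta' Rf beta + noise_sd^2); z-scoring
        divides every coefficient by it (the percent-scale affine map cancels).
        """
        b = self.beta_matrix()
        sd_lat = np.sqrt(np.diag(self.implied_disease_cov()))
        out: dict = {}
        for i, d in enumerate(self.disease_names):
            out[d] = {
                f: b[i, j] / sd_lat[i]
                for j, f in enumerate(self.factor_names)
                if b[i, j] != 0.0
            }
        return out

    # -- (de)serialization for the CLI -------------------------------------

    def to_dict(self) -> dict:
        out = {
            "n_counties": self.n_counties,
            "disease_names": self.disease_names,
            "factor_names": self.factor_names,
            "disease_blocks": self.disease_blocks,
            "within_block_r": self.within_block_r,
            "between_block_r": self.between_block_r,
            "factor_effects": self.factor_effects,
            "noise_sd": self.noise_sd,
            "base_mean": self.base_mean,
            "base_sd": self.base_sd,
            "rng_seed": self.rng_seed,
            "max_clip_fraction": self.max_clip_fraction,
        }
        if self.factor_corr is not None:
            out["factor_corr"] = np.asarray(self.factor_corr).tolist()
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        d = dict(d)
        if "factor_corr" in d and d["factor_corr"] is not None:
            d["factor_corr"] = np.asarray(d["factor_corr"], dtype=float)
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "SyntheticSpec":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class GroundTruth:
    true_correlation: pd.DataFrame          # implied disease correlation matrix
    latent_effects: dict                    # disease -> {factor: latent beta}
    standardized_effects: dict              # disease -> {factor: implied standardized beta}
    planted_communities: list               # list of frozensets over disease+factor labels
    clip_fraction: float = 0.0

    def planted_cover(self, alpha: float = 1.0) -> CommunityCover:
        comms = [Community(frozenset(s), 0.0, 0.0, 0.0) for s in self.planted_communities]
        return CommunityCover(comms, alpha=alpha)

    def to_dict(self) -> dict:
        return {
            "true_correlation": self.true_correlation.round(12).to_dict(),
            "latent_effects": self.latent_effects,
            "standardized_effects": self.standardized_effects,
            "planted_communities": [sorted(c) for c in self.planted_communities],
            "clip_fraction": self.clip_fraction,
        }


def planted_cover(spec: SyntheticSpec) -> CommunityCover:
    """One community per disease block, plus the factors acting on it.

    A factor joins every block in which it has a nonzero effect on at least
    one member disease; overlapping blocks put a disease in several
    communities, mirroring bridge diseases.
    """
    comms = []
    for block, members in spec.disease_blocks.items():
        nodes = set(members)
        for d in members:
            nodes.update(f for f, b in spec.factor_effects.get(d, {}).items() if b != 0.0)
        comms.append(Community(frozenset(nodes), 0.0, 0.0, 0.0))
    return CommunityCover(comms, alpha=1.0)


def generate(spec: SyntheticSpec) -> tuple[PrevalenceTable, RiskFactorTable, GroundTruth]:
    """Draw the two county tables and return them with their ground truth."""
    rng = np.random.default_rng(spec.rng_seed)
    n = spec.n_counties
    p, d = len(spec.factor_names), len(spec.disease_names)

    z_f = rng.standard_normal((n, p))
    rf = spec._factor_corr()
    if spec.factor_corr is not None:
        z_f = z_f @ np.linalg.cholesky(rf).T
    f_mean = np.array([spec.base_mean[f] for f in spec.factor_names])
    f_sd = np.array([spec.base_sd[f] for f in spec.factor_names])
    factors = f_mean + f_sd * z_f

    re = spec.residual_corr()
    # tiny jitter keeps the Cholesky factor defined at the PSD boundary
    chol = np.linalg.cholesky(re + 1e-12 * np.eye(d))
    resid = spec.noise_sd * (rng.standard_normal((n, d)) @ chol.T)
    latent = z_f @ spec.beta_matrix().T + resid
    d_mean = np.array([spec.base_mean[x] for x in spec.disease_names])
    d_sd = np.array([spec.base_sd[x] for x in spec.disease_names])
    diseases = d_mean + d_sd * latent

    clipped = 0
    for arr in (factors, diseases):
        clipped += int(((arr < 0) | (arr > 100)).sum())
    frac = clipped / (n * (p + d))
    if frac > spec.max_clip_fraction:
        raise GenerationError(
            f"{frac:.2%} of cells fall outside [0, 100] "
            f"(tolerance {spec.max_clip_fraction:.0%}); reduce base_sd or shift base_mean"
        )
    np.clip(factors, 0.0, 100.0, out=factors)
    np.clip(diseases, 0.0, 100.0, out=diseases)

    county_ids = [f"{i + 1:05d}" for i in range(n)]
    prev = PrevalenceTable(pd.DataFrame(diseases, index=county_ids, columns=spec.disease_names))
    fact = RiskFactorTable(pd.DataFrame(factors, index=county_ids, columns=spec.factor_names))
    truth = GroundTruth(
        true_correlation=spec.implied_disease_corr(),
        latent_effects={d_: dict(e) for d_, e in spec.factor_effects.items()},
        standardized_effects=spec.implied_standardized_effects(),
        planted_communities=[c.nodes for c in planted_cover(spec).communities],
        clip_fraction=frac,
    )
    return prev, fact, truth


def study_spec(n_counties: int = 3143, rng_seed: int = 0, **overrides) -> SyntheticSpec:
    """The default study-scale scenario: 12 diseases in 4 blocks, 10 factors."""
    return SyntheticSpec(n_counties=n_counties, rng_seed=rng_seed, **overrides)
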