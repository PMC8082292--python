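"""Synthetic multicenter cohorts with known causal structure.

The generator emulates the structure of a multicenter radiogenomics study:
a handful of environments (centers), each contributing a different number
of cases at a different outcome prevalence, and three kinds of features.

* **Causal** features carry the signal.  They are Gaussian with
  environment-specific means (covariate shift between scanners), and the
  binary outcome is drawn from a logistic model on them whose coefficients
  are FIXED across environments — so the conditional law outcome | causal
  is invariant while the marginal prevalence differs by center.
* **Spurious** features are consequences of the outcome whose edge
  strength gamma_e varies across environments (``gamma_e * y + noise``):
  predictive within any one environment, but with an environment-dependent
  relationship that an invariance test should reject.
* **Noise** features are independent of the outcome but carry
  per-environment location/scale batch effects, mimicking
  scanner-dependent feature distributions.

Defaults mirror the cohort this package is modelled on: four centers with
7/12/36/22 cases and wild-type prevalences 3/7, 1/12, 7/36, 15/22.
Dimensionality defaults are modest (3 causal, 5 spurious, 200 noise
features): the high-dimensional regime's structure rather than its
thousands-of-features scale; everything is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .datamodel import (
    VALID_REGIONS,
    VALID_SEQUENCES,
    CohortMetadata,
    FeatureTable,
)

#: Per-center case counts of the reference cohort.
DEFAULT_N_PER_ENV = (7, 12, 36, 22)
#: Per-center wild-type (positive-class) prevalences of the reference cohort.
DEFAULT_PREVALENCE_PER_ENV = (3 / 7, 1 / 12, 7 / 36, 15 / 22)

POSITIVE_LABEL = "wild-type"
NEGATIVE_LABEL = "mutant"

# E[sigmoid(Z)] for Z ~ N(mu, s^2) is well approximated by
# sigmoid(mu / sqrt(1 + c * s^2)) with c = pi^2 / 8 * (8 / pi^2) ... the
# standard logistic-probit matching constant (16 sqrt(3) / (15 pi))^2.
_PROBIT_MATCH = (16 * np.sqrt(3) / (15 * np.pi)) ** 2


@dataclass
class SyntheticConfig:
    """Parameters of the multicenter generator.

    Parameters
    ----------
    n_per_env
        Cases per environment.
    prevalence_per_env
        Target positive-class fraction per environment.  Realized via
        environment-specific mean shifts on the causal features (see
        ``causal_mean_shift_per_env``), never via per-environment
        intercepts, which would break the invariance the method assumes.
    k_causal, k_spurious, k_noise
        Feature counts per block.
    beta
        Logistic coefficients on the causal features, shared by all
        environments.  Length ``k_causal``; default all ones.
    intercept
        Shared intercept of the outcome model.
    causal_mean_shift_per_env
        Mean offset applied to every causal feature in each environment.
        When ``None`` (default) the shifts are solved from
        ``prevalence_per_env`` with a logistic-probit approximation, so the
        realized prevalences land near their targets.
    gamma_per_env
        Outcome-to-spurious edge strength per environment.  Distinct values
        make the spurious block non-invariant.
    batch_shift_scale
        Magnitude of per-environment location/scale perturbations on the
        noise block.  0 disables batch effects.
    seed
        Seed for the generator; same seed, bit-identical output.
    """

    n_per_env: Sequence[int] = DEFAULT_N_PER_ENV
    prevalence_per_env: Sequence[float] = DEFAULT_PREVALENCE_PER_ENV
    k_causal: int = 3
    k_spurious: int = 5
    k_noise: int = 200
    beta: Sequence[float] | None = None
    intercept: float = 0.0
    causal_mean_shift_per_env: Sequence[float] | None = None
    gamma_per_env: Sequence[float] | None = None
    batch_shift_scale: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        self.n_per_env = tuple(int(n) for n in self.n_per_env)
        n_env = len(self.n_per_env)
        if n_env < 1:
            raise ValueError("need at least one environment")
        if any(n <= 0 for n in self.n_per_env):
            raise ValueError("every environment needs at least one sample")
        if self.k_causal < 1:
            raise ValueError("k_causal must be >= 1")
        if min(self.k_spurious, self.k_noise) < 0:
            raise ValueError("feature counts must be >= 0")
        self.prevalence_per_env = tuple(float(p) for p in self.prevalence_per_env)
        if len(self.prevalence_per_env) != n_env:
            raise ValueError("prevalence_per_env length must match n_per_env")
        if any(not (0.0 < p < 1.0) for p in self.prevalence_per_env):
            raise ValueError("prevalences must lie strictly in (0, 1)")
        if self.beta is None:
            self.beta = tuple(1.0 for _ in range(self.k_causal))
        else:
            self.beta = tuple(float(b) for b in self.beta)
            if len(self.beta) != self.k_causal:
                raise ValueError("beta length must equal k_causal")
        if self.gamma_per_env is None:
            # distinct strengths so the spurious block is detectably non-invariant
            self.gamma_per_env = tuple(0.5 + 1.0 * e for e in range(n_env))
        else:
            self.gamma_per_env = tuple(float(g) for g in self.gamma_per_env)
            if len(self.gamma_per_env) != n_env:
                raise ValueError("gamma_per_env length must match n_per_env")
        if self.causal_mean_shift_per_env is None:
            self.causal_mean_shift_per_env = tuple(
                self._shift_for_prevalence(p) for p in self.prevalence_per_env
            )
        else:
            self.causal_mean_shift_per_env = tuple(
                float(m) for m in self.causal_mean_shift_per_env
            )
            if len(self.causal_mean_shift_per_env) != n_env:
                raise ValueError("causal_mean_shift_per_env length must match n_per_env")

    @property
    def n_env(self) -> int:
        return len(self.n_per_env)

    def _shift_for_prevalence(self, prevalence: float) -> float:
        """Mean shift m such that E[sigmoid(b0 + beta . x)] ~ prevalence
        when every causal feature has mean m and unit variance."""
        beta = np.asarray(self.beta)
        s2 = float(beta @ beta)
        target_mu = np.sqrt(1.0 + _PROBIT_MATCH * s2) * _logit(prevalence)
        total_beta = float(beta.sum())
        if total_beta == 0.0:
            raise ValueError(
                "cannot realize a prevalence via mean shifts when beta sums to 0; "
                "set causal_mean_shift_per_env explicitly"
            )
        return (target_mu - self.intercept) / total_beta


@dataclass
class GroundTruth:
    """Which generated feature is which, plus the parameters used."""

    causal_indices: list[int]
    spurious_indices: list[int]
    noise_indices: list[int]
    beta: tuple[float, ...]
    intercept: float
    causal_mean_shift_per_env: tuple[float, ...]
    gamma_per_env: tuple[float, ...]

    def __post_init__(self) -> None:
        blocks = [set(self.causal_indices), set(self.spurious_indices), set(self.noise_indices)]
        total = sum(len(b) for b in blocks)
        union = set().union(*blocks)
        if len(union) != total:
            raise ValueError("feature index blocks must be disjoint")
        if union != set(range(total)):
            raise ValueError("feature index blocks must cover 0..n_features-1")


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def _feature_names(k_causal: int, k_spurious: int, k_noise: int) -> list[str]:
    """Grammar-conformant synthetic names so the parser is exercised end-to-end."""
    filters = ("original", "wavelet.HL", "wavelet.LH", "log.sigma.2.mm.3D", "wavelet2.LL")
    classes = ("firstorder", "glcm", "glrlm", "glszm", "gldm")
    names = []
    for i in range(k_causal):
        names.append(
            f"{filters[i % len(filters)]}_firstorder_Causal{i}_"
            f"{VALID_SEQUENCES[i % len(VALID_SEQUENCES)]}_{VALID_REGIONS[i % len(VALID_REGIONS)]}"
        )
    for i in range(k_spurious):
        names.append(
            f"{filters[(i + 1) % len(filters)]}_glcm_Spurious{i}_"
            f"{VALID_SEQUENCES[i % len(VALID_SEQUENCES)]}_{VALID_REGIONS[i % len(VALID_REGIONS)]}"
        )
    for i in range(k_noise):
        names.append(
            f"{filters[i % len(filters)]}_{classes[i % len(classes)]}_Noise{i}_"
            f"{VALID_SEQUENCES[i % len(VALID_SEQUENCES)]}_{VALID_REGIONS[i % len(VALID_REGIONS)]}"
        )
    return names


def simulate_multicenter(
    config: SyntheticConfig,
) -> tuple[FeatureTable, CohortMetadata, GroundTruth]:
    """Draw one multicenter cohort from the generator.

    Deterministic given ``config.seed``.  Samples are ordered by
    environment; sample IDs are ``S0001``-style, environments ``center1``,
    ``center2``, ...
    """
    rng = np.random.default_rng(config.seed)
    k_c, k_s, k_n = config.k_causal, config.k_spurious, config.k_noise
    n_total = sum(config.n_per_env)
    beta = np.asarray(config.beta)

    X = np.empty((n_total, k_c + k_s + k_n))
    y = np.empty(n_total, dtype=int)
    env_labels: list[str] = []

    # batch-effect parameters for the noise block, one draw per (env, feature)
    loc = rng.normal(0.0, config.batch_shift_scale, size=(config.n_env, k_n))
    log_scale = rng.normal(0.0, config.batch_shift_scale / 2.0, size=(config.n_env, k_n))

    row = 0
    for e, n_e in enumerate(config.n_per_env):
        sl = slice(row, row + n_e)
        shift = config.causal_mean_shift_per_env[e]
        Xc = rng.normal(shift, 1.0, size=(n_e, k_c))
        eta = config.intercept + Xc @ beta
        y_e = (rng.random(n_e) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
        Xs = config.gamma_per_env[e] * y_e[:, None] + rng.normal(0.0, 1.0, size=(n_e, k_s))
        Xn = loc[e] + np.exp(log_scale[e]) * rng.normal(0.0, 1.0, size=(n_e, k_n))
        X[sl, :k_c] = Xc
        X[sl, k_c:k_c + k_s] = Xs
        X[sl, k_c + k_s:] = Xn
        y[sl] = y_e
        env_labels.extend([f"center{e + 1}"] * n_e)
        row += n_e

    sample_ids = [f"S{i + 1:04d}" for i in range(n_total)]
    table = FeatureTable(sample_ids, _feature_names(k_c, k_s, k_n), X)
    metadata = CohortMetadata(
        sample_ids=sample_ids,
        environment=env_labels,
        outcome=[POSITIVE_LABEL if v else NEGATIVE_LABEL for v in y],
        positive_class=POSITIVE_LABEL,
    )
    truth = GroundTruth(
        causal_indices=list(range(k_c)),
        spurious_indices=list(range(k_c, k_c + k_s)),
        noise_indices=list(range(k_c + k_s, k_c + k_s + k_n)),
        beta=tuple(config.beta),
        intercept=config.intercept,
        causal_mean_shift_per_env=tuple(config.causal_mean_shift_per_env),
        gamma_per_env=tuple(config.gamma_per_env),
    )
    return table, metadata, truth


def realized_prevalence(metadata: CohortMetadata) -> dict[str, float]:
    """Exact positive-class fraction per environment."""
    y = metadata.y
    env = metadata.env_array
    return {
        e: float(y[env == e].mean())
        for e in metadata.environments
    }
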