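"""Synthetic connectome cohort generator.

Emulates the statistical structure of a large healthy-young-adult cohort
(n = 655, 60% female, ages 18-35) with per-subject directed streamline
tallies over R parcels, demographic covariates and per-valence free-recall
counts.  The generator exists so that every downstream stage — connectome
construction, graph metrics, covariate-adjusted inference, mediation — can
be validated by parameter recovery against configured effect targets:

* an ICV-adjusted standardized sex difference in weighted transitivity
  (males higher, default d = 0.42),
* a negative age-transitivity correlation (default r = -0.23),
* a negative transitivity-memory partial correlation (default r = -0.12),
* a residual direct sex->memory effect (female advantage, default
  c' = -0.06 on the correlation scale with male coded 1),
* a strong sex-ICV correlation (default |r| = 0.69, males larger).

Mechanism: each subject's network is a mixture ``mix(alpha_i)`` between a
block-modular template ``W0`` and a triangle-enriched companion ``T0``; a
single latent clustering dial ``alpha_i = mix_base + lambda_i`` carries the
sex and age effects (lambda_i = beta_sex*male + beta_age*z_age + noise).
Sex and age therefore act globally, not edge-by-edge.  Multiplicative
log-normal edge noise and binomial streamline sampling
(``N_ij ~ Binomial(waytotal, W_i[i, j])`` per ordered pair) supply
within-subject measurement noise.  Recall counts are Binomial(24, p) per
valence with a logit-linear predictor embedding valence, sex, sex x valence,
recall-room batch and transitivity effects plus a subject-level random
intercept.

``calibrate_effects`` turns the effect-size targets into generator
coefficients.  The network path is solved in closed form from the template's
local transitivity slope and pilot-estimated noise variances; the memory
path (which is nonlinear through the logit link) is solved by secant search
on pilot simulations with common random numbers.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import root
from scipy.special import expit, logit
from scipy.stats import truncnorm

from .connectome import StreamlineTally
from .metrics import weighted_clustering

__all__ = [
    "CohortConfig",
    "Subject",
    "LatentNetworkModel",
    "EffectCoefficients",
    "CalibrationError",
    "make_template",
    "calibrate_effects",
    "generate_cohort",
    "cohort_to_frame",
    "write_cohort",
    "read_cohort",
]

VALENCES = ("negative", "neutral", "positive")

# Observed covariate structure of the emulated cohort: sex-specific age
# moments, ICV moments (arbitrary volume units), and hormonal-contraceptive /
# menstrual-cycle label frequencies among females.
_AGE_SD = {"female": 3.32, "male": 3.46}
_HC_PROBS = {"no": 155 / 391, "yes": 199 / 391, None: 37 / 391}
_MC_PROBS = {
    "first-half": 176 / 391,
    "second-half": 169 / 391,
    "no-cycle": 7 / 391,
    None: 39 / 391,
}


class CalibrationError(RuntimeError):
    """Raised when effect targets cannot be realized; carries a trace."""

    def __init__(self, message: str, trace: list[str] | None = None):
        super().__init__(message)
        self.trace = trace or []


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions of the simulated cohort.

    Effect-size targets follow the convention male = 1, so a positive
    ``d_transitivity`` means males have higher weighted transitivity, while
    ``icv_sex_r`` is the point-biserial correlation between the *female*
    indicator and ICV (negative: males have larger ICV).
    """

    n_subjects: int = 655
    prop_female: float = 0.60
    n_nodes: int = 82
    n_blocks: int = 7
    # demographics
    age_range: tuple[float, float] = (18.0, 35.0)
    age_mean: float = 22.9
    age_sex_gap: float = 0.64  # male minus female mean age, years
    icv_female_mean: float = 15.14
    icv_male_mean: float = 17.64
    icv_female_sd: float = 1.36
    icv_male_sd: float = 1.20
    icv_sex_r: float = -0.69
    prop_room2: float = 0.5
    # effect targets
    d_transitivity: float = 0.42
    r_age_transitivity: float = -0.23
    r_transitivity_memory: float = -0.12
    direct_sex_memory_r: float = -0.06
    # memory task: 24 pictures per valence; baseline expected recall counts,
    # female-advantage interaction pattern (counts, applied to females, mean
    # ~0 so the overall sex effect is carried by the calibrated direct term),
    # and the additive recall improvement in the quieter second recall room.
    n_pictures: int = 24
    memory_means: tuple[float, float, float] = (8.2, 5.6, 8.0)
    female_advantage: tuple[float, float, float] = (-0.05, -0.20, 0.25)
    batch_effect: float = 0.4
    subject_sd: float = 0.35  # logit-scale random intercept SD
    # latent network model
    w_within: float = 0.50
    w_between: float = 0.10
    template_jitter: float = 0.15
    mix_base: float = 0.40
    lambda_sd: float = 0.015
    edge_noise_sd: float = 0.10
    waytotal: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("age_range", "memory_means", "female_advantage"):
            object.__setattr__(self, name, tuple(getattr(self, name)))
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if not 0 < self.prop_female < 1:
            raise ValueError("prop_female must be in (0, 1)")
        if self.n_nodes < 3:
            raise ValueError("n_nodes must be >= 3")
        if self.waytotal < 1:
            raise ValueError("waytotal must be >= 1")
        for name in ("icv_sex_r", "r_age_transitivity", "r_transitivity_memory",
                     "direct_sex_memory_r"):
            if abs(getattr(self, name)) >= 1:
                raise ValueError(f"|{name}| must be < 1")
        if not 0 <= self.w_between <= self.w_within <= 1 or self.w_within == 0:
            raise ValueError("need 0 <= w_between <= w_within <= 1 with w_within > 0")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must be increasing")

    @property
    def prop_male(self) -> float:
        return 1.0 - self.prop_female

    def implied_mediation(self) -> dict[str, float]:
        """Paths implied by the configured targets on the correlation scale.

        With ``a`` the covariate-adjusted sex-transitivity correlation implied
        by ``d_transitivity`` (a and d describe the same partial association:
        d = a / (sqrt(1 - a^2) sqrt(p(1-p)))), the marginal
        transitivity-memory correlation r_tm = c'*a + b gives
        ``b = r_tm - a*c'`` and the indirect effect ``a*b``.
        """
        pq = self.prop_female * self.prop_male
        x = self.d_transitivity * np.sqrt(pq)
        a = x / np.sqrt(1.0 + x * x)
        b = self.r_transitivity_memory - a * self.direct_sex_memory_r
        return {
            "a": float(a),
            "b": float(b),
            "c_prime": float(self.direct_sex_memory_r),
            "indirect": float(a * b),
            "c": float(self.direct_sex_memory_r + a * b),
        }


@dataclass
class Subject:
    """One simulated participant."""

    id: str
    sex: str  # 'female' | 'male'
    age: float
    icv: float
    batch: str  # 'room1' | 'room2'
    hc_use: str | None  # 'no' | 'yes' | 'na' (males) | None (missing)
    mc_phase: str | None
    recall: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be 'female' or 'male', got {self.sex!r}")
        if self.sex == "male":
            if self.hc_use not in (None, "na") or self.mc_phase not in (None, "na"):
                raise ValueError("hc_use/mc_phase must be 'na' for males")
        for v, count in self.recall.items():
            if not (0 <= count <= 24 and float(count).is_integer()):
                raise ValueError(f"recall count for {v} out of range: {count}")


@dataclass
class LatentNetworkModel:
    """Block-modular template and its triangle-enriched companion.

    ``mix(alpha) = clip((1 - alpha) * W0 + alpha * T0, 0, 1)`` interpolates
    from the heterogeneous template toward the smoother, triangle-reinforced
    companion; weighted transitivity increases with alpha (checked
    numerically over the calibrated dial range).
    """

    w0: np.ndarray
    t0: np.ndarray
    blocks: np.ndarray

    def mix(self, alpha: float) -> np.ndarray:
        return np.clip((1.0 - alpha) * self.w0 + alpha * self.t0, 0.0, 1.0)

    def transitivity(self, alpha: float) -> float:
        return weighted_clustering(self.mix(alpha))[3]

    @property
    def n_nodes(self) -> int:
        return self.w0.shape[0]


def make_template(
    n_nodes: int,
    n_blocks: int = 7,
    w_within: float = 0.50,
    w_between: float = 0.10,
    seed: int | None = None,
    jitter: float = 0.15,
    rng: np.random.Generator | None = None,
) -> LatentNetworkModel:
    """Build the latent block-modular weight template.

    ``W0`` assigns level ``w_within`` to edges inside one of ``n_blocks``
    contiguous modules and ``w_between`` elsewhere, with multiplicative
    log-normal jitter (sd ``jitter``) for edge heterogeneity.  The companion
    ``T0`` is the elementwise geometric mean of ``W0`` and its two-step
    weighted-walk (triangle support) matrix, rescaled to max 1: edges that
    participate in strong triangles are up-weighted and the weight profile is
    smoothed, which raises transitivity when mixed in.
    """
    if not 0 <= w_between <= w_within <= 1 or w_within == 0:
        raise ValueError("need 0 <= w_between <= w_within <= 1 with w_within > 0")
    if n_blocks < 2:
        raise ValueError("n_blocks must be >= 2")
    if n_nodes < 3:
        raise ValueError("n_nodes must be >= 3")
    if rng is None:
        rng = np.random.default_rng(seed)
    blocks = np.sort(np.arange(n_nodes) % n_blocks)
    w0 = np.where(blocks[:, None] == blocks[None, :], w_within, w_between).astype(float)
    if jitter > 0:
        noise = np.exp(rng.normal(0.0, jitter, (n_nodes, n_nodes)))
        noise = np.sqrt(noise * noise.T)  # symmetric
        w0 = w0 * noise
    w0 = np.clip((w0 + w0.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(w0, 0.0)
    if not (w0 > 0).any():
        raise ValueError("degenerate template: all weights are zero")
    support = w0 @ w0
    t0 = np.sqrt(w0 * support)
    np.fill_diagonal(t0, 0.0)
    t0_max = t0.max()
    if t0_max <= 0:
        raise ValueError("degenerate template: no triangle support")
    t0 = t0 / t0_max
    return LatentNetworkModel(w0=w0, t0=t0, blocks=blocks)


@dataclass(frozen=True)
class EffectCoefficients:
    """Calibrated generator coefficients and the values they achieve."""

    beta_sex: float
    beta_age: float
    lambda_sd: float
    gamma_memory: float
    theta_sex: float
    t_mean: float       # mean latent transitivity at the base dial
    t_sd_latent: float  # SD of latent transitivity across subjects
    t_slope: float      # d transitivity / d dial at the base dial
    sd_edge_noise: float  # SD of transitivity from edge noise alone
    sd_binomial: float    # extra SD from binomial streamline sampling
    achieved: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# covariates


def _draw_covariates(cfg: CohortConfig, n: int, rng: np.random.Generator) -> pd.DataFrame:
    male = (rng.random(n) >= cfg.prop_female).astype(int)
    sex = np.where(male == 1, "male", "female")

    # sex-specific truncated-normal ages; group means offset by age_sex_gap
    # around the overall mean
    mean_f = cfg.age_mean - cfg.age_sex_gap * cfg.prop_male
    mean_m = mean_f + cfg.age_sex_gap
    age = np.empty(n)
    for is_male, mu, sd in ((0, mean_f, _AGE_SD["female"]), (1, mean_m, _AGE_SD["male"])):
        idx = male == is_male
        a, b = (cfg.age_range[0] - mu) / sd, (cfg.age_range[1] - mu) / sd
        age[idx] = truncnorm.rvs(a, b, loc=mu, scale=sd, size=idx.sum(), random_state=rng)

    # ICV from sex-conditional normals; within-group SDs rescaled so the
    # point-biserial sex-ICV correlation hits the configured target exactly
    gap = cfg.icv_male_mean - cfg.icv_female_mean
    r2 = cfg.icv_sex_r**2
    icv = np.empty(n)
    if r2 < 1e-12 or abs(gap) < 1e-12:
        pooled = cfg.prop_female * cfg.icv_female_mean + cfg.prop_male * cfg.icv_male_mean
        means = {0: pooled, 1: pooled}
        scale = 1.0
    else:
        between = cfg.prop_female * cfg.prop_male * gap**2
        within_target = between * (1.0 - r2) / r2
        within_given = (cfg.prop_female * cfg.icv_female_sd**2
                        + cfg.prop_male * cfg.icv_male_sd**2)
        scale = np.sqrt(within_target / within_given)
        means = {0: cfg.icv_female_mean, 1: cfg.icv_male_mean}
    for is_male, sd in ((0, cfg.icv_female_sd), (1, cfg.icv_male_sd)):
        idx = male == is_male
        icv[idx] = rng.normal(means[is_male], sd * scale, idx.sum())

    batch = np.where(rng.random(n) < cfg.prop_room2, "room2", "room1")

    hc = np.full(n, "na", dtype=object)
    mc = np.full(n, "na", dtype=object)
    females = np.flatnonzero(male == 0)
    hc_levels, hc_p = zip(*_HC_PROBS.items())
    mc_levels, mc_p = zip(*_MC_PROBS.items())
    hc[females] = rng.choice(np.array(hc_levels, dtype=object), size=females.size, p=hc_p)
    mc[females] = rng.choice(np.array(mc_levels, dtype=object), size=females.size, p=mc_p)

    return pd.DataFrame(
        {"sex": sex, "male": male, "age": age, "icv": icv, "batch": batch,
         "hc_use": hc, "mc_phase": mc}
    )


# ---------------------------------------------------------------------------
# recall counts


def _draw_recall(
    cfg: CohortConfig,
    cov: pd.DataFrame,
    t_std: np.ndarray,
    gamma_memory: float,
    theta_sex: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Binomial(24, p) recall counts per valence, logit-linear predictor."""
    n = len(cov)
    male = cov["male"].to_numpy()
    room2 = (cov["batch"] == "room2").to_numpy().astype(float)
    u = rng.normal(0.0, cfg.subject_sd, n)
    counts = np.empty((n, len(VALENCES)), dtype=int)
    for j, _v in enumerate(VALENCES):
        mu = (cfg.memory_means[j]
              + cfg.batch_effect * room2
              + cfg.female_advantage[j] * (1 - male))
        base = logit(np.clip(mu / cfg.n_pictures, 1e-4, 1 - 1e-4))
        eta = base + theta_sex * male + gamma_memory * t_std + u
        counts[:, j] = rng.binomial(cfg.n_pictures, expit(eta))
    return counts


# ---------------------------------------------------------------------------
# calibration


def _edge_noise(cfg: CohortConfig, r: int, rng: np.random.Generator) -> np.ndarray | None:
    """Symmetric multiplicative log-normal edge noise with unit mean."""
    if cfg.edge_noise_sd <= 0:
        return None
    sd = cfg.edge_noise_sd
    log_noise = rng.normal(-0.5 * sd * sd, sd, (r, r))
    return np.exp((log_noise + log_noise.T) / 2.0)


def _subject_weights(
    model: LatentNetworkModel, alpha: float, noise: np.ndarray | None
) -> np.ndarray:
    w = model.mix(alpha)
    if noise is not None:
        w = w * noise
    w = np.clip(w, 0.0, 1.0)
    np.fill_diagonal(w, 0.0)
    return w


def _simulate_subject_network(
    cfg: CohortConfig, model: LatentNetworkModel, alpha: float, rng: np.random.Generator
) -> tuple[np.ndarray, float]:
    """One subject's weight matrix (after edge noise) and latent transitivity."""
    w = _subject_weights(model, alpha, _edge_noise(cfg, model.n_nodes, rng))
    return w, weighted_clustering(w)[3]


def _measured_transitivity(
    cfg: CohortConfig, w: np.ndarray, rng: np.random.Generator
) -> float:
    counts = rng.binomial(cfg.waytotal, w)
    np.fill_diagonal(counts, 0)
    p = counts / float(cfg.waytotal)
    return weighted_clustering((p + p.T) / 2.0)[3]


def _estimate_noise_moments(
    cfg: CohortConfig,
    model: LatentNetworkModel,
    rng: np.random.Generator,
    n_noise: int,
    h: float = 0.03,
) -> tuple[float, float, float, float]:
    """Transitivity response moments under edge noise and binomial sampling.

    Returns ``(t_mean, g_eff, sd_edge, sd_binom)``.  The effective dial
    slope ``g_eff`` is the mean paired difference quotient
    ``(T(base + h) - T(base - h)) / 2h`` computed with the *same* edge-noise
    draw on both sides (common random numbers), because multiplicative edge
    noise shrinks the transitivity response relative to the noiseless
    template slope.
    """
    t_lat = np.empty(n_noise)
    t_meas = np.empty(n_noise)
    slopes = np.empty(n_noise)
    for i in range(n_noise):
        noise = _edge_noise(cfg, model.n_nodes, rng)
        w = _subject_weights(model, cfg.mix_base, noise)
        t_lat[i] = weighted_clustering(w)[3]
        t_meas[i] = _measured_transitivity(cfg, w, rng)
        t_plus = weighted_clustering(_subject_weights(model, cfg.mix_base + h, noise))[3]
        t_minus = weighted_clustering(_subject_weights(model, cfg.mix_base - h, noise))[3]
        slopes[i] = (t_plus - t_minus) / (2.0 * h)
    sd_edge = float(t_lat.std(ddof=1))
    sd_binom = float((t_meas - t_lat).std(ddof=1))
    return float(t_lat.mean()), float(slopes.mean()), sd_edge, sd_binom


def _solve_network_effects(
    cfg: CohortConfig,
    g: float,
    sd_meas_total: float,
    cov_moments: np.ndarray,
    trace: list[str],
) -> tuple[float, float, float, float]:
    """Closed-form dial coefficients hitting the d and r_age targets.

    ``cov_moments`` is the covariance matrix of (male, z_age, icv) estimated
    from a large covariate pilot.  The measured transitivity is locally
    linear in the dial, ``T = g * lambda + e``; its implied joint covariance
    with the covariates yields the ICV-adjusted partial correlation (hence
    Cohen's d) and the plain age correlation in closed form, which are solved
    for (beta_sex, beta_age).
    """
    v_x, v_z, v_icv = np.diag(cov_moments)
    c_xz, c_xicv, c_zicv = cov_moments[0, 1], cov_moments[0, 2], cov_moments[1, 2]
    pq = cfg.prop_female * cfg.prop_male
    var_e = sd_meas_total**2

    def implied(beta: np.ndarray) -> tuple[float, float]:
        bs, ba = beta
        var_lam = bs**2 * v_x + ba**2 * v_z + 2 * bs * ba * c_xz + cfg.lambda_sd**2
        var_t = g * g * var_lam + var_e
        cov_tx = g * (bs * v_x + ba * c_xz)
        cov_tz = g * (bs * c_xz + ba * v_z)
        cov_ticv = g * (bs * c_xicv + ba * c_zicv)
        sigma = np.array(
            [[var_t, cov_tx, cov_tz, cov_ticv],
             [cov_tx, v_x, c_xz, c_xicv],
             [cov_tz, c_xz, v_z, c_zicv],
             [cov_ticv, c_xicv, c_zicv, v_icv]]
        )
        prec = np.linalg.inv(sigma)
        r_p = -prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1])
        d = r_p / (np.sqrt(1 - r_p**2) * np.sqrt(pq))
        r_age = cov_tz / np.sqrt(var_t * v_z)
        return d, r_age

    def residual(beta: np.ndarray) -> np.ndarray:
        d, r_age = implied(beta)
        return np.array([d - cfg.d_transitivity, r_age - cfg.r_age_transitivity])

    sd_t0 = np.sqrt(g * g * cfg.lambda_sd**2 + var_e)
    x0 = np.array(
        [cfg.d_transitivity * sd_t0 / g, cfg.r_age_transitivity * sd_t0 / g]
    )
    sol = root(residual, x0, method="hybr")
    if not sol.success:
        raise CalibrationError(
            f"network effect calibration did not converge: {sol.message}", trace
        )
    beta_sex, beta_age = map(float, sol.x)
    d_chk, r_chk = implied(sol.x)
    trace.append(
        f"network solve: beta_sex={beta_sex:.5f} beta_age={beta_age:.5f} "
        f"implied d={d_chk:.4f} r_age={r_chk:.4f}"
    )
    # the dial must stay inside the locally-linear, monotone region
    dial_span = abs(beta_sex) + 3 * abs(beta_age) + 4 * cfg.lambda_sd
    if cfg.mix_base - dial_span < -0.05 or cfg.mix_base + dial_span > 1.05:
        raise CalibrationError(
            f"calibrated dial range exceeds the template's mixing range "
            f"(span {dial_span:.3f} around base {cfg.mix_base})",
            trace,
        )
    var_lam = (beta_sex**2 * v_x + beta_age**2 * v_z
               + 2 * beta_sex * beta_age * c_xz + cfg.lambda_sd**2)
    sd_t = float(np.sqrt(g * g * var_lam + var_e))
    return beta_sex, beta_age, sd_t, float(d_chk), float(r_chk)


def calibrate_effects(
    config: CohortConfig,
    n_pilot: int = 100_000,
    tolerance: float = 0.02,
    max_iter: int = 10,
    model: LatentNetworkModel | None = None,
    n_noise: int = 1000,
) -> EffectCoefficients:
    """Turn the configured effect targets into generator coefficients.

    The network path (``beta_sex``, ``beta_age``) is solved in closed form
    after estimating the template's transitivity slope (numeric derivative at
    the base dial) and the measurement-noise variance (``n_noise`` pilot
    subjects with edge noise and binomial streamline sampling).  The memory
    path (``gamma_memory`` for the transitivity-memory partial correlation,
    ``theta_sex`` for the residual direct sex effect) is solved by secant
    iteration on covariate-and-recall pilot simulations of size ``n_pilot``
    with common random numbers.  Raises :class:`CalibrationError` with a
    trace when a target cannot be reached within ``tolerance`` after
    ``max_iter`` secant steps.

    Exact-zero targets short-circuit to exactly-zero coefficients.
    """
    from .mediation import estimate_paths, residualize  # local: avoid cycle at import
    from .stats import partial_correlation

    trace: list[str] = []
    seed_root = np.random.SeedSequence([config.seed, 0x5EED])
    s_noise, s_cov, s_mem = seed_root.spawn(3)
    if model is None:
        model = make_template(
            config.n_nodes, config.n_blocks, config.w_within, config.w_between,
            jitter=config.template_jitter,
            rng=np.random.default_rng(np.random.SeedSequence([config.seed, 0x7E3])),
        )

    # noiseless template slope: sanity check that the dial raises transitivity
    h = 0.03
    g0 = (model.transitivity(config.mix_base + h)
          - model.transitivity(config.mix_base - h)) / (2 * h)
    if g0 <= 0:
        raise CalibrationError(
            "template transitivity is not increasing at the base dial", trace
        )
    t_mean, g, sd_edge, sd_binom = _estimate_noise_moments(
        config, model, np.random.default_rng(s_noise), n_noise, h=h
    )
    if g <= 0:
        raise CalibrationError(
            "effective transitivity slope under edge noise is not positive", trace
        )
    sd_meas = float(np.hypot(sd_edge, sd_binom))
    trace.append(
        f"template slope g0={g0:.5f}, effective g={g:.5f}; t_mean={t_mean:.5f} "
        f"sd_edge={sd_edge:.3e} sd_binom={sd_binom:.3e}"
    )

    # large covariate pilot for the joint (male, z_age, icv) moments
    cov_pilot = _draw_covariates(config, 200_000, np.random.default_rng(s_cov))
    z_age = (cov_pilot["age"] - cov_pilot["age"].mean()) / cov_pilot["age"].std()
    mom = np.cov(
        np.vstack([cov_pilot["male"].to_numpy(dtype=float), z_age.to_numpy(),
                   cov_pilot["icv"].to_numpy()])
    )

    if config.d_transitivity == 0 and config.r_age_transitivity == 0:
        beta_sex = beta_age = 0.0
        implied_d = implied_r_age = 0.0
        sd_t = float(np.sqrt(g * g * config.lambda_sd**2 + sd_meas**2))
        trace.append("null network targets: beta_sex = beta_age = 0")
    else:
        beta_sex, beta_age, sd_t, implied_d, implied_r_age = _solve_network_effects(
            config, g, sd_meas, mom, trace
        )
    sd_t_latent = float(np.sqrt(max(sd_t**2 - sd_binom**2, 1e-18)))

    # ---- memory path: secant search on pilot simulations -------------------
    mem_seed = int(s_mem.generate_state(1)[0] % (2**31))
    age_mu, age_sd = float(cov_pilot["age"].mean()), float(cov_pilot["age"].std())
    pilot_cov = _draw_covariates(config, n_pilot, np.random.default_rng(mem_seed))
    z = ((pilot_cov["age"] - age_mu) / age_sd).to_numpy()
    male = pilot_cov["male"].to_numpy(dtype=float)

    def pilot_measures(gamma: float, theta: float) -> tuple[float, float]:
        rng = np.random.default_rng(mem_seed + 1)  # common random numbers
        lam = beta_sex * male + beta_age * z + rng.normal(0, config.lambda_sd, n_pilot)
        t_latent = t_mean + g * lam + rng.normal(0, sd_edge, n_pilot)
        t_meas = t_latent + rng.normal(0, sd_binom, n_pilot)
        t_std = (t_latent - t_mean) / sd_t_latent
        counts = _draw_recall(config, pilot_cov, t_std, gamma, theta, rng)
        total = counts.sum(axis=1).astype(float)
        covars = np.column_stack(
            [pilot_cov["age"], (pilot_cov["batch"] == "room2").astype(float),
             pilot_cov["icv"]]
        )
        r_tm, _ = partial_correlation(t_meas, total, covars)
        xr, mr, yr = residualize(
            np.column_stack([male, t_meas, total]), covars
        ).T
        paths = estimate_paths(xr, mr, yr)
        return float(r_tm), float(paths["c_prime"])

    # derivative-based initial guesses from a gamma = theta = 0 pilot
    rng0 = np.random.default_rng(mem_seed + 1)
    base_counts = _draw_recall(config, pilot_cov, np.zeros(n_pilot), 0.0, 0.0, rng0)
    sd_total0 = float(base_counts.sum(axis=1).std())
    p_v = np.asarray(config.memory_means) / config.n_pictures
    deta = float(np.sum(config.n_pictures * p_v * (1 - p_v)))  # d total / d eta
    pq = config.prop_female * config.prop_male

    gamma = 0.0 if config.r_transitivity_memory == 0 else \
        config.r_transitivity_memory * sd_total0 / deta
    theta = 0.0 if config.direct_sex_memory_r == 0 else \
        config.direct_sex_memory_r * sd_total0 / (deta * np.sqrt(pq))

    if config.r_transitivity_memory == 0 and config.direct_sex_memory_r == 0:
        # exact-zero targets: the null predictor is the exact solution
        achieved_r_tm, achieved_cp = pilot_measures(0.0, 0.0)
        trace.append("null memory targets: gamma = theta = 0")
        max_iter = 0
    else:
        achieved_r_tm, achieved_cp = pilot_measures(gamma, theta)
    # a pilot correlation cannot be solved below its own Monte-Carlo noise
    tol_eff = max(tolerance / 2, 3.0 / np.sqrt(n_pilot))
    converged = (config.r_transitivity_memory == 0
                 and config.direct_sex_memory_r == 0)
    for sweep in range(max_iter):
        err_r = achieved_r_tm - config.r_transitivity_memory
        err_c = achieved_cp - config.direct_sex_memory_r
        trace.append(
            f"memory sweep {sweep}: gamma={gamma:.5f} theta={theta:.5f} "
            f"r_tm={achieved_r_tm:.4f} c'={achieved_cp:.4f}"
        )
        if abs(err_r) <= tol_eff and abs(err_c) <= tol_eff:
            converged = True
            break
        if config.r_transitivity_memory != 0 or gamma != 0:
            step = max(abs(gamma), 0.01) * 0.25
            r_hi, _ = pilot_measures(gamma + step, theta)
            slope = (r_hi - achieved_r_tm) / step
            if abs(slope) > 1e-8:
                gamma -= err_r / slope
        if config.direct_sex_memory_r != 0 or theta != 0:
            step = max(abs(theta), 0.01) * 0.25
            _, c_hi = pilot_measures(gamma, theta + step)
            slope = (c_hi - achieved_cp) / step
            if abs(slope) > 1e-8:
                theta -= err_c / slope
        achieved_r_tm, achieved_cp = pilot_measures(gamma, theta)
    if not converged:
        raise CalibrationError(
            f"memory calibration did not reach tolerance {tolerance} in "
            f"{max_iter} sweeps (r_tm={achieved_r_tm:.4f}, c'={achieved_cp:.4f})",
            trace,
        )

    achieved = {
        "d_transitivity": implied_d,
        "r_age_transitivity": implied_r_age,
        "r_transitivity_memory": achieved_r_tm,
        "direct_sex_memory_r": achieved_cp,
    }
    return EffectCoefficients(
        beta_sex=beta_sex,
        beta_age=beta_age,
        lambda_sd=config.lambda_sd,
        gamma_memory=float(gamma),
        theta_sex=float(theta),
        t_mean=t_mean,
        t_sd_latent=sd_t_latent,
        t_slope=float(g),
        sd_edge_noise=sd_edge,
        sd_binomial=sd_binom,
        achieved=achieved,
    )


# ---------------------------------------------------------------------------
# cohort generation


def generate_cohort(
    config: CohortConfig,
    model: LatentNetworkModel | None = None,
    coefficients: EffectCoefficients | None = None,
) -> tuple[list[Subject], list[StreamlineTally]]:
    """Simulate a full cohort of subjects and their streamline tallies.

    Deterministic given ``config.seed``.  ``model`` and ``coefficients`` may
    be passed in to reuse a template and calibration across replicate cohorts
    (replicates then differ only in their subject-level randomness — change
    ``seed`` via :func:`dataclasses.replace` for each replicate).
    """
    if model is None:
        model = make_template(
            config.n_nodes, config.n_blocks, config.w_within, config.w_between,
            jitter=config.template_jitter,
            rng=np.random.default_rng(np.random.SeedSequence([config.seed, 0x7E3])),
        )
    if model.n_nodes != config.n_nodes:
        raise ValueError("template size does not match config.n_nodes")
    if coefficients is None:
        coefficients = calibrate_effects(config, model=model)

    seed_root = np.random.SeedSequence([config.seed, 0xC0F0])
    s_cov, s_net, s_rec = seed_root.spawn(3)
    n = config.n_subjects
    cov = _draw_covariates(config, n, np.random.default_rng(s_cov))
    z_age = ((cov["age"] - cov["age"].mean()) / cov["age"].std()).to_numpy()
    male = cov["male"].to_numpy(dtype=float)

    rng_net = np.random.default_rng(s_net)
    lam = (coefficients.beta_sex * male + coefficients.beta_age * z_age
           + rng_net.normal(0.0, coefficients.lambda_sd, n))
    tallies: list[StreamlineTally] = []
    t_latent = np.empty(n)
    waytotal = np.full(config.n_nodes, config.waytotal, dtype=int)
    for i in range(n):
        w, t_latent[i] = _simulate_subject_network(
            config, model, config.mix_base + lam[i], rng_net
        )
        counts = rng_net.binomial(config.waytotal, w)
        np.fill_diagonal(counts, 0)
        tallies.append(
            StreamlineTally(counts=counts, waytotal=waytotal.copy(),
                            subject_id=f"s{i:04d}")
        )

    t_std = (t_latent - coefficients.t_mean) / coefficients.t_sd_latent
    recall = _draw_recall(
        config, cov, t_std, coefficients.gamma_memory, coefficients.theta_sex,
        np.random.default_rng(s_rec),
    )

    subjects = []
    for i in range(n):
        row = cov.iloc[i]
        hc = row["hc_use"] if isinstance(row["hc_use"], str) else None
        mc = row["mc_phase"] if isinstance(row["mc_phase"], str) else None
        subjects.append(
            Subject(
                id=f"s{i:04d}",
                sex=row["sex"],
                age=float(row["age"]),
                icv=float(row["icv"]),
                batch=row["batch"],
                hc_use=hc,
                mc_phase=mc,
                recall={v: int(recall[i, j]) for j, v in enumerate(VALENCES)},
            )
        )
    return subjects, tallies


def cohort_to_frame(subjects: list[Subject]) -> pd.DataFrame:
    """Flat covariate-and-recall table, one row per subject."""
    rows = []
    for s in subjects:
        rows.append(
            {
                "id": s.id, "sex": s.sex, "age": s.age, "icv": s.icv,
                "batch": s.batch, "hc_use": s.hc_use, "mc_phase": s.mc_phase,
                "recall_neg": s.recall.get("negative"),
                "recall_neu": s.recall.get("neutral"),
                "recall_pos": s.recall.get("positive"),
            }
        )
    df = pd.DataFrame(rows)
    df["male"] = (df["sex"] == "male").astype(int)
    df["recall_total"] = df[["recall_neg", "recall_neu", "recall_pos"]].sum(axis=1)
    return df


# ---------------------------------------------------------------------------
# cohort I/O

_COHORT_COLUMNS = ["id", "sex", "age", "icv", "batch", "hc_use", "mc_phase",
                   "recall_neg", "recall_neu", "recall_pos"]


def write_cohort(
    subjects: list[Subject], tallies: list[StreamlineTally], directory: str | Path
) -> None:
    """Write cohort CSV, subject manifest and per-subject tally files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    df = cohort_to_frame(subjects)[_COHORT_COLUMNS]
    df.to_csv(directory / "cohort.csv", index=False)
    with open(directory / "manifest.txt", "w") as fh:
        for t in tallies:
            fh.write(t.subject_id + "\n")
    for t in tallies:
        np.savetxt(directory / f"{t.subject_id}_counts.tsv", t.counts,
                   fmt="%d", delimiter="\t")
        np.savetxt(directory / f"{t.subject_id}_waytotal.tsv",
                   t.waytotal[None, :], fmt="%d", delimiter="\t")


def read_cohort(directory: str | Path) -> tuple[list[Subject], list[StreamlineTally]]:
    """Read a cohort written by :func:`write_cohort` (round-trip identity)."""
    directory = Path(directory)
    cohort_file = directory / "cohort.csv"
    manifest_file = directory / "manifest.txt"
    if not cohort_file.exists() or not manifest_file.exists():
        raise FileNotFoundError(
            f"{directory} is not a cohort directory (missing cohort.csv/manifest.txt)"
        )
    df = pd.read_csv(cohort_file)
    missing_cols = set(_COHORT_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"cohort.csv is missing columns: {sorted(missing_cols)}")
    subjects = []
    for i, row in df.iterrows():
        try:
            subjects.append(
                Subject(
                    id=str(row["id"]), sex=row["sex"], age=float(row["age"]),
                    icv=float(row["icv"]), batch=row["batch"],
                    hc_use=row["hc_use"] if isinstance(row["hc_use"], str) else None,
                    mc_phase=row["mc_phase"] if isinstance(row["mc_phase"], str) else None,
                    recall={
                        "negative": int(row["recall_neg"]),
                        "neutral": int(row["recall_neu"]),
                        "positive": int(row["recall_pos"]),
                    },
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"cohort.csv row {i} (id={row.get('id')}): {exc}") from exc
    ids = [line.strip() for line in manifest_file.read_text().splitlines() if line.strip()]
    tallies = []
    for sid in ids:
        counts_file = directory / f"{sid}_counts.tsv"
        way_file = directory / f"{sid}_waytotal.tsv"
        for f in (counts_file, way_file):
            if not f.exists():
                raise FileNotFoundError(f"missing tally file {f.name}")
        try:
            counts = np.loadtxt(counts_file, dtype=int, ndmin=2)
            waytotal = np.loadtxt(way_file, dtype=int, ndmin=1).ravel()
            if counts.shape[0] != counts.shape[1]:
                raise ValueError(f"non-square matrix of shape {counts.shape}")
            tallies.append(StreamlineTally(counts=counts, waytotal=waytotal, subject_id=sid))
        except ValueError as exc:
            raise ValueError(f"malformed tally file for subject {sid}: {exc}") from exc
    return subjects, tallies
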