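"""Mediation of the sex->memory effect by a connectome measure.

Simple three-variable mediation: sex (x, female = 0 / male = 1) ->
weighted transitivity (mediator m) -> recall performance (y).  Nuisance
covariates (age, recall-room batch, ICV) are removed once, on the full
sample, by taking least-squares residuals; residualized variables are
standardized, so every path is reported on the correlation (r) scale:

* ``a`` — effect of x on m (a point-biserial-type correlation),
* ``b`` — effect of m on y adjusted for x,
* ``c`` — total effect of x on y,
* ``c'`` — direct effect of x on y adjusted for m,
* indirect effect = ``a * b``; mediation strength = ``(a * b) / c'``.

Inference for the indirect effect and the ratio uses the bias-corrected and
accelerated (BCa) bootstrap: subjects are resampled with replacement, the
paths recomputed per draw (with per-draw standardization, so the statistic
is scale-free), the bias correction ``z0`` comes from the fraction of
bootstrap statistics below the point estimate and the acceleration from the
jackknife skewness formula.  Residualization is performed once on the full
sample by default (matching a residual-based analysis setup); per-draw
re-residualization is available via ``residualize_per_draw``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "MediationResult",
    "residualize",
    "estimate_paths",
    "bca_bootstrap",
    "run_mediation",
]

DEFAULT_LEVELS = (95.0, 99.0, 99.5)


@dataclass
class MediationResult:
    """Mediation paths on the r scale with BCa bootstrap intervals."""

    a: float
    b: float
    c: float
    c_prime: float
    indirect: float
    ratio: float
    n: int
    b_boot: int = 0
    ci_indirect: dict[float, tuple[float, float]] = field(default_factory=dict)
    ci_ratio: dict[float, tuple[float, float]] = field(default_factory=dict)
    z0_indirect: float = np.nan
    accel_indirect: float = np.nan
    z0_ratio: float = np.nan
    accel_ratio: float = np.nan
    significant: dict[float, bool] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"quantity": "a", "estimate": self.a},
            {"quantity": "b", "estimate": self.b},
            {"quantity": "c", "estimate": self.c},
            {"quantity": "c_prime", "estimate": self.c_prime},
            {"quantity": "indirect", "estimate": self.indirect},
            {"quantity": "ratio", "estimate": self.ratio},
        ]
        df = pd.DataFrame(rows)
        for level in sorted(self.ci_indirect):
            lo, hi = self.ci_indirect[level]
            df.loc[df["quantity"] == "indirect", f"lo{level:g}"] = lo
            df.loc[df["quantity"] == "indirect", f"hi{level:g}"] = hi
        for level in sorted(self.ci_ratio):
            lo, hi = self.ci_ratio[level]
            df.loc[df["quantity"] == "ratio", f"lo{level:g}"] = lo
            df.loc[df["quantity"] == "ratio", f"hi{level:g}"] = hi
        return df


def residualize(variables: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """Residualize columns on covariates (plus intercept), then standardize.

    Returns an array of the same shape whose columns are least-squares
    residuals scaled to unit variance — the correlation scale on which all
    mediation paths live.  Raises on rank-deficient covariate designs and on
    zero-variance residuals.
    """
    v = np.asarray(variables, dtype=float)
    if v.ndim == 1:
        v = v[:, None]
    n = v.shape[0]
    if covariates is None or (hasattr(covariates, "size") and covariates.size == 0):
        z = np.ones((n, 1))
    else:
        c = np.asarray(covariates, dtype=float)
        if c.ndim == 1:
            c = c[:, None]
        z = np.column_stack([np.ones(n), c])
    if np.linalg.matrix_rank(z) < z.shape[1]:
        raise ValueError("covariate design is rank deficient")
    resid = v - z @ np.linalg.lstsq(z, v, rcond=None)[0]
    sd = resid.std(axis=0)
    floor = 1e-10 * np.maximum(v.std(axis=0), 1e-300)
    if np.any(sd <= floor) or np.any(~np.isfinite(sd)):
        bad = np.flatnonzero((sd <= floor) | ~np.isfinite(sd))
        raise ValueError(
            f"zero-variance residuals in column(s) {bad.tolist()}; "
            "variable is fully explained by the covariates"
        )
    return resid / sd


def _paths_from_moments(
    r_xm: np.ndarray, r_xy: np.ndarray, r_my: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Standardized paths from the three pairwise correlations."""
    det = 1.0 - r_xm**2
    a = r_xm
    b = (r_my - r_xy * r_xm) / det
    c_prime = (r_xy - r_my * r_xm) / det
    c = r_xy
    return a, b, c, c_prime


def _corr_rows(x: np.ndarray, m: np.ndarray, y: np.ndarray):
    """Row-wise pairwise correlations for (draws, n) arrays."""
    def std_rows(v):
        mu = v.mean(axis=-1, keepdims=True)
        sd = v.std(axis=-1, keepdims=True)
        return (v - mu) / sd

    xs, ms, ys = std_rows(x), std_rows(m), std_rows(y)
    n = x.shape[-1]
    r_xm = np.einsum("...i,...i->...", xs, ms) / n
    r_xy = np.einsum("...i,...i->...", xs, ys) / n
    r_my = np.einsum("...i,...i->...", ms, ys) / n
    return r_xm, r_xy, r_my


def estimate_paths(x: np.ndarray, m: np.ndarray, y: np.ndarray) -> dict[str, float]:
    """Point estimates of all mediation paths on the r scale.

    Inputs are the residualized variables; they are (re-)standardized here so
    the estimate is scale-invariant.  The decomposition ``c = c' + a*b``
    holds exactly.  A direct effect near zero makes the ratio ``a*b/c'``
    numerically unstable; it is still returned, with a warning.
    """
    x = np.asarray(x, float).ravel()
    m = np.asarray(m, float).ravel()
    y = np.asarray(y, float).ravel()
    if not (len(x) == len(m) == len(y)):
        raise ValueError("x, m, y must have equal lengths")
    for name, v in (("x", x), ("m", m), ("y", y)):
        if v.std() == 0:
            raise ValueError(f"variable {name} has zero variance")
    r_xm, r_xy, r_my = _corr_rows(x, m, y)
    a, b, c, c_prime = _paths_from_moments(r_xm, r_xy, r_my)
    indirect = a * b
    if abs(c_prime) < 1e-2:
        warnings.warn(
            "direct effect c' is near zero; the indirect/direct ratio is unstable",
            RuntimeWarning,
            stacklevel=2,
        )
    ratio = indirect / c_prime if c_prime != 0 else np.inf * np.sign(indirect)
    return {
        "a": float(a), "b": float(b), "c": float(c), "c_prime": float(c_prime),
        "indirect": float(indirect), "ratio": float(ratio),
    }


def _jackknife_stats(x: np.ndarray, m: np.ndarray, y: np.ndarray):
    """Leave-one-out indirect effects and ratios via sum updates."""
    n = len(x)
    sums = {}
    for name, v in (("x", x), ("m", m), ("y", y)):
        sums[name] = v.sum()
    prods = {
        "xx": x * x, "mm": m * m, "yy": y * y,
        "xm": x * m, "xy": x * y, "my": m * y,
    }
    totals = {k: v.sum() for k, v in prods.items()}
    n1 = n - 1

    def loo_corr(sa, sb, sab, saa, sbb, a_i, b_i, ab_i, aa_i, bb_i):
        sa_, sb_ = sa - a_i, sb - b_i
        cov = (sab - ab_i) - sa_ * sb_ / n1
        va = (saa - aa_i) - sa_**2 / n1
        vb = (sbb - bb_i) - sb_**2 / n1
        return cov / np.sqrt(va * vb)

    r_xm = loo_corr(sums["x"], sums["m"], totals["xm"], totals["xx"], totals["mm"],
                    x, m, prods["xm"], prods["xx"], prods["mm"])
    r_xy = loo_corr(sums["x"], sums["y"], totals["xy"], totals["xx"], totals["yy"],
                    x, y, prods["xy"], prods["xx"], prods["yy"])
    r_my = loo_corr(sums["m"], sums["y"], totals["my"], totals["mm"], totals["yy"],
                    m, y, prods["my"], prods["mm"], prods["yy"])
    a, b, c, c_prime = _paths_from_moments(r_xm, r_xy, r_my)
    indirect = a * b
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(c_prime != 0, indirect / c_prime, np.nan)
    return indirect, ratio


def _accel(jack: np.ndarray) -> float:
    jack = jack[np.isfinite(jack)]
    if len(jack) < 3:
        return 0.0
    dev = jack.mean() - jack
    denom = 6.0 * (dev**2).sum() ** 1.5
    if denom == 0:
        return 0.0
    return float((dev**3).sum() / denom)


def _bca_from_boots(
    point: dict[str, float],
    boot_ind: np.ndarray,
    boot_ratio: np.ndarray,
    jack_ind: np.ndarray,
    jack_ratio: np.ndarray,
    levels: tuple[float, ...],
    n: int,
    b_boot: int,
) -> MediationResult:
    """Assemble BCa intervals from bootstrap and jackknife replicates."""
    warn: list[str] = []
    result = MediationResult(
        a=point["a"], b=point["b"], c=point["c"], c_prime=point["c_prime"],
        indirect=point["indirect"], ratio=point["ratio"], n=n, b_boot=b_boot,
    )
    for stat_name, boots, jack, pt, ci_store in (
        ("indirect", boot_ind, jack_ind, point["indirect"], result.ci_indirect),
        ("ratio", boot_ratio, jack_ratio, point["ratio"], result.ci_ratio),
    ):
        finite = boots[np.isfinite(boots)]
        if len(finite) == 0 or np.ptp(finite) == 0:
            raise ValueError(f"bootstrap distribution of {stat_name} is degenerate")
        prop = float(np.mean(finite < pt))
        if prop in (0.0, 1.0):
            warn.append(
                f"z0 for {stat_name} clamped: bootstrap distribution entirely "
                f"{'above' if prop == 0.0 else 'below'} the point estimate"
            )
            prop = min(max(prop, 1.0 / (len(finite) + 1)),
                       1.0 - 1.0 / (len(finite) + 1))
        z0 = float(norm.ppf(prop))
        acc = _accel(jack)
        for level in levels:
            alpha = (1.0 - level / 100.0) / 2.0
            adj = []
            for z_alpha in (norm.ppf(alpha), norm.ppf(1.0 - alpha)):
                zt = z0 + (z0 + z_alpha) / (1.0 - acc * (z0 + z_alpha))
                adj.append(float(np.clip(norm.cdf(zt), 0.0, 1.0)))
            lo, hi = np.percentile(finite, [100 * adj[0], 100 * adj[1]])
            ci_store[level] = (float(lo), float(hi))
        if stat_name == "indirect":
            result.z0_indirect, result.accel_indirect = z0, acc
        else:
            result.z0_ratio, result.accel_ratio = z0, acc
    for level in levels:
        lo, hi = result.ci_indirect[level]
        result.significant[level] = bool(lo > 0.0 or hi < 0.0)
    result.warnings = warn
    return result


def bca_bootstrap(
    x: np.ndarray,
    m: np.ndarray,
    y: np.ndarray,
    b_boot: int = 10_000,
    levels: tuple[float, ...] = DEFAULT_LEVELS,
    rng: np.random.Generator | int | None = None,
    chunk: int = 2000,
) -> MediationResult:
    """BCa bootstrap confidence intervals for the indirect effect and ratio.

    Subjects are resampled with replacement ``b_boot`` times (>= 1000
    required); the paths are recomputed per draw with per-draw
    standardization.  For each statistic the bias correction ``z0`` is
    ``Phi^-1`` of the fraction of bootstrap values below the point estimate
    (clamped with a warning when the fraction is 0 or 1) and the
    acceleration comes from the jackknife skewness formula; both adjust the
    percentile endpoints.  Significance per level means the interval for the
    indirect effect excludes zero.  Fully deterministic given ``rng``.
    """
    if b_boot < 1000:
        raise ValueError("b_boot must be >= 1000 for stable BCa intervals")
    rng = np.random.default_rng(rng)
    x = np.asarray(x, float).ravel()
    m = np.asarray(m, float).ravel()
    y = np.asarray(y, float).ravel()
    n = len(x)
    point = estimate_paths(x, m, y)

    boot_ind = np.empty(b_boot)
    boot_ratio = np.empty(b_boot)
    done = 0
    while done < b_boot:
        size = min(chunk, b_boot - done)
        idx = rng.integers(0, n, size=(size, n))
        r_xm, r_xy, r_my = _corr_rows(x[idx], m[idx], y[idx])
        a, b, c, c_prime = _paths_from_moments(r_xm, r_xy, r_my)
        boot_ind[done:done + size] = a * b
        with np.errstate(divide="ignore", invalid="ignore"):
            boot_ratio[done:done + size] = np.where(c_prime != 0, a * b / c_prime, np.nan)
        done += size

    jack_ind, jack_ratio = _jackknife_stats(x, m, y)
    return _bca_from_boots(point, boot_ind, boot_ratio, jack_ind, jack_ratio,
                           levels, n, b_boot)


def run_mediation(
    cohort: pd.DataFrame,
    metric: pd.Series | np.ndarray,
    outcome: str = "all",
    b_boot: int = 10_000,
    levels: tuple[float, ...] = DEFAULT_LEVELS,
    rng: np.random.Generator | int | None = None,
    covariate_columns: tuple[str, ...] = ("age", "icv"),
    residualize_per_draw: bool = False,
) -> MediationResult:
    """Full mediation analysis of sex -> connectome measure -> recall.

    ``outcome='all'`` uses the summed recall count over the three valence
    categories; ``'positive'`` the positive-picture count only.  The recall
    batch (room) is always among the residualized covariates, together with
    ``covariate_columns`` (default age and ICV).  With
    ``residualize_per_draw`` the covariate adjustment is redone inside every
    bootstrap draw instead of once up front.
    """
    metric = np.asarray(metric, dtype=float)
    if len(metric) != len(cohort):
        raise ValueError("metric length does not match cohort size")
    if outcome == "all":
        y_raw = cohort[["recall_neg", "recall_neu", "recall_pos"]].sum(axis=1).to_numpy(float)
    elif outcome == "positive":
        y_raw = cohort["recall_pos"].to_numpy(float)
    else:
        raise ValueError(f"outcome must be 'all' or 'positive', got {outcome!r}")
    x_raw = (cohort["sex"] == "male").to_numpy(float)
    covars = [cohort[c].to_numpy(float) for c in covariate_columns]
    covars.append((cohort["batch"] == "room2").to_numpy(float))
    z = np.column_stack(covars)

    if not residualize_per_draw:
        vars_ = residualize(np.column_stack([x_raw, metric, y_raw]), z)
        return bca_bootstrap(vars_[:, 0], vars_[:, 1], vars_[:, 2],
                             b_boot=b_boot, levels=levels, rng=rng)

    # re-residualize inside every bootstrap draw and every jackknife sample
    if b_boot < 1000:
        raise ValueError("b_boot must be >= 1000 for stable BCa intervals")
    rng = np.random.default_rng(rng)
    n = len(x_raw)
    raw = np.column_stack([x_raw, metric, y_raw])
    point = estimate_paths(*residualize(raw, z).T)
    boot_ind = np.empty(b_boot)
    boot_ratio = np.empty(b_boot)
    for i in range(b_boot):
        idx = rng.integers(0, n, n)
        try:
            paths = estimate_paths(*residualize(raw[idx], z[idx]).T)
            boot_ind[i] = paths["indirect"]
            boot_ratio[i] = paths["ratio"]
        except ValueError:
            boot_ind[i] = boot_ratio[i] = np.nan
    jack_ind = np.empty(n)
    jack_ratio = np.empty(n)
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        keep[i] = False
        paths = estimate_paths(*residualize(raw[keep], z[keep]).T)
        jack_ind[i] = paths["indirect"]
        jack_ratio[i] = paths["ratio"]
        keep[i] = True
    return _bca_from_boots(point, boot_ind, boot_ratio, jack_ind, jack_ratio,
                           levels, n, b_boot)
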