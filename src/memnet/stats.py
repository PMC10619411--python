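"""Covariate-adjusted inference for connectome and memory analyses.

Linear models with Type-II F tests (the convention of the ``car`` package),
Cohen's d reconstructed from the model t-value so that covariate adjustment
is inherited, partial Pearson correlations, a random-intercept mixed model
estimated by profiled REML with inner/outer (between/within-subject)
denominator degrees of freedom, a node-level Bonferroni scan, and the
robustness covariate variants.

Sex is coded female = 0 / male = 1 throughout, so a positive d means males
have the higher value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import stats as sps
from scipy.optimize import minimize_scalar

__all__ = [
    "TermTest",
    "ModelResult",
    "fit_ols",
    "cohens_d_from_t",
    "partial_correlation",
    "fit_random_intercept_lmm",
    "node_level_scan",
    "covariate_variants",
]


@dataclass(frozen=True)
class TermTest:
    """F test of one model term."""

    term: str
    f: float
    df1: int
    df2: int
    p: float
    cohens_d: float | None = None  # two-group contrasts only
    r: float | None = None         # single-df continuous terms only


@dataclass
class ModelResult:
    """Fitted linear (or mixed) model with per-term Type-II F tests."""

    terms: dict[str, TermTest]
    coef: pd.Series
    n_obs: int
    df_resid: int
    sigma2: float
    group_sizes: dict[str, int] = field(default_factory=dict)
    variance_components: dict[str, float] = field(default_factory=dict)

    def __getitem__(self, term: str) -> TermTest:
        return self.terms[term]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"term": t.term, "F": t.f, "df1": t.df1, "df2": t.df2, "p": t.p,
             "d_or_r": t.cohens_d if t.cohens_d is not None else t.r}
            for t in self.terms.values()
        ]
        return pd.DataFrame(rows)


def cohens_d_from_t(t: float, n1: int, n2: int, df: int) -> float:
    """Cohen's d reconstructed from a model t-value.

    ``d = t * (n1 + n2) / (sqrt(n1 * n2) * sqrt(df))`` — based on the
    t-statistic rather than raw means/SDs, so d inherits the adjustment for
    every covariate in the model.
    """
    if n1 <= 0 or n2 <= 0 or df <= 0:
        raise ValueError("group sizes and df must be positive")
    return float(t * (n1 + n2) / (np.sqrt(n1 * n2) * np.sqrt(df)))


# ---------------------------------------------------------------------------
# design-matrix construction


def _factor_columns(series: pd.Series, name: str) -> tuple[np.ndarray, list[str]]:
    """Treatment-coded dummies (first level is the reference)."""
    cat = pd.Categorical(series)
    levels = list(cat.categories)
    if len(levels) < 2:
        raise ValueError(f"factor {name!r} has fewer than 2 levels")
    cols = np.column_stack([(cat.codes == i).astype(float) for i in range(1, len(levels))])
    names = [f"{name}[{lev}]" for lev in levels[1:]]
    return cols, names


def _term_block(data: pd.DataFrame, term: str) -> tuple[np.ndarray, list[str]]:
    """Columns of one term; interactions are column-wise products."""
    parts = term.split(":")
    blocks = []
    for part in parts:
        if part not in data.columns:
            raise KeyError(f"term component {part!r} not in data")
        col = data[part]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            blocks.append(_factor_columns(col, part))
        else:
            blocks.append((col.to_numpy(dtype=float)[:, None], [part]))
    cols, names = blocks[0]
    for c2, n2 in blocks[1:]:
        cols = np.einsum("ni,nj->nij", cols, c2).reshape(len(cols), -1)
        names = [f"{a}:{b}" for a in names for b in n2]
    return cols, names


def _build_design(
    data: pd.DataFrame, terms: list[str]
) -> tuple[np.ndarray, list[str], dict[str, list[int]]]:
    n = len(data)
    x_cols = [np.ones((n, 1))]
    names = ["Intercept"]
    spans: dict[str, list[int]] = {}
    pos = 1
    for term in terms:
        cols, cnames = _term_block(data, term)
        x_cols.append(cols)
        names.extend(cnames)
        spans[term] = list(range(pos, pos + cols.shape[1]))
        pos += cols.shape[1]
    return np.hstack(x_cols), names, spans


def _check_full_rank(x: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # identify offending columns via pivoted QR
        _, r_mat, piv = sla.qr(x, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r_mat))
        tol = diag.max() * max(x.shape) * np.finfo(float).eps
        bad = [names[piv[i]] for i in range(len(diag)) if diag[i] < tol]
        bad += [names[p] for p in piv[len(diag):]]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


def _rss(x: np.ndarray, y: np.ndarray) -> float:
    beta, res, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    if rank == x.shape[1] and res.size:
        return float(res[0])
    fitted = x @ beta
    return float(np.sum((y - fitted) ** 2))


def _type2_comparisons(terms: list[str]) -> dict[str, list[str]]:
    """For each term, the terms of its Type-II base model.

    The base model for term t contains every term that does not include all
    of t's factors; t's F test compares base vs base + t.
    """
    out = {}
    fsets = {t: frozenset(t.split(":")) for t in terms}
    for t in terms:
        base = [u for u in terms if u != t and not fsets[t] <= fsets[u]]
        out[t] = base
    return out


def _binary_group_sizes(col: np.ndarray) -> tuple[int, int] | None:
    vals = np.unique(col)
    if len(vals) == 2:
        n1 = int((col == vals[1]).sum())
        return int((col == vals[0]).sum()), n1
    return None


def fit_ols(
    data: pd.DataFrame,
    response: str,
    terms: list[str],
) -> ModelResult:
    """Ordinary least squares with Type-II F tests per term.

    Categorical columns (object/category dtype) are treatment-coded;
    interactions are written ``"a:b"``.  For single-column binary terms the
    result carries Cohen's d reconstructed from the t-value; for single-df
    continuous terms a partial correlation ``r = sign(b) sqrt(F/(F+df2))``.

    Raises on rank-deficient designs, naming the collinear columns.
    """
    y = data[response].to_numpy(dtype=float)
    x, names, spans = _build_design(data, terms)
    n, p = x.shape
    if n <= p:
        raise ValueError(f"n={n} must exceed number of parameters p={p}")
    _check_full_rank(x, names)
    beta, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    rss_full = _rss(x, y)
    df_resid = n - p
    sigma2 = rss_full / df_resid
    comparisons = _type2_comparisons(terms)
    # relative floor: a perfectly fitted (e.g. constant) response yields F = 0
    tiny = 1e-12 * max(float(np.sum((y - y.mean()) ** 2)), 1.0)

    tests: dict[str, TermTest] = {}
    for term in terms:
        base_terms = comparisons[term]
        keep = [0] + [i for t in base_terms for i in spans[t]]
        x_base = x[:, keep]
        x_with = x[:, keep + spans[term]]
        q = len(spans[term])
        delta = _rss(x_base, y) - _rss(x_with, y)
        if rss_full <= tiny:
            f = 0.0 if delta <= tiny else np.inf
        else:
            f = max(delta / q / sigma2, 0.0)
        pval = float(sps.f.sf(f, q, df_resid))
        d_val = r_val = None
        if q == 1:
            col = x[:, spans[term][0]]
            b = beta[spans[term][0]]
            t_val = np.sign(b) * np.sqrt(f)
            groups = _binary_group_sizes(col)
            if groups is not None:
                n0, n1 = groups
                d_val = cohens_d_from_t(t_val, n1, n0, df_resid)
            else:
                r_val = float(np.sign(b) * np.sqrt(f / (f + df_resid)))
        tests[term] = TermTest(term, float(f), q, df_resid, pval, d_val, r_val)

    group_sizes = {}
    for term in terms:
        if len(spans[term]) == 1:
            groups = _binary_group_sizes(x[:, spans[term][0]])
            if groups is not None:
                group_sizes[term] = groups[1]
    return ModelResult(
        terms=tests,
        coef=pd.Series(beta, index=names),
        n_obs=n,
        df_resid=df_resid,
        sigma2=sigma2,
        group_sizes=group_sizes,
    )


def partial_correlation(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray | None = None
) -> tuple[float, float]:
    """Partial Pearson correlation of x and y given covariates.

    Both variables are residualized on the covariates (plus intercept) by
    least squares; r is the Pearson correlation of the residuals and p comes
    from ``t = r sqrt((n - 2 - k) / (1 - r^2))``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if covariates is None or (hasattr(covariates, "size") and covariates.size == 0):
        z = np.ones((n, 1))
        k = 0
    else:
        c = np.asarray(covariates, dtype=float)
        if c.ndim == 1:
            c = c[:, None]
        z = np.column_stack([np.ones(n), c])
        k = c.shape[1]
    if n <= k + 2:
        raise ValueError(f"need n > k + 2 (n={n}, k={k})")
    rx = x - z @ np.linalg.lstsq(z, x, rcond=None)[0]
    ry = y - z @ np.linalg.lstsq(z, y, rcond=None)[0]
    sx, sy = rx.std(), ry.std()
    if sx <= 1e-10 * max(x.std(), 1e-300) or sy <= 1e-10 * max(y.std(), 1e-300):
        raise ValueError("zero-variance residuals; partial correlation undefined")
    r = float(rx @ ry / (n * sx * sy))
    r = float(np.clip(r, -1.0, 1.0))
    df = n - 2 - k
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1 - r * r))
    p = float(2 * sps.t.sf(abs(t), df))
    return r, p


# ---------------------------------------------------------------------------
# random-intercept mixed model (profiled REML)


def _whiten(
    y: np.ndarray, x: np.ndarray, groups: np.ndarray, gamma: float
) -> tuple[np.ndarray, np.ndarray]:
    """Multiply by V^{-1/2} for V = I + gamma * Z Z' (balanced groups).

    Within a group of size J, V has eigenvalue 1 + J*gamma on the constant
    vector and 1 elsewhere, so V^{-1/2} v = v - c * mean(v) * 1 with
    ``c = 1 - 1/sqrt(1 + J*gamma)``.
    """
    uniq, inv, counts = np.unique(groups, return_inverse=True, return_counts=True)
    j = counts[0]
    c = 1.0 - 1.0 / np.sqrt(1.0 + j * gamma)

    def w(v: np.ndarray) -> np.ndarray:
        v = np.asarray(v, dtype=float)
        if v.ndim == 1:
            means = np.bincount(inv, weights=v) / counts
            return v - c * means[inv]
        out = np.empty_like(v)
        for col in range(v.shape[1]):
            means = np.bincount(inv, weights=v[:, col]) / counts
            out[:, col] = v[:, col] - c * means[inv]
        return out

    return w(y), w(x)


def fit_random_intercept_lmm(
    data: pd.DataFrame,
    response: str,
    subject: str,
    between_terms: list[str],
    within_terms: list[str],
) -> ModelResult:
    """Random-intercept linear mixed model by profiled REML.

    ``data`` is the long table (one row per subject x within-condition,
    balanced).  For a given variance ratio gamma = sigma2_subject /
    sigma2_resid the GLS fit has closed form after per-subject whitening;
    the REML log-likelihood is maximized over gamma by 1-D bounded search
    (boundary gamma = 0 handled explicitly).

    F tests are Type II on the whitened scale with inner/outer denominator
    degrees of freedom: between-subject terms use
    ``n_subjects - rank(between design)``; within-subject terms (any term
    involving a within factor) use ``n_obs - n_subjects - rank(within
    columns)``.
    """
    terms = list(between_terms) + list(within_terms)
    y = data[response].to_numpy(dtype=float)
    x, names, spans = _build_design(data, terms)
    groups = data[subject].to_numpy()
    uniq, counts = np.unique(groups, return_counts=True)
    if len(set(counts)) != 1:
        raise ValueError("random-intercept fit requires balanced groups")
    n, p = x.shape
    n_subj = len(uniq)
    j = counts[0]
    _check_full_rank(x, names)

    def neg_reml(log_gamma: float) -> float:
        gamma = np.exp(log_gamma)
        yw, xw = _whiten(y, x, groups, gamma)
        rss = _rss(xw, yw)
        xtx = xw.T @ xw
        sign, logdet_xtx = np.linalg.slogdet(xtx)
        logdet_v = n_subj * np.log(1.0 + j * gamma)
        return (n - p) * np.log(rss) + logdet_v + logdet_xtx

    res = minimize_scalar(neg_reml, bounds=(-12.0, 8.0), method="bounded",
                          options={"xatol": 1e-8})
    gamma_hat = float(np.exp(res.x))
    if neg_reml(-30.0) < res.fun:  # boundary: no subject variance
        gamma_hat = 0.0

    yw, xw = _whiten(y, x, groups, gamma_hat)
    beta, _, _, _ = np.linalg.lstsq(xw, yw, rcond=None)
    rss_full = _rss(xw, yw)
    sigma2 = rss_full / (n - p)
    sigma2_subject = gamma_hat * sigma2

    # stratum ranks for denominator df
    between_idx = [0] + [i for t in between_terms for i in spans[t]]
    within_idx = [i for t in within_terms for i in spans[t]]
    rank_between = np.linalg.matrix_rank(x[:, between_idx])
    rank_within = len(within_idx)
    df_between = n_subj - rank_between
    df_within = n - n_subj - rank_within

    comparisons = _type2_comparisons(terms)
    tests: dict[str, TermTest] = {}
    group_sizes: dict[str, int] = {}
    for term in terms:
        keep = [0] + [i for t in comparisons[term] for i in spans[t]]
        q = len(spans[term])
        num = (_rss(xw[:, keep], yw) - _rss(xw[:, keep + spans[term]], yw)) / q
        f = max(num / sigma2, 0.0) if sigma2 > 0 else np.inf
        df2 = df_within if term in within_terms else df_between
        pval = float(sps.f.sf(f, q, df2))
        d_val = r_val = None
        if q == 1:
            col = x[:, spans[term][0]]
            b = beta[spans[term][0]]
            t_val = np.sign(b) * np.sqrt(f)
            groups_sizes = _binary_group_sizes(col)
            if groups_sizes is not None and term not in within_terms:
                # group sizes counted at the subject level
                subj_col = pd.DataFrame({"g": groups, "c": col}).groupby("g")["c"].first()
                n1 = int((subj_col == subj_col.max()).sum())
                n0 = n_subj - n1
                d_val = cohens_d_from_t(t_val, n1, n0, df2)
                group_sizes[term] = n1
            else:
                r_val = float(np.sign(b) * np.sqrt(f / (f + df2)))
        tests[term] = TermTest(term, float(f), q, int(df2), pval, d_val, r_val)

    return ModelResult(
        terms=tests,
        coef=pd.Series(beta, index=names),
        n_obs=n,
        df_resid=n - p,
        sigma2=sigma2,
        group_sizes=group_sizes,
        variance_components={"sigma2_subject": sigma2_subject, "sigma2_resid": sigma2},
    )


def reml_log_likelihood_profile(
    data: pd.DataFrame,
    response: str,
    subject: str,
    between_terms: list[str],
    within_terms: list[str],
    gammas: np.ndarray,
) -> np.ndarray:
    """-2 profiled REML criterion over a grid of variance ratios (for checks)."""
    terms = list(between_terms) + list(within_terms)
    y = data[response].to_numpy(dtype=float)
    x, names, spans = _build_design(data, terms)
    groups = data[subject].to_numpy()
    uniq, counts = np.unique(groups, return_counts=True)
    n, p = x.shape
    n_subj, j = len(uniq), counts[0]
    out = np.empty(len(gammas))
    for i, gamma in enumerate(gammas):
        yw, xw = _whiten(y, x, groups, gamma)
        rss = _rss(xw, yw)
        _, logdet_xtx = np.linalg.slogdet(xw.T @ xw)
        out[i] = (n - p) * np.log(rss) + n_subj * np.log(1 + j * gamma) + logdet_xtx
    return out


# ---------------------------------------------------------------------------
# node-level scan and covariate variants


def node_level_scan(
    clustering: pd.DataFrame,
    cohort: pd.DataFrame,
    alpha: float = 0.05,
    covariate_terms: tuple[str, ...] = ("age", "icv"),
) -> pd.DataFrame:
    """Per-node sex effect on the weighted clustering coefficient.

    Fits ``clustering_node ~ sex + age + ICV`` for each node and flags
    significance at the Bonferroni level ``alpha / R`` (R = number of nodes).
    Per-node failures propagate with the node label attached.
    """
    n_nodes = clustering.shape[1]
    alpha_node = alpha / n_nodes
    rows = []
    df = cohort.copy()
    for node in clustering.columns:
        df["_y"] = clustering[node].to_numpy()
        try:
            res = fit_ols(df, "_y", ["male", *covariate_terms])
        except ValueError as exc:
            raise ValueError(f"node {node!r}: {exc}") from exc
        tt = res["male"]
        rows.append(
            {"node": node, "F": tt.f, "df1": tt.df1, "df2": tt.df2, "p": tt.p,
             "d": tt.cohens_d, "significant": tt.p < alpha_node}
        )
    out = pd.DataFrame(rows)
    out.attrs["alpha_node"] = alpha_node
    out.attrs["alpha"] = alpha
    return out


def covariate_variants(
    metric: pd.Series | np.ndarray,
    cohort: pd.DataFrame,
    extra_covariates: pd.DataFrame | None = None,
) -> dict[str, ModelResult]:
    """Robustness refits of the sex-difference model.

    ``base`` is ``metric ~ sex + age + ICV``.  Each column of
    ``extra_covariates`` (e.g. degree, gray-matter volume) is added in turn.
    ``hc_use`` / ``mc_phase`` replace sex by a factor splitting females by
    hormonal-contraceptive use or menstrual-cycle phase (males are one
    level); females with a missing label are dropped from those fits.
    """
    df = cohort.copy()
    df["_metric"] = np.asarray(metric, dtype=float)
    out = {"base": fit_ols(df, "_metric", ["male", "age", "icv"])}
    if extra_covariates is not None:
        for name in extra_covariates.columns:
            df[name] = extra_covariates[name].to_numpy()
            out[f"plus_{name}"] = fit_ols(df, "_metric", ["male", "age", "icv", name])
    for factor in ("hc_use", "mc_phase"):
        if factor not in cohort.columns:
            continue
        sub = df[df[factor].notna()].copy()
        levels = sub[factor].unique()
        if len(levels) < 2:
            raise ValueError(f"factor {factor!r} collapsed to {levels}; cannot fit")
        sub[factor] = sub[factor].astype("category")
        out[factor] = fit_ols(sub, "_metric", [factor, "age", "icv"])
    return out
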