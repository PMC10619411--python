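"""Pipeline orchestration: simulate -> build -> metrics -> analyze -> mediate.

Wires the stages into a reproducible run with a config file, per-stage
derived random substreams, CSV outputs, a manifest and simple figures.
All numeric figure content is sourced from the result tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectome import (
    ConnectivityMatrix,
    PopulationMask,
    StreamlineTally,
    apply_mask,
    build_population_mask,
    read_matrix,
    symmetrize,
    tally_to_probability,
    write_matrix,
)
from .mediation import MediationResult, run_mediation
from .metrics import compute_metrics
from .stats import ModelResult, fit_ols, fit_random_intercept_lmm, node_level_scan, partial_correlation
from .synthetic import (
    CohortConfig,
    calibrate_effects,
    cohort_to_frame,
    generate_cohort,
    make_template,
    read_cohort,
    write_cohort,
)

__all__ = [
    "RunConfig",
    "build_matrices",
    "metrics_table",
    "long_memory_table",
    "analyze",
    "estimate_effect_sizes",
    "run_all",
    "report",
]

log = logging.getLogger("memnet")

METRIC_COLUMNS = ("strength", "cpl", "efficiency", "transitivity")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    mode: str = "synthetic"  # 'synthetic' | 'real'
    output_dir: str = "memnet_run"
    data_dir: str | None = None  # real mode: directory of matrices + cohort.csv
    cohort: CohortConfig = field(default_factory=CohortConfig)
    mask_threshold: float = 0.01
    mask_k_sd: float = 2.0
    alpha: float = 0.0125  # four connectome measures -> 0.05 / 4
    node_scan_alpha: float = 0.05  # Bonferroni-divided by R inside the scan
    b_boot: int = 10_000
    levels: tuple[float, ...] = (95.0, 99.0, 99.5)
    write_cohort_files: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "real"):
            raise ValueError(f"mode must be 'synthetic' or 'real', got {self.mode!r}")
        if self.mode == "real" and not self.data_dir:
            raise ValueError("real mode requires data_dir")
        if isinstance(self.cohort, dict):
            self.cohort = CohortConfig(**self.cohort)

    @property
    def seed(self) -> int:
        return self.cohort.seed

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# stages


def build_matrices(
    tallies: list[StreamlineTally],
    threshold: float = 0.01,
    k_sd: float = 2.0,
    node_labels: tuple[str, ...] | None = None,
) -> tuple[list[ConnectivityMatrix], PopulationMask]:
    """Tallies -> symmetric matrices -> population mask -> masked matrices."""
    raw = [symmetrize(tally_to_probability(t), node_labels) for t in tallies]
    mask = build_population_mask(raw, threshold=threshold, k_sd=k_sd)
    masked = [apply_mask(m, mask) for m in raw]
    log.info(
        "population mask: %d/%d edges kept (threshold=%g, k_sd=%g)",
        mask.n_edges_kept, mask.n_edges_total, threshold, k_sd,
    )
    return masked, mask


def metrics_table(
    matrices: list[ConnectivityMatrix], ids: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Global metric table plus per-node clustering and strength tables."""
    rows, clust_rows, strength_rows = [], [], []
    for sid, mat in zip(ids, matrices):
        ms, nm = compute_metrics(mat)
        rows.append(
            {"id": sid, "strength": ms.strength_global, "cpl": ms.char_path_length,
             "efficiency": ms.global_efficiency, "transitivity": ms.weighted_transitivity,
             "degree_total": int(nm.degree.sum() // 2), "connected": ms.connected}
        )
        clust_rows.append(nm.clustering)
        strength_rows.append(nm.strength)
    labels = (matrices[0].node_labels
              or tuple(f"region_{i:03d}" for i in range(matrices[0].n_nodes)))
    metrics = pd.DataFrame(rows)
    clustering = pd.DataFrame(np.vstack(clust_rows), columns=labels, index=ids)
    strength = pd.DataFrame(np.vstack(strength_rows), columns=labels, index=ids)
    return metrics, clustering, strength


def long_memory_table(cohort: pd.DataFrame, metric: pd.Series | None = None) -> pd.DataFrame:
    """Long (subject x valence) recall table for the mixed models."""
    frames = []
    for valence, col in (("negative", "recall_neg"), ("neutral", "recall_neu"),
                         ("positive", "recall_pos")):
        f = cohort[["id", "male", "age", "icv", "batch"]].copy()
        f["valence"] = valence
        f["recall"] = cohort[col].to_numpy(dtype=float)
        if metric is not None:
            f["m"] = np.asarray(metric, dtype=float)
        frames.append(f)
    out = pd.concat(frames, ignore_index=True)
    out["room2"] = (out["batch"] == "room2").astype(float)
    return out


def analyze(
    cohort: pd.DataFrame,
    metrics: pd.DataFrame,
    clustering: pd.DataFrame,
    alpha: float = 0.0125,
    node_scan_alpha: float = 0.05,
    focus_metric: str = "transitivity",
) -> dict:
    """The statistical model battery.

    1. valence x sex mixed model of recall (random subject intercept),
    2. per-metric sex x ICV models,
    3. per-metric ICV-adjusted sex-difference models (Cohen's d from t) and,
       for the focus metric, the node-level Bonferroni scan,
    4. recall ~ sex x valence x focus-metric mixed model.
    """
    df = cohort.merge(metrics, on="id")
    if df["icv"].isna().any():
        raise ValueError("missing ICV values")
    results: dict = {}

    long = long_memory_table(df)
    results["memory_model"] = fit_random_intercept_lmm(
        long, "recall", "id",
        between_terms=["male", "age", "room2"],
        within_terms=["valence", "male:valence"],
    )

    icv_models, sex_models = {}, {}
    for m in METRIC_COLUMNS:
        icv_models[m] = fit_ols(df, m, ["male", "icv", "male:icv", "age"])
        sex_models[m] = fit_ols(df, m, ["male", "age", "icv"])
    results["icv_models"] = icv_models
    results["sex_models"] = sex_models
    results["significant_metrics"] = [
        m for m in METRIC_COLUMNS if sex_models[m]["male"].p <= alpha
    ]

    results["node_scan"] = node_level_scan(
        clustering.loc[df["id"]], df, alpha=node_scan_alpha
    )

    long_m = long_memory_table(df, metric=df[focus_metric])
    results["memory_metric_model"] = fit_random_intercept_lmm(
        long_m, "recall", "id",
        between_terms=["male", "m", "male:m", "age", "room2"],
        within_terms=["valence", "male:valence", "m:valence", "male:m:valence"],
    )
    covars = np.column_stack(
        [df["age"], (df["batch"] == "room2").astype(float), df["icv"]]
    )
    r_tm, p_tm = partial_correlation(
        df[focus_metric].to_numpy(float), df["recall_total"].to_numpy(float), covars
    )
    results["r_metric_memory"] = (r_tm, p_tm)
    r_age = float(np.corrcoef(df["age"], df[focus_metric])[0, 1])
    results["r_age_metric"] = r_age
    results["r_sex_icv"] = float(
        np.corrcoef(1.0 - df["male"], df["icv"])[0, 1]
    )  # female-coded indicator, matching the reporting convention
    return results


def estimate_effect_sizes(cohort: pd.DataFrame, transitivity: np.ndarray) -> dict[str, float]:
    """Headline effect sizes of one cohort (used for parameter recovery).

    d: ICV- and age-adjusted sex difference in weighted transitivity;
    r_age: plain age-transitivity correlation; r_tm: transitivity-memory
    partial correlation given age, batch, ICV; r_sex_icv: female-ICV
    point-biserial correlation; indirect: mediation a*b after residualizing
    age, batch and ICV.
    """
    from .mediation import estimate_paths, residualize

    df = cohort
    work = df.copy()
    work["_t"] = np.asarray(transitivity, dtype=float)
    d = fit_ols(work, "_t", ["male", "age", "icv"])["male"].cohens_d
    r_age = float(np.corrcoef(work["age"], work["_t"])[0, 1])
    covars = np.column_stack(
        [work["age"], (work["batch"] == "room2").astype(float), work["icv"]]
    )
    r_tm, _ = partial_correlation(
        work["_t"].to_numpy(float), work["recall_total"].to_numpy(float), covars
    )
    vars_ = residualize(
        np.column_stack([work["male"], work["_t"], work["recall_total"]]), covars
    )
    paths = estimate_paths(*vars_.T)
    r_sex_icv = float(np.corrcoef(1.0 - work["male"], work["icv"])[0, 1])
    return {
        "d_transitivity": float(d),
        "r_age_transitivity": r_age,
        "r_transitivity_memory": float(r_tm),
        "r_sex_icv": r_sex_icv,
        "a": paths["a"],
        "b": paths["b"],
        "c": paths["c"],
        "c_prime": paths["c_prime"],
        "indirect": paths["indirect"],
    }


# ---------------------------------------------------------------------------
# run-all


def _model_frame(name: str, res: ModelResult) -> pd.DataFrame:
    f = res.to_frame()
    f.insert(0, "model", name)
    return f


def _load_real_data(data_dir: Path) -> tuple[pd.DataFrame, list[ConnectivityMatrix]]:
    cohort = pd.read_csv(data_dir / "cohort.csv")
    if "male" not in cohort.columns:
        cohort["male"] = (cohort["sex"] == "male").astype(int)
    if "recall_total" not in cohort.columns:
        cohort["recall_total"] = cohort[
            ["recall_neg", "recall_neu", "recall_pos"]
        ].sum(axis=1)
    matrices = []
    for sid in cohort["id"]:
        path = data_dir / f"{sid}_matrix.tsv"
        if not path.exists():
            raise FileNotFoundError(f"missing connectivity matrix {path.name}")
        matrices.append(ConnectivityMatrix(weights=np.clip(read_matrix(path), 0.0, 1.0)))
    return cohort, matrices


def run_all(config: RunConfig) -> dict:
    """Execute every stage and write a report directory.

    Deterministic given the config (the cohort seed drives every stage).
    Returns the in-memory results dictionary; on a stage failure the
    artifacts written so far remain in place and the error names the stage.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    timings: dict[str, float] = {}
    results: dict = {}
    stage = "simulate"
    try:
        t0 = time.time()
        if config.mode == "synthetic":
            cfg = config.cohort
            subjects, tallies = generate_cohort(cfg)
            cohort = cohort_to_frame(subjects)
            if config.write_cohort_files:
                write_cohort(subjects, tallies, out / "cohort")
            raw_input = tallies
        else:
            cohort, raw_input = _load_real_data(Path(config.data_dir))
        cohort.to_csv(out / "cohort_table.csv", index=False)
        timings[stage] = time.time() - t0

        stage = "build"
        t0 = time.time()
        if config.mode == "synthetic":
            matrices, mask = build_matrices(
                raw_input, config.mask_threshold, config.mask_k_sd
            )
        else:
            mask = build_population_mask(
                raw_input, config.mask_threshold, config.mask_k_sd
            )
            matrices = [apply_mask(m, mask) for m in raw_input]
        write_matrix(out / "population_mask.tsv", mask.keep.astype(int), fmt="%d")
        results["mask"] = mask
        timings[stage] = time.time() - t0

        stage = "metrics"
        t0 = time.time()
        metrics, clustering, strength = metrics_table(matrices, list(cohort["id"]))
        metrics.to_csv(out / "metrics.csv", index=False)
        clustering.to_csv(out / "node_clustering.csv")
        strength.to_csv(out / "node_strength.csv")
        results["metrics"] = metrics
        results["clustering"] = clustering
        timings[stage] = time.time() - t0

        stage = "analyze"
        t0 = time.time()
        analysis = analyze(
            cohort, metrics, clustering,
            alpha=config.alpha, node_scan_alpha=config.node_scan_alpha,
        )
        results["analysis"] = analysis
        frames = [_model_frame("memory", analysis["memory_model"])]
        for m, res in analysis["icv_models"].items():
            frames.append(_model_frame(f"icv_{m}", res))
        for m, res in analysis["sex_models"].items():
            frames.append(_model_frame(f"sex_{m}", res))
        frames.append(_model_frame("memory_x_transitivity", analysis["memory_metric_model"]))
        table = pd.concat(frames, ignore_index=True)
        table["significant"] = table["p"] <= config.alpha
        table.to_csv(out / "model_results.csv", index=False)
        analysis["node_scan"].to_csv(out / "node_scan.csv", index=False)
        timings[stage] = time.time() - t0

        stage = "mediate"
        t0 = time.time()
        merged = cohort.merge(metrics, on="id")
        med = {}
        for i, outcome in enumerate(("all", "positive")):
            med[outcome] = run_mediation(
                merged, merged["transitivity"], outcome=outcome,
                b_boot=config.b_boot, levels=config.levels,
                rng=np.random.default_rng(
                    np.random.SeedSequence([config.seed, 0xB00, i])
                ),
            )
        results["mediation"] = med
        pd.concat(
            [m.to_frame().assign(outcome=k) for k, m in med.items()],
            ignore_index=True,
        ).to_csv(out / "mediation.csv", index=False)
        timings[stage] = time.time() - t0
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    effect_sizes = estimate_effect_sizes(
        cohort.merge(metrics, on="id"), metrics["transitivity"].to_numpy()
    )
    results["effect_sizes"] = effect_sizes
    summary = _summary_text(config, results, effect_sizes)
    (out / "summary.txt").write_text(summary)
    manifest = {
        "memnet_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "mode": config.mode,
        "timings_s": {k: round(v, 2) for k, v in timings.items()},
        "files": {
            f.name: hashlib.sha256(f.read_bytes()).hexdigest()
            for f in sorted(out.glob("*.csv"))
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    report(out, results)
    log.removeHandler(handler)
    handler.close()
    return results


def _summary_text(config: RunConfig, results: dict, effects: dict) -> str:
    lines = [
        f"memnet {__version__} run summary (seed={config.seed}, mode={config.mode})",
        "",
        f"mask: {results['mask'].n_edges_kept}/{results['mask'].n_edges_total} edges kept",
        "",
        "ICV-adjusted sex differences (positive d = males higher):",
    ]
    for m, res in results["analysis"]["sex_models"].items():
        tt = res["male"]
        star = " *" if tt.p <= config.alpha else ""
        lines.append(
            f"  {m:13s} F({tt.df1},{tt.df2}) = {tt.f:7.2f}  p = {tt.p:.2e}  "
            f"d = {tt.cohens_d:+.3f}{star}"
        )
    scan = results["analysis"]["node_scan"]
    n_sig = int(scan["significant"].sum())
    lines += [
        "",
        f"node-level clustering scan: {n_sig}/{len(scan)} nodes significant "
        f"at alpha = {scan.attrs['alpha']}/{len(scan)} = {scan.attrs['alpha_node']:.2e}",
        "",
        f"age-transitivity r = {results['analysis']['r_age_metric']:+.3f}",
        "transitivity-memory partial r = "
        f"{results['analysis']['r_metric_memory'][0]:+.3f} "
        f"(p = {results['analysis']['r_metric_memory'][1]:.3g})",
        f"female-ICV r = {results['analysis']['r_sex_icv']:+.3f}",
        "",
        "mediation of the sex -> recall effect by weighted transitivity",
        "(male = 1; residualized for age, batch, ICV):",
    ]
    for outcome, med in results["mediation"].items():
        lo, hi = med.ci_indirect[99.0] if 99.0 in med.ci_indirect else list(med.ci_indirect.values())[0]
        lines.append(
            f"  outcome={outcome:8s} a = {med.a:+.3f}  b = {med.b:+.3f}  "
            f"c = {med.c:+.3f}  c' = {med.c_prime:+.3f}  "
            f"indirect = {med.indirect:+.4f} [{lo:+.4f}, {hi:+.4f}]  "
            f"ratio = {med.ratio:+.3f}"
        )
    return "\n".join(lines) + "\n"


def report(out_dir: str | Path, results: dict | None = None) -> list[Path]:
    """Figures for a finished run: boxplots, age scatter, mediation diagram.

    Reads the result tables from ``out_dir`` so it can be re-run standalone;
    returns the figure paths.  Matplotlib is imported lazily with the Agg
    backend so headless runs work.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    fig_dir = out_dir / "figures"
    fig_dir.mkdir(exist_ok=True)
    cohort = pd.read_csv(out_dir / "cohort_table.csv")
    metrics = pd.read_csv(out_dir / "metrics.csv")
    df = cohort.merge(metrics, on="id")
    paths = []

    fig, axes = plt.subplots(1, 4, figsize=(12, 3.2))
    rng = np.random.default_rng(0)  # jitter only; cosmetic
    for ax, m in zip(axes, METRIC_COLUMNS):
        groups = [df.loc[df["sex"] == s, m] for s in ("female", "male")]
        ax.boxplot(groups, tick_labels=["female", "male"], showfliers=False)
        for i, g in enumerate(groups, start=1):
            ax.plot(i + rng.uniform(-0.15, 0.15, len(g)), g, ".", ms=2, alpha=0.3)
        ax.set_title(m)
    fig.tight_layout()
    p = fig_dir / "metrics_by_sex.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)

    fig, ax = plt.subplots(figsize=(5, 4))
    for sex, color in (("female", "tab:red"), ("male", "tab:blue")):
        sub = df[df["sex"] == sex]
        ax.plot(sub["age"], sub["transitivity"], ".", color=color, ms=3,
                alpha=0.4, label=sex)
        b = np.polyfit(sub["age"], sub["transitivity"], 1)
        xs = np.linspace(sub["age"].min(), sub["age"].max(), 20)
        ax.plot(xs, np.polyval(b, xs), color=color)
    b = np.polyfit(df["age"], df["transitivity"], 1)
    xs = np.linspace(df["age"].min(), df["age"].max(), 20)
    ax.plot(xs, np.polyval(b, xs), color="black", lw=2, label="all")
    ax.set_xlabel("age (years)")
    ax.set_ylabel("weighted transitivity")
    ax.legend()
    fig.tight_layout()
    p = fig_dir / "age_transitivity.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)

    med_file = out_dir / "mediation.csv"
    if med_file.exists():
        med = pd.read_csv(med_file)
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.axis("off")
        y = 0.9
        for outcome, sub in med.groupby("outcome"):
            vals = dict(zip(sub["quantity"], sub["estimate"]))
            ax.text(
                0.02, y,
                f"outcome = {outcome}:  a = {vals['a']:+.3f},  b = {vals['b']:+.3f},  "
                f"c = {vals['c']:+.3f},  c' = {vals['c_prime']:+.3f},\n"
                f"    indirect = {vals['indirect']:+.4f},  ratio = {vals['ratio']:+.3f}",
                fontsize=10, va="top", family="monospace",
            )
            y -= 0.35
        fig.tight_layout()
        p = fig_dir / "mediation_paths.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths.append(p)
    return paths
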