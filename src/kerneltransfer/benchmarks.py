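"""Committed benchmark experiments and Monte-Carlo validation oracles.

This module wires the generators, transfer operators, and theory into the
experiments the package is validated on:

* closed-form vs. Monte-Carlo risk agreement over a parameter grid
  (projected and translated estimators, plus the baseline law);
* the asymptotic (large-d) behavior of the projected risk;
* gradient descent from the source weights as an independent check that
  translation coincides with fine-tuning-from-source-initialization in the
  linear case;
* a finite-width ReLU network gradient kernel as an independent oracle for
  the NTK recursion;
* the clustered-classification and drug-screen transfer benchmarks with
  their logarithmic learning curves.

Every function is deterministic given its seed arguments.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .evaluation import fit_log_law, mean_cosine_centered, mean_r2, pearson_r
from .kernels import KernelSpec
from .regression import fit_kernel
from .synthetic import (
    CLASSIFICATION_BENCHMARK,
    DRUG_SCREEN_BENCHMARK,
    DrugScreenSim,
    gen_clustered_classification,
    gen_drug_screen,
    gen_weights_with_epsilon,
    refining_class_map,
)
from .theory import (
    LinearTransferTask,
    epsilon_similarity,
    mc_risk,
    risk_baseline,
    risk_projected,
    risk_translated,
)
from .transfer import evaluate_classification, fit_projected, fit_projected_translated

__all__ = [
    "theorem1_grid",
    "theorem2_grid",
    "baseline_sweep",
    "gd_least_squares",
    "finite_width_ntk_samples",
    "classification_transfer_run",
    "classification_learning_curve",
    "scaling_curve_replicate",
    "select_ridge",
    "drug_screen_run",
    "drug_screen_learning_curve",
    "drug_scaling_replicate",
    "RIDGE_GRID",
    "SCALING_BENCHMARK",
]

_GRID = {
    "d": 16,
    "n_s": (4, 8, 12, 16),
    "n_t": (2, 4, 8),
    "c_s": (2, 4, 8),
    "eps_frac": (0.0, 0.25),
}


def _cell_seed(root: int, idx: int) -> int:
    return int((root * 1_000_003 + 7_919 * idx + 1) % (2**31))


def theorem1_grid(trials: int = 20000, seed: int = 0, norm_wt: float = 1.0) -> pd.DataFrame:
    """Closed-form vs. Monte-Carlo risk of the projected estimator.

    One row per grid cell with columns ``d, n_s, n_t, c_s, eps, closed_form,
    mc_mean, mc_se, z_score``.
    """
    d = _GRID["d"]
    rows = []
    idx = 0
    for n_s in _GRID["n_s"]:
        for n_t in _GRID["n_t"]:
            for c_s in _GRID["c_s"]:
                for frac in _GRID["eps_frac"]:
                    idx += 1
                    eps = frac * norm_wt**2
                    ws, wt = gen_weights_with_epsilon(
                        d, c_s, 3, eps, norm_wt, seed=_cell_seed(seed, idx)
                    )
                    closed = risk_projected(
                        d, n_s, n_t, c_s, float(np.sum(wt**2)), epsilon_similarity(wt, ws)
                    ).risk
                    task = LinearTransferTask(d=d, n_s=n_s, n_t=n_t, omega_s=ws, omega_t=wt)
                    mean, se = mc_risk(task, "projected", trials, seed=_cell_seed(seed, idx + 5000))
                    z = (mean - closed) / se if se > 0 else 0.0
                    rows.append(
                        dict(d=d, n_s=n_s, n_t=n_t, c_s=c_s, eps=eps,
                             closed_form=closed, mc_mean=mean, mc_se=se, z_score=z)
                    )
    return pd.DataFrame(rows)


def theorem2_grid(trials: int = 20000, seed: int = 0, norm_wt: float = 1.0) -> pd.DataFrame:
    """Closed-form vs. Monte-Carlo risk of the translated estimator.

    Translation requires matching label dimensions, so the target label
    dimension is set to ``c_s`` in every cell.
    """
    d = _GRID["d"]
    rows = []
    idx = 0
    for n_s in _GRID["n_s"]:
        for n_t in _GRID["n_t"]:
            for c_s in _GRID["c_s"]:
                for frac in _GRID["eps_frac"]:
                    idx += 1
                    eps = frac * norm_wt**2
                    ws, wt = gen_weights_with_epsilon(
                        d, c_s, c_s, eps, norm_wt, seed=_cell_seed(seed, idx)
                    )
                    closed = risk_translated(
                        d, n_s, n_t, float(np.sum((ws - wt) ** 2)), float(np.sum(wt**2))
                    )
                    task = LinearTransferTask(d=d, n_s=n_s, n_t=n_t, omega_s=ws, omega_t=wt)
                    mean, se = mc_risk(task, "translated", trials, seed=_cell_seed(seed, idx + 5000))
                    z = (mean - closed) / se if se > 0 else 0.0
                    rows.append(
                        dict(d=d, n_s=n_s, n_t=n_t, c_s=c_s, eps=eps,
                             closed_form=closed, mc_mean=mean, mc_se=se, z_score=z)
                    )
    return pd.DataFrame(rows)


def baseline_sweep(d: int = 12, trials: int = 20000, seed: int = 0) -> pd.DataFrame:
    """Monte-Carlo baseline risk vs. ``(1 - n_t/d)||omega_t||^2`` for every n_t."""
    ws, wt = gen_weights_with_epsilon(d, 2, 2, 0.5, np.sqrt(2.0), seed=_cell_seed(seed, 77))
    rows = []
    for n_t in range(1, d + 1):
        closed = risk_baseline(d, n_t, float(np.sum(wt**2)))
        task = LinearTransferTask(d=d, n_s=1, n_t=n_t, omega_s=ws, omega_t=wt)
        mean, se = mc_risk(task, "baseline", trials, seed=_cell_seed(seed, 100 + n_t))
        z = (mean - closed) / se if se > 0 else 0.0
        rows.append(dict(d=d, n_t=n_t, closed_form=closed, mc_mean=mean, mc_se=se, z_score=z))
    return pd.DataFrame(rows)


def gd_least_squares(
    W0: np.ndarray,
    X: np.ndarray,
    Y: np.ndarray,
    max_iter: int = 200_000,
    tol: float = 1e-13,
) -> np.ndarray:
    """Gradient descent on ``||Y - W X||_F^2`` from ``W0`` (columns-as-samples).

    The step size is ``1 / (2 sigma_max(X)^2)``; iteration stops when the
    update stalls.  On under-determined problems GD converges to the
    minimizer closest to ``W0``, i.e. ``W0`` plus the minimum-norm fit of the
    initial residual — this loop is used as an independent oracle for that
    fact and never calls the closed-form solvers.
    """
    W = np.array(W0, dtype=float)
    smax = np.linalg.norm(X, 2)
    step = 1.0 / (2.0 * smax**2)
    for _ in range(max_iter):
        grad = 2.0 * (W @ X - Y) @ X.T
        delta = step * grad
        W -= delta
        if float(np.max(np.abs(delta))) < tol:
            break
    return W


def finite_width_ntk_samples(
    X: np.ndarray,
    depth: int,
    width: int,
    n_draws: int,
    seed: int,
    offset: bool = False,
) -> np.ndarray:
    """Per-draw empirical NTK of a finite-width ReLU network.

    For each random initialization, the full parameter-gradient inner
    product matrix ``<grad f(x_i), grad f(x_j)>`` of the network

    ``f(x) = a . g_L``,  ``g_l = sqrt(2/width) relu(W_l g_{l-1})``, ``g_0 = x``

    (all parameters standard normal) is computed exactly by backpropagation.
    Its expectation over initializations is the infinite-width NTK, so the
    draw mean with its standard error is an independent oracle for the
    closed-form recursion.  Returns an array of shape ``(n_draws, N, N)``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if offset:
        X = np.hstack([X, np.ones((X.shape[0], 1))])
    N, d0 = X.shape
    rng = np.random.default_rng(seed)
    c = np.sqrt(2.0 / width)
    out = np.empty((n_draws, N, N))
    for t in range(n_draws):
        Ws = [rng.standard_normal((width, d0))]
        Ws += [rng.standard_normal((width, width)) for _ in range(depth - 1)]
        a = rng.standard_normal(width)
        gs = [X]  # g_0 .. g_L
        zs = []
        for W in Ws:
            z = gs[-1] @ W.T
            zs.append(z)
            gs.append(c * np.maximum(z, 0.0))
        kernel = gs[-1] @ gs[-1].T  # gradient w.r.t. the output weights a
        delta = a[None, :] * c * (zs[-1] > 0)
        kernel += (delta @ delta.T) * (gs[-2] @ gs[-2].T)
        for l in range(depth - 2, -1, -1):
            delta = c * (zs[l] > 0) * (delta @ Ws[l + 1])
            kernel += (delta @ delta.T) * (gs[l] @ gs[l].T)
        out[t] = kernel
    return out


# --- clustered-classification benchmark -----------------------------------


def _laplace(cfg) -> KernelSpec:
    return KernelSpec("laplace", bandwidth=cfg["bandwidth"])


def classification_transfer_run(seed: int, n_t: int | None = None, cfg: dict | None = None) -> dict:
    """One seed of the clustered-classification benchmark.

    Fits the Laplace source model on the source task, a Laplace baseline
    directly on the target data, and the projected predictor (Laplace head
    on the source outputs); returns their test accuracies.
    """
    cfg = dict(CLASSIFICATION_BENCHMARK if cfg is None else cfg)
    if n_t is not None:
        cfg["n_t"] = n_t
    data = gen_clustered_classification(
        n_source_classes=cfg["n_source_classes"],
        n_target_classes=cfg["n_target_classes"],
        class_map=refining_class_map(cfg["n_target_classes"], cfg["blobs_per_class"]),
        d=cfg["d"],
        cluster_sd=cfg["cluster_sd"],
        n_s=cfg["n_s"],
        n_t=cfg["n_t"],
        n_test=cfg["n_test"],
        seed=seed,
    )
    spec = _laplace(cfg)
    source = fit_kernel(spec, data.X_source, data.Y_source, ridge=cfg["source_ridge"])
    baseline = fit_kernel(spec, data.X_target, data.Y_target, ridge=cfg["head_ridge"])
    projected = fit_projected(
        source, data.X_target, data.Y_target, head_spec=spec, ridge=cfg["head_ridge"]
    )
    return {
        "baseline_acc": evaluate_classification(baseline, data.X_test, data.Y_test),
        "projected_acc": evaluate_classification(projected, data.X_test, data.Y_test),
        "source_acc_on_target": evaluate_classification(
            fit_projected(source, data.X_target, data.Y_target, head_spec="linear"),
            data.X_test,
            data.Y_test,
        ),
        "n_t": cfg["n_t"],
    }


def classification_learning_curve(seed: int, n_grid, cfg: dict | None = None) -> np.ndarray:
    """Projected-predictor test accuracy at each target sample count.

    The target pool is drawn once per seed and nested prefixes of it are
    used, so the curve varies only through the sample count.
    """
    cfg = dict(CLASSIFICATION_BENCHMARK if cfg is None else cfg)
    n_grid = np.asarray(n_grid, dtype=int)
    data = gen_clustered_classification(
        n_source_classes=cfg["n_source_classes"],
        n_target_classes=cfg["n_target_classes"],
        class_map=refining_class_map(cfg["n_target_classes"], cfg["blobs_per_class"]),
        d=cfg["d"],
        cluster_sd=cfg["cluster_sd"],
        n_s=cfg["n_s"],
        n_t=int(n_grid.max()),
        n_test=cfg["n_test"],
        seed=seed,
    )
    spec = _laplace(cfg)
    source = fit_kernel(spec, data.X_source, data.Y_source, ridge=cfg["source_ridge"])
    accs = np.empty(n_grid.size)
    for i, n in enumerate(n_grid):
        model = fit_projected(
            source, data.X_target[:n], data.Y_target[:n], head_spec=spec, ridge=cfg["head_ridge"]
        )
        accs[i] = evaluate_classification(model, data.X_test, data.Y_test)
    return accs


# Committed scaling-law benchmark: the learning-curve protocol samples 50
# evenly spaced target sample counts and averages each point over 3 seeds.
# The grid spans the rising (pre-plateau) regime of the committed
# classification benchmark — its projected-predictor accuracy plateaus near
# 0.75 beyond roughly 250 target samples, so the curve stops at 206.  The
# test set is enlarged to 2000 to keep per-point noise small relative to
# the fitted trend.
SCALING_BENCHMARK = {
    "n_grid": tuple(range(10, 207, 4)),  # 50 points
    "seeds_per_point": 3,
    "n_test": 2000,
    "head_points": 5,
}


def scaling_curve_replicate(replicate: int, cfg: dict | None = None) -> dict:
    """One learning-curve replicate: a 3-seed-averaged projected accuracy curve.

    Returns the grid, the averaged curve, the full-range log-law fit, and
    the extrapolation of a fit on the first ``head_points`` points to the
    final grid point.
    """
    scfg = dict(SCALING_BENCHMARK if cfg is None else cfg)
    ccfg = dict(CLASSIFICATION_BENCHMARK)
    ccfg["n_test"] = scfg["n_test"]
    n_grid = np.asarray(scfg["n_grid"], dtype=int)
    k = scfg["seeds_per_point"]
    curves = np.array(
        [classification_learning_curve(replicate * k + j, n_grid, cfg=ccfg) for j in range(k)]
    )
    curve = curves.mean(axis=0)
    fit = fit_log_law(n_grid, curve)
    head = fit_log_law(n_grid[: scfg["head_points"]], curve[: scfg["head_points"]])
    from .evaluation import extrapolate_log_law

    predicted = extrapolate_log_law(head, int(n_grid[-1]))
    return {
        "n_grid": n_grid,
        "curve": curve,
        "fit": fit,
        "head_fit": head,
        "predicted_last": float(predicted),
        "actual_last": float(curve[-1]),
        "extrapolation_error": float(abs(predicted - curve[-1])),
    }


# --- drug-screen benchmark ------------------------------------------------

# The drug-screening protocol selects the ridge coefficient by a grid search
# over {1, 10, 100, 1000, 10000} on validation data rather than fixing it;
# the selected value is scale-dependent, so the search is re-run on the
# synthetic tables (held-out source rows for the source model, k-fold CV on
# the first held-out cell's training drugs for the target-side models).
RIDGE_GRID = (1.0, 10.0, 100.0, 1000.0, 10000.0)


def select_ridge(
    fit_fn,
    X: np.ndarray,
    Y: np.ndarray,
    grid=RIDGE_GRID,
    n_folds: int = 5,
    seed: int = 0,
) -> float:
    """Pick the ridge with lowest k-fold validation MSE.

    ``fit_fn(X, Y, ridge)`` must return a model whose ``predict`` maps
    rows-as-samples to ``c x m`` outputs.
    """
    n = X.shape[0]
    if n < 2:
        raise ValueError("ridge selection needs at least 2 samples")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = [f for f in np.array_split(order, min(n_folds, n)) if f.size]
    best, best_mse = None, np.inf
    for ridge in grid:
        mse = 0.0
        for f in folds:
            train = np.setdiff1d(order, f)
            model = fit_fn(X[train], Y[train], ridge)
            mse += float(np.mean((model.predict(X[f]).T - Y[f]) ** 2))
        if mse < best_mse:
            best, best_mse = ridge, mse
    return float(best)


def _drug_metrics(preds: list, truths: list, groups: list) -> dict:
    P = np.vstack(preds)
    T = np.vstack(truths)
    g = np.concatenate(groups)
    return {
        "pearson_r": pearson_r(P, T),
        "mean_r2": mean_r2(P, T),
        "mean_cosine": mean_cosine_centered(P, T, g),
    }


def drug_screen_run(seed: int, cfg: dict | None = None, n_target_train: int | None = None) -> dict:
    """One seed of the drug-screen transfer benchmark.

    Trains the NTK source model on the source cell lines, then for every
    held-out cell line compares (i) the combined projected+translated NTK
    head, (ii) the direct NTK baseline on the cell's own training drugs, and
    (iii) mean-over-cell-line imputation, on the seen-drug and unseen-drug
    test strata.  Ridge coefficients are selected by cross-validated grid
    search (source: on the source table; target models: on the first
    held-out cell's training drugs).  Metrics are pooled across held-out
    cells (the cell id is the centering group for the cosine metric).
    """
    cfg = dict(DRUG_SCREEN_BENCHMARK if cfg is None else cfg)
    sim: DrugScreenSim = cfg["sim"]
    sim = DrugScreenSim(**{**sim.__dict__, "seed": seed})
    data = gen_drug_screen(
        sim,
        held_out_cells=cfg["held_out_cells"],
        held_out_drugs=cfg["held_out_drugs"],
        n_target_train=n_target_train or cfg["n_target_train"],
    )
    spec = KernelSpec("ntk_fc", depth=cfg["ntk_depth"], offset=cfg["ntk_offset"])
    grid = cfg.get("ridge_grid", RIDGE_GRID)
    folds = cfg.get("cv_folds", 5)

    def fit_direct(X, Y, ridge):
        return fit_kernel(spec, X, Y, ridge=ridge)

    source_ridge = select_ridge(fit_direct, data.X_source, data.Y_source,
                                grid=grid, n_folds=folds, seed=seed)
    source = fit_kernel(spec, data.X_source, data.Y_source, ridge=source_ridge)
    tune = data.targets[0]

    def fit_transfer_head(X, Y, ridge):
        return fit_projected_translated(source, X, Y, head_spec=spec, ridge=ridge)

    transfer_ridge = select_ridge(fit_transfer_head, tune.X_train, tune.Y_train,
                                  grid=grid, n_folds=folds, seed=seed + 1)
    baseline_ridge = select_ridge(fit_direct, tune.X_train, tune.Y_train,
                                  grid=grid, n_folds=folds, seed=seed + 1)
    n_src_cells = data.source_cells.size
    n_src_drugs = data.source_drugs.size
    drug_means = data.Y_source.reshape(n_src_cells, n_src_drugs, -1).mean(axis=0)
    drug_mean_of = dict(zip(data.source_drugs.tolist(), drug_means))

    collect = {
        model: {stratum: {"pred": [], "truth": [], "group": []} for stratum in ("seen", "unseen")}
        for model in ("transfer", "baseline", "mean")
    }
    for tgt in data.targets:
        transfer = fit_projected_translated(
            source, tgt.X_train, tgt.Y_train, head_spec=spec, ridge=transfer_ridge
        )
        baseline = fit_kernel(spec, tgt.X_train, tgt.Y_train, ridge=baseline_ridge)
        for stratum, X, Y, drugs in (
            ("seen", tgt.X_seen, tgt.Y_seen, tgt.seen_drugs),
            ("unseen", tgt.X_unseen, tgt.Y_unseen, tgt.unseen_drugs),
        ):
            group = np.full(Y.shape[0], tgt.cell)
            for model, pred in (
                ("transfer", transfer.predict(X).T),
                ("baseline", baseline.predict(X).T),
            ):
                collect[model][stratum]["pred"].append(pred)
                collect[model][stratum]["truth"].append(Y)
                collect[model][stratum]["group"].append(group)
            if stratum == "seen":  # mean imputation needs the drug in the source
                collect["mean"]["seen"]["pred"].append(
                    np.vstack([drug_mean_of[p] for p in drugs])
                )
                collect["mean"]["seen"]["truth"].append(Y)
                collect["mean"]["seen"]["group"].append(group)

    out = {"ridges": {"source": source_ridge, "transfer": transfer_ridge,
                      "baseline": baseline_ridge}}
    for model, strata in collect.items():
        out[model] = {}
        for stratum, block in strata.items():
            if not block["pred"]:
                continue
            out[model][stratum] = _drug_metrics(block["pred"], block["truth"], block["group"])
    return out


# Target-training-set sizes for drug-screen learning curves: log-spaced and
# confined to the rising regime (the 3-seed-averaged transfer score reaches
# its ~0.94 plateau near 28 training drugs, so the curve stops at 21).
DRUG_CURVE_GRID = (3, 4, 5, 7, 9, 12, 16, 21)


def drug_screen_learning_curve(
    seed: int, n_grid=DRUG_CURVE_GRID, metric: str = "mean_r2", cfg: dict | None = None
) -> dict:
    """Transfer and baseline scores on the unseen-drug stratum vs. training size.

    The unseen stratum is fixed (held-out drugs never enter the training
    pool), so the evaluation set is identical at every curve point; the
    training drugs are nested prefixes of a per-seed permutation.
    """
    n_grid = np.asarray(n_grid, dtype=int)
    transfer_scores = np.empty(n_grid.size)
    baseline_scores = np.empty(n_grid.size)
    for i, n in enumerate(n_grid):
        res = drug_screen_run(seed, cfg=cfg, n_target_train=int(n))
        transfer_scores[i] = res["transfer"]["unseen"][metric]
        baseline_scores[i] = res["baseline"]["unseen"][metric]
    return {
        "n": n_grid,
        "transfer": transfer_scores,
        "baseline": baseline_scores,
        "transfer_fit": fit_log_law(n_grid, transfer_scores),
        "baseline_fit": fit_log_law(n_grid, baseline_scores),
    }


def drug_scaling_replicate(
    replicate: int, n_grid=DRUG_CURVE_GRID, seeds_per_point: int = 3
) -> dict:
    """3-seed-averaged drug-screen learning curves with their log-law fits."""
    n_grid = np.asarray(n_grid, dtype=int)
    t_curves, b_curves = [], []
    for j in range(seeds_per_point):
        res = drug_screen_learning_curve(replicate * seeds_per_point + j, n_grid=n_grid)
        t_curves.append(res["transfer"])
        b_curves.append(res["baseline"])
    t, b = np.mean(t_curves, axis=0), np.mean(b_curves, axis=0)
    return {
        "n_grid": n_grid,
        "transfer": t,
        "baseline": b,
        "transfer_fit": fit_log_law(n_grid, t),
        "baseline_fit": fit_log_law(n_grid, b),
    }
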