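"""Three-stage random-forest variable selection.

Stage 1 (thresholding) ranks variables by replicated OOB permutation
importance and drops those below a data-driven threshold derived from the
importance standard deviations of the ranking.  Stage 2 (interpretation)
grows nested models in importance order and keeps the smallest model whose
mean OOB error is within one standard deviation of the best.  Stage 3
(prediction) adds interpretation variables stepwise, admitting a variable
only when it improves OOB error by more than the noise-level fluctuation
estimated from the stage-2-rejected models.

The nesting invariant prediction <= interpretation <= thresholded holds by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor

from .forest import OobRandomForest


@dataclass
class VsurfConfig:
    ntree_thres: int = 300
    nfor_thres: int = 40
    ntree_interp: int = 100
    nfor_interp: int = 30
    ntree_pred: int = 100
    nfor_pred: int = 10
    seed: int = 0
    task: str = "classification"
    mtry: int | None = None  # default ceil(sqrt(p)) since p varies per stage

    def __post_init__(self) -> None:
        for name in ("ntree_thres", "nfor_thres", "ntree_interp",
                     "nfor_interp", "ntree_pred", "nfor_pred"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class SelectionResult:
    variables: list
    importance_mean: np.ndarray
    importance_sd: np.ndarray
    ranking: list
    threshold_value: float
    vars_thresholded: list
    vars_interpretation: list
    vars_prediction: list
    oob_error_path: pd.DataFrame = field(default=None)
    task: str = "classification"

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "importance": {
                v: {"mean": float(m), "sd": float(s)}
                for v, m, s in zip(self.variables, self.importance_mean, self.importance_sd)
            },
            "threshold_value": float(self.threshold_value),
            "vars_thresholded": list(self.vars_thresholded),
            "vars_interpretation": list(self.vars_interpretation),
            "vars_prediction": list(self.vars_prediction),
            "oob_error_path": (
                self.oob_error_path.to_dict(orient="list")
                if self.oob_error_path is not None else None
            ),
        }


def _columns(X):
    if isinstance(X, pd.DataFrame):
        return list(X.columns), X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    return [f"v{j}" for j in range(X.shape[1])], X


def _mtry(config, p):
    if config.mtry is not None:
        return min(config.mtry, p)
    return max(1, int(np.ceil(np.sqrt(p))))


def _mean_oob_error(Xsub, y, config, ntree, nfor, seed_base):
    errs = np.empty(nfor)
    for r in range(nfor):
        f = OobRandomForest(
            task=config.task, n_trees=ntree, mtry=_mtry(config, Xsub.shape[1]),
            seed=seed_base + r,
        ).fit(Xsub, y)
        errs[r] = f.oob_error_
    return float(errs.mean()), float(errs.std(ddof=1)) if nfor > 1 else 0.0


def rank_importance(X, y, config: VsurfConfig):
    """Replicated OOB permutation importance; returns (names, mean, sd,
    ranking indices descending by mean, ties by first appearance)."""
    names, Xa = _columns(X)
    if Xa.shape[1] < 2:
        raise ValueError("rank_importance requires >= 2 variables")
    if config.task == "classification" and len(np.unique(y)) < 2:
        raise ValueError("classification target has a single class")
    imps = np.empty((config.nfor_thres, Xa.shape[1]))
    for r in range(config.nfor_thres):
        f = OobRandomForest(
            task=config.task, n_trees=config.ntree_thres,
            mtry=_mtry(config, Xa.shape[1]), seed=config.seed * 100003 + r,
        ).fit(Xa, y)
        imps[r] = f.permutation_importance()
    mean = imps.mean(axis=0)
    sd = imps.std(axis=0, ddof=1) if config.nfor_thres > 1 else np.zeros_like(mean)
    order = np.argsort(-mean, kind="stable")
    return names, mean, sd, order


def threshold_step(mean, sd, order):
    """Stage 1: retain variables whose mean importance clears the threshold.

    The threshold is the minimum of a CART regression (unlimited depth,
    minimum leaf 1) of importance sd on rank: with replicated forests, noise
    variables fluctuate around zero with spread comparable to their sd, so
    the smallest fitted sd separates stably important variables from noise.
    """
    ranks = np.arange(len(order), dtype=float)[:, None]
    sd_ranked = np.asarray(sd)[order]
    cart = DecisionTreeRegressor(min_samples_leaf=1, random_state=0)
    cart.fit(ranks, sd_ranked)
    threshold = float(cart.predict(ranks).min())
    keep = [int(j) for j in order if mean[j] >= threshold]
    return keep, threshold


def interpretation_step(vars_thresholded, X, y, config: VsurfConfig):
    """Stage 2: smallest nested model within one sd of the minimal mean OOB
    error.  Returns (selected indices, error path DataFrame)."""
    names, Xa = _columns(X)
    path = []
    for k in range(1, len(vars_thresholded) + 1):
        sub = Xa[:, vars_thresholded[:k]]
        m, s = _mean_oob_error(
            sub, y, config, config.ntree_interp, config.nfor_interp,
            seed_base=config.seed * 100003 + 50021 * k,
        )
        path.append({"n_vars": k, "oob_mean": m, "oob_sd": s})
    path = pd.DataFrame(path)
    i_min = int(path["oob_mean"].idxmin())
    cutoff = path.loc[i_min, "oob_mean"] + path.loc[i_min, "oob_sd"]
    k_sel = int(path.loc[path["oob_mean"] <= cutoff, "n_vars"].iloc[0])
    return vars_thresholded[:k_sel], path


def prediction_step(vars_interpretation, vars_thresholded, interp_path, X, y,
                    config: VsurfConfig):
    """Stage 3: stepwise inclusion; a variable enters only if it lowers mean
    OOB error by more than the mean |first difference| of the OOB errors of
    the stage-2-rejected nested models (0 when none were rejected)."""
    if not vars_interpretation:
        return []
    names, Xa = _columns(X)
    rejected = interp_path[interp_path["n_vars"] > len(vars_interpretation)]
    if len(rejected) >= 2:
        noise_gap = float(np.mean(np.abs(np.diff(rejected["oob_mean"].to_numpy()))))
    else:
        noise_gap = 0.0
    selected = [vars_interpretation[0]]
    err_cur, _ = _mean_oob_error(
        Xa[:, selected], y, config, config.ntree_pred, config.nfor_pred,
        seed_base=config.seed * 100003 + 90001,
    )
    for step, v in enumerate(vars_interpretation[1:], start=1):
        err_new, _ = _mean_oob_error(
            Xa[:, selected + [v]], y, config, config.ntree_pred, config.nfor_pred,
            seed_base=config.seed * 100003 + 90001 + 977 * step,
        )
        if err_cur - err_new > noise_gap:
            selected.append(v)
            err_cur = err_new
    return selected


def run_vsurf(X, y, config: VsurfConfig | None = None) -> SelectionResult:
    """Run all three stages; see module docstring."""
    config = config or VsurfConfig()
    names, _ = _columns(X)
    names_out, mean, sd, order = rank_importance(X, y, config)
    thres_idx, threshold = threshold_step(mean, sd, order)
    interp_idx, path = interpretation_step(thres_idx, X, y, config)
    pred_idx = prediction_step(interp_idx, thres_idx, path, X, y, config)
    return SelectionResult(
        variables=names,
        importance_mean=mean,
        importance_sd=sd,
        ranking=[names[j] for j in order],
        threshold_value=threshold,
        vars_thresholded=[names[j] for j in thres_idx],
        vars_interpretation=[names[j] for j in interp_idx],
        vars_prediction=[names[j] for j in pred_idx],
        oob_error_path=path,
        task=config.task,
    )


def consensus_candidates(results, target_size: int | None = None):
    """Variables present in the interpretation sets of a strict majority of
    selection runs, ranked by selection frequency then mean importance."""
    if len(results) < 2:
        raise ValueError("consensus requires >= 2 selection results")
    freq, mean_imp = {}, {}
    for res in results:
        imp = dict(zip(res.variables, res.importance_mean))
        for v in res.vars_interpretation:
            freq[v] = freq.get(v, 0) + 1
            mean_imp.setdefault(v, []).append(imp[v])
    ranked = sorted(
        freq, key=lambda v: (-freq[v], -float(np.mean(mean_imp[v])))
    )
    need = len(results) / 2
    majority = [v for v in ranked if freq[v] > need]
    if not majority:
        import warnings

        warnings.warn("no variable reaches a strict majority; returning top-k by frequency")
        majority = ranked
    if target_size is not None:
        majority = majority[:target_size]
    return majority
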