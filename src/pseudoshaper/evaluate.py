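"""Scoring inferred pseudotimes against ground truth, plus the two
experiment harnesses used to constrain the method's hyperparameters:
the aggregation-mode ablation and the initialisation-robustness check.

Because pseudotime direction is algorithmically arbitrary, every score is
computed after min-max scaling both vectors to [0, 1] and flipping the
estimate if its Pearson correlation with the truth is negative.  RMSE is
then comparable across curve families, and correlations are reported as
absolute values.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from ._seeds import derive_int_seed, derive_rng
from .errors import InvalidInputError
from .simulate import TrajectoryDataset

__all__ = [
    "EvalResult",
    "score",
    "compare_aggregation_modes",
    "robustness_experiment",
]


@dataclass(frozen=True)
class EvalResult:
    rmse: float
    pearson_abs: float
    spearman_abs: float
    flipped: bool


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise InvalidInputError("cannot scale a constant vector")
    return (x - lo) / (hi - lo)


def score(p, t) -> EvalResult:
    """RMSE and |correlations| between an estimate and the ground truth.

    Both vectors are min-max scaled to [0, 1]; the estimate is flipped
    (x -> 1 - x) when its Pearson correlation with ``t`` is negative, so
    the reported RMSE reflects the better of the two directions.
    """
    p = np.asarray(getattr(p, "values", p), dtype=float)
    t = np.asarray(t, dtype=float)
    if p.shape != t.shape or p.ndim != 1:
        raise InvalidInputError("pseudotime and truth must be equal-length vectors")
    if p.size < 3:
        raise InvalidInputError("need at least 3 cells to score")
    if np.all(t == t[0]):
        raise InvalidInputError("ground truth is constant")
    t = _minmax(t)
    if np.all(p == p[0]):
        # a constant estimate carries no ordering; score it as such
        return EvalResult(
            rmse=float(np.sqrt(np.mean((0.5 - t) ** 2))),
            pearson_abs=0.0,
            spearman_abs=0.0,
            flipped=False,
        )
    p = _minmax(p)
    r = float(np.corrcoef(p, t)[0, 1])
    flipped = r < 0
    if flipped:
        p = 1.0 - p
    rho = float(stats.spearmanr(p, t).statistic)
    return EvalResult(
        rmse=float(np.sqrt(np.mean((p - t) ** 2))),
        pearson_abs=abs(r),
        spearman_abs=abs(rho),
        flipped=flipped,
    )


def compare_aggregation_modes(datasets: list[TrajectoryDataset], cfg):
    """Selection-based vs direct-PC1 aggregation, dataset by dataset.

    Runs the pipeline on each dataset once per aggregation mode with
    identical seeds (the k-means sweep is shared, since the modes differ
    only after it), scores both against the ground truth and reports the
    paired |Pearson| values and the fraction of datasets where the
    selection mode strictly wins.
    """
    from .pipeline import infer_pseudotime

    if not datasets:
        raise InvalidInputError("need at least one dataset")
    pairs = []
    for ds in datasets:
        res_sel = infer_pseudotime(ds.coords, replace(cfg, aggregation="selection"))
        res_pc1 = infer_pseudotime(
            ds.coords, replace(cfg, aggregation="pc1"), _reuse_sweep=res_sel.sweep
        )
        pairs.append(
            (
                score(res_sel.values, ds.t).pearson_abs,
                score(res_pc1.values, ds.t).pearson_abs,
            )
        )
    arr = np.asarray(pairs)
    win_fraction = float(np.mean(arr[:, 0] > arr[:, 1]))
    return arr, win_fraction


def robustness_experiment(
    dataset: TrajectoryDataset, cfg, n_runs: int = 50
) -> np.ndarray:
    """|Pearson| over repeated runs with fresh seeds and cell shuffles.

    Each run shuffles the cells, re-runs the full pipeline with a seed
    derived from the run index, and scores against the shuffled ground
    truth.  The dispersion of the returned vector measures how sensitive
    the ensemble is to k-means stochasticity and to the greedy path
    solver's sensitivity to input order.
    """
    from .pipeline import infer_pseudotime

    if n_runs < 2:
        raise InvalidInputError("need at least 2 runs")
    out = np.empty(n_runs)
    for i in range(n_runs):
        rng = derive_rng(cfg.seed, "shuffle", i)
        perm = rng.permutation(dataset.n)
        run_cfg = replace(cfg, seed=derive_int_seed(cfg.seed, "run", i))
        res = infer_pseudotime(dataset.coords[perm], run_cfg)
        out[i] = score(res.values, dataset.t[perm]).pearson_abs
    return out
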