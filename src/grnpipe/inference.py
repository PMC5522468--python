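"""Tree-ensemble (GENIE3-style) regulatory network inference.

For every target gene an ensemble of regression trees is fitted to predict
the target's expression profile from the profiles of all candidate
regulators (transcription factors), excluding the target itself.  The
importance measure (IM) of a regulator for a target is the average over
trees of the total impurity (variance) reduction attributed to splits on
that regulator.  All regulator->target pairs are then ranked globally by IM;
larger IM indicates a stronger putative regulatory link.

Accounting detail: target profiles are standardized to unit variance by
default, and per-tree importances are the *unnormalized* variance reductions
(each tree's reductions sum to roughly the target's variance), averaged over
the forest.  A target's incoming IMs therefore sum to about 1, which puts
absolute IM thresholds (e.g. 0.006 on a ~126-gene panel) on a comparable
scale across targets.

Sample rows are put into a canonical order (lexicographic by expression
profile) before fitting, so the result is invariant to the order in which
samples arrive; the forest seed for each target is derived from the run seed
and the target's position in the sorted gene list, so results are also
invariant to gene input order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .io import ExpressionMatrix

__all__ = ["InferenceConfig", "infer_grn", "rank_edges"]


@dataclass(frozen=True)
class InferenceConfig:
    n_trees: int = 1000
    max_features: str | int | float = "sqrt"  # candidate features per split
    n_forest_replicates: int = 1
    seed: int = 0
    standardize_targets: bool = True

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.n_forest_replicates < 1:
            raise ValueError("n_forest_replicates must be >= 1")


def _forest_importances(X: np.ndarray, y: np.ndarray, cfg: InferenceConfig, rs: int) -> np.ndarray:
    """Mean over trees of unnormalized impurity reduction per feature."""
    rf = RandomForestRegressor(
        n_estimators=cfg.n_trees,
        max_features=cfg.max_features,
        random_state=rs,
        n_jobs=1,
    )
    rf.fit(X, y)
    imp = np.zeros(X.shape[1])
    for est in rf.estimators_:
        imp += est.tree_.compute_feature_importances(normalize=False)
    return imp / len(rf.estimators_)


def infer_grn(m: ExpressionMatrix, regulators: list[str], cfg: InferenceConfig) -> pd.DataFrame:
    """Rank all regulator->target candidate edges by tree-ensemble importance.

    Parameters
    ----------
    m
        Expression matrix (normalized linear scale is the conventional
        input); absent (all-zero) genes are excluded automatically.
    regulators
        Candidate regulator symbols (the TF list).  Must be a subset of the
        matrix genes.
    cfg
        Forest size, feature-subsampling rule, seed.

    Returns
    -------
    DataFrame with columns regulator, target, im, rank — one row per
    regulator->target pair (no self-edges), sorted by decreasing im with
    ties broken by (regulator, target) lexicographic order.
    """
    unknown = sorted(set(regulators) - set(m.genes))
    if unknown:
        raise ValueError(f"unknown regulator symbols: {unknown}")
    present = set(m.present_genes())
    regs = sorted(r for r in regulators if r in present)
    targets = sorted(present)
    if len(regs) < 2:
        raise ValueError("need at least 2 present regulators")
    if m.shape[1] < 5:
        raise ValueError("need at least 5 samples for tree-ensemble inference")

    values = m.values.loc[sorted(m.genes)].astype(float)
    # canonical sample order: lexicographic by full expression profile
    order = np.lexsort(values.to_numpy())
    values = values.iloc[:, order]

    ss_root = np.random.SeedSequence(cfg.seed)
    im: dict[tuple[str, str], float] = {}
    for t_idx, target in enumerate(targets):
        feats = [r for r in regs if r != target]
        if len(feats) < 1:
            continue
        X = values.loc[feats].to_numpy().T  # samples x regulators
        y = values.loc[target].to_numpy()
        sd = y.std()
        if sd == 0:
            warnings.warn(f"target {target} has zero variance; IMs set to 0", RuntimeWarning, stacklevel=2)
            for r in feats:
                im[(r, target)] = 0.0
            continue
        if cfg.standardize_targets:
            y = y / sd
        acc = np.zeros(len(feats))
        for rep in range(cfg.n_forest_replicates):
            child = np.random.SeedSequence(cfg.seed, spawn_key=(t_idx, rep))
            rs = int(child.generate_state(1)[0] % (2**32 - 1))
            acc += _forest_importances(X, y, cfg, rs)
        acc /= cfg.n_forest_replicates
        for r, v in zip(feats, acc):
            im[(r, target)] = float(v)

    edges = pd.DataFrame(
        [(r, t, v) for (r, t), v in im.items()], columns=["regulator", "target", "im"]
    )
    return rank_edges(edges)


def rank_edges(edges: pd.DataFrame) -> pd.DataFrame:
    """Sort by decreasing IM (ties: lexicographic regulator, target) and assign ranks 1..E."""
    out = edges.sort_values(
        ["im", "regulator", "target"], ascending=[False, True, True], kind="mergesort"
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out
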