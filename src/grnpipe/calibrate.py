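"""Gold-standard calibration of the importance-measure threshold.

The ranked edge list is scored against a literature gold standard of known
regulator->target interactions: for a sweep of IM thresholds the number of
retained predictions and the fraction of gold-standard edges among them
(sensitivity) trace the trade-off curve from which a working threshold is
chosen.  Three selection modes are provided: ``manual`` (a threshold chosen
by inspection, the faithful mode), ``knee`` (maximum perpendicular distance
from the chord of the normalized curve, an automated default) and ``top_k``
(keep the k best-ranked edges).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "GoldStandard",
    "CalibrationCurve",
    "CalibrationResult",
    "sensitivity_curve",
    "select_threshold",
    "build_network",
    "ranking_auroc",
    "ranking_aupr",
]


@dataclass
class GoldStandard:
    edges: list[tuple[str, str]]
    source: str = ""

    def __post_init__(self) -> None:
        if len(set(self.edges)) != len(self.edges):
            raise ValueError("gold standard contains duplicate edges")

    def restrict_to(self, universe: set[str]) -> "GoldStandard":
        """Drop edges whose endpoints are outside the gene universe (with a warning)."""
        kept = [(r, t) for r, t in self.edges if r in universe and t in universe]
        dropped = len(self.edges) - len(kept)
        if dropped:
            warnings.warn(
                f"dropped {dropped} gold-standard edges outside the gene universe",
                RuntimeWarning,
                stacklevel=2,
            )
        return GoldStandard(edges=kept, source=self.source)

    @classmethod
    def read(cls, path, source: str = "") -> "GoldStandard":
        sep = "," if str(path).endswith(".csv") else "\t"
        df = pd.read_csv(path, sep=sep)
        if df.shape[1] < 2:
            raise ValueError("gold-standard file needs 2 columns (regulator, target)")
        cols = list(df.columns[:2])
        return cls(edges=[(str(a), str(b)) for a, b in zip(df[cols[0]], df[cols[1]])], source=source or str(path))


@dataclass
class CalibrationCurve:
    """Points of (im_threshold, n_predictions, n_true_positives, sensitivity)."""

    points: pd.DataFrame

    def __post_init__(self) -> None:
        req = ["im_threshold", "n_predictions", "n_true_positives", "sensitivity"]
        if list(self.points.columns) != req:
            raise ValueError(f"curve columns must be {req}")
        thr = self.points["im_threshold"].to_numpy()
        if len(thr) > 1 and not np.all(np.diff(thr) > 0):
            raise ValueError("thresholds must be strictly increasing")


@dataclass(frozen=True)
class CalibrationResult:
    chosen_threshold: float
    n_edges: int
    n_nodes: int
    selection_mode: str  # manual | knee | top_k
    k: int | None = None


def sensitivity_curve(ranked: pd.DataFrame, gs: GoldStandard, thresholds) -> CalibrationCurve:
    """Count predictions and recovered gold-standard edges at each IM threshold.

    Matching is exact and directed: a prediction counts as a true positive
    only if the identical (regulator, target) pair is in the gold standard.
    """
    if not gs.edges:
        raise ValueError("empty gold standard")
    thresholds = sorted(set(float(t) for t in thresholds))
    ims = ranked["im"].to_numpy(dtype=float)
    is_gs = ranked.apply(lambda r: (r["regulator"], r["target"]) in set(gs.edges), axis=1).to_numpy()
    rows = []
    for t in thresholds:
        keep = ims >= t
        tp = int(np.sum(is_gs & keep))
        rows.append(
            {
                "im_threshold": t,
                "n_predictions": int(keep.sum()),
                "n_true_positives": tp,
                "sensitivity": tp / len(gs.edges),
            }
        )
    return CalibrationCurve(points=pd.DataFrame(rows))


def select_threshold(
    curve: CalibrationCurve | None,
    mode: str,
    k_or_value: float | int | None = None,
    ranked: pd.DataFrame | None = None,
) -> CalibrationResult:
    """Pick the working IM threshold.

    ``manual``: use ``k_or_value`` as the threshold (warn when outside the
    observed IM range).  ``knee``: the curve point maximizing perpendicular
    distance from the chord of the axis-normalized (n_predictions,
    sensitivity) curve; ties go to the larger threshold.  ``top_k``: the IM
    of the ``k_or_value``-th ranked edge.
    """
    if ranked is None:
        raise ValueError("select_threshold needs the ranked edge list")
    ims = ranked["im"].to_numpy(dtype=float)

    if mode == "manual":
        thr = float(k_or_value)
        if len(ims) and not (ims.min() <= thr <= ims.max()):
            warnings.warn(
                f"manual threshold {thr} outside observed IM range "
                f"[{ims.min():.4g}, {ims.max():.4g}]",
                RuntimeWarning,
                stacklevel=2,
            )
        k = None
    elif mode == "top_k":
        k = int(k_or_value)
        if not (1 <= k <= len(ranked)):
            raise ValueError(f"top_k k={k} outside 1..{len(ranked)}")
        thr = float(ranked.loc[ranked["rank"] == k, "im"].iloc[0])
    elif mode == "knee":
        if curve is None or curve.points.empty:
            raise ValueError("knee mode needs a calibration curve")
        pts = curve.points
        if len(pts) == 1:
            thr = float(pts["im_threshold"].iloc[0])
        else:
            x = pts["n_predictions"].to_numpy(dtype=float)
            y = pts["sensitivity"].to_numpy(dtype=float)
            xr = x.max() - x.min() or 1.0
            yr = y.max() - y.min() or 1.0
            xn, yn = (x - x.min()) / xr, (y - y.min()) / yr
            x0, y0, x1, y1 = xn[0], yn[0], xn[-1], yn[-1]
            denom = np.hypot(x1 - x0, y1 - y0) or 1.0
            dist = np.abs((y1 - y0) * xn - (x1 - x0) * yn + x1 * y0 - y1 * x0) / denom
            best = max(range(len(pts)), key=lambda i: (dist[i], pts["im_threshold"].iloc[i]))
            thr = float(pts["im_threshold"].iloc[best])
        k = None
    else:
        raise ValueError(f"unknown selection mode {mode!r}")

    if mode == "top_k":
        kept = ranked[ranked["rank"] <= k]
    else:
        kept = ranked[ranked["im"] >= thr]
    nodes = set(kept["regulator"]) | set(kept["target"])
    return CalibrationResult(
        chosen_threshold=thr, n_edges=len(kept), n_nodes=len(nodes), selection_mode=mode, k=k
    )


def build_network(ranked: pd.DataFrame, result: CalibrationResult) -> nx.DiGraph:
    """Materialize the thresholded directed network with IM edge weights.

    Nodes are exactly the symbols incident to a retained edge.  Edges at the
    threshold boundary (im == threshold) are kept.
    """
    if result.selection_mode == "top_k":
        kept = ranked[ranked["rank"] <= result.k]
    else:
        kept = ranked[ranked["im"] >= result.chosen_threshold]
    if kept.empty:
        raise ValueError("no edges retained at the chosen threshold")
    g = nx.DiGraph()
    for r in kept.itertuples():
        g.add_edge(r.regulator, r.target, im=float(r.im), rank=int(r.rank))
    return g


# -- evaluation utilities (used by tests and recovery benchmarks) ----------------


def _pair_scores(ranked: pd.DataFrame, truth: set[tuple[str, str]]):
    scores = ranked["im"].to_numpy(dtype=float)
    labels = np.array([(r, t) in truth for r, t in zip(ranked["regulator"], ranked["target"])])
    return scores, labels


def ranking_auroc(ranked: pd.DataFrame, truth_edges) -> float:
    """AUROC of the IM ranking against a ground-truth edge set, over the
    candidate pairs present in the ranked list."""
    from sklearn.metrics import roc_auc_score

    scores, labels = _pair_scores(ranked, {(r, t) for r, t, *_ in truth_edges})
    if labels.all() or not labels.any():
        raise ValueError("truth covers all or none of the candidate pairs")
    return float(roc_auc_score(labels, scores))


def ranking_aupr(ranked: pd.DataFrame, truth_edges) -> float:
    """Area under precision-recall for the IM ranking."""
    from sklearn.metrics import average_precision_score

    scores, labels = _pair_scores(ranked, {(r, t) for r, t, *_ in truth_edges})
    if not labels.any():
        raise ValueError("no true edges among candidate pairs")
    return float(average_precision_score(labels, scores))
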