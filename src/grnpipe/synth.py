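"""Ground-truth network and expression simulation for known-answer testing.

The generator produces (i) a signed, weighted ground-truth regulatory network
over ~126 genes of which roughly half are transcription factors, and (ii) a
simulated perturbation time-course screen with the study design of the assay
it emulates: two conditions (control vs treatment) x three timepoints
(6/12/24 h) x three replicates.

Expression model
----------------
Latent log-expression per sample is the fixed point (reached by iterated
propagation, clipped to tame feedback loops) of a linear system

    x  <-  basal + b + W x,        x[signal] held at basal + b + signal level

where ``W[target, regulator]`` carries the signed edge weights, ``b`` is a
per-gene per-sample biological perturbation (log-scale Gaussian, sd
``biological_sd``) representing explant-to-explant variability, and the
signal gene is an exogenous input whose level depends on condition and
timepoint.  Observed expression is

    y = exp(x + measurement noise) * per-sample library factor,

with housekeeping probes simulated as network-independent constants (so that
geometric-mean normalization removes the library factors exactly).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, ProbeAnnotation, SampleDesign

__all__ = [
    "Motif",
    "SyntheticGRNSpec",
    "SimulationConfig",
    "make_grn",
    "simulate_expression",
    "sample_gold_standard",
    "write_dataset",
]


@dataclass(frozen=True)
class Motif:
    """A small circuit to plant verbatim into the random network.

    ``kind`` is ``mutual_activation`` (A<->B, both weights +) or
    ``mutual_repression`` (A<->B, both weights -).
    """

    kind: str
    gene_a: str
    gene_b: str
    weight: float = 1.0

    def edges(self) -> list[tuple[str, str, float]]:
        w = abs(self.weight)
        if self.kind == "mutual_activation":
            return [(self.gene_a, self.gene_b, w), (self.gene_b, self.gene_a, w)]
        if self.kind == "mutual_repression":
            return [(self.gene_a, self.gene_b, -w), (self.gene_b, self.gene_a, -w)]
        raise ValueError(f"unknown motif kind {self.kind!r}")


@dataclass
class SyntheticGRNSpec:
    """Ground-truth signed network plus the roles needed to simulate it."""

    genes: list[str]
    tfs: list[str]
    edges: list[tuple[str, str, float]]  # (regulator, target, signed weight)
    signal_gene: str
    allow_cycles: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        gene_set = set(self.genes)
        tf_set = set(self.tfs)
        if not tf_set <= gene_set:
            raise ValueError("TFs must be a subset of genes")
        for reg, tgt, w in self.edges:
            if reg == tgt:
                raise ValueError(f"self-edge on {reg}")
            if w == 0:
                raise ValueError(f"zero-weight edge {reg}->{tgt}")
            if reg not in tf_set:
                raise ValueError(f"regulator {reg} is not a TF")
            if tgt not in gene_set:
                raise ValueError(f"unknown target {tgt}")
        if len({(r, t) for r, t, _ in self.edges}) != len(self.edges):
            raise ValueError("duplicate directed edges in truth network")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def edge_set(self) -> set[tuple[str, str]]:
        return {(r, t) for r, t, _ in self.edges}

    def weight_matrix(self) -> pd.DataFrame:
        """Dense W with W.loc[target, regulator] = weight."""
        W = pd.DataFrame(0.0, index=self.genes, columns=self.genes)
        for reg, tgt, w in self.edges:
            W.loc[tgt, reg] = w
        return W


@dataclass
class SimulationConfig:
    timepoints: tuple[float, ...] = (6.0, 12.0, 24.0)
    replicates: int = 3
    conditions: tuple[str, ...] = ("control", "treatment")
    signal_profile: dict | None = None  # (condition, timepoint) -> signal level
    noise_sd: float = 0.1
    biological_sd: float = 0.5
    library_size_sd: float = 0.2
    basal_level: float = 1.0
    propagation_steps: int = 20
    clip_bound: float = 12.0
    n_housekeeping: int = 4
    poisson_counts: bool = False
    counts_scale: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.biological_sd < 0 or self.library_size_sd < 0:
            raise ValueError("noise parameters must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.propagation_steps < 1:
            raise ValueError("propagation_steps must be >= 1")

    def signal_level(self, condition: str, timepoint: float) -> float:
        if self.signal_profile is not None:
            return float(self.signal_profile.get((condition, timepoint), 0.0))
        # default: treatment carries a constant exogenous input, control none
        return 2.0 if condition == "treatment" else 0.0


def _gene_names(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def make_grn(
    n_genes: int,
    tf_fraction: float = 0.5,
    density: float = 0.02,
    p_negative: float = 0.3,
    motif_injection: list[Motif] | None = None,
    seed: int = 0,
    weight_range: tuple[float, float] = (0.8, 1.2),
    allow_cycles: bool = True,
) -> SyntheticGRNSpec:
    """Sample a random signed GRN with planted motifs.

    Each (TF, other-gene) ordered pair becomes an edge independently with
    probability ``density``; weight magnitudes are uniform on ``weight_range``
    and negative with probability ``p_negative``.  The first TF is the signal
    gene (the condition-driven exogenous input).  Requested motifs are added
    verbatim after random sampling (overriding any colliding random edge).
    """
    if not (0 < tf_fraction <= 1):
        raise ValueError("tf_fraction must be in (0, 1]")
    if not (0 <= density < 1):
        raise ValueError("density must be in [0, 1)")
    rng = np.random.default_rng(seed)
    genes = _gene_names(n_genes)
    n_tf = max(1, int(round(tf_fraction * n_genes)))
    tfs = genes[:n_tf]
    signal_gene = tfs[0]
    tf_set = set(tfs)

    # admissible (regulator, target) pairs; gene index order doubles as a
    # topological order when cycles are disallowed
    mask = np.zeros((n_tf, n_genes), dtype=bool)
    for i in range(n_tf):
        for j in range(n_genes):
            if i == j:
                continue
            if not allow_cycles and i >= j:
                continue
            mask[i, j] = True
    hit = mask & (rng.random((n_tf, n_genes)) < density)
    mags = rng.uniform(weight_range[0], weight_range[1], size=(n_tf, n_genes))
    signs = np.where(rng.random((n_tf, n_genes)) < p_negative, -1.0, 1.0)
    edges: dict[tuple[str, str], float] = {
        (tfs[i], genes[j]): float(signs[i, j] * mags[i, j]) for i, j in zip(*np.nonzero(hit))
    }

    for motif in motif_injection or []:
        for reg, tgt, w in motif.edges():
            if reg not in tf_set:
                raise ValueError(f"motif regulator {reg} is not a TF")
            if tgt not in set(genes):
                raise ValueError(f"motif gene {tgt} not in network")
            edges[(reg, tgt)] = w

    edge_list = sorted(((r, t, w) for (r, t), w in edges.items()))
    return SyntheticGRNSpec(
        genes=genes,
        tfs=tfs,
        edges=edge_list,
        signal_gene=signal_gene,
        allow_cycles=allow_cycles,
        seed=seed,
    )


def simulate_expression(
    grn: SyntheticGRNSpec, cfg: SimulationConfig
) -> tuple[ExpressionMatrix, list[tuple[str, str, float]]]:
    """Simulate the perturbation screen; returns the matrix and the true edges.

    The matrix includes ``cfg.n_housekeeping`` extra housekeeping probes
    (HK1..) that sit outside the network and carry no noise, so per-sample
    library factors are exactly recoverable by geometric-mean normalization.
    The returned scale is ``normalized`` (continuous positive expression);
    with ``poisson_counts`` a Poisson layer on ``value * counts_scale``
    produces integer raw counts instead.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = grn.genes
    n = len(genes)
    idx = {g: i for i, g in enumerate(genes)}
    W = np.zeros((n, n))
    for reg, tgt, w in grn.edges:
        W[idx[tgt], idx[reg]] = w
    sig = idx[grn.signal_gene]
    lo, hi = -cfg.clip_bound, cfg.clip_bound

    designs: list[SampleDesign] = []
    columns: list[np.ndarray] = []
    clipped_any = False
    for condition in cfg.conditions:
        for tp in cfg.timepoints:
            level = cfg.signal_level(condition, tp)
            for rep in range(1, cfg.replicates + 1):
                sample_id = f"{condition}_{int(tp)}h_r{rep}"
                designs.append(
                    SampleDesign(sample_id=sample_id, condition=condition, timepoint=float(tp), replicate=rep)
                )
                b = rng.normal(0.0, cfg.biological_sd, size=n) if cfg.biological_sd > 0 else np.zeros(n)
                x = np.full(n, cfg.basal_level)
                x[sig] = cfg.basal_level + b[sig] + level
                for _ in range(cfg.propagation_steps):
                    x_new = cfg.basal_level + b + W @ x
                    x_new[sig] = cfg.basal_level + b[sig] + level
                    if (x_new < lo).any() or (x_new > hi).any():
                        clipped_any = True
                    x = np.clip(x_new, lo, hi)
                eps = rng.normal(0.0, cfg.noise_sd, size=n) if cfg.noise_sd > 0 else np.zeros(n)
                columns.append(np.exp(x + eps))

    if clipped_any:
        warnings.warn(
            "cyclic propagation hit the clip bound; clipped latent values present",
            RuntimeWarning,
            stacklevel=2,
        )

    values = np.column_stack(columns)
    all_genes = list(genes)
    if cfg.n_housekeeping > 0:
        hk = np.full((cfg.n_housekeeping, values.shape[1]), np.exp(cfg.basal_level))
        values = np.vstack([values, hk])
        all_genes += [f"HK{i}" for i in range(1, cfg.n_housekeeping + 1)]

    if cfg.library_size_sd > 0:
        lib = np.exp(rng.normal(0.0, cfg.library_size_sd, size=values.shape[1]))
        values = values * lib

    scale = "normalized"
    if cfg.poisson_counts:
        values = rng.poisson(values * cfg.counts_scale).astype(float)
        scale = "raw_counts"

    frame = pd.DataFrame(values, index=all_genes, columns=[d.sample_id for d in designs])
    matrix = ExpressionMatrix(values=frame, design=designs, scale=scale)
    return matrix, list(grn.edges)


def sample_gold_standard(
    grn: SyntheticGRNSpec, n_edges: int, seed: int = 0
) -> list[tuple[str, str]]:
    """Uniform random subset of the true edges, emulating a partial literature list."""
    if n_edges > len(grn.edges):
        raise ValueError(f"requested {n_edges} gold-standard edges but truth has {len(grn.edges)}")
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(grn.edges), size=n_edges, replace=False)
    return sorted((grn.edges[i][0], grn.edges[i][1]) for i in pick)


def annotation_for(grn: SyntheticGRNSpec, cfg: SimulationConfig) -> list[ProbeAnnotation]:
    tf_set = set(grn.tfs)
    ann = [
        ProbeAnnotation(gene=g, is_tf=g in tf_set, category="signalling" if g == grn.signal_gene else "other")
        for g in grn.genes
    ]
    ann += [
        ProbeAnnotation(gene=f"HK{i}", is_housekeeping=True, category="housekeeping")
        for i in range(1, cfg.n_housekeeping + 1)
    ]
    return ann


def write_dataset(grn: SyntheticGRNSpec, cfg: SimulationConfig, outdir) -> dict[str, str]:
    """Write counts/design/annotation/TF-list/truth TSVs consumed by the I/O layer.

    Returns a dict of artifact name -> path.  The truth network is written
    both as a 3-column edge TSV and as GraphML.
    """
    import pathlib

    import networkx as nx

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix, truth = simulate_expression(grn, cfg)

    counts = matrix.values.copy()
    counts.insert(0, "gene", counts.index)
    paths = {
        "counts": str(outdir / "counts.tsv"),
        "design": str(outdir / "design.tsv"),
        "annotation": str(outdir / "annotation.tsv"),
        "tf_list": str(outdir / "tf_list.txt"),
        "truth": str(outdir / "truth_edges.tsv"),
        "truth_graphml": str(outdir / "truth.graphml"),
        "gold_standard": str(outdir / "gold.tsv"),
    }
    counts.to_csv(paths["counts"], sep="\t", index=False)
    matrix.design_frame().to_csv(paths["design"], sep="\t", index=False)

    ann = annotation_for(grn, cfg)
    pd.DataFrame(
        {
            "gene": [a.gene for a in ann],
            "is_tf": [a.is_tf for a in ann],
            "category": [a.category for a in ann],
            "is_housekeeping": [a.is_housekeeping for a in ann],
            "is_positive_control": [a.is_positive_control for a in ann],
        }
    ).to_csv(paths["annotation"], sep="\t", index=False)
    with open(paths["tf_list"], "w") as fh:
        fh.write("\n".join(grn.tfs) + "\n")

    pd.DataFrame(truth, columns=["regulator", "target", "weight"]).to_csv(
        paths["truth"], sep="\t", index=False
    )
    # emulated partial literature gold standard (subsample of the truth)
    gold = sample_gold_standard(grn, min(76, len(grn.edges)), seed=cfg.seed)
    pd.DataFrame(gold, columns=["regulator", "target"]).to_csv(
        paths["gold_standard"], sep="\t", index=False
    )
    g = nx.DiGraph()
    g.add_nodes_from(grn.genes)
    for reg, tgt, w in truth:
        g.add_edge(reg, tgt, weight=float(w))
    nx.write_graphml(g, paths["truth_graphml"])
    return paths
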