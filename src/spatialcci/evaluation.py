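"""Link-prediction metrics and the two robustness benchmarks.

Reconstruction quality is scored as link prediction: held-out (removed)
edges are positives, an equal-size seeded sample of non-edges are negatives,
and the decoder's edge probabilities are the scores. Metrics are AUROC
(trapezoidal area, tied pairs counting one half), average precision
(step-wise sum (R_n - R_{n-1}) P_n over the score sweep) and accuracy at a
probability threshold (0.5 by default).

Two benchmark experiments mirror the standard stress tests for CCI
reconstruction: ``edge_removal_experiment`` deletes a fraction of edges and
asks the model to recover them; ``noise_experiment`` perturbs the expression
features with Gaussian noise of growing standard deviation. Both replicate
over seeds and report per-seed rows plus per-condition averages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .preprocess import ExpressionMatrix, add_gaussian_noise
from .spatial_graph import Adjacency
from .vgae import VGAE, ReconstructedAdjacency


class UndefinedMetricError(ValueError):
    """Rank metrics need at least one positive and one negative label."""


@dataclass
class BinaryScores:
    """Paired labels/scores for a binary ranking problem."""

    labels: np.ndarray
    scores: np.ndarray
    threshold: float = 0.5

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, int)
        self.scores = np.asarray(self.scores, float)
        if self.labels.shape != self.scores.shape:
            raise ValueError("labels and scores must have equal length")
        if self.labels.size == 0:
            raise ValueError("empty input")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be 0/1")


def _require_both_classes(bs: BinaryScores) -> None:
    if bs.labels.min() == bs.labels.max():
        raise UndefinedMetricError("need at least one positive and one negative")


def roc_auc(bs: BinaryScores) -> float:
    """Trapezoidal AUROC; equivalent to the probability that a random
    positive outscores a random negative, ties counting one half."""
    _require_both_classes(bs)
    return float(roc_auc_score(bs.labels, bs.scores))


def average_precision(bs: BinaryScores) -> float:
    """Step-wise average precision sum_n (R_n - R_{n-1}) P_n."""
    _require_both_classes(bs)
    return float(average_precision_score(bs.labels, bs.scores))


def accuracy(bs: BinaryScores, threshold: float | None = None) -> float:
    """(TP + TN) / (TP + TN + FP + FN) at the given score threshold."""
    t = bs.threshold if threshold is None else threshold
    calls = (bs.scores >= t).astype(int)
    return float((calls == bs.labels).mean())


def sample_negative_edges(A: Adjacency, k: int, seed: int) -> list[tuple[int, int]]:
    """k distinct unordered non-edge pairs (i < j, A_ij = 0), seeded."""
    n = A.n_nodes
    ii, jj = np.triu_indices(n, k=1)
    non = A.matrix[ii, jj] == 0
    candidates = np.flatnonzero(non)
    if k > candidates.size:
        raise ValueError(f"requested {k} negative edges but only {candidates.size} non-edges exist")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(candidates, size=k, replace=False)
    return [(int(ii[c]), int(jj[c])) for c in chosen]


def remove_edges(A: Adjacency, fraction: float, seed: int) -> tuple[Adjacency, list[tuple[int, int]]]:
    """Uniformly remove ``fraction`` of the undirected edges; returns the
    reduced graph and the list of removed (held-out positive) edges."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    edges = A.edge_list()
    n_remove = int(round(fraction * len(edges)))
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(edges), size=n_remove, replace=False)
    removed = [edges[i] for i in idx]
    M = A.matrix.copy()
    for i, j in removed:
        M[i, j] = M[j, i] = 0
    if M.sum() == 0:
        raise ValueError("edge removal left an empty graph")
    return Adjacency(M, node_ids=list(A.node_ids)), removed


@dataclass
class EvalReport:
    """Per-seed metric rows plus per-condition arithmetic means.

    ``rows`` has columns (condition, seed, ACC, AUROC, AP); ``averages``
    one row per condition with the means. Display rounds to 3 decimals,
    full precision is retained in the frames.
    """

    rows: pd.DataFrame
    metadata: dict = field(default_factory=dict)
    curves: pd.DataFrame | None = None  # optional per-epoch AUROC/AP traces

    def curves_to_csv(self, path) -> None:
        if self.curves is None:
            raise ValueError("no per-epoch curves were recorded")
        self.curves.to_csv(path, index=False)

    @property
    def averages(self) -> pd.DataFrame:
        return (
            self.rows.groupby("condition", sort=False)[["ACC", "AUROC", "AP"]]
            .mean()
            .reset_index()
        )

    def __str__(self) -> str:
        out = self.rows.copy()
        avg = self.averages.copy()
        avg.insert(1, "seed", "Average")
        disp = pd.concat([out, avg], ignore_index=True)
        for c in ("ACC", "AUROC", "AP"):
            disp[c] = disp[c].map(lambda v: f"{v:.3f}")
        return disp.to_string(index=False)

    def to_tsv(self, path) -> None:
        self.rows.to_csv(path, sep="\t", index=False)


def seed_report(rows: pd.DataFrame | list[dict], metadata: dict | None = None) -> EvalReport:
    """Assemble per-seed metric rows into an EvalReport with per-condition
    average rows appended on display."""
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("at least one row required")
    if "condition" not in df.columns:
        df.insert(0, "condition", "all")
    return EvalReport(rows=df, metadata=metadata or {})


def score_heldout(
    result_probs: ReconstructedAdjacency | np.ndarray,
    positives: list[tuple[int, int]],
    negatives: list[tuple[int, int]],
    threshold: float = 0.5,
) -> BinaryScores:
    probs = result_probs.probs if isinstance(result_probs, ReconstructedAdjacency) else result_probs
    pairs = list(positives) + list(negatives)
    labels = np.r_[np.ones(len(positives)), np.zeros(len(negatives))]
    scores = np.array([probs[i, j] for i, j in pairs])
    return BinaryScores(labels, scores, threshold=threshold)


def _run_one(X: ExpressionMatrix | np.ndarray, A_train: Adjacency,
             positives, negatives, train_config: dict,
             curve_rows: list | None = None, curve_tag: dict | None = None) -> dict:
    cfg = dict(train_config)
    model = VGAE(
        X, A_train,
        hidden_dims=cfg.pop("hidden_dims", (64, 64, 32)),
        latent_dim=cfg.pop("latent_dim", 16),
        pos_weight=cfg.pop("pos_weight", "auto"),
    )
    callback = None
    if curve_rows is not None:
        def callback(epoch, terms, latent, recon):
            bs_e = score_heldout(recon, positives, negatives)
            curve_rows.append({**(curve_tag or {}), "epoch": epoch,
                               "AUROC": roc_auc(bs_e),
                               "AP": average_precision(bs_e)})
    res = model.fit(**cfg, callback=callback)
    bs = score_heldout(res.predict_proba(), positives, negatives)
    return {
        "ACC": accuracy(bs),
        "AUROC": roc_auc(bs),
        "AP": average_precision(bs),
    }


def edge_removal_experiment(
    X: ExpressionMatrix | np.ndarray,
    A: Adjacency,
    fractions: list[float] = (0.1, 0.2, 0.3, 0.4, 0.5),
    seeds: list[int] = (0, 1, 2, 3, 4),
    train_config: dict | None = None,
) -> EvalReport:
    """Recovery of randomly deleted edges.

    Per (fraction, seed): remove that fraction of edges, train on the
    remainder, and score the removed edges against an equal-size seeded
    negative sample.
    """
    train_config = train_config or {}
    rows = []
    for frac in fractions:
        for seed in seeds:
            A_train, removed = remove_edges(A, frac, seed)
            negatives = sample_negative_edges(A, len(removed), seed)
            metrics = _run_one(X, A_train, removed, negatives,
                               {**train_config, "seed": seed})
            rows.append({"condition": f"removed={frac:g}", "seed": seed, **metrics})
    return seed_report(rows, metadata={"experiment": "edge_removal",
                                       "fractions": list(fractions),
                                       "train_config": dict(train_config)})


def noise_experiment(
    X: ExpressionMatrix,
    A: Adjacency,
    std_devs: list[float] = tuple(range(8)),
    seeds: list[int] = (0, 1, 2, 3, 4),
    mask_fraction: float = 0.1,
    train_config: dict | None = None,
    track_curves: bool = False,
) -> EvalReport:
    """Robustness to Gaussian feature noise.

    Per (std_dev, seed): perturb the expression features with N(0, sd^2),
    mask ``mask_fraction`` of edges, train, score the masked edges. At
    sd = 0 this reduces to edge_removal_experiment at the same mask/seed.
    With ``track_curves`` the per-epoch AUROC/AP traces are retained on the
    report for plotting.
    """
    train_config = train_config or {}
    rows = []
    curve_rows: list | None = [] if track_curves else None
    for sd in std_devs:
        for seed in seeds:
            X_noisy = add_gaussian_noise(X, sd, seed)
            A_train, removed = remove_edges(A, mask_fraction, seed)
            negatives = sample_negative_edges(A, len(removed), seed)
            metrics = _run_one(X_noisy, A_train, removed, negatives,
                               {**train_config, "seed": seed},
                               curve_rows=curve_rows,
                               curve_tag={"condition": f"noise_sd={sd:g}",
                                          "seed": seed})
            rows.append({"condition": f"noise_sd={sd:g}", "seed": seed, **metrics})
    report = seed_report(rows, metadata={"experiment": "noise",
                                         "std_devs": list(std_devs),
                                         "mask_fraction": mask_fraction,
                                         "train_config": dict(train_config)})
    if track_curves:
        report.curves = pd.DataFrame(curve_rows)
    return report


def top_gene_network(
    probs: ReconstructedAdjacency | np.ndarray,
    gene_ids: list[str],
    k: int = 10,
) -> pd.DataFrame:
    """Induced subnetwork on the k genes with the largest total communication
    probability (row sums of the probability matrix, diagonal excluded)."""
    import warnings as _warnings

    P = probs.probs if isinstance(probs, ReconstructedAdjacency) else np.asarray(probs, float)
    n = P.shape[0]
    if k > n:
        _warnings.warn(f"k={k} exceeds gene count {n}; clamping", RuntimeWarning)
        k = n
    strength = P.sum(axis=1) - np.diag(P)
    top = np.argsort(-strength, kind="stable")[:k]
    top_set = set(top.tolist())
    rows = []
    for a in top:
        for b in top:
            if a < b and b in top_set:
                rows.append((gene_ids[a], gene_ids[b], P[a, b]))
    df = pd.DataFrame(rows, columns=["gene_i", "gene_j", "probability"])
    return df.sort_values("probability", ascending=False, ignore_index=True)
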