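"""Multi-slice alignment: Gromov-Wasserstein matching, Procrustes, stacking.

Consecutive tissue sections are registered pairwise. Because each slice is
only known up to a rigid motion of the sectioning plane, correspondence is
found with the Gromov-Wasserstein (GW) discrepancy, which compares slices
through their intra-slice distance matrices and is therefore invariant to
rotation and translation of either slice:

    C(i, k, j, l) = (D_X(i, j) - D_Y(k, l))^2
    GW(C, P)      = sum_{i,j,k,l} C(i,k,j,l) P(i,k) P(j,l)

P is a transport plan with uniform marginals (1/n, 1/m), found by entropic
mirror descent: each outer iteration linearizes the GW objective and
projects onto the transport polytope with Sinkhorn-Knopp row/column scaling
P <- diag(u) K diag(v). Given P, a rigid transform (rotation R, translation
t, optionally an isotropic scale) mapping slice X onto slice Y is recovered
in closed form by weighted Procrustes analysis, and slices are stacked into
3D with a fixed inter-slice spacing along z.

An optional fused cost mixes an expression-feature distance into the GW
linearization (weight alpha, default 0 = purely spatial).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .spatial_graph import SpatialCoords


@dataclass
class SlicePair:
    """Two slices to align: point sets plus their intra-slice distances."""

    X_points: np.ndarray
    Y_points: np.ndarray
    D_X: np.ndarray = None
    D_Y: np.ndarray = None
    X_features: np.ndarray | None = None
    Y_features: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X_points = np.asarray(self.X_points, float)
        self.Y_points = np.asarray(self.Y_points, float)
        if self.D_X is None:
            self.D_X = cdist(self.X_points, self.X_points)
        if self.D_Y is None:
            self.D_Y = cdist(self.Y_points, self.Y_points)
        self.D_X = np.asarray(self.D_X, float)
        self.D_Y = np.asarray(self.D_Y, float)
        for D, pts in ((self.D_X, self.X_points), (self.D_Y, self.Y_points)):
            if D.shape != (len(pts), len(pts)):
                raise ValueError("distance matrix inconsistent with its point set")


@dataclass
class MatchingMatrix:
    """Transport plan between two slices with its Sinkhorn scalers."""

    P: np.ndarray
    u: np.ndarray | None = None
    v: np.ndarray | None = None
    gw_cost: float = np.nan
    n_iter: int = 0
    converged: bool = True

    @property
    def row_assignment(self) -> np.ndarray:
        """Hard correspondence: argmax of each row of P."""
        return np.argmax(self.P, axis=1)


@dataclass
class RigidTransform:
    """y ~ scale * R x + t with R a proper rotation (det +1 by default)."""

    R: np.ndarray
    t: np.ndarray
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, float)
        self.t = np.asarray(self.t, float)
        if not np.allclose(self.R.T @ self.R, np.eye(len(self.R)), atol=1e-8):
            raise ValueError("R is not orthogonal")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return self.scale * points @ self.R.T + self.t

    @property
    def angle_deg(self) -> float:
        """Rotation angle (2D: signed; 3D: magnitude from the trace)."""
        if self.R.shape == (2, 2):
            return float(np.degrees(np.arctan2(self.R[1, 0], self.R[0, 0])))
        c = np.clip((np.trace(self.R) - 1) / 2, -1, 1)
        return float(np.degrees(np.arccos(c)))


def init_matching(n: int, m: int) -> MatchingMatrix:
    """Uniform initial plan P = 1/(n*m) everywhere."""
    if n < 1 or m < 1:
        raise ValueError("n and m must be >= 1")
    return MatchingMatrix(np.full((n, m), 1.0 / (n * m)))


def gw_cost(D_X: np.ndarray, D_Y: np.ndarray, P: np.ndarray) -> float:
    """Quadratic GW objective sum C(i,k,j,l) P(i,k) P(j,l) with squared
    distance-difference cost, evaluated by tensor contraction in O(n^2 m)."""
    D_X, D_Y, P = (np.asarray(a, float) for a in (D_X, D_Y, P))
    p, q = P.sum(axis=1), P.sum(axis=0)
    term = (D_X**2 @ p) @ p + q @ (D_Y**2 @ q) - 2.0 * np.einsum(
        "ij,ik,jl,kl->", D_X, P, P, D_Y, optimize=True
    )
    return float(term)


def _sinkhorn(G: np.ndarray, p: np.ndarray, q: np.ndarray, epsilon: float,
              max_iter: int = 500, tol: float = 1e-9,
              a: np.ndarray | None = None, b: np.ndarray | None = None):
    """KL projection of exp(-G/eps) onto the transport polytope.

    Log-domain Sinkhorn-Knopp: P = diag(u) K diag(v) with K = exp(-G/eps),
    alternating row/column scaling until the scalers stop moving. ``a`` and
    ``b`` warm-start the log-scalers.
    """
    from scipy.special import logsumexp

    logK = -G / epsilon
    a = np.zeros(len(p)) if a is None else a
    b = np.zeros(len(q)) if b is None else b
    logp, logq = np.log(p), np.log(q)
    for _ in range(max_iter):
        a = logp - logsumexp(logK + b[None, :], axis=1)
        b_old = b
        b = logq - logsumexp(logK + a[:, None], axis=0)
        if np.max(np.abs(b - b_old)) < tol:
            break
    P = np.exp(logK + a[:, None] + b[None, :])
    with np.errstate(over="ignore"):  # scalers can overflow at sharp epsilon
        return P, a, b


def align_slices(
    pair: SlicePair,
    epsilon: float = 1e-5,
    anneal_from: float = 1e-2,
    anneal_steps: int = 6,
    max_iter: int = 50,
    tol: float = 1e-8,
    patience: int = 10,
    alpha: float = 0.0,
    scale_epsilon: bool = True,
    seed: int | None = None,
) -> MatchingMatrix:
    """Entropically regularized GW matching between two slices.

    Outer loop: linearize the GW objective at the current plan
    (gradient G = c_const - 2 D_X P D_Y, optionally mixed with a feature
    cost by weight ``alpha``), then Sinkhorn-project exp(-G/eps) onto the
    uniform-marginal polytope; stop when the plan moves less than ``tol``.

    The regularization is annealed: the solve starts blurry at
    ``anneal_from`` and is warm-started down a geometric schedule to the
    target ``epsilon``, which avoids the poor local optima a sharp cold
    start falls into while still ending with a near-permutation plan.
    Both epsilons are scaled by the mean squared intra-slice distance when
    ``scale_epsilon`` so the strength is unit-free. ``seed`` is accepted
    for interface uniformity; the solve is deterministic.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    n, m = len(pair.X_points), len(pair.Y_points)
    if n < 2 or m < 2:
        raise ValueError("both slices need at least 2 points")
    D_X, D_Y = pair.D_X, pair.D_Y
    p = np.full(n, 1.0 / n)
    q = np.full(m, 1.0 / m)
    unit = float(np.mean(D_X**2)) if scale_epsilon else 1.0
    start = max(anneal_from, epsilon)
    if anneal_steps < 1 or start == epsilon:
        schedule = [epsilon]
    else:
        schedule = list(np.geomspace(start, epsilon, anneal_steps))

    feat_cost = None
    if alpha > 0:
        if pair.X_features is None or pair.Y_features is None:
            raise ValueError("alpha > 0 requires per-point features on both slices")
        feat_cost = cdist(pair.X_features, pair.Y_features) ** 2

    # constant part of the GW gradient (uniform marginals)
    cX = (D_X**2 @ p)[:, None]
    cY = (D_Y**2 @ q)[None, :]
    P = init_matching(n, m).P
    a = b = None
    total_iters, converged = 0, False
    eps_eff = schedule[-1] * unit
    best = None  # (gw, P, a, b) over the final stage
    for stage, eps_stage in enumerate(schedule):
        eps_eff = eps_stage * unit
        final = stage == len(schedule) - 1
        stage_tol = tol if final else max(tol, 1e-6)
        converged = False
        stagnant = 0
        for it in range(1, max_iter + 1):
            G = cX + cY - 2.0 * D_X @ P @ D_Y
            if feat_cost is not None:
                G = (1 - alpha) * G + alpha * feat_cost
            P_new, a, b = _sinkhorn(G, p, q, eps_eff, max_iter=100,
                                    tol=1e-6, a=a, b=b)
            delta = np.abs(P_new - P).max()
            P = P_new
            total_iters += 1
            if delta < stage_tol:
                converged = True
                break
            if final:
                # unmatched mass (e.g. dropped cells) can make the sharp
                # plan cycle; keep the best-cost iterate and stop early
                cost = gw_cost(D_X, D_Y, P)
                if best is None or cost < best[0] - 1e-12:
                    best = (cost, P.copy(), a.copy(), b.copy())
                    stagnant = 0
                else:
                    stagnant += 1
                    if stagnant >= patience:
                        break
    if not converged:
        if best is not None:
            _, P, a, b = best
        warnings.warn(
            "GW matching cycled at the final epsilon; returning the "
            "best-cost iterate",
            RuntimeWarning,
        )
    # precision polish: re-project the final plan so the marginals hold tight
    G = cX + cY - 2.0 * D_X @ P @ D_Y
    if feat_cost is not None:
        G = (1 - alpha) * G + alpha * feat_cost
    P, a, b = _sinkhorn(G, p, q, eps_eff, max_iter=2000, tol=1e-13, a=a, b=b)
    with np.errstate(over="ignore"):
        u, v = np.exp(a), np.exp(b)
    return MatchingMatrix(P, u=u, v=v, gw_cost=gw_cost(D_X, D_Y, P),
                          n_iter=total_iters, converged=converged)


def procrustes(
    X_points: np.ndarray,
    Y_points: np.ndarray,
    P: np.ndarray | MatchingMatrix | None = None,
    allow_scale: bool = False,
    allow_reflection: bool = False,
) -> tuple[RigidTransform, np.ndarray]:
    """Weighted least-squares rigid transform min ||R X + t - Y||_F^2.

    ``P`` supplies soft correspondence weights (a transport plan); ``None``
    means identity pairing (requires equal sizes). Solved in closed form via
    SVD of the weighted cross-covariance; reflections are excluded (det +1)
    unless ``allow_reflection``. Returns the transform and the aligned X.
    """
    X = np.asarray(X_points, float)
    Y = np.asarray(Y_points, float)
    d = X.shape[1]
    if isinstance(P, MatchingMatrix):
        P = P.P
    if P is None:
        if len(X) != len(Y):
            raise ValueError("identity pairing requires equal point counts")
        P = np.eye(len(X)) / len(X)
    P = np.asarray(P, float)
    w_x = P.sum(axis=1)
    w_y = P.sum(axis=0)
    total = P.sum()
    mu_x = (w_x @ X) / total
    mu_y = (w_y @ Y) / total
    Xc, Yc = X - mu_x, Y - mu_y
    if np.allclose(Xc * w_x[:, None], 0) or np.allclose(Yc * w_y[:, None], 0):
        raise ValueError("degenerate point set: all points coincide")
    # weighted cross-covariance: sum_ik P_ik y_k x_i^T
    H = Yc.T @ P.T @ Xc
    U, S, Vt = np.linalg.svd(H)
    det = np.linalg.det(U @ Vt)
    D = np.eye(d)
    if not allow_reflection and det < 0:
        D[-1, -1] = -1.0
    R = U @ D @ Vt
    scale = 1.0
    if allow_scale:
        var_x = float((w_x * (Xc**2).sum(axis=1)).sum())
        scale = float((S * np.diag(D)).sum() / var_x)
    t = mu_y - scale * R @ mu_x
    transform = RigidTransform(R=R, t=t, scale=scale)
    return transform, transform.apply(X)


def stack_slices(
    slices: list[SpatialCoords | np.ndarray],
    transforms: list[RigidTransform],
    layer_spacing: float,
    layer_labels: list | None = None,
) -> SpatialCoords:
    """Map every slice into the first slice's frame and stack along z.

    ``transforms[s]`` carries slice s into the reference frame (use the
    identity for the first slice); slice s sits at z = s * layer_spacing.
    """
    if layer_spacing <= 0:
        raise ValueError("layer_spacing must be positive")
    if len(transforms) != len(slices):
        raise ValueError("need one transform per slice")
    coords, ids, layers = [], [], []
    for s, (sl, tr) in enumerate(zip(slices, transforms)):
        pts = sl.coords if isinstance(sl, SpatialCoords) else np.asarray(sl, float)
        cid = sl.cell_ids if isinstance(sl, SpatialCoords) else [
            f"s{s}_c{i}" for i in range(len(pts))
        ]
        xy = tr.apply(pts)
        z = np.full(len(pts), s * layer_spacing)
        coords.append(np.column_stack([xy, z]))
        ids.extend(f"L{s}:{c}" for c in cid)
        lab = layer_labels[s] if layer_labels is not None else s
        layers.extend([lab] * len(pts))
    return SpatialCoords(np.vstack(coords), ids, layer=np.asarray(layers))


def identity_transform(d: int = 2) -> RigidTransform:
    return RigidTransform(R=np.eye(d), t=np.zeros(d))
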