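"""Community detection, node roles, and connectivity gradients.

Louvain modularity optimization on (possibly signed) weighted FC matrices,
with the asymmetric negative-weight extension of modularity: positive and
negative subnetworks contribute

    Q* = Q+ - s- / (s+ + s-) * Q-,

where Q+/Q- are standard modularity on the positive/negative weights and
s+/s- their total strengths.  Community assignment is stabilized by
repetition: an agreement matrix over repeated runs plus the modal partition.
Node roles come from the participation coefficient and the within-module
degree z-score; whole-brain organisation from a gradient decomposition (PCA
or diffusion-map embedding) of a node similarity matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Partition", "modularity", "louvain", "louvain_finetuned",
    "consensus_communities", "participation_coefficient",
    "within_module_zscore", "similarity_matrix", "gradient_decomposition",
    "GradientSet",
]


@dataclass(frozen=True)
class Partition:
    """Community labels (contiguous from 1) with the achieved modularity Q."""

    labels: np.ndarray
    q: float

    def __post_init__(self):
        labels = canonical_labels(np.asarray(self.labels, dtype=int))
        object.__setattr__(self, "labels", labels)

    @property
    def n_communities(self) -> int:
        return int(self.labels.max())


def canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel communities 1..k in order of first appearance."""
    out = np.zeros_like(labels)
    nxt = 0
    seen = {}
    for i, lab in enumerate(labels):
        if lab not in seen:
            nxt += 1
            seen[lab] = nxt
        out[i] = seen[lab]
    return out


def _check_square_symmetric(W: np.ndarray) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("W must be square")
    if not np.allclose(W, W.T, atol=1e-10):
        raise ValueError("W must be symmetric")
    return W


def _modularity_matrix(W: np.ndarray, gamma: float) -> np.ndarray:
    """Signed modularity matrix B with Q(partition) = sum of within-community B."""
    Wp = np.clip(W, 0.0, None)
    Wn = np.clip(-W, 0.0, None)
    np.fill_diagonal(Wp, np.clip(np.diag(W), 0.0, None))
    sp = Wp.sum()
    sn = Wn.sum()
    B = np.zeros_like(W)
    if sp > 0:
        kp = Wp.sum(axis=1)
        B += (Wp - gamma * np.outer(kp, kp) / sp) / sp
    if sn > 0:
        kn = Wn.sum(axis=1)
        B -= (Wn - gamma * np.outer(kn, kn) / sn) / (sp + sn)
    return B


def modularity(W: np.ndarray, labels: np.ndarray, gamma: float = 1.0) -> float:
    """Signed modularity Q* of a partition (reduces to Newman-Girvan Q for
    non-negative W)."""
    W = _check_square_symmetric(W)
    B = _modularity_matrix(W, gamma)
    labels = np.asarray(labels)
    same = labels[:, None] == labels[None, :]
    return float(B[same].sum())


def _local_moves(B: np.ndarray, labels: np.ndarray, rng: np.random.Generator) -> bool:
    """Greedy node moves maximizing the within-community sum of B.  In place."""
    n = len(labels)
    improved_any = False
    improved = True
    while improved:
        improved = False
        for i in rng.permutation(n):
            li = labels[i]
            # gain of joining community c (excluding self-pair terms, which
            # are invariant): 2 * sum_{j in c, j != i} B[i, j]
            row = B[i].copy()
            row[i] = 0.0
            gains = np.zeros(int(labels.max()) + 1)
            np.add.at(gains, labels, row)
            best = np.argmax(gains)
            if gains[best] > gains[li] + 1e-12:
                labels[i] = best
                improved = True
                improved_any = True
    return improved_any


def _aggregate(B: np.ndarray, labels: np.ndarray) -> np.ndarray:
    uniq = np.unique(labels)
    k = len(uniq)
    M = np.zeros((k, k))
    for a, la in enumerate(uniq):
        ia = labels == la
        for b, lb in enumerate(uniq):
            M[a, b] = B[np.ix_(ia, labels == lb)].sum()
    return M


def louvain(W: np.ndarray, gamma: float = 1.0, seed=None,
            init: np.ndarray | None = None) -> Partition:
    """One Louvain run (local moves + hierarchical aggregation) on signed W.

    `init` supplies an initial community assignment (used for fine-tuning);
    default is singleton communities.  An all-zero matrix yields a single
    community with Q = 0.
    """
    W = _check_square_symmetric(W)
    n = W.shape[0]
    if not np.any(W):
        return Partition(labels=np.ones(n, dtype=int), q=0.0)
    rng = np.random.default_rng(seed)
    Bl = _modularity_matrix(W, gamma)

    if init is None:
        labels = np.arange(n)
    else:
        labels = canonical_labels(np.asarray(init, dtype=int)) - 1
    mapping = None  # original node -> community at the finest resolved level
    while True:
        moved = _local_moves(Bl, labels, rng)
        uniq, compact = np.unique(labels, return_inverse=True)
        mapping = compact if mapping is None else compact[mapping]
        if not moved or len(uniq) == 1:
            break
        Bl = _aggregate(Bl, labels)
        labels = np.arange(len(uniq))
    q = modularity(W, mapping, gamma)
    return Partition(labels=mapping + 1, q=q)


def louvain_finetuned(W: np.ndarray, gamma: float = 1.0, seed=None) -> Partition:
    """Louvain with iterative fine-tuning: re-run with the current partition
    as initialization until Q stops increasing (tolerance 1e-10)."""
    rng = np.random.default_rng(seed)
    part = louvain(W, gamma, rng)
    while True:
        nxt = louvain(W, gamma, rng, init=part.labels)
        if nxt.q > part.q + 1e-10:
            part = nxt
        else:
            return part


def _agreement_key(labels: np.ndarray) -> tuple:
    return tuple(canonical_labels(labels))


def consensus_communities(W: np.ndarray, n_reps: int = 1000, gamma: float = 1.0,
                          seed=None):
    """Repeat fine-tuned Louvain `n_reps` times.

    Returns (partition, agreement, modal_frequency): agreement(i, j) is the
    fraction of runs placing i and j in the same community; the final
    partition is the modal (most frequent, label-invariant) solution with
    its Q, and modal_frequency its share of the runs.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    W = _check_square_symmetric(W)
    rng = np.random.default_rng(seed)
    n = W.shape[0]
    agreement = np.zeros((n, n))
    counts: dict = {}
    for _ in range(n_reps):
        part = louvain_finetuned(W, gamma, rng)
        same = part.labels[:, None] == part.labels[None, :]
        agreement += same
        key = _agreement_key(part.labels)
        counts[key] = counts.get(key, 0) + 1
    agreement /= n_reps
    modal_key, modal_n = max(counts.items(), key=lambda kv: kv[1])
    labels = np.array(modal_key)
    part = Partition(labels=labels, q=modularity(W, labels, gamma))
    return part, agreement, modal_n / n_reps


def participation_coefficient(W: np.ndarray, labels: np.ndarray, sign: str = "positive"):
    """Participation coefficient P_i = 1 - sum_c (s_ic / s_i)^2.

    Computed on positive weights by default; sign='negative' uses the
    negative weights; sign='both' returns (P_pos, P_neg).  Isolated nodes
    (zero strength) get P = 0 with a warning.
    """
    W = _check_square_symmetric(W)
    labels = np.asarray(labels)
    if len(labels) != W.shape[0]:
        raise ValueError("partition does not cover all nodes")
    if sign == "both":
        return (participation_coefficient(W, labels, "positive"),
                participation_coefficient(W, labels, "negative"))
    Ws = np.clip(W, 0.0, None) if sign == "positive" else np.clip(-W, 0.0, None)
    np.fill_diagonal(Ws, 0.0)
    s = Ws.sum(axis=1)
    p = np.zeros(len(labels))
    isolated = s == 0
    if isolated.any():
        warnings.warn(f"isolated nodes (zero {sign} strength): "
                      f"{np.nonzero(isolated)[0].tolist()}; P set to 0", stacklevel=2)
    for c in np.unique(labels):
        sc = Ws[:, labels == c].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p += np.where(isolated, 0.0, (sc / np.where(s == 0, 1.0, s)) ** 2)
    return np.where(isolated, 0.0, 1.0 - p)


def within_module_zscore(W: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Within-module degree z-score: z_i = (k_i - mean_c) / sd_c over the
    node's own module; modules with sd = 0 (including singletons) get z = 0."""
    W = _check_square_symmetric(W)
    labels = np.asarray(labels)
    if len(labels) != W.shape[0]:
        raise ValueError("partition does not cover all nodes")
    Wd = W.copy()
    np.fill_diagonal(Wd, 0.0)
    z = np.zeros(len(labels))
    for c in np.unique(labels):
        members = labels == c
        if members.sum() == 1:
            warnings.warn(f"singleton module {c}: z_within set to 0", stacklevel=2)
            continue
        k = Wd[np.ix_(members, members)].sum(axis=1)
        sd = k.std()
        if sd == 0:
            z[members] = 0.0
        else:
            z[members] = (k - k.mean()) / sd
    return z


def similarity_matrix(seed_maps) -> np.ndarray:
    """Node-by-node Pearson correlation between vectorized grey-matter
    seed-to-voxel maps."""
    maps = seed_maps.maps if hasattr(seed_maps, "maps") else np.asarray(seed_maps, dtype=float)
    if maps.ndim != 2 or maps.shape[0] < 2:
        raise ValueError("need >= 2 node maps")
    sd = maps.std(axis=1)
    if (sd == 0).any():
        warnings.warn(f"constant seed maps at nodes {np.nonzero(sd == 0)[0].tolist()}; "
                      "similarities undefined (NaN)", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        S = np.corrcoef(maps)
    S[sd == 0, :] = np.nan
    S[:, sd == 0] = np.nan
    return S


@dataclass(frozen=True)
class GradientSet:
    """Gradient loadings per node with explained-variance fractions."""

    components: np.ndarray  # (n_nodes, k)
    explained_variance: np.ndarray
    method: str
    retain_fraction: float
    alpha: float = 0.05


def _sparsify_rows(S: np.ndarray, retain_fraction: float) -> np.ndarray:
    """Keep the top `retain_fraction` entries of each row, zero the rest."""
    n = S.shape[1]
    keep = max(1, int(np.ceil(retain_fraction * n)))
    out = np.zeros_like(S)
    for i in range(S.shape[0]):
        order = np.argsort(S[i])[::-1][:keep]
        out[i, order] = S[i, order]
    return out


def gradient_decomposition(S: np.ndarray, retain_fraction: float = 0.20,
                           method: str = "pca", alpha: float = 0.05,
                           k: int = 3) -> GradientSet:
    """Decompose a node similarity matrix into its principal axes.

    Row-wise, only the top `retain_fraction` of similarities are retained
    (the rest are zeroed).  `method='pca'` takes principal components of the
    sparsified matrix; `method='diffusion'` builds an anisotropic diffusion
    operator (parameter `alpha`) on the symmetrized non-negative affinity and
    embeds nodes by its leading non-trivial eigenvectors.  Components are
    sign-aligned so the loading of the first node is non-negative.
    """
    S = _check_square_symmetric(S)
    n = S.shape[0]
    if k > n - 1:
        warnings.warn(f"k={k} exceeds available rank; truncating to {n - 1}", stacklevel=2)
        k = n - 1
    X = _sparsify_rows(S, retain_fraction)

    if method == "pca":
        Xc = X - X.mean(axis=0, keepdims=True)
        U, sv, Vt = np.linalg.svd(Xc, full_matrices=False)
        var = sv ** 2
        comps = U[:, :k] * sv[:k]
        ev = var[:k] / var.sum()
    elif method == "diffusion":
        A = np.clip((X + X.T) / 2.0, 0.0, None)
        d = A.sum(axis=1)
        d[d == 0] = 1.0
        # anisotropic normalization, then row-stochastic Markov operator
        La = A / np.outer(d ** alpha, d ** alpha)
        dl = La.sum(axis=1)
        dl[dl == 0] = 1.0
        Ms = La / np.sqrt(np.outer(dl, dl))  # symmetric conjugate of the Markov matrix
        vals, vecs = np.linalg.eigh(Ms)
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
        psi = vecs / np.sqrt(dl)[:, None]
        # drop the trivial constant eigenvector, scale by eigenvalue
        comps = psi[:, 1:k + 1] * vals[1:k + 1]
        lam = np.abs(vals[1:])
        ev = np.abs(vals[1:k + 1]) / lam.sum()
    else:
        raise ValueError("method must be 'pca' or 'diffusion'")

    flips = np.where(comps[0] < 0, -1.0, 1.0)
    return GradientSet(components=comps * flips, explained_variance=ev,
                       method=method, retain_fraction=retain_fraction, alpha=alpha)
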