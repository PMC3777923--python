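"""Relaxed variable kernel density estimator (RVKDE) classification.

Two class-conditional densities — one for functionally related pairs, one
for unrelated pairs — are estimated with Gaussian kernels whose per-sample
bandwidth sigma_i scales with R(s_i), the distance from training sample s_i
to its ks-th nearest neighbour within the same class:

    sigma_i = beta * R(s_i) * sqrt(pi) / (Gamma(m/2 + 1)^(1/m) * (alpha*ks)^(1/m))

The sqrt(pi)/Gamma(m/2+1)^(1/m) factor comes from the volume of the m-ball,
V_m(R) = pi^(m/2) R^m / Gamma(m/2 + 1): the ks-NN ball around s_i holds
alpha*ks samples' worth of volume, so sigma_i is the characteristic
per-sample spacing (V_m(R) / (alpha*ks))^(1/m), rescaled by beta. This keeps
the kernel local in any dimension; the inverted placement would inflate
sigma by ~sqrt(m / 2*pi*e) in high dimension and wash out all geometry. At query time only the kt nearest class
samples enter the sum, which truncates the density from below but keeps
evaluation fast. A query v is assigned to the class with the larger
likelihood L_j(v) = (n_j / n) * fhat_j(v); all likelihood arithmetic is done
in log space because the 686-dimensional kernels under- and overflow doubles.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import gammaln, logsumexp

from .errors import PPLinkError

RELATED = "related"
UNRELATED = "unrelated"

# KD-trees stop paying off well before the conjoint-triad dimension; above
# this we brute-force with BLAS.
_KDTREE_MAX_DIM = 15
_BLOCK = 256


@dataclass(frozen=True, order=True)
class RVKDEParams:
    alpha: float = 1.0
    beta: float = 1.0
    ks: int = 5
    kt: int = 50

    def __post_init__(self):
        if self.alpha <= 0 or self.beta <= 0:
            raise PPLinkError("alpha and beta must be positive")
        if self.ks < 1 or self.kt < 1:
            raise PPLinkError("ks and kt must be >= 1")


def _sq_dists(Q: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Squared Euclidean distances, blocked; exact differences when small."""
    Q = np.atleast_2d(np.asarray(Q, dtype=float))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if Q.shape[0] * X.shape[0] * X.shape[1] <= 2_000_000:
        diff = Q[:, None, :] - X[None, :, :]
        return np.einsum("ijk,ijk->ij", diff, diff)
    xn = np.einsum("ij,ij->i", X, X)
    out = np.empty((Q.shape[0], X.shape[0]))
    for lo in range(0, Q.shape[0], _BLOCK):
        q = Q[lo : lo + _BLOCK]
        qn = np.einsum("ij,ij->i", q, q)
        d = qn[:, None] + xn[None, :] - 2.0 * (q @ X.T)
        np.maximum(d, 0.0, out=d)
        out[lo : lo + _BLOCK] = d
    return out


def knn_radii(X: np.ndarray, ks: int) -> np.ndarray:
    """R(s_i) for every sample: distance to its ks-th nearest *other* sample."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if ks >= n:
        raise PPLinkError(f"ks={ks} must be smaller than the class size {n}")
    if X.shape[1] <= _KDTREE_MAX_DIM and n > 64:
        tree = cKDTree(X)
        d, _ = tree.query(X, k=ks + 1)
        return d[:, -1]
    d2 = _sq_dists(X, X)
    np.fill_diagonal(d2, np.inf)
    kth = np.partition(d2, ks - 1, axis=1)[:, ks - 1]
    return np.sqrt(kth)


def knn_radius(samples: np.ndarray, i: int, ks: int) -> float:
    """Distance from sample ``i`` to its ks-th nearest other sample in the set."""
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if ks >= samples.shape[0]:
        raise PPLinkError(f"ks={ks} must be smaller than the set size {samples.shape[0]}")
    d2 = _sq_dists(samples[i : i + 1], samples)[0]
    d2[i] = np.inf
    return float(np.sqrt(np.partition(d2, ks - 1)[ks - 1]))


def bandwidth(R: float, m: int, params: RVKDEParams, sigma_floor: float = 0.0) -> float:
    """Per-sample kernel bandwidth from the ks-NN radius.

    Monotone increasing in beta and R, decreasing in alpha; floored at
    ``sigma_floor`` so duplicate training vectors cannot produce a
    zero-width kernel.
    """
    if R < 0:
        raise PPLinkError(f"knn radius must be non-negative, got {R}")
    log_c = 0.5 * np.log(np.pi) - gammaln(m / 2 + 1) / m - np.log(params.alpha * params.ks) / m
    sigma = params.beta * R * float(np.exp(log_c))
    return max(sigma, sigma_floor)


def _class_sigma_floor(X: np.ndarray) -> float:
    """1e-9 x median pairwise distance of the class (1 if degenerate)."""
    n = X.shape[0]
    if n < 2:
        return 1.0
    if n > 512:
        idx = np.random.default_rng(0).choice(n, size=512, replace=False)
        X = X[np.sort(idx)]
    d2 = _sq_dists(X, X)
    med = float(np.median(np.sqrt(d2[np.triu_indices(X.shape[0], k=1)])))
    return 1e-9 * med if med > 0 else 1.0


@dataclass
class _ClassDensity:
    samples: np.ndarray  # (n_j, m)
    sigmas: np.ndarray  # (n_j,)

    @property
    def n(self) -> int:
        return self.samples.shape[0]


@dataclass
class RVKDEModel:
    """Fitted two-class RVKDE."""

    params: RVKDEParams
    m: int
    classes: dict[str, _ClassDensity] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return sum(c.n for c in self.classes.values())

    def _check_class(self, label: str) -> _ClassDensity:
        if label not in self.classes:
            raise PPLinkError(f"unknown class label {label!r}")
        return self.classes[label]

    def log_density(self, label: str, V: np.ndarray) -> np.ndarray:
        """log fhat_j(v) for each row of V, using the kt nearest class samples."""
        cls = self._check_class(label)
        V = np.atleast_2d(np.asarray(V, dtype=float))
        if V.shape[1] != self.m:
            raise PPLinkError(f"query dimension {V.shape[1]} != model dimension {self.m}")
        kt = min(self.params.kt, cls.n)
        out = np.empty(V.shape[0])
        log_sig = np.log(cls.sigmas)
        const = -0.5 * self.m * np.log(2 * np.pi) - np.log(cls.n)
        for lo in range(0, V.shape[0], _BLOCK):
            q = V[lo : lo + _BLOCK]
            d2 = _sq_dists(q, cls.samples)
            terms = -self.m * log_sig[None, :] - d2 / (2.0 * cls.sigmas[None, :] ** 2)
            if kt < cls.n:
                # keep only the kt nearest samples of each query
                part = np.argpartition(d2, kt - 1, axis=1)[:, :kt]
                terms = np.take_along_axis(terms, part, axis=1)
            out[lo : lo + _BLOCK] = logsumexp(terms, axis=1) + const
        return out

    def density(self, label: str, V: np.ndarray):
        v = np.asarray(V, dtype=float)
        ld = self.log_density(label, V)
        dens = np.exp(ld)
        return float(dens[0]) if v.ndim == 1 else dens

    def log_likelihoods(self, V: np.ndarray) -> dict[str, np.ndarray]:
        """log L_j(v) = log(n_j/n) + log fhat_j(v) per class."""
        n = self.n
        return {
            label: np.log(cls.n / n) + self.log_density(label, V)
            for label, cls in self.classes.items()
        }

    def likelihoods(self, V: np.ndarray):
        v = np.asarray(V, dtype=float)
        ll = self.log_likelihoods(V)
        pair = (np.exp(ll[RELATED]), np.exp(ll[UNRELATED]))
        if v.ndim == 1:
            return float(pair[0][0]), float(pair[1][0])
        return pair

    def classify(self, V: np.ndarray):
        """Class with the larger likelihood; ties (including 0, 0) go to unrelated."""
        v = np.asarray(V, dtype=float)
        ll = self.log_likelihoods(V)
        rel = ll[RELATED] > ll[UNRELATED]
        labels = np.where(rel, RELATED, UNRELATED)
        return str(labels[0]) if v.ndim == 1 else labels

    def score(self, V: np.ndarray):
        """Ranking score L_related / (L_related + L_unrelated) in [0, 1].

        Computed as a logistic of the log-likelihood difference; 0 when both
        likelihoods vanish.
        """
        v = np.asarray(V, dtype=float)
        ll = self.log_likelihoods(V)
        lr, lu = ll[RELATED], ll[UNRELATED]
        out = np.empty_like(lr)
        both_zero = np.isneginf(lr) & np.isneginf(lu)
        only_u = np.isneginf(lu) & ~np.isneginf(lr)
        rest = ~(both_zero | only_u)
        out[both_zero] = 0.0
        out[only_u] = 1.0
        with np.errstate(over="ignore"):
            out[rest] = 1.0 / (1.0 + np.exp(lu[rest] - lr[rest]))
        return float(out[0]) if v.ndim == 1 else out

    def save(self, path) -> None:
        meta = {
            "format": "pplink-rvkde-v1",
            "m": self.m,
            "params": {
                "alpha": self.params.alpha,
                "beta": self.params.beta,
                "ks": self.params.ks,
                "kt": self.params.kt,
            },
            "labels": sorted(self.classes),
        }
        arrays = {"meta": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)}
        for label, cls in self.classes.items():
            arrays[f"samples_{label}"] = cls.samples
            arrays[f"sigmas_{label}"] = cls.sigmas
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "RVKDEModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            if meta.get("format") != "pplink-rvkde-v1":
                raise PPLinkError(f"unrecognized model file format in {path}")
            params = RVKDEParams(**meta["params"])
            model = cls(params=params, m=int(meta["m"]))
            for label in meta["labels"]:
                model.classes[label] = _ClassDensity(
                    samples=data[f"samples_{label}"],
                    sigmas=data[f"sigmas_{label}"],
                )
        return model


def fit(
    related: np.ndarray, unrelated: np.ndarray, params: RVKDEParams
) -> RVKDEModel:
    """Fit per-class adaptive bandwidths and assemble the model.

    Each class needs more than ``ks`` samples (R(s_i) is computed within the
    sample's own class).
    """
    related = np.atleast_2d(np.asarray(related, dtype=float))
    unrelated = np.atleast_2d(np.asarray(unrelated, dtype=float))
    if related.shape[1] != unrelated.shape[1]:
        raise PPLinkError(
            f"dimension mismatch: {related.shape[1]} vs {unrelated.shape[1]}"
        )
    m = related.shape[1]
    model = RVKDEModel(params=params, m=m)
    for label, X in ((RELATED, related), (UNRELATED, unrelated)):
        if X.shape[0] <= params.ks:
            raise PPLinkError(
                f"class {label!r} has {X.shape[0]} samples; needs > ks={params.ks}"
            )
        radii = knn_radii(X, params.ks)
        floor = _class_sigma_floor(X)
        sigmas = np.array([bandwidth(r, m, params, sigma_floor=floor) for r in radii])
        model.classes[label] = _ClassDensity(samples=X, sigmas=sigmas)
    return model


# --- thin functional surface over the model ---------------------------------

def class_density(model: RVKDEModel, label: str, v: np.ndarray):
    return model.density(label, v)


def likelihoods(model: RVKDEModel, v: np.ndarray):
    return model.likelihoods(v)


def classify(model: RVKDEModel, v: np.ndarray):
    return model.classify(v)


def score(model: RVKDEModel, v: np.ndarray):
    return model.score(v)


def f_measure(tp: int, fp: int, fn: int) -> float:
    """F1 = harmonic mean of precision and recall; 0 when undefined."""
    if tp < 0 or fp < 0 or fn < 0:
        raise PPLinkError("counts must be non-negative")
    if tp == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return 2 * precision * recall / (precision + recall)


def default_grid() -> list[RVKDEParams]:
    """Default CV grid over alpha, beta, ks, kt."""
    return [
        RVKDEParams(alpha=a, beta=b, ks=ks, kt=kt)
        for a, b, ks, kt in itertools.product(
            (0.5, 1.0, 2.0), (0.5, 1.0, 2.0, 4.0), (5, 10, 20), (20, 50, 100)
        )
    ]


def _stratified_folds(n: int, folds: int, rng: np.random.Generator) -> np.ndarray:
    perm = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    fold_of[perm] = np.arange(n) % folds
    return fold_of


def grid_search_cv(
    related: np.ndarray,
    unrelated: np.ndarray,
    grid: list[RVKDEParams] | None = None,
    folds: int = 5,
    seed: int = 0,
    return_table: bool = False,
):
    """Pick RVKDE parameters by stratified k-fold CV maximizing the F-measure.

    Fold assignment comes from a seeded shuffle of each class, so the same
    seed reproduces the same folds and the same selection. Ties are broken by
    the smaller (ks, kt, beta, alpha) tuple. Grid points whose ks is too
    large for some training fold are discarded.
    """
    if grid is None:
        grid = default_grid()
    grid = list(grid)
    if not grid:
        raise PPLinkError("parameter grid is empty")
    related = np.atleast_2d(np.asarray(related, dtype=float))
    unrelated = np.atleast_2d(np.asarray(unrelated, dtype=float))
    if min(related.shape[0], unrelated.shape[0]) < folds:
        raise PPLinkError(f"each class needs at least {folds} samples")
    rng = np.random.default_rng(seed)
    fold_rel = _stratified_folds(related.shape[0], folds, rng)
    fold_unr = _stratified_folds(unrelated.shape[0], folds, rng)
    rows = []
    for params in grid:
        scores = []
        valid = True
        for f in range(folds):
            tr_rel = related[fold_rel != f]
            tr_unr = unrelated[fold_unr != f]
            if min(tr_rel.shape[0], tr_unr.shape[0]) <= params.ks:
                valid = False
                break
            model = fit(tr_rel, tr_unr, params)
            pred_rel = model.classify(related[fold_rel == f])
            pred_unr = model.classify(unrelated[fold_unr == f])
            tp = int(np.sum(pred_rel == RELATED))
            fn = int(np.sum(pred_rel == UNRELATED))
            fp = int(np.sum(pred_unr == RELATED))
            scores.append(f_measure(tp, fp, fn))
        rows.append((params, float(np.mean(scores)) if valid else -np.inf))
    best = max(
        rows,
        key=lambda r: (r[1], (-r[0].ks, -r[0].kt, -r[0].beta, -r[0].alpha)),
    )
    if best[1] == -np.inf:
        raise PPLinkError("no grid point is feasible for these class sizes")
    if return_table:
        return best[0], rows
    return best[0]
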