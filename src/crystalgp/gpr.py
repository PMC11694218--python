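"""Gaussian-process regression engine for per-atom energies and multipoles.

The covariance is a product Gaussian ("RBF-cyclic") kernel

    k(x, x') = prod_d exp(-theta_d * delta_d^2)

where delta_d is the plain feature difference for non-cyclic features and the
difference wrapped into (-pi, pi] for the angular ones.  Predictions are

    y(x) = mu + sum_j alpha_j k(x_j, x),

with mu the arithmetic mean of the training outputs and alpha the solution of
(K + sigma^2 I) alpha = y - mu.  Outputs are mean-centred only; no variance
scaling is applied.

Hyperparameters are selected by hold-out cross-validation: minimise the RMSE
over an internal validation set with a seeded, bounded derivative-free search
(random multi-start plus Nelder-Mead refinement in log space).

The module also curates datasets the way the training pipeline expects:
a recovery-error filter (molecular wavefunction energy minus the sum of its
per-atom energies) and a stratified split using Freedman-Diaconis bins on the
output variable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla
from scipy import optimize as sopt

__all__ = [
    "LabelledDataset",
    "Hyperparameters",
    "GPRModel",
    "SCurve",
    "kernel_rbf_cyclic",
    "fit",
    "predict",
    "optimize_hyperparameters",
    "validation_rmse",
    "recovery_filter",
    "stratified_split",
    "s_curve",
    "save_model",
    "load_model",
]


@dataclass
class LabelledDataset:
    """Rows of (feature vector, output) with optional per-geometry energies.

    ``e_wfn`` and ``e_iqa_sum`` (kJ/mol) hold, per geometry, the molecular
    reference energy and the sum of its per-atom labels; they enable the
    recovery-error filter.  ``geometry_ids`` keeps provenance through
    filtering and splitting.
    """

    X: np.ndarray
    y: np.ndarray
    geometry_ids: np.ndarray | None = None
    e_wfn: np.ndarray | None = None
    e_iqa_sum: np.ndarray | None = None

    def __post_init__(self):
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y row counts differ")
        if not np.all(np.isfinite(self.X)) or not np.all(np.isfinite(self.y)):
            raise ValueError("non-finite training data")
        if self.geometry_ids is None:
            self.geometry_ids = np.arange(len(self.y))
        else:
            self.geometry_ids = np.asarray(self.geometry_ids)

    def __len__(self):
        return len(self.y)

    def take(self, idx):
        idx = np.asarray(idx, dtype=int)
        return LabelledDataset(
            self.X[idx],
            self.y[idx],
            self.geometry_ids[idx],
            None if self.e_wfn is None else np.asarray(self.e_wfn)[idx],
            None if self.e_iqa_sum is None else np.asarray(self.e_iqa_sum)[idx],
        )


@dataclass
class Hyperparameters:
    """One positive length-scale theta per feature plus diagonal noise."""

    theta: np.ndarray
    noise: float = 1e-10

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=float).ravel()
        if np.any(self.theta <= 0):
            raise ValueError("theta must be positive")
        if not 1e-14 <= self.noise <= 1e-6:
            raise ValueError(f"noise {self.noise:g} outside [1e-14, 1e-6]")


def _wrapped_diff(delta):
    """Map differences into (-pi, pi]."""
    return delta - 2.0 * np.pi * np.round(delta / (2.0 * np.pi))


def _sq_dists(X1, X2, theta, cyclic):
    """Matrix of sum_d theta_d delta_d^2 between rows of X1 and X2."""
    diff = X1[:, None, :] - X2[None, :, :]
    if cyclic is not None and np.any(cyclic):
        diff[..., cyclic] = _wrapped_diff(diff[..., cyclic])
    return np.einsum("ijd,d->ij", diff**2, theta)


def kernel_rbf_cyclic(x, x_prime, theta, cyclic=None):
    """RBF-cyclic kernel between two feature vectors; value in (0, 1]."""
    x = np.asarray(x, dtype=float).ravel()
    x_prime = np.asarray(x_prime, dtype=float).ravel()
    theta = np.asarray(theta, dtype=float).ravel()
    if not (len(x) == len(x_prime) == len(theta)):
        raise ValueError("feature/theta length mismatch")
    if np.any(theta <= 0):
        raise ValueError("theta must be positive")
    delta = x - x_prime
    if cyclic is not None:
        cyclic = np.asarray(cyclic, dtype=bool)
        delta[cyclic] = _wrapped_diff(delta[cyclic])
    return float(np.exp(-np.sum(theta * delta**2)))


@dataclass
class GPRModel:
    hyperparameters: Hyperparameters
    X: np.ndarray
    mean: float
    alpha: np.ndarray
    cyclic: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def n_train(self):
        return self.X.shape[0]


def fit(dataset: LabelledDataset, hyperparameters: Hyperparameters,
        cyclic=None, allow_duplicates=False, meta=None) -> GPRModel:
    """Solve (K + noise I) alpha = y - mean(y).

    Exactly duplicated inputs with conflicting outputs make the system
    hopeless at tiny noise; they raise unless ``allow_duplicates`` requests
    pre-averaging of the conflicting rows.
    """
    X, y = dataset.X, dataset.y
    if cyclic is None:
        cyclic = np.zeros(X.shape[1], dtype=bool)
    cyclic = np.asarray(cyclic, dtype=bool)

    uniq, inverse = np.unique(X, axis=0, return_inverse=True)
    if len(uniq) < len(X):
        if not allow_duplicates:
            raise ValueError(
                "duplicate training inputs with conflicting outputs; "
                "pass allow_duplicates=True to pre-average them"
            )
        y_avg = np.zeros(len(uniq))
        counts = np.zeros(len(uniq))
        np.add.at(y_avg, inverse, y)
        np.add.at(counts, inverse, 1.0)
        X, y = uniq, y_avg / counts

    theta = hyperparameters.theta
    if X.shape[1] != len(theta):
        raise ValueError("theta length does not match feature dimension")
    K = np.exp(-_sq_dists(X, X, theta, cyclic))
    K[np.diag_indices_from(K)] += hyperparameters.noise
    try:
        cho = sla.cho_factor(K, lower=True)
    except np.linalg.LinAlgError:
        smallest = float(np.linalg.eigvalsh(K)[0])
        raise np.linalg.LinAlgError(
            f"Gram matrix not positive definite after jitter; smallest eigenvalue {smallest:g}"
        ) from None
    mean = float(np.mean(y))
    alpha = sla.cho_solve(cho, y - mean)
    return GPRModel(hyperparameters, X.copy(), mean, alpha, cyclic.copy(), dict(meta or {}))


def predict(model: GPRModel, x) -> float | np.ndarray:
    """mu + sum_j alpha_j k(x_j, x); accepts one vector or a matrix of rows."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X_new = np.atleast_2d(x)
    if X_new.shape[1] != model.X.shape[1]:
        raise ValueError("feature length mismatch")
    K = np.exp(-_sq_dists(X_new, model.X, model.hyperparameters.theta, model.cyclic))
    out = model.mean + K @ model.alpha
    return float(out[0]) if single else out


def predict_gradient(model: GPRModel, x) -> np.ndarray:
    """Analytic d prediction / d features at one input point.

    dk/dx_d = -2 theta_d delta_d k, with the wrapped difference for cyclic
    features (wrapping is locally linear away from the cut, so the same
    expression applies).
    """
    x = np.asarray(x, dtype=float).ravel()
    theta = model.hyperparameters.theta
    diff = x[None, :] - model.X
    if np.any(model.cyclic):
        diff[:, model.cyclic] = _wrapped_diff(diff[:, model.cyclic])
    k = np.exp(-np.einsum("jd,d->j", diff**2, theta))
    return -2.0 * np.einsum("j,jd,d->d", model.alpha * k, diff, theta)


def validation_rmse(model: GPRModel, validation: LabelledDataset) -> float:
    """The hold-out cost: sqrt(mean squared prediction error) over the set."""
    if len(validation) == 0:
        raise ValueError("empty validation set")
    resid = predict(model, validation.X) - validation.y
    return float(np.sqrt(np.mean(resid**2)))


def optimize_hyperparameters(
    train: LabelledDataset,
    validation: LabelledDataset,
    bounds=(1e-3, 1e3),
    noise=1e-10,
    optimize_noise=False,
    noise_bounds=(1e-14, 1e-6),
    n_random=20,
    seed=0,
    cyclic=None,
) -> Hyperparameters:
    """Seeded multi-start search minimising the hold-out RMSE.

    Candidates are the all-ones theta plus ``n_random`` log-uniform draws
    within ``bounds``; the best is refined by Nelder-Mead in log space and the
    returned point is never worse than any candidate.  ``optimize_noise``
    folds log-noise into the search vector; otherwise noise is held fixed.
    """
    if len(validation) == 0:
        raise ValueError("empty validation set")
    if set(map(tuple, train.X)) & set(map(tuple, validation.X)):
        raise ValueError("train and validation sets overlap")
    D = train.X.shape[1]
    rng = np.random.default_rng(seed)
    lo, hi = np.log(bounds[0]), np.log(bounds[1])
    nlo, nhi = np.log(noise_bounds[0]), np.log(noise_bounds[1])

    def unpack(v):
        th = np.exp(np.clip(v[:D], lo, hi))
        if optimize_noise:
            # clamp after exponentiation: exp(log(b)) can round just past b
            nz = float(min(max(np.exp(v[D]), noise_bounds[0]), noise_bounds[1]))
        else:
            nz = noise
        return Hyperparameters(th, nz)

    def cost(v):
        try:
            model = fit(train, unpack(v), cyclic=cyclic)
        except np.linalg.LinAlgError:
            return np.inf
        return validation_rmse(model, validation)

    n_extra = 1 if optimize_noise else 0
    candidates = [np.zeros(D + n_extra)]
    if optimize_noise:
        candidates[0][D] = np.log(noise)
    for _ in range(n_random):
        v = rng.uniform(lo, hi, size=D + n_extra)
        if optimize_noise:
            v[D] = rng.uniform(nlo, nhi)
        candidates.append(v)
    costs = [cost(v) for v in candidates]
    best = int(np.argmin(costs))
    res = sopt.minimize(
        cost, candidates[best], method="Nelder-Mead",
        options={"maxiter": 200 * (D + n_extra), "xatol": 1e-3, "fatol": 1e-12},
    )
    if res.fun <= costs[best]:
        return unpack(res.x)
    return unpack(candidates[best])


def recovery_filter(dataset: LabelledDataset, threshold: float = 1.0) -> LabelledDataset:
    """Drop geometries whose |E_wfn - sum(E_atoms)| exceeds ``threshold`` kJ/mol.

    Strictly-greater errors are removed, so a geometry exactly at the threshold
    is retained; input order is preserved.
    """
    if dataset.e_wfn is None or dataset.e_iqa_sum is None:
        raise ValueError("recovery filter needs e_wfn and e_iqa_sum per geometry")
    e_wfn = np.asarray(dataset.e_wfn, dtype=float)
    e_sum = np.asarray(dataset.e_iqa_sum, dtype=float)
    bad = ~np.isfinite(e_wfn) | ~np.isfinite(e_sum)
    if np.any(bad):
        ids = list(np.asarray(dataset.geometry_ids)[bad])
        raise ValueError(f"missing recovery energies for geometries {ids}")
    keep = np.abs(e_wfn - e_sum) <= threshold
    return dataset.take(np.flatnonzero(keep))


def freedman_diaconis_bins(values: np.ndarray):
    """Bin edges with width 2 IQR n^(-1/3); falls back to one bin if degenerate."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    q75, q25 = np.percentile(values, [75, 25])
    width = 2.0 * (q75 - q25) * n ** (-1.0 / 3.0)
    vmin, vmax = float(np.min(values)), float(np.max(values))
    if width <= 0 or vmax == vmin:
        return np.array([vmin, np.nextafter(vmax, np.inf)])
    n_bins = int(np.ceil((vmax - vmin) / width))
    edges = vmin + width * np.arange(n_bins + 1)
    edges[-1] = max(edges[-1], np.nextafter(vmax, np.inf))
    return edges


def _largest_remainder(counts, total):
    """Allocate ``total`` draws across bins proportionally to ``counts``.

    Ties in the fractional remainders go to the lowest bin index first.
    """
    counts = np.asarray(counts, dtype=float)
    quota = total * counts / counts.sum()
    alloc = np.floor(quota).astype(int)
    short = total - alloc.sum()
    order = np.lexsort((np.arange(len(counts)), -(quota - alloc)))
    for k in order[:short]:
        alloc[k] += 1
    return alloc


def stratified_split(dataset: LabelledDataset, sizes, seed=0):
    """Split into (train, internal, external) sets, stratified on the output.

    The output variable is binned by the Freedman-Diaconis rule; each requested
    set draws from every bin proportionally to occupancy (largest-remainder
    rounding), without replacement and disjointly from the other sets.
    Reproducible for a fixed seed.
    """
    sizes = tuple(int(s) for s in sizes)
    if sum(sizes) > len(dataset):
        raise ValueError(f"requested {sum(sizes)} points from {len(dataset)}")
    rng = np.random.default_rng(seed)
    edges = freedman_diaconis_bins(dataset.y)
    which = np.clip(np.searchsorted(edges, dataset.y, side="right") - 1, 0, len(edges) - 2)
    pools = [list(rng.permutation(np.flatnonzero(which == b))) for b in range(len(edges) - 1)]
    occupied = [b for b in range(len(pools)) if pools[b]]

    out = []
    for size in sizes:
        counts = np.array([len(pools[b]) for b in occupied], dtype=float)
        present = counts > 0
        take = np.zeros(len(occupied), dtype=int)
        take[present] = _largest_remainder(counts[present], min(size, int(counts.sum())))
        # bins may underfill once nearly drained; top up from the fullest bins
        chosen = []
        for slot, b in enumerate(occupied):
            k = min(take[slot], len(pools[b]))
            chosen.extend(pools[b][:k])
            del pools[b][:k]
        while len(chosen) < size:
            b = max(occupied, key=lambda bb: len(pools[bb]))
            chosen.append(pools[b].pop(0))
        out.append(dataset.take(np.array(sorted(chosen))))
    return tuple(out)


@dataclass
class SCurve:
    """Sorted absolute prediction errors with their percentiles."""

    errors: np.ndarray
    percentiles: np.ndarray


def s_curve(model: GPRModel, external: LabelledDataset) -> SCurve:
    """Cumulative distribution of |prediction error| over an external set."""
    if len(external) == 0:
        raise ValueError("empty external set")
    errors = np.sort(np.abs(predict(model, external.X) - external.y))
    n = len(errors)
    percentiles = 100.0 * np.arange(1, n + 1) / n
    return SCurve(errors, percentiles)


def save_model(model: GPRModel, path):
    """Write a model as a self-describing JSON archive.

    Stores hyperparameters, training inputs, weights, output mean, the cyclic
    mask and any metadata (ALF definitions, feature ordering, property name),
    so a saved model is sufficient to reproduce predictions exactly.
    """
    payload = {
        "format": "crystalgp-gpr/1",
        "theta": model.hyperparameters.theta.tolist(),
        "noise": model.hyperparameters.noise,
        "X": model.X.tolist(),
        "mean": model.mean,
        "alpha": model.alpha.tolist(),
        "cyclic": model.cyclic.astype(int).tolist(),
        "meta": model.meta,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> GPRModel:
    """Read a model written by :func:`save_model`."""
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != "crystalgp-gpr/1":
        raise ValueError(f"{path}: not a crystalgp GPR model archive")
    return GPRModel(
        Hyperparameters(np.array(payload["theta"]), payload["noise"]),
        np.array(payload["X"]),
        float(payload["mean"]),
        np.array(payload["alpha"]),
        np.array(payload["cyclic"], dtype=bool),
        dict(payload.get("meta", {})),
    )
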