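"""Discriminant analysis of principal components (DAPC) for chemotyping.

DAPC classifies high-dimensional emission profiles into groups (taxonomic ranks
or ecological guilds) by running linear discriminant analysis on the leading
``m`` principal components of the column-standardized matrix.  Standardizing to
unit variance first gives the two platforms equal weight in a combined table.
The number of retained PCs is chosen by repeated stratified cross-validation:
the ``m`` minimizing the root-mean-squared error of held-out assignment success
(ties broken toward the smaller, more parsimonious ``m``).

Assignment is to the nearest group centroid in discriminant space; the
"posterior" scores are an explicitly heuristic softmin of squared centroid
distances, not Gaussian densities — the assignment itself is identical under
either convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.linalg
from sklearn.model_selection import StratifiedShuffleSplit

from .datamodel import EmissionMatrix, SpeciesAnnotation, ValidationError

__all__ = ["DAPCModel", "XvalResult", "fit_dapc", "predict_dapc", "xval_select_m",
           "default_m_grid", "labels_for_samples"]


@dataclass(frozen=True)
class DAPCModel:
    feature_names: tuple[str, ...]   # columns used (zero-variance ones dropped)
    center: np.ndarray
    scale: np.ndarray
    pc_loadings: np.ndarray          # features x m
    disc_coef: np.ndarray            # m x n_axes, orthonormal in the within metric
    disc_eigenvalues: np.ndarray
    groups: tuple[str, ...]
    centroids: np.ndarray            # k x n_axes
    m: int
    k: int


@dataclass(frozen=True)
class XvalResult:
    grid: tuple[int, ...]
    mean_success: dict[int, float]
    rmse: dict[int, float]
    chosen_m: int


@dataclass(frozen=True)
class DAPCPrediction:
    assignments: tuple[str, ...]
    coordinates: np.ndarray          # samples x n_axes
    scores: np.ndarray               # samples x k, softmin heuristic posterior
    ties: tuple[int, ...]            # row indices where >= 2 centroids tied


def _standardize(X: np.ndarray, feature_names: Sequence[str], scale: bool):
    center = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.all():
        dropped = [feature_names[j] for j in np.nonzero(~keep)[0]]
        warnings.warn(f"dropping {len(dropped)} zero-variance columns "
                      f"(first: {dropped[:3]})", stacklevel=3)
    sd_eff = np.where(keep, sd, 1.0)
    if not scale:
        sd_eff = np.ones_like(sd_eff)
    Z = (X - center) / sd_eff
    return Z[:, keep], center[keep], sd_eff[keep], \
        tuple(feature_names[j] for j in np.nonzero(keep)[0])


def fit_dapc(X: np.ndarray, labels: Sequence[str], m: int,
             feature_names: Optional[Sequence[str]] = None,
             scale: bool = True) -> DAPCModel:
    """Fit the centre/scale -> PCA(m) -> LDA transform chain.

    Parameters
    ----------
    X
        Samples x features matrix.
    labels
        Group label per sample; every group needs >= 2 samples.
    m
        Number of principal components retained before the discriminant step;
        clamped (with a warning) to the rank of the standardized matrix.
    scale
        Scale columns to unit variance (default); centring always happens.
    """
    X = np.asarray(X, dtype=float)
    labels = list(labels)
    if feature_names is None:
        feature_names = tuple(f"f{j}" for j in range(X.shape[1]))
    groups = tuple(dict.fromkeys(labels))
    counts = {g: labels.count(g) for g in groups}
    small = [g for g, c in counts.items() if c < 2]
    if small:
        raise ValidationError(f"groups with < 2 samples: {small}")
    if m < 1:
        raise ValidationError(f"m must be >= 1, got {m}")

    Z, center, sd, kept = _standardize(X, feature_names, scale)
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    tol = S.max() * max(Z.shape) * np.finfo(float).eps if S.size else 0.0
    rank = int((S > tol).sum())
    if m > rank:
        warnings.warn(f"m={m} exceeds matrix rank {rank}; clamped", stacklevel=2)
        m = rank
    loadings = Vt[:m].T                       # features x m
    scores = Z @ loadings                     # = U[:, :m] * S[:m]

    k = len(groups)
    lab = np.array(labels)
    grand = scores.mean(axis=0)
    Sw = np.zeros((m, m))
    Sb = np.zeros((m, m))
    for g in groups:
        sub = scores[lab == g]
        mu = sub.mean(axis=0)
        dev = sub - mu
        Sw += dev.T @ dev
        dmu = (mu - grand)[:, None]
        Sb += sub.shape[0] * (dmu @ dmu.T)
    # small ridge keeps the within-scatter positive definite when m approaches n-k
    Sw += np.eye(m) * (np.trace(Sw) / m + 1.0) * 1e-9
    evals, evecs = scipy.linalg.eigh(Sb, Sw)
    order = np.argsort(evals)[::-1]
    n_axes = min(k - 1, m) if k > 1 else 1
    evals = np.clip(evals[order][:n_axes], 0.0, None)
    W = evecs[:, order][:, :n_axes]
    # deterministic sign: largest-magnitude coefficient of each axis positive
    for a in range(W.shape[1]):
        j = int(np.argmax(np.abs(W[:, a])))
        if W[j, a] < 0:
            W[:, a] = -W[:, a]

    coords = scores @ W
    centroids = np.vstack([coords[lab == g].mean(axis=0) for g in groups])
    return DAPCModel(feature_names=kept, center=center, scale=sd,
                     pc_loadings=loadings, disc_coef=W, disc_eigenvalues=evals,
                     groups=groups, centroids=centroids, m=m, k=k)


def predict_dapc(model: DAPCModel, X: np.ndarray,
                 feature_names: Optional[Sequence[str]] = None) -> DAPCPrediction:
    """Project new samples and assign each to the nearest group centroid.

    Ties (equal distance to >= 2 centroids) are broken by training group order
    and reported in ``ties``.
    """
    X = np.asarray(X, dtype=float)
    if feature_names is not None:
        pos = {f: j for j, f in enumerate(feature_names)}
        missing = [f for f in model.feature_names if f not in pos]
        if missing:
            raise ValidationError(f"missing features: {missing}")
        X = X[:, [pos[f] for f in model.feature_names]]
    elif X.shape[1] != len(model.feature_names):
        raise ValidationError(
            f"expected {len(model.feature_names)} features, got {X.shape[1]}")
    Z = (X - model.center) / model.scale
    coords = Z @ model.pc_loadings @ model.disc_coef
    d2 = ((coords[:, None, :] - model.centroids[None, :, :]) ** 2).sum(axis=2)
    best = d2.argmin(axis=1)
    ties = tuple(int(i) for i in range(len(best))
                 if (np.isclose(d2[i], d2[i, best[i]])).sum() > 1)
    with np.errstate(over="ignore"):
        w = np.exp(-(d2 - d2.min(axis=1, keepdims=True)) / 2.0)
    scores = w / w.sum(axis=1, keepdims=True)
    return DAPCPrediction(
        assignments=tuple(model.groups[b] for b in best),
        coordinates=coords, scores=scores, ties=ties)


def default_m_grid(n_samples: int, n_features: int, k: int,
                   n_points: int = 10) -> tuple[int, ...]:
    """~10 evenly spaced candidate m values from k up to min(n - k, features)."""
    hi = max(k, min(n_samples - k, n_features))
    grid = np.unique(np.linspace(max(1, min(k, hi)), hi, n_points).round().astype(int))
    return tuple(int(g) for g in grid)


def xval_select_m(X: np.ndarray, labels: Sequence[str], grid: Sequence[int],
                  training_fraction: float = 0.9, n_rep: int = 30,
                  seed: int = 0, scale: bool = True) -> XvalResult:
    """Choose the retained-PC count by repeated stratified holdout.

    For every candidate ``m`` and every replicate split, the model is fit on the
    training part and scored on the held-out part; the per-m root-mean-squared
    error ``sqrt(mean((1 - success)^2))`` is minimized, ties going to the
    smallest ``m``.  The same splits are reused across the grid so candidates
    are compared on identical data.
    """
    grid = sorted(set(int(g) for g in grid))
    if not grid:
        raise ValidationError("empty m grid")
    X = np.asarray(X, dtype=float)
    lab = np.array(list(labels))
    splitter = StratifiedShuffleSplit(n_splits=n_rep, train_size=training_fraction,
                                      random_state=seed)
    splits = list(splitter.split(X, lab))
    success: dict[int, list[float]] = {m: [] for m in grid}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for tr, te in splits:
            for m in grid:
                model = fit_dapc(X[tr], lab[tr], m, scale=scale)
                pred = predict_dapc(model, X[te])
                success[m].append(float(np.mean(np.array(pred.assignments) == lab[te])))
    mean_success = {m: float(np.mean(v)) for m, v in success.items()}
    rmse = {m: float(np.sqrt(np.mean((1.0 - np.array(v)) ** 2)))
            for m, v in success.items()}
    chosen = min(grid, key=lambda m: (rmse[m], m))
    return XvalResult(grid=tuple(grid), mean_success=mean_success, rmse=rmse,
                      chosen_m=chosen)


def labels_for_samples(matrix: EmissionMatrix,
                       annotations: dict[str, SpeciesAnnotation],
                       label: str) -> list[Optional[str]]:
    """Per-sample group label from the species annotation table.

    ``alt_trophic_mode`` falls back to the primary trophic mode for species
    without an alternative guild (the alternative-grouping analysis moves only
    the guild-switching species).  A ``None`` entry means the sample carries no
    value for this scheme and should be excluded by the caller.
    """
    out: list[Optional[str]] = []
    for sid, _rep in matrix.sample_ids:
        a = annotations[sid]
        if label == "alt_trophic_mode":
            out.append(a.alt_trophic_mode or a.trophic_mode)
        else:
            out.append({"phylum": a.phylum, "class_": a.class_, "order": a.order,
                        "family": a.family, "trophic_mode": a.trophic_mode,
                        "lifestyle": a.lifestyle, "substrate": a.substrate,
                        "host_type": a.host_type}[label])
    return out
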