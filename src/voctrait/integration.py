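"""Phenotypic integration (PI) of volatile blends.

PI quantifies how strongly the compounds of a blend covary — whether the blend
behaves as one coordinated "chemical communication display" rather than a bag of
independent emissions.  For an ``n`` samples x ``p`` compounds subset:

* **raw index** — the population variance of the eigenvalues of the Pearson
  correlation matrix, ``sum((lambda_i - 1)^2) / p``.  The mean eigenvalue of a
  correlation matrix is exactly 1, so the index runs from 0 (identity
  correlation, no integration) to ``p - 1`` (rank one, perfect integration).
  An equivalent algebraic form, ``sum of squared off-diagonal r / p``, is used
  in the permutation loop for speed; the two are tested to agree to 1e-9.
* **corrected index** — raw minus the random-covariation expectation
  ``(p - 1) / n``, removing the upward bias of estimating correlations from few
  samples.
* **relative PI (%)** — corrected divided by the maximum possible value
  ``p - 1``, times 100.

Significance comes from an empirical null of ``n_null`` draws (default 10,000):
``permute`` mode independently permutes each compound's values across samples
(destroying covariation, preserving marginals); ``subset`` mode redraws random
compound sets of the same size from the full pool.  An observed relative PI
above the null's 95% quantile is flagged significant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np

from .datamodel import (
    CompoundRecord,
    EmissionMatrix,
    SpeciesAnnotation,
    TROPHIC_MODES,
    ValidationError,
)

__all__ = ["PIResult", "integration_index", "corrected_relative_pi", "pi_null",
           "pi_panel", "relative_pi"]

NullMode = Literal["permute", "subset"]


@dataclass(frozen=True)
class PIResult:
    guild: str                 # trophic mode or "all"
    structural_class: str      # class name or "all"
    n: int
    p: int
    raw_index: Optional[float]
    corrected_index: Optional[float]
    relative_pct: Optional[float]
    null_quantile_95: Optional[float]
    p_value: Optional[float]
    n_null: int
    significant: Optional[bool]
    low_n: bool = False
    reason: Optional[str] = None


def _clean_subset(X: np.ndarray) -> tuple[np.ndarray, int]:
    """Drop all-zero and constant columns; return cleaned matrix and p dropped."""
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=0)
    keep = (sd > 0)
    dropped = int((~keep).sum())
    return X[:, keep], dropped


def integration_index(X: np.ndarray) -> float:
    """Raw PI: population variance of the correlation-matrix eigenvalues.

    Constant columns are removed first (with a warning); requires p >= 2 and
    n >= 3 after filtering.
    """
    X, dropped = _clean_subset(X)
    if dropped:
        warnings.warn(f"dropped {dropped} constant column(s) before PI", stacklevel=2)
    n, p = X.shape
    if p < 2:
        raise ValidationError("PI needs >= 2 non-constant compounds")
    if n < 3:
        raise ValidationError("PI needs >= 3 samples")
    corr = np.corrcoef(X, rowvar=False)
    ev = np.linalg.eigvalsh(corr)
    return float(np.mean((ev - 1.0) ** 2))


def corrected_relative_pi(raw_index: float, p: int, n: int) -> tuple[float, float]:
    """Apply the sampling correction and scale to the maximum.

    ``corrected = raw - (p - 1)/n``; ``relative = 100 * corrected / (p - 1)``.
    """
    corrected = raw_index - (p - 1) / n
    relative = 100.0 * corrected / (p - 1)
    return corrected, relative


def relative_pi(X: np.ndarray) -> float:
    """Relative PI (%) of a cleaned subset in one call."""
    Xc, _ = _clean_subset(X)
    n, p = Xc.shape
    raw = integration_index(Xc)
    return corrected_relative_pi(raw, p, n)[1]


def _raw_from_standardized(Z: np.ndarray) -> float:
    """Raw PI from a column-standardized matrix via the Frobenius identity.

    ``sum(lambda^2) = ||R||_F^2 = p + sum_{i != j} r_ij^2`` and the eigenvalues
    of a correlation matrix average to 1, so the eigenvalue variance equals
    ``sum_{i != j} r_ij^2 / p`` — no eigendecomposition needed per draw.
    """
    n, p = Z.shape
    R = (Z.T @ Z) / n
    return float(((R * R).sum() - p) / p)


def pi_null(X: np.ndarray, n_null: int = 10_000, mode: NullMode = "permute",
            seed: int | np.random.SeedSequence = 0,
            pool: Optional[np.ndarray] = None,
            ) -> tuple[np.ndarray, float, float, bool]:
    """Empirical null of relative PI and the 95%-quantile significance call.

    Returns ``(null_values, q95, p_value, significant)`` for the observed subset
    ``X``.  ``permute`` (default) shuffles each compound independently across
    samples; ``subset`` draws random compound sets of size ``p`` from ``pool``
    (full samples x all-compounds matrix) and scores each draw the same way.
    ``p_value = (1 + #{null >= observed}) / (1 + n_null)``; ``significant``
    means observed > q95.
    """
    if n_null < 100:
        warnings.warn(f"n_null={n_null} < 100: 95% quantile is unstable", stacklevel=2)
    Xc, _ = _clean_subset(X)
    n, p = Xc.shape
    if p < 2 or n < 3:
        raise ValidationError("null requires a computable subset (p >= 2, n >= 3)")
    observed = corrected_relative_pi(integration_index(Xc), p, n)[1]
    rng = np.random.default_rng(seed)
    null = np.empty(n_null)
    if mode == "permute":
        # permutation leaves column means/sds unchanged: standardize once
        Z = (Xc - Xc.mean(axis=0)) / Xc.std(axis=0)
        for i in range(n_null):
            Zp = rng.permuted(Z, axis=0)
            raw = _raw_from_standardized(Zp)
            null[i] = corrected_relative_pi(raw, p, n)[1]
    elif mode == "subset":
        if pool is None:
            raise ValidationError("subset mode needs the full compound pool")
        pool = np.asarray(pool, dtype=float)
        usable = np.nonzero(pool.std(axis=0) > 0)[0]
        if usable.size < p:
            raise ValidationError("pool has fewer usable compounds than subset size")
        for i in range(n_null):
            cols = rng.choice(usable, size=p, replace=False)
            sub = pool[:, cols]
            Z = (sub - sub.mean(axis=0)) / sub.std(axis=0)
            raw = _raw_from_standardized(Z)
            null[i] = corrected_relative_pi(raw, p, n)[1]
    else:
        raise ValidationError(f"unknown null mode {mode!r}")
    q95 = float(np.quantile(null, 0.95))
    p_value = float((1 + (null >= observed).sum()) / (1 + n_null))
    return null, q95, p_value, observed > q95


def pi_panel(matrix: EmissionMatrix,
             annotations: dict[str, SpeciesAnnotation],
             compounds: dict[str, CompoundRecord],
             n_null: int = 10_000,
             mode: NullMode = "permute",
             seed: int = 0,
             include_all: bool = True) -> list[PIResult]:
    """PI over every (trophic mode x structural class) cell, plus "all" rows.

    Samples are the replicate rows of the species in each guild (species means
    are not collapsed; ``n`` counts replicates).  Within each cell, compounds
    that are all-zero or constant over the cell's samples are excluded before
    computing the index; cells left with p < 2 or n < 3 are reported as
    incomputable with a reason.  Cells at the n = 3 boundary (a single species)
    are computed but flagged ``low_n``.
    """
    guilds = [g for g in TROPHIC_MODES
              if any(a.trophic_mode == g for a in annotations.values())]
    classes = sorted({compounds[c].structural_class for c in matrix.compound_ids
                      if c in compounds})
    if include_all:
        guilds = guilds + ["all"]
        classes = classes + ["all"]

    results: list[PIResult] = []
    cell_idx = 0
    for guild in guilds:
        rows = [i for i, (sid, _r) in enumerate(matrix.sample_ids)
                if guild == "all" or annotations[sid].trophic_mode == guild]
        for cls in classes:
            cols = [j for j, c in enumerate(matrix.compound_ids)
                    if c in compounds and (cls == "all"
                                           or compounds[c].structural_class == cls)]
            cell_seed = np.random.SeedSequence([seed, cell_idx])
            cell_idx += 1
            sub = matrix.values[np.ix_(rows, cols)] if rows and cols else np.empty((0, 0))
            Xc, _ = _clean_subset(sub)
            n, p = Xc.shape
            if p < 2 or n < 3:
                results.append(PIResult(
                    guild=guild, structural_class=cls, n=n, p=p,
                    raw_index=None, corrected_index=None, relative_pct=None,
                    null_quantile_95=None, p_value=None, n_null=n_null,
                    significant=None,
                    reason=f"incomputable: n={n}, p={p} after filtering"))
                continue
            raw = integration_index(Xc)
            corrected, relative = corrected_relative_pi(raw, p, n)
            _, q95, p_value, significant = pi_null(
                Xc, n_null=n_null, mode=mode, seed=cell_seed,
                pool=matrix.values[rows] if mode == "subset" else None)
            results.append(PIResult(
                guild=guild, structural_class=cls, n=n, p=p,
                raw_index=raw, corrected_index=corrected, relative_pct=relative,
                null_quantile_95=q95, p_value=p_value, n_null=n_null,
                significant=significant, low_n=n <= 3))
    return results
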