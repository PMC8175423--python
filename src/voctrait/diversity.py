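"""Per-species chemical-diversity summaries: Pielou evenness, Shannon entropy,
compound counts, and total emission.

Evenness is computed on the replicate-mean emission profile of each species (one
value per species), using natural logarithms; ``J = H / ln(p)`` over the ``p``
strictly positive compounds is base-invariant and constrained to [0, 1], with
``J = 1`` meaning all detected compounds are emitted in equal abundance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .datamodel import EmissionMatrix

__all__ = ["DiversitySummary", "shannon_entropy", "pielou_evenness", "species_summaries"]


@dataclass(frozen=True)
class DiversitySummary:
    species_id: str
    platform: str
    J: Optional[float]  # None when fewer than 2 compounds detected
    H: Optional[float]  # nats
    n_compounds: int
    total_emission: float


def shannon_entropy(emissions: np.ndarray) -> Optional[float]:
    """Shannon entropy (nats) of the positive relative abundances; None if empty."""
    e = np.asarray(emissions, dtype=float)
    pos = e[e > 0]
    if pos.size == 0:
        return None
    q = pos / pos.sum()
    return float(-(q * np.log(q)).sum())


def pielou_evenness(emissions: np.ndarray) -> Optional[float]:
    """Pielou's J = H / ln(richness) over strictly positive entries.

    Returns None (with a warning) when fewer than 2 compounds are detected —
    evenness of a single compound is undefined.
    """
    e = np.asarray(emissions, dtype=float)
    p = int((e > 0).sum())
    if p < 2:
        warnings.warn("evenness undefined for fewer than 2 detected compounds",
                      stacklevel=2)
        return None
    pos = e[e > 0]
    if np.all(pos == pos[0]):
        return 1.0  # exactly even profile: exact result, no log round-off
    return shannon_entropy(e) / math.log(p)


def species_summaries(matrix: EmissionMatrix) -> pd.DataFrame:
    """One diversity row per species, computed on the replicate-mean profile.

    Columns: ``species_id, platform, J, H, n_compounds, total_emission``;
    J and H are NaN for species with fewer than 2 detected compounds.
    """
    means = matrix.species_means()
    rows = []
    for sid, profile in means.iterrows():
        e = profile.to_numpy()
        p = int((e > 0).sum())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            j = pielou_evenness(e) if p >= 2 else None
        rows.append({
            "species_id": sid,
            "platform": matrix.platform,
            "J": np.nan if j is None else j,
            "H": np.nan if p == 0 else shannon_entropy(e),
            "n_compounds": p,
            "total_emission": float(e.sum()),
        })
    return pd.DataFrame(rows)


def write_diversity_table(table: pd.DataFrame, path: str | Path) -> None:
    Path(path).write_text(
        table.to_csv(sep="\t", index=False, float_format="%.12g", lineterminator="\n"),
        encoding="utf-8", newline="\n")
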