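"""Feature-table normalization chain for the two measurement platforms.

PTR (online) chain, applied in this fixed order:

1. :func:`normalize_reagent_ions` — cps scaled to 1e6 reagent-ion counts (ncps);
2. :func:`subtract_background` — natural cubic spline through the time-stamped
   background series, evaluated at sample times, subtracted, negatives clipped;
3. :func:`area_time_normalize` — division by mycelium area and accumulation time
   (default 70 min);
4. optionally :func:`ncps_to_pmol` where a calibration sensitivity is known;
5. :func:`flag_isotopologues` and :func:`group_fragments` clean up the feature
   table (heavy-isotope features removed, correlated fragment groups annotated).

GC (offline) chain: :func:`internal_standard_normalize`, then
:func:`area_time_normalize` (default 16 h = 960 min collection), with
:func:`kovats_ri` providing retention indices on the n-alkane (C9..C25) scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.interpolate import CubicSpline

from .datamodel import CompoundRecord, EmissionMatrix, ValidationError

__all__ = [
    "SensitivityTable",
    "normalize_reagent_ions",
    "subtract_background",
    "area_time_normalize",
    "ncps_to_pmol",
    "flag_isotopologues",
    "group_fragments",
    "kovats_ri",
    "internal_standard_normalize",
    "DEFAULT_PTR_ACCUMULATION_MIN",
    "DEFAULT_GC_ACCUMULATION_MIN",
]

DEFAULT_PTR_ACCUMULATION_MIN = 70.0
DEFAULT_GC_ACCUMULATION_MIN = 960.0  # 16 h offline collection

#: mass shifts (Da) of one 13C and one 18O substitution relative to the parent
_ISOTOPE_SHIFTS = (1.00336, 2.00425)
_C13_ABUNDANCE = 0.011


@dataclass(frozen=True)
class SensitivityTable:
    """Calibration sensitivities (ncps per ppbv) per PTR compound, optional."""

    sensitivities: Mapping[str, float]

    def __post_init__(self) -> None:
        bad = [c for c, s in self.sensitivities.items() if not s > 0]
        if bad:
            raise ValidationError(f"nonpositive sensitivities for {bad}")


def normalize_reagent_ions(cps: np.ndarray | float, reagent_counts: float) -> np.ndarray:
    """ncps = cps * 1e6 / reagent-ion counts, elementwise."""
    if not reagent_counts > 0:
        raise ValidationError(f"reagent_counts must be > 0, got {reagent_counts}")
    return np.asarray(cps, dtype=float) * 1e6 / reagent_counts


def subtract_background(sample_times: np.ndarray, sample_signals: np.ndarray,
                        background_times: np.ndarray, background_values: np.ndarray,
                        ) -> np.ndarray:
    """Subtract a natural-cubic-spline background, clipping negatives to zero.

    The background series (>= 4 time points, spanning the sample timestamps) is
    interpolated with a natural cubic spline and evaluated at the sample times.
    Values that go negative after subtraction are clipped to 0: downstream
    correlation and evenness statistics require non-negative abundances.
    """
    bt = np.asarray(background_times, dtype=float)
    bv = np.asarray(background_values, dtype=float)
    st = np.asarray(sample_times, dtype=float)
    ss = np.asarray(sample_signals, dtype=float)
    if bt.size < 4:
        raise ValidationError(
            f"cubic-spline background needs >= 4 time points, got {bt.size}; "
            "use a linear-interpolation fallback for sparser series")
    order = np.argsort(bt)
    bt, bv = bt[order], bv[order]
    if st.min() < bt[0] or st.max() > bt[-1]:
        raise ValidationError("sample timestamps outside background time span")
    spline = CubicSpline(bt, bv, bc_type="natural")
    return np.clip(ss - spline(st), 0.0, None)


def area_time_normalize(signal: np.ndarray | float, area_cm2: float,
                        accumulation_minutes: float) -> np.ndarray:
    """Normalize to mycelium area and accumulation time: signal / (area * time)."""
    if not area_cm2 > 0:
        raise ValidationError(f"area_cm2 must be > 0, got {area_cm2}")
    if not accumulation_minutes > 0:
        raise ValidationError(f"accumulation_minutes must be > 0, got {accumulation_minutes}")
    return np.asarray(signal, dtype=float) / (area_cm2 * accumulation_minutes)


def ncps_to_pmol(ncps: np.ndarray, compound_ids: Sequence[str],
                 sensitivities: SensitivityTable, conversion_constant: float = 1.0,
                 ) -> tuple[np.ndarray, list[str]]:
    """Convert ncps columns to pmol cm-2 h-1 where a sensitivity is known.

    The map is ``ncps / sensitivity * conversion_constant`` — a configurable
    linear calibration (the exact flow/molar-volume constant is instrument
    specific, so it is a parameter rather than hard-coded).  Compounds without a
    sensitivity are left in ncps and returned in the flag list, never dropped.
    """
    out = np.array(ncps, dtype=float)
    flagged: list[str] = []
    for j, cid in enumerate(compound_ids):
        s = sensitivities.sensitivities.get(cid)
        if s is None:
            flagged.append(cid)
        else:
            out[..., j] = out[..., j] / s * conversion_constant
    return out, flagged


def _carbon_count_heuristic(mz: float) -> int:
    """Rough carbon count from a protonated mass: ~one carbon per 14 Da of skeleton."""
    return max(1, int(round((mz - 1.008) / 14.0)))


def flag_isotopologues(compounds: Mapping[str, CompoundRecord], matrix: EmissionMatrix,
                       mass_tol_mda: float = 3.0,
                       abundance_window: tuple[float, float] = (0.2, 5.0),
                       check_abundance: bool = True,
                       ) -> dict[str, CompoundRecord]:
    """Flag PTR features that look like 13C / 18O isotopologues of a lighter one.

    A feature F2 is flagged when some F1 exists with ``mz(F2) - mz(F1)`` within
    ``mass_tol_mda`` mDa of a one-13C (+1.00336) or one-18O (+2.00425) shift AND
    — unless ``check_abundance=False`` — the mean intensity ratio F2/F1 lies
    within ``abundance_window`` times the natural-abundance expectation
    (``n_C * 1.1%`` for 13C, from a carbon-count heuristic).  The ratio check
    protects genuine compounds at coincidental mass spacings.
    """
    if matrix.platform != "PTR":
        raise ValidationError("isotopologue flagging applies to the PTR platform")
    means = matrix.values.mean(axis=0)
    mean_of = dict(zip(matrix.compound_ids, means))
    recs = [compounds[c] for c in matrix.compound_ids if c in compounds]
    out = dict(compounds)
    tol = mass_tol_mda / 1000.0
    lo, hi = abundance_window
    for f2 in recs:
        if f2.mz is None:
            continue
        for f1 in recs:
            if f1 is f2 or f1.mz is None or f1.mz >= f2.mz:
                continue
            diff = f2.mz - f1.mz
            if not any(abs(diff - shift) <= tol for shift in _ISOTOPE_SHIFTS):
                continue
            if check_abundance:
                m1 = mean_of.get(f1.compound_id, 0.0)
                if m1 <= 0:
                    continue
                ratio = mean_of.get(f2.compound_id, 0.0) / m1
                expected = _carbon_count_heuristic(f1.mz) * _C13_ABUNDANCE
                if not (lo * expected <= ratio <= hi * expected):
                    continue
            out[f2.compound_id] = replace(f2, is_isotopologue=True)
            break
    return out


def group_fragments(matrix: EmissionMatrix, r2_threshold: float = 0.9,
                    ) -> dict[str, str]:
    """Group mass features whose squared Pearson correlation exceeds a threshold.

    Builds a graph over compounds with an edge wherever r^2 > ``r2_threshold``
    across samples; connected components of size >= 2 become fragment groups
    (``frag_001``, ...).  Constant columns have undefined correlation, treated
    as 0 (no edges).  Groups annotate likely fragment families; columns are not
    collapsed — summing members is a separate, optional reporting step.
    """
    if matrix.n_samples < 3:
        raise ValidationError("fragment grouping needs >= 3 samples")
    X = matrix.values
    sd = X.std(axis=0)
    ok = sd > 0
    n = matrix.n_compounds
    corr = np.zeros((n, n))
    if ok.sum() >= 2:
        sub = np.corrcoef(X[:, ok], rowvar=False)
        corr[np.ix_(ok, ok)] = sub
    adj = (corr ** 2 > r2_threshold)
    np.fill_diagonal(adj, False)

    # connected components by iterative DFS
    assignment: dict[str, str] = {}
    seen = np.zeros(n, dtype=bool)
    group_no = 0
    for start in range(n):
        if seen[start]:
            continue
        stack, members = [start], []
        seen[start] = True
        while stack:
            u = stack.pop()
            members.append(u)
            for v in np.nonzero(adj[u])[0]:
                if not seen[v]:
                    seen[v] = True
                    stack.append(int(v))
        if len(members) >= 2:
            group_no += 1
            gid = f"frag_{group_no:03d}"
            for u in sorted(members):
                assignment[matrix.compound_ids[u]] = gid
    return assignment


def kovats_ri(rt_minutes: float, alkane_rts: Mapping[int, float]) -> float:
    """Retention index by linear interpolation on the n-alkane ladder.

    Uses the temperature-programmed (van den Dool-Kratz) form
    ``RI = 100 * (n + (rt - rt_n) / (rt_{n+1} - rt_n))`` with ``rt_n <= rt <
    rt_{n+1}``; no extrapolation outside the C9..C25 ladder span.
    """
    ns = sorted(alkane_rts)
    rts = [alkane_rts[n] for n in ns]
    if any(b <= a for a, b in zip(rts, rts[1:])):
        raise ValidationError("alkane retention times must be strictly increasing")
    if rt_minutes < rts[0] or rt_minutes > rts[-1]:
        raise ValidationError(
            f"rt {rt_minutes} min outside alkane span [{rts[0]}, {rts[-1]}]; "
            "no extrapolation")
    for (n0, t0), (n1, t1) in zip(zip(ns, rts), zip(ns[1:], rts[1:])):
        if t0 <= rt_minutes <= t1:
            # ladder gaps > 1 carbon interpolate across the full gap
            return 100.0 * (n0 + (n1 - n0) * (rt_minutes - t0) / (t1 - t0))
    raise AssertionError("unreachable")  # pragma: no cover


def internal_standard_normalize(areas: np.ndarray | float, is_area: float,
                                is_reference_area: float) -> np.ndarray:
    """Rescale GC peak areas so the internal standard matches its reference area."""
    if not is_area > 0:
        raise ValidationError(f"internal-standard area must be > 0, got {is_area}")
    if not is_reference_area > 0:
        raise ValidationError("reference area must be > 0")
    return np.asarray(areas, dtype=float) * (is_reference_area / is_area)
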