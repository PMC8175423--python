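"""Domain types and delimited-text IO for dual-platform volatilome tables.

The central container is :class:`EmissionMatrix`: a samples x compounds table of
non-negative emission rates from one measurement platform (online PTR-ToF-MS mass
features, or offline GC-MS annotated compounds), with sample keys of the form
``species:replicate``.  Zeros encode "not detected"; there is no separate missing
code.  Matrices are serialized as TSV with mandatory ``#platform=`` and ``#units=``
pragma lines so that unit provenance always travels with the numbers.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PLATFORMS",
    "UNITS",
    "TROPHIC_MODES",
    "PHYLA",
    "LIFESTYLES",
    "SUBSTRATES",
    "HOST_TYPES",
    "STRUCTURAL_CLASSES",
    "ValidationError",
    "EmissionMatrix",
    "CompoundRecord",
    "SpeciesAnnotation",
    "SampleMeasurementRaw",
    "read_emission_matrix",
    "write_emission_matrix",
    "read_species_annotation",
    "write_species_annotation",
    "read_compound_records",
    "write_compound_records",
    "merge_platforms",
]

# ---------------------------------------------------------------------------
# Closed vocabularies
# ---------------------------------------------------------------------------

PLATFORMS = ("PTR", "GC", "COMBINED")
#: ncps = counts per second normalized to 1e6 reagent-ion counts, per mycelium
#: area and accumulation time; pmol is the calibrated molar emission rate.
UNITS = ("ncps_cm-2_s-1", "pmol_cm-2_h-1")

TROPHIC_MODES = ("mycoparasitic", "mycorrhizal", "phytopathogenic", "saprotrophic")
PHYLA = ("Ascomycota", "Basidiomycota", "Zygomycota")
LIFESTYLES = ("symbiotic", "non_symbiotic")
SUBSTRATES = ("litter", "root", "shoot")
HOST_TYPES = ("tree", "herbaceous")

#: Structural classes used to group compounds for the integration analysis.
#: The vocabulary is closed but configurable at read time.
STRUCTURAL_CLASSES = (
    "alkane",
    "alkene",
    "fatty_alcohol",
    "carboxylic_acid",
    "ester",
    "aldehyde",
    "ketone",
    "monoterpenoid",
    "sesquiterpene",
    "aromatic",
    "unknown",
)


class ValidationError(ValueError):
    """Raised when an input table violates a datamodel invariant."""


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EmissionMatrix:
    """Samples x compounds emission-rate table from a single platform.

    Parameters
    ----------
    values
        Non-negative float matrix, rows = samples, columns = compounds.
    platform
        ``"PTR"`` or ``"GC"``.
    sample_ids
        Ordered ``(species_id, replicate_index)`` pairs, one per row.
    compound_ids
        Ordered compound keys, one per column.
    units
        One of :data:`UNITS`.
    """

    values: np.ndarray
    platform: str
    sample_ids: tuple[tuple[str, int], ...]
    compound_ids: tuple[str, ...]
    units: str

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "sample_ids", tuple((s, int(r)) for s, r in self.sample_ids))
        object.__setattr__(self, "compound_ids", tuple(self.compound_ids))
        _check(self.platform in PLATFORMS, f"unknown platform {self.platform!r}")
        _check(self.units in UNITS, f"unknown units {self.units!r}; allowed: {UNITS}")
        _check(vals.ndim == 2, "values must be 2-D")
        _check(vals.shape == (len(self.sample_ids), len(self.compound_ids)),
               f"shape {vals.shape} does not match {len(self.sample_ids)} samples x "
               f"{len(self.compound_ids)} compounds")
        if np.isnan(vals).any():
            i, j = np.argwhere(np.isnan(vals))[0]
            raise ValidationError(f"NaN at sample {self._key(i)!r}, compound "
                                  f"{self.compound_ids[j]!r}; zeros encode non-detection")
        if (vals < 0).any():
            i, j = np.argwhere(vals < 0)[0]
            raise ValidationError(f"negative value {vals[i, j]} at sample {self._key(i)!r}, "
                                  f"compound {self.compound_ids[j]!r}")
        _check(len(set(self.sample_ids)) == len(self.sample_ids), "duplicate sample keys")
        _check(len(set(self.compound_ids)) == len(self.compound_ids), "duplicate compound ids")

    def _key(self, row: int) -> str:
        s, r = self.sample_ids[row]
        return f"{s}:{r}"

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_compounds(self) -> int:
        return self.values.shape[1]

    @property
    def species(self) -> tuple[str, ...]:
        """Unique species ids in first-appearance order."""
        seen: dict[str, None] = {}
        for s, _ in self.sample_ids:
            seen.setdefault(s)
        return tuple(seen)

    def species_means(self) -> pd.DataFrame:
        """Replicate-mean emission profile per species (species x compounds)."""
        df = self.to_frame()
        species = [s for s, _ in self.sample_ids]
        return df.groupby(pd.Index(species, name="species_id"), sort=False).mean()

    def to_frame(self) -> pd.DataFrame:
        idx = pd.Index([self._key(i) for i in range(self.n_samples)], name="sample")
        return pd.DataFrame(self.values, index=idx, columns=list(self.compound_ids))

    def select_samples(self, rows: Sequence[int]) -> "EmissionMatrix":
        rows = list(rows)
        return EmissionMatrix(self.values[rows], self.platform,
                              tuple(self.sample_ids[i] for i in rows),
                              self.compound_ids, self.units)

    def select_compounds(self, ids: Sequence[str]) -> "EmissionMatrix":
        pos = {c: j for j, c in enumerate(self.compound_ids)}
        missing = [c for c in ids if c not in pos]
        _check(not missing, f"unknown compound ids: {missing}")
        cols = [pos[c] for c in ids]
        return EmissionMatrix(self.values[:, cols], self.platform, self.sample_ids,
                              tuple(ids), self.units)


@dataclass(frozen=True)
class CompoundRecord:
    """Identity of one measured compound or mass feature.

    PTR features carry an ``mz`` (Da); GC compounds carry a Kovats
    ``retention_index``.  Exactly one of the two is populated.
    """

    compound_id: str
    platform: str
    mz: Optional[float] = None
    retention_index: Optional[float] = None
    annotation: str = ""
    structural_class: str = "unknown"
    cluster_letter: Optional[str] = None
    is_isotopologue: bool = False
    fragment_group: Optional[str] = None

    def __post_init__(self) -> None:
        _check(self.platform in ("PTR", "GC"),
               f"compound platform must be PTR or GC, got {self.platform!r}")
        if self.platform == "PTR":
            _check(self.mz is not None and self.retention_index is None,
                   f"{self.compound_id}: PTR records carry mz only")
            _check(self.mz > 0, f"{self.compound_id}: mz must be positive")
        else:
            _check(self.retention_index is not None and self.mz is None,
                   f"{self.compound_id}: GC records carry retention_index only")
            _check(self.retention_index > 0,
                   f"{self.compound_id}: retention_index must be positive")


@dataclass(frozen=True)
class SpeciesAnnotation:
    """Taxonomy and ecological-guild labels for one fungal species."""

    species_id: str
    phylum: str
    class_: str
    order: str
    family: str
    trophic_mode: str
    lifestyle: str
    substrate: str
    alt_trophic_mode: Optional[str] = None
    host_type: Optional[str] = None
    mycelium_area_cm2: float = 1.0

    def __post_init__(self) -> None:
        for name, val, vocab in (
            ("trophic_mode", self.trophic_mode, TROPHIC_MODES),
            ("lifestyle", self.lifestyle, LIFESTYLES),
            ("substrate", self.substrate, SUBSTRATES),
        ):
            _check(val in vocab,
                   f"{self.species_id}: {name} {val!r} not in allowed values {vocab}")
        if self.alt_trophic_mode is not None:
            _check(self.alt_trophic_mode in TROPHIC_MODES,
                   f"{self.species_id}: alt_trophic_mode {self.alt_trophic_mode!r} "
                   f"not in allowed values {TROPHIC_MODES}")
        if self.host_type is not None:
            _check(self.host_type in HOST_TYPES,
                   f"{self.species_id}: host_type {self.host_type!r} "
                   f"not in allowed values {HOST_TYPES}")
        _check(self.mycelium_area_cm2 > 0,
               f"{self.species_id}: mycelium_area_cm2 must be > 0")


@dataclass(frozen=True)
class SampleMeasurementRaw:
    """One raw measurement prior to the preprocessing chain.

    PTR samples carry counts-per-second signals plus reagent-ion counts and a
    background time series; GC samples carry peak areas plus the internal-standard
    area and the n-alkane (C9..C25) retention-time table used for Kovats indices.
    """

    platform: str
    species_id: str
    replicate_index: int
    signal: np.ndarray
    background_times: Optional[np.ndarray] = None
    background_values: Optional[np.ndarray] = None
    reagent_ion_counts: Optional[float] = None
    internal_standard_area: Optional[float] = None
    alkane_rt_table: Optional[Mapping[int, float]] = None

    def __post_init__(self) -> None:
        _check(self.platform in PLATFORMS, f"unknown platform {self.platform!r}")
        if self.reagent_ion_counts is not None:
            _check(self.reagent_ion_counts > 0, "reagent_ion_counts must be > 0")
        if self.alkane_rt_table is not None:
            ns = sorted(self.alkane_rt_table)
            rts = [self.alkane_rt_table[n] for n in ns]
            _check(all(b > a for a, b in zip(rts, rts[1:])),
                   "alkane retention times must be strictly increasing in carbon number")


# ---------------------------------------------------------------------------
# TSV / JSON IO
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.12g"  # 12 significant digits: lossless round-trip contract


def write_emission_matrix(matrix: EmissionMatrix, path: str | Path) -> None:
    """Write a TSV with ``#platform=`` / ``#units=`` pragma lines (UTF-8, LF)."""
    buf = io.StringIO()
    buf.write(f"#platform={matrix.platform}\n#units={matrix.units}\n")
    buf.write("sample\t" + "\t".join(matrix.compound_ids) + "\n")
    for i in range(matrix.n_samples):
        row = "\t".join(_FLOAT_FMT % v for v in matrix.values[i])
        buf.write(f"{matrix._key(i)}\t{row}\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8", newline="\n")


def read_emission_matrix(path: str | Path, platform: Optional[str] = None) -> EmissionMatrix:
    """Read a pragma-headed emission TSV and validate it.

    Raises :class:`ValidationError` on missing pragmas, a platform mismatch,
    ragged rows, duplicate keys, or negative values (naming the offending cell).
    """
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    pragmas: dict[str, str] = {}
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#") and "=" in line:
            key, _, val = line[1:].partition("=")
            pragmas[key.strip()] = val.strip()
            body_start = i + 1
        else:
            break
    _check("platform" in pragmas, f"{path}: missing mandatory #platform= pragma")
    _check("units" in pragmas, f"{path}: missing mandatory #units= pragma")
    file_platform = pragmas["platform"]
    if platform is not None:
        _check(file_platform == platform,
               f"{path}: file platform {file_platform!r} != requested {platform!r}")
    body = lines[body_start:]
    _check(len(body) >= 1, f"{path}: no header row")
    header = body[0].split("\t")
    compound_ids = tuple(header[1:])
    sample_ids: list[tuple[str, int]] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(body[1:], start=body_start + 2):
        if not line.strip():
            continue
        cells = line.split("\t")
        _check(len(cells) == len(header),
               f"{path}:{lineno}: ragged row ({len(cells)} cells, expected {len(header)})")
        key = cells[0]
        sp, _, rep = key.partition(":")
        _check(bool(sp) and rep.isdigit(),
               f"{path}:{lineno}: sample key {key!r} is not 'species:replicate'")
        sample_ids.append((sp, int(rep)))
        try:
            rows.append([float(c) for c in cells[1:]])
        except ValueError as exc:
            raise ValidationError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
    return EmissionMatrix(np.array(rows, dtype=float).reshape(len(rows), len(compound_ids)),
                          file_platform, tuple(sample_ids), compound_ids, pragmas["units"])


_ANNOT_COLS = ["species_id", "phylum", "class_", "order", "family", "trophic_mode",
               "alt_trophic_mode", "lifestyle", "substrate", "host_type",
               "mycelium_area_cm2"]


def write_species_annotation(records: Iterable[SpeciesAnnotation], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append({
            "species_id": r.species_id, "phylum": r.phylum, "class_": r.class_,
            "order": r.order, "family": r.family, "trophic_mode": r.trophic_mode,
            "alt_trophic_mode": r.alt_trophic_mode or "",
            "lifestyle": r.lifestyle, "substrate": r.substrate,
            "host_type": r.host_type or "",
            "mycelium_area_cm2": _FLOAT_FMT % r.mycelium_area_cm2,
        })
    df = pd.DataFrame(rows, columns=_ANNOT_COLS)
    Path(path).write_text(df.to_csv(sep="\t", index=False, lineterminator="\n"),
                          encoding="utf-8", newline="\n")


def read_species_annotation(path: str | Path) -> dict[str, SpeciesAnnotation]:
    """Read the per-species taxonomy/guild TSV into a dict keyed by species_id."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _ANNOT_COLS if c not in df.columns]
    _check(not missing, f"{path}: missing columns {missing}")
    out: dict[str, SpeciesAnnotation] = {}
    for _, row in df.iterrows():
        rec = SpeciesAnnotation(
            species_id=row["species_id"], phylum=row["phylum"], class_=row["class_"],
            order=row["order"], family=row["family"], trophic_mode=row["trophic_mode"],
            alt_trophic_mode=row["alt_trophic_mode"] or None,
            lifestyle=row["lifestyle"], substrate=row["substrate"],
            host_type=row["host_type"] or None,
            mycelium_area_cm2=float(row["mycelium_area_cm2"]),
        )
        _check(rec.species_id not in out, f"{path}: duplicate species_id {rec.species_id!r}")
        out[rec.species_id] = rec
    return out


_COMPOUND_COLS = ["compound_id", "platform", "mz", "retention_index", "annotation",
                  "structural_class", "cluster_letter", "is_isotopologue",
                  "fragment_group"]


def write_compound_records(records: Iterable[CompoundRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append({
            "compound_id": r.compound_id, "platform": r.platform,
            "mz": "" if r.mz is None else _FLOAT_FMT % r.mz,
            "retention_index": "" if r.retention_index is None else _FLOAT_FMT % r.retention_index,
            "annotation": r.annotation, "structural_class": r.structural_class,
            "cluster_letter": r.cluster_letter or "",
            "is_isotopologue": "1" if r.is_isotopologue else "0",
            "fragment_group": r.fragment_group or "",
        })
    df = pd.DataFrame(rows, columns=_COMPOUND_COLS)
    Path(path).write_text(df.to_csv(sep="\t", index=False, lineterminator="\n"),
                          encoding="utf-8", newline="\n")


def read_compound_records(path: str | Path,
                          class_vocabulary: Sequence[str] = STRUCTURAL_CLASSES,
                          ) -> dict[str, CompoundRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _COMPOUND_COLS if c not in df.columns]
    _check(not missing, f"{path}: missing columns {missing}")
    out: dict[str, CompoundRecord] = {}
    for _, row in df.iterrows():
        cls = row["structural_class"]
        _check(cls in class_vocabulary,
               f"{path}: structural_class {cls!r} not in allowed values {tuple(class_vocabulary)}")
        rec = CompoundRecord(
            compound_id=row["compound_id"], platform=row["platform"],
            mz=float(row["mz"]) if row["mz"] else None,
            retention_index=float(row["retention_index"]) if row["retention_index"] else None,
            annotation=row["annotation"], structural_class=cls,
            cluster_letter=row["cluster_letter"] or None,
            is_isotopologue=row["is_isotopologue"] in ("1", "true", "True"),
            fragment_group=row["fragment_group"] or None,
        )
        _check(rec.compound_id not in out, f"{path}: duplicate compound_id {rec.compound_id!r}")
        out[rec.compound_id] = rec
    return out


# ---------------------------------------------------------------------------
# Platform merging
# ---------------------------------------------------------------------------


def merge_platforms(ptr: EmissionMatrix, gc: EmissionMatrix) -> EmissionMatrix:
    """Column-concatenate the PTR and GC tables over identical sample sets.

    Column order is PTR columns first, then GC columns; compound ids keep their
    platform prefixes so the origin stays recoverable.  GC rows are reordered to
    the PTR sample order if needed.  Per-column standardization is deferred to
    the discriminant-analysis stage; the merged table keeps raw values (units
    pragma records the PTR units — downstream unit-variance scaling is what makes
    mixing the two scales legitimate).
    """
    ptr_set, gc_set = set(ptr.sample_ids), set(gc.sample_ids)
    if ptr_set != gc_set:
        only_ptr = sorted(ptr_set - gc_set)
        only_gc = sorted(gc_set - ptr_set)
        raise ValidationError(
            f"sample sets differ; only in PTR: {only_ptr}, only in GC: {only_gc}")
    order = {sid: i for i, sid in enumerate(gc.sample_ids)}
    gc_rows = gc.values[[order[sid] for sid in ptr.sample_ids]]
    return EmissionMatrix(np.hstack([ptr.values, gc_rows]), "COMBINED",
                          ptr.sample_ids, ptr.compound_ids + gc.compound_ids, ptr.units)
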