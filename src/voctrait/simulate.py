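"""Synthetic dual-platform volatilome generator with planted ground truth.

The generator emulates the structure of a mycelium-emission survey: ``n_species``
fungal species measured in ``n_replicates`` biological replicates on two platforms
(a PTR-ToF-MS-like table of mass features and a GC-MS-like table of annotated
compounds), with taxonomy/guild labels, compound structural classes, planted
group-specific biomarkers, and planted within-class covariation blocks.

Generative model (log scale), for compound ``j``, species ``s``, replicate ``r``::

    x = mu0 + a_j + b_{g(s),j} + sum_k lambda_k * f_{s,c(j)} + eps

* ``a_j ~ N(0, 0.5)`` — per-compound baseline offset (some compounds are simply
  bigger emitters than others);
* ``b`` — planted biomarker shift: ``delta * sigma`` added when species ``s``
  carries the label value a biomarker entry targets with compound ``j``;
* ``f_{s,c} ~ N(0, 1)`` — per-species latent factor shared by every compound of
  structural class ``c``; a covariation entry ``(trophic_mode, class, loading)``
  switches it on with weight ``loading`` for species of that trophic mode
  (``trophic_mode=None`` applies it to all species);
* ``eps ~ N(0, sigma)`` — replicate noise; the GC platform uses
  ``sigma0 * gc_sigma_factor`` (default 0.6x) so GC profiles come out more even
  than PTR profiles, matching the qualitative platform contrast.

Emission is ``exp(x)``, masked to exactly 0 with probability ``sparsity`` per
(species, compound) pair — a species either emits a compound in all replicates or
in none, so replicate profiles are species fingerprints.  Masking is never applied
to a planted biomarker in the species that carry its target label: the planted
ground truth would otherwise stop being a biomarker.

Everything is drawn from one seeded :class:`numpy.random.Generator`; identical
scenarios (including seed) produce bit-identical matrices on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .datamodel import (
    HOST_TYPES,
    LIFESTYLES,
    PHYLA,
    STRUCTURAL_CLASSES,
    SUBSTRATES,
    TROPHIC_MODES,
    CompoundRecord,
    EmissionMatrix,
    SpeciesAnnotation,
    ValidationError,
)

__all__ = [
    "BiomarkerSpec",
    "CovariationSpec",
    "SimulationScenario",
    "GroundTruth",
    "simulate",
    "default_biomarker_spec",
    "default_covariation_spec",
    "build_annotations",
]

LabelName = Literal["phylum", "trophic_mode", "lifestyle", "substrate", "host_type"]

#: classes assigned round-robin to generated compounds ("unknown" excluded)
_GEN_CLASSES = tuple(c for c in STRUCTURAL_CLASSES if c != "unknown")


class BiomarkerSpec(BaseModel):
    """One planted biomarker: compounds shifted up for one label value."""

    model_config = ConfigDict(extra="forbid")

    label: LabelName
    class_value: str
    compound_ids: list[str]
    delta: float = Field(ge=0.0, description="log-effect size in units of sigma0")


class CovariationSpec(BaseModel):
    """One planted covariation block: a latent factor over a structural class."""

    model_config = ConfigDict(extra="forbid")

    trophic_mode: Optional[str] = None  # None: factor active in every species
    structural_class: str
    loading: float = Field(ge=0.0, le=1.0)

    @field_validator("trophic_mode")
    @classmethod
    def _known_mode(cls, v: Optional[str]) -> Optional[str]:
        if v is not None and v not in TROPHIC_MODES:
            raise ValueError(f"unknown trophic_mode {v!r}")
        return v

    @field_validator("structural_class")
    @classmethod
    def _known_class(cls, v: str) -> str:
        if v not in STRUCTURAL_CLASSES:
            raise ValueError(f"unknown structural_class {v!r}")
        return v


class SimulationScenario(BaseModel):
    """Full specification of one synthetic study.

    The defaults are the study conditions every downstream benchmark runs under:
    43 species x 3 replicates, 200 PTR mass features + 60 GC compounds, log-normal
    emissions (mu0=2, sigma0=1) with 35% species-level sparsity, six planted
    trophic-mode biomarkers at delta=3 plus biomarkers for the other label
    schemes, and one covariation block (saprotrophic x carboxylic acids, loading
    0.8).  ``biomarker_spec=None`` / ``covariation_spec=None`` select these
    defaults; pass ``[]`` explicitly for a null scenario.
    """

    model_config = ConfigDict(extra="forbid")

    n_species: int = Field(default=43, ge=4)
    n_replicates: int = Field(default=3, ge=2)
    n_ptr_compounds: int = Field(default=200, ge=1)
    n_gc_compounds: int = Field(default=60, ge=1)
    labels: Literal["balanced", "unbalanced"] = "balanced"
    biomarker_spec: Optional[list[BiomarkerSpec]] = None
    covariation_spec: Optional[list[CovariationSpec]] = None
    mu0: float = 2.0
    sigma0: float = Field(default=1.0, gt=0.0)
    gc_sigma_factor: float = Field(default=0.6, gt=0.0)
    compound_offset_sd: float = Field(default=0.5, ge=0.0)
    sparsity: float = Field(default=0.35, ge=0.0, lt=1.0)
    seed: int = 0


@dataclass(frozen=True)
class GroundTruth:
    """What was planted: the answer key downstream stages are scored against."""

    biomarkers: dict[str, dict[str, tuple[str, ...]]]  # label -> class_value -> ids
    covariation_blocks: tuple[tuple[Optional[str], str, float, tuple[str, ...]], ...]
    structural_classes: dict[str, str]  # compound_id -> class

    def planted_for_label(self, label: str) -> tuple[str, ...]:
        """All compound ids planted as biomarkers for one labeling scheme."""
        out: list[str] = []
        for ids in self.biomarkers.get(label, {}).values():
            out.extend(ids)
        return tuple(dict.fromkeys(out))


# ---------------------------------------------------------------------------
# Label schemes
# ---------------------------------------------------------------------------


def build_annotations(n_species: int, labels: str = "balanced") -> dict[str, SpeciesAnnotation]:
    """Deterministic taxonomy/guild table for ``n_species`` synthetic species.

    ``balanced`` cycles every guild label so classes are as equal as possible and
    every value occurs at least twice (stratified splits stay feasible).
    ``unbalanced`` reproduces a survey-like imbalance: 2 mycoparasites, 8
    mycorrhizal, 13 phytopathogens, and the rest saprotrophs — exercising the
    minority-upsampling path.  A handful of species receive an alternative
    trophic mode (the next mode in the cycle), emulating guild-switching taxa.
    """
    out: dict[str, SpeciesAnnotation] = {}
    for i in range(n_species):
        sid = f"sp{i + 1:02d}"
        if labels == "balanced":
            trophic = TROPHIC_MODES[i % 4]
        elif labels == "unbalanced":
            if i < 2:
                trophic = "mycoparasitic"
            elif i < 10:
                trophic = "mycorrhizal"
            elif i < 23:
                trophic = "phytopathogenic"
            else:
                trophic = "saprotrophic"
        else:
            raise ValidationError(f"unknown label preset {labels!r}")
        phylum = PHYLA[i % 3]
        alt = TROPHIC_MODES[(TROPHIC_MODES.index(trophic) + 1) % 4] if i % 7 == 0 else None
        out[sid] = SpeciesAnnotation(
            species_id=sid,
            phylum=phylum,
            class_=f"{phylum[:4]}class{i % 5 + 1}",
            order=f"order{i % 8 + 1}",
            family=f"family{i % 11 + 1}",
            trophic_mode=trophic,
            alt_trophic_mode=alt,
            # cycle periods chosen so no scheme is a function of another:
            # planted biomarkers of one scheme must not predict a different one
            lifestyle=LIFESTYLES[(i // 4) % 2],
            substrate=SUBSTRATES[(i // 3) % 3],
            host_type=HOST_TYPES[(i // 6) % 2],
            mycelium_area_cm2=10.0 + 0.25 * (i % 8),
        )
    _check_coverage(out)
    return out


def _check_coverage(annotations: dict[str, SpeciesAnnotation]) -> None:
    """Every label value used by a scheme must occur at least twice."""
    schemes = {
        "phylum": lambda a: a.phylum,
        "trophic_mode": lambda a: a.trophic_mode,
        "lifestyle": lambda a: a.lifestyle,
        "substrate": lambda a: a.substrate,
        "host_type": lambda a: a.host_type,
    }
    for name, get in schemes.items():
        counts: dict[str, int] = {}
        for a in annotations.values():
            v = get(a)
            if v is not None:
                counts[v] = counts.get(v, 0) + 1
        rare = [v for v, c in counts.items() if c < 2]
        if rare:
            raise ValidationError(f"label scheme {name!r}: values {rare} occur fewer "
                                  f"than twice; stratified splitting is impossible")


# ---------------------------------------------------------------------------
# Default planted structure
# ---------------------------------------------------------------------------


def default_biomarker_spec() -> list[BiomarkerSpec]:
    """Planted biomarkers for each labeling scheme under the default naming.

    Six single-compound trophic-mode biomarkers on the PTR platform (delta=3),
    plus smaller sets for phylum, lifestyle, substrate and host type, split
    between the two platforms.
    """
    spec: list[BiomarkerSpec] = []
    trophic_targets = ["mycoparasitic", "mycorrhizal", "phytopathogenic",
                       "saprotrophic", "mycorrhizal", "phytopathogenic"]
    for j, mode in enumerate(trophic_targets):
        spec.append(BiomarkerSpec(label="trophic_mode", class_value=mode,
                                  compound_ids=[f"PTR_{j:03d}"], delta=3.0))
    for j, phylum in enumerate(PHYLA):
        spec.append(BiomarkerSpec(label="phylum", class_value=phylum,
                                  compound_ids=[f"GC_{j:03d}"], delta=3.0))
    for j, ls in enumerate(LIFESTYLES):
        spec.append(BiomarkerSpec(label="lifestyle", class_value=ls,
                                  compound_ids=[f"PTR_{6 + j:03d}"], delta=3.0))
    for j, sub in enumerate(SUBSTRATES):
        spec.append(BiomarkerSpec(label="substrate", class_value=sub,
                                  compound_ids=[f"GC_{3 + j:03d}"], delta=3.0))
    for j, host in enumerate(HOST_TYPES):
        spec.append(BiomarkerSpec(label="host_type", class_value=host,
                                  compound_ids=[f"PTR_{8 + j:03d}"], delta=3.0))
    return spec


def default_covariation_spec() -> list[CovariationSpec]:
    return [CovariationSpec(trophic_mode="saprotrophic",
                            structural_class="carboxylic_acid", loading=0.8)]


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def _label_value(a: SpeciesAnnotation, label: str) -> Optional[str]:
    return {"phylum": a.phylum, "trophic_mode": a.trophic_mode,
            "lifestyle": a.lifestyle, "substrate": a.substrate,
            "host_type": a.host_type}[label]


def simulate(scenario: SimulationScenario):
    """Generate one synthetic study.

    Returns
    -------
    tuple
        ``(ptr, gc, annotations, compounds, truth)`` — the two
        :class:`~voctrait.datamodel.EmissionMatrix` tables, the per-species
        :class:`~voctrait.datamodel.SpeciesAnnotation` dict, the per-compound
        :class:`~voctrait.datamodel.CompoundRecord` dict, and the
        :class:`GroundTruth` answer key.
    """
    sc = scenario
    annotations = build_annotations(sc.n_species, sc.labels)
    species = list(annotations)

    compounds: dict[str, CompoundRecord] = {}
    for j in range(sc.n_ptr_compounds):
        cid = f"PTR_{j:03d}"
        compounds[cid] = CompoundRecord(
            compound_id=cid, platform="PTR", mz=round(33.0 + 1.003 * j, 3),
            structural_class=_GEN_CLASSES[j % len(_GEN_CLASSES)])
    for j in range(sc.n_gc_compounds):
        cid = f"GC_{j:03d}"
        compounds[cid] = CompoundRecord(
            compound_id=cid, platform="GC", retention_index=900.0 + 25.0 * j,
            structural_class=_GEN_CLASSES[j % len(_GEN_CLASSES)])

    bio = sc.biomarker_spec if sc.biomarker_spec is not None else default_biomarker_spec()
    cov = sc.covariation_spec if sc.covariation_spec is not None else default_covariation_spec()
    for entry in bio:
        unknown = [c for c in entry.compound_ids if c not in compounds]
        if unknown:
            raise ValidationError(f"biomarker_spec names unknown compounds {unknown}")

    rng = np.random.default_rng(sc.seed)
    # one latent factor per (species, class), shared across platforms, drawn
    # up-front so adding/removing covariation entries never shifts other draws
    factors = rng.normal(size=(sc.n_species, len(_GEN_CLASSES)))
    class_index = {c: k for k, c in enumerate(_GEN_CLASSES)}

    matrices: dict[str, EmissionMatrix] = {}
    for platform, n_comp, units in (("PTR", sc.n_ptr_compounds, "ncps_cm-2_s-1"),
                                    ("GC", sc.n_gc_compounds, "pmol_cm-2_h-1")):
        sigma = sc.sigma0 * (sc.gc_sigma_factor if platform == "GC" else 1.0)
        ids = [c for c in compounds if compounds[c].platform == platform]
        cls = np.array([class_index[compounds[c].structural_class] for c in ids])

        a = rng.normal(0.0, sc.compound_offset_sd, size=n_comp)

        # planted biomarker shifts, species x compound
        b = np.zeros((sc.n_species, n_comp))
        protected = np.zeros((sc.n_species, n_comp), dtype=bool)
        col = {c: j for j, c in enumerate(ids)}
        for entry in bio:
            cols = [col[c] for c in entry.compound_ids if c in col]
            if not cols:
                continue
            carriers = [i for i, s in enumerate(species)
                        if _label_value(annotations[s], entry.label) == entry.class_value]
            for i in carriers:
                b[i, cols] += entry.delta * sigma
                protected[i, cols] = True

        # covariation: loading * latent factor, species x compound
        lam = np.zeros((sc.n_species, n_comp))
        for entry in cov:
            in_class = cls == class_index[entry.structural_class]
            for i, s in enumerate(species):
                if entry.trophic_mode is None or \
                        annotations[s].trophic_mode == entry.trophic_mode:
                    lam[i, in_class] = entry.loading
        factor_term = lam * factors[:, cls]

        mean = sc.mu0 + a[None, :] + b + factor_term  # species x compound
        eps = rng.normal(0.0, sigma, size=(sc.n_species, sc.n_replicates, n_comp))
        x = mean[:, None, :] + eps

        mask = rng.random((sc.n_species, n_comp)) < sc.sparsity
        mask &= ~protected
        values = np.exp(x) * (~mask)[:, None, :]

        sample_ids = tuple((s, r + 1) for s in species for r in range(sc.n_replicates))
        matrices[platform] = EmissionMatrix(
            values.reshape(sc.n_species * sc.n_replicates, n_comp),
            platform, sample_ids, tuple(ids), units)

    bio_map: dict[str, dict[str, tuple[str, ...]]] = {}
    for entry in bio:
        bio_map.setdefault(entry.label, {})
        prev = bio_map[entry.label].get(entry.class_value, ())
        bio_map[entry.label][entry.class_value] = prev + tuple(entry.compound_ids)
    blocks = tuple(
        (e.trophic_mode, e.structural_class, e.loading,
         tuple(c for c in compounds if compounds[c].structural_class == e.structural_class))
        for e in cov)
    truth = GroundTruth(
        biomarkers=bio_map, covariation_blocks=blocks,
        structural_classes={c: r.structural_class for c, r in compounds.items()})
    return matrices["PTR"], matrices["GC"], annotations, compounds, truth
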