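"""Synthetic literature corpora with planted structure for end-to-end testing.

The generator emulates the shape of the real corpus — roughly 15 studies
over 21 brain regions with mixed connectivity indicators — while planting
ground truth the pipeline should recover:

* a high-degree core of ``core_size`` regions: intra-core pairs always
  receive a record (the core is a clique at the record level), core ↔
  periphery pairs receive one with probability ``p_core_edge``, and
  periphery pairs with probability ``p_periphery_edge``;
* a structurally balanced sign assignment (each region carries a latent
  polarity; an edge's true sign is the product of its endpoint polarities,
  so sign propagation along any path is exactly consistent);
* controlled frustration: each observed sign is flipped independently with
  probability ``frustration_rate``.

Generation is bit-reproducible given the seed, and the returned ground
truth (core membership, edge list, true signs, flip locations) is the
oracle for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .literature_model import (
    CONNECTIVITY_INDICATORS,
    ConnectivityChangeRecord,
    RecordSet,
    RegionRegistry,
)
from .tract_consistency import TractMap

_MODALITY_CHOICES = ["MRI", "MEG", "EEG", "MRI+EEG", "MRI+DTI"]
_INDICATOR_CHOICES = sorted(CONNECTIVITY_INDICATORS)


class SyntheticSpecError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic corpus (defaults mirror the real corpus
    shape: 21 regions, 15 studies, a 6-region core)."""

    n_regions: int = 21
    n_studies: int = 15
    core_size: int = 6
    p_core_edge: float = 0.7
    p_periphery_edge: float = 0.08
    frustration_rate: float = 0.0
    seed: int = 0
    degree_threshold: int = 10  # core-recovery threshold the calibration must clear

    def __post_init__(self) -> None:
        for name in ("p_core_edge", "p_periphery_edge", "frustration_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SyntheticSpecError(f"{name}={v} outside [0, 1]")
        if not 2 <= self.core_size < self.n_regions:
            raise SyntheticSpecError(
                f"core_size={self.core_size} must satisfy 2 <= core_size < n_regions"
            )
        if self.n_studies < 1:
            raise SyntheticSpecError("n_studies must be >= 1")
        expected_core_degree = (self.core_size - 1) + (
            self.n_regions - self.core_size
        ) * self.p_core_edge
        if expected_core_degree <= self.degree_threshold:
            raise SyntheticSpecError(
                f"infeasible calibration: expected core degree "
                f"{expected_core_degree:.2f} <= threshold {self.degree_threshold}; "
                "raise p_core_edge or n_regions"
            )

    @property
    def region_codes(self) -> list[str]:
        return [f"R{i:02d}" for i in range(1, self.n_regions + 1)]


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure backing a generated record set."""

    core_regions: frozenset[str]
    edges: frozenset[tuple[str, str]]
    true_signs: dict[tuple[str, str], int]
    observed_signs: dict[tuple[str, str], int]
    flipped_pairs: frozenset[tuple[str, str]]
    polarity: dict[str, int]
    study_cohorts: dict[str, tuple[int, int]]


def synthetic_registry(spec: SyntheticSpec) -> RegionRegistry:
    """Registry over the synthetic region codes R01..Rnn."""
    return RegionRegistry(
        {code: f"synthetic region {code}" for code in spec.region_codes}
    )


def _plant_core(spec: SyntheticSpec, rng: np.random.Generator) -> list[str]:
    codes = spec.region_codes
    idx = rng.choice(len(codes), size=spec.core_size, replace=False)
    return sorted(codes[i] for i in sorted(idx))


def generate_records(spec: SyntheticSpec) -> tuple[RecordSet, GroundTruth]:
    """Generate a study record set plus its planted ground truth."""
    rng = np.random.default_rng(spec.seed)
    core = _plant_core(spec, rng)
    core_set = set(core)
    codes = spec.region_codes

    polarity = {c: int(rng.choice([1, -1])) for c in codes}

    edges: list[tuple[str, str]] = []
    for i, a in enumerate(codes):
        for b in codes[i + 1 :]:
            if a in core_set and b in core_set:
                p = 1.0
            elif a in core_set or b in core_set:
                p = spec.p_core_edge
            else:
                p = spec.p_periphery_edge
            if rng.random() < p:
                edges.append((a, b))

    true_signs = {e: polarity[e[0]] * polarity[e[1]] for e in edges}
    flips = {e for e in edges if rng.random() < spec.frustration_rate}
    observed_signs = {
        e: -s if e in flips else s for e, s in true_signs.items()
    }

    study_ids = [f"S{i:02d}" for i in range(1, spec.n_studies + 1)]
    cohorts = {
        sid: (int(rng.integers(10, 61)), int(rng.integers(10, 61)))
        for sid in study_ids
    }

    records = []
    for a, b in edges:
        sid = study_ids[int(rng.integers(spec.n_studies))]
        n_p, n_c = cohorts[sid]
        records.append(
            ConnectivityChangeRecord(
                study_id=sid,
                modality=_MODALITY_CHOICES[int(rng.integers(len(_MODALITY_CHOICES)))],
                indicator=_INDICATOR_CHOICES[int(rng.integers(len(_INDICATOR_CHOICES)))],
                region_a=a,
                region_b=b,
                direction=observed_signs[(a, b)],
                n_patients=n_p,
                n_controls=n_c,
            )
        )

    truth = GroundTruth(
        core_regions=frozenset(core),
        edges=frozenset(edges),
        true_signs=true_signs,
        observed_signs=observed_signs,
        flipped_pairs=frozenset(flips),
        polarity=polarity,
        study_cohorts=cohorts,
    )
    return RecordSet(records=records, source=f"<synthetic seed={spec.seed}>"), truth


def generate_tract_map(spec: SyntheticSpec) -> TractMap:
    """Tract map over the planted core: the planted intra-core edge support.

    Re-derives the planted core from the spec's seed (same draws as
    :func:`generate_records`), so map edges equal the planted intra-core
    support — a clique, hence connected.
    """
    rng = np.random.default_rng(spec.seed)
    core = _plant_core(spec, rng)
    pairs = [
        (a, b) for i, a in enumerate(core) for b in core[i + 1 :]
    ]
    return TractMap.from_pairs(pairs)
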