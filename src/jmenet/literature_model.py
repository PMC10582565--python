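"""Schema and conversions for literature-extracted connectivity-change records.

A record is one study's reported change, in patients relative to healthy
controls, of a connectivity indicator (FC, SC, gFCD, lFCD, EC, ReHo, ...)
for one pair of brain regions.  Quantitative indicators arrive as Pearson
correlations and are reduced to qualitative signed changes through the
Fisher r-to-z transform; region labels are resolved against a controlled
21-region vocabulary, with anatomically motivated label merging applied
before network construction.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

MODALITIES = frozenset({"MRI", "MEG", "EEG", "MRI+EEG", "MRI+DTI"})

#: Indicators that quantify connectivity strength between regions; only
#: these are converted into edges of the signed network.
CONNECTIVITY_INDICATORS = frozenset({"FC", "SC", "gFCD", "lFCD", "EC", "ReHo"})

#: All ingestible indicator labels.  ``network_metric`` covers global/local
#: efficiency style summaries; ``unknown`` covers unclassifiable statistics.
INDICATORS = CONNECTIVITY_INDICATORS | {"network_metric", "unknown"}

#: Controlled vocabulary of region codes and full anatomical names.  The
#: glosses follow the source legend verbatim, including its idiosyncratic
#: readings (e.g. "Pari"); codes are stored without asserting anatomy.
DEFAULT_REGIONS: dict[str, str] = {
    "SmG": "supramarginal gyrus",
    "STG": "superior temporal gyrus",
    "MTG": "middle temporal gyrus",
    "ITG": "inferior temporal gyrus",
    "FG": "frontal gyrus",
    "IFG": "inferior frontal gyrus",
    "SFG": "superior frontal gyrus",
    "PFC": "prefrontal cortex",
    "Prec": "pericalcarine cortex",
    "Ins": "insula",
    "Pari": "orbitofrontal cortex",
    "pACC": "posterior cingulate cortex",
    "mACC": "middle cingulate cortex",
    "BG": "basal ganglia",
    "Hipp": "hippocampus",
    "VC": "visual cortex",
    "Tha": "thalamus",
    "SMC": "primary motor sensory cortex",
    "SMA": "supplementary motor area",
    "Cere": "cerebellum",
}

#: Anatomical label merges applied before network construction: parietal
#: subdivisions collapse to the parietal lobe, peri-rolandic and adjacent
#: midline structures to the sensorimotor cortex, thalamic subnuclei to
#: the thalamus, and striato-pallidal nuclei to the basal ganglia.
DEFAULT_MERGE_MAP: dict[str, str] = {
    "parietal lobule": "Pari",
    "inferior parietal lobule": "Pari",
    "anterior central gyrus": "SMC",
    "posterior central gyrus": "SMC",
    "posterior cingulate gyrus": "SMC",
    "SMA anterior cluster": "SMC",
    "thalamus subregion": "Tha",
    "globus pallidus": "BG",
    "putamen": "BG",
    "caudate": "BG",
    "caudate nuclei": "BG",
}


class LiteratureModelError(ValueError):
    """Base class for record-schema violations."""


class UnknownRegionError(LiteratureModelError):
    """A region label is absent from the registry and the merge map."""


class UnclassifiableDirectionError(LiteratureModelError):
    """A record's change cannot be assigned a sign (z-score at/below tie threshold)."""


class DuplicateRecordError(LiteratureModelError):
    """Two records share the same (study, pair, indicator) triple."""


@dataclass(frozen=True)
class BrainRegion:
    """A controlled-vocabulary brain region: short ``code`` plus full ``name``."""

    code: str
    name: str


class RegionRegistry:
    """Case-insensitive registry of region codes.

    Lookups reject unknown codes; the registry can be extended from config
    (the controlled vocabulary is 20 glossed codes, with room for a
    configured 21st or project-specific additions).
    """

    def __init__(self, regions: Mapping[str, str] | None = None) -> None:
        base = DEFAULT_REGIONS if regions is None else dict(regions)
        self._by_lower: dict[str, BrainRegion] = {}
        for code, name in base.items():
            self._add(code, name)

    def _add(self, code: str, name: str) -> None:
        self._by_lower[code.lower()] = BrainRegion(code=code, name=name)

    def extend(self, regions: Mapping[str, str]) -> None:
        for code, name in regions.items():
            self._add(code, name)

    def lookup(self, code: str) -> BrainRegion:
        try:
            return self._by_lower[code.strip().lower()]
        except KeyError:
            raise UnknownRegionError(
                f"unknown region code {code!r}; known codes: "
                f"{sorted(r.code for r in self._by_lower.values())}"
            ) from None

    def __contains__(self, code: str) -> bool:
        return code.strip().lower() in self._by_lower

    @property
    def codes(self) -> list[str]:
        return sorted(r.code for r in self._by_lower.values())

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RegionRegistry":
        """Load a registry from a YAML config with a ``regions:`` mapping.

        The defaults are always included; the file extends/overrides them.
        """
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        reg = cls()
        reg.extend(payload.get("regions", {}) or {})
        return reg


def load_merge_map(path: str | Path) -> dict[str, str]:
    """Read a raw-label → region-code merge map from YAML (``merge:`` section)."""
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    return dict(payload.get("merge", {}) or {})


def _canonical_pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class ConnectivityChangeRecord:
    """One study's reported connectivity change for one region pair.

    Exactly one of ``direction`` (±1, qualitative) or ``raw_r`` (Pearson
    correlation, |r| < 1) is present.  The pair is stored unordered in
    canonical lexicographic order.
    """

    study_id: str
    modality: str
    indicator: str
    region_a: str
    region_b: str
    direction: int | None = None
    raw_r: float | None = None
    n_patients: int = 0
    n_controls: int = 0

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise LiteratureModelError(
                f"record {self.study_id}: modality {self.modality!r} not in {sorted(MODALITIES)}"
            )
        if self.indicator not in INDICATORS:
            raise LiteratureModelError(
                f"record {self.study_id}: indicator {self.indicator!r} not in {sorted(INDICATORS)}"
            )
        if self.region_a == self.region_b:
            raise LiteratureModelError(
                f"record {self.study_id}: self-pair ({self.region_a}, {self.region_b})"
            )
        if (self.direction is None) == (self.raw_r is None):
            raise LiteratureModelError(
                f"record {self.study_id} ({self.region_a}-{self.region_b}): "
                "exactly one of direction / raw_r must be given"
            )
        if self.direction is not None and self.direction not in (1, -1):
            raise LiteratureModelError(
                f"record {self.study_id}: direction must be +1 or -1, got {self.direction}"
            )
        if self.raw_r is not None and not abs(self.raw_r) < 1:
            raise LiteratureModelError(
                f"record {self.study_id} ({self.region_a}-{self.region_b}): "
                f"raw_r={self.raw_r} outside the open interval (-1, 1)"
            )
        if self.n_patients < 0 or self.n_controls < 0:
            raise LiteratureModelError(f"record {self.study_id}: negative cohort size")
        a, b = _canonical_pair(self.region_a, self.region_b)
        object.__setattr__(self, "region_a", a)
        object.__setattr__(self, "region_b", b)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.region_a, self.region_b)

    @property
    def key(self) -> tuple[str, tuple[str, str], str]:
        """Ingest-uniqueness key: (study, pair, indicator)."""
        return (self.study_id, self.pair, self.indicator)


@dataclass
class RecordSet:
    """Ordered collection of records plus parse provenance.

    Duplicate (study, pair, indicator) triples are rejected on construction.
    """

    records: list[ConnectivityChangeRecord]
    source: str = "<memory>"
    parsed_at: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )

    def __post_init__(self) -> None:
        seen: set = set()
        for rec in self.records:
            if rec.key in seen:
                raise DuplicateRecordError(
                    f"duplicate record for study {rec.key[0]!r}, pair {rec.key[1]}, "
                    f"indicator {rec.key[2]!r}"
                )
            seen.add(rec.key)

    def __iter__(self) -> Iterator[ConnectivityChangeRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def pairs(self) -> set[tuple[str, str]]:
        return {r.pair for r in self.records}


@dataclass(frozen=True)
class CohortSummary:
    """Corpus-level bookkeeping: studies, pooled cohort sizes, modality/indicator mix."""

    n_studies: int
    total_patients: int
    total_controls: int
    modality_counts: dict[str, int]
    indicator_counts: dict[str, int]


def fisher_r_to_z(r: float, context: str = "") -> float:
    """Fisher r-to-z transform, ``z = 0.5 * ln((1+r)/(1-r)) = artanh(r)``.

    Raises a domain error for |r| >= 1, naming the offending record when
    ``context`` is supplied.
    """
    if not abs(r) < 1:
        where = f" in {context}" if context else ""
        raise LiteratureModelError(
            f"Fisher r-to-z undefined for r={r}{where}: |r| must be < 1"
        )
    return math.atanh(r)


def qualitative_direction(
    record: ConnectivityChangeRecord, threshold: float = 0.0
) -> int:
    """Reduce a record to a qualitative signed change (+1 increase, -1 decrease).

    Quantitative records are signed by their Fisher z-score; |z| <= threshold
    (default 0, so only z == 0) is a tie and raises, because a two-category
    increase/decrease conversion has no third class.  The threshold exposes a
    sensitivity-analysis knob for treating small |z| as "no change".
    """
    if record.direction is not None:
        return record.direction
    assert record.raw_r is not None
    z = fisher_r_to_z(
        record.raw_r, context=f"record {record.study_id} {record.pair}"
    )
    if z > threshold:
        return 1
    if z < -threshold:
        return -1
    raise UnclassifiableDirectionError(
        f"record {record.study_id} {record.pair}: z={z:.4g} within tie band "
        f"|z| <= {threshold}; cannot assign increase/decrease"
    )


def signed(record: ConnectivityChangeRecord, threshold: float = 0.0) -> ConnectivityChangeRecord:
    """Return a copy of the record with an explicit ±1 direction."""
    if record.direction is not None:
        return record
    d = qualitative_direction(record, threshold=threshold)
    return replace(record, direction=d, raw_r=None)


def merge_regions(
    records: RecordSet,
    merge_map: Mapping[str, str],
    registry: RegionRegistry | None = None,
) -> RecordSet:
    """Apply a raw-label → region-code merge map to every record.

    Labels already in the registry pass through unchanged; labels in neither
    the map nor the registry raise, listing every unmatched label.  Records
    whose two endpoints merge to the same code are dropped (logged count);
    records that become exact duplicates after merging are collapsed when
    their signs agree and raise otherwise.
    """
    registry = registry or RegionRegistry()
    lower_map = {k.strip().lower(): v for k, v in merge_map.items()}

    unmatched = sorted(
        {
            lab
            for rec in records
            for lab in rec.pair
            if lab.strip().lower() not in lower_map and lab not in registry
        }
    )
    if unmatched:
        raise UnknownRegionError(
            f"labels not in merge map or registry: {unmatched}"
        )

    def resolve(label: str) -> str:
        low = label.strip().lower()
        if low in lower_map:
            return registry.lookup(lower_map[low]).code
        return registry.lookup(label).code

    merged: list[ConnectivityChangeRecord] = []
    seen: dict[tuple, ConnectivityChangeRecord] = {}
    n_self, n_collapsed = 0, 0
    for rec in records:
        a, b = resolve(rec.region_a), resolve(rec.region_b)
        if a == b:
            n_self += 1
            continue
        new = replace(rec, region_a=a, region_b=b)
        if new.key in seen:
            prev = seen[new.key]
            if (prev.direction, prev.raw_r) != (new.direction, new.raw_r):
                raise DuplicateRecordError(
                    f"merge produced conflicting duplicates for {new.key}"
                )
            n_collapsed += 1
            continue
        seen[new.key] = new
        merged.append(new)
    if n_self:
        logger.info("merge_regions: dropped %d self-pair record(s)", n_self)
    if n_collapsed:
        logger.info("merge_regions: collapsed %d duplicate record(s)", n_collapsed)
    return RecordSet(records=merged, source=records.source)


def detect_conflicts(
    records: RecordSet | Iterable[ConnectivityChangeRecord],
    threshold: float = 0.0,
) -> set[tuple[str, str]]:
    """Region pairs reported with both increased and decreased connectivity."""
    signs: dict[tuple[str, str], set[int]] = {}
    for rec in records:
        signs.setdefault(rec.pair, set()).add(
            qualitative_direction(rec, threshold=threshold)
        )
    return {pair for pair, s in signs.items() if len(s) > 1}


def resolve_conflicts(
    records: RecordSet, policy: str = "exclude", threshold: float = 0.0
) -> RecordSet:
    """Remove sign conflicts between records of the same pair.

    ``exclude`` drops every record of a conflicted pair (both conclusions
    are discarded, as a meta-analysis cannot adjudicate them); ``majority``
    keeps the records carrying the more frequent sign (exact ties fall back
    to exclusion for that pair).
    """
    if policy not in ("exclude", "majority"):
        raise ValueError(f"unknown conflict policy {policy!r}")
    conflicts = detect_conflicts(records, threshold=threshold)
    if not conflicts:
        return records
    kept: list[ConnectivityChangeRecord] = []
    for rec in records:
        if rec.pair not in conflicts:
            kept.append(rec)
            continue
        if policy == "majority":
            same = [r for r in records if r.pair == rec.pair]
            tally = sum(qualitative_direction(r, threshold=threshold) for r in same)
            if tally != 0 and qualitative_direction(rec, threshold=threshold) == (
                1 if tally > 0 else -1
            ):
                kept.append(rec)
    logger.info(
        "resolve_conflicts(%s): %d conflicted pair(s), %d -> %d records",
        policy, len(conflicts), len(records), len(kept),
    )
    return RecordSet(records=kept, source=records.source)


def summarize_cohort(records: RecordSet) -> CohortSummary:
    """Summarize the corpus: each study contributes its cohort sizes once."""
    per_study: dict[str, tuple[int, int]] = {}
    modality_counts: dict[str, int] = {}
    indicator_counts: dict[str, int] = {}
    for rec in records:
        sizes = (rec.n_patients, rec.n_controls)
        if rec.study_id in per_study and per_study[rec.study_id] != sizes:
            raise LiteratureModelError(
                f"study {rec.study_id!r}: inconsistent cohort sizes "
                f"{per_study[rec.study_id]} vs {sizes}"
            )
        per_study[rec.study_id] = sizes
        modality_counts[rec.modality] = modality_counts.get(rec.modality, 0) + 1
        indicator_counts[rec.indicator] = indicator_counts.get(rec.indicator, 0) + 1
    return CohortSummary(
        n_studies=len(per_study),
        total_patients=sum(p for p, _ in per_study.values()),
        total_controls=sum(c for _, c in per_study.values()),
        modality_counts=modality_counts,
        indicator_counts=indicator_counts,
    )


# ---------------------------------------------------------------------------
# I/O

CSV_COLUMNS = [
    "study_id", "modality", "indicator", "region_a", "region_b",
    "direction", "raw_r", "n_patients", "n_controls",
]


def _record_from_row(row: Mapping) -> ConnectivityChangeRecord:
    def blank(v) -> bool:
        return v is None or (isinstance(v, float) and math.isnan(v)) or v == ""

    direction = None if blank(row.get("direction")) else int(row["direction"])
    raw_r = None if blank(row.get("raw_r")) else float(row["raw_r"])
    return ConnectivityChangeRecord(
        study_id=str(row["study_id"]),
        modality=str(row["modality"]),
        indicator=str(row["indicator"]),
        region_a=str(row["region_a"]),
        region_b=str(row["region_b"]),
        direction=direction,
        raw_r=raw_r,
        n_patients=int(row["n_patients"]),
        n_controls=int(row["n_controls"]),
    )


def read_records_csv(path: str | Path) -> RecordSet:
    """Read records from the canonical CSV layout (UTF-8, comma, ``.`` decimal)."""
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise LiteratureModelError(f"{path}: missing CSV columns {missing}")
    records = [_record_from_row(row) for row in df.to_dict(orient="records")]
    return RecordSet(records=records, source=str(path))


def read_records_json(path: str | Path) -> RecordSet:
    """Read records from a JSON array of objects with the CSV field names."""
    with open(path) as fh:
        rows = json.load(fh)
    return RecordSet(records=[_record_from_row(r) for r in rows], source=str(path))


def write_records_csv(records: RecordSet, path: str | Path) -> None:
    rows = []
    for rec in records:
        rows.append(
            {
                "study_id": rec.study_id,
                "modality": rec.modality,
                "indicator": rec.indicator,
                "region_a": rec.region_a,
                "region_b": rec.region_b,
                "direction": "" if rec.direction is None else rec.direction,
                "raw_r": "" if rec.raw_r is None else rec.raw_r,
                "n_patients": rec.n_patients,
                "n_controls": rec.n_controls,
            }
        )
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)
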