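"""Hierarchical experiment schema.

Raw quantification events stream in as flat :class:`TimePoint` records; the
assembler sorts them by their metadata into the hierarchy

    time point -> analyte course -> single trial -> replicate trial -> experiment

mirroring how fermentation experiments are actually run: a *single trial* is
one independent fermentation volume (flask, well, bioreactor); a *replicate
trial* groups single trials that differ only in replicate index; an
*experiment* groups replicate trials under one label.

Missing values travel through assembly as NaN and are only dropped inside the
individual feature computations, so replicate statistics can handle ragged
missingness per time point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import AssemblyError
from .identifiers import TrialIdentifier, serialize_identifier

logger = logging.getLogger(__name__)

ANALYTE_TYPES = ("biomass", "substrate", "product", "reporter")

#: Default analyte-name -> type registry; extend via :func:`register_analyte_type`.
_ANALYTE_TYPE_REGISTRY: dict[str, str] = {
    "od600": "biomass",
    "od": "biomass",
    "biomass": "biomass",
    "glucose": "substrate",
    "xylose": "substrate",
    "glycerol": "substrate",
}


def register_analyte_type(name: str, analyte_type: str) -> None:
    """Register the type (biomass/substrate/product/reporter) of an analyte name."""
    if analyte_type not in ANALYTE_TYPES:
        raise ValueError(f"unknown analyte type {analyte_type!r}; expected {ANALYTE_TYPES}")
    _ANALYTE_TYPE_REGISTRY[name.lower()] = analyte_type


def analyte_type_of(name: str) -> str:
    """Resolve an analyte name to its type.

    Registry lookup first; names prefixed ``fluor``/``gfp`` are reporters;
    everything else defaults to product.
    """
    key = name.lower()
    if key in _ANALYTE_TYPE_REGISTRY:
        return _ANALYTE_TYPE_REGISTRY[key]
    if key.startswith("fluor") or key.startswith("gfp"):
        return "reporter"
    return "product"


@dataclass(frozen=True)
class TimePoint:
    """One quantification event: identifier (with analyte and time), value, unit."""

    identifier: TrialIdentifier
    value: float
    unit: str = ""


@dataclass
class AnalyteCourse:
    """One analyte's time course within a single trial.

    ``times`` is strictly increasing (hours); ``values`` may contain NaN for
    missing observations.
    """

    identifier: TrialIdentifier
    analyte_type: str
    times: np.ndarray
    values: np.ndarray
    unit: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.size < 1:
            raise AssemblyError("times and values must be equal-length, non-empty")
        if np.any(np.diff(self.times) <= 0):
            raise AssemblyError("times must be strictly increasing")

    @property
    def analyte_name(self) -> str:
        return self.identifier.analyte_name or ""

    def finite(self) -> tuple[np.ndarray, np.ndarray]:
        """Times and values restricted to finite observations."""
        mask = np.isfinite(self.values)
        return self.times[mask], self.values[mask]

    def __eq__(self, other):
        if not isinstance(other, AnalyteCourse):
            return NotImplemented
        return (
            self.identifier == other.identifier
            and self.analyte_type == other.analyte_type
            and self.unit == other.unit
            and np.array_equal(self.times, other.times)
            and np.array_equal(self.values, other.values, equal_nan=True)
        )


@dataclass
class SingleTrial:
    """One independent fermentation volume; holds one course per analyte."""

    identifier: TrialIdentifier  # trial-level: no analyte_name / sample_time
    courses: dict[str, AnalyteCourse] = field(default_factory=dict)

    def __eq__(self, other):
        if not isinstance(other, SingleTrial):
            return NotImplemented
        return self.identifier == other.identifier and self.courses == other.courses


@dataclass
class ReplicateTrial:
    """Single trials sharing an identifier modulo replicate index."""

    identifier: TrialIdentifier  # replicate_index absent
    singles: list[SingleTrial] = field(default_factory=list)
    #: analyte name -> ReplicateStats, filled by features.replicate_statistics
    statistics: dict = field(default_factory=dict, compare=False)
    blank_corrected: bool = False

    @property
    def analyte_names(self) -> list[str]:
        names: list[str] = []
        for s in self.singles:
            for n in s.courses:
                if n not in names:
                    names.append(n)
        return sorted(names)

    def __eq__(self, other):
        if not isinstance(other, ReplicateTrial):
            return NotImplemented
        return (
            self.identifier == other.identifier
            and self.singles == other.singles
            and self.blank_corrected == other.blank_corrected
        )


@dataclass
class Experiment:
    """Top-level grouping of replicate trials under one label.

    A replicate trial may belong to several experiments; membership is by
    reference, the store keeps it many-to-many.
    """

    label: str
    replicates: list[ReplicateTrial] = field(default_factory=list)
    stage_definitions: list[tuple[float, float]] | None = None
    blank_map: dict[str, str] | None = None  # serialized id -> serialized blank id

    def replicate_by_identifier(self, serialized: str) -> ReplicateTrial:
        for r in self.replicates:
            if serialize_identifier(r.identifier) == serialized:
                return r
        raise KeyError(serialized)

    def __eq__(self, other):
        if not isinstance(other, Experiment):
            return NotImplemented
        return self.label == other.label and self.replicates == other.replicates


def assemble_experiment(points: list[TimePoint], label: str) -> Experiment:
    """Sort a flat stream of time points into the experiment hierarchy.

    Points are grouped by (trial identifier, analyte) into time-sorted
    courses; duplicate (trial, analyte, time) observations are averaged with a
    warning; trials are grouped into replicate trials by replicate
    equivalence. Ordering is deterministic (lexicographic on serialized
    identifiers), so assembly is invariant to input permutation.
    """
    for i, p in enumerate(points):
        if p.identifier.analyte_name is None:
            raise AssemblyError(f"point at index {i} has no analyte name")
        if p.identifier.sample_time is None:
            raise AssemblyError(f"point at index {i} has no sample time")

    # (trial key, analyte) -> time -> list of (value, unit)
    groups: dict[tuple[str, str], dict[float, list[tuple[float, str]]]] = {}
    trial_ids: dict[str, TrialIdentifier] = {}
    for p in points:
        tid = p.identifier.trial_key()
        tkey = serialize_identifier(tid)
        trial_ids.setdefault(tkey, tid)
        cell = groups.setdefault((tkey, p.identifier.analyte_name), {})
        cell.setdefault(p.identifier.sample_time, []).append((p.value, p.unit))

    trials: dict[str, SingleTrial] = {}
    for (tkey, analyte), by_time in sorted(groups.items()):
        times = sorted(by_time)
        values = []
        unit = ""
        for t in times:
            obs = by_time[t]
            unit = obs[0][1] or unit
            if len(obs) > 1:
                logger.warning(
                    "averaging %d duplicate observations of %r at t=%g in %s",
                    len(obs), analyte, t, tkey,
                )
                vals = [v for v, _ in obs if np.isfinite(v)]
                values.append(float(np.mean(vals)) if vals else float("nan"))
            else:
                values.append(obs[0][0])
        trial = trials.setdefault(tkey, SingleTrial(identifier=trial_ids[tkey]))
        from dataclasses import replace as _replace
        course_id = _replace(trial_ids[tkey], analyte_name=analyte)
        trial.courses[analyte] = AnalyteCourse(
            identifier=course_id,
            analyte_type=analyte_type_of(analyte),
            times=np.array(times, dtype=float),
            values=np.array(values, dtype=float),
            unit=unit,
        )

    # group trials into replicate trials by replicate equivalence
    reps: dict[str, ReplicateTrial] = {}
    for tkey in sorted(trials):
        trial = trials[tkey]
        rid = trial.identifier.replicate_key()
        rkey = serialize_identifier(rid)
        rep = reps.setdefault(rkey, ReplicateTrial(identifier=rid))
        rep.singles.append(trial)

    for rep in reps.values():
        seen = [s.identifier.replicate_index for s in rep.singles]
        dup = [i for i in set(seen) if i is not None and seen.count(i) > 1]
        if dup:
            raise AssemblyError(
                f"duplicate replicate indices {dup} under "
                f"{serialize_identifier(rep.identifier)!r}"
            )

    return Experiment(label=label, replicates=[reps[k] for k in sorted(reps)])


def query_courses(e: Experiment, predicate=None, **filters) -> list[AnalyteCourse]:
    """Return all courses matching the filters, in deterministic order.

    Keyword filters: ``analyte_type``, ``analyte_name``, ``strain_name``,
    ``media_name``, ``is_blank``, ``replicate_index``. ``predicate`` is an
    optional callable on (identifier, course) for anything richer.
    """
    out: list[AnalyteCourse] = []
    for rep in e.replicates:
        for single in rep.singles:
            for name in sorted(single.courses):
                course = single.courses[name]
                ident = course.identifier
                if filters.get("analyte_type") not in (None, course.analyte_type):
                    continue
                if filters.get("analyte_name") not in (None, name):
                    continue
                if filters.get("strain_name") not in (None, ident.strain.name):
                    continue
                if filters.get("media_name") not in (None, ident.media.name):
                    continue
                if "is_blank" in filters and filters["is_blank"] != ident.is_blank:
                    continue
                if filters.get("replicate_index") not in (None, ident.replicate_index):
                    continue
                if predicate is not None and not predicate(ident, course):
                    continue
                out.append(course)
    return out
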