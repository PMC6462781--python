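"""Flat trial-identifier grammar.

Every measured datum carries its metadata as a flat, typeable string of
``key:value`` tokens separated by ``|``, suitable for sample-name fields on
analytical equipment (HPLC injection lists, plate-reader layouts)::

    strain:MG1655|media:M9|strain__plasmid:pTrc99a|rep:2|time:4.5

Nested attributes use a double underscore (``strain__plasmid``). Keys are
case-insensitive; values preserve case and may not contain ``|`` or ``:``.
Reserved keys:

=========================== ==================================================
key                         meaning
=========================== ==================================================
strain                      parent strain name (``blank`` marks a cell-free
                            background trial)
strain__knockout            gene knockout (repeatable)
strain__plasmid             plasmid (repeatable)
media                       medium name
media__<component>          component concentration, value ``"<conc> <unit>"``
environment__labware        e.g. flask, 96-well-plate, bioreactor
environment__temperature    degrees Celsius
environment__shaking_speed  rpm
experiment                  experiment label
rep                         replicate index (positive integer)
time                        sample time in hours
analyte                     analyte name for a single quantification event
blank                       ``true``/``false`` explicit blank flag
=========================== ==================================================

Unknown keys are retained verbatim (a warning is logged) so that equipment-
specific annotations survive a round trip.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from math import isfinite
from pathlib import Path

from .errors import IdentifierParseError

logger = logging.getLogger(__name__)

_LIST_KEYS = {"strain__knockout", "strain__plasmid"}
_SCALAR_KEYS = {
    "strain",
    "media",
    "environment__labware",
    "environment__temperature",
    "environment__shaking_speed",
    "experiment",
    "rep",
    "time",
    "analyte",
    "blank",
}


@dataclass(frozen=True)
class Strain:
    """Organism description: wild-type name plus genetic modifications."""

    name: str = ""
    knockouts: tuple[str, ...] = ()
    plasmids: tuple[str, ...] = ()


@dataclass(frozen=True)
class Media:
    """Medium name and optional formulation.

    ``components`` maps component name -> (concentration, unit); concentrations
    are non-negative.
    """

    name: str = ""
    components: tuple[tuple[str, float, str], ...] = ()


@dataclass(frozen=True)
class Environment:
    """Growth conditions: labware, temperature (degC), shaking speed (rpm)."""

    labware: str = ""
    temperature: float | None = None
    shaking_speed: float | None = None


@dataclass(frozen=True)
class TrialIdentifier:
    """Structured metadata for one trial, sample, or quantification event.

    Two identifiers describe replicates of the same condition when they agree
    on everything except ``replicate_index``, ``sample_time`` and
    ``analyte_name`` (see :meth:`replicate_equivalent`).
    """

    strain: Strain = field(default_factory=Strain)
    media: Media = field(default_factory=Media)
    environment: Environment = field(default_factory=Environment)
    experiment_label: str = ""
    replicate_index: int | None = None
    sample_time: float | None = None
    analyte_name: str | None = None
    is_blank: bool = False
    extra: tuple[tuple[str, str], ...] = ()

    def replicate_key(self) -> "TrialIdentifier":
        """Identifier with replicate index, time and analyte stripped."""
        return replace(self, replicate_index=None, sample_time=None, analyte_name=None)

    def trial_key(self) -> "TrialIdentifier":
        """Identifier with time and analyte stripped (keeps replicate)."""
        return replace(self, sample_time=None, analyte_name=None)

    def replicate_equivalent(self, other: "TrialIdentifier") -> bool:
        return self.replicate_key() == other.replicate_key()


def _format_number(x: float) -> str:
    if float(x) == int(x) and abs(x) < 1e15:
        return str(int(x))
    return repr(float(x))


def parse_identifier(s: str) -> TrialIdentifier:
    """Parse a flat identifier string into a :class:`TrialIdentifier`.

    Raises :class:`~fermkit.errors.IdentifierParseError` on an empty string,
    a token without ``:``, or conflicting values for a scalar key.
    """
    if not s or not s.strip():
        raise IdentifierParseError("empty identifier string")

    scalars: dict[str, str] = {}
    knockouts: list[str] = []
    plasmids: list[str] = []
    components: list[tuple[str, float, str]] = []
    extra: list[tuple[str, str]] = []

    for raw in s.split("|"):
        token = raw.strip()
        if not token:
            continue
        if ":" not in token:
            raise IdentifierParseError(f"token {token!r} is not a key:value pair")
        key, _, value = token.partition(":")
        key = key.strip().lower()
        value = value.strip()
        if key in _LIST_KEYS:
            target = knockouts if key == "strain__knockout" else plasmids
            if value not in target:
                target.append(value)
        elif key in _SCALAR_KEYS:
            if key in scalars and scalars[key] != value:
                raise IdentifierParseError(
                    f"conflicting values for scalar key {key!r}: "
                    f"{scalars[key]!r} vs {value!r}"
                )
            scalars[key] = value
        elif key.startswith("media__"):
            comp = key[len("media__"):]
            conc_str, _, unit = value.partition(" ")
            try:
                conc = float(conc_str)
            except ValueError as exc:
                raise IdentifierParseError(
                    f"media component {comp!r} has non-numeric concentration "
                    f"{conc_str!r}"
                ) from exc
            if conc < 0:
                raise IdentifierParseError(
                    f"media component {comp!r} has negative concentration {conc}"
                )
            components.append((comp, conc, unit.strip()))
        else:
            logger.warning("unknown identifier key %r retained verbatim", key)
            extra.append((key, value))

    def _float(key: str) -> float | None:
        if key not in scalars:
            return None
        try:
            v = float(scalars[key])
        except ValueError as exc:
            raise IdentifierParseError(
                f"key {key!r} has non-numeric value {scalars[key]!r}"
            ) from exc
        if not isfinite(v):
            raise IdentifierParseError(f"key {key!r} must be finite")
        return v

    strain_name = scalars.get("strain", "")
    is_blank = strain_name.lower() == "blank"
    if "blank" in scalars:
        flag = scalars["blank"].lower()
        if flag not in {"true", "false"}:
            raise IdentifierParseError(f"blank flag must be true/false, got {flag!r}")
        is_blank = is_blank or flag == "true"

    rep = None
    if "rep" in scalars:
        try:
            rep = int(scalars["rep"])
        except ValueError as exc:
            raise IdentifierParseError(
                f"replicate index must be an integer, got {scalars['rep']!r}"
            ) from exc
        if rep < 1:
            raise IdentifierParseError(f"replicate index must be positive, got {rep}")

    sample_time = _float("time")
    if sample_time is not None and sample_time < 0:
        raise IdentifierParseError(f"sample time must be >= 0, got {sample_time}")
    temperature = _float("environment__temperature")
    shaking = _float("environment__shaking_speed")
    if shaking is not None and shaking < 0:
        raise IdentifierParseError(f"shaking speed must be >= 0, got {shaking}")

    return TrialIdentifier(
        strain=Strain(strain_name, tuple(knockouts), tuple(plasmids)),
        media=Media(scalars.get("media", ""), tuple(components)),
        environment=Environment(scalars.get("environment__labware", ""), temperature, shaking),
        experiment_label=scalars.get("experiment", ""),
        replicate_index=rep,
        sample_time=sample_time,
        analyte_name=scalars.get("analyte") or None,
        is_blank=is_blank,
        extra=tuple(extra),
    )


def serialize_identifier(t: TrialIdentifier) -> str:
    """Serialize to the canonical flat form; ``parse(serialize(t)) == t``.

    Canonical token order: strain, knockouts, plasmids, media, media
    components, environment keys, experiment, rep, time, analyte, blank flag
    (only when not implied by ``strain:blank``), then unknown keys.
    Absent fields are omitted.
    """
    tokens: list[str] = []
    if t.strain.name:
        tokens.append(f"strain:{t.strain.name}")
    tokens += [f"strain__knockout:{k}" for k in t.strain.knockouts]
    tokens += [f"strain__plasmid:{p}" for p in t.strain.plasmids]
    if t.media.name:
        tokens.append(f"media:{t.media.name}")
    for comp, conc, unit in t.media.components:
        value = _format_number(conc) + (f" {unit}" if unit else "")
        tokens.append(f"media__{comp}:{value}")
    env = t.environment
    if env.labware:
        tokens.append(f"environment__labware:{env.labware}")
    if env.temperature is not None:
        tokens.append(f"environment__temperature:{_format_number(env.temperature)}")
    if env.shaking_speed is not None:
        tokens.append(f"environment__shaking_speed:{_format_number(env.shaking_speed)}")
    if t.experiment_label:
        tokens.append(f"experiment:{t.experiment_label}")
    if t.replicate_index is not None:
        tokens.append(f"rep:{t.replicate_index}")
    if t.sample_time is not None:
        tokens.append(f"time:{_format_number(t.sample_time)}")
    if t.analyte_name:
        tokens.append(f"analyte:{t.analyte_name}")
    if t.is_blank and t.strain.name.lower() != "blank":
        tokens.append("blank:true")
    tokens += [f"{k}:{v}" for k, v in t.extra]
    return "|".join(tokens)


def expand_shorthand(s: str, registry: dict[str, str]) -> str:
    """Resolve a shorthand prefix against a registry of full identifiers.

    If the first ``|``-token of ``s`` (a bare name, no ``:``) matches a
    registry key, the registered string is merged with the remaining inline
    tokens; inline scalar values win on conflict, list keys append. Otherwise
    ``s`` is returned unchanged.
    """
    first, _, rest = s.partition("|")
    name = first.strip()
    if ":" in name or name not in registry:
        return s
    full = registry[name]
    try:
        parse_identifier(full)
    except IdentifierParseError as exc:
        raise IdentifierParseError(
            f"shorthand {name!r} resolves to unparseable identifier {full!r}: {exc}"
        ) from exc
    if not rest.strip():
        return full

    # token-level merge: inline scalars override, list keys append
    merged: list[tuple[str, str]] = []
    for token in full.split("|"):
        key, _, value = token.partition(":")
        merged.append((key.strip().lower(), value.strip()))
    for token in rest.split("|"):
        token = token.strip()
        if not token:
            continue
        if ":" not in token:
            raise IdentifierParseError(f"token {token!r} is not a key:value pair")
        key, _, value = token.partition(":")
        key, value = key.strip().lower(), value.strip()
        if key in _LIST_KEYS:
            merged.append((key, value))
        else:
            merged = [(k, v) for k, v in merged if k != key]
            merged.append((key, value))
    return "|".join(f"{k}:{v}" for k, v in merged)


def load_shorthand_registry(path: str | Path) -> dict[str, str]:
    """Read a two-column CSV ``shorthand,identifier`` (header required)."""
    registry: dict[str, str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [c.strip().lower() for c in reader.fieldnames[:2]] != [
            "shorthand",
            "identifier",
        ]:
            raise IdentifierParseError(
                f"shorthand registry {path} must have header 'shorthand,identifier'"
            )
        for row in reader:
            registry[row["shorthand"].strip()] = row["identifier"].strip()
    return registry
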