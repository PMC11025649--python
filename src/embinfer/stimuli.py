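"""Typed stimulus records for the four task protocols, with JSON/TSV I/O.

Protocols
---------
``chwilla``
    Prime-target word pairs labelled related / unrelated (semantic priming).
``metusalem``
    Discourse items: a two-sentence event-evoking discourse, a final
    sentence frame, and three candidate completions — an expected word, an
    unexpected word related to the discourse-level event, and an unexpected
    unrelated word.  The discourse field does NOT include the final
    sentence; the two are concatenated at scoring time.
``mckoon``
    Sentence pairs built from near-identical word multisets, one evoking an
    event that primes the target word by inference and one (the control)
    not, plus that target word.

The single worked example items from the source experimental paradigms ship
as package fixtures; full stimulus sets belong to the original studies and
are user-supplied files following the schemas documented in the README.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path
from typing import Union

__all__ = [
    "StimulusValidationError",
    "ChwillaPair",
    "MetusalemItem",
    "McKoonItem",
    "StimulusSet",
    "read_stimulus_set",
    "write_stimulus_set",
    "metusalem_example_set",
    "mckoon_example_set",
]

PROTOCOLS = ("chwilla", "metusalem", "mckoon")


class StimulusValidationError(ValueError):
    """A stimulus record or file violates its protocol's contract."""


@dataclass(frozen=True)
class ChwillaPair:
    prime: str
    target: str
    related: bool

    def validate(self) -> None:
        if not self.prime or not self.target:
            raise StimulusValidationError("prime and target must be nonempty")
        if self.prime == self.target:
            raise StimulusValidationError(
                f"prime and target identical: {self.prime!r}"
            )


@dataclass(frozen=True)
class MetusalemItem:
    item_id: str
    discourse: str
    sentence: str
    expected: str
    related: str
    unrelated: str

    def validate(self) -> None:
        targets = (self.expected, self.related, self.unrelated)
        if len(set(targets)) != 3:
            raise StimulusValidationError(
                f"item {self.item_id}: target words must be pairwise distinct, "
                f"got {targets}"
            )
        if not self.sentence.strip():
            raise StimulusValidationError(f"item {self.item_id}: empty sentence")


@dataclass(frozen=True)
class McKoonItem:
    item_id: str
    context_sentence: str
    control_sentence: str
    target: str

    def validate(self) -> None:
        if self.context_sentence == self.control_sentence:
            raise StimulusValidationError(
                f"item {self.item_id}: context and control sentences identical"
            )
        if not self.target:
            raise StimulusValidationError(f"item {self.item_id}: empty target")


StimulusItem = Union[ChwillaPair, MetusalemItem, McKoonItem]

_ITEM_TYPES = {
    "chwilla": ChwillaPair,
    "metusalem": MetusalemItem,
    "mckoon": McKoonItem,
}

_BOOL_STRINGS = {
    "true": True, "false": False, "1": True, "0": False,
    "yes": True, "no": False,
}


@dataclass
class StimulusSet:
    protocol: str
    items: list
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.protocol not in PROTOCOLS:
            raise StimulusValidationError(
                f"unknown protocol {self.protocol!r}; expected one of {PROTOCOLS}"
            )
        if not self.items:
            raise StimulusValidationError("stimulus set must be nonempty")
        want = _ITEM_TYPES[self.protocol]
        seen_ids: set[str] = set()
        for i, item in enumerate(self.items):
            if not isinstance(item, want):
                raise StimulusValidationError(
                    f"item {i}: expected {want.__name__}, got {type(item).__name__}"
                )
            item.validate()
            item_id = getattr(item, "item_id", None)
            if item_id is not None:
                if item_id in seen_ids:
                    raise StimulusValidationError(f"duplicate item_id {item_id!r}")
                seen_ids.add(item_id)

    def __len__(self) -> int:
        return len(self.items)


def _fields(protocol: str) -> list[str]:
    import dataclasses

    return [f.name for f in dataclasses.fields(_ITEM_TYPES[protocol])]


def _item_from_record(protocol: str, record: dict, where: str) -> StimulusItem:
    cls = _ITEM_TYPES[protocol]
    missing = [f for f in _fields(protocol) if f not in record]
    if missing:
        raise StimulusValidationError(f"{where}: missing field(s) {missing}")
    kwargs = {f: record[f] for f in _fields(protocol)}
    if protocol == "chwilla" and isinstance(kwargs["related"], str):
        key = kwargs["related"].strip().lower()
        if key not in _BOOL_STRINGS:
            raise StimulusValidationError(
                f"{where}: cannot parse related={kwargs['related']!r} as boolean"
            )
        kwargs["related"] = _BOOL_STRINGS[key]
    return cls(**kwargs)


def read_stimulus_set(path: str | Path, protocol: str) -> StimulusSet:
    """Read and validate a stimulus file (JSON list/object or TSV).

    The format is chosen by extension: ``.json`` for JSON, anything else is
    treated as TSV with a header row matching the protocol's field names.
    Validation failures report the offending row/index.
    """
    path = Path(path)
    if protocol not in PROTOCOLS:
        raise StimulusValidationError(f"unknown protocol {protocol!r}")
    provenance = ""
    records: list[dict]
    if path.suffix.lower() == ".json":
        with open(path, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
        if isinstance(payload, dict):
            provenance = payload.get("provenance", "")
            file_proto = payload.get("protocol")
            if file_proto is not None and file_proto != protocol:
                raise StimulusValidationError(
                    f"file declares protocol {file_proto!r}, expected {protocol!r}"
                )
            records = payload.get("items", [])
        else:
            records = payload
        items = [
            _item_from_record(protocol, rec, f"item {i}")
            for i, rec in enumerate(records)
        ]
    else:
        with open(path, "r", encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            if reader.fieldnames is None:
                raise StimulusValidationError(f"{path}: empty file")
            missing = [f for f in _fields(protocol) if f not in reader.fieldnames]
            if missing:
                raise StimulusValidationError(
                    f"{path}: missing column(s) {missing} for protocol {protocol!r}"
                )
            items = [
                _item_from_record(protocol, row, f"row {rowno}")
                for rowno, row in enumerate(reader, start=2)
            ]
    if not items:
        raise StimulusValidationError(f"{path}: no stimulus records")
    return StimulusSet(protocol=protocol, items=items, provenance=provenance)


def write_stimulus_set(
    stimulus_set: StimulusSet, path: str | Path, format: str = "json"
) -> Path:
    """Write a stimulus set; ``read_stimulus_set`` inverts it exactly."""
    path = Path(path)
    if format == "json":
        payload = {
            "protocol": stimulus_set.protocol,
            "provenance": stimulus_set.provenance,
            "items": [asdict(it) for it in stimulus_set.items],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, ensure_ascii=False)
            fh.write("\n")
    elif format == "tsv":
        fields = _fields(stimulus_set.protocol)
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=fields, delimiter="\t")
            writer.writeheader()
            for item in stimulus_set.items:
                row = asdict(item)
                if "related" in row and isinstance(row["related"], bool):
                    row["related"] = "true" if row["related"] else "false"
                writer.writerow(row)
    else:
        raise ValueError(f"unknown format {format!r}; expected 'json' or 'tsv'")
    return path


def _load_fixture(name: str, protocol: str) -> StimulusSet:
    ref = resources.files("embinfer.data").joinpath(name)
    with resources.as_file(ref) as path:
        return read_stimulus_set(path, protocol)


def metusalem_example_set() -> StimulusSet:
    """The single worked discourse-inference item shipped with the package
    (the red-light / crash scenario), target words stored lowercase."""
    return _load_fixture("metusalem_example.json", "metusalem")


def mckoon_example_set() -> StimulusSet:
    """The single worked word-order inference item shipped with the package
    (the letter-writing debutante), target word stored lowercase."""
    return _load_fixture("mckoon_example.json", "mckoon")
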