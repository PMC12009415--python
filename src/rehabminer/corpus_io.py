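"""Q&A corpus records, position-marker annotation lines, and stratified splits.

A record is one patient inquiry (title + content) plus the ordered doctor
answers, with typed entity mentions (DIS / SYM / TRE) given as character
offsets into the concatenation of those parts.  Relation-annotated instances
use the line format ``LABEL@entity1$entity2$marked_text`` where exactly one
``#`` marks the position of entity 1 (the disease) and exactly one ``*`` marks
entity 2 (the symptom or measure).
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

__all__ = [
    "ENTITY_TYPES",
    "RELATION_LABELS",
    "EntityMention",
    "QARecord",
    "RelationInstance",
    "SplitSpec",
    "AnnotationError",
    "concat_record",
    "filter_single_entity_type",
    "make_marked_instance",
    "parse_annotation",
    "read_annotation_file",
    "write_annotation_file",
    "read_records_jsonl",
    "write_records_jsonl",
    "read_records_csv",
    "write_records_csv",
    "candidate_pairs",
    "stratified_split",
]

ENTITY_TYPES = ("DIS", "SYM", "TRE")
#: Canonical label order; also the class-processing order of stratified_split.
RELATION_LABELS = ("DS", "SFD", "NSFD", "UKN")

#: Entity-2 type admitted for each directed relation (entity 1 is always DIS).
_E2_TYPE = {"DS": "SYM", "SFD": "TRE", "NSFD": "TRE"}


class AnnotationError(ValueError):
    """Malformed annotation line or inconsistent mention annotation."""


@dataclass(frozen=True)
class EntityMention:
    """A typed entity occurrence, located in the concatenated record text."""

    surface: str
    etype: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.etype not in ENTITY_TYPES:
            raise ValueError(f"unknown entity type {self.etype!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad span [{self.start}, {self.end})")


@dataclass
class QARecord:
    """One patient inquiry and its doctor answers.

    Mention offsets refer to the default concatenation (single-space
    separator) of title, content and answers, in that order.
    """

    record_id: str
    question_title: str = ""
    question_content: str = ""
    answers: list[str] = field(default_factory=list)
    mentions: list[EntityMention] = field(default_factory=list)

    def entity_types(self) -> set[str]:
        return {m.etype for m in self.mentions}


@dataclass(frozen=True)
class RelationInstance:
    """An (entity1, entity2, label, marked text) classification unit."""

    label: str | None
    entity1: str
    entity2: str
    marked_text: str

    def __post_init__(self) -> None:
        if self.label is not None and self.label not in RELATION_LABELS:
            raise ValueError(f"unknown relation label {self.label!r}")
        for marker in "#*":
            if _count_unescaped(self.marked_text, marker) != 1:
                raise ValueError(
                    f"marked_text must contain exactly one unescaped {marker!r}"
                )

    def serialize(self) -> str:
        return f"{self.label}@{self.entity1}${self.entity2}${self.marked_text}"


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation/test fractions (default 6:2:2) and shuffle seed."""

    ratios: tuple[float, float, float] = (0.6, 0.2, 0.2)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(r < 0 for r in self.ratios):
            raise ValueError("ratios must be non-negative")
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ValueError("ratios must sum to 1")


# ---------------------------------------------------------------------------
# marker escaping


def _count_unescaped(text: str, marker: str) -> int:
    count = 0
    prev_backslash = False
    for ch in text:
        if ch == marker and not prev_backslash:
            count += 1
        prev_backslash = ch == "\\" and not prev_backslash
    return count


def escape_markers(text: str) -> str:
    """Escape literal ``#`` and ``*`` (and the escape character itself) so
    they cannot be read as position markers."""
    return (
        text.replace("\\", "\\\\").replace("#", r"\#").replace("*", r"\*")
    )


def unescape_markers(text: str) -> str:
    out = []
    i = 0
    while i < len(text):
        if text[i] == "\\" and i + 1 < len(text) and text[i + 1] in "\\#*":
            out.append(text[i + 1])
            i += 2
        else:
            out.append(text[i])
            i += 1
    return "".join(out)


# ---------------------------------------------------------------------------
# record operations


def concat_record(
    record: QARecord, separator: str = " "
) -> tuple[str, list[EntityMention]]:
    """Concatenate title, content and answers into one instance text.

    Returns the text and the record's mentions with offsets remapped to this
    concatenation (stored offsets refer to the single-space default).  Empty
    parts are skipped so separators never double up.
    """
    parts = [record.question_title, record.question_content, *record.answers]
    parts = [p for p in parts if p]
    if not parts:
        raise ValueError(f"record {record.record_id!r} is empty")
    text = separator.join(parts)
    if separator == " ":
        mentions = list(record.mentions)
    else:
        # Segment k starts at sum(len(parts[:k])) + k * len(sep) in either
        # concatenation; shift each mention by the difference.
        default_starts, new_starts = [], []
        pos_d = pos_n = 0
        for p in parts:
            default_starts.append(pos_d)
            new_starts.append(pos_n)
            pos_d += len(p) + 1
            pos_n += len(p) + len(separator)
        mentions = []
        for m in record.mentions:
            seg = max(
                i for i, s in enumerate(default_starts) if s <= m.start
            )
            delta = new_starts[seg] - default_starts[seg]
            mentions.append(replace(m, start=m.start + delta, end=m.end + delta))
    for m in mentions:
        if text[m.start : m.end] != m.surface:
            raise AnnotationError(
                f"mention {m.surface!r} does not match text slice "
                f"{text[m.start:m.end]!r} in record {record.record_id!r}"
            )
    return text, mentions


def filter_single_entity_type(records: Iterable[QARecord]) -> list[QARecord]:
    """Keep only records whose mentions cover at least two entity types."""
    return [r for r in records if len(r.entity_types()) >= 2]


def make_marked_instance(
    record: QARecord,
    e1: EntityMention,
    e2: EntityMention,
    label: str | None,
) -> RelationInstance:
    """Replace the two entity spans with ``#`` / ``*`` position markers."""
    if label in _E2_TYPE:
        if e1.etype != "DIS":
            raise AnnotationError(f"entity 1 must be DIS for {label}, got {e1.etype}")
        if e2.etype != _E2_TYPE[label]:
            raise AnnotationError(
                f"entity 2 must be {_E2_TYPE[label]} for {label}, got {e2.etype}"
            )
    if not (e1.end <= e2.start or e2.end <= e1.start):
        raise AnnotationError("entity spans overlap")
    text, mentions = concat_record(record)
    lookup = {(m.start, m.end): m for m in mentions}
    e1 = lookup.get((e1.start, e1.end), e1)
    e2 = lookup.get((e2.start, e2.end), e2)
    pieces = []
    cursor = 0
    for mention, marker in sorted(
        [(e1, "#"), (e2, "*")], key=lambda t: t[0].start
    ):
        pieces.append(escape_markers(text[cursor : mention.start]))
        pieces.append(marker)
        cursor = mention.end
    pieces.append(escape_markers(text[cursor:]))
    return RelationInstance(
        label=label, entity1=e1.surface, entity2=e2.surface,
        marked_text="".join(pieces),
    )


def candidate_pairs(
    record: QARecord,
) -> list[tuple[EntityMention, EntityMention]]:
    """All ordered (DIS, SYM) and (DIS, TRE) mention pairs of a record."""
    diseases = [m for m in record.mentions if m.etype == "DIS"]
    others = [m for m in record.mentions if m.etype in ("SYM", "TRE")]
    return [
        (d, o)
        for d in diseases
        for o in others
        if d.end <= o.start or o.end <= d.start
    ]


# ---------------------------------------------------------------------------
# annotation line format


def parse_annotation(line: str, lineno: int | None = None) -> RelationInstance:
    """Parse one ``LABEL@entity1$entity2$marked_text`` line.

    Splits on the first ``@`` and the first two ``$`` only, so entity
    surfaces and the text may contain later delimiter characters.  The
    historical spelling ``NSF`` is accepted and normalised to ``NSFD``.
    """
    where = "" if lineno is None else f" (line {lineno})"
    if not line:
        raise AnnotationError(f"empty annotation line{where}")
    label, at, rest = line.partition("@")
    if not at:
        raise AnnotationError(f"missing '@' delimiter{where}")
    if label == "NSF":
        label = "NSFD"
    if label not in RELATION_LABELS:
        raise AnnotationError(f"unknown relation label {label!r}{where}")
    e1, d1, rest = rest.partition("$")
    e2, d2, marked = rest.partition("$")
    if not d1 or not d2:
        raise AnnotationError(f"missing '$' delimiter{where}")
    for marker in "#*":
        n = _count_unescaped(marked, marker)
        if n != 1:
            raise AnnotationError(
                f"expected exactly one {marker!r} marker, found {n}{where}"
            )
    return RelationInstance(label=label, entity1=e1, entity2=e2, marked_text=marked)


def read_annotation_file(path) -> list[RelationInstance]:
    instances = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line:
                instances.append(parse_annotation(line, lineno))
    return instances


def write_annotation_file(path, instances: Iterable[RelationInstance]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for inst in instances:
            fh.write(inst.serialize() + "\n")


# ---------------------------------------------------------------------------
# record I/O


def _record_to_dict(record: QARecord) -> dict:
    return {
        "record_id": record.record_id,
        "question_title": record.question_title,
        "question_content": record.question_content,
        "answers": list(record.answers),
        "mentions": [
            {"surface": m.surface, "etype": m.etype, "start": m.start, "end": m.end}
            for m in record.mentions
        ],
    }


def _record_from_dict(obj: dict) -> QARecord:
    return QARecord(
        record_id=str(obj["record_id"]),
        question_title=obj.get("question_title", ""),
        question_content=obj.get("question_content", ""),
        answers=list(obj.get("answers", [])),
        mentions=[EntityMention(**m) for m in obj.get("mentions", [])],
    )


def write_records_jsonl(path, records: Iterable[QARecord]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for record in records:
            fh.write(json.dumps(_record_to_dict(record), ensure_ascii=False) + "\n")


def read_records_jsonl(path) -> list[QARecord]:
    records = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                records.append(_record_from_dict(json.loads(line)))
    return records


def write_records_csv(path, records: Sequence[QARecord]) -> None:
    """CSV with columns record_id, question_title, question_content,
    answer_1..answer_k and a JSON-encoded mentions column."""
    k = max((len(r.answers) for r in records), default=0)
    header = (
        ["record_id", "question_title", "question_content"]
        + [f"answer_{i + 1}" for i in range(k)]
        + ["mentions"]
    )
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for r in records:
            answers = list(r.answers) + [""] * (k - len(r.answers))
            writer.writerow(
                [r.record_id, r.question_title, r.question_content]
                + answers
                + [json.dumps(_record_to_dict(r)["mentions"], ensure_ascii=False)]
            )


def read_records_csv(path) -> list[QARecord]:
    records = []
    with open(path, encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            answers = [
                row[key]
                for key in sorted(
                    (k for k in row if k.startswith("answer_")),
                    key=lambda k: int(k.split("_")[1]),
                )
                if row[key]
            ]
            records.append(
                QARecord(
                    record_id=row["record_id"],
                    question_title=row["question_title"],
                    question_content=row["question_content"],
                    answers=answers,
                    mentions=[
                        EntityMention(**m) for m in json.loads(row["mentions"] or "[]")
                    ],
                )
            )
    return records


# ---------------------------------------------------------------------------
# stratified split


def _round_half_up(x: float) -> int:
    return int(x + 0.5)


def stratified_split(
    instances: Sequence[RelationInstance], spec: SplitSpec = SplitSpec()
) -> tuple[list[RelationInstance], list[RelationInstance], list[RelationInstance]]:
    """Shuffle and split per class at the given ratios (default 6:2:2).

    Per class the training set receives round-half-up(train_ratio * n); the
    remainder is halved between validation and test.  When the remainder is
    odd, the extra instance goes to whichever of validation/test currently
    holds fewer instances (classes processed in canonical label order,
    ties broken toward test) — the allocation that balances the two
    held-out partitions overall.  Classes with fewer than 3 instances go
    wholly to training with a warning.
    """
    import numpy as np

    rng = np.random.default_rng(spec.seed)
    by_label: dict[str, list[RelationInstance]] = {}
    for inst in instances:
        by_label.setdefault(inst.label, []).append(inst)

    order = [lab for lab in RELATION_LABELS if lab in by_label]
    order += sorted(set(by_label) - set(order))

    train: list[RelationInstance] = []
    val: list[RelationInstance] = []
    test: list[RelationInstance] = []
    for label in order:
        group = list(by_label[label])
        idx = rng.permutation(len(group))
        group = [group[i] for i in idx]
        if len(group) < 3:
            warnings.warn(
                f"class {label!r} has {len(group)} < 3 instances; "
                "placed wholly in training"
            )
            train.extend(group)
            continue
        n_train = _round_half_up(spec.ratios[0] * len(group))
        remainder = len(group) - n_train
        half, extra = divmod(remainder, 2)
        if extra and len(val) < len(test):
            n_val, n_test = half + 1, half
        else:
            n_val, n_test = half, half + extra
        train.extend(group[:n_train])
        val.extend(group[n_train : n_train + n_val])
        test.extend(group[n_train + n_val :])
        assert len(group[n_train + n_val :]) == n_test
    return train, val, test
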