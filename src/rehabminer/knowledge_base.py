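"""Organize predicted relation triples into knowledge dictionaries and graphs.

Triples (disease, symptom-or-measure, relation) are grouped into three
dictionaries keyed by disease name:

* DS   — disease -> its reported symptoms
* SFD  — disease -> rehabilitation measures recommended for it
* NSFD — disease -> measures advised against

UKN (indeterminate) triples are dropped here; duplicate values collapse to
one insertion-ordered occurrence.  Each disease's entry can be exported as a
star-shaped relation network graph (GraphML / DOT), and the SFD/NSFD pair
can be scanned for contradictions — measures some doctors recommend and
others advise against for the same disease.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field

import networkx as nx

__all__ = [
    "RelationTriple",
    "RelationDictionary",
    "build_dictionaries",
    "export_graph",
    "write_dot",
    "detect_contradictions",
]

_DICT_KINDS = ("DS", "SFD", "NSFD")


@dataclass(frozen=True)
class RelationTriple:
    entity1: str
    entity2: str
    relation: str

    def __post_init__(self) -> None:
        if self.relation not in ("DS", "SFD", "NSFD", "UKN"):
            raise ValueError(f"unknown relation {self.relation!r}")


@dataclass
class RelationDictionary:
    """disease -> ordered unique value phrases, for one relation kind."""

    kind: str
    entries: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in _DICT_KINDS:
            raise ValueError(f"dictionary kind must be one of {_DICT_KINDS}")

    def add(self, disease: str, value: str) -> bool:
        """Insert, preserving order and uniqueness; True if newly added."""
        values = self.entries.setdefault(disease, [])
        if value in values:
            return False
        values.append(value)
        return True

    @property
    def n_diseases(self) -> int:
        return len(self.entries)

    @property
    def n_values(self) -> int:
        return sum(len(v) for v in self.entries.values())

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.entries, fh, ensure_ascii=False, indent=2)

    @classmethod
    def from_json(cls, path, kind: str) -> "RelationDictionary":
        with open(path, encoding="utf-8") as fh:
            entries = json.load(fh)
        return cls(kind=kind, entries={k: list(v) for k, v in entries.items()})

    def to_csv(self, path) -> None:
        """Key / Type / Size / Value rows, one disease per row."""
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["Key", "Type", "Size", "Value"])
            for disease, values in self.entries.items():
                writer.writerow(
                    [disease, "list", len(values), json.dumps(values, ensure_ascii=False)]
                )


def build_dictionaries(
    triples,
) -> tuple[dict[str, RelationDictionary], dict[str, int]]:
    """Group triples into the three dictionaries.

    Returns the dictionaries plus bookkeeping counts satisfying
    kept + dropped_ukn + dropped_duplicates == len(triples).
    """
    dicts = {kind: RelationDictionary(kind=kind) for kind in _DICT_KINDS}
    stats = {"kept": 0, "dropped_ukn": 0, "dropped_duplicates": 0}
    for triple in triples:
        if triple.relation == "UKN":
            stats["dropped_ukn"] += 1
            continue
        if dicts[triple.relation].add(triple.entity1, triple.entity2):
            stats["kept"] += 1
        else:
            stats["dropped_duplicates"] += 1
    return dicts, stats


def export_graph(dictionary: RelationDictionary, disease: str) -> nx.Graph:
    """Star graph: the disease at the centre, one edge per value phrase."""
    if disease not in dictionary.entries:
        raise KeyError(f"disease {disease!r} not in {dictionary.kind} dictionary")
    graph = nx.Graph()
    graph.add_node(disease, role="disease")
    for value in dictionary.entries[disease]:
        graph.add_node(value, role="value")
        graph.add_edge(disease, value, relation=dictionary.kind)
    return graph


def write_dot(graph: nx.Graph, path) -> None:
    """Minimal DOT serialization (node and edge attributes included)."""

    def q(s: str) -> str:
        return '"' + str(s).replace('"', r"\"") + '"'

    lines = ["graph relation_network {"]
    for node, attrs in graph.nodes(data=True):
        attr_txt = ", ".join(f"{k}={q(v)}" for k, v in attrs.items())
        lines.append(f"  {q(node)}" + (f" [{attr_txt}]" if attr_txt else "") + ";")
    for a, b, attrs in graph.edges(data=True):
        attr_txt = ", ".join(f"{k}={q(v)}" for k, v in attrs.items())
        lines.append(
            f"  {q(a)} -- {q(b)}" + (f" [{attr_txt}]" if attr_txt else "") + ";"
        )
    lines.append("}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def detect_contradictions(
    sfd: RelationDictionary,
    nsfd: RelationDictionary,
    case_fold: bool = False,
) -> list[dict]:
    """Measures listed as both suitable and unsuitable for the same disease.

    With ``case_fold`` the match also normalises case and surrounding
    whitespace; the reported provenance keeps the original surfaces.
    """

    def norm(s: str) -> str:
        return s.strip().casefold() if case_fold else s

    report = []
    for disease, suitable in sfd.entries.items():
        unsuitable = nsfd.entries.get(disease, [])
        if case_fold and disease not in nsfd.entries:
            folded = {norm(d): d for d in nsfd.entries}
            match = folded.get(norm(disease))
            if match is not None:
                unsuitable = nsfd.entries[match]
        ns_norm = {norm(v): v for v in unsuitable}
        for value in suitable:
            if norm(value) in ns_norm:
                report.append(
                    {
                        "disease": disease,
                        "measure": value,
                        "sfd_values": list(suitable),
                        "nsfd_values": list(unsuitable),
                    }
                )
    return report
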