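"""Seeded generator of synthetic rehabilitation Q&A corpora.

The real study corpus (an orthopedic-rehabilitation consultation forum
scrape) is not public, so this module plants recoverable relation structure
in templated records that mirror its discourse: the patient describes
symptoms and asks a question; a doctor names a (possible) disease and
recommends or advises against rehabilitation measures, sometimes referring
back to the patient's condition with a pronoun phrase instead of repeating
the disease name.

Design choices:

* The token alphabet is synthetic and language-neutral (``disN`` / ``symN`` /
  ``treN`` entity words plus filler) — the pipeline under test must be
  script-agnostic, so no natural language is imitated.
* Each relation label has a small cue lexicon ("recommended"/"take" for
  suitable measures, "avoid"/"reduce" for unsuitable ones, "could_be" for
  disease–symptom speculation); UKN records embed both entities in the
  question with a non-committal answer and no cue.
* Noise sentences are cue-free filler clauses inserted around the
  relation-bearing clause, exercising the attention layer's noise filtering.
* Class proportions default to the annotated-corpus imbalance
  901 : 3602 : 497 : 235 (DS : SFD : NSFD : UKN).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus_io import (
    RELATION_LABELS,
    EntityMention,
    QARecord,
    RelationInstance,
    concat_record,
    make_marked_instance,
)

__all__ = ["GeneratorConfig", "generate_corpus", "corpus_stats", "DEFAULT_CLASS_COUNTS"]

#: Annotated-corpus class counts the default mix is normalised from.
DEFAULT_CLASS_COUNTS = {"DS": 901, "SFD": 3602, "NSFD": 497, "UKN": 235}

DEFAULT_CUES = {
    "DS": ["could_be", "likely", "suggests"],
    "SFD": ["recommended", "take", "apply", "increase", "improve"],
    "NSFD": ["avoid", "reduce", "refrain_from", "limit"],
    "UKN": [],
}

_FILLER = [
    "the", "and", "also", "since", "last", "week", "morning", "often",
    "slightly", "again", "still", "then", "after", "during", "rest",
    "day", "night", "home", "work", "walk",
]


@dataclass(frozen=True)
class GeneratorConfig:
    n_records: int = 1000
    class_mix: dict[str, float] | None = None
    n_diseases: int = 40
    n_symptoms: int = 30
    n_measures: int = 30
    cues: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_CUES.items()}
    )
    noise_sentence_rate: float = 0.0
    coref_rate: float = 0.3
    max_len: int = 200
    seed: int = 0

    def mix(self) -> dict[str, float]:
        if self.class_mix is None:
            total = sum(DEFAULT_CLASS_COUNTS.values())
            return {k: v / total for k, v in DEFAULT_CLASS_COUNTS.items()}
        total = sum(self.class_mix.values())
        if total <= 0:
            raise ValueError("class_mix must have positive mass")
        return {k: self.class_mix.get(k, 0.0) / total for k in RELATION_LABELS}

    def __post_init__(self) -> None:
        if not 0.0 <= self.noise_sentence_rate <= 1.0:
            raise ValueError("noise_sentence_rate must be in [0, 1]")
        if not 0.0 <= self.coref_rate <= 1.0:
            raise ValueError("coref_rate must be in [0, 1]")


def _noise_sentence(rng: np.random.Generator) -> str:
    n = int(rng.integers(4, 8))
    return " ".join(rng.choice(_FILLER, size=n))


def _maybe_noise(parts: list[str], rng, rate: float, slots: int) -> None:
    """Insert up to `slots` cue-free filler sentences at random positions."""
    for _ in range(slots):
        if rng.random() < rate:
            parts.insert(int(rng.integers(0, len(parts) + 1)), _noise_sentence(rng))


def _build_record(
    record_id: str, label: str, cfg: GeneratorConfig, rng: np.random.Generator
) -> tuple[QARecord, RelationInstance]:
    dis = f"dis{int(rng.integers(cfg.n_diseases))}"
    sym = f"sym{int(rng.integers(cfg.n_symptoms))}"
    tre = f"tre{int(rng.integers(cfg.n_measures))}"
    cues = cfg.cues.get(label, [])
    if label != "UKN" and not cues:
        raise ValueError(f"label {label} requested but its cue lexicon is empty")
    cue = str(rng.choice(cues)) if cues else ""
    coref = rng.random() < cfg.coref_rate

    # question clauses / answer clauses as token strings; entity words are
    # unique within a record so offsets can be located by search afterwards.
    title = "help needed"
    if label == "DS":
        q = [f"i feel {sym} when moving", "what is wrong"]
        if coref:
            q.insert(0, f"doctor mentioned {dis} before")
            a = [f"your condition {cue} that again", "please rest well"]
        else:
            a = [f"it {cue} {dis}", "please rest well"]
        e2_surface = sym
    elif label in ("SFD", "NSFD"):
        q = [f"my joint has {sym} lately", "what should i do"]
        if coref:
            q.insert(0, f"i was told i have {dis}")
            a = [f"for your condition {cue} {tre}", "come back if worse"]
        else:
            a = [f"with {dis} you should {cue} {tre}", "come back if worse"]
        e2_surface = tre
    else:  # UKN: both entities in the question, non-committal answer
        q = [f"it has been {dis} for a while", f"can i do {tre} now"]
        a = ["please visit the hospital for a check"]
        e2_surface = tre

    _maybe_noise(q, rng, cfg.noise_sentence_rate, slots=2)
    _maybe_noise(a, rng, cfg.noise_sentence_rate, slots=3)
    content = " ".join(q)
    answers = [" ".join(a)]
    record = QARecord(
        record_id=record_id,
        question_title=title,
        question_content=content,
        answers=answers,
    )
    text, _ = concat_record(record)
    mentions = []
    for surface, etype in ((dis, "DIS"), (sym, "SYM"), (tre, "TRE")):
        start = text.find(surface)
        if start >= 0:
            mentions.append(
                EntityMention(surface=surface, etype=etype, start=start,
                              end=start + len(surface))
            )
    record.mentions = mentions
    by_surface = {m.surface: m for m in mentions}
    gold = make_marked_instance(record, by_surface[dis], by_surface[e2_surface], label)
    return record, gold


def generate_corpus(
    config: GeneratorConfig,
) -> tuple[list[QARecord], list[RelationInstance]]:
    """Generate `n_records` templated records with one gold relation each.

    A pure function of the config (including its seed): the same config
    yields byte-identical corpora.
    """
    if config.n_records <= 0:
        raise ValueError("n_records must be positive")
    rng = np.random.default_rng(config.seed)
    mix = config.mix()
    labels = [lab for lab in RELATION_LABELS]
    probs = np.array([mix[lab] for lab in labels])
    drawn = rng.choice(len(labels), size=config.n_records, p=probs)
    records, golds = [], []
    for i, li in enumerate(drawn):
        record, gold = _build_record(f"rec{i:05d}", labels[int(li)], config, rng)
        if len(gold.marked_text.split()) > config.max_len:
            raise AssertionError("generated instance exceeds max_len tokens")
        records.append(record)
        golds.append(gold)
    return records, golds


def corpus_stats(instances) -> dict[str, dict[str, float]]:
    """Per-label counts and proportions (proportions rounded to 3 decimals)."""
    if not instances:
        raise ValueError("empty instance sequence")
    counts: dict[str, int] = {}
    for inst in instances:
        counts[inst.label] = counts.get(inst.label, 0) + 1
    total = sum(counts.values())
    return {
        label: {"count": n, "proportion": round(n / total, 3)}
        for label, n in sorted(counts.items(), key=lambda kv: kv[0])
    }
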