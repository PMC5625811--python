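"""Decision-level fusion of the face and EEG channels.

Two rules are implemented:

* **Sum rule** — each channel's four emotion-state scores are min-max
  normalized to [0, 1]; the fused decision is the argmax of the elementwise
  sum of the two normalized score vectors.
* **Production rules** — a 12-rule expert table mapping the pair
  (state decided from the face, intensity decided from EEG) to a final
  state. The default table encodes the intuition that a weakly expressed
  emotion reads as its milder neighbour (weak happiness -> neutral, weak
  fear -> sadness) and a strongly expressed one as its intenser neighbour
  (strong neutral -> happiness, strong sadness -> fear), with moderate
  intensity leaving the face decision unchanged.

All argmax decisions break ties toward the lowest index — one deterministic
convention across the whole package.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .labels import (
    EmotionState,
    IntensityLevel,
    STATE_ORDER,
    INTENSITY_ORDER,
    state_from_index,
    parse_state,
    parse_intensity,
)

__all__ = [
    "normalize_scores",
    "decide",
    "SumFusionResult",
    "sum_fusion",
    "ProductionRule",
    "RuleTable",
    "load_rule_table",
    "production_fusion",
]


def normalize_scores(raw: Iterable[float]) -> np.ndarray:
    """Min-max normalize a score vector to [0, 1].

    ``(x - min) / (max - min)`` elementwise. If all scores are equal the
    map is undefined; the convention here is an all-zero output, so a
    non-informative channel is the neutral element of the sum rule.

    Raises ``ValueError`` on fewer than 2 scores or non-finite input.
    """
    x = np.asarray(list(raw) if not isinstance(raw, np.ndarray) else raw, dtype=float).ravel()
    if x.size < 2:
        raise ValueError(f"need at least 2 scores to normalize, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("scores must be finite")
    span = x.max() - x.min()
    if span == 0.0:
        return np.zeros_like(x)
    return (x - x.min()) / span


def decide(sh: Iterable[float]) -> EmotionState:
    """Emotion state of the maximal score; ties go to the lowest index."""
    sh = np.asarray(list(sh) if not isinstance(sh, np.ndarray) else sh, dtype=float).ravel()
    if sh.size != len(STATE_ORDER):
        raise ValueError(f"expected {len(STATE_ORDER)} scores, got {sh.size}")
    return state_from_index(int(np.argmax(sh)))


@dataclass(frozen=True)
class SumFusionResult:
    sums: np.ndarray  # elementwise sum of the two normalized vectors, in [0, 2]
    r_sum: EmotionState


def sum_fusion(sh1: Iterable[float], sh2: Iterable[float]) -> SumFusionResult:
    """Sum-rule fusion of two normalized 4-score vectors."""
    a = np.asarray(list(sh1) if not isinstance(sh1, np.ndarray) else sh1, dtype=float).ravel()
    b = np.asarray(list(sh2) if not isinstance(sh2, np.ndarray) else sh2, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError(f"score vectors differ in length: {a.size} vs {b.size}")
    if a.size != len(STATE_ORDER):
        raise ValueError(f"expected {len(STATE_ORDER)} scores per channel, got {a.size}")
    sums = a + b
    return SumFusionResult(sums=sums, r_sum=decide(sums))


@dataclass(frozen=True)
class ProductionRule:
    """IF (face state, EEG intensity) THEN final state."""

    index: int
    face_state: EmotionState
    eeg_intensity: IntensityLevel
    result: EmotionState


class RuleTable:
    """A total mapping from the 4 x 3 (state, intensity) pairs to a state.

    Validated at construction: every pair must appear exactly once.
    """

    def __init__(self, rules: Iterable[ProductionRule]):
        self.rules: list[ProductionRule] = list(rules)
        mapping: dict[tuple[EmotionState, IntensityLevel], EmotionState] = {}
        for rule in self.rules:
            key = (rule.face_state, rule.eeg_intensity)
            if key in mapping:
                raise ValueError(
                    f"duplicate rule antecedent ({key[0].name.lower()}, {key[1].name.lower()})"
                )
            mapping[key] = rule.result
        missing = [
            (s, v)
            for s in STATE_ORDER
            for v in INTENSITY_ORDER
            if (s, v) not in mapping
        ]
        if missing:
            pairs = ", ".join(f"({s.name.lower()}, {v.name.lower()})" for s, v in missing)
            raise ValueError(f"rule table is not total; missing antecedent(s): {pairs}")
        self._map = mapping

    def __len__(self) -> int:
        return len(self.rules)

    def apply(self, face_state: EmotionState, eeg_intensity: IntensityLevel) -> EmotionState:
        return self._map[(face_state, eeg_intensity)]

    def as_mapping(self) -> Mapping[tuple[EmotionState, IntensityLevel], EmotionState]:
        return dict(self._map)


def _rules_from_rows(rows: Iterable[Mapping[str, str]]) -> list[ProductionRule]:
    rules = []
    for i, row in enumerate(rows, start=1):
        rules.append(
            ProductionRule(
                index=i,
                face_state=parse_state(row["face_state"]),
                eeg_intensity=parse_intensity(row["eeg_intensity"]),
                result=parse_state(row["result"]),
            )
        )
    return rules


def load_rule_table(source: "str | Path | None" = None) -> RuleTable:
    """Load and validate a production-rule table.

    ``source=None`` loads the packaged default table. A user CSV must have
    the header ``face_state,eeg_intensity,result`` with lowercase state and
    intensity names (or integer codes).
    """
    if source is None:
        text = resources.files("emofuse.data").joinpath("production_rules.csv").read_text()
        lines = text.splitlines()
    else:
        lines = Path(source).read_text().splitlines()
    reader = csv.DictReader(lines)
    expected = {"face_state", "eeg_intensity", "result"}
    if reader.fieldnames is None or not expected.issubset(reader.fieldnames):
        raise ValueError(f"rule CSV must have columns {sorted(expected)}, got {reader.fieldnames}")
    return RuleTable(_rules_from_rows(reader))


def production_fusion(
    r1: EmotionState, r2_prime: IntensityLevel, table: "RuleTable | None" = None
) -> EmotionState:
    """Apply the production-rule table to the two channel decisions."""
    if table is None:
        table = load_rule_table()
    return table.apply(EmotionState(r1), IntensityLevel(r2_prime))
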