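"""Preferred-term (PT) vocabulary: SOC membership and peripheral-neuropathy flags.

A licensed MedDRA hierarchy cannot be redistributed, so the package ships a
small editable vocabulary covering the study's 28 peripheral-neuropathy (PN)
PTs plus the common neurological and concurrent non-neurological PTs that
appear in analyses. Users can point any operation at their own CSV with the
same columns (``pt, soc, is_neuro, is_pn, category``).

Symptom categories follow the clinical grouping used for PN manifestations:

* ``hyposensitivity`` — numbness-type symptoms (paraesthesia, hypoaesthesia,
  sensory loss);
* ``hypersensitivity`` — pain/irritation-type symptoms (burning sensation,
  hyperaesthesia, allodynia, electric-shock sensation);
* ``unclassified_sensory`` — terms compatible with either direction
  (sensory disturbance, small fibre neuropathy, axonal neuropathy, the
  generic "peripheral neuropathy");
* ``motor`` — terms with explicit motor involvement only.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, FrozenSet, Iterable, Set

logger = logging.getLogger(__name__)

NEURO_SOC = "Nervous system disorders"
CATEGORIES = ("hyposensitivity", "hypersensitivity", "unclassified_sensory", "motor")
N_PN_TERMS = 28  # size of the shipped PN term list


@dataclass(frozen=True)
class PTEntry:
    pt: str
    soc: str
    is_neuro: bool
    is_pn: bool
    category: str  # one of CATEGORIES or "none"

    def __post_init__(self) -> None:
        if self.is_pn and not self.is_neuro:
            raise ValueError(f"{self.pt}: PN terms must belong to the neurological SOC")
        if self.category != "none" and not self.is_pn:
            raise ValueError(f"{self.pt}: only PN terms carry a symptom category")
        if self.category not in CATEGORIES + ("none",):
            raise ValueError(f"{self.pt}: unknown category {self.category!r}")


@dataclass
class PTVocabulary:
    """Lookup from PT string (case-insensitive) to its classification."""

    entries: Dict[str, PTEntry]
    _warned: Set[str] = field(default_factory=set, repr=False)

    def lookup(self, pt: str) -> PTEntry | None:
        entry = self.entries.get(pt.strip().lower())
        if entry is None:
            key = pt.strip().lower()
            if key not in self._warned:
                self._warned.add(key)
                logger.info("PT %r not in vocabulary; treated as non-neurological", pt)
        return entry

    def is_neuro(self, pt: str) -> bool:
        entry = self.lookup(pt)
        return entry.is_neuro if entry else False

    def is_pn(self, pt: str) -> bool:
        entry = self.lookup(pt)
        return entry.is_pn if entry else False

    def pn_terms(self) -> FrozenSet[str]:
        return frozenset(e.pt for e in self.entries.values() if e.is_pn)

    def pn_subset(self, pts: Iterable[str]) -> FrozenSet[str]:
        return frozenset(p for p in pts if self.is_pn(p))

    def categories_of(self, pts: Iterable[str]) -> FrozenSet[str]:
        cats = set()
        for p in pts:
            entry = self.lookup(p)
            if entry and entry.category != "none":
                cats.add(entry.category)
        return frozenset(cats)

    def soc_of(self, pt: str) -> str:
        entry = self.lookup(pt)
        return entry.soc if entry else "Unknown"

    @classmethod
    def from_csv(cls, path) -> "PTVocabulary":
        entries: Dict[str, PTEntry] = {}
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                entry = PTEntry(
                    pt=row["pt"].strip(),
                    soc=row["soc"].strip(),
                    is_neuro=row["is_neuro"].strip() in {"1", "true", "True"},
                    is_pn=row["is_pn"].strip() in {"1", "true", "True"},
                    category=row["category"].strip() or "none",
                )
                entries[entry.pt.lower()] = entry
        return cls(entries)

    @classmethod
    def default(cls) -> "PTVocabulary":
        ref = resources.files("fqsignals.data") / "pn_vocabulary.csv"
        with resources.as_file(ref) as path:
            vocab = cls.from_csv(path)
        n_pn = len(vocab.pn_terms())
        if n_pn != N_PN_TERMS:
            raise ValueError(f"shipped vocabulary must contain {N_PN_TERMS} PN terms, found {n_pn}")
        return vocab
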