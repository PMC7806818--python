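"""The myeloma drug dictionary: canonical drug names and their categories.

Three categories drive regimen classification:

* ``chemotherapy`` — cytotoxics: cyclophosphamide, melphalan, bendamustine,
  vincristine, etoposide, liposomal doxorubicin, cisplatin;
* ``novel_agent`` — the proteasome inhibitor bortezomib and the
  immunomodulatory drugs thalidomide and lenalidomide;
* ``steroid`` — dexamethasone and prednisolone by default (claims systems
  code steroids by ATC; the exact substance list is a site decision and is
  therefore extensible).

Drug identity is a canonical lowercase name; an optional ATC-code mapping
resolves coded dispensings onto the same names.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping


class DrugCategory(str, enum.Enum):
    CHEMOTHERAPY = "chemotherapy"
    NOVEL_AGENT = "novel_agent"
    STEROID = "steroid"


CHEMOTHERAPY_DRUGS = (
    "cyclophosphamide",
    "melphalan",
    "bendamustine",
    "vincristine",
    "etoposide",
    "liposomal doxorubicin",
    "cisplatin",
)
NOVEL_AGENTS = ("bortezomib", "thalidomide", "lenalidomide")
DEFAULT_STEROIDS = ("dexamethasone", "prednisolone")

#: ATC -> canonical name, for extracts that carry codes instead of names.
DEFAULT_ATC_MAP: dict[str, str] = {
    "L01AA01": "cyclophosphamide",
    "L01AA03": "melphalan",
    "L01AA09": "bendamustine",
    "L01CA02": "vincristine",
    "L01CB01": "etoposide",
    "L01DB01": "liposomal doxorubicin",
    "L01XA01": "cisplatin",
    "L01XG01": "bortezomib",
    "L04AX02": "thalidomide",
    "L04AX04": "lenalidomide",
    "H02AB02": "dexamethasone",
    "H02AB06": "prednisolone",
}


class UnknownDrugError(KeyError):
    """A drug name is not resolvable by the dictionary."""

    def __init__(self, drug: str) -> None:
        super().__init__(drug)
        self.drug = drug

    def __str__(self) -> str:  # pragma: no cover - trivial
        return f"unknown drug: {self.drug!r}"


@dataclass(frozen=True)
class DrugDictionary:
    """Immutable drug-name -> category map with disjoint categories."""

    categories: Mapping[str, DrugCategory]
    atc_map: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_ATC_MAP))

    @classmethod
    def default(cls, extra_steroids: Iterable[str] = ()) -> "DrugDictionary":
        cats: dict[str, DrugCategory] = {}
        for d in CHEMOTHERAPY_DRUGS:
            cats[d] = DrugCategory.CHEMOTHERAPY
        for d in NOVEL_AGENTS:
            cats[d] = DrugCategory.NOVEL_AGENT
        for d in (*DEFAULT_STEROIDS, *extra_steroids):
            if d in cats:
                raise ValueError(f"{d!r} already categorized; categories must be disjoint")
            cats[d] = DrugCategory.STEROID
        return cls(categories=cats)

    def categorize(self, drug: str) -> DrugCategory:
        """Deterministic category lookup; raises :class:`UnknownDrugError`."""
        try:
            return self.categories[drug.strip().lower()]
        except KeyError:
            raise UnknownDrugError(drug) from None

    def resolve(self, name_or_atc: str) -> str:
        """Map a drug name or ATC code to the canonical lowercase name."""
        key = name_or_atc.strip()
        if key.upper() in self.atc_map:
            return self.atc_map[key.upper()]
        name = key.lower()
        if name in self.categories:
            return name
        raise UnknownDrugError(name_or_atc)

    def __contains__(self, drug: str) -> bool:
        return drug.strip().lower() in self.categories

    @property
    def chemotherapy(self) -> frozenset[str]:
        return self._of(DrugCategory.CHEMOTHERAPY)

    @property
    def novel_agents(self) -> frozenset[str]:
        return self._of(DrugCategory.NOVEL_AGENT)

    @property
    def steroids(self) -> frozenset[str]:
        return self._of(DrugCategory.STEROID)

    def _of(self, cat: DrugCategory) -> frozenset[str]:
        return frozenset(d for d, c in self.categories.items() if c is cat)


def categorize_drug(drug: str, dictionary: DrugDictionary | None = None) -> DrugCategory:
    """Module-level convenience over :meth:`DrugDictionary.categorize`."""
    return (dictionary or DrugDictionary.default()).categorize(drug)
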