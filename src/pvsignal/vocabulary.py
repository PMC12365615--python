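"""Drug-name normalisation and PT → SOC aggregation vocabulary.

MedDRA itself is licensed, so the package works from two small user-supplied
plain-text resources: a one-column synonym list for the target drug (trade
names, salts, misspellings) and a two-column TSV mapping each preferred term
(PT) to its primary system organ class (SOC).  Lookups are case-insensitive
after trimming; unmapped PTs are tallied, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

__all__ = ["DrugSynonymSet", "PtSocMap", "UNMAPPED", "is_target_drug", "pt_to_soc"]

#: Marker returned for PTs absent from the mapping.
UNMAPPED = "unmapped"


def _fold(text: str) -> str:
    return str(text).strip().casefold()


@dataclass(frozen=True)
class DrugSynonymSet:
    """A canonical drug name plus its exact-match synonym patterns."""

    canonical_name: str
    synonyms: frozenset[str]

    def __post_init__(self):
        if not self.canonical_name or not self.synonyms:
            raise ValueError("synonym set must be non-empty")
        folded = frozenset(_fold(s) for s in self.synonyms) | {_fold(self.canonical_name)}
        object.__setattr__(self, "synonyms", folded)

    @classmethod
    def from_names(cls, canonical: str, *names: str) -> "DrugSynonymSet":
        return cls(canonical, frozenset((canonical, *names)))

    @classmethod
    def from_file(cls, path: str | Path) -> "DrugSynonymSet":
        """Load from a one-name-per-line file; the first line is canonical."""
        lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
        lines = [ln for ln in lines if ln and not ln.startswith("#")]
        if not lines:
            raise ValueError(f"{path}: empty synonym file")
        return cls(lines[0], frozenset(lines))

    def __contains__(self, name: object) -> bool:
        return isinstance(name, str) and _fold(name) in self.synonyms


def is_target_drug(drug_name: str | None, synonyms: DrugSynonymSet) -> bool:
    """True iff the trimmed, case-folded name is one of the synonyms."""
    if not drug_name:
        return False
    return drug_name in synonyms


@dataclass
class PtSocMap:
    """Many-to-one preferred-term → system-organ-class mapping.

    Follows the MedDRA primary-SOC convention: every PT belongs to exactly one
    SOC.  Conflicting duplicate entries are rejected at construction.  The
    instance keeps a running tally of unmapped lookups.
    """

    entries: dict[str, str]
    version_label: str = ""
    unmapped_tally: int = field(default=0, compare=False)

    def __post_init__(self):
        folded: dict[str, str] = {}
        for pt, soc in self.entries.items():
            key = _fold(pt)
            soc = str(soc).strip()
            if key in folded and folded[key] != soc:
                raise ValueError(f"PT {pt!r} maps to both {folded[key]!r} and {soc!r}")
            folded[key] = soc
        self.entries = folded

    @classmethod
    def from_tsv(cls, path: str | Path, version_label: str = "") -> "PtSocMap":
        """Load from a 2-column TSV with header columns ``pt`` and ``soc``."""
        import pandas as pd

        df = pd.read_csv(path, sep="\t", dtype=str)
        cols = {c.strip().lower(): c for c in df.columns}
        if "pt" not in cols or "soc" not in cols:
            raise ValueError(f"{path}: expected columns 'pt' and 'soc', got {list(df.columns)}")
        entries = dict(zip(df[cols["pt"]].astype(str), df[cols["soc"]].astype(str)))
        return cls(entries, version_label or str(path))

    def lookup(self, pt: str) -> str:
        """Return the SOC for a PT, or :data:`UNMAPPED` (and bump the tally)."""
        soc = self.entries.get(_fold(pt))
        if soc is None:
            self.unmapped_tally += 1
            return UNMAPPED
        return soc

    def socs(self) -> set[str]:
        return set(self.entries.values())


def pt_to_soc(pt: str, mapping: PtSocMap) -> str:
    """Functional alias for :meth:`PtSocMap.lookup`."""
    return mapping.lookup(pt)
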