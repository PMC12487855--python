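"""sgRNA library containers.

A pooled CRISPRi library is a catalog of *elements* — single guides, or
dual-guide cassettes counted as one unit — each either targeting a gene or
serving as a non-targeting control (NTC).  The NTC elements define the null
location (median) and scale (standard deviation) against which every screen
phenotype is measured, so a library without enough of them cannot support
phenotype centering or standardization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .exceptions import ScreenStateError

__all__ = ["SgRNAElement", "SgRNALibrary"]


@dataclass(frozen=True)
class SgRNAElement:
    """One screen element: a guide (or guide pair) with a target or NTC flag.

    ``is_ntc`` is True iff ``gene`` is None; the constructor enforces the
    equivalence so downstream code can rely on either field.
    """

    element_id: str
    gene: str | None
    is_ntc: bool = False
    protospacer: str | None = None

    def __post_init__(self):
        if self.is_ntc != (self.gene is None):
            raise ScreenStateError(
                f"element {self.element_id!r}: is_ntc must be True exactly "
                f"when gene is None (got gene={self.gene!r}, is_ntc={self.is_ntc})"
            )


@dataclass
class SgRNALibrary:
    """An ordered collection of unique elements, optionally tagged by species."""

    elements: list[SgRNAElement]
    species: str = "unspecified"
    _by_id: dict[str, SgRNAElement] = field(init=False, repr=False)

    def __post_init__(self):
        ids = [e.element_id for e in self.elements]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ScreenStateError(f"duplicate element ids: {dupes[:5]}")
        if not any(not e.is_ntc for e in self.elements):
            raise ScreenStateError("library must contain at least one targeting element")
        self._by_id = {e.element_id: e for e in self.elements}
        self._gene_elements: dict[str, list[str]] = {}
        for e in self.elements:
            if e.gene is not None:
                self._gene_elements.setdefault(e.gene, []).append(e.element_id)

    def __len__(self) -> int:
        return len(self.elements)

    def __contains__(self, element_id: str) -> bool:
        return element_id in self._by_id

    def __getitem__(self, element_id: str) -> SgRNAElement:
        return self._by_id[element_id]

    @property
    def element_ids(self) -> list[str]:
        return [e.element_id for e in self.elements]

    @property
    def ntc_ids(self) -> list[str]:
        return [e.element_id for e in self.elements if e.is_ntc]

    @property
    def targeting_ids(self) -> list[str]:
        return [e.element_id for e in self.elements if not e.is_ntc]

    @property
    def genes(self) -> list[str]:
        """Unique targeted gene symbols in first-appearance order."""
        seen: dict[str, None] = {}
        for e in self.elements:
            if e.gene is not None and e.gene not in seen:
                seen[e.gene] = None
        return list(seen)

    def elements_of_gene(self, gene: str) -> list[str]:
        return list(self._gene_elements.get(gene, []))

    def to_frame(self) -> pd.DataFrame:
        """Library as a DataFrame (element_id, gene, is_ntc, protospacer)."""
        return pd.DataFrame(
            {
                "element_id": [e.element_id for e in self.elements],
                "gene": [e.gene for e in self.elements],
                "is_ntc": [e.is_ntc for e in self.elements],
                "protospacer": [e.protospacer for e in self.elements],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, species: str = "unspecified") -> "SgRNALibrary":
        elements = []
        for row in df.itertuples(index=False):
            gene = None if (pd.isna(row.gene) or row.gene == "") else str(row.gene)
            proto = getattr(row, "protospacer", None)
            if proto is not None and (pd.isna(proto) or proto == ""):
                proto = None
            elements.append(
                SgRNAElement(
                    element_id=str(row.element_id),
                    gene=gene,
                    is_ntc=bool(row.is_ntc),
                    protospacer=proto,
                )
            )
        return cls(elements=elements, species=species)
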