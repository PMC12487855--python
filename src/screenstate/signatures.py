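"""Gene signatures, meta-module sets, and GMT file handling.

The four glioblastoma tumor-cell states (MES-like, AC-like, OPC-like,
NPC-like) and the two cell-cycle phases (G1/S, G2/M) are each described by
a gene signature ("meta-module").  A :class:`MetaModuleSet` bundles all
six; any additional signature (e.g. a MEK-activation gene set) is scored
with the same machinery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .exceptions import ScreenStateError

__all__ = ["GeneSignature", "MetaModuleSet", "STATES", "CYCLING_MODULES", "read_gmt", "write_gmt"]

log = logging.getLogger(__name__)

# Fixed order; also the deterministic tie-break order for state assignment.
STATES = ("MES-like", "AC-like", "OPC-like", "NPC-like")
CYCLING_MODULES = ("G1S", "G2M")


@dataclass(frozen=True)
class GeneSignature:
    """A named, duplicate-free, non-empty gene list."""

    name: str
    genes: tuple[str, ...]

    def __init__(self, name: str, genes):
        genes = list(genes)
        if not genes:
            raise ScreenStateError(f"signature {name!r} has an empty gene list")
        deduped = list(dict.fromkeys(genes))
        if len(deduped) != len(genes):
            log.warning(
                "signature %r: %d duplicate gene(s) collapsed", name, len(genes) - len(deduped)
            )
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "genes", tuple(deduped))

    def __len__(self):
        return len(self.genes)


@dataclass
class MetaModuleSet:
    """The four state modules plus the two cycling modules."""

    state_modules: dict[str, GeneSignature]
    cycling_modules: dict[str, GeneSignature]

    def __post_init__(self):
        missing = [s for s in STATES if s not in self.state_modules]
        if missing:
            raise ScreenStateError(f"missing state module(s): {missing}")
        missing = [c for c in CYCLING_MODULES if c not in self.cycling_modules]
        if missing:
            raise ScreenStateError(f"missing cycling module(s): {missing}")

    def all_signatures(self) -> list[GeneSignature]:
        return [self.state_modules[s] for s in STATES] + [
            self.cycling_modules[c] for c in CYCLING_MODULES
        ]

    @classmethod
    def from_signatures(cls, signatures) -> "MetaModuleSet":
        """Build from a list of signatures named after the six modules."""
        by_name = {s.name: s for s in signatures}
        try:
            return cls(
                state_modules={s: by_name[s] for s in STATES},
                cycling_modules={c: by_name[c] for c in CYCLING_MODULES},
            )
        except KeyError as e:
            raise ScreenStateError(f"signature set lacks module {e.args[0]!r}") from None


def read_gmt(path) -> list[GeneSignature]:
    """Parse a GMT file (name TAB description TAB gene1 TAB gene2 ...).

    Duplicate genes within a set are collapsed (logged); a line with no
    genes is an error naming the set.
    """
    signatures = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3 or not any(g.strip() for g in parts[2:]):
                raise ScreenStateError(
                    f"{path}:{lineno}: gene set {parts[0]!r} has no genes"
                )
            genes = [g.strip() for g in parts[2:] if g.strip()]
            signatures.append(GeneSignature(name=parts[0], genes=genes))
    if not signatures:
        log.warning("GMT file %s contained no gene sets", path)
    return signatures


def write_gmt(signatures, path, description: str = "") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sig in signatures:
            fh.write("\t".join([sig.name, description, *sig.genes]) + "\n")
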