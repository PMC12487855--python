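"""Cross-species integration of screen hits.

Two screens (e.g. a human and a mouse CRISPRi screen of the same drug)
are integrated by requiring a gene to be significant *in both* with a
concordant effect direction after ortholog mapping.  No meta-analytic
pooling is performed: a conserved hit is an intersection call, which is
deliberately conservative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .exceptions import AmbiguousMappingError, NoOverlapError, ScreenStateError

__all__ = ["OrthologMap", "ConservedHitSet", "map_orthologs", "conserved_hits", "consensus_signature"]


@dataclass
class OrthologMap:
    """Pairs of (species-A symbol, species-B symbol).

    One-to-many mappings are permitted but flagged in ``ambiguous``;
    exact duplicate pairs collapse to one.
    """

    pairs: list[tuple[str, str]]
    source: str = "unspecified"
    ambiguous: list[str] = field(init=False)

    def __post_init__(self):
        seen = {}
        for a, b in self.pairs:
            seen.setdefault((a, b), None)
        self.pairs = list(seen)
        amb = set()
        count_a: dict[str, int] = {}
        count_b: dict[str, int] = {}
        for a, b in self.pairs:
            count_a[a] = count_a.get(a, 0) + 1
            count_b[b] = count_b.get(b, 0) + 1
        for a, n in count_a.items():
            if n > 1:
                amb.add(a)
        for b, n in count_b.items():
            if n > 1:
                amb.add(b)
        self.ambiguous = sorted(amb)

    def __len__(self):
        return len(self.pairs)


def map_orthologs(genes_a, genes_b, explicit_map: OrthologMap | None = None) -> OrthologMap:
    """Build the ortholog pairing between two symbol lists.

    With an explicit map, restrict it to symbols observed on both sides and
    reject conflicting duplicates (a symbol mapped to two different
    partners).  Without one, pair symbols by case-insensitive equality —
    the usual human/mouse convention (SHOC2 vs Shoc2).  Unmatched symbols
    are recorded on the returned map as ``unmatched_a`` / ``unmatched_b``.
    """
    genes_a = list(genes_a)
    genes_b = list(genes_b)
    if not genes_a or not genes_b:
        raise ScreenStateError("gene symbol lists must be non-empty")

    if explicit_map is not None:
        set_a, set_b = set(genes_a), set(genes_b)
        restricted = [(a, b) for a, b in explicit_map.pairs if a in set_a and b in set_b]
        m = OrthologMap(restricted, source=explicit_map.source)
        if m.ambiguous:
            raise AmbiguousMappingError(
                f"explicit ortholog map has conflicting duplicates for: {m.ambiguous}"
            )
    else:
        by_fold_b: dict[str, list[str]] = {}
        for b in genes_b:
            by_fold_b.setdefault(b.casefold(), []).append(b)
        pairs = []
        for a in genes_a:
            for b in by_fold_b.get(a.casefold(), []):
                pairs.append((a, b))
        m = OrthologMap(pairs, source="case-insensitive symbol identity")

    matched_a = {a for a, _ in m.pairs}
    matched_b = {b for _, b in m.pairs}
    m.unmatched_a = sorted(set(genes_a) - matched_a)  # type: ignore[attr-defined]
    m.unmatched_b = sorted(set(genes_b) - matched_b)  # type: ignore[attr-defined]
    return m


@dataclass
class ConservedHitSet:
    """Genes significant with concordant sign in both screens.

    ``provenance`` holds, per ortholog pair considered, both screens'
    scores and q-values and the call it received (including discordant
    pairs, which are excluded from the hit lists but not hidden).
    """

    kind: str
    alpha: float
    sensitizing: list[str]
    resistance: list[str]
    provenance: pd.DataFrame

    def __repr__(self):
        return (
            f"ConservedHitSet(kind={self.kind!r}, alpha={self.alpha}, "
            f"{len(self.sensitizing)} sensitizing, {len(self.resistance)} resistance)"
        )


def _provenance(table_a, table_b, ortholog_map, alpha):
    if len(ortholog_map) == 0:
        raise NoOverlapError("ortholog map is empty: screens share no genes")
    rows = []
    for a, b in ortholog_map.pairs:
        if a not in table_a.index or b not in table_b.index:
            continue
        ra, rb = table_a.loc[a], table_b.loc[b]
        sig = (ra["q_value"] < alpha) and (rb["q_value"] < alpha)
        concordant = ra["score"] * rb["score"] > 0
        if not sig:
            call = "not_significant"
        elif not concordant:
            call = "discordant"
        elif ra["score"] < 0:
            call = "sensitizing"
        else:
            call = "resistance"
        rows.append(
            {
                "gene_a": a,
                "gene_b": b,
                "score_a": ra["score"],
                "q_a": ra["q_value"],
                "score_b": rb["score"],
                "q_b": rb["q_value"],
                "call": call,
            }
        )
    if not rows:
        raise NoOverlapError("no ortholog pair is present in both score tables")
    return pd.DataFrame(rows)


def conserved_hits(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    ortholog_map: OrthologMap,
    kind: str = "rho",
    alpha: float = 0.05,
) -> ConservedHitSet:
    """Intersect hit calls across two screens.

    A pair is conserved-sensitizing iff q < alpha and score < 0 in both
    screens; conserved-resistance iff q < alpha and score > 0 in both.
    Pairs significant in both but with opposite signs are listed in the
    provenance as discordant and never called hits.
    """
    prov = _provenance(table_a, table_b, ortholog_map, alpha)
    return ConservedHitSet(
        kind=kind,
        alpha=alpha,
        sensitizing=sorted(prov.loc[prov["call"] == "sensitizing", "gene_a"]),
        resistance=sorted(prov.loc[prov["call"] == "resistance", "gene_a"]),
        provenance=prov,
    )


def consensus_signature(
    growth_a: pd.DataFrame,
    growth_b: pd.DataFrame,
    ortholog_map: OrthologMap,
    alpha: float = 0.05,
) -> list[str]:
    """Genes required for growth in both screens (growth-phenotype q < alpha
    and score < 0 in each), sorted by mean score across the two screens
    (most depleted first).  This is the consensus essential/cell-cycle-style
    signature construction."""
    prov = _provenance(growth_a, growth_b, ortholog_map, alpha)
    req = prov[prov["call"] == "sensitizing"].copy()
    req["mean_score"] = (req["score_a"] + req["score_b"]) / 2.0
    req = req.sort_values(["mean_score", "gene_a"], kind="stable")
    return list(req["gene_a"])
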