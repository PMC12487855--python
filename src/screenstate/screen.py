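"""Pooled CRISPRi screen phenotype scoring.

Phenotypes
----------
Three per-element phenotypes are computed from a counts table with T0
(pre-treatment), vehicle, and drug conditions, following the
gamma/tau/rho convention of pooled-screen analysis:

* gamma (growth):      log2(vehicle / T0), NTC-median-centered, divided by
                       the number of population doublings in vehicle;
* tau   (drug):        log2(drug / T0), centered, divided by the doublings
                       under drug;
* rho   (drug/growth): log2(drug / vehicle), centered, divided by the
                       doublings under drug.  rho isolates the drug-gene
                       interaction from the growth effect.

Counts are converted to relative abundance with a pseudocount before the
ratio — element i in a sample contributes (count_i + pc) / (total + pc * n)
— so ratios are invariant to sequencing depth.  Centering subtracts the
median ratio of the non-targeting controls (NTCs); standardized phenotypes
additionally divide by the NTC phenotype standard deviation.

Gene scores are the mean of the top-k elements per gene ranked by absolute
phenotype (sign preserved, ties broken by element id); significance comes
from a Mann-Whitney U test of each gene's elements against the NTC
distribution, with Benjamini-Hochberg FDR across genes.  A per-element
Wald test across replicates is additionally available when the design has
two or more replicates, matching how multi-replicate screens are tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .counts import CountTable, downsample_counts
from .exceptions import (
    InsufficientControlsError,
    MissingConditionError,
    ScreenStateError,
)
from .library import SgRNALibrary
from .stats import adjust_fdr, mannwhitney_vs_ntc, wald_test_replicates

__all__ = [
    "ScreenConfig",
    "ScreenModel",
    "ScreenResults",
    "HitSet",
    "compute_log2_ratio",
    "center_by_ntc",
    "gene_scores_topk",
    "call_hits",
]

KINDS = ("gamma", "tau", "rho")
# (numerator condition, denominator condition) per phenotype kind
_KIND_CONDITIONS = {
    "gamma": ("vehicle", "T0"),
    "tau": ("drug", "T0"),
    "rho": ("drug", "vehicle"),
}
_REPRESENTATIONS = ("raw", "centered", "phenotype", "standardized")


@dataclass
class ScreenConfig:
    """Scoring parameters.

    doublings maps each phenotype kind to the population-doubling count it
    is normalized by: gamma by the vehicle-arm doublings, tau and rho by
    the drug-arm doublings.
    """

    doublings: dict[str, float] = field(
        default_factory=lambda: {"gamma": 10.0, "tau": 5.0, "rho": 5.0}
    )
    pseudocount: float = 1.0
    target_depth: int | None = None
    alpha: float = 0.05
    top_k: int = 3

    def __post_init__(self):
        for kind, d in self.doublings.items():
            if kind not in KINDS:
                raise ScreenStateError(f"unknown phenotype kind {kind!r}")
            if not d > 0:
                raise ScreenStateError(f"doublings for {kind} must be > 0, got {d}")
        if self.pseudocount < 0:
            raise ScreenStateError("pseudocount must be nonnegative")
        if not 0 < self.alpha < 1:
            raise ScreenStateError("alpha must be in (0, 1)")
        if self.top_k < 1:
            raise ScreenStateError("top_k must be >= 1")


def compute_log2_ratio(numerator_counts, denominator_counts, pseudocount: float) -> np.ndarray:
    """Element-wise log2 ratio of relative abundances with a pseudocount.

    Each vector is converted to relative abundance as
    (count + pc) / (total + pc * n) with total the raw column sum, then the
    log2 of the element-wise quotient is returned.  With pc = 0 all counts
    must be positive.
    """
    num = np.asarray(numerator_counts, dtype=float)
    den = np.asarray(denominator_counts, dtype=float)
    if num.shape != den.shape or num.ndim != 1:
        raise ScreenStateError("count vectors must be 1-D and of equal length")
    if (num < 0).any() or (den < 0).any():
        raise ScreenStateError("counts must be nonnegative")
    if pseudocount == 0 and ((num == 0).any() or (den == 0).any()):
        raise ScreenStateError("zero count with pseudocount 0 gives an undefined log ratio")
    n = num.size
    rel_num = (num + pseudocount) / (num.sum() + pseudocount * n)
    rel_den = (den + pseudocount) / (den.sum() + pseudocount * n)
    return np.log2(rel_num / rel_den)


def center_by_ntc(ratios: pd.Series, library: SgRNALibrary) -> pd.Series:
    """Subtract the median non-targeting-control ratio.

    After centering, the median NTC ratio is exactly 0 (up to the usual
    even-count median convention).
    """
    ntc_present = [i for i in library.ntc_ids if i in ratios.index]
    if len(ntc_present) < 2:
        raise InsufficientControlsError(
            f"centering needs >= 2 NTC elements in the data, found {len(ntc_present)}"
        )
    return ratios - float(ratios.loc[ntc_present].median())


def gene_scores_topk(
    phenotypes: pd.Series,
    library: SgRNALibrary,
    top_k: int = 3,
) -> pd.Series:
    """Gene score = mean of the top-k elements by |phenotype|, sign kept.

    Genes with fewer than ``top_k`` elements use all of them.  Ties in
    absolute phenotype at the cut are broken by element id (lexicographic),
    making the score deterministic.  NTC elements never contribute.
    """
    if top_k < 1:
        raise ScreenStateError("top_k must be >= 1")
    rows = []
    for e in library.elements:
        if e.is_ntc or e.element_id not in phenotypes.index:
            continue
        v = float(phenotypes.loc[e.element_id])
        rows.append((e.gene, e.element_id, v, abs(v)))
    if not rows:
        return pd.Series(dtype=float, name="score")
    df = pd.DataFrame(rows, columns=["gene", "element_id", "value", "absval"])
    df = df.sort_values(["absval", "element_id"], ascending=[False, True], kind="stable")
    top = df.groupby("gene", sort=False).head(top_k)
    scores = top.groupby("gene", sort=False)["value"].mean()
    return scores.rename("score")


@dataclass
class HitSet:
    """Significant genes split by effect direction at a given FDR."""

    kind: str
    alpha: float
    sensitizing: list[str]
    resistance: list[str]
    indeterminate: list[str]

    def __repr__(self):
        return (
            f"HitSet(kind={self.kind!r}, alpha={self.alpha}, "
            f"{len(self.sensitizing)} sensitizing, {len(self.resistance)} resistance, "
            f"{len(self.indeterminate)} indeterminate)"
        )


def call_hits(gene_table: pd.DataFrame, alpha: float, kind: str = "?") -> HitSet:
    """Split genes with q < alpha by score sign.

    Negative score = sensitizing (depleted under the numerator condition),
    positive = resistance.  An exactly-zero significant score is reported
    separately as indeterminate rather than silently assigned a direction.
    """
    sig = gene_table[gene_table["q_value"] < alpha]
    return HitSet(
        kind=kind,
        alpha=alpha,
        sensitizing=sorted(sig.index[sig["score"] < 0]),
        resistance=sorted(sig.index[sig["score"] > 0]),
        indeterminate=sorted(sig.index[sig["score"] == 0]),
    )


class ScreenModel:
    """Phenotype-scoring model for one pooled screen.

    Parameters
    ----------
    table : CountTable
        Raw counts; rows are aligned to the library (absent elements are
        treated as count 0).
    library : SgRNALibrary
    config : ScreenConfig, optional

    ``fit`` performs optional depth equalization, computes the per-element
    gamma/tau/rho representations, gene-level top-k scores with
    Mann-Whitney p-values and BH q-values, and (when the design has >= 2
    replicates of the numerator condition) per-element Wald p-values.
    """

    def __init__(self, table: CountTable, library: SgRNALibrary, config: ScreenConfig | None = None):
        self.library = library
        self.config = config or ScreenConfig()
        self.table = table.aligned_to(library)
        if len(library.ntc_ids) < 2:
            raise InsufficientControlsError(
                "screen scoring requires >= 2 non-targeting control elements"
            )

    @classmethod
    def from_files(cls, counts_path, samples_path, library_path, config=None) -> "ScreenModel":
        from .io import read_count_table, read_library

        library = read_library(library_path)
        table = read_count_table(counts_path, samples_path, library=library)
        return cls(table, library, config)

    # -- internal helpers -------------------------------------------------

    def _require_conditions(self, kinds) -> None:
        present = self.table.conditions_present()
        needed = set()
        for kind in kinds:
            needed.update(_KIND_CONDITIONS[kind])
        missing = needed - present
        if missing:
            raise MissingConditionError(
                f"count table lacks condition(s) {sorted(missing)} required for "
                f"{sorted(kinds)}"
            )

    def _element_phenotypes(self, table: CountTable, kinds) -> pd.DataFrame:
        pc = self.config.pseudocount
        idx = pd.Index(self.library.element_ids, name="element_id")
        ntc_mask = pd.Series([self.library[i].is_ntc for i in idx], index=idx)
        out = pd.DataFrame(
            {
                "gene": [self.library[i].gene for i in idx],
                "is_ntc": ntc_mask,
            },
            index=idx,
        )
        for kind in kinds:
            num_cond, den_cond = _KIND_CONDITIONS[kind]
            num = table.condition_sum(num_cond).loc[idx].to_numpy()
            den = table.condition_sum(den_cond).loc[idx].to_numpy()
            raw = pd.Series(compute_log2_ratio(num, den, pc), index=idx)
            centered = center_by_ntc(raw, self.library)
            d = self.config.doublings[kind]
            phenotype = centered / d
            ntc_sd = float(phenotype[ntc_mask].std(ddof=1))
            if ntc_sd == 0:
                standardized = pd.Series(np.nan, index=idx)
            else:
                standardized = phenotype / ntc_sd
            out[f"{kind}_raw"] = raw
            out[f"{kind}_centered"] = centered
            out[f"{kind}_phenotype"] = phenotype
            out[f"{kind}_standardized"] = standardized
        return out

    def _replicate_ratios(self, table: CountTable, kind: str) -> pd.DataFrame | None:
        """Replicate-resolved log2 ratios (replicates x elements) for the
        Wald test; None when the numerator condition has < 2 replicates.

        A numerator replicate is paired with the denominator sample of the
        same replicate id when one exists, otherwise with the summed
        denominator pseudo-sample.
        """
        num_cond, den_cond = _KIND_CONDITIONS[kind]
        num_samples = table.samples_of(num_cond)
        if len(num_samples) < 2:
            return None
        pc = self.config.pseudocount
        idx = pd.Index(self.library.element_ids, name="element_id")
        den_by_rep = {
            table.sample_meta.loc[s, "replicate"]: s for s in table.samples_of(den_cond)
        }
        den_sum = table.condition_sum(den_cond).loc[idx].to_numpy()
        rows = []
        for s in num_samples:
            rep = table.sample_meta.loc[s, "replicate"]
            if rep in den_by_rep:
                den = table.counts[den_by_rep[rep]].loc[idx].to_numpy()
            else:
                den = den_sum
            num = table.counts[s].loc[idx].to_numpy()
            rows.append(compute_log2_ratio(num, den, pc))
        return pd.DataFrame(rows, columns=idx, index=num_samples)

    # -- fitting -----------------------------------------------------------

    def fit(self, kinds=KINDS, seed: int | None = None) -> "ScreenResults":
        """Score the screen.

        Parameters
        ----------
        kinds : iterable of {"gamma", "tau", "rho"}
            Phenotypes to compute; each must have its conditions present.
        seed : int, optional
            Required when ``config.target_depth`` asks for downsampling.
        """
        kinds = tuple(kinds)
        for kind in kinds:
            if kind not in KINDS:
                raise ScreenStateError(f"unknown phenotype kind {kind!r}")
        self._require_conditions(kinds)
        table = self.table
        if self.config.target_depth is not None:
            if seed is None:
                raise ScreenStateError("downsampling requires a seed")
            table = downsample_counts(table, self.config.target_depth, seed)

        phenos = self._element_phenotypes(table, kinds)
        ntc_mask = phenos["is_ntc"].to_numpy()

        gene_tables: dict[str, pd.DataFrame] = {}
        wald: dict[str, pd.Series] = {}
        for kind in kinds:
            values = phenos[f"{kind}_phenotype"]
            scores = gene_scores_topk(values, self.library, self.config.top_k)
            ntc_values = values[ntc_mask].to_numpy()
            vals_np = values.to_numpy()
            pos = {eid: i for i, eid in enumerate(values.index)}
            pvals, n_elem = [], []
            for gene in scores.index:
                elems = [pos[e] for e in self.library.elements_of_gene(gene) if e in pos]
                pvals.append(mannwhitney_vs_ntc(vals_np[elems], ntc_values))
                n_elem.append(len(elems))
            gt = pd.DataFrame(
                {
                    "score": scores,
                    "p_value": pvals,
                    "q_value": adjust_fdr(pvals),
                    "n_elements": n_elem,
                },
                index=scores.index,
            )
            gt["direction"] = np.sign(gt["score"]).astype(int)
            gene_tables[kind] = gt

            reps = self._replicate_ratios(table, kind)
            if reps is not None:
                p = wald_test_replicates(reps.to_numpy(), ntc_mask)
                wald[kind] = pd.Series(p, index=phenos.index, name=f"{kind}_wald_p")

        return ScreenResults(
            model=self,
            element_phenotypes=phenos,
            gene_scores=gene_tables,
            wald_pvalues=wald,
            kinds=kinds,
        )


class ScreenResults:
    """Fitted screen phenotypes and gene-level statistics.

    Attributes
    ----------
    element_phenotypes : DataFrame
        One row per element, columns ``{kind}_{raw|centered|phenotype|
        standardized}`` plus gene and is_ntc.
    gene_scores : dict kind -> DataFrame
        Indexed by gene with score, p_value, q_value, n_elements, direction.
    wald_pvalues : dict kind -> Series
        Per-element Wald p-values where the design permitted (>= 2
        replicates of the numerator condition).
    """

    def __init__(self, model, element_phenotypes, gene_scores, wald_pvalues, kinds):
        self.model = model
        self.element_phenotypes = element_phenotypes
        self.gene_scores = gene_scores
        self.wald_pvalues = wald_pvalues
        self.kinds = kinds

    @property
    def config(self) -> ScreenConfig:
        return self.model.config

    def hits(self, kind: str, alpha: float | None = None) -> HitSet:
        if kind not in self.gene_scores:
            raise ScreenStateError(f"phenotype kind {kind!r} was not fitted")
        return call_hits(self.gene_scores[kind], alpha if alpha is not None else self.config.alpha, kind)

    def summary(self) -> str:
        lib = self.model.library
        lines = [
            "Pooled screen phenotype scoring",
            "=" * 47,
            f"species: {lib.species}   elements: {len(lib)} "
            f"({len(lib.ntc_ids)} NTC)   genes: {len(lib.genes)}",
            f"pseudocount: {self.config.pseudocount}   top_k: {self.config.top_k}   "
            f"alpha: {self.config.alpha}",
        ]
        for kind in self.kinds:
            d = self.config.doublings[kind]
            hs = self.hits(kind)
            lines.append("-" * 47)
            lines.append(
                f"{kind}: doublings={d}   hits at q<{self.config.alpha}: "
                f"{len(hs.sensitizing)} sensitizing / {len(hs.resistance)} resistance"
            )
            gt = self.gene_scores[kind]
            top = gt.reindex(gt["q_value"].sort_values(kind="stable").index).head(5)
            for gene, row in top.iterrows():
                lines.append(
                    f"  {gene:<12} score={row['score']:+.3f}  p={row['p_value']:.3g}  "
                    f"q={row['q_value']:.3g}  n={int(row['n_elements'])}"
                )
        return "\n".join(lines)
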