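"""Synthetic screens and cell populations with known ground truth.

Screen generator
----------------
Growth is exponential with per-doubling log2 fitness offsets.  Element i
of gene g starts at abundance a_i ~ LogNormal(0, 0.5) (library skew) and
after d_c population doublings in condition c has expected relative
abundance

    a_i * 2 ** (d_c * (1 + k_i * phi_c)),

where phi_c is the gene's growth effect in vehicle, growth plus drug
effect under drug, and 0 for non-targeting controls, and k_i is the
knockdown efficiency.  Proportions are renormalized per sample and counts
drawn negative-binomially (variance = mean + dispersion * mean**2) with
mean depth * n_elements * proportion, independently per replicate.
Everything is deterministic under the seed.

Cell-population generator
-------------------------
Works directly on log-normalized-scale values (no UMI sampling): baseline
expression is |Normal(0, noise_sd)| per gene per cell; a cell's true-state
signature genes gain +effect_size; planted cycling cells gain
+effect_size on one of the two cell-cycle modules; optional extra
signatures (e.g. a MEK-activation-like set) can be shifted per state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .counts import CountTable
from .exceptions import ScreenStateError
from .library import SgRNAElement, SgRNALibrary
from .signatures import CYCLING_MODULES, STATES, GeneSignature, MetaModuleSet

__all__ = [
    "EffectSpec",
    "SimulatedScreen",
    "SyntheticCellPopulation",
    "simulate_library",
    "simulate_screen",
    "simulate_cells",
    "synthetic_meta_modules",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class EffectSpec:
    """Ground-truth per-gene effects.

    growth_effect is the per-doubling log2 fitness offset relative to NTC
    (the true gamma); drug_effect is the additional offset under drug (the
    true rho); knockdown scales both, in (0, 1].
    """

    gene: str
    growth_effect: float = 0.0
    drug_effect: float = 0.0
    knockdown: float = 1.0

    def __post_init__(self):
        if not (math.isfinite(self.growth_effect) and math.isfinite(self.drug_effect)):
            raise ScreenStateError(f"effects for {self.gene!r} must be finite")
        if not 0 < self.knockdown <= 1:
            raise ScreenStateError(f"knockdown for {self.gene!r} must be in (0, 1]")


def simulate_library(
    n_genes: int,
    sgrnas_per_gene: int,
    n_ntc: int,
    seed: int,
    species: str = "synthetic",
) -> SgRNALibrary:
    """Generate a library of n_genes * sgrnas_per_gene targeting elements
    plus n_ntc non-targeting elements with unique ids and random
    protospacers (deterministic under seed)."""
    if n_genes < 1 or sgrnas_per_gene < 1:
        raise ScreenStateError("n_genes and sgrnas_per_gene must be >= 1")
    if n_ntc < 0:
        raise ScreenStateError("n_ntc must be >= 0")
    rng = np.random.default_rng(seed)
    width = max(5, len(str(n_genes)))
    elements = []
    for g in range(n_genes):
        gene = f"GENE{g + 1:0{width}d}"
        for s in range(sgrnas_per_gene):
            proto = "".join(rng.choice(_BASES, size=20))
            elements.append(
                SgRNAElement(f"{gene}_sg{s + 1}", gene=gene, is_ntc=False, protospacer=proto)
            )
    for j in range(n_ntc):
        proto = "".join(rng.choice(_BASES, size=20))
        elements.append(
            SgRNAElement(f"NTC_{j + 1:05d}", gene=None, is_ntc=True, protospacer=proto)
        )
    return SgRNALibrary(elements=elements, species=species)


@dataclass
class SimulatedScreen:
    """A simulated screen: counts plus the ground truth that produced them."""

    library: SgRNALibrary
    counts: CountTable
    effects: list[EffectSpec]
    seed: int
    depth: float
    dispersion: float
    doublings: dict[str, float]
    effect_by_gene: dict[str, EffectSpec] = field(init=False)

    def __post_init__(self):
        self.effect_by_gene = {e.gene: e for e in self.effects}

    def _phi(self, element: SgRNAElement, condition: str) -> float:
        """Per-doubling fitness offset k * phi of an element in a condition."""
        if element.is_ntc:
            return 0.0
        eff = self.effect_by_gene.get(element.gene)
        if eff is None:
            return 0.0
        phi = eff.growth_effect
        if condition == "drug":
            phi += eff.drug_effect
        return eff.knockdown * phi

    def expected_centered_log2_ratio(self, kind: str) -> pd.Series:
        """Analytic NTC-relative log2 fold change per element.

        gamma-kind: d_vehicle * k * growth; tau-kind: d_drug * k *
        (growth + drug); rho-kind: their difference.  This is what the
        empirical centered ratios converge to as depth grows and
        dispersion vanishes.
        """
        num_cond, den_cond = {
            "gamma": ("vehicle", "T0"),
            "tau": ("drug", "T0"),
            "rho": ("drug", "vehicle"),
        }[kind]
        vals = {}
        for e in self.library.elements:
            vals[e.element_id] = self.doublings[num_cond] * self._phi(e, num_cond) - self.doublings[
                den_cond
            ] * self._phi(e, den_cond)
        return pd.Series(vals, name=f"expected_{kind}")

    def truth_frame(self) -> pd.DataFrame:
        """Per-gene ground truth (growth_effect, drug_effect, knockdown)."""
        return pd.DataFrame(
            {
                "gene": [e.gene for e in self.effects],
                "growth_effect": [e.growth_effect for e in self.effects],
                "drug_effect": [e.drug_effect for e in self.effects],
                "knockdown": [e.knockdown for e in self.effects],
            }
        ).set_index("gene")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with var = mean + dispersion * mean**2 (Poisson at 0)."""
    if dispersion == 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_screen(
    library: SgRNALibrary,
    effects: list[EffectSpec],
    doublings: dict[str, float] | None = None,
    replicates: int = 2,
    depth: float = 500.0,
    dispersion: float = 0.05,
    seed: int = 0,
    abundance_sigma: float = 0.5,
) -> SimulatedScreen:
    """Simulate counts for a pooled screen under planted gene effects.

    ``doublings`` defaults to {"T0": 0, "vehicle": 10, "drug": 5}, the
    vehicle/drug doubling numbers of a two-arm drug-modifier screen.
    Genes without an EffectSpec default to zero effects.
    """
    if doublings is None:
        doublings = {"T0": 0.0, "vehicle": 10.0, "drug": 5.0}
    if doublings.get("T0", None) != 0:
        raise ScreenStateError("doublings must include T0 = 0")
    for cond, d in doublings.items():
        if d < 0:
            raise ScreenStateError(f"negative doublings for {cond!r}")
    if depth <= 0:
        raise ScreenStateError("depth must be > 0")
    if dispersion < 0:
        raise ScreenStateError("dispersion must be >= 0")
    if replicates < 1:
        raise ScreenStateError("replicates must be >= 1")
    known = set(library.genes)
    for eff in effects:
        if eff.gene not in known:
            raise ScreenStateError(f"effect for unknown gene {eff.gene!r}")

    rng = np.random.default_rng(seed)
    n = len(library)
    a = rng.lognormal(mean=0.0, sigma=abundance_sigma, size=n)

    screen = SimulatedScreen.__new__(SimulatedScreen)  # need _phi before counts exist
    screen.library = library
    screen.effects = list(effects)
    screen.seed = seed
    screen.depth = depth
    screen.dispersion = dispersion
    screen.doublings = dict(doublings)
    screen.effect_by_gene = {e.gene: e for e in effects}

    cols, meta_rows = {}, []
    for cond in ("T0", "vehicle", "drug"):
        if cond not in doublings:
            continue
        d = doublings[cond]
        growth = np.array(
            [2.0 ** (d * (1.0 + screen._phi(e, cond))) for e in library.elements]
        )
        abundance = a * growth
        proportion = abundance / abundance.sum()
        mean = depth * n * proportion
        for r in range(1, replicates + 1):
            sample = f"{cond}_r{r}"
            cols[sample] = _nb_draw(rng, mean, dispersion)
            meta_rows.append({"sample": sample, "condition": cond, "replicate": f"r{r}"})

    counts = pd.DataFrame(cols, index=pd.Index(library.element_ids, name="element_id"))
    sample_meta = pd.DataFrame(meta_rows).set_index("sample")
    screen.counts = CountTable(counts=counts, sample_meta=sample_meta)
    return screen


# ---------------------------------------------------------------------------
# single-cell population
# ---------------------------------------------------------------------------


def synthetic_meta_modules(genes_per_module: int = 30) -> MetaModuleSet:
    """A synthetic stand-in meta-module set with disjoint made-up gene names
    (MESg001..., G1Sg001..., etc.); used wherever real curated modules are
    not supplied."""
    prefix = {
        "MES-like": "MES",
        "AC-like": "AC",
        "OPC-like": "OPC",
        "NPC-like": "NPC",
        "G1S": "G1S",
        "G2M": "G2M",
    }
    def sig(name):
        return GeneSignature(
            name, [f"{prefix[name]}g{i + 1:03d}" for i in range(genes_per_module)]
        )

    return MetaModuleSet(
        state_modules={s: sig(s) for s in STATES},
        cycling_modules={c: sig(c) for c in CYCLING_MODULES},
    )


@dataclass
class SyntheticCellPopulation:
    """Simulated cells with known state, cycling, and signature truth."""

    expression: pd.DataFrame
    true_state: pd.Series
    true_cycling: pd.Series
    signature_shift: dict[str, float]
    seed: int


def simulate_cells(
    n_per_state: dict[str, int],
    signatures: MetaModuleSet,
    effect_size: float = 1.0,
    noise_sd: float = 0.5,
    seed: int = 0,
    cycling_fraction: float = 0.2,
    n_background_genes: int = 2000,
    extra_signature: GeneSignature | None = None,
    extra_shift: dict[str, float] | None = None,
) -> SyntheticCellPopulation:
    """Simulate a log-normalized expression matrix with planted states.

    Each cell of state s gains +effect_size on s's module genes; a
    ``cycling_fraction`` of cells (chosen uniformly) gain +effect_size on
    one randomly chosen cell-cycle module.  ``extra_signature`` genes gain
    ``extra_shift[state]`` in cells of the listed states, emulating e.g. a
    MEK-activation shift confined to MES-like cells.
    """
    if effect_size < 0:
        raise ScreenStateError("effect_size must be >= 0")
    if noise_sd <= 0:
        raise ScreenStateError("noise_sd must be > 0")
    if not 0 <= cycling_fraction <= 1:
        raise ScreenStateError("cycling_fraction must be in [0, 1]")
    unknown = set(n_per_state) - set(STATES)
    if unknown:
        raise ScreenStateError(f"unknown state(s): {sorted(unknown)}")

    genes: list[str] = []
    for sig in signatures.all_signatures():
        genes.extend(g for g in sig.genes if g not in genes)
    if extra_signature is not None:
        genes.extend(g for g in extra_signature.genes if g not in genes)
    genes.extend(f"BGg{i + 1:05d}" for i in range(n_background_genes))

    states = [s for s in STATES for _ in range(n_per_state.get(s, 0))]
    n_cells = len(states)
    if n_cells == 0:
        raise ScreenStateError("population must contain at least one cell")
    cell_ids = [f"cell{i + 1:05d}" for i in range(n_cells)]

    rng = np.random.default_rng(seed)
    expr = np.abs(rng.normal(0.0, noise_sd, size=(n_cells, len(genes))))
    gene_pos = {g: j for j, g in enumerate(genes)}

    for s in STATES:
        idx_cells = [i for i, st in enumerate(states) if st == s]
        if not idx_cells:
            continue
        cols = [gene_pos[g] for g in signatures.state_modules[s].genes]
        expr[np.ix_(idx_cells, cols)] += effect_size

    cycling = rng.random(n_cells) < cycling_fraction
    cyc_cols = {
        c: [gene_pos[g] for g in signatures.cycling_modules[c].genes]
        for c in CYCLING_MODULES
    }
    which = rng.integers(0, 2, size=n_cells)
    for i in np.flatnonzero(cycling):
        expr[i, cyc_cols[CYCLING_MODULES[which[i]]]] += effect_size

    shift = dict(extra_shift or {})
    if extra_signature is not None and shift:
        cols = [gene_pos[g] for g in extra_signature.genes]
        for s, delta in shift.items():
            idx_cells = [i for i, st in enumerate(states) if st == s]
            if idx_cells:
                expr[np.ix_(idx_cells, cols)] += delta

    expression = pd.DataFrame(expr, index=pd.Index(cell_ids, name="cell_id"), columns=genes)
    return SyntheticCellPopulation(
        expression=expression,
        true_state=pd.Series(states, index=expression.index, name="true_state"),
        true_cycling=pd.Series(cycling, index=expression.index, name="true_cycling"),
        signature_shift=shift,
        seed=seed,
    )
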