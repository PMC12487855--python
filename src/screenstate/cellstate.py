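"""Single-cell tumor state and signature scoring.

Module scores follow the bin-matched control-gene convention common in
tumor single-cell work: genes are ranked by mean expression across cells
and split into equal-size bins; each signature gene contributes control
genes sampled from its own bin; a cell's score is its mean expression of
the signature genes minus its mean expression of the pooled control
genes.  Subtracting bin-matched controls cancels per-cell depth and
complexity effects exactly — adding any constant to a cell's whole row
leaves its score unchanged.

State assignment is the argmax of the four state-module scores (fixed
tie-break order MES-like, AC-like, OPC-like, NPC-like); a cell is called
cycling when the larger of its G1/S and G2/M scores exceeds a threshold
(default 0.1).  Group comparisons of any per-cell score use the shared
two-sided Wilcoxon rank-sum engine.

Expression is assumed log-normalized; no normalization happens here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import MissingGenesError, ScreenStateError
from .signatures import CYCLING_MODULES, STATES, GeneSignature, MetaModuleSet
from .stats import rank_test

__all__ = [
    "module_score",
    "assign_state",
    "assign_cycling",
    "state_proportions",
    "compare_groups_ranktest",
    "CellStateModel",
    "CellStateResults",
]


def _expression_bins(gene_means: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-size expression bins by mean expression rank.

    Stable argsort so that tied means keep input order; bin sizes differ
    by at most one.  Returns the bin index of every gene.
    """
    order = np.argsort(gene_means, kind="stable")
    bins = np.empty(gene_means.size, dtype=np.int64)
    for b, chunk in enumerate(np.array_split(order, n_bins)):
        bins[chunk] = b
    return bins


def module_score(
    expression: pd.DataFrame,
    signature: GeneSignature,
    n_bins: int = 25,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Per-cell signature score against bin-matched control genes.

    Parameters
    ----------
    expression : DataFrame, cells x genes (log-normalized scale).
    signature : GeneSignature
        Genes absent from the matrix are dropped; if none remain a
        :class:`MissingGenesError` is raised listing the absentees.
    n_bins, n_ctrl : binning and per-signature-gene control-draw sizes.
    seed : controls the control-gene sampling; fixed seed gives
        bit-identical scores.
    """
    if n_bins < 1 or n_ctrl < 1:
        raise ScreenStateError("n_bins and n_ctrl must be >= 1")
    gene_index = expression.columns
    present = [g for g in signature.genes if g in gene_index]
    if not present:
        raise MissingGenesError(signature.name, list(signature.genes))

    values = expression.to_numpy(dtype=float)
    gene_pos = {g: j for j, g in enumerate(gene_index)}
    means = values.mean(axis=0)
    bins = _expression_bins(means, n_bins)
    members_of_bin = {b: np.flatnonzero(bins == b) for b in np.unique(bins)}

    rng = np.random.default_rng(seed)
    sig_idx = np.array([gene_pos[g] for g in present])
    ctrl_idx = []
    for j in sig_idx:
        pool = members_of_bin[bins[j]]
        replace = pool.size < n_ctrl
        ctrl_idx.append(rng.choice(pool, size=n_ctrl, replace=replace))
    ctrl_idx = np.concatenate(ctrl_idx)

    score = values[:, sig_idx].mean(axis=1) - values[:, ctrl_idx].mean(axis=1)
    return pd.Series(score, index=expression.index, name=signature.name)


def assign_state(scores: pd.DataFrame) -> pd.Series:
    """Argmax state per cell over the four state-module score columns.

    Ties are broken in the fixed order MES-like, AC-like, OPC-like,
    NPC-like, so assignment is deterministic.
    """
    missing = [s for s in STATES if s not in scores.columns]
    if missing:
        raise ScreenStateError(f"missing state score column(s): {missing}")
    mat = scores[list(STATES)].to_numpy(dtype=float)
    if not np.isfinite(mat).all():
        raise ScreenStateError("state scores must be finite")
    # np.argmax returns the first maximum, i.e. the tie-break order above
    labels = np.array(STATES, dtype=object)[np.argmax(mat, axis=1)]
    return pd.Series(labels, index=scores.index, name="state")


def assign_cycling(g1s_score, g2m_score, threshold: float = 0.1):
    """Cycling iff max(G1/S score, G2/M score) > threshold.

    Accepts scalars or aligned vectors; returns the same shape.
    """
    g1s = np.asarray(g1s_score, dtype=float)
    g2m = np.asarray(g2m_score, dtype=float)
    if not (np.isfinite(g1s).all() and np.isfinite(g2m).all()):
        raise ScreenStateError("cycling scores must be finite")
    out = np.maximum(g1s, g2m) > threshold
    if out.ndim == 0:
        return bool(out)
    return out


def state_proportions(states: pd.Series, group_labels: pd.Series) -> pd.DataFrame:
    """Per-group fraction of cells in each state; rows sum to 1.

    Empty groups are simply absent from the result (there is nothing to
    normalize).  States never observed get fraction 0.
    """
    if not states.index.equals(group_labels.index):
        group_labels = group_labels.reindex(states.index)
        if group_labels.isna().any():
            raise ScreenStateError("group labels must cover all cells")
    df = pd.DataFrame({"state": states, "group": group_labels})
    frac = (
        df.groupby("group", observed=True)["state"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
    )
    return frac.reindex(columns=list(STATES), fill_value=0.0)


def compare_groups_ranktest(scores: pd.Series, groups: pd.Series) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum comparison of a per-cell score between
    the two groups defined by a binary label vector.

    Returns (U statistic of the first group, p-value).
    """
    groups = groups.reindex(scores.index)
    levels = pd.unique(groups.dropna())
    if len(levels) != 2:
        raise ScreenStateError(f"need exactly 2 groups, got {len(levels)}")
    x = scores[groups == levels[0]].to_numpy()
    y = scores[groups == levels[1]].to_numpy()
    return rank_test(x, y, alternative="two-sided")


class CellStateModel:
    """Meta-module scoring model for a cells x genes expression matrix.

    Parameters
    ----------
    expression : DataFrame
        Cells x genes, log-normalized scale (rows = cell ids, columns =
        gene symbols).
    modules : MetaModuleSet
        The four state signatures and two cycling signatures.
    n_bins, n_ctrl : module-score parameters (defaults 25 and 100).
    cycling_threshold : threshold on max(G1/S, G2/M) score.
    """

    def __init__(
        self,
        expression: pd.DataFrame,
        modules: MetaModuleSet,
        n_bins: int = 25,
        n_ctrl: int = 100,
        cycling_threshold: float = 0.1,
    ):
        if expression.shape[0] == 0 or expression.shape[1] == 0:
            raise ScreenStateError("expression matrix is empty")
        self.expression = expression
        self.modules = modules
        self.n_bins = n_bins
        self.n_ctrl = n_ctrl
        self.cycling_threshold = cycling_threshold

    def fit(self, seed: int = 0) -> "CellStateResults":
        """Score all six modules, assign states, and call cycling cells."""
        scores = pd.DataFrame(index=self.expression.index)
        for sig in self.modules.all_signatures():
            scores[sig.name] = module_score(
                self.expression, sig, self.n_bins, self.n_ctrl, seed=seed
            )
        states = assign_state(scores)
        cycling = pd.Series(
            assign_cycling(
                scores[CYCLING_MODULES[0]].to_numpy(),
                scores[CYCLING_MODULES[1]].to_numpy(),
                self.cycling_threshold,
            ),
            index=scores.index,
            name="cycling",
        )
        return CellStateResults(self, scores, states, cycling, seed)


class CellStateResults:
    """Per-cell module scores, assigned states, and cycling calls."""

    def __init__(self, model, module_scores, states, cycling, seed):
        self.model = model
        self.module_scores = module_scores
        self.states = states
        self.cycling = cycling
        self.seed = seed
        self.signature_scores: dict[str, pd.Series] = {}

    def score_signature(self, signature: GeneSignature, seed: int | None = None) -> pd.Series:
        """Score an arbitrary signature (e.g. MEK activation) with the same
        binning parameters; cached by signature name."""
        s = module_score(
            self.model.expression,
            signature,
            self.model.n_bins,
            self.model.n_ctrl,
            seed=self.seed if seed is None else seed,
        )
        self.signature_scores[signature.name] = s
        return s

    def proportions(self, group_labels: pd.Series | None = None) -> pd.DataFrame:
        if group_labels is None:
            group_labels = pd.Series("all", index=self.states.index)
        return state_proportions(self.states, group_labels)

    def compare(self, score_name: str, groups: pd.Series) -> tuple[float, float]:
        """Rank-test a module or signature score between two cell groups."""
        if score_name in self.module_scores.columns:
            scores = self.module_scores[score_name]
        elif score_name in self.signature_scores:
            scores = self.signature_scores[score_name]
        else:
            raise ScreenStateError(f"unknown score {score_name!r}")
        return compare_groups_ranktest(scores, groups)

    def to_frame(self) -> pd.DataFrame:
        """Per-cell table: six module scores, any signature scores, state,
        cycling flag."""
        out = self.module_scores.copy()
        for name, s in self.signature_scores.items():
            out[name] = s
        out["state"] = self.states
        out["cycling"] = self.cycling
        return out

    def summary(self) -> str:
        frac = self.states.value_counts(normalize=True).reindex(list(STATES), fill_value=0.0)
        lines = [
            "Cell-state scoring",
            "=" * 47,
            f"cells: {len(self.states)}   genes: {self.model.expression.shape[1]}   "
            f"n_bins: {self.model.n_bins}   n_ctrl: {self.model.n_ctrl}   seed: {self.seed}",
            f"cycling: {self.cycling.mean():.1%} "
            f"(threshold {self.model.cycling_threshold})",
            "state fractions:",
        ]
        for state in STATES:
            lines.append(f"  {state:<9} {frac[state]:.3f}")
        return "\n".join(lines)
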