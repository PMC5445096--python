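"""Two-phase selection of small descriptor subsets from large tables.

The search is split into two sequential phases so the wrapper never faces the
full descriptor space. Phase 1 is a cheap filter: drop near-constant columns,
collapse redundant pairs (|Spearman| above a cutoff, keeping the member better
rank-correlated with the target) and keep the top-M columns by |Spearman| to
the target. Phase 2 is a wrapper: repeated greedy forward selection scored by
k-fold cross-validated relative absolute error (RAE) of a fast internal
learner, each restart reshuffling candidate order and fold assignment from a
derived seed. The result is a list of candidate subsets ranked by internal
RAE, from which callers typically keep the lowest-RAE few.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .chemio import DescriptorTable

__all__ = [
    "SelectionConfig",
    "DescriptorSubset",
    "phase1_filter",
    "phase2_wrapper",
    "select_top_subsets",
    "select_descriptors",
]


@dataclass(frozen=True)
class SelectionConfig:
    variance_floor: float = 1e-8
    redundancy_cutoff: float = 0.95   # rho_max on |Spearman| between descriptors
    prefilter_size: int = 200         # M: columns surviving phase 1
    n_subsets: int = 25               # N: wrapper restarts / candidate subsets
    max_subset_size: int = 15
    improvement_floor: float = 0.01   # minimum relative RAE improvement per step
    cv_folds: int = 5
    internal_learner: str = "linear"  # {"linear", "stump"}
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subsets < 1:
            raise ValueError("n_subsets must be >= 1")
        if not (0 < self.redundancy_cutoff <= 1):
            raise ValueError("redundancy cutoff must be in (0, 1]")
        if self.cv_folds < 2:
            raise ValueError("need at least 2 CV folds")


@dataclass
class DescriptorSubset:
    """A named, ordered list of descriptor names with provenance."""

    name: str
    descriptors: list[str]
    provenance: str = "selected"      # {"selected", "learned", "combined"}
    rae: Optional[float] = None
    parents: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.descriptors:
            raise ValueError("descriptor subset cannot be empty")
        if len(set(self.descriptors)) != len(self.descriptors):
            raise ValueError(f"duplicate names in subset {self.name!r}")
        if self.provenance not in ("selected", "learned", "combined"):
            raise ValueError(f"unknown provenance {self.provenance!r}")

    def __len__(self) -> int:
        return len(self.descriptors)


# ---------------------------------------------------------------------------
# Phase 1: filter
# ---------------------------------------------------------------------------

def phase1_filter(table: DescriptorTable, config: Optional[SelectionConfig] = None
                  ) -> DescriptorTable:
    """Variance / redundancy / relevance filter. Deterministic; ties broken by
    column order."""
    config = config or SelectionConfig()
    if table.target is None:
        raise ValueError("phase 1 requires a target column")
    y = _numeric_target(table)

    x = table.values
    keep = [c for c in x.columns if float(x[c].var(ddof=1)) >= config.variance_floor]
    if not keep:
        raise ValueError("all descriptors removed by the variance floor")
    x = x[keep]

    # relevance of each survivor: |Spearman| to the target
    relevance = {c: abs(_spearman(x[c].to_numpy(), y)) for c in x.columns}

    # pairwise redundancy: for each offending pair keep the more relevant member
    cols = list(x.columns)
    if len(cols) >= 2:
        corr = stats.spearmanr(x.to_numpy(), axis=0).statistic
        if np.ndim(corr) == 0:  # scipy collapses the 2-column case to a scalar
            corr = np.array([[1.0, float(corr)], [float(corr), 1.0]])
    else:
        corr = np.ones((1, 1))
    dropped: set[str] = set()
    for i in range(len(cols)):
        if cols[i] in dropped:
            continue
        for j in range(i + 1, len(cols)):
            if cols[j] in dropped:
                continue
            if abs(corr[i, j]) > config.redundancy_cutoff:
                # keep the member with larger |relevance|; tie -> earlier column
                if relevance[cols[j]] > relevance[cols[i]]:
                    dropped.add(cols[i])
                    break
                dropped.add(cols[j])
    survivors = [c for c in cols if c not in dropped]
    if not survivors:
        raise ValueError("all descriptors removed by the redundancy filter")

    # top-M by relevance (stable: ties keep earlier column first)
    order = sorted(range(len(survivors)),
                   key=lambda k: (-relevance[survivors[k]], k))
    survivors = [survivors[k] for k in order[: config.prefilter_size]]
    survivors = [c for c in cols if c in set(survivors)]  # restore column order
    return DescriptorTable(table.values[survivors].copy(), table.target,
                           table.target_name)


def _numeric_target(table: DescriptorTable) -> np.ndarray:
    """Numeric target vector; class labels become indicator codes (first-seen order)."""
    t = table.target
    if pd.api.types.is_numeric_dtype(t):
        return t.to_numpy(dtype=float)
    labels = list(dict.fromkeys(t))
    return np.array([labels.index(v) for v in t], dtype=float)


def _spearman(a: np.ndarray, b: np.ndarray) -> float:
    r = stats.spearmanr(a, b).statistic
    return 0.0 if np.isnan(r) else float(r)


# ---------------------------------------------------------------------------
# Phase 2: wrapper
# ---------------------------------------------------------------------------

def _cv_rae(x: np.ndarray, y: np.ndarray, cols: list[int], folds: np.ndarray,
            n_folds: int, learner: str) -> float:
    """k-fold cross-validated RAE (%) of the internal learner on the given columns."""
    total_abs_err = 0.0
    total_abs_dev = 0.0
    xs = x[:, cols]
    for f in range(n_folds):
        test = folds == f
        train = ~test
        y_tr, y_te = y[train], y[test]
        if learner == "linear":
            a = np.column_stack([xs[train], np.ones(train.sum())])
            coef, *_ = np.linalg.lstsq(a, y_tr, rcond=None)
            pred = np.column_stack([xs[test], np.ones(test.sum())]) @ coef
        else:  # best single-split regression stump over the candidate columns
            pred = _stump_predict(xs[train], y_tr, xs[test])
        total_abs_err += float(np.sum(np.abs(pred - y_te)))
        total_abs_dev += float(np.sum(np.abs(y_te - y_tr.mean())))
    if total_abs_dev == 0:
        raise ValueError("degenerate target: zero deviation in every test fold")
    return 100.0 * total_abs_err / total_abs_dev


def _stump_predict(x_tr: np.ndarray, y_tr: np.ndarray, x_te: np.ndarray) -> np.ndarray:
    from .qsar_harness import _fit_regression_stump

    feat, thr, left, right = _fit_regression_stump(x_tr, y_tr)
    return np.where(x_te[:, feat] <= thr, left, right)


def phase2_wrapper(table: DescriptorTable, config: Optional[SelectionConfig] = None
                   ) -> list[DescriptorSubset]:
    """N restarts of greedy forward selection, ranked by internal CV RAE.

    Each restart derives its own seed from the base seed, reshuffling candidate
    order (tie-breaks) and the CV fold assignment, so distinct restarts can
    land on distinct subsets; duplicates are merged keeping the best score.
    """
    config = config or SelectionConfig()
    if len(table.descriptor_names) < 2:
        raise ValueError("phase 2 needs at least 2 candidate descriptors")
    if table.target is None:
        raise ValueError("phase 2 requires a target column")
    y = _numeric_target(table)
    if float(np.var(y)) == 0:
        raise ValueError("degenerate target: zero variance")
    x = table.values.to_numpy(dtype=float)
    names = table.descriptor_names
    n = len(y)

    results: dict[frozenset, DescriptorSubset] = {}
    for restart in range(config.n_subsets):
        seed = (config.seed * 1_000_003 + restart) % (2**31)
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(names))
        folds = rng.permutation(np.arange(n) % config.cv_folds)
        chosen: list[int] = []
        best_rae = np.inf
        while len(chosen) < config.max_subset_size:
            step_best, step_col = np.inf, None
            for col in order:
                if col in chosen:
                    continue
                rae = _cv_rae(x, y, chosen + [int(col)], folds, config.cv_folds,
                              config.internal_learner)
                if rae < step_best:
                    step_best, step_col = rae, int(col)
            if step_col is None:
                break
            if chosen and best_rae > 0 and (best_rae - step_best) / best_rae < config.improvement_floor:
                break
            if chosen and best_rae == 0:
                break
            chosen.append(step_col)
            best_rae = step_best
            if best_rae == 0:
                break
        key = frozenset(chosen)
        subset = DescriptorSubset(
            name=f"M{restart + 1}",
            descriptors=[names[c] for c in chosen],
            provenance="selected",
            rae=best_rae,
        )
        if key not in results or subset.rae < results[key].rae:
            results[key] = subset
    ranked = sorted(results.values(), key=lambda s: s.rae)
    for i, s in enumerate(ranked, 1):
        s.name = f"M{i}"
    return ranked


def select_top_subsets(subsets: Sequence[DescriptorSubset], k: int = 2
                       ) -> list[DescriptorSubset]:
    """The k subsets with the lowest RAE; stable on ties (original order wins)."""
    if not subsets:
        raise ValueError("no subsets to select from")
    if k > len(subsets):
        raise ValueError(f"k={k} exceeds the {len(subsets)} available subsets")
    order = sorted(range(len(subsets)),
                   key=lambda i: (subsets[i].rae if subsets[i].rae is not None else np.inf, i))
    return [subsets[i] for i in order[:k]]


def select_descriptors(table: DescriptorTable,
                       config: Optional[SelectionConfig] = None,
                       top: int = 2) -> list[DescriptorSubset]:
    """Convenience: phase 1 then phase 2, returning the ``top`` best subsets."""
    config = config or SelectionConfig()
    reduced = phase1_filter(table, config)
    subsets = phase2_wrapper(reduced, config)
    return select_top_subsets(subsets, min(top, len(subsets)))
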