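"""Compound-similarity and descriptor-redundancy analytics.

Quantifies (i) how structurally diverse a compound set is, through Pearson
similarity of learned code vectors rescaled to [0,1], and (ii) how redundant
a descriptor subset is, through pairwise Spearman/Pearson correlation or
normalized mutual information — low redundancy between descriptors means each
one contributes singular information to a QSAR model. Histogram/scatter
coverage profiles describe how descriptors populate the information zone of
the target. All outputs are plain matrices/tables, exportable for plotting.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .chemio import DescriptorTable

__all__ = [
    "compound_similarity",
    "descriptor_correlation",
    "mutual_information_matrix",
    "coverage_profile",
]

logger = logging.getLogger("hyqsar")


def compound_similarity(codes: DescriptorTable, rescale: str = "affine") -> pd.DataFrame:
    """Compound x compound similarity from learned code rows.

    ``s_ij = (r_ij + 1) / 2`` with r the Pearson correlation between the two
    compounds' code vectors (``rescale='affine'``, default, order-preserving
    and dataset-independent); ``rescale='minmax'`` instead min-max rescales
    the off-diagonal correlations to [0,1] per dataset. Diagonal forced to 1.
    """
    x = codes.values.to_numpy(dtype=float)
    if x.shape[1] < 2:
        raise ValueError("compound similarity needs at least 2 code columns")
    row_range = x.max(axis=1) - x.min(axis=1)
    flat = [codes.ids[i] for i in np.nonzero(row_range == 0)[0]]
    if flat:
        raise ValueError(f"constant code rows (undefined correlation): {flat}")
    r = np.corrcoef(x)
    if rescale == "affine":
        s = (r + 1.0) / 2.0
    elif rescale == "minmax":
        off = r[~np.eye(len(r), dtype=bool)]
        lo, hi = off.min(), off.max()
        s = (r - lo) / (hi - lo) if hi > lo else np.full_like(r, 0.5)
    else:
        raise ValueError(f"unknown rescale mode {rescale!r}")
    np.fill_diagonal(s, 1.0)
    s = np.clip((s + s.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(s, 1.0)
    return pd.DataFrame(s, index=codes.ids, columns=codes.ids)


def descriptor_correlation(table: DescriptorTable, method: str = "spearman"
                           ) -> pd.DataFrame:
    """Pairwise descriptor correlation matrix (rank-based by default, midrank
    ties); a constant column gets zero entries with a warning."""
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown correlation method {method!r}")
    if table.n_compounds < 3:
        raise ValueError("need at least 3 compounds for correlation analysis")
    x = table.values
    constant = [c for c in x.columns if float(x[c].std(ddof=0)) == 0]
    if constant:
        warnings.warn(f"constant descriptor columns set to zero correlation: {constant}")
    corr = x.corr(method=method).to_numpy()
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=x.columns, columns=x.columns)


def _equal_frequency_bins(col: np.ndarray, bins: int) -> np.ndarray:
    """Discretize to at most ``bins`` equal-frequency bins (quantile edges)."""
    distinct = len(np.unique(col))
    b = min(bins, distinct)
    if b <= 1:
        return np.zeros(len(col), dtype=int)
    edges = np.quantile(col, np.linspace(0, 1, b + 1)[1:-1])
    return np.searchsorted(edges, col, side="right")


def _entropy_from_counts(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-np.sum(p * np.log2(p)))


def mutual_information_matrix(table: DescriptorTable, bins: Optional[int] = None
                              ) -> pd.DataFrame:
    """Normalized mutual information between descriptor pairs.

    Columns are discretized to equal-frequency bins (default B = ceil(sqrt(n)));
    the symmetric uncertainty U = 2*MI / (H_i + H_j) normalizes MI into [0,1].
    The plug-in MI estimate carries a strong positive finite-sample bias at
    B ~ sqrt(n) bins, so the Miller-Madow correction
    (m_joint - m_i - m_j + 1) / (2 n ln 2) bits (m = occupied cells) is
    subtracted when positive; independent columns then score near 0 while
    identical columns keep U = 1. Columns with fewer distinct values than
    bins use a reduced bin count for the pairs involving them (logged).
    Diagonal is 1.
    """
    n = table.n_compounds
    if n < 4:
        raise ValueError("need at least 4 compounds for mutual information")
    if bins is not None:
        b = bins
    else:
        # ceil(sqrt(n)) bins, capped so joint cells average >= ~5 samples:
        # beyond that the plug-in estimate is dominated by sparsity bias
        b = min(int(math.ceil(math.sqrt(n))), max(2, int(math.sqrt(n / 5.0))))
    x = table.values.to_numpy(dtype=float)
    cols = table.descriptor_names
    discretized = []
    for j, c in enumerate(cols):
        distinct = len(np.unique(x[:, j]))
        if distinct < b:
            logger.info("column %s has %d distinct values; reduced bin count", c, distinct)
        discretized.append(_equal_frequency_bins(x[:, j], b))
    entropies = [_entropy_from_counts(np.bincount(d)) for d in discretized]

    m = len(cols)
    u = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            joint = np.zeros((discretized[i].max() + 1, discretized[j].max() + 1))
            np.add.at(joint, (discretized[i], discretized[j]), 1.0)
            h_joint = _entropy_from_counts(joint.ravel())
            mi = entropies[i] + entropies[j] - h_joint
            m_joint = int(np.count_nonzero(joint))
            m_i = int(np.count_nonzero(joint.sum(axis=1)))
            m_j = int(np.count_nonzero(joint.sum(axis=0)))
            bias = (m_joint - m_i - m_j + 1) / (2.0 * n * math.log(2.0))
            mi = max(mi - max(bias, 0.0), 0.0)
            denom = entropies[i] + entropies[j]
            u[i, j] = u[j, i] = (2.0 * mi / denom) if denom > 0 else 0.0
    u = np.clip(u, 0.0, 1.0)
    np.fill_diagonal(u, 1.0)
    return pd.DataFrame(u, index=cols, columns=cols)


@dataclass
class CoverageProfile:
    """Per-descriptor 10-bin histograms plus (descriptor, target) scatter data."""

    histograms: pd.DataFrame   # rows: descriptor, columns: bin_0..bin_9 counts
    bin_edges: dict[str, np.ndarray]
    scatter: pd.DataFrame      # columns: descriptor, value, target

    def to_csv(self, hist_path, scatter_path) -> None:
        self.histograms.to_csv(hist_path)
        self.scatter.to_csv(scatter_path, index=False)

    def to_json(self, path) -> None:
        payload = {
            "histograms": {d: self.histograms.loc[d].tolist()
                           for d in self.histograms.index},
            "bin_edges": {d: e.tolist() for d, e in self.bin_edges.items()},
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)


def coverage_profile(table: DescriptorTable, n_bins: int = 10) -> CoverageProfile:
    """Histogram each descriptor over its [min, max] range and export the
    (descriptor value, target) scatter pairs; degenerate ranges collapse to a
    single occupied bin (logged)."""
    if table.target is None:
        raise ValueError("coverage profile requires a target")
    target = np.asarray(table.target)
    hists = {}
    edges = {}
    scatter_rows = []
    for c in table.descriptor_names:
        v = table.values[c].to_numpy(dtype=float)
        lo, hi = float(v.min()), float(v.max())
        if hi == lo:
            logger.info("descriptor %s has a degenerate range; single bin", c)
            counts = np.zeros(n_bins, dtype=int)
            counts[0] = len(v)
            edge = np.array([lo, hi])
        else:
            counts, edge = np.histogram(v, bins=n_bins, range=(lo, hi))
        hists[c] = counts
        edges[c] = edge
        scatter_rows.append(pd.DataFrame({"descriptor": c, "value": v, "target": target}))
    hist_df = pd.DataFrame(hists, index=[f"bin_{i}" for i in range(n_bins)]).T
    return CoverageProfile(hist_df, edges, pd.concat(scatter_rows, ignore_index=True))
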