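"""Weighted coexpression modules: TOM, static tree cut, eigengene-trait tests.

Simplified WGCNA-style workflow: unsigned adjacency |cor|^beta, topological
overlap similarity, average-linkage clustering with a static dissimilarity
cut (clusters below the minimum size are left unassigned as label 0), and
module eigengenes correlated against a binary trait.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from .errors import ValidationError

logger = logging.getLogger(__name__)


def compute_tom(expr: pd.DataFrame, power: float = 6.0) -> pd.DataFrame:
    """Topological overlap similarity of an expression matrix (genes x samples).

    adjacency a_ij = |pearson cor|^power (unsigned network);
    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij), TOM_ii = 1.
    Genes with missing values or zero variance are dropped with a warning.
    """
    if expr.shape[1] < 4:
        raise ValidationError("need >= 4 samples for correlation networks")
    complete = expr.notna().all(axis=1)
    variable = expr.std(axis=1, ddof=0) > 0
    keep = complete & variable
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("dropping %d gene(s) with missing values or zero variance", n_dropped)
    x = expr.loc[keep]
    if len(x) < 5:
        raise ValidationError(f"need >= 5 usable genes, got {len(x)}")
    a = np.abs(np.corrcoef(x.to_numpy())) ** power
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a
    kmin = np.minimum.outer(k, k)
    with np.errstate(invalid="ignore"):
        tom = (shared + a) / (kmin + 1.0 - a)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    return pd.DataFrame(tom, index=x.index, columns=x.index)


@dataclass
class ModuleResult:
    """Gene -> module labels (0 = unassigned) plus eigengene/trait statistics."""

    labels: pd.Series
    power: float
    cut_height: float
    min_module_size: int
    eigengenes: pd.DataFrame = field(default_factory=pd.DataFrame)  # samples x modules
    trait_correlation: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def module_ids(self) -> list[int]:
        return sorted(set(self.labels) - {0})


def detect_modules(
    tom: pd.DataFrame,
    min_module_size: int = 5,
    cut_height: float = 0.95,
    power: float = 6.0,
) -> ModuleResult:
    """Average-linkage clustering on 1 - TOM with a static height cut.

    Clusters smaller than ``min_module_size`` become label 0; surviving
    modules are renumbered 1..M by decreasing size (ties broken by the
    lexicographically first member for determinism).
    """
    t = tom.to_numpy()
    if t.shape[0] != t.shape[1] or not np.allclose(t, t.T, atol=1e-10):
        raise ValidationError("TOM must be square and symmetric")
    dist = squareform(1.0 - t, checks=False)
    link = average(dist)
    raw = fcluster(link, t=cut_height, criterion="distance")
    labels = pd.Series(raw, index=tom.index, name="module")
    sizes = labels.value_counts()
    keep = sizes[sizes >= min_module_size].index
    order = sorted(
        keep,
        key=lambda c: (-sizes[c], str(min(labels.index[labels == c]))),
    )
    remap = {c: i + 1 for i, c in enumerate(order)}
    labels = labels.map(lambda c: remap.get(c, 0)).astype(int)
    return ModuleResult(
        labels=labels,
        power=power,
        cut_height=cut_height,
        min_module_size=min_module_size,
    )


def module_eigengene(expr: pd.DataFrame) -> pd.Series:
    """First principal component (unit variance) of a standardized module.

    Sign-oriented so that the mean correlation with member genes is positive.
    """
    x = expr.to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd
    _, s, vt = np.linalg.svd(z, full_matrices=False)
    pc = vt[0]
    if s[0] == 0:
        return pd.Series(np.zeros(expr.shape[1]), index=expr.columns)
    cors = np.array([np.corrcoef(pc, row)[0, 1] for row in z])
    if np.nanmean(cors) < 0:
        pc = -pc
    pc_sd = pc.std(ddof=0)
    if pc_sd > 0:
        pc = (pc - pc.mean()) / pc_sd
    return pd.Series(pc, index=expr.columns, name="eigengene")


def module_trait_association(
    modules: ModuleResult, expr: pd.DataFrame, trait: pd.Series
) -> ModuleResult:
    """Pearson correlation of each module eigengene with a binary trait.

    ``trait`` is indexed by sample (expr columns); p-values use the Student-t
    reference on n - 2 df. Constant eigengenes report r = 0, p = 1.
    """
    trait = trait.reindex(expr.columns)
    if trait.isna().any():
        raise ValidationError("trait missing for some samples")
    levels = sorted(trait.unique())
    if len(levels) != 2:
        raise ValidationError(f"trait must be binary, got levels {levels}")
    tvals = (trait == levels[1]).to_numpy().astype(float)
    if min(np.bincount(tvals.astype(int))) < 3:
        raise ValidationError("need >= 3 samples per trait level")
    eig = {}
    rows = []
    for m in modules.module_ids:
        members = modules.labels.index[modules.labels == m]
        e = module_eigengene(expr.loc[members])
        eig[m] = e
        if e.std(ddof=0) == 0:
            r, p = 0.0, 1.0
        else:
            r, p = stats.pearsonr(e.to_numpy(), tvals)
        rows.append({"module": m, "n_genes": len(members), "r": float(r), "p": float(p)})
    modules.eigengenes = pd.DataFrame(eig, index=expr.columns)
    modules.trait_correlation = pd.DataFrame(rows, columns=["module", "n_genes", "r", "p"])
    return modules


def scale_free_fit(tom_adjacency_degrees: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of log10 P(k) vs log10 k — diagnostic for the power choice."""
    k = np.asarray(tom_adjacency_degrees, dtype=float)
    k = k[k > 0]
    if len(k) < n_bins:
        return float("nan")
    counts, edges = np.histogram(k, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    ok = counts > 0
    if ok.sum() < 3:
        return float("nan")
    lx = np.log10(centers[ok])
    ly = np.log10(counts[ok] / counts.sum())
    r = np.corrcoef(lx, ly)[0, 1]
    return float(r**2)
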