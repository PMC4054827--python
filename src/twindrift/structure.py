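"""Sample-relationship analyses: clustering and co-twin pairing.

Hierarchical clustering uses Euclidean distance with complete linkage over
sample M-value profiles.  "Co-twins cluster together" is operationalized as
mutual nearest neighbourship among the samples of one timepoint — a
deterministic, linkage-free criterion that coincides with dendrogram
siblinghood for tight pairs; the dendrogram-sibling variant is available
via :func:`dendrogram_siblings`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from skbio.tree import TreeNode

from .preprocess import collapse_replicates

log = logging.getLogger("twindrift.structure")

SNP_CLASSES = ("any_snp", "snp_at_cpg", "none")


@dataclass
class DendrogramResult:
    """Complete-linkage dendrogram: scipy linkage matrix plus leaf labels."""

    linkage: np.ndarray
    labels: list[str]

    def to_newick(self) -> str:
        tree = TreeNode.from_linkage_matrix(self.linkage, self.labels)
        return str(tree).strip()


def hierarchical_cluster(m: pd.DataFrame, method: str = "complete"
                         ) -> DendrogramResult:
    """Agglomerative clustering of samples (columns) on Euclidean distance.

    Missing values are imputed by the probe median first (logged).
    """
    if m.shape[1] < 2:
        raise ValueError("need >= 2 samples to cluster")
    x = m.to_numpy(dtype=float)
    if np.isnan(x).any():
        log.info("imputing %d missing values by probe median",
                 int(np.isnan(x).sum()))
        med = np.nanmedian(x, axis=1)
        idx = np.where(np.isnan(x))
        x[idx] = med[idx[0]]
    z = hierarchy.linkage(x.T, method=method, metric="euclidean")
    return DendrogramResult(linkage=z, labels=list(m.columns))


def dendrogram_siblings(dend: DendrogramResult) -> list[tuple[str, str]]:
    """Leaf pairs merged directly with each other (dendrogram siblings)."""
    n = len(dend.labels)
    out = []
    for a, b, *_ in dend.linkage:
        if a < n and b < n:
            out.append((dend.labels[int(a)], dend.labels[int(b)]))
    return out


def cotwin_pairing_fraction(m: pd.DataFrame, samples: pd.DataFrame,
                            zygosity: str | None = None
                            ) -> tuple[float, dict[str, bool]]:
    """Fraction of co-twin pairs that are mutual nearest neighbours.

    ``m`` must hold the samples of a single timepoint (replicates are
    averaged here).  Distance ties are broken by lexicographic sample id.
    """
    collapsed, meta = collapse_replicates(m, samples)
    if zygosity is not None:
        meta = meta[meta["zygosity"] == zygosity]
    if meta["timepoint"].nunique() != 1:
        raise ValueError("matrix must contain a single timepoint")
    # keep lexicographic column order so argmin tie-break is by sample id
    cols = sorted(meta.index)
    collapsed = collapsed[cols]
    meta = meta.loc[cols]
    pairs = {}
    for pid, grp in meta.groupby("pair_id"):
        if len(grp) == 2:
            pairs[pid] = tuple(grp.index)
    if len(pairs) < 2:
        raise ValueError("need >= 2 evaluable pairs")
    d = squareform(pdist(collapsed.T.to_numpy(), metric="euclidean"))
    np.fill_diagonal(d, np.inf)
    nn = {cols[i]: cols[int(np.argmin(d[i]))] for i in range(len(cols))}
    flags = {pid: (nn[a] == b and nn[b] == a) for pid, (a, b) in pairs.items()}
    return float(np.mean(list(flags.values()))), flags


def subset_probes_by_snp_class(manifest: pd.DataFrame,
                               snp_class: str) -> pd.Index:
    """Probe subset by SNP annotation: any_snp, snp_at_cpg, or none."""
    if snp_class not in SNP_CLASSES:
        raise ValueError(f"unknown SNP class {snp_class!r}; "
                         f"expected one of {SNP_CLASSES}")
    any_snp = manifest["snp_in_probe"].astype(bool)
    if snp_class == "any_snp":
        idx = manifest.index[any_snp]
    elif snp_class == "snp_at_cpg":
        idx = manifest.index[manifest["snp_at_cpg"].astype(bool)]
    else:
        idx = manifest.index[~any_snp]
    if len(idx) == 0:
        import warnings
        warnings.warn(f"SNP class {snp_class!r} selected no probes")
    return idx
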