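"""Observed/expected annotation enrichment with hypergeometric tests.

For a hit set H drawn from a universe U and an annotation category C, the
expected overlap under uniform sampling is |H||C|/|U| and significance is
the hypergeometric upper tail P[X >= observed] for over-representation
(lower tail when the ratio is < 1, i.e. depletion).  Categories come in
four groups: gene features, CpG-island relation (with islands further split
into intragenic/intergenic), known-DMR classes, and regulatory regions;
categories overlap across groups but island relations partition the
universe within their group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .simulate import GENE_FEATURES, ISLAND_RELATIONS

#: Significance tiers for the profile table ('' = not significant at 0.05).
TIERS = ((1e-50, "***"), (1e-20, "**"), (0.05, "*"))


@dataclass(frozen=True)
class EnrichmentResult:
    category: str
    group: str
    observed: int
    expected: float
    ratio: float
    log2_ratio: float
    p_value: float  # the reported tail: upper for enrichment, lower for depletion
    tail: str
    p_upper: float
    p_lower: float


def build_category_sets(manifest: pd.DataFrame) -> dict[str, dict[str, pd.Index]]:
    """Annotation category -> probe id sets, grouped.

    Returns ``{group: {category: Index}}``; empty categories are retained.
    """
    out: dict[str, dict[str, pd.Index]] = {"gene": {}, "island": {},
                                           "dmr_class": {}, "regulatory": {}}
    for feat in GENE_FEATURES:
        out["gene"][feat] = manifest.index[manifest["gene_feature"] == feat]
    island = manifest["island_relation"] == "island"
    intergenic = manifest["gene_feature"] == "intergenic"
    for rel in ISLAND_RELATIONS:
        out["island"][rel] = manifest.index[manifest["island_relation"] == rel]
    out["island"]["island_intragenic"] = manifest.index[island & ~intergenic]
    out["island"]["island_intergenic"] = manifest.index[island & intergenic]
    for cls in ("CDMR", "RDMR"):
        out["dmr_class"][cls] = manifest.index[manifest["dmr_class"] == cls]
    out["regulatory"]["promoter"] = manifest.index[
        manifest["gene_feature"].isin(["TSS200", "TSS1500"])]
    out["regulatory"]["enhancer"] = manifest.index[
        manifest["enhancer"].astype(bool)]
    out["regulatory"]["dhs"] = manifest.index[manifest["dhs"].astype(bool)]
    return out


def enrichment_test(hits: pd.Index, category: pd.Index,
                    universe: pd.Index, *, category_name: str = "",
                    group: str = "") -> EnrichmentResult:
    """Observed/expected ratio and hypergeometric p for one category."""
    hits = pd.Index(hits)
    category = pd.Index(category)
    universe = pd.Index(universe)
    if len(universe) == 0 or len(hits) == 0:
        raise ValueError("universe and hits must be non-empty")
    if len(hits.difference(universe)) or len(category.difference(universe)):
        raise ValueError("hits and category must be subsets of the universe")
    N, K, n = len(universe), len(category), len(hits)
    observed = len(hits.intersection(category))
    expected = n * K / N
    ratio = observed / expected if expected > 0 else float("nan")
    with np.errstate(divide="ignore"):
        log2_ratio = float(np.log2(ratio)) if expected > 0 else float("nan")
    p_upper = float(hypergeom.sf(observed - 1, N, K, n))
    p_lower = float(hypergeom.cdf(observed, N, K, n))
    if expected > 0 and ratio < 1:
        p, tail = p_lower, "lower"
    else:
        p, tail = p_upper, "upper"
    return EnrichmentResult(category=category_name, group=group,
                            observed=observed, expected=float(expected),
                            ratio=float(ratio), log2_ratio=log2_ratio,
                            p_value=p, tail=tail, p_upper=p_upper,
                            p_lower=p_lower)


def significance_tier(p: float) -> str:
    for cut, stars in TIERS:
        if p < cut:
            return stars
    return ""


def enrichment_profile(hits: pd.Index, manifest: pd.DataFrame,
                       universe: pd.Index) -> pd.DataFrame:
    """Enrichment table over all annotation categories.

    One row per category, ordered by group then descending log2 ratio, with
    significance stars at the raw-p tiers (no correction across categories;
    the ``tier`` column flags raw p-values).
    """
    sets = build_category_sets(manifest.loc[universe])
    rows = []
    for group, cats in sets.items():
        for name, probes in cats.items():
            r = enrichment_test(hits, probes, universe,
                                category_name=name, group=group)
            rows.append({
                "category": r.category, "group": r.group,
                "observed": r.observed, "expected": r.expected,
                "ratio": r.ratio, "log2_ratio": r.log2_ratio,
                "p": r.p_value, "tail": r.tail,
                "tier": significance_tier(r.p_value),
            })
    prof = pd.DataFrame(rows)
    prof = prof.sort_values(["group", "log2_ratio"],
                            ascending=[True, False],
                            kind="mergesort").reset_index(drop=True)
    return prof
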