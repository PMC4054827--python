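"""Probe/sample QC, beta-M transforms and normalization.

The processing order mirrors standard 450K practice: detection-p probe
filter, detection-p sample filter, sex-chromosome removal, within-array
design-bias adjustment on beta, beta -> M transform, between-array quantile
normalization on M.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .simulate import Cohort, SEX_CHROMS

log = logging.getLogger("twindrift.preprocess")

EPS = 1e-6


def filter_probes_by_detection(detp: pd.DataFrame,
                               threshold: float = 0.001) -> pd.Series:
    """Keep a probe iff its detection p <= threshold in *every* sample.

    A probe whose detection p exceeds the threshold in one or more samples
    is flagged for removal (strictly-greater at the boundary).
    """
    if detp.empty:
        raise ValueError("empty detection-p matrix")
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    return pd.Series((detp.to_numpy() <= threshold).all(axis=1),
                     index=detp.index)


def filter_samples_by_detection(detp: pd.DataFrame,
                                threshold: float = 0.05) -> pd.Series:
    """Keep a sample iff its mean detection p over probes is <= threshold."""
    if detp.empty:
        raise ValueError("empty detection-p matrix")
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    return detp.mean(axis=0) <= threshold


def drop_sex_chromosomes(matrix: pd.DataFrame,
                         manifest: pd.DataFrame) -> pd.DataFrame:
    """Remove probes on chrX / chrY."""
    missing = matrix.index.difference(manifest.index)
    if len(missing):
        raise KeyError(f"probe(s) missing from manifest: {list(missing[:5])}")
    chrom = manifest.loc[matrix.index, "chrom"]
    keep = ~chrom.isin(SEX_CHROMS)
    out = matrix.loc[keep]
    if out.empty:
        warnings.warn("all probes were on sex chromosomes; result is empty")
    return out


def beta_to_m(beta, eps: float = EPS):
    """M = log2(beta / (1 - beta)) with beta clipped to [eps, 1 - eps]."""
    b = np.asarray(beta, dtype=float)
    if np.nanmin(b) < 0 or np.nanmax(b) > 1:
        raise ValueError("beta values must be in [0, 1]")
    b = np.clip(b, eps, 1 - eps)
    m = np.log2(b / (1 - b))
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(m, index=beta.index, columns=beta.columns)
    if isinstance(beta, pd.Series):
        return pd.Series(m, index=beta.index)
    return m


def m_to_beta(m):
    """Inverse of :func:`beta_to_m` (up to the clipping)."""
    x = np.asarray(m, dtype=float)
    b = expit(x * np.log(2.0))
    if isinstance(m, pd.DataFrame):
        return pd.DataFrame(b, index=m.index, columns=m.columns)
    if isinstance(m, pd.Series):
        return pd.Series(b, index=m.index)
    return b


def adjust_design_bias(beta: pd.DataFrame, manifest: pd.DataFrame,
                       seed: int = 0, max_reference: int = 5000
                       ) -> pd.DataFrame:
    """Within-array quantile mapping of type II probes onto type I probes.

    For each array and each island-relation stratum, type II beta values are
    replaced by the empirical quantiles of a random subset of the stratum's
    type I probes, removing the Infinium II compression while preserving the
    within-array rank order of type II values.  Type I values are unchanged.
    """
    design = manifest.loc[beta.index, "design_type"]
    relation = manifest.loc[beta.index, "island_relation"]
    if design.nunique() < 2:
        warnings.warn("only one design class present; returning input")
        return beta.copy()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 606]))
    out = beta.to_numpy().copy()
    for rel in relation.unique():
        in_rel = (relation == rel).to_numpy()
        i_rows = np.flatnonzero(in_rel & (design == "I").to_numpy())
        ii_rows = np.flatnonzero(in_rel & (design == "II").to_numpy())
        if len(i_rows) < 10 or len(ii_rows) == 0:
            if len(ii_rows):
                warnings.warn(
                    f"too few type I probes in stratum {rel!r}; left unchanged")
            continue
        if len(i_rows) > max_reference:
            i_rows = rng.choice(i_rows, size=max_reference, replace=False)
        for j in range(out.shape[1]):
            ref = np.sort(out[i_rows, j])
            v = out[ii_rows, j]
            # mid-rank plotting positions of the type II values
            order = np.argsort(v, kind="mergesort")
            q = (np.arange(len(v)) + 0.5) / len(v)
            mapped = np.empty_like(v)
            mapped[order] = np.interp(q, (np.arange(len(ref)) + 0.5) / len(ref),
                                      ref)
            out[ii_rows, j] = mapped
    return pd.DataFrame(out, index=beta.index, columns=beta.columns)


def quantile_normalize_between_arrays(m: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the row-mean reference distribution.

    After normalization all columns share the identical sorted value vector;
    within-column ranks are preserved, and tied values receive the mean of
    the reference values over their tied ranks.
    """
    if m.shape[1] < 2:
        warnings.warn("fewer than 2 samples; quantile normalization skipped")
        return m.copy()
    x = m.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("matrix contains missing values; impute first")
    sorted_cols = np.sort(x, axis=0)
    ref = sorted_cols.mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        order = np.argsort(x[:, j], kind="mergesort")
        col = ref.copy()
        sv = x[order, j]
        # average reference values over runs of tied input values
        tie_breaks = np.flatnonzero(np.diff(sv) != 0) + 1
        bounds = np.concatenate([[0], tie_breaks, [len(sv)]])
        for a, b in zip(bounds[:-1], bounds[1:]):
            if b - a > 1:
                col[a:b] = col[a:b].mean()
        out[order, j] = col
    return pd.DataFrame(out, index=m.index, columns=m.columns)


def collapse_replicates(mat: pd.DataFrame,
                        samples: pd.DataFrame) -> tuple[pd.DataFrame,
                                                        pd.DataFrame]:
    """Average replicate arrays per (pair, twin, timepoint).

    Returns the collapsed matrix (one column per biological array, named
    ``pair-Ttwin-timepoint``) and the corresponding collapsed sample table.
    """
    meta = samples.loc[mat.columns]
    key = (meta["pair_id"].astype(str) + "-T"
           + meta["twin_index"].astype(str) + "-" + meta["timepoint"])
    collapsed = mat.T.groupby(key.values).mean().T
    smeta = meta.assign(_key=key.values).groupby("_key").first()
    smeta.index.name = "sample_id"
    smeta = smeta.drop(columns=["replicate_id"])
    return collapsed[smeta.index], smeta


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

@dataclass
class QCResult:
    """Processed matrices plus a machine-readable QC report."""

    beta: pd.DataFrame          # filtered + design-adjusted beta
    m_norm: pd.DataFrame        # quantile-normalized M values
    beta_norm: pd.DataFrame     # beta recomputed from m_norm
    samples: pd.DataFrame       # retained sample sheet rows
    report: dict = field(default_factory=dict)


def run_qc(cohort: Cohort, *,
           probe_detp_threshold: float = 0.001,
           sample_detp_threshold: float = 0.05,
           exclude_samples: Sequence[str] = (),
           design_adjust: bool = True,
           seed: int = 0) -> QCResult:
    """Full QC and normalization chain on a cohort.

    ``exclude_samples`` is a user-supplied outlier list (manual-inspection
    removals), applied after the detection-based sample filter.
    """
    probe_keep = filter_probes_by_detection(cohort.detp, probe_detp_threshold)
    detp = cohort.detp.loc[probe_keep]
    beta = cohort.beta.loc[probe_keep]

    sample_keep = filter_samples_by_detection(detp, sample_detp_threshold)
    kept_samples = [s for s in beta.columns
                    if sample_keep[s] and s not in set(exclude_samples)]
    beta = beta[kept_samples]

    beta = drop_sex_chromosomes(beta, cohort.manifest)
    n_sex_removed = int(probe_keep.sum()) - len(beta)

    if design_adjust:
        beta = adjust_design_bias(beta, cohort.manifest, seed=seed)
    m = beta_to_m(beta)
    m_norm = quantile_normalize_between_arrays(m)
    beta_norm = m_to_beta(m_norm)

    report = {
        "n_probes_input": int(cohort.beta.shape[0]),
        "n_probes_failed_detection": int((~probe_keep).sum()),
        "n_probes_sex_chrom": n_sex_removed,
        "n_probes_retained": int(beta.shape[0]),
        "n_samples_input": int(cohort.beta.shape[1]),
        "n_samples_failed_detection": int((~sample_keep).sum()),
        "n_samples_excluded_manually": len(set(exclude_samples)
                                           & set(cohort.beta.columns)),
        "n_samples_retained": len(kept_samples),
        "sample_mean_detp": {s: float(v) for s, v
                             in cohort.detp.mean(axis=0).items()},
    }
    log.info("QC: %d/%d probes, %d/%d samples retained",
             report["n_probes_retained"], report["n_probes_input"],
             report["n_samples_retained"], report["n_samples_input"])
    return QCResult(beta=beta, m_norm=m_norm, beta_norm=beta_norm,
                    samples=cohort.samples.loc[kept_samples].copy(),
                    report=report)
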