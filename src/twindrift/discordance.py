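"""Within-pair discordance, delta discordance and drift/convergence.

Twin discordance at an age is the probe-wise absolute difference in beta
values between co-twins; its genome-wide summary is the Euclidean distance
between the co-twin beta vectors.  Delta discordance (18 months minus
birth, per probe) quantifies how discordance itself changes with age, and
each pair is labelled drift / converge / stable by the relative change of
its Euclidean distance.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .preprocess import collapse_replicates

log = logging.getLogger("twindrift.discordance")

DISCORDANT_THRESHOLD = 0.2
DYNAMICS_REL_THRESHOLD = 0.10


def _twin_columns(samples: pd.DataFrame, timepoint: str
                  ) -> dict[str, tuple[str, str]]:
    sel = samples[samples["timepoint"] == timepoint]
    out = {}
    for pid, grp in sel.groupby("pair_id"):
        t1 = grp.index[grp["twin_index"] == 1]
        t2 = grp.index[grp["twin_index"] == 2]
        if len(t1) == 1 and len(t2) == 1:
            out[pid] = (t1[0], t2[0])
        else:
            log.info("pair %s incomplete at %s; dropped", pid, timepoint)
    return out


def pair_discordance(beta: pd.DataFrame, samples: pd.DataFrame,
                     timepoint: str) -> pd.DataFrame:
    """|beta_twin1 - beta_twin2| per probe, one column per complete pair.

    Replicate arrays are averaged first; pairs missing a co-twin at the
    timepoint are dropped and logged.
    """
    collapsed, meta = collapse_replicates(beta, samples)
    pairs = _twin_columns(meta, timepoint)
    if not pairs:
        raise ValueError(f"no complete pair at timepoint {timepoint!r}")
    return pd.DataFrame(
        {pid: (collapsed[a] - collapsed[b]).abs()
         for pid, (a, b) in pairs.items()},
        index=beta.index)


def residual_discordance(m: pd.DataFrame,
                         samples: pd.DataFrame) -> pd.DataFrame:
    """Residuals of M-values about the (pair, timepoint) group mean.

    For a two-member group the residuals are +/-(M1 - M2)/2; singleton
    groups get residual 0 with a warning.
    """
    meta = samples.loc[m.columns]
    key = meta["pair_id"].astype(str) + "|" + meta["timepoint"].astype(str)
    out = m.copy()
    singletons = []
    for k, cols in meta.groupby(key.values).groups.items():
        if len(cols) < 2:
            singletons.append(str(k))
            out[list(cols)] = 0.0
            continue
        out[list(cols)] = m[list(cols)].sub(
            m[list(cols)].mean(axis=1), axis=0)
    if singletons:
        warnings.warn(f"singleton pair group(s) {singletons}: residual 0")
    return out


def count_discordant(disc, threshold: float = DISCORDANT_THRESHOLD) -> int:
    """Number of probes with discordance strictly greater than threshold."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    return int((np.asarray(disc, dtype=float) > threshold).sum())


def euclidean_distance(beta1, beta2) -> float:
    """sqrt(sum (beta1 - beta2)^2) over the analysis probe set."""
    a = np.asarray(beta1, dtype=float)
    b = np.asarray(beta2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    return float(np.sqrt(np.sum((a - b) ** 2)))


def delta_discordance(d_birth: pd.DataFrame | pd.Series,
                      d_m18: pd.DataFrame | pd.Series
                      ) -> tuple[pd.DataFrame | pd.Series, dict]:
    """Per-probe discordance change (18 months - birth) plus a summary.

    The summary reports the mean, median and the central mass (fraction of
    |delta| < 0.05) of the pooled delta distribution.
    """
    if isinstance(d_birth, pd.DataFrame):
        if (not d_birth.index.equals(d_m18.index)
                or list(d_birth.columns) != list(d_m18.columns)):
            raise ValueError("birth and 18-month discordance must be matched")
    elif not d_birth.index.equals(d_m18.index):
        raise ValueError("birth and 18-month discordance must be matched")
    delta = d_m18 - d_birth
    flat = np.asarray(delta, dtype=float).ravel()
    summary = {
        "mean": float(np.mean(flat)),
        "median": float(np.median(flat)),
        "central_mass_lt_0.05": float(np.mean(np.abs(flat) < 0.05)),
    }
    return delta, summary


def classify_pair_dynamics(ed_birth: float, ed_m18: float,
                           rel_threshold: float = DYNAMICS_REL_THRESHOLD
                           ) -> str:
    """Label a pair by the relative change in its Euclidean distance."""
    if ed_birth < 0 or ed_m18 < 0:
        raise ValueError("distances must be >= 0")
    if ed_birth == 0:
        warnings.warn("zero distance at birth; labelling stable")
        return "stable"
    rel = (ed_m18 - ed_birth) / ed_birth
    if rel > rel_threshold:
        return "drift"
    if rel < -rel_threshold:
        return "converge"
    return "stable"


def pair_profiles(beta: pd.DataFrame, samples: pd.DataFrame,
                  threshold: float = DISCORDANT_THRESHOLD,
                  rel_threshold: float = DYNAMICS_REL_THRESHOLD
                  ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Per-pair discordance profile across both ages.

    Returns (profiles, delta, summary): one profile row per pair with
    Euclidean distances, discordant-probe counts and the dynamics label;
    the probe x pair delta-discordance matrix; and the pooled delta summary.
    """
    d_birth = pair_discordance(beta, samples, "birth")
    d_m18 = pair_discordance(beta, samples, "m18")
    common = [p for p in d_birth.columns if p in d_m18.columns]
    d_birth, d_m18 = d_birth[common], d_m18[common]
    delta, summary = delta_discordance(d_birth, d_m18)
    rows = []
    for pid in common:
        ed_b = float(np.sqrt((d_birth[pid] ** 2).sum()))
        ed_m = float(np.sqrt((d_m18[pid] ** 2).sum()))
        rows.append({
            "pair_id": pid,
            "ed_birth": ed_b, "ed_m18": ed_m,
            "n_discordant_birth": count_discordant(d_birth[pid], threshold),
            "n_discordant_m18": count_discordant(d_m18[pid], threshold),
            "delta_discordance_mean": float(delta[pid].mean()),
            "dynamics": classify_pair_dynamics(ed_b, ed_m, rel_threshold),
        })
    return (pd.DataFrame(rows).set_index("pair_id"), delta, summary)


def rank_probes_for_ontology(metric: pd.Series,
                             gene_map: pd.Series) -> list[str]:
    """Ranked gene list for GOrilla-style single-list ontology.

    Probes are sorted by descending metric (ties broken by probe id), mapped
    to gene symbols, deduplicated keeping the best rank.  Probes without a
    gene (intergenic) are excluded.
    """
    gm = gene_map[gene_map.astype(str).str.len() > 0].dropna()
    if gm.empty:
        raise ValueError("empty gene map")
    metric = metric.loc[metric.index.intersection(gm.index)]
    metric = metric[np.isfinite(metric)]
    order = sorted(metric.index, key=lambda p: (-metric[p], p))
    seen = set()
    genes = []
    for probe in order:
        g = gm[probe]
        if g not in seen:
            seen.add(g)
            genes.append(g)
    return genes


def weight_discordance(w1: float, w2: float) -> float:
    """Birth-weight discordance: 100 * (heavier - lighter) / heavier."""
    if w1 <= 0 or w2 <= 0:
        raise ValueError("weights must be positive")
    hi, lo = max(w1, w2), min(w1, w2)
    return 100.0 * (hi - lo) / hi
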