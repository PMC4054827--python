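"""Empirical-Bayes moderated paired differential methylation.

The paired birth-vs-18-months design is tested as a one-sample problem on
within-individual M-value differences.  Per-probe residual variances s_g^2
(df = n_g - 1) are shrunk toward a prior (d0, s0^2) estimated by the
moment-matching method of Smyth (2004) on log variances:

    s~_g^2 = (d0 * s0^2 + df_g * s_g^2) / (d0 + df_g)
    t~_g   = b_g / (s~_g / sqrt(n_g)),   t~_g ~ t(d0 + df_g) under H0

With d0 = 0 this reduces exactly to the classic paired t-test; with
d0 -> infinity every probe is tested against the common variance s0^2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from .preprocess import collapse_replicates

log = logging.getLogger("twindrift.differential")

MIN_PROBES_FOR_PRIOR = 10
MIN_N_FOR_PRIOR = 3


@dataclass(frozen=True)
class PriorEstimate:
    """Variance prior: d0 prior degrees of freedom (may be inf), s0^2 scale.

    d0 = 0 turns moderation off (classic per-probe t-test).
    """

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 >= 0):
            raise ValueError("d0 must be >= 0")
        if not (self.s0_sq > 0):
            raise ValueError("s0_sq must be > 0")


def paired_differences(mat: pd.DataFrame,
                       samples: pd.DataFrame) -> pd.DataFrame:
    """Within-individual (18 months - birth) differences, probe x individual.

    Replicate arrays are averaged first; individuals missing either
    timepoint are dropped and logged.  Columns are named ``pair-Ttwin``.
    """
    collapsed, meta = collapse_replicates(mat, samples)
    indiv = (meta["pair_id"].astype(str) + "-T"
             + meta["twin_index"].astype(str))
    cols = {}
    dropped = []
    for ind in dict.fromkeys(indiv):
        sel = meta.index[indiv == ind]
        tps = set(meta.loc[sel, "timepoint"])
        if {"birth", "m18"} <= tps:
            s_birth = sel[meta.loc[sel, "timepoint"] == "birth"][0]
            s_m18 = sel[meta.loc[sel, "timepoint"] == "m18"][0]
            cols[ind] = collapsed[s_m18] - collapsed[s_birth]
        else:
            dropped.append(ind)
    if dropped:
        log.info("dropped %d individual(s) missing a timepoint: %s",
                 len(dropped), dropped)
    if not cols:
        raise ValueError("no individual has both timepoints")
    return pd.DataFrame(cols, index=mat.index)


def estimate_prior(s_sq: np.ndarray | pd.Series,
                   df: float | np.ndarray,
                   min_var_excess: float = 1e-8) -> PriorEstimate:
    """Moment-match (d0, s0^2) from the spread of log sample variances.

    Under the hierarchical model, e_g = log s_g^2 - digamma(df/2) + log(df/2)
    has mean log s0^2 - digamma(d0/2) + log(d0/2) and variance
    trigamma(df/2) + trigamma(d0/2); solving the trigamma equation for d0/2
    by monotone root finding gives the prior.  When the observed spread does
    not exceed trigamma(df/2), the variances are consistent with a single
    common value and d0 = +inf is returned.
    """
    s = np.asarray(s_sq, dtype=float)
    s = s[np.isfinite(s) & (s > 0)]
    if len(s) < MIN_PROBES_FOR_PRIOR:
        raise ValueError(
            f"need >= {MIN_PROBES_FOR_PRIOR} finite variances, got {len(s)}")
    df = float(np.median(np.asarray(df, dtype=float)))
    z = np.log(s)
    e = z - special.digamma(df / 2) + np.log(df / 2)
    ebar = e.mean()
    excess = e.var(ddof=1) - special.polygamma(1, df / 2)
    if excess <= min_var_excess:
        return PriorEstimate(d0=np.inf, s0_sq=float(np.exp(ebar)))
    half_d0 = _trigamma_inverse(excess)
    d0 = 2.0 * half_d0
    s0_sq = float(np.exp(ebar + special.digamma(half_d0) - np.log(half_d0)))
    return PriorEstimate(d0=d0, s0_sq=s0_sq)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (trigamma is strictly decreasing)."""
    lo, hi = 1e-8, 1e8
    f = lambda x: special.polygamma(1, x) - y
    return float(optimize.brentq(f, lo, hi, xtol=1e-12, rtol=1e-12))


def moderated_one_sample_test(diffs: pd.DataFrame,
                              prior: PriorEstimate | None = None,
                              delta_beta: pd.Series | None = None
                              ) -> pd.DataFrame:
    """Per-probe moderated one-sample t-test of mean difference = 0.

    Returns a DataFrame indexed by probe with columns effect, delta_beta,
    n, df, s2, s2_post, t, p, adj_p and direction.  ``delta_beta`` (mean
    paired beta difference) is carried through when given; otherwise the
    M-scale effect sign determines the gain/loss direction.
    """
    x = diffs.to_numpy(dtype=float)
    n = np.isfinite(x).sum(axis=1)
    if x.shape[1] < 2:
        raise ValueError("need >= 2 individuals")
    with np.errstate(invalid="ignore"):
        b = np.nanmean(x, axis=1)
        s2 = np.nanvar(x, axis=1, ddof=1)
    df = np.maximum(n - 1, 0).astype(float)
    testable = n >= 2
    if prior is None:
        ok = n >= MIN_N_FOR_PRIOR
        if ok.sum() < MIN_PROBES_FOR_PRIOR:
            raise ValueError("too few probes with n >= 3 to estimate a prior")
        if (s2[ok] > 0).sum() >= MIN_PROBES_FOR_PRIOR:
            prior = estimate_prior(s2[ok], df[ok])
        else:
            # degenerate input (e.g. identical arrays): no variance to
            # pool, fall back to the unmoderated test
            log.warning("no positive variances; prior moderation disabled")
            prior = PriorEstimate(d0=0.0, s0_sq=1.0)

    d0, s0 = prior.d0, prior.s0_sq
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0)
        df_total = np.full_like(s2, np.inf)
    else:
        s2_post = (d0 * s0 + df * s2) / (d0 + df)
        df_total = d0 + df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = b / np.sqrt(s2_post / np.maximum(n, 1))
        t = np.where((s2_post == 0) & (b == 0), 0.0, t)
    p = 2 * stats.t.sf(np.abs(t), df_total)
    p = np.where(testable, p, np.nan)

    res = pd.DataFrame({
        "effect": b, "n": n, "df": df, "s2": s2, "s2_post": s2_post,
        "t": t, "p": p,
    }, index=diffs.index)
    res["adj_p"] = np.nan
    ok = res["p"].notna()
    res.loc[ok, "adj_p"] = adjust_bh(res.loc[ok, "p"].to_numpy())
    if delta_beta is not None:
        res["delta_beta"] = delta_beta.reindex(res.index)
    else:
        res["delta_beta"] = res["effect"]
    res["direction"] = np.where(res["delta_beta"] > 0, "gain", "loss")
    res.attrs["prior"] = prior
    return res


def adjust_bh(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr
    if np.nanmin(arr) < 0 or np.nanmax(arr) > 1:
        raise ValueError("p-values must be in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def call_admps(result: pd.DataFrame, fdr: float = 0.05,
               min_delta_beta: float = 0.2) -> dict[str, pd.Index]:
    """Call age-associated differentially methylated probes.

    Returns the relaxed set (adjusted p < fdr) and the stringent set, which
    additionally requires an absolute beta change > ``min_delta_beta``.
    """
    if not 0 < fdr <= 1 or not 0 <= min_delta_beta <= 1:
        raise ValueError("thresholds out of range")
    sig = result["adj_p"] < fdr
    stringent = sig & (result["delta_beta"].abs() > min_delta_beta)
    return {"relaxed": result.index[sig],
            "stringent": result.index[stringent]}


def direction_summary(admps: pd.Index,
                      result: pd.DataFrame) -> tuple[float, float]:
    """(gain fraction, loss fraction) over a called probe set."""
    if len(admps) == 0:
        raise ValueError("empty probe set")
    d = result.loc[admps, "direction"]
    gain = float((d == "gain").mean())
    return gain, 1.0 - gain


# ---------------------------------------------------------------------------
# Biological vs technical variation (replicate-pair contrasts)
# ---------------------------------------------------------------------------

def technical_vs_biological(m: pd.DataFrame, samples: pd.DataFrame,
                            fdr: float = 0.05) -> dict:
    """Contrast co-twin variation against replicate-hybridization variation.

    For every pair with replicate arrays at both ages, two moderated
    one-sample tests are run on that pair's arrays: the *biological*
    contrast pairs twin 1 vs twin 2 within each (age, replicate), the
    *technical* contrast pairs replicate 1 vs replicate 2 within each
    (twin, age).  Returns per-pair significant-probe counts, union counts
    across pairs, and volcano coordinates (effect, -log10 adjusted p).
    """
    meta = samples.loc[m.columns]
    rep_pairs = []
    for pid, grp in meta.groupby("pair_id"):
        have = grp.groupby(["twin_index", "timepoint"])["replicate_id"].max()
        if len(have) == 4 and (have >= 2).all():
            rep_pairs.append(pid)
    if not rep_pairs:
        raise ValueError("no pair has replicate arrays at both ages")

    def _col(pid, twin, tp, rep):
        sel = meta[(meta["pair_id"] == pid) & (meta["twin_index"] == twin)
                   & (meta["timepoint"] == tp) & (meta["replicate_id"] == rep)]
        return sel.index[0] if len(sel) else None

    out = {"pairs": {}, "n_pairs": len(rep_pairs)}
    union_bio = pd.Index([])
    union_tech = pd.Index([])
    for pid in rep_pairs:
        bio_cols, tech_cols = {}, {}
        for tp in ("birth", "m18"):
            for rep in (1, 2):
                a, b = _col(pid, 1, tp, rep), _col(pid, 2, tp, rep)
                if a and b:
                    bio_cols[f"{tp}-r{rep}"] = m[a] - m[b]
            for twin in (1, 2):
                a, b = _col(pid, twin, tp, 1), _col(pid, twin, tp, 2)
                if a and b:
                    tech_cols[f"T{twin}-{tp}"] = m[a] - m[b]
        res_bio = moderated_one_sample_test(pd.DataFrame(bio_cols))
        res_tech = moderated_one_sample_test(pd.DataFrame(tech_cols))
        sig_bio = res_bio.index[res_bio["adj_p"] < fdr]
        sig_tech = res_tech.index[res_tech["adj_p"] < fdr]
        union_bio = union_bio.union(sig_bio)
        union_tech = union_tech.union(sig_tech)
        out["pairs"][pid] = {
            "n_significant_biological": int(len(sig_bio)),
            "n_significant_technical": int(len(sig_tech)),
            "volcano_biological": pd.DataFrame({
                "effect": res_bio["effect"],
                "neg_log10_adj_p": -np.log10(
                    np.clip(res_bio["adj_p"], 1e-300, None)),
            }),
            "volcano_technical": pd.DataFrame({
                "effect": res_tech["effect"],
                "neg_log10_adj_p": -np.log10(
                    np.clip(res_tech["adj_p"], 1e-300, None)),
            }),
        }
    out["n_significant_biological"] = int(len(union_bio))
    out["n_significant_technical"] = int(len(union_tech))
    return out
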