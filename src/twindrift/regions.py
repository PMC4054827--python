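"""Bump-hunting detection of differentially methylated regions.

Probes are chained into position clusters (gap <= maxgap), the per-probe
moderated t statistic is smoothed within each cluster by a centered running
mean, and maximal runs of >= min_probes consecutive same-sign probes whose
|smoothed statistic| exceeds a genome-wide quantile threshold are reported
as regions, ranked by area (|sum of smoothed statistics|).
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def cluster_probes(manifest: pd.DataFrame, maxgap: int = 1000) -> pd.Series:
    """Assign a cluster id to every probe by greedy gap chaining.

    A new cluster starts whenever the gap to the previous probe on the same
    chromosome exceeds ``maxgap``.  Positions must be sorted within each
    chromosome.
    """
    ids = np.empty(len(manifest), dtype=np.int64)
    cid = -1
    offset = 0
    for _, grp in manifest.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        if np.any(np.diff(pos) < 0):
            raise ValueError("positions must be sorted within chromosome")
        new = np.concatenate([[True], np.diff(pos) > maxgap])
        ids[offset:offset + len(pos)] = cid + np.cumsum(new)
        cid = ids[offset + len(pos) - 1]
        offset += len(pos)
    return pd.Series(ids, index=manifest.index, name="cluster_id")


def smooth_statistic(values, window: int = 3):
    """Centered running mean with edge truncation.

    Vectors shorter than the window are returned unchanged; window must be
    odd (a centered window needs a middle element).
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    v = np.asarray(values, dtype=float)
    if len(v) < window or window == 1:
        out = v.copy()
    else:
        half = window // 2
        c = np.concatenate([[0.0], np.cumsum(v)])
        n = len(v)
        lo = np.maximum(np.arange(n) - half, 0)
        hi = np.minimum(np.arange(n) + half + 1, n)
        out = (c[hi] - c[lo]) / (hi - lo)
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index)
    return out


def smooth_by_cluster(stat: pd.Series, clusters: pd.Series,
                      window: int = 3) -> pd.Series:
    """Apply :func:`smooth_statistic` within each probe cluster."""
    stat = stat.reindex(clusters.index)
    out = np.empty(len(stat))
    vals = stat.to_numpy()
    cl = clusters.to_numpy()
    breaks = np.flatnonzero(np.diff(cl) != 0) + 1
    for seg in np.split(np.arange(len(cl)), breaks):
        out[seg] = smooth_statistic(vals[seg], window)
    return pd.Series(out, index=clusters.index, name="smoothed")


def find_dmrs(smoothed: pd.Series, clusters: pd.Series,
              manifest: pd.DataFrame, cutoff_quantile: float = 0.995,
              min_probes: int = 4) -> pd.DataFrame:
    """Threshold smoothed statistics into ranked candidate regions.

    The threshold is the ``cutoff_quantile`` of |smoothed| over all probes.
    Runs never cross cluster boundaries and must keep a constant sign
    (coordinated change in one direction); a sign flip splits the run.
    Output coordinates are 0-based half-open spanning first to last probe
    plus one site width.
    """
    if len(smoothed) == 0:
        return _empty_dmr_frame()
    sm = smoothed.reindex(clusters.index).to_numpy()
    thr = float(np.quantile(np.abs(sm), cutoff_quantile))
    above = np.abs(sm) > thr
    sign = np.sign(sm)
    cl = clusters.to_numpy()
    pos = manifest.loc[clusters.index, "pos"].to_numpy()
    chrom = manifest.loc[clusters.index, "chrom"].to_numpy()
    probe_ids = clusters.index.to_numpy()

    records = []
    start = None
    for i in range(len(sm) + 1):
        end_run = (i == len(sm) or not above[i]
                   or (start is not None and (cl[i] != cl[start]
                                              or sign[i] != sign[start])))
        if start is not None and end_run:
            if i - start >= min_probes:
                seg = slice(start, i)
                records.append({
                    "chrom": chrom[start],
                    "start": int(pos[start] - 1),
                    "end": int(pos[i - 1] + 1),
                    "n_probes": i - start,
                    "mean_smoothed_stat": float(sm[seg].mean()),
                    "direction": "gain" if sign[start] > 0 else "loss",
                    "area": float(abs(sm[seg].sum())),
                    "probe_ids": list(probe_ids[seg]),
                })
            start = None
        if i < len(sm) and above[i] and start is None:
            start = i
    if not records:
        return _empty_dmr_frame()
    dmrs = pd.DataFrame(records).sort_values(
        "area", ascending=False, kind="mergesort").reset_index(drop=True)
    dmrs.index.name = "rank"
    dmrs.attrs["threshold"] = thr
    return dmrs


def _empty_dmr_frame() -> pd.DataFrame:
    return pd.DataFrame(columns=["chrom", "start", "end", "n_probes",
                                 "mean_smoothed_stat", "direction", "area",
                                 "probe_ids"])


def annotate_tss_proximity(features, manifest: pd.DataFrame,
                           window: int = 5000) -> tuple[float, pd.Series]:
    """Fraction of features within ``window`` bp of a TSS (closed interval).

    ``features`` is either a DMR table from :func:`find_dmrs` (a region is
    "within" if any constituent probe is) or an iterable of probe ids.
    """
    if "tss_distance" not in manifest.columns:
        raise KeyError("manifest lacks tss_distance")
    tss = manifest["tss_distance"]
    if isinstance(features, pd.DataFrame) and "probe_ids" in features.columns:
        flags = features["probe_ids"].map(
            lambda ps: bool((tss.loc[ps].abs() <= window).any()))
    else:
        probes = pd.Index(features)
        flags = tss.loc[probes].abs() <= window
    if len(flags) == 0:
        return float("nan"), flags
    return float(flags.mean()), flags


def dmrs_to_bed(dmrs: pd.DataFrame) -> pd.DataFrame:
    """6-column BED view of a DMR table (name = rank, score = scaled area)."""
    if dmrs.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "name",
                                     "score", "strand"])
    max_area = dmrs["area"].max()
    return pd.DataFrame({
        "chrom": dmrs["chrom"],
        "start": dmrs["start"],
        "end": dmrs["end"],
        "name": [f"DMR_{i + 1}" for i in range(len(dmrs))],
        "score": np.minimum(
            (1000 * dmrs["area"] / max_area).round().astype(int), 1000),
        "strand": ".",
    })
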