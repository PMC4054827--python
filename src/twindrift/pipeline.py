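"""End-to-end orchestration of the twin-methylome analysis stages.

Each stage function takes the upstream results and returns plain
DataFrames/dicts; :func:`run_all` chains them on a simulated cohort and is
what the CLI and the reproduction script drive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from . import differential, discordance, enrichment, preprocess, regions
from . import structure as cohort_structure
from .preprocess import QCResult, run_qc
from .simulate import (Cohort, SimulationConfig, generate_cohort,
                       generate_manifest, inject_technical_replicates)

log = logging.getLogger("twindrift.pipeline")


def simulate_cohort(config: SimulationConfig, n_islands: int = 250,
                    replicate_pairs: int = 0) -> Cohort:
    """Manifest + cohort under one config; optionally add replicate arrays.

    ``replicate_pairs`` MZ pairs (the first ones) get duplicate arrays at
    both ages with technical noise ``config.sigma_technical``.
    """
    manifest = generate_manifest(config.n_probes, n_islands=n_islands,
                                 seed=config.seed)
    cohort = generate_cohort(config, manifest)
    if replicate_pairs:
        mz = cohort.samples.loc[cohort.samples["zygosity"] == "MZ", "pair_id"]
        pick = list(dict.fromkeys(mz))[:replicate_pairs]
        cohort = inject_technical_replicates(
            cohort, pick, config.sigma_technical, seed=config.seed)
    return cohort


@dataclass
class DifferentialStage:
    result: pd.DataFrame
    admps: dict[str, pd.Index]
    gain_fraction: float
    loss_fraction: float
    summary: dict = field(default_factory=dict)


def dm_stage(qc: QCResult, fdr: float = 0.05,
             min_delta_beta: float = 0.2) -> DifferentialStage:
    """Moderated paired testing + aDMP calling on QC'ed matrices."""
    diffs_m = differential.paired_differences(qc.m_norm, qc.samples)
    diffs_b = differential.paired_differences(qc.beta_norm, qc.samples)
    delta_beta = diffs_b.mean(axis=1)
    result = differential.moderated_one_sample_test(diffs_m,
                                                    delta_beta=delta_beta)
    admps = differential.call_admps(result, fdr=fdr,
                                    min_delta_beta=min_delta_beta)
    if len(admps["relaxed"]):
        gain, loss = differential.direction_summary(admps["stringent"]
                                                    if len(admps["stringent"])
                                                    else admps["relaxed"],
                                                    result)
    else:
        gain = loss = float("nan")
    mean_abs_change = float(
        result.loc[admps["relaxed"], "delta_beta"].abs().mean()
        if len(admps["relaxed"]) else float("nan"))
    summary = {
        "n_tested": int(result["p"].notna().sum()),
        "n_significant": int(len(admps["relaxed"])),
        "n_stringent": int(len(admps["stringent"])),
        "gain_fraction": gain, "loss_fraction": loss,
        # mean |delta beta| of significant probes, total and per-year
        # (the 18-month interval spans 1.5 years)
        "mean_abs_delta_beta_significant": mean_abs_change,
        "mean_abs_delta_beta_per_year": mean_abs_change / 1.5,
        "prior_d0": float(result.attrs["prior"].d0),
        "prior_s0_sq": float(result.attrs["prior"].s0_sq),
    }
    return DifferentialStage(result=result, admps=admps, gain_fraction=gain,
                             loss_fraction=loss, summary=summary)


@dataclass
class RegionStage:
    dmrs: pd.DataFrame
    clusters: pd.Series
    tss_fraction_dmrs: float
    tss_fraction_admps: float


def dmr_stage(dm: DifferentialStage, manifest: pd.DataFrame,
              maxgap: int = 1000, window: int = 3,
              cutoff_quantile: float = 0.995,
              min_probes: int = 4, tss_window: int = 5000) -> RegionStage:
    """Bump hunting on the moderated t statistics."""
    tested = dm.result.index[dm.result["p"].notna()]
    man = manifest.loc[tested].copy()
    clusters = regions.cluster_probes(man, maxgap=maxgap)
    smoothed = regions.smooth_by_cluster(dm.result.loc[tested, "t"],
                                         clusters, window=window)
    dmrs = regions.find_dmrs(smoothed, clusters, man,
                             cutoff_quantile=cutoff_quantile,
                             min_probes=min_probes)
    frac_dmr = (regions.annotate_tss_proximity(dmrs, man, tss_window)[0]
                if len(dmrs) else float("nan"))
    admp_set = dm.admps["stringent"]
    frac_admp = (regions.annotate_tss_proximity(admp_set, man, tss_window)[0]
                 if len(admp_set) else float("nan"))
    return RegionStage(dmrs=dmrs, clusters=clusters,
                       tss_fraction_dmrs=frac_dmr,
                       tss_fraction_admps=frac_admp)


def enrich_stage(hits: pd.Index, manifest: pd.DataFrame,
                 universe: pd.Index) -> pd.DataFrame:
    """Annotation enrichment of a hit set over the QC-passing universe."""
    return enrichment.enrichment_profile(hits, manifest, universe)


@dataclass
class DiscordanceStage:
    profiles: pd.DataFrame
    delta: pd.DataFrame
    summary: dict


def discordance_stage(qc: QCResult,
                      threshold: float = 0.2,
                      rel_threshold: float = 0.10) -> DiscordanceStage:
    profiles, delta, summary = discordance.pair_profiles(
        qc.beta_norm, qc.samples, threshold=threshold,
        rel_threshold=rel_threshold)
    summary["n_pairs"] = int(len(profiles))
    summary["dynamics_counts"] = profiles["dynamics"].value_counts().to_dict()
    return DiscordanceStage(profiles=profiles, delta=delta, summary=summary)


@dataclass
class StructureStage:
    dendrogram: cohort_structure.DendrogramResult
    pairing: dict


def structure_stage(qc: QCResult) -> StructureStage:
    dend = cohort_structure.hierarchical_cluster(qc.m_norm)
    pairing: dict = {}
    for tp in ("birth", "m18"):
        cols = qc.samples.index[qc.samples["timepoint"] == tp]
        sub = qc.m_norm[cols]
        for zyg in ("MZ", "DZ"):
            try:
                frac, flags = cohort_structure.cotwin_pairing_fraction(
                    sub, qc.samples, zygosity=zyg)
            except ValueError:
                continue
            pairing[f"{zyg}_{tp}"] = {"fraction": frac, "pairs": flags}
    return StructureStage(dendrogram=dend, pairing=pairing)


@dataclass
class PipelineResult:
    cohort: Cohort
    qc: QCResult
    dm: DifferentialStage
    dmr: RegionStage
    enrich: pd.DataFrame
    disc: DiscordanceStage
    struct: StructureStage


def run_all(config: SimulationConfig, replicate_pairs: int = 0,
            exclude_samples: tuple[str, ...] = ()) -> PipelineResult:
    """Simulate a cohort and run every analysis stage on it."""
    cohort = simulate_cohort(config, replicate_pairs=replicate_pairs)
    qc = run_qc(cohort, exclude_samples=exclude_samples, seed=config.seed)
    dm = dm_stage(qc)
    dmr = dmr_stage(dm, cohort.manifest)
    universe = qc.beta_norm.index
    hits = dm.admps["stringent"]
    enr = (enrich_stage(hits, cohort.manifest, universe)
           if len(hits) else pd.DataFrame())
    disc = discordance_stage(qc)
    struct = structure_stage(qc)
    return PipelineResult(cohort=cohort, qc=qc, dm=dm, dmr=dmr, enrich=enr,
                          disc=disc, struct=struct)
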