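"""Synthetic twin-cohort methylation data with known ground truth.

Generates Infinium-450K-style probe manifests and probe x sample beta-value
matrices for monozygotic (MZ) and dizygotic (DZ) twin pairs sampled at two
timepoints (birth and 18 months).  The generative model is additive on the
logit-beta scale:

    logit(beta) = mu_probe + delta_probe * [t = 18m]
                  + genetic + shared_env + lambda_pair(t) * nonshared

MZ co-twins share the genetic draw exactly; DZ co-twins share it with a
configurable correlation (default 0.5, sibling-level sharing).  The pair
factor lambda scales only the non-shared component at 18 months, so that
lambda > 1 produces within-pair drift, lambda < 1 convergence and lambda = 1
stable discordance.  Age effects are planted with genomic-category odds
(intergenic / enhancer / open-sea enriched by default), biased toward
methylation gain, and a small number of multi-probe regions carry a common
effect so that region-level detection has something to find.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

AUTOSOMES = [f"chr{i}" for i in range(1, 21)]
SEX_CHROMS = ["chrX", "chrY"]
TIMEPOINTS = ("birth", "m18")

ISLAND_RELATIONS = ("island", "shore", "shelf", "open_sea")
GENE_FEATURES = ("TSS1500", "TSS200", "UTR5", "FirstExon", "Body", "UTR3",
                 "intergenic")

#: Relative odds that a probe in a category carries an age effect.  Keys may
#: name a gene feature, an island relation, or the flags "enhancer"/"dhs".
#: Annotation groups overlap heavily (most enhancer probes are intergenic),
#: so enriching odds (>= 1) combine by taking the strongest applicable one
#: while depleting odds (< 1) multiply; the defaults encode the observed
#: genomic bias of early-life methylation change: intergenic and enhancer
#: probes over-represented, islands and promoters depleted.
DEFAULT_REGION_WEIGHTS: Mapping[str, float] = {
    "intergenic": 6.0,
    "enhancer": 2.5,
    "open_sea": 1.7,
    "island": 0.4,
    "TSS200": 0.25,
    "TSS1500": 0.5,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the twin-cohort generator.

    Standard deviations are on the logit-beta scale.  ``age_effect_mean_beta``
    is the planted per-probe methylation change in beta units (proportion);
    affected probes get exactly this absolute change in their noise-free
    expectation, signed positive with probability ``gain_fraction``.
    """

    n_pairs: int = 15
    mz_fraction: float = 2 / 3
    n_probes: int = 20_000
    frac_age_affected: float = 0.05
    age_effect_mean_beta: float = 0.25
    gain_fraction: float = 0.87
    region_enrichment_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REGION_WEIGHTS))
    sigma_genetic: float = 0.15
    sigma_shared_env: float = 0.4
    sigma_nonshared: float = 0.15
    sigma_technical: float = 0.04
    dz_genetic_correlation: float = 0.5
    pair_dynamics: Mapping[str, float] | None = None
    n_planted_dmrs: int = 8
    dmr_probe_span: tuple[int, int] = (6, 9)
    detection_failure_rate: float = 0.005
    design_ii_compression: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mz_fraction", "frac_age_affected", "gain_fraction",
                     "detection_failure_rate", "dz_genetic_correlation",
                     "design_ii_compression"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("sigma_genetic", "sigma_shared_env", "sigma_nonshared",
                     "sigma_technical"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_pairs < 1 or self.n_probes < 1:
            raise ValueError("n_pairs and n_probes must be positive")
        if self.pair_dynamics is not None:
            for pid, lam in self.pair_dynamics.items():
                if lam <= 0:
                    raise ValueError(f"lambda for {pid} must be > 0")


@dataclass
class TruthTable:
    """Ground truth of a simulated cohort.

    ``probes`` is indexed by probe_id with columns ``true_delta_beta``
    (signed planted beta change, 0 for null probes), ``dmr_id`` (planted
    region id or empty string) and ``qc_fail`` (probe carries detection
    failures).  ``pairs`` is indexed by pair_id with columns ``lam`` and
    ``dynamics`` in {drift, converge, stable}.
    """

    probes: pd.DataFrame
    pairs: pd.DataFrame


@dataclass
class Cohort:
    """A simulated twin cohort: matrices plus metadata and ground truth."""

    beta: pd.DataFrame
    detp: pd.DataFrame
    samples: pd.DataFrame
    manifest: pd.DataFrame
    truth: TruthTable

    def copy(self) -> "Cohort":
        return Cohort(self.beta.copy(), self.detp.copy(), self.samples.copy(),
                      self.manifest.copy(),
                      TruthTable(self.truth.probes.copy(),
                                 self.truth.pairs.copy()))


# ---------------------------------------------------------------------------
# Manifest generation
# ---------------------------------------------------------------------------

def generate_manifest(n_probes: int, n_islands: int = 250, seed: int = 0, *,
                      frac_sex: float = 0.03,
                      p_genic_block: float = 0.7,
                      p_enhancer_intergenic: float = 0.25,
                      p_enhancer_genic: float = 0.05,
                      p_dhs: float = 0.12,
                      p_cdmr: float = 0.03,
                      p_rdmr: float = 0.03,
                      p_snp_in_probe: float = 0.05,
                      p_snp_at_cpg_given_snp: float = 0.15,
                      p_design_i: float = 0.3) -> pd.DataFrame:
    """Simulate a probe annotation manifest.

    Probes are laid down in locally dense blocks (3-12 probes, 50-800 bp
    apart) separated by larger gaps, mimicking the clustered probe spacing of
    the 450K array.  ``n_islands`` blocks are anchored on a CpG island; the
    island relation of every probe is then *derived* from its distance to the
    nearest island edge (inside = island, <=2 kb = shore, <=4 kb = shelf,
    >4 kb = open sea).
    """
    if n_probes < 1:
        raise ValueError("n_probes must be >= 1")
    if n_islands < 0:
        raise ValueError("n_islands must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))

    n_sex = int(round(n_probes * frac_sex))
    n_y = n_sex // 6
    n_x = n_sex - n_y
    quotas = {c: 0 for c in AUTOSOMES + SEX_CHROMS}
    per_auto = (n_probes - n_sex) // len(AUTOSOMES)
    for c in AUTOSOMES:
        quotas[c] = per_auto
    quotas["chr1"] += (n_probes - n_sex) - per_auto * len(AUTOSOMES)
    quotas["chrX"], quotas["chrY"] = n_x, n_y

    rows: list[dict] = []
    blocks: list[dict] = []  # block bookkeeping for islands / genes
    gene_counter = 0
    for chrom in AUTOSOMES + SEX_CHROMS:
        quota = quotas[chrom]
        pos = int(rng.integers(10_000, 50_000))
        placed = 0
        while placed < quota:
            blen = min(int(rng.integers(3, 13)), quota - placed)
            gaps = rng.integers(50, 801, size=max(blen - 1, 0))
            positions = pos + np.concatenate([[0], np.cumsum(gaps)]).astype(int)
            genic = rng.random() < p_genic_block
            gene = None
            if genic:
                gene_counter += 1
                gene = f"GENE{gene_counter:05d}"
            blocks.append({
                "chrom": chrom, "start": int(positions[0]),
                "end": int(positions[-1]), "n": blen, "gene": gene,
                "tss": int(positions[0]) if genic else None,
                "first_row": len(rows),
            })
            for i, p in enumerate(positions):
                if gene is None:
                    feature = "intergenic"
                elif i == 0:
                    feature = "TSS1500"
                elif i == 1:
                    feature = "TSS200"
                elif i == 2:
                    feature = "UTR5"
                elif i == 3 and blen > 4:
                    feature = "FirstExon"
                elif i == blen - 1:
                    feature = "UTR3"
                else:
                    feature = "Body"
                rows.append({"chrom": chrom, "pos": int(p),
                             "gene_feature": feature,
                             "gene": gene if gene is not None else ""})
            placed += blen
            pos = int(positions[-1] + rng.integers(5_000, 50_000))

    man = pd.DataFrame(rows)
    man.index = [f"cg{i:08d}" for i in range(1, len(man) + 1)]
    man.index.name = "probe_id"

    # islands: anchor on a random subset of blocks
    n_isl = min(n_islands, len(blocks))
    isl_blocks = rng.choice(len(blocks), size=n_isl, replace=False)
    islands: dict[str, list[tuple[int, int]]] = {}
    for bi in isl_blocks:
        b = blocks[bi]
        width = max(200, int(0.4 * (b["end"] - b["start"] + 1)))
        islands.setdefault(b["chrom"], []).append(
            (b["start"] - 100, b["start"] - 100 + width))
    man["island_relation"] = _island_relation(man, islands)

    # TSS distances (signed, position minus nearest TSS on the chromosome)
    tss_by_chrom: dict[str, np.ndarray] = {}
    for b in blocks:
        if b["tss"] is not None:
            tss_by_chrom.setdefault(b["chrom"], []).append(b["tss"])
    man["tss_distance"] = _signed_tss_distance(man, {
        c: np.sort(np.asarray(v)) for c, v in tss_by_chrom.items()})

    n = len(man)
    intergenic = (man["gene_feature"] == "intergenic").to_numpy()
    p_enh = np.where(intergenic, p_enhancer_intergenic, p_enhancer_genic)
    man["enhancer"] = rng.random(n) < p_enh
    man["dhs"] = rng.random(n) < np.where(man["enhancer"], 0.5, p_dhs)
    dmr_draw = rng.random(n)
    man["dmr_class"] = np.select(
        [dmr_draw < p_cdmr, dmr_draw < p_cdmr + p_rdmr],
        ["CDMR", "RDMR"], default="none")
    man["snp_in_probe"] = rng.random(n) < p_snp_in_probe
    man["snp_at_cpg"] = man["snp_in_probe"] & (
        rng.random(n) < p_snp_at_cpg_given_snp)
    man["design_type"] = np.where(rng.random(n) < p_design_i, "I", "II")
    return man


def _island_relation(man: pd.DataFrame,
                     islands: Mapping[str, Sequence[tuple[int, int]]]
                     ) -> np.ndarray:
    out = np.full(len(man), "open_sea", dtype=object)
    for chrom, grp in man.groupby("chrom", sort=False):
        ivals = sorted(islands.get(chrom, []))
        if not ivals:
            continue
        starts = np.array([s for s, _ in ivals])
        ends = np.array([e for _, e in ivals])
        pos = grp["pos"].to_numpy()
        d = _distance_to_intervals(pos, starts, ends)
        rel = np.select([d == 0, d <= 2000, d <= 4000],
                        ["island", "shore", "shelf"], default="open_sea")
        out[man.index.get_indexer(grp.index)] = rel
    return out


def _distance_to_intervals(pos: np.ndarray, starts: np.ndarray,
                           ends: np.ndarray) -> np.ndarray:
    """Distance from each position to the nearest interval (0 if inside)."""
    i = np.searchsorted(starts, pos, side="right") - 1
    d_prev = np.where(i >= 0,
                      np.maximum(pos - ends[np.clip(i, 0, None)], 0),
                      np.inf)
    j = np.clip(i + 1, 0, len(starts) - 1)
    d_next = np.where(i + 1 < len(starts), starts[j] - pos, np.inf)
    return np.minimum(d_prev, np.maximum(d_next, 0))


def _signed_tss_distance(man: pd.DataFrame,
                         tss: Mapping[str, np.ndarray]) -> np.ndarray:
    out = np.full(len(man), 10**9, dtype=np.int64)
    for chrom, grp in man.groupby("chrom", sort=False):
        sites = tss.get(chrom)
        if sites is None or len(sites) == 0:
            continue
        pos = grp["pos"].to_numpy()
        j = np.searchsorted(sites, pos)
        left = sites[np.clip(j - 1, 0, len(sites) - 1)]
        right = sites[np.clip(j, 0, len(sites) - 1)]
        use_left = (j > 0) & ((j == len(sites)) |
                              (np.abs(pos - left) <= np.abs(right - pos)))
        nearest = np.where(use_left, left, right)
        out[man.index.get_indexer(grp.index)] = pos - nearest
    return out


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _default_dynamics(pair_ids: Sequence[str]) -> dict[str, float]:
    """Cycle drift / stable / converge lambdas across pairs."""
    lams = [1.6, 1.0, 0.6]
    return {pid: lams[i % 3] for i, pid in enumerate(pair_ids)}


def _dynamics_label(lam: float) -> str:
    if lam > 1.0:
        return "drift"
    if lam < 1.0:
        return "converge"
    return "stable"


def _make_sample_table(config: SimulationConfig,
                       rng: np.random.Generator) -> pd.DataFrame:
    n_mz = int(round(config.n_pairs * config.mz_fraction))
    recs = []
    for k in range(config.n_pairs):
        pid = f"P{k + 1:02d}"
        zyg = "MZ" if k < n_mz else "DZ"
        chor = "MC" if (zyg == "MZ" and rng.random() < 0.5) else "DC"
        sex = "M" if rng.random() < 0.5 else "F"
        mean_w = rng.normal(2500.0, 350.0)
        disc = abs(rng.normal(0.0, 0.12))
        w = (mean_w * (1 + disc / 2), mean_w * (1 - disc / 2))
        for t in (1, 2):
            for tp in TIMEPOINTS:
                recs.append({
                    "sample_id": f"{pid}-T{t}-{tp}-r1",
                    "pair_id": pid, "twin_index": t, "zygosity": zyg,
                    "chorionicity": chor, "sex": sex, "timepoint": tp,
                    "replicate_id": 1,
                    "birth_weight": float(round(w[t - 1])),
                })
    return pd.DataFrame(recs).set_index("sample_id")


def generate_cohort(config: SimulationConfig,
                    manifest: pd.DataFrame) -> Cohort:
    """Draw a full twin cohort under ``config`` on the given manifest.

    Returns a :class:`Cohort` with beta values, detection p-values, the
    sample sheet and the ground-truth table.  Age effects (including the
    planted multi-probe regions) are restricted to autosomal probes that do
    not carry detection failures, so the truth table matches what survives
    the QC filters downstream.
    """
    if len(manifest) != config.n_probes:
        raise ValueError(
            f"manifest has {len(manifest)} probes, config expects "
            f"{config.n_probes}")
    ss = np.random.SeedSequence([config.seed, 202])
    rng = np.random.default_rng(ss)

    samples = _make_sample_table(config, rng)
    pair_ids = list(dict.fromkeys(samples["pair_id"]))
    dynamics = (dict(config.pair_dynamics) if config.pair_dynamics is not None
                else _default_dynamics(pair_ids))
    unknown = set(dynamics) - set(pair_ids)
    if unknown:
        raise ValueError(f"pair_dynamics names unknown pairs: {sorted(unknown)}")
    lam = {pid: float(dynamics.get(pid, 1.0)) for pid in pair_ids}

    n = len(manifest)
    probe_index = manifest.index

    # baseline methylation by island relation (islands hypomethylated)
    base_params = {"island": (2.0, 8.0), "shore": (3.0, 5.0),
                   "shelf": (4.0, 4.0), "open_sea": (6.0, 3.0)}
    beta0 = np.empty(n)
    for rel, (a, b) in base_params.items():
        m = (manifest["island_relation"] == rel).to_numpy()
        beta0[m] = rng.beta(a, b, size=int(m.sum()))
    beta0 = np.clip(beta0, 0.02, 0.98)

    # detection failures first, so planted effects can avoid failed probes
    qc_fail = rng.random(n) < config.detection_failure_rate

    autosomal = manifest["chrom"].isin(AUTOSOMES).to_numpy()
    eligible = autosomal & ~qc_fail

    # planted multi-probe regions on runs of consecutive probes
    dmr_id = np.full(n, "", dtype=object)
    true_delta = np.zeros(n)
    lo, hi = config.dmr_probe_span
    if config.n_planted_dmrs > 0:
        runs = _candidate_runs(manifest, eligible, min_len=hi)
        if len(runs) < config.n_planted_dmrs:
            raise ValueError("not enough dense probe runs to plant regions; "
                             "increase n_probes or reduce n_planted_dmrs")
        chosen = rng.choice(len(runs), size=config.n_planted_dmrs,
                            replace=False)
        for d, ri in enumerate(chosen):
            run = runs[ri]
            span = int(rng.integers(lo, hi + 1))
            start = int(rng.integers(0, len(run) - span + 1))
            idx = run[start:start + span]
            sign = 1.0 if rng.random() < config.gain_fraction else -1.0
            dmr_id[idx] = f"DMR{d + 1:03d}"
            true_delta[idx] = sign * config.age_effect_mean_beta

    # scattered age-affected probes with genomic-category odds
    w = _region_weights(manifest, config.region_enrichment_weights)
    free = eligible & (dmr_id == "")
    if config.frac_age_affected > 0 and free.any():
        p = np.zeros(n)
        p[free] = config.frac_age_affected * w[free] / w[free].mean()
        p = np.clip(p, 0.0, 0.95)
        affected = rng.random(n) < p
        sign = np.where(rng.random(n) < config.gain_fraction, 1.0, -1.0)
        true_delta[affected] = sign[affected] * config.age_effect_mean_beta

    # re-draw baselines of affected probes so beta0 + delta stays in range
    d_mag = config.age_effect_mean_beta
    gain_m = true_delta > 0
    loss_m = true_delta < 0
    beta0[gain_m] = rng.uniform(0.15, min(0.55, 0.97 - d_mag),
                                size=int(gain_m.sum()))
    beta0[loss_m] = rng.uniform(max(0.45, 0.03 + d_mag), 0.85,
                                size=int(loss_m.sum()))
    mu = logit(beta0)
    # Solve for the logit-scale offset that yields the planted *marginal*
    # beta change under the variance components: Gaussian noise smooths the
    # inverse-logit, so logit(beta0 + d) - logit(beta0) alone would
    # attenuate the realized effect.
    sigma_tot = np.sqrt(config.sigma_genetic**2 + config.sigma_shared_env**2
                        + config.sigma_nonshared**2)
    delta_logit = np.zeros(n)
    nz = true_delta != 0
    if nz.any():
        delta_logit[nz] = _solve_delta_logit(mu[nz], true_delta[nz],
                                             sigma_tot)

    # per-pair variance components
    n_mz = int(round(config.n_pairs * config.mz_fraction))
    rho = config.dz_genetic_correlation
    cols: dict[str, np.ndarray] = {}
    for k, pid in enumerate(pair_ids):
        prng = np.random.default_rng(np.random.SeedSequence(
            [config.seed, 303, k]))
        z0 = prng.standard_normal(n)
        if k < n_mz:
            g = (z0, z0)
        else:
            z1 = prng.standard_normal(n)
            g = (z0, rho * z0 + np.sqrt(1 - rho**2) * z1)
        shared = prng.standard_normal(n) * config.sigma_shared_env
        for t in (1, 2):
            for tp in TIMEPOINTS:
                scale = lam[pid] if tp == "m18" else 1.0
                eps = prng.standard_normal(n) * config.sigma_nonshared * scale
                x = (mu + (delta_logit if tp == "m18" else 0.0)
                     + g[t - 1] * config.sigma_genetic + shared + eps)
                cols[f"{pid}-T{t}-{tp}-r1"] = expit(x)

    beta = pd.DataFrame(cols, index=probe_index)
    beta = beta[samples.index]  # column order == sample sheet row order

    # Infinium II intensity bias: compress type II betas toward 0.5
    c = config.design_ii_compression
    if c > 0:
        m2 = (manifest["design_type"] == "II").to_numpy()
        beta.loc[m2] = 0.5 + (beta.loc[m2] - 0.5) * (1 - c)

    # detection p-values: ~0, with planted failures >0.05
    drng = np.random.default_rng(np.random.SeedSequence([config.seed, 404]))
    detp = pd.DataFrame(
        drng.uniform(0.0, 1e-4, size=beta.shape),
        index=probe_index, columns=beta.columns)
    for i in np.flatnonzero(qc_fail):
        k = int(drng.integers(1, 4))
        js = drng.choice(beta.shape[1], size=k, replace=False)
        detp.iloc[i, js] = drng.uniform(0.06, 0.5, size=k)

    truth_probes = pd.DataFrame({
        "true_delta_beta": true_delta,
        "dmr_id": dmr_id,
        "qc_fail": qc_fail,
    }, index=probe_index)
    truth_pairs = pd.DataFrame({
        "lam": [lam[p] for p in pair_ids],
        "dynamics": [_dynamics_label(lam[p]) for p in pair_ids],
    }, index=pd.Index(pair_ids, name="pair_id"))
    return Cohort(beta, detp, samples, manifest.copy(),
                  TruthTable(truth_probes, truth_pairs))


def _solve_delta_logit(mu: np.ndarray, target_delta: np.ndarray,
                       sigma: float, n_nodes: int = 31,
                       iters: int = 60) -> np.ndarray:
    """Logit offsets whose marginal beta change equals ``target_delta``.

    The marginal mean E[expit(mu + delta + sigma*Z)], Z ~ N(0,1), is
    evaluated by Gauss-Hermite quadrature; the offset is found by vectorized
    bisection (the marginal mean is strictly increasing in delta).
    """
    x, w = np.polynomial.hermite.hermgauss(n_nodes)
    z = np.sqrt(2.0) * sigma * x
    w = w / np.sqrt(np.pi)

    def marginal(shift):
        return expit(shift[:, None] + z[None, :]) @ w

    goal = marginal(mu) + target_delta
    if np.any(goal <= 0) or np.any(goal >= 1):
        raise ValueError("planted effect pushes marginal beta out of (0, 1)")
    lo = np.full(len(mu), -30.0)
    hi = np.full(len(mu), 30.0)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        too_low = marginal(mu + mid) < goal
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
    return 0.5 * (lo + hi) - 0.0


def _candidate_runs(manifest: pd.DataFrame, eligible: np.ndarray,
                    min_len: int, maxgap: int = 1000) -> list[np.ndarray]:
    """Positional runs of >= min_len consecutive eligible probes."""
    runs = []
    idx = np.arange(len(manifest))
    for _, grp in manifest.groupby("chrom", sort=False):
        gi = idx[manifest.index.get_indexer(grp.index)]
        pos = grp["pos"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) > maxgap) + 1
        for seg in np.split(np.arange(len(pos)), breaks):
            rows = gi[seg]
            if eligible[rows].all() and len(rows) >= min_len:
                runs.append(rows)
    return runs


def _region_weights(manifest: pd.DataFrame,
                    weights: Mapping[str, float]) -> np.ndarray:
    """Per-probe planting odds: max of enriching odds times depleting odds."""
    enrich = np.ones(len(manifest))
    deplete = np.ones(len(manifest))
    for key, odds in weights.items():
        if key == "enhancer":
            mask = manifest["enhancer"].to_numpy(dtype=bool)
        elif key == "dhs":
            mask = manifest["dhs"].to_numpy(dtype=bool)
        elif key in GENE_FEATURES:
            mask = (manifest["gene_feature"] == key).to_numpy()
        elif key in ISLAND_RELATIONS:
            mask = (manifest["island_relation"] == key).to_numpy()
        else:
            raise ValueError(f"unknown region weight key: {key!r}")
        odds = float(odds)
        if odds >= 1.0:
            enrich = np.maximum(enrich, np.where(mask, odds, 1.0))
        else:
            deplete = deplete * np.where(mask, odds, 1.0)
    return enrich * deplete


# ---------------------------------------------------------------------------
# Technical replicates
# ---------------------------------------------------------------------------

def inject_technical_replicates(cohort: Cohort, pair_ids: Sequence[str],
                                sigma_technical: float,
                                seed: int = 0) -> Cohort:
    """Duplicate every array of the listed pairs with technical noise.

    The duplicate gets logit-scale Gaussian noise of scale
    ``sigma_technical`` and an incremented replicate_id; with
    ``sigma_technical = 0`` the replicate is bit-identical to the original.
    """
    known = set(cohort.samples["pair_id"])
    unknown = set(pair_ids) - known
    if unknown:
        raise ValueError(f"unknown pair ids: {sorted(unknown)}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 505]))
    out = cohort.copy()
    new_beta: dict[str, np.ndarray] = {}
    new_detp: dict[str, np.ndarray] = {}
    new_rows = []
    for sid, row in cohort.samples.iterrows():
        if row["pair_id"] not in pair_ids:
            continue
        rep = int(cohort.samples[
            (cohort.samples["pair_id"] == row["pair_id"])
            & (cohort.samples["twin_index"] == row["twin_index"])
            & (cohort.samples["timepoint"] == row["timepoint"])
        ]["replicate_id"].max()) + 1
        new_id = f"{row['pair_id']}-T{row['twin_index']}-{row['timepoint']}-r{rep}"
        b = np.clip(cohort.beta[sid].to_numpy(), 1e-6, 1 - 1e-6)
        if sigma_technical > 0:
            b = expit(logit(b) + rng.standard_normal(len(b)) * sigma_technical)
        else:
            b = cohort.beta[sid].to_numpy().copy()
        new_beta[new_id] = b
        new_detp[new_id] = cohort.detp[sid].to_numpy().copy()
        r = row.copy()
        r["replicate_id"] = rep
        r.name = new_id
        new_rows.append(r)
    if not new_rows:
        warnings.warn("no arrays matched the listed pairs; nothing injected")
        return out
    out.beta = pd.concat([out.beta, pd.DataFrame(new_beta,
                                                 index=out.beta.index)], axis=1)
    out.detp = pd.concat([out.detp, pd.DataFrame(new_detp,
                                                 index=out.detp.index)], axis=1)
    out.samples = pd.concat([out.samples, pd.DataFrame(new_rows)])
    key = out.samples[["pair_id", "twin_index", "timepoint", "replicate_id"]]
    if key.duplicated().any():
        raise AssertionError("duplicate sample keys after replicate injection")
    return out


def default_config(**overrides) -> SimulationConfig:
    """The study-condition defaults, optionally overridden field-by-field."""
    return replace(SimulationConfig(), **overrides)
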