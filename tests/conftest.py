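import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import twindrift as td

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_run():
    """One full pipeline run on the default cohort (shared across tests)."""
    return td.run_all(td.default_config(seed=1))


@pytest.fixture(scope="session")
def small_cohort():
    """A fast cohort for structural tests: 4k probes, 6 pairs."""
    cfg = td.default_config(seed=11, n_probes=4000, n_pairs=6,
                            n_planted_dmrs=2)
    return td.simulate_cohort(cfg)


@pytest.fixture()
def tiny_manifest():
    """Hand-built manifest: 10 autosomal probes in two clusters + 2 chrX."""
    rows = []
    positions = [100, 600, 1100, 1400, 4000, 4300, 4600, 5000, 5400, 5800]
    for i, pos in enumerate(positions):
        rows.append({"probe_id": f"cg{i:08d}", "chrom": "chr1", "pos": pos,
                     "island_relation": "open_sea", "gene_feature": "Body",
                     "gene": "GENE1", "tss_distance": pos - 100,
                     "enhancer": False, "dhs": False, "dmr_class": "none",
                     "snp_in_probe": False, "snp_at_cpg": False,
                     "design_type": "II" if i % 2 else "I"})
    for i, pos in enumerate([200, 900]):
        rows.append({"probe_id": f"cgX{i:07d}", "chrom": "chrX", "pos": pos,
                     "island_relation": "open_sea",
                     "gene_feature": "intergenic", "gene": "",
                     "tss_distance": 10**9, "enhancer": False, "dhs": False,
                     "dmr_class": "none", "snp_in_probe": False,
                     "snp_at_cpg": False, "design_type": "I"})
    return pd.DataFrame(rows).set_index("probe_id")


def make_samples(n_pairs=2, timepoints=("birth", "m18")):
    rows = []
    for k in range(n_pairs):
        pid = f"P{k + 1:02d}"
        for t in (1, 2):
            for tp in timepoints:
                rows.append({"sample_id": f"{pid}-T{t}-{tp}-r1",
                             "pair_id": pid, "twin_index": t,
                             "zygosity": "MZ", "chorionicity": "DC",
                             "sex": "F", "timepoint": tp, "replicate_id": 1,
                             "birth_weight": 2500.0})
    return pd.DataFrame(rows).set_index("sample_id")


@pytest.fixture()
def two_pair_samples():
    return make_samples(2)


def rng(seed=0):
    return np.random.default_rng(seed)
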