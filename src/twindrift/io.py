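"""TSV readers and writers for cohort matrices and metadata.

All files are tab-separated with headers.  Matrix files (``beta.tsv``,
``detp.tsv``) carry the probe_id as the row key and one column per array;
missing values are written as ``.``.  The beta column order always equals
the sample-sheet row order.
"""

from __future__ import annotations

import os
from pathlib import Path

import pandas as pd

from .simulate import Cohort, TruthTable

NA_TOKEN = "."

MATRIX_FILES = ("beta.tsv", "detp.tsv")
TABLE_FILES = ("samples.tsv", "manifest.tsv", "truth_probes.tsv",
               "truth_pairs.tsv")


def write_matrix(mat: pd.DataFrame, path: str | os.PathLike) -> None:
    mat.to_csv(path, sep="\t", na_rep=NA_TOKEN, index_label="probe_id")


def read_matrix(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="probe_id",
                       na_values=[NA_TOKEN], keep_default_na=False)


def write_cohort(cohort: Cohort, out_dir: str | os.PathLike) -> list[Path]:
    """Write a cohort as a directory of TSV files; returns written paths."""
    if cohort.beta.empty:
        raise ValueError("refusing to write an empty cohort")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if list(cohort.beta.columns) != list(cohort.samples.index):
        raise ValueError("beta column order must equal sample sheet order")
    paths = []
    for name, df in (("beta.tsv", cohort.beta), ("detp.tsv", cohort.detp)):
        p = out / name
        write_matrix(df, p)
        paths.append(p)
    for name, df, label in (
            ("samples.tsv", cohort.samples, "sample_id"),
            ("manifest.tsv", cohort.manifest, "probe_id"),
            ("truth_probes.tsv", cohort.truth.probes, "probe_id"),
            ("truth_pairs.tsv", cohort.truth.pairs, "pair_id")):
        p = out / name
        df.to_csv(p, sep="\t", na_rep=NA_TOKEN, index_label=label)
        paths.append(p)
    return paths


def read_cohort(in_dir: str | os.PathLike) -> Cohort:
    """Read a cohort directory written by :func:`write_cohort`."""
    d = Path(in_dir)
    beta = read_matrix(d / "beta.tsv")
    detp = read_matrix(d / "detp.tsv")
    samples = pd.read_csv(d / "samples.tsv", sep="\t", index_col="sample_id",
                          na_values=[NA_TOKEN], keep_default_na=False)
    manifest = pd.read_csv(d / "manifest.tsv", sep="\t", index_col="probe_id",
                           na_values=[NA_TOKEN], keep_default_na=False)
    for col in ("enhancer", "dhs", "snp_in_probe", "snp_at_cpg"):
        if col in manifest and manifest[col].dtype != bool:
            manifest[col] = manifest[col].astype(str).str.lower().isin(
                ["true", "1"])
    tp = pd.read_csv(d / "truth_probes.tsv", sep="\t", index_col="probe_id",
                     na_values=[NA_TOKEN], keep_default_na=False)
    if "dmr_id" in tp:
        tp["dmr_id"] = tp["dmr_id"].fillna("").astype(str)
    if "qc_fail" in tp and tp["qc_fail"].dtype != bool:
        tp["qc_fail"] = tp["qc_fail"].astype(str).str.lower().isin(
            ["true", "1"])
    pp = pd.read_csv(d / "truth_pairs.tsv", sep="\t", index_col="pair_id",
                     na_values=[NA_TOKEN], keep_default_na=False)
    return Cohort(beta, detp, samples, manifest, TruthTable(tp, pp))
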