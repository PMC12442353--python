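"""Readers and writers for the package's on-disk formats.

All tables are tab-separated text: count tables have taxon ids in the first
column and sample ids in the header; metadata sheets carry one row per
sample; trees are newick.  Readers validate identifiers and value domains
so malformed inputs fail with a named record, and every writer's output is
re-readable by the matching reader (round-trip contract).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import skbio
from skbio import TreeNode

from .exceptions import FormatError

METADATA_REQUIRED = ["sample_id", "isotope", "substrate", "day", "tillage", "replicate"]
ISOTOPES = {"12C", "13C"}


def read_count_table(path) -> pd.DataFrame:
    """Read a taxa × samples integer count table from TSV."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    seen = set()
    for sample in header:  # pandas silently renames duplicate headers
        if sample in seen:
            raise FormatError(f"duplicate sample id: {sample!r}")
        seen.add(sample)
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if frame.index.duplicated().any():
        dup = frame.index[frame.index.duplicated()][0]
        raise FormatError(f"duplicate taxon id: {dup!r}")
    values = frame.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise FormatError("count table contains non-numeric entries")
    if np.isnan(values.astype(float)).any():
        raise FormatError("count table contains missing entries")
    if (values < 0).any():
        raise FormatError("count table contains negative entries")
    if not np.allclose(values, np.round(values)):
        raise FormatError("count table contains non-integer entries")
    return frame.astype(np.int64)


def write_count_table(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t")


def read_metadata(path) -> pd.DataFrame:
    """Read and validate a per-sample metadata sheet.

    Required columns: sample_id, isotope, substrate, day, tillage,
    replicate.  Gradient-fraction rows must carry ``fraction_bd`` (g/mL);
    bulk rows must carry ``dna_yield`` (ng/µL).
    """
    meta = pd.read_csv(path, sep="\t")
    missing = [c for c in METADATA_REQUIRED if c not in meta.columns]
    if missing:
        raise FormatError(f"metadata missing required columns: {missing}")
    if meta["sample_id"].duplicated().any():
        dup = meta["sample_id"][meta["sample_id"].duplicated()].iloc[0]
        raise FormatError(f"duplicate sample id: {dup!r}")
    bad_iso = set(meta["isotope"].dropna()) - ISOTOPES
    if bad_iso:
        raise FormatError(f"isotope must be one of {sorted(ISOTOPES)}; got {sorted(bad_iso)}")
    day = pd.to_numeric(meta["day"], errors="coerce")
    if day.isna().any() or (day < 0).any():
        raise FormatError("day must be a nonnegative number for every sample")
    has_bd = "fraction_bd" in meta.columns and meta["fraction_bd"].notna()
    has_yield = "dna_yield" in meta.columns and meta["dna_yield"].notna()
    if isinstance(has_bd, bool):
        has_bd = pd.Series(has_bd, index=meta.index)
    if isinstance(has_yield, bool):
        has_yield = pd.Series(has_yield, index=meta.index)
    orphan = ~(has_bd | has_yield)
    if orphan.any():
        sid = meta.loc[orphan, "sample_id"].iloc[0]
        raise FormatError(
            f"sample {sid!r} has neither fraction_bd (fraction) nor dna_yield (bulk)"
        )
    return meta.set_index("sample_id")


def write_metadata(meta: pd.DataFrame, path) -> None:
    out = meta.reset_index() if meta.index.name == "sample_id" else meta
    if "fraction_bd" in out.columns:
        out = out.assign(fraction_bd=out["fraction_bd"].round(4))
    out.to_csv(path, sep="\t", index=False)


def read_rrn(path) -> pd.Series:
    """Read a per-taxon predicted rrn copy-number table (taxon_id, rrn)."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if "rrn" not in frame.columns:
        raise FormatError("rrn table needs an 'rrn' column")
    rrn = frame["rrn"].astype(float)
    if (rrn <= 0).any():
        bad = rrn[rrn <= 0].index[0]
        raise FormatError(f"nonpositive rrn for taxon {bad!r}")
    return rrn


def read_tree(path) -> TreeNode:
    """Read a rooted newick tree."""
    return skbio.read(str(path), format="newick", into=TreeNode)


def read_mineralization(path) -> pd.DataFrame:
    """Read a mineralization series TSV (timepoint_h, c12_mg, c13_mg, ...)."""
    frame = pd.read_csv(path, sep="\t")
    required = {"timepoint_h", "c13_mg", "substrate", "tillage", "replicate"}
    missing = required - set(frame.columns)
    if missing:
        raise FormatError(f"mineralization series missing columns: {sorted(missing)}")
    return frame
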