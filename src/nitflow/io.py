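"""Readers and writers for the pipeline's plain-text formats.

Chemistry CSV: day, nh4_in_mgN_d, nh4_out_mgN_L, no2_out_mgN_L,
no3_out_mgN_L, temp_C, ph, do_mgO2_L (optionally n2_mgN_d from the
simulator).  Counts TSV: taxa rows x sample columns (sample headers are
days).  Taxonomy TSV: taxon_id, genus, phylum.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .community import CommunityTable
from .simulate import CommunityCounts, SimOutput

__all__ = [
    "CHEM_COLUMNS",
    "write_chemistry",
    "read_chemistry",
    "write_counts",
    "read_counts",
    "write_taxonomy",
    "read_taxonomy",
    "write_truth",
    "load_community",
    "align_days",
    "FLOAT_FORMAT",
]

CHEM_COLUMNS = ("day", "nh4_in_mgN_d", "nh4_out_mgN_L", "no2_out_mgN_L",
                "no3_out_mgN_L", "temp_C", "ph", "do_mgO2_L")

#: fixed float formatting so identical runs are byte-identical on disk
FLOAT_FORMAT = "%.10g"


def write_chemistry(chem: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in chem.columns if c in CHEM_COLUMNS + ("n2_mgN_d",)]
    chem[cols].to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_chemistry(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in CHEM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"chemistry file {path}: missing columns {missing}")
    for col in ("nh4_in_mgN_d", "nh4_out_mgN_L", "no2_out_mgN_L",
                "no3_out_mgN_L"):
        bad = df.index[df[col] < 0]
        if len(bad):
            raise ValueError(
                f"chemistry file {path}: negative {col} at row {bad[0]}")
    return df


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    """Counts TSV with taxa as rows and sample days as columns."""
    out = counts.T
    out.index.name = "taxon_id"
    out.columns = [f"{c:g}" if isinstance(c, float) else str(c)
                   for c in out.columns]
    out.to_csv(path, sep="\t")


def read_counts(path: str | Path) -> tuple[pd.DataFrame, np.ndarray]:
    """Read a counts TSV; returns (samples x taxa counts, sample days)."""
    raw = pd.read_csv(path, sep="\t", index_col=0)
    counts = raw.T
    neg = np.argwhere(counts.to_numpy() < 0)
    if neg.size:
        i, j = neg[0]
        raise ValueError(
            f"counts file {path}: negative count for taxon "
            f"{counts.columns[j]!r} in sample {counts.index[i]!r}")
    if not np.allclose(counts.to_numpy(),
                       np.round(counts.to_numpy().astype(float))):
        raise ValueError(f"counts file {path}: non-integer counts")
    days = counts.index.to_numpy(dtype=float)
    counts = counts.astype(np.int64)
    counts.index = days
    return counts, days


def write_taxonomy(taxonomy: pd.DataFrame, path: str | Path) -> None:
    out = taxonomy.copy()
    out.index.name = "taxon_id"
    out.to_csv(path, sep="\t")


def read_taxonomy(path: str | Path) -> pd.DataFrame:
    tax = pd.read_csv(path, sep="\t", index_col=0)
    for col in ("genus", "phylum"):
        if col not in tax.columns:
            raise ValueError(f"taxonomy file {path}: missing column {col!r}")
    return tax


def write_truth(sim: SimOutput, counts: CommunityCounts,
                path: str | Path) -> None:
    """Ground-truth JSON: planted stages and guild biomass trajectories."""
    payload = {
        "sample_days": sim.guild_biomass.index.tolist(),
        "true_stage": [int(s) for s in counts.stages],
        "guild_biomass": {g: sim.guild_biomass[g].tolist()
                          for g in sim.guild_biomass.columns},
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def load_community(counts_path: str | Path,
                   taxonomy_path: str | Path) -> CommunityTable:
    counts, days = read_counts(counts_path)
    taxonomy = read_taxonomy(taxonomy_path)
    return CommunityTable(counts=counts, sample_days=days, taxonomy=taxonomy)


def align_days(chem: pd.DataFrame, table: CommunityTable,
               logger=None) -> tuple[pd.DataFrame, CommunityTable]:
    """Restrict chemistry and community to their common sampling days."""
    chem_days = set(chem["day"].to_numpy(dtype=float))
    comm_days = set(table.sample_days.tolist())
    common = sorted(chem_days & comm_days)
    if not common:
        raise ValueError("chemistry and community share no sampling days")
    dropped = sorted((chem_days | comm_days) - set(common))
    if dropped and logger is not None:
        logger.warning("dropping unmatched sampling days: %s", dropped)
    chem_out = chem[chem["day"].isin(common)].reset_index(drop=True)
    mask = np.isin(table.sample_days, common)
    table_out = CommunityTable(
        counts=table.counts.loc[mask],
        sample_days=table.sample_days[mask],
        taxonomy=table.taxonomy,
    )
    return chem_out, table_out
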