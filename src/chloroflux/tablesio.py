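"""Delimited-text readers and writers for all pipeline tables.

Every table is plain tab-separated text with a one-line header; an optional
metadata block (units, enrichment scale, provenance) is carried as leading
``#`` comment lines.  No binary formats.

Formats
-------
MID table
    columns ``metabolite, fragment_id, n_carbons, time_s, replicate, m0...mk``;
    one row per fragment per time per replicate.  Missing high-mass channels
    are treated as zero.
pool table
    ``metabolite, pool_umol_per_gDW, n_carbons``.
biomass table
    ``quantity, value, unit`` rows (protein_mg_per_gDW, lipid_mgFA_per_gDW,
    starch_umolC6_per_gDW, growth_rate_per_h).
enrichment matrix
    rows metabolites, columns time points (percent enrichment).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .fluxest import PoolTable
from .kinetics import LabelSeries
from .mids import IsotopeModel, correct_natural_abundance, enrichment, normalize_mid

__all__ = [
    "read_table",
    "write_table",
    "read_mid_table",
    "read_pool_table",
    "read_biomass_table",
    "correct_mid_table",
    "enrichment_table",
    "label_series_from_enrichment",
]


def write_table(df: pd.DataFrame, path, metadata: dict | None = None,
                index: bool = False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, v in (metadata or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def _mass_columns(df: pd.DataFrame) -> list:
    return sorted((c for c in df.columns if c.startswith("m") and c[1:].isdigit()),
                  key=lambda c: int(c[1:]))


def read_mid_table(path) -> pd.DataFrame:
    df = read_table(path)
    required = {"metabolite", "n_carbons", "time_s", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"MID table missing columns: {sorted(missing)}")
    for c in _mass_columns(df):
        df[c] = df[c].fillna(0.0)
    return df


def read_pool_table(path) -> PoolTable:
    df = read_table(path)
    return PoolTable({
        row["metabolite"]: (float(row["pool_umol_per_gDW"]),
                            int(row["n_carbons"]))
        for _, row in df.iterrows()
    })


def read_biomass_table(path) -> dict:
    df = read_table(path)
    return dict(zip(df["quantity"], df["value"].astype(float)))


def correct_mid_table(df: pd.DataFrame,
                      model: IsotopeModel | None = None) -> pd.DataFrame:
    """Normalize and natural-abundance-correct every row of a MID table."""
    model = model or IsotopeModel()
    mcols = _mass_columns(df)
    out = df.copy()
    for idx, row in df.iterrows():
        n = int(row["n_carbons"])
        raw = row[mcols[: n + 1]].to_numpy(dtype=float)
        mid, _ = normalize_mid(raw, str(row["metabolite"]), n)
        corr = correct_natural_abundance(mid, model)
        out.loc[idx, mcols[: n + 1]] = corr.fractions
    return out


def enrichment_table(df: pd.DataFrame) -> pd.DataFrame:
    """Long-format fractional enrichment per metabolite/time/replicate."""
    mcols = _mass_columns(df)
    rows = []
    for _, row in df.iterrows():
        n = int(row["n_carbons"])
        frac = row[mcols[: n + 1]].to_numpy(dtype=float)
        mid, _ = normalize_mid(frac, str(row["metabolite"]), n)
        rows.append((row["metabolite"], float(row["time_s"]),
                     int(row["replicate"]), enrichment(mid)))
    return pd.DataFrame(rows, columns=["metabolite", "time_s", "replicate",
                                       "enrichment"])


def label_series_from_enrichment(enr: pd.DataFrame,
                                 pools: PoolTable | None = None) -> dict:
    """Pivot a long enrichment table into per-metabolite LabelSeries."""
    out = {}
    for met, g in enr.groupby("metabolite"):
        wide = g.pivot_table(index="replicate", columns="time_s",
                             values="enrichment")
        times = wide.columns.to_numpy(dtype=float)
        pool = n_c = None
        if pools is not None and met in pools:
            pool = pools.pool(met)
            n_c = pools.n_carbons(met)
        out[met] = LabelSeries(str(met), times, wide.to_numpy(),
                               pool_size=pool, n_carbons=n_c)
    return out
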