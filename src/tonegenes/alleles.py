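"""Harmonization of locus-level allele-frequency measurements.

Population-genetic databases report the frequency of the ASPM and MCPH1
"derived" haplotypes either directly or through proxy SNPs in near-perfect
linkage disequilibrium with them.  This module pools all locus-level
measurements available for one genetic sample into a single
sample-size-weighted derived-allele frequency per gene,

    wavg = sum_i(f_i * N_i) / sum_i(N_i),

where ``f_i`` is the derived-allele frequency reported by source *i* and
``N_i`` the number of genotyped alleles (normally twice the number of
genotyped individuals).  LD imperfection between proxies and targets is
deliberately ignored in the pooling; an ``exclude_proxies`` switch allows
the sensitivity analysis that drops proxy loci altogether.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "GENES",
    "ProxyMap",
    "load_default_proxy_map",
    "weighted_average_frequency",
    "harmonize",
    "attach_populations",
]

logger = logging.getLogger(__name__)

GENES = ("ASPM", "MCPH1")

#: expected columns of a locus-level input table
LOCUS_COLUMNS = ["sample_id", "population_id", "gene", "locus_id", "f", "n_alleles", "source"]


@dataclass(frozen=True)
class ProxyMap:
    """Mapping locus_id -> (gene, role) where role is 'target' or 'proxy'."""

    table: pd.DataFrame  # columns: gene, locus_id, derived_allele, role

    def __post_init__(self) -> None:
        t = self.table
        missing = {"gene", "locus_id", "role"} - set(t.columns)
        if missing:
            raise ValueError(f"proxy map lacks columns: {sorted(missing)}")
        for gene in GENES:
            if not (t["gene"] == gene).any():
                raise ValueError(f"proxy map has no locus for gene {gene}")
        dup = t.duplicated(subset=["gene", "locus_id"])
        if dup.any():
            raise ValueError("duplicate locus ids within a gene in proxy map")

    def gene_of(self, locus_id: str) -> str | None:
        hits = self.table.loc[self.table["locus_id"] == locus_id, "gene"]
        return None if hits.empty else str(hits.iloc[0])

    def is_proxy(self, locus_id: str) -> bool:
        hits = self.table.loc[self.table["locus_id"] == locus_id, "role"]
        return bool((hits == "proxy").any())

    @classmethod
    def from_tsv(cls, path) -> "ProxyMap":
        return cls(pd.read_csv(path, sep="\t", dtype=str))


def load_default_proxy_map() -> ProxyMap:
    """The packaged target/proxy locus map for ASPM-D and MCPH1-D."""
    ref = importlib.resources.files("tonegenes.data") / "proxy_snps.tsv"
    with importlib.resources.as_file(ref) as path:
        return ProxyMap.from_tsv(path)


def weighted_average_frequency(observations: pd.DataFrame) -> dict:
    """Pool locus observations for one sample x gene into one frequency.

    Parameters
    ----------
    observations : DataFrame with columns f, n_alleles (plus sample_id,
        population_id, gene, which must each be constant).

    Returns
    -------
    dict with keys sample_id, population_id, gene, wavg, total_n.
    """
    if len(observations) == 0:
        raise ValueError("no locus observations to pool (missing data)")
    for col in ("sample_id", "gene"):
        if col in observations.columns and observations[col].nunique() > 1:
            raise ValueError(f"mixed values of {col!r} in one pooling group")
    f = observations["f"].astype(float)
    n = observations["n_alleles"].astype(float)
    if ((f < 0) | (f > 1)).any():
        raise ValueError("allele frequency outside [0, 1]")
    if (n < 1).any():
        raise ValueError("n_alleles must be >= 1")
    total_n = float(n.sum())
    out = {
        "wavg": float((f * n).sum() / total_n),
        "total_n": int(round(total_n)),
    }
    for col in ("sample_id", "population_id", "gene"):
        if col in observations.columns:
            out[col] = observations[col].iloc[0]
    return out


def harmonize(
    locus_table: pd.DataFrame,
    proxy_map: ProxyMap | None = None,
    exclude_proxies: bool = False,
) -> pd.DataFrame:
    """Aggregate a locus-level table into one row per (sample, gene).

    Rows whose locus cannot be resolved to a gene through the proxy map are
    excluded with a warning.  Samples lacking data for a gene simply have no
    row for it: missing frequencies are never imputed.
    """
    if proxy_map is None:
        proxy_map = load_default_proxy_map()
    cols = ["sample_id", "population_id", "gene", "wavg", "total_n"]
    if len(locus_table) == 0:
        return pd.DataFrame(columns=cols)

    table = locus_table.copy()
    resolved = table["locus_id"].map(proxy_map.gene_of)
    unresolvable = resolved.isna()
    if unresolvable.any():
        bad = sorted(table.loc[unresolvable, "locus_id"].unique())
        logger.warning("excluding %d rows with loci not in the proxy map: %s",
                       int(unresolvable.sum()), bad)
        table = table[~unresolvable]
        resolved = resolved[~unresolvable]
    # a locus determines its gene; trust the map over the input column
    table = table.assign(gene=resolved.values)

    if exclude_proxies:
        keep = ~table["locus_id"].map(proxy_map.is_proxy)
        table = table[keep]

    if len(table) == 0:
        return pd.DataFrame(columns=cols)

    rows = [
        weighted_average_frequency(group)
        for _, group in table.groupby(["sample_id", "gene"], sort=True)
    ]
    return pd.DataFrame(rows)[cols].reset_index(drop=True)


def attach_populations(sample_table: pd.DataFrame, population_metadata: pd.DataFrame) -> pd.DataFrame:
    """Attach (meta)population ids and readable names to a sample table.

    ``population_metadata`` must have columns sample_id, population_id and
    optionally population_name; every sample must be covered (a sample
    belongs to exactly one (meta)population).
    """
    meta = population_metadata.drop_duplicates(subset="sample_id")
    multi = population_metadata.groupby("sample_id")["population_id"].nunique()
    conflicted = multi[multi > 1]
    if len(conflicted):
        raise ValueError(f"samples mapped to multiple populations: {sorted(conflicted.index)}")
    unknown = sorted(set(sample_table["sample_id"]) - set(meta["sample_id"]))
    if unknown:
        raise KeyError(f"samples absent from population metadata: {unknown}")
    keep = ["sample_id", "population_id"]
    if "population_name" in meta.columns:
        keep.append("population_name")
    out = sample_table.drop(columns=[c for c in keep[1:] if c in sample_table.columns])
    return out.merge(meta[keep], on="sample_id", how="left")
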