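"""Assembly of the analysis table joining allele frequencies and tone.

Genetic samples map to languages (Glottocodes) many-to-many, so the merge
is a Cartesian expansion of each sample over its mapped Glottocodes,
annotated with the language's Glottolog family and macroarea.  To avoid
over-counting near-duplicate information the expanded table is then pruned:
within a sample, Glottocodes sharing the same tone value collapse to one
row; within a (meta)population, samples sharing identical (ASPM-D,
MCPH1-D) frequencies collapse to one row.  Divergent values are all kept,
preserving genuine uncertainty.

Derived analysis variables: z-scored allele frequencies, the Africa
indicator, and ``tone2`` (complex tone vs none-or-simple).  Descriptive
Pearson chi-square tests round the module out.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MACROAREAS",
    "merge",
    "collapse_americas",
    "deduplicate",
    "derive_variables",
    "zscore",
    "unit_counts",
    "gof_chisq",
    "contingency_chisq",
    "build_analysis_table",
]

MACROAREAS = ("Africa", "Eurasia", "America", "Papunesia")

_OUTCOME_COLS = {"tone1": "tone1", "tone2": "tone2", "counts": "count"}


def merge(
    sample_frequencies: pd.DataFrame,
    tone_codings: pd.DataFrame,
    sample_to_glottocode: pd.DataFrame,
    glottolog_metadata: pd.DataFrame,
) -> pd.DataFrame:
    """Cartesian sample x mapped-Glottocode expansion with family/macroarea.

    ``sample_frequencies`` is long (sample_id, population_id, gene, wavg) as
    produced by :func:`tonegenes.alleles.harmonize`; it is pivoted wide so a
    row needs both genes to carry both frequencies (missing stays missing).
    """
    wide = (
        sample_frequencies.pivot_table(
            index=["sample_id", "population_id"], columns="gene", values="wavg", aggfunc="first"
        )
        .rename(columns={"ASPM": "aspm_freq", "MCPH1": "mcph1_freq"})
        .reset_index()
    )
    wide.columns.name = None
    expanded = wide.merge(sample_to_glottocode[["sample_id", "glottocode"]], on="sample_id")
    expanded = expanded.merge(tone_codings, on="glottocode", how="left")

    meta_cols = ["glottocode", "family", "macroarea"]
    meta = glottolog_metadata[meta_cols].drop_duplicates("glottocode")
    missing = sorted(set(expanded["glottocode"]) - set(meta["glottocode"]))
    if missing:
        raise KeyError(f"glottocodes lacking family/macroarea metadata: {missing}")
    bad = meta[meta[["family", "macroarea"]].isna().any(axis=1)]
    if len(bad):
        raise KeyError(
            f"glottocodes lacking family/macroarea metadata: {sorted(bad['glottocode'])}"
        )
    return expanded.merge(meta, on="glottocode")


def collapse_americas(table: pd.DataFrame) -> pd.DataFrame:
    """Replace the North/South America labels by a single 'America' (idempotent)."""
    out = table.copy()
    out["macroarea"] = out["macroarea"].replace(
        {"North America": "America", "South America": "America"}
    )
    return out


def deduplicate(table: pd.DataFrame, outcome: str) -> pd.DataFrame:
    """Collapse rows that duplicate the signal for the chosen outcome.

    Within each sample, mapped Glottocodes with an identical outcome value
    are reduced to one row; within each (meta)population, samples with
    identical (aspm_freq, mcph1_freq) are reduced to one row.  Equality is
    exact (label equality for tone, floating equality for frequencies).
    Rows with a missing outcome or missing frequency are dropped first.
    """
    col = _OUTCOME_COLS[outcome]
    out = table.dropna(subset=[col, "aspm_freq", "mcph1_freq"]).copy()
    out = out.drop_duplicates(subset=["sample_id", col], keep="first")
    out = out.drop_duplicates(subset=["population_id", "sample_id", col, "aspm_freq", "mcph1_freq"])
    # within a (meta)population, samples carrying identical allele signals collapse
    out = out.drop_duplicates(subset=["population_id", col, "aspm_freq", "mcph1_freq"])
    return out.reset_index(drop=True)


def zscore(values) -> np.ndarray:
    """Standardize to mean 0, sd 1 (n - 1 denominator)."""
    x = np.asarray(values, dtype=float)
    if len(np.unique(x)) < 2:
        raise ValueError("cannot z-score a constant column")
    return (x - x.mean()) / x.std(ddof=1)


def derive_variables(table: pd.DataFrame) -> pd.DataFrame:
    """Add africa indicator, tone2 and z-scored allele frequencies.

    z-scores are computed over the rows of ``table`` itself, i.e. over the
    final (deduplicated) analysis subset, separately per outcome dataset.
    """
    out = table.copy()
    out["africa"] = (out["macroarea"] == "Africa").astype(int)
    if "tone3way" in out.columns:
        out["tone2"] = out["tone3way"].map(
            lambda v: None if pd.isna(v) else ("Yes" if v == "Complex" else "No")
        )
    out["aspm_z"] = zscore(out["aspm_freq"])
    out["mcph1_z"] = zscore(out["mcph1_freq"])
    return out


def unit_counts(table: pd.DataFrame) -> dict:
    """The samples:populations:glottocodes counting report plus row count."""
    return {
        "observations": int(len(table)),
        "samples": int(table["sample_id"].nunique()),
        "populations": int(table["population_id"].nunique()),
        "glottocodes": int(table["glottocode"].nunique()),
        "families": int(table["family"].nunique()) if "family" in table.columns else None,
    }


def build_analysis_table(
    sample_frequencies: pd.DataFrame,
    tone_codings: pd.DataFrame,
    sample_to_glottocode: pd.DataFrame,
    glottolog_metadata: pd.DataFrame,
    outcome: str = "tone1",
) -> pd.DataFrame:
    """Full pipeline: merge, collapse Americas, add tone2, dedup, derive z-scores."""
    table = merge(sample_frequencies, tone_codings, sample_to_glottocode, glottolog_metadata)
    table = collapse_americas(table)
    if "tone3way" in table.columns:
        table["tone2"] = table["tone3way"].map(
            lambda v: None if pd.isna(v) else ("Yes" if v == "Complex" else "No")
        )
    table = deduplicate(table, outcome)
    return derive_variables(table)


def gof_chisq(observed_counts) -> tuple[float, int, float]:
    """Pearson goodness-of-fit test against equal category probabilities."""
    obs = np.asarray(observed_counts, dtype=float)
    if obs.ndim != 1 or len(obs) < 2:
        raise ValueError("need a 1-D vector of >= 2 category counts")
    if (obs < 0).any() or obs.sum() == 0:
        raise ValueError("counts must be non-negative and not all zero")
    stat, p = stats.chisquare(obs)
    return float(stat), len(obs) - 1, float(p)


def contingency_chisq(table) -> tuple[float, int, float]:
    """Pearson chi-square of independence, no continuity correction."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("degenerate contingency table")
    stat, p, df, _ = stats.chi2_contingency(obs, correction=False)
    return float(stat), int(df), float(p)
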