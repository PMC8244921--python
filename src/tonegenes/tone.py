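"""Harmonization of linguistic-tone codings across typological databases.

Five sources describe tone with incompatible schemes: WALS (3-way labels),
LAPSyD (5-way labels plus a tone count), DL2007 (binary), PHOIBLE (count of
tone symbols) and WPHON (count of tonal contrasts).  Each source is recoded
into up to three per-language codings,

* ``tone1``  — binary: does the language use tone at all ("No"/"Yes"),
* ``tone3way`` — ordered: "None" < "Simple" < "Complex",
* ``count``  — a non-negative integer number of tones/tone symbols,

and the sources are then reconciled per Glottocode by a precedence
hierarchy ("pick the highest available source").  Counts from the two
count-level sources are first *rebased* (1 is collapsed with 2, then every
count >= 2 is shifted down by one) and *aligned* to the LAPSyD gold
standard through a quadratic regression fitted on languages covered by
both sources.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "SOURCES",
    "CATEGORICAL_HIERARCHY",
    "COUNT_HIERARCHY",
    "ALT_CATEGORICAL_HIERARCHY",
    "ALT_COUNT_HIERARCHY",
    "CountAlignmentModel",
    "recode_source",
    "rebase_counts",
    "fit_count_alignment",
    "align_counts",
    "agreement_coding",
    "harmonize_tone",
]

SOURCES = ("WALS", "LAPSyD", "DL2007", "PHOIBLE", "WPHON")

# default precedence (manually curated categorical sources first)
CATEGORICAL_HIERARCHY = ("LAPSyD", "WALS", "DL2007", "WPHON", "PHOIBLE")
COUNT_HIERARCHY = ("LAPSyD", "WPHON", "PHOIBLE")
# alternative hierarchy used as a robustness check
ALT_CATEGORICAL_HIERARCHY = ("WALS", "WPHON", "LAPSyD", "DL2007", "PHOIBLE")
ALT_COUNT_HIERARCHY = ("WPHON", "LAPSyD", "PHOIBLE")

_WALS_VALUES = {"No tones", "Simple tone system", "Complex tone system"}
_LAPSYD_VALUES = {"None", "Marginal", "Simple", "Moderately complex", "Complex"}
_DL2007_VALUES = {"No", "Yes"}

_3WAY_ORDER = ("None", "Simple", "Complex")


def recode_source(source: str, raw_value) -> dict:
    """Recode one source-specific value into partial {tone1, tone3way, count}.

    Sources that carry no information for a coding omit that key entirely.
    Counts are returned *raw* (not rebased, not aligned): rebasing and
    alignment are separate, later steps of the count pipeline.
    """
    if source == "WALS":
        if raw_value not in _WALS_VALUES:
            raise ValueError(f"inadmissible WALS value {raw_value!r}")
        three = {"No tones": "None",
                 "Simple tone system": "Simple",
                 "Complex tone system": "Complex"}[raw_value]
        return {"tone1": "No" if three == "None" else "Yes", "tone3way": three}
    if source == "LAPSyD":
        if isinstance(raw_value, str):
            if raw_value not in _LAPSYD_VALUES:
                raise ValueError(f"inadmissible LAPSyD label {raw_value!r}")
            if raw_value == "None":
                three = "None"
            elif raw_value in ("Marginal", "Simple"):
                three = "Simple"
            else:
                three = "Complex"
            return {"tone1": "No" if three == "None" else "Yes", "tone3way": three}
        # numeric LAPSyD value = the gold-standard tone count
        return {"count": _check_count("LAPSyD", raw_value)}
    if source == "DL2007":
        if raw_value not in _DL2007_VALUES:
            raise ValueError(f"inadmissible DL2007 value {raw_value!r}")
        return {"tone1": raw_value}
    if source == "PHOIBLE":
        c = _check_count("PHOIBLE", raw_value)
        three = "None" if c == 0 else ("Simple" if c <= 2 else "Complex")
        return {"tone1": "No" if c == 0 else "Yes", "tone3way": three, "count": c}
    if source == "WPHON":
        c = _check_count("WPHON", raw_value)
        three = "None" if c == 0 else ("Simple" if c <= 3 else "Complex")
        return {"tone1": "No" if c == 0 else "Yes", "tone3way": three, "count": c}
    raise ValueError(f"unknown source {source!r}")


def _check_count(source: str, value) -> int:
    c = int(value)
    if c != value or c < 0:
        raise ValueError(f"inadmissible {source} count {value!r}")
    return c


def rebase_counts(raw_count: int) -> int:
    """Rebase a tone count: collapse 1 with 2, then shift counts >= 2 down by 1.

    The composition maps 0 -> 0, 1 -> 1 (via 1 -> 2 -> 1) and n -> n - 1 for
    n >= 2, giving a gap-free scale from 0 to the original maximum minus one.
    """
    c = _check_count("rebase", raw_count)
    if c == 1:
        c = 2
    return c if c < 2 else c - 1


@dataclass(frozen=True)
class CountAlignmentModel:
    """Quadratic map from a source's (rebased) counts to the gold scale."""

    source: str
    intercept: float
    linear: float
    quadratic: float
    se: tuple = field(default=(float("nan"),) * 3)

    def predict(self, raw_count: float) -> float:
        c = float(raw_count)
        return self.intercept + self.linear * c + self.quadratic * c * c


#: default alignment coefficients (gold LAPSyD count regressed on
#: rebased WPHON / PHOIBLE counts)
DEFAULT_ALIGNMENTS = {
    "WPHON": CountAlignmentModel("WPHON", 0.08, 0.92, -0.04),
    "PHOIBLE": CountAlignmentModel("PHOIBLE", 0.39, 0.68, -0.04),
}


def fit_count_alignment(paired_counts, source: str) -> CountAlignmentModel:
    """OLS of gold counts on a source's counts and their square.

    ``paired_counts`` is an iterable of (gold_count, source_count) pairs for
    languages present in both databases.
    """
    pairs = np.asarray(list(paired_counts), dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or pairs.shape[0] < 4:
        raise ValueError("need >= 4 (gold, source) pairs to fit a quadratic")
    gold, src = pairs[:, 0], pairs[:, 1]
    X = np.column_stack([np.ones_like(src), src, src ** 2])
    if np.linalg.matrix_rank(X) < 3:
        raise np.linalg.LinAlgError("rank-deficient design (too few distinct source counts)")
    fit = sm.OLS(gold, X).fit()
    return CountAlignmentModel(source, *map(float, fit.params), se=tuple(map(float, fit.bse)))


def _round_half_away(x: float) -> int:
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def align_counts(model: CountAlignmentModel, raw_count) -> int:
    """Predicted gold-scale count: rounded (half away from zero), floored at 0."""
    return max(0, _round_half_away(model.predict(raw_count)))


def _deduce(values: dict) -> dict:
    """Deduce coarser codings from finer ones (binary < 3-way < count)."""
    out = dict(values)
    if "tone3way" not in out and "count" in out:
        c = out["count"]
        out["tone3way"] = "None" if c == 0 else ("Simple" if c <= 2 else "Complex")
        out.setdefault("_prov_tone3way", out.get("_prov_count"))
    if "tone1" not in out and "tone3way" in out:
        out["tone1"] = "No" if out["tone3way"] == "None" else "Yes"
        out.setdefault("_prov_tone1", out.get("_prov_tone3way"))
    return out


def agreement_coding(
    records: pd.DataFrame,
    hierarchy=CATEGORICAL_HIERARCHY,
    count_hierarchy=COUNT_HIERARCHY,
    alignments: dict | None = None,
) -> dict:
    """Reconcile the per-source records of one Glottocode into one ToneCoding.

    ``records`` needs columns source, value_type ('category'|'count') and
    value.  Conflicts are resolved purely by precedence: for each coding the
    value of the highest-ranked source that carries it wins.  Counts from
    non-gold sources are rebased and aligned to the gold scale first.
    Codings no source can supply come back as None (missing), never an error.
    """
    if alignments is None:
        alignments = DEFAULT_ALIGNMENTS
    per_source: dict[str, dict] = {}
    for _, row in records.iterrows():
        src = row["source"]
        value = row["value"]
        if row.get("value_type") == "count" or not isinstance(value, str):
            value = int(value)
        coded = recode_source(src, value)
        per_source.setdefault(src, {}).update(coded)

    result: dict = {}
    # categorical codings by precedence
    for coding in ("tone1", "tone3way"):
        for src in hierarchy:
            if src in per_source and coding in per_source[src]:
                result[coding] = per_source[src][coding]
                result[f"_prov_{coding}"] = src
                break
    # counts by their own precedence, with rebasing + alignment off gold
    for src in count_hierarchy:
        if src in per_source and "count" in per_source[src]:
            raw = per_source[src]["count"]
            rebased = rebase_counts(raw)
            if src in alignments:
                result["count"] = align_counts(alignments[src], rebased)
            else:  # the gold source passes through
                result["count"] = rebased
            result["_prov_count"] = src
            break

    result = _deduce(result)
    provenance = {k.replace("_prov_", ""): v for k, v in result.items() if k.startswith("_prov_")}
    return {
        "tone1": result.get("tone1"),
        "tone3way": result.get("tone3way"),
        "count": result.get("count"),
        "provenance": provenance,
    }


def harmonize_tone(
    long_table: pd.DataFrame,
    hierarchy=CATEGORICAL_HIERARCHY,
    count_hierarchy=COUNT_HIERARCHY,
    alignments: dict | None = None,
) -> pd.DataFrame:
    """Agreement codings for every Glottocode in a long-format source table.

    Input columns: glottocode, source, value_type, value.  Output: one row
    per glottocode with tone1, tone3way, count and provenance columns.
    """
    rows = []
    for glottocode, group in long_table.groupby("glottocode", sort=True):
        coding = agreement_coding(group, hierarchy, count_hierarchy, alignments)
        prov = coding.pop("provenance")
        rows.append({
            "glottocode": glottocode,
            **coding,
            "tone1_source": prov.get("tone1"),
            "tone3way_source": prov.get("tone3way"),
            "count_source": prov.get("count"),
        })
    out = pd.DataFrame(rows)
    if len(out):
        out["count"] = out["count"].astype("Int64")
    return out
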