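"""Constrained permutations and one-language-per-family restricted sampling.

The permutation framework crosses three choices — what is permuted (the
tone outcome; the two allele columns together as linked pairs; each allele
independently), within what strata (unrestricted, within macroareas,
within families), and whether the refitted model controls for macroarea as
a fixed effect — into 18 scenarios named by 3-letter codes (first letter
T/L/I, second U/M/F, third N/F; e.g. TUN, IMF).  Each scenario refits the
regression on permuted data and summarizes how often the permuted fits
beat the observed one on AIC or produce a smaller (more negative) allele
coefficient.

Restricted sampling instead repeatedly draws exactly one row per family
and fits fixed-effects models (no random intercept is needed once every
family contributes a single observation), summarizing the distribution of
the allele coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .regression import FitResult, ModelSpec, fit_glm, fit_mixed

__all__ = [
    "PermutationScenario",
    "ALL_SCENARIOS",
    "permute_table",
    "run_scenario",
    "run_all_scenarios",
    "restricted_sample",
    "run_restricted",
    "RESTRICTED_VARIANTS",
]

_PERMUTE_CODE = {"tone": "T", "alleles-together": "L", "alleles-independent": "I"}
_WITHIN_CODE = {"unrestricted": "U", "macroareas": "M", "families": "F"}
_CONTROL_CODE = {"none": "N", "fixef": "F"}


@dataclass(frozen=True)
class PermutationScenario:
    permute: str          # tone | alleles-together | alleles-independent
    within: str           # unrestricted | macroareas | families
    macroarea_control: str  # none | fixef

    def __post_init__(self):
        for value, table in ((self.permute, _PERMUTE_CODE), (self.within, _WITHIN_CODE),
                             (self.macroarea_control, _CONTROL_CODE)):
            if value not in table:
                raise ValueError(f"unknown scenario parameter {value!r}")

    @property
    def name(self) -> str:
        return (_PERMUTE_CODE[self.permute] + _WITHIN_CODE[self.within]
                + _CONTROL_CODE[self.macroarea_control])

    @classmethod
    def from_name(cls, name: str) -> "PermutationScenario":
        rev = [{v: k for k, v in m.items()} for m in
               (_PERMUTE_CODE, _WITHIN_CODE, _CONTROL_CODE)]
        if len(name) != 3 or any(c not in r for c, r in zip(name.upper(), rev)):
            raise ValueError(f"not a scenario name: {name!r}")
        p, w, c = (r[c] for c, r in zip(name.upper(), rev))
        return cls(p, w, c)


#: the full 3 x 3 x 2 design
ALL_SCENARIOS = tuple(
    PermutationScenario(p, w, c)
    for p in _PERMUTE_CODE
    for w in _WITHIN_CODE
    for c in _CONTROL_CODE
)


def _strata(table: pd.DataFrame, within: str) -> np.ndarray:
    if within == "unrestricted":
        return np.zeros(len(table), dtype=int)
    col = {"macroareas": "macroarea", "families": "family"}[within]
    return pd.factorize(table[col])[0]


def _permuted_index(table: pd.DataFrame, within: str, rng: np.random.Generator) -> np.ndarray:
    idx = np.arange(len(table))
    strata = _strata(table, within)
    out = idx.copy()
    for s in np.unique(strata):
        members = idx[strata == s]
        out[members] = rng.permutation(members)
    return out


def permute_table(table: pd.DataFrame, scenario: PermutationScenario,
                  rng: np.random.Generator, outcome_col: str = "tone1") -> pd.DataFrame:
    """One permuted copy of ``table`` under the scenario's constraints.

    The permuted column(s) are a multiset-preserving rearrangement within
    each stratum; everything else stays in place.
    """
    out = table.reset_index(drop=True).copy()
    if scenario.permute == "tone":
        perm = _permuted_index(out, scenario.within, rng)
        out[outcome_col] = out[outcome_col].to_numpy()[perm]
    elif scenario.permute == "alleles-together":
        perm = _permuted_index(out, scenario.within, rng)
        for col in ("aspm_z", "mcph1_z", "aspm_freq", "mcph1_freq"):
            if col in out.columns:
                out[col] = out[col].to_numpy()[perm]
    else:  # alleles-independent
        for cols in (("aspm_z", "aspm_freq"), ("mcph1_z", "mcph1_freq")):
            perm = _permuted_index(out, scenario.within, rng)
            for col in cols:
                if col in out.columns:
                    out[col] = out[col].to_numpy()[perm]
    return out


def _scenario_spec(base: ModelSpec, scenario: PermutationScenario) -> ModelSpec:
    fixed = tuple(t for t in base.fixed if t != "macroarea")
    if scenario.macroarea_control == "fixef":
        fixed = fixed + ("macroarea",)
    return ModelSpec(base.outcome, base.family, fixed, base.random_intercept)


def _fit(spec: ModelSpec, table: pd.DataFrame, **kwargs) -> FitResult:
    if spec.random_intercept is not None:
        return fit_mixed(spec, table, **kwargs)
    return fit_glm(spec, table)


def run_scenario(
    table: pd.DataFrame,
    scenario: PermutationScenario,
    model_spec: ModelSpec,
    n: int = 1000,
    rng: np.random.Generator | None = None,
    max_failure_rate: float = 0.10,
    **fit_kwargs,
) -> dict:
    """Permutation summary for one scenario.

    Refits the model (with macroarea added/removed per the scenario's
    control parameter) on ``n`` permuted tables and reports the percent of
    permuted fits with a strictly lower AIC and with a strictly smaller
    allele coefficient than the observed fit.  Failed refits are dropped
    from the denominator; more than ``max_failure_rate`` of them aborts.
    """
    if rng is None:
        rng = np.random.default_rng()
    spec = _scenario_spec(model_spec, scenario)
    observed = _fit(spec, table, **fit_kwargs)

    aics, betas_a, betas_m = [], [], []
    failures = 0
    for _ in range(n):
        permuted = permute_table(table, scenario, rng, outcome_col=model_spec.outcome)
        try:
            fit = _fit(spec, permuted, **fit_kwargs)
            if not fit.converged:
                raise RuntimeError("non-converged refit")
        except Exception:
            failures += 1
            continue
        aics.append(fit.aic)
        betas_a.append(fit.params.get("aspm_z", np.nan))
        betas_m.append(fit.params.get("mcph1_z", np.nan))
    if failures > max_failure_rate * n:
        raise RuntimeError(
            f"scenario {scenario.name}: {failures}/{n} permutation refits failed")
    n_ok = n - failures
    aics, betas_a, betas_m = map(np.asarray, (aics, betas_a, betas_m))
    return {
        "scenario": scenario.name,
        "n_permutations": n_ok,
        "n_failures": failures,
        "pct_better_aic": 100.0 * float(np.mean(aics < observed.aic)),
        "pct_smaller_beta_aspm": 100.0 * float(
            np.mean(betas_a < observed.params.get("aspm_z", np.nan))),
        "pct_smaller_beta_mcph1": 100.0 * float(
            np.mean(betas_m < observed.params.get("mcph1_z", np.nan))),
        "observed": observed,
    }


def run_all_scenarios(
    table: pd.DataFrame,
    model_spec: ModelSpec,
    n: int = 1000,
    seed: int | None = None,
    **fit_kwargs,
) -> pd.DataFrame:
    """All 18 scenarios; each gets an independent child RNG stream of ``seed``."""
    master = np.random.SeedSequence(seed)
    children = master.spawn(len(ALL_SCENARIOS))
    rows = []
    for scenario, child in zip(ALL_SCENARIOS, children):
        summary = run_scenario(table, scenario, model_spec, n=n,
                               rng=np.random.default_rng(child), **fit_kwargs)
        summary.pop("observed")
        rows.append(summary)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# restricted sampling

#: model variants fitted per allele on each restricted sample
RESTRICTED_VARIANTS = ("alone", "macroarea", "full")


def restricted_sample(table: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Exactly one uniformly chosen row per family."""
    idx = np.arange(len(table))
    fams = pd.factorize(table["family"])[0]
    chosen = [rng.choice(idx[fams == f]) for f in np.unique(fams)]
    return table.iloc[np.sort(chosen)].reset_index(drop=True)


def _variant_terms(allele: str, variant: str) -> tuple:
    other = {"aspm_z": "mcph1_z", "mcph1_z": "aspm_z"}[allele]
    if variant == "alone":
        return (allele,)
    if variant == "macroarea":
        return (allele, "macroarea")
    if variant == "full":
        return (allele, "macroarea", other)
    raise ValueError(f"unknown restricted-sampling variant {variant!r}")


def run_restricted(
    table: pd.DataFrame,
    outcome: str = "tone1",
    family: str = "binomial",
    variants=RESTRICTED_VARIANTS,
    n: int = 1000,
    rng: np.random.Generator | None = None,
    max_failure_rate: float = 0.10,
) -> pd.DataFrame:
    """Restricted-sampling summaries per allele x model variant.

    Each draw keeps one row per family and fits a fixed-effects GLM of the
    outcome on the allele (plus macroarea and/or the other allele,
    depending on the variant).  Reports the mean/median coefficient, its
    standard deviation and the percent of draws with a negative
    coefficient.
    """
    if table["family"].nunique() < 2:
        raise ValueError("restricted sampling needs >= 2 families")
    if rng is None:
        rng = np.random.default_rng()
    betas: dict[tuple, list] = {
        (a, v): [] for a in ("aspm_z", "mcph1_z") for v in variants}
    failures = 0
    for _ in range(n):
        sub = restricted_sample(table, rng)
        for (allele, variant), store in betas.items():
            spec = ModelSpec(outcome, family, _variant_terms(allele, variant), None)
            try:
                fit = fit_glm(spec, sub)
                if not fit.converged:
                    raise RuntimeError("non-converged")
                store.append(float(fit.params[allele]))
            except Exception:
                failures += 1
                store.append(np.nan)
    total = n * len(betas)
    if failures > max_failure_rate * total:
        raise RuntimeError(f"restricted sampling: {failures}/{total} refits failed")
    rows = []
    for (allele, variant), values in betas.items():
        b = np.asarray(values, dtype=float)
        b = b[np.isfinite(b)]
        rows.append({
            "allele": "aspm" if allele == "aspm_z" else "mcph1",
            "variant": variant,
            "n_resamples": len(b),
            "mean_beta": float(np.mean(b)),
            "median_beta": float(np.median(b)),
            "sd_beta": float(np.std(b, ddof=1)),
            "pct_beta_negative": 100.0 * float(np.mean(b < 0)),
        })
    return pd.DataFrame(rows)
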