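"""Microcosm processing and mixed-model inference.

Turns raw microcosm observations (start/dead counts per species, initial
and final litter dry mass, run duration) into analysis-ready records —
percentage mass loss, mortality exclusion, microbial-background
subtraction, death-corrected community metrics — and runs the inference:
a random-intercept linear mixed model of % mass loss on every subset of
{CWM, FDiv, SR}, ranked by AICc with Akaike weights, plus per-assemblage
simple regressions on assemblage means.

CWM enters the models on the cumulative scale (g consumed per individual
over the whole run), i.e. the per-day rate times duration / 1000.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm

from .functional_metrics import (
    SpeciesPool,
    cwm,
    feve,
    fric,
    gower_dissimilarity,
    rao_fdiv,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MicrocosmRecord",
    "FitResult",
    "ModelSelectionTable",
    "mass_loss",
    "mortality_rate",
    "microbial_correction",
    "estimate_microbial_rate",
    "corrected_abundances",
    "process_microcosms",
    "monoculture_consumption_rate",
    "fit_lmm",
    "aicc",
    "all_subsets_aicc",
    "assemblage_mean_regressions",
]

#: model-term name -> processed-table column
PREDICTORS = {"CWM": "cwm_g_cum", "FDiv": "fdiv_corrected", "SR": "richness"}

#: response modeled by the LMM and the assemblage-mean regressions: litter
#: mass loss attributable to the isopods (microbial background subtracted),
#: as % of the initial litter mass
RESPONSE = "mass_loss_isopod_pct"

MORTALITY_EXCLUSION = 0.5  # strict: excluded iff mortality > 0.5


@dataclass(frozen=True)
class MicrocosmRecord:
    """One experimental unit's raw observations.

    ``start_counts``/``dead_counts`` map species id to the number of
    individuals added / found dead. Animal-free units carry empty counts.
    """

    microcosm_id: str
    assemblage_id: str
    start_counts: Mapping[str, int]
    dead_counts: Mapping[str, int]
    litter_initial_mg: float
    litter_final_mg: float
    duration_days: float

    def __post_init__(self) -> None:
        for sp, n0 in self.start_counts.items():
            nd = self.dead_counts.get(sp, 0)
            if not 0 <= nd <= n0:
                raise ValueError(
                    f"{self.microcosm_id}: dead count {nd} for {sp!r} outside "
                    f"[0, start={n0}]"
                )
        for sp in self.dead_counts:
            if sp not in self.start_counts:
                raise ValueError(
                    f"{self.microcosm_id}: dead count for {sp!r} without start count"
                )
        if self.litter_final_mg > self.litter_initial_mg:
            raise ValueError(
                f"{self.microcosm_id}: final litter mass exceeds initial"
            )
        if self.duration_days <= 0:
            raise ValueError(f"{self.microcosm_id}: duration must be > 0")

    @property
    def treatment(self) -> str:
        present = [sp for sp, n in self.start_counts.items() if n > 0]
        if not present:
            return "blank"
        return "monoculture" if len(present) == 1 else "assemblage"

    @property
    def n_start(self) -> int:
        return int(sum(self.start_counts.values()))


def mass_loss(rec: MicrocosmRecord) -> float:
    """Litter mass loss as a percentage of the initial dry mass."""
    return 100.0 * (rec.litter_initial_mg - rec.litter_final_mg) / rec.litter_initial_mg


def mortality_rate(rec: MicrocosmRecord) -> float:
    """Fraction of added individuals found dead; NaN for animal-free units."""
    n0 = rec.n_start
    if n0 == 0:
        return float("nan")
    return sum(rec.dead_counts.values()) / n0


def estimate_microbial_rate(records: Sequence[MicrocosmRecord]) -> float:
    """Mean microbial decomposition rate (mg/day) over animal-free units."""
    blanks = [r for r in records if r.treatment == "blank"]
    if not blanks:
        raise ValueError(
            "no animal-free microcosms found: supply microbial_rate explicitly"
        )
    rates = [
        (r.litter_initial_mg - r.litter_final_mg) / r.duration_days for r in blanks
    ]
    return float(np.mean(rates))


def microbial_correction(rec: MicrocosmRecord, mean_microbial_rate: float) -> float:
    """Isopod-attributable litter consumption in mg, floored at zero.

    Subtracts the expected microbial loss (rate x duration) from the
    observed total loss.
    """
    loss = rec.litter_initial_mg - rec.litter_final_mg
    return max(0.0, loss - mean_microbial_rate * rec.duration_days)


def corrected_abundances(
    rec: MicrocosmRecord, dead_correction: str = "half"
) -> dict[str, float]:
    """Effective abundances after mortality correction.

    ``half`` assumes deaths occur uniformly in time, so each dead
    individual counts for half its tenure: n_eff = n_start - 0.5 * n_dead.
    ``survivors`` keeps only the animals alive at the end.
    """
    if dead_correction not in ("half", "survivors"):
        raise ValueError(f"unknown dead_correction {dead_correction!r}")
    w = 0.5 if dead_correction == "half" else 1.0
    return {
        sp: n0 - w * rec.dead_counts.get(sp, 0)
        for sp, n0 in rec.start_counts.items()
        if n0 > 0
    }


def process_microcosms(
    records: Sequence[MicrocosmRecord],
    pool: SpeciesPool,
    microbial_rate: float | None = None,
    dead_correction: str = "half",
    trait: str = "consumption_rate",
) -> pd.DataFrame:
    """Build the analysis-ready table from raw records.

    One row per microcosm with mass loss, mortality and exclusion flag,
    microbially corrected isopod consumption, and death-corrected
    community metrics (CWM on the per-day and cumulative scales, Rao
    divergence, FRic, FEve, realized richness).
    """
    if microbial_rate is None:
        microbial_rate = estimate_microbial_rate(records)
    dissim = gower_dissimilarity(pool, trait)
    rows = []
    for rec in records:
        mort = mortality_rate(rec)
        excluded = bool(mort > MORTALITY_EXCLUSION) if np.isfinite(mort) else False
        row = {
            "microcosm_id": rec.microcosm_id,
            "assemblage_id": rec.assemblage_id,
            "treatment": rec.treatment,
            "duration_days": rec.duration_days,
            "n_start": rec.n_start,
            "mass_loss_pct": mass_loss(rec),
            "mortality": mort,
            "excluded": excluded,
            "exclusion_reason": "mortality > 50%" if excluded else "",
            "isopod_consumption_mg": (iso := (
                microbial_correction(rec, microbial_rate)
                if rec.treatment != "blank"
                else 0.0
            )),
            "mass_loss_isopod_pct": 100.0 * iso / rec.litter_initial_mg,
            "cwm_mg_day": np.nan,
            "cwm_g_cum": np.nan,
            "fdiv_corrected": np.nan,
            "fric_corrected": np.nan,
            "feve_corrected": np.nan,
            "richness": 0,
        }
        if rec.treatment != "blank":
            n_eff = corrected_abundances(rec, dead_correction)
            n_eff = {sp: n for sp, n in n_eff.items() if n > 0}
            if n_eff:
                row["cwm_mg_day"] = cwm(n_eff, pool, trait)
                row["cwm_g_cum"] = row["cwm_mg_day"] * rec.duration_days / 1000.0
                row["fdiv_corrected"] = rao_fdiv(n_eff, dissim)
                row["fric_corrected"] = fric(n_eff, pool, trait)
                row["feve_corrected"] = feve(n_eff, pool, trait)
                row["richness"] = sum(1 for v in n_eff.values() if v > 0)
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["microbial_rate_mg_day"] = microbial_rate
    out.attrs["dead_correction"] = dead_correction
    return out


def monoculture_consumption_rate(processed: pd.DataFrame) -> pd.DataFrame:
    """Species-specific consumption rates from monoculture microcosms.

    Per kept record: corrected consumption / (initial individuals x
    duration), in mg per individual per day; aggregated to mean and SD per
    species (the assemblage_id of a monoculture names its species).
    """
    mono = processed[(processed["treatment"] == "monoculture") & ~processed["excluded"]]
    if mono.empty:
        raise ValueError("no kept monoculture records")
    per = mono.assign(
        rate=mono["isopod_consumption_mg"] / (mono["n_start"] * mono["duration_days"])
    )
    out = (
        per.groupby("assemblage_id")["rate"]
        .agg(["mean", "std", "count"])
        .reset_index()
        .rename(
            columns={
                "assemblage_id": "species_id",
                "mean": "rate_mean",
                "std": "rate_sd",
                "count": "n_replicates",
            }
        )
    )
    return out


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """A fitted random-intercept linear mixed model (full ML)."""

    fixed_set: tuple[str, ...]
    loglik: float
    k: int  # intercept + slopes + 2 variance components
    n: int
    params: dict[str, float]
    bse: dict[str, float]
    tvalues: dict[str, float]
    sigma_u: float
    sigma_resid: float

    @property
    def name(self) -> str:
        return "Massloss~1" + "".join(f" + {t}" for t in self.fixed_set)


def fit_lmm(data: pd.DataFrame, fixed_set: Sequence[str]) -> FitResult:
    """Fit the isopod-attributable % mass loss on the given fixed effects
    with an assemblage random intercept, maximising the full likelihood
    (ML, not REML).

    ``fixed_set`` is a subset of {"CWM", "FDiv", "SR"}; the empty set
    fits the intercept-only (null) model. A singular fit (between-
    assemblage variance at zero) is permitted and reported as
    ``sigma_u = 0``.
    """
    fixed_set = tuple(fixed_set)
    unknown = [t for t in fixed_set if t not in PREDICTORS]
    if unknown:
        raise ValueError(f"unknown fixed effects {unknown}; choose from {list(PREDICTORS)}")
    if data["assemblage_id"].nunique() < 2:
        raise ValueError("need >= 2 assemblages for a random-intercept model")
    endog = data[RESPONSE].to_numpy(dtype=float)
    cols = [PREDICTORS[t] for t in fixed_set]
    exog = np.column_stack(
        [np.ones(len(data))] + [data[c].to_numpy(dtype=float) for c in cols]
    )
    names = ["Intercept", *fixed_set]
    model = sm.MixedLM(endog, exog, groups=data["assemblage_id"].to_numpy())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = None
        err: Exception | None = None
        for method in ("lbfgs", "bfgs", "cg", "powell"):
            try:
                cand = model.fit(reml=False, method=method, maxiter=500)
            except Exception as exc:  # singular optimizer step etc.
                err = exc
                continue
            if np.isfinite(cand.llf):
                if result is None or cand.llf > result.llf + 1e-10:
                    result = cand
                if cand.converged:
                    break
        if result is None:
            raise RuntimeError(
                f"mixed-model fit failed for fixed set {fixed_set}: {err}"
            )
    sigma_u = float(np.sqrt(max(0.0, float(np.squeeze(result.cov_re)))))
    return FitResult(
        fixed_set=fixed_set,
        loglik=float(result.llf),
        k=1 + len(fixed_set) + 2,
        n=len(data),
        params=dict(zip(names, (float(v) for v in result.fe_params))),
        bse=dict(zip(names, (float(v) for v in result.bse_fe))),
        tvalues=dict(
            zip(names, (float(v) for v in result.fe_params / result.bse_fe))
        ),
        sigma_u=sigma_u,
        sigma_resid=float(np.sqrt(result.scale)),
    )


def aicc(loglik: float, k: int, n: int) -> float:
    """Akaike information criterion with the small-sample correction,
    AICc = -2 logL + 2k + 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k+1)")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


@dataclass
class ModelSelectionTable:
    """All-subsets model ranking with AICc deltas and Akaike weights."""

    table: pd.DataFrame  # model, logLik, k, AICc, delta, weight (AICc-ascending)
    fits: dict[tuple[str, ...], FitResult] = field(default_factory=dict)
    n: int = 0

    @property
    def best(self) -> FitResult:
        top = tuple(self.table.iloc[0]["fixed_set"])
        return self.fits[top]

    def estimates(self, fixed_set: Sequence[str]) -> pd.DataFrame:
        """Fixed-effect estimates, SEs and t-values for one fitted model."""
        fit = self.fits[tuple(fixed_set)]
        return pd.DataFrame(
            {
                "term": list(fit.params),
                "estimate": list(fit.params.values()),
                "se": list(fit.bse.values()),
                "t_value": list(fit.tvalues.values()),
            }
        )


def all_subsets_aicc(
    data: pd.DataFrame, terms: Sequence[str] = ("CWM", "FDiv", "SR")
) -> ModelSelectionTable:
    """Fit every subset of the candidate fixed effects (all retaining the
    assemblage random intercept), rank by AICc, attach Akaike weights.

    Only non-excluded mixed-assemblage records enter the fits; ``n`` in
    the AICc correction is the number of microcosms used.
    """
    used = data
    if "treatment" in data.columns:
        used = data[data["treatment"] == "assemblage"]
    if "excluded" in used.columns:
        used = used[~used["excluded"]]
    used = used.reset_index(drop=True)
    n = len(used)
    rows = []
    fits: dict[tuple[str, ...], FitResult] = {}
    for r in range(len(terms) + 1):
        for subset in itertools.combinations(terms, r):
            fit = fit_lmm(used, subset)
            fits[subset] = fit
            rows.append(
                {
                    "model": fit.name,
                    "fixed_set": subset,
                    "logLik": fit.loglik,
                    "k": fit.k,
                    "AICc": aicc(fit.loglik, fit.k, n),
                    "sigma_u": fit.sigma_u,
                    "s_resid": fit.sigma_resid,
                }
            )
    table = pd.DataFrame(rows).sort_values("AICc", kind="mergesort").reset_index(drop=True)
    table["delta"] = table["AICc"] - table["AICc"].min()
    rel = np.exp(-table["delta"] / 2.0)
    table["weight"] = rel / rel.sum()
    return ModelSelectionTable(table=table, fits=fits, n=n)


def assemblage_mean_regressions(
    data: pd.DataFrame, terms: Sequence[str] = ("CWM", "FDiv", "SR")
) -> pd.DataFrame:
    """Simple per-predictor regressions on assemblage means.

    Collapses kept mixed-assemblage records to one mean % mass loss (and
    mean predictor value) per assemblage, then ordinary least squares of
    mass loss on each predictor separately, with the two-sided t-test
    p-value for the slope.
    """
    used = data
    if "treatment" in data.columns:
        used = used[used["treatment"] == "assemblage"]
    if "excluded" in used.columns:
        used = used[~used["excluded"]]
    cols = [RESPONSE] + [PREDICTORS[t] for t in terms]
    means = used.groupby("assemblage_id")[cols].mean()
    if len(means) < 3:
        raise ValueError(f"need >= 3 assemblages with kept replicates, got {len(means)}")
    rows = []
    for term in terms:
        x = means[PREDICTORS[term]]
        if np.ptp(x) == 0:  # constant predictor: slope undefined
            logger.info("predictor %s constant across assemblages", term)
            slope = intercept = r2 = p = float("nan")
        else:
            res = stats.linregress(x, means[RESPONSE])
            slope, intercept = res.slope, res.intercept
            r2, p = res.rvalue**2, res.pvalue
        rows.append(
            {
                "predictor": term,
                "slope": slope,
                "intercept": intercept,
                "r_squared": r2,
                "p_value": p,
                "n_assemblages": len(means),
            }
        )
    return pd.DataFrame(rows)
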