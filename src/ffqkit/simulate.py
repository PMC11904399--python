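"""Synthetic FFQ cohorts with known latent diet structure.

The generator emulates the response schema of the 32-week pregnancy FFQ
and the demographic mix of the source cohort (education, smoking, housing,
ethnicity proportions; age and pre-pregnancy BMI) so that every pipeline
stage is testable without access-controlled data.  Each participant draws
k latent pattern scores; the true times-per-week of item j is
``softplus(mu_j + sum_k score_k * sd_k * loading_kj + noise)``, and the
recorded answer is the five-category bin containing that true frequency.
Daily-basics answers come from categorical distributions of plausible
1990s-UK habits.  Optionally a fraction of participants under-report: all
continuous quantities are scaled by a factor before categorisation, with
the factor recorded in the latent truth.

The defaults target intakes of a plausible scale for a pregnant-women
cohort (mean daily energy within 5-10 MJ) but make no claim to reproduce
the source cohort's published means, which would require the real data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.optimize import linear_sum_assignment

from . import schema as sch
from .derivation import DerivationEngine
from .nutrients import COMPOSITION_SLOTS
from .patterns import PatternModel

__all__ = ["CohortConfig", "LatentTruth", "generate_cohort",
           "default_loadings", "recovery_report", "bin_frequency"]

_ENERGY_IX = COMPOSITION_SLOTS.index("energy_kj")

#: mean true times-per-week per weekly item under the defaults
DEFAULT_ITEM_MEANS: dict[str, float] = {
    "c200": 1.0, "c201": 0.6, "c202": 2.5, "c203": 2.0, "c204": 0.3,
    "c205": 1.0, "c206": 0.7, "c207": 0.3, "c208": 2.0, "c209": 2.5,
    "c210": 0.5, "c211": 1.8, "c215": 1.2, "c216": 3.5, "c217": 1.2,
    "c218": 1.5, "c219": 2.0, "c220": 1.2, "c222": 1.5, "c223": 2.5,
    "c224": 2.0, "c225": 1.8, "c226": 2.5, "c227": 1.2, "c228": 3.0,
    "c229": 5.5, "c230": 0.8, "c231": 2.5, "c232": 1.2, "c233": 1.2,
    "c234": 2.0, "c235": 2.0, "c236": 1.2, "c237": 0.8, "c238": 3.0,
    "c239": 1.2, "c240": 0.8, "c241": 0.6, "c242": 0.15, "c243": 0.1,
    "c244": 0.3, "c245": 1.8, "c246": 1.2,
}

_PATTERN_ITEMS: dict[str, dict[str, float]] = {
    "health_conscious": {c: 0.55 for c in
        ["c228", "c229", "c217", "c218", "c233", "c234", "c205", "c206",
         "c231", "c208"]},
    "traditional": {c: 0.5 for c in
        ["c223", "c224", "c225", "c226", "c227", "c202", "c215", "c216",
         "c203"]},
    "processed": {c: 0.5 for c in
        ["c200", "c201", "c210", "c211", "c219", "c220"]},
    "confectionery": {c: 0.5 for c in
        ["c232", "c236", "c238", "c239", "c245", "c246"]},
    "vegetarian": {**{c: 0.5 for c in ["c240", "c241", "c242", "c243", "c244"]},
                   **{"c202": -0.4, "c203": -0.4}},
}


def default_loadings() -> pd.DataFrame:
    """Latent loading matrix (k x items) emulating the five named patterns
    of the source cohort, in softplus-input units."""
    items = list(DEFAULT_ITEM_MEANS)
    rows = {}
    for name, weights in _PATTERN_ITEMS.items():
        rows[name] = [weights.get(c, 0.0) for c in items]
    return pd.DataFrame.from_dict(rows, orient="index", columns=items)


class BasicsConfig(BaseModel):
    """Categorical distributions for the daily-basics answers."""

    bread_slices_probs: list[float] = Field(default=[0.15, 0.50, 0.28, 0.07])
    spread_slices_lambda: float = 2.5
    # code -> tick probability (bread and fat types; independent ticks)
    bread_type_probs: dict[str, float] = Field(default={
        "c252": 0.55, "c253": 0.25, "c254": 0.25, "c255": 0.03, "c256": 0.02})
    fat_bread_probs: dict[str, float] = Field(default={
        "c260": 0.35, "c261": 0.45, "c262": 0.15, "c263": 0.15,
        "c264": 0.02, "c265": 0.02})
    fat_fry_probs: dict[str, float] = Field(default={
        "c266": 0.10, "c267": 0.10, "c268": 0.05, "c269": 0.01,
        "c270": 0.45, "c271": 0.35})
    # code -> (P(usually), P(sometimes))
    milk_type_probs: dict[str, tuple[float, float]] = Field(default={
        "c276": (0.45, 0.10), "c277": (0.35, 0.10), "c278": (0.15, 0.05),
        "c279": (0.02, 0.02), "c280": (0.01, 0.02), "c281": (0.005, 0.005),
        "c282": (0.01, 0.01), "c283": (0.005, 0.005)})
    milk_use_probs: dict[str, tuple[float, float]] = Field(default={
        "c284": (0.80, 0.10), "c285": (0.60, 0.15), "c286": (0.70, 0.15),
        "c287": (0.20, 0.30), "c288": (0.15, 0.20), "c289": (0.15, 0.25)})
    fat_on_meat_probs: list[float] = Field(default=[0.15, 0.35, 0.45, 0.05])
    diet_drink_probs: list[float] = Field(default=[0.20, 0.35, 0.35, 0.10])
    drink_lambdas: dict[str, float] = Field(default={
        "tea_caff": 2.5, "tea_decaf": 0.4, "coffee_caff": 1.8,
        "coffee_decaf": 0.4, "cola_caff": 0.5, "cola_decaf": 0.15})
    sugar_spoons_probs: list[float] = Field(default=[0.55, 0.25, 0.15, 0.05])


class CohortConfig(BaseModel):
    """Cohort size, demographic mix and latent diet structure."""

    n: int = Field(default=2000, ge=1)
    # demographic mix emulating the source cohort's FFQ completers
    education_alevel: float = 0.353
    smoking: float = 0.198
    housing_owned: float = 0.757
    ethnicity_white: float = 0.974
    age_mean: float = 28.6
    age_sd: float = 4.8
    bmi_mean: float = 22.9
    bmi_sd: float = 3.8
    height_mean_m: float = 1.63
    height_sd_m: float = 0.06
    # latent structure
    item_means: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_ITEM_MEANS))
    loadings: dict[str, dict[str, float]] | None = None  # pattern -> item -> loading
    score_sd: dict[str, float] | None = None
    noise_sd: float = 0.4
    missing_rate: float = Field(default=0.02, ge=0.0, le=1.0)
    misreport_fraction: float = Field(default=0.0, ge=0.0, le=1.0)
    misreport_factor: float = Field(default=0.5, gt=0.0)
    # bin edges so category midpoints track the published recode weights
    bin_edges: list[float] = Field(default=[0.25, 1.25, 3.5, 7.5])
    basics: BasicsConfig = Field(default_factory=BasicsConfig)

    @model_validator(mode="after")
    def _check(self) -> "CohortConfig":
        for name in ("education_alevel", "smoking", "housing_owned",
                     "ethnicity_white"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a proportion in [0, 1]")
        if self.loadings is not None:
            for pat, row in self.loadings.items():
                if not all(np.isfinite(list(row.values()))):
                    raise ValueError(f"non-finite loadings for pattern {pat}")
        if list(self.bin_edges) != sorted(self.bin_edges):
            raise ValueError("bin edges must be increasing")
        return self

    def loading_frame(self) -> pd.DataFrame:
        if self.loadings is None:
            return default_loadings()
        items = list(self.item_means)
        return pd.DataFrame.from_dict(
            {p: [row.get(c, 0.0) for c in items]
             for p, row in self.loadings.items()},
            orient="index", columns=items,
        )


@dataclass
class LatentTruth:
    """Per-participant ground truth behind a synthetic cohort."""

    scores: pd.DataFrame        # n x k latent pattern scores
    freq: pd.DataFrame          # n x items true times/week (post misreport factor)
    demographics: pd.DataFrame  # age, bmi, height, weight, flags, misreport factor
    loadings: pd.DataFrame      # k x items generating loadings


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.log1p(np.exp(-np.abs(x))) + np.maximum(x, 0.0)


def _inv_softplus(y: np.ndarray) -> np.ndarray:
    # stable inverse: log(expm1(y))
    y = np.asarray(y, dtype=float)
    return np.where(y > 20, y, np.log(np.expm1(np.maximum(y, 1e-9))))


def bin_frequency(freq: float | np.ndarray, edges: list[float]) -> np.ndarray:
    """Weekly5 category index for a true times-per-week value."""
    return np.digitize(freq, edges)


def _level_down(label: str | None) -> str | None:
    if label == "Yes usually":
        return "Yes sometimes"
    if label == "Yes sometimes":
        return "No not at all"
    return label


def generate_cohort(
    config: CohortConfig, seed: int
) -> tuple[list[sch.FfqResponse], LatentTruth]:
    """Draw a fully reproducible synthetic cohort.

    Returns the schema-valid responses and the latent truth behind them.
    """
    rng = np.random.default_rng(seed)
    n = config.n
    items = list(config.item_means)
    L = config.loading_frame()          # k x items
    patterns = list(L.index)
    sd = np.array([(config.score_sd or {}).get(p, 1.0) for p in patterns])

    ids = [f"P{i:06d}" for i in range(1, n + 1)]
    scores = rng.standard_normal((n, len(patterns)))
    mu = _inv_softplus(np.array([config.item_means[c] for c in items]))
    eta = mu + (scores * sd) @ L.to_numpy() \
        + config.noise_sd * rng.standard_normal((n, len(items)))
    true_freq = _softplus(eta)

    misreport = np.zeros(n)
    factor = np.ones(n)
    if config.misreport_fraction > 0:
        m = rng.random(n) < config.misreport_fraction
        misreport = m.astype(float)
        factor = np.where(m, config.misreport_factor, 1.0)
    reported_freq = true_freq * factor[:, None]

    cats = bin_frequency(reported_freq, config.bin_edges)
    missing = rng.random((n, len(items))) < config.missing_rate

    # demographics
    demo = pd.DataFrame(index=pd.Index(ids, name="participant_id"))
    demo["education_alevel"] = rng.random(n) < config.education_alevel
    demo["smoking"] = rng.random(n) < config.smoking
    demo["housing_owned"] = rng.random(n) < config.housing_owned
    demo["ethnicity_white"] = rng.random(n) < config.ethnicity_white
    demo["age_y"] = config.age_mean + config.age_sd * rng.standard_normal(n)
    demo["bmi"] = np.maximum(
        config.bmi_mean + config.bmi_sd * rng.standard_normal(n), 14.0)
    demo["height_m"] = np.maximum(
        config.height_mean_m + config.height_sd_m * rng.standard_normal(n), 1.3)
    demo["weight_kg"] = demo["bmi"] * demo["height_m"] ** 2
    demo["misreporter"] = misreport.astype(bool)
    demo["misreport_factor"] = factor

    b = config.basics
    responses: list[sch.FfqResponse] = []
    bread_vals = [0.5, 1.5, 3.5, 5.5]
    for i in range(n):
        ans: dict[str, object] = {}
        for j, code in enumerate(items):
            ans[code] = None if missing[i, j] else sch.WEEKLY5_LABELS[cats[i, j]]
        f = factor[i]

        ans["c221"] = sch.FAT_ON_MEAT_LABELS[
            rng.choice(4, p=b.fat_on_meat_probs)]
        ans["c247"] = sch.DIET_DRINK_LABELS[
            rng.choice(4, p=b.diet_drink_probs)]

        slices = bread_vals[rng.choice(4, p=b.bread_slices_probs)] * f
        ans["c250"] = sch.BREAD_SLICE_LABELS[
            int(np.digitize(slices, [1.0, 3.0, 5.0]))]
        spread = float(rng.poisson(b.spread_slices_lambda)) * f
        ans["c275"] = round(spread)
        for code, p in {**b.bread_type_probs, **b.fat_bread_probs,
                        **b.fat_fry_probs}.items():
            ans[code] = bool(rng.random() < p)
        for code, (pu, ps) in b.milk_type_probs.items():
            u = rng.random()
            label = ("Yes usually" if u < pu
                     else "Yes sometimes" if u < pu + ps else "No not at all")
            ans[code] = label
        for code, (pu, ps) in b.milk_use_probs.items():
            u = rng.random()
            label = ("Yes usually" if u < pu
                     else "Yes sometimes" if u < pu + ps else "No not at all")
            if f < 0.75:
                label = _level_down(label)
            ans[code] = label
        for name, lam in b.drink_lambdas.items():
            ans[sch.DRINK_COUNT_CODES[name]] = round(float(rng.poisson(lam)) * f)
        for key in ("sugar_tea", "sugar_coffee"):
            spoons = rng.choice(len(b.sugar_spoons_probs), p=b.sugar_spoons_probs)
            ans[sch.DRINK_COUNT_CODES[key]] = round(float(spoons) * f)
        ans["c251"] = sch.TAKEAWAY_LABELS[rng.choice(5, p=[0.3, 0.4, 0.2, 0.08, 0.02])]
        responses.append(sch.FfqResponse(participant_id=ids[i], answers=ans))

    truth = LatentTruth(
        scores=pd.DataFrame(scores, index=demo.index, columns=patterns),
        freq=pd.DataFrame(reported_freq, index=demo.index, columns=items),
        demographics=demo,
        loadings=L,
    )
    return responses, truth


# ---------------------------------------------------------------------------
# Recovery metrics
# ---------------------------------------------------------------------------


def true_weekly_energy(
    truth: LatentTruth,
    responses: list[sch.FfqResponse],
    engine: DerivationEngine,
) -> pd.Series:
    """Weekly energy implied by the TRUE (continuous) item frequencies plus
    each participant's actual daily-basics answers."""
    ids = [r.participant_id for r in responses]
    if list(truth.freq.index) != ids:
        raise ValueError("truth and responses do not describe the same cohort")
    codes = [c for c in truth.freq.columns
             if c in engine.schema.derivable_weekly5_codes()]
    out = np.zeros(len(responses))
    for i, resp in enumerate(responses):
        behaviour = resp.answers.get("c221")
        e = 0.0
        for c in codes:
            pq = engine.schema[c].portion_question
            e += truth.freq.iloc[i][c] * engine.question_amounts(pq, behaviour)[_ENERGY_IX]
        basics_only = sch.FfqResponse(
            participant_id=resp.participant_id,
            answers={k: (None if engine.schema[k].scale == "weekly5" else v)
                     for k, v in resp.answers.items()},
        )
        e += engine.weekly_nutrients(basics_only)["energy_kj"]
        out[i] = e
    return pd.Series(out, index=truth.freq.index, name="true_weekly_energy_kj")


def match_loadings(
    true_loadings: pd.DataFrame, model: PatternModel
) -> dict[str, float]:
    """Optimal 1:1 match of fitted components to generating patterns by
    absolute loading correlation; returns pattern -> |r|."""
    common = [c for c in true_loadings.columns if c in model.items]
    T = true_loadings[common].to_numpy()                  # k_true x p
    F = model.loadings_frame().loc[common].to_numpy().T   # k_fit x p
    corr = np.zeros((T.shape[0], F.shape[0]))
    for a in range(T.shape[0]):
        for b_ in range(F.shape[0]):
            corr[a, b_] = abs(np.corrcoef(T[a], F[b_])[0, 1])
    rows, cols = linear_sum_assignment(-corr)
    return {true_loadings.index[a]: float(corr[a, b_]) for a, b_ in zip(rows, cols)}


def recovery_report(
    truth: LatentTruth,
    responses: list[sch.FfqResponse],
    daily: pd.DataFrame,
    engine: DerivationEngine,
    model: PatternModel | None = None,
    misreport_flags: pd.Series | None = None,
) -> dict:
    """Compare derived quantities against the generator's latent truth.

    Reports the true-vs-derived energy correlation, matched-component
    loading correlations (when a fitted pattern model is given) and the
    misreporter-flag confusion matrix (when flags are given).
    """
    if set(daily.index) != set(truth.demographics.index):
        raise ValueError("derived nutrients and truth have mismatched ids")
    report: dict = {}
    te = true_weekly_energy(truth, responses, engine)
    de = daily.loc[te.index, "energy_kj"]
    report["energy_correlation"] = float(np.corrcoef(te, de)[0, 1])
    if model is not None:
        matched = match_loadings(truth.loadings, model)
        report["loading_correlations"] = matched
        report["min_loading_correlation"] = min(matched.values())
    if misreport_flags is not None:
        flags = misreport_flags.reindex(truth.demographics.index)
        truth_under = truth.demographics["misreporter"]
        flagged = flags == "under"
        tp = int((flagged & truth_under).sum())
        fn = int((~flagged & truth_under).sum())
        fp = int((flagged & ~truth_under).sum())
        tn = int((~flagged & ~truth_under).sum())
        report["misreport_confusion"] = {"tp": tp, "fp": fp, "fn": fn, "tn": tn}
        if tp + fn:
            report["misreport_sensitivity"] = tp / (tp + fn)
        if tn + fp:
            report["misreport_specificity"] = tn / (tn + fp)
    return report
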