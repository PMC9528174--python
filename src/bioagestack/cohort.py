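"""Synthetic physical-examination cohorts and missingness injectors.

The downstream biological-age (BA) pipeline assumes a participant-by-feature
table of chronological age (CA), gender, biochemical and anthropometric
markers, and binary disease flags.  Real examination cohorts of this kind are
not publicly distributable, so this module generates seeded synthetic cohorts
with the statistical structure the analysis relies on:

* each continuous marker drifts linearly (optionally quadratically) with an
  *effective age* ``CA + delta``, where ``delta`` is a latent per-person aging
  offset (years) — the quantity a BA estimator is supposed to recover;
* markers within a ``corr_block`` share a latent Gaussian factor, giving the
  blocky inter-marker correlation seen in panel data (lipids, liver enzymes,
  blood counts, blood pressure);
* binary urine markers follow logistic models in effective age (three of them
  are generated with no age signal at all and play the role of screen-out
  candidates in feature selection);
* the seven disease flags are Bernoulli draws from logistic models in
  (CA, delta, family history), so faster agers are sicker at fixed CA;
* waist circumference carries an explicit ``delta`` loading, planting the
  aging signal into the body-shape indices (ABSI, WHtR) used by the
  association batteries.

``latent_delta`` is written into the emitted table as an oracle-only column:
estimation stages must never consume it, and :func:`assert_no_oracle` enforces
that contract.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "BiomarkerDef",
    "DiseaseDef",
    "CohortSpec",
    "MissingnessProfile",
    "ORACLE_COLUMNS",
    "CONTINUOUS_BIOMARKERS",
    "BINARY_BIOMARKERS",
    "DISEASES",
    "MASKABLE_COLUMNS",
    "CANDIDATE_FEATURES",
    "default_biomarker_defs",
    "default_disease_defs",
    "default_cohort_spec",
    "default_mnar_profile",
    "generate_cohort",
    "inject_missing",
    "exclusion_accounting",
    "assert_no_oracle",
    "drop_oracle_columns",
]

logger = logging.getLogger(__name__)

#: columns that hold generator ground truth and must never reach an estimator
ORACLE_COLUMNS = ("latent_delta",)

#: the 13 continuous biochemical markers of the examination panel
CONTINUOUS_BIOMARKERS = (
    "sbp", "dbp", "hemoglobin", "white_blood_cell", "platelets", "fsg",
    "sgpt", "sgot", "tc", "tg", "total_bilirubin", "ldl", "hdl",
)

#: the 4 binary urine dipstick markers (positive/negative)
BINARY_BIOMARKERS = ("urine_protein", "urine_sugar", "urine_ketone", "urine_occult_blood")

#: the 7 disease categories diagnosed at examination
DISEASES = (
    "cerebrovascular_disease", "kidney_disease", "heart_disease",
    "vascular_disease", "eye_disease", "nervous_system_disease",
    "other_system_disease",
)

#: feature block eligible for missingness injection (19 columns); age, gender,
#: disease flags and derived anthropometry are never masked
MASKABLE_COLUMNS = CONTINUOUS_BIOMARKERS + BINARY_BIOMARKERS + ("height", "weight")

#: the 22 candidate features entering feature selection
CANDIDATE_FEATURES = (
    CONTINUOUS_BIOMARKERS + BINARY_BIOMARKERS
    + ("gender", "height", "weight", "waist", "bmi")
)


@dataclass(frozen=True)
class BiomarkerDef:
    """Generative definition of one biochemical marker.

    Continuous markers have conditional mean
    ``base_mean + age_slope*(EA-65) + gender_shift*female + nonlinearity*(EA-65)**2``
    with ``EA = CA + delta``, Gaussian noise ``base_sd`` partially shared
    within ``corr_block``.  Binary markers are Bernoulli with logit
    ``logit_intercept + logit_age_slope*(EA-65)``.
    """

    name: str
    kind: str = "continuous"          # "continuous" | "binary"
    base_mean: float = 0.0
    base_sd: float = 1.0
    age_slope: float = 0.0            # units per year of effective age
    gender_shift: float = 0.0         # additive shift for females
    nonlinearity: float = 0.0         # quadratic coefficient in (EA-65)
    corr_block: str | None = None
    logit_intercept: float = -3.0     # binary only
    logit_age_slope: float = 0.0      # binary only

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary"):
            raise ValueError(f"unknown biomarker kind {self.kind!r}")
        if self.kind == "continuous" and self.base_sd <= 0:
            raise ValueError(f"{self.name}: base_sd must be > 0")


@dataclass(frozen=True)
class DiseaseDef:
    """Logistic generative model for one disease flag.

    logit P(disease) = intercept + beta_age*(CA-65) + beta_delta*delta
                       + beta_family*family_disease
    """

    name: str
    intercept: float = -2.0
    beta_age: float = 0.04
    beta_delta: float = 0.06
    beta_family: float = 0.5


def default_biomarker_defs() -> list[BiomarkerDef]:
    """Marker panel with realistic units, age drifts, gender effects and
    correlation blocks.  The three urine markers other than protein carry no
    age signal (they are the selection screen-outs)."""
    C = BiomarkerDef
    return [
        C("sbp", base_mean=135.0, base_sd=15.0, age_slope=0.45, gender_shift=-3.0,
          corr_block="bp"),
        C("dbp", base_mean=80.0, base_sd=9.0, age_slope=-0.12, gender_shift=-2.0,
          corr_block="bp"),
        C("hemoglobin", base_mean=146.0, base_sd=12.0, age_slope=-0.25,
          gender_shift=-12.0, corr_block="blood"),
        C("white_blood_cell", base_mean=6.2, base_sd=1.5, age_slope=-0.012,
          gender_shift=-0.2, corr_block="blood"),
        C("platelets", base_mean=225.0, base_sd=50.0, age_slope=-0.8,
          gender_shift=15.0, corr_block="blood"),
        C("fsg", base_mean=5.6, base_sd=1.1, age_slope=0.02, nonlinearity=-3e-4),
        C("sgpt", base_mean=25.0, base_sd=10.0, age_slope=-0.15, gender_shift=-4.0,
          corr_block="liver"),
        C("sgot", base_mean=26.0, base_sd=9.0, age_slope=0.06, gender_shift=-2.0,
          corr_block="liver"),
        C("tc", base_mean=5.0, base_sd=0.9, age_slope=0.012, gender_shift=0.25,
          corr_block="lipid"),
        C("tg", base_mean=1.6, base_sd=0.8, age_slope=0.006, gender_shift=0.05,
          corr_block="lipid"),
        C("total_bilirubin", base_mean=13.5, base_sd=4.5, age_slope=0.035,
          gender_shift=-1.5, corr_block="liver"),
        C("ldl", base_mean=2.9, base_sd=0.75, age_slope=0.010, gender_shift=0.1,
          corr_block="lipid"),
        C("hdl", base_mean=1.40, base_sd=0.30, age_slope=0.003, gender_shift=0.15,
          corr_block="lipid"),
        C("urine_protein", kind="binary", logit_intercept=-2.9, logit_age_slope=0.035),
        C("urine_sugar", kind="binary", logit_intercept=-3.2, logit_age_slope=0.0),
        C("urine_ketone", kind="binary", logit_intercept=-3.6, logit_age_slope=0.0),
        C("urine_occult_blood", kind="binary", logit_intercept=-3.0, logit_age_slope=0.0),
    ]


def default_disease_defs() -> list[DiseaseDef]:
    D = DiseaseDef
    return [
        D("cerebrovascular_disease", intercept=-3.0, beta_age=0.05, beta_delta=0.07),
        D("kidney_disease", intercept=-3.4, beta_age=0.03, beta_delta=0.07),
        D("heart_disease", intercept=-2.6, beta_age=0.05, beta_delta=0.06),
        D("vascular_disease", intercept=-3.0, beta_age=0.04, beta_delta=0.05),
        D("eye_disease", intercept=-2.8, beta_age=0.05, beta_delta=0.06),
        D("nervous_system_disease", intercept=-3.4, beta_age=0.03, beta_delta=0.06),
        D("other_system_disease", intercept=-1.6, beta_age=0.03, beta_delta=0.05),
    ]


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic cohort draw."""

    n_participants: int
    age_range: tuple[float, float] = (45.0, 90.0)
    prop_female: float = 0.52             # fraction female at the age midpoint
    female_age_slope: float = 0.018       # log-odds of female per year of CA
    latent_aging_sd: float = 5.0          # SD of delta, years
    female_delta_shift: float = -1.0      # mean delta offset for females, years
    biomarker_defs: tuple[BiomarkerDef, ...] = field(
        default_factory=lambda: tuple(default_biomarker_defs()))
    disease_defs: tuple[DiseaseDef, ...] = field(
        default_factory=lambda: tuple(default_disease_defs()))
    block_corr: float = 0.35              # within-block noise correlation
    waist_delta_slope: float = 0.004      # m of waist per year of delta
    family_disease_rate: float = 0.20
    calibration_count: bool = False       # emit an explicit Poisson outcome
    calibration_beta_delta: float = 0.05  # planted Poisson log-rate slope on delta
    calibration_beta_age: float = 0.03
    calibration_intercept: float = -0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError("age_range lower bound must be below upper bound")
        if not 0.0 <= self.prop_female <= 1.0:
            raise ValueError("prop_female must lie in [0, 1]")
        if self.latent_aging_sd < 0:
            raise ValueError("latent_aging_sd must be >= 0")
        if not self.biomarker_defs:
            raise ValueError("biomarker_defs must not be empty")
        if not 0.0 <= self.block_corr < 1.0:
            raise ValueError("block_corr must lie in [0, 1)")


def default_cohort_spec(n_participants: int = 5000, seed: int = 0, **overrides) -> CohortSpec:
    """The default study-condition cohort used by fixtures and benchmarks."""
    return replace(CohortSpec(n_participants=n_participants, seed=seed), **overrides)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw one synthetic cohort table.

    Returns a DataFrame with one row per participant: ``participant_id``,
    ``chronological_age``, ``gender`` (1 = female), anthropometry
    (height/weight/waist in m and kg, ``bmi = weight / height**2``), the 13
    continuous and 4 binary biochemical markers, the 7 disease flags,
    ``family_disease``, and the oracle-only ``latent_delta``.
    Fixed ``spec`` (including seed) gives a byte-identical table.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_participants
    lo, hi = spec.age_range

    ca = rng.uniform(lo, hi, size=n)
    # women outlive men, so the fraction female rises with age in an
    # examination cohort of 45-90 year olds
    if spec.prop_female in (0.0, 1.0):
        p_female = np.full(n, spec.prop_female)
    else:
        base_logit = math.log(spec.prop_female / (1.0 - spec.prop_female))
        p_female = _sigmoid(base_logit
                            + spec.female_age_slope * (ca - (lo + hi) / 2.0))
    female = (rng.random(n) < p_female).astype(np.int64)
    delta = rng.normal(0.0, spec.latent_aging_sd, size=n) + spec.female_delta_shift * female
    ea = ca + delta  # effective age driving the biomarkers

    table: dict[str, np.ndarray] = {
        "participant_id": np.arange(n, dtype=np.int64),
        "chronological_age": ca,
        "gender": female,
    }

    # anthropometry: height mildly shrinks with effective age, waist carries an
    # explicit delta loading so ABSI/WHtR pick up the latent aging rate
    height = (1.695 - 0.125 * female - 0.0012 * (ea - 65.0)
              + rng.normal(0.0, 0.06, size=n))
    bmi_latent = 23.5 + 0.6 * female - 0.02 * (ca - 65.0) + rng.normal(0.0, 2.6, size=n)
    weight = bmi_latent * height ** 2
    waist = (0.84 - 0.035 * female + 0.011 * (bmi_latent - 23.5)
             + 0.0010 * (ca - 65.0) + spec.waist_delta_slope * delta
             + rng.normal(0.0, 0.035, size=n))
    table["height"] = height
    table["weight"] = weight
    table["waist"] = np.clip(waist, 0.45, None)
    table["bmi"] = weight / height ** 2

    # shared latent factors per correlation block
    blocks = sorted({d.corr_block for d in spec.biomarker_defs if d.corr_block})
    block_z = {b: rng.normal(0.0, 1.0, size=n) for b in blocks}
    rho = spec.block_corr

    for d in spec.biomarker_defs:
        if d.kind == "continuous":
            mean = (d.base_mean + d.age_slope * (ea - 65.0)
                    + d.gender_shift * female + d.nonlinearity * (ea - 65.0) ** 2)
            eps = rng.normal(0.0, 1.0, size=n)
            if d.corr_block:
                noise = math.sqrt(rho) * block_z[d.corr_block] + math.sqrt(1.0 - rho) * eps
            else:
                noise = eps
            table[d.name] = mean + d.base_sd * noise
        else:
            p = _sigmoid(d.logit_intercept + d.logit_age_slope * (ea - 65.0))
            table[d.name] = (rng.random(n) < p).astype(np.int64)

    family = (rng.random(n) < spec.family_disease_rate).astype(np.int64)
    table["family_disease"] = family
    for dd in spec.disease_defs:
        logit = (dd.intercept + dd.beta_age * (ca - 65.0)
                 + dd.beta_delta * delta + dd.beta_family * family)
        p = _sigmoid(logit)
        if np.any(p <= 0.0) or np.any(p >= 1.0):
            raise ValueError(f"{dd.name}: disease probabilities left (0, 1)")
        table[dd.name] = (rng.random(n) < p).astype(np.int64)

    if spec.calibration_count:
        rate = np.exp(spec.calibration_intercept
                      + spec.calibration_beta_age * (ca - 65.0)
                      + spec.calibration_beta_delta * delta)
        table["calibration_count"] = rng.poisson(rate)

    table["latent_delta"] = delta
    return pd.DataFrame(table)


# ---------------------------------------------------------------------------
# missingness injection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MissingnessProfile:
    """Target missingness pattern.

    MCAR removes ``global_rate`` of all cells in the maskable block uniformly.
    MNAR removes ``per_variable_rate[v]`` of each listed column, with removal
    probability increasing in the value's rank when ``value_dependence > 0``
    (softmax over standardized ranks), which makes the mechanism genuinely
    not-at-random while still hitting the printed per-variable rates exactly.
    """

    mechanism: str                                   # "MCAR" | "MNAR"
    global_rate: float = 0.0
    per_variable_rate: dict[str, float] = field(default_factory=dict)
    value_dependence: float = 0.5                    # MNAR upper-tail bias strength (mild)

    def __post_init__(self) -> None:
        if self.mechanism not in ("MCAR", "MNAR"):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        rates = ([self.global_rate] if self.mechanism == "MCAR"
                 else list(self.per_variable_rate.values()))
        for r in rates:
            if not 0.0 <= r < 1.0:
                raise ValueError("missing rates must lie in [0, 1)")
        if self.mechanism == "MNAR":
            bad = set(self.per_variable_rate) - set(MASKABLE_COLUMNS)
            if bad:
                raise ValueError(f"MNAR profile names unmaskable columns: {sorted(bad)}")

    @property
    def label(self) -> str:
        if self.mechanism == "MCAR":
            return f"MCAR-{self.global_rate:g}"
        return "MNAR"


def default_mnar_profile(value_dependence: float = 0.5) -> MissingnessProfile:
    """Per-variable rates for the columns exceeding a 2% observed missing
    ratio, averaging ~5% overall across the maskable block."""
    rates = {
        "sgpt": 0.12, "sgot": 0.12, "total_bilirubin": 0.10,
        "ldl": 0.15, "hdl": 0.15, "tg": 0.08, "tc": 0.08,
        "fsg": 0.05, "platelets": 0.04, "white_blood_cell": 0.04,
        "urine_protein": 0.03, "urine_sugar": 0.03,
    }
    return MissingnessProfile("MNAR", per_variable_rate=rates,
                              value_dependence=value_dependence)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def inject_missing(
    table: pd.DataFrame,
    profile: MissingnessProfile,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove values from the maskable feature block of a complete table.

    Returns ``(gapped, mask)`` where ``mask`` is a boolean DataFrame over the
    maskable columns, True exactly where a value was removed.  Realized counts
    are exact: ``round(rate * n)`` per column under MNAR, ``round(rate * cells)``
    overall under MCAR (round half up).  Age, gender, disease flags and derived
    columns are never masked.
    """
    cols = [c for c in MASKABLE_COLUMNS if c in table.columns]
    if not cols:
        raise ValueError("table has no maskable columns")
    block = table[cols]
    if block.isna().any().any():
        raise ValueError("maskable block must be complete before injection")

    n = len(table)
    rng = np.random.default_rng(seed)
    mask = np.zeros((n, len(cols)), dtype=bool)

    if profile.mechanism == "MCAR":
        cells = n * len(cols)
        k = _round_half_up(profile.global_rate * cells)
        if k > cells:
            raise ValueError("requested removals exceed available cells")
        # permutation prefix: masks at increasing rates nest under a fixed
        # seed, so rate comparisons share their masked cells (common random
        # numbers)
        flat = rng.permutation(cells)[:k]
        mask.flat[flat] = True
    else:
        strength = profile.value_dependence
        for j, col in enumerate(cols):
            rate = profile.per_variable_rate.get(col, 0.0)
            k = _round_half_up(rate * n)
            if k == 0:
                continue
            if k > n:
                raise ValueError(f"{col}: requested removals exceed rows")
            if strength > 0:
                # softmax over standardized value ranks: higher values are
                # more likely to go missing (upper-tail bias)
                ranks = pd.Series(block[col].to_numpy()).rank(method="first").to_numpy()
                z = (ranks - ranks.mean()) / ranks.std()
                w = np.exp(strength * z)
                p = w / w.sum()
            else:
                p = None
            idx = rng.choice(n, size=k, replace=False, p=p)
            mask[idx, j] = True

    mask_df = pd.DataFrame(mask, index=table.index, columns=cols)
    gapped = table.copy()
    gapped_block = block.astype(float).where(~mask_df)
    gapped[cols] = gapped_block
    return gapped, mask_df


def exclusion_accounting(
    initial: int,
    outliers: int,
    high_missing: int,
    age_out: int,
) -> int:
    """Sequential sample-exclusion bookkeeping.

    Removes, in order, outlier participants, participants with excessive
    missingness, and participants outside the study age window, logging an
    audit record per step; the running total must never go negative.
    """
    steps = [("outliers", outliers), ("high_missing", high_missing), ("age_out", age_out)]
    if initial < 0 or any(k < 0 for _, k in steps):
        raise ValueError("counts must be nonnegative")
    total = initial
    for name, k in steps:
        total -= k
        logger.info("exclusion step %s: -%d -> %d remaining", name, k, total)
        if total < 0:
            raise ValueError(f"exclusion step {name!r} drives the total negative")
    return total


# ---------------------------------------------------------------------------
# oracle-column guard
# ---------------------------------------------------------------------------

def assert_no_oracle(table: pd.DataFrame, context: str = "estimation") -> None:
    """Raise if a table still carries generator ground-truth columns."""
    leaked = [c for c in ORACLE_COLUMNS if c in table.columns]
    if leaked:
        raise ValueError(
            f"oracle column(s) {leaked} must not reach {context}; "
            "call drop_oracle_columns() first")


def drop_oracle_columns(table: pd.DataFrame) -> pd.DataFrame:
    return table.drop(columns=[c for c in ORACLE_COLUMNS if c in table.columns])
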