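"""Synthetic two-center PICU cohorts.

The study data are not publicly deposited, so this module generates cohorts
with the published statistical structure: two centers (Oviedo n=308 with 15
deaths, Riga n=291 with 9 deaths), per-patient evaluation counts drawn from
the published frequency table, and class-conditional truncated-normal
distributions of MID, PIM2 and TISS28 matching the published means and SDs.
Within a class, MID and PIM2 share a Gaussian-copula correlation (default
0.3); TISS28 is drawn independently.

Two outcome mechanisms are available:

``class_conditional``
    outcomes fixed at the center's exact death count (hypergeometric
    assignment), covariates drawn per class — the default, emulating the
    published summary tables;
``logistic_truth``
    covariates drawn from the survivor-weighted mixture and outcomes drawn
    from a logistic model with known coefficients, recorded in the returned
    :class:`GeneratorTruth` for parameter-recovery testing.

Each patient then receives an evaluation count from the center's table and
that many trapezoid evaluations: the evaluation midpoint is the latent MID
plus normal jitter, and the spreads (SPR, SPRL, SPRR) are half-normal draws
shrunk — never moving MID — until the trapezoid fits inside [0, 100].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from types import MappingProxyType
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, ndtr

from .cohort import COHORT_COLUMNS, Cohort
from .fuzzy import average_by_patient, parameterize_frame

logger = logging.getLogger(__name__)

VARIABLES = ("MID", "PIM2", "TISS28")
VARIABLE_BOUNDS = {"MID": (0.0, 100.0), "PIM2": (0.0, 100.0), "TISS28": (0.0, np.inf)}

#: generating coefficients used by default in ``logistic_truth`` mode; the
#: MID and PIM2 slopes are on their natural percent scales
DEFAULT_TRUTH_COEFFICIENTS: Mapping[str, float] = MappingProxyType(
    {"intercept": -4.6, "MID": 0.045, "PIM2": 0.07}
)


@dataclass(frozen=True)
class CenterProfile:
    """Statistical profile of one center's cohort.

    ``class_conditional`` maps variable -> outcome class -> (location,
    scale) of the pre-truncation normal.  ``eval_count_probs[i]`` is the
    probability a patient receives i+1 evaluations.
    """

    label: str
    n_patients: int
    n_deaths: int
    eval_count_probs: tuple[float, ...]
    class_conditional: Mapping[str, Mapping[str, tuple[float, float]]]
    eval_jitter_sd: float = 5.0
    spr_scale: float = 5.0
    sprl_scale: float = 5.0
    sprr_scale: float = 10.0
    mid_pim2_corr: float = 0.3
    moment_match: bool = False

    def __post_init__(self) -> None:
        if not np.isclose(sum(self.eval_count_probs), 1.0):
            raise ValueError("eval_count_probs must sum to 1")
        if not 0 < self.n_deaths < self.n_patients:
            raise ValueError("need 0 < n_deaths < n_patients")
        for s in (self.eval_jitter_sd, self.spr_scale, self.sprl_scale, self.sprr_scale):
            if s <= 0:
                raise ValueError("all scale parameters must be positive")
        if not -1 < self.mid_pim2_corr < 1:
            raise ValueError("mid_pim2_corr must lie in (-1, 1)")

    @property
    def death_rate(self) -> float:
        return self.n_deaths / self.n_patients


@dataclass
class GeneratorTruth:
    """Latent generating quantities stored alongside every synthetic cohort.

    ``latent`` has one row per patient (patient_id, outcome, latent MID and
    the drawn PIM2/TISS28); ``coefficients`` holds the generating logistic
    coefficients in ``logistic_truth`` mode, otherwise None.  The raw
    synthetic evaluation table is kept so the cohort can round-trip through
    the CSV loader.
    """

    latent: pd.DataFrame
    coefficients: dict[str, float] | None
    evaluations: pd.DataFrame = field(repr=False, default=None)


def default_profiles() -> tuple[CenterProfile, CenterProfile]:
    """The two published center profiles (counts, eval-count frequencies,
    class-conditional means/SDs of MID, PIM2 and TISS28)."""
    oviedo_counts = np.array([73, 83, 71, 43, 19, 7, 4, 3, 5], dtype=float)
    riga_counts = np.array([23, 109, 115, 41, 3, 2], dtype=float)
    oviedo = CenterProfile(
        label="oviedo",
        n_patients=308,
        n_deaths=15,
        eval_count_probs=tuple(oviedo_counts / oviedo_counts.sum()),
        class_conditional={
            "MID": {"survivor": (7.55, 12.29), "nonsurvivor": (54.57, 37.83)},
            "PIM2": {"survivor": (2.29, 6.96), "nonsurvivor": (35.33, 37.60)},
            "TISS28": {"survivor": (16.60, 6.64), "nonsurvivor": (28.07, 12.00)},
        },
    )
    riga = CenterProfile(
        label="riga",
        n_patients=291,
        n_deaths=9,
        eval_count_probs=tuple(riga_counts / riga_counts.sum()),
        class_conditional={
            "MID": {"survivor": (8.51, 10.82), "nonsurvivor": (50.00, 33.22)},
            "PIM2": {"survivor": (1.97, 4.44), "nonsurvivor": (14.33, 15.80)},
            "TISS28": {"survivor": (24.83, 8.90), "nonsurvivor": (30.55, 9.45)},
        },
    )
    return oviedo, riga


def _match_truncnorm(mean: float, sd: float, lo: float, hi: float) -> tuple[float, float]:
    """Pre-truncation (loc, scale) whose truncated moments match mean/sd."""

    def eqs(params):
        loc, log_scale = params
        scale = np.exp(log_scale)
        a, b = (lo - loc) / scale, (hi - loc) / scale
        return [
            stats.truncnorm.mean(a, b, loc=loc, scale=scale) - mean,
            stats.truncnorm.std(a, b, loc=loc, scale=scale) - sd,
        ]

    sol = optimize.fsolve(eqs, [mean, np.log(sd)], full_output=False)
    return float(sol[0]), float(np.exp(sol[1]))


def _truncnorm_from_u(u: np.ndarray, loc: float, scale: float, lo: float, hi: float) -> np.ndarray:
    a, b = (lo - loc) / scale, (hi - loc) / scale
    # clip away exact 0/1 quantiles before the ppf
    u = np.clip(u, 1e-12, 1 - 1e-12)
    return stats.truncnorm.ppf(u, a, b, loc=loc, scale=scale)


def _draw_class(
    profile: CenterProfile, outcome_class: str, m: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Class-conditional (MID, PIM2, TISS28) draws via a Gaussian copula."""
    rho = profile.mid_pim2_corr
    corr = np.array([[1.0, rho, 0.0], [rho, 1.0, 0.0], [0.0, 0.0, 1.0]])
    z = rng.standard_normal((m, 3)) @ np.linalg.cholesky(corr).T
    u = ndtr(z)
    out = {}
    for j, var in enumerate(VARIABLES):
        loc, scale = profile.class_conditional[var][outcome_class]
        lo, hi = VARIABLE_BOUNDS[var]
        if profile.moment_match:
            loc, scale = _match_truncnorm(loc, scale, lo, hi)
        out[var] = _truncnorm_from_u(u[:, j], loc, scale, lo, hi)
    return out


def _make_evaluations(
    profile: CenterProfile,
    patient_ids: np.ndarray,
    latent_mid: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    n = len(patient_ids)
    counts = rng.choice(
        np.arange(1, len(profile.eval_count_probs) + 1),
        size=n,
        p=profile.eval_count_probs,
    )
    rep = np.repeat(np.arange(n), counts)
    m = len(rep)
    mid = np.clip(latent_mid[rep] + rng.normal(0.0, profile.eval_jitter_sd, m), 0.0, 100.0)
    spr = np.abs(rng.normal(0.0, profile.spr_scale, m))
    sprl = np.abs(rng.normal(0.0, profile.sprl_scale, m))
    sprr = np.abs(rng.normal(0.0, profile.sprr_scale, m))
    # shrink spreads (never MID) until the trapezoid fits in [0, 100]
    spr = np.minimum(spr, np.minimum(mid, 100.0 - mid))
    sprl = np.minimum(sprl, mid - spr)
    sprr = np.minimum(sprr, 100.0 - mid - spr)
    short_lo = np.maximum(mid - spr, 0.0)
    short_hi = np.minimum(mid + spr, 100.0)
    return pd.DataFrame(
        {
            "patient_id": patient_ids[rep],
            "rater_role": rng.choice(["physician", "nurse"], size=m),
            "short_lo": short_lo,
            "short_hi": short_hi,
            "long_lo": np.maximum(short_lo - sprl, 0.0),
            "long_hi": np.minimum(short_hi + sprr, 100.0),
        }
    )


def generate_cohort(
    profile: CenterProfile,
    mode: str = "class_conditional",
    seed: int | np.random.SeedSequence | None = None,
    truth_coefficients: Mapping[str, float] | None = None,
) -> tuple[Cohort, GeneratorTruth]:
    """Generate one center's synthetic cohort plus its generating truth."""
    if mode not in ("class_conditional", "logistic_truth"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    n = profile.n_patients

    if mode == "class_conditional":
        outcome = np.zeros(n, dtype=int)
        outcome[rng.permutation(n)[: profile.n_deaths]] = 1
        cov = {var: np.empty(n) for var in VARIABLES}
        for cls, mask in (("survivor", outcome == 0), ("nonsurvivor", outcome == 1)):
            draws = _draw_class(profile, cls, int(mask.sum()), rng)
            for var in VARIABLES:
                cov[var][mask] = draws[var]
        coefficients = None
    else:
        mix = rng.random(n) < profile.death_rate
        cov = {var: np.empty(n) for var in VARIABLES}
        for cls, mask in (("survivor", ~mix), ("nonsurvivor", mix)):
            draws = _draw_class(profile, cls, int(mask.sum()), rng)
            for var in VARIABLES:
                cov[var][mask] = draws[var]
        coefficients = dict(truth_coefficients or DEFAULT_TRUTH_COEFFICIENTS)
        eta = coefficients.get("intercept", 0.0) + sum(
            coefficients.get(var, 0.0) * cov[var] for var in VARIABLES
        )
        outcome = (rng.random(n) < expit(eta)).astype(int)

    width = max(4, len(str(n)))
    patient_ids = np.array([f"{profile.label}-{i + 1:0{width}d}" for i in range(n)])
    evaluations = _make_evaluations(profile, patient_ids, cov["MID"], rng)
    averaged = average_by_patient(parameterize_frame(evaluations))
    frame = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "center": profile.label,
            "outcome": outcome,
            "PIM2": cov["PIM2"],
            "TISS28": cov["TISS28"],
        }
    ).merge(averaged, on="patient_id")
    cohort = Cohort(frame[list(COHORT_COLUMNS)], label=profile.label)
    truth = GeneratorTruth(
        latent=pd.DataFrame(
            {
                "patient_id": patient_ids,
                "outcome": outcome,
                "latent_MID": cov["MID"],
                "PIM2": cov["PIM2"],
                "TISS28": cov["TISS28"],
            }
        ),
        coefficients=coefficients,
        evaluations=evaluations,
    )
    return cohort, truth


def generate_multicenter_with_truth(
    seed: int | None = None,
    mode: str = "class_conditional",
    profiles: tuple[CenterProfile, ...] | None = None,
    truth_coefficients: Mapping[str, float] | None = None,
) -> tuple[Cohort, list[GeneratorTruth]]:
    """Concatenated multi-center cohort plus the per-center truths."""
    profiles = profiles if profiles is not None else default_profiles()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(len(profiles))
    cohorts, truths = [], []
    for profile, child in zip(profiles, children):
        c, t = generate_cohort(profile, mode=mode, seed=child, truth_coefficients=truth_coefficients)
        cohorts.append(c.data)
        truths.append(t)
    combined = pd.concat(cohorts, ignore_index=True)
    return Cohort(combined, label="multicenter"), truths


def generate_multicenter(
    seed: int | np.random.SeedSequence | None = None,
    mode: str = "class_conditional",
) -> Cohort:
    """Default two-center synthetic cohort (n=599, 24 nonsurvivors)."""
    cohort, _ = generate_multicenter_with_truth(seed=seed, mode=mode)
    return cohort


def write_truth(truth: GeneratorTruth, path: str | Path) -> None:
    """Write the latent sidecar CSV (generating coefficients as comments)."""
    df = truth.latent.copy()
    if truth.coefficients is not None:
        for name, value in truth.coefficients.items():
            df[f"coef_{name}"] = value
    df.to_csv(path, index=False)
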