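"""Synthetic longitudinal MS cohorts with known ground truth.

Emulates a relapsing-remitting MS cohort observed at baseline, ~6 and ~18
months: demographic marginals, a heavy-tailed disease-duration
distribution, latent non-linear long-term trajectories of choroid-plexus
volume / T1/T2 ratio / lateral-ventricle volume over disease duration, and
configurable standardized cross-sectional and longitudinal effect sizes.

Every variable is generated on a latent z-scale constructed to have unit
variance at baseline:

    z = curve(d0) + sum_j beta_j * z0_pred_j + slope * t
        + sum_m gamma_m * z0_mod_m * t + b_i + e_it

where ``curve`` is the (empirically standardized) long-term trajectory
evaluated at *baseline* disease duration d0, ``t`` is years since baseline,
``z0_*`` are observed baseline z-values of predictors/moderators, ``b_i`` a
subject random intercept and ``e_it`` within-subject noise.  The long-term
curve is frozen within subject: short-term within-subject change is carried
entirely by the time slopes and interactions, so the generating coefficients
are exactly the estimands of the downstream mixed models.  z-values are
finally mapped to natural units by each variable's location/scale (EDSS by a
monotone two-piece lognormal map to the 0-10 half-point scale).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CurveParams",
    "EffectSpec",
    "CohortSpec",
    "CohortTable",
    "true_curve",
    "sample_cohort",
    "export_cohort",
    "read_cohort",
    "TABLE1_MARGINALS",
]

#: (location, scale) of each continuous variable in natural units.
#: Normalized volumes are on the x1000 scale; lateral-ventricle volume has
#: no published marginal and uses a typical-MS assumption.
TABLE1_MARGINALS: dict[str, tuple[float, float]] = {
    "age": (40.8, 10.9),
    "disease_duration": (9.5, 17.4),  # gamma-matched, right-skewed
    "sdmt": (50.6, 14.7),
    "bvmtr": (25.0, 7.6),
    "cvlt2": (53.1, 12.0),
    "lesion_ml": (11.9, 14.1),
    "nbv": (774.7, 24.3),
    "ncgmv": (416.9, 12.5),
    "ndgmv": (27.5, 3.0),
    "nwmv": (315.7, 16.2),
    "nchpv": (1.6, 0.6),
    "t1t2": (0.5, 0.1),
    "nlvv": (15.0, 8.0),
}

GENDER_PROBS = {"female": 270 / 422, "male": 150 / 422, "non_binary": 2 / 422}
DMT_PROBS = {"high": 257 / 422, "moderate_low": 165 / 422}

#: variables following a latent long-term curve over disease duration
CURVE_VARS = {"nchpv": "chp_volume", "t1t2": "t1t2_ratio", "nlvv": "ventricle"}

OUTCOME_VARS = (
    "nchpv", "t1t2", "nlvv", "lesion_ml", "nbv", "ncgmv", "ndgmv", "nwmv",
    "edss", "sdmt", "bvmtr", "cvlt2",
)

DEFAULT_NOISE_SD_WITHIN = {
    # MRI-derived measures: high scan-rescan reliability
    "nchpv": 0.25, "t1t2": 0.25, "nlvv": 0.25, "lesion_ml": 0.25,
    "nbv": 0.25, "ncgmv": 0.25, "ndgmv": 0.25, "nwmv": 0.25,
    # clinical / cognitive measures: lower test-retest reliability
    "edss": 0.45, "sdmt": 0.45, "bvmtr": 0.45, "cvlt2": 0.45,
}

_Z75 = sps.norm.ppf(0.75)


@dataclass(frozen=True)
class CurveParams:
    """Shape of the latent long-term trajectories (years / z-units).

    ``amplitudes`` give the SD (in z-units) of each standardized curve
    component in the generated variable; the default 0.7 puts about half of
    the between-subject variance on the long-term trajectory.
    """

    chp_plateau_years: float = 12.0
    chp_late_decline: float = 0.005
    ratio_nadir_years: float = 10.0
    ventricle_slope: float = 0.04
    amplitudes: dict[str, float] = field(default_factory=lambda: {
        "chp_volume": 0.7, "t1t2_ratio": 0.7, "ventricle": 0.7})

    def __post_init__(self) -> None:
        if self.chp_plateau_years <= 0 or self.ratio_nadir_years <= 0:
            raise ValueError("plateau and nadir must be > 0")
        if self.ventricle_slope <= 0:
            raise ValueError("ventricle_slope must be > 0")
        if any(a <= 0 for a in self.amplitudes.values()):
            raise ValueError("amplitudes must be > 0")


@dataclass(frozen=True)
class EffectSpec:
    """Standardized generating coefficients (partial betas).

    ``cross_sectional`` maps (predictor, outcome) to the standardized
    coefficient linking observed baseline predictor z to outcome z;
    ``longitudinal_time`` maps outcome to its z/year time slope;
    ``interactions`` maps (baseline moderator, outcome) to the z/(z*year)
    interaction coefficient.  Defaults are the study-calibrated values.
    """

    cross_sectional: dict[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("nchpv", "lesion_ml"): 0.35,
            ("nchpv", "nbv"): -0.30,
            ("nchpv", "ndgmv"): -0.29,
            ("nchpv", "edss"): 0.13,
            ("nchpv", "bvmtr"): -0.16,
        })
    longitudinal_time: dict[str, float] = field(default_factory=lambda: {
        "nchpv": 0.45, "t1t2": 0.29, "nbv": -0.05, "cvlt2": 0.13})
    interactions: dict[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("t1t2", "nbv"): -0.21,
            ("t1t2", "ndgmv"): -0.25,
            ("t1t2", "bvmtr"): -0.23,
        })

    def __post_init__(self) -> None:
        for coll in (self.cross_sectional.values(),
                     self.longitudinal_time.values(),
                     self.interactions.values()):
            if any(abs(b) >= 1 for b in coll):
                raise ValueError("all |beta| must be < 1")


@dataclass(frozen=True)
class CohortSpec:
    n_subjects: int = 422
    p_fu1: float = 0.65
    p_fu2_given_fu1: float = 80 / 276
    fu1_median_months: float = 7.2
    fu1_iqr_months: tuple[float, float] = (6.0, 9.6)
    fu2_median_months: float = 19.2
    fu2_iqr_months: tuple[float, float] = (18.0, 22.8)
    marginals: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(TABLE1_MARGINALS))
    curve_params: CurveParams = field(default_factory=CurveParams)
    effects: EffectSpec = field(default_factory=EffectSpec)
    noise_sd_within: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_NOISE_SD_WITHIN))
    max_duration_years: float = 50.0  # support cap for the duration gamma
    unit_variance_fill: bool = True  # top up var to 1 via random intercepts
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.p_fu1 <= 1 and 0 <= self.p_fu2_given_fu1 <= 1):
            raise ValueError("follow-up probabilities must be in [0, 1]")
        if self.n_subjects < 10:
            raise ValueError("n_subjects must be >= 10")
        for var, (_, scale) in self.marginals.items():
            if scale <= 0:
                raise ValueError(f"scale for {var!r} must be > 0")


@dataclass
class CohortTable:
    """Long-format subject-visit table plus hidden generating ground truth."""

    data: pd.DataFrame
    ground_truth: dict
    spec: CohortSpec | None = None

    @property
    def n_subjects(self) -> int:
        return int(self.data["subject_id"].nunique())

    def baseline(self) -> pd.DataFrame:
        return self.data[self.data["visit"] == 0]


def true_curve(kind: str, d, params: CurveParams | None = None):
    """Latent long-term trajectory value (z-units) at disease duration d.

    chp_volume: saturating rise ``A (1 - exp(-3 d / plateau))`` with an
    optional hinge decline after the plateau; t1t2_ratio: parabola with its
    minimum exactly at the nadir; ventricle: linear increase.
    """
    params = params or CurveParams()
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("disease duration must be >= 0")
    if kind == "chp_volume":
        a = params.amplitudes["chp_volume"]
        p = params.chp_plateau_years
        out = a * (1.0 - np.exp(-3.0 * d / p)) \
            - params.chp_late_decline * np.clip(d - p, 0.0, None)
    elif kind == "t1t2_ratio":
        a = params.amplitudes["t1t2_ratio"]
        nad = params.ratio_nadir_years
        out = a * ((d - nad) ** 2 / nad**2) - a
    elif kind == "ventricle":
        out = params.ventricle_slope * d
    else:
        raise ValueError(f"unknown curve kind {kind!r}")
    return out if out.ndim else float(out)


def _edss_from_z(z: np.ndarray) -> np.ndarray:
    """Monotone two-piece lognormal map of latent z to the EDSS half-point
    scale, calibrated to median 2.0 and IQR (1.5, 3.5)."""
    sig_lo = np.log(2.0 / 1.5) / _Z75
    sig_hi = np.log(3.5 / 2.0) / _Z75
    sig = np.where(z < 0, sig_lo, sig_hi)
    cont = 2.0 * np.exp(sig * z)
    return np.clip(np.round(cont * 2.0) / 2.0, 0.0, 10.0)


def _lognormal_times(rng, n, median, iqr):
    sd = np.log(iqr[1] / iqr[0]) / (2.0 * _Z75)
    return np.exp(rng.normal(np.log(median), sd, size=n))


def _topo_order(effects: EffectSpec) -> list[str]:
    deps = {v: set() for v in OUTCOME_VARS}
    for (pred, out) in effects.cross_sectional:
        deps[out].add(pred)
    order, placed = [], set()
    pool = list(OUTCOME_VARS)
    while pool:
        progress = [v for v in pool if deps[v] <= placed]
        if not progress:
            raise ValueError(f"cyclic cross-sectional EffectSpec among {pool}")
        for v in progress:
            order.append(v)
            placed.add(v)
            pool.remove(v)
    return order


def sample_cohort(spec: CohortSpec | None = None) -> CohortTable:
    """Draw one seeded cohort with the study's visit structure."""
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    cp = spec.curve_params
    eff = spec.effects

    # --- demographics ---------------------------------------------------
    loc_age, sd_age = spec.marginals["age"]
    age = rng.normal(loc_age, sd_age, size=n)
    while np.any(age < 18):  # biological floor; negligible mass
        bad = age < 18
        age[bad] = rng.normal(loc_age, sd_age, size=int(bad.sum()))
    gender = rng.choice(list(GENDER_PROBS), p=list(GENDER_PROBS.values()), size=n)
    dmt = rng.choice(list(DMT_PROBS), p=list(DMT_PROBS.values()), size=n)

    # --- disease duration: moment-matched gamma, truncated at a
    # biologically plausible support cap ------------------------------
    m_dd, s_dd = spec.marginals["disease_duration"]
    shape = (m_dd / s_dd) ** 2
    scale = s_dd**2 / m_dd
    u = rng.uniform(0.0, sps.gamma.cdf(spec.max_duration_years, shape,
                                       scale=scale), size=n)
    dd0 = sps.gamma.ppf(u, shape, scale=scale)

    # --- visit structure ------------------------------------------------
    has_fu1 = rng.random(n) < spec.p_fu1
    has_fu2 = has_fu1 & (rng.random(n) < spec.p_fu2_given_fu1)
    t1m = _lognormal_times(rng, n, spec.fu1_median_months, spec.fu1_iqr_months)
    t2m = _lognormal_times(rng, n, spec.fu2_median_months, spec.fu2_iqr_months)
    t2m = np.maximum(t2m, t1m + 2.0)  # keep visits strictly ordered
    times = np.column_stack([np.zeros(n), t1m / 12.0, t2m / 12.0])

    # --- standardized long-term curve components ------------------------
    curve_term: dict[str, np.ndarray] = {}
    curve_std: dict[str, dict] = {}
    for var, kind in CURVE_VARS.items():
        raw = true_curve(kind, dd0, cp)
        mu, sd = float(np.mean(raw)), float(np.std(raw))
        amp = cp.amplitudes[kind]
        if sd < 1e-12:
            raise ValueError(f"degenerate long-term curve for {var!r}")
        curve_term[var] = amp * (raw - mu) / sd
        curve_std[var] = {"raw_mean": mu, "raw_sd": sd, "amplitude": amp}

    # --- latent z generation (topological in the cross-sectional DAG) ---
    z0: dict[str, np.ndarray] = {}
    z_visits: dict[str, np.ndarray] = {}
    intercepts: dict[str, np.ndarray] = {}
    varcomp: dict[str, dict] = {}
    for var in _topo_order(eff):
        D = curve_term.get(var, np.zeros(n)).copy()
        for (pred, out), beta in eff.cross_sectional.items():
            if out == var:
                D = D + beta * z0[pred]
        var_e = spec.noise_sd_within.get(var, 0.3) ** 2
        var_D = float(np.var(D))
        if spec.unit_variance_fill:
            var_b = 1.0 - var_D - var_e
            if var_b < 0:
                raise ValueError(
                    f"EffectSpec infeasible: negative residual variance for "
                    f"the {var!r} equation (structural+curve variance "
                    f"{var_D:.3f}, within-noise variance {var_e:.3f})")
        else:
            var_b = 0.0
        b = rng.normal(0.0, np.sqrt(var_b), size=n)
        slope = eff.longitudinal_time.get(var, 0.0)
        zmat = np.empty((n, 3))
        for v in range(3):
            t = times[:, v]
            drift = slope * t
            for (mod, out), gamma in eff.interactions.items():
                if out == var:
                    drift = drift + gamma * z0[mod] * t
            e = rng.normal(0.0, np.sqrt(var_e), size=n)
            zmat[:, v] = D + drift + b + e
        z0[var] = zmat[:, 0]
        z_visits[var] = zmat
        intercepts[var] = b
        varcomp[var] = {"curve": float(np.var(curve_term.get(var, np.zeros(1)))),
                        "deterministic": var_D, "intercept": var_b,
                        "within": var_e}

    # --- assemble long table in natural units ---------------------------
    rows = []
    present = np.column_stack([np.ones(n, bool), has_fu1, has_fu2])
    for v in range(3):
        idx = np.flatnonzero(present[:, v])
        rec = {
            "subject_id": [f"s{i:05d}" for i in idx],
            "visit": v,
            "time_years": times[idx, v],
            "age": age[idx],
            "gender": gender[idx],
            "dmt_class": dmt[idx],
            "disease_duration": dd0[idx] + times[idx, v],
        }
        for var in OUTCOME_VARS:
            z = z_visits[var][idx, v]
            if var == "edss":
                rec[var] = _edss_from_z(z)
            else:
                loc, sc = spec.marginals[var]
                rec[var] = loc + sc * z
        rows.append(pd.DataFrame(rec))
    data = (pd.concat(rows, ignore_index=True)
            .sort_values(["subject_id", "visit"], kind="stable")
            .reset_index(drop=True))

    ground_truth = {
        "seed": spec.seed,
        "n_subjects": n,
        "effects": {
            "cross_sectional": {f"{p}->{o}": b
                                for (p, o), b in eff.cross_sectional.items()},
            "longitudinal_time": dict(eff.longitudinal_time),
            "interactions": {f"{m}*time->{o}": g
                             for (m, o), g in eff.interactions.items()},
        },
        "curve_params": {
            "chp_plateau_years": cp.chp_plateau_years,
            "chp_late_decline": cp.chp_late_decline,
            "ratio_nadir_years": cp.ratio_nadir_years,
            "ventricle_slope": cp.ventricle_slope,
            "amplitudes": dict(cp.amplitudes),
        },
        "curve_standardization": curve_std,
        "variance_components": varcomp,
        "random_intercepts": {var: intercepts[var].tolist()
                              for var in OUTCOME_VARS},
        "baseline_duration_years": dd0.tolist(),
    }
    return CohortTable(data=data, ground_truth=ground_truth, spec=spec)


def export_cohort(table: CohortTable, directory: str | os.PathLike
                  ) -> dict[str, str]:
    """Write cohort.csv (long format) and ground_truth.json."""
    directory = os.fspath(directory)
    try:
        os.makedirs(directory, exist_ok=True)
        csv_path = os.path.join(directory, "cohort.csv")
        table.data.to_csv(csv_path, index=False)
        gt_path = os.path.join(directory, "ground_truth.json")
        with open(gt_path, "w") as fh:
            json.dump(table.ground_truth, fh, indent=2)
        return {"cohort": csv_path, "ground_truth": gt_path}
    except OSError as exc:
        raise OSError(f"failed writing cohort to {directory!r}: {exc}") from exc


def read_cohort(directory: str | os.PathLike) -> CohortTable:
    directory = os.fspath(directory)
    data = pd.read_csv(os.path.join(directory, "cohort.csv"))
    gt_path = os.path.join(directory, "ground_truth.json")
    ground_truth = {}
    if os.path.exists(gt_path):
        with open(gt_path) as fh:
            ground_truth = json.load(fh)
    return CohortTable(data=data, ground_truth=ground_truth, spec=None)
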