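"""Synthetic patient cohorts with the study's statistical structure.

The continuous block (hip and lumbar BMD plus the 31 cortical-thickness
and 31 cortical-HU site values) is drawn from a multivariate normal with
configurable marginal means/SDs and a pairwise correlation structure;
draws below a physiological positivity floor are redrawn.  T-scores are
affine transforms of BMD using a young-adult reference derived by
inverting printed (BMD, T-score) moment pairs; osteoporosis status
follows the WHO rule (any-site T < -2.5).  Demographics, complications
and functional scores are drawn from group-conditional models so that
screening-rule group contrasts can be regenerated in distribution.

Only means, SDs and a handful of pairwise correlations are constrained
by the source tables; the joint Gaussian shape and the exchangeable
0.3 correlation among cortical sites are modelling choices, configurable
through :class:`CohortParams`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

N_ROI = 31

#: printed site means/SDs (cortical thickness mm; cortical HU)
CTH_TABLE = {16: (6.01, 1.39), 21: (3.37, 0.84), 23: (2.67, 0.81),
             25: (3.91, 1.03), 28: (6.39, 1.39)}
HU_TABLE = {14: (419.48, 135.38), 23: (474.74, 122.65),
            27: (570.09, 139.75), 29: (919.90, 170.33)}
#: printed hip-BMD correlations for the best-correlated sites
CTH_BMD_R = {16: 0.523, 21: 0.475, 23: 0.501, 25: 0.480, 28: 0.457}
HU_BMD_R = {14: 0.445, 23: 0.449, 27: 0.481, 29: 0.446}

#: hip / lumbar DXA summary moments: (BMD mean, BMD SD, T mean, T SD)
HIP_DXA_MOMENTS = (0.57, 0.19, -2.70, 1.37)
LUMBAR_DXA_MOMENTS = (0.82, 0.16, -2.18, 1.37)

WHO_T_THRESHOLD = -2.5


class ParameterError(ValueError):
    """Invalid cohort parameterization."""


def derive_tscore_reference(bmd_mean: float, bmd_sd: float,
                            t_mean: float, t_sd: float) -> tuple[float, float]:
    """Young-adult reference (mu_ref, sigma_ref) from printed moments.

    T = (BMD - mu_ref) / sigma_ref is affine, so matching both the BMD
    and T first two moments pins the reference down in closed form:
    sigma_ref = bmd_sd / t_sd and mu_ref = bmd_mean - t_mean * sigma_ref.
    """
    if bmd_sd <= 0 or t_sd <= 0:
        raise ParameterError("standard deviations must be positive")
    sigma_ref = bmd_sd / t_sd
    mu_ref = bmd_mean - t_mean * sigma_ref
    return mu_ref, sigma_ref


def bmd_to_tscore(bmd, reference: tuple[float, float]):
    mu_ref, sigma_ref = reference
    return (np.asarray(bmd, dtype=float) - mu_ref) / sigma_ref


@dataclass
class DXARecord:
    """Hip and lumbar DXA densitometry for one patient."""

    bmd_hip: float
    bmd_lumbar: float
    t_hip: float
    t_lumbar: float

    def __post_init__(self) -> None:
        if self.bmd_hip <= 0 or self.bmd_lumbar <= 0:
            raise ParameterError("BMD must be positive")


def _default_means_sds() -> dict[str, tuple[float, float]]:
    out: dict[str, tuple[float, float]] = {
        "bmd_hip": HIP_DXA_MOMENTS[:2],
        "bmd_lumbar": LUMBAR_DXA_MOMENTS[:2],
    }
    for i in range(1, N_ROI + 1):
        # unprinted sites: population-plausible moments, SD kept tight
        # enough that the positivity floor essentially never binds
        out[f"cth_roi{i}"] = CTH_TABLE.get(i, (3.5, 0.8))
        out[f"hu_roi{i}"] = HU_TABLE.get(i, (600.0, 150.0))
    return out


def _default_correlations() -> dict[tuple[str, str], float]:
    corr: dict[tuple[str, str], float] = {("bmd_hip", "bmd_lumbar"): 0.5}
    for i, r in CTH_BMD_R.items():
        corr[("bmd_hip", f"cth_roi{i}")] = r
    for i, r in HU_BMD_R.items():
        corr[("bmd_hip", f"hu_roi{i}")] = r
    return corr


@dataclass
class CohortParams:
    """Parameters of the synthetic cohort generator.

    ``correlations`` overrides specific pairs; every unspecified
    ROI-ROI pair defaults to ``roi_roi_corr`` (exchangeable block),
    BMD-ROI pairs to ``bmd_roi_corr``.  Group-conditional outcome models
    are keyed by the screening groups of the clinical tables.
    """

    n: int = 375
    means_sds: dict[str, tuple[float, float]] = field(default_factory=_default_means_sds)
    correlations: dict[tuple[str, str], float] = field(default_factory=_default_correlations)
    roi_roi_corr: float = 0.3
    bmd_roi_corr: float = 0.3
    lumbar_roi_corr: float = 0.15
    dxa_fraction: float = 56.0 / 375.0
    rng_seed: int = 0
    female_fraction: float = 240.0 / 375.0
    age_mean_sd: tuple[float, float] = (77.81, 9.44)
    height_mean_sd: tuple[float, float] = (162.6, 8.2)
    bmi_mean_sd: tuple[float, float] = (22.95, 3.8)
    ao_class_probs: tuple[float, float, float] = (116 / 375, 219 / 375, 41 / 375)
    fixation_probs: tuple[float, float, float] = (17 / 375, 35 / 375, 323 / 375)
    # complication log-odds: intercept matches the nonosteoporotic rate
    # 12/180 and the group effect the osteoporotic rate 24/195 under the
    # ROI-21 CTh grouping
    complication_logit_base: float = float(np.log((12 / 180) / (1 - 12 / 180)))
    complication_logit_effect: float = float(
        np.log((24 / 195) / (1 - 24 / 195)) - np.log((12 / 180) / (1 - 12 / 180)))
    cth_cutoff: float = 3.185
    hu_cutoff: float = 424.97
    # functional scores by ROI-14 HU group: (nonosteo (mean, sd), osteo (mean, sd))
    fim_by_group: tuple[tuple[float, float], tuple[float, float]] = ((99.23, 16.79), (94.24, 20.09))
    parker_by_group: tuple[tuple[float, float], tuple[float, float]] = ((7.02, 1.87), (6.57, 2.11))
    tug_by_group: tuple[tuple[float, float], tuple[float, float]] = ((19.09, 8.85), (18.11, 9.34))
    twomwt_by_group: tuple[tuple[float, float], tuple[float, float]] = ((66.72, 22.59), (61.96, 23.30))
    fim_available_prob: tuple[float, float] = (0.828, 0.836)
    tug_completed_prob: tuple[float, float] = (0.802, 0.770)
    twomwt_completed_prob: tuple[float, float] = (0.786, 0.765)
    # bare-positivity floors: redrawing is a safety net against
    # unphysical draws, not an active truncation (which would bias the
    # configured moments and correlations)
    positivity_floor: dict[str, float] = field(default_factory=lambda: {
        "bmd": 1e-6, "cth": 1e-3, "hu": 0.0})

    @property
    def variables(self) -> list[str]:
        return (["bmd_hip", "bmd_lumbar"]
                + [f"cth_roi{i}" for i in range(1, N_ROI + 1)]
                + [f"hu_roi{i}" for i in range(1, N_ROI + 1)])

    def correlation_matrix(self) -> np.ndarray:
        names = self.variables
        k = len(names)
        C = np.empty((k, k))
        for i, a in enumerate(names):
            for j, b in enumerate(names):
                if i == j:
                    C[i, j] = 1.0
                    continue
                key = (a, b) if (a, b) in self.correlations else (b, a)
                if key in self.correlations:
                    C[i, j] = self.correlations[key]
                elif "bmd" in a and "bmd" in b:
                    C[i, j] = 0.5
                elif "bmd_lumbar" in (a, b):
                    C[i, j] = self.lumbar_roi_corr
                elif "bmd_hip" in (a, b):
                    C[i, j] = self.bmd_roi_corr
                else:
                    C[i, j] = self.roi_roi_corr
        return C

    def validate(self) -> np.ndarray:
        """Validate and return the Cholesky factor of the correlation matrix."""
        if self.n <= 0:
            raise ParameterError("cohort size must be positive")
        if not 0.0 <= self.dxa_fraction <= 1.0:
            raise ParameterError("dxa_fraction must lie in [0, 1]")
        for name, (m, s) in self.means_sds.items():
            if s <= 0:
                raise ParameterError(f"SD for {name} must be positive")
        C = self.correlation_matrix()
        if not np.allclose(C, C.T):
            raise ParameterError("correlation matrix is not symmetric")
        try:
            L = np.linalg.cholesky(C)
        except np.linalg.LinAlgError as exc:
            raise ParameterError(
                "correlation matrix (BMD x ROI block) is not positive definite; "
                "lower the configured pairwise correlations") from exc
        return L


def _floor_for(name: str, floors: dict[str, float]) -> float:
    if name.startswith("bmd"):
        return floors["bmd"]
    if name.startswith("cth"):
        return floors["cth"]
    return floors["hu"]


def generate_cohort(params: CohortParams) -> pd.DataFrame:
    """Draw a synthetic cohort; fully reproducible from ``params.rng_seed``."""
    L = params.validate()
    rng = np.random.default_rng(params.rng_seed)
    names = params.variables
    mu = np.array([params.means_sds[v][0] for v in names])
    sd = np.array([params.means_sds[v][1] for v in names])
    floors = np.array([_floor_for(v, params.positivity_floor) for v in names])

    n = params.n
    X = mu + (rng.standard_normal((n, len(names))) @ L.T) * sd
    for _ in range(100):
        bad = np.any(X < floors, axis=1)
        if not bad.any():
            break
        X[bad] = mu + (rng.standard_normal((int(bad.sum()), len(names))) @ L.T) * sd
    else:  # pragma: no cover - would need absurd floors
        raise ParameterError("positivity redraw did not converge; floors too high?")

    df = pd.DataFrame(X, columns=names)
    df.insert(0, "patient_id", [f"P{i + 1:04d}" for i in range(n)])

    hip_ref = derive_tscore_reference(*HIP_DXA_MOMENTS)
    lum_ref = derive_tscore_reference(*LUMBAR_DXA_MOMENTS)
    df["t_hip"] = bmd_to_tscore(df["bmd_hip"], hip_ref)
    df["t_lumbar"] = bmd_to_tscore(df["bmd_lumbar"], lum_ref)
    df["osteoporotic_dxa"] = pd.array(
        np.minimum(df["t_hip"], df["t_lumbar"]) < WHO_T_THRESHOLD, dtype="boolean")

    # demographics
    df["sex"] = np.where(rng.random(n) < params.female_fraction, "F", "M")
    df["side"] = np.where(rng.random(n) < 0.5, "left", "right")
    df["age"] = rng.normal(*params.age_mean_sd, n).clip(50, 105)
    df["height_cm"] = rng.normal(*params.height_mean_sd, n).clip(130, 200)
    df["bmi"] = rng.normal(*params.bmi_mean_sd, n).clip(13, 45)
    df["weight_kg"] = df["bmi"] * (df["height_cm"] / 100.0) ** 2
    # class counts in the source tables do not sum exactly to the cohort
    # size, so the probabilities are renormalized
    p_ao = np.asarray(params.ao_class_probs) / np.sum(params.ao_class_probs)
    p_fix = np.asarray(params.fixation_probs) / np.sum(params.fixation_probs)
    df["ao_class"] = rng.choice(["A1", "A2", "A3"], size=n, p=p_ao)
    df["fixation"] = rng.choice(["Gamma3", "Intertan", "PFNA"], size=n, p=p_fix)

    # outcomes conditioned on the screening groups
    cth_osteo = df["cth_roi21"].to_numpy() < params.cth_cutoff
    hu_osteo = df["hu_roi14"].to_numpy() < params.hu_cutoff
    logit = params.complication_logit_base + params.complication_logit_effect * cth_osteo
    p_comp = 1.0 / (1.0 + np.exp(-logit))
    df["complication"] = rng.random(n) < p_comp

    def by_group(spec_pair, clip=None):
        (m0, s0), (m1, s1) = spec_pair
        vals = np.where(hu_osteo, rng.normal(m1, s1, n), rng.normal(m0, s0, n))
        if clip is not None:
            vals = vals.clip(*clip)
        return vals

    df["fim"] = by_group(params.fim_by_group, clip=(18, 126))
    df["parker_palmer"] = by_group(params.parker_by_group, clip=(0, 9))
    df["tug_seconds"] = by_group(params.tug_by_group, clip=(3, 120))
    df["twomwt_meters"] = by_group(params.twomwt_by_group, clip=(0, 250))
    p0, p1 = params.fim_available_prob
    df["fim_available"] = rng.random(n) < np.where(hu_osteo, p1, p0)
    p0, p1 = params.tug_completed_prob
    df["tug_completed"] = rng.random(n) < np.where(hu_osteo, p1, p0)
    p0, p1 = params.twomwt_completed_prob
    df["twomwt_completed"] = rng.random(n) < np.where(hu_osteo, p1, p0)

    # DXA availability by deterministic quota: the first round(f * n) ids
    n_dxa = int(round(params.dxa_fraction * n))
    has_dxa = np.zeros(n, dtype=bool)
    has_dxa[:n_dxa] = True
    df["has_dxa"] = has_dxa
    for col in ("bmd_hip", "bmd_lumbar", "t_hip", "t_lumbar"):
        df.loc[~has_dxa, col] = np.nan
    df.loc[~has_dxa, "osteoporotic_dxa"] = pd.NA

    return df


# ---------------------------------------------------------------------------
# CSV interchange

_REQUIRED_COLUMNS = ["patient_id", "bmd_hip", "t_hip", "cth_roi21", "hu_roi14"]


def write_cohort(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    """Write a cohort CSV; missing DXA is encoded as empty cells."""
    with open(path, "w", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV written by :func:`write_cohort`."""
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError as exc:
        raise ParameterError(f"cohort file {path} is empty") from exc
    if df.shape[0] == 0:
        raise ParameterError(f"cohort file {path} contains no records")
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ParameterError(f"cohort file {path} lacks columns: {missing}")
    if "osteoporotic_dxa" in df.columns:
        df["osteoporotic_dxa"] = df["osteoporotic_dxa"].astype("boolean")
    return df


def cohort_to_csv_bytes(df: pd.DataFrame) -> bytes:
    """Canonical byte serialization (used for determinism checks)."""
    buf = io.StringIO()
    df.to_csv(buf, index=False, lineterminator="\n")
    return buf.getvalue().encode()
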