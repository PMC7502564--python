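"""Synthetic cohorts, diffusion signals and phantom volumes with ground truth.

The real study inputs (multi-shell diffusion MRI of 59 MS patients, manual
lesion masks, clinic visits) are not publicly deposited, so every downstream
stage is exercised on synthetic data with known ground truth:

* :func:`gen_cohort` — per-lesion feature tables with a latent two-type
  (A/B) mixture.  Defaults reproduce the published whole-brain lesion
  moments: pooled mean/SD per metric, between-type differences on FA, RD,
  uFA and f_in, a 52% B-type mixing fraction, per-location lesion rates for
  a 59-patient cohort (1236 lesions in expectation), and per-location
  B-type probabilities.  Within-type SDs are derived by variance
  decomposition: var_within = var_pooled - p(1-p) * delta^2.
* :func:`gen_clinical` — continuous disability/cognition outcomes linear in
  B-type burden with age/sex nuisance, plus a logistic therapy indicator.
* :func:`gen_dwi_voxels` — multi-shell signals from known stick+zeppelin
  tissue parameters, with optional Rician noise.
* :func:`gen_phantom_masks` — toy 3-D label volumes and a region atlas with
  known topography ground truth.

All generators are pure functions of (config, seed).  Feature tables use the
conventional reporting scale (diffusivities in 1e-3 mm^2/s).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dwi import LAMBDA_FREE, GradientScheme
from .topography import RegionAtlas, Thresholds

__all__ = [
    "METRICS",
    "COHORT_LOCATIONS",
    "ClinicalModel",
    "CohortConfig",
    "type_means",
    "gen_cohort",
    "gen_clinical",
    "gen_dwi_voxels",
    "gen_typing_benchmark",
    "PhantomLesion",
    "PhantomSpec",
    "default_phantom_spec",
    "gen_phantom_masks",
]

METRICS = (
    "FA", "MD", "RD", "AD",
    "uFA", "uMD", "uRD", "uAD",
    "f_in", "lambda_diff", "v_AD", "v_MD",
)

COHORT_LOCATIONS = ("periventricular", "juxtacortical", "brainstem", "cerebellum", "deep_wm")

# Published whole-brain lesion moments (reporting scale, 1e-3 mm^2/s for
# diffusivities) and between-type (B - A) differences for the four metrics
# that separate the two lesion types.
_POOLED_MEANS = {
    "FA": 0.32, "MD": 0.57, "RD": 0.47, "AD": 0.77,
    "uFA": 0.83, "uMD": 1.30, "uRD": 0.44, "uAD": 2.99,
    "f_in": 0.34, "lambda_diff": 2.09, "v_AD": 1.35, "v_MD": 1.60,
}
_POOLED_SDS = {
    "FA": 0.11, "MD": 0.09, "RD": 0.10, "AD": 0.11,
    "uFA": 0.09, "uMD": 0.19, "uRD": 0.26, "uAD": 0.11,
    "f_in": 0.13, "lambda_diff": 0.35, "v_AD": 0.32, "v_MD": 0.28,
}
_TYPE_DELTAS = {"FA": -0.15, "RD": 0.17, "uFA": -0.12, "f_in": -0.20}

_LESION_COUNTS = {
    "periventricular": 357, "juxtacortical": 343,
    "brainstem": 44, "cerebellum": 60, "deep_wm": 432,
}
_P_B_LOCATION = {
    "periventricular": 0.54, "juxtacortical": 0.60,
    "brainstem": 0.50, "cerebellum": 0.53, "deep_wm": 0.46,
}

# Physical ranges each metric is clipped to (reporting scale).  The ceiling
# at the free-water diffusivity reproduces the boundary pile-up seen for
# uAD, which the metric-screening stage is designed to catch.
_BOUNDS = {m: (0.0, LAMBDA_FREE * 1e3) for m in METRICS}
_BOUNDS.update(FA=(0.0, 1.0), uFA=(0.0, 1.0), f_in=(0.0, 1.0))


@dataclass(frozen=True)
class ClinicalModel:
    """One outcome model: linear-Gaussian or logistic in B-type burden."""

    kind: str  # "linear" | "logistic"
    intercept: float
    beta_burden: float
    beta_age: float = 0.0
    beta_sex: float = 0.0
    noise_sd: float = 1.0
    center_burden: bool = False
    clip: tuple[float, float] | None = None


def _default_clinical() -> dict[str, ClinicalModel]:
    # Scaled so that B-count burden explains a moderate-to-strong share of
    # outcome variance (the study reports correlations of 0.4-0.67).
    logit_023 = float(np.log(0.23 / 0.77))
    return {
        "MSSS": ClinicalModel("linear", 0.9, 0.12, 0.010, -0.10, 1.2),
        "EDSS": ClinicalModel("linear", 0.4, 0.08, 0.020, -0.10, 1.0, clip=(0.0, 10.0)),
        "cognitive_global_z": ClinicalModel("linear", 0.6, -0.08, -0.010, 0.10, 0.9),
        "therapy_high": ClinicalModel(
            "logistic", logit_023, 0.12, 0.0, 0.0, 0.0, center_burden=True
        ),
    }


@dataclass(frozen=True)
class CohortConfig:
    """Generator configuration; defaults are the published study conditions."""

    n_patients: int = 59
    lesion_rate_per_location: dict = field(
        default_factory=lambda: {k: v / 59.0 for k, v in _LESION_COUNTS.items()}
    )
    p_b_per_location: dict = field(default_factory=lambda: dict(_P_B_LOCATION))
    p_b_global: float = 0.52
    feature_means: dict = field(default_factory=lambda: dict(_POOLED_MEANS))
    feature_sds: dict = field(default_factory=lambda: dict(_POOLED_SDS))
    type_deltas: dict = field(default_factory=lambda: dict(_TYPE_DELTAS))
    feature_correlation: np.ndarray | None = None
    # Lognormal lesion volumes; the B/A mean ratio 1.64 turns the 52% B-type
    # count share into the published 64% B-type volume share, and the pooled
    # mean of ~0.54 cm^3 matches ~11.4 cm^3 total lesion volume per patient.
    volume_mean_a_mm3: float = 400.0
    volume_b_over_a: float = 1.64
    volume_sigma_log: float = 1.0
    patient_intercept_sd: float = 0.0  # per-patient shift, in within-type SD units
    clinical_coeffs: dict = field(default_factory=_default_clinical)
    age_mean: float = 44.7
    age_sd: float = 9.3
    p_female: float = 37.0 / 59.0
    p_secondary_progressive: float = 6.0 / 59.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        for name, p in [("p_b_global", self.p_b_global), ("p_female", self.p_female),
                        ("p_secondary_progressive", self.p_secondary_progressive),
                        *self.p_b_per_location.items()]:
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability {name} outside [0, 1]")
        if any(r < 0 for r in self.lesion_rate_per_location.values()):
            raise ValueError("lesion rates must be >= 0")
        if any(s < 0 for s in self.feature_sds.values()):
            raise ValueError("feature SDs must be >= 0")
        for table, what in [(self.feature_means, "mean"), (self.feature_sds, "SD"),
                            (self.type_deltas, "delta")]:
            unknown = set(table) - set(METRICS)
            if unknown:
                raise ValueError(f"unknown metric name(s) in {what} map: {sorted(unknown)}")


def type_means(config: CohortConfig) -> tuple[dict, dict, dict]:
    """Per-type means and within-type SDs by variance decomposition.

    With mixing fraction p = P(B) and delta = mean_B - mean_A:
    ``mean_A = pooled_mean - p * delta`` and
    ``var_within = pooled_var - p (1 - p) delta^2`` (error if negative).
    """
    p = config.p_b_global
    means_a, means_b, within_sd = {}, {}, {}
    for m in config.feature_means:
        delta = config.type_deltas.get(m, 0.0)
        mu = config.feature_means[m]
        var_within = config.feature_sds[m] ** 2 - p * (1.0 - p) * delta**2
        if var_within < 0:
            raise ValueError(
                f"metric {m}: pooled SD {config.feature_sds[m]} is too small for "
                f"between-type delta {delta} at p_B={p} (negative within-type variance)"
            )
        means_a[m] = mu - p * delta
        means_b[m] = means_a[m] + delta
        within_sd[m] = float(np.sqrt(var_within))
    return means_a, means_b, within_sd


def _draw_features(rng, n, means, sds, corr=None):
    names = list(means)
    z = rng.standard_normal((n, len(names)))
    if corr is not None:
        corr = np.asarray(corr, dtype=float)
        if corr.shape != (len(names), len(names)):
            raise ValueError("feature_correlation must be metrics x metrics")
        z = z @ np.linalg.cholesky(corr).T
    out = {}
    for j, m in enumerate(names):
        lo, hi = _BOUNDS[m]
        out[m] = np.clip(means[m] + sds[m] * z[:, j], lo, hi)
    return out


def gen_cohort(
    config: CohortConfig | None = None, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (patient table, lesion feature table, ground truth).

    Lesion counts per patient and location are Poisson with the configured
    rates; each lesion draws a latent type, per-type clipped-Gaussian
    features and a lognormal volume.  Clinical outcomes are attached via
    :func:`gen_clinical` using the true per-patient B-type lesion count as
    burden.
    """
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    means_a, means_b, within_sd = type_means(config)
    n_pat = config.n_patients
    patients = pd.DataFrame(
        {
            "patient_id": [f"P{i:03d}" for i in range(1, n_pat + 1)],
            "age": rng.normal(config.age_mean, config.age_sd, n_pat),
            "sex_female": (rng.random(n_pat) < config.p_female).astype(int),
            "ms_type": np.where(
                rng.random(n_pat) < config.p_secondary_progressive, "SP", "RR"
            ),
        }
    )

    rows = []
    for pid in patients["patient_id"]:
        for loc in COHORT_LOCATIONS:
            rate = config.lesion_rate_per_location.get(loc, 0.0)
            for _ in range(rng.poisson(rate)):
                rows.append((pid, loc))
    n_les = len(rows)
    lesions = pd.DataFrame(rows, columns=["patient_id", "location"])
    lesions.insert(0, "lesion_id", [f"L{i:05d}" for i in range(1, n_les + 1)])

    p_b = lesions["location"].map(config.p_b_per_location).to_numpy(dtype=float)
    is_b = rng.random(n_les) < p_b
    # per-type feature draws, assembled row-wise
    feats_a = _draw_features(rng, n_les, means_a, within_sd, config.feature_correlation)
    feats_b = _draw_features(rng, n_les, means_b, within_sd, config.feature_correlation)
    for m in config.feature_means:
        lesions[m] = np.where(is_b, feats_b[m], feats_a[m])

    if config.patient_intercept_sd > 0:
        pat_idx = lesions["patient_id"].map(
            {p: i for i, p in enumerate(patients["patient_id"])}
        ).to_numpy()
        for m in config.feature_means:
            shift = rng.normal(0.0, config.patient_intercept_sd * within_sd[m], n_pat)
            lo, hi = _BOUNDS[m]
            lesions[m] = np.clip(lesions[m] + shift[pat_idx], lo, hi)

    mean_vol = np.where(
        is_b, config.volume_mean_a_mm3 * config.volume_b_over_a, config.volume_mean_a_mm3
    )
    sig = config.volume_sigma_log
    mu_log = np.log(mean_vol) - sig**2 / 2.0
    lesions["volume_mm3"] = rng.lognormal(mu_log, sig)

    truth = lesions[["lesion_id", "patient_id", "location", "volume_mm3"]].copy()
    truth["true_type"] = np.where(is_b, "B", "A")

    burden = (
        truth[truth["true_type"] == "B"].groupby("patient_id").size()
        .reindex(patients["patient_id"], fill_value=0)
    )
    patients = gen_clinical(patients, burden, config.clinical_coeffs, rng=rng)
    return patients, lesions, truth


def gen_clinical(
    patients: pd.DataFrame,
    burden,
    coeffs: dict[str, ClinicalModel] | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Attach outcome columns ``y = a + b*burden + b_age*age + b_sex*sex + e``
    (Gaussian e) and Bernoulli outcomes through a logistic link."""
    coeffs = coeffs if coeffs is not None else _default_clinical()
    rng = rng if rng is not None else np.random.default_rng(seed)
    burden = pd.Series(burden)
    if not burden.index.equals(pd.Index(patients["patient_id"])):
        burden = burden.reindex(patients["patient_id"])
        if burden.isna().any():
            raise ValueError("burden is not aligned with patient ids")
    x = burden.to_numpy(dtype=float)
    out = patients.copy()
    out["burden_b_count"] = x
    age = out["age"].to_numpy(dtype=float)
    sex = out["sex_female"].to_numpy(dtype=float)
    for name, mdl in coeffs.items():
        if mdl.noise_sd < 0:
            raise ValueError("noise SD must be >= 0")
        xb = x - x.mean() if mdl.center_burden else x
        lin = mdl.intercept + mdl.beta_burden * xb + mdl.beta_age * age + mdl.beta_sex * sex
        if mdl.kind == "linear":
            y = lin + rng.normal(0.0, mdl.noise_sd, len(out))
            if mdl.clip is not None:
                y = np.clip(y, *mdl.clip)
        elif mdl.kind == "logistic":
            y = (rng.random(len(out)) < 1.0 / (1.0 + np.exp(-lin))).astype(int)
        else:
            raise ValueError(f"unknown outcome kind {mdl.kind!r}")
        out[name] = y
    return out


def gen_typing_benchmark(
    n_lesions: int = 1000, seed: int = 0, metrics: tuple[str, ...] = ("FA", "RD", "uFA", "f_in")
) -> tuple[pd.DataFrame, np.ndarray]:
    """Flat lesion sample for clustering benchmarks: ``n_lesions`` draws of
    the typing metrics from the default two-type mixture (52% B), with the
    published pooled moments and between-type differences.

    Returns ``(features, is_b)``.
    """
    cfg = CohortConfig()
    means_a, means_b, within_sd = type_means(cfg)
    rng = np.random.default_rng(seed)
    is_b = rng.random(n_lesions) < cfg.p_b_global
    feats_a = _draw_features(rng, n_lesions, {m: means_a[m] for m in metrics},
                             {m: within_sd[m] for m in metrics})
    feats_b = _draw_features(rng, n_lesions, {m: means_b[m] for m in metrics},
                             {m: within_sd[m] for m in metrics})
    X = pd.DataFrame({m: np.where(is_b, feats_b[m], feats_a[m]) for m in metrics})
    return X, is_b


# --------------------------------------------------------------------------
# voxel-signal phantoms
# --------------------------------------------------------------------------

def gen_dwi_voxels(
    true_params: pd.DataFrame,
    scheme: GradientScheme,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    s0: float = 1.0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-direction multi-shell signals from stick+zeppelin ground truth.

    ``true_params`` needs columns ``f_in`` and ``lambda_diff`` (mm^2/s);
    optional ``nx, ny, nz`` fibre orientation (random uniform otherwise).
    Rician noise adds two independent Gaussian channels:
    ``S_noisy = sqrt((S + e1)^2 + e2^2)`` with ``e ~ N(0, sigma^2)``.
    With ``noise_sigma = 0`` the output is deterministic.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    n = len(true_params)
    f = true_params["f_in"].to_numpy(dtype=float)
    lam = true_params["lambda_diff"].to_numpy(dtype=float)
    if {"nx", "ny", "nz"}.issubset(true_params.columns):
        axes = true_params[["nx", "ny", "nz"]].to_numpy(dtype=float)
        axes = axes / np.linalg.norm(axes, axis=1, keepdims=True)
    else:
        axes = rng.standard_normal((n, 3))
        axes /= np.linalg.norm(axes, axis=1, keepdims=True)

    b, g = scheme.b, scheme.g
    cos2 = (axes @ g.T) ** 2  # (n_voxels, n_meas)
    lam_perp = (1.0 - f) * lam
    intra = np.exp(-b[None, :] * lam[:, None] * cos2)
    extra = np.exp(
        -b[None, :] * (lam_perp[:, None] + (lam[:, None] - lam_perp[:, None]) * cos2)
    )
    signals = s0 * (f[:, None] * intra + (1.0 - f[:, None]) * extra)
    if noise_sigma > 0:
        e1 = rng.normal(0.0, noise_sigma, signals.shape)
        e2 = rng.normal(0.0, noise_sigma, signals.shape)
        signals = np.sqrt((signals + e1) ** 2 + e2**2)

    truth = pd.DataFrame(
        {
            "voxel": np.arange(n),
            "f_in": f,
            "lambda_diff": lam,
            "nx": axes[:, 0], "ny": axes[:, 1], "nz": axes[:, 2],
            "s0": s0,
        }
    )
    return signals, truth


# --------------------------------------------------------------------------
# phantom label volumes
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomLesion:
    """A box lesion placed to realize a requested region-overlap fraction.

    ``extent = (w, h, d)`` voxels with ``d`` along the placement axis;
    ``overlap_layers`` of the ``d`` layers lie inside (or, for
    periventricular, in contact with) the target region, so the intended
    overlap fraction is ``overlap_layers / d``.
    """

    location_class: str  # periventricular|juxtacortical|brainstem|cerebellum|deep_wm
    extent: tuple[int, int, int] = (4, 4, 10)
    overlap_layers: int = 0


@dataclass(frozen=True)
class PhantomSpec:
    shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    lesions: tuple[PhantomLesion, ...] = ()


def default_phantom_spec() -> PhantomSpec:
    """A mixed phantom: clear members of each class, one boundary-abutting
    periventricular lesion, and one sub-threshold (26-voxel) lesion."""
    return PhantomSpec(
        lesions=(
            PhantomLesion("periventricular", (4, 4, 16), 1),   # 6.25% contact
            PhantomLesion("deep_wm", (4, 4, 10), 0),
            PhantomLesion("juxtacortical", (4, 4, 10), 3),     # 30% in cortex
            PhantomLesion("brainstem", (4, 4, 10), 7),         # 70% infratentorial
            PhantomLesion("cerebellum", (4, 4, 10), 7),
            PhantomLesion("deep_wm", (2, 2, 7), 0),            # 28 voxels, retained
            PhantomLesion("deep_wm", (2, 13, 1), 0),           # 26 voxels, sub-threshold
        )
    )


def _build_atlas(shape, voxel_size) -> RegionAtlas:
    vent = np.zeros(shape, dtype=bool)
    vent[26:38, 20:44, 24:40] = True
    cortex = np.zeros(shape, dtype=bool)
    cortex[:, 56:, :] = True
    brainstem = np.zeros(shape, dtype=bool)
    brainstem[24:40, 24:40, 0:12] = True
    cerebellum = np.zeros(shape, dtype=bool)
    cerebellum[24:40, 40:56, 0:14] = True
    return RegionAtlas(vent, cortex, brainstem, cerebellum, voxel_size)


def gen_phantom_masks(
    spec: PhantomSpec | None = None, seed: int | None = None
) -> tuple[np.ndarray, RegionAtlas, pd.DataFrame]:
    """Build (lesion label volume, region atlas, ground-truth table).

    Lesions of one class are stacked in parallel slots two voxels apart so
    components never merge.  The truth table records the intended class, the
    intended overlap fraction, and a sub-threshold flag for lesions smaller
    than the 27 mm^3 filter.
    """
    spec = spec or default_phantom_spec()
    if any(s <= 0 for s in spec.shape) or any(v <= 0 for v in spec.voxel_size):
        raise ValueError("volume dimensions and voxel size must be positive")
    rng = np.random.default_rng(seed)
    atlas = _build_atlas(spec.shape, spec.voxel_size)
    labels = np.zeros(spec.shape, dtype=np.int16)
    voxel_vol = float(np.prod(spec.voxel_size))
    thr = Thresholds()
    slot_offsets: dict[str, int] = {}
    records = []
    for i, les in enumerate(spec.lesions, start=1):
        w, h, d = les.extent
        k = les.overlap_layers
        if k > d:
            raise ValueError("overlap_layers cannot exceed lesion depth")
        off = slot_offsets.get(les.location_class, 0)
        slot_offsets[les.location_class] = off + w + 3
        jit = int(rng.integers(0, 2)) if seed is not None else 0
        cls = les.location_class
        if cls == "periventricular":
            # abut the +x ventricle face; k contact layers means the lesion
            # starts k-1 voxels inside the 1-voxel dilation zone (k=1: flush)
            sl = (slice(38, 38 + d), slice(22 + off + jit, 22 + off + jit + w),
                  slice(26, 26 + h))
            frac = k / d if k > 0 else 0.0
        elif cls == "juxtacortical":
            sl = (slice(4 + off + jit, 4 + off + jit + w), slice(56 - (d - k), 56 + k),
                  slice(40 + jit, 40 + jit + h))
            frac = k / d
        elif cls == "brainstem":
            sl = (slice(26 + off, 26 + off + w), slice(26 + jit, 26 + jit + h),
                  slice(12 - k, 12 + (d - k)))
            frac = k / d
        elif cls == "cerebellum":
            sl = (slice(26 + off, 26 + off + w), slice(42 + jit, 42 + jit + h),
                  slice(14 - k, 14 + (d - k)))
            frac = k / d
        elif cls == "deep_wm":
            sl = (slice(6 + off + jit, 6 + off + jit + w), slice(6, 6 + h),
                  slice(44, 44 + d))
            frac = 0.0
        else:
            raise ValueError(f"unknown location class {cls!r}")
        if any(s.stop > dim or s.start < 0 for s, dim in zip(sl, spec.shape)):
            raise ValueError(f"lesion {i} ({cls}) does not fit in the volume")
        if np.any(labels[sl] != 0):
            raise ValueError(f"lesion {i} overlaps a previously placed lesion")
        labels[sl] = i
        n_vox = w * h * d
        if cls in ("brainstem", "cerebellum"):
            expected = "infratentorial" if frac > thr.infratentorial else "deep_wm"
        elif cls == "periventricular":
            expected = "periventricular" if frac > thr.periventricular else "deep_wm"
        elif cls == "juxtacortical":
            expected = "juxtacortical" if frac > thr.juxtacortical else "deep_wm"
        else:
            expected = "deep_wm"
        records.append(
            {
                "phantom_id": i,
                "location_class": cls,
                "expected_location": expected,
                "intended_fraction": frac,
                "n_voxels": n_vox,
                "volume_mm3": n_vox * voxel_vol,
                "sub_threshold": n_vox * voxel_vol < thr.min_volume_mm3,
            }
        )
    return labels, atlas, pd.DataFrame(records)
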