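"""Diffusion-MRI signal models and per-voxel fits.

Two families of metrics are computed from multi-shell data:

* **Macroscopic DTI** — a single diffusion tensor fitted by log-linear least
  squares to the low-b shell (b <= 1000 s/mm^2 plus b=0), yielding FA, MD,
  RD and AD from the tensor eigenvalues.

* **Microscopic spherical-mean metrics** — the per-shell orientation average
  of the signal ("spherical mean") removes fibre-orientation and dispersion
  effects, leaving only per-axon (microscopic) diffusion.  Fitting the
  spherical mean across shells with a single axially symmetric micro-tensor
  gives the microscopic diffusivities uAD (= lambda_parallel), uRD
  (= lambda_perp), uMD and uFA.  The two-compartment extension (MC-SMT)
  models a stick (intra-neurite) plus tortuosity-constrained zeppelin
  (extra-neurite) sharing one intrinsic diffusivity, giving the intra-neurite
  volume fraction f_in, the intrinsic diffusivity lambda_diff and the derived
  extra-neurite diffusivities v_AD = (1 - f_in) * lambda_diff and
  v_MD = (lambda_diff + 2 v_AD) / 3.

All diffusivities are in mm^2/s internally; b-values in s/mm^2.  Reports and
tables use the conventional 1e-3 mm^2/s scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.special import erf

__all__ = [
    "LAMBDA_FREE",
    "GradientScheme",
    "DTIFit",
    "SMTFit",
    "MCSMTFit",
    "fibonacci_directions",
    "default_scheme",
    "read_bval_bvec",
    "write_bval_bvec",
    "forward_dti_signal",
    "fit_dti",
    "spherical_mean",
    "forward_smt_mean",
    "smt_microtensor_fit",
    "forward_mcsmt_mean",
    "mcsmt_fit",
    "dti_metrics_from_eigenvalues",
    "smt_metrics_from_lambdas",
    "mcsmt_metrics_from_params",
    "fit_voxel_all",
    "fit_map",
]

#: Upper bound on any fitted diffusivity (mm^2/s); approximately the
#: diffusivity of free water at body temperature.
LAMBDA_FREE = 3.0e-3


# --------------------------------------------------------------------------
# gradient scheme
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GradientScheme:
    """A multi-shell acquisition: b-values and unit gradient directions.

    Parameters
    ----------
    b : (N,) array of b-values in s/mm^2.
    g : (N, 3) array of unit direction vectors.
    shell_tolerance : b-values within this tolerance are grouped into one
        shell (s/mm^2).
    """

    b: np.ndarray
    g: np.ndarray
    shell_tolerance: float = 50.0

    def __post_init__(self):
        b = np.asarray(self.b, dtype=float).ravel()
        g = np.asarray(self.g, dtype=float).reshape(-1, 3)
        if b.shape[0] != g.shape[0]:
            raise ValueError("b and g must have the same length")
        if np.any(b < 0):
            raise ValueError("negative b-value")
        norms = np.linalg.norm(g, axis=1)
        nz = b > self.shell_tolerance
        if np.any(np.abs(norms[nz] - 1.0) > 1e-6):
            raise ValueError("gradient directions must be unit-norm")
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "g", g)

    def __len__(self) -> int:
        return self.b.shape[0]

    @property
    def b0_mask(self) -> np.ndarray:
        return self.b <= self.shell_tolerance

    def shells(self) -> list[tuple[float, np.ndarray]]:
        """Nonzero shells as ``(mean_b, index_mask)``, ascending in b."""
        out = []
        remaining = ~self.b0_mask
        for bv in np.unique(np.round(self.b[remaining] / self.shell_tolerance)):
            mask = remaining & (
                np.abs(self.b - bv * self.shell_tolerance) <= self.shell_tolerance / 2
            )
            if mask.any():
                out.append((float(self.b[mask].mean()), mask))
        out.sort(key=lambda t: t[0])
        # merge shells closer than tolerance (rounding can split one shell)
        merged: list[tuple[float, np.ndarray]] = []
        for bv, mask in out:
            if merged and bv - merged[-1][0] <= self.shell_tolerance:
                pb, pm = merged.pop()
                nm = pm | mask
                merged.append((float(self.b[nm].mean()), nm))
            else:
                merged.append((bv, mask))
        return merged


def fibonacci_directions(n: int) -> np.ndarray:
    """``n`` near-uniform unit vectors on the sphere (spherical Fibonacci)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def default_scheme(
    bvals: tuple[float, ...] = (1000.0, 2000.0, 3000.0),
    n_per_shell: int = 60,
    n_b0: int = 5,
) -> GradientScheme:
    """Three-shell scheme: 60 directions per shell at b = 1000/2000/3000
    s/mm^2 plus 5 b=0 measurements; directions by spherical Fibonacci with a
    per-shell rotation offset so shells do not share directions."""
    b_list = [np.zeros(n_b0)]
    g_list = [np.tile([1.0, 0.0, 0.0], (n_b0, 1))]
    for k, bv in enumerate(bvals):
        dirs = fibonacci_directions(n_per_shell)
        theta = 2.0 * np.pi * k / max(1, len(bvals)) / 7.0
        rot = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0.0],
                [np.sin(theta), np.cos(theta), 0.0],
                [0.0, 0.0, 1.0],
            ]
        )
        b_list.append(np.full(n_per_shell, float(bv)))
        g_list.append(dirs @ rot.T)
    return GradientScheme(np.concatenate(b_list), np.vstack(g_list))


def read_bval_bvec(bval_path, bvec_path) -> GradientScheme:
    """Read an FSL-dialect b-value row and 3-row b-vector matrix."""
    b = np.loadtxt(bval_path).ravel()
    g = np.loadtxt(bvec_path)
    if g.shape[0] == 3:
        g = g.T
    # FSL writes zero vectors for b=0; normalize the rest defensively
    norms = np.linalg.norm(g, axis=1)
    g = np.where(norms[:, None] > 0, g / np.where(norms == 0, 1, norms)[:, None], g)
    g[norms == 0] = [1.0, 0.0, 0.0]
    return GradientScheme(b, g)


def write_bval_bvec(scheme: GradientScheme, bval_path, bvec_path) -> None:
    np.savetxt(bval_path, scheme.b[None, :], fmt="%.1f")
    np.savetxt(bvec_path, scheme.g.T, fmt="%.8f")


# --------------------------------------------------------------------------
# fitted-parameter containers
# --------------------------------------------------------------------------

def _fa_from_eigs(evals: np.ndarray) -> float:
    evals = np.asarray(evals, dtype=float)
    md = evals.mean()
    denom = np.sum(evals**2)
    if denom <= 0:
        return 0.0
    fa = np.sqrt(1.5 * np.sum((evals - md) ** 2) / denom)
    return float(min(1.0, fa))


@dataclass(frozen=True)
class DTIFit:
    """Single-tensor fit: eigenvalues (descending) and derived metrics."""

    eigenvalues: np.ndarray
    s0: float
    fa: float
    md: float
    rd: float
    ad: float
    clamped: bool = False


@dataclass(frozen=True)
class SMTFit:
    """Microscopic (per-axon) tensor from the spherical-mean decay."""

    uad: float   # lambda_parallel, mm^2/s
    urd: float   # lambda_perp, mm^2/s
    umd: float
    ufa: float
    residual: float = 0.0


@dataclass(frozen=True)
class MCSMTFit:
    """Two-compartment spherical-mean fit (stick + tortuosity zeppelin)."""

    f_in: float
    lambda_diff: float
    v_ad: float
    v_md: float
    residual: float = 0.0


def dti_metrics_from_eigenvalues(evals, s0: float = 1.0, clamped: bool = False) -> DTIFit:
    """Derive FA/MD/RD/AD from an eigenvalue triple (sorted descending)."""
    evals = np.sort(np.asarray(evals, dtype=float))[::-1]
    md = float(evals.mean())
    ad = float(evals[0])
    rd = float((evals[1] + evals[2]) / 2.0)
    return DTIFit(evals, float(s0), _fa_from_eigs(evals), md, rd, ad, clamped)


def smt_metrics_from_lambdas(lam_par: float, lam_perp: float, residual: float = 0.0) -> SMTFit:
    """uMD and uFA derived from the fitted micro-tensor eigenvalue pair."""
    umd = (lam_par + 2.0 * lam_perp) / 3.0
    ufa = _fa_from_eigs([lam_par, lam_perp, lam_perp])
    return SMTFit(float(lam_par), float(lam_perp), float(umd), ufa, float(residual))


def mcsmt_metrics_from_params(f_in: float, lambda_diff: float, residual: float = 0.0) -> MCSMTFit:
    """v_AD by the tortuosity constraint and v_MD from the zeppelin triple."""
    v_ad = (1.0 - f_in) * lambda_diff
    v_md = (lambda_diff + 2.0 * v_ad) / 3.0
    return MCSMTFit(float(f_in), float(lambda_diff), float(v_ad), float(v_md), float(residual))


# --------------------------------------------------------------------------
# forward models
# --------------------------------------------------------------------------

def forward_dti_signal(tensor: np.ndarray, s0: float, scheme: GradientScheme) -> np.ndarray:
    """Monoexponential tensor signal ``S_i = S0 exp(-b_i g_i^T D g_i)``."""
    D = np.asarray(tensor, dtype=float)
    if D.shape != (3, 3) or not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("tensor must be symmetric 3x3")
    evals = np.linalg.eigvalsh(D)
    if evals[0] < -1e-12:
        raise ValueError("tensor must be positive semi-definite")
    adc = np.einsum("ij,jk,ik->i", scheme.g, D, scheme.g)
    return s0 * np.exp(-scheme.b * adc)


def _sph_factor(x):
    """sqrt(pi) * erf(sqrt(x)) / (2 sqrt(x)), the spherical average of
    exp(-x t^2) over t = cos(theta) in [-1, 1]; series for small x."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = x < 1e-8
    xs = x[small]
    out[small] = 1.0 - xs / 3.0 + xs**2 / 10.0
    xl = x[~small]
    out[~small] = np.sqrt(np.pi) * erf(np.sqrt(xl)) / (2.0 * np.sqrt(xl))
    return out


def forward_smt_mean(b, lam_par: float, lam_perp: float) -> np.ndarray:
    """Spherical mean of an axially symmetric tensor ("zeppelin"):
    eps(b) = exp(-b lam_perp) * sqrt(pi) erf(sqrt(b (lam_par-lam_perp)))
             / (2 sqrt(b (lam_par-lam_perp))),
    with the continuous limit exp(-b lam) as lam_par -> lam_perp."""
    b = np.asarray(b, dtype=float)
    if lam_perp < 0 or lam_par < lam_perp:
        raise ValueError("require 0 <= lam_perp <= lam_par")
    return np.exp(-b * lam_perp) * _sph_factor(b * (lam_par - lam_perp))


def forward_mcsmt_mean(f_in: float, lambda_diff: float, b) -> np.ndarray:
    """Two-compartment spherical mean: stick (intra-neurite) plus
    tortuosity-constrained zeppelin (extra-neurite), sharing lambda_diff."""
    if not (0.0 <= f_in <= 1.0):
        raise ValueError("f_in must lie in [0, 1]")
    if not (0.0 < lambda_diff <= LAMBDA_FREE):
        raise ValueError("lambda_diff must lie in (0, lambda_free]")
    b = np.asarray(b, dtype=float)
    lam_perp = (1.0 - f_in) * lambda_diff
    stick = _sph_factor(b * lambda_diff)
    zeppelin = np.exp(-b * lam_perp) * _sph_factor(b * (lambda_diff - lam_perp))
    return f_in * stick + (1.0 - f_in) * zeppelin


# --------------------------------------------------------------------------
# fits
# --------------------------------------------------------------------------

def fit_dti(signals: np.ndarray, scheme: GradientScheme, b_max: float = 1000.0) -> DTIFit:
    """Log-linear least-squares tensor fit on the b <= ``b_max`` shell
    (plus b=0).  Higher shells are ignored: at strong diffusion weighting the
    single-tensor model is badly biased by non-Gaussian effects."""
    signals = np.asarray(signals, dtype=float).ravel()
    if signals.shape[0] != len(scheme):
        raise ValueError("signal length does not match scheme")
    use = scheme.b <= b_max + scheme.shell_tolerance / 2
    b, g, s = scheme.b[use], scheme.g[use], signals[use]
    if np.any(s <= 0):
        raise ValueError("non-positive signal in DTI fit")
    if not scheme.b0_mask[use].any():
        raise ValueError("at least one b=0 measurement required")
    nz = b > scheme.shell_tolerance
    if nz.sum() < 6:
        raise ValueError("at least 6 diffusion-weighted directions required")
    X = np.column_stack(
        [
            np.ones_like(b),
            -b * g[:, 0] ** 2,
            -b * g[:, 1] ** 2,
            -b * g[:, 2] ** 2,
            -2.0 * b * g[:, 0] * g[:, 1],
            -2.0 * b * g[:, 0] * g[:, 2],
            -2.0 * b * g[:, 1] * g[:, 2],
        ]
    )
    if np.linalg.matrix_rank(X) < 7:
        raise ValueError("singular design matrix (collinear directions)")
    beta, *_ = np.linalg.lstsq(X, np.log(s), rcond=None)
    D = np.array(
        [
            [beta[1], beta[4], beta[5]],
            [beta[4], beta[2], beta[6]],
            [beta[5], beta[6], beta[3]],
        ]
    )
    evals = np.linalg.eigvalsh(D)[::-1]
    clamped = bool(np.any(evals < 0))
    if clamped:
        warnings.warn("negative tensor eigenvalue clamped to 0", stacklevel=2)
        evals = np.maximum(evals, 0.0)
    return dti_metrics_from_eigenvalues(evals, s0=float(np.exp(beta[0])), clamped=clamped)


def spherical_mean(
    signals: np.ndarray,
    scheme: GradientScheme,
    min_directions: int = 30,
    noise_sigma: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-shell direction-averaged signal, normalized by the b=0 mean.

    Returns ``(b_shells, eps)`` with eps(0) omitted (it is 1 by definition).

    With a known noise level ``noise_sigma``, each magnitude measurement is
    first debiased by the Rician second-moment relation
    ``S^2 ~ M^2 - 2 sigma^2``; without it the noise floor inflates the
    high-b shell means and biases the microscopic fits at low SNR.
    """
    signals = np.asarray(signals, dtype=float).ravel()
    if noise_sigma > 0:
        signals = np.sqrt(np.maximum(signals**2 - 2.0 * noise_sigma**2, 0.0))
    if signals.shape[0] != len(scheme):
        raise ValueError("signal length does not match scheme")
    if not scheme.b0_mask.any():
        raise ValueError("b=0 measurements required for normalization")
    s0 = signals[scheme.b0_mask].mean()
    if s0 <= 0:
        raise ValueError("non-positive b=0 signal")
    shells = scheme.shells()
    if not shells:
        raise ValueError("no nonzero shells")
    b_out, eps = [], []
    for bv, mask in shells:
        if mask.sum() == 0:
            raise ValueError(f"empty shell at b={bv}")
        if mask.sum() < min_directions:
            warnings.warn(
                f"shell b={bv:.0f} has only {int(mask.sum())} directions; "
                "spherical mean may be orientation-biased",
                stacklevel=2,
            )
        b_out.append(bv)
        eps.append(signals[mask].mean() / s0)
    return np.asarray(b_out), np.asarray(eps)


def _multistart_ls(residual_fn, starts, bounds, tol=1e-12):
    best = None
    for x0 in starts:
        try:
            res = least_squares(
                residual_fn, x0, bounds=bounds, xtol=tol, ftol=tol, gtol=tol
            )
        except Exception:
            continue
        if res.success or res.status > 0:
            cost = float(res.cost)
            if best is None or cost < best[1] - 1e-14 or (
                abs(cost - best[1]) <= 1e-14 and res.x[0] < best[0][0]
            ):
                best = (res.x, cost)
    if best is None:
        raise RuntimeError("spherical-mean fit failed to converge from all starts")
    return best


def _check_shell_means(eps: np.ndarray, b: np.ndarray):
    eps = np.asarray(eps, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if eps.shape != b.shape:
        raise ValueError("shell means and b-values must align")
    if (b <= 0).any():
        raise ValueError("shell b-values must be positive")
    if np.count_nonzero(b > 0) < 2:
        raise ValueError("at least 2 nonzero shells required")
    if np.any(eps <= 0) or np.any(eps > 1.0 + 1e-9):
        raise ValueError("shell means must lie in (0, 1]")
    return eps, b


def smt_microtensor_fit(
    shell_means, b_shells, lambda_free: float = LAMBDA_FREE
) -> SMTFit:
    """Fit (lambda_parallel, lambda_perp) to the per-shell spherical means by
    bounded least squares with grid multi-start; lambda_perp is parametrized
    as a fraction of lambda_parallel so the ordering constraint is built in."""
    eps, b = _check_shell_means(shell_means, b_shells)

    def resid(p):
        lam_par, ratio = p
        return forward_smt_mean(b, lam_par, ratio * lam_par) - eps

    starts = [
        (lp, r)
        for lp in (0.5e-3, 1.5e-3, 2.5e-3, 0.999 * lambda_free)
        for r in (0.02, 0.3, 0.7, 0.98)
    ]
    (lam_par, ratio), cost = _multistart_ls(
        resid, starts, bounds=([1e-7, 0.0], [lambda_free, 1.0])
    )
    return smt_metrics_from_lambdas(lam_par, ratio * lam_par, residual=cost)


def mcsmt_fit(shell_means, b_shells, lambda_free: float = LAMBDA_FREE) -> MCSMTFit:
    """Fit (f_in, lambda_diff) of the two-compartment spherical-mean model;
    v_AD and v_MD follow from the tortuosity constraint."""
    eps, b = _check_shell_means(shell_means, b_shells)
    if np.all(1.0 - eps < 1e-6):
        raise ValueError("no attenuation across shells: parameters unidentifiable")

    def resid(p):
        f_in, lam = p
        return forward_mcsmt_mean(f_in, lam, b) - eps

    starts = [
        (f, lam)
        for f in (0.1, 0.4, 0.7, 0.95)
        for lam in (0.8e-3, 1.6e-3, 2.4e-3, 0.999 * lambda_free)
    ]
    (f_in, lam), cost = _multistart_ls(
        resid, starts, bounds=([0.0, 1e-7], [1.0, lambda_free])
    )
    return mcsmt_metrics_from_params(f_in, lam, residual=cost)


# --------------------------------------------------------------------------
# map-level fitting
# --------------------------------------------------------------------------

#: Column order of :func:`fit_voxel_all` output (table scale: diffusivities
#: in 1e-3 mm^2/s).
METRIC_NAMES = (
    "FA", "MD", "RD", "AD",
    "uFA", "uMD", "uRD", "uAD",
    "f_in", "lambda_diff", "v_AD", "v_MD",
)

_SCALE = {name: 1e3 for name in METRIC_NAMES}
_SCALE.update(FA=1.0, uFA=1.0, f_in=1.0)


def fit_voxel_all(signals: np.ndarray, scheme: GradientScheme) -> dict[str, float]:
    """All 12 metrics for one voxel, on the table scale (1e-3 mm^2/s)."""
    dti = fit_dti(signals, scheme)
    b, eps = spherical_mean(signals, scheme)
    smt = smt_microtensor_fit(eps, b)
    mc = mcsmt_fit(eps, b)
    raw = dict(
        FA=dti.fa, MD=dti.md, RD=dti.rd, AD=dti.ad,
        uFA=smt.ufa, uMD=smt.umd, uRD=smt.urd, uAD=smt.uad,
        f_in=mc.f_in, lambda_diff=mc.lambda_diff, v_AD=mc.v_ad, v_MD=mc.v_md,
    )
    return {k: v * _SCALE[k] for k, v in raw.items()}


def fit_map(
    dwi: np.ndarray, scheme: GradientScheme, mask: np.ndarray | None = None
) -> dict[str, np.ndarray]:
    """Fit every voxel in ``mask`` of a 4-D volume (x, y, z, measurement).

    Voxels are independent; the result does not depend on traversal order.
    Returns one 3-D map per metric (NaN outside the mask / failed fits).
    """
    dwi = np.asarray(dwi, dtype=float)
    if dwi.ndim != 4 or dwi.shape[3] != len(scheme):
        raise ValueError("dwi must be 4-D with last axis matching the scheme")
    if mask is None:
        mask = np.ones(dwi.shape[:3], dtype=bool)
    maps = {name: np.full(dwi.shape[:3], np.nan) for name in METRIC_NAMES}
    for idx in zip(*np.nonzero(mask)):
        try:
            vals = fit_voxel_all(dwi[idx], scheme)
        except (ValueError, RuntimeError):
            continue
        for name, v in vals.items():
            maps[name][idx] = v
    return maps
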