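"""Synthetic climate/NDVI scenarios with known ground truth, and fGn series.

The generator is the forward counterpart of the residual-attribution model:
per pixel,

    T_t    = T0 + temp_trend * t + eps_T
    P_t    = P0 + precip_trend * t + eps_P
    NDVI_t = a * T_t + b * P_t + c + human_rate * t + eta

with t = 1..n_years, independent Gaussian interannual noise per pixel, and
NDVI clipped to [0, 1] (a warning fires if clipping touches more than 10%
of values, since clipping bends the linear structure the estimators
assume).  The ground truth records, per pixel, the trend slope of the realised
climate component a*T_t + b*P_t (the climate forcing the pixel actually
experienced, interannual weather variability included; only the NDVI
observation noise eta is excluded) and the human-component slope
human_rate, plus the true CC share obtained by applying the same
six-condition contribution scheme the estimator uses - so recovery tests
measure estimation error, not definitional mismatch.

Defaults emulate a 21-year annual record over an alpine-meadow-like
region: mild baseline climate with a warming/wetting drift, and a
blockwise human-activity field mixing degradation, no pressure, and
restoration-driven greening.

Fractional Gaussian noise with prescribed Hurst exponent H is generated by
circulant embedding (exact autocovariance; Davies-Harte), falling back to
the sequential conditional (Hosking) recursion if the embedding is
infeasible for some H/n combination.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .attribution import contribution_rates
from .cube import AnnualCube, GridTransform
from .trend import _slope_core


@dataclass
class ScenarioConfig:
    """Parameters of the synthetic study region.

    ``a``, ``b``, ``c`` are the per-pixel climate sensitivities (NDVI per
    degC, NDVI per mm, baseline NDVI); ``human_rate`` is the deterministic
    linear human-activity component in NDVI/yr, either a scalar or a
    ``(rows, cols)`` field.  ``human_blocks``, when set and ``human_rate``
    is None, tiles the grid into equal column bands with the given rates.
    """

    n_years: int = 21
    shape: tuple[int, int] = (25, 20)
    a: float = 0.02            # NDVI per degC
    b: float = 2e-4            # NDVI per mm
    c: float = 0.30            # baseline NDVI
    t0: float = 3.0            # degC mean at t=0
    p0: float = 550.0          # mm mean at t=0
    temp_trend: float = 0.02   # degC / yr
    precip_trend: float = 1.0  # mm / yr
    temp_sd: float = 0.6       # degC interannual noise
    precip_sd: float = 60.0    # mm interannual noise
    human_rate: float | np.ndarray | None = None
    human_blocks: tuple[float, ...] = (-0.003, 0.0015, 0.0025, 0.0035)
    noise_sd: float = 0.01     # NDVI observation noise
    seed: int = 0
    transform: GridTransform = field(default_factory=GridTransform)

    def __post_init__(self) -> None:
        if self.n_years < 4:
            raise ValueError("n_years must be >= 4")
        for name in ("temp_sd", "precip_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def human_rate_field(self) -> np.ndarray:
        rows, cols = self.shape
        if self.human_rate is not None:
            hr = np.asarray(self.human_rate, dtype=float)
            if hr.ndim == 0:
                return np.full((rows, cols), float(hr))
            if hr.shape != (rows, cols):
                raise ValueError("human_rate field shape does not match grid")
            return hr
        # equal column bands, left to right
        edges = np.linspace(0, cols, len(self.human_blocks) + 1).astype(int)
        out = np.empty((rows, cols))
        for k, rate in enumerate(self.human_blocks):
            out[:, edges[k]:edges[k + 1]] = rate
        return out


@dataclass
class ScenarioTruth:
    """Noise-free component slopes and the true CC share per pixel.

    ``slope_climate`` is the per-pixel OLS trend of the realised climate
    component a*T_t + b*P_t; ``slope_obs`` = slope_climate + human_rate is
    the trend of the observation-noise-free NDVI, so the decomposition is
    exact by construction.
    """

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    human_rate: np.ndarray
    slope_climate: np.ndarray  # trend of a*T_t + b*P_t per pixel
    slope_obs: np.ndarray      # slope_climate + human_rate
    cc_share: np.ndarray       # %, NaN where the noise-free slope is ~0


def _pixel_noise(ss: np.random.SeedSequence, n_years: int,
                 shape: tuple[int, int], sd: float) -> np.ndarray:
    """Per-pixel independent noise series from per-pixel substreams.

    Each pixel draws from its own child stream (spawned row-major), so
    enlarging the grid never reshuffles the noise of existing pixels.
    """
    rows, cols = shape
    out = np.empty((n_years, rows, cols))
    children = ss.spawn(rows * cols)
    for k, child in enumerate(children):
        r, c = divmod(k, cols)
        out[:, r, c] = np.random.default_rng(child).normal(0.0, 1.0, n_years)
    return out * sd


def generate_scenario(
    config: ScenarioConfig,
) -> tuple[AnnualCube, AnnualCube, AnnualCube, ScenarioTruth]:
    """Simulate (T, P, NDVI) cubes and the matching ground truth."""
    rows, cols = config.shape
    n = config.n_years
    t = np.arange(1, n + 1, dtype=float)[:, None, None]
    root = np.random.SeedSequence(config.seed)
    ss_t, ss_p, ss_n = root.spawn(3)

    T = config.t0 + config.temp_trend * t + _pixel_noise(ss_t, n, config.shape, config.temp_sd)
    P = config.p0 + config.precip_trend * t + _pixel_noise(ss_p, n, config.shape, config.precip_sd)
    hr = config.human_rate_field()
    ndvi = (
        config.a * T + config.b * P + config.c
        + hr[None] * t
        + _pixel_noise(ss_n, n, config.shape, config.noise_sd)
    )
    clip_frac = np.mean((ndvi < 0) | (ndvi > 1))
    if clip_frac > 0.10:
        warnings.warn(
            f"{clip_frac:.1%} of NDVI values clipped to [0,1]; "
            "clipping distorts the linear structure"
        )
    ndvi = np.clip(ndvi, 0.0, 1.0)

    years = list(range(2000, 2000 + n))
    tr = config.transform
    cube_t = AnnualCube(T, years, tr)
    cube_p = AnnualCube(P, years, tr)
    cube_n = AnnualCube(ndvi, years, tr)

    slope_climate, _ = _slope_core(config.a * T + config.b * P)
    slope_obs = slope_climate + hr
    cc_share = np.full((rows, cols), np.nan)
    for r, c in np.ndindex(rows, cols):
        cc, _, cond = contribution_rates(
            slope_obs[r, c], slope_climate[r, c], hr[r, c]
        )
        if cond != "undefined_stable":
            cc_share[r, c] = cc
    truth = ScenarioTruth(
        a=np.full((rows, cols), config.a),
        b=np.full((rows, cols), config.b),
        c=np.full((rows, cols), config.c),
        human_rate=hr,
        slope_climate=slope_climate,
        slope_obs=slope_obs,
        cc_share=cc_share,
    )
    return cube_t, cube_p, cube_n, truth


# ---------------------------------------------------------------------------
# fractional Gaussian noise


def fgn_autocovariance(k: np.ndarray, H: float) -> np.ndarray:
    """Exact unit-variance fGn autocovariance gamma(k)."""
    k = np.abs(np.asarray(k, dtype=float))
    return 0.5 * ((k + 1) ** (2 * H) - 2 * k ** (2 * H) + np.abs(k - 1) ** (2 * H))


def _fgn_davies_harte(n: int, H: float, rng: np.random.Generator) -> np.ndarray | None:
    """Circulant-embedding sampler; None if the embedding is not nonnegative."""
    gamma = fgn_autocovariance(np.arange(n + 1), H)
    # first row of the circulant matrix of size m = 2n: gamma(0..n), gamma(n-1..1)
    row = np.concatenate([gamma, gamma[-2:0:-1]])
    m = 2 * n
    lam = np.fft.rfft(row).real  # eigenvalues, length n + 1
    if np.min(lam) < -1e-10 * np.max(lam):
        return None
    lam = np.clip(lam, 0.0, None)
    # Hermitian half-spectrum with E|w_k|^2 summing to gamma(0) over the circle
    w = np.empty(n + 1, dtype=complex)
    w[0] = np.sqrt(lam[0] / m) * rng.normal()
    w[n] = np.sqrt(lam[n] / m) * rng.normal()
    re = rng.normal(size=n - 1)
    im = rng.normal(size=n - 1)
    w[1:n] = np.sqrt(lam[1:n] / (2 * m)) * (re + 1j * im)
    return m * np.fft.irfft(w, n=m)[:n]


def _fgn_hosking(n: int, H: float, rng: np.random.Generator) -> np.ndarray:
    """Sequential conditional (Durbin-Levinson) sampler; O(n^2)."""
    gamma = fgn_autocovariance(np.arange(n), H)
    x = np.empty(n)
    phi = np.empty(n)
    x[0] = rng.normal()
    v = 1.0
    prev = np.empty(n)
    for t in range(1, n):
        if t == 1:
            phi[0] = gamma[1]
        else:
            kappa = (gamma[t] - np.dot(prev[: t - 1], gamma[t - 1:0:-1])) / v
            phi[: t - 1] = prev[: t - 1] - kappa * prev[t - 2::-1]
            phi[t - 1] = kappa
        v *= 1.0 - phi[t - 1] ** 2
        mean = np.dot(phi[:t], x[t - 1::-1])
        x[t] = mean + np.sqrt(v) * rng.normal()
        prev[:t] = phi[:t]
    return x


def generate_fgn(n: int, H: float, seed: int | np.random.SeedSequence) -> np.ndarray:
    """Unit-variance fractional Gaussian noise of length n with exponent H.

    Uses exact-covariance circulant embedding, falling back to the
    sequential conditional recursion when the embedding is infeasible.
    H = 0.5 reduces to i.i.d. standard Gaussian noise.
    """
    if not (0.0 < H < 1.0):
        raise ValueError(f"H must lie in (0, 1), got {H}")
    if n < 16:
        raise ValueError(f"n must be >= 16, got {n}")
    rng = np.random.default_rng(seed)
    if H == 0.5:
        return rng.normal(size=n)
    x = _fgn_davies_harte(n, H, rng)
    if x is None:
        x = _fgn_hosking(n, H, rng)
    return x
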