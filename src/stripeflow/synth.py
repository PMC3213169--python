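"""Synthetic embryo movies, expression profiles, cohorts and count tables.

Every downstream stage of the pipeline (segmentation, profile extraction,
spline feature detection, phenotype statistics) is testable against known
ground truth produced here; nothing needs to be downloaded.

The generative model
--------------------
A seven-stripe pair-rule expression pattern along the anteroposterior (AP)
axis, in percent egg length (% EL).  The resolved pattern is a baseline
plus a sum of asymmetric Gaussians (independent anterior/posterior widths)
with piecewise-linear amplitude trajectories in developmental time, plus a
broad anterior "shoulder" component that raises the 1-2 interstripe floor
and thereby controls the anterior/posterior border-height asymmetry of
stripe 2.  Early in cycle 14 the interstripe valleys are unresolved: each
valley's window is replaced by a straight descending chord (one broad
expression domain) and cross-fades to the resolved shape after a per-embryo
onset time, so the order and timing of border appearance are exact model
properties.  Embryo-to-embryo positional variability is a rigid AP shift of
the whole pattern with a possibly time-dependent scale ``sigma_pos``.

Genotype presets encode the qualitative stripe-2 contracts: the WT
stripe-2/stripe-1 amplitude ratio increases through maturation, the MSE
ratio decreases, and the INV_MSE ratio is near constant; WT represses its
anterior border over time, MSE has symmetric borders throughout, INV_MSE
fails to fully repress.  At 29C the developmental timeline is compressed by
the ratio of cellularization landmark times (38.2 min at 25C vs 30.6 min at
29C).  No numeric amplitude or width is a published value: the paper-scale
quantities are figure-only, so preset numbers are free parameters chosen
once to be realistic; see docs/methods.md.

Image scenes emulate a laterally imaged ellipsoidal embryo's midsagittal
plane: a cortical monolayer of cycle-14 nuclei, interior yolk
autofluorescence, a bright vitelline-membrane ring just outside the
cortex, and optional cellularization membrane lines that split nuclei into
a yolk-facing and an outside-facing half (the segmentation fusion rule's
raison d'etre).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genetics import CrossSchema, cross_expectation
from .quantify import ExpressionProfile

__all__ = [
    "StripeModelParams",
    "SceneSpec",
    "EmbryoImageSeries",
    "GroundTruth",
    "Cohort",
    "EmbryoProfiles",
    "stripe_model_params",
    "model_intensity",
    "true_features",
    "generate_profile",
    "generate_embryo_series",
    "generate_cohort",
    "generate_count_table",
    "schedule_membrane_splits",
]

#: cellularization landmark times (minutes): membrane at basal end of nuclei
LANDMARK_25C = 38.2
LANDMARK_29C = 30.6


class ModelWindowError(ValueError):
    """Requested timepoint lies outside the modeled developmental window."""


def _smoothstep(u):
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


@dataclass
class StripeModelParams:
    """Generative parameters for the seven-stripe expression model."""

    preset: str = "WT"
    temperature: str = "25C"
    mu: np.ndarray = field(default_factory=lambda: np.array(
        [31.0, 40.0, 47.5, 55.0, 62.5, 70.0, 77.5]))
    sigma_a: np.ndarray = field(default_factory=lambda: np.full(7, 1.8))
    sigma_p: np.ndarray = field(default_factory=lambda: np.full(7, 1.8))
    #: amplitude knots: developmental minutes and per-stripe values (7, K)
    amp_t: np.ndarray = field(default_factory=lambda: np.array(
        [18.0, 24.0, 30.0, 36.0, 42.0, 48.0, 60.0]))
    amp: np.ndarray | None = None
    #: anterior-shoulder amplitude (raises the 1-2 interstripe floor)
    shoulder: np.ndarray = field(default_factory=lambda: np.array(
        [0.22, 0.22, 0.22, 0.15, 0.08, 0.03, 0.03]))
    #: embryo positional jitter SD (% EL) at the amplitude knots
    sigma_pos_v: np.ndarray = field(default_factory=lambda: np.full(7, 1.5))
    sigma_n: float = 0.05
    #: embryo-to-embryo CV of the stripe-2 amplitude (biological variability
    #: that persists despite within-embryo normalization)
    amp_cv: float = 0.15
    baseline: float = 0.05
    #: per-embryo valley-resolution onsets (developmental minutes): mean, sd
    onset12: tuple[float, float] = (26.4, 2.2)
    onset23: tuple[float, float] = (25.5, 2.2)
    #: posterior valleys (3-4, 4-5, ...) resolve at onset23 + k * this lag
    posterior_onset_lag: float = 1.2
    onset_ramp_min: float = 2.0
    time_scale: float = 1.0  # developmental minutes per absolute minute
    t_window: tuple[float, float] = (21.0, 57.0)
    nucleus_spacing_el: float = 1.0

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        if np.any(np.diff(self.mu) <= 0):
            raise ValueError("stripe centers must be strictly increasing")
        self.sigma_a = np.asarray(self.sigma_a, dtype=float)
        self.sigma_p = np.asarray(self.sigma_p, dtype=float)
        if np.any(self.sigma_a <= 0) or np.any(self.sigma_p <= 0):
            raise ValueError("stripe widths must be positive")
        if self.amp is None:
            self.amp = _default_amp(self.preset, len(self.amp_t))
        self.amp = np.asarray(self.amp, dtype=float)
        if np.any(self.amp < 0):
            raise ValueError("amplitudes must be nonnegative")
        if self.amp.shape != (len(self.mu), len(self.amp_t)):
            raise ValueError("amp must have shape (n_stripes, n_knots)")

    # -- trajectory evaluation (developmental minutes) ---------------------

    def amplitude(self, td: float) -> np.ndarray:
        return np.array([np.interp(td, self.amp_t, row) for row in self.amp])

    def shoulder_amp(self, td: float) -> float:
        return float(np.interp(td, self.amp_t, self.shoulder))

    def sigma_pos(self, td: float) -> float:
        return float(np.interp(td, self.amp_t, self.sigma_pos_v))

    def dev_time(self, t: float) -> float:
        return t * self.time_scale

    def a2_a1_ratio(self, t: float) -> float:
        """Stripe-2 to stripe-1 amplitude ratio at absolute time t."""
        a = self.amplitude(self.dev_time(t))
        return float(a[1] / a[0])

    def check_window(self, t: float) -> None:
        lo, hi = self.t_window
        if not lo <= t <= hi:
            raise ModelWindowError(
                f"t = {t} min outside modeled window [{lo}, {hi}] min")

    def valley_onsets(self, t_on12: float, t_on23: float) -> np.ndarray:
        """Resolution onset (developmental min) for valleys 1-2 .. 6-7."""
        lags = self.posterior_onset_lag * np.arange(0, 6)
        out = t_on23 + lags  # valleys 2-3 .. 6-7 use index 0.. of lags
        return np.concatenate([[t_on12], out[:5]])


def _default_amp(preset: str, nk: int) -> np.ndarray:
    a1 = np.ones(nk)
    posterior = np.array([0.30, 0.35, 0.40, 0.55, 0.75, 0.90, 0.90])
    a2 = {
        "WT": np.array([0.40, 0.48, 0.55, 0.70, 0.85, 1.00, 1.00]),
        "MSE": np.array([0.60, 0.66, 0.72, 0.64, 0.57, 0.50, 0.50]),
        "INV_MSE": np.array([0.72, 0.74, 0.75, 0.75, 0.75, 0.75, 0.75]),
    }[preset]
    rows = [a1, a2] + [posterior * s for s in (1.0, 0.95, 0.9, 0.85, 0.9)]
    return np.vstack(rows)


_PRESET_OVERRIDES = {
    ("WT", "25C"): {},
    ("MSE", "25C"): dict(
        onset12=(24.8, 2.0), onset23=(25.9, 2.0),
        shoulder=np.full(7, 0.03),
        sigma_pos_v=np.array([1.2, 1.2, 1.2, 1.5, 1.85, 2.2, 2.2]),
    ),
    ("INV_MSE", "25C"): dict(
        onset12=(27.3, 2.2), onset23=(25.2, 2.2),
        shoulder=np.array([0.22, 0.22, 0.22, 0.20, 0.18, 0.16, 0.16]),
        sigma_pos_v=np.full(7, 1.5),
    ),
    ("WT", "29C"): {},
    ("MSE", "29C"): dict(
        onset12=(26.8, 2.0), onset23=(25.8, 2.0),
        shoulder=np.full(7, 0.03),
        sigma_pos_v=np.array([1.2, 1.2, 1.2, 1.5, 1.85, 2.2, 2.2]),
    ),
}


def stripe_model_params(preset: str = "WT", temperature: str = "25C",
                        **overrides) -> StripeModelParams:
    """Build the named genotype/temperature preset.

    WT presets use decreasing positional SD and a shoulder that decays
    (anterior border represses over time); MSE uses a flat, small shoulder
    (symmetric borders) and growing positional SD; INV_MSE keeps a partially
    decaying shoulder (incomplete anterior repression).  29C compresses the
    timeline by the landmark ratio 38.2/30.6 and shortens the window.
    """
    if preset not in ("WT", "MSE", "INV_MSE"):
        raise ValueError(f"unknown preset {preset!r}")
    if temperature not in ("25C", "29C"):
        raise ValueError(f"unknown temperature {temperature!r}")
    kw: dict = dict(preset=preset, temperature=temperature)
    kw.update(_PRESET_OVERRIDES.get((preset, temperature), {}))
    if temperature == "29C":
        kw.setdefault("time_scale", LANDMARK_25C / LANDMARK_29C)
        kw.setdefault("t_window", (18.0, 45.0))
    if preset == "WT":
        kw.setdefault("sigma_pos_v", np.array([1.5, 1.5, 1.5, 1.4, 1.3, 1.2, 1.2]))
    kw.update(overrides)
    return StripeModelParams(**kw)


# ---------------------------------------------------------------------------
# Continuous intensity model


def _resolved(params: StripeModelParams, x: np.ndarray, amps: np.ndarray,
              mu_eff: np.ndarray, shoulder: float) -> np.ndarray:
    y = np.full_like(x, params.baseline, dtype=float)
    for s in range(len(mu_eff)):
        d = x - mu_eff[s]
        sig = np.where(d < 0, params.sigma_a[s], params.sigma_p[s])
        y += amps[s] * np.exp(-0.5 * (d / sig) ** 2)
    y += shoulder * np.exp(-0.5 * ((x - (mu_eff[1] - 3.5)) / 2.5) ** 2)
    return y


def model_intensity(params: StripeModelParams, x, t: float, z: float = 0.0,
                    t_on12: float | None = None,
                    t_on23: float | None = None,
                    a2_scale: float = 1.0) -> np.ndarray:
    """Noise-free model intensity at AP positions ``x`` (% EL) and time t.

    ``z`` is the embryo's standard-normal positional jitter; the rigid AP
    shift is ``z * sigma_pos(t)``.  ``a2_scale`` is the embryo's stripe-2
    amplitude multiplier.  Valley onsets default to the preset means.
    Raises :class:`ModelWindowError` outside the modeled window.
    """
    params.check_window(t)
    x = np.atleast_1d(np.asarray(x, dtype=float))
    td = params.dev_time(t)
    if t_on12 is None:
        t_on12 = params.onset12[0]
    if t_on23 is None:
        t_on23 = params.onset23[0]
    amps = params.amplitude(td)
    amps = amps.copy()
    amps[1] *= a2_scale
    mu_eff = params.mu + z * params.sigma_pos(td)
    y = _resolved(params, x, amps, mu_eff, params.shoulder_amp(td))

    onsets = params.valley_onsets(t_on12, t_on23)
    for k in range(6):  # valley between stripes k+1 and k+2
        w = float(_smoothstep((td - onsets[k]) / params.onset_ramp_min))
        if w >= 1.0:
            continue
        xl = mu_eff[k] + 0.8
        xr = mu_eff[k + 1] + 0.6
        yl = _resolved(params, np.array([xl]), amps, mu_eff, params.shoulder_amp(td))[0]
        yr = _resolved(params, np.array([xr]), amps, mu_eff, params.shoulder_amp(td))[0]
        inside = (x >= xl) & (x <= xr)
        if not np.any(inside):
            continue
        chord = yl + (yr - yl) * (x[inside] - xl) / (xr - xl)
        y[inside] = (1.0 - w) * chord + w * y[inside]
    return y


def true_features(params: StripeModelParams, t: float, z: float = 0.0,
                  t_on12: float | None = None, t_on23: float | None = None,
                  a2_scale: float = 1.0,
                  grid_n: int = 10001, min_prominence: float = 0.01) -> dict:
    """Ground-truth stripe features by dense-grid brute force on the model.

    Strict local extrema of the noiseless model are found on a uniform grid
    (10^4 points by default), shallow min/max pairs below ``min_prominence``
    are dropped, maxima are matched to stripe identities by proximity to the
    (jitter-shifted) stripe centers, and border positions are the linear
    interpolants of the half-height crossings.
    """
    x = np.linspace(0.0, 100.0, grid_n)
    y = model_intensity(params, x, t, z=z, t_on12=t_on12, t_on23=t_on23,
                        a2_scale=a2_scale)
    td = params.dev_time(t)
    mu_eff = params.mu + z * params.sigma_pos(td)

    d = np.diff(y)
    sign = np.sign(d)
    nz = sign != 0
    # indices of strict direction changes
    ext_idx = []
    kinds = []
    last_sign = 0.0
    for i in range(len(d)):
        if sign[i] == 0:
            continue
        if last_sign != 0 and sign[i] != last_sign:
            ext_idx.append(i)
            kinds.append("max" if last_sign > 0 else "min")
        last_sign = sign[i]
    ext = [(float(x[i]), float(y[i]), k) for i, k in zip(ext_idx, kinds)]
    # prune shallow adjacent pairs
    changed = True
    while changed and len(ext) >= 2:
        gaps = [abs(ext[i + 1][1] - ext[i][1]) for i in range(len(ext) - 1)]
        j = int(np.argmin(gaps))
        if gaps[j] < min_prominence:
            del ext[j:j + 2]
        else:
            changed = False

    maxima = [(p, v) for p, v, k in ext if k == "max"]
    minima = [(p, v) for p, v, k in ext if k == "min"]

    def stripe_peak(s: int):
        cands = [(abs(p - mu_eff[s - 1]), p, v) for p, v in maxima
                 if abs(p - mu_eff[s - 1]) <= 3.0]
        if not cands:
            return None
        _, p, v = min(cands)
        return p, v

    def valley_min(lo_mu: float, hi_mu: float):
        cands = [(p, v) for p, v in minima if lo_mu < p < hi_mu]
        if not cands:
            return None
        return min(cands, key=lambda pv: pv[1])

    def crossing(xa: float, xb: float, level: float):
        lo, hi = sorted([xa, xb])
        m = (x >= lo) & (x <= hi)
        xs, ys = x[m], y[m] - level
        s = np.where(np.diff(np.sign(ys)) != 0)[0]
        if s.size == 0:
            return None
        i = s[0]
        frac = ys[i] / (ys[i] - ys[i + 1])
        return float(xs[i] + frac * (xs[i + 1] - xs[i]))

    out: dict = {"t_min": t, "n_maxima": len(maxima)}
    p1 = stripe_peak(1)
    p2 = stripe_peak(2)
    m12 = valley_min(mu_eff[0], mu_eff[1])
    m23 = valley_min(mu_eff[1], mu_eff[2])
    out["peak1_pos"], out["peak1_val"] = p1 if p1 else (np.nan, np.nan)
    out["peak2_pos"], out["peak2_val"] = p2 if p2 else (np.nan, np.nan)
    out["min12_pos"], out["min12_val"] = m12 if m12 else (np.nan, np.nan)
    out["min23_pos"], out["min23_val"] = m23 if m23 else (np.nan, np.nan)
    out["anterior_min_present"] = m12 is not None
    out["posterior_min_present"] = m23 is not None
    out["stripe2_present"] = (p2 is not None and m12 is not None and m23 is not None)
    if p2 and m12:
        out["h2a"] = p2[1] - m12[1]
        out["b2a_pos"] = crossing(m12[0], p2[0], 0.5 * (p2[1] + m12[1]))
    else:
        out["h2a"] = np.nan
        out["b2a_pos"] = np.nan
    if p2 and m23:
        out["h2p"] = p2[1] - m23[1]
        out["b2p_pos"] = crossing(p2[0], m23[0], 0.5 * (p2[1] + m23[1]))
    else:
        out["h2p"] = np.nan
        out["b2p_pos"] = np.nan
    out["relative_activation"] = (p2[1] / p1[1]) if (p1 and p2) else np.nan
    out["relative_repression"] = (out["h2a"] / out["h2p"]
                                  if np.isfinite(out["h2a"]) and out["h2p"] else np.nan)
    return out


# ---------------------------------------------------------------------------
# Profile and cohort generation


def generate_profile(params: StripeModelParams, t: float, seed,
                     z: float = 0.0, t_on12: float | None = None,
                     t_on23: float | None = None, a2_scale: float = 1.0,
                     embryo_id: str = "", edge: str = "ventral") -> ExpressionProfile:
    """Sampled expression profile at nucleus spacing with per-nucleus noise.

    Deterministic given (params, t, z, onsets, a2_scale, seed).  Intensities
    are the model values plus iid Gaussian nucleus noise (sd ``sigma_n``),
    clipped at zero (fluorescence is nonnegative).
    """
    params.check_window(t)
    rng = np.random.default_rng(seed)
    x = np.arange(0.0, 100.0 + 1e-9, params.nucleus_spacing_el)
    y = model_intensity(params, x, t, z=z, t_on12=t_on12, t_on23=t_on23,
                        a2_scale=a2_scale)
    if params.sigma_n > 0:
        y = y + rng.normal(0.0, params.sigma_n, size=x.size)
    y = np.clip(y, 0.0, None)
    return ExpressionProfile(x=x, y=y, embryo_id=embryo_id, t_min=t, edge=edge)


@dataclass
class EmbryoRealization:
    """Per-embryo latent variables drawn by the cohort generator."""

    embryo_id: str
    seed: int
    z: float
    t_on12: float
    t_on23: float
    a2_scale: float = 1.0


@dataclass
class EmbryoProfiles:
    realization: EmbryoRealization
    times: np.ndarray
    profiles: list[ExpressionProfile]
    truth: pd.DataFrame


@dataclass
class Cohort:
    params: StripeModelParams
    embryos: list[EmbryoProfiles]

    def truth_table(self) -> pd.DataFrame:
        frames = []
        for e in self.embryos:
            df = e.truth.copy()
            df.insert(0, "embryo_id", e.realization.embryo_id)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


def default_times(params: StripeModelParams) -> np.ndarray:
    """3-min frame grid: 21-48 min at 25C, 21-39 min at 29C."""
    hi = 48.0 if params.temperature == "25C" else 39.0
    return np.arange(21.0, hi + 1e-9, 3.0)


def _realize(params: StripeModelParams, rng: np.random.Generator,
             embryo_id: str, seed: int) -> EmbryoRealization:
    z = float(rng.normal())
    t12 = float(rng.normal(*params.onset12))
    t23 = float(rng.normal(*params.onset23))
    a2 = float(max(0.2, rng.normal(1.0, params.amp_cv)))
    return EmbryoRealization(embryo_id=embryo_id, seed=seed, z=z,
                             t_on12=t12, t_on23=t23, a2_scale=a2)


def generate_cohort(params: StripeModelParams, n_embryos: int, seed,
                    times=None) -> Cohort:
    """Profile-level cohort with per-embryo jitter, onsets and truth tables."""
    if n_embryos < 2:
        raise ValueError("a cohort needs at least 2 embryos")
    if times is None:
        times = default_times(params)
    times = np.asarray(times, dtype=float)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_embryos)
    embryos = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        emb_seed = int(child.generate_state(1)[0] % (2 ** 31))
        real = _realize(params, rng, f"{params.preset}_{params.temperature}_e{i:03d}",
                        emb_seed)
        profiles = []
        truth_rows = []
        for j, t in enumerate(times):
            profiles.append(generate_profile(
                params, float(t), seed=emb_seed + j, z=real.z,
                t_on12=real.t_on12, t_on23=real.t_on23,
                a2_scale=real.a2_scale, embryo_id=real.embryo_id))
            truth_rows.append(true_features(
                params, float(t), z=real.z, t_on12=real.t_on12,
                t_on23=real.t_on23, a2_scale=real.a2_scale))
        embryos.append(EmbryoProfiles(realization=real, times=times,
                                      profiles=profiles,
                                      truth=pd.DataFrame(truth_rows)))
    return Cohort(params=params, embryos=embryos)


# ---------------------------------------------------------------------------
# Image rendering


@dataclass
class SceneSpec:
    """Geometry and rendering parameters for one synthetic embryo movie.

    Defaults mirror the imaging configuration: 512x512 pixels, 16-bit
    depth, anterior left, dorsal up.  The seed fully determines the output.
    """

    shape: tuple[int, int] = (512, 512)
    center: tuple[float, float] = (256.0, 256.0)  # (x, y)
    semi_axes: tuple[float, float] = (230.0, 115.0)  # embryo (a, b), px
    band_offset: float = 10.0  # nuclei centerline inset from the surface
    nucleus_radius: float = 4.0
    n_nuclei: int = 110
    ring_offset: float = 4.0
    ring_thickness: float = 2.5
    yolk_level: float = 0.25
    cortex_level: float = 0.5   # cytoplasmic autofluorescence in the cortical layer
    nucleus_level: float = 1.0
    ring_level: float = 1.3
    membrane_dim: float = 0.45
    reporter_background: float = 0.03
    pixel_noise_sd: float = 0.02
    bit_depth: int = 16
    intensity_scale: float = 20000.0
    membrane_schedule: tuple[tuple[int, int], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        per = _ellipse_perimeter(self.semi_axes[0] - self.band_offset,
                                 self.semi_axes[1] - self.band_offset)
        spacing = per / self.n_nuclei
        if spacing < 2.05 * self.nucleus_radius:
            raise ValueError(
                f"nucleus count {self.n_nuclei} infeasible for band geometry: "
                f"spacing {spacing:.1f} px < nucleus diameter")


def _ellipse_arc(a: float, b: float, n: int = 4096):
    th = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    x = a * np.cos(th)
    y = b * np.sin(th)
    seg = np.hypot(np.diff(x, append=x[:1]), np.diff(y, append=y[:1]))
    s = np.concatenate([[0.0], np.cumsum(seg)[:-1]])
    return th, x, y, s, float(seg.sum())


def _ellipse_perimeter(a: float, b: float) -> float:
    return _ellipse_arc(a, b)[4]


def _nucleus_centers(scene: SceneSpec, phase: float) -> np.ndarray:
    """(n, 2) array of (x, y) nucleus centers at equal arc spacing."""
    a = scene.semi_axes[0] - scene.band_offset
    b = scene.semi_axes[1] - scene.band_offset
    th, ex, ey, s, per = _ellipse_arc(a, b)
    targets = (np.arange(scene.n_nuclei) / scene.n_nuclei + phase) % 1.0 * per
    xs = np.interp(targets, s, ex, period=per)
    ys = np.interp(targets, s, ey, period=per)
    cx, cy = scene.center
    return np.column_stack([cx + xs, cy + ys])


def _rho(scene: SceneSpec, a: float, b: float):
    h, w = scene.shape
    yy, xx = np.mgrid[0:h, 0:w]
    cx, cy = scene.center
    return np.sqrt(((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2)


def _stamp_disks(img: np.ndarray, centers: np.ndarray, radius: float,
                 values: np.ndarray) -> None:
    h, w = img.shape
    r = int(np.ceil(radius))
    for (cx, cy), v in zip(centers, values):
        x0, x1 = int(cx) - r - 1, int(cx) + r + 2
        y0, y1 = int(cy) - r - 1, int(cy) + r + 2
        x0, y0 = max(x0, 0), max(y0, 0)
        x1, y1 = min(x1, w), min(y1, h)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        m = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius ** 2
        img[y0:y1, x0:x1][m] = v


def _membrane_line_mask(shape, center_xy, radial_dir, half_len: float,
                        half_width: float) -> np.ndarray:
    """Mask of a short line through a nucleus, tangential to the cortex."""
    h, w = shape
    cx, cy = center_xy
    r = int(np.ceil(half_len)) + 2
    x0, x1 = max(int(cx) - r, 0), min(int(cx) + r + 1, w)
    y0, y1 = max(int(cy) - r, 0), min(int(cy) + r + 1, h)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx, dy = xx - cx, yy - cy
    rx, ry = radial_dir
    along_r = dx * rx + dy * ry
    along_t = -dx * ry + dy * rx
    m = (np.abs(along_r) <= half_width) & (np.abs(along_t) <= half_len)
    out = np.zeros(shape, dtype=bool)
    out[y0:y1, x0:x1] = m
    return out


def _band_mask(scene: SceneSpec, half_thickness: float) -> np.ndarray:
    """Truth cortical band: tube of given half thickness around the centerline."""
    a = scene.semi_axes[0] - scene.band_offset
    b = scene.semi_axes[1] - scene.band_offset
    th, ex, ey, s, per = _ellipse_arc(a, b, n=4096)
    cx, cy = scene.center
    pts = np.column_stack([cx + ex, cy + ey])
    step = max(1, int(len(pts) / per))  # ~1 px steps along the centerline
    pts = pts[::step]
    tmp = np.zeros(scene.shape, dtype=float)
    _stamp_disks(tmp, pts, half_thickness, np.ones(len(pts)))
    return tmp > 0


def _ring_mask(scene: SceneSpec) -> np.ndarray:
    a, b = scene.semi_axes
    lo = _rho(scene, a + scene.ring_offset - scene.ring_thickness / 2,
              b + scene.ring_offset - scene.ring_thickness / 2)
    hi = _rho(scene, a + scene.ring_offset + scene.ring_thickness / 2,
              b + scene.ring_offset + scene.ring_thickness / 2)
    return (lo >= 1.0) & (hi <= 1.0)


def _quantize(img: np.ndarray, scene: SceneSpec) -> np.ndarray:
    maxval = 2 ** scene.bit_depth - 1
    out = np.clip(np.round(img * scene.intensity_scale), 0, maxval)
    return out.astype(np.uint16)


@dataclass
class EmbryoImageSeries:
    """Registered two-channel frames for one embryo."""

    embryo_id: str
    genotype: str
    temperature: str
    times: np.ndarray            # registered minutes
    frame_times: np.ndarray      # raw acquisition minutes (times + t0)
    t0_event_time: float
    nuclear: np.ndarray          # (T, H, W) uint16
    reporter: np.ndarray         # (T, H, W) uint16
    anterior_px: tuple[float, float]
    posterior_px: tuple[float, float]
    scene: SceneSpec

    def save_tiff(self, directory) -> tuple[str, str]:
        import os
        import tifffile
        os.makedirs(directory, exist_ok=True)
        p1 = os.path.join(directory, f"{self.embryo_id}_nuclear.tif")
        p2 = os.path.join(directory, f"{self.embryo_id}_reporter.tif")
        tifffile.imwrite(p1, self.nuclear)
        tifffile.imwrite(p2, self.reporter)
        return p1, p2


@dataclass
class GroundTruth:
    """Rendered truth: per-nucleus records, per-frame features, region masks."""

    nuclei: pd.DataFrame
    features: pd.DataFrame
    band_mask: np.ndarray
    ring_mask: np.ndarray
    realization: EmbryoRealization


def schedule_membrane_splits(scene: SceneSpec, frame_index: int, k: int,
                             seed=0) -> tuple[tuple[int, int], ...]:
    """Pick k non-adjacent nuclei to split by membrane lines in one frame."""
    rng = np.random.default_rng(seed)
    if k > scene.n_nuclei // 2:
        raise ValueError("cannot place that many non-adjacent splits")
    chosen: list[int] = []
    order = rng.permutation(scene.n_nuclei)
    for idx in order:
        if all(min(abs(idx - c), scene.n_nuclei - abs(idx - c)) > 1 for c in chosen):
            chosen.append(int(idx))
        if len(chosen) == k:
            break
    return tuple((frame_index, c) for c in sorted(chosen))


def generate_embryo_series(params: StripeModelParams, scene: SceneSpec,
                           embryo_id: str = "emb000",
                           times=None) -> tuple[EmbryoImageSeries, GroundTruth]:
    """Render a two-channel movie plus ground truth for one embryo.

    Frames are 3 minutes apart.  Reporter nucleus intensities equal the
    1-D model evaluated at each nucleus's AP position plus nucleus-level
    noise; rendering adds pixel noise and 16-bit quantization.
    """
    if times is None:
        times = default_times(params)
    times = np.asarray(times, dtype=float)
    if times.size >= 2 and not np.allclose(np.diff(times), 3.0):
        raise ValueError("frame interval must be 3 minutes")
    for t in times:
        params.check_window(float(t))

    rng = np.random.default_rng(scene.seed)
    real = _realize(params, rng, embryo_id, seed=int(scene.seed))
    phase = float(rng.uniform())
    centers = _nucleus_centers(scene, phase)
    n = len(centers)
    brightness = scene.nucleus_level * (1.0 + 0.08 * rng.standard_normal(n))
    t0 = float(rng.uniform(5.0, 15.0))

    cx, cy = scene.center
    a, b = scene.semi_axes
    ap = (centers[:, 0] - (cx - a)) / (2 * a) * 100.0

    yolk_rho = _rho(scene, a - scene.band_offset - scene.nucleus_radius - 3,
                    b - scene.band_offset - scene.nucleus_radius - 3)
    yolk = np.where(yolk_rho < 1.0,
                    scene.yolk_level * (1.0 - 0.4 * yolk_rho ** 2), 0.0)
    band = _band_mask(scene, scene.nucleus_radius + 1.0)
    ring = _ring_mask(scene)
    embryo_rho = _rho(scene, a, b)

    split_by_frame: dict[int, list[int]] = {}
    for fi, ni in scene.membrane_schedule:
        split_by_frame.setdefault(int(fi), []).append(int(ni))

    radial = centers - np.array([[cx, cy]])
    # radial direction on the ellipse uses the gradient of the implicit form
    radial = np.column_stack([radial[:, 0] / a ** 2, radial[:, 1] / b ** 2])
    radial /= np.linalg.norm(radial, axis=1, keepdims=True)

    nuc_frames, rep_frames = [], []
    nuc_rows = []
    feat_rows = []
    for j, t in enumerate(times):
        values = model_intensity(params, ap, float(t), z=real.z,
                                 t_on12=real.t_on12, t_on23=real.t_on23,
                                 a2_scale=real.a2_scale)
        if params.sigma_n > 0:
            values = values + rng.normal(0.0, params.sigma_n, size=n)
        values = np.clip(values, 0.0, None)

        nuc = yolk.copy()
        nuc[band] = np.maximum(nuc[band], scene.cortex_level)
        _stamp_disks(nuc, centers, scene.nucleus_radius, brightness)
        for ni in split_by_frame.get(j, []):
            line = _membrane_line_mask(scene.shape, centers[ni], radial[ni],
                                       half_len=1.5 * scene.nucleus_radius,
                                       half_width=1.2)
            nuc[line & (nuc > 0.75 * scene.nucleus_level)] *= scene.membrane_dim
        nuc[ring] = scene.ring_level
        nuc = nuc + rng.normal(0.0, scene.pixel_noise_sd, size=nuc.shape)

        rep = np.where(embryo_rho < 1.0, scene.reporter_background, 0.0)
        _stamp_disks(rep, centers, scene.nucleus_radius, values)
        rep = rep + rng.normal(0.0, scene.pixel_noise_sd, size=rep.shape)

        nuc_frames.append(_quantize(nuc, scene))
        rep_frames.append(_quantize(rep, scene))

        split_set = set(split_by_frame.get(j, []))
        for i in range(n):
            nuc_rows.append({
                "t_min": float(t), "nucleus_id": i,
                "x_px": centers[i, 0], "y_px": centers[i, 1],
                "ap_percent_el": ap[i],
                "true_value": values[i],
                "true_mean_image": values[i] * scene.intensity_scale,
                "split": i in split_set,
            })
        feat_rows.append(true_features(
            params, float(t), z=real.z, t_on12=real.t_on12,
            t_on23=real.t_on23, a2_scale=real.a2_scale))

    series = EmbryoImageSeries(
        embryo_id=embryo_id, genotype=params.preset,
        temperature=params.temperature, times=times,
        frame_times=times + t0, t0_event_time=t0,
        nuclear=np.stack(nuc_frames), reporter=np.stack(rep_frames),
        anterior_px=(cx - a, cy), posterior_px=(cx + a, cy), scene=scene)
    truth = GroundTruth(
        nuclei=pd.DataFrame(nuc_rows), features=pd.DataFrame(feat_rows),
        band_mask=band, ring_mask=ring, realization=real)
    return series, truth


# ---------------------------------------------------------------------------
# Genotype count tables


def generate_count_table(cross: CrossSchema, total_n: int,
                         viability_multipliers: dict | None = None,
                         seed=0) -> pd.DataFrame:
    """Multinomial genotype/sex count table under scaled Mendelian odds.

    Multipliers (in [0, 1]) are looked up per class label or per
    ``(class, sex)``; unlisted classes keep multiplier 1.  The draw is over
    surviving classes x sexes with mass frequency/2 per sex, scaled by the
    multipliers and renormalized.
    """
    exp = cross_expectation(cross)
    mult = viability_multipliers or {}
    for v in mult.values():
        if not 0.0 <= v <= 1.0:
            raise ValueError("viability multipliers must lie in [0, 1]")
    rows = []
    for _, r in exp.iterrows():
        for sex in ("female", "male"):
            m = mult.get((r["class"], sex), mult.get(r["class"], 1.0))
            rows.append({"class": r["class"], "sex": sex,
                         "mass": r["frequency"] / 2.0 * m})
    df = pd.DataFrame(rows)
    total_mass = df["mass"].sum()
    if total_mass <= 0:
        raise ValueError("scaled frequencies sum to zero mass")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(int(total_n), (df["mass"] / total_mass).to_numpy())
    df["count"] = counts
    return df[["class", "sex", "count"]]
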