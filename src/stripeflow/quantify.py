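"""Expression-profile construction and spline-based stripe feature detection.

Per-nucleus fluorescence tables are projected onto the anteroposterior (AP)
axis to give 1-D expression profiles (percent egg length vs mean nuclear
fluorescence).  A cubic smoothing spline is fit to each profile and its
extrema define the stripe features used throughout: peak positions/heights
and border positions/heights.

Conventions
-----------
* AP coordinate is percent egg length (% EL), 0 at the anterior pole.
* Profile intensities are normalized to the stripe-1 peak (or another
  reference stripe) so the spline's roughness trade-off operates on a fixed
  scale; the smoothing-parameter semantics are scale dependent.
* The smoothing spline minimizes ``p * sum((y - f(x))**2) +
  (1 - p) * integral(f''(x)**2)``.  ``p = 1`` interpolates the data and
  ``p = 0`` degenerates to the least-squares straight line.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import PPoly, make_smoothing_spline
from scipy.optimize import brentq

__all__ = [
    "ExpressionProfile",
    "TimeRegistration",
    "EmbryoAxis",
    "SplineFit",
    "Extremum",
    "Border",
    "StripeFeatures",
    "register_time",
    "extract_edge_profile",
    "normalize_profile",
    "fit_smoothing_spline",
    "detect_extrema",
    "stripe_features",
    "track_stripes",
    "interstripe_presence",
]

#: AP bin width (% EL) inside which samples are averaged before fitting.
DUPLICATE_BIN_EL = 0.1

#: Minimum number of nuclei expected in an edge profile.
MIN_PROFILE_SAMPLES = 30


@dataclass
class ExpressionProfile:
    """Ordered (AP % EL, intensity) samples from one embryo edge at one time."""

    x: np.ndarray
    y: np.ndarray
    embryo_id: str = ""
    t_min: float = np.nan
    edge: str = "ventral"
    normalization: str | None = None
    low_n: bool = False

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must have the same shape")
        if self.x.size and np.any(np.diff(self.x) < 0):
            order = np.argsort(self.x, kind="stable")
            self.x = self.x[order]
            self.y = self.y[order]


@dataclass(frozen=True)
class TimeRegistration:
    """Frame times registered to the completion of the 13th nuclear division.

    ``uncertainty_min`` carries the stated precision of the registration
    event (the final mitotic wave lasts about half a minute).
    """

    times: np.ndarray
    t0: float
    uncertainty_min: float = 0.5


@dataclass(frozen=True)
class EmbryoAxis:
    """AP axis of an embryo in pixel coordinates (x, y), anterior first."""

    anterior: tuple[float, float]
    posterior: tuple[float, float]

    @property
    def length(self) -> float:
        d = np.subtract(self.posterior, self.anterior)
        return float(np.hypot(*d))

    @property
    def unit(self) -> np.ndarray:
        d = np.subtract(self.posterior, self.anterior)
        return d / np.hypot(*d)


def register_time(frame_times, t0_event_time, uncertainty_min: float = 0.5) -> TimeRegistration:
    """Shift frame acquisition times so t = 0 at the registration event."""
    if t0_event_time is None:
        raise ValueError("t0 event time is required to register frame times")
    t = np.asarray(frame_times, dtype=float)
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("frame times must be strictly increasing")
    return TimeRegistration(times=t - float(t0_event_time), t0=float(t0_event_time),
                            uncertainty_min=uncertainty_min)


def extract_edge_profile(
    nuclei: pd.DataFrame,
    edge: str,
    axis: EmbryoAxis,
    embryo_id: str = "",
    t_min: float = np.nan,
    min_samples: int = MIN_PROFILE_SAMPLES,
) -> ExpressionProfile:
    """Project one side's nuclei onto the AP axis.

    ``nuclei`` must carry ``x_px``, ``y_px`` and ``mean_fluo`` columns.  With
    anterior left and dorsal up (image rows growing downward), dorsal nuclei
    lie on the negative side of the axis normal and ventral nuclei on the
    positive side.
    """
    if edge not in ("dorsal", "ventral"):
        raise ValueError(f"edge must be 'dorsal' or 'ventral', got {edge!r}")
    pts = nuclei[["x_px", "y_px"]].to_numpy(dtype=float)
    rel = pts - np.asarray(axis.anterior, dtype=float)
    u = axis.unit
    along = rel @ u
    # normal pointing ventrally (downward in image coordinates)
    normal = np.array([-u[1], u[0]])
    if normal[1] < 0:
        normal = -normal
    side = rel @ normal
    keep = side >= 0 if edge == "ventral" else side < 0
    ap = np.clip(along[keep] / axis.length * 100.0, 0.0, 100.0)
    fluo = nuclei["mean_fluo"].to_numpy(dtype=float)[keep]
    low_n = ap.size < min_samples
    if low_n:
        warnings.warn(
            f"{edge} profile has only {ap.size} nuclei (< {min_samples})",
            stacklevel=2,
        )
    order = np.argsort(ap, kind="stable")
    return ExpressionProfile(x=ap[order], y=fluo[order], embryo_id=embryo_id,
                             t_min=t_min, edge=edge, low_n=low_n)


def _average_duplicates(x: np.ndarray, y: np.ndarray, bin_el: float = DUPLICATE_BIN_EL):
    """Average intensities whose AP positions share a ``bin_el`` bin."""
    if x.size == 0:
        return x, y
    bins = np.round(x / bin_el).astype(np.int64)
    uniq, inv = np.unique(bins, return_inverse=True)
    xs = np.bincount(inv, weights=x) / np.bincount(inv)
    ys = np.bincount(inv, weights=y) / np.bincount(inv)
    return xs, ys


# ---------------------------------------------------------------------------
# Smoothing spline


@dataclass
class SplineFit:
    """Cubic smoothing spline with roughness parameter ``p`` in [0, 1]."""

    p: float
    x: np.ndarray
    y: np.ndarray
    _ppoly: PPoly
    residuals: np.ndarray

    def __call__(self, xq) -> np.ndarray:
        return self._ppoly(xq)

    def derivative(self, xq) -> np.ndarray:
        return self._ppoly.derivative()(xq)

    @property
    def domain(self) -> tuple[float, float]:
        return float(self.x[0]), float(self.x[-1])


def fit_smoothing_spline(profile, p: float = 0.5) -> SplineFit:
    """Fit the p-convention cubic smoothing spline to a profile.

    Accepts an :class:`ExpressionProfile` or an ``(x, y)`` pair.  Duplicate
    AP positions are averaged before fitting.  Internally this maps onto the
    penalized least-squares formulation ``SSR + lam * integral(f'')`` with
    ``lam = (1 - p) / p``; the two conventions have the same minimizer.
    """
    if isinstance(profile, ExpressionProfile):
        x, y = profile.x, profile.y
    else:
        x, y = profile
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
    if not 0.0 <= p <= 1.0:
        raise ValueError("roughness parameter p must lie in [0, 1]")
    x, y = _average_duplicates(x, y)
    if x.size < 4:
        raise ValueError(f"need at least 4 samples to fit a cubic spline, got {x.size}")

    if p == 0.0:
        # infinite roughness penalty: closed-form least-squares line
        coef = np.polyfit(x, y, 1)
        # represent the line as a single-interval PPoly so evaluation,
        # differentiation and root finding use one code path
        pp = PPoly(np.array([[coef[0]], [coef[1] + coef[0] * x[0]]]),
                   np.array([x[0], x[-1]]), extrapolate=True)
        fitted = pp(x)
    else:
        lam = (1.0 - p) / p
        bspl = make_smoothing_spline(x, y, lam=lam)
        pp = PPoly.from_spline(bspl, extrapolate=False)
        fitted = pp(x)
    return SplineFit(p=p, x=x, y=y, _ppoly=pp, residuals=y - fitted)


def normalize_profile(profile: ExpressionProfile, reference: int = 1,
                      features: "StripeFeatures | None" = None,
                      p: float = 0.5) -> ExpressionProfile:
    """Divide intensities by the reference stripe's peak value.

    The reference peak is located with the spline pipeline unless
    pre-computed ``features`` are supplied; low-amplitude wiggles (below 5%
    of the intensity range) are ignored when numbering stripes.  Raises if
    the reference stripe has no peak at this timepoint.
    """
    if features is None:
        fit = fit_smoothing_spline(profile, p=p)
        prom = 0.05 * float(np.ptp(profile.y)) if profile.y.size else 0.0
        features = stripe_features(detect_extrema(fit), fit,
                                   min_prominence=prom)
    peak = features.peak(reference)
    if peak is None:
        raise ValueError(f"reference stripe {reference} has no peak in this profile")
    _, value = peak
    if value <= 0:
        raise ValueError("reference peak value must be positive")
    return replace(profile, y=profile.y / value, normalization=f"stripe{reference}")


# ---------------------------------------------------------------------------
# Extrema and stripe features


@dataclass(frozen=True)
class Extremum:
    position: float
    value: float
    kind: str  # "min" | "max"


@dataclass(frozen=True)
class Border:
    """Stripe border: the half-height crossing between adjacent extrema.

    ``position`` is where the spline crosses the mean of the two extremal
    values; ``height`` is the difference of those values.
    """

    position: float
    height: float
    min_value: float
    max_value: float


def detect_extrema(fit: SplineFit, tol: float = 1e-9) -> list[Extremum]:
    """Interior local extrema of the spline, alternating min/max.

    Extrema are the sign changes of f' found from the exact polynomial roots
    of the derivative; domain endpoints are excluded.
    """
    lo, hi = fit.domain
    dp = fit._ppoly.derivative()
    roots = dp.roots(extrapolate=False)
    roots = roots[np.isfinite(roots)]
    span = hi - lo
    margin = 1e-9 * max(span, 1.0)
    roots = np.unique(roots[(roots > lo + margin) & (roots < hi - margin)])
    if roots.size == 0:
        return []
    # merge numerically coincident roots
    keep = np.concatenate([[True], np.diff(roots) > 1e-7 * span])
    roots = roots[keep]
    edges = np.concatenate([[lo], roots, [hi]])
    out: list[Extremum] = []
    for i, r in enumerate(roots):
        hl = (r - edges[i]) / 2
        hr = (edges[i + 2] - r) / 2
        sl = np.sign(dp(r - hl))
        sr = np.sign(dp(r + hr))
        if sl > tol >= -sr or (sl > 0 and sr < 0):
            kind = "max"
        elif sl < 0 < sr:
            kind = "min"
        else:
            continue  # tangency / inflection, not an extremum
        out.append(Extremum(float(r), float(fit(r)), kind))
    # enforce alternation (possible duplicate kinds after tangency drops)
    cleaned: list[Extremum] = []
    for e in out:
        if cleaned and cleaned[-1].kind == e.kind:
            better = e.value > cleaned[-1].value if e.kind == "max" else e.value < cleaned[-1].value
            if better:
                cleaned[-1] = e
        else:
            cleaned.append(e)
    return cleaned


def _prune_shallow(extrema: list[Extremum], min_prominence: float) -> list[Extremum]:
    """Iteratively drop the shallowest adjacent (min, max) pair.

    Removing an adjacent opposite-kind pair preserves alternation; repeat
    until every adjacent value gap is at least ``min_prominence``.
    """
    ext = list(extrema)
    while len(ext) >= 2:
        gaps = [abs(ext[i + 1].value - ext[i].value) for i in range(len(ext) - 1)]
        i = int(np.argmin(gaps))
        if gaps[i] >= min_prominence:
            break
        del ext[i:i + 2]
    return ext


@dataclass
class StripeFeatures:
    """Per-timepoint stripe features extracted from one spline fit."""

    extrema: list[Extremum]
    maxima: list[Extremum]
    stripe_ids: list[int | None]
    anterior_borders: list[Border | None]
    posterior_borders: list[Border | None]
    embryo_id: str = ""
    t_min: float = np.nan

    def _index_of(self, stripe: int) -> int | None:
        for i, s in enumerate(self.stripe_ids):
            if s == stripe:
                return i
        return None

    def peak(self, stripe: int) -> tuple[float, float] | None:
        """(position, value) of the stripe's peak, if present."""
        i = self._index_of(stripe)
        if i is None:
            return None
        m = self.maxima[i]
        return m.position, m.value

    def border(self, stripe: int, side: str) -> Border | None:
        i = self._index_of(stripe)
        if i is None:
            return None
        if side in ("A", "anterior"):
            return self.anterior_borders[i]
        if side in ("P", "posterior"):
            return self.posterior_borders[i]
        raise ValueError(f"side must be 'A' or 'P', got {side!r}")

    def n_peaks(self) -> int:
        return len(self.maxima)


def _border_between(fit: SplineFit, e_min: Extremum, e_max: Extremum) -> Border:
    level = 0.5 * (e_min.value + e_max.value)
    a, b = sorted([e_min.position, e_max.position])
    pos = brentq(lambda xx: fit(xx) - level, a, b, xtol=1e-10)
    return Border(position=float(pos), height=float(e_max.value - e_min.value),
                  min_value=e_min.value, max_value=e_max.value)


def stripe_features(
    extrema: list[Extremum],
    fit: SplineFit,
    min_prominence: float = 0.0,
    embryo_id: str = "",
    t_min: float = np.nan,
) -> StripeFeatures:
    """Assemble per-stripe peaks and borders from alternating extrema.

    Peaks are numbered anterior to posterior starting at stripe 1; use
    :func:`track_stripes` to reconcile identities across timepoints.  A
    border is the unique crossing of the spline with the mean of the two
    flanking extremal values (uniqueness follows from strict monotonicity
    of the spline between its extrema).
    """
    for a, b in zip(extrema, extrema[1:]):
        if a.kind == b.kind:
            raise ValueError("extrema must alternate min/max along AP")
        if b.position <= a.position:
            raise ValueError("extrema must be ordered along AP")
    if min_prominence > 0:
        extrema = _prune_shallow(extrema, min_prominence)
    maxima: list[Extremum] = []
    ant: list[Border | None] = []
    post: list[Border | None] = []
    for i, e in enumerate(extrema):
        if e.kind != "max":
            continue
        maxima.append(e)
        left = extrema[i - 1] if i > 0 else None
        right = extrema[i + 1] if i + 1 < len(extrema) else None
        ant.append(_border_between(fit, left, e) if left is not None else None)
        post.append(_border_between(fit, right, e) if right is not None else None)
    ids: list[int | None] = list(range(1, len(maxima) + 1))
    return StripeFeatures(extrema=list(extrema), maxima=maxima, stripe_ids=ids,
                          anterior_borders=ant, posterior_borders=post,
                          embryo_id=embryo_id, t_min=t_min)


def track_stripes(features_by_time: list[StripeFeatures], gate_el: float = 3.0,
                  n_stripes: int = 7, value_floor: float = 0.25) -> None:
    """Reconcile stripe identities across timepoints, in place.

    The most mature timepoint (most substantial peaks; latest among ties)
    anchors the numbering: maxima above ``value_floor`` of the tallest peak
    are numbered anterior to posterior starting at stripe 1.  The pair-rule
    pattern is quasi-periodic, so when the spacing between consecutive
    anchored peaks is a multiple of the typical interstripe distance the
    intervening stripe ids are skipped rather than shifted — an
    undetectably weak stripe stays missing instead of silently relabeling
    its posterior neighbors.  Identities propagate to neighboring
    timepoints by nearest-position matching with a ``gate_el`` (% EL) gate;
    unmatched peaks get ``None``.
    """
    if not features_by_time:
        return

    def anchored(f: StripeFeatures) -> list[Extremum]:
        if not f.maxima:
            return []
        vmax = max(m.value for m in f.maxima)
        keep = [m for m in f.maxima if m.value >= value_floor * vmax]
        return sorted(keep, key=lambda m: m.value, reverse=True)[:n_stripes]

    counts = [len(anchored(f)) for f in features_by_time]
    anchor = max(range(len(counts)), key=lambda i: (counts[i], i))
    af = features_by_time[anchor]
    top = sorted(anchored(af), key=lambda m: m.position)
    gaps = np.diff([m.position for m in top])
    g_ref = float(np.median(gaps)) if len(gaps) >= 2 else 7.0
    af.stripe_ids = [None] * len(af.maxima)
    sid = 1
    for k, m in enumerate(top):
        if k > 0:
            sid += max(1, int(round(gaps[k - 1] / g_ref)))
        af.stripe_ids[af.maxima.index(m)] = sid
    ref = {s: m.position for s, m in zip(af.stripe_ids, af.maxima) if s is not None}

    def assign(feats: StripeFeatures, running: dict[int, float]) -> None:
        pairs = []
        for j, m in enumerate(feats.maxima):
            for s, pos in running.items():
                d = abs(m.position - pos)
                if d <= gate_el:
                    pairs.append((d, j, s))
        pairs.sort()
        used_j: set[int] = set()
        used_s: set[int] = set()
        ids: list[int | None] = [None] * len(feats.maxima)
        for d, j, s in pairs:
            if j in used_j or s in used_s:
                continue
            ids[j] = s
            used_j.add(j)
            used_s.add(s)
            running[s] = feats.maxima[j].position
        feats.stripe_ids = ids

    running = dict(ref)
    for i in range(anchor - 1, -1, -1):
        assign(features_by_time[i], running)
    running = dict(ref)
    for i in range(anchor + 1, len(features_by_time)):
        assign(features_by_time[i], running)


def interstripe_presence(
    features_by_time: list[StripeFeatures],
    stripe: int = 2,
    gate_el: float = 3.0,
) -> pd.DataFrame:
    """Presence of the stripe's flanking interstripe minima at each timepoint.

    The minima flanking the stripe at the most mature timepoint anchor
    backward nearest-position tracking (within ``gate_el``), so a flanking
    minimum counts as present even before the stripe's own peak resolves.
    Returns a frame with columns ``t_min``, ``anterior``, ``posterior``.
    """
    anchor_idx = None
    for i in range(len(features_by_time) - 1, -1, -1):
        f = features_by_time[i]
        if f.peak(stripe) is not None and f.border(stripe, "A") and f.border(stripe, "P"):
            anchor_idx = i
            break
    rows = []
    if anchor_idx is None:
        for f in features_by_time:
            rows.append({"t_min": f.t_min, "anterior": False, "posterior": False})
        return pd.DataFrame(rows)

    anchor = features_by_time[anchor_idx]
    j = anchor._index_of(stripe)
    k = anchor.extrema.index(anchor.maxima[j])
    ant_pos = anchor.extrema[k - 1].position
    post_pos = anchor.extrema[k + 1].position

    def nearest_min(feats: StripeFeatures, pos: float) -> float | None:
        cands = [e.position for e in feats.extrema if e.kind == "min" and abs(e.position - pos) <= gate_el]
        if not cands:
            return None
        return min(cands, key=lambda c: abs(c - pos))

    # track backward and forward from the anchor so positions follow drift
    presence: dict[int, tuple[bool, bool]] = {}
    for direction in (-1, 1):
        a_run, p_run = ant_pos, post_pos
        idxs = range(anchor_idx, -1, -1) if direction < 0 else range(anchor_idx, len(features_by_time))
        for i in idxs:
            f = features_by_time[i]
            a = nearest_min(f, a_run)
            p = nearest_min(f, p_run)
            if a is not None:
                a_run = a
            if p is not None:
                p_run = p
            presence[i] = (a is not None, p is not None)
    for i, f in enumerate(features_by_time):
        a, p = presence[i]
        rows.append({"t_min": f.t_min, "anterior": a, "posterior": p})
    return pd.DataFrame(rows)
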