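"""Stripe-2 maturation phenotypes and cohort statistics.

Within-embryo scaling makes embryos comparable across experiments: stripe 1
serves as an internal control, so *relative activation* is the ratio of the
stripe-2 peak to the stripe-1 peak and *relative repression* is the ratio
of the anterior (2A) to posterior (2P) stripe-2 border heights.  Two
initiation phenotypes follow the flanking interstripe minima through time:
the incipient-stripe time (both minima present and stably maintained) and
the border-order class (which minimum was detected first).  Cohort-level
precision is the across-embryo standard deviation of stripe-2 positions
per timepoint.  Group comparisons use the two-sided Mann-Whitney-Wilcoxon
rank-sum test, exact for small samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import (StripeFeatures, detect_extrema, fit_smoothing_spline,
                       interstripe_presence, stripe_features, track_stripes)

__all__ = [
    "PhenotypeSeries",
    "relative_activation",
    "relative_repression",
    "detect_incipient_stripe",
    "classify_border_order",
    "positional_variation",
    "compare_groups",
    "scale_developmental_time",
    "channel_concordance",
    "phenotype_series",
    "cohort_summary",
]

#: border-height ratios above this are flagged for exclusion from time-series
#: plots (they stay in all statistical testing)
PLOT_EXCLUSION_RATIO = 10.0

LANDMARK_25C = 38.2
LANDMARK_29C = 30.6


def relative_activation(features: StripeFeatures, reference: int = 1) -> float | None:
    """Stripe-2 peak value over the reference stripe's peak value.

    Returns None when either peak is missing at this timepoint (the cell is
    dropped from that timepoint, never the embryo).
    """
    p2 = features.peak(2)
    pr = features.peak(reference)
    if p2 is None or pr is None or pr[1] <= 0:
        return None
    return p2[1] / pr[1]


def relative_repression(features: StripeFeatures,
                        exclusion_threshold: float = PLOT_EXCLUSION_RATIO
                        ) -> tuple[float, bool] | None:
    """Anterior over posterior stripe-2 border height, with exclusion flag.

    Returns ``(ratio, plot_excluded)``; very large ratios (including an
    infinite one from a zero posterior height) are flagged but retained for
    statistics.  None when either border is missing.
    """
    ba = features.border(2, "A")
    bp = features.border(2, "P")
    if ba is None or bp is None:
        return None
    if bp.height == 0:
        return math.inf, True
    ratio = ba.height / bp.height
    return ratio, ratio > exclusion_threshold


def _persistence_ok(present: np.ndarray, start: int, max_misses: int = 1) -> bool:
    return int(np.sum(~present[start:])) <= max_misses


def detect_incipient_stripe(presence: pd.DataFrame,
                            max_missing: int = 1) -> float | None:
    """Earliest time when both flanking minima exist and persist.

    ``presence`` comes from :func:`stripeflow.quantify.interstripe_presence`
    (columns ``t_min``, ``anterior``, ``posterior``).  Persistence tolerates
    at most one missing later timepoint, which absorbs occasional detection
    dropouts of a weakly expressed stripe.  Returns None when no timepoint
    qualifies (a valid outcome).
    """
    if len(presence) < 3:
        raise ValueError("need features at >= 3 timepoints")
    both = (presence["anterior"] & presence["posterior"]).to_numpy()
    times = presence["t_min"].to_numpy(dtype=float)
    for i in range(len(both)):
        if both[i] and _persistence_ok(both, i + 1, max_missing):
            return float(times[i])
    return None


def classify_border_order(presence: pd.DataFrame,
                          max_missing: int = 1) -> str:
    """Which stripe-2 border's interstripe minimum appeared first.

    A minimum's first detection only counts if it persists (at most one
    missing later timepoint), confirming it develops into a mature
    interstripe.  Same-frame first detections, or a minimum that never
    stably appears, give ``"unresolved"``.
    """
    def first_stable(col: str) -> float | None:
        pres = presence[col].to_numpy()
        times = presence["t_min"].to_numpy(dtype=float)
        for i in range(len(pres)):
            if pres[i] and _persistence_ok(pres, i + 1, max_missing):
                return float(times[i])
        return None

    ta = first_stable("anterior")
    tp = first_stable("posterior")
    if ta is None or tp is None or ta == tp:
        return "unresolved"
    return "anterior_first" if ta < tp else "posterior_first"


def positional_variation(df: pd.DataFrame, trait: str,
                         time_col: str = "t_min") -> pd.DataFrame:
    """Across-embryo sample SD (% EL) of a positional trait per timepoint.

    ``trait`` is a column such as ``peak2_pos``, ``b2a_pos`` or
    ``b2p_pos``.  Uses the textbook n-1 sample SD over embryos; cells with
    fewer than two embryos are undefined (NaN).
    """
    if trait not in df.columns:
        raise ValueError(f"no column {trait!r} in phenotype table")
    def _sd(x):
        x = x.dropna()
        return x.std(ddof=1) if len(x) >= 2 else np.nan
    g = df.groupby(time_col)[trait]
    out = pd.DataFrame({"sd": g.apply(_sd), "n": g.apply(lambda x: x.notna().sum())})
    return out.reset_index()


# ---------------------------------------------------------------------------
# Rank-sum test


def compare_groups(sample_a, sample_b) -> float:
    """Two-sided Mann-Whitney-Wilcoxon rank-sum p-value.

    Exact enumeration (via a subset-sum recursion over midranks,
    mathematically identical to enumerating all rank assignments) when the
    smaller sample has at most 8 observations; the normal approximation
    with tie correction otherwise.  Exclusion-flagged (even infinite)
    phenotype values participate through their ranks.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # midranks; handles inf
    w = float(ranks[:n1].sum())
    N = n1 + n2
    mean_w = n1 * (N + 1) / 2.0

    if min(n1, n2) <= 8:
        ranks2 = np.round(ranks * 2).astype(np.int64)
        k = min(n1, n2)
        total2 = int(ranks2.sum())
        dp = np.zeros((k + 1, total2 + 1))
        dp[0, 0] = 1.0
        for r in ranks2:
            r = int(r)
            dp[1:, r:] = dp[1:, r:] + dp[:-1, :total2 + 1 - r]
        counts = dp[k]
        # observed doubled rank sum for the smaller group
        w_small = w if n1 <= n2 else float(ranks[n1:].sum())
        w2 = int(round(w_small * 2))
        mean2 = k * (total2 / N)
        dev = abs(w2 - mean2)
        sums = np.arange(total2 + 1)
        extreme = np.abs(sums - mean2) >= dev - 1e-9
        return float(counts[extreme].sum() / counts.sum())

    tie_counts = np.unique(pooled, return_counts=True)[1]
    tie_term = np.sum(tie_counts ** 3 - tie_counts) / (N * (N - 1))
    var_w = n1 * n2 / 12.0 * ((N + 1) - tie_term)
    if var_w <= 0:
        return 1.0
    z = (w - mean_w) / math.sqrt(var_w)
    return float(2.0 * stats.norm.sf(abs(z)))


def scale_developmental_time(t, landmark_25c: float = LANDMARK_25C,
                             landmark_29c: float = LANDMARK_29C):
    """Map absolute 29C minutes onto the 25C developmental timeline.

    Development is faster at 29C (the cellularization membrane reaches the
    basal end of nuclei at 30.6 min vs 38.2 min at 25C), so scaled time is
    ``t * landmark_25c / landmark_29c``.
    """
    if landmark_25c <= 0 or landmark_29c <= 0:
        raise ValueError("landmark times must be positive")
    return np.asarray(t, dtype=float) * (landmark_25c / landmark_29c)


def channel_concordance(table: pd.DataFrame, ch_a: str = "channel_a",
                        ch_b: str = "channel_b",
                        embryo_col: str = "embryo_id") -> pd.DataFrame:
    """Per-embryo squared Pearson correlation of two nuclear channels.

    Each channel is normalized to its maximum within the embryo before the
    correlation (the normalization does not change r^2 but matches the
    reporting convention).  A constant channel gives NaN.
    """
    rows = []
    for emb, g in table.groupby(embryo_col):
        x = g[ch_a].to_numpy(dtype=float)
        y = g[ch_b].to_numpy(dtype=float)
        if x.max() > 0:
            x = x / x.max()
        if y.max() > 0:
            y = y / y.max()
        if np.ptp(x) == 0 or np.ptp(y) == 0 or len(x) < 3:
            r2 = np.nan
        else:
            r2 = float(stats.pearsonr(x, y)[0] ** 2)
        rows.append({embryo_col: emb, "r_squared": r2, "n_nuclei": len(x)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Per-embryo pipeline and cohort summaries


@dataclass
class PhenotypeSeries:
    """Per-embryo phenotype trajectories plus initiation phenotypes."""

    embryo_id: str
    genotype: str
    temperature: str
    table: pd.DataFrame              # one row per registered timepoint
    initiation_time: float | None
    border_order: str


def phenotype_series(profiles, embryo_id: str = "", genotype: str = "",
                     temperature: str = "25C", p: float = 0.5,
                     min_prominence: float = 0.06,
                     exclusion_threshold: float = PLOT_EXCLUSION_RATIO
                     ) -> PhenotypeSeries:
    """Full feature pipeline for one embryo's profile time series.

    Each profile is scaled to its maximum (the spline's roughness trade-off
    is defined on the [0, 1] intensity scale), fit with the smoothing
    spline, and reduced to stripe features; extremal pairs shallower than
    ``min_prominence`` (on the normalized scale) are treated as noise.
    Stripe identities are reconciled across time, and the phenotype table
    (relative activation/repression, stripe-2 positions) is assembled
    together with the incipient-stripe time and border-order class.  All
    reported phenotypes are intensity ratios, so the scaling cancels.
    """
    feats: list[StripeFeatures] = []
    for prof in profiles:
        ymax = float(np.max(prof.y)) if prof.y.size else 0.0
        scaled = prof if ymax <= 0 else type(prof)(
            x=prof.x, y=prof.y / ymax, embryo_id=prof.embryo_id,
            t_min=prof.t_min, edge=prof.edge)
        fit = fit_smoothing_spline(scaled, p=p)
        ext = detect_extrema(fit)
        feats.append(stripe_features(ext, fit, min_prominence=min_prominence,
                                     embryo_id=embryo_id, t_min=prof.t_min))
    track_stripes(feats)
    presence = interstripe_presence(feats, stripe=2)

    rows = []
    for f in feats:
        act = relative_activation(f)
        rep = relative_repression(f, exclusion_threshold)
        p2 = f.peak(2)
        ba = f.border(2, "A")
        bp = f.border(2, "P")
        rows.append({
            "t_min": f.t_min,
            "relative_activation": act if act is not None else np.nan,
            "relative_repression": rep[0] if rep is not None else np.nan,
            "plot_excluded": bool(rep[1]) if rep is not None else False,
            "peak2_pos": p2[0] if p2 else np.nan,
            "peak2_val": p2[1] if p2 else np.nan,
            "b2a_pos": ba.position if ba else np.nan,
            "b2p_pos": bp.position if bp else np.nan,
            "h2a": ba.height if ba else np.nan,
            "h2p": bp.height if bp else np.nan,
        })
    table = pd.DataFrame(rows)
    init = detect_incipient_stripe(presence) if len(presence) >= 3 else None
    order = classify_border_order(presence) if len(presence) >= 3 else "unresolved"
    return PhenotypeSeries(embryo_id=embryo_id, genotype=genotype,
                           temperature=temperature, table=table,
                           initiation_time=init, border_order=order)


def cohort_table(series_list: list[PhenotypeSeries]) -> pd.DataFrame:
    """Long-format table across embryos (one row per embryo x timepoint)."""
    frames = []
    for s in series_list:
        df = s.table.copy()
        df.insert(0, "embryo_id", s.embryo_id)
        df.insert(1, "genotype", s.genotype)
        df.insert(2, "temperature", s.temperature)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def cohort_summary(series_list: list[PhenotypeSeries],
                   phenotypes: tuple[str, ...] = ("relative_activation",
                                                  "relative_repression")
                   ) -> pd.DataFrame:
    """Mean, SEM, SD and n per genotype x timepoint, plus rank-sum p-values.

    Statistics are over embryos (never nuclei); a missing phenotype drops
    that embryo's cell at that timepoint only.  Pairwise rank-sum p-values
    between genotypes are attached per timepoint and phenotype.
    """
    long = cohort_table(series_list)
    rows = []
    for (geno, t), g in long.groupby(["genotype", "t_min"]):
        for ph in phenotypes:
            vals = g[ph].replace([np.inf, -np.inf], np.nan).dropna()
            rows.append({
                "genotype": geno, "t_min": t, "phenotype": ph,
                "mean": vals.mean() if len(vals) else np.nan,
                "sd": vals.std(ddof=1) if len(vals) >= 2 else np.nan,
                "sem": vals.sem(ddof=1) if len(vals) >= 2 else np.nan,
                "n": int(len(vals)),
            })
    summary = pd.DataFrame(rows)

    comps = []
    genos = sorted(long["genotype"].unique())
    for t, gt in long.groupby("t_min"):
        for ph in phenotypes:
            for i in range(len(genos)):
                for j in range(i + 1, len(genos)):
                    va = gt.loc[gt["genotype"] == genos[i], ph].dropna()
                    vb = gt.loc[gt["genotype"] == genos[j], ph].dropna()
                    if len(va) == 0 or len(vb) == 0:
                        continue
                    comps.append({
                        "t_min": t, "phenotype": ph,
                        "group_a": genos[i], "group_b": genos[j],
                        "p_value": compare_groups(va, vb),
                        "n_a": len(va), "n_b": len(vb),
                    })
    summary.attrs["comparisons"] = pd.DataFrame(comps)
    return summary
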