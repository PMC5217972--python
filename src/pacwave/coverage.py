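"""Coverage profiles and inference of the headful-packaging model.

The host-flank read-depth profile left of an integrated phage carries the
whole packaging story: a decaying staircase whose step ratio is the
continuation probability ``1 - 1/m`` of the processive series, whose step
spacing is the headful size ``H`` (hence the terminal redundancy
``r = H/L_p - 1``), and whose extent is set by the series-length tail.
The phage-frame profile peaks at the packaging-initiation (pac) region.

All estimators here are point estimators working on binned depth; none of
them assumes the geometric decay they are meant to corroborate (period
detection uses moving-average detrending plus autocorrelation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .genome import AttSite, ReplicatedGenome
from .simulate import phage_distance_to_junction
from .stats import binom_test_two_sided


@dataclass
class CoverageProfile:
    """Binned mean per-base depth over one named frame."""

    frame: str
    bin_size: int
    depth: np.ndarray
    length: int
    topology: str = "circular"

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        want = -(-self.length // self.bin_size)
        if len(self.depth) != want:
            raise ValueError("depth array does not tile the frame")

    @property
    def n_bins(self) -> int:
        return len(self.depth)


def binned_coverage(starts, ends, frame: str, frame_length: int,
                    bin_size: int = 1000, topology: str = "circular") -> CoverageProfile:
    """Depth profile from half-open alignment intervals.

    ``depth[i]`` is (aligned bases falling in bin i) / (bin width); on
    circular frames intervals may wrap and the final partial bin uses its
    true width.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    L = frame_length
    diff = np.zeros(L + 1)
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size:
        s = starts % L
        e = ends.copy()
        # normalise wrap: interval length in [0, L]
        ln = (e - starts) % L
        ln[ln == 0] = np.where((e - starts)[ln == 0] != 0, L, 0)
        e = s + ln
        wrap = e > L
        np.add.at(diff, s, 1.0)
        np.add.at(diff, np.minimum(e, L), -1.0)
        if wrap.any():
            np.add.at(diff, np.zeros(wrap.sum(), dtype=np.int64), 1.0)
            np.add.at(diff, (e[wrap] - L), -1.0)
    per_base = np.cumsum(diff[:-1])
    nb = -(-L // bin_size)
    bounds = np.arange(nb) * bin_size
    sums = np.add.reduceat(per_base, bounds)
    widths = np.minimum(bounds + bin_size, L) - bounds
    return CoverageProfile(frame, bin_size, sums / widths, L, topology)


def flank_series(profile: CoverageProfile, att_pos: int, direction: str,
                 span: int) -> np.ndarray:
    """Depth as a function of distance from the att site along one flank.

    ``direction='toward_attL'`` walks down-coordinate from ``att_pos``
    (the left flank); ``'toward_attR'`` walks up-coordinate.  Distances are
    bin-resolution; the series wraps on circular frames.
    """
    nb = profile.n_bins
    b0 = att_pos // profile.bin_size
    n = min(span // profile.bin_size, nb - 1)
    if direction == "toward_attL":
        idx = (b0 - 1 - np.arange(n)) % nb
    else:
        idx = (b0 + 1 + np.arange(n)) % nb
    return profile.depth[idx]


def near_att_fraction(read_midpoints, att_pos: int, frame_length: int,
                      direction: str = "toward_attL",
                      window: tuple[int, int] = (800_000, 10_000)) -> tuple[float, int, int]:
    """Fraction of host reads whose midpoint falls in the att-linked window.

    ``window = (flank_bp, off_side_bp)``: ``flank_bp`` on the packaging
    side of the att site plus a small margin on the other side.  Returns
    ``(fraction, numerator, denominator)``.
    """
    up, down = window
    if up + down >= frame_length:
        raise ValueError("window larger than the genome")
    mids = np.asarray(read_midpoints, dtype=np.int64)
    if mids.size == 0:
        return 0.0, 0, 0
    rel = (mids - att_pos) % frame_length
    rel = np.where(rel > frame_length // 2, rel - frame_length, rel)
    if direction == "toward_attL":
        hit = (rel >= -up) & (rel <= down)
    else:
        hit = (rel >= -down) & (rel <= up)
    k = int(hit.sum())
    return k / mids.size, k, int(mids.size)


def estimate_background(profile: CoverageProfile, att_pos: int,
                        direction: str = "toward_attL",
                        exclude: tuple[int, int] = (1_000_000, 50_000),
                        pool_bins: int = 5) -> float:
    """Median depth outside an exclusion zone around the att site.

    The median is robust to the att-linked enrichment tail; the zone is
    asymmetric, wide on the packaging side.  Depth is pooled over
    ``pool_bins`` consecutive bins before taking the median: at the few
    reads per bin typical of the background floor the raw per-bin median
    is biased low by count quantisation.
    """
    up, down = exclude
    L = profile.length
    if up + down >= L:
        raise ValueError("no bins remain outside the exclusion zone")
    centers = (np.arange(profile.n_bins) + 0.5) * profile.bin_size
    rel = (centers - att_pos) % L
    rel = np.where(rel > L / 2, rel - L, rel)
    if direction == "toward_attL":
        keep = (rel < -up) | (rel > down)
    else:
        keep = (rel < -down) | (rel > up)
    if not keep.any():
        raise ValueError("no bins remain outside the exclusion zone")
    vals = profile.depth[keep]
    if pool_bins > 1 and vals.size >= 2 * pool_bins:
        m = vals.size - vals.size % pool_bins
        vals = vals[:m].reshape(-1, pool_bins).mean(axis=1)
    return float(np.median(vals))


def flank_extent(profile: CoverageProfile, att_pos: int, direction: str,
                 background: float, threshold_mult: float = 2.0,
                 run_rule: int = 3, max_span: int | None = None,
                 smooth_bins: int = 15) -> int:
    """Reach of above-background enrichment along the packaging flank, bp.

    Walks away from the att site over a ``smooth_bins``-wide moving median
    of the profile and stops after more than ``run_rule`` consecutive
    values at or below ``threshold_mult * background``: isolated low bins
    are tolerated, and short sampling dips (common at a handful of reads
    per bin) do not truncate the walk — only a sustained drop does.  The
    default 15-bin window is still a fifth of the ~72-kb wave structure
    the profile carries, and the median keeps step edges sharp.
    A zero background falls back to an absolute floor of 0.1x.
    """
    thr = threshold_mult * max(background, 0.1)
    span = max_span if max_span is not None else (profile.n_bins - 1) * profile.bin_size
    series = flank_series(profile, att_pos, direction, span).astype(float)
    if smooth_bins > 1 and series.size > smooth_bins:
        w = smooth_bins | 1
        pad = w // 2
        padded = np.pad(series, pad, mode="edge")
        series = np.array([np.median(padded[i:i + w])
                           for i in range(series.size)])
    low = 0
    last_pass = -1
    for i, v in enumerate(series):
        if v > thr:
            last_pass = i
            low = 0
        else:
            low += 1
            if low > run_rule:
                break
    return (last_pass + 1) * profile.bin_size


def headful_window_means(profile: CoverageProfile, att_pos: int, direction: str,
                         H: float, n_windows: int = 12,
                         first_offset: float | None = None) -> np.ndarray:
    """Mean depth over successive headful-sized windows along the flank.

    Window 1 covers host distance ``[0, first_offset)`` — the tail of the
    first headful, whose leading ``d = H - first_offset`` bases are phage —
    and windows j >= 2 each cover a further full headful.  With geometric
    series continuation the window means decay as ``(1 - 1/m)**(j-1)``.
    """
    if H <= 0:
        raise ValueError("H must be positive")
    delta = H if first_offset is None else first_offset
    edges = [0.0, delta] + [delta + j * H for j in range(1, n_windows)]
    if edges[-1] > (profile.n_bins - 1) * profile.bin_size:
        raise ValueError("windows exceed the genome")
    series = flank_series(profile, att_pos, direction, int(edges[-1]) + profile.bin_size)
    b = profile.bin_size
    out = []
    for j in range(n_windows):
        lo = int(round(edges[j] / b))
        hi = max(int(round(edges[j + 1] / b)), lo + 1)
        out.append(float(series[lo:hi].mean()))
    return np.asarray(out)


def estimate_processivity(window_means, background: float = 0.0) -> float:
    """Mean headfuls per packaging series from window means.

    m_hat = sum_j max(w_j - bg, 0) / (w_1 - bg); exact for geometric decay
    as the window count grows.  Negative-after-subtraction windows are
    truncated at zero, a small upward bias documented in the tests.
    """
    w = np.asarray(window_means, dtype=float) - background
    if w[0] <= 0:
        raise ValueError("first window does not rise above background")
    return float(np.maximum(w, 0.0).sum() / w[0])


def detect_wave_period(profile: CoverageProfile, att_pos: int, direction: str,
                       span: int = 800_000, max_lag: int = 120_000,
                       detrend_window: int = 100_000,
                       min_lag: int = 20_000,
                       threshold: float = 0.1) -> float | None:
    """Wave period of the flank profile by detrended autocorrelation, bp.

    log(depth + 0.5) is detrended by subtracting a centered moving average
    (window ~100 kb), the residual autocorrelation is normalised at lag 0,
    and the period is the first local maximum past ``min_lag``, refined by
    quadratic interpolation over the three bins around the peak.  Returns
    ``None`` when no peak exceeds ``threshold``.
    """
    b = profile.bin_size
    x = flank_series(profile, att_pos, direction, span).astype(float)
    if x.size < 4 or np.allclose(x, x[0]):
        return None
    logd = np.log(x + 0.5)
    w = max(3, int(round(detrend_window / b)) | 1)
    pad = w // 2
    padded = np.pad(logd, pad, mode="reflect")
    trend = np.convolve(padded, np.ones(w) / w, mode="valid")
    resid = logd - trend
    resid = resid - resid.mean()
    n = resid.size
    var = float(np.dot(resid, resid))
    if var == 0:
        return None
    nlags = min(int(max_lag // b), n - 2)
    ac = np.array([np.dot(resid[: n - l], resid[l:]) for l in range(nlags + 1)]) / var
    lo = max(2, int(np.ceil(min_lag / b)))
    if lo >= nlags:
        return None
    # strongest autocorrelation peak past the short-lag exclusion; sampling
    # noise puts ripples on the curve, so the global maximum is used rather
    # than the first local one
    l = lo + int(np.argmax(ac[lo:nlags]))
    if ac[l] <= threshold:
        return None
    denom = ac[l - 1] - 2 * ac[l] + ac[l + 1]
    delta = 0.5 * (ac[l - 1] - ac[l + 1]) / denom if denom < 0 else 0.0
    return float((l + np.clip(delta, -1, 1)) * b)


def estimate_redundancy(period_T: float, phage_length: int) -> float:
    """Terminal redundancy r = (T - L_p) / L_p; negative values are possible
    when the detected period undershoots the genome (caller flags them)."""
    if period_T <= 0:
        raise ValueError("period must be positive")
    return (period_T - phage_length) / phage_length


@dataclass
class PacEstimate:
    """Location of the packaging-initiation coverage maximum."""

    pos_max: int | None      # argmax of the smoothed circular profile
    pos_edge: int | None     # half-rise crossing left of the maximum
    downslope: int           # sign of the gradient over the next quarter genome


def estimate_pac_position(profile: CoverageProfile,
                          smooth: int = 2000) -> PacEstimate:
    """Packaging-initiation locus from the circular phage profile.

    ``pos_max`` is the maximum of the circularly smoothed profile (moving
    average ~2 kb).  Because jittered initiation produces a flat-topped
    maximum one headful-drift wide, the argmax sits near the middle of
    that plateau; ``pos_edge`` — the point where the profile climbs through
    half its range on the rising side of the maximum — marks where the
    maximum *starts* and is unbiased under symmetric cleavage jitter, so
    the pipeline reports it as the pac estimate.  A flat profile yields
    ``PacEstimate(None, None, 0)``.
    """
    d = profile.depth.astype(float)
    if d.size == 0 or np.allclose(d, d[0]):
        return PacEstimate(None, None, 0)
    w = max(1, int(round(smooth / profile.bin_size)))
    kern = np.ones(w) / w
    sm = np.real(np.fft.ifft(np.fft.fft(d) * np.fft.fft(kern, d.size)))
    sm = np.roll(sm, -(w // 2))  # center the circular moving average
    nb = d.size
    peak = int(np.argmax(sm))
    q = max(1, nb // 4)
    after = sm[(peak + np.arange(1, q + 1)) % nb]
    slope = np.polyfit(np.arange(q), after, 1)[0]
    level = 0.5 * (sm[peak] + sm.min())
    edge = peak
    for step in range(1, nb):
        i = (peak - step) % nb
        if sm[i] < level:
            edge = (i + 1) % nb
            break
    else:
        edge = peak
    b = profile.bin_size
    return PacEstimate(
        pos_max=int((peak + 0.5) * b) % profile.length,
        pos_edge=int(edge * b) % profile.length,
        downslope=int(np.sign(slope)),
    )


def directionality_test(hybrid_left: int, hybrid_right: int):
    """Which host flank the junction reads support, with exact binomial p.

    Returns ``(direction, p)`` with ``direction`` in {'left', 'right',
    None}; both counts zero gives ``(None, None)``.
    """
    if hybrid_left < 0 or hybrid_right < 0:
        raise ValueError("counts must be non-negative")
    n = hybrid_left + hybrid_right
    if n == 0:
        return None, None
    p = binom_test_two_sided(hybrid_left, n, 0.5)
    if hybrid_left == hybrid_right:
        return None, p
    return ("left" if hybrid_left > hybrid_right else "right"), p


@dataclass
class PackagingEstimates:
    """Inferred packaging model parameters (None = not estimable)."""

    host_fraction: float | None = None
    near_att_fraction: float | None = None
    near_att_counts: tuple[int, int] | None = None
    period_T: float | None = None
    headful_H_hat: float | None = None
    redundancy_r_hat: float | None = None
    processivity_m_hat: float | None = None
    pac_pos_hat: int | None = None
    pac_downslope: int = 0
    direction: str | None = None
    direction_counts: tuple[int, int] = (0, 0)
    direction_p: float | None = None
    flank_extent: int | None = None
    background_depth: float | None = None
    window_means: list[float] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["window_means"] = list(map(float, self.window_means))
        return d


class PackagingEstimator(BaseEstimator):
    """Infers the headful-packaging model from classified reads.

    ``fit`` consumes the read-classification table (the output of
    ``ReadOriginClassifier.classify``) plus the two reference frames and
    the att site, and populates trailing-underscore attributes:
    ``host_profile_``, ``phage_profile_``, ``estimates_`` and one attribute
    per estimate (``period_T_``, ``processivity_m_hat_``, ...).

    Parameters follow the analysis defaults: 1-kb bins (depth values then
    compare directly to per-base coverage), a 2x-background threshold with
    a 3-bin run rule for the flank extent, and 12 headful windows for the
    processivity sum.
    """

    def __init__(self, bin_size: int = 1000, n_windows: int = 12,
                 threshold_mult: float = 2.0, run_rule: int = 3,
                 span: int = 800_000, max_lag: int = 120_000,
                 detrend_window: int = 100_000,
                 near_att_window: tuple[int, int] = (800_000, 10_000),
                 background_exclude: tuple[int, int] = (1_000_000, 50_000),
                 pac_smooth: int = 2000):
        self.bin_size = bin_size
        self.n_windows = n_windows
        self.threshold_mult = threshold_mult
        self.run_rule = run_rule
        self.span = span
        self.max_lag = max_lag
        self.detrend_window = detrend_window
        self.near_att_window = near_att_window
        self.background_exclude = background_exclude
        self.pac_smooth = pac_smooth

    def fit(self, classified: pd.DataFrame, *, host: ReplicatedGenome,
            phage: ReplicatedGenome, att: AttSite):
        est = PackagingEstimates()
        df = classified
        total = len(df)
        host_df = df[df.label == "host"]
        phage_df = df[df.label == "phage"]
        n_left = int((df.label == "hybrid-left").sum())
        n_right = int((df.label == "hybrid-right").sum())
        est.direction_counts = (n_left, n_right)
        side, p = directionality_test(n_left, n_right)
        est.direction, est.direction_p = side, p
        direction = "toward_attR" if side == "right" else "toward_attL"
        est.host_fraction = len(host_df) / total if total else None

        self.phage_profile_ = binned_coverage(
            phage_df.pos, phage_df.pos_end, "phage", phage.length,
            self.bin_size, phage.topology)
        pac = estimate_pac_position(self.phage_profile_, self.pac_smooth)
        est.pac_pos_hat, est.pac_downslope = pac.pos_edge, pac.downslope
        if est.pac_pos_hat is None:
            est.flags.append("flat phage profile: pac position undefined")

        self.host_profile_ = binned_coverage(
            host_df.pos, host_df.pos_end, "host", host.length,
            self.bin_size, host.topology)
        if len(host_df) == 0:
            est.flags.append("no host reads: flank estimates not applicable")
        else:
            # defaults assume a Mb-scale host; clip windows on small frames
            L = host.length
            near_win = (min(self.near_att_window[0], int(L * 0.4)),
                        min(self.near_att_window[1], int(L * 0.05)))
            exclude = (min(self.background_exclude[0], int(L * 0.5)),
                       min(self.background_exclude[1], int(L * 0.05)))
            span = min(self.span, int(L * 0.45))
            mids = ((host_df.pos + (host_df.pos_end - host_df.pos) % host.length // 2)
                    % host.length)
            frac, k, n = near_att_fraction(
                mids, att.attB_pos, host.length, direction, near_win)
            est.near_att_fraction, est.near_att_counts = frac, (k, n)
            est.background_depth = estimate_background(
                self.host_profile_, att.attB_pos, direction, exclude)
            est.flank_extent = flank_extent(
                self.host_profile_, att.attB_pos, direction,
                est.background_depth, self.threshold_mult, self.run_rule,
                max_span=span + 200_000)
            # period detection is restricted to the enriched flank: beyond
            # the extent the profile is background and only dilutes the
            # autocorrelation
            span_detect = int(min(span, max(300_000, est.flank_extent + 50_000)))
            est.period_T = detect_wave_period(
                self.host_profile_, att.attB_pos, direction,
                span_detect, self.max_lag, self.detrend_window)
            if est.period_T is not None:
                est.headful_H_hat = est.period_T
                est.redundancy_r_hat = estimate_redundancy(est.period_T, phage.length)
                if est.redundancy_r_hat < 0:
                    est.flags.append("detected period below genome length")
            else:
                est.flags.append("no wave period detected")
            H = est.period_T if est.period_T else phage.length
            pac_for_d = est.pac_pos_hat if est.pac_pos_hat is not None else 0
            d = phage_distance_to_junction(att, pac_for_d, phage.length, direction)
            try:
                w = headful_window_means(
                    self.host_profile_, att.attB_pos, direction, H,
                    self.n_windows, first_offset=max(H - d, self.bin_size))
                est.window_means = list(w)
                bg = est.background_depth or 0.0
                if w[0] > bg:
                    est.processivity_m_hat = estimate_processivity(w, bg)
                else:
                    est.flags.append("first headful window at background")
            except ValueError as e:
                est.flags.append(str(e))
        self.estimates_ = est
        for k_, v in est.to_dict().items():
            setattr(self, k_ + "_", v)
        return self
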