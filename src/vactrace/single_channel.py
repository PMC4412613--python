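"""Single-channel measurement pipeline: amplitude histograms, Gaussian
mixtures, open probability, unitary current/conductance, I/V curves.

The analysis chain mirrors standard patch-clamp practice for patches with a
small number of identical channels:

1. all-point amplitude histogram of the quasi-stationary trace segment;
2. least-squares sum-of-Gaussians fit of the histogram for K = 1 ..
   max_channels + 1 components (shared peak width by default), with the
   component count selected by the Bayesian information criterion;
3. the baseline peak is the component nearest the modal current (not
   nearest zero, to tolerate leak offsets); peaks are ordered from the
   baseline outward, and peak k corresponds to k channels open
   simultaneously;
4. open probability from peak areas,  Po = sum_k k A_k / (N sum_k A_k),
   i.e. NPo normalised per channel under channel independence;
5. unitary current i = mean adjacent peak spacing (signed away from
   baseline), and chord conductance g = i / V at the most extreme applied
   voltage, because the I/V curves are not linear.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import InvalidInputError, NoReversalError, VactraceError
from .gating import Trace

__all__ = [
    "AmplitudeHistogram",
    "Peak",
    "PeakMixture",
    "IVPoint",
    "IVCurve",
    "build_amplitude_histogram",
    "fit_peak_mixture",
    "open_probability",
    "unitary_current",
    "chord_conductance_extreme_voltage",
    "build_iv_curve",
    "estimate_reversal",
    "analyze_trace",
    "PatchAnalysis",
    "DEFAULT_BIN_WIDTH_PA",
]

DEFAULT_BIN_WIDTH_PA = 0.1


@dataclass(frozen=True)
class AmplitudeHistogram:
    """All-point amplitude histogram of a current trace."""

    bin_edges_pA: np.ndarray
    counts: np.ndarray
    source_voltage_mV: float | None = None

    def __post_init__(self):
        edges = np.asarray(self.bin_edges_pA, float)
        counts = np.asarray(self.counts)
        if edges.ndim != 1 or np.any(np.diff(edges) <= 0):
            raise InvalidInputError("bin edges must be strictly increasing")
        if counts.size != edges.size - 1:
            raise InvalidInputError("counts must have len(edges) - 1 entries")
        object.__setattr__(self, "bin_edges_pA", edges)
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def total_samples(self) -> int:
        return int(self.counts.sum())

    @property
    def bin_centres_pA(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_pA[:-1] + self.bin_edges_pA[1:])

    @property
    def bin_width_pA(self) -> float:
        return float(self.bin_edges_pA[1] - self.bin_edges_pA[0])


@dataclass(frozen=True)
class Peak:
    """One Gaussian component: centre (pA), width sd (pA), area (sample*pA)."""

    centre_pA: float
    sd_pA: float
    area: float


@dataclass(frozen=True)
class PeakMixture:
    """Fitted Gaussian mixture of an amplitude histogram.

    ``peaks`` are ordered from the baseline outward, so ``peaks[k]`` is the
    level with k channels open; ``n_channels = len(peaks) - 1``.
    ``goodness`` is the reduced chi-square of the Poisson-weighted fit.
    """

    peaks: tuple[Peak, ...]
    baseline_index: int = 0
    goodness: float = math.nan
    source_voltage_mV: float | None = None

    def __post_init__(self):
        if not self.peaks:
            raise InvalidInputError("mixture needs at least one peak")
        if any(p.area <= 0 for p in self.peaks):
            raise InvalidInputError("peak areas must be > 0")

    @property
    def n_channels(self) -> int:
        return len(self.peaks) - 1

    @property
    def centres_pA(self) -> np.ndarray:
        return np.array([p.centre_pA for p in self.peaks])

    @property
    def areas(self) -> np.ndarray:
        return np.array([p.area for p in self.peaks])


@dataclass(frozen=True)
class IVPoint:
    voltage_mV: float
    current_pA: float
    sd_pA: float | None = None
    n: int = 1


@dataclass(frozen=True)
class IVCurve:
    """Ordered (voltage, current) points with per-point replication."""

    points: tuple[IVPoint, ...]
    label: str = ""

    def __post_init__(self):
        if not self.points:
            raise InvalidInputError("empty I/V curve")
        v = [p.voltage_mV for p in self.points]
        if len(set(v)) != len(v):
            raise InvalidInputError("duplicate voltages in I/V curve")
        object.__setattr__(self, "points",
                           tuple(sorted(self.points, key=lambda p: p.voltage_mV)))

    @property
    def voltages_mV(self) -> np.ndarray:
        return np.array([p.voltage_mV for p in self.points])

    @property
    def currents_pA(self) -> np.ndarray:
        return np.array([p.current_pA for p in self.points])

    @property
    def sem_pA(self) -> np.ndarray:
        return np.array([
            (p.sd_pA / math.sqrt(p.n)) if (p.sd_pA is not None and p.n > 1)
            else math.nan
            for p in self.points
        ])


def build_amplitude_histogram(trace, bin_width_pA: float = DEFAULT_BIN_WIDTH_PA,
                              voltage_mV: float | None = None) -> AmplitudeHistogram:
    """All-point histogram with bins anchored to an absolute grid.

    Accepts a :class:`~vactrace.gating.Trace` (its quasi-stationary test
    segment is used) or a plain sample array.  Anchoring the bin grid at
    integer multiples of the bin width makes histograms of different traces
    share edges, so concatenation adds histograms elementwise.
    """
    if bin_width_pA <= 0:
        raise InvalidInputError("bin width must be > 0")
    if isinstance(trace, Trace):
        samples = trace.test_segment()
        if voltage_mV is None:
            voltage_mV = trace.voltage_mV
    else:
        samples = np.asarray(trace, float)
    if samples.size == 0:
        raise InvalidInputError("empty trace")
    lo = math.floor(samples.min() / bin_width_pA) * bin_width_pA
    hi = math.ceil(samples.max() / bin_width_pA) * bin_width_pA
    n_bins = max(1, int(round((hi - lo) / bin_width_pA)))
    edges = lo + bin_width_pA * np.arange(n_bins + 1)
    if edges[-1] < samples.max():  # guard against float rounding
        edges = np.append(edges, edges[-1] + bin_width_pA)
    counts, _ = np.histogram(samples, edges)
    assert counts.sum() == samples.size, "histogram must conserve samples"
    return AmplitudeHistogram(edges, counts, source_voltage_mV=voltage_mV)


def _gaussian_sum(x, amps, centres, sds):
    y = np.zeros_like(x)
    for a, c, s in zip(amps, centres, sds):
        y += a * np.exp(-0.5 * ((x - c) / s) ** 2)
    return y


def _initial_guesses(hist: AmplitudeHistogram):
    """Modal current and a robust width estimate of the modal peak."""
    x = hist.bin_centres_pA
    c = hist.counts.astype(float)
    idx = int(np.argmax(c))
    mode = x[idx]
    half = c >= 0.5 * c.max()
    lo = idx
    while lo > 0 and half[lo - 1]:
        lo -= 1
    hi = idx
    while hi < c.size - 1 and half[hi + 1]:
        hi += 1
    fwhm = x[hi] - x[lo] + hist.bin_width_pA
    sd0 = max(fwhm / 2.355, hist.bin_width_pA)
    return mode, sd0


def _detect_candidate_peaks(hist: AmplitudeHistogram, sd0: float):
    """Candidate level positions and their smoothed heights.

    Peak detection runs on log(1 + smoothed counts) so that minor levels
    (a fraction of a percent of the samples) are still found next to a
    dominant baseline peak; spurious bumps in the inter-level transition
    bridge are dealt with later by ladder consistency.
    """
    from scipy.signal import find_peaks

    c = hist.counts.astype(float)
    half_w = max(1, int(round(sd0 / hist.bin_width_pA)))
    kernel = np.exp(-0.5 * (np.arange(-3 * half_w, 3 * half_w + 1) / half_w) ** 2)
    kernel /= kernel.sum()
    smooth = np.convolve(c, kernel, mode="same")
    pk, _ = find_peaks(np.log1p(smooth), prominence=0.7, height=math.log(6.0))
    if pk.size == 0:
        pk = np.array([int(np.argmax(smooth))])
    order = np.argsort(hist.bin_centres_pA[pk])
    return hist.bin_centres_pA[pk][order], smooth[pk][order]


def _ladder_levels(centres, heights, baseline_idx, direction, max_levels,
                   tol_frac=0.12):
    """Equally-spaced level positions supported by detected peaks.

    Channels of one population produce current levels on a ladder
    ``c_base + k * d``; detected bumps off the ladder (transition
    artefacts) are discarded.  The spacing ``d`` is chosen from pairwise
    peak separations as the one explaining the most detected weight; the
    level list is the contiguous run of ladder positions, starting at the
    baseline, that have a detected peak (binomial level occupancy cannot
    skip an intermediate level).
    """
    c_base = centres[baseline_idx]
    rel = (centres - c_base) * direction
    onward = rel >= -1e-12
    if onward.sum() <= 1:
        return np.array([c_base])
    cands = sorted({round(abs(a - b), 6)
                    for i, a in enumerate(centres) for b in centres[:i]
                    if abs(a - b) > 0})
    best = None
    for d in cands:
        k = rel / d
        on = (np.abs(k - np.round(k)) <= tol_frac) & onward & (np.round(k) >= 0) \
            & (np.round(k) <= max_levels - 1)
        score = float(np.log1p(heights[on]).sum())
        if best is None or score > best[0] or (score == best[0] and d > best[1]):
            best = (score, d, on, np.round(k).astype(int))
    _, d, on, kk = best
    occupied = {int(k) for k, keep in zip(kk, on) if keep}
    levels = [c_base]
    k = 1
    while k in occupied and len(levels) < max_levels:
        levels.append(c_base + direction * k * d)
        k += 1
    return np.asarray(levels)


def _bridge_background(x, b, centres, sd):
    """Flat pedestal confined between the outermost level centres.

    Filtered gating transitions deposit samples between the current levels
    at a roughly uniform density; a box (smoothed by the peak width) from
    the lowest to the highest centre models them without leaking counts
    beyond the outer peaks.
    """
    from scipy.special import ndtr

    lo, hi = np.min(centres), np.max(centres)
    if hi - lo < sd:
        return np.zeros_like(x)
    return b * (ndtr((x - lo) / sd) - ndtr((x - hi) / sd))


def _fit_components(x, y, w, n_comp, centres0, sd0, shared_sd, bin_width,
                    centre_halfwidth=None):
    """One bounded least-squares fit: n_comp Gaussians + bridge background.

    ``centre_halfwidth`` ties each centre to within that distance of its
    starting (ladder) position; ``None`` leaves centres free in the data
    range.
    """
    centres0 = np.asarray(centres0, float)
    amps0 = np.maximum(np.interp(centres0, x, y), 1.0)
    span = x[-1] - x[0]
    if centre_halfwidth is None:
        c_lb = np.full(n_comp, x[0] - 1.0)
        c_ub = np.full(n_comp, x[-1] + 1.0)
    else:
        c_lb = centres0 - centre_halfwidth
        c_ub = centres0 + centre_halfwidth
    if shared_sd:
        p0 = np.concatenate([amps0, centres0, [sd0, 0.0]])
        lb = np.concatenate([np.zeros(n_comp), c_lb, [bin_width / 4.0, 0.0]])
        ub = np.concatenate([np.full(n_comp, 2.0 * y.max() + 10.0), c_ub,
                             [max(span, bin_width), y.max()]])

        def model(p):
            centres = p[n_comp:2 * n_comp]
            sd = p[2 * n_comp]
            return (_gaussian_sum(x, p[:n_comp], centres, np.full(n_comp, sd))
                    + _bridge_background(x, p[2 * n_comp + 1], centres, sd))
    else:
        p0 = np.concatenate([amps0, centres0, np.full(n_comp, sd0), [0.0]])
        lb = np.concatenate([np.zeros(n_comp), c_lb,
                             np.full(n_comp, bin_width / 4.0), [0.0]])
        ub = np.concatenate([np.full(n_comp, 2.0 * y.max() + 10.0), c_ub,
                             np.full(n_comp, max(span, bin_width)), [y.max()]])

        def model(p):
            centres = p[n_comp:2 * n_comp]
            sds = p[2 * n_comp:3 * n_comp]
            return (_gaussian_sum(x, p[:n_comp], centres, sds)
                    + _bridge_background(x, p[-1], centres, float(np.mean(sds))))

    p0 = np.clip(p0, lb + 1e-12, ub - 1e-12)
    fit = least_squares(lambda p: (model(p) - y) * w, p0, bounds=(lb, ub),
                        max_nfev=400)
    return float(np.sum(fit.fun ** 2)), fit.x


def fit_peak_mixture(hist: AmplitudeHistogram, max_channels: int = 4,
                     shared_sd: bool = True,
                     current_direction: int | None = None) -> PeakMixture:
    """Sum-of-Gaussians fit of an amplitude histogram.

    The component count is the number of detected, ladder-consistent
    current levels (at most ``max_channels + 1``): candidate peaks are
    found on a log scale so that rarely visited levels next to a dominant
    baseline are kept, then filtered to an equally-spaced ladder, which
    discards the spurious bumps that filtered gating transitions leave
    between levels.  The retained components are refined by
    Poisson-weighted (weights 1/sqrt(counts + 1)) bounded least squares
    with centres tied near their ladder positions, a shared peak width by
    default, and a pedestal term absorbing the inter-level transition
    samples.  Peak areas are amplitude * sd * sqrt(2 pi).

    ``current_direction`` (+1 or -1) is the sign of the open-channel
    current; when given, the baseline is the outermost detected level on
    the opposite side, which stays correct even when NPo is large enough
    that an open level is the modal current.  When ``None`` the baseline
    is the detected level nearest the modal current (leak-offset
    tolerant).
    """
    if max_channels < 1:
        raise InvalidInputError("max_channels must be >= 1")
    if hist.total_samples == 0 or hist.counts.size < 4:
        raise InvalidInputError("histogram is degenerate")
    x = hist.bin_centres_pA
    y = hist.counts.astype(float)
    w = 1.0 / np.sqrt(y + 1.0)
    mode, sd0 = _initial_guesses(hist)
    cand_centres, cand_heights = _detect_candidate_peaks(hist, sd0)

    if current_direction is not None and current_direction != 0:
        direction = 1.0 if current_direction > 0 else -1.0
        baseline_idx = 0 if direction > 0 else cand_centres.size - 1
    else:
        baseline_idx = int(np.argmin(np.abs(cand_centres - mode)))
        mean = float((x * y).sum() / y.sum())
        direction = -1.0 if mean < cand_centres[baseline_idx] else 1.0

    levels = _ladder_levels(cand_centres, cand_heights, baseline_idx,
                            direction, max_levels=max_channels + 1)
    for _repair in range(3):
        n_comp = levels.size
        d = abs(levels[1] - levels[0]) if n_comp > 1 else 6.0 * sd0
        try:
            chi2, p = _fit_components(x, y, w, n_comp, levels, sd0, shared_sd,
                                      hist.bin_width_pA,
                                      centre_halfwidth=0.3 * d)
        except Exception as exc:
            raise VactraceError(f"mixture fit failed: {exc}") from exc
        amps = p[:n_comp]
        centres = p[n_comp:2 * n_comp]
        sds = (np.full(n_comp, p[2 * n_comp]) if shared_sd else
               p[2 * n_comp:3 * n_comp])
        # occupancies of independent identical channels are unimodal in the
        # level index: a >10x jump outward marks a halved-spacing artefact
        # (a transition bump mistaken for an intermediate level); keep every
        # other ladder position and refit
        if n_comp >= 3 and any(10.0 * amps[k] * sds[k] < amps[k + 1] * sds[k + 1]
                               for k in range(1, n_comp - 1)):
            levels = levels[::2]
            continue
        break

    # drop numerically empty components (area below one sample)
    n_samples_per_comp = amps * sds * math.sqrt(2.0 * math.pi) / hist.bin_width_pA
    keep = n_samples_per_comp >= 1.0
    # levels must stay contiguous from the baseline: cut at the first empty one
    cut = n_comp
    for i in range(n_comp):
        if not keep[i]:
            cut = i
            break
    cut = max(cut, 1)
    amps, centres, sds = amps[:cut], centres[:cut], sds[:cut]

    peaks = tuple(
        Peak(centre_pA=float(centres[i]), sd_pA=float(sds[i]),
             area=float(amps[i] * sds[i] * math.sqrt(2.0 * math.pi)))
        for i in range(centres.size)
    )
    n_par = (2 * centres.size + 2) if shared_sd else (3 * centres.size + 2)
    dof = max(1, x.size - n_par)
    return PeakMixture(peaks=peaks, baseline_index=0, goodness=chi2 / dof,
                       source_voltage_mV=hist.source_voltage_mV)


def open_probability(mix: PeakMixture, n_channels: int | None = None) -> float:
    """Per-channel open probability from peak areas: NPo / N.

    Peak k (counting from the baseline) is weighted by k open channels;
    ``n_channels`` defaults to the maximum simultaneous open level observed,
    i.e. ``mix.n_channels``.
    """
    if n_channels is None:
        n_channels = max(1, mix.n_channels)
    if n_channels < 1:
        raise InvalidInputError("n_channels must be >= 1")
    if n_channels < mix.n_channels:
        raise InvalidInputError(
            f"n_channels={n_channels} inconsistent with {mix.n_channels} open levels"
        )
    areas = mix.areas
    k = np.arange(areas.size)
    return float((k * areas).sum() / (n_channels * areas.sum()))


def unitary_current(mix: PeakMixture) -> float:
    """Mean adjacent peak spacing (pA), signed away from the baseline."""
    if len(mix.peaks) < 2:
        raise InvalidInputError("unitary current undefined for a single peak")
    centres = mix.centres_pA
    return float(np.mean(np.diff(centres)))


def chord_conductance_extreme_voltage(iv, current_pA: float | None = None) -> float:
    """Chord conductance g = i/V (pS), at the most extreme voltage of an I/V.

    ``iv`` may be an :class:`IVCurve` (the point with the largest |V| is
    used) or a voltage in mV paired with ``current_pA``.
    """
    if isinstance(iv, IVCurve):
        p = max(iv.points, key=lambda p: abs(p.voltage_mV))
        v, i = p.voltage_mV, p.current_pA
    else:
        v, i = float(iv), float(current_pA)
    if v == 0:
        raise InvalidInputError("chord conductance undefined at 0 mV")
    return 1000.0 * i / v


def build_iv_curve(points, label: str = "") -> IVCurve:
    """Build an I/V curve from per-voltage currents.

    ``points`` is an iterable of (voltage_mV, currents) where currents is a
    scalar or a sequence of per-patch values (mean, sd and n are recorded).
    """
    pts = []
    for v, cur in points:
        arr = np.atleast_1d(np.asarray(cur, float))
        sd = float(arr.std(ddof=1)) if arr.size > 1 else None
        pts.append(IVPoint(voltage_mV=float(v), current_pA=float(arr.mean()),
                           sd_pA=sd, n=int(arr.size)))
    return IVCurve(tuple(pts), label=label)


def estimate_reversal(iv: IVCurve) -> float:
    """Reversal potential (mV) by linear interpolation at the zero crossing.

    With several crossings the one nearest 0 mV is returned.  Raises
    :class:`NoReversalError` when the current does not change sign (strong
    rectification makes the reversal unmeasurable).
    """
    v = iv.voltages_mV
    i = iv.currents_pA
    crossings = []
    for a in range(len(v) - 1):
        if i[a] == 0.0:
            crossings.append(v[a])
        elif i[a] * i[a + 1] < 0:
            frac = i[a] / (i[a] - i[a + 1])
            crossings.append(v[a] + frac * (v[a + 1] - v[a]))
    if i[-1] == 0.0:
        crossings.append(v[-1])
    if not crossings:
        raise NoReversalError("I/V curve does not cross zero current")
    return float(min(crossings, key=abs))


@dataclass(frozen=True)
class PatchAnalysis:
    """Bundle of single-patch results at one voltage."""

    histogram: AmplitudeHistogram
    mixture: PeakMixture
    n_channels: int
    open_probability: float
    unitary_current_pA: float | None
    conductance_pS: float | None
    voltage_mV: float


def analyze_trace(trace: Trace, bin_width_pA: float = DEFAULT_BIN_WIDTH_PA,
                  max_channels: int = 4) -> PatchAnalysis:
    """Histogram -> mixture -> Po/N/i/g for one quasi-stationary trace.

    The open-channel current direction is taken from the applied voltage
    and the truth/assumed reversal (chord model), which anchors the
    baseline peak even when an open level is the modal current.
    """
    e_rev = trace.truth.reversal_mV if trace.truth is not None else 0.0
    dv = trace.voltage_mV - e_rev
    direction = (1 if dv > 0 else -1) if dv != 0 else None
    hist = build_amplitude_histogram(trace, bin_width_pA)
    mix = fit_peak_mixture(hist, max_channels=max_channels,
                           current_direction=direction)
    po = open_probability(mix)
    if len(mix.peaks) >= 2:
        i = unitary_current(mix)
        g = chord_conductance_extreme_voltage(trace.voltage_mV, i)
    else:
        i = None
        g = None
    return PatchAnalysis(histogram=hist, mixture=mix,
                         n_channels=max(1, mix.n_channels),
                         open_probability=po, unitary_current_pA=i,
                         conductance_pS=g, voltage_mV=trace.voltage_mV)
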