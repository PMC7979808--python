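"""Per-pixel bleach correction and multi-tau autocorrelation.

The multi-tau scheme uses ``q`` blocks of progressively pair-averaged traces:
block 0 (bin width 1 frame) holds lag channels 1..p, every later block b
(bin width 2^b frames) holds channels p/2+1..p, giving quasi-logarithmic lag
spacing out to p·2^(q−1) frames.  The correlation estimator is symmetrically
normalized,

    G(τ) = ⟨F(t)·F(t+τ)⟩ / (⟨F⟩_left · ⟨F⟩_right) − 1,

with the two means taken over the overlapping segments at each lag; this is
exactly the direct estimator at block-0 lags and the direct estimator of the
pair-averaged trace at binned lags, which the tests exploit as an oracle.

Photobleaching is removed before correlation by fitting a polynomial f(t) to
each trace and applying the variance-preserving correction
F_c(t) = F(t)/√(f(t)/f(0)) + f(0)·(1 − √(f(t)/f(0))).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .stack import ImageStack, bin_spatial


class CorrectionError(ValueError):
    """Bleach correction impossible (fitted trend non-positive)."""


class DegenerateTraceError(ValueError):
    """Zero-variance trace; ACF undefined."""


@dataclass(frozen=True)
class CorrelatorScheme:
    """Multi-tau lag structure: p channels in block 0, q blocks total."""

    p: int = 16
    q: int = 12

    def __post_init__(self) -> None:
        if self.p < 4 or self.p % 2:
            raise ValueError("p must be even and >= 4")
        if self.q < 1:
            raise ValueError("q must be >= 1")

    def lag_frames(self, n_frames: int | None = None) -> np.ndarray:
        """All lag times in frames; truncated to lags measurable in
        ``n_frames`` when given."""
        lags = list(range(1, self.p + 1))
        for b in range(1, self.q):
            w = 2 ** b
            lags.extend(ch * w for ch in range(self.p // 2 + 1, self.p + 1))
        lags = np.array(lags, dtype=np.int64)
        if n_frames is not None:
            lags = lags[lags < n_frames]
        return lags


@dataclass
class PixelACF:
    """One pixel's autocorrelation curve."""

    lags: np.ndarray  # seconds, strictly increasing, lags[0] = frame_time
    G: np.ndarray
    sd: np.ndarray
    mean_intensity: float
    valid: bool = True

    def __post_init__(self) -> None:
        if not (len(self.lags) == len(self.G) == len(self.sd)):
            raise ValueError("lags, G and sd must have equal length")

    def restricted(self, lag_range: tuple[float, float]) -> "PixelACF":
        lo, hi = lag_range
        keep = (self.lags >= lo) & (self.lags <= hi)
        return PixelACF(self.lags[keep], self.G[keep], self.sd[keep],
                        self.mean_intensity, self.valid)


def bleach_correct(trace: np.ndarray, order: int = 8) -> np.ndarray:
    """Polynomial detrending that preserves the initial mean and the local
    fluctuation variance.  ``order=0`` returns the trace unchanged."""
    trace = np.asarray(trace, dtype=np.float64)
    if order < 0:
        raise ValueError("order must be >= 0")
    if trace.size <= order + 1:
        raise ValueError("trace shorter than polynomial order + 2")
    if order == 0:
        return trace.copy()
    t = np.arange(trace.size, dtype=np.float64)
    coef = np.polynomial.polynomial.polyfit(t, trace, order)
    f = np.polynomial.polynomial.polyval(t, coef)
    if np.any(f <= 0):
        raise CorrectionError("fitted bleach trend non-positive; trace unusable")
    s = np.sqrt(f / f[0])
    return trace / s + f[0] * (1.0 - s)


def bleach_correct_matrix(traces: np.ndarray, order: int = 8) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise bleach correction of a (T, P) matrix.

    Returns (corrected, ok) where ``ok`` flags columns whose fitted trend
    stayed positive; failed columns are passed through uncorrected.
    """
    traces = np.asarray(traces, dtype=np.float64)
    if order == 0:
        return traces.copy(), np.ones(traces.shape[1], dtype=bool)
    T = traces.shape[0]
    t = np.arange(T, dtype=np.float64)
    coef = np.polynomial.polynomial.polyfit(t, traces, order)
    f = np.polynomial.polynomial.polyval(t, coef).T  # (T, P)
    ok = np.all(f > 0, axis=0)
    s = np.ones_like(f)
    s[:, ok] = np.sqrt(f[:, ok] / f[0, ok])
    out = traces / s + np.where(ok, f[0], 0.0) * (1.0 - s)
    return out, ok


def _multitau_matrix(traces: np.ndarray, scheme: CorrelatorScheme) -> tuple[np.ndarray, np.ndarray]:
    """Multi-tau G for a (T, P) matrix; returns (lag_frames, G (L, P))."""
    work = np.asarray(traces, dtype=np.float64)
    T = work.shape[0]
    lag_list: list[int] = []
    g_list: list[np.ndarray] = []
    for b in range(scheme.q):
        if b > 0:
            n2 = work.shape[0] // 2
            if n2 == 0:
                break
            work = 0.5 * (work[: 2 * n2 : 2] + work[1 : 2 * n2 : 2])
        w = 2 ** b
        channels = range(1, scheme.p + 1) if b == 0 else range(scheme.p // 2 + 1, scheme.p + 1)
        n = work.shape[0]
        for ch in channels:
            if ch >= n:
                continue
            lag = ch * w
            if lag >= T:
                continue
            xa = work[:-ch]
            xb = work[ch:]
            ma = xa.mean(axis=0)
            mb = xb.mean(axis=0)
            denom = ma * mb
            with np.errstate(divide="ignore", invalid="ignore"):
                g = (xa * xb).mean(axis=0) / denom - 1.0
            lag_list.append(lag)
            g_list.append(g)
    order = np.argsort(lag_list, kind="stable")
    lags = np.array(lag_list, dtype=np.int64)[order]
    G = np.stack(g_list, axis=0)[order]
    return lags, G


def multitau_acf(
    trace: np.ndarray,
    scheme: CorrelatorScheme = CorrelatorScheme(),
    frame_time: float = 0.002,
    n_segments: int = 8,
) -> PixelACF:
    """Multi-tau ACF of one intensity trace with segment-based error bars.

    The per-lag standard deviation is the SD of the ACFs of ``n_segments``
    equal sub-traces divided by √n_segments.  A zero-variance trace raises
    :class:`DegenerateTraceError`.
    """
    trace = np.asarray(trace, dtype=np.float64)
    if trace.size < 2 * scheme.p:
        raise ValueError("trace shorter than 2·p frames")
    if np.ptp(trace) == 0:
        raise DegenerateTraceError("zero-variance trace")
    lags, G = _multitau_matrix(trace[:, None], scheme)
    G = G[:, 0]
    sd = _segment_sd(trace[:, None], scheme, lags, n_segments)[:, 0]
    return PixelACF(lags * frame_time, G, sd, float(trace.mean()))


def _segment_sd(traces: np.ndarray, scheme: CorrelatorScheme,
                lags: np.ndarray, n_segments: int) -> np.ndarray:
    T, P = traces.shape
    seg_len = T // n_segments
    segs = []
    if seg_len >= 2 * scheme.p:
        for s in range(n_segments):
            sl, sg = _multitau_matrix(traces[s * seg_len : (s + 1) * seg_len], scheme)
            # align on the full-trace lag grid
            aligned = np.full((len(lags), P), np.nan)
            idx = {int(v): i for i, v in enumerate(sl)}
            for i, v in enumerate(lags):
                j = idx.get(int(v))
                if j is not None:
                    aligned[i] = sg[j]
            segs.append(aligned)
    if not segs:
        return np.full((len(lags), P), np.nan)
    arr = np.stack(segs, axis=0)
    import warnings

    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sd = np.nanstd(arr, axis=0, ddof=1) / np.sqrt(len(segs))
    return sd


def direct_acf(trace: np.ndarray, lags_frames: np.ndarray) -> np.ndarray:
    """O(T·τ) direct-sum estimator with symmetric normalization.

    Independent oracle for the multi-tau correlator; returns G at the given
    integer frame lags.
    """
    trace = np.asarray(trace, dtype=np.float64)
    out = np.empty(len(lags_frames))
    for i, lag in enumerate(lags_frames):
        lag = int(lag)
        xa, xb = trace[:-lag], trace[lag:]
        out[i] = (xa * xb).mean() / (xa.mean() * xb.mean()) - 1.0
    return out


@dataclass
class ACFMap:
    """Per-pixel ACFs of a (possibly spatially binned) stack."""

    lags: np.ndarray  # seconds (L,)
    G: np.ndarray  # (L, H', W')
    sd: np.ndarray  # (L, H', W')
    mean_intensity: np.ndarray  # (H', W')
    valid: np.ndarray  # (H', W') bool
    frame_time: float = 0.002
    binning: int = 1

    @property
    def shape(self) -> tuple[int, int]:
        return self.G.shape[1:]

    def pixel(self, row: int, col: int) -> PixelACF:
        return PixelACF(self.lags, self.G[:, row, col], self.sd[:, row, col],
                        float(self.mean_intensity[row, col]), bool(self.valid[row, col]))


def acf_map(
    stack: ImageStack,
    scheme: CorrelatorScheme = CorrelatorScheme(),
    binning: int = 1,
    bleach_order: int = 8,
    lag_range: tuple[float, float] | None = None,
    n_segments: int = 8,
    background: float = 0.0,
) -> ACFMap:
    """Bleach-corrected multi-tau ACF for every (binned) pixel.

    ``background`` (camera offset counts per unbinned pixel) is subtracted
    from every trace before correlation so that the amplitude 1/N refers to
    the fluorescence signal, not signal + offset.  Per-pixel degeneracies
    (constant traces, failed bleach fits) are flagged in ``valid`` rather
    than raised.
    """
    if binning > 1:
        stack = bin_spatial(stack, binning, mode="sum")
    traces = stack.traces()  # (T, P)
    if background:
        traces = traces - background * binning * binning
    ptp = np.ptp(traces, axis=0)
    nondeg = ptp > 0
    corrected, ok = bleach_correct_matrix(traces, bleach_order)
    valid = nondeg & ok
    lags_f, G = _multitau_matrix(corrected, scheme)
    sd = _segment_sd(corrected, scheme, lags_f, n_segments)
    lags_s = lags_f * stack.frame_time
    H, W = stack.height, stack.width
    if lag_range is not None:
        lo, hi = lag_range
        keep = (lags_s >= lo) & (lags_s <= hi)
        lags_s, G, sd = lags_s[keep], G[keep], sd[keep]
    G[:, ~valid.reshape(-1)] = np.nan
    return ACFMap(
        lags=lags_s,
        G=G.reshape(len(lags_s), H, W),
        sd=sd.reshape(len(lags_s), H, W),
        mean_intensity=traces.mean(axis=0).reshape(H, W),
        valid=valid.reshape(H, W),
        frame_time=stack.frame_time,
        binning=stack.geometry.binning if stack.geometry else binning,
    )
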