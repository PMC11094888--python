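"""The 22 canonical time-series characteristics (catch22).

Pure NumPy/SciPy re-implementation of the published catch22 feature set.
Every feature z-scores its input internally, matching the reference C
implementation, so raw radiomic feature series can be passed directly.

Features that are mathematically undefined for a given input (constant
series, or series shorter than an algorithm's minimum support) return NaN
rather than raising.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import LSQUnivariateSpline

__all__ = ["CATCH22_NAMES", "catch22_all", "catch22_single"]

CATCH22_NAMES = [
    "DN_HistogramMode_5",
    "DN_HistogramMode_10",
    "CO_f1ecac",
    "CO_FirstMin_ac",
    "CO_HistogramAMI_even_2_5",
    "CO_trev_1_num",
    "MD_hrv_classic_pnn40",
    "SB_BinaryStats_mean_longstretch1",
    "SB_TransitionMatrix_3ac_sumdiagcov",
    "PD_PeriodicityWang_th0_01",
    "CO_Embed2_Dist_tau_d_expfit_meandiff",
    "IN_AutoMutualInfoStats_40_gaussian_fmmi",
    "FC_LocalSimple_mean1_tauresrat",
    "DN_OutlierInclude_p_001_mdrmd",
    "DN_OutlierInclude_n_001_mdrmd",
    "SP_Summaries_welch_rect_area_5_1",
    "SB_BinaryStats_diff_longstretch0",
    "SB_MotifThree_quantile_hh",
    "SC_FluctAnal_2_rsrangefit_50_1_logi_prop_r1",
    "SC_FluctAnal_2_dfa_50_1_2_logi_prop_r1",
    "SP_Summaries_welch_rect_centroid",
    "FC_LocalSimple_mean3_stderr",
]


# ---------------------------------------------------------------- helpers

def _zscore(x: np.ndarray) -> np.ndarray:
    mu = x.mean()
    sd = x.std(ddof=1)
    return (x - mu) / sd


def _autocorr(y: np.ndarray) -> np.ndarray:
    """Full autocorrelation function, lag 0..n-1, biased normalisation."""
    n = y.size
    m = y - y.mean()
    nfft = int(2 ** np.ceil(np.log2(2 * n - 1)))
    f = np.fft.rfft(m, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n]
    if acov[0] == 0:
        return np.full(n, np.nan)
    return acov / acov[0]

def _first_zero_ac(ac: np.ndarray) -> int:
    """First lag at which the ACF drops to or below zero."""
    n = ac.size
    for i in range(1, n):
        if ac[i] <= 0:
            return i
    return n


# ---------------------------------------------------------------- features

def _histogram_mode(y: np.ndarray, n_bins: int) -> float:
    counts, edges = np.histogram(y, bins=n_bins)
    centers = (edges[:-1] + edges[1:]) / 2
    return float(centers[counts == counts.max()].mean())


def DN_HistogramMode_5(y, ac):
    return _histogram_mode(y, 5)


def DN_HistogramMode_10(y, ac):
    return _histogram_mode(y, 10)


def CO_f1ecac(y, ac):
    n = y.size
    thresh = 1.0 / np.e
    for i in range(1, n):
        if ac[i] < thresh:
            # linear interpolation between lags i-1 and i
            return float(i - 1 + (thresh - ac[i - 1]) / (ac[i] - ac[i - 1]))
    return float(n)


def CO_FirstMin_ac(y, ac):
    n = y.size
    for i in range(1, n - 1):
        if ac[i] < ac[i - 1] and ac[i] < ac[i + 1]:
            return float(i)
    return float(n)


def CO_HistogramAMI_even_2_5(y, ac, tau=2, n_bins=5):
    n = y.size
    if n <= tau:
        return np.nan
    lo, hi = y.min() - 0.1, y.max() + 0.1
    edges = np.linspace(lo, hi, n_bins + 1)
    b1 = np.digitize(y[: n - tau], edges) - 1
    b2 = np.digitize(y[tau:], edges) - 1
    joint = np.zeros((n_bins, n_bins))
    np.add.at(joint, (b1, b2), 1.0)
    joint /= joint.sum()
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    mask = joint > 0
    return float(np.sum(joint[mask] * np.log(joint[mask] / np.outer(px, py)[mask])))


def CO_trev_1_num(y, ac):
    d = np.diff(y)
    return float(np.mean(d ** 3))


def MD_hrv_classic_pnn40(y, ac):
    d = np.abs(np.diff(y)) * 1000
    return float(np.mean(d > 40))


def _longest_stretch(b: np.ndarray, target: int, end_idx: int, best: int) -> float:
    # Change-point scan replicating the reference implementation's counting:
    # interior stretches include the preceding boundary sample; the final
    # truncated stretch (at end_idx) does not.
    last = 0
    for i in range(min(end_idx, b.size - 1) + 1):
        change = i + 1 < b.size and b[i + 1] != b[i]
        if change or i == end_idx:
            if b[i] == target:
                best = max(best, i - last + (1 if (change and i != end_idx) else 0))
            if change:
                last = i
    return float(best)


def SB_BinaryStats_mean_longstretch1(y, ac):
    if y.size < 2:
        return 0.0
    return _longest_stretch((y > 0).astype(int), 1, y.size - 2, 1)


def SB_BinaryStats_diff_longstretch0(y, ac):
    if y.size < 3:
        return 0.0
    return _longest_stretch((np.diff(y) >= 0).astype(int), 0, y.size - 2, 1)


def _tercile_cuts(v: np.ndarray):
    """Tercile cut points with midpoint-interpolated quantiles."""
    s = np.sort(v)
    m = s.size
    out = []
    for p in (1 / 3, 2 / 3):
        idx = p * m - 0.5
        lo = max(int(np.floor(idx)), 0)
        hi = min(int(np.ceil(idx)), m - 1)
        frac = idx - np.floor(idx)
        out.append(s[lo] * (1 - frac) + s[hi] * frac)
    return np.asarray(out)


def SB_TransitionMatrix_3ac_sumdiagcov(y, ac):
    tau = _first_zero_ac(ac)
    yd = y[::tau]
    nd = yd.size
    if nd < 2:
        return np.nan
    sym = np.digitize(yd, _tercile_cuts(yd))
    T = np.zeros((3, 3))
    np.add.at(T, (sym[:-1], sym[1:]), 1.0)
    T /= (nd - 1)
    cov = np.cov(T.T)  # covariance between the matrix columns
    return float(np.trace(cov))


def PD_PeriodicityWang_th0_01(y, ac):
    n = y.size
    th = 0.01
    if int(np.ceil(n / 3)) < 3:
        return 0.0  # no interior lag can qualify as a peak
    x = np.arange(n, dtype=float)
    try:
        spl = LSQUnivariateSpline(x, y, t=[(n - 1) / 2.0], k=3)
        v = y - spl(x)
    except Exception:
        return np.nan
    max_tau = int(np.ceil(n / 3))
    denom = np.dot(v, v)
    if denom == 0:
        return 0.0
    acf = np.array([np.dot(v[: n - t], v[t:]) for t in range(max_tau + 1)]) / denom
    # first acceptable peak after a trough, both at lag >= 2
    trough = -1
    for i in range(2, acf.size - 1):
        slope_in = acf[i] - acf[i - 1]
        slope_out = acf[i + 1] - acf[i]
        if slope_in < 0 and slope_out > 0:
            trough = i
        elif slope_in > 0 and slope_out < 0 and trough > 0:
            if acf[i] > 0 and acf[i] - acf[trough] >= th:
                return float(i - 1)
    return 0.0


def CO_Embed2_Dist_tau_d_expfit_meandiff(y, ac):
    n = y.size
    tau = _first_zero_ac(ac)
    if tau > n / 10:
        tau = n // 10  # may degenerate to 0 for very short series
    m = n - tau
    d = np.sqrt(np.diff(y[:m]) ** 2 + np.diff(y[tau:]) ** 2)
    if d.size < 2 or not np.all(np.isfinite(d)):
        return np.nan
    l = d.mean()
    if l == 0:
        return np.nan
    # Scott-rule bin count; compare bin probabilities against the fitted
    # exponential density evaluated at bin centres.
    bw = 3.5 * d.std(ddof=1) / d.size ** (1 / 3)
    rng_d = d.max() - d.min()
    n_bins = max(1, int(np.ceil(rng_d / bw))) if bw > 0 else 1
    counts, edges = np.histogram(d, bins=n_bins)
    prob = counts / d.size
    centers = (edges[:-1] + edges[1:]) / 2
    expf = np.exp(-centers / l) / l
    return float(np.mean(np.abs(prob - expf)))


def IN_AutoMutualInfoStats_40_gaussian_fmmi(y, ac):
    n = y.size
    max_tau = min(40, int(np.ceil(n / 2)))
    # per-lag Pearson correlation (each lag re-centred on its own segments)
    r = np.empty(max_tau)
    for t in range(1, max_tau + 1):
        a, b = y[: n - t], y[t:]
        with np.errstate(invalid="ignore"):
            r[t - 1] = np.corrcoef(a, b)[0, 1]
    r2 = np.clip(r, -0.999999999, 0.999999999) ** 2
    ami = -0.5 * np.log(1 - r2)
    for i in range(1, ami.size - 1):
        if ami[i] < ami[i - 1] and ami[i] < ami[i + 1]:
            return float(i)
    return float(ami.size)


def FC_LocalSimple_mean1_tauresrat(y, ac):
    res = y[1:] - y[:-1]
    ac_res = _autocorr(res)
    return float(_first_zero_ac(ac_res) / _first_zero_ac(ac))


def FC_LocalSimple_mean3_stderr(y, ac):
    train = 3
    n = y.size
    if n <= train + 1:
        return np.nan
    means = np.convolve(y, np.ones(train) / train, mode="valid")[:-1]
    res = y[train:] - means
    return float(res.std(ddof=1))


def _outlier_include_mdrmd(y: np.ndarray) -> float:
    n = y.size
    inc = 0.01
    if y.max() < inc:
        return 0.0
    n_thresh = int(y.max() / inc) + 1
    thresholds = np.arange(n_thresh) * inc
    asc = np.sort(y)
    cnt = n - np.searchsorted(asc, thresholds, side="left")
    # positions (1-based) of the top-c values, largest first; ties share
    # identical values so their relative order never affects inclusion
    order = np.argsort(-y, kind="stable") + 1
    med_by_count = {}
    msdti4 = np.zeros(n_thresh)
    for j, c in enumerate(cnt):
        if c > 0:
            if c not in med_by_count:
                med_by_count[c] = np.median(order[:c]) / (n / 2) - 1
            msdti4[j] = med_by_count[c]
    # trim where the event rate falls below 2% of the above-zero count
    c0 = cnt[0]
    if c0 == 0:
        return 0.0
    rate = (cnt - 1) * 100.0 / c0
    keep = np.flatnonzero(rate > 2)
    lim = keep[-1] if keep.size else 0
    return float(np.median(msdti4[: lim + 1]))


def DN_OutlierInclude_p_001_mdrmd(y, ac):
    return _outlier_include_mdrmd(y)


def DN_OutlierInclude_n_001_mdrmd(y, ac):
    return _outlier_include_mdrmd(-y)


def _welch_rect(y: np.ndarray):
    """One-sided PSD over angular frequency, rectangular window.

    DC and Nyquist bins carry half weight, as in a proper one-sided
    periodogram.
    """
    n = y.size
    nfft = int(2 ** np.ceil(np.log2(n)))
    s = np.abs(np.fft.rfft(y, nfft)) ** 2 / n / np.pi
    s[0] /= 2
    s[-1] /= 2
    w = np.linspace(0, np.pi, s.size)
    return w, s


def SP_Summaries_welch_rect_area_5_1(y, ac):
    w, s = _welch_rect(y)
    dw = w[1] - w[0]
    return float(np.sum(s[: s.size // 5]) * dw)


def SP_Summaries_welch_rect_centroid(y, ac):
    w, s = _welch_rect(y)
    csum = np.cumsum(s)
    half = csum[-1] / 2
    idx = np.flatnonzero(csum > half)
    if idx.size == 0:
        return np.nan
    return float(w[idx[0]])


def SB_MotifThree_quantile_hh(y, ac):
    n = y.size
    idx = np.argsort(y, kind="stable")
    sym = np.empty(n, dtype=int)
    bounds = np.round(np.linspace(0, n, 4)).astype(int)
    for s in range(3):
        sym[idx[bounds[s]:bounds[s + 1]]] = s
    joint = np.zeros((3, 3))
    np.add.at(joint, (sym[:-1], sym[1:]), 1.0)
    joint /= joint.sum()
    mask = joint > 0
    return float(-np.sum(joint[mask] * np.log(joint[mask])))


def _fluct_anal(y: np.ndarray, how: str, lag: int) -> float:
    """Two-regime scaling split of a fluctuation function.

    Fits the log-log fluctuation curve with two straight lines joined at
    every candidate scale (segments share the joint point) and reports the
    proportion of scales left of the best split, where the objective is
    the sum of the two residual 2-norms.
    """
    size = y.size
    if size < 10:
        return 0.0
    tau = np.unique(np.round(np.exp(np.linspace(np.log(5), np.log(size // 2), 50))).astype(int))
    ntt = tau.size
    if ntt < 12:
        return 0.0  # too few scales for a two-regime fit
    scs = size // lag
    cs = np.cumsum(y[::lag][:scs])
    F = np.empty(ntt)
    for k, t in enumerate(tau):
        n_buf = scs // t
        if n_buf == 0:
            return np.nan
        x = np.arange(1, t + 1, dtype=float)
        tot = 0.0
        for b in range(n_buf):
            seg = cs[b * t:(b + 1) * t]
            A = np.polyfit(x, seg, 1)
            resid = seg - (A[0] * x + A[1])
            if how == "dfa":
                tot += np.sum(resid ** 2)
            else:  # rsrangefit
                tot += (resid.max() - resid.min()) ** 2
        F[k] = np.sqrt(tot / (n_buf * t)) if how == "dfa" else np.sqrt(tot / n_buf)
    logtt = np.log(tau)
    logff = np.log(F)
    min_points = 6
    best = np.inf
    best_i = min_points
    for i in range(min_points, ntt - min_points + 1):
        obj = 0.0
        for sl in (slice(0, i), slice(i - 1, ntt)):
            a = np.polyfit(logtt[sl], logff[sl], 1)
            obj += np.sqrt(np.sum((logff[sl] - np.polyval(a, logtt[sl])) ** 2))
        if obj < best:
            best = obj
            best_i = i
    return float(best_i / ntt)


def SC_FluctAnal_2_dfa_50_1_2_logi_prop_r1(y, ac):
    return _fluct_anal(y, "dfa", lag=2)


def SC_FluctAnal_2_rsrangefit_50_1_logi_prop_r1(y, ac):
    return _fluct_anal(y, "rsrangefit", lag=1)


_FEATURES = [
    DN_HistogramMode_5,
    DN_HistogramMode_10,
    CO_f1ecac,
    CO_FirstMin_ac,
    CO_HistogramAMI_even_2_5,
    CO_trev_1_num,
    MD_hrv_classic_pnn40,
    SB_BinaryStats_mean_longstretch1,
    SB_TransitionMatrix_3ac_sumdiagcov,
    PD_PeriodicityWang_th0_01,
    CO_Embed2_Dist_tau_d_expfit_meandiff,
    IN_AutoMutualInfoStats_40_gaussian_fmmi,
    FC_LocalSimple_mean1_tauresrat,
    DN_OutlierInclude_p_001_mdrmd,
    DN_OutlierInclude_n_001_mdrmd,
    SP_Summaries_welch_rect_area_5_1,
    SB_BinaryStats_diff_longstretch0,
    SB_MotifThree_quantile_hh,
    SC_FluctAnal_2_rsrangefit_50_1_logi_prop_r1,
    SC_FluctAnal_2_dfa_50_1_2_logi_prop_r1,
    SP_Summaries_welch_rect_centroid,
    FC_LocalSimple_mean3_stderr,
]


def catch22_all(series) -> dict[str, float]:
    """Compute all 22 characteristics for one series.

    Returns a dict keyed by the canonical feature names. Constant series
    yield NaN for every characteristic (z-normalisation is undefined).
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("series must be 1-D with length >= 2")
    if not np.all(np.isfinite(x)) or x.std(ddof=1) == 0:
        return {name: np.nan for name in CATCH22_NAMES}
    y = _zscore(x)
    ac = _autocorr(y)
    out = {}
    for name, fn in zip(CATCH22_NAMES, _FEATURES):
        try:
            with np.errstate(all="ignore"):
                out[name] = float(fn(y, ac))
        except Exception:
            out[name] = np.nan
    return out


def catch22_single(series, name: str) -> float:
    return catch22_all(series)[name]
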