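"""Independent brute-force oracles used by the test suite.

These deliberately use naive per-segment loops and direct formula
evaluation, sharing no code path with the package implementation.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import get_window
from scipy.stats import t as t_dist


def welch_cross_spectra_brute(
    data: np.ndarray,
    fs: float,
    nperseg: int,
    overlap: float = 0.5,
    window: str = "hann",
    detrend: str = "constant",
) -> tuple[np.ndarray, np.ndarray]:
    """Per-segment DFTs, conjugate products averaged with explicit loops.

    Returns (freqs, S) with S shape (n_ch, n_ch, n_freq), one-sided
    density scaling.
    """
    n_ch, n_samples = data.shape
    step = nperseg - int(round(overlap * nperseg))
    starts = list(range(0, n_samples - nperseg + 1, step))
    win = get_window(window, nperseg, fftbins=True)
    n_freq = nperseg // 2 + 1
    S = np.zeros((n_ch, n_ch, n_freq), dtype=complex)
    for s0 in starts:
        Z = []
        for c in range(n_ch):
            seg = data[c, s0 : s0 + nperseg].astype(float)
            if detrend == "constant":
                seg = seg - seg.mean()
            Z.append(np.fft.rfft(seg * win))
        for a in range(n_ch):
            for b in range(n_ch):
                S[a, b] += Z[a] * np.conj(Z[b])
    S /= len(starts)
    S /= fs * np.sum(win**2)
    S[..., 1:] *= 2.0
    if nperseg % 2 == 0:
        S[..., -1] /= 2.0
    return np.fft.rfftfreq(nperseg, 1.0 / fs), S


def imaginary_coherence_brute(S: np.ndarray) -> np.ndarray:
    """|Im coherency| per bin with explicit loops; diagonal zero."""
    n_ch, _, n_freq = S.shape
    ic = np.zeros((n_ch, n_ch, n_freq))
    for a in range(n_ch):
        for b in range(n_ch):
            if a == b:
                continue
            for k in range(n_freq):
                denom = np.sqrt(S[a, a, k].real * S[b, b, k].real)
                ic[a, b, k] = abs((S[a, b, k] / denom).imag) if denom > 0 else np.nan
    return np.minimum(ic, 1.0)


def band_mean_brute(ic: np.ndarray, freqs: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Arithmetic mean over bins with lo <= f <= hi, NaNs excluded."""
    n_ch = ic.shape[0]
    out = np.zeros((n_ch, n_ch))
    for a in range(n_ch):
        for b in range(n_ch):
            if a == b:
                continue
            vals = [
                ic[a, b, k]
                for k in range(len(freqs))
                if lo <= freqs[k] <= hi and np.isfinite(ic[a, b, k])
            ]
            out[a, b] = sum(vals) / len(vals)
    return out


def bh_adjust_brute(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p, direct formula."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, m * p[i] / rank)
        adjusted[i] = min(running_min, 1.0)
    return adjusted


def pooled_ttest_brute(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Student pooled-variance t and two-sided p from the closed formula."""
    na, nb = len(a), len(b)
    ma, mb = np.mean(a), np.mean(b)
    sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
    t = (ma - mb) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    df = na + nb - 2
    p = 2.0 * t_dist.sf(abs(t), df)
    return float(t), float(p)


def auc_pairs_brute(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC by exhaustive positive-negative pair counting, ties 1/2."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))
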