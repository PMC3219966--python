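"""Exact sliding-window median and MAD.

The rank-expectation statistic needs, for every position of a re-ranked
signal, the median and the median absolute deviation (MAD) of a large
centred window (default 10,001 bins, truncated at the array ends).  No
installed library computes an exact sliding median+MAD pair at this scale,
so this kernel maintains a sorted window buffer incrementally (binary-search
insert/delete) and extracts the MAD by an outward two-pointer walk from the
median, which selects the k-th smallest absolute deviation without
materialising the deviation array.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def _rolling_median_mad(x: np.ndarray, half: int):  # pragma: no cover - numba
    n = x.shape[0]
    med = np.empty(n)
    mad = np.empty(n)
    wmax = 2 * half + 1
    if wmax > n:
        wmax = n
    buf = np.empty(wmax)
    cnt = 0
    lo = 0
    hi = 0
    for i in range(n):
        new_hi = i + half + 1
        if new_hi > n:
            new_hi = n
        while hi < new_hi:
            v = x[hi]
            a, b = 0, cnt
            while a < b:  # bisect_right
                m2 = (a + b) >> 1
                if buf[m2] <= v:
                    a = m2 + 1
                else:
                    b = m2
            for k in range(cnt, a, -1):
                buf[k] = buf[k - 1]
            buf[a] = v
            cnt += 1
            hi += 1
        new_lo = i - half
        if new_lo < 0:
            new_lo = 0
        while lo < new_lo:
            v = x[lo]
            a, b = 0, cnt
            while a < b:  # bisect_left
                m2 = (a + b) >> 1
                if buf[m2] < v:
                    a = m2 + 1
                else:
                    b = m2
            for k in range(a, cnt - 1):
                buf[k] = buf[k + 1]
            cnt -= 1
            lo += 1
        if cnt & 1:
            m = buf[cnt >> 1]
        else:
            m = 0.5 * (buf[(cnt >> 1) - 1] + buf[cnt >> 1])
        med[i] = m
        # MAD: the median of |buf[j] - m| found by walking outward from m.
        a, b = 0, cnt
        while a < b:  # first index with buf[idx] >= m
            m2 = (a + b) >> 1
            if buf[m2] < m:
                a = m2 + 1
            else:
                b = m2
        r = a
        l = a - 1
        if cnt & 1:
            k1 = cnt >> 1
            k2 = k1
        else:
            k1 = (cnt >> 1) - 1
            k2 = cnt >> 1
        taken = 0
        d1 = 0.0
        d2 = 0.0
        while taken <= k2:
            dl = m - buf[l] if l >= 0 else np.inf
            dr = buf[r] - m if r < cnt else np.inf
            if dl <= dr:
                d = dl
                l -= 1
            else:
                d = dr
                r += 1
            if taken == k1:
                d1 = d
            if taken == k2:
                d2 = d
            taken += 1
        mad[i] = 0.5 * (d1 + d2)
    return med, mad


def rolling_median_mad(x: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    """Centred sliding median and MAD with window truncation at both ends.

    ``window`` must be odd.  Returns ``(median, mad)`` arrays of the same
    length as ``x``.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    x = np.ascontiguousarray(x, dtype=np.float64)
    if x.size == 0:
        return np.empty(0), np.empty(0)
    return _rolling_median_mad(x, window // 2)
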