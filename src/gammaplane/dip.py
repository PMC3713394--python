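"""Hartigan's dip test of unimodality.

The dip statistic is the maximum distance between the empirical CDF and
the closest unimodal CDF, computed by the classic iterative algorithm:
alternate between the greatest convex minorant (GCM) of the empirical CDF
left of a candidate modal interval and the least concave majorant (LCM)
right of it, shrinking the modal interval until the fit stops improving.
The p-value is calibrated by Monte Carlo against samples of the same size
from the uniform distribution, the asymptotically least-favourable
unimodal null.

Implementation notes: the statistic works on the sorted sample with CDF
values in counts (i / n); all internal distances are therefore integers
plus linear interpolation terms, and the final dip is the accumulated
maximum divided by 2n.  The smallest attainable dip is 1 / (2n).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

__all__ = ["dip_statistic", "dip_test", "InsufficientDataError"]

MIN_SAMPLES = 10


class InsufficientDataError(ValueError):
    """Too few samples for a meaningful dip test."""


def dip_statistic(samples) -> float:
    """Dip statistic of a 1-D sample (sorted internally).

    Returns the sup-norm distance between the empirical CDF and the
    nearest unimodal CDF; always >= 1/(2n), with equality for samples
    that are exactly uniform-spaced.
    """
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if n < 1:
        raise ValueError("empty sample")
    if n == 1:
        return 0.0
    if n <= 3 or x[0] == x[-1]:
        return 1.0 / (2.0 * n)

    # mn[j]: previous touch point of the GCM through (x_i, i); mj[k]: next
    # touch point of the LCM.  Pure index bookkeeping, 1-based like the
    # original published algorithm, shifted to 0-based here.
    mn = np.zeros(n, dtype=np.int64)
    for j in range(1, n):
        mn[j] = j - 1
        while True:
            mnj = mn[j]
            mnmnj = mn[mnj]
            if mnj == 0 or (x[j] - x[mnj]) * (mnj - mnmnj) < (x[mnj] - x[mnmnj]) * (j - mnj):
                break
            mn[j] = mnmnj

    mj = np.zeros(n, dtype=np.int64)
    mj[n - 1] = n - 1
    for k in range(n - 2, -1, -1):
        mj[k] = k + 1
        while True:
            mjk = mj[k]
            mjmjk = mj[mjk]
            if mjk == n - 1 or (x[k] - x[mjk]) * (mjk - mjmjk) < (x[mjk] - x[mjmjk]) * (k - mjk):
                break
            mj[k] = mjmjk

    low, high = 0, n - 1
    dip = 1.0  # in count units; divided by 2n on return

    while True:
        # GCM touch points from high down to low; LCM from low up to high.
        gcm = [high]
        while gcm[-1] > low:
            gcm.append(int(mn[gcm[-1]]))
        l_gcm = len(gcm)
        ig = l_gcm - 1

        lcm = [low]
        while lcm[-1] < high:
            lcm.append(int(mj[lcm[-1]]))
        l_lcm = len(lcm)
        ih = l_lcm - 1

        # Largest vertical distance between the GCM and the LCM over the
        # current interval, tracked at curve touch points.
        ix, iv = l_gcm - 2, 1
        d = 0.0
        if l_gcm != 2 or l_lcm != 2:
            while True:
                gcmix, lcmiv = gcm[ix], lcm[iv]
                if gcmix > lcmiv:
                    gcmi1 = gcm[ix + 1]
                    dx = (lcmiv - gcmi1 + 1) - (x[lcmiv] - x[gcmi1]) * (gcmix - gcmi1) / (
                        x[gcmix] - x[gcmi1]
                    )
                    iv += 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv - 1
                else:
                    lcmiv1 = lcm[iv - 1]
                    dx = (x[gcmix] - x[lcmiv1]) * (lcmiv - lcmiv1) / (x[lcmiv] - x[lcmiv1]) - (
                        gcmix - lcmiv1 - 1
                    )
                    ix -= 1
                    if dx > d:
                        d = dx
                        ig = ix + 1
                        ih = iv
                if ix < 0:
                    ix = 0
                if iv > l_lcm - 1:
                    iv = l_lcm - 1
                if gcm[ix] == lcm[iv]:
                    break
        else:
            d = 1.0

        if d <= dip:
            break

        # Max deviation of the empirical CDF below the GCM on the left
        # flank and above the LCM on the right flank of the new modal
        # interval.
        dip_l = 0.0
        for j in range(ig, l_gcm - 1):
            jb, je = gcm[j + 1], gcm[j]
            max_t = 1.0
            if je - jb > 1 and x[je] != x[jb]:
                c = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    t = (jj - jb + 1) - (x[jj] - x[jb]) * c
                    if t > max_t:
                        max_t = t
            if max_t > dip_l:
                dip_l = max_t

        dip_u = 0.0
        for j in range(ih, l_lcm - 1):
            jb, je = lcm[j], lcm[j + 1]
            max_t = 1.0
            if je - jb > 1 and x[je] != x[jb]:
                c = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    t = (x[jj] - x[jb]) * c - (jj - jb - 1)
                    if t > max_t:
                        max_t = t
            if max_t > dip_u:
                dip_u = max_t

        dipnew = max(dip_l, dip_u)
        if dipnew > dip:
            dip = dipnew
        low, high = gcm[ig], lcm[ih]

    return dip / (2.0 * n)


@lru_cache(maxsize=64)
def _null_dips(n: int, n_boot: int, seed: int) -> tuple[float, ...]:
    """Sorted dip statistics of n_boot uniform samples of size n."""
    rng = np.random.default_rng(seed)
    dips = np.empty(n_boot)
    for i in range(n_boot):
        dips[i] = dip_statistic(rng.random(n))
    dips.sort()
    return tuple(dips)


def dip_test(samples, n_boot: int = 500, seed: int = 0) -> tuple[float, float]:
    """Dip statistic and bootstrap p-value against the uniform null.

    p = (1 + #{null dips >= observed}) / (1 + n_boot); small p rejects
    unimodality.  Null replicates are cached per (n, n_boot, seed), so
    repeated tests at one sample size pay the Monte Carlo cost once.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < MIN_SAMPLES:
        raise InsufficientDataError(
            f"dip test needs >= {MIN_SAMPLES} samples, got {x.size}"
        )
    d = dip_statistic(x)
    null = np.asarray(_null_dips(int(x.size), int(n_boot), int(seed)))
    n_ge = int(np.sum(null >= d))
    p = (1.0 + n_ge) / (1.0 + n_boot)
    return d, float(p)
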