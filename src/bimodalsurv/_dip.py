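"""Hartigan's dip statistic and its Monte-Carlo null distribution.

The dip measures how far a sample's empirical CDF is from the nearest
unimodal CDF in sup norm.  It is computed by the classical alternating-fit
algorithm: fit the greatest convex minorant (GCM) and least concave majorant
(LCM) of the ECDF over a shrinking candidate modal interval, track the
largest GCM/LCM separation, and accumulate the deviations of the ECDF from
the two hulls outside the modal interval.  All bookkeeping is done on the
count scale; the final statistic is the maximal deviation divided by 2n, so
a perfectly unimodal-looking sample of n distinct points attains the lower
bound 1/(2n) and two equal point masses attain the upper bound 1/4.

The null distribution (sample of size n from any continuous unimodal
distribution is asymptotically hardest for the uniform) is estimated by
Monte Carlo on Uniform(0,1) samples; :class:`DipNullDistribution` caches the
simulated null dips so a whole expression matrix screened at a common sample
size pays for the simulation once.
"""

from __future__ import annotations

import numpy as np

__all__ = ["dip_statistic", "dip_pvalue", "DipNullDistribution"]


def _gcm_pointers(x: np.ndarray) -> np.ndarray:
    """mn[j] = previous touch point of the greatest convex minorant at j."""
    n = x.size
    mn = np.zeros(n, dtype=np.intp)
    for j in range(1, n):
        mn[j] = j - 1
        while True:
            mnj = mn[j]
            mnmnj = mn[mnj]
            if mnj == 0 or (x[j] - x[mnj]) * (mnj - mnmnj) < (x[mnj] - x[mnmnj]) * (
                j - mnj
            ):
                break
            mn[j] = mnmnj
    return mn


def _lcm_pointers(x: np.ndarray) -> np.ndarray:
    """mj[k] = next touch point of the least concave majorant at k."""
    n = x.size
    mj = np.zeros(n, dtype=np.intp)
    mj[n - 1] = n - 1
    for k in range(n - 2, -1, -1):
        mj[k] = k + 1
        while True:
            mjk = mj[k]
            mjmjk = mj[mjk]
            if mjk == n - 1 or (x[k] - x[mjk]) * (mjk - mjmjk) < (
                x[mjk] - x[mjmjk]
            ) * (k - mjk):
                break
            mj[k] = mjmjk
    return mj


def _dip_sorted(x: np.ndarray) -> float:
    """Dip of an already-sorted 1-d float array (no validation)."""
    n = x.size
    low, high = 0, n - 1
    dip = 1.0  # count scale; lower bound 1/(2n) after final scaling

    mn = _gcm_pointers(x)
    mj = _lcm_pointers(x)

    while True:
        # change points of the GCM from high down to low, and LCM from low up
        gcm = [high]
        while gcm[-1] > low:
            gcm.append(mn[gcm[-1]])
        l_gcm = len(gcm)
        lcm = [low]
        while lcm[-1] < high:
            lcm.append(mj[lcm[-1]])
        l_lcm = len(lcm)

        # largest separation between the two hulls inside [low, high]
        ig, ih = l_gcm - 1, 1
        ix, iv = l_gcm - 2, 1
        d = 0.0
        if l_gcm != 2 or l_lcm != 2:
            while True:
                gcmix = gcm[ix]
                lcmiv = lcm[iv]
                if gcmix > lcmiv:
                    # next hull point comes from the LCM: ECDF vs GCM chord
                    gcmi1 = gcm[ix + 1]
                    dx = (lcmiv - gcmi1 + 1) - (x[lcmiv] - x[gcmi1]) * (
                        gcmix - gcmi1
                    ) / (x[gcmix] - x[gcmi1])
                    iv += 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv - 1
                else:
                    # next hull point comes from the GCM: LCM chord vs ECDF
                    lcmiv1 = lcm[iv - 1]
                    dx = (x[gcmix] - x[lcmiv1]) * (lcmiv - lcmiv1) / (
                        x[lcmiv] - x[lcmiv1]
                    ) - (gcmix - lcmiv1 - 1)
                    ix -= 1
                    if dx >= d:
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
        if d < dip:
            break

        # deviation of the ECDF below the GCM over the left flank
        dip_l = 0.0
        for j in range(ig, l_gcm - 1):
            max_t = 1.0
            jj, jjj = gcm[j], gcm[j + 1]
            if jj > jjj + 1:
                dxh = x[jj] - x[jjj]
                for jk in range(jjj + 1, jj):
                    t = (jk - jjj + 1) - (x[jk] - x[jjj]) * (jj - jjj) / dxh
                    if max_t < t:
                        max_t = t
            if dip_l < max_t:
                dip_l = max_t

        # deviation of the ECDF above the LCM over the right flank
        dip_u = 0.0
        for j in range(ih, l_lcm - 1):
            max_t = 1.0
            jj, jjj = lcm[j], lcm[j + 1]
            if jjj > jj + 1:
                dxh = x[jjj] - x[jj]
                for jk in range(jj + 1, jjj):
                    t = (x[jk] - x[jj]) * (jjj - jj) / dxh - (jk - jj - 1)
                    if max_t < t:
                        max_t = t
            if dip_u < max_t:
                dip_u = max_t

        dipnew = max(dip_l, dip_u)
        if dip < dipnew:
            dip = dipnew
        if low == gcm[ig] and high == lcm[ih]:
            break
        low = gcm[ig]
        high = lcm[ih]

    return dip / (2.0 * n)


def dip_statistic(x) -> float:
    """Hartigan & Hartigan's dip statistic of a 1-d sample.

    Parameters
    ----------
    x : array_like
        Sample values; at least 4 finite observations, not all identical.
        A sorted copy is taken internally.

    Returns
    -------
    float
        The dip, in (0, 0.25].
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 4:
        raise ValueError(f"dip statistic needs n >= 4 observations, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("dip statistic requires finite values")
    x = np.sort(x)
    if x[0] == x[-1]:
        raise ValueError("degenerate sample: all values identical")
    return _dip_sorted(x)


class DipNullDistribution:
    """Monte-Carlo dip null distribution for samples of size ``n``.

    Simulates ``n_boot`` dips of Uniform(0,1) samples of size ``n`` — the
    standard reference null for the dip test — once, and converts observed
    dips to p-values via the add-one Monte-Carlo rule
    ``p = (1 + #{null >= observed}) / (n_boot + 1)``.
    """

    def __init__(self, n: int, n_boot: int = 2000, rng=None):
        if n < 4:
            raise ValueError("dip null distribution needs n >= 4")
        if n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        rng = np.random.default_rng(rng)
        self.n = int(n)
        self.n_boot = int(n_boot)
        null = np.empty(self.n_boot)
        for b in range(self.n_boot):
            u = np.sort(rng.random(self.n))
            null[b] = _dip_sorted(u)
        self.null_dips = np.sort(null)

    def pvalue(self, dip: float) -> float:
        n_ge = self.n_boot - np.searchsorted(self.null_dips, dip, side="left")
        return (1.0 + n_ge) / (self.n_boot + 1.0)


def dip_pvalue(dip: float, n: int, n_boot: int = 2000, rng=None) -> float:
    """Monte-Carlo p-value of an observed dip at sample size ``n``.

    For screening many samples of the same size, build one
    :class:`DipNullDistribution` and reuse it instead.
    """
    return DipNullDistribution(n, n_boot=n_boot, rng=rng).pvalue(dip)
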