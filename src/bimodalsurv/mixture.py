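"""Two-component univariate normal mixture fitted by EM.

This is the parametric half of the bimodality screen: genes flagged as
non-unimodal by the dip test are fitted with a mixture

    f(x) = w1 * N(x; mu1, sigma1^2) + (1 - w1) * N(x; mu2, sigma2^2)

whose parameters feed the bimodal score |mu1 - mu2| / max(sigma1, sigma2).
The fit uses plain EM with a deterministic moment-based first start (split
at the sample median) plus random-responsibility restarts, a variance floor
to keep the likelihood bounded, and canonical ordering mu1 <= mu2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TwoComponentNormalMixture", "NormalMixtureResults", "fit_two_component_mixture"]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class NormalMixtureResults:
    """Converged (or best-effort) parameters of a two-component normal mixture.

    Components are ordered so that ``mu1 <= mu2``; weights sum to one and
    both standard deviations respect the variance floor used in the fit.
    ``loglik_path`` holds the per-iteration log-likelihood of the winning
    start (non-decreasing, the EM ascent property).
    """

    mu1: float
    mu2: float
    sigma1: float
    sigma2: float
    w1: float
    loglik: float
    n_iter: int
    converged: bool
    n_obs: int
    loglik_path: np.ndarray = field(repr=False, default=None)

    @property
    def w2(self) -> float:
        return 1.0 - self.w1

    @property
    def params(self) -> np.ndarray:
        return np.array([self.mu1, self.mu2, self.sigma1, self.sigma2, self.w1, self.w2])

    def summary(self) -> str:
        lines = [
            "Two-component normal mixture (EM)",
            "=" * 41,
            f"{'n_obs':<12}{self.n_obs:>10}",
            f"{'converged':<12}{str(self.converged):>10}",
            f"{'n_iter':<12}{self.n_iter:>10}",
            f"{'loglik':<12}{self.loglik:>10.4f}",
            "-" * 41,
            f"{'':<8}{'mu':>10}{'sigma':>10}{'weight':>10}",
            f"{'comp 1':<8}{self.mu1:>10.4f}{self.sigma1:>10.4f}{self.w1:>10.4f}",
            f"{'comp 2':<8}{self.mu2:>10.4f}{self.sigma2:>10.4f}{self.w2:>10.4f}",
        ]
        return "\n".join(lines)


def _loglik(x, mu1, mu2, s1, s2, w1):
    z1 = (x - mu1) / s1
    z2 = (x - mu2) / s2
    l1 = np.log(w1) - np.log(s1) - 0.5 * (z1 * z1 + _LOG_2PI)
    l2 = np.log1p(-w1) - np.log(s2) - 0.5 * (z2 * z2 + _LOG_2PI)
    m = np.maximum(l1, l2)
    return float(np.sum(m + np.log(np.exp(l1 - m) + np.exp(l2 - m))))


class TwoComponentNormalMixture:
    """Model object holding the data; ``fit`` runs EM and returns results.

    Parameters
    ----------
    endog : array_like
        Observed values (e.g. one gene's log2(FPKM + 1) across samples);
        at least 10 finite observations, not all identical.
    """

    def __init__(self, endog):
        x = np.asarray(endog, dtype=float).ravel()
        x = x[np.isfinite(x)]
        if x.size < 10:
            raise ValueError(
                f"mixture fit needs >= 10 finite observations, got {x.size}"
            )
        if np.all(x == x[0]):
            raise ValueError("degenerate sample: all values identical")
        self.endog = x
        self.nobs = x.size

    # -- starting values ---------------------------------------------------
    def _median_split_start(self):
        x = self.endog
        med = np.median(x)
        lo, hi = x[x <= med], x[x > med]
        if hi.size < 2:  # heavy ties at the median: fall back to halves
            xs = np.sort(x)
            lo, hi = xs[: x.size // 2], xs[x.size // 2 :]
        return (
            float(np.mean(lo)),
            float(np.mean(hi)),
            float(np.std(lo) if np.std(lo) > 0 else np.std(x)),
            float(np.std(hi) if np.std(hi) > 0 else np.std(x)),
            lo.size / x.size,
        )

    def _em(self, start, tol, max_iter, var_floor):
        x = self.endog
        mu1, mu2, s1, s2, w1 = start
        s1 = max(s1, var_floor)
        s2 = max(s2, var_floor)
        w1 = min(max(w1, 1e-6), 1.0 - 1e-6)
        path = []
        ll_old = -np.inf
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            # E-step: responsibilities of component 1
            z1 = (x - mu1) / s1
            z2 = (x - mu2) / s2
            a1 = np.log(w1) - np.log(s1) - 0.5 * z1 * z1
            a2 = np.log1p(-w1) - np.log(s2) - 0.5 * z2 * z2
            m = np.maximum(a1, a2)
            p1 = np.exp(a1 - m)
            p2 = np.exp(a2 - m)
            r1 = p1 / (p1 + p2)
            # M-step
            n1 = r1.sum()
            n2 = x.size - n1
            if n1 < 1e-10 or n2 < 1e-10:
                break  # one component died; keep last params
            mu1 = float(np.dot(r1, x) / n1)
            mu2 = float(np.dot(1.0 - r1, x) / n2)
            s1 = max(float(np.sqrt(np.dot(r1, (x - mu1) ** 2) / n1)), var_floor)
            s2 = max(float(np.sqrt(np.dot(1.0 - r1, (x - mu2) ** 2) / n2)), var_floor)
            w1 = float(n1 / x.size)
            ll = _loglik(x, mu1, mu2, s1, s2, w1)
            path.append(ll)
            if ll - ll_old < tol and np.isfinite(ll_old):
                converged = True
                break
            ll_old = ll
        ll = path[-1] if path else _loglik(x, mu1, mu2, s1, s2, w1)
        return (mu1, mu2, s1, s2, w1), ll, it, converged, np.asarray(path)

    def fit(
        self,
        tol: float = 1e-8,
        max_iter: int = 500,
        var_floor: float = 1e-3,
        n_starts: int = 5,
        rng=None,
    ) -> NormalMixtureResults:
        """Run EM from several starts and keep the best log-likelihood.

        The first start is deterministic (component moments from a split at
        the sample median), so with ``n_starts=1`` the fit needs no seed;
        the remaining ``n_starts - 1`` starts draw random responsibilities
        from ``rng``.
        """
        if n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        rng = np.random.default_rng(rng)
        x = self.endog
        starts = [self._median_split_start()]
        sd = float(np.std(x))
        for _ in range(n_starts - 1):
            r = rng.random(x.size)
            n1 = r.sum()
            mu1 = float(np.dot(r, x) / n1)
            mu2 = float(np.dot(1 - r, x) / (x.size - n1))
            starts.append((mu1, mu2, sd, sd, n1 / x.size))

        best = None
        for st in starts:
            params, ll, it, conv, path = self._em(st, tol, max_iter, var_floor)
            if best is None or ll > best[1]:
                best = (params, ll, it, conv, path)
        (mu1, mu2, s1, s2, w1), ll, it, conv, path = best
        if mu1 > mu2:
            mu1, mu2, s1, s2, w1 = mu2, mu1, s2, s1, 1.0 - w1
        return NormalMixtureResults(
            mu1=mu1,
            mu2=mu2,
            sigma1=s1,
            sigma2=s2,
            w1=w1,
            loglik=ll,
            n_iter=it,
            converged=conv,
            n_obs=self.nobs,
            loglik_path=path,
        )


def fit_two_component_mixture(
    x, tol=1e-8, max_iter=500, var_floor=1e-3, n_starts=5, rng=None
) -> NormalMixtureResults:
    """Functional wrapper around :class:`TwoComponentNormalMixture`."""
    return TwoComponentNormalMixture(x).fit(
        tol=tol, max_iter=max_iter, var_floor=var_floor, n_starts=n_starts, rng=rng
    )
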