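"""Zero-truncated binomial mixture model of the gene-frequency spectrum.

A pan-genome of gene families is modelled as K classes; a family of class
k is detected in each of G sequenced genomes independently with
probability rho_k, and classes are mixed with weights pi_k.  Families seen
in zero genomes are unobservable, so the likelihood is conditioned on at
least one detection:

    P(j | k) = C(G,j) rho_k^j (1-rho_k)^(G-j) / (1 - (1-rho_k)^G),  j=1..G

The unobserved mass U = sum_k pi_k (1-rho_k)^G extrapolates the pan-genome
(pan = n_obs / (1-U)) and the core genome (core = pan * sum_k pi_k rho_k^G).

The interface follows the Model / Results convention: build a
``BinomialMixture`` from a spectrum (or a presence/absence matrix), call
``fit`` (EM, multiple restarts) or ``fit_select_k`` (BIC scan), and read
estimates off the returned ``BinomialMixtureResults``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

from .panmatrix import PanMatrix, SpectrumCounts, spectrum as _spectrum

__all__ = [
    "truncated_pmf",
    "BinomialMixture",
    "BinomialMixtureResults",
    "PanEstimate",
    "fit_em",
    "select_K",
]

_EPS = 1e-300


def _log_binom_pmf(j: np.ndarray, G: int, rho: np.ndarray) -> np.ndarray:
    """log C(G,j) + j log rho + (G-j) log(1-rho); shape (len(j), len(rho))."""
    j = np.asarray(j, dtype=float)[:, None]
    rho = np.asarray(rho, dtype=float)[None, :]
    logc = gammaln(G + 1) - gammaln(j + 1) - gammaln(G - j + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = j * np.log(np.maximum(rho, _EPS)) + (G - j) * np.log(
            np.maximum(1.0 - rho, _EPS)
        )
    return logc + term


def truncated_pmf(j, G: int, pi, rho) -> float | np.ndarray:
    """Mixture probability of being observed in exactly j of G genomes,
    conditioned on being observed at least once.

    Truncation is applied to the mixture as a whole — the generative
    reading in which ``pi`` are the weights among *all* families,
    observed or not:  P(j) = sum_k pi_k Binom(j; G, rho_k) / (1 - U)
    with U = sum_k pi_k (1 - rho_k)^G.  This is the form consistent with
    extrapolating the pan-genome as n_obs / (1 - U).  Vectorized over j.
    """
    pi = np.asarray(pi, dtype=float)
    rho = np.asarray(rho, dtype=float)
    if np.any((rho <= 0) & (pi > 0)):
        raise ValueError("component with rho = 0 and positive weight is never observable")
    if np.any(rho > 1) or np.any(pi < 0):
        raise ValueError("invalid mixture parameters")
    scalar = np.isscalar(j)
    j_arr = np.atleast_1d(np.asarray(j, dtype=int))
    if np.any((j_arr < 1) | (j_arr > G)):
        raise ValueError("j must lie in 1..G")
    log_pj_k = _log_binom_pmf(j_arr, G, rho)
    U = float(np.sum(pi * (1.0 - rho) ** G))
    with np.errstate(divide="ignore"):
        mix = np.exp(logsumexp(log_pj_k + np.log(np.maximum(pi, _EPS)), axis=1))
    out = mix / max(1.0 - U, _EPS)
    return float(out[0]) if scalar else out


@dataclass(frozen=True)
class PanEstimate:
    pan_size: int
    core_size: int
    ratio_to_mean_genome: float | None
    unobserved_prob: float


@dataclass
class BinomialMixtureResults:
    """EM fit of the zero-truncated binomial mixture.

    ``pi``/``rho`` are stored in canonical form (rho ascending).
    """

    model: "BinomialMixture"
    K: int
    pi: np.ndarray
    rho: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    loglik_path: np.ndarray = field(repr=False, default=None)

    @property
    def G(self) -> int:
        return self.model.G

    @property
    def n_obs(self) -> int:
        return self.model.n_obs

    @property
    def n_params(self) -> int:
        return 2 * self.K - 1

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.n_params * math.log(self.n_obs)

    @property
    def unobserved_prob(self) -> float:
        return float(np.sum(self.pi * (1.0 - self.rho) ** self.G))

    def estimate_pan_core(self, mean_genome_size: float | None = None) -> PanEstimate:
        """Extrapolate pan- and core-genome sizes from the fitted mixture."""
        U = self.unobserved_prob
        if U >= 1.0 - 1e-12:
            raise ValueError("unobserved mass ~1: pan-genome size unbounded "
                             "(non-identifiable fit)")
        pan = round(self.n_obs / (1.0 - U))
        core = round(pan * float(np.sum(self.pi * self.rho ** self.G)))
        ratio = None
        if mean_genome_size:
            ratio = round(pan / mean_genome_size, 1)
        return PanEstimate(pan_size=int(pan), core_size=int(core),
                           ratio_to_mean_genome=ratio, unobserved_prob=U)

    def predict_spectrum(self) -> np.ndarray:
        """Expected spectrum counts under the fit (length G)."""
        j = np.arange(1, self.G + 1)
        return self.n_obs * truncated_pmf(j, self.G, self.pi, self.rho)

    def summary(self, mean_genome_size: float | None = None) -> str:
        est = self.estimate_pan_core(mean_genome_size)
        lines = [
            "Zero-truncated binomial mixture",
            "=" * 47,
            f"genomes (G):          {self.G}",
            f"observed clusters:    {self.n_obs}",
            f"components (K):       {self.K}",
            f"log-likelihood:       {self.loglik:.3f}",
            f"BIC:                  {self.bic:.3f}",
            f"converged:            {self.converged} ({self.n_iter} iterations)",
            "-" * 47,
            "  k        pi       rho",
        ]
        for k in range(self.K):
            lines.append(f"  {k + 1}  {self.pi[k]:8.4f}  {self.rho[k]:8.4f}")
        lines += [
            "-" * 47,
            f"unobserved mass U:    {est.unobserved_prob:.4f}",
            f"pan-genome estimate:  {est.pan_size}",
            f"core-genome estimate: {est.core_size}",
        ]
        if est.ratio_to_mean_genome is not None:
            lines.append(f"pan / mean genome:    {est.ratio_to_mean_genome}")
        return "\n".join(lines)


class BinomialMixture:
    """Zero-truncated binomial mixture model of a gene-frequency spectrum."""

    def __init__(self, spectrum: SpectrumCounts):
        if spectrum.n_obs < 1:
            raise ValueError("empty spectrum")
        self.spectrum = spectrum
        self.G = spectrum.G
        self.y = np.asarray(spectrum.y, dtype=float)
        self.n_obs = spectrum.n_obs
        self._j = np.arange(1, self.G + 1)

    @classmethod
    def from_matrix(cls, matrix: PanMatrix) -> "BinomialMixture":
        return cls(_spectrum(matrix))

    # -- EM machinery -----------------------------------------------------

    def _loglik(self, pi: np.ndarray, rho: np.ndarray) -> float:
        p = truncated_pmf(self._j, self.G, pi, rho)
        return float(np.sum(self.y * np.log(np.maximum(p, _EPS))))

    def _em_once(self, pi: np.ndarray, rho: np.ndarray, max_iter: int,
                 tol: float, pin_last_rho: bool = False,
                 ) -> tuple[np.ndarray, np.ndarray, float, int, bool,
                            np.ndarray]:
        y = self.y
        G = self.G
        j = self._j.astype(float)
        ll_prev = -np.inf
        path = []
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            # E-step over observed families (untruncated component densities;
            # truncation is carried by the latent never-observed class)
            log_w = _log_binom_pmf(self._j, G, rho) + np.log(np.maximum(pi, _EPS))
            log_norm = logsumexp(log_w, axis=1, keepdims=True)
            R = np.exp(log_w - log_norm)  # (G, K) responsibilities
            # latent unobserved families, apportioned to components
            U_k = pi * (1.0 - rho) ** G
            U = float(U_k.sum())
            n0 = self.n_obs * U / max(1.0 - U, 1e-12)
            n0_k = n0 * U_k / max(U, _EPS) if U > 0 else np.zeros_like(pi)
            # M-step
            N_k = (y[:, None] * R).sum(axis=0) + n0_k
            det_k = (y[:, None] * j[:, None] * R).sum(axis=0)  # detections
            pi = N_k / N_k.sum()
            with np.errstate(invalid="ignore", divide="ignore"):
                rho = np.where(N_k > 0, det_k / (G * np.maximum(N_k, _EPS)), 0.5)
            rho = np.clip(rho, 1e-9, 1.0)
            if pin_last_rho:
                rho[-1] = 1.0
            ll = self._loglik(pi, rho)
            path.append(ll)
            if ll < ll_prev - 1e-6:
                raise AssertionError(
                    f"EM log-likelihood decreased: {ll_prev} -> {ll}"
                )
            if abs(ll - ll_prev) < tol:
                converged = True
                ll_prev = ll
                break
            ll_prev = ll
        return pi, rho, ll_prev, it, converged, np.asarray(path)

    def _initial_params(self, K: int, rng: np.random.Generator) -> tuple:
        # stratified rho starts: jittered quantiles of the observed j/G mass
        probs = self.y / self.y.sum()
        cdf = np.cumsum(probs)
        q = (np.arange(K) + 0.5) / K
        idx = np.searchsorted(cdf, q)
        rho0 = (self._j[np.clip(idx, 0, self.G - 1)] / self.G).astype(float)
        rho0 = np.clip(rho0 + rng.uniform(-0.1, 0.1, size=K), 0.02, 0.999)
        pi0 = rng.dirichlet(np.ones(K))
        return pi0, rho0

    def fit(self, K: int = 3, n_starts: int = 20, max_iter: int = 2000,
            tol: float = 1e-9, seed: int | None = None,
            fix_core_component: bool = False) -> BinomialMixtureResults:
        """Maximum-likelihood EM fit with ``n_starts`` random restarts.

        ``fix_core_component`` pins one component at rho = 1 (an always-
        detected core class) for comparison with the free fit.  Components
        whose weight collapses below 1e-10 are dropped with a warning; the
        returned parameters are canonical (rho ascending).
        """
        if K < 1:
            raise ValueError("K must be >= 1")
        if self.n_obs < K:
            raise ValueError("fewer observed families than components")
        rng = np.random.default_rng(seed)
        best = None
        for s in range(max(1, n_starts)):
            if K == 1 and s == 0:
                pi0, rho0 = np.ones(1), np.array([max(
                    0.01, min(1.0, float((self.y * self._j).sum())
                              / (self.G * self.y.sum())))])
            else:
                pi0, rho0 = self._initial_params(K, rng)
            if fix_core_component:
                rho0[-1] = 1.0
            pi, rho, ll, it, conv, path = self._em_once(
                pi0, rho0, max_iter, tol, pin_last_rho=fix_core_component)
            if best is None or ll > best[2]:
                best = (pi, rho, ll, it, conv, path)
        pi, rho, ll, it, conv, path = best
        keep = pi > 1e-10
        if keep.sum() < K:
            warnings.warn(f"dropped {K - int(keep.sum())} degenerate "
                          "component(s) with vanishing weight")
            pi, rho = pi[keep], rho[keep]
            pi = pi / pi.sum()
        order = np.argsort(rho)
        return BinomialMixtureResults(
            model=self, K=int(keep.sum()), pi=pi[order], rho=rho[order],
            loglik=ll, n_iter=it, converged=conv, loglik_path=path,
        )

    def fit_select_k(self, k_range=range(1, 9), n_starts: int = 20,
                     seed: int | None = None,
                     **fit_kw) -> BinomialMixtureResults:
        """Fit each K in ``k_range`` and return the minimum-BIC fit
        (ties broken toward smaller K).  Per-K BICs are attached as
        ``result.bic_table``.
        """
        ks = list(k_range)
        if not ks:
            raise ValueError("empty K range")
        rng = np.random.default_rng(seed)
        fits = []
        for K in ks:
            sub_seed = int(rng.integers(0, 2**31 - 1))
            fits.append(self.fit(K=K, n_starts=n_starts, seed=sub_seed, **fit_kw))
        best = min(fits, key=lambda r: (r.bic, r.K))
        best.bic_table = {f.K: f.bic for f in fits}  # type: ignore[attr-defined]
        return best


def fit_em(spectrum: SpectrumCounts, K: int, n_starts: int = 20,
           max_iter: int = 2000, tol: float = 1e-9,
           seed: int | None = None) -> BinomialMixtureResults:
    """Functional wrapper around ``BinomialMixture(...).fit(...)``."""
    return BinomialMixture(spectrum).fit(K=K, n_starts=n_starts,
                                         max_iter=max_iter, tol=tol, seed=seed)


def select_K(spectrum: SpectrumCounts, k_range=range(1, 9),
             seed: int | None = None, **kw) -> BinomialMixtureResults:
    """Functional wrapper around ``BinomialMixture(...).fit_select_k(...)``."""
    return BinomialMixture(spectrum).fit_select_k(k_range=k_range, seed=seed, **kw)
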