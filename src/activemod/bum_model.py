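"""Beta-uniform mixture (BUM) model for p-value vectors.

A vector of differential-expression p-values is modelled as a two-component
mixture: a Uniform(0, 1) noise component with weight ``lambda`` and a
Beta(alpha, 1) signal component (density ``alpha * x**(alpha - 1)``,
enriched near zero for ``alpha < 1``) with weight ``1 - lambda``:

    f(x) = lambda + (1 - lambda) * alpha * x**(alpha - 1)

From a maximum-likelihood fit of (lambda, alpha) a target false discovery
rate is inverted into a significance threshold ``tau``, and each gene is
scored

    W(x) = (alpha - 1) * (log(x) - log(tau)),

which is positive for p < tau, zero at p = tau, and negative for p > tau.
These signed scores are the node weights of the maximum-weight connected
subgraph problem downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import minimize

from .errors import ParameterError, ValidationError

#: Parameter box for the likelihood optimiser; both lambda and alpha live in
#: the open unit interval, kept off the boundary by this margin.
BOUND_EPS = 1e-5

#: Distance from a bound at which a fitted parameter is flagged as pinned.
BOUNDARY_TOL = 1e-4

#: Minimum number of p-values for a meaningful mixture fit.
MIN_PVALUES = 50

#: Log-likelihood gain over the uniform model below which a fit is treated
#: as carrying no signal. The uniform model has log-likelihood exactly 0, so
#: this is a likelihood-ratio cut (2*LLR ~ 14, i.e. p ~ 1e-3 against a
#: two-parameter alternative, conservative for the boundary-case mixture).
NO_SIGNAL_LLR = 7.0


@dataclass(frozen=True)
class BumFit:
    """Fitted beta-uniform mixture parameters.

    Attributes
    ----------
    lambda_
        Mixture weight of the uniform (noise) component.
    alpha
        Beta shape parameter of the signal component (< 1 means enrichment
        of small p-values).
    n
        Number of p-values the model was fitted to.
    log_likelihood
        Attained log-likelihood.
    boundary
        True if the optimiser ended pinned to a parameter bound — typically a
        sign that the data carry no signal (lambda -> 1) or pure signal.
    """

    lambda_: float
    alpha: float
    n: int
    log_likelihood: float
    boundary: bool = False

    @property
    def pi_upper(self) -> float:
        """Conservative estimate of the noise ceiling, f(1) = lambda + (1-lambda)*alpha.

        This is the model density at p = 1, an upper bound on the proportion
        of true nulls, and the supremum of attainable FDR targets.
        """
        return self.lambda_ + (1.0 - self.lambda_) * self.alpha

    @property
    def no_signal(self) -> bool:
        """True when the data are indistinguishable from uniform noise.

        Judged by the likelihood gain over the pure-uniform model (whose
        log-likelihood is exactly zero); near-uniform samples land on the
        unidentifiable ridge lambda + (1-lambda)*alpha ~ 1, where the fitted
        parameters are meaningless and tau can degenerate.
        """
        return self.log_likelihood < NO_SIGNAL_LLR


@dataclass(frozen=True)
class ScoringScheme:
    """A BUM fit together with a target FDR and the implied threshold tau."""

    fit: BumFit
    fdr: float
    tau: float

    def score(self, p):
        """W(p) = (alpha - 1) * (ln p - ln tau); vectorised."""
        return node_score(p, self)


def bum_density(x, lambda_: float, alpha: float):
    """Mixture density f(x) = lambda + (1 - lambda) * alpha * x**(alpha-1).

    ``x`` may be a scalar or array with entries in (0, 1]; parameters must
    lie in (0, 1). The density integrates to one over (0, 1].
    """
    _check_params(lambda_, alpha)
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0.0) or np.any(x > 1.0):
        raise ValidationError("bum_density requires x in (0, 1]")
    out = lambda_ + (1.0 - lambda_) * alpha * np.power(x, alpha - 1.0)
    return float(out) if out.ndim == 0 else out


def _check_params(lambda_: float, alpha: float) -> None:
    if not (0.0 < lambda_ < 1.0 and 0.0 < alpha < 1.0):
        raise ParameterError(
            f"BUM parameters must lie in (0, 1); got lambda={lambda_}, alpha={alpha}"
        )


def _negloglik(theta: np.ndarray, logx: np.ndarray) -> float:
    lam, alpha = theta
    # density written as exp((alpha-1)*log x) so log x is computed once
    f = lam + (1.0 - lam) * alpha * np.exp((alpha - 1.0) * logx)
    return -float(np.sum(np.log(f)))


def fit_bum(pvalues, min_n: int = MIN_PVALUES) -> BumFit:
    """Maximum-likelihood fit of the beta-uniform mixture.

    Uses bounded L-BFGS-B started from a fixed 5x5 grid over
    ``(lambda, alpha) in [0.05, 0.95]^2`` and keeps the best attained
    likelihood, which makes the fit deterministic for a given input. The
    likelihood surface is flat-to-bimodal near the boundary when either
    component is nearly absent, hence the multi-start.

    Raises
    ------
    ValidationError
        If fewer than ``min_n`` p-values are supplied, or any lies outside
        (0, 1] (zeros must be clamped upstream).
    """
    pv = np.asarray(pvalues, dtype=float)
    if pv.ndim != 1:
        pv = pv.ravel()
    if pv.size < min_n:
        raise ValidationError(f"need at least {min_n} p-values, got {pv.size}")
    if np.any(pv <= 0.0) or np.any(pv > 1.0):
        raise ValidationError("p-values must lie in (0, 1] (clamp zeros first)")

    logx = np.log(pv)
    bounds = [(BOUND_EPS, 1.0 - BOUND_EPS)] * 2
    starts = [
        (lam, alph)
        for lam in np.linspace(0.05, 0.95, 5)
        for alph in np.linspace(0.05, 0.95, 5)
    ]
    best = None
    for theta0 in starts:
        res = minimize(
            _negloglik,
            x0=np.array(theta0),
            args=(logx,),
            method="L-BFGS-B",
            bounds=bounds,
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    lam, alpha = float(best.x[0]), float(best.x[1])
    pinned = any(
        abs(v - b) < BOUNDARY_TOL for v in (lam, alpha) for b in (BOUND_EPS, 1.0 - BOUND_EPS)
    )
    return BumFit(
        lambda_=lam,
        alpha=alpha,
        n=int(pv.size),
        log_likelihood=-float(best.fun),
        boundary=pinned,
    )


def model_fdr(fit: BumFit, tau: float) -> float:
    """Model-based FDR at threshold tau: pi_upper * tau / F(tau).

    ``F(tau) = lambda*tau + (1-lambda)*tau**alpha`` is the mixture CDF, the
    expected fraction of p-values called significant at tau; the numerator
    bounds the expected fraction of those that are null.
    """
    lam, alpha = fit.lambda_, fit.alpha
    F = lam * tau + (1.0 - lam) * tau**alpha
    return fit.pi_upper * tau / F


def fdr_threshold(fit: BumFit, fdr: float) -> float:
    """Invert a target FDR into the significance threshold tau.

    Closed form: ``tau = ((pi_upper - lambda*fdr) / (fdr*(1-lambda)))**(1/(alpha-1))``.
    The map is strictly increasing in ``fdr`` and reaches tau = 1 exactly at
    ``fdr = pi_upper``; targets above that are infeasible under the model.
    """
    if not (0.0 < fdr < 1.0):
        raise ParameterError(f"fdr must lie in (0, 1), got {fdr}")
    pi = fit.pi_upper
    if fdr > pi:
        raise ParameterError(
            f"fdr={fdr:g} infeasible for this fit: attainable range is (0, {pi:.6g}]"
        )
    lam, alpha = fit.lambda_, fit.alpha
    base = (pi - lam * fdr) / (fdr * (1.0 - lam))
    tau = float(base ** (1.0 / (alpha - 1.0)))
    if not (tau > 0.0 and np.isfinite(tau)):
        # alpha -> 1 sends the exponent to -inf and tau underflows: the fit
        # is too close to uniform for any threshold to be meaningful
        raise ParameterError(
            f"threshold degenerate for fdr={fdr:g} (alpha={alpha:.4g} too "
            "close to 1; the fit carries no usable signal)"
        )
    return min(tau, 1.0)


def scoring_scheme(fit: BumFit, fdr: float) -> ScoringScheme:
    """Bundle a fit with a target FDR and its threshold tau."""
    return ScoringScheme(fit=fit, fdr=fdr, tau=fdr_threshold(fit, fdr))


def node_score(p, scheme: ScoringScheme):
    """Signed node weight W(p) = (alpha - 1) * (ln p - ln tau).

    Positive iff p < tau (alpha < 1 makes the prefactor negative), zero at
    p = tau. Vectorised over ``p``; entries must lie in (0, 1].
    """
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0.0) or np.any(p > 1.0):
        raise ValidationError("node_score requires p in (0, 1]")
    out = (scheme.fit.alpha - 1.0) * (np.log(p) - np.log(scheme.tau))
    return float(out) if out.ndim == 0 else out


def fit_report(fit: BumFit, pvalues, bins: int = 30) -> dict:
    """JSON-serialisable diagnostics: parameters plus a histogram of the
    p-values with the fitted density evaluated at the bin centres."""
    pv = np.asarray(pvalues, dtype=float)
    counts, edges = np.histogram(pv, bins=bins, range=(0.0, 1.0), density=True)
    centres = 0.5 * (edges[:-1] + edges[1:])
    return {
        "lambda": fit.lambda_,
        "alpha": fit.alpha,
        "n": fit.n,
        "log_likelihood": fit.log_likelihood,
        "pi_upper": fit.pi_upper,
        "boundary": fit.boundary,
        "histogram": {
            "bin_centres": centres.tolist(),
            "density": counts.tolist(),
            "fitted_density": bum_density(centres, fit.lambda_, fit.alpha).tolist(),
        },
    }


def write_fit_report(fit: BumFit, pvalues, path: str | Path, bins: int = 30) -> None:
    Path(path).write_text(json.dumps(fit_report(fit, pvalues, bins), indent=1) + "\n")
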