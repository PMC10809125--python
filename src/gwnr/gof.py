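"""Goodness-of-fit F test: does the geographically weighted model beat the global one?

Under H0 every coefficient surface is constant over space, so the GWNR model
collapses to the global MNR model. The test compares the two error sums of
squares through the statistic

    F1* = { y'[(I - L) - (I - G)'(I - G)] y / tau1 } / { y'(I - G)'(I - G) y / gamma1 }

whose null distribution is approximated by an F with non-integer degrees of
freedom df1 = tau1^2 / tau2 and df2 = gamma1^2 / gamma2, where

    gamma_i = tr( ((I - G)'(I - G))^i ),
    tau_i   = tr( ((I - L) - (I - G)'(I - G))^i ),   i = 1, 2.

The degrees of freedom come from Satterthwaite moment matching: a quadratic
form x'Ax in standard normal x has mean tr(A) and variance 2 tr(A^2), and
matching both to a scaled chi-square c*chi2_r gives c = gamma2/gamma1 and
r = gamma1^2/gamma2 (exactly chi-square when A is idempotent). H0 is
rejected at level alpha when F1* exceeds the upper-alpha F quantile.

Because L is a symmetric idempotent projection, the numerator quadratic form
equals SSE_MNR - SSE_GWNR; the implementation computes both and verifies the
identity at run time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import DegenerateTestError, InvalidInputError
from .fitting import GwnrFit, MnrFit

__all__ = [
    "TraceSet",
    "GofTestResult",
    "gamma_traces",
    "tau_traces",
    "satterthwaite",
    "sse_chi2_approx_check",
    "f_quantile",
    "gof_test",
]

IDEMPOTENCY_TOL = 1e-8


@dataclass(frozen=True)
class TraceSet:
    """Trace quantities driving the degrees of freedom of the test."""

    gamma1: float
    gamma2: float
    tau1: float
    tau2: float

    @property
    def c(self) -> float:
        return self.gamma2 / self.gamma1

    @property
    def r(self) -> float:
        return self.gamma1**2 / self.gamma2

    @property
    def df1(self) -> float:
        return self.tau1**2 / self.tau2

    @property
    def df2(self) -> float:
        return self.gamma1**2 / self.gamma2


@dataclass(frozen=True)
class GofTestResult:
    """Full goodness-of-fit report."""

    sse_mnr: float
    sse_gwnr: float
    traces: TraceSet
    df1: float
    df2: float
    f_stat: float
    critical: float
    p_value: float
    alpha: float
    reject_h0: bool

    def to_dict(self) -> dict:
        return {
            "sse_mnr": self.sse_mnr,
            "sse_gwnr": self.sse_gwnr,
            "gamma1": self.traces.gamma1,
            "gamma2": self.traces.gamma2,
            "tau1": self.traces.tau1,
            "tau2": self.traces.tau2,
            "df1": self.df1,
            "df2": self.df2,
            "f_stat": self.f_stat,
            "critical": self.critical,
            "p_value": self.p_value,
            "alpha": self.alpha,
            "reject_h0": self.reject_h0,
        }


def _residual_form(G: np.ndarray) -> np.ndarray:
    G = np.asarray(G, dtype=float)
    if G.ndim != 2 or G.shape[0] != G.shape[1]:
        raise InvalidInputError("G must be a square matrix")
    if not np.all(np.isfinite(G)):
        raise InvalidInputError("G contains non-finite entries")
    ImG = np.eye(G.shape[0]) - G
    return ImG.T @ ImG


def gamma_traces(G: np.ndarray) -> tuple[float, float]:
    """gamma1 = tr(A), gamma2 = tr(A^2) for A = (I-G)'(I-G).

    Computed from the symmetric product A itself (tr(A^2) = sum A .* A),
    not from an expansion in tr(G) and tr(G'G).
    """
    A = _residual_form(G)
    return float(np.trace(A)), float(np.sum(A * A))


def tau_traces(
    L: np.ndarray, G: np.ndarray, allow_degenerate: bool = False
) -> tuple[float, float]:
    """tau1 = tr(B), tau2 = tr(B^2) for B = (I - L) - (I - G)'(I - G).

    L must be a symmetric idempotent projection (validated); non-positive
    tau1 or tau2 means the weighted fit does not dominate the global one
    numerically and raises unless ``allow_degenerate``.
    """
    L = np.asarray(L, dtype=float)
    G = np.asarray(G, dtype=float)
    if L.shape != G.shape:
        raise InvalidInputError("L and G must have the same shape")
    scale = max(1.0, float(np.abs(L).max()))
    if np.abs(L - L.T).max() > IDEMPOTENCY_TOL * scale:
        raise InvalidInputError("L is not symmetric")
    if np.abs(L @ L - L).max() > IDEMPOTENCY_TOL * max(1.0, scale**2):
        raise InvalidInputError("L is not idempotent: the global hat matrix must be a projection")
    B = (np.eye(L.shape[0]) - L) - _residual_form(G)
    tau1, tau2 = float(np.trace(B)), float(np.sum(B * B))
    # tau at float-roundoff scale means B is numerically zero (G coincides with L)
    if not allow_degenerate and (tau1 <= 1e-10 or tau2 <= 1e-20):
        raise DegenerateTestError(
            f"tau1 = {tau1:g}, tau2 = {tau2:g}: the geographically weighted fit does not "
            "dominate the global fit numerically (e.g. uniform weights); no heterogeneity to test"
        )
    return tau1, tau2


def satterthwaite(gamma1: float, gamma2: float) -> tuple[float, float]:
    """Scaled-chi-square constants (c, r) matching mean gamma1 and variance 2*gamma2.

    c = gamma2/gamma1 and r = gamma1^2/gamma2, so that c*r = gamma1 and
    2*c^2*r = 2*gamma2 hold exactly.
    """
    if not (gamma1 > 0 and gamma2 > 0 and np.isfinite(gamma1) and np.isfinite(gamma2)):
        raise InvalidInputError(f"gamma1 and gamma2 must be positive, got {gamma1}, {gamma2}")
    return gamma2 / gamma1, gamma1**2 / gamma2


def sse_chi2_approx_check(
    G: np.ndarray, sigma2: float = 1.0, reps: int = 5000, seed: int = 0
) -> float:
    """KS distance between simulated SSE/sigma2 draws and the c*chi2_r approximation.

    Simulates sum_i lambda_i * zeta_i^2 with zeta iid standard normal, where
    lambda are the eigenvalues of (I-G)'(I-G) — the exact finite-sample law of
    SSE/sigma2 — and measures how far the scaled-chi-square approximation is
    from it. A diagnostic, not a fitting step.
    """
    if reps < 1000:
        raise InvalidInputError("use at least 1000 replicates for a stable KS distance")
    if not sigma2 > 0:
        raise InvalidInputError("sigma2 must be positive")
    lam = np.linalg.eigvalsh(_residual_form(G))
    lam = np.clip(lam, 0.0, None)
    c, r = satterthwaite(float(lam.sum()), float((lam**2).sum()))
    rng = np.random.default_rng(seed)
    zeta2 = rng.standard_normal((reps, lam.size)) ** 2
    sample = zeta2 @ lam
    ks = stats.kstest(sample, lambda x: stats.chi2.cdf(x / c, r))
    return float(ks.statistic)


def f_quantile(alpha: float, df1: float, df2: float) -> float:
    """Upper-alpha quantile of the F distribution with continuous degrees of freedom."""
    if not (0 < alpha < 1):
        raise InvalidInputError(f"alpha must lie in (0, 1), got {alpha}")
    if not (df1 > 0 and df2 > 0):
        raise InvalidInputError(f"degrees of freedom must be positive, got {df1}, {df2}")
    return float(stats.f.isf(alpha, df1, df2))


def gof_test(y: np.ndarray, mnr: MnrFit, gwnr: GwnrFit, alpha: float = 0.05) -> GofTestResult:
    """Run the goodness-of-fit F test of the weighted model against the global one.

    Both fits must come from the same response and design matrix. Returns a
    full report; raises a degenerate-test error when tau1 or tau2 is not
    positive, and a division-degenerate error when SSE_GWNR is zero.
    """
    y = np.asarray(y, dtype=float).ravel()
    if not (0 < alpha < 1):
        raise InvalidInputError(f"alpha must lie in (0, 1), got {alpha}")
    if mnr.design.values.shape != gwnr.design.values.shape or not np.array_equal(
        mnr.design.values, gwnr.design.values
    ):
        raise InvalidInputError("MNR and GWNR fits must share one design matrix")
    L, G = mnr.L, gwnr.G
    gamma1, gamma2 = gamma_traces(G)
    tau1, tau2 = tau_traces(L, G)
    traces = TraceSet(gamma1=gamma1, gamma2=gamma2, tau1=tau1, tau2=tau2)

    A = _residual_form(G)
    B = (np.eye(len(y)) - L) - A
    num_qf = float(y @ B @ y)
    den_qf = float(y @ A @ y)
    if den_qf <= 0 or gwnr.sse <= 0:
        raise DegenerateTestError("SSE_GWNR is zero; the F statistic is undefined")
    # numerator identity: y'(I-L)y = SSE_MNR exactly because L is a projection
    sse_diff = mnr.sse - gwnr.sse
    scale = max(1.0, abs(mnr.sse), abs(gwnr.sse))
    if abs(num_qf - sse_diff) > 1e-8 * scale:
        raise InvalidInputError(
            f"numerator quadratic form {num_qf:g} disagrees with SSE_MNR - SSE_GWNR "
            f"{sse_diff:g}; the global hat matrix is not a projection"
        )

    f_stat = (num_qf / tau1) / (den_qf / gamma1)
    df1, df2 = traces.df1, traces.df2
    critical = f_quantile(alpha, df1, df2)
    p_value = float(stats.f.sf(f_stat, df1, df2))
    return GofTestResult(
        sse_mnr=mnr.sse,
        sse_gwnr=gwnr.sse,
        traces=traces,
        df1=df1,
        df2=df2,
        f_stat=f_stat,
        critical=critical,
        p_value=p_value,
        alpha=alpha,
        reject_h0=bool(f_stat > critical),
    )
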