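"""Two-state homozygosity-by-descent hidden Markov model.

States are ``nonHBD`` (0) and ``HBD`` (1).  The chain is parameterised by
the inbreeding coefficient ``f`` (stationary HBD probability) and a rate
``a`` per cM; the expected HBD segment length is ``1/(a(1-f))`` cM.  Over a
genetic distance ``d``::

    P(HBD    -> HBD) = exp(-a d) + f (1 - exp(-a d))
    P(nonHBD -> HBD) = f (1 - exp(-a d))

Emissions at a marker with alt-allele frequency ``p`` are Hardy-Weinberg
genotype probabilities in the nonHBD state and, in the HBD state, allelic
probabilities ``{1-p, 0, p}`` contaminated by a small genotyping-error rate
``eps`` towards the HWE distribution (so an isolated heterozygote does not
zero the likelihood of an HBD stretch).

Both (f, a) are estimated per individual and submap by maximum likelihood
(forward algorithm + derivative-free optimisation); the chain restarts at
each chromosome from its stationary distribution (1-f, f), encoded as an
infinite predecessor distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import expit, logit

MISSING = -1

_F_MAX = 0.5
_A_MIN = 1e-4
_A_MAX = 4.0


@dataclass(frozen=True)
class HBDModelParams:
    """Markov-chain parameters: inbreeding coefficient f, rate a (per cM)."""

    f: float
    a: float

    def __post_init__(self) -> None:
        if not 0 <= self.f < 1:
            raise ValueError("f must be in [0, 1)")
        if self.a <= 0:
            raise ValueError("a must be > 0")

    @property
    def expected_hbd_length_cM(self) -> float:
        return 1.0 / (self.a * (1.0 - self.f))


@dataclass
class EmissionModel:
    """Per-marker alt-allele frequencies plus a genotyping-error rate."""

    freqs: np.ndarray
    eps: float = 1e-3

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if not 0 <= self.eps <= 0.05:
            raise ValueError("eps must be in [0, 0.05]")

    def validate(self) -> None:
        if np.any((self.freqs <= 0) | (self.freqs >= 1)):
            bad = np.flatnonzero((self.freqs <= 0) | (self.freqs >= 1))
            raise ValueError(
                f"allele frequencies must lie strictly in (0,1); "
                f"offending marker indices {bad[:5].tolist()}..."
            )


@dataclass
class HBDModelFit:
    """ML fit of (f, a) on one submap, with the f = f0 null profile fit."""

    params: HBDModelParams
    loglik: float
    loglik_h0: float
    converged: bool

    @property
    def retained(self) -> bool:
        """Submap-retention filter: fits with a > 1 are discarded."""
        return self.converged and self.params.a <= 1.0


def transition_matrix(d: float, params: HBDModelParams) -> np.ndarray:
    """2x2 transition matrix over (nonHBD, HBD) for genetic distance d (cM)."""
    if d < 0:
        raise ValueError("genetic distance must be >= 0")
    e = math.exp(-params.a * d) if np.isfinite(d) else 0.0
    p_to_hbd = params.f * (1.0 - e)
    return np.array(
        [[1.0 - p_to_hbd, p_to_hbd], [1.0 - e - p_to_hbd, e + p_to_hbd]]
    )


def emission_prob(
    genotype: int, p: float, state: int, eps: float = 1e-3
) -> float:
    """P(genotype | state) at one marker; ``genotype`` counts alt copies,
    -1 is missing (probability 1 in both states)."""
    if not 0 < p < 1:
        raise ValueError("p must be in (0,1)")
    if genotype == MISSING:
        return 1.0
    hwe = ((1 - p) ** 2, 2 * p * (1 - p), p**2)[genotype]
    if state == 0:
        return hwe
    hbd = (1 - p, 0.0, p)[genotype]
    return (1 - eps) * hbd + eps * hwe


# ---------------------------------------------------------------------------
# Forward / backward kernels (numba-jitted when available)


def _forward_kernel(g, d, p, f, a, eps):  # pragma: no cover - jitted
    ll = 0.0
    a0 = 1.0 - f  # alpha for nonHBD
    a1 = f
    first = True
    for i in range(g.shape[0]):
        di = d[i]
        if first:
            b0, b1 = 1.0 - f, f
            first = False
        else:
            if math.isinf(di):
                e = 0.0
            else:
                e = math.exp(-a * di)
            t01 = f * (1.0 - e)
            t11 = e + t01
            b0 = a0 * (1.0 - t01) + a1 * (1.0 - t11)
            b1 = a0 * t01 + a1 * t11
        gi = g[i]
        if gi >= 0:
            pi = p[i]
            if gi == 0:
                hwe = (1.0 - pi) * (1.0 - pi)
                hbd = 1.0 - pi
            elif gi == 1:
                hwe = 2.0 * pi * (1.0 - pi)
                hbd = 0.0
            else:
                hwe = pi * pi
                hbd = pi
            b0 *= hwe
            b1 *= (1.0 - eps) * hbd + eps * hwe
        s = b0 + b1
        if s <= 0.0:
            return -np.inf
        ll += math.log(s)
        a0 = b0 / s
        a1 = b1 / s
    return ll


def _posterior_kernel(g, d, p, f, a, eps):  # pragma: no cover - jitted
    n = g.shape[0]
    alpha = np.empty((n, 2))
    scale = np.empty(n)
    a0, a1 = 1.0 - f, f
    for i in range(n):
        if i == 0:
            b0, b1 = 1.0 - f, f
        else:
            di = d[i]
            e = 0.0 if math.isinf(di) else math.exp(-a * di)
            t01 = f * (1.0 - e)
            t11 = e + t01
            b0 = a0 * (1.0 - t01) + a1 * (1.0 - t11)
            b1 = a0 * t01 + a1 * t11
        gi = g[i]
        if gi >= 0:
            pi = p[i]
            if gi == 0:
                hwe = (1.0 - pi) * (1.0 - pi)
                hbd = 1.0 - pi
            elif gi == 1:
                hwe = 2.0 * pi * (1.0 - pi)
                hbd = 0.0
            else:
                hwe = pi * pi
                hbd = pi
            b0 *= hwe
            b1 *= (1.0 - eps) * hbd + eps * hwe
        s = b0 + b1
        scale[i] = s
        a0, a1 = b0 / s, b1 / s
        alpha[i, 0] = a0
        alpha[i, 1] = a1
    # backward
    post = np.empty(n)
    bt0, bt1 = 1.0, 1.0
    for i in range(n - 1, -1, -1):
        denom = alpha[i, 0] * bt0 + alpha[i, 1] * bt1
        post[i] = alpha[i, 1] * bt1 / denom
        if i == 0:
            break
        # fold emission at i and transition (i-1 -> i) into beta
        gi = g[i]
        if gi >= 0:
            pi = p[i]
            if gi == 0:
                hwe = (1.0 - pi) * (1.0 - pi)
                hbd = 1.0 - pi
            elif gi == 1:
                hwe = 2.0 * pi * (1.0 - pi)
                hbd = 0.0
            else:
                hwe = pi * pi
                hbd = pi
            e0 = hwe
            e1 = (1.0 - eps) * hbd + eps * hwe
        else:
            e0 = e1 = 1.0
        di = d[i]
        if math.isinf(di):
            # chain restart: beta resets, next segment independent
            bt0, bt1 = 1.0, 1.0
            continue
        e = math.exp(-a * di)
        t01 = f * (1.0 - e)
        t11 = e + t01
        nb0 = (1.0 - t01) * e0 * bt0 + t01 * e1 * bt1
        nb1 = (1.0 - t11) * e0 * bt0 + t11 * e1 * bt1
        s = scale[i]
        bt0, bt1 = nb0 / s, nb1 / s
    return post


try:  # numba gives a ~100x speedup on the marker loop; fall back to python
    from numba import njit

    _forward_kernel = njit(cache=True, fastmath=False)(_forward_kernel)
    _posterior_kernel = njit(cache=True, fastmath=False)(_posterior_kernel)
except ImportError:  # pragma: no cover
    pass


def _prep(genotypes, distances, em: EmissionModel):
    g = np.ascontiguousarray(genotypes, dtype=np.int8)
    d = np.ascontiguousarray(distances, dtype=np.float64)
    p = np.ascontiguousarray(em.freqs, dtype=np.float64)
    if not (g.shape == d.shape == p.shape):
        raise ValueError("genotypes, distances and frequencies must align")
    obs = g >= 0
    if np.any((p[obs] <= 0) | (p[obs] >= 1)):
        raise ValueError("allele frequencies at observed markers must be in (0,1)")
    return g, d, p


def forward_loglik(
    genotypes: np.ndarray,
    distances: np.ndarray,
    em: EmissionModel,
    params: HBDModelParams,
) -> float:
    """Scaled forward-algorithm log-likelihood of one individual's genotypes.

    ``distances[i]`` is the genetic distance (cM) from marker i-1; an
    infinite entry restarts the chain at the stationary distribution
    (chromosome boundary).  ``distances[0]`` is ignored.
    """
    g, d, p = _prep(genotypes, distances, em)
    return float(_forward_kernel(g, d, p, params.f, params.a, em.eps))


def posterior_hbd(
    genotypes: np.ndarray,
    distances: np.ndarray,
    em: EmissionModel,
    params: HBDModelParams,
) -> np.ndarray:
    """Per-marker P(HBD | data) by the forward-backward algorithm."""
    g, d, p = _prep(genotypes, distances, em)
    if params.f == 0:
        return np.zeros(len(g))
    return np.asarray(_posterior_kernel(g, d, p, params.f, params.a, em.eps))


# ---------------------------------------------------------------------------
# Maximum-likelihood estimation

_STARTS = ((0.05, 0.05), (0.01, 0.5), (0.2, 0.1))


def _null_fit(g, d, p, eps, f0) -> tuple[float, float]:
    """Profile log-likelihood with f fixed at f0, maximised over a."""
    res = minimize_scalar(
        lambda la: -_forward_kernel(g, d, p, f0, math.exp(la), eps),
        bounds=(math.log(_A_MIN), math.log(_A_MAX)),
        method="bounded",
        options={"xatol": 1e-6},
    )
    return -res.fun, math.exp(res.x)


def fit_ml(
    genotypes: np.ndarray,
    distances: np.ndarray,
    em: EmissionModel,
    f0: float = 0.001,
    fit_null: bool = True,
    min_informative: int = 50,
    tie_tol: float = 0.1,
    a_ref: float = 0.06,
) -> HBDModelFit:
    """Maximum-likelihood fit of (f, a) on one submap.

    Bounded Nelder-Mead on (logit(f / 0.5), log a) from three fixed starts,
    plus a one-dimensional profile over f at the reference rate ``a_ref``;
    f is searched in [0, 0.5] and a in (1e-4, 4].  When f approaches 0 the
    likelihood is flat in a, so among candidate optima whose log-likelihoods
    are within ``tie_tol`` (practically indistinguishable) the fit with
    the smallest a is reported — the parsimonious solution with the fewest,
    longest HBD segments.  ``loglik_h0`` is the profile likelihood with f
    fixed at ``f0`` (skipped when ``fit_null`` is false, e.g. when only the
    point estimate is needed).
    """
    g, d, p = _prep(genotypes, distances, em)
    n_inf = int((g >= 0).sum())
    if n_inf < min_informative:
        raise ValueError(
            f"only {n_inf} informative markers; need >= {min_informative}"
        )
    eps = em.eps

    def neg(x):
        f = _F_MAX * expit(x[0])
        a = math.exp(x[1])
        if a < _A_MIN or a > _A_MAX:
            return np.inf
        return -_forward_kernel(g, d, p, f, a, eps)

    candidates: list[tuple[float, float, float]] = []  # (f, a, loglik)
    any_ok = False
    for f_s, a_s in _STARTS:
        x0 = np.array([logit(f_s / _F_MAX), math.log(a_s)])
        res = minimize(
            neg, x0, method="Nelder-Mead",
            options={"fatol": 1e-6, "xatol": 1e-4, "maxiter": 500},
        )
        any_ok = any_ok or res.success
        candidates.append(
            (
                float(_F_MAX * expit(res.x[0])),
                float(np.clip(math.exp(res.x[1]), _A_MIN, _A_MAX)),
                -float(res.fun),
            )
        )
    prof = minimize_scalar(
        lambda lf: -_forward_kernel(g, d, p, _F_MAX * expit(lf), a_ref, eps),
        bounds=(-18.0, logit(0.98)),
        method="bounded",
        options={"xatol": 1e-6},
    )
    candidates.append((float(_F_MAX * expit(prof.x)), a_ref, -float(prof.fun)))
    any_ok = any_ok or bool(prof.success)

    ll_max = max(c[2] for c in candidates)
    f_hat, a_hat, loglik = min(
        (c for c in candidates if c[2] >= ll_max - tie_tol), key=lambda c: c[1]
    )
    ll0 = np.nan
    if fit_null:
        ll0, a_null = _null_fit(g, d, p, eps, f0)
        if loglik < ll0:  # optimiser landed below the nested null: report it
            loglik, f_hat, a_hat = ll0, f0, a_null
    return HBDModelFit(
        params=HBDModelParams(f=f_hat, a=a_hat),
        loglik=loglik,
        loglik_h0=ll0,
        converged=bool(any_ok),
    )


# ---------------------------------------------------------------------------
# Model-based simulation (used for calibration checks and null studies)


def simulate_hmm_genotypes(
    distances: np.ndarray,
    em: EmissionModel,
    params: HBDModelParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw one individual's genotypes from the HBD-HMM itself.

    States follow the (f, a) Markov chain along ``distances`` (inf restarts
    at stationarity); genotypes are drawn from the state's emission
    distribution, with the error mixture applied in the HBD state.
    """
    em.validate()
    d = np.asarray(distances, dtype=float)
    p = em.freqs
    n = len(d)
    states = np.empty(n, dtype=np.int8)
    f, a = params.f, params.a
    u = rng.random(n)
    for i in range(n):
        if i == 0 or np.isinf(d[i]):
            pr = f
        else:
            e = math.exp(-a * d[i])
            pr = f * (1 - e) + (e if states[i - 1] == 1 else 0.0)
        states[i] = 1 if u[i] < pr else 0
    geno = np.empty(n, dtype=np.int8)
    v = rng.random(n)
    w = rng.random(n)
    for i in range(n):
        pi = p[i]
        if states[i] == 0 or w[i] < em.eps:
            hom_ref = (1 - pi) ** 2
            geno[i] = int(v[i] >= hom_ref) + int(v[i] >= hom_ref + 2 * pi * (1 - pi))
        else:
            geno[i] = 0 if v[i] < 1 - pi else 2
    return geno
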