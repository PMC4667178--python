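"""Single-point (marker-by-marker) inbreeding estimators.

These are the moment comparators to the multi-point HMM: the classic
excess-homozygosity F statistic computed against a set of reference
frequencies, and its admixture-aware variant that plugs in ancestry-
weighted individual allele frequencies.  In a structured sample evaluated
with pooled frequencies the moment estimator inherits the Wahlund bias;
individual frequencies remove it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MISSING = -1


@dataclass
class SinglePointEstimate:
    id: str
    f_hat: float  # raw moment estimate, may be negative
    freq_source: str

    @property
    def f_hat_trunc(self) -> float:
        """Negative estimates set to 0 (the convention used in comparisons)."""
        return max(self.f_hat, 0.0)


def moment_f(
    genotypes: np.ndarray,
    freqs: np.ndarray,
    ind_id: str = "",
    freq_source: str = "SAMPLE",
    unbiased: bool = False,
    n_sample: int | None = None,
) -> SinglePointEstimate:
    """Excess-homozygosity moment estimator of f.

    ``f_hat = (O_hom - E_hom) / (M - E_hom)`` where O_hom counts observed
    homozygotes over the M non-missing markers with frequency in (0,1) and
    ``E_hom = sum(1 - 2 p (1-p))`` is the HWE expectation.  With
    ``unbiased=True`` the small-sample correction ``2p(1-p) * 2n/(2n-1)``
    is applied (n = ``n_sample`` individuals behind the frequencies).
    """
    g = np.asarray(genotypes)
    p = np.asarray(freqs, dtype=float)
    use = (g != MISSING) & (p > 0) & (p < 1)
    if not use.any():
        raise ValueError("no usable markers (non-missing, frequency in (0,1))")
    g, p = g[use], p[use]
    m = len(g)
    het_exp = 2 * p * (1 - p)
    if unbiased:
        if not n_sample:
            raise ValueError("unbiased correction requires n_sample")
        het_exp = het_exp * (2 * n_sample) / (2 * n_sample - 1)
    e_hom = float(np.sum(1.0 - het_exp))
    o_hom = float(np.sum(g != 1))
    denom = m - e_hom
    if denom <= 0:
        raise ValueError("degenerate marker set: expected homozygosity equals M")
    return SinglePointEstimate(
        id=ind_id, f_hat=(o_hom - e_hom) / denom, freq_source=freq_source
    )


def individual_frequencies(
    q_a: float, p_pop_a: np.ndarray, p_pop_b: np.ndarray
) -> np.ndarray:
    """Ancestry-weighted per-marker frequencies for a two-way admixed
    individual: ``q_a * p_A + (1 - q_a) * p_B``."""
    if not 0 <= q_a <= 1:
        raise ValueError("ancestry proportion must be in [0,1]")
    return q_a * np.asarray(p_pop_a, dtype=float) + (1 - q_a) * np.asarray(
        p_pop_b, dtype=float
    )
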