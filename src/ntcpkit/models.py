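"""Radiobiological dose-response models.

Implements the Poisson single-dose response, the relative-seriality (RS)
normal tissue complication probability, the generalized equivalent uniform
dose (gEUD), the Lyman probit (LKB) complication probability, and a
linear-quadratic fractionation rescaling.

The RS product is evaluated in log space: with the shipped seriality
s = 1e-4 the naive per-bin product ``(1 - P**s) ** dv`` loses all
precision, while ``log(-expm1(s * log P))`` stays well conditioned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .dvh import DifferentialDVH, make_differential

__all__ = [
    "RSParams",
    "LKBParams",
    "RS_PRESETS",
    "poisson_response",
    "rs_ntcp",
    "geud",
    "lkb_ntcp",
    "max_normalized_slope",
    "eqd2_dvh",
]

LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class RSParams:
    """Relative-seriality model parameters.

    ``d50`` is the uniform whole-organ dose giving 50% response, ``gamma``
    the maximum normalized slope of the response curve, and ``s`` the
    relative seriality (s = 1 serial, s -> 0 parallel).
    """

    d50: float
    gamma: float
    s: float
    endpoint_label: str = ""

    def __post_init__(self) -> None:
        if self.d50 <= 0:
            raise ValueError("d50 must be positive")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.s <= 0:
            raise ValueError("s must be positive")


@dataclass(frozen=True)
class LKBParams:
    """Lyman-Kutcher-Burman model parameters (TD50, slope m, volume effect n).

    No preset values are shipped; they must be supplied explicitly.
    """

    td50: float
    m: float
    n: float
    endpoint_label: str = ""

    def __post_init__(self) -> None:
        if self.td50 <= 0:
            raise ValueError("td50 must be positive")
        if self.m <= 0:
            raise ValueError("m must be positive")
        if self.n <= 0:
            raise ValueError("n must be positive")


#: Published RS parameter sets for the two whole-brain-RT endpoints.
RS_PRESETS: dict[str, RSParams] = {
    "parotid_xerostomia_rs": RSParams(
        d50=24.9, gamma=0.26, s=1e-4, endpoint_label="xerostomia"
    ),
    "lacrimal_dryeye_rs": RSParams(
        d50=63.9, gamma=0.34, s=1e-4, endpoint_label="dry_eye"
    ),
}


def _log_poisson_response(dose, p: RSParams):
    """Natural log of the Poisson response, vectorized over dose."""
    dose = np.asarray(dose, dtype=float)
    if np.any(dose < 0):
        raise ValueError("dose must be non-negative")
    return -LN2 * np.exp(np.e * p.gamma * (1.0 - dose / p.d50))


def poisson_response(dose, p: RSParams):
    """Poisson dose-response P(D) = 2^(-exp(e * gamma * (1 - D/D50))).

    Strictly increasing in dose; equals 0.5 at D = D50 and approaches 1
    for large doses.  Accepts scalars or arrays.
    """
    out = np.exp(_log_poisson_response(dose, p))
    return float(out) if np.isscalar(dose) or np.ndim(dose) == 0 else out


def rs_ntcp(d: DifferentialDVH, p: RSParams) -> float:
    """Relative-seriality NTCP of a differential DVH.

    NTCP = [1 - prod_i (1 - P(D_i)^s)^dv_i]^(1/s), evaluated in log space.
    A single-bin DVH reduces exactly to ``poisson_response`` for any s.
    Bins with P = 0 contribute nothing to the product exponent; a bin with
    P numerically 1 forces NTCP = 1 (continuity limits).
    """
    logp = _log_poisson_response(d.bin_dose, p)  # <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        # 1 - P^s = -expm1(s * log P) in (0, 1]; log of it is <= 0.
        terms = np.log(-np.expm1(p.s * logp))
        # P = 0 bins: logp = -inf -> term = log(1) = 0.
        terms = np.where(np.isinf(logp), 0.0, terms)
        a = float(np.dot(d.bin_volume, terms))
        if np.isneginf(a):  # some bin has P = 1 and positive volume
            return 1.0
        inner = np.exp(a)  # prod_i (1 - P_i^s)^dv_i
        if inner >= 1.0:  # all volume at P = 0
            return 0.0
        return float(np.exp(np.log1p(-inner) / p.s))


def geud(d: DifferentialDVH, n: float) -> float:
    """Generalized equivalent uniform dose, (sum_i dv_i * D_i^(1/n))^n."""
    if n <= 0:
        raise ValueError("volume-effect parameter n must be positive")
    a = 1.0 / n
    return float(np.dot(d.bin_volume, np.power(d.bin_dose, a)) ** n)


def lkb_ntcp(d: DifferentialDVH, p: LKBParams) -> float:
    """LKB complication probability: probit of (gEUD - TD50) / (m * TD50)."""
    t = (geud(d, p.n) - p.td50) / (p.m * p.td50)
    return float(norm.cdf(t))


def max_normalized_slope(p: RSParams, step: float = 1e-4, upper: float = 3.0) -> float:
    """Numerically maximized slope of P with respect to normalized dose D/D50.

    Evaluates the response on a dense grid of D/D50 in [0, upper] and
    returns the largest central-difference slope.  For the Poisson form
    this equals gamma analytically; the grid search is the check.
    """
    x = np.arange(0.0, upper + step / 2, step)
    prob = poisson_response(x * p.d50, p)
    slope = np.gradient(prob, x)
    return float(slope.max())


def eqd2_dvh(d: DifferentialDVH, n_fractions: int, alpha_beta: float) -> DifferentialDVH:
    """Rescale each bin dose to its equi-effective dose in 2 Gy fractions.

    EQD2_i = D_i * (D_i / n_fractions + alpha/beta) / (2 + alpha/beta);
    volumes are unchanged.  Opt-in: the shipped parameter sets were fitted
    and applied at a single fractionation, so no correction is applied by
    default anywhere else in the package.
    """
    if n_fractions < 1:
        raise ValueError("n_fractions must be at least 1")
    if alpha_beta <= 0:
        raise ValueError("alpha_beta must be positive")
    dose = d.bin_dose * (d.bin_dose / n_fractions + alpha_beta) / (2.0 + alpha_beta)
    return make_differential(
        dose, d.bin_volume, label=d.structure_label, volume_cc=d.volume_cc
    )
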