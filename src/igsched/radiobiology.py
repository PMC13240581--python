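"""Radiobiological models: EQD2 conversion, Poisson-LQ TCP, gEUD, LKB NTCP.

TCP uses the Kallman (TCD50, gamma) parameterization of the Poisson
linear-quadratic response,

    P(D) = 2 ** ( -exp( e * gamma * (1 - D / TCD50) ) ),

with heterogeneous response over a differential DVH as the volume-weighted
product  TCP = prod_i P(D_i)^{v_i}  (uniform clonogen density).  NTCP follows
the Lyman-Kutcher-Burman model:  NTCP = Phi( (gEUD - TD50) / (m * TD50) )
with the generalized equivalent uniform dose
gEUD = ( sum_i v_i D_i^{1/n} )^n.  Dose axes are converted to the equivalent
dose in 2-Gy fractions, EQD2 = D (d + a/b) / (2 + a/b) with per-bin fraction
size d = D / n_fractions, before either model is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm

from .dvh import DVH

_E = float(np.e)
_EXP_GUARD = 700.0  # exp() overflow guard; beyond this the response is 0 anyway


@dataclass(frozen=True)
class TcpParams:
    """Target response parameters: TCD50 (Gy), normalized slope gamma, alpha/beta (Gy)."""

    tcd50: float
    gamma: float
    alpha_beta: float

    def __post_init__(self) -> None:
        if min(self.tcd50, self.gamma, self.alpha_beta) <= 0:
            raise ValueError("TCP parameters must all be positive")


@dataclass(frozen=True)
class NtcpParams:
    """LKB parameters: TD50 (Gy), slope m, volume exponent n, alpha/beta (Gy)."""

    td50: float
    m: float
    n: float
    alpha_beta: float
    endpoint: str = ""

    def __post_init__(self) -> None:
        if self.td50 <= 0 or self.m <= 0 or self.alpha_beta <= 0:
            raise ValueError("TD50, m and alpha/beta must be positive")
        if not (0 < self.n <= 1):
            raise ValueError("volume exponent n must lie in (0, 1]")


# Default parameter registry (breast chest-wall course; TCD50 from a
# multi-center adjuvant-radiotherapy tumor-control fit).
DEFAULT_TCP_PARAMS: dict[str, TcpParams] = {
    "PTVsc": TcpParams(tcd50=39.3, gamma=1.7, alpha_beta=4.0),
    "PTVcw": TcpParams(tcd50=39.3, gamma=1.7, alpha_beta=4.0),
}
DEFAULT_NTCP_PARAMS: dict[str, NtcpParams] = {
    "heart": NtcpParams(td50=48.0, m=0.1, n=0.35, alpha_beta=3.0, endpoint="pericarditis"),
    "lung_ipsi": NtcpParams(td50=30.8, m=0.18, n=0.87, alpha_beta=3.0, endpoint="pneumonitis"),
}


def eqd2(total_dose, n_fractions: int, alpha_beta: float):
    """Equivalent dose in 2-Gy fractions for ``total_dose`` given in
    ``n_fractions`` equal fractions:  EQD2 = D (d + a/b) / (2 + a/b),
    d = D / n_fractions.  Vectorized over ``total_dose``."""
    if n_fractions < 1:
        raise ValueError("n_fractions must be >= 1")
    if alpha_beta <= 0:
        raise ValueError("alpha/beta must be positive")
    d = np.asarray(total_dose, dtype=float)
    per_fx = d / n_fractions
    out = d * (per_fx + alpha_beta) / (2.0 + alpha_beta)
    return float(out) if np.isscalar(total_dose) else out


def dvh_to_eqd2(dvh: DVH, n_fractions: int, alpha_beta: float) -> DVH:
    """Transform a physical-dose DVH to the EQD2 domain (per-bin conversion).

    The dose axis is remapped bin by bin; cumulative volumes are unchanged.
    Resulting edges are nonuniform.
    """
    edges = eqd2(dvh.edges, n_fractions, alpha_beta)
    return DVH(dvh.structure, edges, dvh.cum_volume.copy(), dvh.n_voxels, bin_width=None)


def _differential(dvh: DVH) -> tuple[np.ndarray, np.ndarray]:
    doses, vols = dvh.differential()
    total = vols.sum()
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"differential DVH volumes sum to {total}, expected 1")
    return doses, vols


def poisson_tcp(dvh_eqd2: DVH, params: TcpParams) -> float:
    """Tumor control probability of a (EQD2-domain) DVH.

    Per-bin Poisson-LQ response combined as a volume-weighted product; the
    exponential is guarded so doses up to hundreds of Gy cannot overflow.
    """
    doses, vols = _differential(dvh_eqd2)
    arg = np.clip(_E * params.gamma * (1.0 - doses / params.tcd50), None, _EXP_GUARD)
    # P_i = 2^(-E_i)  =>  prod P_i^{v_i} = 2^(-sum v_i E_i)
    s = float(np.sum(vols * np.exp(arg)))
    return float(2.0 ** (-s))


def geud(dvh_eqd2: DVH, n: float) -> float:
    """Generalized equivalent uniform dose (sum_i v_i D_i^{1/n})^n.

    ``n = 1`` recovers the mean dose (parallel organ); ``n -> 0`` approaches
    the maximum dose (serial organ).  Evaluated in log space for stability at
    small ``n``.
    """
    if not (0 < n <= 1):
        raise ValueError("volume exponent n must lie in (0, 1]")
    doses, vols = _differential(dvh_eqd2)
    keep = vols > 0
    doses, vols = doses[keep], vols[keep]
    pos = doses > 0
    if not pos.any():
        return 0.0
    with np.errstate(divide="ignore"):
        log_terms = np.log(vols[pos]) + np.log(doses[pos]) / n
    return float(np.exp(n * logsumexp(log_terms)))


def lkb_ntcp(dvh_eqd2: DVH, params: NtcpParams) -> float:
    """LKB normal tissue complication probability of a (EQD2-domain) DVH."""
    eud = geud(dvh_eqd2, params.n)
    t = (eud - params.td50) / (params.m * params.td50)
    return float(norm.cdf(t))
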