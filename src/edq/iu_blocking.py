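"""Blocking probability of the inpatient unit modelled as a G/GI/c2/c2 loss system.

The IU has ``c2`` beds and no buffer: an arriving admission (transfer from
the ED or direct) that finds every bed occupied is blocked.  The blocking
probability is computed with a diffusion-style approximation driven by the
per-bed offered load ``rho_d`` and the stay-time SCV, with the classical
Erlang-B recurrence kept alongside as an exact M/M/c/c oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = ["IULoad", "BlockingResult", "blocking_probability", "erlang_b"]

# |beta| below this uses the analytic beta->0 limit of the formula (0/0 form).
_BETA_EPS = 1e-6


@dataclass(frozen=True)
class IULoad:
    """Offered load on the inpatient unit.

    ``lambda_transfer`` is the ED-to-IU transfer rate (x * R_d) and
    ``lambda_direct`` the direct admission rate, both in patients/hour.
    ``mu_I`` is the IU service rate 1/mean(LOS) in 1/hours and
    ``scv_service`` the squared coefficient of variation of the stay time.
    """

    c2: int
    mu_I: float
    lambda_transfer: float
    lambda_direct: float
    scv_service: float

    def __post_init__(self) -> None:
        if self.c2 < 1:
            raise ValueError("c2 must be >= 1")
        if self.mu_I <= 0:
            raise ValueError("mu_I must be positive")
        if self.lambda_transfer < 0 or self.lambda_direct < 0:
            raise ValueError("arrival rates must be non-negative")
        if self.scv_service < 0:
            raise ValueError("scv_service must be non-negative")


@dataclass(frozen=True)
class BlockingResult:
    """Blocking probability with its un-clamped diagnostic intermediates."""

    p_b: float
    rho_d: float
    beta: float
    k: float
    v: float
    alpha: float
    raw_p_b: float
    overloaded: bool


def _alpha(beta: float) -> float:
    # [1 + beta*Phi(beta)/phi(beta)]^-1 ; phi(beta) underflows for |beta|>~38,
    # where the blocking value is 0 to double precision anyway.
    phi = norm.pdf(beta)
    if phi == 0.0:
        return 0.0 if beta > 0 else 1.0
    return 1.0 / (1.0 + beta * norm.cdf(beta) / phi)


def blocking_probability(load: IULoad) -> BlockingResult:
    """Diffusion approximation of the loss probability of the c2-bed IU.

    rho_d = (lambda_transfer + lambda_direct) / (c2 * mu_I),
    beta = sqrt(c2)(1 - rho_d), k = sqrt(c2), v = (1 + C_a^2)/2,
    alpha = [1 + beta Phi(beta)/phi(beta)]^-1 and

        P_b = alpha * beta * exp(-k beta / v)
              / ((1 - exp(-k beta / v)) * rho_d * sqrt(c2)).

    At beta = 0 the 0/0 form is replaced by its analytic limit
    alpha * v / (c2 * rho_d).  The returned ``p_b`` is clamped to [0, 1]
    (the raw value is kept for diagnostics); zero traffic gives p_b = 0.
    """
    c2 = load.c2
    lam = load.lambda_transfer + load.lambda_direct
    rho_d = lam / (c2 * load.mu_I)
    k = np.sqrt(c2)
    v = (1.0 + load.scv_service) / 2.0
    beta = k * (1.0 - rho_d)
    alpha = _alpha(beta)
    if rho_d == 0.0:
        return BlockingResult(0.0, 0.0, beta, k, v, alpha, 0.0, False)
    with np.errstate(over="ignore", divide="ignore"):
        if abs(beta) < _BETA_EPS:
            raw = alpha * v / (c2 * rho_d)
        else:
            t = k * beta / v
            if t > 0:  # e^{-t} <= 1: evaluate as printed
                expo = np.exp(-t)
                raw = alpha * beta * expo / ((1.0 - expo) * rho_d * k)
            else:  # multiply through by e^{t}: avoids overflow for beta < 0
                raw = alpha * beta / (np.expm1(t) * rho_d * k)
    # vanishing offered load sends the printed expression to infinity;
    # the clamp below caps it at certain blocking (see module docs)
    p_b = float(min(max(raw, 0.0), 1.0))
    return BlockingResult(
        p_b=p_b, rho_d=float(rho_d), beta=float(beta), k=float(k), v=float(v),
        alpha=float(alpha), raw_p_b=float(raw), overloaded=bool(rho_d > 1.0),
    )


def blocking_probability_vec(c2: int, mu_I: float, total_arrival: np.ndarray,
                             scv_service: float) -> np.ndarray:
    """Vectorised clamped blocking probability over an array of arrival rates.

    Same formula as :func:`blocking_probability`; used by grid scans where
    per-point object construction would dominate the cost.
    """
    lam = np.asarray(total_arrival, dtype=float)
    rho_d = lam / (c2 * mu_I)
    k = np.sqrt(c2)
    v = (1.0 + scv_service) / 2.0
    beta = k * (1.0 - rho_d)
    phi = norm.pdf(beta)
    safe_rho = np.where(rho_d > 0, rho_d, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(phi > 0.0,
                         1.0 / (1.0 + beta * norm.cdf(beta) / np.where(phi > 0, phi, 1.0)),
                         np.where(beta > 0, 0.0, 1.0))
        t = k * beta / v
        pos = t > 0
        expo = np.exp(-np.abs(t))
        raw_pos = alpha * beta * expo / ((1.0 - expo) * safe_rho * k)
        raw_neg = alpha * beta / (np.expm1(np.where(pos, -1.0, t)) * safe_rho * k)
        raw = np.where(pos, raw_pos, raw_neg)
        limit = alpha * v / (c2 * safe_rho)
        raw = np.where(np.abs(beta) < _BETA_EPS, limit, raw)
    raw = np.where(rho_d == 0.0, 0.0, raw)
    return np.clip(np.nan_to_num(raw, nan=0.0, posinf=1.0, neginf=0.0), 0.0, 1.0)


def erlang_b(c: int, offered_load: float) -> float:
    """Exact Erlang-B loss probability via the stable recurrence.

    B(0) = 1, B(j) = a B(j-1) / (j + a B(j-1)).  Used as the classical
    M/M/c/c oracle against which the diffusion formula is sanity-checked.
    """
    if c < 1:
        raise ValueError("c must be >= 1")
    if offered_load < 0:
        raise ValueError("offered load must be >= 0")
    b = 1.0
    a = offered_load
    for j in range(1, c + 1):
        b = a * b / (j + a * b)
    return b
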