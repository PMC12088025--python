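"""The skilled-birth-attendance risk model and its recommendation rule.

A woman's risk of starting active labour without a skilled birth
attendant (SBA) is modelled as

    P(SBA) = 1 − Gk(t) · F(d)

where ``t`` is her estimated time (hours) to access an SBA from the
first signs of labour, ``Gk`` the parity-specific latent-phase duration
CDF, ``d`` the planned move date to a maternity waiting home (MWH) in
days relative to the expected due date (``+inf`` = no MWH stay, at
which ``F`` is 1 and the model reduces to ``1 − Gk(t)``), and ``F`` the
CDF of the labour-onset offset ADD − EDD.  Onset date and latent-phase
duration are assumed independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

from .distributions import NO_MWH, LatentPhaseDistribution, OnsetDistribution, Parity

__all__ = [
    "Scenario",
    "RiskEstimate",
    "Recommendation",
    "p_sba",
    "risk_category",
    "recommend_move_date",
    "DEFAULT_MOVE_DATES",
]

#: MWH scenarios in table order: no stay, on the EDD, then 1–4 weeks early.
DEFAULT_MOVE_DATES: tuple[float, ...] = (NO_MWH, 0.0, -7.0, -14.0, -21.0, -28.0)

RiskCategory = Literal["salmon", "light_green", "dark_green"]


@dataclass(frozen=True)
class Scenario:
    """One prediction case: parity, access time t (hours), move date d (days)."""

    parity: Parity
    access_time_t: float
    move_date_d: float = NO_MWH
    max_move_date: float = 0.0

    def __post_init__(self) -> None:
        if self.access_time_t < 0:
            raise ValueError("access time t must be >= 0 hours")
        if not (self.move_date_d == NO_MWH or self.move_date_d <= self.max_move_date):
            raise ValueError(
                f"move date d={self.move_date_d} must be <= {self.max_move_date} days "
                "relative to the EDD, or the no-MWH sentinel"
            )


@dataclass(frozen=True)
class RiskEstimate:
    """P(SBA) with its two model components and the display colour band."""

    p_sba: float
    gk_of_t: float
    f_of_d: float
    category: RiskCategory


def risk_category(p: float) -> RiskCategory:
    """Colour band for a P(SBA) value: salmon below 0.90, light green in
    [0.90, 0.95), dark green at or above 0.95."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability must lie in [0, 1], got {p}")
    if p < 0.90:
        return "salmon"
    if p < 0.95:
        return "light_green"
    return "dark_green"


def p_sba(
    scenario: Scenario,
    onset: OnsetDistribution,
    latent: LatentPhaseDistribution,
) -> RiskEstimate:
    """Evaluate P(SBA) = 1 − Gk(t)·F(d) for one scenario.

    With ``d = NO_MWH`` the onset factor is exactly 1, so the estimate
    reduces to ``1 − Gk(t)``.
    """
    if latent.parity != scenario.parity:
        raise ValueError(
            f"scenario is for a {scenario.parity} woman but the latent-phase "
            f"distribution is for {latent.parity} women"
        )
    g = float(latent.cdf(scenario.access_time_t))
    f = float(onset.cdf(scenario.move_date_d))
    p = 1.0 - g * f
    return RiskEstimate(p_sba=p, gk_of_t=g, f_of_d=f, category=risk_category(p))


@dataclass(frozen=True)
class Recommendation:
    """Outcome of the move-date rule: the chosen d and whether the
    threshold was met."""

    move_date_d: float
    p_sba: float
    met: bool


def recommend_move_date(
    parity: Parity,
    access_time_t: float,
    threshold: float,
    onset: OnsetDistribution,
    latent: LatentPhaseDistribution,
    candidates: Sequence[float] = DEFAULT_MOVE_DATES,
) -> Recommendation:
    """Pick the least burdensome MWH move date meeting a P(SBA) threshold.

    Candidates are considered from least burdensome (no MWH stay) to
    most (earliest move); the first whose P(SBA) reaches ``threshold``
    is returned.  If none qualifies, the candidate with the highest
    P(SBA) is returned flagged ``met=False`` — the device always
    displays all scenarios, so an unmeetable threshold is an answer,
    not an error.
    """
    if not candidates:
        raise ValueError("candidate move-date list must be non-empty")
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must lie in (0, 1], got {threshold}")
    ordered = sorted(set(float(d) for d in candidates), reverse=True)  # inf first
    best: Recommendation | None = None
    for d in ordered:
        est = p_sba(Scenario(parity, access_time_t, d), onset, latent)
        if est.p_sba >= threshold:
            return Recommendation(move_date_d=d, p_sba=est.p_sba, met=True)
        if best is None or est.p_sba > best.p_sba:
            best = Recommendation(move_date_d=d, p_sba=est.p_sba, met=False)
    return best


def parse_access_time(text: str) -> float:
    """Parse an access time given as decimal hours ("10.25") or as
    hours-and-minutes text ("10h15")."""
    s = text.strip().lower()
    if "h" in s:
        hours, _, minutes = s.partition("h")
        h = float(hours) if hours else 0.0
        m = float(minutes) if minutes else 0.0
        if m < 0 or m >= 60:
            raise ValueError(f"minutes must lie in [0, 60): {text!r}")
        return h + m / 60.0
    return float(s)


def parse_move_date(text: str) -> float:
    """Parse a move date: signed days, ``none`` (no MWH) or ``edd`` (0)."""
    s = text.strip().lower()
    if s in ("none", "no_mwh", "no-mwh", "inf", "+inf"):
        return NO_MWH
    if s == "edd":
        return 0.0
    return float(s)


def _move_date_key(d: float) -> str:
    """Stable column key for a move date (used by tables and exports)."""
    if math.isinf(d):
        return "no_mwh"
    if d == 0:
        return "on_edd"
    mag = abs(d)
    text = f"{mag:g}".replace(".", "p")
    return f"minus_{text}" if d < 0 else f"plus_{text}"
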