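"""Deaths-averted accounting.

Translates per-year effect estimates (deaths per 1,000 WRA; negative =
beneficial) into counts of lives saved using the WRA population at risk,
optionally discounts them by the share of the effect attributable to other
funding streams, and totals them over a reporting window.  Arithmetic is
kept at full precision internally; integer rounding happens only at report
boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ImpactLedger",
    "deaths_averted",
    "adjust_for_other_funding",
    "window_total",
    "build_ledger",
]


def deaths_averted(effect_per_1000, wra_pop):
    """Per-year lives saved: ``-effect x population / 1000``.

    A negative effect (mortality reduction) yields positive lives saved;
    harmful years come out negative and are deliberately not clipped.
    """
    effect = np.asarray(effect_per_1000, dtype=float)
    pop = np.asarray(wra_pop, dtype=float)
    if effect.shape != pop.shape:
        raise ValueError(f"length mismatch: {effect.shape} vs {pop.shape}")
    if np.any(pop <= 0):
        raise ValueError("populations must be positive")
    return -effect * pop / 1000.0


def adjust_for_other_funding(lives, share: float, round_counts: bool = True):
    """Discount lives saved by the share attributable to other funding.

    ``share`` is the fraction of the estimated effect credited to non-USG
    donors; the adjusted figure is ``lives x (1 - share)``, rounded to the
    nearest integer for count-scale reporting unless ``round_counts`` is
    off.
    """
    if not (0.0 <= share <= 1.0):
        raise ValueError(f"share must be in [0, 1], got {share}")
    adjusted = np.asarray(lives, dtype=float) * (1.0 - share)
    if round_counts:
        adjusted = np.round(adjusted)
    if np.ndim(lives) == 0:
        return float(adjusted)
    return adjusted


def window_total(annual, years: int | None = None):
    """Total lives saved over a reporting window.

    A scalar annual figure is multiplied by ``years``; a series is summed.
    Returns ``(total, total in millions rounded to 1 d.p.)``.
    """
    if np.ndim(annual) == 0:
        if years is None or years < 1:
            raise ValueError("scalar input needs years >= 1")
        total = float(annual) * years
    else:
        total = float(np.sum(np.asarray(annual, dtype=float)))
    return total, round(total / 1e6, 1)


@dataclass
class ImpactLedger:
    """Per-year deaths-averted record with adjustment and totals."""

    years: list[int]
    lives_saved: np.ndarray
    effect_source: str = "scm"
    adjustment_share: float = 0.0

    adjusted: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.lives_saved = np.asarray(self.lives_saved, dtype=float)
        self.adjusted = adjust_for_other_funding(
            self.lives_saved, self.adjustment_share, round_counts=False
        )

    @property
    def annual_mean(self) -> float:
        return float(self.lives_saved.mean())

    @property
    def annual_mean_adjusted(self) -> float:
        return float(self.adjusted.mean())

    @property
    def total(self) -> float:
        return float(self.lives_saved.sum())

    @property
    def total_adjusted(self) -> float:
        return float(self.adjusted.sum())

    def to_dict(self) -> dict:
        return {
            "effect_source": self.effect_source,
            "adjustment_share": self.adjustment_share,
            "per_year": {
                int(y): {"lives_saved": round(float(v)),
                         "lives_saved_adjusted": round(float(a))}
                for y, v, a in zip(self.years, self.lives_saved, self.adjusted)
            },
            "annual_mean": round(self.annual_mean),
            "annual_mean_adjusted": round(self.annual_mean_adjusted),
            "window_total": round(self.total),
            "window_total_adjusted": round(self.total_adjusted),
            "window_total_millions": window_total(self.lives_saved)[1],
            "window_total_adjusted_millions": window_total(self.adjusted)[1],
        }


def build_ledger(effect_series, wra_pop_series, years,
                 effect_source: str = "scm",
                 adjustment_share: float = 0.0) -> ImpactLedger:
    """Assemble an impact ledger from aligned effect and population series."""
    lives = deaths_averted(effect_series, wra_pop_series)
    return ImpactLedger(
        years=list(years), lives_saved=lives,
        effect_source=effect_source, adjustment_share=adjustment_share,
    )
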