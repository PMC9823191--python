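"""Techno-economic accounting of fermentation runs.

Per-mode cost ledgers (chemicals, consumables, labour) and production
cost per gram dry cell weight. Energy, equipment and rent are outside the
ledger by design: they vary too much between laboratory set-ups to
transfer.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["CostLedger", "labour_cost", "total_and_unit_cost", "cost_table"]


def labour_cost(rate_usd_h: float, workers: int, hours: float) -> float:
    """Labour = hourly rate x number of workers x hours."""
    if rate_usd_h < 0 or workers < 0 or hours < 0:
        raise ValueError("labour inputs must be >= 0")
    return rate_usd_h * workers * hours


@dataclass
class CostLedger:
    """Cost components of one fermentation run.

    Labour may be given directly (``labour_usd``) or derived from
    rate x workers x hours; a directly entered value wins, so ledgers can
    carry historical figures that do not match the formula.
    """

    mode: str
    chemicals_usd: float
    consumables_usd: float
    dcw_g: float
    labour_usd: float | None = None
    labour_rate_usd_h: float | None = None
    workers: int | None = None
    hours: float | None = None

    def __post_init__(self) -> None:
        if self.chemicals_usd < 0 or self.consumables_usd < 0:
            raise ValueError("cost components must be >= 0")
        if self.labour_usd is None:
            if None in (self.labour_rate_usd_h, self.workers, self.hours):
                raise ValueError(
                    "provide labour_usd or (labour_rate_usd_h, workers, hours)")
            self.labour_usd = labour_cost(
                self.labour_rate_usd_h, self.workers, self.hours)

    @property
    def total_usd(self) -> float:
        return self.chemicals_usd + self.consumables_usd + self.labour_usd


def total_and_unit_cost(ledger: CostLedger) -> tuple[float, float]:
    """(total USD, USD per g dry cell weight) for one ledger."""
    if ledger.dcw_g <= 0:
        raise ValueError("dcw_g must be > 0")
    total = ledger.total_usd
    return total, total / ledger.dcw_g


def cost_table(ledgers: list[CostLedger], ndigits: int = 2) -> pd.DataFrame:
    """Side-by-side cost report, unit cost rounded for display."""
    rows = []
    for lg in ledgers:
        total, unit = total_and_unit_cost(lg)
        rows.append({
            "mode": lg.mode,
            "chemicals_usd": lg.chemicals_usd,
            "consumables_usd": lg.consumables_usd,
            "labour_usd": lg.labour_usd,
            "total_usd": total,
            "dcw_g": lg.dcw_g,
            "usd_per_g_dcw": round(unit, ndigits),
        })
    return pd.DataFrame(rows)
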