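"""Accounting ledgers for sequential exclusion steps.

Every filtering stage of the pipeline (variant QC, gene-set refinement,
cohort assembly) records how many items each step removed and how many
remain, so that the bookkeeping ``removed + retained == previous retained``
can be checked at every step and exported as a table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import DataError


@dataclass
class LedgerStep:
    label: str
    removed: int
    retained: int


@dataclass
class Ledger:
    """Sequential exclusion accounting with conservation checking.

    Parameters
    ----------
    start_label : str
        Name of the initial pool (e.g. ``"participants"`` or ``"genes"``).
    start_count : int
        Size of the pool before any exclusion.
    """

    start_label: str
    start_count: int
    steps: list[LedgerStep] = field(default_factory=list)

    def exclude(self, label: str, removed: int) -> int:
        """Record a step removing ``removed`` items; returns the new retained count."""
        if removed < 0:
            raise DataError(f"ledger step {label!r}: negative removal count {removed}")
        current = self.retained
        if removed > current:
            raise DataError(
                f"ledger step {label!r}: cannot remove {removed} from {current} remaining"
            )
        self.steps.append(LedgerStep(label, removed, current - removed))
        return self.retained

    def add(self, label: str, added: int) -> int:
        """Record a merge step adding ``added`` items (e.g. merging a held-out group)."""
        if added < 0:
            raise DataError(f"ledger step {label!r}: negative addition count {added}")
        self.steps.append(LedgerStep(label, -added, self.retained + added))
        return self.retained

    @property
    def retained(self) -> int:
        return self.steps[-1].retained if self.steps else self.start_count

    def check(self) -> None:
        """Verify removed + retained equals the previous retained at every step."""
        prev = self.start_count
        for s in self.steps:
            if s.removed + s.retained != prev:
                raise DataError(
                    f"ledger conservation violated at {s.label!r}: "
                    f"{s.removed} + {s.retained} != {prev}"
                )
            prev = s.retained

    def to_frame(self) -> pd.DataFrame:
        rows = [{"step": self.start_label, "removed": 0, "retained": self.start_count}]
        rows += [{"step": s.label, "removed": s.removed, "retained": s.retained} for s in self.steps]
        return pd.DataFrame(rows)
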