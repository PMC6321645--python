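"""Stage bookkeeping: per-stage record counts and reconciliation.

Every pipeline stage logs how many records went in, came out, and were
filtered, so the run report can be reconciled line by line (inputs = outputs
+ filtered at every stage).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("wheatbsa")

__all__ = ["StageLog", "mean_called_sites"]


def mean_called_sites(totals) -> int:
    """Average per-bulk called-SNP totals for one reference, rounded to the
    nearest integer (the convention used for whole-table summary counts)."""
    arr = np.asarray(list(totals), dtype=float)
    if arr.size == 0:
        raise ValueError("no totals supplied")
    return int(np.floor(arr.mean() + 0.5))


@dataclass
class StageLog:
    """Accumulates (stage, n_in, n_out, n_filtered) rows and checks that they
    reconcile."""

    rows: list = field(default_factory=list)

    def add(self, stage: str, n_in: int, n_out: int, detail: str = "") -> None:
        n_filtered = n_in - n_out
        self.rows.append(
            {"stage": stage, "in": int(n_in), "out": int(n_out),
             "filtered": int(n_filtered), "detail": detail}
        )
        logger.info("%s: %d in, %d out, %d filtered %s", stage, n_in, n_out, n_filtered, detail)

    def reconciled(self) -> bool:
        return all(r["in"] == r["out"] + r["filtered"] for r in self.rows)

    def as_text(self) -> str:
        width = max((len(r["stage"]) for r in self.rows), default=5)
        lines = [f"{'stage'.ljust(width)}  {'in':>9} {'out':>9} {'filtered':>9}  detail"]
        for r in self.rows:
            lines.append(
                f"{r['stage'].ljust(width)}  {r['in']:>9} {r['out']:>9} {r['filtered']:>9}  {r['detail']}"
            )
        return "\n".join(lines)
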