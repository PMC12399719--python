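"""Stage bookkeeping shared by the prescreen and pose-filter stages."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass
class StageReport:
    """In/out counts of one pipeline stage.

    ``residual_pct`` is measured against the *first* stage's input size
    (``n_initial``), not against this stage's own input, so the column is a
    running fraction of the starting library that is still alive.
    """

    stage: str
    n_in: int
    n_out: int
    n_initial: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_out <= self.n_in):
            raise ValueError("need 0 <= n_out <= n_in")
        if self.n_initial <= 0:
            raise ValueError("n_initial must be positive")

    @property
    def residual_pct(self) -> float:
        return 100.0 * self.n_out / self.n_initial

    @property
    def residual_pct_rounded(self) -> float:
        """Residual percentage at two decimals, round-half-even."""
        return round(self.residual_pct, 2)

    def as_row(self) -> dict:
        return {
            "stage": self.stage,
            "n_in": self.n_in,
            "n_out": self.n_out,
            "residual_pct": f"{self.residual_pct_rounded:.2f}",
        }
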