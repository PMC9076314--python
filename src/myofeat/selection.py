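"""Greedy forward feature selection with a minimum-gain stopping rule.

Step 1 picks the single best-scoring feature; each later step tries the
current set plus every remaining candidate and accepts the best extension
only if it improves the score by at least ``min_gain`` (default 0.25
percentage points of the scored metric).  Ties break toward the earlier
pool position, so a run is fully reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

__all__ = ["SelectionTrace", "forward_select", "default_pool", "DEFAULT_POOL"]


#: The canonical 32-feature candidate pool: the two proposed nonlinear
#: features, sixteen classical time-domain features, four individually
#: selectable AR coefficients, the six TD-PSD descriptors, and the two
#: TSD-only descriptors.
DEFAULT_POOL: tuple[str, ...] = (
    "LMAV", "NSV",
    "MAV", "IEMG", "RMS", "VAR", "SSI", "WL", "ZC", "SSC", "WAMP", "MYOP",
    "LOGDET", "DAMV", "DASDV", "SKW", "KURT", "MOB", "COM", "MFL",
    "AR1", "AR2", "AR3", "AR4",
    "TDPSD_M0", "TDPSD_M0M2", "TDPSD_M0M4", "TDPSD_SPARSE", "TDPSD_IRF",
    "TDPSD_WLR",
    "TSD_COV", "TSD_TKEO",
)


def default_pool() -> list[str]:
    """The registry's canonical 32-feature selection pool."""
    return list(DEFAULT_POOL)


@dataclass
class SelectionTrace:
    """Record of one forward-selection run."""

    selected: list[str] = field(default_factory=list)
    scores: list[float] = field(default_factory=list)   # best score after each step
    gains: list[float] = field(default_factory=list)    # improvement at each step
    stop_reason: str = ""

    @property
    def final_score(self) -> float:
        return self.scores[-1] if self.scores else float("nan")

    def to_dict(self) -> dict:
        return {
            "selected": list(self.selected),
            "scores": list(self.scores),
            "gains": list(self.gains),
            "stop_reason": self.stop_reason,
        }


def forward_select(
    pool: Sequence[str],
    evaluator: Callable[[tuple[str, ...]], float],
    min_gain: float = 0.25,
) -> SelectionTrace:
    """Greedy forward selection over ``pool`` scored by ``evaluator``.

    ``evaluator`` maps a feature-name tuple to a score (higher is better)
    and must be deterministic.  The first feature is always accepted (the
    best single feature); subsequent candidates are accepted only while the
    best extension gains at least ``min_gain``.
    """
    pool = list(pool)
    if not pool:
        raise ValueError("empty candidate pool")
    trace = SelectionTrace()
    remaining = list(pool)
    current: list[str] = []
    current_score = float("-inf")
    while remaining:
        best_feat, best_score = None, float("-inf")
        for feat in remaining:  # pool order == tie-break order
            subset = tuple(current + [feat])
            try:
                score = float(evaluator(subset))
            except Exception as exc:
                raise RuntimeError(f"evaluator failed on subset {subset}") from exc
            if score > best_score:
                best_feat, best_score = feat, score
        gain = best_score - current_score
        if current and gain < min_gain:
            trace.stop_reason = (
                f"gain {gain:.4g} below min_gain {min_gain} "
                f"(best extension {best_feat!r})"
            )
            return trace
        current.append(best_feat)
        remaining.remove(best_feat)
        trace.selected.append(best_feat)
        trace.scores.append(best_score)
        trace.gains.append(gain if current_score > float("-inf") else best_score)
        current_score = best_score
        if len(current) == 1 and min_gain == float("inf"):
            trace.stop_reason = "min_gain is infinite: single best feature only"
            return trace
    trace.stop_reason = "pool exhausted"
    return trace
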