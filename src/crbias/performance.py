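"""Bias measures pooled across simulation repetitions.

For each event ``i`` three measures are computed from the per-repetition
estimates, each averaged over repetitions with a normal-approximation 95%
confidence interval (Monte-Carlo standard error of the mean):

* ``theta_RCT``  = E[Gamma_hat_i - Gamma_hat_i0]: difference of the
  subdistribution estimate from its counterpart in a paired hypothetical RCT
  population (rho = 0, pi = 0.5, same hazard parameters);
* ``theta_Exp``  = E[Gamma_hat_i - Gamma_i]: bias of the subdistribution
  estimate from the explicitly computed least-false effect at the current rho;
* ``theta_CSH``  = E[gamma_hat_i - gamma_i]: bias of the cause-specific
  estimate from the prescribed treatment effect.

``theta_RCT - theta_Exp`` isolates the bias due purely to the
confounder–treatment correlation (the remainder being omitted-variable bias).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .true_effects import TrueEffects

__all__ = [
    "ConsistencyError",
    "InsufficientReplicationError",
    "RepetitionRecord",
    "MEASURES",
    "compute_bias_measures",
    "write_bias_table",
    "read_bias_table",
]

MEASURES = ("theta_RCT", "theta_Exp", "theta_CSH")

_Z975 = 1.959963984540054  # standard-normal 97.5% quantile


class ConsistencyError(ValueError):
    """Truths were computed for different parameters than the records."""


class InsufficientReplicationError(ValueError):
    """Fewer than two repetitions: no Monte-Carlo standard error exists."""


@dataclass(frozen=True)
class RepetitionRecord:
    """Converged estimates from one repetition, for one event type."""

    rep: int
    event: int
    gamma_hat: float    # cause-specific (Cox) estimate
    Gamma_hat: float    # subdistribution (Fine-Gray) estimate
    Gamma_hat_rct: float  # subdistribution estimate in the paired RCT population


def compute_bias_measures(
    records: list[RepetitionRecord],
    truths: TrueEffects,
    *,
    rho: float | None = None,
    pi: float | None = None,
) -> pd.DataFrame:
    """Pool repetition records into the three bias measures per event.

    Returns a long-format table with columns
    ``event, measure, estimate, ci_low, ci_high, n_reps``.  When ``rho``/``pi``
    are given they are checked against the provenance stored in ``truths``
    (the least-false Gamma's are rho-specific, so mixing them up silently
    would corrupt ``theta_Exp``).
    """
    if rho is not None and not np.isclose(rho, truths.rho):
        raise ConsistencyError(
            f"records are for rho={rho} but truths were computed at rho={truths.rho}"
        )
    if pi is not None and not np.isclose(pi, truths.pi):
        raise ConsistencyError(
            f"records are for pi={pi} but truths were computed at pi={truths.pi}"
        )
    rows = []
    for event in (1, 2):
        recs = [r for r in records if r.event == event]
        if len(recs) < 2:
            raise InsufficientReplicationError(
                f"need at least 2 repetitions for event {event}, got {len(recs)}"
            )
        diffs = {
            "theta_RCT": np.array([r.Gamma_hat - r.Gamma_hat_rct for r in recs]),
            "theta_Exp": np.array([r.Gamma_hat - truths.Gamma(event) for r in recs]),
            "theta_CSH": np.array([r.gamma_hat - truths.gamma(event) for r in recs]),
        }
        for measure in MEASURES:
            d = diffs[measure]
            est = float(d.mean())
            se = float(d.std(ddof=1) / np.sqrt(d.size))
            rows.append(
                {
                    "event": event,
                    "measure": measure,
                    "estimate": est,
                    "ci_low": est - _Z975 * se,
                    "ci_high": est + _Z975 * se,
                    "n_reps": d.size,
                }
            )
    return pd.DataFrame(rows)


def write_bias_table(table: pd.DataFrame, path) -> None:
    """Write the long-format bias table (optionally with scenario columns)."""
    table.to_csv(path, index=False)


def read_bias_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
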