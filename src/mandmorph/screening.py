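"""Smirnov–Grubbs outlier screening of Procrustes distances to the mean.

Distances from a mean shape are non-negative and only unusually *large*
values indicate aberrant specimens, so the one-sided upper test is the
default.  The screen can run once (the study design removed a single
outlier before analysis) or iterate until no further outlier is found; an
optional hook lets the caller re-superimpose the retained specimens between
iterations so distances are always measured in the current shape space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import stats

__all__ = ["OutlierReport", "grubbs_critical_value", "grubbs_statistic", "grubbs_screen"]


@dataclass
class OutlierReport:
    """Result of a Grubbs screen.

    ``statistic`` and ``critical_value`` refer to the first test performed;
    ``outlier_ids`` records removals in order.  ``degenerate_sd`` flags a
    zero-variance sample in which no test is possible.
    """

    tested_n: int
    statistic: float
    critical_value: float
    alpha: float
    outlier_ids: list[str] = field(default_factory=list)
    degenerate_sd: bool = False
    rounds: list[dict] = field(default_factory=list)

    @property
    def n_removed(self) -> int:
        return len(self.outlier_ids)

    def to_dict(self) -> dict:
        return {
            "tested_n": self.tested_n,
            "statistic": self.statistic,
            "critical_value": self.critical_value,
            "alpha": self.alpha,
            "outlier_ids": list(self.outlier_ids),
            "degenerate_sd": self.degenerate_sd,
            "rounds": list(self.rounds),
        }


def grubbs_critical_value(n: int, alpha: float) -> float:
    """One-sided upper Grubbs critical value.

    G_crit = (n-1)/sqrt(n) * sqrt(t^2 / (n - 2 + t^2)) with
    t the upper alpha/n quantile of Student's t on n-2 degrees of freedom.
    """
    if n < 3:
        raise ValueError("Grubbs test requires n >= 3")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    t = stats.t.ppf(1.0 - alpha / n, n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))


def grubbs_statistic(values: np.ndarray) -> tuple[float, int]:
    """One-sided upper Grubbs statistic G = (max - mean)/sd and the index of
    the maximum.  Sample standard deviation (ddof=1)."""
    values = np.asarray(values, dtype=float)
    sd = values.std(ddof=1)
    idx = int(np.argmax(values))
    if sd == 0.0:
        return 0.0, idx
    return float((values[idx] - values.mean()) / sd), idx


def grubbs_screen(
    distances: np.ndarray,
    ids: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
    iterative: bool = False,
    recompute: Optional[Callable[[list[str]], np.ndarray]] = None,
) -> OutlierReport:
    """Screen to-mean Procrustes distances for outliers.

    Parameters
    ----------
    distances
        Distances of each specimen to the mean shape.
    ids
        Specimen identifiers (defaults to stringified indices).
    alpha
        Significance level of the test.
    iterative
        Repeat the test on the retained specimens until no outlier remains.
    recompute
        Optional hook called with the retained ids after each removal; must
        return fresh to-mean distances for those ids (e.g. after
        re-superimposition).  Without it, iteration simply drops the removed
        value.
    """
    distances = np.asarray(distances, dtype=float)
    if ids is None:
        ids = [str(i) for i in range(len(distances))]
    ids = [str(s) for s in ids]
    if len(ids) != len(distances):
        raise ValueError("ids and distances length mismatch")
    if len(distances) < 3:
        raise ValueError("Grubbs test requires n >= 3")

    current = distances.copy()
    current_ids = list(ids)
    report: Optional[OutlierReport] = None
    removed: list[str] = []
    rounds: list[dict] = []

    while True:
        n = len(current)
        if n < 3:
            break
        sd = current.std(ddof=1)
        if sd == 0.0:
            if report is None:
                report = OutlierReport(
                    tested_n=n,
                    statistic=0.0,
                    critical_value=grubbs_critical_value(n, alpha),
                    alpha=alpha,
                    degenerate_sd=True,
                )
            break
        G, idx = grubbs_statistic(current)
        crit = grubbs_critical_value(n, alpha)
        rounds.append(
            {"n": n, "statistic": G, "critical_value": crit,
             "candidate": current_ids[idx], "removed": bool(G > crit)}
        )
        if report is None:
            report = OutlierReport(
                tested_n=n, statistic=G, critical_value=crit, alpha=alpha
            )
        if G <= crit:
            break
        removed.append(current_ids[idx])
        current_ids.pop(idx)
        current = np.delete(current, idx)
        if not iterative:
            break
        if recompute is not None:
            current = np.asarray(recompute(list(current_ids)), dtype=float)
            if len(current) != len(current_ids):
                raise ValueError("recompute hook returned wrong length")

    assert report is not None
    report.outlier_ids = removed
    report.rounds = rounds
    return report
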