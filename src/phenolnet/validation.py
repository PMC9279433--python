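"""Validation of predicted outputs against metabolomics presence calls.

Predicted and measured presence are pooled over all (metabolite, sample)
cells of a fixed metabolite universe into one 2×2 contingency table, and the
association is quantified with a two-sided Fisher exact test, computed by
exact hypergeometric enumeration over all tables with the same margins
(probability-mass two-sided rule).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping

__all__ = ["ContingencyTable", "confusion_counts", "fisher_two_sided"]


@dataclass(frozen=True)
class ContingencyTable:
    """Confusion counts over (metabolite, sample) cells."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_counts(
    predicted: Mapping[str, set[str]],
    measured: Mapping[str, set[str]],
    universe: set[str],
) -> ContingencyTable:
    """Pool per-sample predicted/measured sets into one contingency table.

    The universe fixes which metabolites are scored (e.g. those whose
    prediction differs between model versions); measured calls outside it
    are ignored with a warning.  Counts sum over the samples present in
    ``predicted`` (missing measurement sets default to empty).
    """
    tp = fp = fn = tn = 0
    for sample in sorted(predicted):
        pred = predicted[sample] & universe
        meas_raw = measured.get(sample, set())
        outside = meas_raw - universe
        if outside:
            warnings.warn(
                f"sample {sample!r}: {len(outside)} measured metabolites "
                f"outside the scored universe were ignored")
        meas = meas_raw & universe
        tp += len(pred & meas)
        fp += len(pred - meas)
        fn += len(meas - pred)
        tn += len(universe - pred - meas)
    return ContingencyTable(tp=tp, fp=fp, fn=fn, tn=tn)


def fisher_two_sided(t: ContingencyTable) -> float:
    """Two-sided Fisher exact p-value by hypergeometric enumeration.

    Sums the probabilities of all tables with the observed margins whose
    probability does not exceed that of the observed table (comparison done
    in exact integer arithmetic, so no tolerance is involved).  A zero
    margin yields p = 1 by convention, with a warning.
    """
    a, b, c, d = t.tp, t.fp, t.fn, t.tn
    r1, r2 = a + b, c + d
    c1 = a + c
    n = t.total
    if n == 0 or 0 in (r1, r2, c1, b + d):
        warnings.warn("degenerate contingency table (zero margin); p = 1")
        return 1.0
    # table with first cell x has weight C(r1, x) * C(r2, c1 - x); the
    # common denominator C(n, c1) cancels in the <= comparison
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weight_obs = math.comb(r1, a) * math.comb(r2, c1 - a)
    num = 0
    for x in range(lo, hi + 1):
        w = math.comb(r1, x) * math.comb(r2, c1 - x)
        if w <= weight_obs:
            num += w
    return float(Fraction(num, math.comb(n, c1)))
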