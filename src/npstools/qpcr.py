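"""ChIP-qPCR quantification: percent input by the 2^(-dCt) method, replicate
summaries (mean +/- SEM) and unpaired two-tailed t-tests.

Percent input compares the IP signal to the total chromatin, correcting the
input Ct for the fraction of chromatin actually used as input:

    adjusted_input_Ct = Ct_input - log2(input_dilution)
    percent_input     = 100 * 2^(adjusted_input_Ct - Ct_IP)

With a 1% input (dilution 0.01), the adjustment adds log2(100) ~ 6.64
cycles. The dilution is a required column because it differs between
protocols and is never recoverable from the Ct values themselves.

Group comparisons use the classic Student's unpaired two-tailed t-test with
pooled variance (Welch's correction available by flag).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["QPCRMeasurement", "GroupSummary", "percent_input", "percent_input_table", "summarize_and_test"]


@dataclass(frozen=True)
class QPCRMeasurement:
    """One replicate at one locus: IP and input Ct plus the input dilution."""

    target_region: str
    strain: str
    replicate: str
    ct_ip: float
    ct_input: float
    input_dilution: float

    def __post_init__(self) -> None:
        for label, ct in (("Ct_IP", self.ct_ip), ("Ct_input", self.ct_input)):
            if not (math.isfinite(ct) and ct > 0):
                raise ValueError(f"{label} must be finite and > 0, got {ct}")
        if not (0 < self.input_dilution <= 1):
            raise ValueError(f"input_dilution must be in (0, 1], got {self.input_dilution}")


@dataclass(frozen=True)
class GroupSummary:
    """Mean +/- SEM per group and the unpaired two-tailed t-test between them."""

    mean_a: float
    sem_a: float
    n_a: int
    mean_b: float
    sem_b: float
    n_b: int
    t: float
    p: float
    welch: bool


def percent_input(m: QPCRMeasurement) -> float:
    """Percent input of one measurement by the dilution-corrected 2^(-dCt) method."""
    adjusted_input = m.ct_input - math.log2(m.input_dilution)
    value = 100.0 * 2.0 ** (adjusted_input - m.ct_ip)
    if not math.isfinite(value):
        raise ValueError(f"non-finite percent input from {m}")
    return value


def percent_input_table(table: pd.DataFrame) -> pd.DataFrame:
    """Vectorized percent input over a measurement table.

    Expects columns ``target_region, strain, replicate, Ct_IP, Ct_input,
    input_dilution``; returns a copy with a ``percent_input`` column.
    """
    required = {"target_region", "strain", "replicate", "Ct_IP", "Ct_input", "input_dilution"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    out = table.copy()
    adjusted = out["Ct_input"] - np.log2(out["input_dilution"])
    out["percent_input"] = 100.0 * np.power(2.0, adjusted - out["Ct_IP"])
    return out


def summarize_and_test(
    group_a: Sequence[float], group_b: Sequence[float], *, welch: bool = False
) -> GroupSummary:
    """Mean, SEM and unpaired two-tailed t-test p between two percent-input groups.

    The default is the pooled-variance Student's t-test; ``welch=True``
    drops the equal-variance assumption.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 replicates")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return GroupSummary(
        mean_a=float(a.mean()),
        sem_a=float(a.std(ddof=1) / math.sqrt(len(a))),
        n_a=len(a),
        mean_b=float(b.mean()),
        sem_b=float(b.std(ddof=1) / math.sqrt(len(b))),
        n_b=len(b),
        t=float(t),
        p=float(p),
        welch=welch,
    )
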