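"""Relative qPCR quantification by the 2^-ddCt method.

Target gene Ct values are normalized to a reference gene (beta-actin role)
within each sample (dCt = Ct_target - Ct_reference), then to a calibrator
group (ddCt = dCt - mean dCt of the reference group); relative quantity is
RQ = 2^-ddCt.  Group differences are tested on the replicate dCt values with
Welch's two-sample t-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import ttest_ind


def relative_quantity(ct_target: float, ct_reference: float,
                      calibrator_delta_ct: float) -> float:
    """RQ = 2^-(dCt - calibrator dCt); strictly positive."""
    for v in (ct_target, ct_reference, calibrator_delta_ct):
        if not math.isfinite(v):
            raise ValueError("Ct inputs must be finite")
    ddct = (ct_target - ct_reference) - calibrator_delta_ct
    return 2.0 ** (-ddct)


@dataclass(frozen=True)
class GroupComparison:
    gene: str
    mean_rq: dict[str, float]
    p_value: float
    direction: str  # up | down | none, relative to the comparison group


def compare_groups(measurements: pd.DataFrame, gene: str,
                   reference_group: str = "fine",
                   comparison_group: str = "coarse") -> GroupComparison:
    """Mean RQ per group and Welch-t p-value on replicate dCt values.

    ``measurements`` needs columns sample, group, gene, ct_target,
    ct_reference; the calibrator is the reference group's mean dCt, so the
    reference group's mean RQ is ~1 and the comparison group's mean RQ is its
    fold change.  Requires >= 2 replicates per group.
    """
    df = measurements[measurements["gene"] == gene]
    dct = {}
    for grp in (reference_group, comparison_group):
        sub = df[df["group"] == grp]
        if len(sub) < 2:
            raise ValueError(f"need >= 2 replicates in group {grp!r} for {gene}")
        dct[grp] = (sub["ct_target"] - sub["ct_reference"]).to_numpy(dtype=float)
    calibrator = float(np.mean(dct[reference_group]))
    mean_rq = {grp: float(np.mean(2.0 ** (-(v - calibrator))))
               for grp, v in dct.items()}
    p = float(ttest_ind(dct[comparison_group], dct[reference_group],
                        equal_var=False)[1])
    # lower dCt in the comparison group means higher expression
    diff = float(np.mean(dct[comparison_group]) - np.mean(dct[reference_group]))
    direction = "up" if diff < 0 else ("down" if diff > 0 else "none")
    return GroupComparison(gene=gene, mean_rq=mean_rq, p_value=p, direction=direction)
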