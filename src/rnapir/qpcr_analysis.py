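"""Relative quantification of qPCR and 3C-qPCR readouts (Livak 2^-ddCt).

Per replicate, dCt = Ct(target) - Ct(reference); ddCt is the difference of
group mean dCt (test minus control) and the fold change is 2^-ddCt. For
expression assays the reference is a housekeeping gene (IPO8 here); for
3C-qPCR the reference is a constitutive ligation junction (the ERCC3
interaction), so the same arithmetic yields a relative interaction
frequency. Standard errors are computed on the dCt scale, where the data
are approximately normal, and propagated as SE(ddCt) =
sqrt(SE_test^2 + SE_control^2); the reported fold interval
2^-(ddCt +/- SE) is asymmetric by construction. Group comparisons are
two-sided Welch t-tests on dCt with Bonferroni correction when several
comparisons are made.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CtMeasurement",
    "DdctResult",
    "read_ct_csv",
    "delta_ct",
    "delta_delta_ct",
    "ttest_bonferroni",
    "quantify_3c",
]

logger = logging.getLogger(__name__)

CT_COLUMNS = ("sample_id", "group", "target", "replicate", "ct")

DEFAULT_3C_REFERENCE = "ERCC3_interaction"


@dataclass(frozen=True)
class CtMeasurement:
    sample_id: str
    group: str
    target: str
    replicate: int
    ct: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.ct):
            raise ValueError(f"non-finite Ct for {self.sample_id}/{self.target}")


@dataclass(frozen=True)
class DdctResult:
    target: str
    reference: str
    control_group: str
    test_group: str
    delta_ct_control: float
    delta_ct_test: float
    ddct: float
    fold: float                  # 2^-ddCt, relative to the control group
    se_ddct: float
    fold_low: float              # 2^-(ddct + SE)
    fold_high: float             # 2^-(ddct - SE)
    n_control: int
    n_test: int
    p_raw: float
    p_adj: float

    def as_dict(self) -> dict:
        return {
            "target": self.target,
            "reference": self.reference,
            "control_group": self.control_group,
            "test_group": self.test_group,
            "ddct": self.ddct,
            "fold": self.fold,
            "se_ddct": self.se_ddct,
            "fold_low": self.fold_low,
            "fold_high": self.fold_high,
            "n_control": self.n_control,
            "n_test": self.n_test,
            "p_raw": self.p_raw,
            "p_adj": self.p_adj,
        }


def read_ct_csv(path: str | Path) -> pd.DataFrame:
    """Read a Ct table (CSV: sample_id, group, target, replicate, ct)."""
    df = pd.read_csv(path)
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    if not np.isfinite(df["ct"]).all():
        raise ValueError(f"{path}: non-finite Ct values")
    return df[list(CT_COLUMNS)]


def _as_frame(measurements: Sequence[CtMeasurement] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(measurements, pd.DataFrame):
        return measurements
    return pd.DataFrame([m.__dict__ for m in measurements])


def delta_ct(
    measurements: Sequence[CtMeasurement] | pd.DataFrame,
    target: str,
    reference: str,
    group: str,
) -> np.ndarray:
    """Per-unit dCt = Ct(target) - Ct(reference) for one group.

    Technical replicates of the same (sample_id, target) are averaged
    first; target and reference are then matched within sample_id, so each
    biological sample contributes one dCt. When every sample_id is unique
    per replicate, units are simply the replicates.
    """
    df = _as_frame(measurements)
    sub = df[df["group"] == group]
    if sub.empty:
        raise ValueError(f"no measurements for group {group!r}")
    for assay in (target, reference):
        if not (sub["target"] == assay).any():
            raise ValueError(f"group {group!r}: missing assay {assay!r}")
    mean_ct = sub.groupby(["sample_id", "target"])["ct"].mean().unstack()
    if target not in mean_ct or reference not in mean_ct:
        raise ValueError(f"group {group!r}: missing assay {target!r} or {reference!r}")
    pairs = mean_ct[[target, reference]].dropna()
    if pairs.empty:
        raise ValueError(
            f"group {group!r}: no sample has both {target!r} and {reference!r}"
        )
    return (pairs[target] - pairs[reference]).to_numpy(dtype=float)


def delta_delta_ct(
    measurements: Sequence[CtMeasurement] | pd.DataFrame,
    target: str,
    reference: str,
    control_group: str,
    test_group: str,
    n_comparisons: int = 1,
) -> DdctResult:
    """Livak relative quantification of *target* in test vs control group."""
    d_ctrl = delta_ct(measurements, target, reference, control_group)
    d_test = delta_ct(measurements, target, reference, test_group)
    if d_ctrl.size < 2 or d_test.size < 2:
        raise ValueError("need >=2 dCt units per group for a standard error")
    ddct = float(d_test.mean() - d_ctrl.mean())
    se = float(
        np.sqrt(
            d_test.var(ddof=1) / d_test.size + d_ctrl.var(ddof=1) / d_ctrl.size
        )
    )
    p_raw, p_adj = _welch_bonferroni(d_ctrl, d_test, n_comparisons)
    return DdctResult(
        target=target,
        reference=reference,
        control_group=control_group,
        test_group=test_group,
        delta_ct_control=float(d_ctrl.mean()),
        delta_ct_test=float(d_test.mean()),
        ddct=ddct,
        fold=float(2.0 ** -ddct),
        se_ddct=se,
        fold_low=float(2.0 ** -(ddct + se)),
        fold_high=float(2.0 ** -(ddct - se)),
        n_control=int(d_ctrl.size),
        n_test=int(d_test.size),
        p_raw=p_raw,
        p_adj=p_adj,
    )


def _welch_bonferroni(a: np.ndarray, b: np.ndarray, m: int) -> tuple[float, float]:
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            warnings.warn("zero variance in both groups with equal means; p = 1")
            return 1.0, 1.0
        return 0.0, 0.0  # deterministically different groups
    t = stats.ttest_ind(b, a, equal_var=False)
    p_raw = float(t.pvalue)
    return p_raw, min(1.0, m * p_raw)


def ttest_bonferroni(
    delta_ct_groups: Mapping[str, Sequence[float]],
    control_group: str = "control",
    m: int | None = None,
) -> dict[str, tuple[float, float]]:
    """Welch t-test of each non-control group's dCt against the control.

    Returns ``{group: (p_raw, p_adj)}`` with p_adj = min(1, m * p_raw);
    *m* defaults to the number of comparisons made.
    """
    if control_group not in delta_ct_groups:
        raise ValueError(f"control group {control_group!r} absent")
    others = [g for g in delta_ct_groups if g != control_group]
    if m is None:
        m = max(1, len(others))
    ctrl = np.asarray(delta_ct_groups[control_group], dtype=float)
    out: dict[str, tuple[float, float]] = {}
    for g in others:
        vals = np.asarray(delta_ct_groups[g], dtype=float)
        if ctrl.size < 2 or vals.size < 2:
            raise ValueError(f"group {g!r}: need >=2 values per group")
        out[g] = _welch_bonferroni(ctrl, vals, m)
    return out


def quantify_3c(
    measurements: Sequence[CtMeasurement] | pd.DataFrame,
    junction: str,
    control_group: str,
    test_group: str,
    reference: str = DEFAULT_3C_REFERENCE,
    n_comparisons: int = 1,
) -> DdctResult:
    """Relative interaction frequency of a 3C ligation junction.

    Same dCt arithmetic as expression quantification, with a constitutive
    interaction (ERCC3 by default) as the internal reference; ``fold`` is
    the interaction frequency in the test group relative to control.
    """
    return delta_delta_ct(
        measurements, junction, reference, control_group, test_group, n_comparisons
    )
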