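"""Efficiency-corrected relative quantification of qPCR data.

Implements the ratio form of relative quantification (Pfaffl): for a
target assay with amplification base E_t and a reference assay with base
E_r,

    ratio = E_t**(dCq_target) / E_r**(dCq_reference)

where dCq = mean Cq(control) - mean Cq(case).  With both efficiencies at
100% (E = 2) this reduces exactly to the familiar 2^-ddCq.  Technical
replicates are averaged on the Cq scale; biological replicates are
summarized by the geometric mean of per-sample ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

EFFICIENCY_MIN_PCT = 50.0
EFFICIENCY_MAX_PCT = 110.0


@dataclass(frozen=True)
class CqMeasurement:
    """One quantification-cycle reading."""

    sample_id: str
    group: str  # "case" | "control"
    target: str
    cq: float
    efficiency_pct: float = 100.0

    def __post_init__(self) -> None:
        if not 0 < self.cq < 45:
            raise ValueError("Cq must lie inside the run's 45 cycles")
        if self.group not in ("case", "control"):
            raise ValueError("group must be 'case' or 'control'")
        if not EFFICIENCY_MIN_PCT <= self.efficiency_pct <= EFFICIENCY_MAX_PCT:
            raise ValueError("efficiency percent out of plausible range")


@dataclass(frozen=True)
class RelExprResult:
    """Fold change of a target in case vs control, reference-normalized."""

    target: str
    ratio: float
    per_sample: dict[str, float]

    def __post_init__(self) -> None:
        if self.ratio <= 0:
            raise ValueError("ratio must be positive")


def amplification_base(efficiency_pct: float) -> float:
    """Per-cycle amplification factor E = 1 + efficiency/100."""
    if not EFFICIENCY_MIN_PCT <= efficiency_pct <= EFFICIENCY_MAX_PCT:
        raise ValueError(
            f"efficiency {efficiency_pct}% outside "
            f"[{EFFICIENCY_MIN_PCT}, {EFFICIENCY_MAX_PCT}]"
        )
    return 1.0 + efficiency_pct / 100.0


def relative_ratio(
    target_case_cq: float,
    target_control_cq: float,
    reference_case_cq: float,
    reference_control_cq: float,
    e_target: float = 2.0,
    e_reference: float = 2.0,
) -> float:
    """Efficiency-corrected case/control expression ratio.

    ratio = E_t^(Cq_t,control - Cq_t,case) / E_r^(Cq_r,control - Cq_r,case)
    """
    for cq in (target_case_cq, target_control_cq, reference_case_cq, reference_control_cq):
        if cq is None or not math.isfinite(cq):
            raise ValueError("all four mean Cq values are required")
    num = e_target ** (target_control_cq - target_case_cq)
    den = e_reference ** (reference_control_cq - reference_case_cq)
    return num / den


def relative_expression(
    measurements: Iterable[CqMeasurement],
    target: str,
    reference: str,
) -> RelExprResult:
    """Per-sample Pfaffl ratios against the control-group mean Cq.

    Technical replicates (same sample, group, target) are first averaged
    on the Cq scale.  Each case sample's ratio uses the control-group
    mean Cq of target and reference as calibrator; the reported fold
    change is the geometric mean over case samples.
    """
    df = pd.DataFrame([m.__dict__ for m in measurements])
    if df.empty:
        raise ValueError("no measurements")
    for gene in (target, reference):
        if gene not in set(df["target"]):
            raise ValueError(f"no Cq measurements for {gene!r}")
    eff = df.groupby("target")["efficiency_pct"].mean()
    e_t = amplification_base(float(eff[target]))
    e_r = amplification_base(float(eff[reference]))
    cq = (
        df.groupby(["target", "group", "sample_id"])["cq"].mean().rename("cq").reset_index()
    )

    def control_mean(gene: str) -> float:
        sel = cq[(cq["target"] == gene) & (cq["group"] == "control")]["cq"]
        if sel.empty:
            raise ValueError(f"missing control Cq for {gene!r}")
        return float(sel.mean())

    cal_t, cal_r = control_mean(target), control_mean(reference)
    per_sample: dict[str, float] = {}
    cases = sorted(set(cq[cq["group"] == "case"]["sample_id"]))
    if not cases:
        raise ValueError("no case samples")
    for sid in cases:
        t_cq = cq[(cq["target"] == target) & (cq["sample_id"] == sid) & (cq["group"] == "case")]["cq"]
        r_cq = cq[(cq["target"] == reference) & (cq["sample_id"] == sid) & (cq["group"] == "case")]["cq"]
        if t_cq.empty or r_cq.empty:
            raise ValueError(f"sample {sid!r} lacks target or reference Cq")
        per_sample[sid] = relative_ratio(
            float(t_cq.iloc[0]), cal_t, float(r_cq.iloc[0]), cal_r, e_t, e_r
        )
    ratio = float(np.exp(np.mean(np.log(list(per_sample.values())))))
    return RelExprResult(target, ratio, per_sample)


def read_cq_tsv(path: str | Path) -> list[CqMeasurement]:
    """Read measurements from TSV with columns
    sample_id, group, target, cq, efficiency_pct."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        out.append(
            CqMeasurement(
                str(row["sample_id"]),
                str(row["group"]),
                str(row["target"]),
                float(row["cq"]),
                float(row.get("efficiency_pct", 100.0)),
            )
        )
    return out
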