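"""Reporter-assay arithmetic: ΔΔCT repair efficiency and GFP-fraction ratios.

The qPCR-based end-joining readout uses the comparative-CT method against an
internal-control probe: ΔCT = CT(target) − CT(reference) within each sample,
ΔΔCT = ΔCT(sample) − ΔCT(control), relative efficiency = 2^(−ΔΔCT), so the
control condition is 1 (100%) by construction.  Flow-based GFP reporter
readouts are normalized the same way: sample GFP-positive fraction divided
by the control fraction.  No amplification-efficiency correction is applied.
Technical-replicate CT values are averaged before ΔΔCT; spread (SEM) is
propagated across biological replicates only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

Number = Union[float, int]
CtValue = Union[Number, Sequence[Number]]  # scalar or technical replicates


def _mean_ct(value: CtValue, name: str) -> float:
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    if arr.size == 0 or not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError(f"{name} must be positive and finite, got {value!r}")
    return float(arr.mean())


@dataclass
class QpcrMeasurement:
    """One sample's CT values; either may carry technical replicates."""

    ct_target: CtValue
    ct_reference: CtValue
    condition: str = ""
    replicate_id: int = 0

    @property
    def delta_ct(self) -> float:
        return _mean_ct(self.ct_target, "ct_target") - _mean_ct(self.ct_reference, "ct_reference")


@dataclass
class RepairEfficiency:
    relative_efficiency: float          # control = 1
    condition: str = ""
    sem: Optional[float] = None

    @property
    def percent(self) -> float:
        return 100.0 * self.relative_efficiency


def ddct_efficiency(sample: QpcrMeasurement, control: QpcrMeasurement) -> RepairEfficiency:
    """Comparative-CT relative repair efficiency, 2^(−ΔΔCT)."""
    ddct = sample.delta_ct - control.delta_ct
    return RepairEfficiency(relative_efficiency=float(2.0 ** (-ddct)),
                            condition=sample.condition)


def ddct_efficiency_replicates(
    samples: Sequence[QpcrMeasurement], controls: Sequence[QpcrMeasurement]
) -> RepairEfficiency:
    """Per-biological-replicate ΔΔCT efficiencies, summarized as mean ± SEM.

    Replicates are paired by position (sample i against control i).
    """
    if len(samples) != len(controls) or len(samples) == 0:
        raise ValueError("need equal, non-zero numbers of sample and control replicates")
    vals = np.array([ddct_efficiency(s, c).relative_efficiency
                     for s, c in zip(samples, controls)])
    sem = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else None
    return RepairEfficiency(relative_efficiency=float(vals.mean()),
                            condition=samples[0].condition, sem=sem)


def gfp_relative(sample_gfp_fraction: float, control_gfp_fraction: float,
                 condition: str = "") -> RepairEfficiency:
    """GFP-positive fraction normalized so the control condition equals 1."""
    for name, v in (("sample_gfp_fraction", sample_gfp_fraction),
                    ("control_gfp_fraction", control_gfp_fraction)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    if control_gfp_fraction == 0:
        raise ValueError("control_gfp_fraction must be > 0")
    return RepairEfficiency(
        relative_efficiency=sample_gfp_fraction / control_gfp_fraction,
        condition=condition,
    )
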