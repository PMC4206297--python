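"""Per-nucleus phenotype classification: diffuse / foci / diffuse-with-foci.

A nucleus is scored from two features: its detected focus count and the
ratio rho = mean nucleoplasm intensity / reference diffuse intensity of the
unirradiated cohort.  Nuclei without an appreciable number of foci are
"diffuse"; focus-bearing nuclei with a depleted nucleoplasm (rho low) are
"foci"; focus-bearing nuclei whose nucleoplasm is back at the reference
level (e.g. proteasome blocked while synthesis continues) are
"diffuse_with_foci".  Intermediate rho is assigned to the nearer class.
Per-condition fractions are summarized as mean +/- SEM across replicates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .foci import NucleusIntensityRecord

PHENOTYPES = ("diffuse", "foci", "diffuse_with_foci")


@dataclass(frozen=True)
class PhenotypeThresholds:
    f_min: int = 5         # minimum focus count to call foci present
    rho_lo: float = 0.3    # below: nucleoplasm depleted
    rho_hi: float = 0.7    # at or above: nucleoplasm at reference level

    def validate(self) -> None:
        if self.f_min < 1:
            raise ValueError("f_min must be >= 1")
        if not (0.0 <= self.rho_lo < self.rho_hi):
            raise ValueError(
                f"need 0 <= rho_lo < rho_hi, got rho_lo={self.rho_lo}, rho_hi={self.rho_hi}"
            )


@dataclass
class PhenotypeCall:
    label: str
    focus_count: int
    rho: float             # nucleoplasm-to-reference ratio


def classify_nucleus(
    record: NucleusIntensityRecord,
    reference: float,
    thresholds: PhenotypeThresholds = PhenotypeThresholds(),
) -> PhenotypeCall:
    """Deterministic phenotype call for one nucleus.

    Rule (rho = mean_nucleoplasm / reference, F = focus_count):
      * F <  f_min                -> diffuse (no focus pattern to score)
      * F >= f_min, rho <  rho_lo -> foci
      * F >= f_min, rho >= rho_hi -> diffuse_with_foci
      * F >= f_min, intermediate  -> nearer of the two boundaries,
                                     ties -> diffuse_with_foci
    """
    thresholds.validate()
    if not np.isfinite(reference) or reference <= 0:
        raise ValueError(f"reference must be positive, got {reference}")
    rho = record.mean_nucleoplasm / reference
    f = record.focus_count
    if f < thresholds.f_min:
        label = "diffuse"
    elif rho < thresholds.rho_lo:
        label = "foci"
    elif rho >= thresholds.rho_hi:
        label = "diffuse_with_foci"
    else:
        label = "foci" if abs(rho - thresholds.rho_lo) < abs(rho - thresholds.rho_hi) \
            else "diffuse_with_foci"
    return PhenotypeCall(label=label, focus_count=f, rho=float(rho))


def phenotype_fractions(labels_per_replicate: Sequence[Sequence[str]]) -> pd.DataFrame:
    """Per-class percentages with mean +/- SEM across replicates.

    ``labels_per_replicate`` is one list of phenotype labels per replicate.
    Within each replicate the three class percentages sum to exactly 100.
    SEM is the across-replicate standard deviation / sqrt(N); NaN for N = 1.
    """
    if len(labels_per_replicate) == 0:
        raise ValueError("at least one replicate is required")
    per_rep = []
    for i, labels in enumerate(labels_per_replicate):
        labels = list(labels)
        if len(labels) == 0:
            raise ValueError(f"replicate {i} contains no nuclei")
        unknown = set(labels) - set(PHENOTYPES)
        if unknown:
            raise ValueError(f"unknown phenotype labels: {sorted(unknown)}")
        n = len(labels)
        per_rep.append({p: 100.0 * labels.count(p) / n for p in PHENOTYPES})
    table = pd.DataFrame(per_rep, index=[f"replicate_{i+1}" for i in range(len(per_rep))])
    n_rep = len(per_rep)
    summary = pd.DataFrame({
        "mean_pct": table.mean(axis=0),
        "sem_pct": table.std(axis=0, ddof=1) / np.sqrt(n_rep) if n_rep > 1
                   else pd.Series(np.nan, index=table.columns),
    })
    summary.index.name = "phenotype"
    for col in table.index:
        summary[col] = table.loc[col]
    return summary
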