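"""ChIP fold enrichment at telomeres, normalized to a control locus.

Quantifies how strongly a telomere-associated protein (e.g. Rif1 or Rif2)
is bound at telomeric repeats relative to a non-telomeric control locus
(ARO1), correcting for input chromatin:

    fold = (tel_IP / ARO1_IP) / (tel_input / ARO1_input)

Replicates are summarized by the geometric mean (folds are ratio-scale) and
condition effects (e.g. ethanol vs control growth) as the ratio of summarized
folds, so 0.5 reads as a two-fold depletion under stress.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ChipMeasurement",
    "EnrichmentResult",
    "fold_enrichment",
    "relative_change",
    "summarize_replicates",
    "ct_to_quantity",
]


@dataclass(frozen=True)
class ChipMeasurement:
    """One qPCR quantification quadruple (linear-scale quantities)."""

    tel_ip: float
    aro_ip: float
    tel_input: float
    aro_input: float
    condition: str = ""
    replicate: int = 0

    def __post_init__(self) -> None:
        for name in ("tel_ip", "aro_ip", "tel_input", "aro_input"):
            v = getattr(self, name)
            if not (v > 0):
                raise ValueError(f"{name} must be strictly positive, got {v}")


@dataclass(frozen=True)
class EnrichmentResult:
    fold: float
    log2_fold: float
    n_replicates: int
    spread: float  # SD of per-replicate log2 folds

    def __post_init__(self) -> None:
        if self.fold <= 0:
            raise ValueError("fold must be positive")


def fold_enrichment(m: ChipMeasurement) -> float:
    """Telomere fold enrichment: (tel_IP/ARO1_IP) / (tel_input/ARO1_input)."""
    return (m.tel_ip / m.aro_ip) / (m.tel_input / m.aro_input)


def summarize_replicates(measurements, method: str = "geometric") -> EnrichmentResult:
    """Combine replicate folds for one condition.

    Geometric mean by default (arithmetic behind `method='arithmetic'`);
    spread is the SD of the per-replicate log2 folds.
    """
    measurements = list(measurements)
    if not measurements:
        raise ValueError("need >= 1 replicate")
    conditions = {m.condition for m in measurements}
    if len(conditions) > 1:
        raise ValueError(f"mixed conditions in one summary: {sorted(conditions)}")
    folds = np.array([fold_enrichment(m) for m in measurements])
    log2f = np.log2(folds)
    if method == "geometric":
        fold = float(2.0 ** log2f.mean())
    elif method == "arithmetic":
        fold = float(folds.mean())
    else:
        raise ValueError(f"unknown method {method!r}")
    spread = float(log2f.std(ddof=1)) if len(folds) > 1 else 0.0
    return EnrichmentResult(
        fold=fold, log2_fold=float(np.log2(fold)), n_replicates=len(folds), spread=spread
    )


def relative_change(stress: EnrichmentResult, control: EnrichmentResult) -> float:
    """Stress fold over control fold; 0.5 = two-fold reduction under stress."""
    return stress.fold / control.fold


def ct_to_quantity(ct, efficiency: float = 2.0):
    """Convert a qPCR cycle-threshold value to a relative quantity.

    quantity = efficiency ** (-Ct); with perfect doubling (efficiency 2) one
    fewer cycle means twice the template.
    """
    if not (1.0 < efficiency <= 2.0):
        raise ValueError("efficiency must be in (1, 2]")
    return efficiency ** (-np.asarray(ct, dtype=float))
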