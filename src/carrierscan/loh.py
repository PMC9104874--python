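"""Loss-of-heterozygosity calling from tumour/normal allele fractions.

A germline heterozygous carrier has a variant allele fraction (VAF)
near 0.5 in normal tissue. Somatic loss of the wild-type allele pushes
the tumour VAF of the germline variant towards 1: in a tumour of
purity ``p`` where every tumour cell has deleted the wild-type allele,
the expected VAF is ``1 / (2 - p)`` (tumour cells contribute one
variant allele each, admixed normal cells one variant and one
wild-type allele each). The caller classifies each observation from
the wild-type allele fraction ``1 - tumour_vaf`` with explicit,
configurable thresholds that replace visual chromatogram inspection;
the defaults are declared conventions of this package, not published
cut-offs. Partial loss is read as allelic imbalance compatible with
contaminating normal stromal cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum


class LOHState(str, Enum):
    RETAINED_HET = "retained_het"
    PARTIAL_LOSS = "partial_loss"
    COMPLETE_LOSS = "complete_loss"
    UNINFORMATIVE = "uninformative"


class Preservation(str, Enum):
    FRESH_FROZEN = "fresh_frozen"
    FFPE = "FFPE"


@dataclass(frozen=True)
class LOHObservation:
    """One tumour/normal allele-fraction measurement for one carrier."""

    carrier_id: str
    variant_id: str
    tissue: str
    preservation: Preservation
    normal_vaf: float
    tumour_vaf: float
    tumour_depth: int

    def __post_init__(self) -> None:
        for name in ("normal_vaf", "tumour_vaf"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} {value} outside [0, 1]")
        if self.tumour_depth < 0:
            raise ValueError("tumour_depth must be non-negative")


@dataclass(frozen=True)
class LOHThresholds:
    """Decision thresholds on the wild-type allele fraction (wtf).

    complete loss: wtf < ``complete_max`` (default 0.10)
    partial loss:  complete_max <= wtf < ``partial_max`` (default 0.35)
    retained het:  wtf >= partial_max
    uninformative: tumour depth < ``depth_min`` (default 20) or the
    germline is not credibly heterozygous (normal VAF outside
    [``het_min``, ``het_max``], default [0.2, 0.8]).
    """

    complete_max: float = 0.10
    partial_max: float = 0.35
    depth_min: int = 20
    het_min: float = 0.20
    het_max: float = 0.80

    def __post_init__(self) -> None:
        if not 0.0 < self.complete_max < self.partial_max <= 1.0:
            raise ValueError("require 0 < complete_max < partial_max <= 1")


@dataclass(frozen=True)
class LOHCall:
    state: LOHState
    wild_type_fraction: float


def call_loh(obs: LOHObservation, thresholds: LOHThresholds | None = None) -> LOHCall:
    """Classify one observation as retained/partial/complete loss.

    Monotone in tumour VAF: increasing the tumour VAF never moves the
    call away from complete loss.
    """
    t = thresholds or LOHThresholds()
    wtf = 1.0 - obs.tumour_vaf
    if obs.tumour_depth < t.depth_min or not t.het_min <= obs.normal_vaf <= t.het_max:
        return LOHCall(state=LOHState.UNINFORMATIVE, wild_type_fraction=wtf)
    # 1e-9 guard so a wtf that equals a threshold up to float rounding
    # (e.g. 1 - 0.9) lands on the inclusive side
    if wtf < t.complete_max - 1e-9:
        state = LOHState.COMPLETE_LOSS
    elif wtf < t.partial_max - 1e-9:
        state = LOHState.PARTIAL_LOSS
    else:
        state = LOHState.RETAINED_HET
    return LOHCall(state=state, wild_type_fraction=wtf)


def expected_variant_fraction(purity: float, state: LOHState) -> float:
    """Expected tumour VAF for a given tumour purity and somatic state.

    With wild-type-allele deletion in every tumour cell, allele
    counting over a purity-``p`` mixture gives ``1 / (2 - p)``; a
    retained heterozygous tumour stays at 0.5.
    """
    if not 0.0 <= purity <= 1.0:
        raise ValueError(f"purity {purity} outside [0, 1]")
    if state in (LOHState.COMPLETE_LOSS, LOHState.PARTIAL_LOSS):
        return 1.0 / (2.0 - purity)
    return 0.5


def min_purity_for_complete_loss(thresholds: LOHThresholds | None = None) -> float:
    """Purity above which a noise-free deletion is called complete loss.

    Solves 1/(2-p) > 1 - complete_max; with the default 0.10 threshold
    this gives p > 8/9.
    """
    t = thresholds or LOHThresholds()
    return 2.0 - 1.0 / (1.0 - t.complete_max)
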