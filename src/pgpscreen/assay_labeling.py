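"""Assay-readout thresholding into Y/N class labels.

Three assays define the class labels:

* **Inhibition** (calcein-AM): readout is the percent of the maximum
  fluorescence response produced by the reference inhibitor elacridar.
  Responses below 10% of the maximum are negative.  Responses between 6%
  and 12% fall in a non-confident zone where the binary call is less
  reliable; the Y/N value is still assigned by the 10% cut-off.
* **ATPase activation**: readout is fold-stimulation of vanadate-sensitive
  ATPase activity over the DMSO control.  A compound is an activator when
  the fold-stimulation exceeds 2; [1.5, 2.0] is the non-confident range.
* **Monolayer efflux**: readout is the B→A/A→B apparent-permeability ratio.
  Ratios ≥ 2.1 indicate P-gp-mediated efflux; ratios in [1.5, 2.0] require
  a follow-up experiment with elacridar to decide the call.

The (inhibition, ATPase, efflux) label triple maps onto a profile category:
Y/N/N is a "true" inhibitor, Y/Y/Y a substrate, N/N/N a non-substrate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .core_io import ClassLabel, ProfileCategory

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AssayThresholds:
    """Cut-offs and non-confident zones for the three assays.

    Units: ``inhibition_min_pct`` is percent of the elacridar maximum
    response; ``atpase_fold_min`` is fold-stimulation over the DMSO
    control; ``efflux_ratio_min`` is the dimensionless B→A/A→B ratio.
    """

    inhibition_min_pct: float = 10.0
    atpase_fold_min: float = 2.0
    efflux_ratio_min: float = 2.1
    inhibition_nonconfident: tuple[float, float] = (6.0, 12.0)
    atpase_nonconfident: tuple[float, float] = (1.5, 2.0)
    efflux_followup: tuple[float, float] = (1.5, 2.0)

    def __post_init__(self) -> None:
        for v in (self.inhibition_min_pct, self.atpase_fold_min, self.efflux_ratio_min):
            if v <= 0:
                raise ValueError("thresholds must be strictly positive")
        for lo, hi in (self.inhibition_nonconfident, self.atpase_nonconfident,
                       self.efflux_followup):
            if lo > hi:
                raise ValueError("interval lower bound must be <= upper bound")


DEFAULT_THRESHOLDS = AssayThresholds()


def label_inhibition(pct_max_response: float,
                     thresholds: AssayThresholds = DEFAULT_THRESHOLDS) -> ClassLabel:
    """Label the calcein-AM inhibition assay from % of maximum response.

    Negative below the 10% cut-off (so Y at exactly 10%); labels inside the
    observed [6, 12]% zone are flagged non-confident.
    """
    if pct_max_response < 0:
        raise ValueError("percent response must be >= 0")
    lo, hi = thresholds.inhibition_nonconfident
    value = "Y" if pct_max_response >= thresholds.inhibition_min_pct else "N"
    return ClassLabel(value, confident=not lo <= pct_max_response <= hi)


def label_atpase(fold_stimulation: float,
                 thresholds: AssayThresholds = DEFAULT_THRESHOLDS) -> ClassLabel:
    """Label the ATPase-activation assay from fold-stimulation over control.

    Activator only when strictly above the 2-fold cut-off; [1.5, 2.0] is the
    non-confident range (such compounds are N).
    """
    if fold_stimulation < 0:
        raise ValueError("fold-stimulation must be >= 0")
    lo, hi = thresholds.atpase_nonconfident
    value = "Y" if fold_stimulation > thresholds.atpase_fold_min else "N"
    return ClassLabel(value, confident=not lo <= fold_stimulation <= hi)


def label_efflux(ratio: float,
                 elacridar_followup_confirms: bool | None = None,
                 thresholds: AssayThresholds = DEFAULT_THRESHOLDS) -> ClassLabel:
    """Label the monolayer-efflux assay from the B→A/A→B permeability ratio.

    Effluxed (Y) at ratio ≥ 2.1.  Ratios in [1.5, 2.0] are decided by the
    elacridar follow-up experiment and flagged non-confident; requesting a
    label in this zone without a follow-up result is an error.  Ratios in
    the gap (2.0, 2.1) are not covered by either rule and are labelled N
    with a non-confident flag and a warning.
    """
    if ratio <= 0:
        raise ValueError("permeability ratio must be > 0")
    if ratio >= thresholds.efflux_ratio_min:
        return ClassLabel("Y")
    lo, hi = thresholds.efflux_followup
    if lo <= ratio <= hi:
        if elacridar_followup_confirms is None:
            raise ValueError(
                f"efflux ratio {ratio} lies in the follow-up zone [{lo}, {hi}]; "
                "supply elacridar_followup_confirms"
            )
        return ClassLabel("Y" if elacridar_followup_confirms else "N",
                          confident=False)
    if ratio > hi:  # gap between the follow-up zone and the Y cut-off
        logger.warning(
            "efflux ratio %.3g falls between the follow-up zone and the %.2g "
            "cut-off; labelled N (non-confident)", ratio, thresholds.efflux_ratio_min,
        )
        return ClassLabel("N", confident=False)
    return ClassLabel("N")


_PROFILE_TABLE = {
    ("Y", "N", "N"): ProfileCategory.TRUE_INHIBITOR,
    ("Y", "Y", "Y"): ProfileCategory.SUBSTRATE,
    ("N", "N", "N"): ProfileCategory.NON_SUBSTRATE,
}


def classify_profile(inhibition: ClassLabel, atpase: ClassLabel,
                     efflux: ClassLabel) -> ProfileCategory:
    """Map an (inhibition, ATPase, efflux) label triple to a profile category.

    Y/N/N → true inhibitor; Y/Y/Y → substrate; N/N/N → non-substrate; the
    remaining five triples → other.
    """
    triple = (inhibition.value, atpase.value, efflux.value)
    return _PROFILE_TABLE.get(triple, ProfileCategory.OTHER)
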