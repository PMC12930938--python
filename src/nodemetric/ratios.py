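"""Intra-patient ADC ratio normalization.

Absolute ADC values vary across scanners, sequences and patients, which
limits the transferability of absolute cut-offs. Two dimensionless ratios
reference a target node against healthy tissue of the same patient, measured
by the same reader in the same sequence:

* ``cADC`` — target-node ADC divided by the arithmetic mean of (up to) three
  contralateral benign nodes' ADCs;
* ``mADC`` — target-node ADC divided by the ADC of a fixed region in
  adjacent muscle.

Because both are within-patient quotients, a common multiplicative shift of
all of a patient's ADC measurements cancels exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .data import ReferencePanel, Sequence

__all__ = ["RatioSet", "compute_cadc", "compute_madc", "annotate_ratios"]


@dataclass
class RatioSet:
    """Normalized ratios of one record, per sequence (dimensionless).

    ``n_contralateral_used`` records how many contralateral reference values
    entered each cADC denominator (the design case is three).
    """

    cadc: dict[Sequence, float] = field(default_factory=dict)
    madc: dict[Sequence, float] = field(default_factory=dict)
    n_contralateral_used: dict[Sequence, int] = field(default_factory=dict)


def compute_cadc(target_adc: float, contralateral_adcs) -> float:
    """Target ADC over the mean contralateral-node ADC.

    With three references this is ADC_tLN / ((ADC_cLN1+ADC_cLN2+ADC_cLN3)/3).
    Accepts one to three references; fewer than three is allowed (a warning
    is emitted) so real-world tables with incomplete panels remain usable.
    """
    vals = list(contralateral_adcs)
    if not vals:
        raise ValueError("cADC requires at least one contralateral reference ADC")
    if not target_adc > 0:
        raise ValueError(f"target ADC must be positive, got {target_adc!r}")
    for v in vals:
        if not v > 0:
            raise ValueError(f"contralateral ADC must be positive, got {v!r}")
    if len(vals) < 3:
        warnings.warn(
            f"cADC computed from {len(vals)} contralateral reference(s); "
            "the design case uses 3",
            stacklevel=2,
        )
    return target_adc / (sum(vals) / len(vals))


def compute_madc(target_adc: float, muscle_adc: float) -> float:
    """Target ADC over the muscle reference ADC."""
    if not target_adc > 0:
        raise ValueError(f"target ADC must be positive, got {target_adc!r}")
    if not muscle_adc > 0:
        raise ValueError(f"muscle ADC must be positive, got {muscle_adc!r}")
    return target_adc / muscle_adc


def annotate_ratios(records, panels) -> list[str]:
    """Attach a :class:`RatioSet` to every record, in place.

    For each sequence with a target ADC, cADC is computed when the record's
    (patient, reader) panel has at least one contralateral value for that
    sequence, and mADC when it has a muscle value. Records whose patient has
    no panel carry empty ratios plus a diagnostic. Returns the diagnostics.

    Raises ``ValueError`` on duplicate panels for the same (patient, reader).
    """
    panel_map: dict[tuple[str, str], ReferencePanel] = {}
    for p in panels:
        key = (p.patient_id, p.reader)
        if key in panel_map:
            raise ValueError(
                f"duplicate reference panel for patient {p.patient_id}, "
                f"reader {p.reader.value}"
            )
        panel_map[key] = p

    diagnostics: list[str] = []
    for rec in records:
        rs = RatioSet()
        panel = panel_map.get((rec.patient_id, rec.reader))
        if panel is None:
            diagnostics.append(
                f"no reference panel for patient {rec.patient_id}, reader "
                f"{rec.reader.value}: node {rec.node_id} carries no ratios"
            )
            rec.ratios = rs
            continue
        for seq, target in rec.adc.items():
            contra = panel.contralateral_adc.get(seq, [])
            if contra:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    rs.cadc[seq] = compute_cadc(target, contra)
                rs.n_contralateral_used[seq] = len(contra)
                if len(contra) < 3:
                    diagnostics.append(
                        f"patient {rec.patient_id} reader {rec.reader.value} "
                        f"{seq.value}: cADC uses {len(contra)} reference(s)"
                    )
            muscle = panel.muscle_adc.get(seq)
            if muscle is not None:
                rs.madc[seq] = compute_madc(target, muscle)
        rec.ratios = rs
    return diagnostics
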