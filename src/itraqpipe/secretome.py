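"""Secretory-potential triage of candidate biomarkers.

A tissue protein can only become a serum or urine marker if it can
leave the cell.  The rubric marks a protein "secretory" when at least
one of four independent lines of evidence holds:

1. extracellular or membrane-bound subcellular location,
2. release via the exosome pathway,
3. classical secretion (signal peptide, SignalP-style prediction),
4. non-classical secretion (SecretomeP-style prediction).

The predictors themselves are never run here; their verdicts arrive as
boolean flags in an annotation table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .io_formats import AnnotationRecord

EXTRACELLULAR_OR_MEMBRANE = "extracellular_or_membrane"
EXOSOMAL = "exosomal"
CLASSICAL_SIGNALP = "classical_signalp"
NONCLASSICAL_SECRETOMEP = "nonclassical_secretomep"

CRITERIA = (EXTRACELLULAR_OR_MEMBRANE, EXOSOMAL,
            CLASSICAL_SIGNALP, NONCLASSICAL_SECRETOMEP)


@dataclass(frozen=True)
class SecretionCall:
    protein_id: str
    criteria_met: frozenset[str]

    @property
    def is_secretory(self) -> bool:
        return bool(self.criteria_met)


def classify_secretion(annotation: AnnotationRecord) -> SecretionCall:
    """Apply the four-criterion rubric to one protein's flags."""
    met = set()
    if annotation.is_extracellular or annotation.is_membrane_bound:
        met.add(EXTRACELLULAR_OR_MEMBRANE)
    if annotation.is_exosomal:
        met.add(EXOSOMAL)
    if annotation.signalp_secreted:
        met.add(CLASSICAL_SIGNALP)
    if annotation.secretomep_secreted:
        met.add(NONCLASSICAL_SECRETOMEP)
    return SecretionCall(annotation.protein_id, frozenset(met))


def classify_table(annotations: Iterable[AnnotationRecord]) -> list[SecretionCall]:
    return [classify_secretion(a) for a in annotations]


def summarize_secretome(calls: Sequence[SecretionCall]) -> dict:
    """Non-exclusive per-criterion counts plus the secretory fraction.

    A protein meeting several criteria is counted under each, so the
    per-criterion counts can sum to more than the secretory count.
    """
    counts = {c: 0 for c in CRITERIA}
    n_secretory = 0
    for call in calls:
        if call.is_secretory:
            n_secretory += 1
        for c in call.criteria_met:
            counts[c] += 1
    n = len(calls)
    return {
        "n_proteins": n,
        "n_secretory": n_secretory,
        "fraction_secretory": (n_secretory / n) if n else 0.0,
        "per_criterion": counts,
    }
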