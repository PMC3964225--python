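"""Peptide-to-protein reporter-ratio quantitation and filtering.

The quantitation model works in log10 space: a protein's per-sample
ratio is the geometric mean of its qualifying peptide ratios, and the
dispersion of those peptides defines a multiplicative 95% confidence
half-width, the *error factor* (EF).  EF is reported as a percent,
``EF% = (10^(t * SE) - 1) * 100``, so EF% = 0 means the peptides agree
exactly and EF% < 11.1 means the true ratio is within ~±11% of the
reported one at 95% confidence.

Identification reliability is controlled with a target-decoy *local*
false discovery rate: the decoy/target ratio inside a sliding rank
window of the score-sorted identification list, monotonized with
pool-adjacent-violators so that a lower score never claims a lower FDR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .io_formats import PeptideRecord, RatioMatrix, infer_groups

__all__ = [
    "ProteinQuant",
    "aggregate_protein_ratio",
    "filter_quantified",
    "estimate_local_fdr",
    "merge_itraq_sets",
    "quantify_sets",
]

#: accession prefixes conventionally marking reverse-database entries
DECOY_PREFIXES = ("REV_", "rev_", "DECOY_", "decoy_")

#: cap used when turning peptide confidences into a ProteinPilot-style
#: "unused" score; keeps a single conf=1.0 peptide from dominating
_MAX_PEPTIDE_SCORE = 4.0


@dataclass
class ProteinQuant:
    """Aggregated per-protein quantitation across the samples of one set.

    ``sample_ratios`` holds the recalculated geometric-mean ratio per
    sample; ``n_peptides`` and ``ef_percent`` are bookkeeping for the
    downstream reliability filters.  ``ef_percent`` is +inf for a sample
    quantified by a single peptide (no CI can be formed).
    """

    accession: str
    sample_ratios: dict[str, float] = field(default_factory=dict)
    n_peptides: dict[str, int] = field(default_factory=dict)
    ef_percent: dict[str, float] = field(default_factory=dict)
    unused_score: float = 0.0
    local_fdr: float = 0.0
    is_decoy: bool = False

    def __post_init__(self) -> None:
        for s, r in self.sample_ratios.items():
            if r <= 0:
                raise ValueError(f"non-positive ratio for sample {s!r}")
            if self.n_peptides.get(s, 0) < 1:
                raise ValueError(
                    f"ratio present for sample {s!r} without peptides")
        if not 0.0 <= self.local_fdr <= 1.0:
            raise ValueError("local_fdr outside [0, 1]")


def aggregate_protein_ratio(peptides: Sequence[PeptideRecord],
                            min_confidence: float = 0.95) -> ProteinQuant:
    """Recalculate one protein's per-sample ratios from its peptides.

    A peptide contributes to a sample when it is a non-decoy
    identification with confidence >= ``min_confidence`` and carries a
    ratio for that sample.  The per-sample ratio is the geometric mean
    of contributing peptide ratios; EF% is derived from the t-based 95%
    CI of the mean log10 ratio.

    A protein whose peptides all fail the confidence gate yields a quant
    with no ratios — that is not an error, the protein is simply
    identified-but-not-quantified.
    """
    if not peptides:
        raise ValueError("no peptide records given")
    accessions = {p.accession for p in peptides}
    if len(accessions) > 1:
        raise ValueError(f"mixed accessions in one aggregation: {sorted(accessions)}")
    accession = peptides[0].accession

    targets = [p for p in peptides if not p.is_decoy]
    qualifying = [p for p in targets if p.confidence >= min_confidence]

    per_sample: dict[str, list[float]] = {}
    for p in qualifying:
        for sample, ratio in p.channel_ratios.items():
            per_sample.setdefault(sample, []).append(math.log10(ratio))

    ratios: dict[str, float] = {}
    n_pep: dict[str, int] = {}
    ef: dict[str, float] = {}
    for sample, logs in per_sample.items():
        n = len(logs)
        mean = float(np.mean(logs))
        ratios[sample] = 10.0 ** mean
        n_pep[sample] = n
        if n == 1:
            ef[sample] = math.inf
        else:
            sd = float(np.std(logs, ddof=1))
            se = sd / math.sqrt(n)
            half = stats.t.ppf(0.975, n - 1) * se
            ef[sample] = (10.0 ** half - 1.0) * 100.0

    # ProteinPilot-style identification score: summed -log10(1 - conf)
    # over distinct target peptide sequences (best confidence each)
    best: dict[str, float] = {}
    for p in targets:
        best[p.sequence] = max(best.get(p.sequence, 0.0), p.confidence)
    unused = sum(min(-math.log10(max(1.0 - c, 1e-10)), _MAX_PEPTIDE_SCORE)
                 for c in best.values())

    return ProteinQuant(
        accession=accession,
        sample_ratios=ratios,
        n_peptides=n_pep,
        ef_percent=ef,
        unused_score=unused,
        is_decoy=not targets,
    )


def filter_quantified(quants: Sequence[ProteinQuant],
                      min_peptides: int = 3,
                      max_ef_percent: float = 11.1,
                      keep_fraction: float = 0.95) -> list[ProteinQuant]:
    """Apply the quantitation-reliability filters.

    A sample-level ratio survives only if it rests on at least
    ``min_peptides`` peptides and has EF% strictly below
    ``max_ef_percent``.  Proteins retaining no ratio are dropped.  Of
    the remainder, only the ``floor(keep_fraction * n)`` proteins with
    the smallest worst-case (maximum over samples) EF% are kept, ties
    broken by input order.
    """
    if not 0.0 < keep_fraction <= 1.0:
        raise ValueError(f"keep_fraction {keep_fraction} outside (0, 1]")
    if min_peptides < 1:
        raise ValueError("min_peptides must be >= 1")

    surviving: list[ProteinQuant] = []
    for q in quants:
        keep = {
            s: r for s, r in q.sample_ratios.items()
            if q.n_peptides[s] >= min_peptides
            and q.ef_percent[s] < max_ef_percent
        }
        if not keep:
            continue
        surviving.append(replace(
            q,
            sample_ratios=keep,
            n_peptides={s: q.n_peptides[s] for s in keep},
            ef_percent={s: q.ef_percent[s] for s in keep},
        ))

    n_keep = math.floor(keep_fraction * len(surviving))
    if n_keep == len(surviving):
        return surviving
    order = sorted(range(len(surviving)),
                   key=lambda i: (max(surviving[i].ef_percent.values()), i))
    chosen = sorted(order[:n_keep])
    return [surviving[i] for i in chosen]


def estimate_local_fdr(entries: Sequence[tuple[float, bool]],
                       window: int = 20) -> list[float]:
    """Windowed target-decoy local FDR, PAVA-monotonized.

    ``entries`` are ``(score, is_decoy)`` pairs; higher scores are
    better.  Entries are ranked by decreasing score (stable for ties)
    and each target's raw local FDR is ``min(1, decoys / targets)``
    inside the rank window of ``window`` entries centered on it (clipped
    at the list ends).  The raw values are then made non-decreasing with
    decreasing score by pool-adjacent-violators, so the estimate is a
    proper local error rate.  Decoy entries get local FDR 1.

    Returns the estimates aligned with the input order.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    entries = list(entries)
    n = len(entries)
    if not any(not d for _, d in entries):
        raise ValueError("need at least one target entry")
    for score, _ in entries:
        if not np.isfinite(score):
            raise ValueError("scores must be finite")

    order = sorted(range(n), key=lambda i: -entries[i][0])
    is_decoy_sorted = [entries[i][1] for i in order]

    half = window // 2
    raw: list[float] = []
    target_positions: list[int] = []
    for pos in range(n):
        if is_decoy_sorted[pos]:
            continue
        lo = max(0, pos - half)
        hi = min(n, lo + window)
        lo = max(0, hi - window)
        d = sum(1 for k in range(lo, hi) if is_decoy_sorted[k])
        t = (hi - lo) - d
        raw.append(min(1.0, d / t) if t else 1.0)
        target_positions.append(pos)

    iso = _pava_non_decreasing(raw)

    lfdr_sorted = [1.0] * n
    for pos, v in zip(target_positions, iso):
        lfdr_sorted[pos] = min(1.0, max(0.0, v))
    out = [1.0] * n
    for rank, i in enumerate(order):
        out[i] = lfdr_sorted[rank]
    return out


def _pava_non_decreasing(values: Sequence[float]) -> list[float]:
    """Pool-adjacent-violators projection onto non-decreasing sequences."""
    blocks: list[list[float]] = []  # [mean, weight]
    for v in values:
        blocks.append([float(v), 1.0])
        while len(blocks) > 1 and blocks[-2][0] > blocks[-1][0]:
            m2, w2 = blocks.pop()
            m1, w1 = blocks.pop()
            blocks.append([(m1 * w1 + m2 * w2) / (w1 + w2), w1 + w2])
    out: list[float] = []
    for mean, weight in blocks:
        out.extend([mean] * int(round(weight)))
    return out


def is_decoy_accession(accession: str) -> bool:
    return accession.startswith(DECOY_PREFIXES)


def merge_itraq_sets(sets: Sequence[tuple[str, Sequence[ProteinQuant]]],
                     group_map: Mapping[str, str] | None = None,
                     max_local_fdr: float = 0.05) -> RatioMatrix:
    """Compile per-set protein quants into one ratio matrix.

    Proteins are matched by accession across sets (union); decoy /
    reverse-sequence entries are removed; only proteins whose local FDR
    is <= ``max_local_fdr`` are kept.  Cells stay missing where a set
    did not quantify the protein.  Sample ids must be unique across
    sets; groups come from ``group_map`` or the C/N prefix convention.
    """
    seen_samples: dict[str, str] = {}
    accession_order: list[str] = []
    cells: dict[str, dict[str, float]] = {}

    for set_id, quants in sets:
        set_samples: set[str] = set()
        set_accessions: set[str] = set()
        for q in quants:
            if q.accession in set_accessions:
                raise ValueError(
                    f"redundant accession {q.accession!r} in set {set_id!r}")
            set_accessions.add(q.accession)
            for s in q.sample_ratios:
                if s in seen_samples and seen_samples[s] != set_id:
                    raise ValueError(
                        f"sample {s!r} appears in sets "
                        f"{seen_samples[s]!r} and {set_id!r}")
                seen_samples[s] = set_id
                set_samples.add(s)
            if q.is_decoy or is_decoy_accession(q.accession):
                continue
            if q.local_fdr > max_local_fdr:
                continue
            if q.accession not in cells:
                accession_order.append(q.accession)
                cells[q.accession] = {}
            cells[q.accession].update(q.sample_ratios)

    sample_order = list(seen_samples)
    import pandas as pd
    df = pd.DataFrame(np.nan, index=accession_order, columns=sample_order,
                      dtype=float)
    for acc, row in cells.items():
        for s, r in row.items():
            df.at[acc, s] = r
    groups = dict(group_map) if group_map is not None else infer_groups(sample_order)
    return RatioMatrix(df, {s: groups[s] for s in sample_order})


def quantify_sets(peptide_sets: Sequence[tuple[str, Sequence[PeptideRecord]]],
                  min_confidence: float = 0.95,
                  min_peptides: int = 3,
                  max_ef_percent: float = 11.1,
                  keep_fraction: float = 0.95,
                  fdr_threshold: float = 0.05,
                  fdr_window: int = 20,
                  group_map: Mapping[str, str] | None = None,
                  log: list[str] | None = None) -> RatioMatrix:
    """Full peptide-to-matrix quantitation across several iTRAQ sets.

    Per set: peptides are grouped by accession, aggregated, and passed
    through the peptide-count / EF / percentile filters.  Identification
    scores are pooled at the protein level across sets (summed unused
    score, decoy status) to estimate local FDR, and the surviving quants
    are merged into one :class:`RatioMatrix`.

    ``log``, when given, collects human-readable per-stage drop counts.
    """
    aggregated: list[tuple[str, list[ProteinQuant]]] = []
    score_by_acc: dict[str, float] = {}
    decoy_by_acc: dict[str, bool] = {}
    for set_id, records in peptide_sets:
        by_acc: dict[str, list[PeptideRecord]] = {}
        for r in records:
            by_acc.setdefault(r.accession, []).append(r)
        quants = [aggregate_protein_ratio(recs, min_confidence)
                  for recs in by_acc.values()]
        for q in quants:
            score_by_acc[q.accession] = score_by_acc.get(q.accession, 0.0) \
                + q.unused_score
            decoy = q.is_decoy or is_decoy_accession(q.accession)
            decoy_by_acc[q.accession] = decoy_by_acc.get(q.accession, True) and decoy
        filtered = filter_quantified(quants, min_peptides, max_ef_percent,
                                     keep_fraction)
        if log is not None:
            log.append(f"set {set_id}: {len(quants)} proteins aggregated, "
                       f"{len(quants) - len(filtered)} dropped by "
                       f"peptide/EF/percentile filters")
        aggregated.append((set_id, filtered))

    accs = list(score_by_acc)
    lfdr = estimate_local_fdr(
        [(score_by_acc[a], decoy_by_acc[a]) for a in accs], window=fdr_window)
    lfdr_by_acc = dict(zip(accs, lfdr))

    with_fdr = [
        (set_id, [replace(q, local_fdr=lfdr_by_acc[q.accession])
                  for q in quants])
        for set_id, quants in aggregated
    ]
    matrix = merge_itraq_sets(with_fdr, group_map=group_map,
                              max_local_fdr=fdr_threshold)
    if log is not None:
        n_dropped = len([a for a in accs if not decoy_by_acc[a]
                         and lfdr_by_acc[a] > fdr_threshold])
        log.append(f"local FDR > {fdr_threshold}: {n_dropped} target "
                   f"proteins dropped; matrix {matrix.shape[0]} proteins "
                   f"x {matrix.shape[1]} samples")
    return matrix
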