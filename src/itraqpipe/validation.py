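"""Orthogonal-validation calculators.

Implements the arithmetic behind the wet-lab validation arms of a
tissue-biomarker study: immunohistochemistry combined-score change
calls, qPCR relative quantification (2^-ddCt with housekeeping
normalization), Western-blot densitometry fold changes, ELISA
mean + k*SD cutoffs, and 2x2 contingency association.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

INCREASED = "increased"
DECREASED = "decreased"
NO_CHANGE = "no_change"

TUMOR = "tumor"
NORMAL = "normal"


# ---------------------------------------------------------------------------
# immunohistochemistry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IHCScore:
    """Ordinal stain scores for one tissue core.

    intensity: 0 none, 1 weak, 2 moderate, 3 strong.
    frequency: 0 none, 1 (1-25%), 2 (26-50%), 3 (51-75%), 4 (76-100%).
    The combined score is their sum, 0-7.
    """

    intensity: int
    frequency: int

    def __post_init__(self) -> None:
        if self.intensity not in (0, 1, 2, 3):
            raise ValueError(f"intensity {self.intensity} outside 0-3")
        if self.frequency not in (0, 1, 2, 3, 4):
            raise ValueError(f"frequency {self.frequency} outside 0-4")
        if (self.intensity == 0) != (self.frequency == 0):
            raise ValueError(
                "no-expression convention violated: intensity and frequency "
                "must be zero together")

    @property
    def combined(self) -> int:
        return self.intensity + self.frequency


def ihc_change_call(cancer: IHCScore, normal: IHCScore,
                    tolerance: int = 1) -> str:
    """Call increased/decreased/no_change from paired combined scores.

    A tumor combined score within ``tolerance`` (default ±1) of the
    matched normal is not considered a real change.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    diff = cancer.combined - normal.combined
    if abs(diff) <= tolerance:
        return NO_CHANGE
    return INCREASED if diff > 0 else DECREASED


def summarize_ihc_calls(calls: Iterable[str]) -> dict[str, int]:
    out = {INCREASED: 0, DECREASED: 0, NO_CHANGE: 0}
    for c in calls:
        out[c] += 1
    return out


# ---------------------------------------------------------------------------
# qPCR relative quantification
# ---------------------------------------------------------------------------

@dataclass
class CtTable:
    """Long-format qPCR threshold cycles for paired tumor/normal samples.

    ``data`` columns: sample_id, condition (tumor|normal), pair_id,
    gene, ct.  Every sample must carry all three housekeeping genes,
    and tumors and normals must pair one-to-one by pair_id.
    """

    data: pd.DataFrame
    housekeeping_genes: list[str] = field(
        default_factory=lambda: ["HPRT1", "RPL13A", "ACTB"])

    def __post_init__(self) -> None:
        required = {"sample_id", "condition", "pair_id", "gene", "ct"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"Ct table missing columns: {sorted(missing)}")
        if len(self.housekeeping_genes) != 3:
            raise ValueError("exactly three housekeeping genes are required")
        if (self.data["ct"] <= 0).any():
            raise ValueError("Ct values must be positive")
        bad_cond = set(self.data["condition"]) - {TUMOR, NORMAL}
        if bad_cond:
            raise ValueError(f"unknown conditions: {sorted(bad_cond)}")
        for sample, sub in self.data.groupby("sample_id"):
            genes = set(sub["gene"])
            lacking = [g for g in self.housekeeping_genes if g not in genes]
            if lacking:
                raise ValueError(
                    f"sample {sample!r} missing housekeeping Ct for {lacking}")
            if sub.duplicated(subset="gene").any():
                raise ValueError(f"duplicate gene Ct in sample {sample!r}")
        pairs = self.data[["pair_id", "condition", "sample_id"]].drop_duplicates()
        for pair, sub in pairs.groupby("pair_id"):
            conds = sorted(sub["condition"])
            if conds != [NORMAL, TUMOR]:
                raise ValueError(
                    f"pair {pair!r} is not one tumor + one normal sample")

    @property
    def pair_ids(self) -> list:
        return sorted(self.data["pair_id"].unique())

    @property
    def target_genes(self) -> list[str]:
        hk = set(self.housekeeping_genes)
        seen: list[str] = []
        for g in self.data["gene"]:
            if g not in hk and g not in seen:
                seen.append(g)
        return seen


def signed_fold(ratio: float) -> float:
    """Fold-change sign convention: ratios < 1 become negative reciprocals.

    A 13-fold down-regulation (ratio 0.0769) is reported as -13.0; folds
    at or above 1 are reported as-is.
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    return ratio if ratio >= 1.0 else -1.0 / ratio


def ddct_fold_changes(table: CtTable) -> pd.DataFrame:
    """Per-gene 2^-ddCt fold changes across matched pairs.

    Per sample, dCt = Ct(gene) - mean Ct of the three housekeeping
    genes; per pair, ddCt = dCt(tumor) - dCt(normal).  The per-gene
    fold is the geometric mean over pairs of 2^-ddCt, reported with the
    negative-reciprocal convention, with a paired two-tailed t-test of
    the ddCt values against zero.

    Returns a DataFrame indexed by gene with columns ``ratio`` (raw
    geometric-mean 2^-ddCt), ``fold_change`` (signed convention),
    ``paired_p`` and ``n_pairs``.
    """
    data = table.data
    hk = table.housekeeping_genes

    # per-sample dCt for every gene
    dct: dict[tuple, dict[str, float]] = {}
    for (pair, cond), sub in data.groupby(["pair_id", "condition"]):
        ct = dict(zip(sub["gene"], sub["ct"].astype(float)))
        hk_mean = float(np.mean([ct[g] for g in hk]))
        dct[(pair, cond)] = {g: c - hk_mean for g, c in ct.items()}

    rows = []
    for gene in table.target_genes:
        ddcts = []
        for pair in table.pair_ids:
            t_d = dct[(pair, TUMOR)]
            n_d = dct[(pair, NORMAL)]
            if gene not in t_d or gene not in n_d:
                raise ValueError(
                    f"gene {gene!r} missing from one side of pair {pair!r}")
            ddcts.append(t_d[gene] - n_d[gene])
        ddcts = np.asarray(ddcts, dtype=float)
        ratio = float(2.0 ** (-ddcts.mean()))   # geometric mean of 2^-ddCt
        p = _paired_p_against_zero(ddcts)
        rows.append({"gene": gene, "ratio": ratio,
                     "fold_change": signed_fold(ratio),
                     "paired_p": p, "n_pairs": len(ddcts)})
    return pd.DataFrame(rows).set_index("gene")


def _paired_p_against_zero(diffs: np.ndarray) -> float:
    if len(diffs) < 2:
        return float("nan")
    if np.allclose(diffs, diffs[0]):
        # degenerate: zero variance; the test is decided by the mean
        return 1.0 if math.isclose(diffs[0], 0.0, abs_tol=1e-12) else 0.0
    t, p = stats.ttest_1samp(diffs, 0.0)
    return float(p)


# ---------------------------------------------------------------------------
# Western-blot densitometry
# ---------------------------------------------------------------------------

def densitometry_fold(pairs: Sequence[tuple[float, float, float, float]]
                      ) -> tuple[float, float]:
    """Loading-normalized cancer/normal band fold across matched pairs.

    Each pair is (cancer_band, normal_band, cancer_loading,
    normal_loading); the per-pair fold is the loading-control-normalized
    band ratio.  Returns the mean fold over pairs and a paired
    two-tailed t-test of the log2 folds against zero.
    """
    if not pairs:
        raise ValueError("no pairs given")
    folds = []
    for cb, nb, cl, nl in pairs:
        if min(cb, nb, cl, nl) <= 0:
            raise ValueError("band and loading intensities must be positive")
        folds.append((cb / cl) / (nb / nl))
    folds = np.asarray(folds, dtype=float)
    p = _paired_p_against_zero(np.log2(folds))
    return float(folds.mean()), p


# ---------------------------------------------------------------------------
# ELISA
# ---------------------------------------------------------------------------

@dataclass
class ElisaCohort:
    """Continuous analyte levels (ng/mL) with case/control labels.

    ``data`` columns: subject_id, level, label (case|control); optional
    clinical covariates (sex, grade, stage) may ride along.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"subject_id", "level", "label"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"ELISA cohort missing columns: {sorted(missing)}")
        if (self.data["level"] < 0).any():
            raise ValueError("analyte levels must be non-negative")
        bad = set(self.data["label"]) - {"case", "control"}
        if bad:
            raise ValueError(f"unknown labels: {sorted(bad)}")

    def levels(self, label: str) -> np.ndarray:
        return self.data.loc[self.data["label"] == label, "level"].to_numpy(float)


def elisa_cutoff(controls: Sequence[float], k: float = 2.0) -> float:
    """Control mean + k standard deviations (sample SD, ddof=1).

    The classical upper reference limit: with k=2, ~97.7% of a normal
    control population falls below the cutoff.
    """
    controls = np.asarray(list(controls), dtype=float)
    if len(controls) < 2:
        raise ValueError("need >= 2 control measurements")
    return float(controls.mean() + k * controls.std(ddof=1))


def classify_levels(levels: Sequence[float], cutoff: float) -> list[str]:
    """Label each level 'high' (> cutoff) or 'low'."""
    return ["high" if lv > cutoff else "low" for lv in levels]


def cutoff_contingency(cohort: ElisaCohort, cutoff: float) -> np.ndarray:
    """2x2 table [[control low, control high], [case low, case high]]."""
    out = np.zeros((2, 2), dtype=int)
    for row_idx, label in enumerate(("control", "case")):
        levels = cohort.levels(label)
        high = sum(1 for lv in levels if lv > cutoff)
        out[row_idx] = [len(levels) - high, high]
    return out


def load_serum_contingency_fixture() -> dict[str, pd.DataFrame]:
    """Packaged serum-marker 2x2 tables (low/high analyte vs clinical status).

    Returns one 2x2 count DataFrame per clinical variable (status, sex,
    grade, stage), rows = variable levels, columns = low/high marker.
    The stage table is shipped as printed in its source even though its
    margins are internally inconsistent with the cohort size.
    """
    from importlib import resources
    import io as _io
    text = (resources.files("itraqpipe") / "data" / "serum_marker_contingency.csv").read_text()
    df = pd.read_csv(_io.StringIO(text))
    out: dict[str, pd.DataFrame] = {}
    for variable, sub in df.groupby("variable", sort=False):
        out[variable] = (sub.set_index("level")[["low_hsp27", "high_hsp27"]]
                         .astype(int))
    return out


# ---------------------------------------------------------------------------
# contingency association
# ---------------------------------------------------------------------------

def contingency_association(table: Sequence[Sequence[float]]
                            ) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on a 2x2 table.

    Returns (chi2, two-sided p) with 1 degree of freedom.  Any zero row
    or column margin is an error: the association is undefined there.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero margin: association undefined")
    chi2, p, dof, _ = stats.chi2_contingency(t, correction=False)
    assert dof == 1
    return float(chi2), float(p)
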