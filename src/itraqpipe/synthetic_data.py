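"""Ground-truth simulators for every pipeline input.

The discovery-phase generator emulates a matched tumor/normal iTRAQ
4-plex experiment: each set labels a pooled-normal reference channel
plus three study samples, peptide reporter ratios are drawn lognormally
around the protein's true fold (tumor channels of dysregulated
proteins) or around 1, and the identification list is contaminated with
low-confidence false targets and score-matched decoy (reverse) entries
so the local-FDR estimator has something honest to estimate.

The validation-arm generator produces IHC score pairs, paired qPCR Ct
tables and ELISA case/control cohorts with configurable truth, down to
the zero-noise limits in which every calculator must recover the truth
exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import PeptideRecord, infer_groups
from .validation import CtTable, ElisaCohort

UP = "up"
DOWN = "down"
NONE = "none"


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Discovery-phase study design and noise model.

    Defaults emulate the profiled cohort: 10 tumor/normal pairs spread
    over seven 4-plex sets (one channel per set is the pooled-normal
    reference), ~1600 identified proteins of which 15 are truly up
    (2-fold) and 40 truly down (0.45-fold), 20% peptide-level CV, and
    an identification list carrying false targets and matched decoys.
    """

    n_pairs: int = 10
    n_sets: int = 7
    channels_per_set: int = 4          # one of these is the reference
    n_proteins: int = 1600
    n_true_up: int = 15
    n_true_down: int = 40
    up_fold: float = 2.0
    down_fold: float = 0.45
    peptide_cv: float = 0.2
    peptide_rate: float = 4.0          # peptides/protein/set = 1 + Poisson(rate)
    decoy_fraction: float = 0.5        # decoy share of *false* identifications
    false_id_fraction: float = 0.15    # false targets relative to n_proteins
    confidence_high_frac: float = 0.9  # true peptides drawn >= 0.95 confidence
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_true_up + self.n_true_down > self.n_proteins:
            raise ValueError("more true dysregulated proteins than proteins")
        if self.up_fold <= 0 or self.down_fold <= 0:
            raise ValueError("folds must be positive")
        if self.peptide_cv < 0:
            raise ValueError("peptide_cv must be >= 0")
        if not 0.0 <= self.decoy_fraction < 1.0:
            raise ValueError("decoy_fraction must be in [0, 1)")
        if self.channels_per_set < 2:
            raise ValueError("need the reference plus >= 1 sample channel")
        capacity = self.n_sets * (self.channels_per_set - 1)
        if capacity < 2 * self.n_pairs:
            raise ValueError(
                f"{self.n_sets} sets x {self.channels_per_set - 1} sample "
                f"channels cannot hold {2 * self.n_pairs} samples")


@dataclass
class SimulatedSet:
    """One iTRAQ set: its samples, randomized reference tag, peptides."""

    set_id: str
    sample_ids: list[str]
    reference_tag: str
    peptides: list[PeptideRecord] = field(default_factory=list)


def _lognormal_sigma(cv: float) -> float:
    # multiplicative noise with the requested coefficient of variation
    return math.sqrt(math.log(1.0 + cv * cv))


# ---------------------------------------------------------------------------
# discovery-phase simulation
# ---------------------------------------------------------------------------

def simulate_peptide_sets(config: SimulationConfig
                          ) -> tuple[list[SimulatedSet], pd.DataFrame]:
    """Generate per-set peptide tables plus the ground-truth table.

    Returns ``(sets, truth)``: peptide records per iTRAQ set, and a
    truth DataFrame indexed by protein id with columns ``direction``
    (up/down/none), ``fold`` and ``is_false_id`` (identifications with
    no underlying true protein).  Decoy accessions carry a ``REV_``
    prefix and never appear in the truth table.
    """
    rng = np.random.default_rng(config.seed)
    sigma = _lognormal_sigma(config.peptide_cv)

    samples = [f"C{i + 1}" for i in range(config.n_pairs)] + \
              [f"N{i + 1}" for i in range(config.n_pairs)]
    interleaved = [s for pair in zip(samples[:config.n_pairs],
                                     samples[config.n_pairs:]) for s in pair]
    per_set = config.channels_per_set - 1
    set_samples = [interleaved[i * per_set:(i + 1) * per_set]
                   for i in range(config.n_sets)]
    set_samples = [s for s in set_samples if s]

    # ground truth: dysregulated proteins drawn without replacement
    proteins = [f"PROT{i + 1:05d}" for i in range(config.n_proteins)]
    dys = rng.choice(config.n_proteins,
                     size=config.n_true_up + config.n_true_down,
                     replace=False)
    direction = np.full(config.n_proteins, NONE, dtype=object)
    fold = np.ones(config.n_proteins)
    direction[dys[:config.n_true_up]] = UP
    fold[dys[:config.n_true_up]] = config.up_fold
    direction[dys[config.n_true_up:]] = DOWN
    fold[dys[config.n_true_up:]] = config.down_fold

    n_false = int(round(config.false_id_fraction * config.n_proteins))
    false_ids = [f"FALS{i + 1:05d}" for i in range(n_false)]
    if config.decoy_fraction > 0:
        n_decoy = int(round(n_false * config.decoy_fraction
                            / (1.0 - config.decoy_fraction)))
    else:
        n_decoy = 0
    decoy_ids = [f"REV_PROT{i + 1:05d}" for i in range(n_decoy)]

    truth = pd.DataFrame(
        {"direction": list(direction) + [NONE] * n_false,
         "fold": list(fold) + [1.0] * n_false,
         "is_false_id": [False] * config.n_proteins + [True] * n_false},
        index=proteins + false_ids)
    truth.index.name = "protein_id"

    tags = [f"{113 + i}" for i in range(config.channels_per_set)]
    sets: list[SimulatedSet] = []
    for k, sample_ids in enumerate(set_samples):
        set_id = f"set{k + 1}"
        reference_tag = tags[int(rng.integers(len(tags)))]
        peptides: list[PeptideRecord] = []

        for p_idx, acc in enumerate(proteins):
            n_pep = 1 + int(rng.poisson(config.peptide_rate))
            true_ratio = {
                s: (fold[p_idx] if s.startswith("C") else 1.0)
                for s in sample_ids
            }
            for j in range(n_pep):
                conf = _true_confidence(rng, config.confidence_high_frac)
                noise = (np.exp(rng.normal(0.0, sigma, size=len(sample_ids)))
                         if sigma > 0 else np.ones(len(sample_ids)))
                ratios = {s: float(true_ratio[s] * noise[i])
                          for i, s in enumerate(sample_ids)}
                peptides.append(PeptideRecord(
                    accession=acc,
                    sequence=f"{acc}.{set_id}.p{j + 1}",
                    confidence=conf, is_decoy=False, channel_ratios=ratios))

        # false targets and decoys: sparse, low-confidence, no true signal
        for acc_list, is_decoy in ((false_ids, False), (decoy_ids, True)):
            for acc in acc_list:
                if rng.random() > 1.0 / len(set_samples):
                    continue        # each false id hits ~one set
                for j in range(1 + int(rng.integers(2))):
                    conf = float(rng.uniform(0.30, 0.97))
                    noise = np.exp(rng.normal(0.0, max(sigma, 0.1),
                                              size=len(sample_ids)))
                    ratios = {s: float(noise[i])
                              for i, s in enumerate(sample_ids)}
                    peptides.append(PeptideRecord(
                        accession=acc,
                        sequence=f"{acc}.{set_id}.p{j + 1}",
                        confidence=conf, is_decoy=is_decoy,
                        channel_ratios=ratios))

        sets.append(SimulatedSet(set_id, list(sample_ids), reference_tag,
                                 peptides))
    return sets, truth


def _true_confidence(rng: np.random.Generator, high_frac: float) -> float:
    if rng.random() < high_frac:
        return float(rng.uniform(0.95, 0.9999))
    return float(rng.uniform(0.50, 0.95))


def simulate_identifications(n_targets: int, n_false: int,
                             seed: int) -> tuple[list[tuple[float, bool]], list[bool]]:
    """Score-level identification list for FDR-calibration studies.

    Correct targets score Normal(5.5, 2); false targets and an equal
    number of decoys share the Normal(2, 1.2) score distribution (the
    concatenated-search assumption), so the two classes overlap and the
    local FDR transitions smoothly through the usual cutoffs — a
    separated design would leave nothing to calibrate.  Returns
    ``(entries, is_false_target)`` where ``entries`` feed
    :func:`itraqpipe.quantify.estimate_local_fdr` and
    ``is_false_target`` marks, for each entry, a target with no true
    protein behind it (decoys are False there).
    """
    rng = np.random.default_rng(seed)
    scores = np.concatenate([
        rng.normal(5.5, 2.0, size=n_targets),
        rng.normal(2.0, 1.2, size=n_false),
        rng.normal(2.0, 1.2, size=n_false),
    ]).clip(min=0.0)
    is_decoy = [False] * (n_targets + n_false) + [True] * n_false
    is_false = [False] * n_targets + [True] * n_false + [False] * n_false
    entries = list(zip(scores.tolist(), is_decoy))
    return entries, is_false


# ---------------------------------------------------------------------------
# validation-arm simulation
# ---------------------------------------------------------------------------

@dataclass
class ValidationConfig:
    """Truth and noise for the IHC / qPCR / ELISA cohort generators.

    ELISA group means default to the serum marker levels the pipeline's
    cutoff logic is designed around (control 1.233, case 2.334 ng/mL,
    control SD 0.648 so that mean + 2 SD = 2.529).
    """

    # IHC
    ihc_n_cases: int = 85
    ihc_frac_increased: float = 0.7
    ihc_true_shift: int = 3
    ihc_noise: float = 0.0             # SD of integer jitter on tumor scores
    # qPCR
    ct_n_pairs: int = 4
    ct_noise_sd: float = 0.0
    gene_folds: dict = field(default_factory=lambda: {
        "SUCLG1": 2.0 ** -3.70,        # ~13-fold down
        "IDH3A": 1.0 / 7.31,
        "PDHB": 1.0 / 7.0,
        "GENE_NULL": 1.0,
        "GENE_UP4": 4.0,
    })
    housekeeping_genes: tuple = ("HPRT1", "RPL13A", "ACTB")
    # ELISA
    elisa_n_cases: int = 36
    elisa_n_controls: int = 18
    elisa_case_mean: float = 2.334
    elisa_control_mean: float = 1.233
    elisa_control_sd: float = 0.648
    elisa_case_sd: float = 0.9
    exact_moments: bool = True         # rescale draws to the exact mean/SD


def simulate_validation_cohorts(config: ValidationConfig, seed: int
                                ) -> tuple[pd.DataFrame, CtTable, ElisaCohort]:
    """Generate (IHC score table, paired Ct table, ELISA cohort)."""
    rng = np.random.default_rng(seed)
    return (_simulate_ihc(config, rng),
            _simulate_ct(config, rng),
            _simulate_elisa(config, rng))


def _simulate_ihc(cfg: ValidationConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    n_increased = int(round(cfg.ihc_frac_increased * cfg.ihc_n_cases))
    for i in range(cfg.ihc_n_cases):
        truly_increased = i < n_increased
        normal_int = int(rng.integers(1, 3))       # 1-2
        normal_freq = int(rng.integers(1, 3))      # 1-2
        combined_shift = cfg.ihc_true_shift if truly_increased else 0
        if cfg.ihc_noise > 0:
            combined_shift += int(round(rng.normal(0.0, cfg.ihc_noise)))
        cancer_combined = int(np.clip(normal_int + normal_freq
                                      + combined_shift, 1, 7))
        cancer_int = int(np.clip(cancer_combined - normal_freq, 1, 3))
        cancer_freq = int(np.clip(cancer_combined - cancer_int, 1, 4))
        rows.append({"case_id": f"case{i + 1}",
                     "cancer_intensity": cancer_int,
                     "cancer_frequency": cancer_freq,
                     "normal_intensity": normal_int,
                     "normal_frequency": normal_freq,
                     "truly_increased": truly_increased})
    return pd.DataFrame(rows)


def _simulate_ct(cfg: ValidationConfig, rng: np.random.Generator) -> CtTable:
    hk = list(cfg.housekeeping_genes)
    rows = []
    for pair in range(1, cfg.ct_n_pairs + 1):
        for cond in ("normal", "tumor"):
            sample = f"{cond[0].upper()}{pair}"
            hk_cts = 18.0 + rng.uniform(0.0, 4.0, size=len(hk))
            hk_mean = float(hk_cts.mean())
            for g, ct in zip(hk, hk_cts):
                rows.append({"sample_id": sample, "condition": cond,
                             "pair_id": pair, "gene": g, "ct": float(ct)})
            for gene, fold in cfg.gene_folds.items():
                dct_normal = 5.0       # fixed baseline abundance
                dct = dct_normal if cond == "normal" \
                    else dct_normal - math.log2(fold)
                noise = rng.normal(0.0, cfg.ct_noise_sd) \
                    if cfg.ct_noise_sd > 0 else 0.0
                rows.append({"sample_id": sample, "condition": cond,
                             "pair_id": pair, "gene": gene,
                             "ct": float(hk_mean + dct + noise)})
    return CtTable(pd.DataFrame(rows), housekeeping_genes=hk)


def _exact_moment_sample(rng: np.random.Generator, n: int,
                         mean: float, sd: float) -> np.ndarray:
    """Right-skewed positive draw affinely rescaled to the exact moments."""
    cv = sd / mean
    sigma = _lognormal_sigma(cv)
    raw = rng.lognormal(-0.5 * sigma * sigma, sigma, size=n)
    raw = (raw - raw.mean()) / raw.std(ddof=1)
    out = mean + sd * raw
    if (out < 0).any():
        raise ValueError(
            "exact-moment rescaling produced a negative level; use "
            "exact_moments=False for this configuration")
    return out


def _simulate_elisa(cfg: ValidationConfig, rng: np.random.Generator) -> ElisaCohort:
    if cfg.exact_moments:
        controls = _exact_moment_sample(rng, cfg.elisa_n_controls,
                                        cfg.elisa_control_mean,
                                        cfg.elisa_control_sd)
        cases = _exact_moment_sample(rng, cfg.elisa_n_cases,
                                     cfg.elisa_case_mean, cfg.elisa_case_sd)
    else:
        sig_ctl = _lognormal_sigma(cfg.elisa_control_sd / cfg.elisa_control_mean)
        sig_cas = _lognormal_sigma(cfg.elisa_case_sd / cfg.elisa_case_mean)
        controls = cfg.elisa_control_mean * rng.lognormal(
            -0.5 * sig_ctl ** 2, sig_ctl, size=cfg.elisa_n_controls)
        cases = cfg.elisa_case_mean * rng.lognormal(
            -0.5 * sig_cas ** 2, sig_cas, size=cfg.elisa_n_cases)
    rows = [{"subject_id": f"ctl{i + 1}", "level": float(v), "label": "control"}
            for i, v in enumerate(controls)]
    rows += [{"subject_id": f"case{i + 1}", "level": float(v), "label": "case"}
             for i, v in enumerate(cases)]
    return ElisaCohort(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# recovery scoring
# ---------------------------------------------------------------------------

def recovery_report(truth: pd.DataFrame,
                    calls: Sequence) -> dict[str, float]:
    """Confusion-matrix summary of dysregulation calls against truth.

    ``truth`` is the table from :func:`simulate_peptide_sets`; ``calls``
    are :class:`~itraqpipe.dysregulation.DysregulationCall` records.
    Proteins in the truth table that received no call count as called
    none (not quantified); calls for unknown proteins are an error.

    Returns sensitivity (truly dysregulated called with the correct
    direction), specificity (truly-null called none), direction
    accuracy (correct direction among truly dysregulated proteins
    called in either direction), and the false-call rate (share of all
    dysregulation calls that are wrong).
    """
    called: dict[str, str] = {}
    for c in calls:
        if c.protein_id not in truth.index:
            raise ValueError(f"call for unknown protein {c.protein_id!r}")
        called[c.protein_id] = c.direction

    tp = fp = 0
    n_true_dys = n_true_null = tn = 0
    dys_called = dys_called_correct = 0
    for pid, row in truth.iterrows():
        t_dir = row["direction"]
        c_dir = called.get(pid, NONE)
        if t_dir == NONE:
            n_true_null += 1
            if c_dir == NONE:
                tn += 1
            else:
                fp += 1
        else:
            n_true_dys += 1
            if c_dir == t_dir:
                tp += 1
            if c_dir != NONE:
                dys_called += 1
                if c_dir == t_dir:
                    dys_called_correct += 1
            if c_dir != NONE and c_dir != t_dir:
                fp += 1

    n_calls = sum(1 for d in called.values() if d != NONE)
    return {
        "sensitivity": tp / n_true_dys if n_true_dys else float("nan"),
        "specificity": tn / n_true_null if n_true_null else float("nan"),
        "direction_accuracy": (dys_called_correct / dys_called
                               if dys_called else float("nan")),
        "false_call_rate": fp / n_calls if n_calls else 0.0,
        "n_calls": float(n_calls),
    }
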