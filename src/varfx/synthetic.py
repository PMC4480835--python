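"""Synthetic proteins, homology families and labeled variants with a planted,
feature-expressible effect signal.

The generator emulates the structure of curated variant-effect training data:
homologous protein families (each family derived from one founder by point
mutation at 10–30% of positions, so within-family identity clears the
homology edge threshold and cross-family identity does not), a ~60:40
effect:neutral class balance, and label noise.

The planted rule is expressed through features the built-in providers
actually compute, so downstream learnability is attributable to implemented
code: a variant is 'effect' iff its position is critical (deep enough inside
the sequence, measured by the same scaled terminus-proximity the feature
provider emits) AND the absolute hydropathy delta between wild-type and
variant residue exceeds a threshold.  Labels are then flipped independently
with a configurable noise rate, and the class mix is brought to the target
effect fraction by rejection sampling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from ._tables import AMINO_ACIDS, HYDROPHOBICITY
from .io import EFFECT, NEUTRAL, ProteinRecord, VariantDataset, VariantRecord
from .metrics import ConfusionCounts


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic benchmark.

    Defaults: 10 families of 3 proteins (30 proteins, 10 homology clusters),
    lengths 80–150, 2,000 variants at 60% effect with 5% label noise; the
    deepest half of each sequence is critical and a hydropathy delta above
    2.0 (Kyte–Doolittle units) is disruptive.
    """

    seed: int = 0
    n_families: int = 10
    family_size: int = 3
    mutation_rate_range: tuple[float, float] = (0.10, 0.30)
    protein_length_range: tuple[int, int] = (80, 150)
    n_variants: int = 2000
    effect_fraction: float = 0.6
    noise_rate: float = 0.05
    critical_position_fraction: float = 0.5
    delta_threshold: float = 2.0

    def __post_init__(self):
        if not 0 < self.effect_fraction < 1:
            raise ValueError("effect_fraction must be in (0, 1)")
        if not 0 <= self.noise_rate < 0.5:
            raise ValueError("noise_rate must be in [0, 0.5)")
        if not 0 < self.critical_position_fraction <= 1:
            raise ValueError("critical_position_fraction must be in (0, 1]")


def is_critical_position(position: int, length: int, fraction: float) -> bool:
    """Critical = scaled terminus proximity above (1 - fraction).

    Uses the same depth scaling as the terminus-proximity feature provider:
    min(pos, L - pos + 1) / ((L + 1) / 2).
    """
    depth = min(position, length - position + 1) / ((length + 1) / 2.0)
    return depth > (1.0 - fraction)


def true_label(variant: VariantRecord, length: int, config: SyntheticConfig) -> str:
    """The planted rule before noise."""
    delta = abs(HYDROPHOBICITY[variant.wt_aa] - HYDROPHOBICITY[variant.var_aa])
    critical = is_critical_position(variant.position, length,
                                    config.critical_position_fraction)
    return EFFECT if (critical and delta > config.delta_threshold) else NEUTRAL


def generate_proteins(config: SyntheticConfig):
    """Protein families by founder mutation.

    Returns (proteins dict, family map protein_id -> family index).  Each
    family shares a founder length; members mutate the founder at a per-family
    rate drawn from ``mutation_rate_range``, keeping within-family identity
    comfortably above the default homology edge threshold while cross-family
    pairs stay below it.
    """
    rng = np.random.default_rng(config.seed)
    aa = np.array(list(AMINO_ACIDS))
    proteins: dict[str, ProteinRecord] = {}
    family_map: dict[str, int] = {}
    lo, hi = config.protein_length_range
    for fam in range(config.n_families):
        length = int(rng.integers(lo, hi + 1))
        founder = rng.choice(aa, size=length)
        rate = rng.uniform(*config.mutation_rate_range)
        for member in range(config.family_size):
            seq = founder.copy()
            if member > 0:
                mutate = rng.random(length) < rate
                for pos in np.flatnonzero(mutate):
                    choices = [a for a in AMINO_ACIDS if a != seq[pos]]
                    seq[pos] = choices[rng.integers(len(choices))]
            pid = f"fam{fam:02d}_p{member}"
            proteins[pid] = ProteinRecord(id=pid, sequence="".join(seq))
            family_map[pid] = fam
    return proteins, family_map


def generate_variants(config: SyntheticConfig,
                      proteins: Mapping[str, ProteinRecord]) -> VariantDataset:
    """Labeled variants under the planted rule, noise-flipped, then rejection
    sampled to the configured effect fraction.

    Raises when the configured class mix cannot be reached within a draw
    budget (diagnosing the observed raw class rates).
    """
    rng = np.random.default_rng(config.seed + 1)
    ids = list(proteins)
    n_effect_target = int(round(config.n_variants * config.effect_fraction))
    n_neutral_target = config.n_variants - n_effect_target
    quota = {EFFECT: n_effect_target, NEUTRAL: n_neutral_target}
    collected: dict[tuple, VariantRecord] = {}
    counts = {EFFECT: 0, NEUTRAL: 0}
    draws = 0
    max_draws = 400 * config.n_variants
    while counts[EFFECT] < quota[EFFECT] or counts[NEUTRAL] < quota[NEUTRAL]:
        draws += 1
        if draws > max_draws:
            raise ValueError(
                f"cannot reach effect fraction {config.effect_fraction} after "
                f"{max_draws} draws (collected {counts}); adjust the rule "
                "parameters or the target fraction")
        protein = proteins[ids[rng.integers(len(ids))]]
        position = int(rng.integers(1, len(protein) + 1))
        wt = protein.residue(position)
        if wt not in AMINO_ACIDS:
            continue
        choices = [a for a in AMINO_ACIDS if a != wt]
        var = choices[rng.integers(len(choices))]
        key = (protein.id, position, wt, var)
        if key in collected:
            continue
        variant = VariantRecord(protein.id, position, wt, var, source="synthetic")
        label = true_label(variant, len(protein), config)
        if rng.random() < config.noise_rate:
            label = NEUTRAL if label == EFFECT else EFFECT
        if counts[label] >= quota[label]:
            continue
        counts[label] += 1
        collected[key] = VariantRecord(protein.id, position, wt, var,
                                       label=label, source="synthetic")
    return VariantDataset(proteins=dict(proteins), variants=list(collected.values()))


def generate_dataset(config: SyntheticConfig):
    """Convenience: (dataset, family map)."""
    proteins, family_map = generate_proteins(config)
    return generate_variants(config, proteins), family_map


def worked_confusion_tables(seed: int = 0):
    """Fixture confusion tables with directly computed expected metric values.

    Includes the canonical {TP=40, FP=20, TN=30, FN=10} table plus perfect
    and symmetric tables; expectations are plain arithmetic from the metric
    definitions, independent of the metrics module.
    """
    tables = [
        (
            ConfusionCounts(TP=40, FP=20, TN=30, FN=10),
            {
                "q2": 70 / 100,
                "mcc": (40 * 30 - 20 * 10) / (60 * 50 * 50 * 40) ** 0.5,
                "accuracy_effect": 40 / 60,
                "coverage_effect": 40 / 50,
                "accuracy_neutral": 30 / 40,
                "coverage_neutral": 30 / 50,
                "f_effect": 2 * (40 / 60) * (40 / 50) / ((40 / 60) + (40 / 50)),
                "f_neutral": 2 * (30 / 40) * (30 / 50) / ((30 / 40) + (30 / 50)),
            },
        ),
        (
            ConfusionCounts(TP=50, FP=0, TN=50, FN=0),
            {"q2": 1.0, "mcc": 1.0, "accuracy_effect": 1.0, "coverage_effect": 1.0,
             "accuracy_neutral": 1.0, "coverage_neutral": 1.0,
             "f_effect": 1.0, "f_neutral": 1.0},
        ),
        (
            ConfusionCounts(TP=25, FP=25, TN=25, FN=25),
            {"q2": 0.5, "mcc": 0.0, "accuracy_effect": 0.5, "coverage_effect": 0.5,
             "accuracy_neutral": 0.5, "coverage_neutral": 0.5,
             "f_effect": 0.5, "f_neutral": 0.5},
        ),
    ]
    rng = np.random.default_rng(seed)
    for _ in range(5):
        tp, fp, tn, fn = (int(x) for x in rng.integers(1, 200, size=4))
        expected = {
            "q2": (tp + tn) / (tp + fp + tn + fn),
            "mcc": (tp * tn - fp * fn) / ((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)) ** 0.5,
            "accuracy_effect": tp / (tp + fp),
            "coverage_effect": tp / (tp + fn),
            "accuracy_neutral": tn / (tn + fn),
            "coverage_neutral": tn / (tn + fp),
        }
        tables.append((ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn), expected))
    return tables
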