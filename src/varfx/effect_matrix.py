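"""Alignment-free effect-probability substitution matrix.

In-silico saturation mutagenesis — predicting all 19 possible substitutions
at every residue position of a protein set with a trained ensemble — yields,
for each ordered amino-acid pair (wt, var), the fraction of wt→var
predictions classified as 'effect'.  That 20×20 table is a substitution
matrix of effect probabilities, usable as a single-sequence feature for the
alignment-free prediction mode: it supplies a generic prior for how
disruptive a substitution type tends to be, without any alignment.

Cells never observed have no probability (undefined, not zero); the diagonal
is undefined by construction since wt = var is not a variant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from ._tables import AA_INDEX, AMINO_ACIDS
from .features import Provider, VARIANT
from .io import PredictionResult, ProteinRecord, VariantDataset, VariantRecord

logger = logging.getLogger(__name__)


@dataclass
class EffectMatrix:
    """20×20 effect probabilities (NaN = undefined) with per-cell support counts."""

    probabilities: np.ndarray
    support: np.ndarray

    def __post_init__(self):
        if self.probabilities.shape != (20, 20) or self.support.shape != (20, 20):
            raise ValueError("effect matrix must be 20x20")
        defined = ~np.isnan(self.probabilities)
        if np.any((self.probabilities[defined] < 0) | (self.probabilities[defined] > 1)):
            raise ValueError("probabilities must be in [0, 1]")
        if np.any(self.support < 0):
            raise ValueError("support counts must be >= 0")

    def cell(self, wt: str, var: str) -> float | None:
        value = self.probabilities[AA_INDEX[wt], AA_INDEX[var]]
        return None if np.isnan(value) else float(value)


def saturation_variants(proteins: Mapping[str, ProteinRecord]) -> list[VariantRecord]:
    """All 19 substitutions per residue position, position-major then
    alphabetical by variant residue — a deterministic enumeration."""
    variants = []
    for protein in proteins.values():
        for position in range(1, len(protein) + 1):
            wt = protein.residue(position)
            if wt not in AA_INDEX:
                continue
            for var in AMINO_ACIDS:
                if var != wt:
                    variants.append(VariantRecord(protein.id, position, wt, var,
                                                  source="saturation"))
    return variants


def saturation_predict(ensemble, proteins: Mapping[str, ProteinRecord],
                       registry) -> list[PredictionResult]:
    """Predict every possible substitution at every position of every protein."""
    from .ensemble import predict  # local import to avoid a cycle

    dataset = VariantDataset(proteins=dict(proteins),
                             variants=saturation_variants(proteins))
    return predict(ensemble, dataset, registry, variants=dataset.variants)


def derive_effect_matrix(results: Iterable[PredictionResult],
                         threshold: float = -0.05) -> EffectMatrix:
    """Cell (wt, var) = fraction of wt→var predictions classified effect.

    Classification re-applies ``threshold`` to the raw averaged-output
    difference, so one set of saturation predictions can be re-thresholded.
    """
    results = list(results)
    if not results:
        raise ValueError("no predictions to derive the matrix from")
    effect = np.zeros((20, 20))
    support = np.zeros((20, 20), dtype=int)
    for r in results:
        i, j = AA_INDEX[r.wt_aa], AA_INDEX[r.var_aa]
        support[i, j] += 1
        if (r.avg_output_effect - r.avg_output_neutral) > threshold:
            effect[i, j] += 1
    probs = np.full((20, 20), np.nan)
    defined = support > 0
    probs[defined] = effect[defined] / support[defined]
    return EffectMatrix(probabilities=probs, support=support)


def matrix_feature(matrix: EffectMatrix, wt: str, var: str) -> float | None:
    """Cell probability for use as a candidate descriptor; None when undefined."""
    return matrix.cell(wt, var)


class EffectMatrixProvider(Provider):
    """Feature provider exposing the effect-probability matrix cell.

    Undefined cells propagate the missing-feature marker (the variant row is
    then excluded from the assembled matrix, never imputed).
    """

    name = "effect_matrix"
    kind = VARIANT
    value_names = ("effect_probability",)

    def __init__(self, matrix: EffectMatrix):
        self.matrix = matrix

    def variant_values(self, protein, variant):
        value = self.matrix.cell(variant.wt_aa, variant.var_aa)
        if value is None:
            return None
        return np.array([value])


def save_effect_matrix(matrix: EffectMatrix, path) -> None:
    """Write the probability TSV plus a `.support.tsv` companion with counts."""
    index = list(AMINO_ACIDS)
    pd.DataFrame(matrix.probabilities, index=index, columns=index).to_csv(
        path, sep="\t", float_format="%.6f", na_rep="NA")
    pd.DataFrame(matrix.support, index=index, columns=index).to_csv(
        str(path) + ".support.tsv", sep="\t")


def load_effect_matrix(path) -> EffectMatrix:
    probs = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    probs = probs.loc[list(AMINO_ACIDS), list(AMINO_ACIDS)].to_numpy(dtype=float)
    try:
        support_df = pd.read_csv(str(path) + ".support.tsv", sep="\t", index_col=0)
        support = support_df.loc[list(AMINO_ACIDS), list(AMINO_ACIDS)].to_numpy(dtype=int)
    except FileNotFoundError:
        support = (~np.isnan(probs)).astype(int)
        logger.warning("no support companion for %s; assuming support 1 per defined cell",
                       path)
    return EffectMatrix(probabilities=probs, support=support)
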