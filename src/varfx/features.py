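"""Per-variant feature encoding: windows, deltas, global and pluggable features.

Per-residue features are scanned in sliding windows of w in {1, 5, 9, 13, 17,
21} consecutive residues centred on the variant position.  Window cells that
fall outside the sequence are zero-filled and flagged by an explicit per-cell
padding indicator, so every windowed descriptor has a fixed length of
w * (values-per-residue + 1).  Delta features are elementwise
native-minus-variant differences of a per-residue feature.

Providers are registered by name; a descriptor resolves to a provider plus a
window.  External per-residue profiles (evolutionary or structural features
computed by outside tools) enter through :class:`PrecomputedProfileProvider`;
when a profile is missing for a protein the affected variant rows are
excluded, never silently imputed.

Column normalization is z-scoring whose parameters are fitted on training
rows only (see :class:`Scaler`), stored, and reused unchanged on cross-train
and test rows.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ._tables import (
    AA_INDEX,
    AAINDEX_SCALES,
    AMINO_ACIDS,
    CHARGE,
    HYDROPHOBICITY,
    VOLUME,
    contact_potential_table,
    validate_contact_table,
)
from .io import ProteinRecord, VariantDataset, VariantRecord

logger = logging.getLogger(__name__)

ALLOWED_WINDOWS = (1, 5, 9, 13, 17, 21)

PER_RESIDUE = "per_residue"
VARIANT = "variant"
GLOBAL = "global"


@dataclass(frozen=True)
class FeatureDescriptor:
    """A named, resolvable feature: provider plus (for windowed kinds) a window."""

    provider: str
    window: int = 1
    name: str = ""

    def __post_init__(self):
        if self.window not in ALLOWED_WINDOWS:
            raise ValueError(f"window must be one of {ALLOWED_WINDOWS}, got {self.window}")
        if not self.name:
            object.__setattr__(self, "name", f"{self.provider}@w{self.window}")


def biophysical_features(aa: str) -> np.ndarray:
    """(charge, hydrophobicity, volume) for one residue on documented scales."""
    if aa not in AMINO_ACIDS:
        raise ValueError(f"unknown amino acid {aa!r}")
    return np.array([CHARGE[aa], HYDROPHOBICITY[aa], VOLUME[aa]])


def compute_delta(feature_native: Sequence[float], feature_variant: Sequence[float]) -> np.ndarray:
    """Elementwise native - variant difference."""
    a = np.asarray(feature_native, dtype=float)
    b = np.asarray(feature_variant, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"delta length mismatch: {a.shape} vs {b.shape}")
    return a - b


def contact_potential_feature(wt: str, var: str, potential_table: np.ndarray) -> np.ndarray:
    """wt row, var row, and their native-minus-variant delta (60 values)."""
    table = validate_contact_table(potential_table)
    row_wt = table[AA_INDEX[wt]]
    row_var = table[AA_INDEX[var]]
    return np.concatenate([row_wt, row_var, row_wt - row_var])


def global_features(protein: ProteinRecord,
                    structure_states: Sequence[str] | None = None,
                    accessibility_states: Sequence[str] | None = None):
    """Amino-acid composition (sums to 1), scaled length, optional structure bins.

    Returns ``(values, names)``.  When no structure/accessibility states are
    supplied the corresponding cells are absent from the output entirely
    (missing features are never encoded as zero).
    """
    counts = np.zeros(20)
    n = 0
    for aa in protein.sequence:
        if aa in AA_INDEX:
            counts[AA_INDEX[aa]] += 1
            n += 1
    values = list(counts / max(n, 1))
    names = [f"composition:{aa}" for aa in AMINO_ACIDS]
    values.append(min(len(protein), 1000) / 1000.0)
    names.append("length_scaled")
    if structure_states is not None:
        for state in "HEC":
            values.append(sum(1 for s in structure_states if s == state) / len(structure_states))
            names.append(f"ss_composition:{state}")
    if accessibility_states is not None:
        for state in "be":
            values.append(sum(1 for s in accessibility_states if s == state) / len(accessibility_states))
            names.append(f"acc_composition:{state}")
    return np.array(values), names


class Provider:
    """Base class for feature providers.

    ``kind`` is one of ``per_residue`` (windowable, per-position values),
    ``variant`` (depends on the substitution), ``global`` (whole protein).
    """

    name: str
    kind: str
    value_names: tuple[str, ...]

    @property
    def n_values(self) -> int:
        return len(self.value_names)

    def per_residue(self, protein: ProteinRecord, position: int) -> np.ndarray:
        raise NotImplementedError

    def variant_values(self, protein: ProteinRecord, variant: VariantRecord):
        raise NotImplementedError

    def global_values(self, protein: ProteinRecord):
        raise NotImplementedError


class BiophysicalProvider(Provider):
    """Charge, hydrophobicity and volume of the residue at each position (scaled)."""

    name = "biophys"
    kind = PER_RESIDUE
    value_names = ("charge", "hydrophobicity", "volume")
    _scale = np.array([1.0, 4.5, 227.8])

    def per_residue(self, protein, position):
        return biophysical_features(protein.residue(position)) / self._scale


class BiophysicalDeltaProvider(Provider):
    """Native-minus-variant delta of (charge, hydrophobicity, volume)."""

    name = "biophys_delta"
    kind = VARIANT
    value_names = ("d_charge", "d_hydrophobicity", "d_volume")
    _scale = np.array([1.0, 4.5, 227.8])

    def variant_values(self, protein, variant):
        return compute_delta(biophysical_features(variant.wt_aa),
                             biophysical_features(variant.var_aa)) / self._scale


class AAIndexProvider(Provider):
    """One curated AAindex-style scale per residue position."""

    kind = PER_RESIDUE

    def __init__(self, scale: str):
        if scale not in AAINDEX_SCALES:
            raise ValueError(f"unknown scale {scale!r}; have {sorted(AAINDEX_SCALES)}")
        self.scale = scale
        self.name = f"aaindex:{scale}"
        self.value_names = (scale,)
        table = AAINDEX_SCALES[scale]
        self._max = max(abs(v) for v in table.values())

    def per_residue(self, protein, position):
        return np.array([AAINDEX_SCALES[self.scale][protein.residue(position)] / self._max])


class AAIndexDeltaProvider(Provider):
    kind = VARIANT

    def __init__(self, scale: str):
        self._base = AAIndexProvider(scale)
        self.name = f"aaindex_delta:{scale}"
        self.value_names = (f"d_{scale}",)

    def variant_values(self, protein, variant):
        table = AAINDEX_SCALES[self._base.scale]
        return np.array([(table[variant.wt_aa] - table[variant.var_aa]) / self._base._max])


class OneHotProvider(Provider):
    """Explicit sequence: 20-dimensional one-hot identity of each residue."""

    name = "onehot"
    kind = PER_RESIDUE
    value_names = tuple(f"is_{aa}" for aa in AMINO_ACIDS)

    def per_residue(self, protein, position):
        vec = np.zeros(20)
        aa = protein.residue(position)
        if aa in AA_INDEX:
            vec[AA_INDEX[aa]] = 1.0
        return vec


class OneHotVariantProvider(Provider):
    """Sequence and variant profile stand-in: one-hot wt plus one-hot var."""

    name = "onehot_wt_var"
    kind = VARIANT
    value_names = tuple(f"wt_{aa}" for aa in AMINO_ACIDS) + tuple(
        f"var_{aa}" for aa in AMINO_ACIDS)

    def variant_values(self, protein, variant):
        vec = np.zeros(40)
        vec[AA_INDEX[variant.wt_aa]] = 1.0
        vec[20 + AA_INDEX[variant.var_aa]] = 1.0
        return vec


class ContactPotentialRowProvider(Provider):
    """Contact-potential profile (20 pair energies) of the residue at each position."""

    name = "contact_row"
    kind = PER_RESIDUE
    value_names = tuple(f"cp_{aa}" for aa in AMINO_ACIDS)

    def __init__(self, table: np.ndarray | None = None):
        self.table = validate_contact_table(
            contact_potential_table() if table is None else table)

    def per_residue(self, protein, position):
        return self.table[AA_INDEX[protein.residue(position)]].copy()


class ContactPotentialDeltaProvider(Provider):
    """wt contact-potential row, var row and their delta (60 values)."""

    name = "contact_wt_var_delta"
    kind = VARIANT
    value_names = (
        tuple(f"cp_wt_{aa}" for aa in AMINO_ACIDS)
        + tuple(f"cp_var_{aa}" for aa in AMINO_ACIDS)
        + tuple(f"cp_delta_{aa}" for aa in AMINO_ACIDS)
    )

    def __init__(self, table: np.ndarray | None = None):
        self.table = validate_contact_table(
            contact_potential_table() if table is None else table)

    def variant_values(self, protein, variant):
        return contact_potential_feature(variant.wt_aa, variant.var_aa, self.table)


class TerminusProximityProvider(Provider):
    """min(position, length - position + 1) scaled to (0, 1]; 1 = mid-sequence."""

    name = "terminus_proximity"
    kind = VARIANT
    value_names = ("terminus_proximity",)

    def variant_values(self, protein, variant):
        length = len(protein)
        depth = min(variant.position, length - variant.position + 1)
        return np.array([depth / ((length + 1) / 2.0)])


class CompositionProvider(Provider):
    name = "composition"
    kind = GLOBAL
    value_names = tuple(f"comp_{aa}" for aa in AMINO_ACIDS)

    def global_values(self, protein):
        values, _ = global_features(protein)
        return values[:20]


class LengthProvider(Provider):
    name = "length"
    kind = GLOBAL
    value_names = ("length_scaled",)

    def global_values(self, protein):
        return np.array([min(len(protein), 1000) / 1000.0])


class NoiseProvider(Provider):
    """Deterministic pure-noise control feature (no signal by construction)."""

    kind = VARIANT

    def __init__(self, salt: int = 0):
        self.salt = salt
        self.name = f"noise:{salt}"
        self.value_names = ("noise",)

    def variant_values(self, protein, variant):
        key = f"{self.salt}|{protein.id}|{variant.token}".encode()
        seed = zlib.crc32(key)
        return np.random.default_rng(seed).standard_normal(1)


class PrecomputedProfileProvider(Provider):
    """External per-residue profiles loaded from TSV.

    Expected columns: protein_id, position, feature_name, value — one row per
    cell.  ``per_residue`` returns None for proteins without a profile; the
    assembly step then excludes the affected variant rows with a logged count.
    """

    kind = PER_RESIDUE

    def __init__(self, name: str, path=None, frame: pd.DataFrame | None = None):
        self.name = name
        if frame is None:
            frame = pd.read_csv(path, sep="\t",
                                dtype={"protein_id": str, "feature_name": str})
        self.value_names = tuple(sorted(frame["feature_name"].unique()))
        self._data: dict[tuple[str, int], np.ndarray] = {}
        order = {f: i for i, f in enumerate(self.value_names)}
        for (pid, pos), grp in frame.groupby(["protein_id", "position"]):
            vec = np.full(len(order), np.nan)
            for fname, value in zip(grp["feature_name"], grp["value"]):
                vec[order[fname]] = float(value)
            self._data[(pid, int(pos))] = vec

    def per_residue(self, protein, position):
        vec = self._data.get((protein.id, position))
        if vec is None or np.isnan(vec).any():
            return None
        return vec


class ProviderRegistry(dict):
    """Mapping provider name -> Provider with a convenience register()."""

    def register(self, provider: Provider) -> Provider:
        if provider.name in self:
            raise ValueError(f"provider {provider.name!r} already registered")
        self[provider.name] = provider
        return provider

    def resolve(self, descriptor: FeatureDescriptor) -> Provider:
        if descriptor.provider not in self:
            raise KeyError(f"descriptor {descriptor.name!r}: no provider "
                           f"{descriptor.provider!r} registered")
        provider = self[descriptor.provider]
        if provider.kind != PER_RESIDUE and descriptor.window != 1:
            raise ValueError(
                f"descriptor {descriptor.name!r}: windows apply to per-residue "
                f"providers only ({provider.kind!r} given)")
        return provider


def default_registry(contact_table: np.ndarray | None = None) -> ProviderRegistry:
    """Registry with every built-in provider."""
    reg = ProviderRegistry()
    reg.register(BiophysicalProvider())
    reg.register(BiophysicalDeltaProvider())
    reg.register(OneHotProvider())
    reg.register(OneHotVariantProvider())
    reg.register(ContactPotentialRowProvider(contact_table))
    reg.register(ContactPotentialDeltaProvider(contact_table))
    reg.register(TerminusProximityProvider())
    reg.register(CompositionProvider())
    reg.register(LengthProvider())
    for scale in AAINDEX_SCALES:
        reg.register(AAIndexProvider(scale))
        reg.register(AAIndexDeltaProvider(scale))
    return reg


def noali_descriptors(include_matrix: bool = False) -> list[FeatureDescriptor]:
    """Alignment-free feature profile: global composition and length, explicit
    wt/var encoding, contact-potential profiles and delta, hydrophobicity and
    volume (with deltas via the biophysical block), index scales and terminus
    proximity; plus the effect-probability matrix feature when available."""
    descriptors = [
        FeatureDescriptor("composition"),
        FeatureDescriptor("length"),
        FeatureDescriptor("onehot_wt_var"),
        FeatureDescriptor("contact_wt_var_delta"),
        FeatureDescriptor("biophys", window=5),
        FeatureDescriptor("biophys_delta"),
        FeatureDescriptor("aaindex:polarity_grantham"),
        FeatureDescriptor("aaindex_delta:polarity_grantham"),
        FeatureDescriptor("terminus_proximity"),
    ]
    if include_matrix:
        descriptors.append(FeatureDescriptor("effect_matrix"))
    return descriptors


def encode_window(protein: ProteinRecord, position: int, w: int,
                  per_residue_feature: Provider) -> np.ndarray:
    """Windowed per-residue features with per-cell padding indicators.

    For each of the w cells: the provider's values (zeros when the cell falls
    outside the sequence) followed by one padding flag (1 = padded).
    Returns None when the provider reports a missing profile for any
    in-sequence cell.
    """
    if w not in ALLOWED_WINDOWS:
        raise ValueError(f"window must be one of {ALLOWED_WINDOWS}, got {w}")
    if not 1 <= position <= len(protein):
        raise ValueError(f"position {position} outside 1..{len(protein)}")
    half = (w - 1) // 2
    k = per_residue_feature.n_values
    out = np.zeros(w * (k + 1))
    for cell, pos in enumerate(range(position - half, position + half + 1)):
        base = cell * (k + 1)
        if 1 <= pos <= len(protein):
            values = per_residue_feature.per_residue(protein, pos)
            if values is None:
                return None
            out[base:base + k] = values
        else:
            out[base + k] = 1.0
    return out


def column_layout(descriptors: Sequence[FeatureDescriptor],
                  registry: ProviderRegistry) -> list[str]:
    """Deterministic column names: descriptor order, window cell, sub-feature."""
    names = []
    for d in descriptors:
        provider = registry.resolve(d)
        if provider.kind == PER_RESIDUE:
            half = (d.window - 1) // 2
            for offset in range(-half, half + 1):
                for sub in provider.value_names:
                    names.append(f"{d.name}[{offset:+d}].{sub}")
                names.append(f"{d.name}[{offset:+d}].pad")
        else:
            for sub in provider.value_names:
                names.append(f"{d.name}.{sub}")
    return names


@dataclass
class FeatureMatrix:
    """Rectangular matrix of per-variant feature vectors with a shared layout."""

    X: np.ndarray
    column_names: list[str]
    variant_indices: list[int]
    n_excluded: int = 0

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]


@dataclass
class Scaler:
    """Per-column z-score parameters; fitted on training rows only."""

    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray, rows: np.ndarray | None = None) -> "Scaler":
        sub = X if rows is None else X[rows]
        mean = sub.mean(axis=0)
        sd = sub.std(axis=0)
        sd = np.where(sd < 1e-8, 1.0, sd)  # constant columns pass through
        return cls(mean=mean, sd=sd)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.sd

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "sd": self.sd.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "Scaler":
        return cls(mean=np.array(d["mean"]), sd=np.array(d["sd"]))


def assemble_feature_matrix(dataset: VariantDataset,
                            descriptors: Sequence[FeatureDescriptor],
                            registry: ProviderRegistry,
                            variants: Sequence[VariantRecord] | None = None) -> FeatureMatrix:
    """Encode every variant into one fixed-layout numeric row.

    Variants whose external profiles are missing are excluded with a logged
    count; their indices are absent from ``variant_indices``.
    """
    if variants is None:
        variants = dataset.variants
    providers = [registry.resolve(d) for d in descriptors]
    names = column_layout(descriptors, registry)
    global_cache: dict[tuple[str, str], np.ndarray] = {}
    rows, kept = [], []
    n_excluded = 0
    for i, v in enumerate(variants):
        protein = dataset.proteins[v.protein_id]
        parts = []
        ok = True
        for d, provider in zip(descriptors, providers):
            if provider.kind == PER_RESIDUE:
                vals = encode_window(protein, v.position, d.window, provider)
            elif provider.kind == VARIANT:
                vals = provider.variant_values(protein, v)
            else:
                key = (d.name, protein.id)
                if key not in global_cache:
                    global_cache[key] = provider.global_values(protein)
                vals = global_cache[key]
            if vals is None:
                ok = False
                break
            parts.append(np.asarray(vals, dtype=float))
        if not ok:
            n_excluded += 1
            continue
        row = np.concatenate(parts)
        if not np.all(np.isfinite(row)):
            raise ValueError(f"non-finite feature value for variant {v.token} on {v.protein_id}")
        rows.append(row)
        kept.append(i)
    if n_excluded:
        logger.warning("excluded %d variant rows with missing external profiles", n_excluded)
    X = np.vstack(rows) if rows else np.zeros((0, len(names)))
    if X.shape[1] != len(names):
        raise RuntimeError("feature layout mismatch")
    return FeatureMatrix(X=X, column_names=names, variant_indices=kept,
                         n_excluded=n_excluded)
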