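"""Data model and readers/writers for sequences, variant tables and predictions.

The atomic unit of data is a :class:`VariantRecord`: one single amino-acid
substitution on one protein, written with the compact token convention
``<wt><position><var>`` (e.g. ``R109Q``), positions 1-based.  Labels are one
of ``neutral`` (no change of molecular function), ``effect`` (any change,
gain or loss), or ``unlabeled``.

Two alphabet policies exist: in strict mode (default) any residue outside the
20-letter canonical alphabet is an error; in lenient mode the non-canonical
codes B, Z, X, U, O are mapped to ``X`` and such positions are never valid
variant sites.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

from ._tables import AMINO_ACIDS

logger = logging.getLogger(__name__)

NEUTRAL = "neutral"
EFFECT = "effect"
UNLABELED = "unlabeled"
LABELS = (NEUTRAL, EFFECT, UNLABELED)

_NONCANONICAL = set("BZXUO")
_TOKEN_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z])$")


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence; positions are 1-based throughout the package."""

    id: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)

    def residue(self, position: int) -> str:
        """Residue at 1-based ``position``."""
        if not 1 <= position <= len(self.sequence):
            raise ValueError(
                f"protein {self.id!r}: position {position} outside 1..{len(self.sequence)}"
            )
        return self.sequence[position - 1]


@dataclass(frozen=True)
class VariantRecord:
    """One substitution ``wt_aa`` -> ``var_aa`` at ``position`` of ``protein_id``."""

    protein_id: str
    position: int
    wt_aa: str
    var_aa: str
    label: str = UNLABELED
    source: str = ""

    def __post_init__(self):
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.wt_aa == self.var_aa:
            raise ValueError(f"wild-type and variant residue identical: {self.token}")
        for aa in (self.wt_aa, self.var_aa):
            if aa not in AMINO_ACIDS:
                raise ValueError(f"non-canonical residue {aa!r} in variant {self.token}")
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")

    @property
    def token(self) -> str:
        return f"{self.wt_aa}{self.position}{self.var_aa}"

    @property
    def key(self) -> tuple:
        return (self.protein_id, self.position, self.wt_aa, self.var_aa)


@dataclass
class VariantDataset:
    """Proteins keyed by id plus a deduplicated list of variants."""

    proteins: dict[str, ProteinRecord]
    variants: list[VariantRecord] = field(default_factory=list)

    def __post_init__(self):
        seen = set()
        unique = []
        for v in self.variants:
            if v.protein_id not in self.proteins:
                raise ValueError(f"variant {v.token}: unknown protein {v.protein_id!r}")
            prot = self.proteins[v.protein_id]
            if v.position > len(prot):
                raise ValueError(
                    f"variant {v.token} on {v.protein_id}: position beyond sequence "
                    f"length {len(prot)}"
                )
            if prot.residue(v.position) != v.wt_aa:
                raise ValueError(
                    f"variant {v.token} on {v.protein_id}: sequence has "
                    f"{prot.residue(v.position)} at position {v.position}"
                )
            if v.key not in seen:
                seen.add(v.key)
                unique.append(v)
        self.variants = unique

    def labeled(self) -> list[VariantRecord]:
        return [v for v in self.variants if v.label != UNLABELED]

    def __len__(self) -> int:
        return len(self.variants)


@dataclass(frozen=True)
class PredictionResult:
    """Ensemble output for one variant.

    ``score`` is the averaged output difference scaled to [-100, +100]
    (negative = neutral, positive = effect); ``ri`` is the 0..10 reliability
    index and ``display_digit`` its single-digit 0..9 projection.
    """

    protein_id: str
    position: int
    wt_aa: str
    var_aa: str
    avg_output_effect: float
    avg_output_neutral: float
    score: float
    predicted_class: str
    ri: int
    display_digit: int

    @property
    def token(self) -> str:
        return f"{self.wt_aa}{self.position}{self.var_aa}"


def _clean_sequence(seq: str, record_id: str, strict: bool) -> str:
    seq = seq.upper()
    cleaned = []
    for pos, aa in enumerate(seq, start=1):
        if aa in AMINO_ACIDS:
            cleaned.append(aa)
        elif strict:
            raise ValueError(
                f"protein {record_id!r}: non-canonical residue {aa!r} at position {pos}"
            )
        elif aa in _NONCANONICAL:
            cleaned.append("X")
        else:
            raise ValueError(
                f"protein {record_id!r}: unknown character {aa!r} at position {pos}"
            )
    return "".join(cleaned)


def read_fasta(path, strict: bool = True) -> dict[str, ProteinRecord]:
    """Read a FASTA file into an ordered mapping id -> ProteinRecord.

    Ids are the first whitespace-delimited header token; sequences are
    upper-cased and validated against the alphabet policy.
    """
    proteins: dict[str, ProteinRecord] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = _clean_sequence(str(rec.seq), rec.id, strict)
        if rec.id in proteins:
            raise ValueError(f"duplicate protein id {rec.id!r} in {path}")
        proteins[rec.id] = ProteinRecord(id=rec.id, sequence=seq)
    if not proteins:
        raise ValueError(f"no FASTA records found in {path}")
    return proteins


def parse_variant_token(token: str) -> tuple[str, int, str]:
    """Decompose a substitution token like ``R109Q`` into (wt, position, var)."""
    m = _TOKEN_RE.match(token.strip())
    if m is None:
        raise ValueError(f"malformed variant token {token!r} (expected <AA><pos><AA>)")
    wt, pos_s, var = m.group(1).upper(), m.group(2), m.group(3).upper()
    position = int(pos_s)
    if position < 1:
        raise ValueError(f"variant token {token!r}: position must be >= 1")
    for aa in (wt, var):
        if aa not in AMINO_ACIDS:
            raise ValueError(f"variant token {token!r}: non-canonical residue {aa!r}")
    if wt == var:
        raise ValueError(f"variant token {token!r}: wild-type equals variant")
    return wt, position, var


def format_variant(v: VariantRecord) -> str:
    return v.token


_LABEL_ALIASES = {
    "neutral": NEUTRAL, "effect": EFFECT, "unlabeled": UNLABELED, "": UNLABELED,
}


def _normalize_label(raw) -> str:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return UNLABELED
    key = str(raw).strip().lower()
    if key not in _LABEL_ALIASES:
        raise ValueError(f"unknown label {raw!r} (expected neutral/effect/unlabeled)")
    return _LABEL_ALIASES[key]


def load_variant_table(path, proteins: Mapping[str, ProteinRecord]) -> VariantDataset:
    """Load a TSV variant table (protein_id, variant_token[, label[, source]]).

    Every row is validated against the protein sequences; a wild-type
    mismatch or unknown protein id raises with the offending row number.
    Duplicate (protein, position, wt, var) rows are collapsed.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"protein_id", "variant_token"}
    if not required.issubset(df.columns):
        raise ValueError(f"variant table {path}: missing columns {required - set(df.columns)}")
    variants = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        pid = row.protein_id
        if pid not in proteins:
            raise ValueError(f"{path} row {row_no}: unknown protein id {pid!r}")
        wt, pos, var = parse_variant_token(row.variant_token)
        prot = proteins[pid]
        if pos > len(prot):
            raise ValueError(
                f"{path} row {row_no}: position {pos} beyond length {len(prot)} of {pid}"
            )
        if prot.residue(pos) != wt:
            raise ValueError(
                f"{path} row {row_no}: wild-type mismatch, sequence of {pid} has "
                f"{prot.residue(pos)} at {pos}, token says {wt}"
            )
        label = _normalize_label(getattr(row, "label", UNLABELED))
        source = getattr(row, "source", "")
        variants.append(VariantRecord(pid, pos, wt, var, label=label, source=source))
    return VariantDataset(proteins=dict(proteins), variants=variants)


def write_variant_table(dataset: VariantDataset, path) -> None:
    rows = [
        {"protein_id": v.protein_id, "variant_token": v.token,
         "label": v.label, "source": v.source}
        for v in dataset.variants
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# PMD-style functional-effect grades: '=' means function equivalent to
# wild-type; any graded increase or decrease means effect; conflicting
# annotation sets collapse to effect.
_PMD_EFFECT = {"+", "++", "+++", "-", "--", "---"}


def map_pmd_annotation(raw) -> str:
    """Map a PMD-style annotation (or a set of them) to neutral/effect.

    ``'='`` -> neutral; any ``+``/``-`` grade -> effect; a set containing
    more than one distinct code (conflicting assays) -> effect.
    """
    if isinstance(raw, str):
        codes = {raw}
    else:
        codes = set(raw)
    if not codes:
        raise ValueError("empty annotation set")
    norm = set()
    for code in codes:
        c = str(code).replace(" ", "")
        if c == "=":
            norm.add("=")
        elif c in _PMD_EFFECT:
            norm.add(c)
        else:
            raise ValueError(f"unrecognized functional-effect annotation {code!r}")
    if norm == {"="}:
        return NEUTRAL
    return EFFECT


_PRED_COLUMNS = [
    "protein_id", "variant_token", "score", "predicted_class", "ri", "display_digit",
]


def write_predictions(results: Iterable[PredictionResult], path) -> None:
    """Write predictions as TSV (score on the -100..+100 scale, RI 0-10, digit 0-9)."""
    results = list(results)
    if not results:
        raise ValueError("no predictions to write")
    rows = [
        {
            "protein_id": r.protein_id,
            "variant_token": r.token,
            "score": f"{r.score:.2f}",
            "predicted_class": r.predicted_class,
            "ri": r.ri,
            "display_digit": r.display_digit,
        }
        for r in results
    ]
    pd.DataFrame(rows, columns=_PRED_COLUMNS).to_csv(path, sep="\t", index=False)


def read_predictions(path) -> pd.DataFrame:
    """Read a prediction TSV back into a DataFrame (scores as floats)."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "variant_token": str})
    df["score"] = df["score"].astype(float)
    return df


def variant_from_token(protein: ProteinRecord, token: str, label: str = UNLABELED,
                       source: str = "") -> VariantRecord:
    wt, pos, var = parse_variant_token(token)
    return VariantRecord(protein.id, pos, wt, var, label=label, source=source)
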