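"""PSI-BLAST ASCII PSSM profiles, FASTA sequences, and tabular dataset I/O.

A position-specific scoring matrix (PSSM) is the L×20 evolutionary profile
PSI-BLAST emits for a query of length L: cell p_{i,j} is the log-odds of the
residue at position i mutating to amino-acid type j. PSI-BLAST's
``-out_ascii_pssm`` dump prints two 20-column blocks per position — the
log-odds scores followed by weighted observed percentages. The parser
consumes the log-odds block by default and remaps columns from PSI-BLAST's
native residue order to canonical alphabetical order, so that column j
always means the j-th letter of A..Y downstream.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

from mlec.dataset import MultiLabelDataset

#: The 20 standard amino acids in alphabetical (canonical) order.
CANONICAL_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: Column order used by PSI-BLAST ASCII output.
PSIBLAST_COLUMN_ORDER = "ARNDCQEGHILKMFPSTWYV"

# canonical column j holds the native column of the same residue letter
_NATIVE_TO_CANONICAL = np.array(
    [PSIBLAST_COLUMN_ORDER.index(aa) for aa in CANONICAL_ALPHABET]
)
_CANONICAL_TO_NATIVE = np.array(
    [CANONICAL_ALPHABET.index(aa) for aa in PSIBLAST_COLUMN_ORDER]
)

_AMBIGUOUS_RESIDUES = set("BZXUJO")


class PSSMParseError(ValueError):
    """Raised when an ASCII PSSM file cannot be parsed."""


@dataclass
class ProteinSequence:
    """A named amino-acid sequence.

    Residues outside the 20-letter canonical alphabet (B, Z, X, U, ...) are
    tolerated with a warning: the PSSM rows they produce are ordinary score
    rows and the feature transform depends only on matrix values.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()
        if len(self.residues) == 0:
            raise ValueError(f"sequence {self.id!r} has zero residues")
        nonstandard = sorted(set(self.residues) - set(CANONICAL_ALPHABET))
        if nonstandard:
            bad = [c for c in nonstandard if c not in _AMBIGUOUS_RESIDUES]
            if bad:
                raise ValueError(
                    f"sequence {self.id!r} contains non-amino-acid characters {bad}"
                )
            warnings.warn(
                f"sequence {self.id!r} contains non-standard residues "
                f"{nonstandard}; kept as-is",
                stacklevel=2,
            )

    @property
    def L(self) -> int:
        return len(self.residues)


@dataclass
class PSSMProfile:
    """An L×20 PSSM with columns in canonical alphabetical order."""

    sequence_id: str
    scores: np.ndarray
    residues: str = ""

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValueError(
                f"profile {self.sequence_id!r}: scores must be L×20, "
                f"got shape {self.scores.shape}"
            )
        if self.scores.shape[0] < 1:
            raise ValueError(f"profile {self.sequence_id!r} is empty")
        if not self.residues:
            self.residues = "X" * self.scores.shape[0]
        if len(self.residues) != self.scores.shape[0]:
            raise ValueError(
                f"profile {self.sequence_id!r}: {self.scores.shape[0]} score rows "
                f"but {len(self.residues)} residues"
            )

    @property
    def L(self) -> int:
        return self.scores.shape[0]


def _is_residue_header(tokens: list[str]) -> bool:
    return (
        len(tokens) in (20, 40)
        and all(len(t) == 1 and t.isalpha() and t.isupper() for t in tokens)
        and set(tokens) == set(PSIBLAST_COLUMN_ORDER)
    )


def parse_ascii_pssm(
    text: str, sequence_id: str = "", block: str = "log_odds"
) -> PSSMProfile:
    """Parse a PSI-BLAST ``-out_ascii_pssm`` dump into a :class:`PSSMProfile`.

    Parameters
    ----------
    text:
        Full file content.
    sequence_id:
        Identifier to attach; defaults to empty.
    block:
        ``"log_odds"`` (default) selects the first 20-column block;
        ``"percentages"`` selects the second (weighted observed percentages).

    Columns are remapped from PSI-BLAST native order (A R N D C Q E G H I L K
    M F P S T W Y V) to canonical alphabetical order. Values are taken
    exactly as printed.
    """
    if block not in ("log_odds", "percentages"):
        raise ValueError(f"unknown block {block!r}")
    lines = text.splitlines()
    header_idx = None
    for i, line in enumerate(lines):
        if _is_residue_header(line.split()):
            header_idx = i
            break
    if header_idx is None:
        raise PSSMParseError(
            "no residue-order header line found (expected the 20 amino-acid "
            "letters in PSI-BLAST order)"
        )

    rows: list[list[float]] = []
    residues: list[str] = []
    expected_index = 1
    for lineno, line in enumerate(lines[header_idx + 1 :], start=header_idx + 2):
        tokens = line.split()
        if not tokens:
            continue
        if not tokens[0].lstrip("-").isdigit():
            break  # trailing K/Lambda statistics block
        if len(tokens) < 2 or len(tokens[1]) != 1 or not tokens[1].isalpha():
            raise PSSMParseError(f"line {lineno}: expected 'index residue scores...'")
        try:
            values = [float(t) for t in tokens[2:]]
        except ValueError as exc:
            raise PSSMParseError(f"line {lineno}: non-numeric score field") from exc
        # 20 log-odds, optionally 20 percentages, optionally info + weight
        if len(values) not in (20, 22, 40, 42):
            raise PSSMParseError(
                f"line {lineno}: expected 20 score fields per block, "
                f"got {len(values)} numeric fields"
            )
        if block == "percentages":
            if len(values) < 40:
                raise PSSMParseError(
                    f"line {lineno}: file has no percentages block"
                )
            row = values[20:40]
        else:
            row = values[:20]
        rows.append(row)
        residues.append(tokens[1].upper())
        expected_index += 1

    if not rows:
        raise PSSMParseError("profile contains no score rows")

    native = np.array(rows, dtype=float)
    canonical = native[:, _NATIVE_TO_CANONICAL]
    return PSSMProfile(
        sequence_id=sequence_id, scores=canonical, residues="".join(residues)
    )


def write_ascii_pssm(profile: PSSMProfile) -> str:
    """Serialize a profile in the PSI-BLAST ASCII dialect.

    The log-odds block carries the profile values (printed with full float
    precision so write→parse round-trips exactly); the percentages block and
    the two trailing per-row statistics are filled with zeros.
    """
    out = io.StringIO()
    out.write(
        "\nLast position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapless real matches to pseudocounts\n"
    )
    letters = "  ".join(PSIBLAST_COLUMN_ORDER)
    out.write(f"            {letters}   {letters}\n")
    native = profile.scores[:, _CANONICAL_TO_NATIVE]
    for i in range(profile.L):
        cells = " ".join(repr(float(v)) for v in native[i])
        zeros = " ".join("0" for _ in range(20))
        out.write(f"{i + 1:5d} {profile.residues[i]}  {cells}  {zeros}  0.00 0.00\n")
    out.write("\n")
    return out.getvalue()


def read_fasta(text: str) -> list[ProteinSequence]:
    """Read FASTA content into :class:`ProteinSequence` records.

    IDs are the first whitespace-separated header token; residues are
    uppercased. Empty records and duplicate IDs are errors.
    """
    records = list(SeqIO.parse(io.StringIO(text), "fasta"))
    seqs = []
    for rec in records:
        if len(rec.seq) == 0:
            raise ValueError(f"FASTA record {rec.id!r} has an empty sequence")
        seqs.append(ProteinSequence(id=rec.id, residues=str(rec.seq)))
    seen: dict[str, int] = {}
    for s in seqs:
        seen[s.id] = seen.get(s.id, 0) + 1
    dups = sorted(k for k, v in seen.items() if v > 1)
    if dups:
        raise ValueError(f"duplicate FASTA IDs: {dups}")
    return seqs


def load_dataset(features_path, labels_path) -> MultiLabelDataset:
    """Join a features CSV and a labels CSV on their ID column.

    Both files are comma-delimited with a header row; the first column is the
    sample ID. Rows are returned in features-file order; the labels file may
    be in any order. Label cells must be 0/1. Samples whose label row is all
    zero are kept with a warning — prediction-mode inputs may be unannotated.
    """
    feats = pd.read_csv(features_path)
    labs = pd.read_csv(labels_path)
    fid = feats.columns[0]
    lid = labs.columns[0]
    feat_ids = feats[fid].astype(str).tolist()
    lab_ids = labs[lid].astype(str).tolist()
    missing = sorted(set(feat_ids) - set(lab_ids))
    extra = sorted(set(lab_ids) - set(feat_ids))
    if missing or extra:
        raise ValueError(
            f"ID mismatch between features and labels: missing from labels "
            f"{missing}, extra in labels {extra}"
        )
    if len(set(feat_ids)) != len(feat_ids):
        raise ValueError("duplicate IDs in features file")
    labs = labs.set_index(lid).loc[feat_ids]
    Y = labs.to_numpy()
    if not np.isin(Y, (0, 1)).all():
        bad = sorted(set(Y.ravel()) - {0, 1})
        raise ValueError(f"labels must be binary; found values {bad}")
    empty = int((Y.sum(axis=1) == 0).sum())
    if empty:
        warnings.warn(
            f"{empty} sample(s) have no labels; kept (prediction-mode input)",
            stacklevel=2,
        )
    X = feats.drop(columns=[fid]).to_numpy(dtype=float)
    return MultiLabelDataset(
        ids=feat_ids,
        X=X,
        Y=Y.astype(int),
        feature_names=[str(c) for c in feats.columns[1:]],
        label_names=[str(c) for c in labs.columns],
    )
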