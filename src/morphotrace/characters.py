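"""Discrete morphological character matrices and associated tables.

Cells take states 0-3, ``?`` (missing / unknown) or ``-`` (inapplicable).
Missing and inapplicable cells are coded apart in the data model so that
coding decisions stay auditable, but every analysis in this package treats
them identically (as no constraint on the tip).

Also houses readers/validators for the small tabular inputs: character
metadata (name, sexual vs non-reproductive class, copulatory-group tags),
continuous trait tables, and species occurrence records.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "INAPPLICABLE",
    "MatrixError",
    "CharacterMatrix",
    "CharacterMeta",
    "read_matrix",
    "read_character_meta",
    "read_traits",
    "read_occurrences",
    "validate_occurrences",
]

MISSING = -1
INAPPLICABLE = -2

_SYMBOL_TO_CODE = {"0": 0, "1": 1, "2": 2, "3": 3, "?": MISSING,
                   "-": INAPPLICABLE, "–": INAPPLICABLE}
_CODE_TO_SYMBOL = {0: "0", 1: "1", 2: "2", 3: "3", MISSING: "?",
                   INAPPLICABLE: "-"}


class MatrixError(ValueError):
    pass


class CharacterMatrix:
    """Rectangular taxa x characters matrix of unordered discrete states.

    Characters are addressed 1-based throughout, matching the usual
    presentation of morphological matrices.
    """

    def __init__(self, taxa: Sequence[str], data: np.ndarray):
        data = np.asarray(data, dtype=np.int8)
        if data.ndim != 2:
            raise MatrixError("matrix data must be 2-dimensional")
        if len(taxa) != data.shape[0]:
            raise MatrixError(
                f"{len(taxa)} taxa but {data.shape[0]} matrix rows")
        if len(set(taxa)) != len(taxa):
            raise MatrixError("duplicate taxon labels in matrix")
        bad = ~np.isin(data, list(_CODE_TO_SYMBOL))
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise MatrixError(
                f"invalid state code {int(data[i, j])} for taxon "
                f"{taxa[i]!r}, character {j + 1}")
        self.taxa = list(taxa)
        self.data = data
        self._row = {t: i for i, t in enumerate(self.taxa)}

    # -- shape -------------------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return self.data.shape[0]

    @property
    def n_characters(self) -> int:
        return self.data.shape[1]

    def _check_char(self, char: int) -> None:
        if not 1 <= char <= self.n_characters:
            raise IndexError(
                f"character index {char} out of range 1..{self.n_characters}")

    # -- access ------------------------------------------------------------

    def state(self, taxon: str, char: int) -> int:
        self._check_char(char)
        if taxon not in self._row:
            raise KeyError(f"taxon {taxon!r} not in matrix")
        return int(self.data[self._row[taxon], char - 1])

    def column(self, char: int) -> dict[str, int]:
        self._check_char(char)
        col = self.data[:, char - 1]
        return {t: int(col[i]) for i, t in enumerate(self.taxa)}

    def observed_states(self, char: int,
                        taxa: Optional[Iterable[str]] = None) -> set[int]:
        """Distinct observed (non-missing, non-inapplicable) states."""
        col = self.column(char)
        if taxa is not None:
            col = {t: col[t] for t in taxa}
        return {s for s in col.values() if s >= 0}

    def is_binary(self, char: int) -> bool:
        """True when no observed state exceeds 1 anywhere in the matrix."""
        return self.observed_states(char) <= {0, 1}

    def subset_taxa(self, taxa: Sequence[str]) -> "CharacterMatrix":
        rows = [self._row[t] for t in taxa]
        return CharacterMatrix(list(taxa), self.data[rows, :])

    # -- serialisation -----------------------------------------------------

    @classmethod
    def from_csv(cls, source: Union[str, Path, io.TextIOBase]) -> "CharacterMatrix":
        df = pd.read_csv(source, header=None, dtype=str, keep_default_na=False)
        taxa = df.iloc[:, 0].tolist()
        cells = df.iloc[:, 1:]
        widths = cells.apply(lambda r: r.notna().sum(), axis=1)
        data = np.empty((len(taxa), cells.shape[1]), dtype=np.int8)
        for i, taxon in enumerate(taxa):
            for j in range(cells.shape[1]):
                sym = str(cells.iat[i, j]).strip()
                if sym not in _SYMBOL_TO_CODE:
                    raise MatrixError(
                        f"unknown symbol {sym!r} for taxon {taxon!r}, "
                        f"character {j + 1}")
                data[i, j] = _SYMBOL_TO_CODE[sym]
        return cls(taxa, data)

    @classmethod
    def from_nexus(cls, source: Union[str, Path, io.TextIOBase]) -> "CharacterMatrix":
        import dendropy
        if isinstance(source, (str, Path)):
            text = Path(source).read_text()
        else:
            text = source.read()
        try:
            dmat = dendropy.StandardCharacterMatrix.get(
                data=text, schema="nexus", preserve_underscores=True)
        except Exception as exc:
            raise MatrixError(f"cannot read NEXUS characters block: {exc}") from exc
        taxa = [t.label for t in dmat.taxon_namespace]
        ncol = max(len(dmat[t]) for t in dmat.taxon_namespace)
        data = np.empty((len(taxa), ncol), dtype=np.int8)
        for i, taxon in enumerate(dmat.taxon_namespace):
            seq = dmat[taxon]
            if len(seq) != ncol:
                raise MatrixError(
                    f"ragged row for taxon {taxon.label!r}: "
                    f"{len(seq)} of {ncol} characters")
            for j, cell in enumerate(seq):
                sym = str(cell.symbol)
                if sym not in _SYMBOL_TO_CODE:
                    raise MatrixError(
                        f"unknown symbol {sym!r} for taxon {taxon.label!r}, "
                        f"character {j + 1}")
                data[i, j] = _SYMBOL_TO_CODE[sym]
        return cls(taxa, data)

    def to_csv(self) -> str:
        lines = []
        for i, taxon in enumerate(self.taxa):
            syms = [_CODE_TO_SYMBOL[int(s)] for s in self.data[i]]
            lines.append(",".join([taxon] + syms))
        return "\n".join(lines) + "\n"

    def to_nexus(self) -> str:
        body = []
        width = max(len(t) for t in self.taxa) + 2
        for i, taxon in enumerate(self.taxa):
            syms = "".join(_CODE_TO_SYMBOL[int(s)] for s in self.data[i])
            body.append(f"    {taxon:<{width}}{syms}")
        return (
            "#NEXUS\n\nBEGIN DATA;\n"
            f"  DIMENSIONS NTAX={self.n_taxa} NCHAR={self.n_characters};\n"
            "  FORMAT DATATYPE=STANDARD SYMBOLS=\"0123\" MISSING=? GAP=-;\n"
            "  MATRIX\n" + "\n".join(body) + "\n  ;\nEND;\n")


def read_matrix(path: Union[str, Path], format: str = "csv"):
    """Read a character matrix from ``csv`` or ``nexus``."""
    if format == "csv":
        return CharacterMatrix.from_csv(path)
    if format == "nexus":
        return CharacterMatrix.from_nexus(path)
    raise ValueError(f"unknown matrix format {format!r}")


# -- character metadata -----------------------------------------------------

VALID_CLASSES = {"sexual", "non-reproductive"}
VALID_GROUPS = {"AG", "RG", "CG", "PG", "GG"}


@dataclass
class CharacterMeta:
    """Per-character annotations: name, sexual vs non-reproductive class and
    copulatory-group tags."""

    table: pd.DataFrame

    def __post_init__(self):
        required = {"char", "name", "char_class"}
        if not required <= set(self.table.columns):
            raise MatrixError(
                f"character metadata must have columns {sorted(required)}")
        bad = set(self.table["char_class"]) - VALID_CLASSES
        if bad:
            raise MatrixError(f"invalid character classes {sorted(bad)}")
        self.table = self.table.set_index("char", drop=False)

    def __len__(self) -> int:
        return len(self.table)

    def name(self, char: int) -> str:
        return str(self.table.loc[char, "name"])

    def char_class(self, char: int) -> str:
        return str(self.table.loc[char, "char_class"])

    def is_sexual(self, char: int) -> bool:
        return self.char_class(char) == "sexual"

    @property
    def sexual_characters(self) -> list[int]:
        return [int(c) for c in self.table.index
                if self.table.loc[c, "char_class"] == "sexual"]

    def groups(self, char: int) -> set[str]:
        raw = self.table.loc[char].get("groups", "")
        if not isinstance(raw, str) or not raw:
            return set()
        tags = {t.strip() for t in raw.split(";") if t.strip()}
        bad = tags - VALID_GROUPS
        if bad:
            raise MatrixError(f"invalid group tags {sorted(bad)} for "
                              f"character {char}")
        return tags

    def validate_against(self, matrix: CharacterMatrix) -> None:
        want = set(range(1, matrix.n_characters + 1))
        have = {int(c) for c in self.table.index}
        if want != have:
            raise MatrixError(
                f"metadata covers characters {sorted(have)} but matrix has "
                f"{matrix.n_characters} characters")


def read_character_meta(path: Union[str, Path, io.TextIOBase]) -> CharacterMeta:
    df = pd.read_csv(path, dtype={"char": int}, keep_default_na=False)
    return CharacterMeta(df)


# -- trait tables -----------------------------------------------------------

TRAIT_COLUMNS = ["species", "max_copulatory_organs", "complexity",
                 "max_body_length", "max_segments", "region"]
VALID_REGIONS = {"Western Atlantic", "Eastern Atlantic", "Indo-Pacific"}


def read_traits(path: Union[str, Path, io.TextIOBase]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRAIT_COLUMNS) - set(df.columns)
    if missing:
        raise MatrixError(f"trait table missing columns {sorted(missing)}")
    bad = set(df["region"]) - VALID_REGIONS
    if bad:
        raise MatrixError(f"invalid regions {sorted(bad)}")
    for col in ("max_copulatory_organs", "complexity", "max_segments"):
        vals = df[col]
        if (vals < 0).any() or (vals != vals.astype(int)).any():
            raise MatrixError(f"column {col!r} must hold non-negative integers")
    return df.set_index("species", drop=False)


# -- occurrences ------------------------------------------------------------

def validate_occurrences(df: pd.DataFrame) -> pd.DataFrame:
    missing = {"species", "lat", "lon"} - set(df.columns)
    if missing:
        raise MatrixError(f"occurrence table missing columns {sorted(missing)}")
    if df["species"].isna().any() or (df["species"].astype(str) == "").any():
        raise MatrixError("occurrence records with empty species label")
    if ((df["lat"] < -90) | (df["lat"] > 90)).any():
        raise MatrixError("latitude outside [-90, 90]")
    if ((df["lon"] < -180) | (df["lon"] > 180)).any():
        raise MatrixError("longitude outside [-180, 180]")
    return df


def read_occurrences(path: Union[str, Path, io.TextIOBase]) -> pd.DataFrame:
    return validate_occurrences(pd.read_csv(path))
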