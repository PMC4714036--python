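"""Discrete morphological character matrices.

The analysis's sole empirical input is a taxa x characters table of
unordered discrete states (small non-negative integers) with missing
cells.  Matrices are read from NEXUS (DATA/CHARACTERS block) or plain TSV
and validated on construction.  The coding convention follows standard
cladistic practice: state 0 is the supposed plesiomorphic state, "?" (and
the inapplicable "-", treated identically) marks missing data, and all
characters are unordered.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for a missing / inapplicable cell in the integer grid.
MISSING: int = -1


class MatrixParseError(ValueError):
    """Raised when a matrix source violates the expected dialect."""


class MatrixValidationError(ValueError):
    """Raised when cell values or labels violate matrix invariants."""


@dataclass(frozen=True)
class CharacterMeta:
    """Per-character metadata: the observed states and ordering flag."""

    observed_states: tuple[int, ...]
    unordered: bool = True

    @property
    def n_states(self) -> int:
        return len(self.observed_states)


@dataclass(frozen=True)
class MatrixSummary:
    """Composition counts for a matrix (all recomputable from the cells)."""

    n_taxa: int
    n_char: int
    n_binary: int
    n_multistate: int
    n_invariant: int
    n_uninformative: int
    missing_fraction_per_taxon: dict[str, float]
    missing_fraction_per_char: dict[int, float]


class CharacterMatrix:
    """A validated taxa x characters grid of unordered discrete states.

    Parameters
    ----------
    taxa:
        Ordered unique taxon labels (rows).
    data:
        Integer array of shape ``(n_taxa, n_char)``; missing cells are
        :data:`MISSING`.
    outgroup_taxa:
        Subset of ``taxa`` designated as outgroups (used for rooting and
        character polarisation downstream).
    """

    def __init__(self, taxa, data, outgroup_taxa=()):
        taxa = list(taxa)
        data = np.asarray(data, dtype=np.int8)
        if data.ndim != 2:
            raise MatrixValidationError("data must be a 2-D taxa x characters array")
        if len(taxa) != data.shape[0]:
            raise MatrixValidationError(
                f"{len(taxa)} taxon labels for {data.shape[0]} rows"
            )
        if len(set(taxa)) != len(taxa):
            dupes = sorted({t for t in taxa if taxa.count(t) > 1})
            raise MatrixValidationError(f"duplicate taxon labels: {dupes}")
        if data.shape[0] < 4 or data.shape[1] < 1:
            raise MatrixValidationError(
                "need at least 4 taxa and 1 character for any downstream analysis"
            )
        if ((data < 0) & (data != MISSING)).any():
            raise MatrixValidationError("negative state code that is not MISSING")
        unknown = set(outgroup_taxa) - set(taxa)
        if unknown:
            raise MatrixValidationError(f"outgroup taxa not in matrix: {sorted(unknown)}")
        self.taxa: list[str] = taxa
        self.data: np.ndarray = data
        self.data.setflags(write=False)
        self.outgroup_taxa: tuple[str, ...] = tuple(outgroup_taxa)
        self.char_meta: list[CharacterMeta] = [
            CharacterMeta(observed_states=tuple(self._observed(c)))
            for c in range(self.n_char)
        ]

    # -- basic accessors -------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return self.data.shape[0]

    @property
    def n_char(self) -> int:
        return self.data.shape[1]

    @property
    def ingroup_taxa(self) -> list[str]:
        og = set(self.outgroup_taxa)
        return [t for t in self.taxa if t not in og]

    def taxon_index(self, label: str) -> int:
        return self.taxa.index(label)

    def cell(self, taxon: str, char: int) -> int:
        """State code (or :data:`MISSING`) for ``taxon`` at character ``char``."""
        return int(self.data[self.taxon_index(taxon), char])

    def _observed(self, char: int) -> list[int]:
        col = self.data[:, char]
        return sorted(int(s) for s in np.unique(col[col != MISSING]))

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, CharacterMatrix)
            and self.taxa == other.taxa
            and np.array_equal(self.data, other.data)
        )

    def __repr__(self) -> str:
        return f"CharacterMatrix({self.n_taxa} taxa x {self.n_char} characters)"

    # -- summaries -------------------------------------------------------

    def summarize(self) -> MatrixSummary:
        n_binary = n_multi = n_invariant = n_uninform = 0
        for c, meta in enumerate(self.char_meta):
            k = meta.n_states
            if k <= 1:
                n_invariant += 1
            elif k == 2:
                n_binary += 1
            else:
                n_multi += 1
            col = self.data[:, c]
            scored = col[col != MISSING]
            # parsimony-informative: at least two states each in >= 2 taxa
            counts = np.bincount(scored) if scored.size else np.array([])
            if (counts >= 2).sum() < 2:
                n_uninform += 1
        miss = self.data == MISSING
        return MatrixSummary(
            n_taxa=self.n_taxa,
            n_char=self.n_char,
            n_binary=n_binary,
            n_multistate=n_multi,
            n_invariant=n_invariant,
            n_uninformative=n_uninform,
            missing_fraction_per_taxon={
                t: float(miss[i].mean()) for i, t in enumerate(self.taxa)
            },
            missing_fraction_per_char={
                c: float(miss[:, c].mean()) for c in range(self.n_char)
            },
        )


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------


def read_matrix(source, format: str = "nexus", outgroup_taxa=()) -> CharacterMatrix:
    """Read a character matrix from a NEXUS or TSV source.

    ``source`` may be a path, a string of file content, or an open text
    stream.  State symbols are single characters ``0``..``9`` mapped to
    integers by symbol value; ``?`` and ``-`` both map to missing.
    Polymorphic codings such as ``(01)`` are rejected outright rather than
    silently collapsed.
    """
    text = _slurp(source)
    if format == "nexus":
        return _read_nexus(text, outgroup_taxa)
    if format == "tsv":
        return _read_tsv(text, outgroup_taxa)
    raise ValueError(f"unknown matrix format: {format!r}")


def _slurp(source) -> str:
    if hasattr(source, "read"):
        return source.read()
    s = str(source)
    if "\n" not in s and len(s) < 4096:
        try:
            with open(s, "r") as fh:
                return fh.read()
        except (OSError, ValueError):
            pass
    return s


_MATRIX_BLOCK_RE = re.compile(r"\bMATRIX\b(.*?);", re.IGNORECASE | re.DOTALL)


def _read_nexus(text: str, outgroup_taxa) -> CharacterMatrix:
    import dendropy

    # pre-scan the MATRIX block so duplicate labels get a named error
    # (dendropy would otherwise overwrite or concatenate rows)
    block = _MATRIX_BLOCK_RE.search(text)
    if block:
        seen: set[str] = set()
        for line in block.group(1).splitlines():
            line = line.strip()
            if not line or line.startswith("["):
                continue
            label = line.split()[0].strip("'\"")
            if label in seen:
                raise MatrixParseError(f"duplicate taxon label: {label!r}")
            seen.add(label)
    if "(" in (block.group(1) if block else text):
        raise MatrixParseError(
            "polymorphic codings like (01) are not supported; recode or split the cell"
        )
    try:
        dmat = dendropy.StandardCharacterMatrix.get(data=text, schema="nexus")
    except Exception as exc:  # dendropy raises several error classes
        raise MatrixParseError(f"NEXUS parse failure: {exc}") from exc
    taxa, rows = [], []
    n_char = None
    for taxon in dmat:
        seq = dmat[taxon]
        row = []
        for cell in seq:
            sym = cell.symbol
            if sym is None or cell.state_denomination != 0:
                if sym in ("?", "-"):
                    row.append(MISSING)
                    continue
                raise MatrixParseError(
                    f"unsupported (polymorphic/unknown) cell for taxon {taxon.label!r}"
                )
            if sym in ("?", "-"):
                row.append(MISSING)
            elif sym.isdigit():
                row.append(int(sym))
            else:
                raise MatrixParseError(
                    f"state symbol {sym!r} is not a digit (character "
                    f"{len(row) + 1}, taxon {taxon.label!r})"
                )
        if n_char is None:
            n_char = len(row)
        elif len(row) != n_char:
            raise MatrixParseError(
                f"ragged row for taxon {taxon.label!r}: {len(row)} cells, expected {n_char}"
            )
        taxa.append(taxon.label)
        rows.append(row)
    try:
        return CharacterMatrix(taxa, np.array(rows, dtype=np.int8), outgroup_taxa)
    except MatrixValidationError as exc:
        raise MatrixParseError(str(exc)) from exc


def _read_tsv(text: str, outgroup_taxa) -> CharacterMatrix:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise MatrixParseError("empty TSV source")
    header = lines[0].split("\t")
    n_char = len(header) - 1
    taxa, rows = [], []
    for i, ln in enumerate(lines[1:], start=1):
        fields = ln.split("\t")
        label = fields[0]
        if len(fields) - 1 != n_char:
            raise MatrixParseError(
                f"row {i} (taxon {label!r}) has {len(fields) - 1} cells, expected {n_char}"
            )
        row = []
        for c, tok in enumerate(fields[1:]):
            tok = tok.strip()
            if tok in ("?", "-", ""):
                row.append(MISSING)
            elif tok.lstrip("-").isdigit() and int(tok) >= 0:
                row.append(int(tok))
            else:
                raise MatrixParseError(
                    f"undeclared state symbol {tok!r} at character {c + 1}, taxon {label!r}"
                )
        if label in taxa:
            raise MatrixParseError(f"duplicate taxon label: {label!r}")
        taxa.append(label)
        rows.append(row)
    try:
        return CharacterMatrix(taxa, np.array(rows, dtype=np.int8), outgroup_taxa)
    except MatrixValidationError as exc:
        raise MatrixParseError(str(exc)) from exc


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------


def write_nexus(matrix: CharacterMatrix) -> str:
    """Serialize to a NEXUS DATA block; round-trips cell-for-cell."""
    max_state = int(max((s for m in matrix.char_meta for s in m.observed_states), default=0))
    symbols = "".join(str(s) for s in range(max_state + 1))
    width = max(len(t) for t in matrix.taxa) + 2
    out = io.StringIO()
    out.write("#NEXUS\n\nBEGIN DATA;\n")
    out.write(f"  DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_char};\n")
    out.write(f'  FORMAT DATATYPE=STANDARD MISSING=? GAP=- SYMBOLS="{symbols}";\n')
    out.write("  MATRIX\n")
    for i, t in enumerate(matrix.taxa):
        label = t.replace(" ", "_")
        cells = "".join(
            "?" if s == MISSING else str(int(s)) for s in matrix.data[i]
        )
        out.write(f"    {label:<{width}}{cells}\n")
    out.write("  ;\nEND;\n")
    return out.getvalue()


def write_tsv(matrix: CharacterMatrix) -> str:
    """Serialize to TSV: header of 1-based character ids, one row per taxon."""
    df = pd.DataFrame(
        matrix.data,
        index=matrix.taxa,
        columns=[str(c + 1) for c in range(matrix.n_char)],
    ).astype(object)
    df[df == MISSING] = "?"
    return df.to_csv(sep="\t", index_label="taxon")
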