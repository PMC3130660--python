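"""Reading, writing and validation of labelled phylogenetic distance matrices.

The on-disk format is the PHYLIP *square* distance-matrix dialect as
emitted by ``protdist`` and friends: an integer count line followed by one
row per protein, each row being a label and ``count`` distances.  Rows may
wrap across physical lines.  Both the strict fixed-width and the relaxed
whitespace-delimited variants parse here; output is always written in the
relaxed form.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, TextIO, Union

import numpy as np

__all__ = [
    "DistanceMatrix",
    "MatrixParseError",
    "MatrixValidationError",
    "SpeciesMapError",
    "read_phylip_square",
    "write_phylip_square",
    "read_species_map",
    "extract_species",
]

#: Maximum |v_ij - v_ji| accepted on read before the matrix is rejected.
#: Within this band the matrix is symmetrized by averaging.  Text round-off
#: in program output motivates the non-zero tolerance.
SYMMETRY_TOL = 1e-6

Source = Union[str, Path, TextIO]


class MatrixParseError(ValueError):
    """Malformed PHYLIP square input (count/row mismatch, bad token...)."""


class MatrixValidationError(ValueError):
    """Structurally parseable input that violates a matrix invariant."""


class SpeciesMapError(KeyError):
    """A protein label could not be assigned a species tag."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return self.args[0] if self.args else ""


@dataclass
class DistanceMatrix:
    """A labelled, symmetric, nonnegative matrix of phylogenetic distances.

    Parameters
    ----------
    labels
        Ordered protein identifiers, one per row.
    values
        Square array of pairwise distances (substitutions/site).
    species
        Optional per-protein species tag, aligned with ``labels``.  When
        absent, downstream code treats every protein as pairable with any
        other.

    Notes
    -----
    Distances of exactly ``0.0`` between *distinct* proteins are legal
    (identical sequences) and are handled downstream by edge omission,
    never rejected here.
    """

    labels: list[str]
    values: np.ndarray
    species: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise MatrixValidationError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        if n and not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise MatrixValidationError("nonzero diagonal entry")
        if n and not np.allclose(self.values, self.values.T, atol=1e-9, rtol=0.0):
            raise MatrixValidationError("matrix is not symmetric")
        if n and float(self.values.min(initial=0.0)) < 0.0:
            raise MatrixValidationError("negative distance")
        if self.species is not None and len(self.species) != n:
            raise MatrixValidationError(
                f"{len(self.species)} species tags for {n} labels"
            )

    @property
    def n(self) -> int:
        return len(self.labels)

    def distance(self, i: int, j: int) -> float:
        return float(self.values[i, j])

    def with_species(self, species: Sequence[str]) -> "DistanceMatrix":
        """Return a copy carrying the given species tags."""
        return DistanceMatrix(list(self.labels), self.values.copy(), list(species))


def _as_text(source: Source) -> str:
    if isinstance(source, Path):
        return source.read_text()
    if isinstance(source, str):
        if source and "\n" not in source and Path(source).is_file():
            return Path(source).read_text()
        return source
    return source.read()


def read_phylip_square(source: Source, species: Optional[Sequence[str]] = None) -> DistanceMatrix:
    """Parse a PHYLIP square distance matrix.

    ``source`` may be a path, an open text stream, or the raw text itself.
    Rows wrapped across physical lines are supported; tokens are
    whitespace-delimited (relaxed dialect, which also accepts strict
    fixed-width output whose labels contain no spaces).

    Raises
    ------
    MatrixParseError
        On count/row mismatches or unparseable tokens, naming the
        offending line.
    MatrixValidationError
        On asymmetry beyond :data:`SYMMETRY_TOL`, negative distances, or a
        nonzero diagonal.
    """
    text = _as_text(source)
    # token stream with source line numbers for error reporting
    toks: list[tuple[str, int]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        for tok in line.split():
            toks.append((tok, lineno))
    if not toks:
        raise MatrixParseError("empty input")

    head, head_line = toks[0]
    try:
        n = int(head)
    except ValueError:
        raise MatrixParseError(
            f"line {head_line}: expected taxon count, got {head!r}"
        ) from None
    if n < 0:
        raise MatrixParseError(f"line {head_line}: negative taxon count {n}")

    pos = 1
    labels: list[str] = []
    values = np.zeros((n, n), dtype=float)
    for row in range(n):
        if pos >= len(toks):
            raise MatrixParseError(
                f"line {toks[-1][1]}: expected {n} rows, input ended after {row}"
            )
        label, _ = toks[pos]
        pos += 1
        labels.append(label)
        for col in range(n):
            if pos >= len(toks):
                raise MatrixParseError(
                    f"line {toks[-1][1]}: row {label!r} has {col} of {n} distances"
                )
            tok, tok_line = toks[pos]
            pos += 1
            try:
                values[row, col] = float(tok)
            except ValueError:
                raise MatrixParseError(
                    f"line {tok_line}: bad distance {tok!r} in row {label!r}"
                ) from None
    if pos != len(toks):
        raise MatrixParseError(
            f"line {toks[pos][1]}: trailing data after {n} rows"
        )

    if n:
        asym = np.abs(values - values.T)
        if float(asym.max()) > SYMMETRY_TOL:
            i, j = np.unravel_index(int(asym.argmax()), asym.shape)
            raise MatrixValidationError(
                f"asymmetry {values[i, j]!r} vs {values[j, i]!r} "
                f"at ({labels[i]}, {labels[j]}) exceeds {SYMMETRY_TOL}"
            )
        if float(values.min()) < 0.0:
            raise MatrixValidationError("negative distance in matrix")
        values = (values + values.T) / 2.0
        np.fill_diagonal(values, 0.0)

    return DistanceMatrix(labels, values, list(species) if species else None)


def write_phylip_square(mat: DistanceMatrix, dest: Union[str, Path, TextIO]) -> None:
    """Write ``mat`` in relaxed PHYLIP square format (full precision)."""
    buf = io.StringIO()
    buf.write(f"{mat.n}\n")
    for i, label in enumerate(mat.labels):
        row = " ".join(format(v, ".17g") for v in mat.values[i])
        buf.write(f"{label} {row}\n")
    text = buf.getvalue()
    if isinstance(dest, (str, Path)):
        Path(dest).write_text(text)
    else:
        dest.write(text)


def read_species_map(source: Source) -> dict[str, str]:
    """Read a two-column TSV mapping ``protein_id <TAB> species``."""
    text = _as_text(source)
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2 or not parts[0] or not parts[1]:
            raise SpeciesMapError(f"line {lineno}: expected 'protein<TAB>species'")
        mapping[parts[0]] = parts[1]
    return mapping


def extract_species(
    labels: Sequence[str],
    *,
    delimiter: Optional[str] = None,
    index: int = 0,
    mapping: Optional[Mapping[str, str]] = None,
) -> list[str]:
    """Assign one species tag to every protein label.

    Exactly one rule applies: either split each label on ``delimiter`` and
    take the token at ``index``, or look each label up in ``mapping``.

    Raises
    ------
    SpeciesMapError
        If a label is missing from ``mapping``, yields an empty species
        token, or no rule was given.
    """
    if (delimiter is None) == (mapping is None):
        raise SpeciesMapError("exactly one of delimiter or mapping must be given")
    out: list[str] = []
    for label in labels:
        if mapping is not None:
            if label not in mapping:
                raise SpeciesMapError(f"no species mapping for protein {label!r}")
            tag = mapping[label]
        else:
            parts = label.split(delimiter)
            if index >= len(parts):
                raise SpeciesMapError(
                    f"label {label!r} has no field {index} under delimiter {delimiter!r}"
                )
            tag = parts[index]
        if not tag:
            raise SpeciesMapError(f"empty species token for protein {label!r}")
        out.append(tag)
    return out
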