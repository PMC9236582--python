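"""Alignment I/O, undetermined-column removal, pattern compression and partitions.

Site indices are 0-based everywhere inside the package; user-facing files and
reports (partition definitions, site-weight tables, serialized samples) use
1-based indices with inclusive ranges, following the conventions of the common
phylogenetics file formats.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

import numpy as np
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentFormatError, ValidationError

DNA_STATES = "ACGT"
AA_STATES = "ARNDCQEGHILKMFPSTWYV"

# IUPAC nucleotide ambiguity codes -> compatible state sets.
DNA_AMBIGUITY = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT", "X": "ACGT", "-": "ACGT", "?": "ACGT", ".": "ACGT",
}

# Amino-acid codes; B/Z/J are the standard two-state ambiguities, U/O are mapped
# to their closest canonical residues (selenocysteine -> C, pyrrolysine -> K).
AA_AMBIGUITY = {ch: ch for ch in AA_STATES}
AA_AMBIGUITY.update({
    "B": "ND", "Z": "QE", "J": "IL", "U": "C", "O": "K",
    "X": AA_STATES, "-": AA_STATES, "?": AA_STATES, "*": AA_STATES, ".": AA_STATES,
})

_DNAISH = set("ACGTUNRYSWKMBDHVX-?.")


def states_for(alphabet: str) -> str:
    if alphabet == "dna":
        return DNA_STATES
    if alphabet == "aa":
        return AA_STATES
    raise ValidationError(f"unknown alphabet {alphabet!r}")


def ambiguity_map(alphabet: str) -> dict:
    return DNA_AMBIGUITY if alphabet == "dna" else AA_AMBIGUITY


class Alignment:
    """A taxa x sites character matrix.

    Parameters
    ----------
    taxa : list of str
        Unique sequence names, in file order.
    matrix : ndarray of shape (n_taxa, n_sites), dtype ``<U1``
        Upper-case character codes.
    alphabet : {"dna", "aa"}
    partition_map : ndarray of int, optional
        Per-site partition id (0-based), or None for unpartitioned data.
    """

    def __init__(self, taxa, matrix, alphabet, partition_map=None):
        taxa = list(taxa)
        matrix = np.asarray(matrix, dtype="<U1")
        if matrix.ndim != 2:
            raise ValidationError("alignment matrix must be 2-dimensional")
        if len(taxa) != matrix.shape[0]:
            raise ValidationError("taxa list does not match matrix rows")
        if len(set(taxa)) != len(taxa):
            dupes = sorted({t for t in taxa if taxa.count(t) > 1})
            raise ValidationError(f"duplicate taxon names: {dupes}")
        if matrix.shape[1] < 1:
            raise ValidationError("alignment has no sites")
        amb = ambiguity_map(alphabet)  # also validates alphabet
        bad = set(np.unique(matrix)) - set(amb)
        if bad:
            raise ValidationError(f"characters not in {alphabet} alphabet: {sorted(bad)}")
        self.taxa = taxa
        self.matrix = matrix
        self.alphabet = alphabet
        self.partition_map = None if partition_map is None else np.asarray(partition_map)
        if self.partition_map is not None and self.partition_map.shape != (matrix.shape[1],):
            raise ValidationError("partition_map length must equal the number of sites")
        self._cache = {}

    @property
    def n_taxa(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def subset_sites(self, indices) -> "Alignment":
        """New alignment restricted to the given (0-based) site indices, in order."""
        idx = np.asarray(indices, dtype=int)
        pm = None if self.partition_map is None else self.partition_map[idx]
        return Alignment(self.taxa, self.matrix[:, idx], self.alphabet, pm)

    def __eq__(self, other):
        return (
            isinstance(other, Alignment)
            and self.taxa == other.taxa
            and self.alphabet == other.alphabet
            and np.array_equal(self.matrix, other.matrix)
        )

    def __repr__(self):
        return f"Alignment(n_taxa={self.n_taxa}, n_sites={self.n_sites}, alphabet={self.alphabet!r})"


@dataclass
class PatternAlignment:
    """Unique alignment columns with multiplicities.

    ``patterns`` has shape (n_taxa, p); ``pattern_weights`` sums to the original
    number of sites; ``site_to_pattern`` maps each original column to its pattern.
    """

    patterns: np.ndarray
    pattern_weights: np.ndarray
    site_to_pattern: np.ndarray
    alphabet: str

    @property
    def n_patterns(self) -> int:
        return self.patterns.shape[1]

    def expand(self) -> np.ndarray:
        """Reconstruct the original character matrix."""
        return self.patterns[:, self.site_to_pattern]


@dataclass
class Partition:
    name: str
    model: str
    ranges: list  # list of (start, end) 1-based inclusive


@dataclass
class PartitionScheme:
    partitions: list = field(default_factory=list)

    @property
    def names(self):
        return [p.name for p in self.partitions]

    def site_indices(self, part_idx: int) -> np.ndarray:
        """0-based site indices of one partition, in ascending order."""
        out = []
        for start, end in self.partitions[part_idx].ranges:
            out.append(np.arange(start - 1, end))
        return np.concatenate(out)

    def partition_map(self, n_sites: int) -> np.ndarray:
        pm = np.full(n_sites, -1, dtype=int)
        for i in range(len(self.partitions)):
            pm[self.site_indices(i)] = i
        return pm


def detect_alphabet(matrix: np.ndarray) -> str:
    """Guess dna vs aa: call it DNA when >=90% of characters are nucleotide-ish."""
    chars = matrix.ravel()
    frac = np.isin(chars, list(_DNAISH)).mean()
    return "dna" if frac >= 0.9 else "aa"


def read_alignment(path, format: str = "fasta", alphabet: str | None = None) -> Alignment:
    """Read a FASTA or relaxed PHYLIP alignment.

    Undetermined columns are retained; use :func:`remove_undetermined_columns`.
    """
    fmt = {"fasta": "fasta", "phylip": "phylip-relaxed"}.get(format)
    if fmt is None:
        raise AlignmentFormatError(f"unsupported format {format!r}")
    try:
        msa = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        raise AlignmentFormatError(f"cannot parse {path} as {format}: {exc}") from exc
    if len(msa) == 0:
        raise AlignmentFormatError(f"{path}: no sequences")
    taxa = [rec.id for rec in msa]
    matrix = np.array([list(str(rec.seq).upper()) for rec in msa], dtype="<U1")
    if alphabet is None:
        alphabet = detect_alphabet(matrix)
    return Alignment(taxa, matrix, alphabet)


def write_alignment(aln: Alignment, path, format: str = "fasta") -> None:
    fmt = {"fasta": "fasta", "phylip": "phylip-relaxed"}.get(format)
    if fmt is None:
        raise AlignmentFormatError(f"unsupported format {format!r}")
    records = [
        SeqRecord(Seq("".join(row)), id=name, description="")
        for name, row in zip(aln.taxa, aln.matrix)
    ]
    AlignIO.write(MultipleSeqAlignment(records), str(path), fmt)


def undetermined_mask(aln: Alignment) -> np.ndarray:
    """Boolean mask of columns in which every character is a gap or fully
    ambiguous code (carries no state information for any taxon)."""
    amb = ambiguity_map(aln.alphabet)
    full = states_for(aln.alphabet)
    wild = [c for c, s in amb.items() if len(s) == len(full)]
    return np.isin(aln.matrix, wild).all(axis=0)


def remove_undetermined_columns(aln: Alignment):
    """Drop fully undetermined columns.

    Returns
    -------
    (Alignment, ndarray)
        The filtered alignment and the 0-based indices of the kept columns.
    """
    mask = undetermined_mask(aln)
    kept = np.nonzero(~mask)[0]
    if kept.size == 0:
        raise ValidationError("all columns are fully undetermined")
    if kept.size == aln.n_sites:
        return aln, kept
    return aln.subset_sites(kept), kept


def compress_patterns(aln: Alignment) -> PatternAlignment:
    """Collapse identical columns into unique patterns with multiplicities."""
    patterns, inverse, counts = np.unique(
        aln.matrix, axis=1, return_inverse=True, return_counts=True
    )
    return PatternAlignment(patterns, counts.astype(float), inverse.astype(int), aln.alphabet)


_RANGE_RE = re.compile(r"^\s*(\d+)\s*-\s*(\d+)\s*$")


def parse_partitions(path, aln: Alignment) -> PartitionScheme:
    """Parse a partition definition file.

    One partition per line, RAxML-style::

        WAG+G4, gene1 = 1-100
        WAG+G4, gene2 = 101-180, 241-260

    The leading model token (up to the first comma) is optional; ranges are
    1-based inclusive. Ranges must be disjoint and jointly cover every site.
    """
    if hasattr(path, "read"):
        lines = path.read().splitlines()
    else:
        with open(path) as fh:
            lines = fh.read().splitlines()
    scheme = PartitionScheme()
    for lineno, line in enumerate(lines, 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValidationError(f"partition line {lineno}: missing '='")
        left, right = line.split("=", 1)
        left = left.strip()
        if "," in left:
            model, name = (s.strip() for s in left.split(",", 1))
        else:
            model, name = "", left
        if not name:
            raise ValidationError(f"partition line {lineno}: empty name")
        ranges = []
        for chunk in right.split(","):
            mm = _RANGE_RE.match(chunk)
            if not mm:
                raise ValidationError(f"partition line {lineno}: bad range {chunk!r}")
            start, end = int(mm.group(1)), int(mm.group(2))
            if not (1 <= start <= end <= aln.n_sites):
                raise ValidationError(
                    f"partition line {lineno}: range {start}-{end} outside 1..{aln.n_sites}"
                )
            ranges.append((start, end))
        scheme.partitions.append(Partition(name, model, ranges))
    if not scheme.partitions:
        raise ValidationError("no partitions defined")
    covered = np.zeros(aln.n_sites, dtype=int)
    for i in range(len(scheme.partitions)):
        covered[scheme.site_indices(i)] += 1
    if (covered > 1).any():
        raise ValidationError("partitions overlap")
    if (covered == 0).any():
        holes = np.nonzero(covered == 0)[0][:5] + 1
        raise ValidationError(f"partition coverage hole at sites {holes.tolist()}...")
    return scheme
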