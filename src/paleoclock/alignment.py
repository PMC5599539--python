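"""Multi-gene nucleotide alignment handling.

Reads pre-aligned FASTA matrices, sanitizes them, trims ambiguous alignment
ends, collapses identical haplotypes, and concatenates per-gene matrices into
a single partitioned supermatrix.

Coordinates are 0-based half-open internally; anything rendered for a user
(config strings, reports) is 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Permitted characters: unambiguous bases, IUPAC ambiguity codes, gap.
UNAMBIGUOUS = frozenset("ACGT")
ALPHABET = frozenset("ACGTRYSWKMBDHVN-")


class AlignmentError(ValueError):
    """Raised for malformed or inconsistent alignment input."""


@dataclass(frozen=True)
class Alignment:
    """An aligned set of nucleotide sequences.

    Parameters
    ----------
    taxa:
        Unique sequence labels, in input order.
    seqs:
        Upper-case sequences, one per taxon, all of equal length, over the
        IUPAC nucleotide alphabet plus ``-`` and ``N``.
    """

    taxa: tuple[str, ...]
    seqs: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.seqs):
            raise AlignmentError("taxa and sequences differ in number")
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise AlignmentError(f"duplicate labels: {', '.join(dupes)}")
        if self.seqs:
            lengths = {len(s) for s in self.seqs}
            if len(lengths) > 1:
                raise AlignmentError(
                    f"unequal lengths: {sorted(lengths)}"
                )
            bad = {c for s in self.seqs for c in s} - ALPHABET
            if bad:
                raise AlignmentError(
                    f"illegal characters: {', '.join(sorted(bad))}"
                )

    @property
    def length(self) -> int:
        """Number of alignment columns."""
        return len(self.seqs[0]) if self.seqs else 0

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def row(self, label: str) -> str:
        """Sequence for one taxon."""
        try:
            return self.seqs[self.taxa.index(label)]
        except ValueError:
            raise KeyError(f"taxon not in alignment: {label}") from None

    def subset(self, labels) -> "Alignment":
        """Alignment restricted to ``labels`` (kept in the given order)."""
        return Alignment(tuple(labels), tuple(self.row(t) for t in labels))

    def columns(self, start: int, stop: int) -> "Alignment":
        """Alignment restricted to columns ``[start, stop)`` (0-based)."""
        if not (0 <= start <= stop <= self.length):
            raise AlignmentError(f"column range [{start}, {stop}) out of bounds")
        return Alignment(self.taxa, tuple(s[start:stop] for s in self.seqs))


@dataclass(frozen=True)
class PartitionScheme:
    """Ordered gene partitions of a concatenated alignment.

    ``intervals`` are 0-based half-open column ranges, contiguous and
    non-overlapping, whose union covers the concatenated length.
    """

    genes: tuple[str, ...]
    intervals: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.intervals):
            raise AlignmentError("genes and intervals differ in number")
        if len(set(self.genes)) != len(self.genes):
            raise AlignmentError("duplicate gene names in partition scheme")
        pos = 0
        for gene, (start, stop) in zip(self.genes, self.intervals):
            if start != pos or stop <= start:
                raise AlignmentError(
                    f"partition {gene!r}: interval [{start}, {stop}) not "
                    f"contiguous from column {pos}"
                )
            pos = stop

    @property
    def total_length(self) -> int:
        return self.intervals[-1][1] if self.intervals else 0

    def interval(self, gene: str) -> tuple[int, int]:
        try:
            return self.intervals[self.genes.index(gene)]
        except ValueError:
            raise KeyError(f"gene not in scheme: {gene}") from None

    def extract(self, alignment: Alignment, gene: str) -> Alignment:
        """Columns of one gene from the concatenated alignment."""
        start, stop = self.interval(gene)
        return alignment.columns(start, stop)

    def one_based(self) -> list[tuple[str, int, int]]:
        """1-based inclusive ranges for reports and config files."""
        return [(g, a + 1, b) for g, (a, b) in zip(self.genes, self.intervals)]

    def to_config_lines(self) -> list[str]:
        return [
            f'gene = "{g}", range = "{a}-{b}"' for g, a, b in self.one_based()
        ]


def read_fasta(path) -> Alignment:
    """Read an aligned FASTA file.

    Sequences are upper-cased.  Duplicate labels, unequal lengths and
    characters outside the IUPAC nucleotide alphabet are each reported as a
    distinct :class:`AlignmentError`.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    taxa = tuple(r.id for r in records)
    seqs = tuple(str(r.seq).upper() for r in records)
    return Alignment(taxa, seqs)


def write_fasta(alignment: Alignment, path) -> None:
    """Write an alignment as FASTA (one record per taxon, single-line ids)."""
    records = [
        SeqRecord(Seq(s), id=t, description="")
        for t, s in zip(alignment.taxa, alignment.seqs)
    ]
    SeqIO.write(records, str(path), "fasta")


def trim_ambiguous_ends(alignment: Alignment) -> Alignment:
    """Strip leading/trailing columns containing ambiguity codes.

    A column is ambiguous if any row holds a character that is neither an
    unambiguous base nor a gap.  Only runs of such columns at the two
    alignment ends are removed; interior columns are untouched.
    """
    if alignment.n_taxa == 0 or alignment.length == 0:
        raise AlignmentError("empty alignment")
    ok = frozenset("ACGT-")

    def clean(col: int) -> bool:
        return all(s[col] in ok for s in alignment.seqs)

    start = 0
    while start < alignment.length and not clean(start):
        start += 1
    if start == alignment.length:
        raise AlignmentError("no unambiguous core")
    stop = alignment.length
    while stop > start and not clean(stop - 1):
        stop -= 1
    return alignment.columns(start, stop)


def collapse_haplotypes(alignment: Alignment) -> tuple[Alignment, dict[str, list[str]]]:
    """Collapse identical sequences to unique haplotypes.

    Equality is exact string equality (an ``N`` never matches an ``A``).  The
    representative of each haplotype is the first-encountered taxon in input
    order.  Returns the collapsed alignment and a map
    ``representative -> [member taxa]`` (representative included).
    """
    reps: dict[str, str] = {}
    members: dict[str, list[str]] = {}
    for taxon, seq in zip(alignment.taxa, alignment.seqs):
        if seq in reps:
            members[reps[seq]].append(taxon)
        else:
            reps[seq] = taxon
            members[taxon] = [taxon]
    keep = tuple(members.keys())
    return alignment.subset(keep), members


def concatenate_partitions(
    named_alignments: list[tuple[str, Alignment]],
) -> tuple[Alignment, PartitionScheme]:
    """Concatenate per-gene alignments sharing one taxon set.

    Taxon order of the output follows the first gene; every other gene must
    contain exactly the same taxa (any order).
    """
    if not named_alignments:
        raise AlignmentError("no partitions to concatenate")
    first = named_alignments[0][1]
    taxa = first.taxa
    taxon_set = set(taxa)
    for gene, aln in named_alignments[1:]:
        if set(aln.taxa) != taxon_set:
            missing = sorted(taxon_set ^ set(aln.taxa))
            raise AlignmentError(
                f"taxon mismatch in partition {gene!r}: {', '.join(missing)}"
            )
    genes = tuple(g for g, _ in named_alignments)
    rows = {t: [] for t in taxa}
    intervals = []
    pos = 0
    for gene, aln in named_alignments:
        for t in taxa:
            rows[t].append(aln.row(t))
        intervals.append((pos, pos + aln.length))
        pos += aln.length
    concat = Alignment(taxa, tuple("".join(rows[t]) for t in taxa))
    return concat, PartitionScheme(genes, tuple(intervals))
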