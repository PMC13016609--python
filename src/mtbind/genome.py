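"""Circular-genome tiling probe design and sequence annotations.

The probe library mirrors a custom high-density binding array: the circular
genome is partitioned into overlapping fixed-width windows (default 33 nt,
shifted 2 nt per consecutive probe, wrapping across the origin), and every
window is synthesised in both orientations (the window itself and its reverse
complement), each followed by a constant primer-binding sequence.

Coordinates are 0-based half-open throughout; a probe is keyed to the genome
by the coordinate of the middle nucleotide of its variable region.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "CircularGenome",
    "Probe",
    "ProbeLibrary",
    "MotifAnnotation",
    "DEFAULT_PRIMER",
    "sanitize_genome",
    "reverse_complement",
    "tile_circular_genome",
    "annotate_gn10g",
    "dipyrimidine_density",
    "read_genome_fasta",
    "write_library_tsv",
    "read_library_tsv",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Constant primer-binding sequence appended to every variable region.
#: The physical array used a 27-nt primer whose sequence is not public; any
#: fixed 27-mer serves since the primer never enters genome-coordinate logic.
DEFAULT_PRIMER = "CGTAGCATCGGAACGTTCGATTGCGCA"


@dataclass(frozen=True)
class CircularGenome:
    """A sanitized nucleotide sequence treated as circular."""

    name: str
    sequence: str
    circular: bool = True

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __post_init__(self) -> None:
        bad = re.search(r"[^ACGT]", self.sequence)
        if bad:
            raise ValueError(
                f"genome {self.name!r} has invalid character "
                f"{self.sequence[bad.start()]!r} at position {bad.start()}"
            )


@dataclass(frozen=True)
class Probe:
    probe_id: str
    start: int
    orientation: str  # "forward" | "reverse_complement"
    variable_seq: str
    full_seq: str
    mid_coord: int


@dataclass
class ProbeLibrary:
    genome: CircularGenome
    window: int
    step: int
    probes: list[Probe]
    primer: str = DEFAULT_PRIMER
    control_seqs: list[str] = field(default_factory=list)

    @property
    def n_per_orientation(self) -> int:
        return sum(1 for p in self.probes if p.orientation == "forward")

    def forward_probes(self) -> list[Probe]:
        return [p for p in self.probes if p.orientation == "forward"]

    def reverse_probes(self) -> list[Probe]:
        return [p for p in self.probes if p.orientation == "reverse_complement"]


@dataclass(frozen=True)
class MotifAnnotation:
    probe_id: str
    has_gn10g: bool
    match_offsets: tuple[int, ...]


def sanitize_genome(raw_sequence: str, name: str = "genome",
                    circular: bool = True) -> CircularGenome:
    """Uppercase, replace every ambiguous N with a cytosine, validate.

    Characters outside {A, C, G, T, N} are rejected with their position.
    """
    if not raw_sequence:
        raise ValueError("empty genome sequence")
    seq = raw_sequence.upper()
    bad = re.search(r"[^ACGTN]", seq)
    if bad:
        raise ValueError(
            f"invalid character {seq[bad.start()]!r} at position {bad.start()}"
        )
    return CircularGenome(name=name, sequence=seq.replace("N", "C"),
                          circular=circular)


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement of an {A,C,G,T} string."""
    bad = re.search(r"[^ACGT]", seq)
    if bad:
        raise ValueError(
            f"invalid character {seq[bad.start()]!r} at position {bad.start()}"
        )
    return seq.translate(_COMPLEMENT)[::-1]


def _window_at(sequence: str, start: int, window: int) -> str:
    """Window of `sequence` starting at `start`, wrapping past the end."""
    end = start + window
    if end <= len(sequence):
        return sequence[start:end]
    return sequence[start:] + sequence[: end - len(sequence)]


def tile_circular_genome(genome: CircularGenome, window: int = 33,
                         step: int = 2,
                         primer: str = DEFAULT_PRIMER) -> ProbeLibrary:
    """Tile the genome into two-orientation probes.

    Forward probes start at offsets 0, step, 2*step, ... < L and wrap across
    the origin, giving ceil(L/step) probes per orientation on a circular
    genome.  For each forward window a reverse-complement probe is emitted at
    the same genome coordinates.  On a linear genome, windows that would run
    past the end are rejected instead of wrapped.
    """
    L = genome.length
    if not 0 < window <= L:
        raise ValueError(f"window {window} outside (0, {L}]")
    if not 0 < step <= window:
        raise ValueError(f"step {step} outside (0, {window}]")

    probes: list[Probe] = []
    for start in range(0, L, step):
        if not genome.circular and start + window > L:
            continue
        var = _window_at(genome.sequence, start, window)
        mid = (start + window // 2) % L
        probes.append(Probe(
            probe_id=f"p{start:06d}_fwd", start=start, orientation="forward",
            variable_seq=var, full_seq=var + primer, mid_coord=mid))
        rc = reverse_complement(var)
        probes.append(Probe(
            probe_id=f"p{start:06d}_rev", start=start,
            orientation="reverse_complement",
            variable_seq=rc, full_seq=rc + primer, mid_coord=mid))
    return ProbeLibrary(genome=genome, window=window, step=step,
                        probes=probes, primer=primer)


def _motif_offsets(seq: str, spacer: int = 10) -> tuple[int, ...]:
    """Start offsets of G-N{spacer}-G on either strand of `seq`.

    A match on the bottom strand reads C-N{spacer}-C on the given strand, so
    both patterns are scanned on `seq` directly; offsets are reported in the
    coordinates of `seq`.  Overlapping matches are all reported.
    """
    hits = set()
    for pat in (f"(?=G.{{{spacer}}}G)", f"(?=C.{{{spacer}}}C)"):
        hits.update(m.start() for m in re.finditer(pat, seq))
    return tuple(sorted(hits))


def annotate_gn10g(probe: Probe) -> MotifAnnotation:
    """Scan a probe's variable region for the GN(10)G motif on both strands."""
    if len(probe.variable_seq) < 12:
        raise ValueError("variable region shorter than the 12-nt motif")
    offsets = _motif_offsets(probe.variable_seq)
    return MotifAnnotation(probe_id=probe.probe_id,
                           has_gn10g=bool(offsets), match_offsets=offsets)


def dipyrimidine_density(seq: str, circular: bool = False) -> float:
    """Adjacent-pyrimidine (dipyrimidine) sites per kb of duplex.

    Counts dinucleotides that are pyrimidine-pyrimidine on EITHER strand of
    the duplex: YY (Y in {C,T}) on the given strand, plus RR (R in {A,G}),
    which reads YY on the complementary strand.  Mixed dinucleotides carry no
    dipyrimidine site.  For circular sequences the junction dinucleotide
    (last base, first base) is included.  The density is normalised by the
    duplex length in kb.
    """
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    bad = re.search(r"[^ACGT]", s)
    if bad:
        raise ValueError(
            f"invalid character {s[bad.start()]!r} at position {bad.start()}"
        )
    pairs = zip(s, s[1:])
    if circular:
        pairs = list(pairs) + [(s[-1], s[0])]
    pyr = frozenset("CT")
    pur = frozenset("AG")
    n = sum(1 for a, b in pairs
            if (a in pyr and b in pyr) or (a in pur and b in pur))
    return n / (len(s) / 1000.0)


# ---------------------------------------------------------------------------
# IO

def read_genome_fasta(path: str | Path, circular: bool = True) -> CircularGenome:
    """Read the first record of a FASTA file and sanitize it."""
    record = next(SeqIO.parse(str(path), "fasta"), None)
    if record is None:
        raise ValueError(f"no FASTA records in {path}")
    return sanitize_genome(str(record.seq), name=record.id, circular=circular)


def library_frame(library: ProbeLibrary) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "probe_id": [p.probe_id for p in library.probes],
            "start": [p.start for p in library.probes],
            "orientation": [p.orientation for p in library.probes],
            "mid_coord": [p.mid_coord for p in library.probes],
            "variable_seq": [p.variable_seq for p in library.probes],
            "full_seq": [p.full_seq for p in library.probes],
        }
    )


def write_library_tsv(library: ProbeLibrary, path: str | Path) -> None:
    library_frame(library).to_csv(path, sep="\t", index=False)


def infer_genome_length(frame: pd.DataFrame) -> int:
    """Genome length implied by a library table's start/mid coordinates.

    Probes whose middle nucleotide wrapped past the origin satisfy
    L = start + window//2 - mid_coord; without any wrapped probe the tiling
    is linear and L = max(start) + window.
    """
    window = len(frame["variable_seq"].iloc[0])
    half = window // 2
    wrapped = frame[frame["start"] + half != frame["mid_coord"]]
    if len(wrapped):
        lengths = (wrapped["start"] + half - wrapped["mid_coord"]).unique()
        if len(lengths) != 1:
            raise ValueError("inconsistent wrap coordinates in library")
        return int(lengths[0])
    return int(frame["start"].max()) + window


def read_library_tsv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    required = {"probe_id", "start", "orientation", "mid_coord",
                "variable_seq", "full_seq"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"library file missing columns: {sorted(missing)}")
    return frame
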