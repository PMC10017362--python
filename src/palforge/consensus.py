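"""Occupancy-thresholded consensus construction from an aligned protein family.

The pipeline: parse an aligned FASTA family, profile each alignment
column (occupancy = non-gap fraction; conservation = modal fraction
among non-gap symbols), call a consensus residue per column, drop
columns whose occupancy falls below a threshold (default 10%), map
alignment columns onto a reference member's ungapped numbering, and
assemble a tagged expression construct by swapping terminal regions
for affinity tags.

Coordinates are 1-based inclusive everywhere. Alignment columns and
consensus positions are distinct coordinate systems and are never mixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GAP_CHARS = frozenset("-.")
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")
AMBIGUOUS_AA = frozenset("XBZU")
ALLOWED = STANDARD_AA | AMBIGUOUS_AA | GAP_CHARS

#: Fixed residue order used to break consensus ties deterministically.
TIE_ORDER = "ARNDCQEGHILKMFPSTWYV"

DEFAULT_OCCUPANCY_THRESHOLD = 0.10


class AlignmentError(ValueError):
    """Malformed alignment input."""


@dataclass(frozen=True)
class AlignedFamily:
    """An in-memory MSA: (identifier, gapped sequence) records."""

    records: tuple[tuple[str, str], ...]
    alignment_length: int

    @property
    def n_records(self) -> int:
        return len(self.records)

    def column(self, index: int) -> str:
        """Symbols of 1-based column ``index`` across all records."""
        return "".join(seq[index - 1] for _, seq in self.records)

    def sequence(self, identifier: str) -> str:
        for rid, seq in self.records:
            if rid == identifier:
                return seq
        raise KeyError(f"record {identifier!r} not in family")


def make_family(records: list[tuple[str, str]]) -> AlignedFamily:
    """Validate and normalize records ('.'->'-', uppercase) into a family."""
    if not records:
        raise AlignmentError("empty alignment")
    norm = []
    length = len(records[0][1])
    for i, (rid, seq) in enumerate(records, start=1):
        seq = seq.upper().replace(".", "-")
        if len(seq) != length:
            raise AlignmentError(
                f"record {i} ({rid!r}) has length {len(seq)}, expected {length}"
            )
        for pos, ch in enumerate(seq, start=1):
            if ch not in ALLOWED:
                raise AlignmentError(
                    f"illegal symbol {ch!r} at column {pos} of record {rid!r}"
                )
        norm.append((rid, seq))
    return AlignedFamily(tuple(norm), length)


def parse_alignment(path: str | Path) -> AlignedFamily:
    """Read an aligned FASTA file into an :class:`AlignedFamily`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    return make_family(records)


def write_alignment(family: AlignedFamily, path: str | Path) -> None:
    recs = [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in family.records]
    SeqIO.write(recs, str(path), "fasta")


@dataclass(frozen=True)
class ColumnProfile:
    column_index: int  # 1-based
    occupancy: float
    residue_counts: dict[str, int]
    consensus_residue: str | None  # None for an all-gap column
    conservation: float


def _consensus_call(counts: dict[str, int]) -> str | None:
    """Modal residue with deterministic tie-break; ambiguous codes cannot win
    unless the column holds only ambiguous codes."""
    if not counts:
        return None
    designable = {aa: c for aa, c in counts.items() if aa in STANDARD_AA}
    pool = designable or counts
    best = max(pool.values())
    order = TIE_ORDER + "XBZU"
    for aa in order:
        if pool.get(aa) == best:
            return aa
    # unreachable for the allowed alphabet
    return sorted(pool)[0]


def compute_column_profiles(family: AlignedFamily) -> list[ColumnProfile]:
    """One profile per alignment column. Counts exclude gaps; X/B/Z/U count
    toward occupancy but are not eligible consensus residues."""
    n = family.n_records
    profiles = []
    for col in range(1, family.alignment_length + 1):
        symbols = family.column(col)
        counts: dict[str, int] = {}
        for ch in symbols:
            if ch not in GAP_CHARS:
                counts[ch] = counts.get(ch, 0) + 1
        nongap = sum(counts.values())
        occupancy = nongap / n
        consensus = _consensus_call(counts)
        conservation = (max(counts.values()) / nongap) if nongap else 0.0
        profiles.append(ColumnProfile(col, occupancy, counts, consensus, conservation))
    return profiles


@dataclass(frozen=True)
class ConsensusResult:
    profiles: tuple[ColumnProfile, ...]
    occupancy_threshold: float
    consensus_sequence: str
    kept_columns: tuple[int, ...]
    column_to_position: dict[int, int]  # kept alignment column -> 1-based consensus position

    @property
    def position_to_column(self) -> dict[int, int]:
        return {pos: col for col, pos in self.column_to_position.items()}


def build_consensus(
    profiles: list[ColumnProfile],
    threshold: float = DEFAULT_OCCUPANCY_THRESHOLD,
) -> ConsensusResult:
    """Keep columns with occupancy >= threshold; call one residue per kept column.

    The comparison is strict at the boundary: occupancy exactly equal to
    the threshold is kept, anything below is removed.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"occupancy threshold must be in (0, 1], got {threshold}")
    kept, residues = [], []
    for prof in profiles:
        if prof.occupancy >= threshold:
            kept.append(prof.column_index)
            residues.append(prof.consensus_residue or "X")
    col_to_pos = {col: i + 1 for i, col in enumerate(kept)}
    return ConsensusResult(
        tuple(profiles), threshold, "".join(residues), tuple(kept), col_to_pos
    )


@dataclass(frozen=True)
class ReferenceMap:
    """Alignment columns mapped to a reference member's ungapped numbering."""

    reference_id: str
    pairs: tuple[tuple[int, int, str], ...]  # (column, ref number, ref residue)
    consensus_to_reference: dict[int, int]
    reference_to_consensus: dict[int, int]

    def column_for_reference(self, ref_number: int) -> int | None:
        for col, num, _ in self.pairs:
            if num == ref_number:
                return col
        return None

    def reference_for_column(self, column: int) -> int | None:
        for col, num, _ in self.pairs:
            if col == column:
                return num
        return None


def map_to_reference(
    family: AlignedFamily, consensus: ConsensusResult, reference_id: str
) -> ReferenceMap:
    """Number every non-gap reference column 1..N and cross-link with the
    kept-column consensus positions. Lookups at reference-gap columns
    return an absent sentinel (None), never an error."""
    try:
        ref_seq = family.sequence(reference_id)
    except KeyError as exc:
        raise KeyError(f"reference {reference_id!r} not found in family") from exc
    pairs = []
    num = 0
    for col, ch in enumerate(ref_seq, start=1):
        if ch not in GAP_CHARS:
            num += 1
            pairs.append((col, num, ch))
    cons_to_ref, ref_to_cons = {}, {}
    for col, num, _ in pairs:
        pos = consensus.column_to_position.get(col)
        if pos is not None:
            cons_to_ref[pos] = num
            ref_to_cons[num] = pos
    return ReferenceMap(reference_id, tuple(pairs), cons_to_ref, ref_to_cons)


REGION_NAMES = (
    "signal_peptide",
    "prodomain_nonconserved",
    "prodomain_conserved",
    "core",
    "cap",
    "c_terminal_tail",
)


@dataclass(frozen=True)
class RegionAnnotation:
    name: str
    span: tuple[int, int]  # inclusive 1-based consensus positions

    def __post_init__(self) -> None:
        if self.name not in REGION_NAMES:
            raise ValueError(f"unknown region name {self.name!r}")
        if self.span[0] > self.span[1] or self.span[0] < 1:
            raise ValueError(f"bad span {self.span} for region {self.name!r}")


@dataclass(frozen=True)
class ConstructDesign:
    sequence: str
    edits: tuple[tuple[str, tuple[int, int], str], ...]  # (op, span, inserted)
    n_tag: str
    c_tag: str


def _check_regions(regions: list[RegionAnnotation], length: int) -> None:
    ordered = sorted(regions, key=lambda r: r.span)
    for a, b in zip(ordered, ordered[1:]):
        if a.span[1] >= b.span[0]:
            raise ValueError(f"regions overlap: {a.name} {a.span} and {b.name} {b.span}")
    for r in regions:
        if r.span[1] > length:
            raise ValueError(f"region {r.name} {r.span} extends past consensus length {length}")


def assemble_construct(
    consensus: ConsensusResult | str,
    regions: list[RegionAnnotation],
    n_tag: str = "HHHHHH",
    c_tag: str = "HHHHHH",
) -> ConstructDesign:
    """Swap the N-terminal dispensable regions and the C-terminal tail for tags.

    The retained body runs from the start of ``prodomain_conserved`` (or
    position 1 if that region is not annotated) through the position
    immediately before ``c_terminal_tail`` (or the last position if no
    tail is annotated): ``n_tag + body + c_tag``. The edit log replays on
    the consensus to reproduce the construct exactly.
    """
    seq = consensus if isinstance(consensus, str) else consensus.consensus_sequence
    _check_regions(regions, len(seq))
    by_name = {r.name: r for r in regions}

    start = by_name["prodomain_conserved"].span[0] if "prodomain_conserved" in by_name else 1
    end = by_name["c_terminal_tail"].span[0] - 1 if "c_terminal_tail" in by_name else len(seq)
    if start > end:
        raise ValueError(f"retained body is empty (positions {start}..{end})")

    edits = []
    if end < len(seq) or c_tag:
        edits.append(("replace_c_terminus", (end + 1, len(seq)), c_tag))
    if start > 1 or n_tag:
        edits.append(("replace_n_terminus", (1, start - 1), n_tag))
    construct = n_tag + seq[start - 1 : end] + c_tag
    assert replay_edits(seq, edits) == construct
    return ConstructDesign(construct, tuple(edits), n_tag, c_tag)


def replay_edits(
    consensus_sequence: str,
    edits: list[tuple[str, tuple[int, int], str]] | tuple,
) -> str:
    """Apply an edit log to the consensus; inverse check for ConstructDesign."""
    seq = consensus_sequence
    for op, (lo, hi), inserted in edits:
        # span is inclusive over the *current* coordinates; terminal replacements
        # are applied C-terminus first so earlier spans stay valid
        seq = seq[: lo - 1] + inserted + seq[hi:]
    return seq
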