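"""Ligase-activity-determinant (LAD) site location, classification and mutation.

Two conserved positions flanking the S1 Asx-binding pocket steer a
legumain between endopeptidase-dominant (Gly at both, "AEP-like") and
ligase-dominant behavior (hydrophobic residue at either, "PAL-like").
This module resolves those positions through an explicit reference map,
classifies sequences, applies mutation plans with a replayable lineage,
and emits the canonical three-variant ligase panel
(LAD1->Val, LAD2->Ala, and the double mutant).
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass, replace

AEP_STATE_DEFAULT = frozenset("G")
PAL_STATE_DEFAULT = frozenset("VILAFM")

AEP_LIKE = "AEP-like"
PAL_LIKE = "PAL-like"
AMBIGUOUS = "ambiguous"


class LadError(ValueError):
    pass


@dataclass(frozen=True)
class LadSite:
    name: str  # LAD1 | LAD2
    position: int  # 1-based position in the subject sequence
    observed_residue: str
    aep_state: frozenset[str] = AEP_STATE_DEFAULT
    pal_state: frozenset[str] = PAL_STATE_DEFAULT

    def __post_init__(self) -> None:
        if self.name not in ("LAD1", "LAD2"):
            raise LadError(f"LAD site name must be LAD1 or LAD2, got {self.name!r}")


@dataclass(frozen=True)
class MutationPlan:
    substitutions: tuple[tuple[int, str, str], ...]  # (position, from, to)
    label: str

    def __post_init__(self) -> None:
        positions = [pos for pos, _, _ in self.substitutions]
        if len(set(positions)) != len(positions):
            raise LadError("duplicate positions in mutation plan")

    def inverse(self) -> "MutationPlan":
        return MutationPlan(
            tuple((pos, to, frm) for pos, frm, to in self.substitutions),
            label=f"revert({self.label})",
        )


@dataclass(frozen=True)
class EnzymeVariant:
    name: str
    sequence: str
    lad_sites: tuple[LadSite, LadSite]
    classification: str
    lineage: tuple[tuple[str, MutationPlan], ...] = ()  # (parent name, plan applied)


def _resolve(ref_lookup, ref_position: int) -> int | None:
    if isinstance(ref_lookup, Mapping):
        return ref_lookup.get(ref_position)
    # duck-typed ReferenceMap from consensus_design
    lut = getattr(ref_lookup, "reference_to_consensus", None)
    if lut is not None:
        return lut.get(ref_position)
    raise TypeError("ref_lookup must be a mapping or expose reference_to_consensus")


def locate_lad_sites(
    subject: str,
    ref_lookup,
    lad_reference_positions: tuple[int, int],
    aep_state: frozenset[str] = AEP_STATE_DEFAULT,
    pal_state: frozenset[str] = PAL_STATE_DEFAULT,
) -> tuple[LadSite, LadSite]:
    """Resolve the two LAD reference positions onto the subject and report
    the observed residues. No mutation is performed.

    ``ref_lookup`` maps reference numbering to subject positions: either a
    plain mapping or a :class:`~palforge.consensus.ReferenceMap`. A
    reference position that does not resolve (e.g. mapped into a trimmed
    column) is an error, never a silent shift.
    """
    sites = []
    for name, ref_pos in zip(("LAD1", "LAD2"), lad_reference_positions):
        pos = _resolve(ref_lookup, ref_pos)
        if pos is None:
            raise LadError(
                f"{name}: reference position {ref_pos} does not resolve to a "
                f"subject position (trimmed or unaligned column)"
            )
        if not 1 <= pos <= len(subject):
            raise LadError(f"{name}: mapped position {pos} outside subject sequence")
        observed = subject[pos - 1]
        if observed in "-.":
            raise LadError(f"{name}: reference position {ref_pos} maps to a gap")
        sites.append(LadSite(name, pos, observed, aep_state, pal_state))
    return sites[0], sites[1]


def classify_activity(sites: tuple[LadSite, LadSite]) -> str:
    """AEP-like if both LADs sit in the AEP state set; PAL-like if at least
    one sits in the PAL (hydrophobic) set; otherwise ambiguous."""
    lad1, lad2 = sites
    if lad1.observed_residue in lad1.aep_state and lad2.observed_residue in lad2.aep_state:
        return AEP_LIKE
    if lad1.observed_residue in lad1.pal_state or lad2.observed_residue in lad2.pal_state:
        return PAL_LIKE
    return AMBIGUOUS


def make_variant(
    name: str,
    sequence: str,
    lad_positions: tuple[int, int],
    aep_state: frozenset[str] = AEP_STATE_DEFAULT,
    pal_state: frozenset[str] = PAL_STATE_DEFAULT,
) -> EnzymeVariant:
    """Build a variant with LAD sites located by direct subject positions."""
    identity = {p: p for p in lad_positions}
    sites = locate_lad_sites(sequence, identity, lad_positions, aep_state, pal_state)
    return EnzymeVariant(name, sequence, sites, classify_activity(sites))


def apply_mutations(parent: EnzymeVariant, plan: MutationPlan) -> EnzymeVariant:
    """Apply a substitution plan; lineage records (parent, plan) so replay
    reproduces the child sequence exactly."""
    seq = list(parent.sequence)
    for pos, frm, to in plan.substitutions:
        if not 1 <= pos <= len(seq):
            raise LadError(f"substitution position {pos} outside sequence")
        if seq[pos - 1] != frm:
            raise LadError(
                f"substitution at position {pos} expects {frm!r} but parent "
                f"carries {seq[pos - 1]!r}"
            )
        seq[pos - 1] = to
    child_seq = "".join(seq)
    new_sites = tuple(
        replace(s, observed_residue=child_seq[s.position - 1]) for s in parent.lad_sites
    )
    return EnzymeVariant(
        name=plan.label,
        sequence=child_seq,
        lad_sites=new_sites,  # type: ignore[arg-type]
        classification=classify_activity(new_sites),
        lineage=parent.lineage + ((parent.name, plan),),
    )


def design_pal_panel(
    parent: EnzymeVariant, name_prefix: str | None = None
) -> tuple[EnzymeVariant, EnzymeVariant, EnzymeVariant]:
    """Emit the three ligase variants of a Gly/Gly parent: LAD1->Val,
    LAD2->Ala, and the double mutant (suffixes 1, 2, 3)."""
    lad1, lad2 = parent.lad_sites
    if parent.classification != AEP_LIKE or lad1.observed_residue != "G" or lad2.observed_residue != "G":
        raise LadError(
            "ligase panel is defined only for an AEP-like parent with Gly at "
            f"both LAD sites (got {lad1.observed_residue}/{lad2.observed_residue}, "
            f"{parent.classification})"
        )
    prefix = name_prefix if name_prefix is not None else f"{parent.name}-PAL"
    plans = (
        MutationPlan(((lad1.position, "G", "V"),), label=f"{prefix}1"),
        MutationPlan(((lad2.position, "G", "A"),), label=f"{prefix}2"),
        MutationPlan(((lad2.position, "G", "A"), (lad1.position, "G", "V")), label=f"{prefix}3"),
    )
    return tuple(apply_mutations(parent, plan) for plan in plans)  # type: ignore[return-value]


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    return sum(x != y for x, y in zip(a, b))
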