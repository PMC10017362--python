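"""Asx-specific cleavage, cyclization, ligation and splice-cascade modeling.

An Asx-specific enzyme (endopeptidase or ligase) acts C-terminal to an
Asn/Asp P1 residue. Depending on conditions the acyl-enzyme intermediate
is resolved by water (hydrolysis), by the substrate's own N terminus
(head-to-tail cyclization) or by an incoming nucleophile peptide
(intermolecular ligation). Every predicted species carries exact
monoisotopic and average masses so products can be matched against
observed MS peaks.

Recognition follows an Asx-Xaa-Yaa tripeptide motif: P1 is Asn or Asp,
P1' (Xaa) is any residue except Pro and P2' (Yaa) is hydrophobic. Motif
violations are reported as warnings, never refusals, since disfavored
substrates still react (only less efficiently).
"""

from __future__ import annotations

from dataclasses import dataclass

from . import masses

#: Default hydrophobic set for the Yaa / P2'' position.
HYDROPHOBIC_DEFAULT = frozenset("FILMVAWY")

#: Smallest chemically plausible backbone macrocycle.
MIN_RING = 5


class ReactionError(ValueError):
    """A predicted reaction violates its preconditions."""


@dataclass(frozen=True)
class Peptide:
    """A peptide chain with topology and cysteine oxidation state."""

    sequence: str
    topology: str = "linear"
    disulfide_count: int = 0
    name: str | None = None

    def __post_init__(self) -> None:
        masses.validate_sequence(self.sequence)
        if self.topology not in ("linear", "cyclic"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.topology == "cyclic" and len(self.sequence) < MIN_RING:
            raise ValueError(
                f"cyclic peptide of length {len(self.sequence)} below "
                f"minimum ring size {MIN_RING}"
            )
        max_ss = self.sequence.count("C") // 2
        if not 0 <= self.disulfide_count <= max_ss:
            raise ValueError(
                f"disulfide_count {self.disulfide_count} exceeds floor(#Cys/2)={max_ss}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def peptide_mass(p: Peptide) -> tuple[float, float]:
    """Return ``(mono_mass, avg_mass)`` in Da for a peptide.

    Linear chains carry one terminal water; head-to-tail cycles carry
    none; each disulfide bond removes two hydrogens.
    """
    out = []
    for mono in (True, False):
        if p.topology == "linear":
            m = masses.linear_mass(p.sequence, monoisotopic=mono)
        else:
            m = masses.cyclic_mass(p.sequence, monoisotopic=mono)
        m -= masses.disulfide_correction(p.disulfide_count, monoisotopic=mono)
        out.append(m)
    return out[0], out[1]


@dataclass(frozen=True)
class MotifRule:
    """Residue-class configuration for the Asx-Xaa-Yaa recognition motif."""

    p1_residues: frozenset[str] = frozenset("ND")
    p1prime_excluded: frozenset[str] = frozenset("P")
    p2prime_hydrophobic: frozenset[str] = HYDROPHOBIC_DEFAULT
    p1dprime_favored: frozenset[str] = frozenset("G")


DEFAULT_RULE = MotifRule()


@dataclass(frozen=True)
class RecognitionSite:
    """An Asn/Asp P1 position with its Schechter–Berger context."""

    p1_position: int  # 1-based
    p1_residue: str
    p2: str | None
    p1prime: str | None
    p2prime: str | None
    motif_ok: bool


def find_p1_sites(p: Peptide, rule: MotifRule = DEFAULT_RULE) -> list[RecognitionSite]:
    """Report every Asn/Asp position with motif evaluation, in sequence order.

    ``motif_ok`` requires P1' != Pro and hydrophobic P2' when both exist;
    context absent past a chain end is not held against the site. Cyclic
    peptides wrap context around the ring.
    """
    seq, n = p.sequence, len(p.sequence)
    cyclic = p.topology == "cyclic"

    def at(i: int) -> str | None:  # 0-based with wrap-around for rings
        if cyclic:
            return seq[i % n]
        return seq[i] if 0 <= i < n else None

    sites = []
    for idx, aa in enumerate(seq):
        if aa not in rule.p1_residues:
            continue
        p1p, p2p, p2 = at(idx + 1), at(idx + 2), at(idx - 1)
        ok = True
        if p1p is not None and p1p in rule.p1prime_excluded:
            ok = False
        if p2p is not None and p2p not in rule.p2prime_hydrophobic:
            ok = False
        sites.append(RecognitionSite(idx + 1, aa, p2, p1p, p2p, ok))
    return sites


@dataclass(frozen=True)
class ReactionProduct:
    kind: str  # hydrolysis_n_fragment | hydrolysis_c_fragment | cyclic | ligated | intermediate | leaving_group | cap
    peptide: Peptide
    mono_mass: float
    avg_mass: float


@dataclass(frozen=True)
class ProductSet:
    products: tuple[ReactionProduct, ...]
    warnings: tuple[str, ...] = ()

    def by_kind(self, kind: str) -> ReactionProduct:
        hits = [pr for pr in self.products if pr.kind == kind]
        if len(hits) != 1:
            raise KeyError(f"expected exactly one {kind!r} product, got {len(hits)}")
        return hits[0]


def _product(kind: str, peptide: Peptide) -> ReactionProduct:
    mono, avg = peptide_mass(peptide)
    return ReactionProduct(kind, peptide, mono, avg)


def _site_warnings(site: RecognitionSite) -> list[str]:
    if site.motif_ok:
        return []
    return [
        f"P1 site at position {site.p1_position} violates the Asx-Xaa-Yaa motif "
        f"(P1'={site.p1prime}, P2'={site.p2prime}); reaction expected but inefficient"
    ]


def _check_site(p: Peptide, site: RecognitionSite) -> None:
    if not 1 <= site.p1_position <= len(p):
        raise ReactionError(f"site position {site.p1_position} outside peptide")
    if p.sequence[site.p1_position - 1] != site.p1_residue:
        raise ReactionError(
            f"site residue {site.p1_residue} does not match sequence at "
            f"position {site.p1_position}"
        )


def predict_cleavage(p: Peptide, site: RecognitionSite) -> ProductSet:
    """Hydrolysis C-terminal to P1.

    Linear substrate -> N-fragment (prefix through P1) + C-fragment.
    Cyclic substrate -> ring opening: one linear chain starting at P1+1,
    gaining one water.
    """
    _check_site(p, site)
    warnings = _site_warnings(site)
    cut = site.p1_position
    if p.topology == "cyclic":
        opened = p.sequence[cut:] + p.sequence[:cut]
        prod = Peptide(opened, "linear", p.disulfide_count, name=f"{p.name or 'ring'}-opened")
        return ProductSet((_product("hydrolysis_n_fragment", prod),), tuple(warnings))
    if cut == len(p):
        raise ReactionError("cleavage at the last residue leaves an empty C-fragment")
    n_frag = Peptide(p.sequence[:cut], "linear", name="n_fragment")
    c_frag = Peptide(p.sequence[cut:], "linear", name="c_fragment")
    return ProductSet(
        (_product("hydrolysis_n_fragment", n_frag),
         _product("hydrolysis_c_fragment", c_frag)),
        tuple(warnings),
    )


def predict_cyclization(p: Peptide, site: RecognitionSite) -> ProductSet:
    """Head-to-tail cyclization at P1, releasing the suffix as leaving group."""
    _check_site(p, site)
    if p.topology != "linear":
        raise ReactionError("cyclization substrate must be linear")
    cut = site.p1_position
    if cut == len(p):
        raise ReactionError("no leaving group: P1 is the last residue")
    if cut < MIN_RING:
        raise ReactionError(
            f"ring of {cut} residues below minimum ring size {MIN_RING}"
        )
    cyc = Peptide(p.sequence[:cut], "cyclic", name=f"cyclo({p.sequence[:cut]})")
    leave = Peptide(p.sequence[cut:], "linear", name="leaving_group")
    return ProductSet(
        (_product("cyclic", cyc), _product("leaving_group", leave)),
        tuple(_site_warnings(site)),
    )


def predict_ligation(
    donor: Peptide,
    donor_site: RecognitionSite,
    acceptor: Peptide,
    rule: MotifRule = DEFAULT_RULE,
) -> ProductSet:
    """Intermolecular transpeptidation: donor prefix through P1 + acceptor.

    The incoming nucleophile's first residue (P1'') strongly favors Gly
    and its second (P2'') a hydrophobic residue; departures are flagged
    as warnings on the product set.
    """
    _check_site(donor, donor_site)
    if donor.topology != "linear" or acceptor.topology != "linear":
        raise ReactionError("ligation requires linear donor and acceptor")
    if len(acceptor) == 0:
        raise ReactionError("empty acceptor")
    cut = donor_site.p1_position
    if cut == len(donor):
        raise ReactionError("no leaving group: donor P1 is the last residue")

    warnings = _site_warnings(donor_site)
    if acceptor.sequence[0] not in rule.p1dprime_favored:
        warnings.append(
            f"acceptor P1'' residue {acceptor.sequence[0]!r} is not favored "
            f"(favored: {''.join(sorted(rule.p1dprime_favored))})"
        )
    if len(acceptor) >= 2 and acceptor.sequence[1] not in rule.p2prime_hydrophobic:
        warnings.append(
            f"acceptor P2'' residue {acceptor.sequence[1]!r} outside the hydrophobic set"
        )

    ligated = Peptide(donor.sequence[:cut] + acceptor.sequence, "linear",
                      name="ligated")
    leave = Peptide(donor.sequence[cut:], "linear", name="leaving_group")
    return ProductSet(
        (_product("ligated", ligated), _product("leaving_group", leave)),
        tuple(warnings),
    )


def predict_splice_cascade(
    p: Peptide,
    cap_site: RecognitionSite | None,
    cyc_site: RecognitionSite,
) -> ProductSet:
    """Cap removal by Asn hydrolysis followed by Asp-specific cyclization.

    Products: the N-terminal cap (through the Asn), the cap-removed
    linear intermediate, the cyclic product (cap end + 1 through the
    Asp) and the C-terminal leaving group. ``cap_site=None`` degenerates
    to plain cyclization.
    """
    if cap_site is None:
        return predict_cyclization(p, cyc_site)
    _check_site(p, cap_site)
    _check_site(p, cyc_site)
    if p.topology != "linear":
        raise ReactionError("splice substrate must be linear")
    if cap_site.p1_residue != "N":
        raise ReactionError("cap-removal site must be an Asn")
    if cyc_site.p1_residue != "D":
        raise ReactionError("cyclization site must be an Asp")
    cap_end, cyc_end = cap_site.p1_position, cyc_site.p1_position
    if cap_end >= cyc_end:
        raise ReactionError(
            f"cap site (position {cap_end}) must precede cyclization site "
            f"(position {cyc_end})"
        )
    if cyc_end - cap_end < MIN_RING:
        raise ReactionError(
            f"segment of {cyc_end - cap_end} residues between sites below "
            f"minimum ring size {MIN_RING}"
        )
    if cyc_end == len(p):
        raise ReactionError("no leaving group: cyclization P1 is the last residue")

    warnings = _site_warnings(cap_site) + _site_warnings(cyc_site)
    cap = Peptide(p.sequence[:cap_end], "linear", name="cap")
    inter = Peptide(p.sequence[cap_end:], "linear", name="intermediate")
    ring_seq = p.sequence[cap_end:cyc_end]
    cyc = Peptide(ring_seq, "cyclic", name=f"cyclo({ring_seq})")
    leave = Peptide(p.sequence[cyc_end:], "linear", name="leaving_group")
    return ProductSet(
        (_product("cap", cap),
         _product("intermediate", inter),
         _product("cyclic", cyc),
         _product("leaving_group", leave)),
        tuple(warnings),
    )


def site_at(p: Peptide, position: int, rule: MotifRule = DEFAULT_RULE) -> RecognitionSite:
    """Return the recognition site at a declared 1-based P1 position."""
    for s in find_p1_sites(p, rule):
        if s.p1_position == position:
            return s
    raise ReactionError(f"no Asn/Asp at position {position}")
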