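"""Synthetic input generators with known ground truth.

Every downstream stage — consensus calling, LAD classification,
Michaelis-Menten fitting, product quantification — is exercised on
families, variant sets, rate tables and product profiles generated here,
so the whole pipeline is testable without any external dataset. All
randomness flows from one explicit seed per call; fixed seed means
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .consensus import AlignedFamily, make_family
from .engineering import AEP_LIKE, PAL_LIKE
from .masses import STANDARD_RESIDUES

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"


class SpecError(ValueError):
    pass


@dataclass(frozen=True)
class FamilySpec:
    """Recipe for an aligned family with a known truth consensus.

    ``per_column_conservation`` gives, per truth column, the chance a
    member carries the truth residue (otherwise uniform over the other
    19). ``insert_blocks`` are (anchor column, insert length,
    carrier_fraction): carriers hold random residues across the block,
    everyone else holds gaps, so the block's occupancy is known exactly.
    """

    truth_consensus: str
    n_sequences: int
    per_column_conservation: tuple[float, ...]
    insert_blocks: tuple[tuple[int, int, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sequences <= 0:
            raise SpecError("n_sequences must be positive")
        bad = set(self.truth_consensus) - STANDARD_RESIDUES
        if bad:
            raise SpecError(f"truth consensus contains nonstandard symbols {sorted(bad)}")
        if len(self.per_column_conservation) != len(self.truth_consensus):
            raise SpecError("per_column_conservation length must match truth consensus")
        if any(not 0 <= p <= 1 for p in self.per_column_conservation):
            raise SpecError("conservation probabilities must lie in [0, 1]")
        for i, (anchor, length, frac) in enumerate(self.insert_blocks):
            if not 0 <= anchor <= len(self.truth_consensus):
                raise SpecError(
                    f"insert block {i} anchors at column {anchor}, outside the "
                    f"truth consensus (length {len(self.truth_consensus)})"
                )
            if length <= 0:
                raise SpecError(f"insert block {i} has non-positive length {length}")
            if not 0 <= frac < 1:
                raise SpecError(f"insert block {i} carrier fraction {frac} outside [0, 1)")


@dataclass(frozen=True)
class FamilyTruth:
    truth_consensus: str
    column_kind: tuple[str, ...]  # 'core' | 'insert' per alignment column
    occupancy: tuple[float, ...]  # realized non-gap fraction per column
    core_columns: tuple[int, ...]  # 1-based alignment columns of truth positions
    insert_columns: tuple[int, ...]


def uniform_conservation(length: int, p: float) -> tuple[float, ...]:
    return tuple([p] * length)


def generate_family(spec: FamilySpec) -> tuple[AlignedFamily, FamilyTruth]:
    """Sample an aligned family realizing the spec's occupancy structure.

    Core columns are fully occupied; each insert block is carried by
    exactly ``round(carrier_fraction * n)`` members (gaps elsewhere), so
    the truth occupancy record matches an independent per-column count
    exactly.
    """
    rng = np.random.default_rng(spec.seed)
    n, L = spec.n_sequences, len(spec.truth_consensus)
    aa = np.frombuffer(AA_ORDER.encode(), dtype="S1")

    # core residues: truth residue with prob p, else uniform over the other 19
    core = np.empty((n, L), dtype="S1")
    for j, (truth_aa, p) in enumerate(zip(spec.truth_consensus, spec.per_column_conservation)):
        keep = rng.random(n) < p
        others = aa[aa != truth_aa.encode()]
        core[:, j] = np.where(keep, truth_aa.encode(), others[rng.integers(0, 19, size=n)])

    # build per-column segments: inserts attach after their anchor column
    blocks_by_anchor: dict[int, list[tuple[int, float]]] = {}
    for anchor, length, frac in spec.insert_blocks:
        blocks_by_anchor.setdefault(anchor, []).append((length, frac))

    columns: list[np.ndarray] = []
    kinds: list[str] = []
    occ: list[float] = []
    core_cols: list[int] = []

    def emit_inserts(anchor: int) -> None:
        for length, frac in blocks_by_anchor.get(anchor, []):
            n_carriers = int(round(frac * n))
            carriers = rng.choice(n, size=n_carriers, replace=False)
            for _ in range(length):
                col = np.full(n, b"-", dtype="S1")
                col[carriers] = aa[rng.integers(0, 20, size=n_carriers)]
                columns.append(col)
                kinds.append("insert")
                occ.append(n_carriers / n)

    emit_inserts(0)
    for j in range(L):
        columns.append(core[:, j])
        kinds.append("core")
        occ.append(1.0)
        core_cols.append(len(columns))
        emit_inserts(j + 1)

    matrix = np.stack(columns, axis=1)
    records = [
        (f"seq{i + 1:04d}", matrix[i].tobytes().decode()) for i in range(n)
    ]
    family = make_family(records)
    insert_cols = tuple(i + 1 for i, k in enumerate(kinds) if k == "insert")
    truth = FamilyTruth(
        spec.truth_consensus, tuple(kinds), tuple(occ), tuple(core_cols), insert_cols
    )
    return family, truth


@dataclass(frozen=True)
class LabeledVariant:
    name: str
    sequence: str
    label: str  # AEP-like | PAL-like


def generate_lad_variants(
    base: str,
    lad_positions: tuple[int, int],
    n_per_class: int,
    seed: int = 0,
    background_rate: float = 0.0,
    protected_positions: tuple[int, ...] = (),
) -> list[LabeledVariant]:
    """Emit labeled AEP-like (Gly/Gly retained) and PAL-like sequences.

    PAL-like members cycle through the three mutation patterns (double
    mutant first, then each single), mirroring the canonical panel.
    Background substitutions at ``background_rate`` never touch the LAD
    positions or any protected (e.g. catalytic-triad) position.
    """
    pos1, pos2 = lad_positions
    for name, pos in (("LAD1", pos1), ("LAD2", pos2)):
        if not 1 <= pos <= len(base):
            raise SpecError(f"{name} position {pos} outside base sequence")
        if base[pos - 1] != "G":
            raise SpecError(
                f"base must carry Gly at {name} position {pos}, found {base[pos - 1]!r}"
            )
    rng = np.random.default_rng(seed)
    untouchable = set(lad_positions) | set(protected_positions)
    pal_patterns = ({pos1: "V", pos2: "A"}, {pos1: "V"}, {pos2: "A"})

    def mutate(seq: list[str]) -> list[str]:
        if background_rate <= 0:
            return seq
        for i in range(len(seq)):
            if (i + 1) in untouchable:
                continue
            if rng.random() < background_rate:
                options = [a for a in AA_ORDER if a != seq[i]]
                seq[i] = options[rng.integers(0, len(options))]
        return seq

    out = []
    for k in range(n_per_class):
        seq = mutate(list(base))
        out.append(LabeledVariant(f"aep{k + 1:03d}", "".join(seq), AEP_LIKE))
    for k in range(n_per_class):
        seq = mutate(list(base))
        for pos, res in pal_patterns[k % 3].items():
            seq[pos - 1] = res
        out.append(LabeledVariant(f"pal{k + 1:03d}", "".join(seq), PAL_LIKE))
    return out


@dataclass(frozen=True)
class RateSpec:
    """Truth parameters for a simulated initial-rate series."""

    kcat_true: float  # s^-1
    km_true: float  # uM
    enzyme_conc: float  # M
    substrate_concs: tuple[float, ...]  # uM
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kcat_true <= 0 or self.km_true <= 0 or self.enzyme_conc <= 0:
            raise SpecError("kinetic truth parameters must be positive")
        if any(s <= 0 for s in self.substrate_concs):
            raise SpecError("substrate concentrations must be positive")
        if self.noise_cv < 0:
            raise SpecError("noise_cv must be non-negative")


def noiseless_rate(spec: RateSpec, s_uM: float) -> float:
    """v = kcat*E0*S/(KM+S) in uM/s, with E0 converted to uM."""
    e0_uM = spec.enzyme_conc * 1e6
    return spec.kcat_true * e0_uM * s_uM / (spec.km_true + s_uM)


def generate_rate_data(spec: RateSpec) -> pd.DataFrame:
    """Rate table with multiplicative Gaussian noise (CV = noise_cv),
    truncated at zero. Columns: substrate_uM, rate_uM_per_s."""
    rng = np.random.default_rng(spec.seed)
    s = np.array(spec.substrate_concs, dtype=float)
    v = np.array([noiseless_rate(spec, x) for x in s])
    if spec.noise_cv > 0:
        v = v * (1.0 + spec.noise_cv * rng.standard_normal(len(s)))
        v = np.clip(v, 0.0, None)
    return pd.DataFrame({"substrate_uM": s, "rate_uM_per_s": v})


def generate_product_profiles(
    ph_grid: tuple[float, ...] | list[float],
    ch_midpoint_ph: float,
    ch_slope: float,
    seed: int = 0,
    ch_max: float = 25.0,
    converted_percent: float = 60.0,
) -> pd.DataFrame:
    """Per-pH product percentages whose C/H ratio follows a logistic in pH.

    C/H(pH) = ch_max / (1 + exp(-slope * (pH - midpoint))). The converted
    fraction is split between cyclized and hydrolyzed according to C/H;
    the remainder stays substrate, so rows always sum to 100. The seed is
    accepted for interface uniformity (the profile itself is
    deterministic).
    """
    if not 0 < converted_percent <= 100:
        raise SpecError("converted_percent must lie in (0, 100]")
    rows = []
    for ph in ph_grid:
        ch = ch_max / (1.0 + np.exp(-ch_slope * (ph - ch_midpoint_ph)))
        cyc = converted_percent * ch / (1.0 + ch)
        hyd = converted_percent - cyc
        rows.append(
            {
                "ph": ph,
                "percent_hydrolyzed": hyd,
                "percent_cyclized": cyc,
                "percent_remaining": 100.0 - converted_percent,
                "ch_ratio": ch,
            }
        )
    return pd.DataFrame(rows)
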