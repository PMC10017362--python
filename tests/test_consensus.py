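import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from palforge.consensus import (
    TIE_ORDER,
    AlignedFamily,
    AlignmentError,
    RegionAnnotation,
    assemble_construct,
    build_consensus,
    compute_column_profiles,
    make_family,
    map_to_reference,
    parse_alignment,
    replay_edits,
    write_alignment,
)


# ---------------------------------------------------------------- oracle
# Deliberately naive re-implementation of per-column bookkeeping, kept
# independent of the package internals.

def oracle_profiles(rows):
    n = len(rows)
    out = []
    for col in range(len(rows[0])):
        symbols = [r[col] for r in rows]
        nongap = [s for s in symbols if s not in "-."]
        occupancy = len(nongap) / n
        counts = {}
        for s in nongap:
            counts[s] = counts.get(s, 0) + 1
        designable = {a: c for a, c in counts.items() if a in "ACDEFGHIKLMNPQRSTVWY"}
        pool = designable if designable else counts
        consensus = None
        if pool:
            best = max(pool.values())
            for aa in TIE_ORDER + "XBZU":
                if pool.get(aa) == best:
                    consensus = aa
                    break
        conservation = max(counts.values()) / len(nongap) if nongap else 0.0
        out.append((occupancy, counts, consensus, conservation))
    return out


def random_rows(rng, n_rows, n_cols, gap_p=0.2):
    alphabet = "ACDEFGHIKLMNPQRSTVWYXBZU"
    return [
        "".join(
            "-" if rng.random() < gap_p else rng.choice(alphabet)
            for _ in range(n_cols)
        )
        for _ in range(n_rows)
    ]


# ---------------------------------------------------------------- parsing

def test_two_record_family(tmp_path):
    f = tmp_path / "aln.fasta"
    f.write_text(">a\nAC-\n>b\nA-C\n")
    fam = parse_alignment(f)
    assert fam.alignment_length == 3
    assert fam.n_records == 2


def test_ragged_alignment_rejected_naming_record(tmp_path):
    f = tmp_path / "aln.fasta"
    f.write_text(">a\nACD\n>b\nACDE\n")
    with pytest.raises(AlignmentError, match="record 2"):
        parse_alignment(f)


def test_dot_gaps_and_lowercase_normalized():
    fam = make_family([("a", "ac.d"), ("b", "AC-D")])
    assert fam.records[0][1] == "AC-D"


def test_illegal_symbol_rejected_with_position():
    with pytest.raises(AlignmentError, match="column 3"):
        make_family([("a", "AC7D")])


def test_write_parse_round_trip(tmp_path):
    rng = random.Random(7)
    fam = make_family(
        [(f"s{i}", row) for i, row in enumerate(random_rows(rng, 20, 30))]
    )
    path = tmp_path / "rt.fasta"
    write_alignment(fam, path)
    assert parse_alignment(path) == fam


def test_empty_family_rejected():
    with pytest.raises(AlignmentError, match="empty"):
        make_family([])


# ---------------------------------------------------------------- profiles

def test_identical_sequences_fully_occupied_and_conserved():
    fam = make_family([(f"s{i}", "MKVL") for i in range(10)])
    for prof in compute_column_profiles(fam):
        assert prof.occupancy == 1.0
        assert prof.conservation == 1.0


def test_hand_counted_mixed_column():
    rows = ["A"] * 5 + ["G"] * 3 + ["-"] * 2
    fam = make_family([(f"s{i}", r) for i, r in enumerate(rows)])
    (prof,) = compute_column_profiles(fam)
    assert prof.occupancy == pytest.approx(0.8)
    assert prof.consensus_residue == "A"
    assert prof.conservation == pytest.approx(0.625)
    assert prof.residue_counts == {"A": 5, "G": 3}


def test_all_gap_column_gives_sentinel():
    fam = make_family([("a", "A-"), ("b", "A-")])
    profs = compute_column_profiles(fam)
    assert profs[1].occupancy == 0.0
    assert profs[1].consensus_residue is None


def test_ambiguous_codes_occupy_but_cannot_win():
    rows = ["X", "X", "X", "A", "-"]
    fam = make_family([(f"s{i}", r) for i, r in enumerate(rows)])
    (prof,) = compute_column_profiles(fam)
    assert prof.occupancy == pytest.approx(0.8)
    assert prof.consensus_residue == "A"  # X outnumbers A but is not designable


def test_ambiguous_only_column_falls_back_to_ambiguous_code():
    fam = make_family([("a", "X"), ("b", "X")])
    (prof,) = compute_column_profiles(fam)
    assert prof.consensus_residue == "X"


def test_consensus_tie_break_uses_fixed_residue_order():
    rows = ["R", "R", "A", "A"]
    fam = make_family([(f"s{i}", r) for i, r in enumerate(rows)])
    (prof,) = compute_column_profiles(fam)
    assert prof.consensus_residue == "A"  # A precedes R in the tie order


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_profiles_match_brute_force_oracle(seed):
    rng = random.Random(seed)
    n_rows, n_cols = rng.choice([(10, 20), (50, 200), (30, 80)])
    rows = random_rows(rng, n_rows, n_cols)
    fam = make_family([(f"s{i}", r) for i, r in enumerate(rows)])
    profs = compute_column_profiles(fam)
    expected = oracle_profiles(rows)
    assert len(profs) == len(expected)
    for prof, (occ, counts, consensus, cons) in zip(profs, expected):
        assert prof.occupancy == pytest.approx(occ, abs=0)
        assert prof.residue_counts == counts
        assert prof.consensus_residue == consensus
        assert prof.conservation == pytest.approx(cons, abs=0)


def test_column_permutation_permutes_profiles():
    rng = random.Random(11)
    rows = random_rows(rng, 15, 25)
    perm = list(range(25))
    rng.shuffle(perm)
    fam = make_family([(f"s{i}", r) for i, r in enumerate(rows)])
    permuted = make_family(
        [(f"s{i}", "".join(r[j] for j in perm)) for i, r in enumerate(rows)]
    )
    base = compute_column_profiles(fam)
    shuffled = compute_column_profiles(permuted)
    for new_col, old_col in enumerate(perm):
        a, b = shuffled[new_col], base[old_col]
        assert (a.occupancy, a.residue_counts, a.consensus_residue, a.conservation) == (
            b.occupancy, b.residue_counts, b.consensus_residue, b.conservation
        )


# ---------------------------------------------------------------- consensus

def test_threshold_boundary_is_kept_not_removed():
    # 1/10 occupancy == threshold 0.10 exactly -> kept
    rows = ["A-"] + ["AA"] * 9
    fam = make_family([(f"s{i}", r) for i, r in enumerate(rows)])
    profs = compute_column_profiles(fam)
    # column 2 occupancy = 0.9; craft a 0.1 column instead
    rows = ["AA"] + ["A-"] * 9
    fam = make_family([(f"s{i}", r) for i, r in enumerate(rows)])
    result = build_consensus(compute_column_profiles(fam), threshold=0.10)
    assert result.kept_columns == (1, 2)


def test_sub_threshold_column_removed():
    rows = ["AA"] + ["A-"] * 19  # col 2 occupancy 0.05
    fam = make_family([(f"s{i}", r) for i, r in enumerate(rows)])
    result = build_consensus(compute_column_profiles(fam), threshold=0.10)
    assert result.kept_columns == (1,)
    assert result.consensus_sequence == "A"


def test_all_identical_family_consensus_is_member():
    fam = make_family([(f"s{i}", "MKVLNDA") for i in range(5)])
    result = build_consensus(compute_column_profiles(fam))
    assert result.consensus_sequence == "MKVLNDA"


def test_smallest_positive_threshold_keeps_all_nonempty_columns():
    rows = ["A-A", "AA-"]
    fam = make_family([(f"s{i}", r) for i, r in enumerate(rows)])
    result = build_consensus(compute_column_profiles(fam), threshold=1e-9)
    assert result.kept_columns == (1, 2, 3)


def test_invalid_threshold_rejected():
    fam = make_family([("a", "A")])
    profs = compute_column_profiles(fam)
    for bad in (0.0, -0.1, 1.5):
        with pytest.raises(ValueError, match="threshold"):
            build_consensus(profs, threshold=bad)


@given(st.integers(min_value=0, max_value=10_000))
@settings(max_examples=30, deadline=None)
def test_raising_threshold_never_lengthens_consensus(seed):
    rng = random.Random(seed)
    rows = random_rows(rng, 12, 30, gap_p=0.4)
    profs = compute_column_profiles(
        make_family([(f"s{i}", r) for i, r in enumerate(rows)])
    )
    lengths = [
        len(build_consensus(profs, threshold=t).consensus_sequence)
        for t in (0.05, 0.10, 0.25, 0.5, 0.75, 1.0)
    ]
    assert lengths == sorted(lengths, reverse=True)


def test_column_to_position_map_is_ordered_and_dense():
    rows = ["A-C-", "A-C-", "AAC-"]
    fam = make_family([(f"s{i}", r) for i, r in enumerate(rows)])
    result = build_consensus(compute_column_profiles(fam), threshold=0.5)
    assert result.kept_columns == (1, 3)
    assert result.column_to_position == {1: 1, 3: 2}
    assert result.position_to_column == {1: 1, 2: 3}


# ---------------------------------------------------------------- reference map

def test_reference_numbering_skips_gaps():
    fam = make_family([("ref", "A-CD"), ("x", "AACD")])
    result = build_consensus(compute_column_profiles(fam))
    rmap = map_to_reference(fam, result, "ref")
    assert [(c, n) for c, n, _ in rmap.pairs] == [(1, 1), (3, 2), (4, 3)]
    assert rmap.reference_for_column(2) is None  # gapped in reference


def test_unknown_reference_rejected():
    fam = make_family([("a", "ACD")])
    result = build_consensus(compute_column_profiles(fam))
    with pytest.raises(KeyError, match="nope"):
        map_to_reference(fam, result, "nope")


def test_reference_with_nterminal_extension_offsets_numbering_by_12():
    """Reference carries a 12-residue N-terminal extension absent from the
    rest of the family; aligned core positions map with a +12 offset."""
    ext = "WWWWWWWWWWWW"
    core = "MKVLNDAGHIKL"
    n_members = 30
    rows = [("ref", ext + core)] + [
        (f"s{i}", "-" * 12 + core) for i in range(n_members)
    ]
    fam = make_family(rows)
    result = build_consensus(compute_column_profiles(fam), threshold=0.10)
    # extension columns: occupancy 1/31 < 0.10 -> trimmed from the consensus
    assert len(result.consensus_sequence) == len(core)
    rmap = map_to_reference(fam, result, "ref")
    for pos in range(1, len(core) + 1):
        assert rmap.consensus_to_reference[pos] == pos + 12
        assert rmap.reference_to_consensus[pos + 12] == pos


# ---------------------------------------------------------------- construct

TOY = "MSPPNNNCOREPXXX"


def toy_regions():
    return [
        RegionAnnotation("signal_peptide", (1, 2)),
        RegionAnnotation("prodomain_nonconserved", (3, 4)),
        RegionAnnotation("prodomain_conserved", (5, 8)),
        RegionAnnotation("core", (9, 12)),
        RegionAnnotation("c_terminal_tail", (13, 15)),
    ]


def test_toy_construct_assembly():
    design = assemble_construct(TOY, toy_regions())
    assert design.sequence == "HHHHHH" + "NNNCOREP" + "HHHHHH"


def test_empty_tags_and_no_regions_is_identity():
    design = assemble_construct(TOY, [], n_tag="", c_tag="")
    assert design.sequence == TOY
    assert design.edits == ()


def test_edit_log_replays_to_construct():
    design = assemble_construct(TOY, toy_regions(), n_tag="HH", c_tag="KKK")
    assert replay_edits(TOY, design.edits) == design.sequence


def test_overlapping_regions_rejected_naming_pair():
    regions = [
        RegionAnnotation("prodomain_conserved", (5, 9)),
        RegionAnnotation("core", (9, 12)),
    ]
    with pytest.raises(ValueError, match="prodomain_conserved.*core"):
        assemble_construct(TOY, regions)


def test_out_of_bounds_region_rejected():
    with pytest.raises(ValueError, match="past consensus length"):
        assemble_construct(TOY, [RegionAnnotation("core", (10, 99))])


def test_bad_region_name_rejected():
    with pytest.raises(ValueError, match="unknown region"):
        RegionAnnotation("linker", (1, 2))


# ---------------------------------------------------------------- pipeline truth recovery

def test_consensus_recovers_generated_truth():
    from palforge.synthetic import FamilySpec, generate_family, uniform_conservation

    truth = "MKVLNDAGHIKLWQESTYFRPCMKVLNDAGHIKL"
    spec = FamilySpec(
        truth_consensus=truth,
        n_sequences=500,
        per_column_conservation=uniform_conservation(len(truth), 0.7),
        insert_blocks=((10, 5, 0.05), (20, 3, 0.08)),
        seed=42,
    )
    family, meta = generate_family(spec)
    result = build_consensus(compute_column_profiles(family), threshold=0.10)
    # every sub-threshold insert column removed
    assert all(col not in result.column_to_position for col in meta.insert_columns)
    # kept columns are exactly the core columns, recovering the truth
    assert result.kept_columns == meta.core_columns
    matches = sum(a == b for a, b in zip(result.consensus_sequence, truth))
    assert matches / len(truth) >= 0.99
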