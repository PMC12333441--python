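"""Barcode decoding, count conservation and enrichment reporting."""

import itertools

import pytest

from delforge.blocks import BEAD_BINDER_ID, TARGET_BINDER_ID
from delforge.chem import TagSchema
from delforge.codons import hamming_distance
from delforge.decode import (
    REASON_CODON,
    REASON_CONSTANT,
    REASON_LENGTH,
    CodonMatcher,
    CountTable,
    count_reads,
    decode_read,
    enrichment_report,
    marginal_uniformity_pvalue,
    match_codon,
)
from delforge.selection import GroundTruth, SelectionConfig, generate_reads, simulate_selection


def mutate(seq, pos, base):
    assert seq[pos] != base
    return seq[:pos] + base + seq[pos + 1 :]


# ---------------------------------------------------------------------------
# codon matching

def test_exact_match(toy_codon_sets):
    cset = toy_codon_sets[0]
    for i, s in enumerate(cset.sequences):
        assert match_codon(s, cset) == i


def test_every_single_mutant_corrects_back(toy_codon_sets):
    cset = toy_codon_sets[0]
    matcher = CodonMatcher(cset)
    for i, s in enumerate(cset.sequences):
        for pos in range(len(s)):
            for base in "ACGT":
                if base == s[pos]:
                    continue
                assert matcher.match(mutate(s, pos, base)) == i


def test_double_mutant_is_unassigned(toy_codon_sets):
    cset = toy_codon_sets[0]
    matcher = CodonMatcher(cset)
    s = cset.sequences[0]
    double = mutate(mutate(s, 0, "T" if s[0] != "T" else "G"), 1, "T" if s[1] != "T" else "G")
    # reject only if it is >= 2 away from every codon (it could land near another)
    if all(hamming_distance(double, c) >= 2 for c in cset.sequences):
        assert matcher.match(double) is None


def test_length_mismatch_unassigned(toy_codon_sets):
    matcher = CodonMatcher(toy_codon_sets[0])
    assert matcher.match("ACGT") is None


def test_ambiguous_mutants_rejected_for_substandard_sets():
    # distance-2 set: the shared mutant neighbourhood must never mis-assign
    matcher = CodonMatcher(["AAAA", "AATT"])
    assert matcher.match("AAAT") is None  # distance 1 from both
    assert matcher.match("AAAA") == 0  # exact still fine


# ---------------------------------------------------------------------------
# read decoding

@pytest.fixture(scope="module")
def decode_env(toy_codon_sets, tag_schema, toy_blocks):
    matchers = [CodonMatcher(cs) for cs in toy_codon_sets]
    block_ids = [[b.id for b in s] for s in toy_blocks]
    return tag_schema, matchers, block_ids


def test_error_free_read_decodes(toy_library, decode_env):
    schema, matchers, block_ids = decode_env
    m = toy_library[17]
    key, reason = decode_read(m.tag, schema, matchers, block_ids)
    assert reason is None
    assert key == (m.bb1_id, m.bb2_id, m.bb3_id)


def test_one_error_in_codon_is_corrected(toy_library, decode_env):
    schema, matchers, block_ids = decode_env
    m = toy_library[0]
    sl = schema.codon_slices()[1]
    pos = sl.start + 3
    read = mutate(m.tag, pos, "T" if m.tag[pos] != "T" else "G")
    key, reason = decode_read(read, schema, matchers, block_ids)
    assert key == (m.bb1_id, m.bb2_id, m.bb3_id)


def test_scrambled_primer_fails_constant_region(toy_library, decode_env):
    schema, matchers, block_ids = decode_env
    m = toy_library[0]
    read = m.tag[: -len(schema.closing_primer)] + "TTTTTTTTTT"[: len(schema.closing_primer)]
    key, reason = decode_read(read, schema, matchers, block_ids)
    assert key is None and reason == REASON_CONSTANT


def test_wrong_length_read(toy_library, decode_env):
    schema, matchers, block_ids = decode_env
    key, reason = decode_read(toy_library[0].tag + "A", schema, matchers, block_ids)
    assert key is None and reason == REASON_LENGTH


def test_no_single_error_read_is_ever_misassigned(toy_library, decode_env):
    """Exhaustive: every single mutant of every tag decodes to its source."""
    schema, matchers, block_ids = decode_env
    slices = schema.codon_slices()
    for m in toy_library[::7]:  # systematic subsample keeps this brisk
        truth_key = (m.bb1_id, m.bb2_id, m.bb3_id)
        for pos in range(len(m.tag)):
            for base in "ACGT":
                if base == m.tag[pos]:
                    continue
                key, reason = decode_read(mutate(m.tag, pos, base), schema, matchers, block_ids)
                if key is not None:
                    assert key == truth_key
                else:
                    # rejections must come from codon positions only if
                    # ambiguous — never from a correctable single error
                    assert not any(sl.start <= pos < sl.stop for sl in slices), (
                        f"single codon error at {pos} was rejected"
                    )


# ---------------------------------------------------------------------------
# counting

def test_count_conservation_from_synthetic_reads(toy_library, decode_env, toy_codon_sets):
    schema, _matchers, block_ids = decode_env
    truth = GroundTruth(target_binder_block_ids={TARGET_BINDER_ID}, p_target=0.3,
                        p_background=0.01)
    cfg = SelectionConfig(copies_per_member=50_000, read_depth=10_000,
                          substitution_error_rate=0.01, seed=21)
    ab = simulate_selection(toy_library, truth, cfg)
    reads = generate_reads(ab, cfg)
    table = count_reads(reads, schema, toy_codon_sets, block_ids)
    assert table.n_reads == 10_000
    assert table.n_assigned + table.n_unassigned == table.n_reads


def test_error_free_round_trip_assigns_everything(toy_library, decode_env, toy_codon_sets, tmp_path):
    from delforge.selection import write_fastq

    schema, _matchers, block_ids = decode_env
    truth = GroundTruth(target_binder_block_ids={TARGET_BINDER_ID}, p_target=0.3,
                        p_background=0.01)
    cfg = SelectionConfig(copies_per_member=50_000, read_depth=10_000,
                          substitution_error_rate=0.0, seed=22)
    ab = simulate_selection(toy_library, truth, cfg)
    path = tmp_path / "reads.fastq"
    write_fastq(generate_reads(ab, cfg), path)
    table = count_reads(path, schema, toy_codon_sets, block_ids)
    assert table.n_assigned == 10_000
    assert table.n_unassigned == 0


def test_repeated_tag_counts(toy_library, decode_env, toy_codon_sets):
    schema, _m, block_ids = decode_env
    m = toy_library[3]
    reads = [(f"r{i}", m.tag) for i in range(10)]
    table = count_reads(reads, schema, toy_codon_sets, block_ids)
    assert table.counts[(m.bb1_id, m.bb2_id, m.bb3_id)] == 10


def test_empty_fastq(tmp_path, decode_env, toy_codon_sets):
    schema, _m, block_ids = decode_env
    path = tmp_path / "empty.fastq"
    path.write_text("")
    table = count_reads(path, schema, toy_codon_sets, block_ids)
    assert table.n_reads == 0 and not table.counts


def test_malformed_fastq_names_record(tmp_path, decode_env, toy_codon_sets):
    schema, _m, block_ids = decode_env
    path = tmp_path / "bad.fastq"
    path.write_text("@r1\nACGT\n+\nIIII\nnot-a-header\nACGT\n+\nIIII\n")
    with pytest.raises(ValueError, match="record"):
        count_reads(path, schema, toy_codon_sets, block_ids)


def test_marginals_sum_to_assigned(toy_library, decode_env, toy_codon_sets):
    schema, _m, block_ids = decode_env
    reads = [(f"r{i}", m.tag) for i, m in enumerate(toy_library)]
    table = count_reads(reads, schema, toy_codon_sets, block_ids)
    for cycle in (1, 2, 3):
        assert sum(table.marginal(cycle).values()) == table.n_assigned


# ---------------------------------------------------------------------------
# enrichment reporting

def test_uniform_counts_give_flat_ratios(toy_library, decode_env, toy_codon_sets):
    schema, _m, block_ids = decode_env
    reads = [(f"r{i}", m.tag) for i, m in enumerate(toy_library)]
    table = count_reads(reads, schema, toy_codon_sets, block_ids)
    report = enrichment_report(table, baseline=table)
    for cycle_ratios in report.ratios:
        for r in cycle_ratios.values():
            assert r == pytest.approx(1.0)
    assert marginal_uniformity_pvalue(table, 1) > 0.99


def test_empty_table_rejected():
    with pytest.raises(ValueError):
        enrichment_report(CountTable())


def test_planted_binder_ranks_first_and_controls_flagged(toy_library, decode_env, toy_codon_sets):
    schema, _m, block_ids = decode_env
    truth = GroundTruth(target_binder_block_ids={TARGET_BINDER_ID}, p_target=0.3,
                        p_background=0.005)
    cfg = SelectionConfig(copies_per_member=1_000_000, rounds=2, read_depth=50_000,
                          substitution_error_rate=0.005, seed=23)
    ab = simulate_selection(toy_library, truth, cfg)
    table = count_reads(generate_reads(ab, cfg), schema, toy_codon_sets, block_ids)
    controls = [b for cycle in block_ids for b in cycle if "ctrl" in b]
    report = enrichment_report(table, control_ids=controls)
    assert report.top_block(3) == TARGET_BINDER_ID
    assert report.control_flags[2]["ctrl3-no-acid"] is True
    assert report.control_flags[2][TARGET_BINDER_ID] is False
    # cycles 1 and 2 stay uniform: no block is significantly enriched
    for cycle in (1, 2):
        assert marginal_uniformity_pvalue(table, cycle, n_blocks=7) > 0.01


def test_preclear_drops_bead_binder_count(toy_library, decode_env, toy_codon_sets):
    schema, _m, block_ids = decode_env
    truth = GroundTruth(
        target_binder_block_ids={TARGET_BINDER_ID},
        bead_binder_block_ids={BEAD_BINDER_ID},
        p_target=0.3, p_bead=0.5, p_background=0.005,
    )
    counts = {}
    for preclear in (False, True):
        cfg = SelectionConfig(copies_per_member=1_000_000, rounds=2, read_depth=50_000,
                              substitution_error_rate=0.005, seed=24, preclear=preclear)
        ab = simulate_selection(toy_library, truth, cfg)
        table = count_reads(generate_reads(ab, cfg), schema, toy_codon_sets, block_ids)
        counts[preclear] = table.marginal(3)[BEAD_BINDER_ID]
    assert counts[True] < counts[False]
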