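import numpy as np
import pytest

from secscan.cmcore import score_sequence
from secscan.synth import (
    PlantedItem,
    SyntheticGenomeSpec,
    build_seed_alignment,
    make_decoy_canonical,
    make_genome,
    mutate,
    sample_gene,
    sample_trna,
    template_sequence,
)


def test_seed_alignments_are_deterministic():
    a = build_seed_alignment("bacteria")
    b = build_seed_alignment("bacteria")
    assert a.sequences == b.sequences


def test_sampling_is_deterministic(euk_model):
    assert sample_trna(euk_model, 42) == sample_trna(euk_model, 42)
    assert sample_gene(euk_model, 42)[0] == sample_gene(euk_model, 42)[0]


def test_sampled_lengths_in_trnasec_range(euk_model):
    for seed in range(15):
        seq, struct = sample_trna(euk_model, seed)
        assert 90 <= len(seq) <= 101
        assert len(struct) == len(seq)


def test_sample_structure_matches_realized_pairs(euk_model):
    seq, struct, cmap = sample_gene(euk_model, 77)
    assert struct.count("(") == len([c for c in euk_model.pair_of if
                                     euk_model.pair_of[c] > c])
    assert len(cmap) == euk_model.consensus_length


def test_samples_score_best_under_generating_model(all_models):
    """Cross-entropy: mean bit score is highest under the generating model."""
    gen = all_models[0]   # eukaryota
    scores = {m.domain_tag: [] for m in all_models}
    for seed in range(20):
        seq, _ = sample_trna(gen, 2000 + seed)
        for m in all_models:
            scores[m.domain_tag].append(score_sequence(m, seq)[0])
    means = {k: np.mean(v) for k, v in scores.items()}
    assert means["eukaryota"] > means["bacteria"]
    assert means["eukaryota"] > means["archaea"]


# -- decoys -------------------------------------------------------------------


def test_decoy_is_a_canonical_trna():
    seq, struct = template_sequence("canonical")
    from secscan.cmcore import annotate_structure
    from secscan.cmcore.stockholm import SeedAlignment
    cs, _ = annotate_structure(SeedAlignment(sequences=[("t", seq)],
                                             consensus_structure=struct))
    counts = cs.pair_counts()
    assert counts["A-stem"] + counts["T-stem"] == 12   # 7/5 fold
    assert counts["D-stem"] == 4


def test_decoy_lengths_and_determinism():
    for seed in range(10):
        d = make_decoy_canonical(seed)
        assert 70 <= len(d) <= 80
        assert d == make_decoy_canonical(seed)


def test_decoys_score_below_reporting_threshold(all_models):
    n, below = 30, 0
    for seed in range(n):
        d = make_decoy_canonical(3000 + seed)
        best = max(score_sequence(m, d)[0] for m in all_models)
        below += best < 40.0
    assert below >= 0.95 * n


# -- mutation modes -----------------------------------------------------------


def test_mutate_zero_rate_is_identity(euk_model):
    seq, struct, _ = sample_gene(euk_model, 8)
    assert mutate(seq, struct, 0.0, 1, mode="random") == seq


def test_mutate_rate_bounds(euk_model):
    seq, struct, _ = sample_gene(euk_model, 8)
    with pytest.raises(ValueError):
        mutate(seq, struct, 1.5, 1)


def test_compensatory_mutation_preserves_pairing(euk_model):
    from secscan.alphabet import pairs_canonically
    from secscan.synth import _structure_pairs
    seq, struct, _ = sample_gene(euk_model, 9)
    mut = mutate(seq, struct, 0.0, 2, mode="compensatory", n_pairs=3)
    changed = [i for i, (a, b) in enumerate(zip(seq, mut)) if a != b]
    assert len(changed) == 6   # three pairs, both partners each
    for i, j in _structure_pairs(struct):
        assert pairs_canonically(mut[i], mut[j]) or \
            not pairs_canonically(seq[i], seq[j])


def test_disruptive_mutation_breaks_one_partner(euk_model):
    from secscan.alphabet import pairs_canonically
    from secscan.synth import _structure_pairs
    seq, struct, _ = sample_gene(euk_model, 10)
    mut = mutate(seq, struct, 0.0, 3, mode="disruptive", n_pairs=1)
    changed = [i for i, (a, b) in enumerate(zip(seq, mut)) if a != b]
    assert len(changed) == 1
    broken = [(i, j) for i, j in _structure_pairs(struct)
              if not pairs_canonically(mut[i], mut[j])
              and pairs_canonically(seq[i], seq[j])]
    assert len(broken) == 1


# -- genome assembly ----------------------------------------------------------


def test_genome_generation_is_byte_deterministic():
    spec = SyntheticGenomeSpec(contig_lengths=[800, 400],
                               planted=[PlantedItem(kind="bacteria")], seed=5)
    g1, t1 = make_genome(spec)
    g2, t2 = make_genome(spec)
    assert g1 == g2 and t1 == t2


def test_truth_records_match_planted_sequence(euk_model):
    spec = SyntheticGenomeSpec(contig_lengths=[900],
                               planted=[PlantedItem(kind="eukaryota")], seed=6)
    genome, truth = make_genome(spec)
    t = truth[0]
    gene = genome[t.contig][t.start:t.end]
    score, _ = score_sequence(euk_model, gene)
    assert score > 40.0


def test_requested_gc_content_is_respected():
    spec = SyntheticGenomeSpec(contig_lengths=[20000], gc=0.7, seed=8)
    genome, _ = make_genome(spec)
    seq = genome["contig1"]
    gc = (seq.count("G") + seq.count("C")) / len(seq)
    assert abs(gc - 0.7) < 0.02


def test_overfull_contig_rejected():
    spec = SyntheticGenomeSpec(contig_lengths=[120],
                               planted=[PlantedItem(kind="eukaryota")], seed=9)
    with pytest.raises(ValueError):
        make_genome(spec)


def test_planted_intron_has_requested_length_and_position():
    spec = SyntheticGenomeSpec(
        contig_lengths=[700],
        planted=[PlantedItem(kind="eukaryota", intron_len=16)], seed=10)
    genome, truth = make_genome(spec)
    t = truth[0]
    assert t.intron_end - t.intron_start == 16
    assert t.start < t.intron_start < t.end


# -- property: random-mode mutation is a length/alphabet-preserving map -------

from hypothesis import given, settings
from hypothesis import strategies as st


@settings(max_examples=25, deadline=None, derandomize=True)
@given(rate=st.floats(0.0, 1.0), seed=st.integers(0, 2**20))
def test_random_mutation_preserves_length_and_alphabet(rate, seed):
    from secscan.cmcore import load_bundled_model
    model = load_bundled_model("eukaryota")
    seq, struct, _ = sample_gene(model, 123)
    mut = mutate(seq, struct, rate, seed, mode="random")
    assert len(mut) == len(seq)
    assert set(mut) <= set("ACGT")
    if rate == 0.0:
        assert mut == seq
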