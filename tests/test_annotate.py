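import numpy as np
import pytest

from secscan.alphabet import revcomp
from secscan.annotate import (
    AnnotateError,
    TRNACandidate,
    annotate_hit,
    apply_thresholds,
    classify_copy,
    classify_fold,
    default_arm_minima,
    detect_cca,
    detect_intron,
    extract_anticodon,
    filter_arms,
    find_discriminator,
    parse_arms,
)
from secscan.cmcore import score_sequence
from secscan.scan import GenomicInterval, Hit
from secscan.synth import sample_gene

FLANK = "ACGTTGCA" * 8   # 64 nt of fixed flank


def make_hit(model, gene, strand="+", tail="G", lflank=FLANK, rflank=FLANK):
    """Embed an oriented gene in a one-contig genome and build its Hit."""
    cassette = gene + tail
    fwd = cassette if strand == "+" else revcomp(cassette)
    contig = lflank + fwd + rflank
    if strand == "+":
        iv = GenomicInterval("c1", len(lflank), len(lflank) + len(gene), "+")
    else:
        iv = GenomicInterval("c1", len(lflank) + len(tail),
                             len(lflank) + len(cassette), "-")
    score, _ = score_sequence(model, gene)
    hit = Hit(interval=iv, domain_tag=model.domain_tag, bit_score=score,
              matched_sequence=gene, model=model)
    return hit, {"c1": contig}


def _delete(seq, cmap, cols):
    drop = sorted(cmap[c] for c in cols)
    return "".join(b for i, b in enumerate(seq) if i not in drop)


def _cols(model, *labels):
    return [model.position_map.col(l) for l in labels]


# -- arms ---------------------------------------------------------------------


@pytest.mark.parametrize("name,expect", [
    ("eukaryota", (9, 4)), ("bacteria", (8, 5)), ("archaea", (9, 4))])
def test_arm_counts_of_clean_samples(all_models, name, expect):
    model = next(m for m in all_models if m.domain_tag == name)
    hit, _ = make_hit(model, sample_gene(model, 1)[0])
    arm = parse_arms(hit, model)
    assert (arm.pair_counts["A-stem"], arm.pair_counts["T-stem"]) == expect
    assert arm.at_stem_total == 13


def test_deleted_acceptor_pair_reduces_count(euk_model):
    seq, _, cmap = sample_gene(euk_model, 2)
    # remove the outermost acceptor pair (positions 1 and 72)
    mut = _delete(seq, cmap, _cols(euk_model, "1", "72"))
    hit, _ = make_hit(euk_model, mut)
    arm = parse_arms(hit, euk_model)
    assert arm.pair_counts["A-stem"] == 8


# -- anticodon and thresholds -------------------------------------------------


def test_anticodon_extraction_canonical_and_variant(bact_model):
    hit, _ = make_hit(bact_model, sample_gene(bact_model, 3)[0])
    assert extract_anticodon(hit, bact_model) == "UCA"
    # Geodermatophilaceae-style CUA variant (reads UAG Sec codons)
    hit2, _ = make_hit(bact_model, sample_gene(bact_model, 3, anticodon="CUA")[0])
    assert extract_anticodon(hit2, bact_model) == "CUA"


def test_anticodon_undefined_when_position_deleted(euk_model):
    seq, _, cmap = sample_gene(euk_model, 4)
    mut = _delete(seq, cmap, _cols(euk_model, "35"))
    hit, _ = make_hit(euk_model, mut)
    assert extract_anticodon(hit, euk_model) is None


def _cand(score, anticodon):
    hit = Hit(interval=GenomicInterval("c", 0, 10, "+"), domain_tag=None,
              bit_score=score, matched_sequence="A" * 10)
    return TRNACandidate(hit=hit, anticodon=anticodon)


def test_stringent_threshold_for_non_uca_anticodons():
    cands = [_cand(47.0, "UCA"), _cand(47.0, "CUA"), _cand(60.2, "CUA"),
             _cand(47.0, None)]
    kept = apply_thresholds(cands, T=40.0, T_nonUCA=55.0)
    assert [(c.bit_score, c.anticodon) for c in kept] == \
        [(47.0, "UCA"), (60.2, "CUA")]
    with pytest.raises(AnnotateError):
        apply_thresholds(cands, T=60.0, T_nonUCA=55.0)


# -- arm filter ---------------------------------------------------------------


def _full_candidate(model, gene, **kw):
    hit, genome = make_hit(model, gene, **kw)
    return annotate_hit(hit, genome), genome


def test_clean_samples_pass_default_arm_filter(all_models):
    for model in all_models:
        cand, _ = _full_candidate(model, sample_gene(model, 5)[0])
        assert filter_arms([cand]) == [cand]


def test_missing_variable_arm_is_filtered(euk_model):
    seq, _, cmap = sample_gene(euk_model, 6)
    vcols = [c for c in euk_model.match_cols
             if euk_model.structure.arm[c].startswith("V-")]
    mut = "".join(b for i, b in enumerate(seq)
                  if i not in {cmap[c] for c in vcols if c in cmap})
    hit, genome = make_hit(euk_model, mut)
    cand = annotate_hit(hit, genome)
    assert filter_arms([cand]) == []


def test_truncated_d_stem_is_filtered(euk_model):
    seq, _, cmap = sample_gene(euk_model, 7)
    dpairs = euk_model.structure.stem_pairs("D-stem")
    drop = [c for i, j in dpairs[2:] for c in (i, j)]   # keep only 2 pairs
    mut = _delete(seq, cmap, drop)
    hit, genome = make_hit(euk_model, mut)
    cand = annotate_hit(hit, genome)
    assert cand.arm_annotation.pair_counts["D-stem"] <= 2
    assert filter_arms([cand]) == []


def test_default_minima_follow_consensus(euk_model):
    minima = default_arm_minima(euk_model)
    assert minima == {"A-stem": 7, "D-stem": 4, "C-stem": 4,
                      "V-stem": 2, "T-stem": 2}


# -- discriminator and CCA ----------------------------------------------------


def test_discriminator_is_14_residues_past_position_61(euk_model):
    gene = sample_gene(euk_model, 8)[0]
    hit, genome = make_hit(euk_model, gene, tail="G")
    disc = find_discriminator(hit, genome)
    assert disc is not None and disc[0] == "G"
    pos61 = hit.parse.col_to_pos[euk_model.position_map.col("61")]
    assert disc[1] - (hit.interval.start + pos61) == 14
    cand = annotate_hit(hit, genome)
    assert cand.g73


def test_discriminator_none_at_contig_end(euk_model):
    gene = sample_gene(euk_model, 9)[0]
    hit, genome = make_hit(euk_model, gene, tail="", rflank="")
    assert find_discriminator(hit, genome) is None


def test_discriminator_overshoots_on_12bp_at_stem(bact_model):
    """7/5-fold genes (12-bp AT-stem) break the 13-bp assumption: the fixed
    +14 rule lands one residue 3' of the structural discriminator."""
    seq, _, cmap = sample_gene(bact_model, 10)
    mut = _delete(seq, cmap, _cols(bact_model, "1", "72"))  # 7-bp acceptor stem
    hit, genome = make_hit(bact_model, mut, tail="GCCA")
    cand = annotate_hit(hit, genome)
    assert cand.fold_label == "7/5"
    structural = hit.interval.end      # the G immediately 3' of the gene
    assert cand.discriminator is not None
    assert cand.discriminator[1] == structural + 1
    assert cand.discriminator[0] == "C"     # first base of the CCA tail
    assert cand.discriminator_flagged


def test_cca_detection(bact_model, euk_model):
    hit, genome = make_hit(bact_model, sample_gene(bact_model, 11)[0], tail="GCCA")
    cand = annotate_hit(hit, genome)
    assert cand.cca_tail
    hit2, genome2 = make_hit(euk_model, sample_gene(euk_model, 12)[0], tail="GTTT")
    cand2 = annotate_hit(hit2, genome2)
    assert not cand2.cca_tail


def test_cca_false_when_discriminator_undefined(euk_model, caplog):
    gene = sample_gene(euk_model, 13)[0]
    hit, genome = make_hit(euk_model, gene, tail="", rflank="")
    cand = TRNACandidate(hit=hit)
    with caplog.at_level("WARNING"):
        assert detect_cca(cand, genome) is False
    assert any("discriminator" in r.message for r in caplog.records)


# -- fold classification ------------------------------------------------------


@pytest.mark.parametrize("counts,label,total", [
    ((9, 4), "9/4", 13), ((8, 5), "8/5", 13), ((7, 5), "7/5", 12),
    ((6, 4), "other", 10)])
def test_fold_labels(counts, label, total):
    from secscan.annotate import ArmAnnotation
    arm = ArmAnnotation(pair_counts={"A-stem": counts[0], "T-stem": counts[1]},
                        loop_lengths={}, bulges=[])
    assert classify_fold(arm) == label
    assert arm.at_stem_total == total


# -- introns ------------------------------------------------------------------


@pytest.mark.parametrize("ilen", [16, 25])
def test_intron_detected_one_base_past_anticodon(euk_model, ilen):
    seq, _, cmap = sample_gene(euk_model, 14)
    point = cmap[euk_model.position_map.col("37")] + 1
    rng = np.random.default_rng(ilen)
    intron = "".join("ACGT"[i] for i in rng.integers(4, size=ilen))
    with_intron = seq[:point] + intron + seq[point:]
    hit, genome = make_hit(euk_model, with_intron)
    res = detect_intron(hit)
    assert res is not None
    iv, mature = res
    assert iv.length == ilen
    assert len(mature) == len(with_intron) - ilen
    # the residue between the anticodon and the intron is position 37
    pos36 = hit.parse.col_to_pos[euk_model.position_map.col("36")]
    assert (iv.start - hit.interval.start) - (pos36 + 1) == 1


def test_clean_candidate_has_no_intron(euk_model):
    hit, _ = make_hit(euk_model, sample_gene(euk_model, 15)[0])
    assert detect_intron(hit) is None


def test_spliced_mature_sequence_scores_at_least_unspliced(euk_model):
    seq, _, cmap = sample_gene(euk_model, 16)
    point = cmap[euk_model.position_map.col("37")] + 1
    with_intron = seq[:point] + "TTGCATGCATGCAAGT" + seq[point:]
    hit, genome = make_hit(euk_model, with_intron)
    cand = annotate_hit(hit, genome)
    assert cand.intron is not None
    assert len(cand.mature_sequence) == len(with_intron) - cand.intron.length
    mature_score, _ = score_sequence(euk_model, cand.mature_sequence)
    full_score, _ = score_sequence(euk_model, with_intron)
    assert mature_score >= full_score


# -- copy classification ------------------------------------------------------


def _pair_bases(model, seq, cmap, stem="A-stem"):
    for i, j in model.structure.stem_pairs(stem):
        yield i, j, cmap[i], cmap[j]


def test_copy_identical_requires_matching_flanks(euk_model):
    gene = sample_gene(euk_model, 17)[0]
    hit1, genome = make_hit(euk_model, gene)
    top = annotate_hit(hit1, genome)
    copy = annotate_hit(hit1, genome)
    klass, _ = classify_copy(copy, top, euk_model, genome=genome)
    assert klass == "identical"


def test_copy_compensatory_double_substitution(euk_model):
    seq, _, cmap = sample_gene(euk_model, 18)
    for i, j, pi, pj in _pair_bases(euk_model, seq, cmap):
        if seq[pi] == "G" and seq[pj] == "C":
            mut = list(seq)
            mut[pi], mut[pj] = "A", "T"     # G-C -> A-U, still paired
            mut = "".join(mut)
            break
    else:
        pytest.skip("no G-C acceptor pair in this sample")
    top, genome = _full_candidate(euk_model, seq)
    copy, _ = _full_candidate(euk_model, mut)
    klass, details = classify_copy(copy, top, euk_model)
    assert klass == "compensatory"
    assert any(d.klass == "compensatory" and (d.lcol, d.rcol) == (i, j)
               for d in details)


def test_copy_with_broken_pair_is_disrupted(euk_model):
    seq, _, cmap = sample_gene(euk_model, 19)
    i, j, pi, pj = next(_pair_bases(euk_model, seq, cmap))
    mut = list(seq)
    mut[pi] = mut[pj] = "C"                 # C-C cannot pair
    top, genome = _full_candidate(euk_model, seq)
    copy, _ = _full_candidate(euk_model, "".join(mut))
    klass, details = classify_copy(copy, top, euk_model)
    assert klass == "disrupted"


def test_copy_classification_symmetric_per_pair(euk_model):
    from secscan.synth import mutate
    seq, struct, _ = sample_gene(euk_model, 20)
    mut = mutate(seq, struct, 0.0, 99, mode="disruptive", n_pairs=2)
    top, _ = _full_candidate(euk_model, seq)
    copy, _ = _full_candidate(euk_model, mut)
    _, d1 = classify_copy(copy, top, euk_model)
    _, d2 = classify_copy(top, copy, euk_model)
    assert {(p.lcol, p.rcol): p.klass for p in d1} == \
        {(p.lcol, p.rcol): p.klass for p in d2}


def test_copies_from_different_genomes_rejected(euk_model):
    gene = sample_gene(euk_model, 21)[0]
    a, _ = _full_candidate(euk_model, gene)
    b, _ = _full_candidate(euk_model, gene)
    a.genome_id, b.genome_id = "g1", "g2"
    with pytest.raises(AnnotateError):
        classify_copy(a, b, euk_model)


# -- rendering ----------------------------------------------------------------


def test_cloverleaf_svg_has_five_arms_and_two_circles(euk_model):
    from secscan.render import render_cloverleaf
    cand, _ = _full_candidate(euk_model, sample_gene(euk_model, 22)[0])
    text, svg = render_cloverleaf(cand)
    assert all(f'id="arm-{k}"' in svg for k in "ADCVT")
    assert 'id="anticodon-circle"' in svg and 'id="discriminator-circle"' in svg


def test_cloverleaf_without_discriminator_circles_only_anticodon(euk_model):
    from secscan.render import render_svg
    gene = sample_gene(euk_model, 23)[0]
    hit, genome = make_hit(euk_model, gene, tail="", rflank="")
    cand = annotate_hit(hit, genome)
    assert cand.discriminator is None
    svg = render_svg(cand)
    assert 'id="anticodon-circle"' in svg
    assert 'id="discriminator-circle"' not in svg


def test_text_rendering_is_deterministic(bact_model):
    from secscan.render import render_text
    cand, _ = _full_candidate(bact_model, sample_gene(bact_model, 24)[0],
                              tail="GCCA")
    assert render_text(cand) == render_text(cand)
    assert "anticodon (UCA)" in render_text(cand)
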