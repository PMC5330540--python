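import numpy as np
import pytest

from secscan.alphabet import revcomp
from secscan.scan import (
    GenomicInterval,
    Hit,
    ScanConfig,
    ScanError,
    assign_domain,
    resolve_overlaps,
    scan_genome,
)
from secscan.synth import PlantedItem, SyntheticGenomeSpec, make_genome


def _hit(start, end, score, strand="+", tag="eukaryota", contig="c1"):
    return Hit(interval=GenomicInterval(contig, start, end, strand),
               domain_tag=tag, bit_score=score, matched_sequence="")


@pytest.fixture(scope="module")
def planted_genome():
    spec = SyntheticGenomeSpec(contig_lengths=[3000],
                               planted=[PlantedItem(kind="eukaryota")], seed=11)
    return make_genome(spec)


@pytest.fixture(scope="module")
def planted_hits(planted_genome, all_models):
    genome, _ = planted_genome
    return scan_genome(genome, all_models)


def test_planted_gene_recovered_with_exact_coordinates(planted_genome,
                                                       planted_hits):
    genome, truth = planted_genome
    resolved = resolve_overlaps(planted_hits)
    assert len(resolved) == 1
    h = resolved[0]
    t = truth[0]
    assert (h.interval.start, h.interval.end, h.interval.strand) == \
        (t.start, t.end, t.strand)
    assert h.domain_tag == "eukaryota"


def test_coordinates_roundtrip_to_matched_sequence(planted_genome, planted_hits):
    genome, _ = planted_genome
    for h in resolve_overlaps(planted_hits):
        seq = genome[h.interval.contig][h.interval.start:h.interval.end]
        if h.interval.strand == "-":
            seq = revcomp(seq)
        assert seq.upper() == h.matched_sequence.upper()


def test_threshold_monotonicity(planted_genome, all_models, planted_hits):
    genome, _ = planted_genome
    strict = scan_genome(genome, all_models, ScanConfig(threshold=60.0,
                                                        stringent_threshold=60.0))
    base_keys = {(h.interval, h.domain_tag) for h in planted_hits}
    strict_keys = {(h.interval, h.domain_tag) for h in strict}
    assert strict_keys <= base_keys
    assert all(h.bit_score >= 60.0 for h in strict)


def test_reverse_strand_gene_found_on_minus(all_models):
    spec = SyntheticGenomeSpec(contig_lengths=[1200],
                               planted=[PlantedItem(kind="bacteria", strand="-")],
                               seed=23)
    genome, truth = make_genome(spec)
    resolved = resolve_overlaps(scan_genome(genome, all_models))
    assert len(resolved) == 1
    assert resolved[0].interval.strand == "-"
    assert (resolved[0].interval.start, resolved[0].interval.end) == \
        (truth[0].start, truth[0].end)


def test_null_genome_yields_no_hits(all_models):
    spec = SyntheticGenomeSpec(contig_lengths=[12000], planted=[], seed=7)
    genome, _ = make_genome(spec)
    assert scan_genome(genome, all_models) == []


def test_multi_contig_scan_equals_union_of_per_contig_scans(all_models):
    model = all_models[:1]
    spec = SyntheticGenomeSpec(contig_lengths=[900, 900],
                               planted=[PlantedItem(kind="eukaryota", contig=0),
                                        PlantedItem(kind="eukaryota", contig=1)],
                               seed=31)
    genome, _ = make_genome(spec)
    together = scan_genome(genome, model)
    apart = scan_genome({"contig1": genome["contig1"]}, model) + \
        scan_genome({"contig2": genome["contig2"]}, model)
    assert {(h.interval, round(h.bit_score, 3)) for h in together} == \
        {(h.interval, round(h.bit_score, 3)) for h in apart}


def test_empty_genome_and_missing_models_rejected(all_models):
    with pytest.raises(ScanError):
        scan_genome({}, all_models)
    with pytest.raises(ScanError):
        scan_genome({"c": "ACGT" * 100}, [])


def test_short_contig_skipped_with_warning(all_models, caplog):
    genome = {"tiny": "ACGTACGT", "ok": "ACGT" * 250}
    with caplog.at_level("WARNING"):
        scan_genome(genome, all_models[:1])
    assert any("tiny" in r.message for r in caplog.records)


def test_config_validation():
    with pytest.raises(ScanError):
        ScanConfig(threshold=60.0, stringent_threshold=55.0)
    with pytest.raises(ScanError):
        ScanConfig(threshold=-1.0)


# -- overlap resolution ------------------------------------------------------


def test_overlap_max_score_survives():
    a, b = _hit(100, 190, 62.1), _hit(150, 240, 55.0)
    out = resolve_overlaps([a, b])
    assert out == [a]


def test_opposite_strands_do_not_compete():
    a, b = _hit(100, 190, 62.1, "+"), _hit(100, 190, 55.0, "-")
    assert len(resolve_overlaps([a, b])) == 2


def test_nonoverlapping_hits_all_survive():
    a, b = _hit(100, 190, 62.1), _hit(190, 280, 55.0)  # half-open: no overlap
    assert len(resolve_overlaps([a, b])) == 2


def test_tie_break_longer_then_domain_then_leftmost():
    # equal score: longer interval wins
    a, b = _hit(100, 200, 50.0), _hit(100, 190, 50.0)
    assert resolve_overlaps([a, b]) == [a]
    # equal score and length: eukaryota preferred over bacteria over archaea
    e = _hit(100, 190, 50.0, tag="eukaryota")
    b2 = _hit(100, 190, 50.0, tag="bacteria")
    r = _hit(100, 190, 50.0, tag="archaea")
    assert resolve_overlaps([r, b2, e]) == [e]
    # everything equal except position: leftmost start wins
    l1, l2 = _hit(100, 190, 50.0), _hit(101, 191, 50.0)
    assert resolve_overlaps([l1, l2]) == [l1]


def test_assign_domain_is_argmax():
    cluster = [_hit(0, 90, 71.2, tag="eukaryota"), _hit(0, 90, 58.9, tag="bacteria")]
    assert assign_domain(cluster) == "eukaryota"
    assert assign_domain(cluster[:1]) == "eukaryota"
    with pytest.raises(ScanError):
        assign_domain([])


def test_cross_model_discrimination_on_sampled_genes(all_models):
    """Sequences sampled from the bacterial model should be labeled bacteria."""
    from secscan.cmcore import score_sequence
    from secscan.synth import sample_gene
    bact = next(m for m in all_models if m.domain_tag == "bacteria")
    wins = 0
    n = 25
    for seed in range(n):
        seq, _, _ = sample_gene(bact, 7000 + seed)
        scores = {m.domain_tag: score_sequence(m, seq)[0] for m in all_models}
        wins += max(scores, key=scores.get) == "bacteria"
    assert wins >= 0.95 * n
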