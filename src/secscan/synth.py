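"""Synthetic-data generation: seed alignments, model sampling, genomes.

This module defines the study conditions for everything testable without
downloads: it constructs the bundled domain seed alignments (eukaryota
9/4 fold with a 6-bp D-stem, bacteria 8/5 with a 6-bp D-stem, archaea
9/4 with a 7-bp D-stem, all with a 13-bp AT-stem, plus a canonical 7/5
tRNA used as decoy), samples sequences from covariance models, plants
genes and decoys in iid background genomes, and injects substitutions,
compensatory/disruptive pair mutations and C-loop introns, emitting
truth files alongside.

Sequences produced here use the DNA alphabet (T); scoring treats T and U
as identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from secscan.alphabet import revcomp, to_dna
from secscan.cmcore.model import CovarianceModel
from secscan.cmcore.stockholm import SeedAlignment, write_stockholm
from secscan.cmcore.structure import annotate_structure

_NT = "ACGT"
_WC = {"A": "T", "T": "A", "C": "G", "G": "C"}
_WC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
_PAIRING = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"), ("G", "T"), ("T", "G")}

# ---------------------------------------------------------------------------
# seed templates: (segment name, 5'->3' sequence) with '<'/'>' stem marks.
# D-loop carries G18/G19, the anticodon loop is C-U-[anticodon]-x-x with U33,
# the T-loop ends at position 61, and stems are perfect Watson-Crick helixes.
# ---------------------------------------------------------------------------


def _arm(seq5: str, loop: str, *, close: str | None = None) -> list[tuple[str, str]]:
    seq3 = close if close is not None else revcomp(seq5)
    return [(seq5, "<"), (loop, "."), (seq3, ">")]


def _template(domain: str) -> list[tuple[str, str]]:
    if domain == "eukaryota":
        a5, d5, c5, v5, t5 = "GCCCGGGTG", "GCGGAT", "CCGGAT", "GGCTGGG", "GGTC"
        dloop, cloop, vloop, tloop = "AGGA", "CTTCAAA", "TTCAA", "TTCGAAT"
        link_ad, link_dc, link_vt = "AT", "G", "A"
    elif domain == "bacteria":
        a5, d5, c5, v5, t5 = "GGAAGATC", "TCCGGT", "GGGCTT", "CCGTGGG", "GGTCC"
        dloop, cloop, vloop, tloop = "AGGT", "CTTCAAG", "CGCAA", "TTCGACT"
        link_ad, link_dc, link_vt = "GA", "A", "T"
    elif domain == "archaea":
        a5, d5, c5, v5, t5 = "GCGGGAGTG", "CGCCGGT", "GCCCGT", "GCCGGTG", "GGGT"
        dloop, cloop, vloop, tloop = "AGGA", "CTTCAAA", "CTTTA", "TTCAAAT"
        link_ad, link_dc, link_vt = "CA", "G", "C"
    elif domain == "canonical":
        # 7/5 fold, 4-bp D-stem, long D-loop, short V arm; Ser-style GCT anticodon
        a5, d5, c5, v5, t5 = "GCAGCCA", "GCTC", "GCAGG", "GGC", "CGGTC"
        dloop, cloop, vloop, tloop = "AGGTAAAG", "CTGCTAA", "AGTT", "TTCGATT"
        link_ad, link_dc, link_vt = "GT", "A", ""
    else:
        raise ValueError(f"unknown template {domain!r}")
    segs: list[tuple[str, str]] = [(a5, "<"), (link_ad, ".")]
    segs += _arm(d5, dloop)
    segs += [(link_dc, ".")]
    segs += _arm(c5, cloop)
    segs += _arm(v5, vloop)
    segs += [(link_vt, ".")]
    segs += _arm(t5, tloop)
    segs += [(revcomp(a5), ">")]
    return segs


def template_sequence(domain: str) -> tuple[str, str]:
    """Consensus sequence and WUSS structure string for a domain template."""
    segs = _template(domain)
    seq = "".join(s for s, _ in segs)
    struct = "".join(m * len(s) for s, m in segs)
    return seq, struct


def build_seed_alignment(domain: str, nseq: int = 32,
                         seed: int = 20240601) -> SeedAlignment:
    """Deterministic gap-free seed alignment around the domain template.

    Row 1 is the template; later rows carry two compensatory pair swaps
    plus a loop substitution away from the invariant positions (G18/G19,
    U33, the UCA anticodon).  Depth and divergence are chosen so that
    model-sampled sequences score well clear of the 40-bit reporting
    threshold while stems stay informative for covariation.
    """
    offset = {"eukaryota": 1, "bacteria": 2, "archaea": 3, "canonical": 4}[domain]
    rng = np.random.default_rng(seed + offset)
    seq, struct = template_sequence(domain)
    base = SeedAlignment(sequences=[("tpl", seq)], consensus_structure=struct,
                         domain_tag=None if domain == "canonical" else domain)
    cs, pmap = annotate_structure(base)
    frozen_labels = {"18", "19", "33", "34", "35", "36"}
    frozen = {pmap.label_to_col[l] for l in frozen_labels if l in pmap.label_to_col}
    pairs = sorted((i, j) for i, j in cs.pair_partner.items() if i < j)
    unpaired = [c for c in cs.match_cols
                if c not in cs.pair_partner and c not in frozen]

    rows = [(f"{domain[:3]}1", seq)]
    for k in range(1, nseq):
        row = list(seq)
        for i, j in [pairs[t] for t in rng.choice(len(pairs), size=2, replace=False)]:
            old = (row[i], row[j])
            choices = [p for p in _WC_PAIRS if p != old]
            x, y = choices[rng.integers(len(choices))]
            row[i], row[j] = x, y
        for c in rng.choice(unpaired, size=1, replace=False):
            row[c] = _NT[rng.integers(4)]
        rows.append((f"{domain[:3]}{k + 1}", "".join(row)))

    labels = [pmap.col_to_label.get(c) for c in range(len(seq))]
    return SeedAlignment(sequences=rows, consensus_structure=struct,
                         position_labels=labels,
                         domain_tag=None if domain == "canonical" else domain,
                         name=f"tRNA-Sec-{domain}" if domain != "canonical"
                         else "tRNA-canonical")


def regenerate_bundled_seeds(outdir) -> None:
    """Write the four bundled seed Stockholm files into a directory."""
    from pathlib import Path
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for domain in ("eukaryota", "bacteria", "archaea", "canonical"):
        (out / f"{domain}.stk").write_text(write_stockholm(build_seed_alignment(domain)))


# ---------------------------------------------------------------------------
# sampling from a model
# ---------------------------------------------------------------------------


def _sample_walk(model: CovarianceModel, rng: np.random.Generator
                 ) -> tuple[str, list[tuple[int, int]], dict[int, int]]:
    """Emit one sequence from the model's joint distribution.

    Returns (sequence, realized pair positions, match-column -> position).
    """
    states = model.states
    nodes = model.nodes

    def gen(v: int) -> tuple[list[str], list[tuple[int, int]], dict[int, int]]:
        s = states[v]
        if s.kind == "E":
            return [], [], {}
        if s.kind == "B":
            lseq, lp, lm = gen(s.children[0])
            rseq, rp, rm = gen(s.children[1])
            off = len(lseq)
            pairs = lp + [(i + off, j + off) for i, j in rp]
            cmap = dict(lm)
            cmap.update({c: p + off for c, p in rm.items()})
            return lseq + rseq, pairs, cmap
        left: list[str] = []
        right: list[str] = []
        pair_here = False
        n = nodes[s.node]
        cmap: dict[int, int] = {}
        if s.kind == "MP":
            flat = np.asarray(s.emit_prob).ravel()
            idx = rng.choice(16, p=flat / flat.sum())
            left, right = [_NT[idx // 4]], [_NT[idx % 4]]
            pair_here = True
        elif s.kind in ("ML", "IL"):
            p = np.asarray(s.emit_prob)
            left = [_NT[rng.choice(4, p=p / p.sum())]]
        elif s.kind in ("MR", "IR"):
            p = np.asarray(s.emit_prob)
            right = [_NT[rng.choice(4, p=p / p.sum())]]
        nxt = s.children[rng.choice(len(s.children), p=s.t_prob)]
        inner, pairs, inner_map = gen(nxt)
        seq = left + inner + right
        pairs = [(i + len(left), j + len(left)) for i, j in pairs]
        cmap = {c: p + len(left) for c, p in inner_map.items()}
        if pair_here:
            pairs.append((0, len(seq) - 1))
            cmap[n.lcol] = 0
            cmap[n.rcol] = len(seq) - 1
        elif s.kind == "ML" and n.kind == "MATL":
            cmap[n.lcol] = 0
        elif s.kind == "MR" and n.kind == "MATR":
            cmap[n.rcol] = len(seq) - 1
        return seq, pairs, cmap

    seq, pairs, cmap = gen(model.root_state)
    return "".join(seq), sorted(pairs), cmap


def _sample_main_path(model: CovarianceModel, rng: np.random.Generator
                      ) -> tuple[str, list[tuple[int, int]], dict[int, int]]:
    """Emit a sequence along the consensus (indel-free) path.

    Emissions are drawn from the match-state distributions; transitions
    are pinned to the match path, so the result realizes every consensus
    column ("error-free" sample).
    """
    seq: list[str] = []
    pairs: list[tuple[int, int]] = []
    cmap: dict[int, int] = {}

    def gen(nidx: int) -> tuple[list[str], list[tuple[int, int]], dict[int, int]]:
        n = model.nodes[nidx]
        if n.kind == "END":
            return [], [], {}
        if n.kind == "BIF":
            ls, lp, lm = gen(n.bif_left)
            rs, rp, rm = gen(n.bif_right)
            off = len(ls)
            return (ls + rs, lp + [(i + off, j + off) for i, j in rp],
                    {**lm, **{c: p + off for c, p in rm.items()}})
        left: list[str] = []
        right: list[str] = []
        cm: dict[int, int] = {}
        if n.kind == "MATP":
            s = model.states[model.state_id[(nidx, "MP")]]
            flat = np.asarray(s.emit_prob).ravel()
            idx = rng.choice(16, p=flat / flat.sum())
            left, right = [_NT[idx // 4]], [_NT[idx % 4]]
        elif n.kind == "MATL":
            s = model.states[model.state_id[(nidx, "ML")]]
            p = np.asarray(s.emit_prob)
            left = [_NT[rng.choice(4, p=p / p.sum())]]
        elif n.kind == "MATR":
            s = model.states[model.state_id[(nidx, "MR")]]
            p = np.asarray(s.emit_prob)
            right = [_NT[rng.choice(4, p=p / p.sum())]]
        inner, ip, im = gen(n.child)
        out = left + inner + right
        ip = [(i + len(left), j + len(left)) for i, j in ip]
        cm = {c: p + len(left) for c, p in im.items()}
        if n.kind == "MATP":
            ip.append((0, len(out) - 1))
            cm[n.lcol] = 0
            cm[n.rcol] = len(out) - 1
        elif n.kind == "MATL":
            cm[n.lcol] = 0
        elif n.kind == "MATR":
            cm[n.rcol] = len(out) - 1
        return out, ip, cm

    seq, pairs, cmap = gen(0)
    return "".join(seq), sorted(pairs), cmap


def sample_trna(model: CovarianceModel, seed: int, with_map: bool = False):
    """Sample (sequence, dot-bracket structure) from the model; reproducible.

    With ``with_map=True`` also returns the match-column -> sequence
    position mapping of the generating parse.
    """
    rng = np.random.default_rng(seed)
    seq, pairs, cmap = _sample_walk(model, rng)
    struct = ["."] * len(seq)
    for i, j in pairs:
        struct[i] = "("
        struct[j] = ")"
    if with_map:
        return seq, "".join(struct), cmap
    return seq, "".join(struct)


def sample_gene(model: CovarianceModel, seed: int, anticodon: str = "UCA"
                ) -> tuple[str, str, dict[int, int]]:
    """Sample an error-free gene: consensus path, pinned anticodon.

    Emissions come from the model, but the parse follows the consensus
    path (no indels), every stem pair is canonical (WC/GU, redrawn from
    the restricted pair distribution when the free draw mismatches) and
    the anticodon is fixed (UCA, or a variant such as CUA for non-UGA
    Sec codons) — the properties of a functional tRNA-Sec gene.
    Mutations and introns are applied separately and explicitly.
    """
    rng0 = np.random.default_rng(seed)
    seq, pairs, cmap = _sample_main_path(model, rng0)
    struct = ["."] * len(seq)
    for i, j in pairs:
        struct[i] = "("
        struct[j] = ")"
    struct = "".join(struct)
    row = list(seq)
    # stems of a functional tRNA pair (WC or GU): redraw any sampled
    # mismatch from the pair emission distribution restricted to
    # canonically pairing cells
    rng = np.random.default_rng(seed + 10**6)
    emit_by_cols = {}
    for s in model.states:
        if s.kind == "MP":
            n = model.nodes[s.node]
            emit_by_cols[(n.lcol, n.rcol)] = np.asarray(s.emit_prob)
    for (lcol, rcol), prob in emit_by_cols.items():
        if lcol not in cmap or rcol not in cmap:
            continue
        i, j = cmap[lcol], cmap[rcol]
        if (row[i], row[j]) in _PAIRING:
            continue
        cells = [(a, b) for a in range(4) for b in range(4)
                 if (_NT[a], _NT[b]) in _PAIRING]
        w = np.array([prob[a, b] for a, b in cells])
        a, b = cells[rng.choice(len(cells), p=w / w.sum())]
        row[i], row[j] = _NT[a], _NT[b]
    for lbl, base in zip(("34", "35", "36"), to_dna(anticodon)):
        col = model.position_map.col(lbl)
        if col is None or col not in cmap:
            raise ValueError("model cannot pin the anticodon (missing 34-36)")
        row[cmap[col]] = base
    return "".join(row), struct, cmap


def make_decoy_canonical(seed: int) -> str:
    """A canonical (7/5 fold, 4-bp D-stem) tRNA-like decoy sequence."""
    from secscan.cmcore import load_bundled_model
    seq, _ = sample_trna(load_bundled_model("canonical"), seed)
    return seq


# ---------------------------------------------------------------------------
# mutation modes
# ---------------------------------------------------------------------------


def _structure_pairs(structure: str) -> list[tuple[int, int]]:
    stack: list[int] = []
    pairs = []
    for i, ch in enumerate(structure):
        if ch in "(<[{":
            stack.append(i)
        elif ch in ")>]}":
            pairs.append((stack.pop(), i))
    return sorted(pairs)


def mutate(seq: str, structure: str, sub_rate: float, seed: int,
           mode: str = "random", n_pairs: int = 1) -> str:
    """Mutate a sequence with knowledge of its secondary structure.

    random: iid substitutions at ``sub_rate``.  compensatory: ``n_pairs``
    paired positions rewritten jointly to a different Watson-Crick pair.
    disruptive: one partner of each of ``n_pairs`` pairs mutated so the
    pair no longer forms (no WC, no GU).
    """
    if not 0.0 <= sub_rate <= 1.0:
        raise ValueError("sub_rate must be within [0, 1]")
    rng = np.random.default_rng(seed)
    row = list(to_dna(seq))
    if mode == "random":
        for i in range(len(row)):
            if rng.random() < sub_rate:
                row[i] = _NT[(rng.choice(3) + 1 + _NT.index(row[i])) % 4] \
                    if row[i] in _NT else _NT[rng.integers(4)]
        return "".join(row)
    # only positions that currently pair canonically carry a structural signal
    pairs = [(i, j) for i, j in _structure_pairs(structure)
             if (row[i], row[j]) in _PAIRING]
    if not pairs:
        raise ValueError(f"{mode} mode needs canonically paired positions")
    chosen = [pairs[t] for t in rng.choice(len(pairs), size=min(n_pairs, len(pairs)),
                                           replace=False)]
    if mode == "compensatory":
        for i, j in chosen:
            old = (row[i], row[j])
            opts = [(x, y) for x, y in _WC_PAIRS if x != old[0] and y != old[1]]
            x, y = opts[rng.integers(len(opts))]
            row[i], row[j] = x, y
    elif mode == "disruptive":
        for i, j in chosen:
            partner = row[j]
            opts = [x for x in _NT
                    if (x, partner) not in _PAIRING and x != row[i]]
            row[i] = opts[rng.integers(len(opts))]
    else:
        raise ValueError(f"unknown mutation mode {mode!r}")
    return "".join(row)


# ---------------------------------------------------------------------------
# genome assembly
# ---------------------------------------------------------------------------


@dataclass
class PlantedItem:
    """One gene or decoy to plant in a synthetic genome."""

    kind: str                      # 'eukaryota' | 'bacteria' | 'archaea' | 'decoy'
    strand: str = "+"
    contig: int = 0
    mutation_mode: str | None = None
    sub_rate: float = 0.0
    n_pairs: int = 1
    intron_len: int = 0
    anticodon: str = "UCA"
    disc_base: str = "G"
    cca: bool | None = None        # default: genomic CCA for bacteria only


@dataclass
class TruthRecord:
    contig: str
    start: int                     # 0-based half-open, forward strand
    end: int
    strand: str
    kind: str
    mutation: str
    intron_start: int = -1         # forward-strand coords, -1 if absent
    intron_end: int = -1
    seed: int = 0


@dataclass
class SyntheticGenomeSpec:
    contig_lengths: list[int]
    planted: list[PlantedItem] = field(default_factory=list)
    gc: float = 0.5
    seed: int = 1
    contig_prefix: str = "contig"


def _background(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p)


def _planted_sequence(item: PlantedItem, seed: int
                      ) -> tuple[str, int, int]:
    """Forward-orientation planted cassette.

    Returns (sequence, gene length within cassette, intron offset) where
    the gene occupies the cassette prefix [0, gene_len) and the trailing
    discriminator/CCA bases extend past it.
    """
    from secscan.cmcore import load_bundled_model
    if item.kind == "decoy":
        seq = make_decoy_canonical(seed)
        return seq, len(seq), -1
    model = load_bundled_model(item.kind)
    seq, struct, cmap = sample_gene(model, seed, anticodon=item.anticodon)
    if item.mutation_mode:
        seq = mutate(seq, struct, item.sub_rate, seed + 1,
                     mode=item.mutation_mode, n_pairs=item.n_pairs)
    intron_at = -1
    if item.intron_len > 0:
        col37 = model.position_map.col("37")
        if col37 is None or col37 not in cmap:
            raise ValueError("cannot place intron: position 37 not emitted")
        intron_at = cmap[col37] + 1    # one base 3' of position 37
        rng = np.random.default_rng(seed + 2)
        intron = "".join(_NT[i] for i in rng.integers(4, size=item.intron_len))
        seq = seq[:intron_at] + intron + seq[intron_at:]
    gene_len = len(seq)
    cca = item.cca if item.cca is not None else item.kind == "bacteria"
    tail = item.disc_base + ("CCA" if cca else "")
    return seq + tail, gene_len, intron_at


def make_genome(spec: SyntheticGenomeSpec
                ) -> tuple[dict[str, str], list[TruthRecord]]:
    """Build contigs with planted items; return sequences and truth records."""
    rng = np.random.default_rng(spec.seed)
    contigs = [_background(rng, ln, spec.gc) for ln in spec.contig_lengths]
    truth: list[TruthRecord] = []
    by_contig: dict[int, list[PlantedItem]] = {}
    for item in spec.planted:
        by_contig.setdefault(item.contig, []).append(item)
    for ci, items in sorted(by_contig.items()):
        if ci >= len(contigs):
            raise ValueError(f"planted item refers to missing contig {ci}")
        ln = spec.contig_lengths[ci]
        nslots = len(items)
        slot = ln // nslots
        for k, item in enumerate(items):
            item_seed = int(rng.integers(2**31))
            cassette, gene_len, intron_at = _planted_sequence(item, item_seed)
            margin = 25
            if len(cassette) + 2 * margin > slot:
                raise ValueError("planted items exceed contig capacity")
            start = k * slot + margin + int(rng.integers(slot - len(cassette) - 2 * margin))
            fwd = cassette if item.strand == "+" else revcomp(cassette)
            # on '-' the cassette 3' tail (disc/CCA) precedes the gene in
            # forward coordinates
            arr = np.array([_NT.index(c) if c in _NT else 0 for c in fwd])
            contigs[ci][start:start + len(arr)] = arr
            if item.strand == "+":
                gstart, gend = start, start + gene_len
                istart = start + intron_at if intron_at >= 0 else -1
            else:
                gstart = start + (len(cassette) - gene_len)
                gend = start + len(cassette)
                istart = (gend - intron_at - item.intron_len) if intron_at >= 0 else -1
            truth.append(TruthRecord(
                contig=f"{spec.contig_prefix}{ci + 1}",
                start=gstart, end=gend, strand=item.strand, kind=item.kind,
                mutation=item.mutation_mode or "none",
                intron_start=istart,
                intron_end=istart + item.intron_len if istart >= 0 else -1,
                seed=item_seed))
    seqs = {f"{spec.contig_prefix}{i + 1}": "".join(_NT[b] for b in arr)
            for i, arr in enumerate(contigs)}
    return seqs, truth
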