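"""Model training: sequence filtering, folding, iterative align-rebuild.

Mirrors how the domain models were curated: candidate training
sequences are screened for structural plausibility and a UCA anticodon,
then the alignment is refined by repeatedly aligning all sequences to
the current model and rebuilding the model from the induced alignment
until the alignment is stable.  Folding is maximum base pairing
(Nussinov-style, minimum hairpin loop 3) with an adapter point for an
external thermodynamic folder.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from secscan.alphabet import to_dna
from secscan.cmcore.cyk import score_sequence
from secscan.cmcore.model import CovarianceModel, build_model
from secscan.cmcore.stockholm import SeedAlignment

logger = logging.getLogger(__name__)

_PAIR_OK = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"), ("G", "T"), ("T", "G")}


class TrainingError(ValueError):
    pass


@dataclass
class TrainingSet:
    sequences: list[tuple[str, str]]
    domain_tag: str | None = None

    def __post_init__(self) -> None:
        for sid, seq in self.sequences:
            if not 60 <= len(seq) <= 130:
                raise TrainingError(
                    f"training sequence {sid!r} length {len(seq)} outside 60-130")


def _anticodon_of(model: CovarianceModel, seq: str) -> tuple[float, str | None]:
    score, parse = score_sequence(model, seq)
    cols = model.position_map.anticodon_columns()
    bases = []
    for c in cols:
        pos = parse.col_to_pos.get(c)
        if pos is None:
            return score, None
        bases.append(to_dna(seq)[pos])
    return score, "".join(bases).replace("T", "U")


def filter_training(seqs: TrainingSet, model: CovarianceModel,
                    min_score: float = 0.0) -> TrainingSet:
    """Keep structurally plausible sequences with a UCA anticodon.

    Sequences scoring below ``min_score`` bits on the bootstrap model or
    with an anticodon other than UCA are discarded; an empty result is
    an error.
    """
    kept, dropped = [], 0
    for sid, seq in seqs.sequences:
        score, ac = _anticodon_of(model, seq)
        if score >= min_score and ac == "UCA":
            kept.append((sid, seq))
        else:
            dropped += 1
    logger.info("filter_training: kept %d, discarded %d", len(kept), dropped)
    if not kept:
        raise TrainingError("no training sequences left after filtering")
    return TrainingSet(sequences=kept, domain_tag=seqs.domain_tag)


# ---------------------------------------------------------------------------
# maximum base-pair folding
# ---------------------------------------------------------------------------


def fold_sequence(seq: str, min_hairpin: int = 3) -> str:
    """Nussinov maximum-pairing fold (WC + GU), dot-bracket output.

    Deterministic tie-break: a 5' base is paired whenever pairing does
    not lose pairs, with the 5'-most admissible partner preferred.
    """
    s = to_dna(seq)
    n = len(s)
    if n < 10:
        raise ValueError("sequence too short to fold (need >= 10 nt)")
    N = np.zeros((n + 1, n + 1), dtype=np.int32)   # N[i][j]: best pairs in s[i:j]
    for span in range(2, n + 1):
        for i in range(0, n - span + 1):
            j = i + span
            best = N[i + 1][j]
            for k in range(i + min_hairpin + 1, j):
                if (s[i], s[k]) in _PAIR_OK:
                    cand = 1 + N[i + 1][k] + N[k + 1][j]
                    if cand > best:
                        best = cand
            N[i][j] = best
    out = ["."] * n
    stack = [(0, n)]
    while stack:
        i, j = stack.pop()
        if j - i < 2:
            continue
        paired = False
        for k in range(i + min_hairpin + 1, j):
            if (s[i], s[k]) in _PAIR_OK and 1 + N[i + 1][k] + N[k + 1][j] == N[i][j]:
                out[i], out[k] = "(", ")"
                stack.append((k + 1, j))
                stack.append((i + 1, k))
                paired = True
                break
        if not paired:
            stack.append((i + 1, j))
    return "".join(out)


# ---------------------------------------------------------------------------
# iterative alignment
# ---------------------------------------------------------------------------


def _induced_alignment(model: CovarianceModel,
                       seqs: list[tuple[str, str]],
                       parses) -> SeedAlignment:
    """Multiple alignment induced by per-sequence model parses."""
    match_cols = model.match_cols
    # insert slots: (anchor column, phase) -> max run length over sequences
    slot_len: dict[tuple[float, int], int] = {}
    per_seq_inserts: list[dict[tuple[float, int], list[int]]] = []
    for (_sid, _seq), parse in zip(seqs, parses):
        mine: dict[tuple[float, int], list[int]] = {}
        for node_idx, side, run in parse.insert_runs():
            key = _slot_key(model, node_idx, side)
            mine.setdefault(key, []).extend(run)
        for key, positions in mine.items():
            slot_len[key] = max(slot_len.get(key, 0), len(positions))
        per_seq_inserts.append(mine)

    # final column order: inserts interleaved with match columns
    events: list[tuple[tuple[float, int], str, int | None]] = []
    for key in slot_len:
        events.append((key, "ins", None))
    for c in match_cols:
        events.append(((float(c), 0), "match", c))
    events.sort(key=lambda e: e[0])

    rows = []
    for (sid, seq), parse, mine in zip(seqs, parses, per_seq_inserts):
        dna = to_dna(seq)
        row = []
        for key, kind, col in events:
            if kind == "match":
                pos = parse.col_to_pos.get(col)
                row.append(dna[pos] if pos is not None else "-")
            else:
                positions = mine.get(key, [])
                width = slot_len[key]
                row.append("".join(dna[p] for p in positions).ljust(width, "-"))
        rows.append((sid, "".join(row)))

    struct = []
    labels: list[str | None] = []
    pmap = model.position_map
    for key, kind, col in events:
        if kind == "match":
            if col in model.pair_of:
                struct.append("<" if model.pair_of[col] > col else ">")
            else:
                struct.append(".")
            labels.append(None if pmap is None else pmap.col_to_label.get(col))
        else:
            struct.append("." * slot_len[key])
            labels.extend([None] * slot_len[key])
    return SeedAlignment(sequences=rows, consensus_structure="".join(struct),
                         position_labels=labels if pmap is not None else None,
                         domain_tag=model.domain_tag, name=model.name)


def _slot_key(model: CovarianceModel, node_idx: int, side: str) -> tuple[float, int]:
    """Ordering key of an insert slot relative to the match columns."""
    n = model.nodes[node_idx]
    if side == "L":
        if n.kind == "ROOT":
            return (-1.0, 1)
        if n.lcol is not None:
            return (float(n.lcol), 1)          # just after its left match column
        # BEGR insert: before the first match column of its subtree
        first = _first_col_in_subtree(model, node_idx)
        return (float(first), -1)
    if n.kind == "ROOT":
        return (float(10**9), 1)
    return (float(n.rcol), -1)                 # just before its right match column


def _first_col_in_subtree(model: CovarianceModel, node_idx: int) -> int:
    cols = []
    stack = [node_idx]
    while stack:
        n = model.nodes[stack.pop()]
        for c in (n.lcol, n.rcol):
            if c is not None:
                cols.append(c)
        if n.kind == "BIF":
            stack.extend([n.bif_left, n.bif_right])
        elif n.child is not None:
            stack.append(n.child)
    return min(cols) if cols else 0


def iterative_align(seqs: TrainingSet, seed_model: CovarianceModel,
                    max_iter: int = 10,
                    pseudocount: float | None = None
                    ) -> tuple[SeedAlignment, CovarianceModel]:
    """Iterate {align to model, rebuild model} until the alignment is stable.

    The summed training bit score never decreases between returned
    iterations: if an iteration lowers it, the previous model is
    returned with a warning.
    """
    if not seqs.sequences:
        raise TrainingError("empty training set")
    pc = seed_model.emission_pseudocount if pseudocount is None else pseudocount
    model = seed_model
    prev_rows: list[str] | None = None
    prev: tuple[SeedAlignment, CovarianceModel, float] | None = None
    for it in range(1, max_iter + 1):
        parses = []
        total = 0.0
        for _sid, seq in seqs.sequences:
            sc, parse = score_sequence(model, seq)
            total += sc
            parses.append(parse)
        aln = _induced_alignment(model, seqs.sequences, parses)
        logger.info("iteration %d: total training score %.2f", it, total)
        if prev is not None and total < prev[2] - 1e-6:
            logger.warning("training score decreased at iteration %d; "
                           "returning previous model", it)
            return prev[0], prev[1]
        rows = [r for _, r in aln.sequences]
        if prev_rows == rows:
            return aln, model
        prev = (aln, model, total)
        prev_rows = rows
        model = build_model(
            aln, pseudocount=pc,
            transition_pseudocount=seed_model.transition_pseudocount,
            name=seed_model.name)
    logger.warning("no convergence within %d iterations; returning last", max_iter)
    return prev[0], prev[1]
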