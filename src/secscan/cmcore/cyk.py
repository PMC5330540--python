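"""Banded CYK dynamic programming over covariance-model states.

``score_sequence`` aligns a whole sequence to the whole model (glocal)
and returns the maximum-score parse via traceback.  ``window_scores``
runs the same recurrences over a longer sequence with a span band W and
reports, for every start position, the best-scoring model parse length
— this is the scanning kernel.  Tables are float32 and vectorised over
(start, span); insert self-loops are resolved by a single pass over the
span axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from secscan.alphabet import encode
from secscan.cmcore.model import SPLIT_STATES, CovarianceModel, State

NEG = np.float32(-np.inf)


@dataclass
class Parse:
    """Alignment of sequence positions to model columns (0-based)."""

    score: float
    col_to_pos: dict[int, int] = field(default_factory=dict)
    realized_pairs: list[tuple[int, int, int, int]] = field(default_factory=list)
    inserts: list[tuple[int, str, int]] = field(default_factory=list)  # node, side, pos

    def insert_runs(self) -> list[tuple[int, str, list[int]]]:
        """Consecutive inserted positions grouped per (node, side)."""
        runs: list[tuple[int, str, list[int]]] = []
        for node, side, pos in sorted(self.inserts, key=lambda x: x[2]):
            if runs and runs[-1][0] == node and runs[-1][1] == side and runs[-1][2][-1] == pos - 1:
                runs[-1][2].append(pos)
            else:
                runs.append((node, side, [pos]))
        return runs


def _emission_2d(s: State, codes_pad: np.ndarray, S: int, W: int,
                 idx_right: np.ndarray) -> np.ndarray | None:
    """Emission score table e[i, d] for a state, or None if non-emitting."""
    if s.kind == "MP":
        e = s.emit.astype(np.float32)[codes_pad[:S, None], codes_pad[idx_right]]
        e[:, :2] = NEG  # a pair needs span >= 2
        return e
    if s.kind in ("ML", "IL"):
        e = np.broadcast_to(
            s.emit.astype(np.float32)[codes_pad[:S]][:, None], (S, W + 1)).copy()
        e[:, 0] = NEG
        return e
    if s.kind in ("MR", "IR"):
        e = s.emit.astype(np.float32)[codes_pad[idx_right]]
        e[:, 0] = NEG
        return e
    return None


_BIF_BAND = 25   # split-point band around the left subtree's consensus span
_INS_CAP = 45    # span headroom above a subtree's consensus span


def _node_spans(model: CovarianceModel) -> list[int]:
    """Consensus span (emitted match columns) of each node's subtree."""
    spans = [0] * len(model.nodes)
    for n in reversed(model.nodes):
        if n.kind == "END":
            spans[n.idx] = 0
        elif n.kind == "BIF":
            spans[n.idx] = spans[n.bif_left] + spans[n.bif_right]
        else:
            own = 2 if n.kind == "MATP" else 1 if n.kind in ("MATL", "MATR") else 0
            spans[n.idx] = own + spans[n.child]
    return spans


def _fill_tables(model: CovarianceModel, codes: np.ndarray, W: int,
                 keep_all: bool) -> dict[int, np.ndarray]:
    """Run the DP; return tables for all states (keep_all) or the root only.

    The bifurcation split point is banded to +-_BIF_BAND around the left
    subtree's consensus span unless the whole span axis fits inside the
    band: parses needing more than that many net indels on one side of a
    bifurcation score far below any reporting threshold.
    """
    L = len(codes)
    S = L + W + 2                       # padded start axis
    codes_pad = np.full(S, 5, dtype=np.int64)   # 5 = out-of-sequence sentinel
    codes_pad[:L] = codes
    idx_right = np.arange(S)[:, None] + np.arange(W + 1)[None, :] - 1
    np.clip(idx_right, 0, S - 1, out=idx_right)

    states = model.states
    node_spans = _node_spans(model)

    def cap_of(s: State) -> int:
        return min(W, node_spans[s.node] + _INS_CAP)

    nparents = {s.idx: 0 for s in states}
    for s in states:
        for c in set(s.children):
            if c != s.idx:
                nparents[c] += 1
    tables: dict[int, np.ndarray] = {}
    root = model.root_state
    tmp = np.empty((S, W + 1), dtype=np.float32)

    def consume(child: int) -> None:
        if keep_all or child == root:
            return
        nparents[child] -= 1
        if nparents[child] <= 0:
            tables.pop(child, None)

    order: list[State] = []
    for n in reversed(model.nodes):
        for kind in ("IR", "IL"):
            if (n.idx, kind) in model.state_id:
                order.append(states[model.state_id[(n.idx, kind)]])
        for kind in SPLIT_STATES[n.kind]:
            order.append(states[model.state_id[(n.idx, kind)]])

    def fold_child(best: np.ndarray, child: np.ndarray, t: float,
                   dl: int, dd: int, cap: int) -> None:
        """best[i, d] = max(best[i, d], child[i+dl, d-dd] + t) for d <= cap."""
        src = child[dl:S, : cap + 1 - dd]
        dst = best[: S - dl, dd: cap + 1]
        buf = tmp[: S - dl, : cap + 1 - dd]
        np.add(src, np.float32(t), out=buf)
        np.maximum(dst, buf, out=dst)

    for s in order:
        if s.kind == "E":
            M = np.full((S, W + 1), NEG, dtype=np.float32)
            M[: L + 1, 0] = 0.0
            tables[s.idx] = M
            continue
        cap = cap_of(s)
        if s.kind == "B":
            lchild, rchild = s.children
            ML_, MR_ = tables[lchild], tables[rchild]
            M = np.full((S, W + 1), NEG, dtype=np.float32)
            mid = node_spans[states[lchild].node]
            klo = max(0, mid - _BIF_BAND)
            khi = min(cap, mid + _BIF_BAND)
            if W <= 2 * _BIF_BAND:
                klo, khi = 0, min(cap, W)
            for k in range(klo, khi + 1):
                lc = ML_[: S - k, k]
                dst = M[: S - k, k: cap + 1]
                buf = tmp[: S - k, : cap + 1 - k]
                np.add(lc[:, None], MR_[k:, : cap + 1 - k], out=buf)
                np.maximum(dst, buf, out=dst)
            tables[s.idx] = M
            consume(lchild)
            consume(rchild)
            continue

        dl, dd = s.dl, s.dl + s.dr
        if s.kind in ("IL", "IR"):
            # best over non-self children, then resolve the self-loop along d
            A = np.full((S, W + 1), NEG, dtype=np.float32)
            self_t = None
            for k, c in enumerate(s.children):
                if c == s.idx:
                    self_t = np.float32(s.t[k])
                    continue
                fold_child(A, tables[c], s.t[k], dl, dd, cap)
            e1 = s.emit.astype(np.float32)[codes_pad]
            M = np.full((S, W + 1), NEG, dtype=np.float32)
            if s.kind == "IL":
                for d in range(1, cap + 1):
                    col = np.maximum(A[: S - 1, d], self_t + M[1:, d - 1])
                    M[: S - 1, d] = e1[: S - 1] + col
            else:
                e2 = e1[idx_right]
                for d in range(1, cap + 1):
                    col = np.maximum(A[:, d], self_t + M[:, d - 1])
                    M[:, d] = e2[:, d] + col
            tables[s.idx] = M
            for c in set(s.children):
                if c != s.idx:
                    consume(c)
            continue

        best = np.full((S, W + 1), NEG, dtype=np.float32)
        for k, c in enumerate(s.children):
            fold_child(best, tables[c], s.t[k], dl, dd, cap)
        e = _emission_2d(s, codes_pad, S, W, idx_right)
        if e is not None:
            best[:, : cap + 1] += e[:, : cap + 1]
        tables[s.idx] = best
        for c in set(s.children):
            consume(c)

    return tables


def window_scores(model: CovarianceModel, codes: np.ndarray,
                  W: int) -> tuple[np.ndarray, np.ndarray]:
    """Best glocal parse score and span per start position.

    Returns (score[L+1], span[L+1]) float32/int32 arrays: score[i] is the
    best bit score of a parse of the full model over seq[i : i+span[i]].
    """
    L = len(codes)
    tables = _fill_tables(model, codes, W, keep_all=False)
    root = tables[model.root_state][: L + 1, :]
    spans = np.argmax(root, axis=1).astype(np.int32)
    scores = root[np.arange(L + 1), spans]
    return scores, spans


def score_sequence(model: CovarianceModel, seq: str) -> tuple[float, Parse]:
    """Score a full sequence against the full model; return bit score + parse."""
    if not seq:
        raise ValueError("empty sequence")
    codes = encode(seq)
    L = len(codes)
    tables = _fill_tables(model, codes, L, keep_all=True)
    score = float(tables[model.root_state][0, L])
    parse = Parse(score=score)
    if np.isfinite(score):
        _traceback(model, tables, codes, parse)
    return score, parse


def _traceback(model: CovarianceModel, tables: dict[int, np.ndarray],
               codes: np.ndarray, parse: Parse) -> None:
    L = len(codes)
    S = L + L + 2
    codes_pad = np.full(S, 5, dtype=np.int64)
    codes_pad[:L] = codes
    stack = [(model.root_state, 0, L)]
    while stack:
        v, i, d = stack.pop()
        s = model.states[v]
        n = model.nodes[s.node]
        if s.kind == "E":
            continue
        if s.kind == "B":
            lchild, rchild = s.children
            ks = np.arange(d + 1)
            vals = tables[lchild][i, ks] + tables[rchild][i + ks, d - ks]
            k = int(np.argmax(vals))
            stack.append((rchild, i + k, d - k))
            stack.append((lchild, i, k))
            continue
        # record emissions
        if s.kind == "MP":
            parse.col_to_pos[n.lcol] = i
            parse.col_to_pos[n.rcol] = i + d - 1
            parse.realized_pairs.append((n.lcol, n.rcol, i, i + d - 1))
        elif s.kind == "ML":
            if n.lcol is not None:
                parse.col_to_pos[n.lcol] = i
        elif s.kind == "MR":
            if n.rcol is not None:
                parse.col_to_pos[n.rcol] = i + d - 1
        elif s.kind == "IL":
            parse.inserts.append((s.node, "L", i))
        elif s.kind == "IR":
            parse.inserts.append((s.node, "R", i + d - 1))
        # emission score at (i, d)
        if s.kind == "MP":
            e = np.float32(s.emit[codes_pad[i], codes_pad[i + d - 1]])
        elif s.kind in ("ML", "IL"):
            e = np.float32(s.emit[codes_pad[i]])
        elif s.kind in ("MR", "IR"):
            e = np.float32(s.emit[codes_pad[i + d - 1]])
        else:
            e = np.float32(0.0)
        dl, dd = s.dl, s.dl + s.dr
        ni, nd = i + dl, d - dd
        best_k, best_val = None, None
        for k, c in enumerate(s.children):
            if nd < 0:
                continue
            val = np.float32(tables[c][ni, nd] + np.float32(s.t[k])) + e
            if best_val is None or val > best_val:
                best_val, best_k = val, k
        if best_k is None:
            raise RuntimeError("traceback failed")
        stack.append((s.children[best_k], ni, nd))
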