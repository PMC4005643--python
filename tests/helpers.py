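"""Independent oracles for the duplex aligner tests.

``brute_force_mfe`` enumerates every legal antiparallel pairing of a
query against a window and scores it with the public scalar accessors of
the energy model.  It shares no code with the dynamic program (which works
on numeric tables inside a numba kernel), so agreement between the two is
a genuine cross-check, feasible for sequences up to ~9 nt.
"""

from __future__ import annotations

from bulgescan.energy import EnergyModel, can_pair
from bulgescan.seqio import NucleotideSequence


def transition_cost(model: EnergyModel, q: str, w: str,
                    i1: int, j1: int, i2: int, j2: int) -> float | None:
    """Cost of going from pair (i1, j1) to pair (i2, j2); None if illegal.

    Positions are 0-based; i ascends on the query, j descends on the
    window (antiparallel).
    """
    gq = i2 - i1 - 1
    gt = j1 - j2 - 1
    if gq < 0 or gt < 0:
        return None
    stack = model.stack_energy(q[i1], q[i2], w[j1], w[j2])
    if gq == 0 and gt == 0:
        return stack
    if gt == 0 or gq == 0:
        size = gq + gt
        if size > model.max_bulge:
            return None
        cost = model.loop_init("bulge", size)
        if size == 1:
            cost += stack
        return cost
    size = gq + gt
    if size > model.max_internal:
        return None
    return model.loop_init("internal", size) + model.asymmetry_penalty(gq, gt)


def score_structure(model: EnergyModel, q: str, w: str,
                    pairs: list[tuple[int, int]]) -> float | None:
    """Total energy of one pairing (0-based (i, j) list, i asc, j desc)."""
    total = model.duplex_init
    total += model.terminal_penalty(q[pairs[0][0]], w[pairs[0][1]])
    total += model.terminal_penalty(q[pairs[-1][0]], w[pairs[-1][1]])
    for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
        c = transition_cost(model, q, w, i1, j1, i2, j2)
        if c is None:
            return None
        total += c
    return total


def brute_force_mfe(query: NucleotideSequence, window: NucleotideSequence,
                    model: EnergyModel) -> float | None:
    """Exhaustive minimum over all antiparallel pairings; None if nothing
    scores below zero (the aligner's no-duplex sentinel)."""
    q, w = query.residues, window.residues
    m, n = len(q), len(w)
    best = [None]

    def extend(i_last: int, j_last: int, energy: float) -> None:
        # close the structure here
        closed = energy + model.terminal_penalty(q[i_last], w[j_last])
        if best[0] is None or closed < best[0]:
            best[0] = closed
        for i in range(i_last + 1, m):
            for j in range(j_last - 1, -1, -1):
                if not can_pair(q[i], w[j]):
                    continue
                c = transition_cost(model, q, w, i_last, j_last, i, j)
                if c is not None:
                    extend(i, j, energy + c)

    for i in range(m):
        for j in range(n):
            if can_pair(q[i], w[j]):
                opening = model.duplex_init + model.terminal_penalty(q[i], w[j])
                extend(i, j, opening)
    if best[0] is None or best[0] >= -1e-9:
        return None
    return best[0]


def random_rna(rng, length: int, gc: float = 0.5) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join("ACGU"[i] for i in rng.choice(4, size=length, p=probs))
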