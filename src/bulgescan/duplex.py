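"""Minimum-free-energy intermolecular alignment of an miRNA to a transcript.

This is the core of the bulge-tolerant target aligner: a dynamic program
over all antiparallel pairings of the miRNA (query) with a target window,
allowing mismatches, G:U wobbles, and asymmetric bulges / internal loops,
scored with the nearest-neighbor model in :mod:`bulgescan.energy`.
Alignments are trimmed to begin and end on a base pair; unpaired terminal
residues fall outside the reported site.  A window with no stabilizing
alignment (best energy >= 0) yields ``None``, the "no duplex" sentinel,
so transcriptome scans never abort.

Determinism: among equal-MFE alignments the aligner prefers more base
pairs, then fewer loops, then the 5'-most target start.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _dp
from .energy import BASE_CODE, BASES, EnergyModel, can_pair, encode, is_wobble
from .seqio import NucleotideSequence, reverse_complement

_EPS = 1e-9


@dataclass(frozen=True)
class LoopRecord:
    """A non-helical element between two consecutive base pairs.

    ``target_side_length`` counts unpaired target nucleotides;
    ``flank5_query_pos`` is the miRNA position of the base pair on the
    miRNA-5' side of the loop.
    """

    kind: str  # mismatch | target_bulge | query_bulge | internal_loop
    query_span: tuple[int, int] | None
    target_span: tuple[int, int] | None
    target_side_length: int
    flank5_query_pos: int

    @property
    def query_side_length(self) -> int:
        if self.query_span is None:
            return 0
        return self.query_span[1] - self.query_span[0] + 1


@dataclass(frozen=True)
class DuplexAlignment:
    """An miRNA:target-site pairing with its thermodynamic scores.

    ``pairs`` are (miRNA position, transcript position), strictly
    increasing in miRNA position and strictly decreasing in transcript
    position (antiparallel duplex); coordinates are 1-based inclusive.
    """

    query: NucleotideSequence
    target_id: str
    target_start: int
    target_end: int
    pairs: tuple[tuple[int, int], ...]
    loops: tuple[LoopRecord, ...]
    mfe: float
    perfect_mfe: float
    site_seq: str = ""  # target residues spanning target_start..target_end

    @property
    def mfe_ratio(self) -> float:
        return mfe_ratio(self)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def target_position_of(self, query_pos: int) -> int | None:
        """Transcript position paired to an miRNA position, if paired."""
        for qp, tp in self.pairs:
            if qp == query_pos:
                return tp
        return None

    def query_position_of(self, target_pos: int) -> int | None:
        for qp, tp in self.pairs:
            if tp == target_pos:
                return qp
        return None

    def target_base_of(self, query_pos: int) -> str | None:
        """Target residue paired to an miRNA position, if paired."""
        tp = self.target_position_of(query_pos)
        if tp is None or not self.site_seq:
            return None
        return self.site_seq[tp - self.target_start]

    def pair_string(self) -> str:
        """One character per miRNA position: '|' Watson-Crick, 'o' wobble,
        '.' unpaired."""
        chars = ["."] * len(self.query)
        for qp, _ in self.pairs:
            chars[qp - 1] = "o" if self._is_wobble(qp) else "|"
        return "".join(chars)

    def _is_wobble(self, qp: int) -> bool:
        tb = self.target_base_of(qp)
        return tb is not None and is_wobble(self.query.residues[qp - 1], tb)

    def loop_summary(self) -> str:
        parts = []
        for lp in self.loops:
            parts.append(f"{lp.kind}@{lp.flank5_query_pos}"
                         f"(q{lp.query_side_length}/t{lp.target_side_length})")
        return ";".join(parts) if parts else "helix"


def perfect_complement_mfe(query: NucleotideSequence, model: EnergyModel) -> float:
    """Energy of the fully Watson-Crick-paired duplex of the query against
    its exact reverse complement (closed-form stacking sum)."""
    s = query.residues
    comp = {"A": "U", "U": "A", "C": "G", "G": "C"}
    total = model.duplex_init
    total += model.terminal_penalty(s[0], comp[s[0]])
    total += model.terminal_penalty(s[-1], comp[s[-1]])
    for i in range(len(s) - 1):
        total += model.stack_energy(s[i], s[i + 1], comp[s[i]], comp[s[i + 1]])
    return total


def mfe_ratio(a: DuplexAlignment) -> float:
    """mfe / perfect_mfe; defined only for a stabilizing perfect duplex."""
    if a.perfect_mfe >= 0:
        raise ValueError("degenerate query: perfect-complement MFE is not negative")
    return a.mfe / a.perfect_mfe


def duplex_mfe(
    query: NucleotideSequence,
    target_window: NucleotideSequence,
    model: EnergyModel,
    *,
    target_id: str | None = None,
    offset: int = 1,
    enforce_length: bool = True,
) -> DuplexAlignment | None:
    """Minimum-free-energy alignment of ``query`` against one target window.

    ``offset`` is the 1-based transcript coordinate of the window's first
    nucleotide, so reported coordinates are transcript-anchored.  Returns
    ``None`` (the no-duplex sentinel) when no alignment scores below zero.
    ``enforce_length`` applies the miRNA-scale preconditions (query 18-26
    nt, window <= 60 nt); tests may relax it to run tiny oracle cases.
    """
    if enforce_length:
        if not 18 <= len(query) <= 26:
            raise ValueError(f"query length {len(query)} outside 18-26 nt")
        if len(target_window) > 60:
            raise ValueError(f"target window longer than 60 nt ({len(target_window)})")
    q = encode(query.residues)
    r = encode(target_window.residues[::-1])
    H, NP, NL, Pi, Pk = _dp.fill(
        q, r, model.stack, model.pair_ok, model.bulge_init, model.internal_init,
        model.asymmetry, model.asymmetry_max, _terminal_table(model),
        model.max_bulge, model.max_internal,
    )
    n = len(target_window)
    # closing terminal penalty + duplex initiation, then pick the optimum
    best = (np.inf, 0, 0, -1, -1)
    term = _terminal_table(model)
    for i in range(len(q)):
        for k in range(n):
            if H[i, k] >= _dp.BIG:
                continue
            e = H[i, k] + model.duplex_init + term[q[i], r[k]]
            key = (e, -int(NP[i, k]), int(NL[i, k]), -k, i)
            if (key[0] < best[0] - _EPS) or (
                abs(key[0] - best[0]) <= _EPS and key[1:] < best[1:]
            ):
                best = key
    e_best, _, _, neg_k, i_best = best
    if not np.isfinite(e_best) or e_best >= -_EPS:
        return None
    # traceback
    cells = []
    i, k = i_best, -neg_k
    while i >= 0:
        cells.append((i, k))
        i, k = int(Pi[i, k]), int(Pk[i, k])
    cells.reverse()
    pairs = tuple((i + 1, n - k) for i, k in cells)  # window coordinates
    w_start = pairs[-1][1]
    w_end = pairs[0][1]
    loops = _loops_from_pairs(
        tuple((qp, offset + tp - 1) for qp, tp in pairs)
    )
    return DuplexAlignment(
        query=query,
        target_id=target_id or target_window.id,
        target_start=offset + w_start - 1,
        target_end=offset + w_end - 1,
        pairs=tuple((qp, offset + tp - 1) for qp, tp in pairs),
        loops=loops,
        mfe=float(e_best),
        perfect_mfe=perfect_complement_mfe(query, model),
        site_seq=target_window.residues[w_start - 1 : w_end],
    )


def _terminal_table(model: EnergyModel) -> np.ndarray:
    term = np.zeros((4, 4))
    for a in BASES:
        for b in BASES:
            if can_pair(a, b):
                term[BASE_CODE[a], BASE_CODE[b]] = model.terminal_penalty(a, b)
    return term


def _loops_from_pairs(pairs: tuple[tuple[int, int], ...]) -> tuple[LoopRecord, ...]:
    """Classify the gaps between consecutive pairs (window coordinates)."""
    loops = []
    for (q1, t1), (q2, t2) in zip(pairs, pairs[1:]):
        gq = q2 - q1 - 1
        gt = t1 - t2 - 1
        if gq == 0 and gt == 0:
            continue
        qspan = (q1 + 1, q2 - 1) if gq else None
        tspan = (t2 + 1, t1 - 1) if gt else None
        if gq and gt:
            kind = "mismatch" if gq == 1 and gt == 1 else "internal_loop"
        elif gq:
            kind = "query_bulge"
        else:
            kind = "target_bulge"
        loops.append(
            LoopRecord(
                kind=kind,
                query_span=qspan,
                target_span=tspan,
                target_side_length=gt,
                flank5_query_pos=q1,
            )
        )
    return tuple(loops)


def scan_transcript(
    query: NucleotideSequence,
    transcript: NucleotideSequence,
    model: EnergyModel,
    stride: int = 1,
    *,
    min_ratio: float | None = None,
    margin: int | None = None,
) -> list[DuplexAlignment]:
    """Scan a whole transcript for stabilizing duplex sites.

    A window of ``len(query) + max_bulge + margin`` nucleotides (margin
    defaults to ``max_bulge``, so a maximal target bulge always fits)
    slides at the given stride; overlapping optima are merged so each
    distinct site is reported once, best energy first, and the result is
    sorted by MFE ratio descending.
    """
    if len(transcript) < len(query):
        raise ValueError("transcript shorter than query")
    if margin is None:
        margin = model.max_bulge
    wlen = min(len(transcript), len(query) + model.max_bulge + margin)
    starts = list(range(0, len(transcript) - wlen + 1, stride))
    if starts[-1] != len(transcript) - wlen:
        starts.append(len(transcript) - wlen)
    candidates: list[DuplexAlignment] = []
    for s in starts:
        window = NucleotideSequence(
            id=transcript.id, residues=transcript.residues[s : s + wlen]
        )
        aln = duplex_mfe(
            query, window, model,
            target_id=transcript.id, offset=s + 1, enforce_length=False,
        )
        if aln is not None:
            candidates.append(aln)
    # greedy merge: best alignment claims its span; overlapping rivals
    # (including the same site seen from shifted windows) are dropped
    candidates.sort(
        key=lambda a: (a.mfe, -a.n_pairs, len(a.loops), a.target_start)
    )
    accepted: list[DuplexAlignment] = []
    for aln in candidates:
        if any(
            aln.target_start <= b.target_end and b.target_start <= aln.target_end
            for b in accepted
        ):
            continue
        accepted.append(aln)
    if min_ratio is not None:
        accepted = [a for a in accepted if a.mfe_ratio >= min_ratio]
    accepted.sort(key=lambda a: -a.mfe_ratio)
    return accepted


def make_perfect_site(query: NucleotideSequence) -> NucleotideSequence:
    """The exact reverse-complement target site of a query (convenience)."""
    rc = reverse_complement(query)
    return NucleotideSequence(id=f"{query.id}_perfect_site", residues=rc.residues)
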