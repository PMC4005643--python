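"""Target-site filters and the predicted slice coordinate.

Two filter layers are implemented.  The *classic* layer is the relaxed
position-weighted plant score: each mismatch costs 1.0, each G:U wobble
0.5 and each indel nucleotide 1.0, with every penalty doubled when it
falls inside miRNA positions 2-13; thresholds (score <= 3.5, <= 6 G:U,
<= 1 indel event, <= 5 mismatches) are inclusive.  The *gstar* layer is
the thermodynamic screen: MFE ratio >= 0.8 and at least one target-side
bulge of >= 4 nt.  All verdicts are computed and reported independently.

Penalty accounting for loops: an n1 x n2 internal loop contributes
min(n1, n2) mismatches (placed on its miRNA positions) plus |n1 - n2|
indel nucleotides as a single indel event; a bulge contributes its length
in indel nucleotides as one event; unpaired miRNA positions outside the
trimmed helix count as mismatches at their own positions.  Target-side
indel nucleotides take the doubling weight of the base pair flanking the
loop on the miRNA-5' side.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

from .duplex import DuplexAlignment, LoopRecord
from .energy import is_wobble

#: miRNA positions whose penalties are doubled (5' + central region)
CORE_START, CORE_END = 2, 13

#: region labels for target-bulge positions, by the miRNA-5' flanking pair
REGION_5PRIME_END = 8
REGION_CENTRAL_END = 12

SLICE_GUIDE_POS = 10  # slicing occurs between the pairs to positions 10/11


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for both filter layers (defaults reproduce the published
    screen: 3.5 / 6 G:U / 1 indel / 5 mismatches; MFE ratio 0.8; 4-nt
    target bulge).  All thresholds are inclusive."""

    max_score: float = 3.5
    max_gu: int = 6
    max_indel: int = 1
    max_mismatch: int = 5
    min_mfe_ratio: float = 0.8
    min_target_bulge: int = 4

    def __post_init__(self) -> None:
        if not 0 < self.min_mfe_ratio <= 1:
            raise ValueError("min_mfe_ratio must be in (0, 1]")
        for name in ("max_score", "max_gu", "max_indel", "max_mismatch",
                     "min_target_bulge"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


class PenaltyCounts(NamedTuple):
    mismatches: int
    gu_pairs: int
    indel_events: int


@dataclass(frozen=True)
class TargetSite:
    """A transcript-anchored alignment with scores and filter verdicts."""

    alignment: DuplexAlignment
    allen_score: float
    counts: PenaltyCounts
    slice_position: int | None
    verdicts: dict[str, bool] = field(default_factory=dict)

    @property
    def passes_classic(self) -> bool:
        return all(self.verdicts[k] for k in ("score", "gu", "indel", "mismatch"))

    @property
    def passes_gstar(self) -> bool:
        return all(self.verdicts[k] for k in ("mfe_ratio", "target_bulge"))


def _weight(pos: float) -> float:
    return 2.0 if CORE_START <= pos <= CORE_END else 1.0


def allen_score(a: DuplexAlignment) -> tuple[float, PenaltyCounts]:
    """Position-weighted penalty score of an alignment, with raw counts.

    The score is additive over features: each G:U pair, mismatch position
    and indel nucleotide contributes its weighted penalty independently.
    """
    score = 0.0
    mismatches = 0
    gu = 0
    indel_events = 0
    for qp, tp in a.pairs:
        tb = a.target_base_of(qp)
        qb = a.query.residues[qp - 1]
        if tb is not None and is_wobble(qb, tb):
            gu += 1
            score += 0.5 * _weight(qp)
    for lp in a.loops:
        nq = lp.query_side_length
        nt = lp.target_side_length
        n_mm = min(nq, nt)
        if n_mm and lp.query_span:
            for pos in range(lp.query_span[0], lp.query_span[0] + n_mm):
                mismatches += 1
                score += 1.0 * _weight(pos)
        extra = abs(nq - nt)
        if extra:
            indel_events += 1
            if nq > nt and lp.query_span:
                # the surplus nucleotides are the loop's 3'-most miRNA positions
                for pos in range(lp.query_span[0] + n_mm, lp.query_span[1] + 1):
                    score += 1.0 * _weight(pos)
            else:
                # target-side surplus: weighted by the miRNA-5' flanking pair
                score += extra * 1.0 * _weight(lp.flank5_query_pos)
    # unpaired miRNA termini outside the trimmed helix count as mismatches
    first_q = a.pairs[0][0]
    last_q = a.pairs[-1][0]
    for pos in list(range(1, first_q)) + list(range(last_q + 1, len(a.query) + 1)):
        mismatches += 1
        score += 1.0 * _weight(pos)
    return score, PenaltyCounts(mismatches, gu, indel_events)


def detect_target_bulges(a: DuplexAlignment) -> list[tuple[LoopRecord, str]]:
    """All target-side bulges of an alignment with a region label taken
    from the miRNA-5' flanking pair: 5prime (<= 8), central (9-12),
    3prime (>= 13)."""
    out = []
    for lp in a.loops:
        if lp.kind != "target_bulge":
            continue
        p = lp.flank5_query_pos
        if p <= REGION_5PRIME_END:
            region = "5prime"
        elif p <= REGION_CENTRAL_END:
            region = "central"
        else:
            region = "3prime"
        out.append((lp, region))
    return out


def predicted_slice_site(a: DuplexAlignment) -> int | None:
    """Transcript position paired to miRNA position 10 -- the expected 5'
    end of the 3' cleavage fragment.  Cleavage occurs between this
    position and the one paired to miRNA position 11; if either guide
    position is unpaired the site is slice-incompetent and ``None`` is
    returned."""
    p10 = a.target_position_of(SLICE_GUIDE_POS)
    p11 = a.target_position_of(SLICE_GUIDE_POS + 1)
    if p10 is None or p11 is None:
        return None
    return p10


def apply_filters(site: TargetSite, cfg: FilterConfig, mode: str = "gstar") -> dict[str, bool]:
    """Evaluate every filter and return the verdict table.

    ``mode`` selects which verdicts constitute a pass for callers using
    ``passes_classic`` / ``passes_gstar``; all verdicts are always
    reported.
    """
    if mode not in ("classic", "gstar"):
        raise ValueError(f"unknown filter mode {mode!r}")
    bulges = detect_target_bulges(site.alignment)
    max_bulge = max((lp.target_side_length for lp, _ in bulges), default=0)
    verdicts = {
        "score": site.allen_score <= cfg.max_score,
        "gu": site.counts.gu_pairs <= cfg.max_gu,
        "indel": site.counts.indel_events <= cfg.max_indel,
        "mismatch": site.counts.mismatches <= cfg.max_mismatch,
        "mfe_ratio": site.alignment.mfe_ratio >= cfg.min_mfe_ratio,
        "target_bulge": max_bulge >= cfg.min_target_bulge,
    }
    site.verdicts.update(verdicts)
    return verdicts


def build_target_site(
    a: DuplexAlignment, cfg: FilterConfig | None = None, mode: str = "gstar"
) -> TargetSite:
    """Score an alignment, locate its slice coordinate and run the filters."""
    score, counts = allen_score(a)
    site = TargetSite(
        alignment=a,
        allen_score=score,
        counts=counts,
        slice_position=predicted_slice_site(a),
    )
    apply_filters(site, cfg or FilterConfig(), mode)
    return site
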