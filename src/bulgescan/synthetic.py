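"""Synthetic transcriptomes, implanted target sites and degradome reads.

The generator emulates, at the sequence level, engineered miRNA target
sites whose architecture is controlled: a site is the reverse complement
of the miRNA with a target-side bulge of configurable size inserted at a
configurable position and optional mismatching positions, implanted into
an i.i.d. random transcriptome; the matching degradome library places
``signal_reads`` 5' ends exactly at the true slice position (transcript
position paired to miRNA nucleotide 10) over uniform Poisson background.
Everything is deterministic under a fixed seed, and the ground truth
tables returned by each stage are exact, so every downstream stage can be
tested against known answers without any external data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .energy import PAIRABLE
from .seqio import NucleotideSequence, reverse_complement

logger = logging.getLogger(__name__)

_SLICE_GUIDE_POS = 10
_BASES = "ACGU"


@dataclass(frozen=True)
class SiteSpec:
    """Architecture of one implanted site.

    ``bulge_after`` is the miRNA position 5' of the bulge (the bulge sits
    between the target nucleotides pairing miRNA positions ``bulge_after``
    and ``bulge_after + 1``); ``mismatches`` are miRNA positions whose
    target partners are mutated to non-pairing residues.
    """

    mirna: NucleotideSequence
    bulge_size: int = 6
    bulge_after: int = 6
    mismatches: tuple[int, ...] = ()
    transcript_index: int = 0
    offset: int = 101  # 1-based transcript coordinate of the site start


@dataclass(frozen=True)
class DegradomeSpec:
    """Signal and noise levels of the simulated degradome library."""

    signal_reads: int = 50
    background_rate: float = 0.01  # reads per nucleotide
    read_len: int = 20


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_transcripts: int = 10
    transcript_len: int = 1000
    gc_fraction: float = 0.42
    site_specs: tuple[SiteSpec, ...] = ()
    degradome: DegradomeSpec = field(default_factory=DegradomeSpec)

    def __post_init__(self) -> None:
        if not 0 <= self.gc_fraction <= 1:
            raise ValueError("gc_fraction must be in [0, 1]")
        if self.degradome.background_rate < 0 or self.degradome.signal_reads < 0:
            raise ValueError("degradome rates must be >= 0")


@dataclass(frozen=True)
class SyntheticSite:
    """A generated site plus its ground-truth alignment bookkeeping."""

    seq: NucleotideSequence
    #: intended base pairs as {miRNA position: 1-based site position}
    pairs: dict[int, int]
    bulge_span: tuple[int, int] | None  # 1-based site coordinates
    slice_index: int | None  # site position pairing miRNA nt 10, if paired


@dataclass(frozen=True)
class ImplantedSite:
    transcript_id: str
    start: int  # 1-based inclusive
    end: int
    site: SyntheticSite
    slice_position: int | None  # absolute transcript coordinate


@dataclass(frozen=True)
class TranscriptomeTruth:
    transcripts: tuple[NucleotideSequence, ...]
    sites: tuple[ImplantedSite, ...]


def _pairs_with(a: str, b: str) -> bool:
    return (a, b) in PAIRABLE


def make_site(
    mirna: NucleotideSequence,
    bulge_size: int,
    bulge_after: int,
    mismatches: tuple[int, ...] = (),
    rng: np.random.Generator | None = None,
) -> SyntheticSite:
    """Build a target-site sequence with a target-side bulge and optional
    mismatches, recording the intended alignment.

    The site is the reverse complement of the miRNA with ``bulge_size``
    random nucleotides inserted between the positions pairing miRNA
    ``bulge_after`` and ``bulge_after + 1``.  Inserted nucleotides are
    resampled until they cannot pair with either flanking miRNA base, so
    the intended bulge architecture is preserved.  A bulge at a terminal
    pair would be a dangling end, not a bulge, and raises ValueError.
    """
    rng = rng or np.random.default_rng(0)
    L = len(mirna)
    if bulge_size < 0:
        raise ValueError("bulge_size must be >= 0")
    if bulge_size > 0 and not 2 <= bulge_after <= L - 2:
        raise ValueError(
            f"bulge_after={bulge_after} puts the bulge at a terminal pair "
            f"(allowed range 2..{L - 2}); terminal bulges are dangling ends"
        )
    if any(not 1 <= p <= L for p in mismatches):
        raise ValueError("mismatch positions must be within the miRNA")
    residues = list(reverse_complement(mirna).residues)
    # mutate specified partners to residues that cannot pair
    for p in mismatches:
        idx = L - p  # 0-based index of the partner in the RC
        choices = [b for b in _BASES if not _pairs_with(mirna.residues[p - 1], b)]
        residues[idx] = choices[int(rng.integers(len(choices)))]
    bulge_span = None
    if bulge_size > 0:
        flank3 = mirna.residues[bulge_after - 1]      # miRNA base 5' of bulge
        flank5 = mirna.residues[bulge_after]          # miRNA base 3' of bulge
        fill = []
        while len(fill) < bulge_size:
            b = _BASES[int(rng.integers(4))]
            if _pairs_with(flank3, b) or _pairs_with(flank5, b):
                continue
            fill.append(b)
        insert_at = L - bulge_after  # 0-based: after partner of bulge_after+1
        residues[insert_at:insert_at] = fill
        bulge_span = (insert_at + 1, insert_at + bulge_size)
    pairs = {}
    for p in range(1, L + 1):
        if p in mismatches:
            continue
        idx = L - p + 1 + (bulge_size if p <= bulge_after else 0)
        pairs[p] = idx
    slice_index = pairs.get(_SLICE_GUIDE_POS)
    if _SLICE_GUIDE_POS + 1 not in pairs:
        slice_index = None
    seq = NucleotideSequence(id=f"{mirna.id}_site", residues="".join(residues))
    return SyntheticSite(seq=seq, pairs=pairs, bulge_span=bulge_span,
                         slice_index=slice_index)


def make_transcriptome(cfg: SimulationConfig) -> tuple[list[NucleotideSequence], TranscriptomeTruth]:
    """Random transcripts at the configured GC fraction with the specified
    sites implanted; ground truth records coordinates and slice positions."""
    rng = np.random.default_rng([cfg.seed, 0])
    gc = cfg.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seqs = []
    for i in range(cfg.n_transcripts):
        draw = rng.choice(4, size=cfg.transcript_len, p=probs)
        seqs.append(list("".join(_BASES[j] for j in draw)))
    implanted = []
    for spec in cfg.site_specs:
        site = make_site(spec.mirna, spec.bulge_size, spec.bulge_after,
                         spec.mismatches, rng)
        start = spec.offset
        end = start + len(site.seq) - 1
        if not 1 <= start or end > cfg.transcript_len:
            raise ValueError(
                f"site (length {len(site.seq)}) at offset {start} exceeds "
                f"transcript length {cfg.transcript_len}"
            )
        tidx = spec.transcript_index
        tid = f"synthetic_t{tidx}"
        seqs[tidx][start - 1 : end] = list(site.seq.residues)
        slice_abs = None if site.slice_index is None else start + site.slice_index - 1
        implanted.append(
            ImplantedSite(transcript_id=tid, start=start, end=end, site=site,
                          slice_position=slice_abs)
        )
    transcripts = [
        NucleotideSequence(id=f"synthetic_t{i}", residues="".join(s))
        for i, s in enumerate(seqs)
    ]
    return transcripts, TranscriptomeTruth(
        transcripts=tuple(transcripts), sites=tuple(implanted)
    )


def simulate_degradome(
    truth: TranscriptomeTruth, cfg: SimulationConfig
) -> tuple[list[NucleotideSequence], dict[str, dict[int, int]]]:
    """Simulate a degradome library with known ground truth.

    ``signal_reads`` reads start exactly at each implanted slice position;
    Poisson(background_rate x length) background reads start at uniform
    positions.  Reads are transcript suffixes of ``read_len`` nt,
    truncated (and logged) near transcript ends.  Returns the reads and
    the exact per-transcript 5'-end count table.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    spec = cfg.degradome
    reads: list[NucleotideSequence] = []
    table: dict[str, dict[int, int]] = {t.id: {} for t in truth.transcripts}
    by_id = {t.id: t for t in truth.transcripts}
    truncated = 0

    def emit(tid: str, pos: int, tag: str, i: int) -> None:
        nonlocal truncated
        s = by_id[tid].residues[pos - 1 : pos - 1 + spec.read_len]
        if len(s) < spec.read_len:
            truncated += 1
        reads.append(NucleotideSequence(id=f"{tag}_{tid}_{pos}_{i}", residues=s))
        table[tid][pos] = table[tid].get(pos, 0) + 1

    for implant in truth.sites:
        if implant.slice_position is None:
            continue
        for i in range(spec.signal_reads):
            emit(implant.transcript_id, implant.slice_position, "sig", i)
    for t in truth.transcripts:
        n_bg = int(rng.poisson(spec.background_rate * len(t)))
        if n_bg:
            positions = rng.integers(1, len(t) + 1, size=n_bg)
            for i, pos in enumerate(sorted(int(p) for p in positions)):
                emit(t.id, pos, "bg", i)
    if truncated:
        logger.info("simulate_degradome: truncated %d reads at transcript ends",
                    truncated)
    return reads, table
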