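"""Degradome (PARE) slice-site validation.

A slicing event leaves the 5' end of the 3' cleavage fragment exactly at
the transcript position paired to miRNA position 10.  This module maps
degradome reads to a transcriptome by exact 5'-prefix matching, builds
per-transcript 5'-end count profiles, grades the signal at predicted
slice sites into the standard ordinal evidence categories 0-4, and
attaches an empirical p-value from a shuffled-miRNA null.

Category semantics (c = raw count at the slice position, M = transcript
maximum, med = median over positions with nonzero counts):

    c == 0            no hit (None)
    c == 1            4
    c == M, unique    0
    c == M, shared    1
    med < c < M       2
    1 < c <= med      3

The single-read rule takes precedence over the maximum rules, so a
transcript whose only signature is one read at the slice site is category
4, not 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from statistics import median

import numpy as np

from .duplex import scan_transcript
from .energy import EnergyModel, default_model
from .scoring import FilterConfig, TargetSite, build_target_site
from .seqio import NucleotideSequence

logger = logging.getLogger(__name__)


@dataclass
class DegradomeProfile:
    """Per-transcript, per-position 5'-end read counts.

    ``library_size`` is the total number of read placements in the
    library (multi-mapping reads counted at every locus), so the
    per-million normalization over all profiles sums to exactly 1e6.
    """

    transcript_id: str
    counts: dict[int, int] = field(default_factory=dict)
    library_size: int = 0

    def raw(self, position: int) -> int:
        return self.counts.get(position, 0)

    def normalized(self, position: int) -> float:
        if self.library_size == 0:
            return 0.0
        return self.raw(position) * 1e6 / self.library_size

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class DegradomeHit:
    """A predicted target site together with its degradome evidence."""

    site: TargetSite
    library: str
    reads_at_slice: int
    category: int | None
    p_value: float | None = None
    n_shuffles: int = 0


def map_degradome(
    reads: list[NucleotideSequence],
    transcriptome: list[NucleotideSequence],
    prefix_len: int = 20,
) -> list[DegradomeProfile]:
    """Map reads to transcripts by exact sense-strand 5'-prefix match.

    Each read's 5' prefix of ``prefix_len`` nt is matched against every
    transcript; every match increments the count at the transcript
    position of the read's 5' end (multi-mapping reads increment every
    locus).  Reads shorter than ``prefix_len`` are skipped with a logged
    tally.
    """
    if prefix_len < 15:
        raise ValueError("prefix_len must be >= 15")
    index: dict[str, list[tuple[str, int]]] = {}
    for t in transcriptome:
        s = t.residues
        for i in range(len(s) - prefix_len + 1):
            index.setdefault(s[i : i + prefix_len], []).append((t.id, i + 1))
    profiles = {t.id: DegradomeProfile(transcript_id=t.id) for t in transcriptome}
    skipped = 0
    placements = 0
    for read in reads:
        if len(read) < prefix_len:
            skipped += 1
            continue
        for tid, pos in index.get(read.residues[:prefix_len], []):
            prof = profiles[tid]
            prof.counts[pos] = prof.counts.get(pos, 0) + 1
            placements += 1
    if skipped:
        logger.info("map_degradome: skipped %d reads shorter than %d nt",
                    skipped, prefix_len)
    for prof in profiles.values():
        prof.library_size = placements
    return list(profiles.values())


def categorize_site(profile: DegradomeProfile, slice_position: int) -> int | None:
    """Ordinal evidence category 0-4 at a slice position; None = no hit."""
    nonzero = [c for c in profile.counts.values() if c > 0]
    if not nonzero:
        return None
    c = profile.raw(slice_position)
    if c == 0:
        return None
    if c == 1:
        return 4
    m = max(nonzero)
    if c == m:
        return 0 if nonzero.count(m) == 1 else 1
    med = median(nonzero)
    return 2 if c > med else 3


def _shuffle(mirna: NucleotideSequence, rng: np.random.Generator) -> NucleotideSequence:
    """Mononucleotide-preserving shuffle (a random permutation)."""
    residues = list(mirna.residues)
    rng.shuffle(residues)
    return NucleotideSequence(id=f"{mirna.id}_shuffled", residues="".join(residues))


def site_pvalue(
    hit: DegradomeHit,
    mirna: NucleotideSequence,
    transcriptome: list[NucleotideSequence],
    profile_set: dict[str, DegradomeProfile],
    n_shuffles: int,
    seed: int,
    model: EnergyModel | None = None,
    stride: int = 1,
) -> float:
    """Add-one empirical p-value of a degradome hit under a shuffled-miRNA
    null.

    Each of ``n_shuffles`` mononucleotide-preserving shuffles of the miRNA
    is rescanned against the same transcriptome and profiles; a shuffle
    succeeds if any of its slice-competent sites reaches a category <=
    the observed one at an MFE ratio >= the observed one.  The estimator
    floor is 1 / (1 + n_shuffles).
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    if hit.category is None:
        return 1.0
    model = model or default_model()
    observed_ratio = hit.site.alignment.mfe_ratio
    rng = np.random.default_rng(seed)
    successes = 0
    for _ in range(n_shuffles):
        decoy = _shuffle(mirna, rng)
        if _decoy_achieves(decoy, transcriptome, profile_set, hit.category,
                           observed_ratio, model, stride):
            successes += 1
    return (1 + successes) / (1 + n_shuffles)


def _decoy_achieves(decoy, transcriptome, profile_set, obs_category, obs_ratio,
                    model, stride) -> bool:
    from .scoring import predicted_slice_site

    for transcript in transcriptome:
        prof = profile_set.get(transcript.id)
        if prof is None or not prof.counts:
            continue
        for aln in scan_transcript(decoy, transcript, model, stride=stride,
                                   min_ratio=obs_ratio):
            pos = predicted_slice_site(aln)
            if pos is None:
                continue
            cat = categorize_site(prof, pos)
            if cat is not None and cat <= obs_category:
                return True
    return False


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end settings: filters, mapping and the empirical null."""

    filters: FilterConfig = field(default_factory=FilterConfig)
    mode: str = "gstar"
    prefix_len: int = 20
    stride: int = 1
    n_shuffles: int = 0  # 0 disables p-values
    seed: int = 0


def run_degradome_pipeline(
    mirnas: list[NucleotideSequence],
    transcriptome: list[NucleotideSequence],
    degradome_reads: dict[str, list[NucleotideSequence]],
    cfg: PipelineConfig | None = None,
    model: EnergyModel | None = None,
) -> dict[str, list[DegradomeHit]]:
    """scan -> filter -> map -> categorize -> p-value, per library.

    Libraries are analyzed separately (no pooling); each library name maps
    to its hits, sorted by (category ascending, p-value ascending), with
    no-hit sites (zero slice-site reads) reported last.  Deterministic for
    a fixed ``cfg.seed``.
    """
    cfg = cfg or PipelineConfig()
    model = model or default_model()

    predicted: list[tuple[NucleotideSequence, TargetSite]] = []
    for mirna in mirnas:
        for transcript in transcriptome:
            if len(transcript) < len(mirna):
                continue
            for aln in scan_transcript(mirna, transcript, model, stride=cfg.stride):
                site = build_target_site(aln, cfg.filters, cfg.mode)
                passes = site.passes_gstar if cfg.mode == "gstar" else site.passes_classic
                if passes and site.slice_position is not None:
                    predicted.append((mirna, site))

    results: dict[str, list[DegradomeHit]] = {}
    for lib_name, reads in degradome_reads.items():
        profiles = {
            p.transcript_id: p
            for p in map_degradome(reads, transcriptome, cfg.prefix_len)
        }
        hits = []
        for mirna, site in predicted:
            prof = profiles[site.alignment.target_id]
            c = prof.raw(site.slice_position)
            category = categorize_site(prof, site.slice_position)
            hit = DegradomeHit(
                site=site, library=lib_name, reads_at_slice=c,
                category=category, n_shuffles=cfg.n_shuffles,
            )
            if cfg.n_shuffles >= 1 and category is not None:
                p = site_pvalue(hit, mirna, transcriptome, profiles,
                                cfg.n_shuffles, cfg.seed, model, cfg.stride)
                hit = DegradomeHit(
                    site=site, library=lib_name, reads_at_slice=c,
                    category=category, p_value=p, n_shuffles=cfg.n_shuffles,
                )
            hits.append(hit)
        hits.sort(key=lambda h: (
            h.category if h.category is not None else 99,
            h.p_value if h.p_value is not None else 2.0,
            h.site.alignment.target_id,
            h.site.alignment.target_start,
        ))
        results[lib_name] = hits
    return results


def profiles_from_table(rows, transcriptome_ids=None) -> dict[str, DegradomeProfile]:
    """Build profiles from pre-mapped (transcript_id, position, count) rows."""
    profiles: dict[str, DegradomeProfile] = {}
    total = 0
    for tid, pos, count in rows:
        prof = profiles.setdefault(tid, DegradomeProfile(transcript_id=tid))
        prof.counts[int(pos)] = prof.counts.get(int(pos), 0) + int(count)
        total += int(count)
    if transcriptome_ids:
        for tid in transcriptome_ids:
            profiles.setdefault(tid, DegradomeProfile(transcript_id=tid))
    for prof in profiles.values():
        prof.library_size = total
    return profiles
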