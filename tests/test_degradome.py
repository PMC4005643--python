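import numpy as np
import pytest

from bulgescan.degradome import (
    DegradomeProfile,
    PipelineConfig,
    categorize_site,
    map_degradome,
    profiles_from_table,
    run_degradome_pipeline,
    site_pvalue,
)
from bulgescan.seqio import NucleotideSequence
from bulgescan.synthetic import (
    DegradomeSpec,
    SimulationConfig,
    SiteSpec,
    make_transcriptome,
    simulate_degradome,
)
from bulgescan import MIR398A


def _seq(residues, sid="t"):
    return NucleotideSequence(id=sid, residues=residues)


def _profile(counts, tid="t"):
    p = DegradomeProfile(transcript_id=tid, counts=dict(counts))
    p.library_size = sum(counts.values())
    return p


# ---------------------------------------------------------------- mapping

def test_map_single_read(rng):
    from helpers import random_rna

    tx = _seq(random_rna(rng, 300))
    read = _seq(tx.residues[99:124], "r1")  # 5' end at position 100
    (prof,) = map_degradome([read], [tx])
    assert prof.counts == {100: 1}
    assert prof.library_size == 1


def test_multimapping_read_counts_every_locus(rng):
    from helpers import random_rna

    core = random_rna(rng, 40)
    t1 = _seq(random_rna(rng, 30) + core + random_rna(rng, 30), "t1")
    t2 = _seq(random_rna(rng, 50) + core + random_rna(rng, 10), "t2")
    read = _seq(core[:20], "r")
    profiles = {p.transcript_id: p for p in map_degradome([read], [t1, t2])}
    assert profiles["t1"].counts.get(31) == 1
    assert profiles["t2"].counts.get(51) == 1
    # library size counts placements, so per-million sums to 1e6
    total = sum(
        p.normalized(pos) for p in profiles.values() for pos in p.counts
    )
    assert total == pytest.approx(1e6)


def test_short_reads_skipped(rng):
    from helpers import random_rna

    tx = _seq(random_rna(rng, 100))
    (prof,) = map_degradome([_seq("ACGUACGU", "tiny")], [tx])
    assert prof.counts == {}


def test_prefix_len_precondition(rng):
    with pytest.raises(ValueError):
        map_degradome([], [], prefix_len=10)


def test_mapping_reproduces_simulated_ground_truth():
    """Mapping the simulated library recovers the generator's count table
    exactly when all reads map uniquely."""
    cfg = SimulationConfig(
        seed=11, n_transcripts=3, transcript_len=400,
        site_specs=(SiteSpec(mirna=MIR398A, offset=101),),
        degradome=DegradomeSpec(signal_reads=20, background_rate=0.02),
    )
    tx, truth = make_transcriptome(cfg)
    reads, table = simulate_degradome(truth, cfg)
    profiles = {p.transcript_id: p for p in map_degradome(reads, tx)}
    mapped = {tid: profiles[tid].counts for tid in table}
    assert mapped == {tid: dict(pos) for tid, pos in table.items()}
    n_placements = sum(sum(c.values()) for c in mapped.values())
    assert n_placements == sum(1 for r in reads if len(r) >= 20)


# ------------------------------------------------------------ categories

@pytest.mark.parametrize("counts,pos,expected", [
    ({10: 50, 20: 3, 30: 1}, 10, 0),    # unique maximum
    ({10: 50, 20: 50, 30: 1}, 10, 1),   # shared maximum
    ({10: 5, 20: 9, 30: 2, 40: 2}, 10, 2),  # above median, below max
    ({10: 2, 20: 9, 30: 2, 40: 2}, 10, 3),  # at or below median
    ({10: 1}, 10, 4),                   # single read: category 4
    ({10: 0, 20: 5}, 10, None),         # zero support: no hit
    ({}, 10, None),                     # empty profile
])
def test_categorize_site_rules(counts, pos, expected):
    assert categorize_site(_profile(counts), pos) == expected


def test_categories_partition_all_supported_sites(rng):
    """Every position with >= 1 read gets exactly one category 0-4."""
    for _ in range(50):
        n = int(rng.integers(1, 12))
        counts = {int(p): int(c) for p, c in zip(
            rng.choice(500, size=n, replace=False),
            rng.integers(1, 30, size=n),
        )}
        prof = _profile(counts)
        for pos, c in counts.items():
            cat = categorize_site(prof, pos)
            assert cat in (0, 1, 2, 3, 4)
            if c == 1:
                assert cat == 4


# -------------------------------------------------------------- p-values

def _small_world(seed=3):
    cfg = SimulationConfig(
        seed=seed, n_transcripts=2, transcript_len=300,
        site_specs=(SiteSpec(mirna=MIR398A, offset=101),),
        degradome=DegradomeSpec(signal_reads=30, background_rate=0.01),
    )
    tx, truth = make_transcriptome(cfg)
    reads, _ = simulate_degradome(truth, cfg)
    return cfg, tx, truth, reads


def test_pvalue_requires_shuffles(model):
    cfg, tx, truth, reads = _small_world()
    res = run_degradome_pipeline([MIR398A], tx, {"lib": reads},
                                 PipelineConfig(stride=5), model)
    hit = res["lib"][0]
    profiles = {p.transcript_id: p for p in map_degradome(reads, tx)}
    with pytest.raises(ValueError):
        site_pvalue(hit, MIR398A, tx, profiles, n_shuffles=0, seed=1, model=model)


def test_pvalue_floor_and_strong_site(model):
    """The add-one estimator never returns below 1/(1+n), and a strong
    implanted site reaches that floor against a shuffled-miRNA null."""
    cfg, tx, truth, reads = _small_world()
    res = run_degradome_pipeline([MIR398A], tx, {"lib": reads},
                                 PipelineConfig(stride=5), model)
    hit = res["lib"][0]
    assert hit.category == 0
    profiles = {p.transcript_id: p for p in map_degradome(reads, tx)}
    n = 19
    p = site_pvalue(hit, MIR398A, tx, profiles, n_shuffles=n, seed=5,
                    model=model, stride=5)
    assert p >= 1 / (1 + n) - 1e-12
    assert p <= 0.05


# -------------------------------------------------------------- pipeline

def test_pipeline_finds_implanted_bulged_site(model):
    cfg, tx, truth, reads = _small_world()
    res = run_degradome_pipeline([MIR398A], tx, {"lib": reads},
                                 PipelineConfig(stride=1), model)
    hits = [h for h in res["lib"] if h.category is not None]
    assert len(hits) == 1
    hit = hits[0]
    assert hit.site.slice_position == truth.sites[0].slice_position
    assert hit.category == 0
    assert hit.reads_at_slice == 30


def test_pipeline_central_mutation_yields_no_slice_competent_hits(model):
    """The 2m-style central mutation abolishes predicted slicing."""
    cfg = SimulationConfig(
        seed=4, n_transcripts=2, transcript_len=300,
        site_specs=(SiteSpec(mirna=MIR398A, offset=101, mismatches=(10, 11)),),
        degradome=DegradomeSpec(signal_reads=30, background_rate=0.01),
    )
    tx, truth = make_transcriptome(cfg)
    reads, _ = simulate_degradome(truth, cfg)
    res = run_degradome_pipeline([MIR398A], tx, {"lib": reads},
                                 PipelineConfig(stride=1), model)
    assert res["lib"] == []


def test_pipeline_empty_degradome_reports_no_hits(model):
    cfg, tx, truth, _ = _small_world()
    res = run_degradome_pipeline([MIR398A], tx, {"lib": []},
                                 PipelineConfig(stride=5), model)
    assert res["lib"]
    assert all(h.category is None and h.reads_at_slice == 0 for h in res["lib"])


def test_profiles_from_table():
    profiles = profiles_from_table([("t1", 100, 5), ("t1", 100, 2), ("t2", 7, 1)])
    assert profiles["t1"].counts == {100: 7}
    assert profiles["t2"].library_size == 8
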