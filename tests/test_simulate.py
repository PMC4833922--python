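"""Simulator determinism, geometry, noise statistics, and truth recovery."""

import math

import numpy as np
import pytest

from ampcall import (
    ConfigError,
    PanelConfig,
    ReadSimConfig,
    Variant,
    bin_pair,
    build_tile_index,
    call_sample,
    make_panel,
    revcomp,
)
from ampcall.reads import Read, ReadPair
from ampcall.simulate import (
    PlantedVariant,
    random_truth,
    simulate_reads,
    write_fastq,
    write_panel,
)


def to_pairs(recs1, recs2):
    out = []
    for (id1, b1, q1), (id2, b2, q2) in zip(recs1, recs2):
        out.append(
            ReadPair(
                r1=Read(id1, b1, tuple(ord(c) - 33 for c in q1)),
                r2=Read(id2, b2, tuple(ord(c) - 33 for c in q2)),
            )
        )
    return out


class TestMakePanel:
    def test_primers_are_reference_flanks(self):
        panel = make_panel(PanelConfig(n_tiles=4, seed=5))
        ref = panel.reference[panel.config.chrom]
        for tile in panel.tiles:
            s = tile.spec
            fwd_flank = ref[s.start - 1 - panel.config.primer_len : s.start - 1]
            rev_flank = ref[s.end : s.end + panel.config.primer_len]
            assert tile.fwd_primer.sequence == fwd_flank
            assert tile.rev_primer.sequence == revcomp(rev_flank)

    def test_prefixes_unique_and_indexable(self):
        panel = make_panel(PanelConfig(n_tiles=8, seed=5))
        index = build_tile_index(
            panel.specs, panel.primers, panel.reference, panel.config.primer_len
        )
        assert len(index.entries) == 16

    def test_deterministic_per_seed(self, tmp_path):
        files = []
        for sub in ("a", "b"):
            d = tmp_path / sub
            d.mkdir()
            panel = make_panel(PanelConfig(n_tiles=5, seed=9))
            write_panel(panel, str(d / "r.fa"), str(d / "c.tsv"), str(d / "s.tsv"))
            files.append(d)
        for name in ("r.fa", "c.tsv", "s.tsv"):
            assert (files[0] / name).read_bytes() == (files[1] / name).read_bytes()

    def test_different_seeds_differ(self):
        a = make_panel(PanelConfig(n_tiles=3, seed=1))
        b = make_panel(PanelConfig(n_tiles=3, seed=2))
        assert a.reference != b.reference

    def test_zero_tiles(self):
        panel = make_panel(PanelConfig(n_tiles=0, seed=1))
        assert panel.specs == [] and panel.primers == {}

    def test_tiles_non_overlapping(self):
        panel = make_panel(PanelConfig(n_tiles=10, seed=2))
        spans = sorted((s.start, s.end) for s in panel.specs)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 < s2


class TestSimulateReads:
    def _panel(self):
        return make_panel(PanelConfig(n_tiles=2, insert_len=60, primer_len=15, seed=3))

    def test_noiseless_vaf1_all_pairs_carry_variant(self):
        panel = self._panel()
        tile = panel.tiles[0]
        var = Variant(
            tile.spec.chrom, tile.spec.start + 20,
            tile.insert_ref[20], "A" if tile.insert_ref[20] != "A" else "C",
        )
        truth = [PlantedVariant(var, 1.0, "s1")]
        reads = simulate_reads(
            panel, truth, ReadSimConfig(depth=50, error_rate=0.0, seed=4)
        )
        recs1, recs2 = reads["s1"]
        index = build_tile_index(panel.specs, panel.primers, panel.reference, 15)
        hits = 0
        for pair in to_pairs(recs1, recs2):
            bound = bin_pair(pair, index)
            if bound.tile.key != tile.key:
                continue
            assert bound.insert_fwd.bases[20] == var.alt
            assert bound.insert_rev.bases[20] == var.alt
            hits += 1
        assert hits == 50

    def test_error_rate_binomial_mean(self):
        """Observed per-read mismatch count matches Binomial(read_len, e)."""
        panel = self._panel()
        rate = 0.005
        cfg = ReadSimConfig(depth=500, error_rate=rate, read_len=90, seed=8)
        reads = simulate_reads(panel, [], cfg, samples=["s1"])
        recs1, _ = reads["s1"]
        core_by_tile = {
            t.spec.fwd_name: (
                t.fwd_primer.sequence + t.insert_ref + revcomp(t.rev_primer.sequence)
            )[:90]
            for t in panel.tiles
        }
        total_mm, total_bases = 0, 0
        for rid, bases, _q in recs1:
            core = core_by_tile[rid.split(":")[1]]
            total_mm += sum(a != b for a, b in zip(bases, core))
            total_bases += len(core)
        observed = total_mm / total_bases
        se = math.sqrt(rate * (1 - rate) / total_bases)
        assert abs(observed - rate) < 3 * se

    def test_deterministic_fastq_bytes(self, tmp_path):
        panel = self._panel()
        paths = []
        for sub in ("a", "b"):
            d = tmp_path / sub
            d.mkdir()
            reads = simulate_reads(
                panel, [], ReadSimConfig(depth=20, seed=6), samples=["s1"]
            )
            p = d / "r1.fastq"
            write_fastq(reads["s1"][0], str(p))
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_exact_counts_mode(self):
        panel = self._panel()
        tile = panel.tiles[0]
        var = Variant(
            tile.spec.chrom, tile.spec.start + 30,
            tile.insert_ref[30], "A" if tile.insert_ref[30] != "A" else "C",
        )
        truth = [PlantedVariant(var, 0.4, "s1")]
        cfg = ReadSimConfig(depth=40, error_rate=0.0, exact_counts=True, seed=2)
        reads = simulate_reads(panel, truth, cfg)
        recs1, _ = reads["s1"]
        carriers = sum(
            1
            for rid, bases, _q in recs1
            if rid.split(":")[1] == tile.spec.fwd_name
            and bases[15 + 30] == var.alt
        )
        assert carriers == 16  # round(0.4 * 40)

    def test_read_too_short_rejected(self):
        panel = self._panel()
        with pytest.raises(ConfigError, match="read_len"):
            simulate_reads(panel, [], ReadSimConfig(read_len=10, seed=1))

    def test_off_panel_reads_unassigned(self):
        panel = self._panel()
        cfg = ReadSimConfig(depth=200, error_rate=0.0, off_panel_fraction=0.3, seed=5)
        reads = simulate_reads(panel, [], cfg, samples=["s1"])
        index = build_tile_index(panel.specs, panel.primers, panel.reference, 15)
        recs1, recs2 = reads["s1"]
        for pair in to_pairs(recs1, recs2):
            bound = bin_pair(pair, index)
            if ":offpanel" in pair.r1.id:
                assert bound is None
            else:
                assert bound is not None


def test_noiseless_end_to_end_recovers_truth_exactly(tmp_path):
    """With zero sequencing error the PASS set equals the planted truth."""
    panel = make_panel(PanelConfig(n_tiles=6, seed=13))
    rng = np.random.default_rng(13)
    truth = random_truth(panel, ["s1"], rng, snv_per_sample=3, indel_per_sample=2)
    reads = simulate_reads(
        panel, truth, ReadSimConfig(depth=60, error_rate=0.0, seed=13)
    )
    d = tmp_path
    write_panel(panel, str(d / "r.fa"), str(d / "c.tsv"), str(d / "s.tsv"))
    f1, f2 = str(d / "s1_r1.fastq"), str(d / "s1_r2.fastq")
    write_fastq(reads["s1"][0], f1)
    write_fastq(reads["s1"][1], f2)
    index = build_tile_index(panel.specs, panel.primers, panel.reference, 20)
    result = call_sample("s1", f1, f2, index)
    passed = {c.variant for c in result.calls if c.passed}
    assert passed == {t.variant for t in truth}
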