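"""Barcode extraction, greedy sphere clustering, cluster retention, QC."""

import numpy as np
import pytest

from trescreen import counting
from trescreen.counting import (
    BarcodeCluster,
    FastqError,
    RawBarcodeTally,
    count_sample,
    extract_barcodes,
    qc_flag,
    retain_clusters,
    sphere_cluster,
)
from trescreen.dictionary import BarcodeDictionary, DictionaryEntry

from conftest import dp_levenshtein

A24 = "A" * 24
SPIKE = "G" * 24 + "TTTT"


def make_dict(mapping):
    entries = {
        bc: DictionaryEntry(bc, prom, prom.split("|")[0], "minTK", 1)
        for bc, prom in mapping.items()
    }
    return BarcodeDictionary(entries=entries)


class TestExtract:
    def test_takes_first_24_nt(self):
        t = extract_barcodes(["ACGT" * 6 + "TTTT"])
        assert t.counts == {"ACGT" * 6: 1}

    def test_short_read_dropped(self):
        t = extract_barcodes(["ACGT" * 5])
        assert t.dropped_reads == 1 and not t.counts

    def test_n_in_barcode_dropped(self):
        t = extract_barcodes(["N" + "A" * 23 + "CCC"])
        assert t.dropped_reads == 1

    def test_spike_fraction_arithmetic(self):
        reads = [SPIKE] * 100 + [A24] * 900
        t = extract_barcodes(reads, spike_in_refs=[SPIKE])
        assert t.spike_in_counts == {"spike_0": 100}
        assert t.tre_read_fraction == pytest.approx(0.9)


def brute_force_sphere(counts, radius):
    order = sorted(counts, key=lambda bc: (-counts[bc], bc))
    assigned, clusters = set(), []
    for c in order:
        if c in assigned:
            continue
        assigned.add(c)
        members = {c: counts[c]}
        for bc in sorted(counts):
            if bc not in assigned and dp_levenshtein(c, bc) <= radius:
                members[bc] = counts[bc]
                assigned.add(bc)
        clusters.append((c, members))
    return clusters


class TestSphereCluster:
    def test_single_error_absorbed_into_abundant_centroid(self):
        t = RawBarcodeTally("s", {A24: 100, "A" * 23 + "T": 2})
        cl = sphere_cluster(t)
        assert len(cl) == 1
        assert cl[0].centroid == A24 and cl[0].total == 102

    def test_radius_zero_is_identity(self):
        counts = {A24: 3, "C" * 24: 1}
        cl = sphere_cluster(RawBarcodeTally("s", counts), radius=0)
        assert len(cl) == 2 and all(len(c.members) == 1 for c in cl)

    def test_count_tie_takes_lexicographically_smaller_centroid(self):
        b = "C" + "A" * 23
        cl = sphere_cluster(RawBarcodeTally("s", {A24: 10, b: 10}))
        assert len(cl) == 1 and cl[0].centroid == A24 and cl[0].total == 20

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 200))
        base = ["".join(rng.choice(list("ACGT"), 24)) for _ in range(n // 3 + 1)]
        counts = {}
        for _ in range(n):
            bc = list(base[rng.integers(len(base))])
            for _ in range(rng.integers(0, 2)):
                bc[rng.integers(24)] = "ACGT"[rng.integers(4)]
            counts["".join(bc)] = counts.get("".join(bc), 0) + int(rng.integers(1, 50))
        got = sphere_cluster(RawBarcodeTally("s", counts))
        expect = brute_force_sphere(counts, 1)
        assert [(c.centroid, c.members) for c in got] == expect

    def test_cluster_totals_conserve_reads(self):
        rng = np.random.default_rng(11)
        counts = {
            "".join(rng.choice(list("ACGT"), 24)): int(rng.integers(1, 100))
            for _ in range(150)
        }
        cl = sphere_cluster(RawBarcodeTally("s", counts))
        assert sum(c.total for c in cl) == sum(counts.values())
        members = [bc for c in cl for bc in c.members]
        assert sorted(members) == sorted(counts)  # partition


class TestRetention:
    B2 = "A" * 23 + "T"  # distance 1 from A24

    def test_centroid_in_dict_members_absent_retained(self):
        d = make_dict({A24: "P|minTK"})
        cl = [BarcodeCluster(A24, {A24: 5, self.B2: 1})]
        out = retain_clusters(cl, d)
        assert out.accepted == {A24: 6}

    def test_member_mapping_to_other_promoter_discards_cluster(self):
        d = make_dict({A24: "P|minTK", self.B2: "Q|minTK"})
        cl = [BarcodeCluster(A24, {A24: 5, self.B2: 1})]
        assert retain_clusters(cl, d).accepted == {}

    def test_member_mapping_to_same_promoter_retained(self):
        d = make_dict({A24: "P|minTK", self.B2: "P|minTK"})
        cl = [BarcodeCluster(A24, {A24: 5, self.B2: 3})]
        assert retain_clusters(cl, d).accepted == {A24: 8}

    def test_centroid_absent_discards_even_if_member_present(self):
        d = make_dict({self.B2: "P|minTK"})
        cl = [BarcodeCluster(A24, {A24: 5, self.B2: 1})]
        assert retain_clusters(cl, d).accepted == {}


class TestQcFlag:
    def _sample(self, frac):
        return counting.SampleCounts("s", {}, qc={"tre_read_fraction": frac})

    def test_typical_sample_not_flagged(self):
        s = qc_flag(self._sample(0.9), [0.9, 0.9, 0.9])
        assert s.qc["flagged"] is False

    def test_low_fraction_sample_flagged(self):
        s = qc_flag(self._sample(0.2), [0.9, 0.9, 0.2])
        assert s.qc["flagged"] is True

    def test_single_sample_cohort_uses_absolute_floor(self):
        assert qc_flag(self._sample(0.8), [0.8]).qc["flagged"] is False
        assert qc_flag(self._sample(0.4), [0.4]).qc["flagged"] is True


class TestEndToEnd:
    def test_error_free_counts_match_simulated_truth(self, small_screen):
        screen, _ = small_screen
        d = make_dict(screen.truth.barcode_to_promoter)
        sid = screen.counts.meta.sample_id.iloc[0]
        sc = count_sample(
            screen.sample_reads[sid], d, screen.spike_in_refs, sample_id=sid
        )
        truth_col = screen.counts.values[sid]
        for bc, c in sc.accepted.items():
            assert c == truth_col[bc]
        assert sum(sc.accepted.values()) == int(truth_col.sum())

    def test_errored_reads_recovered_into_clusters(self, small_screen):
        # with barcodes >= 3 edits apart, radius-1 clustering recovers all
        # single-error reads: accepted >= the number of error-free reads
        _, units = small_screen
        from trescreen import simulate
        from trescreen.design import DesignConfig

        cfg = simulate.SimulationConfig(
            n_barcodes_per_promoter=4, dna_depth=60, rna_depth=60,
            substitution_error_rate=0.01, spike_in_fraction=0.0,
        )
        screen = simulate.simulate_screen(units, DesignConfig(), cfg, seed=9)
        d = make_dict(screen.truth.barcode_to_promoter)
        sid = screen.counts.meta.sample_id.iloc[1]
        sc = count_sample(screen.sample_reads[sid], d, [], sample_id=sid)
        # error-free reads per barcode
        from collections import Counter

        exact = Counter(
            r[:24] for r in screen.sample_reads[sid]
            if r[:24] in screen.truth.barcode_to_promoter
        )
        for bc, n_exact in exact.items():
            assert sc.accepted.get(bc, 0) >= n_exact


def test_fastq_reader_rejects_malformed_records(tmp_path):
    p = tmp_path / "bad.fastq"
    p.write_text("@r1\nACGT\n+\nIIII\nBADHEADER\nACGT\n+\nIIII\n")
    with pytest.raises(FastqError, match="index 1"):
        list(counting.read_fastq_seqs(p))
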