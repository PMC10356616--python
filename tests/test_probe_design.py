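"""Probe design: melting temperatures, window scan, specificity, assembly,
codebook construction and order-sheet I/O."""

import numpy as np
import pytest
from Bio.SeqUtils import MeltingTemp as mt
from hypothesis import given, settings
from hypothesis import strategies as st

from plantfish import probe_design as pdn

SEQ = st.text(alphabet="ACGT", min_size=10, max_size=40)


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestComputeTm:
    def test_frozen_hand_summed_value(self):
        # 20-mer summed by hand from the printed unified NN table
        # (ΔH=-152.8+4.4? -> Tm 55.2049 °C at 50 mM Na+, 100 nM oligo)
        assert pdn.compute_tm("AGCGTTGCTAGGCATCATTT", 50, 100) == pytest.approx(55.2049, abs=1e-3)

    def test_agrees_with_biopython_nn(self, rng):
        for _ in range(50):
            s = random_seq(rng, int(rng.integers(8, 61)))
            if s == pdn.reverse_complement(s):
                continue  # Biopython switches to the self-complementary duplex model
            ref = mt.Tm_NN(s, nn_table=mt.DNA_NN4, Na=50, dnac1=100, dnac2=0, saltcorr=5)
            assert pdn.compute_tm(s, 50, 100) == pytest.approx(ref, abs=1e-6)

    @given(SEQ.filter(lambda s: len(s) >= 10))
    @settings(max_examples=50, deadline=None)
    def test_reverse_complement_symmetry(self, seq):
        assert pdn.compute_tm(seq) == pytest.approx(
            pdn.compute_tm(pdn.reverse_complement(seq)), abs=1e-9
        )

    def test_gc_rich_melts_higher_than_at_rich(self):
        assert pdn.compute_tm("G" * 11 + "C" * 11) > pdn.compute_tm("A" * 11 + "T" * 11)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            pdn.compute_tm("ACGTACG")

    def test_prefix_summation_matches_direct(self, rng):
        seq = random_seq(rng, 200)
        pre = pdn._TmPrefix(seq, 50.0, 100.0)
        for _ in range(20):
            i = int(rng.integers(0, 170))
            j = i + int(rng.integers(10, 30))
            assert pre.tm(i, j) == pytest.approx(pdn.compute_tm(seq[i:j]), abs=1e-9)


class TestScanWindows:
    def test_gc_fraction_definition(self):
        win = "GC" * 11 + "AT" * 11  # 44 nt, 22 G/C
        assert pdn.gc_fraction(win) == 0.5

    def test_homopolymer_yields_nothing(self):
        gene = pdn.TargetGene("polyA", "A" * 200)
        assert pdn.scan_candidate_windows(gene) == []

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError):
            pdn.TargetGene("bad", "ACGTN" * 20)

    def test_matches_brute_force_enumeration(self, rng):
        seq = random_seq(rng, 300)
        gene = pdn.TargetGene("g", seq)
        cfg = pdn.DesignConfig()
        got = pdn.scan_candidate_windows(gene, cfg)

        expected = []
        for start in range(0, 300):
            for length in range(cfg.window_len_min, cfg.window_len_max + 1):
                end = start + length
                if end > len(seq):
                    continue
                window = seq[start:end]
                if not cfg.gc_min <= pdn.gc_fraction(window) <= cfg.gc_max:
                    continue
                best = None
                for plp_len in range(cfg.half_len_min, cfg.half_len_max + 1):
                    primer_len = length - cfg.gap_nt - plp_len
                    if not cfg.half_len_min <= primer_len <= cfg.half_len_max:
                        continue
                    tm_a = mt.Tm_NN(
                        seq[start : start + plp_len],
                        nn_table=mt.DNA_NN4, Na=50, dnac1=100, dnac2=0, saltcorr=5,
                    )
                    tm_b = mt.Tm_NN(
                        seq[start + plp_len + cfg.gap_nt : end],
                        nn_table=mt.DNA_NN4, Na=50, dnac1=100, dnac2=0, saltcorr=5,
                    )
                    obj = abs(tm_a - 60) + abs(tm_b - 60)
                    if best is None or obj < best[0]:
                        best = (obj, plp_len, tm_a, tm_b)
                if best is None:
                    continue
                if abs(best[2] - 60) > 5 or abs(best[3] - 60) > 5:
                    continue
                expected.append((start, end, best[1]))

        assert [(w.start, w.end, len(w.plp_half)) for w in got] == expected

    def test_emitted_windows_satisfy_invariants(self, rng):
        gene = pdn.TargetGene("g", random_seq(rng, 500))
        for w in pdn.scan_candidate_windows(gene):
            assert 40 <= w.length <= 50
            assert 0.40 <= w.gc <= 0.60
            assert 20 <= len(w.plp_half) <= 25
            assert 20 <= len(w.primer_half) <= 25
            assert w.gap_nt == 2
            assert len(w.plp_half) + w.gap_nt + len(w.primer_half) == w.length
            assert abs(w.tm_plp - 60) <= 5 and abs(w.tm_primer - 60) <= 5


class TestSpecificity:
    def _window(self, seq, start=0):
        gene = pdn.TargetGene("t", seq)
        wins = pdn.scan_candidate_windows(gene)
        assert wins, "fixture transcript must yield at least one window"
        return wins[0]

    def test_self_only_record_passes(self, rng):
        seq = random_seq(rng, 200)
        win = self._window(seq)
        ok, hits = pdn.specificity_screen(win, {"t": seq}, "t")
        assert ok and hits == []

    def test_exact_copy_under_other_id_fails(self, rng):
        seq = random_seq(rng, 200)
        win = self._window(seq)
        ok, hits = pdn.specificity_screen(
            win, {"t": seq, "copy": win.plp_half + win.primer_half}, "t"
        )
        assert not ok and hits == ["copy"]

    def test_planted_kmer_flags_exactly_that_record(self, rng):
        seq = random_seq(rng, 300)
        win = self._window(seq)
        planted = win.plp_half[:15]
        txome = {"t": seq}
        for i in range(10):
            txome[f"bg{i}"] = random_seq(rng, 1000)
        txome["hit"] = random_seq(rng, 500) + planted + random_seq(rng, 485)
        ok, hits = pdn.specificity_screen(win, txome, "t", k=15)
        assert not ok and hits == ["hit"]


class TestSelectProbeSet:
    def test_empty_candidates(self):
        assert pdn.select_probe_set([], 4) == ([], True)

    def test_greedy_choice_is_best_compatible(self, rng):
        gene = pdn.TargetGene("g", random_seq(rng, 400))
        candidates = pdn.scan_candidate_windows(gene)
        chosen, short = pdn.select_probe_set(candidates, 4)
        assert len(chosen) <= 4
        for a in chosen:
            for b in chosen:
                assert a is b or not a.overlaps(b)
        # independent re-derivation of the greedy order
        ranked = sorted(candidates, key=lambda w: (w.tm_objective, w.start))
        picked = []
        for w in ranked:
            if len(picked) == 4:
                break
            if all(not w.overlaps(p) for p in picked):
                picked.append(w)
        assert sorted(chosen, key=lambda w: w.start) == sorted(picked, key=lambda w: w.start)

    def test_disjoint_perfect_candidates_all_kept(self, rng):
        gene = pdn.TargetGene("g", random_seq(rng, 2000))
        candidates = pdn.scan_candidate_windows(gene)
        chosen, short = pdn.select_probe_set(candidates, 4)
        assert len(chosen) == 4 and not short


class TestAssembly:
    @pytest.fixture
    def pair(self, rng):
        seq = random_seq(rng, 300)
        gene = pdn.TargetGene("g", seq)
        win = pdn.scan_candidate_windows(gene)[0]
        barcode = "ACCGTTAGCAGATTGCCAGT"
        return pdn.assemble_snail_pair("g", win, barcode, "BC001", transcript=seq), win, barcode

    def test_padlock_arm_recovers_target_footprint(self, pair):
        snail, win, _ = pair
        assert snail.padlock_seq.startswith(pdn.reverse_complement(win.plp_half))
        assert snail.primer_seq.startswith(pdn.reverse_complement(win.primer_half))

    def test_circularization_gap_zero(self, pair):
        snail, _, _ = pair
        assert pdn.circularization_gap(snail) == 0

    def test_oligo_lengths_follow_config_arithmetic(self, pair):
        snail, win, barcode = pair
        cfg = pdn.DesignConfig()
        assert len(snail.padlock_seq) == (
            len(win.plp_half) + len(cfg.linker_5) + len(barcode) + len(cfg.linker_3)
            + len(cfg.anchor_arm)
        )
        assert len(snail.primer_seq) == (
            len(win.primer_half) + cfg.splint_nt + len(cfg.anchor_arm)
        )

    def test_barcode_sharing_kmer_with_transcript_rejected(self, rng):
        seq = random_seq(rng, 300)
        gene = pdn.TargetGene("g", seq)
        win = pdn.scan_candidate_windows(gene)[0]
        colliding = seq[100:120]
        with pytest.raises(ValueError, match="collides"):
            pdn.assemble_snail_pair("g", win, colliding, "BCbad", transcript=seq)


class TestCodebook:
    def test_capacity_printed_design_points(self):
        assert pdn.codebook_capacity(7, 4) == 28
        assert pdn.codebook_capacity(14, 4, {1: 14, 2: 14, 3: 14, 4: 8}) == 50
        assert pdn.codebook_capacity(0, 4) == 0

    def test_capacity_equals_brute_force_slot_count(self, rng):
        for _ in range(30):
            rounds = int(rng.integers(0, 21))
            channels = int(rng.integers(1, 7))
            limits = {
                c: int(rng.integers(0, rounds + 1))
                for c in range(1, channels + 1)
                if rng.random() < 0.5
            }
            brute = sum(
                1
                for r in range(1, rounds + 1)
                for c in range(1, channels + 1)
                if limits.get(c) is None or r <= limits[c]
            )
            assert pdn.codebook_capacity(rounds, channels, limits) == brute

    def test_28_genes_need_exactly_7_rounds(self):
        cb = pdn.build_codebook([f"g{i}" for i in range(28)], n_channels=4)
        assert cb.n_rounds == 7

    def test_single_gene_gets_first_slot(self):
        cb = pdn.build_codebook(["solo"])
        assert cb.entries["solo"] == (1, 1)

    def test_channel_limit_capacity_edge(self):
        limits = {1: 14, 2: 14, 3: 14, 4: 8}
        genes = [f"g{i}" for i in range(50)]
        cb = pdn.build_codebook(genes, n_rounds=14, channel_round_limit=limits)
        assert len(cb.entries) == 50
        assert all(r <= limits[c] for r, c in cb.entries.values())
        with pytest.raises(ValueError, match="capacity"):
            pdn.build_codebook(genes + ["g50"], n_rounds=14, channel_round_limit=limits)

    def test_slots_row_major_and_injective(self):
        genes = [f"g{i}" for i in range(9)]
        cb = pdn.build_codebook(genes, n_channels=4)
        slots = [cb.entries[g] for g in genes]
        assert slots == [(1, 1), (1, 2), (1, 3), (1, 4), (2, 1), (2, 2), (2, 3), (2, 4), (3, 1)]
        assert len(set(slots)) == len(slots)
        for gene, (r, c) in cb.entries.items():
            assert cb.gene_at(r, c) == gene

    def test_barcodes_orthogonal(self):
        cb = pdn.build_codebook([f"g{i}" for i in range(28)])
        barcodes = list(cb.barcode_seqs.values())
        assert all(len(b) == 20 for b in barcodes)
        for i, a in enumerate(barcodes):
            assert 0.40 <= pdn.gc_fraction(a) <= 0.60
            for b in barcodes[i + 1 :]:
                assert sum(x != y for x, y in zip(a, b)) >= 8

    def test_bridge_links_barcode_to_channel_detection(self):
        cb = pdn.build_codebook([f"g{i}" for i in range(8)])
        for gene, bridge in cb.bridge_seqs.items():
            barcode = cb.barcode_seqs[cb.gene_barcode[gene]]
            channel = cb.entries[gene][1]
            det = cb.detection_seqs[channel][0]
            assert bridge[:15] == pdn.reverse_complement(barcode)[:15]
            assert bridge[15:] == pdn.reverse_complement(det)

    def test_codebook_csv_round_trip(self, tmp_path):
        cb = pdn.build_codebook([f"g{i}" for i in range(6)])
        path = tmp_path / "cb.csv"
        pdn.write_codebook_csv(cb, path)
        back = pdn.read_codebook_csv(path)
        assert back.entries == cb.entries
        assert back.barcode_seqs == cb.barcode_seqs


class TestOrderSheet:
    def test_row_counts_for_one_gene(self, rng, tmp_path):
        seq = random_seq(rng, 1500)
        pairs, cb, _ = pdn.design_probe_sets({"g1": seq})
        sheet = pdn.write_order_sheet(pairs, cb, tmp_path / "sheet.tsv")
        assert (sheet["type"] == "padlock").sum() == 4
        assert (sheet["type"] == "primer").sum() == 4
        assert (sheet["type"] == "bridge").sum() == 1
        assert (sheet["type"] == "detection").sum() == 4

    def test_empty_design_writes_header_only(self, tmp_path):
        cb = pdn.build_codebook(["g"])
        cb.bridge_seqs.clear()
        cb.detection_seqs.clear()
        sheet = pdn.write_order_sheet([], cb, tmp_path / "sheet.tsv")
        assert len(sheet) == 0
        assert (tmp_path / "sheet.tsv").read_text().splitlines()[0].startswith("name\t")

    def test_round_trip_identical(self, rng, tmp_path):
        pairs, cb, _ = pdn.design_probe_sets({"g1": random_seq(rng, 800)})
        path = tmp_path / "sheet.tsv"
        sheet = pdn.write_order_sheet(pairs, cb, path)
        back = pdn.read_order_sheet(path)
        assert back.equals(sheet)
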