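"""Motif scanning, folding energies, landscapes and periodicity."""

import shutil
import subprocess

import numpy as np
import pytest

from riboquad import structure as st

RG4_PROBE = "UGUGGGAGGGGCGGGUCUGGGUGC"
MUT_PROBE = "UGUAGAAAGAGCAGAUCUAGAUGC"
MOTIF = "GGGAGGGAGGGAGGG"


# --- independent brute-force grammar oracle (recursive descent, no regex) ---

def _parse_tracts(s, min_tract, loop_min, loop_max, tracts_left):
    """Can ``s`` be split as G-tract (loop G-tract)*, with the given
    counts and ranges, consuming the whole string?"""
    n = len(s)
    if tracts_left == 1:
        return n >= min_tract and all(c == "G" for c in s)
    for tlen in range(min_tract, n + 1):
        if any(c != "G" for c in s[:tlen]):
            break
        for llen in range(loop_min, loop_max + 1):
            rest = s[tlen + llen :]
            if tlen + llen >= n:
                break
            if _parse_tracts(rest, min_tract, loop_min, loop_max, tracts_left - 1):
                return True
    return False


def brute_force_matches(seq, pattern_id):
    m, lo, hi = st.MOTIF_PATTERNS[pattern_id]
    out = set()
    min_len = 4 * m + 3 * lo
    for i in range(len(seq)):
        if seq[i] != "G":
            continue
        for j in range(i + min_len, len(seq) + 1):
            if seq[j - 1] != "G":
                continue
            if _parse_tracts(seq[i:j], m, lo, hi, 4):
                out.add((i, j))
    return out


class TestScanMotifs:
    def test_rg4_probe_matches(self):
        assert len(st.scan_motifs(RG4_PROBE, "G3N7")) >= 1

    def test_mutant_probe_clean(self):
        assert st.scan_motifs(MUT_PROBE, "G3N7") == []

    def test_g2n1_minimal(self):
        matches = st.scan_motifs("GGAGGAGGAGG", "G2N1")
        assert len(matches) == 1
        assert (matches[0].start, matches[0].end) == (0, 11)

    def test_invalid_alphabet_errors(self):
        with pytest.raises(ValueError):
            st.scan_motifs("GGGTGGG", "G3N7")

    @pytest.mark.parametrize("pattern", ["G3N7", "G2N3"])
    def test_agrees_with_brute_force_oracle(self, pattern, rng):
        for _ in range(40):
            seq = "".join(rng.choice(list("ACGU"), size=120, p=[0.2, 0.2, 0.4, 0.2]))
            found = {(m.start, m.end) for m in st.scan_motifs(seq, pattern)}
            assert found == brute_force_matches(seq, pattern)


class TestFoldEnergy:
    def test_unpairable_sequence_is_zero(self):
        assert st.fold_energy("AAAAAAAAAA") == 0.0
        assert st.fold_energy("AAAAAAAAAA", allow_g4=True) == 0.0

    def test_long_stem_stabilizes(self):
        assert st.fold_energy("GGGGGGAAAACCCCCC") < 0

    def test_quadruplex_option_stabilizes_g_tract_sequence(self):
        assert st.fold_energy(MOTIF, allow_g4=True) < st.fold_energy(MOTIF)

    def test_isolated_pair_scores_nothing(self):
        # a single G..C pair cannot stack -> no stability
        assert st.fold_energy("GAAAAC") == 0.0

    def test_relaxation_on_random_sequences(self, rng):
        saw_pattern = saw_clean = False
        for _ in range(200):
            seq = "".join(rng.choice(list("ACGU"), size=60, p=[0.2, 0.2, 0.35, 0.25]))
            ds = st.fold_energy(seq)
            ds_g4 = st.fold_energy(seq, allow_g4=True)
            assert ds_g4 <= ds <= 0
            if st.scan_motifs(seq, "G3N7"):
                saw_pattern = True
            else:
                saw_clean = True
                assert ds_g4 == ds
        assert saw_pattern and saw_clean

    def test_matches_thermodynamic_engine_qualitatively(self):
        """Sign agreement with RNAfold on stereotypical inputs."""
        if shutil.which("RNAfold") is None:
            pytest.skip("RNAfold not on PATH")

        def mfe(seq):
            out = subprocess.run(
                ["RNAfold", "--noPS"], input=seq, capture_output=True, text=True
            ).stdout
            return float(out.splitlines()[1].rsplit("(", 1)[1].rstrip(")"))

        assert mfe("AAAAAAAAAA") == 0.0 == st.fold_energy("AAAAAAAAAA")
        assert mfe("GGGGGGAAAACCCCCC") < 0
        assert st.fold_energy("GGGGGGAAAACCCCCC") < 0


class TestG4Delta:
    def test_g_free_sequence_has_zero_gain(self):
        t = st.g4_delta("ACACACAUAUGUAUAUACACAC")
        assert t.dg_g4 == 0.0
        assert t.dg_ds == t.dg_ds_g4

    def test_probe_gains_stability(self):
        t = st.g4_delta(RG4_PROBE)
        assert t.dg_g4 > 0
        assert t.dg_g4_signed == -t.dg_g4

    def test_zero_variance_cohort_zscores(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            triples = st.g4_delta_cohort({"a": "AAAA", "b": "AAAA"})
        assert all(t.zscore == 0.0 for t in triples.values())

    def test_cohort_zscores_standardized(self, rng):
        seqs = {
            f"s{i}": "".join(rng.choice(list("ACGU"), size=50)) for i in range(20)
        }
        seqs["g4"] = MOTIF + "A" * 35
        triples = st.g4_delta_cohort(seqs)
        z = np.array([t.zscore for t in triples.values()])
        assert z.mean() == pytest.approx(0.0, abs=1e-9)
        assert z.std() == pytest.approx(1.0, abs=1e-9)


def _plant(centers, n, fill="A"):
    s = list(fill * n)
    for c in centers:
        s[c - 7 : c + 8] = MOTIF
    return "".join(s)


class TestLandscape:
    def test_homopolymer_is_flat_with_no_minima(self):
        ls = st.landscape("A" * 120)
        assert np.all(ls.window_energy == 0)
        assert ls.minima == []

    def test_single_motif_minimum_near_its_center(self):
        ls = st.landscape(_plant([41], 160), anchor=0)
        assert len(ls.minima) == 1
        assert abs(ls.minima[0] - 41) <= 5

    def test_two_motifs_two_ordered_minima(self):
        ls = st.landscape(_plant([41, 82], 220), anchor=0)
        assert len(ls.minima) == 2
        assert ls.minima == sorted(ls.minima)
        assert abs(ls.minima[0] - 41) <= 5 and abs(ls.minima[1] - 82) <= 5

    def test_anchor_translation_equivariance(self):
        seq = _plant([41, 82], 220)
        base = st.landscape(seq, anchor=0).minima
        shifted = st.landscape(seq, anchor=15).minima
        assert [m - 15 for m in base] == shifted

    def test_short_sequence_warns_and_is_empty(self):
        with pytest.warns(UserWarning, match="empty landscape"):
            ls = st.landscape("ACGU" * 5)
        assert len(ls.window_energy) == 0 and ls.minima == []

    def test_track_length_contract(self):
        seq = _plant([41], 100)
        ls = st.landscape(seq)
        assert len(ls.window_energy) == len(seq) - 34


class TestPeriodicity:
    def test_exact_multiples_recover_constructed_period(self):
        p = st.periodicity([40, 80, 120] * 50, max_offset=160)
        assert p.dominant_period == pytest.approx(40.0)

    def test_jittered_41nt_combs_recover_period(self):
        hits = 0
        for seed in range(20):
            g = np.random.default_rng(seed)
            offs = [
                41 * m + g.integers(-2, 3) for _ in range(200) for m in (1, 2, 3)
            ]
            p = st.periodicity(offs, max_offset=160)
            hits += abs(p.dominant_period - 41) <= 2
        assert hits >= 19

    def test_uniform_offsets_have_no_stable_period(self):
        dominant = set()
        for seed in range(10):
            g = np.random.default_rng(seed)
            p = st.periodicity(g.integers(0, 160, size=600), max_offset=160)
            dominant.add(round(p.dominant_period))
        assert len(dominant) >= 3

    def test_too_few_offsets_error_advises_pooling(self):
        with pytest.raises(ValueError, match="pool"):
            st.periodicity([41, 82], max_offset=160)

    def test_planted_periods_recovered(self):
        for period in (30, 41, 50):
            g = np.random.default_rng(period)
            offs = [
                period * m + g.integers(-2, 3)
                for _ in range(70)
                for m in (1, 2, 3)
            ]
            p = st.periodicity(offs, max_offset=int(3.9 * period))
            assert abs(p.dominant_period - period) <= 2


class TestRibosomeSpan:
    def test_human_ribosome_bounds(self):
        assert st.ribosome_span(250) == 38
        assert st.ribosome_span(300) == 46

    def test_unit_distance(self):
        assert st.ribosome_span(6.5) == 1

    def test_non_positive_errors(self):
        with pytest.raises(ValueError):
            st.ribosome_span(0)
        with pytest.raises(ValueError):
            st.ribosome_span(250, -1)
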