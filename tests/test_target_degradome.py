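"""Target-site scanning and degradome cleavage validation."""

import numpy as np
import pandas as pd
import pytest

from peonymir.smallrna_catalog import revcomp
from peonymir.target_degradome import (
    CORE_WEIGHT,
    DegradomeProfile,
    build_profiles,
    categorize,
    predict_targets,
    profile_for,
    validate_cleavage,
)

MIRNA = "ATGCATGCATGCATGCATGCA"  # 21 nt; pos 5 = 'A', pos 15 = 'G', pos 20 = 'C'


def _embed(mirna, at=100, length=400, mutate=None):
    """Transcript with the site's reverse complement at 1-based *at*."""
    rng = np.random.default_rng(0)
    seq = list("".join(rng.choice(list("ACGT"), size=length)))
    site = list(revcomp(mirna))
    if mutate:
        for widx, base in mutate.items():
            site[widx] = base
    seq[at - 1 : at - 1 + len(site)] = site
    return "".join(seq)


def brute_force_scan(mirna, transcript, max_penalty=2.5):
    """Independent all-windows penalty oracle (plain python)."""
    wc = {"A": "T", "C": "G", "G": "C", "T": "A"}
    wobble = {"G": "T", "T": "G"}
    L = len(mirna)
    out = []
    for s0 in range(len(transcript) - L + 1):
        window = transcript[s0 : s0 + L]
        penalty = 0.0
        for i in range(1, L + 1):  # miRNA position, 5'->3'
            t = window[L - i]
            m = mirna[i - 1]
            if t == wc[m]:
                cost = 0.0
            elif wobble.get(m) == t:
                cost = 0.5
            else:
                cost = 1.0
            if 2 <= i <= 13:
                cost *= 2.0
            penalty += cost
        if penalty <= max_penalty:
            out.append((s0 + 1, s0 + L, round(penalty, 6)))
    return out


class TestPredictTargets:
    def test_perfect_complement_penalty_zero_and_cleavage_site(self):
        tr = {"t1": _embed(MIRNA, at=100)}
        sites = predict_targets("m", MIRNA, tr)
        assert len(sites) == 1
        s = sites[0]
        assert s.penalty == 0.0
        assert (s.start, s.end) == (100, 120)
        assert s.alignment == "|" * 21
        # cleavage opposite miRNA position 10: end - 9
        assert s.cleavage_pos == s.end - 9
        assert s.start <= s.cleavage_pos <= s.end

    def test_position_weighting_of_mismatches(self):
        # mismatch at miRNA position 5 (core, x2) -> penalty 2.0
        # miRNA pos 5 = 'A' pairs window index 21-5=16; 'C' is a mismatch
        tr5 = {"t": _embed(MIRNA, mutate={16: "C"})}
        (s5,) = predict_targets("m", MIRNA, tr5)
        assert s5.penalty == 2.0
        assert s5.alignment[4] == "x"
        # mismatch at position 20 (outside core) -> penalty 1.0
        # miRNA pos 20 = 'C' pairs window index 1; 'A' is a mismatch
        tr20 = {"t": _embed(MIRNA, mutate={1: "A"})}
        (s20,) = predict_targets("m", MIRNA, tr20)
        assert s20.penalty == 1.0
        assert s20.alignment[19] == "x"

    def test_gu_wobble_costs_half(self):
        # miRNA pos 15 = 'G' pairs window index 6: target 'T' is a G:U
        # wobble, cost 0.5 (position 15 is outside the weighted core)
        tr = {"t": _embed(MIRNA, mutate={6: "T"})}
        (s,) = predict_targets("m", MIRNA, tr)
        assert s.penalty == 0.5
        assert s.alignment[14] == "o"

    def test_zero_cutoff_keeps_only_perfect_sites(self):
        tr = {"perfect": _embed(MIRNA), "near": _embed(MIRNA, mutate={1: "T"})}
        sites = predict_targets("m", MIRNA, tr, max_penalty=0.0)
        assert [s.transcript_id for s in sites] == ["perfect"]

    def test_mirna_longer_than_transcript_yields_no_sites(self):
        assert predict_targets("m", MIRNA, {"t": "ACGT"}) == []

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        mirnas = ["".join(rng.choice(list("ACGT"), size=21)) for _ in range(3)]
        transcripts = {}
        for i in range(50):
            length = int(rng.integers(200, 5000))
            seq = "".join(rng.choice(list("ACGT"), size=length))
            if i % 3 == 0:  # make sure some windows actually pass
                m = mirnas[i % len(mirnas)]
                pos = int(rng.integers(0, length - len(m)))
                mutated = list(revcomp(m))
                mutated[0] = "ACGT"[int(rng.integers(4))]
                seq = seq[:pos] + "".join(mutated) + seq[pos + len(m):]
            transcripts[f"t{i}"] = seq
        for mi, m in enumerate(mirnas):
            got = [
                (s.transcript_id, s.start, s.end, round(s.penalty, 6))
                for s in predict_targets(f"m{mi}", m, transcripts)
            ]
            expected = [
                (tid, a, b, p)
                for tid in transcripts
                for (a, b, p) in brute_force_scan(m, transcripts[tid])
            ]
            assert sorted(got) == sorted(expected)


class TestProfiles:
    def test_counts_accumulate_per_position(self):
        df = pd.DataFrame(
            {"transcript_id": ["t", "t"], "position": [100, 100], "count": [3, 4]}
        )
        profiles = build_profiles(df, {"t": 200}, "FD")
        assert profiles["t"].counts[99] == 7

    def test_empty_table_gives_no_profiles_and_zero_on_demand(self):
        df = pd.DataFrame(columns=["transcript_id", "position", "count"])
        profiles = build_profiles(df, {"t": 50}, "FD")
        assert profiles == {}
        prof = profile_for(profiles, "t", {"t": 50}, "FD")
        assert prof.total == 0

    def test_out_of_bounds_records_skipped(self, caplog):
        df = pd.DataFrame(
            {"transcript_id": ["t", "t"], "position": [999, 10], "count": [1, 2]}
        )
        profiles = build_profiles(df, {"t": 100}, "FD")
        assert profiles["t"].total == 2

    def test_planted_peak_is_argmax(self, run_dir, truth, transcripts):
        deg = pd.read_csv(run_dir / "degradome_FD.tsv", sep="\t")
        lengths = {t: len(s) for t, s in transcripts.items()}
        profiles = build_profiles(deg, lengths, "FD")
        for _, tid, pos in truth.planted_cleavage_sites:
            assert int(profiles[tid].counts.argmax()) + 1 == pos


def _profile(counts, library="FD"):
    return DegradomeProfile("t", np.asarray(counts, dtype=np.int64), library)


def _site(cleavage_pos, start=1, end=21):
    from peonymir.target_degradome import TargetSite

    return TargetSite("m", "t", start, end, 0.0, "|" * 21, cleavage_pos)


class TestValidateCleavage:
    def test_all_zero_profile_gives_none(self):
        assert validate_cleavage(_site(10), _profile([0] * 30)) is None

    def test_unique_maximum_is_category_zero(self):
        counts = [0] * 30
        counts[9] = 50
        counts[20] = 3
        vc = validate_cleavage(_site(10), _profile(counts))
        assert vc.category == 0 and vc.peak_pos == 10 and vc.peak_count == 50

    def test_tied_maximum_is_category_one(self):
        counts = [0] * 30
        counts[9] = 5
        counts[25] = 5
        assert validate_cleavage(_site(10), _profile(counts)).category == 1

    def test_single_raw_count_is_category_four(self):
        counts = [0] * 30
        counts[9] = 1
        assert validate_cleavage(_site(10), _profile(counts)).category == 4

    def test_between_mean_and_max_is_category_two(self):
        counts = [4] * 29 + [0]
        counts[9] = 10
        counts[5] = 30  # transcript max elsewhere
        vc = validate_cleavage(_site(10), _profile(counts))
        assert vc.category == 2

    def test_peak_found_within_window_of_expected_site(self):
        counts = [0] * 30
        counts[10] = 8  # one position downstream of expected
        vc = validate_cleavage(_site(10), _profile(counts), window=1)
        assert vc.peak_pos == 11
        assert abs(vc.peak_pos - 10) <= 1

    def test_category_monotone_in_peak_count(self):
        rng = np.random.default_rng(9)
        base = rng.integers(0, 6, size=60)
        cats = []
        for peak in range(1, 40):
            counts = base.copy()
            counts[14] = peak
            cats.append(categorize(int(counts[14]), counts))
        assert all(a >= b for a, b in zip(cats, cats[1:]))

    def test_synthetic_validated_pairs_equal_planted_set(self, validated, truth):
        got = {
            (r.mirna_sequence, r.transcript_id) for r in validated.itertuples()
        }
        seq_of = {m.id: m.sequence for m in truth.planted_mirnas}
        planted = {
            (seq_of[mid], tid) for mid, tid, _ in truth.planted_cleavage_sites
        }
        assert got == planted
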