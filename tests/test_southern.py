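import numpy as np
import pytest

from haplokit import southern
from haplokit.errors import ConfigError, DomainError
from haplokit.io_core import GenomicSequence, reverse_complement
from conftest import random_dna


class TestRecognitionSite:
    def test_taqi(self):
        assert southern.TAQI.site == "TCGA"
        assert southern.TAQI.cut_offset == 1
        assert southern.TAQI.palindromic

    def test_bad_offset(self):
        with pytest.raises(ConfigError):
            southern.RecognitionSite("x", "TCGA", 9)

    def test_bad_alphabet(self):
        with pytest.raises(ConfigError):
            southern.RecognitionSite("x", "TCGN", 1)


class TestDigest:
    def test_no_site_single_fragment(self):
        seq = GenomicSequence("s", "AAAACCCCGGGG")
        res = southern.digest(seq, southern.TAQI)
        assert len(res.fragments) == 1
        assert res.fragments[0].length == 12

    def test_worked_example(self):
        # TCGA at 0-based 2 and 8; cuts after the T at offsets 3 and 9
        seq = GenomicSequence("s", "AATCGAAATCGAAA")
        res = southern.digest(seq, southern.TAQI)
        assert [f.length for f in res.fragments] == [3, 6, 5]
        assert res.cut_positions == [3, 9]

    def test_n_window_never_cut(self):
        seq = GenomicSequence("s", "AATCGNAATTT")
        res = southern.digest(seq, southern.TAQI)
        assert len(res.fragments) == 1

    def test_site_at_start(self):
        # cut offset 1 after position 0 -> fragment of 1 bp then remainder
        seq = GenomicSequence("s", "TCGAAAAA")
        res = southern.digest(seq, southern.TAQI)
        assert [f.length for f in res.fragments] == [1, 7]

    def test_conservation_on_random_sequences(self, rng):
        for _ in range(100):
            n = int(rng.integers(20, 2000))
            seq = GenomicSequence("s", random_dna(rng, n))
            res = southern.digest(seq, southern.TAQI)
            assert sum(f.length for f in res.fragments) == n
            assert len(res.fragments) == len(res.cut_positions) + 1

    def test_random_enzymes_conservation(self, rng):
        for _ in range(30):
            site = random_dna(rng, int(rng.integers(4, 7)))
            enzyme = southern.RecognitionSite(
                "e", site, int(rng.integers(0, len(site) + 1))
            )
            n = int(rng.integers(50, 3000))
            seq = GenomicSequence("s", random_dna(rng, n))
            res = southern.digest(seq, enzyme)
            assert sum(f.length for f in res.fragments) == n
            assert len(res.fragments) == len(res.cut_positions) + 1

    def test_nonpalindromic_cuts_both_strands(self):
        enzyme = southern.RecognitionSite("e", "GGTCTC", 6)
        seq = GenomicSequence("s", "AAAGGTCTCAAAAAAGAGACCTTT")
        res = southern.digest(seq, enzyme)
        assert len(res.cut_positions) == 2


# ---------------------------------------------------------------------------
# quadratic-time Smith-Waterman oracle with the same scoring scheme
# ---------------------------------------------------------------------------


def sw_oracle(a: str, b: str):
    """Three-state affine-gap Smith-Waterman with the production scoring
    scheme; returns (matches, aligned pairs, score) of the optimal alignment."""
    NEG = float("-inf")
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    back: dict[tuple, tuple | None] = {}
    best_score, best_cell = 0.0, None
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = (
                southern.MATCH_SCORE
                if a[i - 1] == b[j - 1]
                else southern.MISMATCH_SCORE
            )
            cands = [
                (M[i - 1][j - 1] + s, ("M", i - 1, j - 1)),
                (X[i - 1][j - 1] + s, ("X", i - 1, j - 1)),
                (Y[i - 1][j - 1] + s, ("Y", i - 1, j - 1)),
                (s, None),  # fresh local start
            ]
            M[i][j], back[("M", i, j)] = max(cands, key=lambda t: t[0])
            xc = [
                (M[i - 1][j] + southern.GAP_OPEN, ("M", i - 1, j)),
                (X[i - 1][j] + southern.GAP_EXTEND, ("X", i - 1, j)),
            ]
            X[i][j], back[("X", i, j)] = max(xc, key=lambda t: t[0])
            yc = [
                (M[i][j - 1] + southern.GAP_OPEN, ("M", i, j - 1)),
                (Y[i][j - 1] + southern.GAP_EXTEND, ("Y", i, j - 1)),
            ]
            Y[i][j], back[("Y", i, j)] = max(yc, key=lambda t: t[0])
            if M[i][j] > best_score:
                best_score, best_cell = M[i][j], ("M", i, j)
    if best_cell is None:
        return 0, 0, 0.0
    matches = pairs = 0
    cell = best_cell
    while cell is not None:
        state, i, j = cell
        if state == "M":
            pairs += 1
            if a[i - 1] == b[j - 1]:
                matches += 1
        cell = back[(state, i, j)]
    return matches, pairs, best_score


def oracle_hit(frag_seq, probe, min_identity=0.80, min_overlap=60):
    best = (0, 0)
    for s in (frag_seq, reverse_complement(frag_seq)):
        matches, pairs, _ = sw_oracle(s, probe)
        if matches > best[0]:
            best = (matches, pairs)
    return best[1] >= min_overlap and best[0] / best[1] >= min_identity


class TestHybridize:
    def _run(self, residues, probe, **kw):
        seq = GenomicSequence("s", residues)
        return southern.hybridize(southern.digest(seq, southern.TAQI), seq, probe, **kw)

    def test_exact_internal_substring(self, rng):
        probe = random_dna(rng, 100)
        frag1 = random_dna(rng, 150) + probe + random_dna(rng, 150)
        frag2 = random_dna(rng, 300)
        residues = frag1.replace("TCGA", "TCGT") + "TCGA" + frag2.replace("TCGA", "TCGT")
        res = self._run(residues, probe)
        hits = [f.probe_hit for f in res.fragments]
        assert hits[0] is True
        assert all(not h for h in hits[1:])

    def test_reverse_complement_flagged(self, rng):
        probe = random_dna(rng, 100)
        residues = (random_dna(rng, 50) + reverse_complement(probe)
                    + random_dna(rng, 50)).replace("TCGA", "TCGT")
        res = self._run(residues, probe)
        assert res.fragments[0].probe_hit

    def test_mutated_probe_still_flagged(self, rng):
        target = random_dna(rng, 100)
        probe = list(target)
        idx = rng.choice(100, size=10, replace=False)
        for i in idx:
            probe[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[probe[i]]
        probe = "".join(probe)
        residues = (random_dna(rng, 100) + target + random_dna(rng, 100)).replace(
            "TCGA", "TCGT"
        )
        res = self._run(residues, probe, min_identity=0.80, min_overlap_bp=60)
        assert res.fragments[0].probe_hit
        assert oracle_hit(residues, probe)

    def test_short_probe_rejected(self, rng):
        with pytest.raises(ConfigError):
            self._run(random_dna(rng, 200), "ACGTACGT")

    def test_agrees_with_local_alignment_oracle(self, rng):
        probe = random_dna(rng, 80)
        cases = []
        # homologous fragments at varying divergence + unrelated fragments
        for rate in (0.0, 0.05, 0.1, 0.3):
            target = list(probe)
            for i in np.nonzero(rng.random(80) < rate)[0]:
                target[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[target[i]]
            cases.append(random_dna(rng, 60) + "".join(target) + random_dna(rng, 60))
        cases += [random_dna(rng, 300) for _ in range(4)]
        for residues in cases:
            residues = residues.replace("TCGA", "TCGT")
            res = self._run(residues, probe, min_overlap_bp=60)
            assert res.fragments[0].probe_hit == oracle_hit(residues, probe)


class TestBandPattern:
    def test_close_sizes_merge(self):
        pattern = southern.to_band_pattern([5000.0, 5100.0], tolerance=0.05)
        assert len(pattern.bands) == 1
        assert pattern.bands[0].size_bp == pytest.approx(5050.0)

    def test_distant_sizes_stay_apart(self):
        pattern = southern.to_band_pattern([5000.0, 7000.0], tolerance=0.05)
        assert len(pattern.bands) == 2
        assert [b.size_bp for b in pattern.bands] == [7000.0, 5000.0]  # descending

    def test_empty(self):
        assert southern.to_band_pattern([]).bands == []

    def test_single_linkage_chain(self):
        # consecutive 4% steps merge transitively even though ends differ >5%
        pattern = southern.to_band_pattern([1000.0, 1040.0, 1081.0], tolerance=0.05)
        assert len(pattern.bands) == 1

    def test_fragments_carry_members(self):
        frags = [southern.Fragment("c", 1, 5000), southern.Fragment("c", 6000, 11050)]
        pattern = southern.to_band_pattern(frags, tolerance=0.05)
        assert len(pattern.bands) == 1
        assert set(pattern.bands[0].members) == {"c:1-5000", "c:6000-11050"}

    def test_negative_size_rejected(self):
        with pytest.raises(DomainError):
            southern.to_band_pattern([-5.0])


class TestMatchBands:
    def _pattern(self, sizes):
        return southern.to_band_pattern(list(map(float, sizes)), tolerance=0.01)

    def test_identical_patterns_all_match(self):
        p = self._pattern([3000, 5000, 7000])
        report = southern.match_bands(p, p)
        assert len(report.matches) == 3
        assert not report.unmatched_predicted and not report.unmatched_observed

    def test_extra_observed_bands_unmatched(self):
        predicted = self._pattern([3000, 5000, 7000])
        observed = self._pattern([3000, 5000, 7000, 9000, 12000])
        report = southern.match_bands(predicted, observed)
        assert len(report.matches) == 3
        assert len(report.unmatched_observed) == 2
        assert sorted(b.size_bp for b in report.unmatched_observed) == [9000, 12000]

    def test_one_to_one(self):
        predicted = self._pattern([5000, 5100])
        observed = self._pattern([5050])
        report = southern.match_bands(predicted, observed)
        assert len(report.matches) == 1
        assert len(report.unmatched_predicted) == 1

    def test_tolerance_respected(self):
        report = southern.match_bands(
            self._pattern([1000]), self._pattern([1200]), tolerance=0.05
        )
        assert not report.matches

    def test_report_round_trip_file(self, tmp_path):
        report = southern.match_bands(
            self._pattern([3000, 9000]), self._pattern([3000, 5000])
        )
        out = tmp_path / "match.tsv"
        southern.write_match_report(report, out)
        text = out.read_text()
        assert "matched" in text and "unmatched_predicted" in text


class TestEndToEnd:
    def test_no_dropout_zero_unmatched(self, small_haplotype):
        seqs, truth = small_haplotype
        predicted = []
        for seq in seqs:
            res = southern.hybridize(
                southern.digest(seq, southern.TAQI), seq, truth.probe
            )
            predicted.extend(f for f in res.fragments if f.probe_hit)
        report = southern.match_bands(
            southern.to_band_pattern(predicted),
            southern.to_band_pattern(truth.observed_bands),
        )
        assert report.unmatched_observed == []
        assert report.unmatched_predicted == []
        assert report.matches  # at least one probe-positive band exists
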