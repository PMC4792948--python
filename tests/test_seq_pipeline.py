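"""Window extraction, read classification and position profiling."""

from collections import Counter

import numpy as np
import pytest
from Bio.Seq import reverse_complement

import xovermap as xm
from xovermap.seq_pipeline import (
    default_class_anchors,
    extract_window,
    extract_windows,
    profile_positions,
)
from xovermap.simulator import (
    DONOR_CONTEXT,
    RECIPIENT_CONTEXT,
    library_amplicon,
    left_junction_amplicon,
    right_junction_amplicon,
    simulate_cointegrate_pool,
    simulate_reads,
)
from xovermap.site_model import ALPHABET


@pytest.fixture(scope="module")
def amplicon(site):
    return library_amplicon(site.top_strand)


class TestExtractWindow:
    def test_perfect_template(self, site, anchors, amplicon):
        res = extract_window(amplicon, anchors)
        assert res.ok and res.window == site.window_wt

    def test_reverse_complement_is_canonicalized(self, site, anchors, amplicon):
        res = extract_window(reverse_complement(amplicon), anchors)
        assert res.ok and res.window == site.window_wt and res.strand == "-"

    def test_anchor_over_budget_fails(self, site, anchors, amplicon):
        """Two substitutions in the 5' anchor exceed the 1-mismatch budget."""
        i = amplicon.find(anchors.left)
        bad = amplicon[:i] + "CA" + amplicon[i + 2:]
        assert amplicon[i:i + 2] == "TG"  # mutating T->C, G->A
        res = extract_window(bad, anchors, max_anchor_mismatch=1)
        assert not res.ok and res.reason == "anchor_fail"

    def test_one_anchor_mismatch_is_tolerated(self, site, anchors, amplicon):
        i = amplicon.find(anchors.left)
        near = amplicon[:i] + "C" + amplicon[i + 1:]
        res = extract_window(near, anchors, max_anchor_mismatch=1)
        assert res.ok and res.window == site.window_wt

    def test_insertion_changes_spacing(self, site, anchors, amplicon):
        i = amplicon.find(anchors.left) + len(anchors.left) + 4
        res = extract_window(amplicon[:i] + "GG" + amplicon[i:], anchors)
        assert not res.ok and res.reason == "length_fail"

    def test_ambiguous_window_base(self, site, anchors, amplicon):
        i = amplicon.find(anchors.left) + len(anchors.left) + 2
        res = extract_window(amplicon[:i] + "N" + amplicon[i + 1:], anchors)
        assert not res.ok and res.reason == "ambiguous_base"

    def test_malformed_record_raises(self, anchors):
        with pytest.raises(xm.DataError):
            extract_window(object(), anchors)

    def test_abnormal_fraction_is_rejected(self, site, anchors, amplicon):
        """With anchor-targeted corruption, the rejected read fraction
        matches the injected abnormal fraction within 3 binomial SE, and
        rejections coincide with the simulator's truth labels."""
        depth, frac = 5000, 0.10
        rs = simulate_reads([amplicon], depth=depth, error_rate=0.0,
                            abnormal_fraction=frac, seed=21, anchors=anchors)
        results = [extract_window(s, anchors) for s in rs.sequences()]
        rejected = np.array([not r.ok for r in results])
        truth = (rs.truth["abnormal_mode"] != "").to_numpy()
        se = np.sqrt(frac * (1 - frac) / depth)
        assert abs(rejected.mean() - frac) < 3 * se
        # every clean read passes; corrupted reads overwhelmingly fail
        assert not rejected[~truth].any()
        assert rejected[truth].mean() > 0.99


class TestProfilePositions:
    def test_single_window(self):
        prof = profile_positions(["AAAAAAAAAA"])
        assert prof.frequencies[:, ALPHABET.index("A")].tolist() == [1.0] * 10

    def test_manual_tally_oracle(self):
        """Frequencies equal hand-tallied counts/8 on a toy window set."""
        windows = ["ACG", "ACG", "ATG", "CCG", "ACC", "ACG", "TCG", "ACG"]
        prof = profile_positions(windows)
        for j in range(3):
            tally = Counter(w[j] for w in windows)
            for b in ALPHABET:
                assert prof.counts[j, ALPHABET.index(b)] == tally[b]
        assert prof.frequencies[0, ALPHABET.index("A")] == pytest.approx(6 / 8)
        np.testing.assert_allclose(prof.frequencies.sum(axis=1), 1.0)

    def test_empty_input_raises(self):
        with pytest.raises(xm.DataError):
            profile_positions([])

    def test_exhaustive_library_profile_is_exact(self, site, spec, anchors):
        """Error-free round-robin reads over the nominal 40-molecule library
        reproduce the analytic 92.5/2.5 distribution exactly."""
        templates = [library_amplicon(m) for m in xm.exhaustive_library(spec)]
        rs = simulate_reads(templates, depth=40, error_rate=0.0, seed=0,
                            template_mode="cycle")
        windows, cc = extract_windows(rs.sequences(), anchors)
        assert cc.retained == 40
        prof = profile_positions(windows, wt=site.window_wt)
        for j, wt_base in enumerate(site.window_wt):
            expected = [0.025] * 4
            expected[ALPHABET.index(wt_base)] = 0.925
            np.testing.assert_allclose(prof.frequencies[j], expected)

    def test_idempotence(self, site, spec, anchors):
        """Re-profiling the retained windows reproduces identical counts."""
        templates = [library_amplicon(m) for m in xm.draw_library(spec, 500, 3)]
        rs = simulate_reads(templates, depth=1000, error_rate=0.002,
                            abnormal_fraction=0.05, seed=13, anchors=anchors)
        windows, _ = extract_windows(rs.sequences(), anchors)
        prof1 = profile_positions(windows)
        again, cc = extract_windows(
            [library_amplicon_like(site, w) for w in windows], anchors
        )
        assert cc.retained == len(windows)
        prof2 = profile_positions(again)
        np.testing.assert_array_equal(prof1.counts, prof2.counts)


def library_amplicon_like(site, window):
    """Rebuild a canonical amplicon carrying the given window bases."""
    mol = site.top_strand
    for ordinal, base in enumerate(window, start=1):
        pos = site.randomized_window[ordinal - 1]
        mol = mol[: pos - 1] + base + mol[pos:]
    return library_amplicon(mol)


@pytest.fixture(scope="module")
def class_anchors():
    return default_class_anchors(DONOR_CONTEXT, RECIPIENT_CONTEXT)


class TestClassifyReads:
    def test_known_pool_classifies_diagonally(self, site, spec, class_anchors):
        pool = simulate_cointegrate_pool(spec, 6, 200, seed=2)
        reads = {
            "library": [library_amplicon(m) for m in xm.draw_library(spec, 200, 4)],
            "left_site": pool.left_amplicons,
            "right_site": pool.right_amplicons,
        }
        mixed = [s for group in reads.values() for s in group]
        out = xm.classify_reads(mixed, class_anchors)
        assert not out["unassigned"]
        for label, group in reads.items():
            assert sorted(out[label]) == sorted(group)

    def test_reverse_complement_reads_classify(self, site, class_anchors):
        amp = library_amplicon(site.top_strand)
        out = xm.classify_reads([reverse_complement(amp)], class_anchors)
        assert out["library"] == [reverse_complement(amp)]

    def test_unmatched_read_is_unassigned(self, class_anchors):
        out = xm.classify_reads(["ACGT" * 15], class_anchors)
        assert len(out["unassigned"]) == 1

    def test_indistinguishable_anchor_sets_rejected(self):
        with pytest.raises(xm.ConfigError):
            xm.classify_reads([], {"a": ("AAAA", "CCCC"), "b": ("AAAA", "CCCC")})

    def test_misassignment_under_sequencing_error(self, site, spec,
                                                  class_anchors, anchors):
        """At error 0.001, fewer than 1% of reads leave their true class."""
        pool = simulate_cointegrate_pool(spec, 6, 500, seed=6)
        lib = [library_amplicon(m) for m in xm.draw_library(spec, 500, 7)]
        labels, reads = [], []
        for label, templates in (("library", lib),
                                 ("left_site", pool.left_amplicons),
                                 ("right_site", pool.right_amplicons)):
            rs = simulate_reads(templates, depth=1000, error_rate=0.001,
                                seed=len(label))
            labels += [label] * 1000
            reads += rs.sequences()
        out = xm.classify_reads(reads, class_anchors)
        assigned = {}
        for label, group in out.items():
            for s in group:
                assigned.setdefault(s, label)
        wrong = sum(
            1 for s, true in zip(reads, labels)
            if assigned.get(s) not in (true, "unassigned")
        )
        assert wrong / len(reads) < 0.01


class TestJunctionProfiles:
    def test_profile_junctions_counts_balance(self, site, spec, anchors):
        pool = simulate_cointegrate_pool(spec, 6, 300, seed=8)
        lib = [library_amplicon(m) for m in xm.draw_library(spec, 300, 9)]
        reads = []
        for templates, prefix in ((lib, "lib"),
                                  (pool.left_amplicons, "l"),
                                  (pool.right_amplicons, "r")):
            rs = simulate_reads(templates, depth=400, error_rate=0.001,
                                abnormal_fraction=0.1, seed=10, anchors=anchors,
                                read_id_prefix=prefix)
            reads.extend(rs.records)
        pair = xm.profile_junctions(
            reads, site, default_class_anchors(DONOR_CONTEXT, RECIPIENT_CONTEXT)
        )
        total = sum(cc.total for cc in pair.counts.values())
        assert total == len(reads)
        for prof in (pair.library, pair.left, pair.right):
            np.testing.assert_allclose(prof.frequencies.sum(axis=1), 1.0)

    def test_profile_tsv_roundtrip(self, site, spec, tmp_path):
        from xovermap.seq_pipeline import read_profile, write_profile

        windows = [site.window_bases(m) for m in xm.draw_library(spec, 200, 11)]
        prof = profile_positions(windows, wt=site.window_wt)
        path = tmp_path / "profile.tsv"
        write_profile(prof, path)
        back = read_profile(path)
        np.testing.assert_array_equal(prof.counts, back.counts)
        assert back.wt == site.window_wt
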