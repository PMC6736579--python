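"""MAG partitioning: coverage QC, amplicon matching, read recruitment."""

import math

import numpy as np
import pytest

from ampmag import fixtures, maglink
from ampmag.errors import ConsistencyError, InputError
from ampmag.io_formats import DepthTrack, SeqRecord
from ampmag.maglink import CoverageQC, LinkConfig, MagRecord


def _substitute(seq, positions):
    out = list(seq)
    for p in positions:
        out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
    return "".join(out)


def _track(name, depths):
    return DepthTrack(name, positions=np.arange(len(depths)),
                      depth=np.asarray(depths))


class TestCoverageQC:
    def test_uniform_profile_passes(self):
        gene = _track("g", [20] * 100)
        contig = _track("c", [20] * 400)
        qc = maglink.qc_coverage(("g", (50, 150)), gene, contig)
        assert qc.cv == 0.0
        assert qc.depth_ratio == 1.0
        assert qc.passed

    def test_half_spiked_profile_arithmetic(self):
        """100x on one half, 0 on the other: mean 50, stdev 50 -> cv 1.0;
        vs contig 20x -> ratio 2.5. Passes at cv_max 1.0 (inclusive),
        fails at cv_max 0.5."""
        gene = _track("g", [100] * 50 + [0] * 50)
        contig = _track("c", [20] * 400)
        qc = maglink.qc_coverage(("g", (0, 100)), gene, contig)
        assert qc.cv == pytest.approx(1.0)
        assert qc.depth_ratio == pytest.approx(2.5)
        assert qc.passed  # cv <= 1.0 and 0.25 <= 2.5 <= 4.0
        strict = maglink.qc_coverage(("g", (0, 100)), gene, contig,
                                     LinkConfig(cv_max=0.5))
        assert not strict.passed

    def test_zero_mean_gene_fails_with_infinite_cv(self):
        gene = _track("g", [0] * 100)
        contig = _track("c", [20] * 400)
        qc = maglink.qc_coverage(("g", (0, 100)), gene, contig)
        assert not qc.passed
        assert math.isinf(qc.cv)

    def test_interval_outside_contig_span_rejected(self):
        gene = _track("g", [20] * 100)
        contig = _track("c", [20] * 50)
        with pytest.raises(InputError):
            maglink.qc_coverage(("g", (0, 100)), gene, contig)

    def test_invariant_under_joint_depth_scaling(self):
        gene = _track("g", [30] * 40 + [10] * 60)
        for scale in (1, 3, 10):
            g = _track("g", (np.array([30] * 40 + [10] * 60) * scale))
            c = _track("c", np.full(200, 20 * scale))
            qc = maglink.qc_coverage(("g", (0, 100)), g, c)
            ref = maglink.qc_coverage(("g", (0, 100)), gene,
                                      _track("c", [20] * 200))
            assert qc.cv == pytest.approx(ref.cv)
            assert qc.depth_ratio == pytest.approx(ref.depth_ratio)
            assert qc.passed == ref.passed


def _mag_with_gene(mag_id, gene_seq):
    gene = SeqRecord(f"{mag_id}_16S", gene_seq)
    return MagRecord(mag_id=mag_id,
                     genes=[(f"{mag_id}_16S", gene, f"{mag_id}_c1")])


class TestMatchAmplicons:
    def test_embedded_amplicon_matches_perfectly(self, rng):
        amp = SeqRecord("amp", fixtures.random_seq(rng, 250))
        gene = (fixtures.random_seq(rng, 400) + amp.seq
                + fixtures.random_seq(rng, 350))
        mag = _mag_with_gene("MagA", gene)
        ev = maglink.match_amplicons([amp], [mag])
        assert len(ev) == 1
        otu, mag_id, gene_id, ident, cov = ev[0]
        assert (otu, mag_id) == ("amp", "MagA")
        assert ident == 100.0 and cov == 100.0

    def test_two_substitutions_pass_three_fail(self, rng):
        """99.2% identity passes the 99% threshold; 98.8% does not."""
        amp = SeqRecord("amp", fixtures.random_seq(rng, 250))
        two = _mag_with_gene("M2", _substitute(amp.seq, [50, 130]))
        three = _mag_with_gene("M3", _substitute(amp.seq, [50, 130, 200]))
        assert len(maglink.match_amplicons([amp], [two])) == 1
        assert maglink.match_amplicons([amp], [three]) == []

    def test_partial_alignment_fails_coverage(self, rng):
        """Only 200 of 250 amplicon nt alignable: 80% coverage < 90%."""
        amp = SeqRecord("amp", fixtures.random_seq(rng, 250))
        mag = _mag_with_gene("M", fixtures.random_seq(rng, 300) + amp.seq[:200])
        assert maglink.match_amplicons([amp], [mag]) == []

    def test_minus_strand_gene_matched(self, rng):
        from ampmag.io_formats import reverse_complement

        amp = SeqRecord("amp", fixtures.random_seq(rng, 250))
        mag = _mag_with_gene("M", reverse_complement(amp.seq))
        ev = maglink.match_amplicons([amp], [mag])
        assert len(ev) == 1 and ev[0][3] == 100.0

    def test_qc_failing_gene_ignored(self, rng):
        amp = SeqRecord("amp", fixtures.random_seq(rng, 250))
        mag = _mag_with_gene("M", amp.seq)
        mag.qc[f"M_16S"] = CoverageQC(0, 20, math.inf, 0, passed=False)
        assert maglink.match_amplicons([amp], [mag]) == []


class TestPartition:
    def test_three_way_classification(self, rng):
        amp = SeqRecord("amp", fixtures.random_seq(rng, 250))
        mag_a = _mag_with_gene("A", amp.seq)                      # matching
        mag_b = _mag_with_gene("B", fixtures.random_seq(rng, 800))  # not
        mag_c = MagRecord(mag_id="C")                             # no 16S
        mags = [mag_a, mag_b, mag_c]
        res = maglink.partition(mags, maglink.match_amplicons([amp], mags))
        assert res.biofilm_linked == {"A"}
        assert res.planktonic == {"B"}
        assert res.excluded == {"C"}

    def test_no_amplicons_all_planktonic(self, rng):
        mags = [_mag_with_gene(f"M{i}", fixtures.random_seq(rng, 500))
                for i in range(4)]
        res = maglink.partition(mags, maglink.match_amplicons([], mags))
        assert res.planktonic == {f"M{i}" for i in range(4)}
        assert not res.biofilm_linked

    def test_all_genes_failing_qc_excludes_mag(self, rng):
        mag = _mag_with_gene("M", fixtures.random_seq(rng, 500))
        mag.qc["M_16S"] = CoverageQC(0, 20, math.inf, 0, passed=False)
        res = maglink.partition([mag], [])
        assert res.excluded == {"M"}

    def test_unknown_mag_in_evidence_rejected(self):
        with pytest.raises(ConsistencyError):
            maglink.partition([MagRecord(mag_id="A")],
                              [("amp", "ZZZ", "g", 100.0, 100.0)])

    def test_planted_23_mag_recovery(self, mag_fixture):
        """23 planted MAGs partition as 12 linked / 8 planktonic / 3 excluded."""
        mags, amplicons, truth = mag_fixture
        ev = maglink.match_amplicons(amplicons, mags)
        res = maglink.partition(mags, ev)
        assert res.biofilm_linked == set(truth["biofilm_linked"])
        assert res.planktonic == set(truth["planktonic"])
        assert res.excluded == set(truth["excluded"])
        assert (len(res.biofilm_linked), len(res.planktonic),
                len(res.excluded)) == (12, 8, 3)

    def test_disjoint_cover_over_random_fixtures(self):
        """The three sets always partition the input MAG ids."""
        rng = np.random.default_rng(7)
        for trial in range(25):
            n_mags = int(rng.integers(3, 9))
            n_linked = int(rng.integers(0, n_mags + 1))
            n_lacking = int(rng.integers(0, n_mags - n_linked + 1))
            spec = fixtures.FixtureSpec(
                seed=int(rng.integers(0, 2**31 - 1)),
                n_mags=n_mags, n_biofilm_linked=n_linked,
                n_lacking_16s=n_lacking, amplicon_length=120,
                gene_length=300, contig_length=400, n_extra_amplicons=1,
            )
            mags, amplicons, _ = fixtures.make_mag_set(spec)
            res = maglink.partition(mags,
                                    maglink.match_amplicons(amplicons, mags))
            ids = {m.mag_id for m in mags}
            assert res.biofilm_linked | res.planktonic | res.excluded == ids
            assert not (res.biofilm_linked & res.planktonic)
            assert not (res.biofilm_linked & res.excluded)
            assert not (res.planktonic & res.excluded)

    def test_threshold_monotonicity(self, mag_fixture):
        """Raising thresholds never moves a MAG from planktonic to linked."""
        mags, amplicons, _ = mag_fixture
        prev_linked = None
        for ident in (97.0, 99.0, 99.9):
            ev = maglink.match_amplicons(
                amplicons, mags, LinkConfig(min_identity=ident)
            )
            linked = maglink.partition(mags, ev).biofilm_linked
            if prev_linked is not None:
                assert linked <= prev_linked
            prev_linked = linked


class TestRecruitReads:
    def test_identical_read_recruited(self, rng):
        reps = [SeqRecord(f"Otu{i}", fixtures.random_seq(rng, 250))
                for i in range(3)]
        counts, recruited = maglink.recruit_reads(
            reps, {"MG": [SeqRecord("r1", reps[1].seq)]}
        )
        assert counts.at["Otu1", "MG"] == 1
        assert bool(recruited.at["Otu1", "MG"])
        assert counts["MG"].sum() == 1

    def test_unmatched_read_recruited_nowhere(self, rng):
        reps = [SeqRecord("Otu0", fixtures.random_seq(rng, 250))]
        counts, _ = maglink.recruit_reads(
            reps, {"MG": [SeqRecord("r1", fixtures.random_seq(rng, 250))]}
        )
        assert counts["MG"].sum() == 0

    def test_planted_reads_recruit_to_source(self, default_spec):
        """Reads planted from specific OTUs recruit back to them (>=99%)."""
        spec = fixtures.FixtureSpec(seed=default_spec.seed,
                                    reads_per_metagenome=60)
        rng = np.random.default_rng(3)
        reps = [SeqRecord(f"Otu{i}", fixtures.random_seq(rng, 250))
                for i in range(4)]
        read_sets, truth = fixtures.make_read_sets(
            spec, reps, {"MG1": ["Otu1"], "MG2": ["Otu2", "Otu3"]}
        )
        counts, _ = maglink.recruit_reads(reps, read_sets)
        assert counts.at["Otu1", "MG1"] >= 0.99 * spec.reads_per_metagenome
        assert counts.at["Otu0", "MG1"] == 0
        # column sums never exceed reads supplied (each read <= one OTU)
        assert (counts.sum(axis=0) <= spec.reads_per_metagenome).all()
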