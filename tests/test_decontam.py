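"""Contaminant screen: blank-share statistic, flagging, annotation, culling."""

import numpy as np
import pytest

from ampmag import align, decontam, fixtures
from ampmag.errors import (
    AnnotationError,
    ConfigurationError,
    DepthError,
    ReviewError,
)
from ampmag.io_formats import CountTable, ReferenceDB, SeqRecord


def _table(counts, roles, otu_ids=None, sample_ids=None):
    counts = np.asarray(counts)
    otu_ids = otu_ids or [f"Otu{i+1}" for i in range(counts.shape[0])]
    sample_ids = sample_ids or list(roles)
    return CountTable(otu_ids=otu_ids, sample_ids=sample_ids, counts=counts,
                      roles=roles)


ROLES_1B1S = {"S1": "specimen", "B1": "blank"}


class TestRelativeAbundance:
    def test_column_normalization(self):
        t = _table([[10, 1], [30, 1], [60, 8]], ROLES_1B1S)
        rel = decontam.relative_abundance(t)
        assert rel["S1"].tolist() == [0.1, 0.3, 0.6]
        assert np.allclose(rel.sum(axis=0), 1.0, atol=1e-12)

    def test_zero_depth_sample_named(self):
        t = _table([[1, 0], [2, 0]], ROLES_1B1S)
        with pytest.raises(DepthError, match="B1"):
            decontam.relative_abundance(t)


class TestBlankShare:
    def test_absent_from_blanks_is_zero(self):
        t = _table([[100, 0], [100, 50]], ROLES_1B1S)
        assert decontam.blank_share(t, "Otu1") == 0.0

    def test_absent_from_specimens_is_one(self):
        t = _table([[0, 10], [100, 40]], ROLES_1B1S)
        assert decontam.blank_share(t, "Otu1") == 1.0

    def test_hand_arithmetic(self):
        # blank lib 1000 with 100 reads (rel 0.10); specimen lib 1000 with
        # 900 reads (rel 0.90): share = 0.10 / (0.10 + 0.90) = 0.10
        t = _table([[900, 100], [100, 900]], ROLES_1B1S)
        assert decontam.blank_share(t, "Otu1") == pytest.approx(0.10)

    def test_unknown_otu_raises_keyerror(self):
        t = _table([[1, 1]], ROLES_1B1S)
        with pytest.raises(KeyError):
            decontam.blank_share(t, "nope")


class TestFlagging:
    def test_blank_only_always_flagged(self):
        t = _table([[0, 10], [50, 10]], ROLES_1B1S)
        flags = decontam.flag_contaminants(t, decontam.DecontamConfig(tau=1.0))
        assert [f.otu_id for f in flags] == ["Otu1"]

    def test_boundary_share_is_flagged(self):
        """share exactly equal to tau is flagged (inclusive boundary)."""
        t = _table([[900, 100], [100, 900]], ROLES_1B1S)
        flags = decontam.flag_contaminants(t, decontam.DecontamConfig(tau=0.10))
        assert "Otu1" in {f.otu_id for f in flags}

    def test_no_blanks_is_configuration_error(self):
        t = _table([[1, 2]], {"S1": "specimen", "S2": "specimen"})
        with pytest.raises(ConfigurationError):
            decontam.flag_contaminants(t)

    def test_threshold_monotonicity(self, count_fixture):
        table, _ = count_fixture
        prev = None
        for tau in (0.05, 0.10, 0.30, 0.60, 0.95):
            ids = {f.otu_id
                   for f in decontam.flag_contaminants(
                       table, decontam.DecontamConfig(tau=tau))}
            if prev is not None:
                assert ids <= prev
            prev = ids

    def test_planted_truth_recovered(self, count_fixture):
        """Planted contaminants (share >= 0.6) all flagged at tau 0.10;
        background OTUs (true share < 0.01) never flagged."""
        table, truth = count_fixture
        flags = decontam.flag_contaminants(table)
        flagged = {f.otu_id for f in flags}
        assert flagged == set(truth["contaminant_ids"])

    def test_permutation_invariance(self, count_fixture):
        table, _ = count_fixture
        rng = np.random.default_rng(0)
        otu_perm = rng.permutation(len(table.otu_ids))
        samp_perm = rng.permutation(len(table.sample_ids))
        shuffled = CountTable(
            otu_ids=[table.otu_ids[i] for i in otu_perm],
            sample_ids=[table.sample_ids[j] for j in samp_perm],
            counts=table.counts[np.ix_(otu_perm, samp_perm)],
            roles=dict(table.roles),
        )
        a = decontam.flag_contaminants(table)
        b = decontam.flag_contaminants(shuffled)
        assert [(f.otu_id, f.blank_share) for f in a] == [
            (f.otu_id, f.blank_share) for f in b
        ]


class TestAnnotate:
    def _db(self):
        recs = [
            SeqRecord("RefSkin", "ACGGTTACGGATCCGGAAATTTCCGGGATC" * 3),
            SeqRecord("RefSoil", "TTTTGGGGCCCCAAAATTTTGGGGCCCCAA" * 3),
        ]
        meta = {
            "RefSkin": {"taxonomy": "Bacteria;Staph",
                        "environment_source": "human skin"},
            "RefSoil": {"taxonomy": "Bacteria;Brady",
                        "environment_source": "soil"},
        }
        return ReferenceDB(records=recs, meta=meta)

    def _flag(self, otu_id):
        return decontam.FlagRecord(otu_id=otu_id, blank_share=1.0,
                                   per_blank_relabund={},
                                   per_specimen_mean_relabund=0.0)

    def test_exact_match_carries_environment_label(self):
        db = self._db()
        flags = [self._flag("OtuX")]
        reps = {"OtuX": SeqRecord("OtuX", db.records[0].seq)}
        decontam.annotate_flagged(flags, reps, db)
        assert flags[0].hits[0].subject_id == "RefSkin"
        assert flags[0].hits[0].environment_source == "human skin"
        assert flags[0].hits[0].identity == 100.0

    def test_empty_flag_list_unchanged(self):
        assert decontam.annotate_flagged([], {}, self._db()) == []

    def test_missing_rep_seq_is_annotation_error(self):
        with pytest.raises(AnnotationError, match="OtuX"):
            decontam.annotate_flagged([self._flag("OtuX")], {}, self._db())

    def test_hits_equal_exhaustive_top_k(self, rng):
        """Annotation hits equal an exhaustive DP ranking over seed-sharing
        subjects."""
        recs = [SeqRecord(f"R{i:02d}", fixtures.random_seq(rng, 120))
                for i in range(30)]
        db = ReferenceDB(records=recs, meta={
            r.id: {"taxonomy": "", "environment_source": ""} for r in recs
        })
        rep = SeqRecord("OtuX", fixtures.mutate(recs[4].seq, 2, rng))
        flags = [self._flag("OtuX")]
        decontam.annotate_flagged(flags, {"OtuX": rep}, db,
                                  decontam.DecontamConfig(top_k=10))
        index = align.build_index(db, k=8)
        cands = align.seed_candidates(rep, index)
        params = align.EvalueParams(m=len(rep.seq), n=index.total_length)
        expected = align.rank_hits(
            [align.align_best_strand(rep, r, eval_params=params)
             for r in recs if r.id in cands],
            10,
        )
        assert [(h.subject_id, h.score) for h in flags[0].hits] == [
            (h.subject_id, h.score) for h in expected
        ]


class TestApplyReview:
    def _flags(self, table, tau=0.10):
        return decontam.flag_contaminants(table,
                                          decontam.DecontamConfig(tau=tau))

    def test_flag_and_cull_counting(self):
        """22 flagged, 17 removed -> report n_flagged=22, n_removed=17."""
        n = 30
        counts = np.zeros((n, 2), dtype=int)
        counts[:, 0] = 10          # specimen
        counts[:22, 1] = 50        # 22 OTUs heavy in the blank
        counts[22:, 1] = 0
        counts[22:, 0] = 100
        t = _table(counts, ROLES_1B1S)
        flags = self._flags(t)
        assert len(flags) == 22
        decisions = {f.otu_id: "remove" for f in flags[:17]}
        culled, report = decontam.apply_review(t, flags, decisions)
        assert report.n_flagged == 22
        assert report.n_removed == 17
        assert report.n_retained_otus == n - 17
        # undecided flagged OTUs stay, recorded as pending
        assert sum(1 for f in flags if f.decision == "pending") == 5

    def test_remove_none_is_identity(self, count_fixture):
        table, _ = count_fixture
        flags = self._flags(table)
        culled, report = decontam.apply_review(table, flags, {})
        assert np.array_equal(culled.counts, table.counts)
        assert report.pct_sequences_retained == 100.0

    def test_retention_percentage_arithmetic(self):
        """OTUs carrying 30.1% of reads removed -> 69.9% retained."""
        t = _table([[699, 0], [301, 100]], ROLES_1B1S)
        flags = self._flags(t)
        assert [f.otu_id for f in flags] == ["Otu2"]
        culled, report = decontam.apply_review(t, flags, {"Otu2": "remove"})
        # removed 301 + 100 = 401 of 1100... compute explicitly:
        total = 699 + 301 + 100
        survived = 699
        assert report.pct_sequences_retained == pytest.approx(
            100.0 * survived / total
        )

    def test_culling_conservation(self, count_fixture):
        """input reads == surviving reads + removed-OTU reads, exactly."""
        table, _ = count_fixture
        flags = self._flags(table)
        decisions = {f.otu_id: "remove" for f in flags}
        culled, _ = decontam.apply_review(table, flags, decisions)
        removed = table.counts.sum() - culled.counts.sum()
        removed_direct = sum(
            table.counts[table.otu_ids.index(f.otu_id), :].sum() for f in flags
        )
        assert removed == removed_direct

    def test_decision_for_unflagged_rejected(self):
        t = _table([[699, 0], [301, 100]], ROLES_1B1S)
        flags = self._flags(t)
        with pytest.raises(ReviewError):
            decontam.apply_review(t, flags, {"Otu1": "remove"})
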