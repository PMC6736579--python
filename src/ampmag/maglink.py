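"""Partition metagenome-assembled genomes by 16S amplicon recruitment.

Biofilm 16S amplicons are aligned against the 16S genes carried by
crustal-fluid MAGs. A MAG whose (QC-passing) 16S gene matches any amplicon
at >= 99% identity over >= 90% of the amplicon length is *biofilm-linked*
(a planktonic lineage that also colonizes surfaces); a QC-passing 16S-bearing
MAG with no such match is *planktonic*; MAGs without a usable 16S gene are
*excluded* from the comparison. Reconstructed 16S genes are screened first
with a coverage-uniformity QC (assembled 16S genes are notoriously
chimera-prone): the per-base depth over the gene must be internally uniform
(coefficient of variation <= cv_max) and commensurate with its parent
contig's depth (ratio within [ratio_lo, ratio_hi]); all boundaries inclusive.

``recruit_reads`` measures the converse overlap: which amplicon OTUs recruit
raw metagenomic reads from a fluid community, at the same thresholds, with
coverage measured on the shorter of read and OTU representative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import align
from .errors import ConfigurationError, ConsistencyError, InputError
from .io_formats import DepthTrack, GeneFeature, SeqRecord


@dataclass
class LinkConfig:
    min_identity: float = 99.0        # percent, inclusive
    min_query_coverage: float = 90.0  # percent of amplicon length, inclusive
    cv_max: float = 1.0               # max coefficient of variation of gene depth
    ratio_lo: float = 0.25            # gene/contig mean-depth ratio bounds
    ratio_hi: float = 4.0

    def __post_init__(self) -> None:
        if not (0 < self.min_identity <= 100):
            raise ConfigurationError("min_identity must be in (0, 100]")
        if not (0 < self.min_query_coverage <= 100):
            raise ConfigurationError("min_query_coverage must be in (0, 100]")


@dataclass
class CoverageQC:
    gene_mean_depth: float
    contig_mean_depth: float
    cv: float
    depth_ratio: float
    passed: bool


@dataclass
class MagRecord:
    """A MAG with its reconstructed 16S genes (sense strand) and QC status."""

    mag_id: str
    genes: list[tuple[str, SeqRecord, str]] = field(default_factory=list)
    qc: dict[str, CoverageQC] = field(default_factory=dict)
    completeness: float | None = None

    def gene_passes(self, gene_id: str) -> bool:
        """A gene passes unless an explicit failing QC record exists."""
        rec = self.qc.get(gene_id)
        return rec is None or rec.passed

    @property
    def usable(self) -> bool:
        return any(self.gene_passes(g) for g, _, _ in self.genes)


@dataclass
class PartitionResult:
    biofilm_linked: set[str]
    planktonic: set[str]
    excluded: set[str]
    evidence: list[tuple[str, str, str, float, float]]

    def to_dict(self) -> dict:
        return {
            "biofilm_linked": sorted(self.biofilm_linked),
            "planktonic": sorted(self.planktonic),
            "excluded": sorted(self.excluded),
            "evidence": [
                {
                    "otu_id": o, "mag_id": m, "gene_id": g,
                    "identity": i, "query_coverage": c,
                }
                for o, m, g, i, c in self.evidence
            ],
        }


def qc_coverage(
    gene: tuple[str, tuple[int, int]],
    gene_track: DepthTrack,
    contig_track: DepthTrack,
    config: LinkConfig | None = None,
) -> CoverageQC:
    """Coverage-uniformity QC for one reconstructed gene.

    ``gene_track`` holds depth of reads mapped onto the reconstructed gene
    itself (gene-local coordinates); ``contig_track`` covers the parent
    contig. cv is the population stdev/mean of per-base gene depth; a gene
    with zero mean depth fails with cv recorded as infinite.
    """
    config = config or LinkConfig()
    gene_id, (start, end) = gene
    if end <= start:
        raise InputError(f"gene {gene_id!r}: empty interval")
    c_lo, c_hi = contig_track.span
    if start < c_lo or end > c_hi:
        raise InputError(
            f"gene {gene_id!r} interval [{start}, {end}) outside contig track span"
        )
    gene_depth = gene_track.dense()
    contig_depth = contig_track.dense()
    gene_mean = float(gene_depth.mean())
    contig_mean = float(contig_depth.mean())
    if gene_mean == 0:
        return CoverageQC(0.0, contig_mean, math.inf, 0.0, passed=False)
    cv = float(gene_depth.std()) / gene_mean  # population stdev
    ratio = gene_mean / contig_mean if contig_mean > 0 else math.inf
    passed = (cv <= config.cv_max) and (config.ratio_lo <= ratio <= config.ratio_hi)
    return CoverageQC(gene_mean, contig_mean, cv, ratio, passed)


def qc_mag_genes(
    mags: Sequence[MagRecord],
    genes: Sequence[GeneFeature],
    gene_tracks: Mapping[str, DepthTrack],
    contig_tracks: Mapping[str, DepthTrack],
    config: LinkConfig | None = None,
) -> None:
    """Run qc_coverage for every MAG gene with available tracks (in place)."""
    config = config or LinkConfig()
    by_id = {g.gene_id: g for g in genes}
    for mag in mags:
        for gene_id, _, contig_id in mag.genes:
            gt = gene_tracks.get(gene_id)
            ct = contig_tracks.get(contig_id)
            feat = by_id.get(gene_id)
            if gt is None or ct is None or feat is None:
                continue
            mag.qc[gene_id] = qc_coverage(
                (gene_id, (feat.start, feat.end)), gt, ct, config
            )


def match_amplicons(
    amplicons: Sequence[SeqRecord],
    mags: Sequence[MagRecord],
    config: LinkConfig | None = None,
    scoring: align.ScoringScheme | None = None,
) -> list[tuple[str, str, str, float, float]]:
    """All amplicon x QC-passing-gene pairs meeting both thresholds.

    Each pair is aligned on both strands (best taken); thresholds inclusive.
    """
    config = config or LinkConfig()
    evidence = []
    for mag in mags:
        for gene_id, gene_seq, _ in mag.genes:
            if not mag.gene_passes(gene_id):
                continue
            for amp in amplicons:
                res = align.align_best_strand(amp, gene_seq, scoring)
                if (
                    res.identity >= config.min_identity
                    and res.query_coverage >= config.min_query_coverage
                ):
                    evidence.append(
                        (amp.id, mag.mag_id, gene_id, res.identity,
                         res.query_coverage)
                    )
    return evidence


def partition(
    mags: Sequence[MagRecord],
    evidence: Sequence[tuple[str, str, str, float, float]],
) -> PartitionResult:
    """Disjoint cover: biofilm-linked / planktonic / excluded."""
    all_ids = {m.mag_id for m in mags}
    bad = {e[1] for e in evidence} - all_ids
    if bad:
        raise ConsistencyError(f"evidence references unknown MAG(s): {sorted(bad)}")
    excluded = {m.mag_id for m in mags if not m.genes or not m.usable}
    matched = {e[1] for e in evidence}
    biofilm = (matched & all_ids) - excluded
    planktonic = all_ids - excluded - biofilm
    return PartitionResult(
        biofilm_linked=biofilm,
        planktonic=planktonic,
        excluded=excluded,
        evidence=list(evidence),
    )


def recruit_reads(
    otu_reps: Sequence[SeqRecord],
    read_sets: Mapping[str, Sequence[SeqRecord]],
    config: LinkConfig | None = None,
    scoring: align.ScoringScheme | None = None,
    k: int = 8,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Recruit metagenomic reads to amplicon OTU representatives.

    Each read goes to at most one OTU: the best-scoring passing alignment,
    ties broken by higher identity then lexicographic OTU id. Coverage is
    measured on the shorter of read and representative, since fluid
    metagenome reads may be shorter than the amplicon. Returns (counts,
    recruited-at-all boolean), OTU x metagenome.
    """
    config = config or LinkConfig()
    otu_ids = [r.id for r in otu_reps]
    metagenomes = list(read_sets)
    counts = pd.DataFrame(0, index=otu_ids, columns=metagenomes, dtype=np.int64)
    if otu_reps:
        from .io_formats import ReferenceDB

        db = ReferenceDB(
            records=list(otu_reps), meta={r.id: {} for r in otu_reps}
        )
        index = align.build_index(db, k=k)
        for mg_id, reads in read_sets.items():
            for read in reads:
                best = None
                for hit in align.search(read, index, top_k=len(otu_reps),
                                        scoring=scoring):
                    short = min(len(read.seq), len(index.subjects[hit.subject_id].seq))
                    if len(read.seq) <= short:
                        cov_short = hit.query_coverage
                    else:
                        cov_short = 100.0 * (
                            hit.subject_span[1] - hit.subject_span[0]
                        ) / short
                    if hit.identity >= config.min_identity and cov_short >= config.min_query_coverage:
                        key = (-hit.score, -hit.identity, hit.subject_id)
                        if best is None or key < best[0]:
                            best = (key, hit.subject_id)
                if best is not None:
                    counts.at[best[1], mg_id] += 1
    return counts, counts > 0
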