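"""Blank-informed contaminant screening for low-biomass OTU tables.

Low-biomass amplicon libraries are easily dominated by reagent ("kitome")
sequences. When several extraction blanks are sequenced alongside the
specimens, each blank is an independent observation of the contaminant pool,
and OTUs whose abundance concentrates in the blanks can be flagged for
review before any culling.

The per-OTU statistic is the *blank share*

    share = b / (b + s)

where ``b`` is the OTU's mean relative abundance across blank libraries and
``s`` its mean across specimen libraries (0 when both are 0). Means of
depth-normalized abundances are used, rather than pooled raw reads, so that
library-size imbalance between blanks and specimens cannot dominate the
statistic. An OTU is flagged iff share >= tau (boundary inclusive); the
default tau of 0.10 follows the convention of a 10% abundance threshold.
This is a deterministic screen, not a hypothesis test: flagged OTUs are
annotated with their closest reference-database matches (taxonomy and
environmental source) and a human reviewer decides what is culled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import align
from .errors import (
    AnnotationError,
    ConfigurationError,
    DepthError,
    ReviewError,
)
from .io_formats import CountTable, ReferenceDB, SeqRecord

DECISION_REMOVE = "remove"
DECISION_RETAIN = "retain"
DECISION_PENDING = "pending"


@dataclass
class DecontamConfig:
    tau: float = 0.10              # blank-share flagging threshold
    top_k: int = 10                # reference hits reported per flagged OTU
    pseudo_depth_min: int = 1      # minimum usable library size [reads]

    def __post_init__(self) -> None:
        if not (0 < self.tau <= 1):
            raise ConfigurationError("tau must be in (0, 1]")
        if self.top_k < 1:
            raise ConfigurationError("top_k must be >= 1")


@dataclass
class FlagRecord:
    otu_id: str
    blank_share: float
    per_blank_relabund: dict[str, float]
    per_specimen_mean_relabund: float
    flagged: bool = True
    hits: list[align.AlignmentResult] = field(default_factory=list)
    decision: str = DECISION_PENDING


@dataclass
class RetentionReport:
    n_flagged: int
    n_removed: int
    n_retained_otus: int
    pct_sequences_retained: float
    parameters: dict
    records: list[FlagRecord]

    def to_dict(self) -> dict:
        return {
            "n_flagged": self.n_flagged,
            "n_removed": self.n_removed,
            "n_retained_otus": self.n_retained_otus,
            "pct_sequences_retained": self.pct_sequences_retained,
            "decisions": {r.otu_id: r.decision for r in self.records},
        }


def relative_abundance(
    table: CountTable, pseudo_depth_min: int = 1
) -> pd.DataFrame:
    """Depth-normalize: each sample column sums to 1; zeros preserved."""
    depths = table.counts.sum(axis=0)
    shallow = [
        s for s, d in zip(table.sample_ids, depths) if d < max(pseudo_depth_min, 1)
    ]
    if shallow:
        raise DepthError(f"sample(s) below usable depth: {shallow}")
    rel = table.counts / depths[np.newaxis, :]
    return pd.DataFrame(rel, index=table.otu_ids, columns=table.sample_ids)


def _require_roles(table: CountTable) -> None:
    if not table.blank_ids:
        raise ConfigurationError("decontamination requires at least one blank")
    if not table.specimen_ids:
        raise ConfigurationError("decontamination requires at least one specimen")


def blank_shares(table: CountTable, pseudo_depth_min: int = 1) -> pd.Series:
    """Blank share b/(b+s) for every OTU (vectorized)."""
    _require_roles(table)
    rel = relative_abundance(table, pseudo_depth_min)
    b = rel[table.blank_ids].mean(axis=1)
    s = rel[table.specimen_ids].mean(axis=1)
    denom = b + s
    share = pd.Series(0.0, index=rel.index)
    nz = denom > 0
    share[nz] = b[nz] / denom[nz]
    return share


def blank_share(table: CountTable, otu_id: str) -> float:
    """Blank share of one OTU; KeyError for unknown ids."""
    shares = blank_shares(table)
    if otu_id not in shares.index:
        raise KeyError(otu_id)
    return float(shares[otu_id])


def flag_contaminants(
    table: CountTable, config: DecontamConfig | None = None
) -> list[FlagRecord]:
    """Flag OTUs with blank share >= tau; sorted by descending share, then id."""
    config = config or DecontamConfig()
    _require_roles(table)
    rel = relative_abundance(table, config.pseudo_depth_min)
    shares = blank_shares(table, config.pseudo_depth_min)
    spec_mean = rel[table.specimen_ids].mean(axis=1)
    records = []
    for otu_id in table.otu_ids:
        share = float(shares[otu_id])
        if share >= config.tau:
            records.append(
                FlagRecord(
                    otu_id=otu_id,
                    blank_share=share,
                    per_blank_relabund={
                        b: float(rel.at[otu_id, b]) for b in table.blank_ids
                    },
                    per_specimen_mean_relabund=float(spec_mean[otu_id]),
                    flagged=True,
                )
            )
    records.sort(key=lambda r: (-r.blank_share, r.otu_id))
    return records


def annotate_flagged(
    flags: list[FlagRecord],
    rep_seqs: Mapping[str, SeqRecord],
    db: ReferenceDB,
    config: DecontamConfig | None = None,
    scoring: align.ScoringScheme | None = None,
    k: int = 8,
) -> list[FlagRecord]:
    """Populate each flagged OTU's closest reference hits (in place)."""
    config = config or DecontamConfig()
    missing = [f.otu_id for f in flags if f.otu_id not in rep_seqs]
    if missing:
        raise AnnotationError(
            f"flagged OTU(s) lacking a representative sequence: {missing}"
        )
    if not flags:
        return flags
    index = align.build_index(db, k=k)
    for rec in flags:
        rec.hits = align.search(
            rep_seqs[rec.otu_id], index, top_k=config.top_k, scoring=scoring
        )
    return flags


def apply_review(
    table: CountTable,
    flags: list[FlagRecord],
    decisions: Mapping[str, str],
    config: DecontamConfig | None = None,
) -> tuple[CountTable, RetentionReport]:
    """Cull reviewer-approved contaminants; undecided flags default to retain.

    ``decisions`` maps otu_id -> remove/retain and may only name flagged
    OTUs. The report records the fraction of input reads surviving culling.
    """
    config = config or DecontamConfig()
    flagged_ids = {f.otu_id for f in flags}
    unknown = set(decisions) - flagged_ids
    if unknown:
        raise ReviewError(f"decision(s) for unflagged OTU(s): {sorted(unknown)}")
    bad = {o: d for o, d in decisions.items()
           if d not in (DECISION_REMOVE, DECISION_RETAIN)}
    if bad:
        raise ReviewError(f"unknown decision value(s): {bad}")
    removed_ids = []
    for rec in flags:
        rec.decision = decisions.get(rec.otu_id, DECISION_PENDING)
        if rec.decision == DECISION_REMOVE:
            removed_ids.append(rec.otu_id)
    culled = table.drop_otus(removed_ids)
    total = int(table.counts.sum())
    surviving = int(culled.counts.sum())
    pct = 100.0 * surviving / total if total else 100.0
    report = RetentionReport(
        n_flagged=len(flags),
        n_removed=len(removed_ids),
        n_retained_otus=len(culled.otu_ids),
        pct_sequences_retained=pct,
        parameters={
            "tau": config.tau,
            "top_k": config.top_k,
            "pseudo_depth_min": config.pseudo_depth_min,
            "statistic": "blank_share = mean_blank_relabund / "
                         "(mean_blank_relabund + mean_specimen_relabund)",
        },
        records=flags,
    )
    return culled, report


def flags_to_frame(flags: list[FlagRecord]) -> pd.DataFrame:
    """Tabular view of flag records (one row per flagged OTU)."""
    rows = []
    for f in flags:
        row = {
            "otu_id": f.otu_id,
            "blank_share": f.blank_share,
            "per_specimen_mean_relabund": f.per_specimen_mean_relabund,
            "flagged": f.flagged,
            "decision": f.decision,
        }
        for b, v in f.per_blank_relabund.items():
            row[f"relabund[{b}]"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def hits_to_frame(flags: list[FlagRecord]) -> pd.DataFrame:
    """One row per (flagged OTU, reference hit), ranked as searched."""
    rows = []
    for f in flags:
        for rank, h in enumerate(f.hits, 1):
            rows.append(
                {
                    "otu_id": f.otu_id,
                    "rank": rank,
                    "subject_id": h.subject_id,
                    "percent_identity": h.identity,
                    "percent_coverage": h.query_coverage,
                    "evalue": h.evalue,
                    "strand": h.strand,
                    "taxonomy": h.taxonomy,
                    "environment_source": h.environment_source,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "otu_id", "rank", "subject_id", "percent_identity",
            "percent_coverage", "evalue", "strand", "taxonomy",
            "environment_source",
        ],
    )
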