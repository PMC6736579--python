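"""Deterministic synthetic-data generator with recorded planted truth.

Every input the toolkit reads can be generated here, so the whole pipeline
is testable offline. Each generated object comes with a *truth* record of
every planted quantity, and planted truths are exact, not approximate:

* Count tables are built from exact expected per-sample compositions.
  Blanks are dominated by a planted "kit" community (contaminant OTUs take
  1 − ε of the blank mass, background OTUs share ε); specimen columns are
  solved from each contaminant's target blank share, so the expected blank
  share of every OTU is analytic. Background base abundances are log-normal
  (skewed, as in real low-biomass communities) and libraries are multinomial
  at exactly the specified depth — between-library variation comes from the
  multinomial resampling alone.
* Mutated copies of a source sequence carry a FIXED number of substitutions,
  placed away from the ends and outside a protected k-mer window, so the
  identity of the planted match, the guarantee of a shared seed word, and
  read-recruitment truth all hold exactly rather than in expectation.
* MAG sets plant an exact three-way partition (linked / unlinked / lacking a
  16S gene); by default 12 of 23 MAGs carry a near-identical amplicon match,
  8 carry an unrelated 16S gene and 3 carry none.

Same seed, same bytes: all sampling is routed through
``numpy.random.default_rng`` seeded from (per-operation salt, spec.seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import io_formats
from .errors import SpecError
from .io_formats import (
    CountTable,
    DepthTrack,
    GeneFeature,
    ReferenceDB,
    SeqRecord,
)
from .maglink import CoverageQC, MagRecord

_BASES = np.array(list("ACGT"))

_ENV_SOURCES = [
    "reagent", "human skin", "soil", "seawater",
    "marine sediment", "freshwater", "hydrothermal fluid",
]
_GENERA = [
    "Pseudomonas", "Ralstonia", "Bradyrhizobium", "Colwellia", "Arcobacter",
    "Thermus", "Sulfurimonas", "Desulfotomaculum", "Nitrospira", "Shewanella",
]

# Marker panel planted by default: entry -> (biofilm present, plankton present).
DEFAULT_PANEL_PATTERN: list[tuple[str, str, str, bool, bool]] = [
    ("Carbon fixation", "Wood Ljungdahl", "codhCD", True, True),
    ("Carbon fixation", "Calvin cycle", "Rubisco", False, True),
    ("Nitrogen", "Dissimilatory nitrite reduction", "nirBD", True, False),
    ("Nitrogen", "Denitrification", "nirS", True, False),
    ("Nitrogen", "Nitrous oxide reduction", "nosZD", False, True),
    ("Sulfur", "Sulfite reduction", "dsrABCMK/dsrD", True, False),
    ("Sulfur", "Thiosulfate oxidation", "soxYZ", True, False),
    ("Hydrogen", "Hydrogen oxidation", "hydA", True, True),
    ("Iron", "Iron reduction/oxidation", "mtrA", False, False),
]

_CATEGORIES = [
    "Biofilm formation", "Flagellar assembly",
    "Lipopolysaccharide biosynthesis", "Carbohydrate metabolism",
    "Energy metabolism",
]


@dataclass
class FixtureSpec:
    """Conditions under which all synthetic inputs are generated."""

    seed: int = 0
    # amplicon community
    n_otus: int = 200
    n_specimens: int = 4
    n_blanks: int = 2
    depth: int = 50_000
    n_contaminants: int = 20
    planted_contaminants: list[tuple[str, float]] | None = None
    share_range: tuple[float, float] = (0.6, 1.0)
    lognormal_sigma: float = 0.8
    blank_background_mass: float = 0.002  # ε: background share of blank mass
    # reference database
    n_reference: int = 50
    reference_length: tuple[int, int] = (300, 500)
    rep_substitutions: int = 2   # planted divergence of contaminant rep seqs
    # MAG set
    n_mags: int = 23
    n_biofilm_linked: int = 12
    n_lacking_16s: int = 3
    n_extra_amplicons: int = 3   # amplicons matching no MAG
    amplicon_length: int = 250
    gene_length: int = 1200
    contig_length: int = 3000
    linked_substitutions: int = 2
    # read recruitment
    reads_per_metagenome: int = 200
    read_mutation_rate: float = 0.005  # fixed count: round(rate * length)
    k: int = 8

    def __post_init__(self) -> None:
        if self.n_contaminants >= self.n_otus:
            raise SpecError("n_contaminants must be < n_otus")
        if self.n_biofilm_linked + self.n_lacking_16s > self.n_mags:
            raise SpecError("n_biofilm_linked + n_lacking_16s exceeds n_mags")
        if self.planted_contaminants is not None:
            for otu, share in self.planted_contaminants:
                if not (0 <= share <= 1):
                    raise SpecError(f"planted share for {otu!r} outside [0, 1]")
        lo, hi = self.share_range
        if not (0 < lo <= hi <= 1):
            raise SpecError("share_range must satisfy 0 < lo <= hi <= 1")
        if self.linked_substitutions > self.amplicon_length - 2 * 2 - self.k:
            raise SpecError("more substitutions than mutable positions")
        if self.gene_length < self.amplicon_length:
            raise SpecError("gene_length must be >= amplicon_length")
        if self.contig_length < self.gene_length:
            raise SpecError("contig_length must be >= gene_length")


def _rng(spec: FixtureSpec, salt: int) -> np.random.Generator:
    return np.random.default_rng([salt, spec.seed])


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def mutate(
    seq: str,
    n_subs: int,
    rng: np.random.Generator,
    protect_k: int = 8,
    end_margin: int = 2,
) -> str:
    """Copy with exactly ``n_subs`` substitutions.

    Substitutions avoid the first/last ``end_margin`` positions (so the
    optimal local alignment spans the whole copy) and a protected window of
    ``protect_k`` consecutive positions (so copy and source are guaranteed
    to share an exact k-mer seed).
    """
    length = len(seq)
    if protect_k > 0:
        w_lo, w_hi = end_margin, length - end_margin - protect_k
        if w_hi < w_lo:
            raise SpecError("sequence too short for the protected window")
        w = int(rng.integers(w_lo, w_hi + 1))
        protected = set(range(w, w + protect_k))
    else:
        protected = set()
    candidates = [
        i for i in range(end_margin, length - end_margin) if i not in protected
    ]
    if n_subs > len(candidates):
        raise SpecError("more substitutions requested than mutable positions")
    chosen = rng.choice(len(candidates), size=n_subs, replace=False)
    out = list(seq)
    for ci in sorted(int(c) for c in chosen):
        pos = candidates[ci]
        alternatives = [b for b in "ACGT" if b != out[pos]]
        out[pos] = alternatives[int(rng.integers(0, 3))]
    return "".join(out)


# ---------------------------------------------------------------------------
# count tables

def make_count_table(spec: FixtureSpec) -> tuple[CountTable, dict]:
    """OTU table with planted contaminants and exact expected blank shares."""
    rng = _rng(spec, 1)
    otu_ids = [f"Otu{i + 1:04d}" for i in range(spec.n_otus)]
    if spec.planted_contaminants is not None:
        cont_ids = [o for o, _ in spec.planted_contaminants]
        unknown = set(cont_ids) - set(otu_ids)
        if unknown:
            raise SpecError(f"planted contaminant(s) not among OTU ids: {unknown}")
        shares = np.array([s for _, s in spec.planted_contaminants])
    else:
        idx = np.sort(rng.choice(spec.n_otus, spec.n_contaminants, replace=False))
        cont_ids = [otu_ids[i] for i in idx]
        shares = rng.uniform(*spec.share_range, size=len(cont_ids))
    cont_pos = [otu_ids.index(o) for o in cont_ids]
    bg_pos = [i for i in range(spec.n_otus) if i not in set(cont_pos)]

    eps = spec.blank_background_mass
    # blank composition: contaminants take 1-ε, split log-normally
    w = rng.lognormal(0.0, 1.0, size=len(cont_ids))
    b = (1.0 - eps) * w / w.sum()
    # specimen composition solved from target shares: share = b/(b+s)
    with np.errstate(divide="ignore"):
        s = np.where(shares > 0, b * (1.0 / np.maximum(shares, 1e-300) - 1.0), np.inf)
    s_total = float(s.sum())
    if s_total >= 0.95:
        raise SpecError(
            f"planted shares infeasible: contaminants would need {s_total:.2f} "
            "of each specimen library"
        )
    base = rng.lognormal(0.0, spec.lognormal_sigma, size=len(bg_pos))
    base /= base.sum()

    p_spec = np.zeros(spec.n_otus)
    p_blank = np.zeros(spec.n_otus)
    p_spec[cont_pos] = s
    p_spec[bg_pos] = (1.0 - s_total) * base
    p_blank[cont_pos] = b
    p_blank[bg_pos] = eps * base

    sample_ids = [f"S{i + 1:02d}" for i in range(spec.n_specimens)] + [
        f"B{i + 1:02d}" for i in range(spec.n_blanks)
    ]
    roles = {s_: io_formats.ROLE_SPECIMEN for s_ in sample_ids[: spec.n_specimens]}
    roles.update(
        {s_: io_formats.ROLE_BLANK for s_ in sample_ids[spec.n_specimens:]}
    )
    cols = []
    for sid in sample_ids:
        p = p_spec if roles[sid] == io_formats.ROLE_SPECIMEN else p_blank
        cols.append(rng.multinomial(spec.depth, p / p.sum()))
    counts = np.stack(cols, axis=1)

    bg_share = eps / (eps + (1.0 - s_total))
    expected = {o: bg_share for o in otu_ids}
    expected.update({o: float(sh) for o, sh in zip(cont_ids, shares)})
    truth = {
        "contaminant_ids": list(cont_ids),
        "expected_shares": expected,
        "background_share": bg_share,
        "depth": spec.depth,
    }
    return (
        CountTable(otu_ids=otu_ids, sample_ids=sample_ids, counts=counts,
                   roles=roles),
        truth,
    )


# ---------------------------------------------------------------------------
# reference database and representative sequences

def make_refdb(spec: FixtureSpec) -> ReferenceDB:
    rng = _rng(spec, 2)
    records, meta = [], {}
    for i in range(spec.n_reference):
        rid = f"Ref{i + 1:04d}"
        length = int(rng.integers(*spec.reference_length))
        records.append(SeqRecord(id=rid, seq=random_seq(rng, length)))
        env = "reagent" if i < spec.n_contaminants else _ENV_SOURCES[
            i % len(_ENV_SOURCES)
        ]
        genus = _GENERA[int(rng.integers(0, len(_GENERA)))]
        meta[rid] = {
            "taxonomy": f"Bacteria;{genus}", "environment_source": env,
        }
    return ReferenceDB(records=records, meta=meta)


def make_rep_seqs(
    spec: FixtureSpec, db: ReferenceDB, truth: Mapping
) -> dict[str, SeqRecord]:
    """Representative sequences: contaminant OTUs are near-copies of
    'reagent' reference records (shared k-mer guaranteed); the rest random."""
    rng = _rng(spec, 3)
    cont_ids = list(truth["contaminant_ids"])
    table_otus = [f"Otu{i + 1:04d}" for i in range(spec.n_otus)]
    reps: dict[str, SeqRecord] = {}
    reagent = [r for r in db.records
               if db.meta[r.id]["environment_source"] == "reagent"]
    for j, otu in enumerate(table_otus):
        if otu in cont_ids and reagent:
            src = reagent[cont_ids.index(otu) % len(reagent)]
            off_max = len(src.seq) - spec.amplicon_length
            off = int(rng.integers(0, off_max + 1)) if off_max > 0 else 0
            window = src.seq[off : off + spec.amplicon_length]
            seq = mutate(window, spec.rep_substitutions, rng, protect_k=spec.k)
        else:
            seq = random_seq(rng, spec.amplicon_length)
        reps[otu] = SeqRecord(id=otu, seq=seq)
    return reps


# ---------------------------------------------------------------------------
# MAG sets

def make_mag_set(
    spec: FixtureSpec,
) -> tuple[list[MagRecord], list[SeqRecord], dict]:
    """MAGs with a planted partition plus the amplicons that define it."""
    rng = _rng(spec, 4)
    n_unlinked = spec.n_mags - spec.n_biofilm_linked - spec.n_lacking_16s
    mag_ids = [f"Mag{i + 1:03d}" for i in range(spec.n_mags)]
    order = rng.permutation(spec.n_mags)
    linked = sorted(mag_ids[i] for i in order[: spec.n_biofilm_linked])
    unlinked = sorted(
        mag_ids[i]
        for i in order[spec.n_biofilm_linked : spec.n_biofilm_linked + n_unlinked]
    )
    lacking = sorted(
        mag_ids[i] for i in order[spec.n_biofilm_linked + n_unlinked :]
    )

    amplicons = [
        SeqRecord(id=f"Amp{i + 1:03d}", seq=random_seq(rng, spec.amplicon_length))
        for i in range(spec.n_biofilm_linked + spec.n_extra_amplicons)
    ]
    mags: list[MagRecord] = []
    amp_to_mag: dict[str, str] = {}
    for mag_id in mag_ids:
        if mag_id in lacking:
            mags.append(MagRecord(mag_id=mag_id))
            continue
        gene_id = f"{mag_id}_16S"
        contig_id = f"{mag_id}_c1"
        if mag_id in linked:
            amp = amplicons[linked.index(mag_id)]
            amp_to_mag[amp.id] = mag_id
            insert = mutate(amp.seq, spec.linked_substitutions, rng,
                            protect_k=spec.k)
            pad = spec.gene_length - spec.amplicon_length
            left = int(rng.integers(0, pad + 1))
            seq = (random_seq(rng, left) + insert
                   + random_seq(rng, pad - left))
        else:
            seq = random_seq(rng, spec.gene_length)
        gene = SeqRecord(id=gene_id, seq=seq)
        mags.append(
            MagRecord(mag_id=mag_id, genes=[(gene_id, gene, contig_id)])
        )
    truth = {
        "biofilm_linked": linked,
        "planktonic": unlinked,
        "excluded": lacking,
        "amplicon_to_mag": amp_to_mag,
    }
    return mags, amplicons, truth


# ---------------------------------------------------------------------------
# depth tracks

def make_depth_tracks(
    spec: FixtureSpec,
    profile: str = "uniform",
    gene_id: str = "gene",
    contig_id: str = "contig",
    contig_depth: int = 20,
) -> tuple[DepthTrack, DepthTrack]:
    """One (gene, contig) track pair with a named coverage shape.

    ``uniform``: gene depth equals contig depth everywhere (cv 0, ratio 1).
    ``spiked``: first half of the gene at 5x contig depth, second half 0 —
    the shape of a chimeric assembly (cv 1, ratio 2.5).
    ``zero``: no reads map to the gene at all.
    """
    glen, clen = spec.gene_length, spec.contig_length
    gpos = np.arange(glen)
    if profile == "uniform":
        gdepth = np.full(glen, contig_depth)
    elif profile == "spiked":
        gdepth = np.zeros(glen, dtype=np.int64)
        gdepth[: glen // 2] = 5 * contig_depth
    elif profile == "zero":
        gdepth = np.zeros(glen, dtype=np.int64)
    else:
        raise SpecError(f"unknown depth profile {profile!r}")
    gene_track = DepthTrack(contig_id=gene_id, positions=gpos, depth=gdepth)
    contig_track = DepthTrack(
        contig_id=contig_id,
        positions=np.arange(clen),
        depth=np.full(clen, contig_depth),
    )
    return gene_track, contig_track


# ---------------------------------------------------------------------------
# annotations

def make_annotations(
    spec: FixtureSpec,
    pattern: Sequence[tuple[str, str, str, bool, bool]] | None = None,
    biofilm_mags: Sequence[str] | None = None,
    planktonic_mags: Sequence[str] | None = None,
):
    """Annotation table + marker panel realizing a planted presence pattern.

    ``pattern`` rows are (metabolism, function, gene-symbol-set,
    present-in-biofilm, present-in-plankton). Returns (AnnotationTable,
    MarkerPanel, truth).
    """
    from .funccompare import AnnotationTable, MarkerPanel, PanelEntry
    import pandas as pd

    rng = _rng(spec, 5)
    pattern = list(pattern if pattern is not None else DEFAULT_PANEL_PATTERN)
    if biofilm_mags is None or planktonic_mags is None:
        _, _, truth_part = make_mag_set(spec)
        biofilm_mags = truth_part["biofilm_linked"]
        planktonic_mags = truth_part["planktonic"]
    biofilm_mags = list(biofilm_mags)
    planktonic_mags = list(planktonic_mags)

    rows: list[dict] = []
    orf_counter: dict[str, int] = {}

    def _add_row(mag: str, gene: str, category: str) -> None:
        orf_counter[mag] = orf_counter.get(mag, 0) + 1
        rows.append(
            {
                "mag_id": mag,
                "orf_id": f"{mag}_orf{orf_counter[mag]:05d}",
                "gene": gene,
                "category": category,
            }
        )

    panel_entries = []
    for metabolism, function, gene_set, in_bio, in_plank in pattern:
        symbols = [g for g in gene_set.split("/") if g]
        panel_entries.append(
            PanelEntry(metabolism=metabolism, function=function,
                       genes=frozenset(symbols))
        )
        for present, frac in ((in_bio, biofilm_mags), (in_plank, planktonic_mags)):
            if present:
                if not frac:
                    raise SpecError(
                        "pattern plants a gene in an empty fraction"
                    )
                mag = frac[int(rng.integers(0, len(frac)))]
                _add_row(mag, symbols[0], metabolism)
    # background KO annotations feeding the category profiles
    for mag in biofilm_mags + planktonic_mags:
        for cat in _CATEGORIES:
            for _ in range(int(rng.integers(1, 6))):
                ko = f"K{int(rng.integers(0, 100000)):05d}"
                _add_row(mag, ko, cat)
    orf_totals = {
        mag: int(rng.integers(max(800, orf_counter.get(mag, 0)), 3000))
        for mag in biofilm_mags + planktonic_mags
    }
    annotations = AnnotationTable(rows=pd.DataFrame(rows), orf_totals=orf_totals)
    panel = MarkerPanel(entries=panel_entries)
    truth = {
        "pattern": {
            f"{m}|{f}|{g}": {"biofilm_linked": b, "planktonic": p}
            for m, f, g, b, p in pattern
        }
    }
    return annotations, panel, truth


# ---------------------------------------------------------------------------
# metagenome reads

def make_read_sets(
    spec: FixtureSpec,
    otu_reps: Sequence[SeqRecord],
    sources: Mapping[str, Sequence[str]] | None = None,
) -> tuple[dict[str, list[SeqRecord]], dict]:
    """Reads drawn from OTU representatives with a fixed substitution count.

    ``sources`` maps metagenome id -> OTU ids reads are generated from
    (default: one metagenome sampling every representative). Each read
    carries round(read_mutation_rate * length) substitutions.
    """
    rng = _rng(spec, 6)
    by_id = {r.id: r for r in otu_reps}
    if sources is None:
        sources = {"MG01": [r.id for r in otu_reps]}
    n_subs = int(round(spec.read_mutation_rate * spec.amplicon_length))
    read_sets: dict[str, list[SeqRecord]] = {}
    truth: dict[str, dict[str, str]] = {}
    for mg_id, otus in sources.items():
        reads: list[SeqRecord] = []
        truth[mg_id] = {}
        for i in range(spec.reads_per_metagenome):
            src = by_id[otus[i % len(otus)]]
            read_id = f"{mg_id}_read{i + 1:05d}"
            reads.append(
                SeqRecord(
                    id=read_id,
                    seq=mutate(src.seq, n_subs, rng, protect_k=spec.k),
                )
            )
            truth[mg_id][read_id] = src.id
        read_sets[mg_id] = reads
    return read_sets, {"read_sources": truth, "substitutions_per_read": n_subs}


# ---------------------------------------------------------------------------
# one-shot simulation of every input format

def simulate_all(spec: FixtureSpec, outdir: str | Path) -> dict:
    """Write every format the toolkit reads, plus truth.json; returns truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    table, table_truth = make_count_table(spec)
    io_formats.write_count_table(table, outdir / "counts.tsv", "plain_tsv")
    io_formats.write_count_table(table, outdir / "counts.shared", "mothur_shared")
    io_formats.write_roles(table.roles, outdir / "roles.tsv")

    db = make_refdb(spec)
    io_formats.write_fasta(db.records, outdir / "refdb.fasta")
    io_formats.write_reference_meta(db.meta, outdir / "refdb_meta.tsv")
    reps = make_rep_seqs(spec, db, table_truth)
    io_formats.write_fasta(list(reps.values()), outdir / "rep_seqs.fasta")

    mags, amplicons, mag_truth = make_mag_set(spec)
    io_formats.write_fasta(amplicons, outdir / "amplicons.fasta")
    rng = _rng(spec, 7)
    gene_records, contigs, features = [], [], []
    gene_depth_tracks, contig_depth_tracks = [], []
    for mag in mags:
        for gene_id, gene_seq, contig_id in mag.genes:
            gene_records.append(gene_seq)
            pad = spec.contig_length - len(gene_seq.seq)
            left = int(rng.integers(0, pad + 1))
            strand = "+" if rng.integers(0, 2) == 0 else "-"
            embedded = (gene_seq.seq if strand == "+"
                        else io_formats.reverse_complement(gene_seq.seq))
            contigs.append(
                SeqRecord(
                    id=contig_id,
                    seq=(random_seq(rng, left) + embedded
                         + random_seq(rng, pad - left)),
                )
            )
            features.append(
                GeneFeature(gene_id=gene_id, contig_id=contig_id,
                            start=left, end=left + len(gene_seq.seq),
                            strand=strand)
            )
            gt, ct = make_depth_tracks(
                spec, "uniform", gene_id=gene_id, contig_id=contig_id
            )
            gene_depth_tracks.append(
                DepthTrack(gene_id, gt.positions[: len(gene_seq.seq)],
                           gt.depth[: len(gene_seq.seq)])
            )
            contig_depth_tracks.append(ct)
    io_formats.write_fasta(gene_records, outdir / "mag_genes.fasta")
    io_formats.write_fasta(contigs, outdir / "contigs.fasta")
    io_formats.write_gff3_genes(features, outdir / "mag_genes.gff3")
    io_formats.write_depth(gene_depth_tracks, outdir / "gene_depth.tsv")
    io_formats.write_depth(contig_depth_tracks, outdir / "contig_depth.tsv")

    annotations, panel, panel_truth = make_annotations(
        spec,
        biofilm_mags=mag_truth["biofilm_linked"],
        planktonic_mags=mag_truth["planktonic"],
    )
    annotations.write(outdir / "annotations.tsv", outdir / "orf_totals.tsv")
    panel.write(outdir / "marker_panel.tsv")

    truth = {
        "seed": spec.seed,
        "count_table": table_truth,
        "mag_partition": mag_truth,
        "marker_pattern": panel_truth,
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return truth
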