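"""Readers and writers for every external format the toolkit touches.

Formats handled: plain wide TSV OTU tables (rows = OTUs, columns = samples),
the mothur ``shared`` dialect (rows = samples, ``label``/``Group``/``numOtus``
bookkeeping columns), sample-role manifests, FASTA, GFF3 gene rows,
samtools-depth-style per-base depth TSVs, and JSON/TSV report output.

Coordinate convention: external GFF3 and depth files are 1-based inclusive
(their standards); everything in memory is 0-based half-open. Conversion
happens only here, at the I/O boundary. Minus-strand genes are
reverse-complemented at extraction time so downstream code always sees the
sense strand.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .errors import FormatError, InputError, ManifestError

#: IUPAC nucleotide codes accepted in sequence records (T and U both allowed).
IUPAC_CODES = set("ACGTURYSWKMBDHVN")

ROLE_BLANK = "blank"
ROLE_SPECIMEN = "specimen"
_VALID_ROLES = {ROLE_BLANK, ROLE_SPECIMEN}

REPORT_VERSION = "1"


@dataclass
class SeqRecord:
    """A nucleotide sequence. ``seq`` is upper-cased and IUPAC-validated."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if not self.seq:
            raise InputError(f"sequence {self.id!r} is empty")
        bad = set(self.seq) - IUPAC_CODES
        if bad:
            raise FormatError(
                f"sequence {self.id!r} contains non-IUPAC characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ReferenceDB:
    """Reference 16S sequences with taxonomy / environmental-source metadata."""

    records: list[SeqRecord]
    meta: dict[str, dict[str, str]]

    def __post_init__(self) -> None:
        missing = [r.id for r in self.records if r.id not in self.meta]
        if missing:
            raise FormatError(f"reference records lacking metadata: {missing[:5]}")

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class DepthTrack:
    """Per-base read depth along one contig (or one reconstructed gene).

    Positions are stored 0-based; missing positions mean depth 0.
    """

    contig_id: str
    positions: np.ndarray
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if self.positions.size == 0:
            raise InputError(f"depth track {self.contig_id!r} is empty")
        if np.any(np.diff(self.positions) <= 0):
            raise FormatError(
                f"depth track {self.contig_id!r}: positions not strictly increasing"
            )
        if np.any(self.depth < 0):
            raise FormatError(f"depth track {self.contig_id!r}: negative depth")

    @property
    def span(self) -> tuple[int, int]:
        """Half-open interval covered by the track (first to last position)."""
        return int(self.positions[0]), int(self.positions[-1]) + 1

    def dense(self, start: int | None = None, end: int | None = None) -> np.ndarray:
        """Per-base depth over ``[start, end)`` with gaps filled as 0."""
        lo, hi = self.span
        if start is None:
            start = lo
        if end is None:
            end = hi
        if end <= start:
            raise InputError("empty interval requested from depth track")
        out = np.zeros(end - start, dtype=np.int64)
        sel = (self.positions >= start) & (self.positions < end)
        out[self.positions[sel] - start] = self.depth[sel]
        return out


@dataclass
class GeneFeature:
    """A gene located on a contig; coordinates 0-based half-open, in memory."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise FormatError(f"gene {self.gene_id!r}: unknown strand {self.strand!r}")
        if self.end <= self.start:
            raise FormatError(f"gene {self.gene_id!r}: end <= start")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class CountTable:
    """OTU × sample counts with per-sample role labels (blank / specimen)."""

    otu_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if len(set(self.otu_ids)) != len(self.otu_ids):
            raise FormatError("duplicate OTU ids in count table")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids in count table")
        if self.counts.shape != (len(self.otu_ids), len(self.sample_ids)):
            raise FormatError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.otu_ids)} OTUs x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            flt = np.asarray(self.counts, dtype=float)
            if np.any(~np.isfinite(flt)) or np.any(flt != np.floor(flt)):
                raise FormatError("counts must be integers")
            self.counts = flt.astype(np.int64)
        self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise FormatError("counts must be non-negative")
        for s in self.sample_ids:
            if s not in self.roles:
                raise ManifestError(f"sample {s!r} missing from roles manifest")
            if self.roles[s] not in _VALID_ROLES:
                raise ManifestError(
                    f"sample {s!r} has unknown role {self.roles[s]!r}"
                )

    @property
    def blank_ids(self) -> list[str]:
        return [s for s in self.sample_ids if self.roles[s] == ROLE_BLANK]

    @property
    def specimen_ids(self) -> list[str]:
        return [s for s in self.sample_ids if self.roles[s] == ROLE_SPECIMEN]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.otu_ids, columns=self.sample_ids)

    def drop_otus(self, otu_ids: Iterable[str]) -> "CountTable":
        """Return a new table without the given OTU rows."""
        drop = set(otu_ids)
        keep = [i for i, o in enumerate(self.otu_ids) if o not in drop]
        return CountTable(
            otu_ids=[self.otu_ids[i] for i in keep],
            sample_ids=list(self.sample_ids),
            counts=self.counts[keep, :].copy(),
            roles=dict(self.roles),
        )


# ---------------------------------------------------------------------------
# count tables

def read_roles(path: str | Path) -> dict[str, str]:
    """Read a two-column (sample_id, role) TSV manifest; header optional."""
    path = Path(path)
    if not path.exists():
        raise ManifestError(f"roles manifest not found: {path}")
    roles: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ManifestError(f"{path}:{ln}: expected 2 columns")
            sample, role = parts
            if ln == 1 and (sample.lower(), role.lower()) == ("sample_id", "role"):
                continue
            if role not in _VALID_ROLES:
                raise ManifestError(f"{path}:{ln}: unknown role {role!r}")
            if sample in roles:
                raise ManifestError(f"{path}:{ln}: duplicate sample {sample!r}")
            roles[sample] = role
    return roles


def read_count_table(
    path: str | Path,
    dialect: str = "plain_tsv",
    roles_path: str | Path | None = None,
    roles: Mapping[str, str] | None = None,
) -> CountTable:
    """Read an OTU count table in either supported dialect.

    ``plain_tsv``: wide TSV, first column OTU id, one column per sample.
    ``mothur_shared``: mothur's shared file; ``Group`` becomes the sample id
    and the ``label``/``numOtus`` columns are dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"count table not found: {path}")
    if roles is None:
        if roles_path is None:
            raise ManifestError("a roles manifest is required")
        roles = read_roles(roles_path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if dialect == "plain_tsv":
        df = df.set_index(df.columns[0])
        otu_ids = [str(x) for x in df.index]
        sample_ids = [str(c) for c in df.columns]
        mat = df
    elif dialect == "mothur_shared":
        required = {"label", "Group", "numOtus"}
        if not required.issubset(df.columns):
            raise FormatError(
                f"{path}: not a mothur shared file (needs columns {sorted(required)})"
            )
        if df["Group"].duplicated().any():
            raise FormatError(f"{path}: duplicate Group entries")
        sample_ids = [str(g) for g in df["Group"]]
        data = df.drop(columns=["label", "Group", "numOtus"]).T
        data.columns = sample_ids
        otu_ids = [str(x) for x in data.index]
        mat = data
    else:
        raise FormatError(f"unknown count-table dialect {dialect!r}")

    try:
        values = mat.astype(float).to_numpy()
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric count ({exc})") from exc
    if np.any(~np.isfinite(values)) or np.any(values != np.floor(values)):
        raise FormatError(f"{path}: counts must be integral")
    if np.any(values < 0):
        raise FormatError(f"{path}: counts must be non-negative")
    table_roles = {s: roles[s] for s in sample_ids if s in roles}
    return CountTable(
        otu_ids=otu_ids,
        sample_ids=sample_ids,
        counts=values.astype(np.int64),
        roles=table_roles,
    )


def write_count_table(
    table: CountTable, path: str | Path, dialect: str = "plain_tsv", label: str = "0.03"
) -> None:
    path = Path(path)
    if dialect == "plain_tsv":
        table.to_dataframe().to_csv(path, sep="\t", index_label="otu_id")
    elif dialect == "mothur_shared":
        wide = table.to_dataframe().T
        out = pd.DataFrame(
            {"label": label, "Group": wide.index, "numOtus": len(table.otu_ids)}
        )
        out = pd.concat([out.reset_index(drop=True), wide.reset_index(drop=True)], axis=1)
        out.to_csv(path, sep="\t", index=False)
    else:
        raise FormatError(f"unknown count-table dialect {dialect!r}")


def write_roles(roles: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\trole\n")
        for sample, role in roles.items():
            fh.write(f"{sample}\t{role}\n")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[SeqRecord]:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"FASTA not found: {path}")
    records = [
        SeqRecord(id=r.id, seq=str(r.seq), description=_strip_id(r.description, r.id))
        for r in SeqIO.parse(str(path), "fasta")
    ]
    if len({r.id for r in records}) != len(records):
        raise FormatError(f"{path}: duplicate sequence ids")
    return records


def _strip_id(description: str, rec_id: str) -> str:
    if description.startswith(rec_id):
        return description[len(rec_id):].strip()
    return description


def write_fasta(records: Sequence[SeqRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_reference_db(fasta_path: str | Path, meta_path: str | Path) -> ReferenceDB:
    """Reference FASTA plus a TSV of (id, taxonomy, environment_source)."""
    records = read_fasta(fasta_path)
    meta_df = pd.read_csv(meta_path, sep="\t", dtype=str).fillna("")
    needed = {"id", "taxonomy", "environment_source"}
    if not needed.issubset(meta_df.columns):
        raise FormatError(f"{meta_path}: needs columns {sorted(needed)}")
    meta = {
        str(row["id"]): {
            "taxonomy": str(row["taxonomy"]),
            "environment_source": str(row["environment_source"]),
        }
        for _, row in meta_df.iterrows()
    }
    return ReferenceDB(records=records, meta=meta)


def write_reference_meta(meta: Mapping[str, Mapping[str, str]], path: str | Path) -> None:
    rows = [
        {"id": k, "taxonomy": v.get("taxonomy", ""),
         "environment_source": v.get("environment_source", "")}
        for k, v in meta.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GFF3

def read_gff3_genes(
    path: str | Path, feature_types: tuple[str, ...] = ("rRNA", "gene")
) -> list[GeneFeature]:
    """Keep only rows of the configured feature types; convert to 0-based."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"GFF3 not found: {path}")
    genes: list[GeneFeature] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}:{ln}: expected 9 GFF3 columns")
            seqid, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = parts
            if ftype not in feature_types:
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: non-integer coordinates") from exc
            if end1 < start1:
                raise FormatError(f"{path}:{ln}: end < start")
            if strand not in {"+", "-"}:
                raise FormatError(f"{path}:{ln}: unknown strand {strand!r}")
            gene_id = _gff3_id(attrs) or f"{seqid}:{start1}-{end1}"
            genes.append(
                GeneFeature(
                    gene_id=gene_id, contig_id=seqid,
                    start=start1 - 1, end=end1, strand=strand,
                )
            )
    return genes


def _gff3_id(attrs: str) -> str | None:
    for item in attrs.split(";"):
        item = item.strip()
        if item.startswith("ID="):
            return item[3:]
    return None


def write_gff3_genes(genes: Sequence[GeneFeature], path: str | Path,
                     feature_type: str = "rRNA") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.contig_id}\tampmag\t{feature_type}\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


_COMPLEMENT = str.maketrans("ACGTURYSWKMBDHVN", "TGCAAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    """Reverse complement over the full IUPAC alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


def extract_gene(contig: SeqRecord, gene: GeneFeature) -> SeqRecord:
    """Slice a gene out of its contig, sense strand (minus genes revcomp'ed)."""
    if gene.end > len(contig.seq):
        raise FormatError(
            f"gene {gene.gene_id!r} extends past contig {contig.id!r}"
        )
    sub = contig.seq[gene.start : gene.end]
    if gene.strand == "-":
        sub = reverse_complement(sub)
    return SeqRecord(id=gene.gene_id, seq=sub, description=f"from {contig.id}")


# ---------------------------------------------------------------------------
# depth tables

def read_depth(path: str | Path) -> list[DepthTrack]:
    """samtools-depth-style TSV: contig, 1-based position, depth."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"depth table not found: {path}")
    df = pd.read_csv(path, sep="\t", header=None, names=["contig", "pos", "depth"],
                     dtype={"contig": str})
    try:
        pos = df["pos"].astype(np.int64)
        depth = df["depth"].astype(np.int64)
    except ValueError as exc:
        raise FormatError(f"{path}: non-integer position or depth") from exc
    tracks = []
    for contig, grp in df.assign(pos=pos, depth=depth).groupby("contig", sort=False):
        tracks.append(
            DepthTrack(
                contig_id=str(contig),
                positions=grp["pos"].to_numpy() - 1,  # to 0-based
                depth=grp["depth"].to_numpy(),
            )
        )
    return tracks


def write_depth(tracks: Sequence[DepthTrack], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in tracks:
            for p, d in zip(t.positions, t.depth):
                fh.write(f"{t.contig_id}\t{p + 1}\t{d}\n")


# ---------------------------------------------------------------------------
# reports

def make_report(payload: Mapping, parameters: Mapping) -> dict:
    """Wrap a result payload with the version/parameters block every report carries."""
    return {"version": REPORT_VERSION, "parameters": dict(parameters), **payload}


def write_report(report, path: str | Path, format: str = "json") -> None:
    path = Path(path)
    if format == "json":
        with open(path, "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
            fh.write("\n")
    elif format == "tsv":
        if isinstance(report, pd.DataFrame):
            report.to_csv(path, sep="\t", index=True)
        else:
            pd.DataFrame(list(report)).to_csv(path, sep="\t", index=False)
    else:
        raise FormatError(f"unknown report format {format!r}")


def read_report(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, Seq):
        return str(obj)
    raise TypeError(f"cannot serialize {type(obj)!r}")
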