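"""Functional gene-content comparison of MAG fractions.

Consumes upstream annotation output (KEGG-ortholog/gene-symbol assignments
per ORF, functional category labels, and total predicted ORFs per MAG) and
compares the biofilm-linked and planktonic fractions two ways:

* category profiles, normalized to the fraction's total predicted ORF count
  (annotated genes in category / total ORFs over the fraction's MAGs), with
  signed differences between fractions and a per-gene 0-1 "spider plot"
  table rescaled by the maximum across the two fractions;
* presence/absence of a marker-gene panel (rows of metabolism / function /
  gene-symbol set): a panel entry is present in a fraction iff any of its
  MAGs carries at least one of the entry's symbols.

Excluded MAGs never contribute to either fraction's profile.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import FormatError, InputError, PanelError
from .maglink import PartitionResult

FRACTION_BIOFILM = "biofilm_linked"
FRACTION_PLANKTONIC = "planktonic"


@dataclass
class AnnotationTable:
    """Rows of (mag_id, orf_id, gene, category) plus per-MAG ORF totals."""

    rows: pd.DataFrame
    orf_totals: dict[str, int]

    def __post_init__(self) -> None:
        needed = {"mag_id", "orf_id", "gene", "category"}
        if not needed.issubset(self.rows.columns):
            raise FormatError(f"annotation table needs columns {sorted(needed)}")
        if self.rows.duplicated(["mag_id", "orf_id", "gene"]).any():
            raise FormatError("duplicate (mag_id, orf_id, gene) annotation rows")
        per_mag = self.rows.groupby("mag_id")["orf_id"].nunique()
        for mag_id, n_annotated in per_mag.items():
            total = self.orf_totals.get(str(mag_id))
            if total is None:
                raise FormatError(f"MAG {mag_id!r} missing from ORF totals")
            if total < n_annotated:
                raise FormatError(
                    f"MAG {mag_id!r}: ORF total {total} < {n_annotated} annotated ORFs"
                )

    @classmethod
    def read(cls, annotations_path: str | Path, orf_totals_path: str | Path
             ) -> "AnnotationTable":
        rows = pd.read_csv(annotations_path, sep="\t", dtype=str)
        totals_df = pd.read_csv(orf_totals_path, sep="\t", dtype=str)
        if not {"mag_id", "total_orfs"}.issubset(totals_df.columns):
            raise FormatError("ORF totals TSV needs columns mag_id, total_orfs")
        totals = {
            str(r["mag_id"]): int(r["total_orfs"]) for _, r in totals_df.iterrows()
        }
        return cls(rows=rows, orf_totals=totals)

    def write(self, annotations_path: str | Path, orf_totals_path: str | Path
              ) -> None:
        self.rows.to_csv(annotations_path, sep="\t", index=False)
        pd.DataFrame(
            {"mag_id": list(self.orf_totals), "total_orfs": list(self.orf_totals.values())}
        ).to_csv(orf_totals_path, sep="\t", index=False)


@dataclass
class PanelEntry:
    metabolism: str
    function: str
    genes: frozenset[str]  # alternative symbols, any one confers presence

    def __post_init__(self) -> None:
        if not self.genes:
            raise PanelError(
                f"panel entry {self.metabolism}/{self.function} has no gene symbols"
            )

    @property
    def label(self) -> str:
        return f"{self.metabolism}|{self.function}|{'/'.join(sorted(self.genes))}"


@dataclass
class MarkerPanel:
    entries: list[PanelEntry]

    @classmethod
    def read(cls, path: str | Path) -> "MarkerPanel":
        df = pd.read_csv(path, sep="\t", dtype=str)
        needed = {"metabolism", "function", "gene"}
        if not needed.issubset(df.columns):
            raise FormatError(f"marker panel needs columns {sorted(needed)}")
        entries = [
            PanelEntry(
                metabolism=str(r["metabolism"]),
                function=str(r["function"]),
                genes=frozenset(
                    g.strip() for g in str(r["gene"]).split("/") if g.strip()
                ),
            )
            for _, r in df.iterrows()
        ]
        return cls(entries=entries)

    def write(self, path: str | Path) -> None:
        pd.DataFrame(
            [
                {
                    "metabolism": e.metabolism,
                    "function": e.function,
                    "gene": "/".join(sorted(e.genes)),
                }
                for e in self.entries
            ]
        ).to_csv(path, sep="\t", index=False)


@dataclass
class FractionProfile:
    fraction: str
    total_orfs: int
    category_abundance: dict[str, float]  # annotated genes / total ORFs
    gene_abundance: dict[str, float]      # per gene symbol, same denominator
    gene_category: dict[str, str]


def build_profile(
    annotations: AnnotationTable,
    mag_ids: Iterable[str],
    fraction_label: str,
) -> FractionProfile:
    """ORF-normalized functional profile over one fraction's MAGs."""
    mag_ids = set(map(str, mag_ids))
    total = sum(annotations.orf_totals.get(m, 0) for m in mag_ids)
    missing = [m for m in mag_ids if m not in annotations.orf_totals]
    if missing:
        raise InputError(f"MAG(s) missing from ORF totals: {sorted(missing)}")
    if total <= 0:
        raise InputError(f"fraction {fraction_label!r} has zero total ORFs")
    sub = annotations.rows[annotations.rows["mag_id"].isin(mag_ids)]
    cat_counts = sub.groupby("category").size()
    gene_counts = sub.groupby("gene").size()
    gene_cat = dict(zip(sub["gene"], sub["category"]))
    return FractionProfile(
        fraction=fraction_label,
        total_orfs=total,
        category_abundance={str(c): n / total for c, n in cat_counts.items()},
        gene_abundance={str(g): n / total for g, n in gene_counts.items()},
        gene_category=gene_cat,
    )


def compare_profiles(
    a: FractionProfile,
    b: FractionProfile,
    categories: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Signed per-category differences (a − b) and a per-gene spider table.

    Categories present in only one profile count as 0 in the other; category
    order follows the supplied list, else lexicographic. Spider values are
    each gene's normalized abundance rescaled to [0, 1] by the maximum
    across the two fractions (so at least one fraction sits at 1 unless both
    are 0).
    """
    if categories is None:
        categories = sorted(
            set(a.category_abundance) | set(b.category_abundance)
        )
    diff = pd.DataFrame(
        {
            "category": list(categories),
            a.fraction: [a.category_abundance.get(c, 0.0) for c in categories],
            b.fraction: [b.category_abundance.get(c, 0.0) for c in categories],
        }
    )
    diff["difference"] = diff[a.fraction] - diff[b.fraction]
    genes = sorted(set(a.gene_abundance) | set(b.gene_abundance))
    rows = []
    for g in genes:
        va = a.gene_abundance.get(g, 0.0)
        vb = b.gene_abundance.get(g, 0.0)
        peak = max(va, vb)
        rows.append(
            {
                "gene": g,
                "category": a.gene_category.get(g, b.gene_category.get(g, "")),
                a.fraction: va / peak if peak > 0 else 0.0,
                b.fraction: vb / peak if peak > 0 else 0.0,
            }
        )
    spider = pd.DataFrame(rows, columns=["gene", "category", a.fraction, b.fraction])
    return diff, spider


def marker_presence(
    annotations: AnnotationTable,
    partition: PartitionResult,
    panel: MarkerPanel,
) -> pd.DataFrame:
    """Presence/absence of each panel entry per fraction (boolean matrix).

    An entry is present for a fraction iff any of the fraction's MAGs
    carries at least one of the entry's gene symbols (case-insensitive).
    """
    fractions = {
        FRACTION_BIOFILM: {str(m) for m in partition.biofilm_linked},
        FRACTION_PLANKTONIC: {str(m) for m in partition.planktonic},
    }
    rows = annotations.rows
    gene_lower = rows["gene"].str.lower()
    out = []
    for entry in panel.entries:
        symbols = {g.lower() for g in entry.genes}
        carriers = set(rows.loc[gene_lower.isin(symbols), "mag_id"].astype(str))
        out.append(
            {
                "metabolism": entry.metabolism,
                "function": entry.function,
                "gene": "/".join(sorted(entry.genes)),
                FRACTION_BIOFILM: bool(carriers & fractions[FRACTION_BIOFILM]),
                FRACTION_PLANKTONIC: bool(carriers & fractions[FRACTION_PLANKTONIC]),
            }
        )
    return pd.DataFrame(out)


def render_presence(presence: pd.DataFrame, check: str = "✓") -> pd.DataFrame:
    """Render booleans as check-mark / blank for human-facing TSV output."""
    out = presence.copy()
    for col in (FRACTION_BIOFILM, FRACTION_PLANKTONIC):
        out[col] = out[col].map(lambda v: check if v else "")
    return out
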