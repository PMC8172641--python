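"""External representations: gene-order tables, Ks tables, FASTA pairs, config.

Gene orders are rank-based (0-based, gapless per chromosome): the depth and
chaining analyses operate in units of genes, so physical coordinates are not
modelled.  Strand is carried through for block-orientation reporting only.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Union

import pandas as pd
import yaml

PathLike = Union[str, Path]

GENE_ORDER_COLUMNS = ["chrom", "rank", "gene_id", "family_id"]
KS_COLUMNS = ["gene_a", "gene_b", "ks"]


class FormatError(ValueError):
    """Invalid external table content."""


# --------------------------------------------------------------------------
# Genome (ordered gene lists with family labels)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    family_id: str
    rank: int
    strand: str = "unknown"  # {+, -, unknown}


@dataclass
class Genome:
    """Ordered gene lists per chromosome, with family labels.

    Invariants (enforced by :meth:`validate`): ranks strictly increasing and
    gapless within each chromosome; gene ids unique genome-wide.
    """

    chromosomes: dict[str, list[GeneRecord]] = field(default_factory=dict)

    def validate(self) -> "Genome":
        seen: set[str] = set()
        for chrom, genes in self.chromosomes.items():
            ranks = [g.rank for g in genes]
            expected = list(range(len(genes)))
            if ranks != expected:
                gaps = sorted(set(expected) - set(ranks))
                raise FormatError(
                    f"rank gap on {chrom}: got {ranks[:10]}..., missing {gaps[:10]}"
                )
            for g in genes:
                if g.gene_id in seen:
                    raise FormatError(f"duplicate gene_id {g.gene_id!r}")
                seen.add(g.gene_id)
        return self

    @property
    def n_genes(self) -> int:
        return sum(len(g) for g in self.chromosomes.values())

    def genes(self):
        for chrom in self.chromosomes:
            for g in self.chromosomes[chrom]:
                yield chrom, g

    def gene_ids(self) -> set[str]:
        return {g.gene_id for _, g in self.genes()}

    def families(self) -> dict[str, list[tuple[str, GeneRecord]]]:
        """family_id -> list of (chrom, gene)."""
        fams: dict[str, list[tuple[str, GeneRecord]]] = {}
        for chrom, g in self.genes():
            fams.setdefault(g.family_id, []).append((chrom, g))
        return fams

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (chrom, g.rank, g.gene_id, g.family_id, g.strand)
            for chrom, g in self.genes()
        ]
        return pd.DataFrame(rows, columns=GENE_ORDER_COLUMNS + ["strand"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Genome":
        missing = [c for c in GENE_ORDER_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"gene-order table missing columns: {missing}")
        df = df.sort_values(["chrom", "rank"], kind="mergesort")
        has_strand = "strand" in df.columns
        chroms: dict[str, list[GeneRecord]] = {}
        for row in df.itertuples(index=False):
            strand = getattr(row, "strand", "unknown") if has_strand else "unknown"
            if strand not in {"+", "-", "unknown"}:
                strand = "unknown"
            chroms.setdefault(str(row.chrom), []).append(
                GeneRecord(str(row.gene_id), str(row.family_id), int(row.rank), strand)
            )
        return cls(chroms).validate()


def read_gene_order(source: Union[PathLike, _io.TextIOBase]) -> Genome:
    """Read a gene-order TSV (chrom, rank, gene_id, family_id[, strand])."""
    df = pd.read_csv(source, sep="\t", dtype=str)
    if "rank" not in df.columns:
        raise FormatError("gene-order table missing 'rank' column")
    try:
        df["rank"] = df["rank"].astype(int)
    except ValueError as exc:
        raise FormatError(f"non-integer rank: {exc}") from exc
    return Genome.from_frame(df)


def write_gene_order(genome: Genome, dest: PathLike) -> None:
    genome.to_frame().to_csv(dest, sep="\t", index=False)


# --------------------------------------------------------------------------
# Ks tables
# --------------------------------------------------------------------------

def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def read_ks_table(source: Union[PathLike, _io.TextIOBase]) -> pd.DataFrame:
    """Read and validate a Ks TSV (gene_a, gene_b, ks[, family_id, node_id]).

    Symmetric duplicate rows collapse to one record; the same pair reported
    with different Ks values is an error.  Pair keys are stored in sorted
    order so the table is orientation-free.
    """
    df = pd.read_csv(source, sep="\t", dtype={"gene_a": str, "gene_b": str})
    missing = [c for c in KS_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"ks table missing columns: {missing}")
    ks = pd.to_numeric(df["ks"], errors="coerce")
    if ks.isna().any():
        bad = df.loc[ks.isna(), "ks"].iloc[0]
        raise FormatError(f"non-numeric ks value: {bad!r}")
    import numpy as np

    if not np.isfinite(ks.to_numpy(dtype=float)).all():
        raise FormatError("non-finite ks value")
    if (ks < 0).any():
        raise FormatError("negative ks value")
    df = df.assign(ks=ks.astype(float))

    keys = [
        _pair_key(a, b) for a, b in zip(df["gene_a"], df["gene_b"])
    ]
    df = df.assign(gene_a=[k[0] for k in keys], gene_b=[k[1] for k in keys])
    grouped = df.groupby(["gene_a", "gene_b"], sort=False)
    if (grouped["ks"].nunique() > 1).any():
        bad = grouped["ks"].nunique()
        pair = bad[bad > 1].index[0]
        raise FormatError(f"conflicting ks values for pair {pair}")
    out = grouped.first().reset_index()
    return out


def write_ks_table(df: pd.DataFrame, dest: PathLike) -> None:
    df.to_csv(dest, sep="\t", index=False)


# --------------------------------------------------------------------------
# paired coding sequences (FASTA)
# --------------------------------------------------------------------------

def read_fasta(source: Union[PathLike, _io.TextIOBase]) -> dict[str, str]:
    """Minimal FASTA reader returning {id: sequence} (uppercased)."""
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        lines = Path(source).read_text().splitlines()
    seqs: dict[str, list[str]] = {}
    name = None
    for line in lines:
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            name = line[1:].split()[0]
            if name in seqs:
                raise FormatError(f"duplicate FASTA id {name!r}")
            seqs[name] = []
        else:
            if name is None:
                raise FormatError("FASTA data before first header")
            seqs[name].append(line.upper())
    return {k: "".join(v) for k, v in seqs.items()}


# --------------------------------------------------------------------------
# run configuration
# --------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Pipeline settings with the analysis-protocol defaults.

    ``max_gap``/``min_pairs`` are the "ten genes / five pairs" chaining
    thresholds; MAPS defaults are 3000 null trees, 1000-tree resamples
    repeated 100 times, alpha 0.05 and minimum WGD retention 0.2.
    """

    seed: int = 0
    ks_window: tuple[float, float] = (0.01, 3.0)
    mixture_k_max: int = 4
    mixture_n_boot: int = 200
    mixture_alpha: float = 0.05
    max_gap: int = 10
    min_pairs: int = 5
    maps_n_null: int = 3000
    maps_resample_size: int = 1000
    maps_resample_reps: int = 100
    maps_alpha: float = 0.05
    maps_retention_min: float = 0.2

    def validate(self) -> "RunConfig":
        lo, hi = self.ks_window
        positive = {
            "ks_window upper": hi,
            "mixture_k_max": self.mixture_k_max,
            "mixture_n_boot": self.mixture_n_boot,
            "mixture_alpha": self.mixture_alpha,
            "max_gap": self.max_gap,
            "min_pairs": self.min_pairs,
            "maps_n_null": self.maps_n_null,
            "maps_resample_size": self.maps_resample_size,
            "maps_resample_reps": self.maps_resample_reps,
            "maps_alpha": self.maps_alpha,
            "maps_retention_min": self.maps_retention_min,
        }
        for name, value in positive.items():
            if value <= 0:
                raise FormatError(f"config threshold {name} must be positive")
        if not (0 <= lo < hi):
            raise FormatError("ks_window must satisfy 0 <= low < high")
        return self

    @classmethod
    def from_yaml(cls, source: PathLike) -> "RunConfig":
        raw = yaml.safe_load(Path(source).read_text()) or {}
        if "ks_window" in raw:
            raw["ks_window"] = tuple(raw["ks_window"])
        return cls(**raw).validate()

    def to_yaml(self, dest: PathLike) -> None:
        d = asdict(self)
        d["ks_window"] = list(d["ks_window"])
        Path(dest).write_text(yaml.safe_dump(d, sort_keys=False))
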