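"""Readers and writers for the external formats the pipeline touches.

Dialects are deliberately strict: a featureCounts table, a Bismark
cytosine report, a GTF, a UCSC chain file and a GMT gene-set file each
have exactly one accepted shape, and anything else raises
:class:`FormatError` rather than being guessed at.

Coordinate conventions: gene models and cytosine records are 1-based
inclusive (the native GTF/Bismark convention); chain arithmetic and BED
output are 0-based half-open (the native UCSC convention).  Conversion
happens only at these boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "SampleMeta",
    "CountTable",
    "CytosineRecord",
    "GeneModel",
    "Chain",
    "GeneSetCollection",
    "read_counts",
    "write_counts",
    "read_cytosine_report",
    "write_cytosine_report",
    "read_gtf",
    "write_gtf",
    "read_chain",
    "write_chain",
    "read_gmt",
    "write_gmt",
    "write_dmr_bed",
    "write_table",
]


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


VALID_CONTEXTS = ("CpG", "CHG", "CHH")
# Bismark writes the CpG context as "CG"; normalise on input.
_CONTEXT_ALIASES = {"CG": "CpG", "CpG": "CpG", "CHG": "CHG", "CHH": "CHH"}


@dataclass(frozen=True)
class SampleMeta:
    """Identity of one sequenced library: sample id, species, comparison group."""

    sample_id: str
    species: str
    group: str = ""

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValidationError("sample_id must be non-empty")
        if not self.species:
            raise ValidationError(f"sample {self.sample_id!r}: species must be non-empty")


@dataclass
class CountTable:
    """Gene-by-sample integer read counts with per-gene lengths.

    ``lengths_bp`` may be 1-D (one length per gene, the featureCounts
    case) or 2-D genes x samples (the cross-species orthologue case,
    where each sample's species contributes its own gene length).
    """

    gene_ids: list[str]
    lengths_bp: np.ndarray
    counts: np.ndarray
    samples: list[SampleMeta]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.lengths_bp = np.asarray(self.lengths_bp)
        n_genes, n_samples = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise ValidationError("gene_ids length does not match count rows")
        if len(self.samples) != n_samples:
            raise ValidationError("samples length does not match count columns")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate sample_id in count table")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.floor(self.counts)):
                raise ValidationError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValidationError("counts must be non-negative")
        if np.any(self.lengths_bp <= 0):
            raise ValidationError("gene lengths must be positive")
        if self.lengths_bp.ndim not in (1, 2):
            raise ValidationError("lengths_bp must be 1-D or 2-D")
        if self.lengths_bp.shape[0] != n_genes:
            raise ValidationError("lengths_bp rows do not match gene count")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def lengths_matrix(self) -> np.ndarray:
        """Per-gene-per-sample lengths, broadcasting 1-D lengths."""
        if self.lengths_bp.ndim == 1:
            return np.broadcast_to(self.lengths_bp[:, None], self.counts.shape)
        return self.lengths_bp


@dataclass(frozen=True)
class CytosineRecord:
    """One cytosine with methylated/unmethylated read counts (1-based)."""

    chrom: str
    pos: int
    strand: str
    n_meth: int
    n_unmeth: int
    context: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"invalid strand {self.strand!r}")
        if self.n_meth < 0 or self.n_unmeth < 0:
            raise ValidationError("read counts must be non-negative")
        if self.context not in VALID_CONTEXTS:
            raise ValidationError(f"invalid context {self.context!r}")

    @property
    def coverage(self) -> int:
        return self.n_meth + self.n_unmeth


@dataclass
class GeneModel:
    """Strand-aware gene span with exon structure (1-based inclusive)."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"gene {self.gene_id}: start > end")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: invalid strand {self.strand!r}")
        self.exons = sorted(self.exons)
        prev_end = None
        for s, e in self.exons:
            if s < self.start or e > self.end:
                raise ValidationError(f"gene {self.gene_id}: exon ({s},{e}) outside gene span")
            if s > e:
                raise ValidationError(f"gene {self.gene_id}: exon start > end")
            if prev_end is not None and s <= prev_end:
                raise ValidationError(f"gene {self.gene_id}: overlapping exons")
            prev_end = e

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def introns(self) -> list[tuple[int, int]]:
        """Gene span minus exons, as sorted 1-based inclusive intervals."""
        if not self.exons:
            return []
        out = []
        cursor = self.start
        for s, e in self.exons:
            if s > cursor:
                out.append((cursor, s - 1))
            cursor = e + 1
        if cursor <= self.end:
            out.append((cursor, self.end))
        return out


@dataclass
class Chain:
    """One UCSC alignment chain (0-based half-open coordinates).

    ``blocks`` holds (size, dt, dq) triples; the final block carries
    size only and is stored with dt = dq = 0.
    """

    score: float
    t_name: str
    t_size: int
    t_strand: str
    t_start: int
    t_end: int
    q_name: str
    q_size: int
    q_strand: str
    q_start: int
    q_end: int
    blocks: list[tuple[int, int, int]]
    chain_id: str = ""

    def validate(self) -> None:
        t_span = sum(size + dt for size, dt, _ in self.blocks)
        q_span = sum(size + dq for size, _, dq in self.blocks)
        if t_span != self.t_end - self.t_start:
            raise FormatError(
                f"chain {self.chain_id or self.t_name}: block sums ({t_span}) "
                f"do not match target span ({self.t_end - self.t_start})"
            )
        if q_span != self.q_end - self.q_start:
            raise FormatError(
                f"chain {self.chain_id or self.t_name}: block sums ({q_span}) "
                f"do not match query span ({self.q_end - self.q_start})"
            )


class GeneSetCollection:
    """Named gene sets (GMT semantics) with optional descriptions."""

    def __init__(
        self,
        sets: Mapping[str, Iterable[str]],
        descriptions: Mapping[str, str] | None = None,
    ) -> None:
        self.sets: dict[str, set[str]] = {}
        self.descriptions: dict[str, str] = {}
        for name, members in sets.items():
            members = set(members)
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")
            self.sets[name] = members
            self.descriptions[name] = (descriptions or {}).get(name, "")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return self.sets == other.sets


# ---------------------------------------------------------------------------
# featureCounts tables


_FC_META_COLS = ["Geneid", "Chr", "Start", "End", "Strand", "Length"]


def read_counts(path: str | Path, samples: Sequence[SampleMeta] | None = None) -> CountTable:
    """Read a featureCounts-style TSV into a :class:`CountTable`.

    The dialect is: optional leading ``#`` comment lines, then a header
    with ``Geneid``/``Chr``/``Start``/``End``/``Strand``/``Length``
    followed by one column per sample.  If ``samples`` is given it must
    cover every sample column (matched by sample_id); otherwise samples
    are synthesised with species ``"unknown"``.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    idx = 0
    while idx < len(lines) and lines[idx].startswith("#"):
        idx += 1
    if idx >= len(lines):
        raise FormatError(f"{path}: empty count file")
    header = lines[idx].rstrip("\n").split("\t")
    for required in ("Geneid", "Length"):
        if required not in header:
            raise FormatError(f"{path}: header is missing required column {required!r}")
    meta_present = [c for c in _FC_META_COLS if c in header]
    if header[: len(meta_present)] != meta_present:
        raise FormatError(f"{path}: metadata columns must precede sample columns")
    sample_names = header[len(meta_present):]
    if not sample_names:
        raise FormatError(f"{path}: no sample columns")
    gid_col = header.index("Geneid")
    len_col = header.index("Length")

    gene_ids: list[str] = []
    lengths: list[int] = []
    counts: list[list[int]] = []
    for lineno, line in enumerate(lines[idx + 1 :], start=idx + 2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != len(header):
            raise FormatError(f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}")
        gene_ids.append(fields[gid_col])
        try:
            lengths.append(int(fields[len_col]))
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-integer Length {fields[len_col]!r}") from None
        row = []
        for name, value in zip(sample_names, fields[len(meta_present):]):
            try:
                row.append(int(value))
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-integer count {value!r} for sample {name}"
                ) from None
        counts.append(row)

    if samples is not None:
        by_id = {s.sample_id: s for s in samples}
        missing = [n for n in sample_names if n not in by_id]
        if missing:
            raise FormatError(f"{path}: no SampleMeta for sample column(s) {missing}")
        metas = [by_id[n] for n in sample_names]
    else:
        metas = [SampleMeta(n, "unknown") for n in sample_names]
    return CountTable(
        gene_ids=gene_ids,
        lengths_bp=np.array(lengths, dtype=np.int64),
        counts=np.array(counts, dtype=np.int64).reshape(len(gene_ids), len(metas)),
        samples=metas,
    )


def write_counts(table: CountTable, path: str | Path) -> None:
    """Write a featureCounts-style TSV (placeholder Chr/Start/End/Strand)."""
    if table.lengths_bp.ndim != 1:
        raise ValidationError("write_counts requires per-gene (1-D) lengths")
    with open(path, "w") as fh:
        fh.write("# Program:convergemeth\n")
        fh.write("\t".join(_FC_META_COLS + table.sample_ids) + "\n")
        for i, gid in enumerate(table.gene_ids):
            length = int(table.lengths_bp[i])
            row = [gid, ".", "1", str(length), "+", str(length)]
            row += [str(int(c)) for c in table.counts[i]]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Bismark cytosine reports


def read_cytosine_report(path: str | Path) -> list[CytosineRecord]:
    """Parse a Bismark cytosine/CX report (6 or 7 tab-separated columns).

    Columns: chrom, 1-based position, strand, count methylated, count
    unmethylated, context, optional trinucleotide.  The "CG" context
    token is normalised to the CpG class.
    """
    path = Path(path)
    records: list[CytosineRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) not in (6, 7):
                raise FormatError(f"{path}:{lineno}: expected 6-7 columns, got {len(fields)}")
            chrom, pos_s, strand, meth_s, unmeth_s, ctx = fields[:6]
            if ctx not in _CONTEXT_ALIASES:
                raise FormatError(f"{path}:{lineno}: unknown context token {ctx!r}")
            try:
                pos, n_meth, n_unmeth = int(pos_s), int(meth_s), int(unmeth_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer field") from None
            if n_meth < 0 or n_unmeth < 0:
                raise FormatError(f"{path}:{lineno}: negative read count")
            records.append(
                CytosineRecord(chrom, pos, strand, n_meth, n_unmeth, _CONTEXT_ALIASES[ctx])
            )
    return records


def write_cytosine_report(records: Iterable[CytosineRecord], path: str | Path) -> None:
    """Write records in Bismark cytosine-report layout (CpG emitted as CG)."""
    inv = {"CpG": "CG", "CHG": "CHG", "CHH": "CHH"}
    with open(path, "w") as fh:
        for rec in records:
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t{rec.strand}\t{rec.n_meth}\t"
                f"{rec.n_unmeth}\t{inv[rec.context]}\n"
            )


# ---------------------------------------------------------------------------
# GTF


def _gtf_attributes(raw: str, path: Path, lineno: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in raw.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        parts = chunk.split(None, 1)
        if len(parts) != 2:
            continue
        attrs[parts[0]] = parts[1].strip().strip('"')
    return attrs


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Read gene and exon features from a GTF into :class:`GeneModel` list.

    Coordinates stay 1-based inclusive.  Exon features are attached to
    their gene via the ``gene_id`` attribute; an exon outside its gene
    span raises :class:`ValidationError`.
    """
    path = Path(path)
    genes: dict[str, dict] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GTF fields")
            chrom, _src, feature, start_s, end_s, _score, strand, _frame, attr_s = fields
            if feature not in ("gene", "exon"):
                continue
            attrs = _gtf_attributes(attr_s, path, lineno)
            gid = attrs.get("gene_id")
            if gid is None:
                raise FormatError(f"{path}:{lineno}: {feature} feature missing gene_id attribute")
            start, end = int(start_s), int(end_s)
            if feature == "gene":
                if gid not in genes:
                    order.append(gid)
                genes[gid] = {"chrom": chrom, "strand": strand, "start": start, "end": end}
            else:
                exons.setdefault(gid, []).append((start, end))
    models = []
    for gid in order:
        g = genes[gid]
        models.append(
            GeneModel(
                gene_id=gid,
                chrom=g["chrom"],
                strand=g["strand"],
                start=g["start"],
                end=g["end"],
                exons=exons.get(gid, []),
            )
        )
    orphan = set(exons) - set(genes)
    if orphan:
        raise ValidationError(f"{path}: exon features without gene feature: {sorted(orphan)}")
    return models


def write_gtf(models: Iterable[GeneModel], path: str | Path, source: str = "convergemeth") -> None:
    with open(path, "w") as fh:
        for m in models:
            attrs = f'gene_id "{m.gene_id}";'
            fh.write(
                f"{m.chrom}\t{source}\tgene\t{m.start}\t{m.end}\t.\t{m.strand}\t.\t{attrs}\n"
            )
            for s, e in m.exons:
                fh.write(
                    f"{m.chrom}\t{source}\texon\t{s}\t{e}\t.\t{m.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# UCSC chain files


def read_chain(path: str | Path) -> list[Chain]:
    """Parse a UCSC chain file; every chain's block sums are validated."""
    path = Path(path)
    chains: list[Chain] = []
    current: Chain | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("chain"):
                fields = line.split()
                if len(fields) not in (12, 13):
                    raise FormatError(f"{path}:{lineno}: malformed chain header")
                current = Chain(
                    score=float(fields[1]),
                    t_name=fields[2],
                    t_size=int(fields[3]),
                    t_strand=fields[4],
                    t_start=int(fields[5]),
                    t_end=int(fields[6]),
                    q_name=fields[7],
                    q_size=int(fields[8]),
                    q_strand=fields[9],
                    q_start=int(fields[10]),
                    q_end=int(fields[11]),
                    blocks=[],
                    chain_id=fields[12] if len(fields) == 13 else "",
                )
                chains.append(current)
            else:
                if current is None:
                    raise FormatError(f"{path}:{lineno}: block line before chain header")
                fields = line.split()
                if len(fields) == 3:
                    current.blocks.append((int(fields[0]), int(fields[1]), int(fields[2])))
                elif len(fields) == 1:
                    current.blocks.append((int(fields[0]), 0, 0))
                else:
                    raise FormatError(f"{path}:{lineno}: malformed block line")
    for chain in chains:
        chain.validate()
    return chains


def write_chain(chains: Iterable[Chain], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in chains:
            head = (
                f"chain {c.score:g} {c.t_name} {c.t_size} {c.t_strand} {c.t_start} "
                f"{c.t_end} {c.q_name} {c.q_size} {c.q_strand} {c.q_start} {c.q_end}"
            )
            if c.chain_id:
                head += f" {c.chain_id}"
            fh.write(head + "\n")
            for i, (size, dt, dq) in enumerate(c.blocks):
                if i == len(c.blocks) - 1:
                    fh.write(f"{size}\n")
                else:
                    fh.write(f"{size} {dt} {dq}\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# GMT / BED / result tables


def read_gmt(path: str | Path) -> GeneSetCollection:
    path = Path(path)
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, desc = fields[0], fields[1]
            sets[name] = set(fields[2:])
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in collection:
            desc = collection.descriptions.get(name, "") or "na"
            members = "\t".join(sorted(collection[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")


def write_dmr_bed(dmrs: Iterable, path: str | Path) -> None:
    """Write DMRs as BED (1-based inclusive -> 0-based half-open)."""
    with open(path, "w") as fh:
        for d in dmrs:
            name = getattr(d, "direction", ".")
            fh.write(f"{d.chrom}\t{d.start - 1}\t{d.end}\t{name}\n")


def write_table(records: Sequence, path: str | Path) -> None:
    """Write a sequence of dataclasses/dicts as a plain TSV."""
    if not records:
        Path(path).write_text("")
        return
    first = records[0]
    if hasattr(first, "__dataclass_fields__"):
        rows = [{k: getattr(r, k) for k in r.__dataclass_fields__} for r in records]
    else:
        rows = [dict(r) for r in records]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
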