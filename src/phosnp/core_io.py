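"""Domain types, file readers/writers, and packaged reference-table fixtures.

Coordinate convention: all protein and genomic coordinates are 1-based
inclusive throughout the package.  TSV is the canonical exchange format; a
minimal VCF dialect is accepted for SNP tables only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codon_effects import SYMBOLS

logger = logging.getLogger(__name__)

AA_LETTERS = set(SYMBOLS) - {"*"}
PHOSPHO_RESIDUES = ("S", "T", "Y")


class ParseError(ValueError):
    """Malformed input file."""


class SchemaError(ValueError):
    """TSV header does not match the declared schema."""


class ValidationError(ValueError):
    """Rows violate a domain-type invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProteinRecord:
    """A protein model: id, amino-acid sequence, optional owning gene."""

    id: str
    sequence: str
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"protein {self.id}: empty sequence")
        body, last = self.sequence[:-1], self.sequence[-1]
        if "*" in body or (last != "*" and last not in AA_LETTERS):
            raise ValidationError(
                f"protein {self.id}: invalid residue or internal stop"
            )
        bad = set(body) - AA_LETTERS
        if bad:
            raise ValidationError(f"protein {self.id}: invalid residues {bad}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneModel:
    """Chromosome, strand and ordered exon blocks defining a spliced CDS.

    Exons are 1-based inclusive genomic intervals sorted by genomic
    coordinate, non-overlapping; total exon length must be divisible by 3.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValidationError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if not self.exons:
            raise ValidationError(f"gene {self.gene_id}: no exons")
        object.__setattr__(self, "exons", tuple(tuple(e) for e in self.exons))
        prev_end = 0
        for start, end in self.exons:
            if start > end or start <= prev_end:
                raise ValidationError(
                    f"gene {self.gene_id}: exons must be sorted and non-overlapping"
                )
            prev_end = end
        if self.cds_length % 3 != 0:
            raise ValidationError(
                f"gene {self.gene_id}: CDS length {self.cds_length} not divisible by 3"
            )

    @property
    def cds_length(self) -> int:
        return sum(end - start + 1 for start, end in self.exons)


@dataclass(frozen=True)
class SnpRecord:
    """A single-nucleotide polymorphism carried by one or more accessions."""

    chrom: str
    pos: int
    ref: str
    alt: str
    accessions: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "accessions", frozenset(self.accessions))
        if self.ref == self.alt:
            raise ValidationError(f"SNP {self.chrom}:{self.pos}: ref == alt")
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValidationError(f"SNP {self.chrom}:{self.pos}: not single-nucleotide")
        if self.ref not in "ACGT" or self.alt not in "ACGT":
            raise ValidationError(f"SNP {self.chrom}:{self.pos}: non-ACGT allele")
        if not self.accessions:
            raise ValidationError(f"SNP {self.chrom}:{self.pos}: no accessions")

    @property
    def key(self) -> tuple[str, int, str]:
        """Non-redundancy identity: (chrom, pos, alt)."""
        return (self.chrom, self.pos, self.alt)


@dataclass(frozen=True)
class PhosphoSite:
    """An S/T/Y residue carrying (or predicted to carry) a phosphate group."""

    protein_id: str
    position: int
    residue: str
    status: str
    score: float | None = None

    def __post_init__(self) -> None:
        if self.residue not in PHOSPHO_RESIDUES:
            raise ValidationError(
                f"site {self.protein_id}:{self.position}: residue {self.residue!r}"
            )
        if self.status not in ("experimental", "predicted"):
            raise ValidationError(
                f"site {self.protein_id}:{self.position}: status {self.status!r}"
            )
        if self.status == "predicted" and self.score is None:
            raise ValidationError(
                f"site {self.protein_id}:{self.position}: predicted site needs a score"
            )


@dataclass(frozen=True)
class DomainAnnotation:
    """A conserved-domain interval on a protein (1-based inclusive)."""

    protein_id: str
    start: int
    end: int
    domain_id: str

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValidationError(
                f"domain {self.domain_id} on {self.protein_id}: bad interval"
            )


@dataclass(frozen=True)
class TermAnnotation:
    """Association of a protein with an annotation term (e.g. GO Slim)."""

    protein_id: str
    term_id: str

    def __post_init__(self) -> None:
        if not self.protein_id or not self.term_id:
            raise ValidationError("term annotation with empty id")


@dataclass
class TableReadResult:
    """Typed records plus the count of rows rejected by validation."""

    records: list
    n_rejected: int = 0
    rejected_rows: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an id -> sequence map.

    Ids are the first whitespace-delimited token of each header.  An empty
    file yields an empty map (with a warning); sequence data appearing before
    any header is a parse error naming the line.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip() == "":
                continue
            if not line.startswith(">"):
                raise ParseError(
                    f"{path}:{lineno}: sequence data before first FASTA header"
                )
            break
        else:
            logger.warning("FASTA file %s is empty", path)
            return {}
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(path: str | Path, sequences: dict[str, str], width: int = 60) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# GFF3 subset (CDS features grouped by Parent)
# ---------------------------------------------------------------------------


def read_gene_models(path: str | Path) -> dict[str, GeneModel]:
    """Read CDS features from a GFF3 subset, grouped by their Parent id.

    Only ``CDS`` features are used; all other feature types are ignored.
    """
    blocks: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GFF3 columns")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = cols
            if ftype != "CDS":
                continue
            attr_map = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            parent = attr_map.get("Parent") or attr_map.get("ID")
            if parent is None:
                raise ParseError(f"{path}:{lineno}: CDS without Parent attribute")
            entry = blocks.setdefault(
                parent, {"chrom": chrom, "strand": strand, "exons": []}
            )
            entry["exons"].append((int(start), int(end)))
    models = {}
    for gene_id, entry in blocks.items():
        models[gene_id] = GeneModel(
            gene_id=gene_id,
            chrom=entry["chrom"],
            strand=entry["strand"],
            exons=tuple(sorted(entry["exons"])),
        )
    return models


def write_gene_models(path: str | Path, models: Iterable[GeneModel]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for model in models:
            # phase of each CDS block = (3 - cumulative length % 3) % 3,
            # accumulated in translation order
            ordered = (
                model.exons if model.strand == "+" else tuple(reversed(model.exons))
            )
            cum = 0
            phases = {}
            for start, end in ordered:
                phases[(start, end)] = (3 - cum % 3) % 3
                cum += end - start + 1
            for start, end in model.exons:
                fh.write(
                    f"{model.chrom}\tphosnp\tCDS\t{start}\t{end}\t.\t"
                    f"{model.strand}\t{phases[(start, end)]}\tParent={model.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

_SCHEMAS = {
    "snps": ["chrom", "pos", "ref", "alt", "accessions"],
    "sites": ["protein_id", "position", "residue", "status", "score"],
    "domains": ["protein_id", "start", "end", "domain_id"],
    "terms": ["protein_id", "term_id"],
}


def _check_schema(df: pd.DataFrame, schema: str, path) -> None:
    required = [c for c in _SCHEMAS[schema] if c != "score"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def read_snps(path: str | Path) -> TableReadResult:
    """Read a SNP table; dispatches on extension (.vcf -> minimal VCF)."""
    path = Path(path)
    if path.suffix.lower() == ".vcf":
        return read_vcf_minimal(path)
    df = _read_tsv(path)
    _check_schema(df, "snps", path)
    result = TableReadResult(records=[])
    for idx, row in df.iterrows():
        try:
            accs = frozenset(a for a in row["accessions"].split(",") if a)
            for alt in row["alt"].split(","):  # multi-allelic rows split per alt
                result.records.append(
                    SnpRecord(row["chrom"], int(row["pos"]), row["ref"], alt, accs)
                )
        except (ValidationError, ValueError) as exc:
            result.n_rejected += 1
            result.rejected_rows.append((idx, str(exc)))
    _report_rejects(result, path)
    return result


def read_vcf_minimal(path: str | Path) -> TableReadResult:
    """Read the minimal VCF dialect: CHROM POS ID REF ALT + accession columns.

    Optional QUAL/FILTER/INFO/FORMAT columns are tolerated and ignored.  A
    sample column whose genotype mentions allele index i carries the i-th alt
    allele.  Multi-allelic lines are split into one record per alt.
    """
    header = None
    result = TableReadResult(records=[])
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("##"):
                continue
            if line.startswith("#"):
                header = line.lstrip("#").split("\t")
                continue
            if header is None:
                raise ParseError(f"{path}:{lineno}: VCF data before #CHROM header")
            cols = line.split("\t")
            row = dict(zip(header, cols))
            skip = {"CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO",
                    "FORMAT"}
            sample_names = [h for h in header if h not in skip]
            try:
                alts = row["ALT"].split(",")
                for i, alt in enumerate(alts, start=1):
                    accs = frozenset(
                        name for name in sample_names
                        if str(i) in row.get(name, "").replace("|", "/").split("/")
                    )
                    result.records.append(
                        SnpRecord(row["CHROM"], int(row["POS"]), row["REF"], alt, accs)
                    )
            except (ValidationError, ValueError, KeyError) as exc:
                result.n_rejected += 1
                result.rejected_rows.append((lineno, str(exc)))
    _report_rejects(result, path)
    return result


def read_sites(
    path: str | Path, proteome: dict[str, str] | None = None
) -> TableReadResult:
    """Read a phosphosite table, optionally validating residues vs a proteome."""
    df = _read_tsv(path)
    _check_schema(df, "sites", path)
    result = TableReadResult(records=[])
    for idx, row in df.iterrows():
        try:
            score = row.get("score", "")
            site = PhosphoSite(
                row["protein_id"],
                int(row["position"]),
                row["residue"],
                row["status"],
                float(score) if score not in ("", None) else None,
            )
            if proteome is not None:
                seq = proteome.get(site.protein_id)
                if seq is None:
                    raise ValidationError(
                        f"site row {idx}: unknown protein {site.protein_id}"
                    )
                if not (1 <= site.position <= len(seq)) or (
                    seq[site.position - 1] != site.residue
                ):
                    raise ValidationError(
                        f"site row {idx}: residue {site.residue} does not match "
                        f"sequence at {site.protein_id}:{site.position}"
                    )
            result.records.append(site)
        except (ValidationError, ValueError) as exc:
            result.n_rejected += 1
            result.rejected_rows.append((idx, str(exc)))
    _report_rejects(result, path)
    return result


def read_domains(
    path: str | Path, proteome: dict[str, str] | None = None
) -> TableReadResult:
    df = _read_tsv(path)
    _check_schema(df, "domains", path)
    result = TableReadResult(records=[])
    for idx, row in df.iterrows():
        try:
            dom = DomainAnnotation(
                row["protein_id"], int(row["start"]), int(row["end"]), row["domain_id"]
            )
            if proteome is not None:
                seq = proteome.get(dom.protein_id)
                if seq is None or dom.end > len(seq):
                    raise ValidationError(
                        f"domain row {idx}: interval outside {dom.protein_id}"
                    )
            result.records.append(dom)
        except (ValidationError, ValueError) as exc:
            result.n_rejected += 1
            result.rejected_rows.append((idx, str(exc)))
    _report_rejects(result, path)
    return result


def read_terms(path: str | Path) -> TableReadResult:
    df = _read_tsv(path)
    _check_schema(df, "terms", path)
    result = TableReadResult(records=[])
    for idx, row in df.iterrows():
        try:
            result.records.append(TermAnnotation(row["protein_id"], row["term_id"]))
        except (ValidationError, ValueError) as exc:
            result.n_rejected += 1
            result.rejected_rows.append((idx, str(exc)))
    _report_rejects(result, path)
    return result


def read_table(path: str | Path, schema: str) -> TableReadResult:
    """Dispatch to the reader for ``schema`` in {snps, sites, domains, terms}."""
    readers = {
        "snps": read_snps,
        "sites": read_sites,
        "domains": read_domains,
        "terms": read_terms,
    }
    if schema not in readers:
        raise SchemaError(f"unknown schema {schema!r}")
    return readers[schema](path)


def _report_rejects(result: TableReadResult, path) -> None:
    if result.n_rejected:
        logger.warning(
            "%s: rejected %d invalid row(s): %s",
            path,
            result.n_rejected,
            "; ".join(str(r) for r in result.rejected_rows[:5]),
        )


# ---------------------------------------------------------------------------
# Writers (TSV mirrors of the record types)
# ---------------------------------------------------------------------------


def write_snps(path: str | Path, snps: Iterable[SnpRecord]) -> None:
    rows = [
        {
            "chrom": s.chrom,
            "pos": s.pos,
            "ref": s.ref,
            "alt": s.alt,
            "accessions": ",".join(sorted(s.accessions)),
        }
        for s in snps
    ]
    pd.DataFrame(rows, columns=_SCHEMAS["snps"]).to_csv(path, sep="\t", index=False)


def write_sites(path: str | Path, sites: Iterable[PhosphoSite]) -> None:
    rows = [
        {
            "protein_id": s.protein_id,
            "position": s.position,
            "residue": s.residue,
            "status": s.status,
            "score": "" if s.score is None else repr(s.score),
        }
        for s in sites
    ]
    pd.DataFrame(rows, columns=_SCHEMAS["sites"]).to_csv(path, sep="\t", index=False)


def write_domains(path: str | Path, domains: Iterable[DomainAnnotation]) -> None:
    rows = [
        {
            "protein_id": d.protein_id,
            "start": d.start,
            "end": d.end,
            "domain_id": d.domain_id,
        }
        for d in domains
    ]
    pd.DataFrame(rows, columns=_SCHEMAS["domains"]).to_csv(path, sep="\t", index=False)


def write_terms(path: str | Path, terms: Iterable[TermAnnotation]) -> None:
    rows = [{"protein_id": t.protein_id, "term_id": t.term_id} for t in terms]
    pd.DataFrame(rows, columns=_SCHEMAS["terms"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Packaged reference-table fixtures
# ---------------------------------------------------------------------------


def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged reference table.

    ``table1``: proteins with nine or more experimentally identified
    phosphosites (AGI id, site count, per-residue breakdown, protein length,
    nucleic-acid-metabolism GO:6139 flag).

    ``table2``: proteins with candidate phosphorylation hotspots at window
    size 10 (AGI id, number of significant windows, "count(start)"
    descriptors transcribed verbatim).
    """
    if name not in ("table1", "table2"):
        raise ValueError(f"unknown fixture {name!r}")
    with resources.files("phosnp.data").joinpath(f"{name}.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    if name == "table1":
        df["go6139"] = df["go6139"].astype(bool)
    return df


def parse_window_descriptors(descriptor: str) -> list[tuple[int, int]]:
    """Parse 'count(start)' descriptors, e.g. '5(6), 6(4)' -> [(5,6),(6,4)]."""
    out = []
    for token in descriptor.split(","):
        token = token.strip()
        count, start = token.rstrip(")").split("(")
        out.append((int(count), int(start)))
    return out
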