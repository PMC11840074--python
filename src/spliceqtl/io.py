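"""Readers and writers for the external representations the pipeline touches.

Genotypes arrive as VCF v4.x (only the GT field is required), gene models as
GTF 2.2, junction read counts and sample metadata as TSV.  Everything is
parsed into plain in-memory containers with strict validation: multi-allelic
records, malformed genotypes, duplicate junction keys and overlapping exons
are rejected loudly with the offending line or cell named, never silently
dropped.

All coordinates are stored 1-based inclusive (VCF/GTF convention).  Junctions
are keyed by the intron's first and last base plus strand, convertible to BED
by subtracting one from the start.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import gffutils
import numpy as np
import pandas as pd

MISSING = "."

__all__ = [
    "VariantRecord",
    "GenotypeMatrix",
    "TranscriptModel",
    "SampleTable",
    "JunctionCountMatrix",
    "ResultSchema",
    "VcfParseError",
    "GtfParseError",
    "ValidationError",
    "junction_key",
    "parse_genotypes",
    "write_genotypes",
    "parse_gene_models",
    "write_gene_models",
    "parse_junction_counts",
    "write_junction_counts",
    "write_results_table",
]


class VcfParseError(ValueError):
    """Raised on malformed VCF input; message names the offending line."""


class GtfParseError(ValueError):
    """Raised on malformed GTF input; message names the offending line."""


class ValidationError(ValueError):
    """Raised when parsed data violates a domain invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic SNP/indel site (1-based position, single alternate allele)."""

    chrom: str
    pos: int
    id: str
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"variant {self.id}: pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValidationError(f"variant {self.id}: ref and alt must be non-empty")
        if self.ref == self.alt:
            raise ValidationError(f"variant {self.id}: ref and alt must differ")


@dataclass
class GenotypeMatrix:
    """Samples x variants alternate-allele dosage matrix.

    ``dosage`` is float with values in {0, 1, 2} and NaN for missing calls;
    shape ``(n_samples, n_variants)``.  ``population`` maps sample id to a
    population label (may be empty until a sample table is attached).
    Variants are stored sorted by (chrom, pos).
    """

    variants: list[VariantRecord]
    samples: list[str]
    dosage: np.ndarray
    population: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.samples), len(self.variants)):
            raise ValidationError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        vals = self.dosage[np.isfinite(self.dosage)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValidationError("dosage values must be in {0,1,2} or missing (NaN)")
        keys = [(v.chrom, v.pos) for v in self.variants]
        if keys != sorted(keys):
            order = sorted(range(len(keys)), key=lambda i: keys[i])
            self.variants = [self.variants[i] for i in order]
            self.dosage = self.dosage[:, order]
        if len(set(self.samples)) != len(self.samples):
            raise ValidationError("duplicate sample ids")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    def dosage_of(self, variant_id: str) -> np.ndarray:
        """Dosage vector (over samples) for one variant id."""
        idx = self.variant_ids.index(variant_id)
        return self.dosage[:, idx]

    def with_populations(self, table: "SampleTable") -> "GenotypeMatrix":
        pop = {s: table.df.loc[s, "population"] for s in self.samples if s in table.df.index}
        return GenotypeMatrix(self.variants, self.samples, self.dosage.copy(), pop)

    def population_mask(self, label: str) -> np.ndarray:
        return np.array([self.population.get(s) == label for s in self.samples])


@dataclass
class TranscriptModel:
    """One transcript: ordered exons (1-based inclusive) plus optional CDS.

    Exons are stored sorted ascending by genomic start regardless of strand;
    ``cds`` is the (start, end) span of the coding region in *transcript*
    coordinates, where transcript coordinate 1 is the 5' end (the highest
    genomic position for minus-strand transcripts).
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.transcript_id}: strand must be + or -")
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        prev_end = 0
        for s, e in self.exons:
            if s > e:
                raise ValidationError(f"{self.transcript_id}: exon start {s} > end {e}")
            if s <= prev_end:
                raise ValidationError(f"{self.transcript_id}: overlapping exons at {s}")
            prev_end = e
        if self.cds is not None:
            cs, ce = self.cds
            if not (1 <= cs <= ce <= self.length):
                raise ValidationError(
                    f"{self.transcript_id}: CDS span {self.cds} outside transcript "
                    f"length {self.length}"
                )

    @property
    def length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1] + 1, self.exons[i + 1][0] - 1)
            for i in range(len(self.exons) - 1)
        ]

    @property
    def tss(self) -> int:
        """First transcribed base (strand-aware)."""
        return self.exons[0][0] if self.strand == "+" else self.exons[-1][1]

    def transcript_span_to_genomic(self, lo: int, hi: int) -> list[tuple[int, int]]:
        """Genomic intervals (sorted, 1-based) covered by transcript coords [lo, hi]."""
        if not (1 <= lo <= hi <= self.length):
            raise ValueError(f"{self.transcript_id}: span ({lo}, {hi}) outside transcript")
        # transcript coord -> plus-strand offset coord
        if self.strand == "-":
            lo, hi = self.length - hi + 1, self.length - lo + 1
        out = []
        offset = 0
        for s, e in self.exons:
            n = e - s + 1
            a, b = max(lo, offset + 1), min(hi, offset + n)
            if a <= b:
                out.append((s + (a - offset - 1), s + (b - offset - 1)))
            offset += n
        return out

    def genomic_to_transcript(self, gpos: int) -> int:
        """Map a genomic position inside an exon to 1-based transcript coords."""
        offset = 0
        for s, e in self.exons:
            if s <= gpos <= e:
                plus_coord = offset + (gpos - s + 1)
                return plus_coord if self.strand == "+" else self.length - plus_coord + 1
            offset += e - s + 1
        raise ValueError(f"{self.transcript_id}: position {gpos} not exonic")


@dataclass
class SampleTable:
    """Per-sample metadata: population label, altitude (m) and blood phenotypes.

    Backed by a DataFrame indexed by sample id with columns ``population``,
    ``altitude``, ``hb`` (g/dL), ``wbc`` (1e9/L), ``platelets`` (1e9/L);
    phenotype columns may hold NaN.
    """

    df: pd.DataFrame

    COLUMNS = ("population", "altitude", "hb", "wbc", "platelets")

    def __post_init__(self) -> None:
        if self.df.index.duplicated().any():
            raise ValidationError("duplicate sample ids in sample table")
        for col in self.COLUMNS:
            if col not in self.df.columns:
                self.df[col] = np.nan
        alt = pd.to_numeric(self.df["altitude"], errors="coerce")
        if (alt.dropna() < 0).any():
            raise ValidationError("altitude must be >= 0")
        self.df = self.df[list(self.COLUMNS)]

    @classmethod
    def read_tsv(cls, path) -> "SampleTable":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=[MISSING])
        return cls(df)

    def write_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", na_rep=MISSING, float_format="%.6g")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def _is_text(source) -> bool:
    return isinstance(source, str) and ("\n" in source or source.startswith("##"))


def _read_lines(source) -> list[str]:
    if _is_text(source):
        return source.splitlines()
    with open(os.fspath(source)) as fh:
        return fh.read().splitlines()


def parse_genotypes(vcf_text_or_path) -> GenotypeMatrix:
    """Parse a VCF v4.x with GT fields into a :class:`GenotypeMatrix`.

    Only biallelic records are accepted; ``./.`` (or any genotype containing a
    missing allele) becomes NaN.  Sample order is preserved from the header;
    variants are sorted by (chrom, pos) on storage.
    """
    lines = _read_lines(vcf_text_or_path)
    samples: list[str] | None = None
    variants: list[VariantRecord] = []
    rows: list[list[float]] = []
    for ln, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        if line.startswith("##"):
            continue
        if line.startswith("#CHROM"):
            cols = line.rstrip("\n").split("\t")
            if cols[:9] != ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]:
                raise VcfParseError(f"line {ln}: malformed #CHROM header line")
            samples = cols[9:]
            continue
        if line.startswith("#"):
            continue
        if samples is None:
            raise VcfParseError(f"line {ln}: data record before #CHROM header (missing header)")
        fields = line.split("\t")
        if len(fields) != 9 + len(samples):
            raise VcfParseError(
                f"line {ln}: expected {9 + len(samples)} columns, got {len(fields)}"
            )
        chrom, pos, vid, ref, alt = fields[0], fields[1], fields[2], fields[3], fields[4]
        if "," in alt:
            raise VcfParseError(f"line {ln}: multi-allelic record (ALT={alt!r}) rejected")
        fmt = fields[8].split(":")
        if "GT" not in fmt:
            raise VcfParseError(f"line {ln}: FORMAT lacks GT field")
        gt_idx = fmt.index("GT")
        try:
            variants.append(VariantRecord(chrom, int(pos), vid, ref, alt))
        except (ValueError, ValidationError) as exc:
            raise VcfParseError(f"line {ln}: {exc}") from exc
        row: list[float] = []
        for si, cell in enumerate(fields[9:]):
            gt = cell.split(":")[gt_idx]
            alleles = gt.replace("|", "/").split("/")
            if len(alleles) != 2 or any(a not in ("0", "1", ".") for a in alleles):
                raise VcfParseError(
                    f"line {ln}: malformed GT {gt!r} for sample {samples[si]!r}"
                )
            if "." in alleles:
                row.append(np.nan)
            else:
                row.append(float(int(alleles[0]) + int(alleles[1])))
        rows.append(row)
    if samples is None:
        raise VcfParseError("missing #CHROM header line")
    dosage = (
        np.array(rows, dtype=float).T if rows else np.empty((len(samples), 0))
    )
    return GenotypeMatrix(variants, list(samples), dosage)


def write_genotypes(gm: GenotypeMatrix, path=None) -> str:
    """Serialize a :class:`GenotypeMatrix` as minimal VCF v4.2 text.

    Returns the text; also writes it to ``path`` when given.  Round-trips
    exactly through :func:`parse_genotypes`.
    """
    out = ["##fileformat=VCFv4.2", '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">']
    out.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(gm.samples))
    code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    for j, v in enumerate(gm.variants):
        gts = [
            code[d] if np.isfinite(d) else "./."
            for d in gm.dosage[:, j]
        ]
        out.append(
            f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref}\t{v.alt}\t.\t.\t.\tGT\t" + "\t".join(gts)
        )
    text = "\n".join(out) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------


def parse_gene_models(gtf_text_or_path) -> list[TranscriptModel]:
    """Parse GTF 2.2 exon/CDS features into :class:`TranscriptModel` objects.

    Exons are grouped per transcript and sorted ascending by start regardless
    of strand; CDS features are converted to a transcript-coordinate span
    respecting strand.
    """
    lines = _read_lines(gtf_text_or_path)
    # Pre-scan for line-numbered attribute errors before handing to gffutils.
    for ln, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 9:
            raise GtfParseError(f"line {ln}: expected 9 tab-separated fields")
        if parts[2] in ("exon", "CDS") and 'transcript_id "' not in parts[8]:
            raise GtfParseError(f"line {ln}: {parts[2]} feature lacks transcript_id")
    text = "\n".join(lines) + "\n"
    db = gffutils.create_db(
        text,
        ":memory:",
        from_string=True,
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    exons: dict[str, dict] = {}
    cds_parts: dict[str, list[tuple[int, int]]] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tid = feat.attributes["transcript_id"][0]
        gid = feat.attributes.get("gene_id", [tid])[0]
        if feat.featuretype == "exon":
            rec = exons.setdefault(
                tid, {"gene_id": gid, "chrom": feat.seqid, "strand": feat.strand, "exons": []}
            )
            rec["exons"].append((feat.start, feat.end))
        else:
            cds_parts.setdefault(tid, []).append((feat.start, feat.end))
    models = []
    for tid, rec in exons.items():
        tx = TranscriptModel(rec["gene_id"], tid, rec["chrom"], rec["strand"], rec["exons"])
        if tid in cds_parts:
            coords = []
            for s, e in cds_parts[tid]:
                coords.append(tx.genomic_to_transcript(s))
                coords.append(tx.genomic_to_transcript(e))
            tx.cds = (min(coords), max(coords))
            tx.__post_init__()
        models.append(tx)
    return models


def write_gene_models(models: list[TranscriptModel], path=None) -> str:
    """Serialize transcript models as GTF 2.2 exon (and CDS) features."""
    out = []
    for tx in models:
        attrs = f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}";'
        for s, e in tx.exons:
            out.append(
                f"{tx.chrom}\tspliceqtl\texon\t{s}\t{e}\t.\t{tx.strand}\t.\t{attrs}"
            )
        if tx.cds is not None:
            for s, e in tx.transcript_span_to_genomic(*tx.cds):
                out.append(
                    f"{tx.chrom}\tspliceqtl\tCDS\t{s}\t{e}\t.\t{tx.strand}\t0\t{attrs}"
                )
    text = "\n".join(out) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


# ---------------------------------------------------------------------------
# junction counts
# ---------------------------------------------------------------------------


def junction_key(chrom: str, start: int, end: int, strand: str, tag: str = "") -> str:
    """Canonical junction key: intron first/last base (1-based) plus strand.

    ``tag`` distinguishes intron-retention pseudo-junctions (``IR5``/``IR3``).
    """
    base = f"{chrom}:{start}-{end}:{strand}"
    return f"{base}:{tag}" if tag else base


@dataclass
class JunctionCountMatrix:
    """Junction read counts: one row per junction key, one column per sample."""

    meta: pd.DataFrame  # index = key, columns chrom, intron_start, intron_end, strand, tag
    counts: pd.DataFrame  # index = key, columns = samples, int

    def __post_init__(self) -> None:
        if self.meta.index.duplicated().any():
            dup = self.meta.index[self.meta.index.duplicated()][0]
            raise ValidationError(f"duplicate junction key {dup!r}")
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("negative junction count")
        self.counts = self.counts.astype(int)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def row(self, key: str) -> np.ndarray:
        """Counts for one junction key; zeros when the key is absent."""
        if key in self.counts.index:
            return self.counts.loc[key].to_numpy(dtype=float)
        return np.zeros(len(self.counts.columns))


_JUNC_COLS = ["chrom", "intron_start", "intron_end", "strand"]


def parse_junction_counts(tsv_text_or_path) -> JunctionCountMatrix:
    """Read a junction-count TSV (chrom, intron_start, intron_end, strand[, tag], samples...)."""
    if _is_text(tsv_text_or_path):
        from io import StringIO

        handle = StringIO(tsv_text_or_path)
    else:
        handle = tsv_text_or_path
    df = pd.read_csv(handle, sep="\t")
    missing_cols = [c for c in _JUNC_COLS if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"junction table lacks columns {missing_cols}")
    has_tag = "tag" in df.columns
    sample_cols = [c for c in df.columns if c not in _JUNC_COLS + ["tag"]]
    if not sample_cols:
        raise ValidationError("junction table has no sample columns")
    tags = df["tag"].fillna("").astype(str) if has_tag else pd.Series("", index=df.index)
    keys = [
        junction_key(r.chrom, int(r.intron_start), int(r.intron_end), r.strand, t)
        for r, t in zip(df.itertuples(), tags)
    ]
    counts = df[sample_cols]
    for col in sample_cols:
        bad = counts[col].isna()
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ValidationError(f"empty count cell at junction {keys[i]!r}, sample {col!r}")
        vals = pd.to_numeric(counts[col], errors="coerce")
        if vals.isna().any() or (vals % 1 != 0).any():
            raise ValidationError(f"non-integer count in sample column {col!r}")
    meta = pd.DataFrame(
        {
            "chrom": df["chrom"].astype(str).values,
            "intron_start": df["intron_start"].astype(int).values,
            "intron_end": df["intron_end"].astype(int).values,
            "strand": df["strand"].astype(str).values,
            "tag": tags.values,
        },
        index=pd.Index(keys, name="key"),
    )
    counts = pd.DataFrame(counts.to_numpy(dtype=int), index=meta.index, columns=sample_cols)
    return JunctionCountMatrix(meta, counts)


def write_junction_counts(jcm: JunctionCountMatrix, path=None) -> str:
    """Serialize a junction-count matrix as TSV; round-trips exactly."""
    out = jcm.meta.copy()
    if (out["tag"] == "").all():
        out = out.drop(columns=["tag"])
    out = pd.concat([out, jcm.counts], axis=1)
    text = out.to_csv(sep="\t", index=False)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


# ---------------------------------------------------------------------------
# generic results tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ResultSchema:
    """Column schema for a deterministic TSV result table."""

    columns: tuple[str, ...]
    sort_by: tuple[str, ...]
    float_precision: int = 6


def write_results_table(rows, schema: ResultSchema, path) -> pd.DataFrame:
    """Write result rows (mappings) as a sorted TSV with a fixed float format.

    Rows must carry exactly the schema's columns; the output is sorted by the
    schema's key so reruns are byte-identical.  Returns the written frame.
    """
    rows = list(rows)
    for r in rows:
        if set(r) != set(schema.columns):
            raise ValidationError(
                f"row columns {sorted(r)} do not match schema {sorted(schema.columns)}"
            )
    df = pd.DataFrame(rows, columns=list(schema.columns))
    if rows:
        df = df.sort_values(list(schema.sort_by), kind="mergesort").reset_index(drop=True)
    df.to_csv(
        path,
        sep="\t",
        index=False,
        na_rep=MISSING,
        float_format=f"%.{schema.float_precision}g",
    )
    return df
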