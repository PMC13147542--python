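"""Coding-consequence calling for short variants, plus genotype QC rules.

Given a reference genome (FASTA), gene models (GFF3 CDS features) and a
table of VCF-style variants, each variant is mapped into spliced CDS
coordinates, the edit is applied, and reference and edited coding sequences
are translated up to their first stop codon. Categories follow the usual
vocabulary: synonymous, missense, nonsense, frameshift, inframe_indel,
non_coding. The module also implements two quality rules from haploid
segregant sequencing: dropping heterozygous-flagged calls (impossible in a
haploid, hence low quality) and flank-agreement imputation of missing
genotypes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "GeneModel",
    "Variant",
    "ConsequenceCall",
    "GenotypeMatrix",
    "read_genome",
    "read_gene_models",
    "read_variants",
    "spliced_cds",
    "classify_variant",
    "scan_for_truncations",
    "drop_heterozygous",
    "impute_flanked",
]

CATEGORIES = (
    "synonymous",
    "missense",
    "nonsense",
    "frameshift",
    "inframe_indel",
    "non_coding",
)


@dataclass(frozen=True)
class GeneModel:
    """CDS structure of one gene (1-based inclusive GFF3 intervals)."""

    gene_id: str
    chromosome: str
    strand: str
    cds_intervals: tuple[tuple[int, int], ...]  # sorted by genomic position

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        ivs = tuple(sorted((int(a), int(b)) for a, b in self.cds_intervals))
        for (a, b), (c, _) in zip(ivs, ivs[1:]):
            if c <= b:
                raise ValueError(f"{self.gene_id}: overlapping CDS intervals")
        for a, b in ivs:
            if a > b or a < 1:
                raise ValueError(f"{self.gene_id}: bad interval ({a}, {b})")
        object.__setattr__(self, "cds_intervals", ivs)

    @property
    def span(self) -> tuple[int, int]:
        return self.cds_intervals[0][0], self.cds_intervals[-1][1]


@dataclass(frozen=True)
class Variant:
    """VCF-style variant: 1-based pos, anchored ref/alt alleles for indels."""

    chromosome: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if self.ref == self.alt:
            raise ValueError("ref and alt are identical")

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)


@dataclass(frozen=True)
class ConsequenceCall:
    gene_id: str
    variant: Variant
    category: str
    protein_length_ref: int
    protein_length_alt: int
    premature_stop: bool


# ---------------------------------------------------------------------------
# readers


def read_genome(fasta_path: str | Path) -> dict[str, str]:
    """Load a FASTA genome as {chromosome: uppercase sequence}."""
    genome: dict[str, str] = {}
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        if record.id in genome:
            raise ValueError(f"duplicate chromosome name {record.id}")
        seq = str(record.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence for chromosome {record.id}")
        genome[record.id] = seq
    if not genome:
        raise ValueError(f"no sequences in {fasta_path}")
    return genome


def read_gene_models(gff3_path: str | Path) -> list[GeneModel]:
    """Read gene models from GFF3 CDS features, grouped by their parent.

    When a gene carries several transcripts the longest total CDS is kept.
    """
    import gffutils

    db = gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    # transcript id -> (gene id, chrom, strand, intervals)
    by_tx: dict[str, dict] = {}
    for cds in db.features_of_type("CDS"):
        parents = cds.attributes.get("Parent", [cds.id or "unparented"])
        for tx_id in parents:
            entry = by_tx.setdefault(
                tx_id,
                {"chrom": cds.seqid, "strand": cds.strand, "intervals": []},
            )
            entry["intervals"].append((cds.start, cds.end))
    # map transcripts up to genes where possible
    models: dict[str, GeneModel] = {}
    for tx_id, entry in by_tx.items():
        gene_id = tx_id
        try:
            tx = db[tx_id]
            gene_id = tx.attributes.get("Parent", [tx_id])[0]
        except gffutils.FeatureNotFoundError:
            pass
        model = GeneModel(
            gene_id=gene_id,
            chromosome=entry["chrom"],
            strand=entry["strand"],
            cds_intervals=tuple(entry["intervals"]),
        )
        prev = models.get(gene_id)
        if prev is None or _cds_length(model) > _cds_length(prev):
            models[gene_id] = model
    return sorted(models.values(), key=lambda m: (m.chromosome, m.span))


def _cds_length(model: GeneModel) -> int:
    return sum(b - a + 1 for a, b in model.cds_intervals)


def read_variants(path: str | Path) -> list[Variant]:
    """Read a variant table (TSV with CHROM, POS, REF, ALT; '#CHROM' accepted)."""
    df = pd.read_csv(path, sep="\t", comment=None, dtype=str)
    df.columns = [c.lstrip("#").upper() for c in df.columns]
    required = ["CHROM", "POS", "REF", "ALT"]
    if not set(required) <= set(df.columns):
        raise ValueError(f"variant table needs columns {required}")
    return [
        Variant(str(r.CHROM), int(r.POS), str(r.REF).upper(), str(r.ALT).upper())
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# consequence calling


def spliced_cds(genome: dict[str, str], gene: GeneModel) -> str:
    """Spliced coding sequence in transcription order (strand-aware)."""
    chrom = genome[gene.chromosome]
    for a, b in gene.cds_intervals:
        if b > len(chrom):
            raise ValueError(
                f"{gene.gene_id}: interval ({a}, {b}) outside chromosome "
                f"{gene.chromosome} (length {len(chrom)})"
            )
    seq = "".join(chrom[a - 1 : b] for a, b in gene.cds_intervals)
    if gene.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def _translate_to_stop(cds: str) -> str:
    """Translate with the standard code up to (excluding) the first stop."""
    usable = len(cds) - len(cds) % 3
    protein = str(Seq(cds[:usable]).translate())
    stop = protein.find("*")
    return protein if stop < 0 else protein[:stop]


def _plus_strand_cds_index(gene: GeneModel, pos: int) -> int | None:
    """Index of genomic pos within the plus-strand concatenated CDS, or None."""
    offset = 0
    for a, b in gene.cds_intervals:
        if a <= pos <= b:
            return offset + (pos - a)
        offset += b - a + 1
    return None


def classify_variant(
    genome: dict[str, str], gene: GeneModel, variant: Variant
) -> ConsequenceCall:
    """Call the coding consequence of one variant on one gene model.

    The variant is mapped into spliced CDS coordinates, the edit applied,
    and both reference and edited CDS translated up to the first stop.
    Variants entirely outside the CDS — and, conservatively, variants
    spanning a CDS boundary — are called ``non_coding``.
    """
    chrom = genome.get(variant.chromosome)
    if chrom is None:
        raise ValueError(f"unknown chromosome {variant.chromosome}")
    observed = chrom[variant.pos - 1 : variant.pos - 1 + len(variant.ref)]
    if observed != variant.ref:
        raise ValueError(
            f"ref mismatch at {variant.chromosome}:{variant.pos}: "
            f"genome has {observed!r}, variant claims {variant.ref!r}"
        )

    ref_cds = spliced_cds(genome, gene)
    ref_protein = _translate_to_stop(ref_cds)

    alt_cds = _edit_cds(gene, variant, ref_cds)
    if alt_cds is None:
        return ConsequenceCall(
            gene_id=gene.gene_id,
            variant=variant,
            category="non_coding",
            protein_length_ref=len(ref_protein),
            protein_length_alt=len(ref_protein),
            premature_stop=False,
        )

    alt_protein = _translate_to_stop(alt_cds)
    indel_delta = len(variant.alt) - len(variant.ref)
    if indel_delta != 0:
        category = "frameshift" if indel_delta % 3 != 0 else "inframe_indel"
    elif alt_protein == ref_protein:
        category = "synonymous"
    elif len(alt_protein) < len(ref_protein) and ref_protein.startswith(alt_protein):
        category = "nonsense"
    else:
        category = "missense"
    return ConsequenceCall(
        gene_id=gene.gene_id,
        variant=variant,
        category=category,
        protein_length_ref=len(ref_protein),
        protein_length_alt=len(alt_protein),
        premature_stop=len(alt_protein) < len(ref_protein),
    )


def _edit_cds(gene: GeneModel, variant: Variant, ref_cds: str) -> str | None:
    """Apply a VCF-style edit to the spliced CDS; None when non-coding.

    SNPs and anchored indels are handled; the changed bases (everything
    after the shared anchor for indels) must fall entirely inside one CDS
    interval, otherwise the variant is treated as non-coding (with a
    warning when it partially overlaps the CDS).
    """
    nref, nalt = len(variant.ref), len(variant.alt)
    if nref == nalt:
        # (multi-)nucleotide substitution: every ref base must be in CDS
        plus_indices = [
            _plus_strand_cds_index(gene, variant.pos + k) for k in range(nref)
        ]
        if any(i is None for i in plus_indices):
            if any(i is not None for i in plus_indices):
                warnings.warn(
                    f"variant {variant.chromosome}:{variant.pos} straddles a "
                    "CDS boundary; treated as non-coding",
                    stacklevel=3,
                )
            return None
        cds = list(ref_cds)
        L = len(ref_cds)
        for k, plus_idx in enumerate(plus_indices):
            base = variant.alt[k]
            if gene.strand == "+":
                cds[plus_idx] = base
            else:
                cds[L - 1 - plus_idx] = str(Seq(base).complement())
        return "".join(cds)

    # anchored indel: bases after the anchor are deleted/inserted
    if variant.ref[0] != variant.alt[0]:
        # non-anchored representation; fall back to replace-span semantics
        warnings.warn(
            f"indel {variant.chromosome}:{variant.pos} lacks a shared anchor "
            "base; treated as non-coding",
            stacklevel=3,
        )
        return None
    if nref > nalt:  # deletion of ref[nalt..] (with alt length 1 typical)
        deleted = range(variant.pos + 1, variant.pos + nref)
        idx = [_plus_strand_cds_index(gene, p) for p in deleted]
        if any(i is None for i in idx):
            if any(i is not None for i in idx):
                warnings.warn(
                    f"deletion {variant.chromosome}:{variant.pos} straddles a "
                    "CDS boundary; treated as non-coding",
                    stacklevel=3,
                )
            return None
        if any(j - i != 1 for i, j in zip(idx, idx[1:])):
            warnings.warn(
                f"deletion {variant.chromosome}:{variant.pos} spans an intron; "
                "treated as non-coding",
                stacklevel=3,
            )
            return None
        L = len(ref_cds)
        if gene.strand == "+":
            drop = set(idx)
        else:
            drop = {L - 1 - i for i in idx}
        return "".join(b for i, b in enumerate(ref_cds) if i not in drop)

    # insertion after the anchor base: coding only when the anchor and the
    # following genomic base are CDS-consecutive (insertions at an exon
    # boundary land in the intron/flank and are non-coding)
    anchor_idx = _plus_strand_cds_index(gene, variant.pos)
    next_idx = _plus_strand_cds_index(gene, variant.pos + 1)
    if anchor_idx is None or next_idx != anchor_idx + 1:
        if anchor_idx is not None or next_idx is not None:
            warnings.warn(
                f"insertion {variant.chromosome}:{variant.pos} falls on a CDS "
                "boundary; treated as non-coding",
                stacklevel=3,
            )
        return None
    inserted = variant.alt[1:]
    if gene.strand == "+":
        at = anchor_idx + 1
        return ref_cds[:at] + inserted + ref_cds[at:]
    # minus strand: the insertion lands immediately upstream of the anchor's
    # transcript position, reverse-complemented
    at = len(ref_cds) - 1 - anchor_idx
    rc_ins = str(Seq(inserted).reverse_complement())
    return ref_cds[:at] + rc_ins + ref_cds[at:]


def scan_for_truncations(
    variants: list[Variant],
    genes: list[GeneModel],
    genome: dict[str, str],
) -> list[ConsequenceCall]:
    """Classify every variant against overlapping genes; keep truncating calls.

    Returns the calls whose category is frameshift or nonsense (protein-
    truncating candidates), in input variant order.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for gene in genes:
        by_chrom.setdefault(gene.chromosome, []).append(gene)
    calls: list[ConsequenceCall] = []
    for variant in variants:
        for gene in by_chrom.get(variant.chromosome, []):
            lo, hi = gene.span
            if variant.pos + len(variant.ref) - 1 < lo or variant.pos > hi:
                continue
            call = classify_variant(genome, gene, variant)
            if call.category in ("frameshift", "nonsense"):
                calls.append(call)
    return calls


# ---------------------------------------------------------------------------
# genotype QC and imputation


def drop_heterozygous(calls: pd.DataFrame, zygosity_column: str = "zygosity") -> pd.DataFrame:
    """Remove heterozygous-flagged genotype calls.

    The samples are haploid, so heterozygous calls indicate mapping or
    calling artifacts and are used as a quality filter.
    """
    if zygosity_column not in calls.columns:
        raise ValueError(f"missing zygosity column {zygosity_column!r}")
    zyg = calls[zygosity_column].astype(str).str.lower()
    return calls.loc[~zyg.isin({"het", "heterozygous", "0/1", "1/0", "0|1", "1|0"})].copy()


@dataclass(frozen=True)
class GenotypeMatrix:
    """Strains x markers parental-haplotype calls ('P1'/'P2'/NaN).

    ``markers`` carries one row per marker (index aligned with ``data``
    columns) with ``chromosome`` and ``pos``; markers are position-sorted
    within each chromosome.
    """

    data: pd.DataFrame
    markers: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.data.columns) != list(self.markers.index):
            raise ValueError("data columns and marker table index differ")
        for chrom, grp in self.markers.groupby("chromosome", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"markers on {chrom} not strictly increasing")

    @classmethod
    def from_csv(cls, path: str | Path) -> "GenotypeMatrix":
        """Read a strains x markers CSV; columns named ``chrom:pos``."""
        data = pd.read_csv(path, index_col=0)
        data = data.where(data.notna() & (data != "NA"))
        markers = pd.DataFrame(
            [c.split(":") for c in data.columns],
            columns=["chromosome", "pos"],
            index=data.columns,
        )
        markers["pos"] = markers["pos"].astype(int)
        return cls(data=data, markers=markers)

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, na_rep="NA")

    def n_called(self) -> int:
        return int(self.data.notna().sum().sum())


def impute_flanked(matrix: GenotypeMatrix) -> GenotypeMatrix:
    """Fill missing genotypes whose flanking calls agree.

    For each strain and each missing marker, when the nearest called markers
    on both sides (same chromosome) carry the same parental label, the gap is
    filled with that label; disagreeing flanks, and runs touching a
    chromosome end, stay missing. Called genotypes are never modified.
    """
    out = matrix.data.copy()
    for _, grp in matrix.markers.groupby("chromosome", sort=False):
        cols = list(grp.index)
        block = out[cols]
        fwd = block.ffill(axis=1)
        bwd = block.bfill(axis=1)
        fill = block.isna() & fwd.notna() & bwd.notna() & (fwd == bwd)
        out[cols] = block.where(~fill, fwd)
    return GenotypeMatrix(data=out, markers=matrix.markers)
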