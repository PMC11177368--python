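"""Minimal variant-consequence prediction on a toy gene model.

Classifies SNVs against GFF3 transcripts: coding changes are translated
with the standard genetic code (reverse-complemented on minus-strand
transcripts) into stop_gained / missense / synonymous calls; other variants
fall into intron, upstream/downstream (within a configurable distance of
the transcript, 100 kb by default) or intergenic.  Impact classes follow
the usual severity map (stop_gained HIGH, missense MODERATE, synonymous
LOW, everything else MODIFIER).

The gene model carries its own reference sequence; because toy chromosomes
are mostly empty, the companion FASTA may cover only a slice of each
chromosome, with the slice start encoded as ``offset=<bp>`` (0-based) in
the record description.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

from Bio.Seq import Seq

from .core_io import VariantInfo

IMPACT_OF = {
    "stop_gained": "HIGH",
    "missense_variant": "MODERATE",
    "synonymous_variant": "LOW",
    "intron_variant": "MODIFIER",
    "upstream_gene_variant": "MODIFIER",
    "downstream_gene_variant": "MODIFIER",
    "intergenic_variant": "MODIFIER",
}

_IMPACT_RANK = {"MODIFIER": 0, "LOW": 1, "MODERATE": 2, "HIGH": 3}


@dataclass
class Transcript:
    id: str
    gene: str
    chrom: str
    strand: str                      # "+" or "-"
    exons: list[tuple[int, int]]     # 1-based inclusive
    cds: list[tuple[int, int]]

    def __post_init__(self):
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        for a, b in zip(self.exons, self.exons[1:]):
            if a[1] >= b[0]:
                raise ValueError(f"transcript {self.id}: overlapping exons")
        if self.strand not in "+-":
            raise ValueError(f"transcript {self.id}: bad strand {self.strand!r}")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


@dataclass
class GeneModel:
    transcripts: list[Transcript]
    # chrom -> (offset_bp, sequence); sequence[i] is the base at
    # 1-based position offset_bp + i + 1
    sequences: dict[str, tuple[int, str]] = field(default_factory=dict)

    def ref_base(self, chrom: str, pos: int) -> str:
        if chrom not in self.sequences:
            raise KeyError(f"no reference sequence for chromosome {chrom}")
        offset, seq = self.sequences[chrom]
        i = pos - offset - 1
        if not (0 <= i < len(seq)):
            raise KeyError(f"position {chrom}:{pos} outside the reference slice")
        return seq[i].upper()

    def validate(self) -> None:
        for tx in self.transcripts:
            total = sum(e - s + 1 for s, e in tx.cds)
            if total % 3 != 0:
                raise ValueError(
                    f"transcript {tx.id}: CDS length {total} not divisible by 3")

    @classmethod
    def from_gff3(cls, gff_path: str | os.PathLike,
                  fasta_path: str | os.PathLike | None = None) -> "GeneModel":
        """Load gene/mRNA/exon/CDS features (1-based inclusive) via gffutils."""
        import gffutils

        db = gffutils.create_db(str(gff_path), ":memory:",
                                merge_strategy="create_unique", force=True)
        transcripts = []
        for mrna in db.features_of_type("mRNA"):
            gene = mrna.attributes.get("gene_name",
                                       mrna.attributes.get("Parent", ["?"]))[0]
            exons = [(f.start, f.end)
                     for f in db.children(mrna, featuretype="exon")]
            cds = [(f.start, f.end)
                   for f in db.children(mrna, featuretype="CDS")]
            transcripts.append(Transcript(
                id=mrna.id, gene=gene, chrom=mrna.seqid, strand=mrna.strand,
                exons=exons if exons else cds, cds=cds))
        sequences = {}
        if fasta_path is not None:
            from Bio import SeqIO
            for rec in SeqIO.parse(str(fasta_path), "fasta"):
                offset = 0
                for tok in rec.description.split():
                    if tok.startswith("offset="):
                        offset = int(tok.split("=", 1)[1])
                sequences[rec.id] = (offset, str(rec.seq))
        model = cls(transcripts, sequences)
        model.validate()
        return model

    def to_gff3(self, gff_path: str | os.PathLike,
                fasta_path: str | os.PathLike | None = None) -> None:
        with open(gff_path, "w") as fh:
            fh.write("##gff-version 3\n")
            for tx in self.transcripts:
                gid = f"gene_{tx.gene}"
                fh.write(f"{tx.chrom}\t.\tgene\t{tx.start}\t{tx.end}\t.\t"
                         f"{tx.strand}\t.\tID={gid};Name={tx.gene}\n")
                fh.write(f"{tx.chrom}\t.\tmRNA\t{tx.start}\t{tx.end}\t.\t"
                         f"{tx.strand}\t.\tID={tx.id};Parent={gid};"
                         f"gene_name={tx.gene}\n")
                for s, e in tx.exons:
                    fh.write(f"{tx.chrom}\t.\texon\t{s}\t{e}\t.\t{tx.strand}"
                             f"\t.\tParent={tx.id}\n")
                for s, e in tx.cds:
                    fh.write(f"{tx.chrom}\t.\tCDS\t{s}\t{e}\t.\t{tx.strand}"
                             f"\t0\tParent={tx.id}\n")
        if fasta_path is not None:
            with open(fasta_path, "w") as fh:
                for chrom, (offset, seq) in self.sequences.items():
                    fh.write(f">{chrom} offset={offset}\n")
                    for i in range(0, len(seq), 70):
                        fh.write(seq[i:i + 70] + "\n")


@dataclass
class ConsequenceRecord:
    variant_id: str
    transcript_id: str | None
    consequence: str
    impact: str
    amino_acids: str | None = None    # "X/Y" for coding changes
    gene: str | None = None


def _spliced_cds_index(tx: Transcript, pos: int) -> int | None:
    """0-based index of a genomic position within the spliced CDS."""
    off = 0
    for s, e in tx.cds:
        if s <= pos <= e:
            idx = off + (pos - s)
            if tx.strand == "-":
                total = sum(e2 - s2 + 1 for s2, e2 in tx.cds)
                return total - 1 - idx
            return idx
        off += e - s + 1
    return None


def _cds_sequence(tx: Transcript, model: GeneModel) -> str:
    parts = [
        "".join(model.ref_base(tx.chrom, p) for p in range(s, e + 1))
        for s, e in tx.cds]
    seq = "".join(parts)
    if tx.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def classify_coding(tx: Transcript, model: GeneModel, variant: VariantInfo
                    ) -> ConsequenceRecord:
    ref_base = model.ref_base(tx.chrom, variant.pos)
    if ref_base != variant.ref_allele.upper():
        raise ValueError(
            f"variant {variant.id}: ref allele {variant.ref_allele!r} "
            f"disagrees with model reference {ref_base!r} at "
            f"{tx.chrom}:{variant.pos}")
    cds_seq = _cds_sequence(tx, model)
    i = _spliced_cds_index(tx, variant.pos)
    alt = variant.alt_allele.upper()
    if tx.strand == "-":
        alt = str(Seq(alt).reverse_complement())
    codon_i = i // 3
    within = i % 3
    codon = cds_seq[3 * codon_i: 3 * codon_i + 3]
    new_codon = codon[:within] + alt + codon[within + 1:]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(new_codon).translate())
    if aa_alt == aa_ref:
        term = "synonymous_variant"
    elif aa_alt == "*":
        term = "stop_gained"
    else:
        term = "missense_variant"
    return ConsequenceRecord(
        variant_id=variant.id, transcript_id=tx.id, consequence=term,
        impact=IMPACT_OF[term], amino_acids=f"{aa_ref}/{aa_alt}",
        gene=tx.gene)


def annotate_variants(variants: list[VariantInfo], model: GeneModel,
                      updown_distance_bp: int = 100_000
                      ) -> list[ConsequenceRecord]:
    """One record per variant x overlapping/nearby transcript.

    A variant beyond ``updown_distance_bp`` of every transcript gets a
    single intergenic record, so every variant receives at least one.
    """
    model.validate()
    records: list[ConsequenceRecord] = []
    for v in variants:
        hit = False
        for tx in model.transcripts:
            if tx.chrom != v.chrom:
                continue
            if tx.start <= v.pos <= tx.end:
                if any(s <= v.pos <= e for s, e in tx.cds):
                    records.append(classify_coding(tx, model, v))
                else:
                    records.append(ConsequenceRecord(
                        v.id, tx.id, "intron_variant", "MODIFIER", None,
                        tx.gene))
                hit = True
            elif tx.start - updown_distance_bp <= v.pos < tx.start:
                term = ("upstream_gene_variant" if tx.strand == "+"
                        else "downstream_gene_variant")
                records.append(ConsequenceRecord(
                    v.id, tx.id, term, "MODIFIER", None, tx.gene))
                hit = True
            elif tx.end < v.pos <= tx.end + updown_distance_bp:
                term = ("downstream_gene_variant" if tx.strand == "+"
                        else "upstream_gene_variant")
                records.append(ConsequenceRecord(
                    v.id, tx.id, term, "MODIFIER", None, tx.gene))
                hit = True
        if not hit:
            records.append(ConsequenceRecord(
                v.id, None, "intergenic_variant", "MODIFIER", None, None))
    return records


def impact_filter(records: list[ConsequenceRecord],
                  min_impact: str = "MODERATE") -> set[str]:
    """Variant ids whose maximal impact over transcripts reaches min_impact."""
    if min_impact not in _IMPACT_RANK:
        raise ValueError(f"unknown impact class {min_impact!r}")
    best: dict[str, int] = {}
    for r in records:
        rank = _IMPACT_RANK[r.impact]
        best[r.variant_id] = max(best.get(r.variant_id, -1), rank)
    need = _IMPACT_RANK[min_impact]
    return {vid for vid, rank in best.items() if rank >= need}


def write_consequences_tsv(records: list[ConsequenceRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("Uploaded_variation\tTranscript\tConsequence\tIMPACT\t"
                 "Amino_acids\tGene\n")
        for r in records:
            fh.write(f"{r.variant_id}\t{r.transcript_id or '-'}\t"
                     f"{r.consequence}\t{r.impact}\t{r.amino_acids or '-'}\t"
                     f"{r.gene or '-'}\n")
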