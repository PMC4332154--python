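"""Readers and writers for the package's on-disk formats.

FASTA/FASTQ through Biopython, GFF3 through gffutils (1-based
inclusive; the simulator's ground truth travels in a ``truth=``
attribute and a ``##sequence-region`` directive carries the genome
length), expression matrices and domain tables as TSV via pandas.
"""

from __future__ import annotations

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation import FEATURE_COLUMNS, GenomeAnnotation, TruthAnnotation


def write_fasta(genome: str, path, genome_id: str = "genome") -> None:
    SeqIO.write([SeqRecord(Seq(genome), id=genome_id, description="")], path, "fasta")


def read_fasta(path) -> tuple[str, str]:
    """First record as (id, sequence)."""
    rec = next(SeqIO.parse(path, "fasta"))
    return rec.id, str(rec.seq).upper()


def write_fastq(records, path) -> None:
    SeqIO.write(records, path, "fastq")


def read_fastq(path):
    return list(SeqIO.parse(path, "fastq"))


# ------------------------------------------------------------------ GFF3


def write_gff3(annotation: GenomeAnnotation, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {annotation.genome_id} 1 {annotation.G}\n")
        has_truth = "truth" in annotation.features.columns
        for f in annotation.features.itertuples():
            attrs = f"ID={f.id}"
            if has_truth and isinstance(f.truth, str):
                attrs += f";truth={f.truth}"
            strand = f.strand if f.strand in "+-" else "."
            fh.write(
                f"{annotation.genome_id}\tminitn\t{f.type}\t{f.start}\t{f.end}\t.\t"
                f"{strand}\t.\t{attrs}\n"
            )


def read_gff3(path, domains: pd.DataFrame | None = None):
    """Load an annotation; returns :class:`TruthAnnotation` when truth
    attributes are present, else :class:`GenomeAnnotation`."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genome_id, G = "genome", None
    for d in db.directives:
        if d.startswith("sequence-region"):
            parts = d.split()
            genome_id, G = parts[1], int(parts[3])
    rows, truths = [], []
    for feat in db.all_features(order_by=("start",)):
        fid = feat.attributes.get("ID", [feat.id])[0]
        rows.append((fid, feat.featuretype, feat.start, feat.end,
                     feat.strand if feat.strand in "+-" else "."))
        truths.append(feat.attributes.get("truth", [None])[0])
        genome_id = feat.seqid
    features = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    if G is None:
        G = int(features["end"].max()) if len(features) else 0
    if any(t is not None for t in truths):
        features["truth"] = truths
        return TruthAnnotation(
            features=features, G=G, genome_id=genome_id,
            domains=domains if domains is not None else pd.DataFrame(
                columns=["orf_id", "domain_id", "aa_start", "aa_end", "truth"]
            ),
        )
    return GenomeAnnotation(features=features, G=G, genome_id=genome_id)


# ------------------------------------------------------------ flat tables


def write_expression(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="feature")


def read_expression(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="feature")


def write_domain_tsv(domains: pd.DataFrame, path) -> None:
    domains.to_csv(path, sep="\t", index=False)


def write_smorf_gff3(hits: pd.DataFrame, path, genome_id: str = "genome") -> None:
    """smORF candidates as GFF3 CDS features with candidate_smorf=true."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, h in enumerate(hits.itertuples(), 1):
            fh.write(
                f"{genome_id}\tminitn\tCDS\t{h.genome_start}\t{h.genome_end}\t.\t"
                f"{h.strand}\t0\tID=smorf_cand_{i:04d};parent_ncrna={h.seq_id};"
                f"candidate_smorf=true\n"
            )


def write_peptides_fasta(hits: pd.DataFrame, path) -> None:
    records = [
        SeqRecord(Seq(h.peptide), id=f"{h.seq_id}|frame{h.frame}|{h.nt_start}-{h.nt_end}",
                  description="")
        for h in hits.itertuples()
    ]
    SeqIO.write(records, path, "fasta")
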