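"""Readers and writers for the package's on-disk formats.

Counts travel as TSV (genes x samples) or MatrixMarket plus a sample
metadata TSV; orthology as OrthoFinder-dialect ``Orthogroups.tsv``
(handled by :class:`gutmap.ortho.OrthologyTable`); protein sequences as
FASTA via Biopython; planted truth and run reports as JSON.  Stage-stamped
TSVs carry a ``# gutmap stage=<stage>`` header comment so intermediate
artifacts are self-describing.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from scipy import io as spio
from scipy import sparse
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .dataset import ExpressionDataset


def write_counts_tsv(ds: ExpressionDataset, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# gutmap stage={ds.stage}\n")
        ds.values.to_csv(fh, sep="\t")


def read_counts_tsv(path, meta_path, stage: str | None = None,
                    ) -> ExpressionDataset:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        header_stage = None
        if first.startswith("# gutmap stage="):
            header_stage = first.strip().split("=", 1)[1]
            values = pd.read_csv(fh, sep="\t", index_col=0)
        else:
            fh.seek(0)
            values = pd.read_csv(fh, sep="\t", index_col=0)
    meta = read_meta_tsv(meta_path)
    return ExpressionDataset(values, meta.loc[values.columns],
                             stage=stage or header_stage or "raw")


def write_meta_tsv(ds: ExpressionDataset, path) -> None:
    ds.meta.to_csv(path, sep="\t", index_label="sample")


def read_meta_tsv(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col="sample")
    meta["ap_rank"] = meta["ap_rank"].astype(int)
    return meta


def write_counts_mtx(ds: ExpressionDataset, prefix) -> None:
    """MatrixMarket triple: <prefix>.mtx, <prefix>.genes.txt, <prefix>.samples.txt."""
    prefix = Path(prefix)
    spio.mmwrite(str(prefix) + ".mtx",
                 sparse.csr_matrix(ds.values.to_numpy()))
    Path(str(prefix) + ".genes.txt").write_text(
        "\n".join(ds.values.index) + "\n")
    Path(str(prefix) + ".samples.txt").write_text(
        "\n".join(ds.values.columns) + "\n")


def read_counts_mtx(prefix, meta_path) -> ExpressionDataset:
    prefix = Path(prefix)
    m = spio.mmread(str(prefix) + ".mtx").toarray()
    genes = Path(str(prefix) + ".genes.txt").read_text().splitlines()
    samples = Path(str(prefix) + ".samples.txt").read_text().splitlines()
    values = pd.DataFrame(m, index=genes, columns=samples)
    meta = read_meta_tsv(meta_path)
    return ExpressionDataset(values, meta.loc[samples], stage="raw")


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_tf_flags(flags: dict[str, bool], path) -> None:
    pd.Series(flags, name="tf").rename_axis("gene").astype(int).to_csv(
        path, sep="\t")


def read_tf_flags(path) -> dict[str, bool]:
    s = pd.read_csv(path, sep="\t", index_col="gene")["tf"]
    return {g: bool(v) for g, v in s.items()}


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
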