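"""File round-tripping: FASTA/FASTQ via Biopython, tables via pandas."""

from __future__ import annotations

import gzip
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .classify import ReadLabel
from .design import RepairTemplate
from .fragments import chain_to_string

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_templates",
    "labels_frame",
    "write_labels",
]


def _open_text(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> dict[str, str]:
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fastq(path):
    """Yield ``(read_id, sequence, quality string)``."""
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            qual = "".join(
                chr(q + 33) for q in rec.letter_annotations["phred_quality"]
            )
            yield rec.id, str(rec.seq).upper(), qual


def write_templates(templates: list[RepairTemplate], out_dir) -> tuple[Path, Path]:
    """Template panel as FASTA plus a TSV of design codes, arms and
    substitutions."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta = out_dir / "templates.fa"
    tsv = out_dir / "templates.tsv"
    write_fasta({t.design_code.replace(" ", "_"): t.sequence for t in templates}, fasta)
    rows = []
    for t in templates:
        rows.append(
            {
                "design_code": t.design_code,
                "strand": t.strand,
                "total_len": t.total_len,
                "left_arm_len": t.left_arm_len,
                "right_arm_len": t.right_arm_len,
                "substitutions": ";".join(
                    f"{s.rel_pos}:{s.ref_base}>{s.alt_base}" + ("(PAM)" if s.pam_mask else "")
                    for s in t.subs
                ),
            }
        )
    pd.DataFrame(rows).to_csv(tsv, sep="\t", index=False)
    return fasta, tsv


def labels_frame(labels: list[ReadLabel]) -> pd.DataFrame:
    rows = []
    for lab in labels:
        rows.append(
            {
                "read_id": lab.read_id,
                "category": lab.category,
                "presence": ",".join(
                    f"{r}:{int(v)}" for r, v in sorted(lab.presence.items())
                ),
                "chain": chain_to_string(lab.chain) if lab.chain else "",
                "novel": lab.chain.novel_seq if lab.chain else "",
                "left_flank_end": lab.chain.left_flank_end if lab.chain else "",
                "right_flank_start": lab.chain.right_flank_start if lab.chain else "",
                "orientation": lab.orientation,
                "n_indels": lab.n_indels,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "read_id", "category", "presence", "chain", "novel",
            "left_flank_end", "right_flank_start", "orientation", "n_indels",
        ],
    )


def write_labels(labels: list[ReadLabel], path) -> None:
    labels_frame(labels).to_csv(path, sep="\t", index=False)
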