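"""Readers and writers for the plain-text formats used across the pipeline.

Expression matrices, rhythm records, ground truth and transcript models are
tab-separated; gene sets use GMT; transcript regions can be exported as a
FASTA with one record per region (``<id>_5utr``, ``<id>_cds``,
``<id>_3utr``).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "write_rhythms_tsv", "read_rhythms_tsv",
    "write_ground_truth_tsv", "read_ground_truth_tsv",
    "write_models_tsv", "read_models_tsv",
    "write_gmt", "read_gmt",
    "write_region_fasta", "read_region_fasta",
]


def write_rhythms_tsv(rhythms: pd.DataFrame, path) -> None:
    rhythms.to_csv(path, sep="\t", index=False)


def read_rhythms_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("is_cycling", "tested"):
        if col in df:
            df[col] = df[col].astype(bool)
    return df


def write_ground_truth_tsv(truth, path) -> None:
    truth.genes.to_csv(path, sep="\t", index=False)


def read_ground_truth_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["is_rhythmic"] = df["is_rhythmic"].astype(bool)
    return df


def write_models_tsv(models: pd.DataFrame, path) -> None:
    models.to_csv(path, sep="\t", index=False)


def read_models_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_gmt(genesets: dict, path, description: str = "synthetic") -> None:
    with open(path, "w") as fh:
        for name, members in genesets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def read_gmt(path) -> dict:
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = parts[2:]
    return sets


def _counts_to_sequence(row, suffix) -> str:
    # deterministic homopolymer blocks: composition is what matters downstream
    return "".join(base.upper() * int(row[f"{base}{suffix}"])
                   for base in "acgu")


def write_region_fasta(models: pd.DataFrame, path) -> None:
    """Three records per transcript with suffixes _5utr/_cds/_3utr.

    Sequences are composition-faithful block sequences (base order carries
    no information in the cost model).
    """
    records = []
    for _, row in models.iterrows():
        for region, sfx in (("5utr", "5"), ("cds", "C"), ("3utr", "3")):
            seq = _counts_to_sequence(row, sfx)
            records.append(SeqRecord(Seq(seq), id=f"{row['transcript_id']}_{region}",
                                     description=""))
    SeqIO.write(records, path, "fasta")


def read_region_fasta(path, decay: pd.Series | None = None) -> pd.DataFrame:
    """Rebuild a transcript-model table from a region FASTA.

    ``decay`` optionally supplies per-transcript decay rates (indexed by
    transcript id); otherwise the decay_rate column is NaN.
    """
    from .energy_cost import counts_from_sequence

    data = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        tid, _, region = rec.id.rpartition("_")
        sfx = {"5utr": "5", "cds": "C", "3utr": "3"}.get(region)
        if sfx is None:
            raise ValueError(f"unrecognised region suffix in {rec.id!r}")
        counts = counts_from_sequence(str(rec.seq))
        row = data.setdefault(tid, {})
        for base, cnt in counts.items():
            row[f"{base.lower()}{sfx}"] = cnt
    out = pd.DataFrame.from_dict(data, orient="index")
    cols = [f"{b}{s}" for s in ("5", "C", "3") for b in "acgu"]
    out = out.reindex(columns=cols).fillna(0).astype(int)
    out.insert(0, "transcript_id", out.index)
    out["decay_rate"] = (out["transcript_id"].map(decay)
                         if decay is not None else np.nan)
    return out.reset_index(drop=True)
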