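"""Reading and writing the text formats the pipeline exchanges.

Coverage goes through 4-column bedGraph (one file per strand), genomes
through FASTA (Biopython), sites/annotations through headered TSV and masks
through BED.  All coordinates are 0-based half-open.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import GenomeSpec
from .profiles import StrandedProfile

CHROM = "genome"


def write_bedgraph(values: np.ndarray, path, chrom: str = CHROM) -> None:
    """Run-length-compressed 4-column bedGraph."""
    values = np.asarray(values)
    change = np.flatnonzero(np.diff(values)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(values)]])
    with open(path, "w") as fh:
        for a, b in zip(starts, ends):
            fh.write(f"{chrom}\t{a}\t{b}\t{values[a]:g}\n")


def read_bedgraph(path, length: int) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "value"])
    out = np.zeros(length)
    for row in df.itertuples(index=False):
        out[row.start:row.end] = row.value
    return out


def write_profile(profile: StrandedProfile, prefix) -> tuple[Path, Path]:
    prefix = Path(prefix)
    fwd = prefix.with_name(prefix.name + ".fwd.bedgraph")
    rev = prefix.with_name(prefix.name + ".rev.bedgraph")
    write_bedgraph(profile.fwd, fwd)
    write_bedgraph(profile.rev, rev)
    return fwd, rev


def read_profile(fwd_path, rev_path, genome: GenomeSpec) -> StrandedProfile:
    return StrandedProfile(
        fwd=read_bedgraph(fwd_path, genome.length),
        rev=read_bedgraph(rev_path, genome.length),
        genome=genome,
    )


def write_genome_fasta(genome: GenomeSpec, path) -> None:
    if genome.sequence is None:
        raise ValueError("genome has no sequence")
    rec = SeqRecord(Seq(genome.sequence), id=CHROM,
                    description=f"oriC={genome.oriC} dif={genome.dif}")
    SeqIO.write([rec], path, "fasta")


def read_genome_fasta(path, oriC: int | None = None, dif: int | None = None) -> GenomeSpec:
    rec = next(SeqIO.parse(path, "fasta"))
    seq = str(rec.seq).upper()
    meta = dict(
        kv.split("=") for kv in rec.description.split() if "=" in kv
    )
    base = GenomeSpec.ecoli_like(len(seq))
    return GenomeSpec(
        length=len(seq),
        oriC=int(meta.get("oriC", base.oriC)) if oriC is None else oriC,
        dif=int(meta.get("dif", base.dif)) if dif is None else dif,
        sequence=seq,
    )


def write_sites_tsv(sites: pd.DataFrame, path) -> None:
    sites.to_csv(path, sep="\t", index=False)


def read_sites_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_bed(intervals, path, chrom: str = CHROM, names=None) -> None:
    with open(path, "w") as fh:
        for i, (a, b) in enumerate(intervals):
            name = names[i] if names is not None else f"region{i}"
            fh.write(f"{chrom}\t{a}\t{b}\t{name}\n")


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :4]
    df.columns = ["chrom", "start", "end", "name"][: df.shape[1]]
    return df


def write_truth_tsv(truth, path, chrom: str = CHROM) -> None:
    rows = [
        (chrom, s.center, s.center + 1, s.kind, s.fold, "+") for s in truth
    ]
    pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"]) \
        .to_csv(path, sep="\t", index=False)
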