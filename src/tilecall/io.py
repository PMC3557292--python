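"""File-format plumbing: FASTA, VCF, BED and folding-energy TSV."""
from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .design import TilingDesign
from .detection import CandidateRegion, SubstitutionCall
from .simulate import TruthRecord, TruthSet


def read_fasta(path) -> SeqRecord:
    """Read a single-record FASTA; multi-record files are rejected."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(
            f"expected exactly one FASTA record, found {len(records)} in "
            f"{path}")
    return records[0]


def write_fasta(path, seq: str, seq_id: str) -> None:
    SeqIO.write([SeqRecord(Seq(seq), id=seq_id, description="")],
                str(path), "fasta")


def read_folding_tsv(path, design: TilingDesign) -> np.ndarray:
    """Per-probe folding energies aligned to the design order."""
    df = pd.read_csv(path, sep="\t")
    s = pd.Series(df["energy"].to_numpy(), index=df["probe_id"])
    out = s.reindex(design.probe_ids())
    if out.isna().any():
        raise ValueError(f"{int(out.isna().sum())} design probes missing "
                         "from the folding-energy table")
    return out.to_numpy()


def write_folding_tsv(path, design: TilingDesign,
                      energies: np.ndarray) -> None:
    pd.Series(energies, index=design.probe_ids(), name="energy") \
        .rename_axis("probe_id").to_csv(path, sep="\t")


def _vcf_header(chrom: str, length: int) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={chrom},length={length}>")
    header.add_line('##INFO=<ID=REGION_START,Number=1,Type=Integer,'
                    'Description="Start of the candidate region">')
    header.add_line('##INFO=<ID=REGION_END,Number=1,Type=Integer,'
                    'Description="End of the candidate region">')
    return header


def write_calls_vcf(path, calls: Sequence[SubstitutionCall], chrom: str,
                    genome_length: int) -> None:
    """Substitution calls as an uncompressed VCF; QUAL carries the LLR."""
    header = _vcf_header(chrom, genome_length)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for call in sorted(calls, key=lambda c: c.position):
            rec = vf.new_record(
                contig=chrom, start=call.position - 1, stop=call.position,
                alleles=(call.ref_base, call.alt_base),
                qual=float(call.llr))
            rec.info["REGION_START"] = call.region.start
            rec.info["REGION_END"] = call.region.end
            vf.write(rec)


def write_truth_vcf(path, truth: TruthSet, chrom: str,
                    genome_length: int) -> None:
    header = _vcf_header(chrom, genome_length)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for rec_t in sorted(truth.records, key=lambda r: r.position):
            rec = vf.new_record(
                contig=chrom, start=rec_t.position - 1, stop=rec_t.position,
                alleles=(rec_t.ref_base, rec_t.alt_base))
            vf.write(rec)


def read_calls_vcf(path) -> list[SubstitutionCall]:
    calls = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            region = CandidateRegion(
                rec.info.get("REGION_START", rec.pos),
                rec.info.get("REGION_END", rec.pos), 0.0, False)
            calls.append(SubstitutionCall(
                rec.pos, rec.ref, rec.alts[0],
                float(rec.qual) if rec.qual is not None else 0.0, region))
    return calls


def read_truth_vcf(path) -> TruthSet:
    records = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            records.append(TruthRecord(rec.pos, rec.ref, rec.alts[0]))
    return TruthSet(records)


def write_structural_bed(path, regions: Sequence[CandidateRegion],
                         chrom: str) -> None:
    """Structural (deletion-like) regions as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for r in regions:
            if r.structural:
                fh.write(f"{chrom}\t{r.start - 1}\t{r.end}\tstructural\t"
                         f"{r.mean_residual:.4f}\n")
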